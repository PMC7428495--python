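"""Synthetic two-session resting-state cohort generator.

Emulates a multi-subject test–retest acquisition at the parcel level:
block-modular inter-parcel covariance, subject- and session-specific
perturbations of that covariance, AR(1) temporal autocorrelation,
bounded-random-walk head motion, white-matter / CSF / global nuisance
contamination, and occasional coupled motion+intensity spike artifacts.

Every downstream stage of the package can therefore be exercised and
validated without any image download: the generator returns the ground
truth (per-session correlation matrices, module partition, injected
spike volumes) alongside the data.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CohortSpec",
    "SessionRecord",
    "GroundTruth",
    "build_block_covariance",
    "generate_cohort",
    "write_cohort",
    "read_session",
]


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of the synthetic cohort.

    Defaults mirror the acquisition the package emulates: 69 subjects
    scanned in two sessions, TR = 3 s, 120 usable volumes per run, and a
    100-parcel whole-brain parcellation.  The free statistical parameters
    (module count, within/between-module correlation, perturbation scales,
    AR(1) coefficient, spike probability, nuisance gain) are fixed at
    values that produce realistic-looking parcel series; ``session_sd`` is
    the knob that drives test–retest variability.
    """

    n_subjects: int = 69
    n_parcels: int = 100
    n_volumes: int = 120
    tr_seconds: float = 3.0
    n_modules: int = 5
    r_within: float = 0.5
    r_between: float = 0.1
    subject_sd: float = 0.05
    session_sd: float = 0.05
    ar1_coef: float = 0.4
    motion_spike_prob: float = 0.02
    nuisance_gain: float = 0.5
    seed: int = 0
    n_sessions: int = 2
    n_runs: int = 1
    #: reuse session 1's noise stream for session 2 (with ``session_sd = 0``
    #: this makes the two sessions bit-identical — useful for degeneracy tests)
    shared_session_noise: bool = False

    def __post_init__(self) -> None:
        if not (abs(self.r_between) < abs(self.r_within) < 1) and not (
            self.r_within == self.r_between == 0.0
        ):
            raise ValueError(
                "require |r_between| < |r_within| < 1 "
                f"(got r_within={self.r_within}, r_between={self.r_between})"
            )
        if self.n_volumes * self.tr_seconds < 300:
            raise ValueError(
                "run must span at least 300 s so a clean 5-min interval can exist "
                f"(got {self.n_volumes * self.tr_seconds:.0f} s)"
            )
        if not (0 <= self.ar1_coef < 1):
            raise ValueError("ar1_coef must lie in [0, 1)")
        for name in ("subject_sd", "session_sd", "nuisance_gain"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not (0 <= self.motion_spike_prob <= 1):
            raise ValueError("motion_spike_prob must be a probability")


@dataclass
class SessionRecord:
    """One run's data: parcel series, motion parameters, nuisance signals."""

    timeseries: np.ndarray  # (n_volumes, n_parcels)
    motion: np.ndarray  # (n_volumes, 6): tx ty tz (mm), rx ry rz (rad)
    wm_signal: np.ndarray
    csf_signal: np.ndarray
    global_signal: np.ndarray
    subject_id: str
    session_id: str
    run_id: str
    censor_mask: np.ndarray | None = None  # True = usable volume

    def __post_init__(self) -> None:
        t = self.timeseries.shape[0]
        if self.motion.shape != (t, 6):
            raise ValueError(f"motion must be (T, 6), got {self.motion.shape}")
        for name in ("wm_signal", "csf_signal", "global_signal"):
            if getattr(self, name).shape != (t,):
                raise ValueError(f"{name} must have length {t}")
        if np.isnan(self.timeseries).any() or np.isnan(self.motion).any():
            raise ValueError("missing values are not allowed")


@dataclass
class GroundTruth:
    """What the generator actually used, for parameter-recovery tests."""

    #: (subject_id, session_id) -> true inter-parcel correlation matrix
    covariance: dict
    #: module label per parcel, contiguous from 1
    partition: np.ndarray
    #: (subject_id, session_id, run_id) -> sorted array of spike volume indices
    spike_volumes: dict
    #: identity-shrinkage factor applied to make the block matrix PD (0 if none)
    shrinkage: float = 0.0


# ---------------------------------------------------------------------------
# covariance construction


def build_block_covariance(spec: CohortSpec, return_shrinkage: bool = False):
    """Block correlation matrix: ``r_within`` inside modules, ``r_between``
    elsewhere, unit diagonal.

    Parcels are split into ``n_modules`` contiguous, near-equal blocks.  If
    the matrix is not positive definite it is shrunk toward the identity by
    the minimal factor ``s`` such that the smallest eigenvalue reaches 1e-6;
    pass ``return_shrinkage=True`` to obtain ``s`` alongside the matrix.
    """
    p, m = spec.n_parcels, spec.n_modules
    labels = module_partition(p, m)
    same = labels[:, None] == labels[None, :]
    cov = np.where(same, spec.r_within, spec.r_between).astype(float)
    np.fill_diagonal(cov, 1.0)

    lam_min = float(np.linalg.eigvalsh(cov)[0])
    s = 0.0
    if lam_min <= 1e-6:
        # (1-s)*cov + s*I has smallest eigenvalue (1-s)*lam_min + s
        s = (1e-6 - lam_min) / (1.0 - lam_min)
        if not (0 <= s < 1):
            raise ValueError("block covariance cannot be made positive definite")
        cov = (1.0 - s) * cov + s * np.eye(p)
    if return_shrinkage:
        return cov, s
    return cov


def module_partition(n_parcels: int, n_modules: int) -> np.ndarray:
    """Contiguous near-equal module labels, 1-based."""
    if not (1 <= n_modules <= n_parcels):
        raise ValueError("need 1 <= n_modules <= n_parcels")
    sizes = [len(b) for b in np.array_split(np.arange(n_parcels), n_modules)]
    return np.repeat(np.arange(1, n_modules + 1), sizes)


def _perturb_correlation(
    corr: np.ndarray, sd: float, rng: np.random.Generator
) -> np.ndarray:
    """Random correlation matrix centered on ``corr`` with entry scale ~sd.

    Draws from a Wishart distribution with scale ``corr/df`` and
    ``df = max(1/sd^2, P + 2)`` degrees of freedom, then rescales to unit
    diagonal.  Off-diagonal entries fluctuate around ``corr`` with
    standard deviation of roughly ``sd``, and — unlike an additive
    symmetric perturbation, whose spectral norm ~2·sd·sqrt(P) swamps the
    smallest eigenvalues at realistic P — the draw is positive definite
    and well-conditioned by construction.  The achievable entry scale
    saturates near 1/sqrt(P) (the df floor).
    """
    if sd == 0:
        return corr.copy()
    p = corr.shape[0]
    df = int(max(round(1.0 / sd**2), p + 2))
    chol = np.linalg.cholesky(corr)
    z = rng.normal(size=(p, df))
    w = (chol @ z) @ (chol @ z).T / df
    d = np.sqrt(np.diag(w))
    out = w / np.outer(d, d)
    np.fill_diagonal(out, 1.0)
    return out


# ---------------------------------------------------------------------------
# signal generation

_BASELINE = 1000.0  # arbitrary BOLD-like offset
_SIGNAL_SD = 10.0  # parcel-series sd in the same units
_WALK_STEP_MM = 0.01  # motion random-walk innovation sd, translations
_WALK_STEP_RAD = 2e-4  # motion random-walk innovation sd, rotations
_WALK_RHO = 0.95  # mean-reversion of the bounded walk
_SPIKE_TRANS_MM = (0.6, 0.65)  # uniform range of a spike's translation step
_SPIKE_JOLT_SD = 30.0  # intensity level-shift at a spike, in signal-sd units


def _ar1_series(rng: np.random.Generator, t: int, coef: float, n: int = 1) -> np.ndarray:
    """Unit-variance AR(1) columns, shape (t, n)."""
    e = rng.normal(size=(t, n))
    if coef == 0:
        return e
    x = np.empty_like(e)
    x[0] = e[0] / np.sqrt(1.0 - coef**2)
    for i in range(1, t):
        x[i] = coef * x[i - 1] + e[i]
    return x * np.sqrt(1.0 - coef**2)


def _bounded_walk(rng: np.random.Generator, t: int, step: float) -> np.ndarray:
    """Mean-reverting random walk starting at 0 (volume 1 is the reference)."""
    x = np.zeros(t)
    for i in range(1, t):
        x[i] = _WALK_RHO * x[i - 1] + rng.normal(0.0, step)
    return x


def _generate_run(
    spec: CohortSpec,
    chol: np.ndarray,
    rng: np.random.Generator,
) -> tuple:
    """One run's timeseries/motion/nuisance; returns arrays + spike volumes."""
    t, p = spec.n_volumes, spec.n_parcels

    # neural signal: spatially correlated AR(1) Gaussian series
    latent = _ar1_series(rng, t, spec.ar1_coef, p)
    signal = latent @ chol.T

    # nuisance sources, unit variance, temporally smooth
    wm = _ar1_series(rng, t, 0.8)[:, 0]
    csf = _ar1_series(rng, t, 0.8)[:, 0]
    drift = _ar1_series(rng, t, 0.9)[:, 0]

    # per-parcel nuisance loadings around 1
    load = rng.normal(1.0, 0.3, size=(3, p))
    contamination = (
        np.outer(wm, load[0]) + np.outer(csf, load[1]) + np.outer(drift, load[2])
    )
    series = signal + spec.nuisance_gain * contamination

    # motion: bounded random walks per parameter
    motion = np.column_stack(
        [_bounded_walk(rng, t, _WALK_STEP_MM) for _ in range(3)]
        + [_bounded_walk(rng, t, _WALK_STEP_RAD) for _ in range(3)]
    )

    # spikes: persistent level shifts in position and intensity so FD and
    # DVARS flag exactly the spike volume, and the two flags co-occur;
    # successive steps on an axis move its offset back toward zero so the
    # accumulated excursion stays inside the 1.5 mm overall-motion limit
    spike = rng.random(t) < spec.motion_spike_prob
    spike[0] = False
    spike_volumes = np.flatnonzero(spike)
    axis_offset = np.zeros(3)
    jolt_offset = 0.0
    for v in spike_volumes:
        amp = rng.uniform(*_SPIKE_TRANS_MM)
        axis = rng.integers(0, 3)
        step = -amp if axis_offset[axis] > 0 else amp
        axis_offset[axis] += step
        motion[v:, axis] += step
        jolt = -_SPIKE_JOLT_SD if jolt_offset > 0 else _SPIKE_JOLT_SD
        jolt_offset += jolt
        series[v:, :] += jolt

    series = _BASELINE + _SIGNAL_SD * series
    # the global signal comes from a whole-brain mask, not the parcel set:
    # mostly the parcel mean, plus WM/CSF and unparcellated tissue, so it is
    # strongly but not exactly collinear with the parcels
    global_signal = (
        series.mean(axis=1)
        + _SIGNAL_SD * (0.2 * wm + 0.2 * csf + 0.1 * rng.normal(size=t))
    )
    return series, motion, wm, csf, global_signal, spike_volumes


def generate_cohort(spec: CohortSpec) -> tuple[list[SessionRecord], GroundTruth]:
    """Generate all runs of the cohort plus the ground truth.

    Reproducible from ``spec.seed`` alone: per-(subject, session) RNG
    streams are spawned from a :class:`numpy.random.SeedSequence`, so the
    output is bit-identical for identical specs.  With
    ``shared_session_noise=True`` both sessions of a subject consume the
    same stream, and with ``session_sd = 0`` they are then identical.
    """
    population, shrink = build_block_covariance(spec, return_shrinkage=True)
    partition = module_partition(spec.n_parcels, spec.n_modules)

    records: list[SessionRecord] = []
    covariance: dict = {}
    spikes: dict = {}

    root = np.random.SeedSequence(spec.seed)
    for s in range(spec.n_subjects):
        sid = f"sub-{s + 1:03d}"
        subj_rng = np.random.default_rng(
            np.random.SeedSequence(spec.seed, spawn_key=(s, 0))
        )
        subject_corr = _perturb_correlation(population, spec.subject_sd, subj_rng)
        for sess in range(spec.n_sessions):
            ses_id = f"ses-{sess + 1}"
            # the covariance perturbation is keyed on the true session, the
            # acquisition-noise stream optionally on the shared key, so
            # shared_session_noise isolates the session_sd effect
            perturb_rng = np.random.default_rng(
                np.random.SeedSequence(spec.seed, spawn_key=(s, 100 + sess))
            )
            noise_key = 0 if spec.shared_session_noise else sess
            ses_rng = np.random.default_rng(
                np.random.SeedSequence(spec.seed, spawn_key=(s, 1 + noise_key))
            )
            session_corr = _perturb_correlation(
                subject_corr, spec.session_sd, perturb_rng
            )
            covariance[(sid, ses_id)] = session_corr
            chol = np.linalg.cholesky(session_corr)
            for run in range(spec.n_runs):
                run_id = f"run-{run + 1}"
                series, motion, wm, csf, gs, sv = _generate_run(spec, chol, ses_rng)
                records.append(
                    SessionRecord(
                        timeseries=series,
                        motion=motion,
                        wm_signal=wm,
                        csf_signal=csf,
                        global_signal=gs,
                        subject_id=sid,
                        session_id=ses_id,
                        run_id=run_id,
                    )
                )
                spikes[(sid, ses_id, run_id)] = sv
    del root
    return records, GroundTruth(covariance, partition, spikes, shrink)


# ---------------------------------------------------------------------------
# on-disk dialects


def _run_stem(rec: SessionRecord) -> str:
    return f"{rec.subject_id}_{rec.session_id}_{rec.run_id}"


def write_cohort(records: list[SessionRecord], truth: GroundTruth, outdir) -> None:
    """Write the cohort in plain-text dialects.

    Per run: a volumes × parcels TSV (header = parcel IDs), a 6-column
    whitespace-delimited motion file (same dialect as realignment "rp"
    files), and a 3-column nuisance TSV (wm, csf, global).  Ground truth
    goes to JSON (partition, spikes, shrinkage) and one TSV per session
    correlation matrix.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for rec in records:
        stem = _run_stem(rec)
        cols = [f"parcel{j + 1:03d}" for j in range(rec.timeseries.shape[1])]
        pd.DataFrame(rec.timeseries, columns=cols).to_csv(
            out / f"{stem}_timeseries.tsv", sep="\t", index=False, float_format="%.6f"
        )
        np.savetxt(out / f"{stem}_motion.txt", rec.motion, fmt="%.8f")
        pd.DataFrame(
            {
                "wm": rec.wm_signal,
                "csf": rec.csf_signal,
                "global": rec.global_signal,
            }
        ).to_csv(out / f"{stem}_nuisance.tsv", sep="\t", index=False,
                 float_format="%.6f")

    gt_dir = out / "ground_truth"
    gt_dir.mkdir(exist_ok=True)
    meta = {
        "partition": truth.partition.tolist(),
        "shrinkage": truth.shrinkage,
        "spike_volumes": {
            "_".join(k): v.tolist() for k, v in truth.spike_volumes.items()
        },
    }
    (gt_dir / "ground_truth.json").write_text(json.dumps(meta, indent=1))
    for (sid, ses), corr in truth.covariance.items():
        np.savetxt(gt_dir / f"{sid}_{ses}_correlation.tsv", corr,
                   delimiter="\t", fmt="%.6f")


def read_session(directory, subject_id: str, session_id: str,
                 run_id: str) -> SessionRecord:
    """Read one run back from the :func:`write_cohort` dialects."""
    d = Path(directory)
    stem = f"{subject_id}_{session_id}_{run_id}"
    ts = pd.read_csv(d / f"{stem}_timeseries.tsv", sep="\t").to_numpy()
    motion = np.loadtxt(d / f"{stem}_motion.txt")
    nuis = pd.read_csv(d / f"{stem}_nuisance.tsv", sep="\t")
    return SessionRecord(
        timeseries=ts,
        motion=motion,
        wm_signal=nuis["wm"].to_numpy(),
        csf_signal=nuis["csf"].to_numpy(),
        global_signal=nuis["global"].to_numpy(),
        subject_id=subject_id,
        session_id=session_id,
        run_id=run_id,
    )
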