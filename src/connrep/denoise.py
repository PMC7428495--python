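"""Nuisance regression and temporal filtering.

Two regressor sets are supported: *simple* (9 columns — 6 rigid-body
motion parameters, WM, CSF and the global signal) and *complex* (30
columns — 24 motion terms: the 6 basic parameters, their temporal
derivatives, their squares and the squared derivatives; WM and CSF plus
their derivatives; global signal plus its derivative).  The set is
de-collinearized by PCA (all numerically nonzero components kept), fit by
least squares on usable volumes only, and the residuals are band-pass
filtered (0.009–0.1 Hz, zero-phase Butterworth) after linear interpolation
over censored volumes.  Temporal derivative = backward difference with a
leading zero, matching the FD convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .cohort import SessionRecord

__all__ = [
    "RegressorSet",
    "DenoisedSeries",
    "build_regressors",
    "pca_orthogonalize",
    "regress_nuisance",
    "bandpass",
    "denoise_record",
]

BAND_LOW_HZ = 0.009
BAND_HIGH_HZ = 0.1
FILTER_ORDER = 4

_MOTION_LABELS = ["tx", "ty", "tz", "rx", "ry", "rz"]


@dataclass
class RegressorSet:
    matrix: np.ndarray  # (T, K)
    labels: list[str]
    pipeline: str  # "simple" | "complex" | "pca"

    def __post_init__(self) -> None:
        if self.matrix.shape[1] != len(self.labels):
            raise ValueError("labels must match columns")


@dataclass
class DenoisedSeries:
    data: np.ndarray  # (T, P) residual, band-passed
    censor_mask: np.ndarray  # carried through; censored volumes never enter connectivity
    metadata: dict = field(default_factory=dict)


def _derivative(x: np.ndarray) -> np.ndarray:
    """Backward difference with first element 0 (per-column for 2-D)."""
    d = np.zeros_like(x, dtype=float)
    d[1:] = np.diff(x, axis=0)
    return d


def build_regressors(record: SessionRecord, pipeline: str) -> RegressorSet:
    """Assemble the simple (9) or complex (30) nuisance regressor matrix."""
    for name in ("wm_signal", "csf_signal", "global_signal"):
        sig = getattr(record, name, None)
        if sig is None or np.asarray(sig).size == 0:
            raise ValueError(f"missing nuisance signal: {name}")
    m = np.asarray(record.motion, dtype=float)
    wm = np.asarray(record.wm_signal, dtype=float)
    csf = np.asarray(record.csf_signal, dtype=float)
    gsr = np.asarray(record.global_signal, dtype=float)

    if pipeline == "simple":
        cols = [m, wm[:, None], csf[:, None], gsr[:, None]]
        labels = _MOTION_LABELS + ["wm", "csf", "gsr"]
    elif pipeline == "complex":
        dm = _derivative(m)
        cols = [
            m, dm, m**2, dm**2,
            wm[:, None], csf[:, None],
            _derivative(wm)[:, None], _derivative(csf)[:, None],
            gsr[:, None], _derivative(gsr)[:, None],
        ]
        labels = (
            _MOTION_LABELS
            + [f"d_{l}" for l in _MOTION_LABELS]
            + [f"{l}_sq" for l in _MOTION_LABELS]
            + [f"d_{l}_sq" for l in _MOTION_LABELS]
            + ["wm", "csf", "d_wm", "d_csf", "gsr", "d_gsr"]
        )
    else:
        raise ValueError(f"pipeline must be 'simple' or 'complex', got {pipeline!r}")

    mat = np.column_stack(cols)
    assert mat.shape[1] == (9 if pipeline == "simple" else 30)
    return RegressorSet(mat, labels, pipeline)


def pca_orthogonalize(regressors: RegressorSet,
                      rel_tol: float = 1e-10) -> RegressorSet:
    """Replace the regressors by their principal components.

    Columns are mean-centered and components are kept for every eigenvalue
    exceeding ``rel_tol`` times the largest; the retained scores span the
    same space as the numerically independent directions of the input.
    The purpose is de-collinearization, not dimension reduction, so no
    variance cutoff is applied.
    """
    x = regressors.matrix - regressors.matrix.mean(axis=0)
    t, k = x.shape
    if t <= k:
        raise ValueError(f"need more volumes than regressors (T={t}, K={k})")
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    if s.size == 0 or s[0] == 0:
        keep = 0
    else:
        keep = int(np.sum((s / s[0]) ** 2 > rel_tol))
    scores = u[:, :keep] * s[:keep]
    return RegressorSet(scores, [f"pc{i + 1}" for i in range(keep)], "pca")


def regress_nuisance(
    timeseries: np.ndarray,
    components: np.ndarray,
    censor_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Project out the nuisance components, fitting on usable volumes only.

    The least-squares fit (with intercept) is estimated on usable volumes;
    fitted values are subtracted at *all* volumes so censored samples stay
    aligned for the later interpolation step.
    """
    y = np.asarray(timeseries, dtype=float)
    x = np.asarray(components, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    t = y.shape[0]
    mask = np.ones(t, dtype=bool) if censor_mask is None else np.asarray(censor_mask)
    n_use = int(mask.sum())
    if n_use <= x.shape[1] + 1:
        raise ValueError(
            f"underdetermined fit: {n_use} usable volumes for "
            f"{x.shape[1]} components + intercept"
        )
    design = np.column_stack([np.ones(t), x])
    beta, *_ = np.linalg.lstsq(design[mask], y[mask], rcond=None)
    return y - design @ beta


def bandpass(
    series: np.ndarray,
    censor_mask: np.ndarray | None,
    tr_seconds: float,
    low_hz: float = BAND_LOW_HZ,
    high_hz: float = BAND_HIGH_HZ,
    order: int = FILTER_ORDER,
) -> DenoisedSeries:
    """Zero-phase Butterworth band-pass with censoring-aware interpolation.

    Censored volumes are replaced by linear interpolation between their
    nearest usable neighbors (nearest-value extension at the edges) before
    filtering; the censor mask is retained so those volumes are still
    dropped downstream.
    """
    y = np.asarray(series, dtype=float)
    t = y.shape[0]
    nyquist = 1.0 / (2.0 * tr_seconds)
    if not (0 < low_hz < high_hz < nyquist):
        raise ValueError(
            f"band ({low_hz}, {high_hz}) Hz infeasible for TR={tr_seconds}s "
            f"(Nyquist {nyquist:.4f} Hz)"
        )
    mask = np.ones(t, dtype=bool) if censor_mask is None else np.asarray(censor_mask)
    if not mask.any():
        raise ValueError("no usable volumes")
    if not mask.all():
        idx = np.arange(t)
        good = idx[mask]
        y = y.copy()
        for j in range(y.shape[1]):
            y[~mask, j] = np.interp(idx[~mask], good, y[good, j])

    sos = signal.butter(order, [low_hz, high_hz], btype="bandpass",
                        fs=1.0 / tr_seconds, output="sos")
    filtered = signal.sosfiltfilt(sos, y, axis=0)
    return DenoisedSeries(
        data=filtered,
        censor_mask=mask,
        metadata={"band_hz": (low_hz, high_hz), "order": order,
                  "tr_seconds": tr_seconds},
    )


def denoise_record(
    record: SessionRecord,
    pipeline: str,
    tr_seconds: float,
    censor_mask: np.ndarray | None = None,
) -> DenoisedSeries:
    """Full denoising chain: regressors -> PCA -> regression -> band-pass."""
    regs = build_regressors(record, pipeline)
    comps = pca_orthogonalize(regs)
    resid = regress_nuisance(record.timeseries, comps.matrix, censor_mask)
    out = bandpass(resid, censor_mask, tr_seconds)
    out.metadata["pipeline"] = pipeline
    out.metadata["n_components"] = comps.matrix.shape[1]
    return out
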