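"""Motion/intensity quality control: FD, DVARS, censoring, run selection.

Framewise displacement (FD) summarizes inter-volume head motion as the sum
of absolute backward differences of the three translations (mm) plus the
three rotations converted to arc length on a 50 mm sphere.  DVARS is the
root-mean-square of the volume-to-volume intensity change, computed here
across parcels (the package's whole-brain proxy).  A volume is "bad" when
FD >= 0.5 mm or DVARS >= its per-run threshold (run mean + 3 SD); the
censoring ladder then decides between using the whole run, a clean 5-min
interval, scrubbing (<= 20 bad volumes), or taking the run off-study.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict

import numpy as np

from .cohort import SessionRecord

__all__ = [
    "QCReport",
    "framewise_displacement",
    "dvars",
    "censoring_decision",
    "qc_record",
    "select_runs",
]

HEAD_RADIUS_MM = 50.0

FD_MAX_MM = 0.5
DVARS_N_SD = 3.0
OVERALL_TRANSLATION_MAX_MM = 1.5
OVERALL_ROTATION_MAX_DEG = 1.5
MAX_SCRUBBED_VOLUMES = 20
MIN_CLEAN_INTERVAL_S = 300.0


@dataclass
class QCReport:
    fd: np.ndarray
    dvars: np.ndarray
    dvars_threshold: float
    bad_volumes: np.ndarray  # sorted indices
    decision: str  # use-whole-run | use-interval | scrubbed | off-study
    interval: tuple[int, int] | None  # [start, end) when decision == use-interval
    censor_mask: np.ndarray | None  # True = usable; None when off-study

    @property
    def n_usable(self) -> int:
        return 0 if self.censor_mask is None else int(self.censor_mask.sum())

    def to_json(self) -> str:
        d = asdict(self)
        d["fd"] = self.fd.tolist()
        d["dvars"] = self.dvars.tolist()
        d["bad_volumes"] = self.bad_volumes.tolist()
        d["censor_mask"] = (
            None if self.censor_mask is None else self.censor_mask.astype(int).tolist()
        )
        return json.dumps(d)


def framewise_displacement(motion: np.ndarray) -> np.ndarray:
    """FD_i = |Δdx|+|Δdy|+|Δdz| + 50·(|Δα|+|Δβ|+|Δγ|), FD_1 = 0.

    ``motion`` is (T, 6): translations in mm then rotations in radians;
    the backward difference makes volume 1 the reference.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError(f"motion must have 6 columns, got shape {motion.shape}")
    d = np.abs(np.diff(motion, axis=0))
    fd = np.zeros(motion.shape[0])
    fd[1:] = d[:, :3].sum(axis=1) + HEAD_RADIUS_MM * d[:, 3:].sum(axis=1)
    return fd


def dvars(timeseries: np.ndarray) -> np.ndarray:
    """Root-mean-square intensity change across parcels; DVARS_1 = 0."""
    ts = np.asarray(timeseries, dtype=float)
    if ts.ndim != 2 or ts.shape[0] < 2:
        raise ValueError("timeseries must be (T, P) with T >= 2")
    out = np.zeros(ts.shape[0])
    out[1:] = np.sqrt(np.mean(np.diff(ts, axis=0) ** 2, axis=1))
    return out


def _longest_clean_interval(bad: np.ndarray, t: int, min_len: int):
    """Longest contiguous bad-free interval of length >= min_len.

    Returns [start, end) or None; earliest interval wins ties.
    """
    is_bad = np.zeros(t, dtype=bool)
    is_bad[bad] = True
    best = None
    start = 0
    for i in range(t + 1):
        if i == t or is_bad[i]:
            length = i - start
            if length >= min_len and (best is None or length > best[1] - best[0]):
                best = (start, i)
            start = i + 1
    return best


def censoring_decision(
    fd: np.ndarray,
    dvars_values: np.ndarray,
    motion: np.ndarray,
    tr_seconds: float,
    *,
    fd_max: float = FD_MAX_MM,
    dvars_n_sd: float = DVARS_N_SD,
    translation_max_mm: float = OVERALL_TRANSLATION_MAX_MM,
    rotation_max_deg: float = OVERALL_ROTATION_MAX_DEG,
    max_scrubbed: int = MAX_SCRUBBED_VOLUMES,
    min_interval_s: float = MIN_CLEAN_INTERVAL_S,
) -> QCReport:
    """Apply the censoring ladder to one run.

    1. overall motion (range of any translation column >= 1.5 mm or any
       rotation column >= 1.5 deg) -> off-study;
    2. no bad volumes -> use-whole-run;
    3. a contiguous clean interval of >= 5 min exists -> use-interval
       (longest such, earliest on ties);
    4. at most 20 bad volumes -> scrubbed;
    5. otherwise off-study.
    """
    fd = np.asarray(fd, dtype=float)
    dv = np.asarray(dvars_values, dtype=float)
    t = fd.shape[0]
    thr = float(dv.mean() + dvars_n_sd * dv.std(ddof=0))
    bad = np.flatnonzero((fd >= fd_max) | (dv >= thr))

    trans_range = np.ptp(motion[:, :3], axis=0)
    rot_range_deg = np.degrees(np.ptp(motion[:, 3:], axis=0))
    if (trans_range >= translation_max_mm).any() or (
        rot_range_deg >= rotation_max_deg
    ).any():
        return QCReport(fd, dv, thr, bad, "off-study", None, None)

    if bad.size == 0:
        return QCReport(fd, dv, thr, bad, "use-whole-run", None,
                        np.ones(t, dtype=bool))

    min_len = math.ceil(min_interval_s / tr_seconds)
    interval = _longest_clean_interval(bad, t, min_len)
    if interval is not None:
        mask = np.zeros(t, dtype=bool)
        mask[interval[0]:interval[1]] = True
        return QCReport(fd, dv, thr, bad, "use-interval", interval, mask)

    if bad.size <= max_scrubbed:
        mask = np.ones(t, dtype=bool)
        mask[bad] = False
        return QCReport(fd, dv, thr, bad, "scrubbed", None, mask)

    return QCReport(fd, dv, thr, bad, "off-study", None, None)


def qc_record(record: SessionRecord, tr_seconds: float, **kwargs) -> QCReport:
    """FD + DVARS + censoring decision for one :class:`SessionRecord`."""
    fd = framewise_displacement(record.motion)
    dv = dvars(record.timeseries)
    return censoring_decision(fd, dv, record.motion, tr_seconds, **kwargs)


def select_runs(reports: list[QCReport]) -> int | None:
    """Index of the run to analyze: first run unless off-study, then the
    next usable one; ``None`` when every run is off-study (excluded)."""
    if not reports:
        raise ValueError("at least one run per session is required")
    for i, rep in enumerate(reports):
        if rep.decision != "off-study":
            return i
    return None
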