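"""Session-to-session reproducibility statistics: TRT, Hc, pSI.

TRT (test–retest variability, %) = 100·|m₂ − m₁| / ((m₁ + m₂)/2): 0 for a
perfectly reproducible measure, larger for less reproducible ones.  Hub
co-occurrence Hc is the Dice overlap of the two sessions' hub sets.
Probabilistic scaled inclusivity pSI compares two module co-assignment
matrices per node: pSI_i = (Σ_j P₁(i,j)·P₂(i,j))² / (Σ_j P₁(i,j) · Σ_j
P₂(i,j)), which is 1 when the (deterministic) module structure agrees
exactly and 0 when it is unrelated.

0/0 cases (both measures zero; both hub sets empty) are reported as
missing (nan) with a warning rather than forced to 0 or 1.
"""

from __future__ import annotations

import warnings

import numpy as np

from .graph import CoAssignmentMatrix

__all__ = ["trt", "hub_cooccurrence", "psi"]


def trt(m1: float, m2: float) -> float:
    """Test–retest variability in percent; scale-invariant and symmetric."""
    denom = (m1 + m2) / 2.0
    if denom == 0:
        warnings.warn("TRT undefined for m1 + m2 = 0; returning nan")
        return float("nan")
    return 100.0 * abs(m2 - m1) / denom


def hub_cooccurrence(h1, h2) -> float:
    """Dice coefficient of two hub sets: 2|H₁∩H₂| / (|H₁|+|H₂|)."""
    s1, s2 = set(h1), set(h2)
    if not s1 and not s2:
        warnings.warn("hub co-occurrence undefined for two empty hub sets")
        return float("nan")
    return 2.0 * len(s1 & s2) / (len(s1) + len(s2))


def psi(p1, p2) -> np.ndarray:
    """Per-node probabilistic scaled inclusivity of two co-assignment
    matrices; bounded in [0, 1] with 1 iff the rows agree up to scale."""
    m1 = p1.matrix if isinstance(p1, CoAssignmentMatrix) else np.asarray(p1, float)
    m2 = p2.matrix if isinstance(p2, CoAssignmentMatrix) else np.asarray(p2, float)
    if m1.shape != m2.shape or m1.ndim != 2 or m1.shape[0] != m1.shape[1]:
        raise ValueError(f"co-assignment shapes differ: {m1.shape} vs {m2.shape}")
    for m in (m1, m2):
        if not np.allclose(np.diag(m), 1.0):
            raise ValueError("co-assignment diagonal must be 1")
    cross = (m1 * m2).sum(axis=1)
    return cross**2 / (m1.sum(axis=1) * m2.sum(axis=1))
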