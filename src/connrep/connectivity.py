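"""Network construction from denoised parcel series.

The construction grid: Pearson or partial correlation (precision-matrix
inversion, no regularization); sign handling abs/pos/neg; weights either
taken directly from the (partial) correlations or from Fisher r-to-Z
values mapped through the standard-normal CDF, w = (2Φ(Z) − 1)^4; binary
networks by keeping the k strongest edges at a requested density.  All
outputs are symmetric with a zero diagonal (no self-connections); weighted
entries lie in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

__all__ = [
    "ConnectivityMatrix",
    "pearson_correlation",
    "partial_correlation",
    "apply_sign_mode",
    "fisher_z",
    "z_to_weight",
    "binarize_by_density",
    "weighted_network",
]

SIGN_MODES = ("abs", "pos", "neg")
Z_WEIGHT_EXPONENT = 4


@dataclass
class ConnectivityMatrix:
    matrix: np.ndarray
    kind: str  # "pearson" | "partial"
    sign_mode: str | None = None
    weight_scheme: str | None = None  # "raw" | "zphi" | None
    n_usable_volumes: int | None = None
    density: float | None = None  # binary networks only
    metadata: dict = field(default_factory=dict)


def _usable(series: np.ndarray, censor_mask) -> np.ndarray:
    y = np.asarray(series, dtype=float)
    if censor_mask is not None:
        y = y[np.asarray(censor_mask, dtype=bool)]
    return y


def pearson_correlation(series: np.ndarray,
                        censor_mask: np.ndarray | None = None) -> np.ndarray:
    """Pairwise Pearson r on usable volumes; diagonal set to 0."""
    y = _usable(series, censor_mask)
    if y.shape[0] < 3:
        raise ValueError("need at least 3 usable volumes")
    sd = y.std(axis=0)
    dead = np.flatnonzero(sd <= 1e-12 * np.maximum(1.0, np.abs(y.mean(axis=0))))
    if dead.size:
        raise ValueError(f"zero-variance parcel(s): {dead.tolist()}")
    r = np.corrcoef(y, rowvar=False)
    np.fill_diagonal(r, 0.0)
    return r


def partial_correlation(series: np.ndarray,
                        censor_mask: np.ndarray | None = None) -> np.ndarray:
    """Partial correlations from the inverse covariance (precision) matrix.

    partial_ij = −Ω_ij / sqrt(Ω_ii · Ω_jj) with Ω = Σ⁻¹.  Requires more
    usable volumes than parcels + 1 and an invertible covariance; no
    shrinkage is applied — an ill-posed request errors out rather than
    being silently regularized.
    """
    y = _usable(series, censor_mask)
    n, p = y.shape
    if n <= p + 1:
        raise ValueError(
            f"partial correlation needs usable volumes > parcels + 1 "
            f"(got n={n}, P={p})"
        )
    cov = np.cov(y, rowvar=False)
    # symmetric eigendecomposition-based inverse: keeps omega exactly
    # symmetric with a positive diagonal, which plain inv() loses on
    # ill-conditioned input (band-passed series lose temporal rank)
    w, v = np.linalg.eigh(cov)
    if w[0] <= 1e-12 * w[-1]:
        raise ValueError(
            "numerically singular covariance (relative eigenvalue "
            f"{w[0] / w[-1]:.2e}): partial correlations are undefined. "
            "Note that nuisance regression and band-pass filtering reduce "
            "the effective temporal rank well below the volume count, so "
            "usable volumes > parcels + 1 is necessary but not sufficient."
        )
    omega = (v / w) @ v.T
    d = np.sqrt(np.diag(omega))
    pc = -omega / np.outer(d, d)
    pc = (pc + pc.T) / 2.0
    np.fill_diagonal(pc, 0.0)
    return pc


def apply_sign_mode(matrix: np.ndarray, mode: str) -> np.ndarray:
    """abs -> |x|; pos -> max(x, 0); neg -> max(−x, 0)."""
    m = np.asarray(matrix, dtype=float)
    if not np.allclose(m, m.T):
        raise ValueError("sign modes expect a symmetric matrix")
    if mode == "abs":
        return np.abs(m)
    if mode == "pos":
        return np.maximum(m, 0.0)
    if mode == "neg":
        return np.maximum(-m, 0.0)
    raise ValueError(f"mode must be one of {SIGN_MODES}, got {mode!r}")


def fisher_z(matrix: np.ndarray, n: int, p: int = 2) -> np.ndarray:
    """Fisher r-to-Z scaled by the effective degrees of freedom.

    Z = sqrt(n − 3 − (p − 2)) · atanh(r), with ``n`` the number of usable
    volumes and ``p`` the controller count: 2 for plain correlations, the
    parcel count for partial correlations.
    """
    r = np.asarray(matrix, dtype=float)
    off = ~np.eye(r.shape[0], dtype=bool)
    if (np.abs(r[off]) >= 1).any():
        raise ValueError("|r| must be < 1 off the diagonal")
    dof = n - 3 - (p - 2)
    if dof <= 0:
        raise ValueError(f"non-positive effective dof: n={n}, p={p}")
    z = np.sqrt(dof) * np.arctanh(r)
    np.fill_diagonal(z, 0.0)
    return z


def z_to_weight(z: np.ndarray, exponent: int = Z_WEIGHT_EXPONENT) -> np.ndarray:
    """w = (2Φ(Z) − 1)^exponent ∈ [0, 1]; even in Z for the default exponent.

    Sign modes are applied to Z *before* this transform (zeroing negative
    Z for "pos", etc.) — applying them after would be a no-op since the
    default transform is even.
    """
    z = np.asarray(z, dtype=float)
    if not np.isfinite(z).all():
        raise ValueError("Z must be finite")
    w = (2.0 * norm.cdf(z) - 1.0) ** exponent
    np.fill_diagonal(w, 0.0)
    return w


def weighted_network(
    corr: np.ndarray,
    sign_mode: str,
    weight_scheme: str,
    n_usable: int | None = None,
    kind: str = "pearson",
) -> np.ndarray:
    """Weights in [0, 1] from a (partial) correlation matrix.

    ``raw``: sign mode applied to r directly (|r| etc. are already in
    [0, 1]).  ``zphi``: sign mode applied to the Fisher Z values, then
    w = (2Φ(Z) − 1)^4.
    """
    if weight_scheme == "raw":
        return apply_sign_mode(corr, sign_mode)
    if weight_scheme == "zphi":
        if n_usable is None:
            raise ValueError("zphi weights require the usable-volume count")
        p_ctrl = 2 if kind == "pearson" else corr.shape[0]
        z = fisher_z(corr, n_usable, p_ctrl)
        return z_to_weight(apply_sign_mode(z, sign_mode))
    raise ValueError(f"weight_scheme must be 'raw' or 'zphi', got {weight_scheme!r}")


def binarize_by_density(matrix: np.ndarray, density: float) -> np.ndarray:
    """Adjacency keeping the k = round(d·P(P−1)/2) strongest edges.

    Rounding is half-up; ties at the cutoff are broken toward the smaller
    (i, j) lexicographic index so the edge set is deterministic and nested
    across densities.
    """
    if not (0 < density < 1):
        raise ValueError("density must lie in (0, 1)")
    m = np.asarray(matrix, dtype=float)
    p = m.shape[0]
    n_pairs = p * (p - 1) // 2
    k = int(np.floor(density * n_pairs + 0.5))
    if k == 0:
        raise ValueError(f"density {density} yields zero edges for P={p}")
    iu, ju = np.triu_indices(p, k=1)
    vals = m[iu, ju]
    # sort by value desc, then i asc, then j asc
    order = np.lexsort((ju, iu, -vals))
    adj = np.zeros((p, p))
    sel = order[:k]
    adj[iu[sel], ju[sel]] = 1.0
    adj += adj.T
    return adj
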