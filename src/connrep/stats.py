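"""Nonparametric factorial comparison of strategies.

Graph-measure TRT values are rarely normally distributed, so strategies
are compared with the aligned rank transform (ART): for each effect of a
complete within-subject factorial design, the response is aligned — every
estimated effect except the one of interest (including the additive
subject effect) is subtracted — then ranked (average ranks for ties), and
a conventional factorial ANOVA with subject as a blocking factor is run
on the aligned ranks; only the effect of interest is read off.

With S subjects and a complete a×b within-subject design the additive
subject-block model leaves (S−1)(ab−1) − ... more precisely
N−1 − (S−1) − Σ effect dof error degrees of freedom; for 69 subjects and
a 2×2 design that is 204.  Pairwise comparisons use the Wilcoxon signed
rank test; multiplicity over the four graph measures is handled by
Bonferroni correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations, product

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "FactorialDesign",
    "EffectResult",
    "art_align",
    "art_anova",
    "wilcoxon_signed_rank",
    "bonferroni",
]

N_MEASURES_CORRECTED = 4  # λ_n, C_n, E_n, BC_n


@dataclass
class EffectResult:
    effect: str
    f_statistic: float
    df_num: int
    df_den: int
    p_value: float
    p_bonferroni: float


class FactorialDesign:
    """A complete crossed within-subject factorial design in long format.

    Every subject must contribute exactly one response per factor-level
    cell; alignment is only defined for complete designs.
    """

    def __init__(self, data: pd.DataFrame, response: str, factors: list[str],
                 subject: str = "subject"):
        self.data = data.reset_index(drop=True)
        self.response = response
        self.factors = list(factors)
        self.subject = subject
        self.levels = {f: sorted(self.data[f].unique()) for f in self.factors}
        self._validate()

    def _validate(self) -> None:
        counts = self.data.groupby(
            [self.subject] + self.factors, observed=True
        ).size()
        if (counts != 1).any():
            bad = counts[counts != 1]
            raise ValueError(
                f"design not complete crossed; offending cells:\n{bad.head(20)}"
            )
        subjects = self.data[self.subject].unique()
        expected = len(subjects) * int(
            np.prod([len(v) for v in self.levels.values()])
        )
        if len(self.data) != expected:
            missing = [
                (s, c)
                for s in subjects
                for c in product(*(self.levels[f] for f in self.factors))
                if (s, *c) not in counts.index
            ]
            raise ValueError(f"missing design cells: {missing[:20]}")

    def effect_names(self) -> list[str]:
        names = []
        for size in range(1, len(self.factors) + 1):
            for combo in combinations(self.factors, size):
                names.append(":".join(combo))
        return names


def _effect_factors(effect: str) -> tuple[str, ...]:
    return tuple(effect.split(":"))


def _effect_estimates(df: pd.DataFrame, response: str,
                      effect_factors: tuple[str, ...]) -> pd.Series:
    """Factorial effect estimates τ per level combination, by
    inclusion–exclusion over marginal means (balanced design)."""
    grand = df[response].mean()
    est = pd.Series(0.0, index=pd.MultiIndex.from_product(
        [sorted(df[f].unique()) for f in effect_factors], names=effect_factors
    ))
    for size in range(0, len(effect_factors) + 1):
        for sub in combinations(effect_factors, size):
            sign = (-1) ** (len(effect_factors) - len(sub))
            if size == 0:
                est += sign * grand
                continue
            marg = df.groupby(list(sub), observed=True)[response].mean()
            # broadcast the marginal mean over the full effect index
            vals = marg.loc[
                list(zip(*(est.index.get_level_values(f) for f in sub)))
                if len(sub) > 1
                else est.index.get_level_values(sub[0])
            ].to_numpy()
            est += sign * vals
    return est


def _lookup(est: pd.Series, df: pd.DataFrame,
            effect_factors: tuple[str, ...]) -> np.ndarray:
    if len(effect_factors) == 1:
        return est.loc[df[effect_factors[0]]].to_numpy()
    keys = list(zip(*(df[f] for f in effect_factors)))
    return est.loc[keys].to_numpy()


def art_align(design: FactorialDesign, effect: str) -> pd.DataFrame:
    """Response aligned for one effect, plus its average-tie ranks.

    aligned = response − fitted(subject block + all factorial effects)
    + estimated effect of interest; returned as the design's data with
    ``aligned`` and ``aligned_rank`` columns appended.
    """
    df = design.data.copy()
    y = df[design.response].to_numpy(dtype=float)
    grand = y.mean()
    subj_mean = df.groupby(design.subject, observed=True)[
        design.response].transform("mean").to_numpy()
    cell_mean = df.groupby(design.factors, observed=True)[
        design.response].transform("mean").to_numpy()
    residual = y - subj_mean - cell_mean + grand
    tau = _effect_estimates(df, design.response, _effect_factors(effect))
    df["aligned"] = residual + _lookup(tau, df, _effect_factors(effect))
    df["aligned_rank"] = sps.rankdata(df["aligned"])
    return df


def _balanced_rm_anova(df: pd.DataFrame, response: str, factors: list[str],
                       subject: str) -> dict[str, tuple[float, int, int, float]]:
    """Balanced within-subject factorial ANOVA with an additive subject
    block; returns {effect: (F, df_num, df_den, p)}."""
    y = df[response].to_numpy(dtype=float)
    n = y.size
    grand = y.mean()
    ss_total = float(((y - grand) ** 2).sum())

    subj_means = df.groupby(subject, observed=True)[response].mean()
    n_cells = int(np.prod([df[f].nunique() for f in factors]))
    ss_subject = n_cells * float(((subj_means - grand) ** 2).sum())
    df_subject = len(subj_means) - 1

    effects = {}
    ss_effects, df_effects = {}, {}
    for size in range(1, len(factors) + 1):
        for combo in combinations(factors, size):
            name = ":".join(combo)
            tau = _effect_estimates(df, response, combo)
            reps = n / len(tau)  # observations per effect-level combination
            ss_effects[name] = reps * float((tau.to_numpy() ** 2).sum())
            df_effects[name] = int(
                np.prod([df[f].nunique() - 1 for f in combo])
            )

    ss_error = ss_total - ss_subject - sum(ss_effects.values())
    df_error = (n - 1) - df_subject - sum(df_effects.values())
    if df_error <= 0:
        raise ValueError("rank-deficient design: no error degrees of freedom")
    ms_error = max(ss_error, 0.0) / df_error
    for name, ss in ss_effects.items():
        f = np.inf if ms_error == 0 else (ss / df_effects[name]) / ms_error
        p = float(sps.f.sf(f, df_effects[name], df_error)) if np.isfinite(f) else 0.0
        effects[name] = (float(f), df_effects[name], df_error, p)
    return effects


def art_anova(design: FactorialDesign, effects: list[str] | None = None,
              n_tests: int = N_MEASURES_CORRECTED) -> list[EffectResult]:
    """ART factorial repeated-measures ANOVA.

    For each requested effect (all mains and interactions by default) the
    response is aligned and ranked, the full factorial model with a
    subject block is fit on the ranks, and that effect's F test is
    reported with its raw and Bonferroni-corrected (×``n_tests``) p.
    """
    if effects is None:
        effects = design.effect_names()
    results = []
    for effect in effects:
        aligned = art_align(design, effect)
        table = _balanced_rm_anova(aligned, "aligned_rank", design.factors,
                                   design.subject)
        f, dfn, dfd, p = table[effect]
        results.append(EffectResult(effect, f, dfn, dfd, p, bonferroni(p, n_tests)))
    return results


def wilcoxon_signed_rank(x, y) -> tuple[float, float]:
    """Paired Wilcoxon signed rank test (zero differences dropped; normal
    approximation with continuity correction beyond n = 25).

    The statistic is T+, the rank sum of the positive differences x − y,
    so swapping the arguments mirrors it about n(n+1)/4.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired vectors must have equal length")
    diffs = (x - y)[x != y]
    if diffs.size == 0:
        warnings.warn("all paired differences are zero; test undefined")
        return float("nan"), float("nan")
    if diffs.size < 6:
        raise ValueError("need at least 6 non-tied pairs")
    ranks = sps.rankdata(np.abs(diffs))
    t_plus = float(ranks[diffs > 0].sum())
    method = "exact" if diffs.size <= 25 else "approx"
    try:
        res = sps.wilcoxon(x, y, zero_method="wilcox", correction=True,
                           method=method)
    except ValueError:  # ties prevent the exact distribution
        res = sps.wilcoxon(x, y, zero_method="wilcox", correction=True,
                           method="approx")
    return t_plus, float(res.pvalue)


def bonferroni(p, n_tests: int = N_MEASURES_CORRECTED):
    """min(1, p·n_tests), elementwise for array input."""
    scaled = np.minimum(1.0, np.asarray(p, dtype=float) * n_tests)
    return float(scaled) if scaled.ndim == 0 else scaled
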