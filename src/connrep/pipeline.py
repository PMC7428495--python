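"""Orchestration of the full strategy grid.

Four analyses compare network-construction strategies on test–retest
variability (TRT) of the normalized global graph measures:

* **1a** — binary networks at densities 5–40%, absolute correlations:
  2×2 within-subject design, denoising (simple vs. complex) × correlation
  (Pearson vs. partial), one ART ANOVA per density and measure.
* **1b** — weighted networks, absolute values: 2×2×2 adding the weight
  scheme (raw correlation vs. Fisher-Z/Φ transform).
* **2** — weighted raw-weight networks under simple denoising: 3×2,
  sign handling (abs/pos/neg) × correlation.
* **3** — parcellation granularity (e.g. 100 vs. 200 parcels): Wilcoxon
  signed rank tests on the normalized measures, Pearson correlations only
  (partial correlations are infeasible when parcels approach the number
  of usable volumes, and the package refuses to regularize silently).

Null-network and modularity seeds are derived deterministically from the
base seed and the strategy cell, so a fixed configuration yields
byte-identical outputs.  Null networks are seeded per (subject, strategy)
— the binary null depends only on size and density, and the weighted null
permutes each session's own weights, so sharing the seed across sessions
is statistically neutral while keeping TRT exactly zero for identical
sessions.  Modularity realizations are seeded per (subject, session).
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path

import numpy as np
import pandas as pd

from . import connectivity as conn
from . import graph as gr
from . import qc as qcm
from . import reproducibility as rep
from . import stats as st
from .cohort import SessionRecord
from .denoise import denoise_record

__all__ = ["StrategyGrid", "run_analysis", "run_granularity_comparison", "report"]

DENSITIES_DEFAULT = (0.05, 0.10, 0.20, 0.30, 0.40)


@dataclass
class StrategyGrid:
    """Levels of each construction factor for one analysis."""

    analysis: str
    denoising: tuple = ("simple", "complex")
    correlation: tuple = ("pearson", "partial")
    sign_modes: tuple = ("abs",)
    weight_schemes: tuple = ("raw",)
    network: str = "weighted"  # "binary" | "weighted"
    densities: tuple = DENSITIES_DEFAULT

    def __post_init__(self) -> None:
        for name in ("denoising", "correlation", "sign_modes", "weight_schemes"):
            if not getattr(self, name):
                raise ValueError(f"empty grid: no levels for {name}")
        if self.network not in ("binary", "weighted"):
            raise ValueError("network must be 'binary' or 'weighted'")
        if self.network == "binary" and not self.densities:
            raise ValueError("empty grid: binary networks need densities")

    @classmethod
    def for_analysis(cls, analysis: str) -> "StrategyGrid":
        if analysis == "1a":
            return cls("1a", network="binary")
        if analysis == "1b":
            return cls("1b", weight_schemes=("raw", "zphi"), network="weighted")
        if analysis == "2":
            return cls("2", denoising=("simple",),
                       sign_modes=("abs", "pos", "neg"), network="weighted")
        if analysis == "3":
            return cls("3", denoising=("simple",), correlation=("pearson",),
                       network="weighted")
        raise ValueError(f"unknown analysis {analysis!r}")

    def cells(self) -> list[dict]:
        dens = self.densities if self.network == "binary" else (None,)
        out = []
        for pipe, kind, sign, scheme, d in product(
            self.denoising, self.correlation, self.sign_modes,
            self.weight_schemes, dens,
        ):
            out.append({
                "denoising": pipe, "correlation": kind, "sign_mode": sign,
                "weight_scheme": scheme, "network": self.network, "density": d,
            })
        return out

    def design_factors(self) -> list[str]:
        factors = []
        for name, attr in (
            ("denoising", self.denoising),
            ("correlation", self.correlation),
            ("sign_mode", self.sign_modes),
            ("weight_scheme", self.weight_schemes),
        ):
            if len(attr) > 1:
                factors.append(name)
        return factors


def _derive_seed(*tokens) -> int:
    digest = hashlib.sha256("|".join(map(str, tokens)).encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


def _prepare_sessions(records: list[SessionRecord], tr_seconds: float):
    """QC every run, pick the run per session, drop incomplete subjects."""
    by_session: dict = {}
    for rec in records:
        by_session.setdefault((rec.subject_id, rec.session_id), []).append(rec)

    chosen: dict = {}
    qc_rows = []
    excluded = set()
    for (sid, ses), runs in sorted(by_session.items()):
        runs = sorted(runs, key=lambda r: r.run_id)
        reports = [qcm.qc_record(r, tr_seconds) for r in runs]
        idx = qcm.select_runs(reports)
        for r, rp in zip(runs, reports):
            qc_rows.append({
                "subject": sid, "session": ses, "run": r.run_id,
                "decision": rp.decision, "n_bad": len(rp.bad_volumes),
                "n_usable": rp.n_usable,
            })
        if idx is None:
            excluded.add(sid)
        else:
            chosen[(sid, ses)] = (runs[idx], reports[idx])

    sessions_per_subject: dict = {}
    for (sid, ses) in chosen:
        sessions_per_subject.setdefault(sid, set()).add(ses)
    n_sessions = max((len(v) for v in sessions_per_subject.values()), default=0)
    for sid, sess in sessions_per_subject.items():
        if len(sess) < n_sessions:
            excluded.add(sid)
    chosen = {k: v for k, v in chosen.items() if k[0] not in excluded}
    return chosen, pd.DataFrame(qc_rows), sorted(excluded)


def _build_network(corr_mat: np.ndarray, cell: dict, n_usable: int) -> np.ndarray:
    w = conn.weighted_network(
        corr_mat, cell["sign_mode"], cell["weight_scheme"],
        n_usable=n_usable, kind=cell["correlation"],
    )
    if cell["network"] == "binary":
        return conn.binarize_by_density(w, cell["density"])
    return w


def _cell_tokens(cell: dict) -> tuple:
    return tuple(cell[k] for k in
                 ("denoising", "correlation", "sign_mode", "weight_scheme",
                  "network", "density"))


def run_analysis(
    records: list[SessionRecord],
    grid: StrategyGrid,
    tr_seconds: float = 3.0,
    seed: int = 0,
    n_null: int = gr.N_NULL_DEFAULT,
    n_modularity: int = gr.N_MODULARITY_REALIZATIONS,
    include_hubs: bool = False,
    include_psi: bool = False,
) -> dict:
    """Run QC → denoise → connect → graph → reproducibility → stats.

    Returns a dict with the tidy ``reproducibility`` table (one TRT row
    per subject × cell × measure, plus Hc/pSI rows when requested), the
    ``effects`` table, the per-run ``qc`` table, excluded subjects, and
    machine-readable per-cell ``failures``.
    """
    chosen, qc_table, excluded = _prepare_sessions(records, tr_seconds)
    subjects = sorted({sid for sid, _ in chosen})
    sessions = sorted({ses for _, ses in chosen})
    if len(sessions) != 2:
        raise ValueError(f"need exactly 2 sessions, found {sessions}")

    denoised_cache: dict = {}
    corr_cache: dict = {}
    failures: list[dict] = []

    def get_corr(sid, ses, pipe, kind):
        key = (sid, ses, pipe, kind)
        if key in corr_cache:
            return corr_cache[key]
        rec, report = chosen[(sid, ses)]
        dkey = (sid, ses, pipe)
        if dkey not in denoised_cache:
            denoised_cache[dkey] = denoise_record(
                rec, pipe, tr_seconds, report.censor_mask)
        den = denoised_cache[dkey]
        fn = (conn.pearson_correlation if kind == "pearson"
              else conn.partial_correlation)
        mat = fn(den.data, den.censor_mask)
        out = (mat, int(den.censor_mask.sum()))
        corr_cache[key] = out
        return out

    rows: list[dict] = []
    for cell in grid.cells():
        tokens = _cell_tokens(cell)
        for sid in subjects:
            per_session = {}
            try:
                for ses in sessions:
                    mat, n_use = get_corr(sid, ses, cell["denoising"],
                                          cell["correlation"])
                    w = _build_network(mat, cell, n_use)
                    null_seed = _derive_seed(seed, "null", sid, *tokens)
                    norm = gr.normalized_global_measures(
                        w, n_null=n_null, seed=null_seed)
                    per_session[ses] = {"network": w, "measures": norm}
            except ValueError as e:
                failures.append({"subject": sid, **cell, "error": str(e)})
                continue

            s1, s2 = (per_session[s] for s in sessions)
            base = {"subject": sid, "analysis": grid.analysis, **cell}
            for name in gr.GLOBAL_MEASURE_NAMES:
                m1 = s1["measures"][name]["normalized"]
                m2 = s2["measures"][name]["normalized"]
                rows.append({**base, "measure": f"{name}_n", "level": "global",
                             "statistic": "trt", "value": rep.trt(m1, m2),
                             "session1": m1, "session2": m2})

            if include_hubs and cell["network"] == "weighted":
                hubs = []
                for s in (s1, s2):
                    nm = gr.nodal_measures(s["network"],
                                           include_efficiency=False)
                    hubs.append(np.flatnonzero(gr.hub_scores(nm).is_hub))
                rows.append({**base, "measure": "hub_set", "level": "global",
                             "statistic": "hc",
                             "value": rep.hub_cooccurrence(*hubs)})
            if include_psi and cell["network"] == "weighted":
                cms = []
                for ses, s in zip(sessions, (s1, s2)):
                    mod_seed = _derive_seed(seed, "modularity", sid, ses,
                                            *tokens)
                    cm, _ = gr.newman_coassignment(
                        s["network"], n_modularity, mod_seed)
                    cms.append(cm)
                psi_vals = rep.psi(*cms)
                for node, v in enumerate(psi_vals):
                    rows.append({**base, "measure": "psi",
                                 "level": f"nodal:{node}",
                                 "statistic": "psi", "value": float(v)})

    repro = pd.DataFrame(rows)
    effects = _strategy_effects(repro, grid)
    return {
        "reproducibility": repro,
        "effects": effects,
        "qc": qc_table,
        "excluded": excluded,
        "failures": pd.DataFrame(failures),
    }


def _complete_subjects(df: pd.DataFrame, factors: list[str]) -> pd.DataFrame:
    """Keep subjects with a value in every factor cell (complete cases)."""
    n_cells = int(np.prod([df[f].nunique() for f in factors]))
    counts = df.groupby("subject", observed=True).size()
    keep = counts[counts == n_cells].index
    dropped = sorted(set(counts.index) - set(keep))
    if dropped:
        warnings.warn(f"dropping incomplete subjects from the design: {dropped}")
    return df[df["subject"].isin(keep)]


def _strategy_effects(repro: pd.DataFrame, grid: StrategyGrid) -> pd.DataFrame:
    """ART ANOVA per measure (and per density for binary networks)."""
    factors = grid.design_factors()
    if repro.empty or not factors:
        return pd.DataFrame()
    trt_df = repro[(repro["statistic"] == "trt") &
                   repro["value"].notna()].copy()
    expected_levels = {"denoising": len(grid.denoising),
                       "correlation": len(grid.correlation),
                       "sign_mode": len(grid.sign_modes),
                       "weight_scheme": len(grid.weight_schemes)}
    out = []
    densities = (sorted(trt_df["density"].dropna().unique())
                 if grid.network == "binary" else [None])
    for density in densities:
        sub = (trt_df[trt_df["density"] == density]
               if density is not None else trt_df)
        for measure, mdf in sub.groupby("measure", observed=True):
            if any(mdf[f].nunique() < expected_levels[f] for f in factors):
                warnings.warn(
                    f"skipping ANOVA for {measure}: a design factor lost "
                    "all values at some level (see the failures table)")
                continue
            mdf = _complete_subjects(mdf, factors)
            if mdf.empty:
                continue
            design = st.FactorialDesign(mdf, "value", factors)
            for res in st.art_anova(design):
                out.append({
                    "analysis": grid.analysis, "measure": measure,
                    "density": density, "effect": res.effect,
                    "F": res.f_statistic, "df_num": res.df_num,
                    "df_den": res.df_den, "p": res.p_value,
                    "p_bonferroni": res.p_bonferroni,
                })
    return pd.DataFrame(out)


def run_granularity_comparison(
    records_by_parcellation: dict[int, list[SessionRecord]],
    tr_seconds: float = 3.0,
    seed: int = 0,
    n_null: int = gr.N_NULL_DEFAULT,
) -> dict:
    """Analysis 3: Wilcoxon signed rank tests between the session-1
    normalized global measures of two parcellation granularities
    (simple denoising, Pearson, abs, raw weights, weighted networks)."""
    if len(records_by_parcellation) != 2:
        raise ValueError("exactly two parcellation granularities required")
    grid = StrategyGrid.for_analysis("3")
    tables = {}
    for p, records in records_by_parcellation.items():
        res = run_analysis(records, grid, tr_seconds, seed=_derive_seed(seed, p),
                           n_null=n_null)
        tbl = res["reproducibility"]
        tables[p] = tbl[tbl["statistic"] == "trt"]

    p_lo, p_hi = sorted(records_by_parcellation)
    rows, repro_rows = [], []
    for measure in [f"{n}_n" for n in gr.GLOBAL_MEASURE_NAMES]:
        pair = []
        for p in (p_lo, p_hi):
            sub = tables[p][tables[p]["measure"] == measure]
            pair.append(sub.set_index("subject")["session1"])
        joined = pd.concat(pair, axis=1, keys=[p_lo, p_hi]).dropna()
        stat, pval = st.wilcoxon_signed_rank(joined[p_lo], joined[p_hi])
        rows.append({
            "analysis": "3", "measure": measure, "statistic": stat,
            "p": pval, "p_bonferroni": st.bonferroni(pval),
            "n_subjects": len(joined),
        })
    repro = pd.concat(
        [t.assign(n_parcels=p) for p, t in tables.items()], ignore_index=True
    )
    return {"effects": pd.DataFrame(rows), "reproducibility": repro}


def report(results: dict, outdir) -> None:
    """Write tidy CSVs, a per-cell TRT summary, and (for binary grids) a
    TRT-versus-density figure."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    repro = results["reproducibility"]
    repro.to_csv(out / "reproducibility.csv", index=False)
    if isinstance(results.get("effects"), pd.DataFrame):
        results["effects"].to_csv(out / "effects.csv", index=False)
    if isinstance(results.get("qc"), pd.DataFrame):
        results["qc"].to_csv(out / "qc.csv", index=False)

    trt_df = repro[repro["statistic"] == "trt"]
    if trt_df.empty:
        return
    cell_cols = [c for c in ("denoising", "correlation", "sign_mode",
                             "weight_scheme", "network", "density", "measure")
                 if c in trt_df.columns]
    summary = (trt_df.groupby(cell_cols, dropna=False, observed=True)["value"]
               .agg(["mean", "std", "count"]).reset_index())
    summary.to_csv(out / "trt_summary.csv", index=False)

    if "density" in trt_df.columns and trt_df["density"].notna().any():
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        binary = trt_df[trt_df["density"].notna()]
        fig, axes = plt.subplots(1, 4, figsize=(16, 4), sharex=True)
        for ax, measure in zip(axes, sorted(binary["measure"].unique())):
            sub = binary[binary["measure"] == measure]
            for keys, grp in sub.groupby(["denoising", "correlation"],
                                         observed=True):
                curve = grp.groupby("density", observed=True)["value"].mean()
                ax.plot(curve.index * 100, curve.values, marker="o",
                        label="-".join(map(str, keys)))
            ax.set_title(measure)
            ax.set_xlabel("density (%)")
            ax.set_ylabel("TRT (%)")
        axes[-1].legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(out / "trt_vs_density.png", dpi=120)
        plt.close(fig)
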