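"""Module/gene-trait association and intramodular hub selection.

Module eigengenes are correlated with the binary disease phenotype (in
every cohort) and with the lung-function traits FVC and DL_CO (in the
cohorts that measured them); candidate modules must reach |cor| >= 0.5
with a Benjamini-Hochberg adjusted p <= 0.05 for all of those trait
tests.  Within candidate modules, genes are ranked by a HubScore that
combines connectivity-based importance (consensus module membership kME)
with trait-based gene significance GS; the top 5% per module (95th
percentile of HubScores) are flagged as intramodular hubs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import ExpressionMatrix, TraitTable
from .genesets import bh_adjust
from .modules import GREY, ModuleAssignment, ModuleEigengenes

__all__ = [
    "CorrelationResult",
    "CandidateModuleReport",
    "correlation_test",
    "select_candidate_modules",
    "gene_significance",
    "module_membership",
    "hub_score",
    "select_hubs",
]

LUNG_TRAITS = ("fvc", "dlco")


@dataclass
class CorrelationResult:
    """Pearson correlation with an asymptotic two-sided p-value."""

    r: float
    n: int
    p: float
    method: str


def correlation_test(x, y, method: str = "student") -> CorrelationResult:
    """Pearson correlation with Student-t or Fisher-z asymptotic p-value.

    Student: t = r * sqrt((n-2)/(1-r^2)), p from t(n-2).
    Fisher:  z = atanh(r) * sqrt(n-3), p from the standard normal.
    Incomplete pairs are dropped first.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = x.size
    min_n = 3 if method == "student" else 4
    if n < min_n:
        raise ValueError(f"need >= {min_n} complete pairs, got {n}")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("constant vector: correlation undefined")
    r = float(np.clip(np.corrcoef(x, y)[0, 1], -1.0, 1.0))
    if abs(r) > 1 - 1e-12:
        r = float(np.sign(r))
    if method == "student":
        if abs(r) == 1.0:
            p = 0.0
        else:
            t = r * np.sqrt((n - 2) / (1 - r**2))
            p = 2 * stats.t.sf(abs(t), df=n - 2)
    elif method == "fisher":
        if abs(r) == 1.0:
            warnings.warn("|r| = 1: Fisher p-value degenerates to 0")
            p = 0.0
        else:
            z = np.arctanh(r) * np.sqrt(n - 3)
            p = 2 * stats.norm.sf(abs(z))
    else:
        raise ValueError(f"unknown method {method!r}")
    return CorrelationResult(r=r, n=int(n), p=float(min(p, 1.0)), method=method)


@dataclass
class CandidateModuleReport:
    """Tidy module x (cohort, trait) correlation table plus the selection."""

    table: pd.DataFrame  # columns: module, cohort, trait, r, n, p, p_adj
    selected: list[str]
    cor_threshold: float
    p_threshold: float

    def passes(self, module: str) -> bool:
        return module in self.selected


def _row_correlations(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise-complete Pearson correlation of each matrix row with y.

    Returns (r, n_complete); rows with fewer than 3 complete pairs or zero
    variance get NaN.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    valid = ~np.isnan(X) & ~np.isnan(y)[None, :]
    Xz = np.where(valid, X, 0.0)
    yz = np.where(np.isnan(y), 0.0, y)
    n = valid.sum(axis=1).astype(float)
    sx = Xz.sum(axis=1)
    sy = valid @ yz
    sxx = (Xz**2).sum(axis=1)
    syy = valid @ (yz**2)
    sxy = Xz @ yz
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxy - sx * sy / n
        vx = sxx - sx**2 / n
        vy = syy - sy**2 / n
        r = cov / np.sqrt(vx * vy)
    r[(n < 3) | ~np.isfinite(r)] = np.nan
    return np.clip(r, -1, 1), n.astype(int)


def select_candidate_modules(
    eigengenes: ModuleEigengenes,
    traits: dict[str, TraitTable],
    cor_threshold: float = 0.5,
    p_threshold: float = 0.05,
    method: str = "fisher",
) -> CandidateModuleReport:
    """Select modules trait-correlated in every cohort.

    A module is selected when |r| >= ``cor_threshold`` and BH-adjusted
    p <= ``p_threshold`` hold for the phenotype in *every* cohort and for
    both lung-function traits (in each cohort providing them).  BH
    families are per (cohort, trait) across modules.
    """
    rows = []
    modules = eigengenes.module_names
    for cohort_name, tt in traits.items():
        if cohort_name not in eigengenes.eigengenes:
            raise ValueError(f"no eigengenes for cohort {cohort_name!r}")
        me = eigengenes.cohort(cohort_name)
        trait_vectors = {"phenotype": tt.phenotype}
        for lt in LUNG_TRAITS:
            if tt.has_trait(lt):
                trait_vectors[lt] = tt.trait(lt)
        for trait_name, vec in trait_vectors.items():
            aligned = vec.reindex(me.index)
            for mod in modules:
                res = correlation_test(me[mod].to_numpy(), aligned.to_numpy(), method)
                rows.append(
                    {
                        "module": mod,
                        "cohort": cohort_name,
                        "trait": trait_name,
                        "r": res.r,
                        "n": res.n,
                        "p": res.p,
                    }
                )
    table = pd.DataFrame(rows)
    if table.empty:
        return CandidateModuleReport(table, [], cor_threshold, p_threshold)
    table["p_adj"] = np.nan
    for _, idx in table.groupby(["cohort", "trait"]).groups.items():
        table.loc[idx, "p_adj"] = bh_adjust(table.loc[idx, "p"].to_numpy())
    ok = (table["r"].abs() >= cor_threshold) & (table["p_adj"] <= p_threshold)
    table["passes"] = ok
    selected = [
        mod for mod, sub in table.groupby("module") if bool(sub["passes"].all())
    ]
    # keep module order by eigengene column order
    selected = [m for m in modules if m in selected]
    return CandidateModuleReport(table, selected, cor_threshold, p_threshold)


@dataclass
class SignificanceTable:
    """Gene significance GS = cor(expression, trait) per (cohort, trait)."""

    gs: pd.DataFrame  # genes x "cohort:trait" columns
    p: pd.DataFrame

    @property
    def trait_columns(self) -> list[str]:
        return list(self.gs.columns)


def gene_significance(
    cohorts: list[ExpressionMatrix], traits: dict[str, TraitTable]
) -> SignificanceTable:
    """Correlate every gene with the phenotype and available lung traits.

    The binary phenotype is treated as 0/1 numeric (point-biserial).
    Genes with fewer than 3 complete pairs get a missing GS.
    """
    gs_cols, p_cols = {}, {}
    for c in cohorts:
        tt = traits.get(c.cohort_name)
        if tt is None:
            continue
        trait_vectors = {"phenotype": tt.phenotype}
        for lt in LUNG_TRAITS:
            if tt.has_trait(lt):
                trait_vectors[lt] = tt.trait(lt)
        X = c.values.to_numpy(dtype=float)
        for trait_name, vec in trait_vectors.items():
            y = vec.reindex(c.values.columns).to_numpy(dtype=float)
            r, n = _row_correlations(X, y)
            with np.errstate(invalid="ignore", divide="ignore"):
                t = r * np.sqrt((n - 2) / (1 - r**2))
                p = 2 * stats.t.sf(np.abs(t), df=np.maximum(n - 2, 1))
            p[np.isnan(r)] = np.nan
            key = f"{c.cohort_name}:{trait_name}"
            gs_cols[key] = pd.Series(r, index=c.values.index)
            p_cols[key] = pd.Series(p, index=c.values.index)
    if not gs_cols:
        raise ValueError("no traits available in any cohort")
    return SignificanceTable(pd.DataFrame(gs_cols), pd.DataFrame(p_cols))


def module_membership(
    assign: ModuleAssignment,
    eigengenes: ModuleEigengenes,
    cohorts: list[ExpressionMatrix],
) -> pd.DataFrame:
    """Per-cohort and consensus kME of each assigned gene to its own module.

    Consensus kME is the per-cohort value of smallest magnitude when the
    signs agree across cohorts, and 0 when they disagree.
    """
    genes = [g for g in assign.gene_ids if assign.labels[g] != GREY]
    out = pd.DataFrame(index=pd.Index(genes, name="gene_id"))
    out["module"] = assign.labels.loc[genes]
    kme_cols = []
    for c in cohorts:
        me = eigengenes.cohort(c.cohort_name)
        vals = np.empty(len(genes))
        for mod, members in assign.modules().items():
            members = [g for g in members if g in out.index]
            X = c.values.loc[members].to_numpy(dtype=float)
            r, _ = _row_correlations(X, me[mod].to_numpy(dtype=float))
            pos = [out.index.get_loc(g) for g in members]
            vals[pos] = r
        col = f"kME:{c.cohort_name}"
        out[col] = vals
        kme_cols.append(col)
    out["consensus_kME"] = consensus_kme(out[kme_cols].to_numpy(dtype=float))
    out.attrs["kme_columns"] = kme_cols
    return out


def consensus_kme(K: np.ndarray) -> np.ndarray:
    """Consensus of per-cohort kME values (rows = genes, cols = cohorts).

    The value of smallest magnitude across cohorts, keeping the common
    sign; 0 whenever the cohorts disagree in sign.
    """
    K = np.atleast_2d(np.asarray(K, dtype=float))
    signs_agree = (np.sign(K) == np.sign(K[:, [0]])).all(axis=1) & (K != 0).all(axis=1)
    idx = np.abs(K).argmin(axis=1)
    signed = np.take_along_axis(K, idx[:, None], axis=1).ravel()
    return np.where(signs_agree, signed, 0.0)


def hub_score(
    membership: pd.DataFrame,
    significance: SignificanceTable,
    formula: str = "product",
) -> pd.DataFrame:
    """Combine consensus |kME| with mean trait |GS| into a HubScore in [0, 1].

    ``product`` (default): |consensus kME| * mean over available traits of
    |GS|; ``mean``: the average of the two components; ``rank-average``:
    mean of the within-module rank-quantiles of the two components.  Genes
    without any GS are excluded from hub ranking.
    """
    common = membership.index.intersection(significance.gs.index)
    out = membership.loc[common].copy()
    gs = significance.gs.loc[common]
    mean_abs_gs = gs.abs().mean(axis=1, skipna=True)
    no_gs = gs.isna().all(axis=1)
    if no_gs.any():
        warnings.warn(f"{int(no_gs.sum())} gene(s) lack GS; excluded from hub ranking")
        out = out.loc[~no_gs]
        mean_abs_gs = mean_abs_gs.loc[~no_gs]
    for col in gs.columns:
        out[f"GS:{col}"] = gs.loc[out.index, col]
    kme_part = out["consensus_kME"].abs()
    if formula == "product":
        score = kme_part * mean_abs_gs
    elif formula == "mean":
        score = (kme_part + mean_abs_gs) / 2
    elif formula == "rank-average":
        score = pd.Series(index=out.index, dtype=float)
        for _, sub in out.groupby("module"):
            rk = kme_part.loc[sub.index].rank(pct=True)
            rg = mean_abs_gs.loc[sub.index].rank(pct=True)
            score.loc[sub.index] = (rk + rg) / 2
    else:
        raise ValueError(f"unknown HubScore formula {formula!r}")
    out["hub_score"] = score.clip(0.0, 1.0)
    out["is_hub"] = False
    return out


def select_hubs(hubs: pd.DataFrame, q: float = 0.95, modules=None) -> pd.DataFrame:
    """Flag the top (1-q) fraction of HubScores within each module as hubs.

    The threshold is the linear-interpolation q-quantile of the module's
    scores; ties at the threshold are all included, and every module gets
    at least its top-scoring gene.
    """
    if not (0 < q < 1):
        raise ValueError("q must be in (0, 1)")
    out = hubs.copy()
    out["is_hub"] = False
    out["hub_quantile"] = q
    for mod, sub in out.groupby("module"):
        if modules is not None and mod not in modules:
            continue
        scores = sub["hub_score"].to_numpy(dtype=float)
        thr = np.quantile(scores, q)
        flag = scores >= thr
        if not flag.any():
            flag[np.argmax(scores)] = True
        out.loc[sub.index[flag], "is_hub"] = True
    return out
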