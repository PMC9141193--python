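"""Permutation-based module preservation (Zsummary) in test cohorts.

For a module defined in a reference cohort, density statistics (mean
intra-module adjacency, mean intra-module correlation, eigengene variance
explained, mean |kME|) measure how tightly the module's genes still
co-express in a test cohort, and connectivity statistics (correlations
between reference and test of intramodular connectivity kIM, of kME, and
of the gene-gene correlation pattern) measure whether the wiring is
retained.  Each observed statistic is standardized against a permutation
null built from random same-size gene sets drawn from the test cohort's
gene universe (excluding the module under test):

    Z = (observed - null mean) / null sd
    Zdensity = median of the density Zs
    Zconnectivity = median of the connectivity Zs
    Zsummary = (Zdensity + Zconnectivity) / 2

Convention: Zsummary < 2 no evidence of preservation, 2-10 moderate,
>= 10 strong.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import ExpressionMatrix
from .modules import ModuleAssignment, _module_eigengene

__all__ = [
    "PreservationResult",
    "module_preservation",
    "classify_preservation",
    "DENSITY_STATS",
    "CONNECTIVITY_STATS",
]

DENSITY_STATS = ("mean_adj", "mean_cor", "var_explained", "mean_kme")
CONNECTIVITY_STATS = ("cor_kim", "cor_kme", "cor_cor")

ZSUMMARY_MODERATE = 2.0
ZSUMMARY_STRONG = 10.0


def classify_preservation(
    z: float, moderate: float = ZSUMMARY_MODERATE, strong: float = ZSUMMARY_STRONG
) -> str:
    """Map a Zsummary value onto the none / moderate / strong convention."""
    if not np.isfinite(z):
        raise ValueError(f"non-finite Zsummary: {z}")
    if z < moderate:
        return "none"
    if z < strong:
        return "moderate"
    return "strong"


@dataclass
class PreservationResult:
    """Per-module observed statistics, Z scores and preservation class."""

    table: pd.DataFrame
    n_permutations: int
    seed: int

    def zsummary(self, module: str) -> float:
        return float(self.table.loc[module, "Zsummary"])

    def preservation_class(self, module: str) -> str:
        return str(self.table.loc[module, "class"])

    def summary(self) -> str:
        lines = [f"module preservation ({self.n_permutations} permutations, seed {self.seed})"]
        for mod, row in self.table.iterrows():
            lines.append(
                f"  {mod}: Zdensity={row['Zdensity']:.2f} "
                f"Zconnectivity={row['Zconnectivity']:.2f} "
                f"Zsummary={row['Zsummary']:.2f} [{row['class']}]"
            )
        return "\n".join(lines)


def _corr(X: np.ndarray) -> np.ndarray:
    sd = X.std(axis=1)
    Z = X - X.mean(axis=1, keepdims=True)
    denom = np.where(sd == 0, 1.0, sd * np.sqrt(X.shape[1]))
    Zn = Z / denom[:, None]
    r = Zn @ Zn.T
    np.fill_diagonal(r, 1.0)
    return np.clip(r, -1, 1)


def _adjacency(C: np.ndarray, mode: str, power: float) -> np.ndarray:
    a = np.abs(C) ** power if mode == "unsigned" else ((1 + C) / 2) ** power
    np.fill_diagonal(a, 0.0)
    return a


def _safe_cor(x: np.ndarray, y: np.ndarray) -> float:
    if x.std() == 0 or y.std() == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def _kme(X: np.ndarray, me: np.ndarray) -> np.ndarray:
    """Correlation of every row of X with the eigengene vector."""
    Z = X - X.mean(axis=1, keepdims=True)
    zn = np.linalg.norm(Z, axis=1)
    m = me - me.mean()
    mn = np.linalg.norm(m)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Z @ m) / (zn * mn)
    return np.nan_to_num(np.clip(r, -1, 1), nan=0.0)


def _geneset_stats(
    X_ref: np.ndarray, X_test: np.ndarray, mode: str, power: float
) -> dict[str, float]:
    """The 7 preservation statistics of one gene set."""
    C_ref = _corr(X_ref)
    C_test = _corr(X_test)
    A_test = _adjacency(C_test, mode, power)
    A_ref = _adjacency(C_ref, mode, power)
    iu = np.triu_indices(C_test.shape[0], k=1)

    me_test, ve_test = _module_eigengene(X_test)
    me_ref, _ = _module_eigengene(X_ref)
    kme_test = _kme(X_test, me_test)
    kme_ref = _kme(X_ref, me_ref)

    return {
        "mean_adj": float(A_test[iu].mean()),
        "mean_cor": float(C_test[iu].mean()),
        "var_explained": float(ve_test),
        "mean_kme": float(np.abs(kme_test).mean()),
        "cor_kim": _safe_cor(A_ref.sum(axis=1), A_test.sum(axis=1)),
        "cor_kme": _safe_cor(kme_ref, kme_test),
        "cor_cor": _safe_cor(C_ref[iu], C_test[iu]),
    }


def module_preservation(
    reference: ExpressionMatrix,
    assignment: ModuleAssignment,
    test: ExpressionMatrix,
    n_permutations: int = 100,
    seed: int = 42,
    mode: str = "signed",
    power: float = 6,
    modules: list[str] | None = None,
    min_present_fraction: float = 0.5,
) -> PreservationResult:
    """Zsummary preservation of reference modules in an independent test cohort.

    Results are bit-reproducible for a fixed seed.  Modules with fewer
    than 3 genes in the test cohort are dropped; modules with under
    ``min_present_fraction`` of their genes present raise a warning.
    """
    if n_permutations < 20:
        raise ValueError("need at least 20 permutations")
    rng = np.random.default_rng(seed)
    test_genes = pd.Index(test.gene_ids)
    ref_genes = pd.Index(reference.gene_ids)
    shared = test_genes.intersection(ref_genes)
    wanted = modules if modules is not None else list(assignment.modules())
    rows = {}
    for mod in wanted:
        members = assignment.genes_in(mod)
        present = [g for g in members if g in shared]
        if len(present) < 3:
            warnings.warn(f"module {mod!r}: <3 genes in test cohort; skipped")
            continue
        if len(present) < min_present_fraction * len(members):
            warnings.warn(
                f"module {mod!r}: only {len(present)}/{len(members)} genes in test cohort"
            )
        X_ref = reference.values.loc[present].to_numpy(dtype=float)
        X_test = test.values.loc[present].to_numpy(dtype=float)
        observed = _geneset_stats(X_ref, X_test, mode, power)

        universe = shared.difference(present)
        if len(universe) < len(present):
            raise ValueError(f"module {mod!r}: gene universe too small for permutations")
        null = {s: np.empty(n_permutations) for s in observed}
        universe_arr = np.asarray(universe)
        for b in range(n_permutations):
            pick = rng.choice(universe_arr, size=len(present), replace=False)
            Xr = reference.values.loc[pick].to_numpy(dtype=float)
            Xt = test.values.loc[pick].to_numpy(dtype=float)
            perm = _geneset_stats(Xr, Xt, mode, power)
            for s, v in perm.items():
                null[s][b] = v
        zs = {}
        for s, v in observed.items():
            mu, sd = null[s].mean(), null[s].std(ddof=1)
            zs[s] = (v - mu) / sd if sd > 0 else 0.0
        z_density = float(np.median([zs[s] for s in DENSITY_STATS]))
        z_connect = float(np.median([zs[s] for s in CONNECTIVITY_STATS]))
        z_summary = (z_density + z_connect) / 2
        row = {f"obs_{s}": v for s, v in observed.items()}
        row.update({f"Z_{s}": zs[s] for s in observed})
        row.update(
            {
                "n_genes": len(present),
                "Zdensity": z_density,
                "Zconnectivity": z_connect,
                "Zsummary": z_summary,
                "class": classify_preservation(z_summary),
            }
        )
        rows[mod] = row
    table = pd.DataFrame(rows).T
    table.index.name = "module"
    return PreservationResult(table, n_permutations, seed)
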