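"""Curated gene sets: GMT I/O, set algebra and over-representation tests.

Hub gene lists are triaged against curated collections -- the secretome,
known-disease genes, lung-function GWA genes, single-cell marker tables
and externally computed differential-expression lists -- via set algebra
and one-sided hypergeometric enrichment with Benjamini-Hochberg control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GeneSet",
    "EnrichmentResult",
    "read_gmt",
    "write_gmt",
    "read_gene_list",
    "intersect_gene_sets",
    "hypergeometric_enrichment",
    "bh_adjust",
    "filter_marker_sets",
]


@dataclass(frozen=True)
class GeneSet:
    """A named set of unique, upper-cased gene symbols."""

    name: str
    genes: frozenset[str]
    category: str = ""
    # curated sets read from disk must be non-empty; empty sets only arise
    # as legal results of set algebra (allow_empty)
    allow_empty: bool = False

    def __post_init__(self):
        object.__setattr__(
            self, "genes", frozenset(str(g).upper() for g in self.genes if str(g))
        )
        if not self.genes and not self.allow_empty:
            raise ValueError(f"gene set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return str(gene).upper() in self.genes


@dataclass
class EnrichmentResult:
    """One-sided hypergeometric over-representation of a query in a target."""

    query: str
    target: str
    universe_size: int
    target_in_universe: int
    query_size: int
    overlap: frozenset[str]
    p: float
    p_adj: float = np.nan

    @property
    def k(self) -> int:
        return len(self.overlap)


def read_gmt(path) -> list[GeneSet]:
    """Read gene sets from GMT (name <tab> description <tab> genes...)."""
    sets = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            name, desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
            if genes:
                sets.append(GeneSet(name, frozenset(genes), category=desc))
    return sets


def write_gmt(sets: list[GeneSet], path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.category or "na", *sorted(s.genes)]) + "\n")


def read_gene_list(path, name: str | None = None, category: str = "") -> GeneSet:
    """Read a plain one-symbol-per-line gene list."""
    with open(path) as fh:
        genes = [line.strip() for line in fh if line.strip()]
    return GeneSet(name or str(path), frozenset(genes), category=category)


def intersect_gene_sets(a: GeneSet, b: GeneSet, mode: str = "intersection") -> GeneSet:
    """Set algebra on upper-cased symbols; provenance kept in the name."""
    if mode == "intersection":
        genes, sep = a.genes & b.genes, "&"
    elif mode == "difference":
        genes, sep = a.genes - b.genes, "-"
    else:
        raise ValueError(f"unknown mode {mode!r}")
    name = f"({a.name}){sep}({b.name})"
    category = "/".join(x for x in (a.category, b.category) if x)
    return GeneSet(name, genes, category=category, allow_empty=True)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def hypergeometric_enrichment(
    query: GeneSet, targets: list[GeneSet], universe: GeneSet
) -> list[EnrichmentResult]:
    """One-sided (over-representation) hypergeometric tests with BH control.

    For each target, k = |query ∩ target ∩ universe| and
    p = P(X >= k), X ~ Hypergeometric(N=|universe|, K=|target ∩ universe|,
    n=|query ∩ universe|).  Query genes outside the universe are dropped
    with a warning.
    """
    if len(universe) == 0:
        raise ValueError("empty universe")
    q = query.genes & universe.genes
    dropped = len(query.genes) - len(q)
    if dropped:
        warnings.warn(f"{dropped} query gene(s) outside the universe dropped")
    N, n = len(universe), len(q)
    results = []
    for t in targets:
        tg = t.genes & universe.genes
        K = len(tg)
        overlap = frozenset(q & tg)
        k = len(overlap)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if k > 0 else 1.0
        results.append(
            EnrichmentResult(query.name, t.name, N, K, n, overlap, min(p, 1.0))
        )
    adj = bh_adjust([r.p for r in results])
    for r, a in zip(results, adj):
        r.p_adj = float(a)
    return results


def enrichment_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "query": [r.query for r in results],
            "target": [r.target for r in results],
            "N": [r.universe_size for r in results],
            "K": [r.target_in_universe for r in results],
            "n": [r.query_size for r in results],
            "k": [r.k for r in results],
            "p": [r.p for r in results],
            "p_adj": [r.p_adj for r in results],
            "overlap": [";".join(sorted(r.overlap)) for r in results],
        }
    )


def filter_marker_sets(
    markers: pd.DataFrame, fdr_max: float = 0.05, logfc_min: float = 0.5
) -> list[GeneSet]:
    """Turn a (cell_type, gene, fdr, logfc) marker table into GeneSets.

    Rows must pass fdr <= ``fdr_max`` and |logfc| >= ``logfc_min``; when a
    cell type carries both signs of fold change, separate ``_up`` and
    ``_down`` sets are emitted.
    """
    required = {"cell_type", "gene", "fdr", "logfc"}
    missing = required - set(markers.columns)
    if missing:
        raise ValueError(f"marker table lacks columns: {sorted(missing)}")
    passing = markers[(markers["fdr"] <= fdr_max) & (markers["logfc"].abs() >= logfc_min)]
    if passing.empty:
        warnings.warn("no marker rows pass the fdr/logfc filters")
        return []
    sets = []
    for cell, sub in passing.groupby("cell_type"):
        up = sub.loc[sub["logfc"] > 0, "gene"]
        down = sub.loc[sub["logfc"] < 0, "gene"]
        if len(up) and len(down):
            sets.append(GeneSet(f"{cell}_up", frozenset(up), category="cell-marker"))
            sets.append(GeneSet(f"{cell}_down", frozenset(down), category="cell-marker"))
        else:
            genes = up if len(up) else down
            sets.append(GeneSet(str(cell), frozenset(genes), category="cell-marker"))
    return sets
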