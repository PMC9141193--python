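"""Consensus module detection and module eigengenes.

Genes are clustered by average-linkage hierarchical clustering of the
dissimilarity ``1 - consensus TOM``.  The tree is cut statically at a
fraction of the maximum merge height; branches of at least
``min_module_size`` genes become modules and the remaining genes are
rescued into the module whose consensus kME (minimum across cohorts of
the correlation with that module's eigengene) exceeds a threshold,
otherwise they stay unassigned ("grey").  Modules whose eigengenes are
highly correlated in every cohort are merged.  The module eigengene is
the first principal component of the standardized member expression,
sign-oriented along the module's mean profile and scaled to unit
variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage, to_tree
from scipy.spatial.distance import squareform

from .data_io import ExpressionMatrix
from .network import ConsensusTOM, TOMMatrix

__all__ = [
    "GREY",
    "MODULE_COLORS",
    "Dendrogram",
    "ModuleAssignment",
    "ModuleEigengenes",
    "detect_modules",
    "merge_modules",
    "compute_eigengenes",
]

GREY = "grey"

# Conventional color sequence for module labels, assigned by decreasing size.
MODULE_COLORS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
    "paleturquoise", "violet", "darkolivegreen", "darkmagenta", "sienna3",
    "yellowgreen", "skyblue3", "plum1", "orangered4", "mediumpurple3",
)


@dataclass
class Dendrogram:
    """Average-linkage merge history over genes (scipy linkage encoding)."""

    linkage_matrix: np.ndarray
    gene_ids: list[str]

    @property
    def heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]

    def leaf_order(self) -> list[str]:
        tree = to_tree(self.linkage_matrix)
        return [self.gene_ids[i] for i in tree.pre_order(lambda x: x.id)]

    def to_newick_like(self) -> str:
        """Nested-parenthesis text serialization with merge heights."""

        def rec(node):
            if node.is_leaf():
                return self.gene_ids[node.id]
            return f"({rec(node.left)},{rec(node.right)}):{node.dist:.6g}"

        return rec(to_tree(self.linkage_matrix)) + ";"


@dataclass
class ModuleAssignment:
    """gene -> module label; "grey" marks unassigned genes."""

    labels: pd.Series
    min_module_size: int = 0

    def __post_init__(self) -> None:
        self.labels = self.labels.astype(str)

    @property
    def gene_ids(self) -> list[str]:
        return [str(g) for g in self.labels.index]

    def modules(self) -> dict[str, list[str]]:
        """Module label -> member genes, grey excluded, decreasing size."""
        out: dict[str, list[str]] = {}
        for label, members in self.labels.groupby(self.labels):
            if label != GREY:
                out[label] = list(members.index.astype(str))
        return dict(sorted(out.items(), key=lambda kv: (-len(kv[1]), kv[1][0])))

    def sizes(self) -> pd.Series:
        return self.labels.value_counts()

    def genes_in(self, label: str) -> list[str]:
        return list(self.labels.index[self.labels == label].astype(str))

    def to_tsv(self, path) -> None:
        self.labels.rename("module").to_csv(path, sep="\t", index_label="gene_id")


@dataclass
class ModuleEigengenes:
    """Per-cohort sample x module eigengene tables with variance explained."""

    eigengenes: dict[str, pd.DataFrame]
    var_explained: pd.DataFrame  # modules x cohorts

    @property
    def cohort_names(self) -> list[str]:
        return list(self.eigengenes)

    @property
    def module_names(self) -> list[str]:
        return list(next(iter(self.eigengenes.values())).columns)

    def cohort(self, name: str) -> pd.DataFrame:
        return self.eigengenes[name]


def _standardize_rows(X: np.ndarray) -> np.ndarray:
    mu = np.nanmean(X, axis=1, keepdims=True)
    sd = np.nanstd(X, axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    return np.nan_to_num(Z, nan=0.0)


def _module_eigengene(X: np.ndarray) -> tuple[np.ndarray, float]:
    """First right singular vector of standardized member expression.

    Returns the eigengene (unit variance, oriented along the mean member
    profile) and the fraction of variance it explains.
    """
    Z = _standardize_rows(np.asarray(X, dtype=float))
    u, s, vt = np.linalg.svd(Z, full_matrices=False)
    me = vt[0]
    var_explained = float(s[0] ** 2 / np.sum(s**2)) if s.sum() > 0 else 0.0
    mean_profile = Z.mean(axis=0)
    if np.dot(me, mean_profile) < 0:
        me = -me
    sd = me.std(ddof=1)
    if sd > 0:
        me = (me - me.mean()) / sd
    return me, var_explained


def compute_eigengenes(
    assign: ModuleAssignment,
    cohorts: list[ExpressionMatrix],
    include_grey: bool = False,
) -> ModuleEigengenes:
    """Per-cohort module eigengenes and variance explained."""
    modules = assign.modules()
    if include_grey and (assign.labels == GREY).any():
        modules[GREY] = assign.genes_in(GREY)
    eigengenes: dict[str, pd.DataFrame] = {}
    var_rows: dict[str, dict[str, float]] = {m: {} for m in modules}
    for c in cohorts:
        cols = {}
        for label, genes in modules.items():
            present = [g for g in genes if g in c.values.index]
            if not present:
                raise ValueError(f"module {label!r} has no genes in cohort {c.cohort_name!r}")
            me, ve = _module_eigengene(c.values.loc[present].to_numpy())
            cols[label] = me
            var_rows[label][c.cohort_name] = ve
        eigengenes[c.cohort_name] = pd.DataFrame(cols, index=c.sample_ids)
    var_explained = pd.DataFrame(var_rows).T
    return ModuleEigengenes(eigengenes, var_explained)


def _corr_with(gene_vec: np.ndarray, me: np.ndarray) -> float:
    sx, sy = gene_vec.std(), me.std()
    if sx == 0 or sy == 0:
        return 0.0
    return float(np.corrcoef(gene_vec, me)[0, 1])


def _consensus_kme_table(
    genes: list[str],
    module_labels: list[str],
    eigengenes: ModuleEigengenes,
    cohorts: list[ExpressionMatrix],
) -> pd.DataFrame:
    """Consensus (min across cohorts, signed) kME of each gene to each module."""
    per_cohort = []
    for c in cohorts:
        X = c.values.loc[genes].to_numpy(dtype=float)
        Z = _standardize_rows(X)
        ME = eigengenes.cohort(c.cohort_name)[module_labels].to_numpy(dtype=float)
        ZME = (ME - ME.mean(axis=0)) / ME.std(axis=0, ddof=0)
        n = Z.shape[1]
        kme = (Z / np.linalg.norm(Z, axis=1, keepdims=True).clip(min=1e-300)) @ (
            ZME / np.sqrt(n)
        )
        per_cohort.append(kme)
    cons = np.minimum.reduce(per_cohort)
    return pd.DataFrame(cons, index=genes, columns=module_labels)


def _relabel_by_size(labels: pd.Series) -> pd.Series:
    """Assign conventional color names by decreasing module size.

    Ties are broken by the module's first gene id in matrix order.
    """
    first_pos = {}
    for pos, (gene, lab) in enumerate(labels.items()):
        if lab != GREY and lab not in first_pos:
            first_pos[lab] = pos
    sizes = labels.value_counts()
    mods = [l for l in sizes.index if l != GREY]
    mods.sort(key=lambda l: (-sizes[l], first_pos[l]))
    mapping = {}
    for i, l in enumerate(mods):
        mapping[l] = MODULE_COLORS[i] if i < len(MODULE_COLORS) else f"module{i + 1}"
    mapping[GREY] = GREY
    return labels.map(mapping)


def _branch_seeds(
    D: np.ndarray,
    genes: list[str],
    positions: np.ndarray,
    min_module_size: int,
    cut_height_fraction: float,
    tag: str,
) -> tuple[pd.Series | None, np.ndarray | None]:
    """Cut the average-linkage tree of a gene subset; return branch labels
    of size >= min_module_size (None when no branch qualifies)."""
    if positions.size < min_module_size:
        return None, None
    sub = D[np.ix_(positions, positions)]
    Z = linkage(squareform(sub, checks=False), method="average")
    cut_h = cut_height_fraction * float(Z[:, 2].max())
    flat = fcluster(Z, t=cut_h, criterion="distance")
    lab = pd.Series(
        [f"{tag}_b{b}" for b in flat],
        index=pd.Index([genes[i] for i in positions], name="gene_id"),
    )
    sizes = lab.value_counts()
    keep = set(sizes.index[sizes >= min_module_size])
    if not keep:
        return None, Z
    lab[~lab.isin(keep)] = GREY
    return lab, Z


def detect_modules(
    ct: ConsensusTOM | TOMMatrix,
    cohorts: list[ExpressionMatrix],
    min_module_size: int = 30,
    cut_height_fraction: float = 0.99,
    kme_rescue_threshold: float = 0.3,
    max_cycles: int = 5,
) -> tuple[Dendrogram, ModuleAssignment]:
    """Detect consensus modules from the consensus TOM.

    One cycle: static cut of the average-linkage tree at
    ``cut_height_fraction`` of the maximum merge height; branches of at
    least ``min_module_size`` genes seed provisional modules; every gene
    is then (re)assigned by consensus kME -- it joins the module whose
    eigengene it correlates with most (minimum across cohorts) provided
    that correlation exceeds ``kme_rescue_threshold``, and is grey
    otherwise.  This rescues genes from small branches and demotes weakly
    attached branch members alike; modules falling below
    ``min_module_size`` dissolve into grey.

    Cycles repeat on the still-grey genes (a branch holding two modules
    yields one eigengene and demotes the minority module; re-cutting the
    grey remainder recovers it) until no new branch seeds a module or the
    assignment stabilises.
    """
    tom = ct.consensus if isinstance(ct, ConsensusTOM) else ct
    if tom.values.size == 0:
        raise ValueError("empty consensus TOM")
    if min_module_size < 3:
        raise ValueError("min_module_size must be >= 3")
    if not (0 < cut_height_fraction <= 1):
        raise ValueError("cut_height_fraction must be in (0, 1]")
    genes = tom.gene_ids
    D = 1.0 - tom.values
    np.fill_diagonal(D, 0.0)
    index = pd.Index(genes, name="gene_id")
    labels = pd.Series(GREY, index=index)
    dendro = None
    for cycle in range(max_cycles):
        grey_pos = np.flatnonzero((labels == GREY).to_numpy())
        seeds, Z = _branch_seeds(
            D, genes, grey_pos, min_module_size, cut_height_fraction, f"c{cycle}"
        )
        if cycle == 0:
            dendro = Dendrogram(Z, genes)
        if seeds is None:
            break
        provisional = labels.copy()
        new = seeds[seeds != GREY]
        provisional.loc[new.index] = new
        assignment = ModuleAssignment(provisional, min_module_size)
        if not assignment.modules():
            break
        eig = compute_eigengenes(assignment, cohorts)
        module_labels = list(assignment.modules())
        kme = _consensus_kme_table(genes, module_labels, eig, cohorts)
        best = kme.idxmax(axis=1)
        best_val = kme.max(axis=1)
        new_labels = pd.Series(
            np.where(best_val > kme_rescue_threshold, best, GREY), index=index
        )
        sizes = new_labels.value_counts()
        too_small = sizes.index[(sizes < min_module_size) & (sizes.index != GREY)]
        new_labels[new_labels.isin(too_small)] = GREY
        if (new_labels == labels).all():
            break
        labels = new_labels
    if dendro is None:  # fewer genes than min_module_size
        Z = linkage(squareform(D, checks=False), method="average")
        dendro = Dendrogram(Z, genes)
    labels = _relabel_by_size(labels)
    return dendro, ModuleAssignment(labels, min_module_size)


def merge_modules(
    assign: ModuleAssignment,
    cohorts: list[ExpressionMatrix],
    merge_cor: float = 0.75,
) -> ModuleAssignment:
    """Iteratively merge modules whose eigengenes are consensus-correlated.

    The consensus eigengene correlation of a module pair is the minimum
    across cohorts; the most correlated pair above ``merge_cor`` is merged
    (into the larger module's provisional label), eigengenes are
    recomputed, and the loop repeats.  Final labels follow the size-ranked
    color convention, so the result is a fixed point of the operation.
    """
    if not (0 < merge_cor < 1):
        raise ValueError("merge_cor must be in (0, 1)")
    labels = assign.labels.copy()
    while True:
        current = ModuleAssignment(labels.copy(), assign.min_module_size)
        mods = list(current.modules())
        if len(mods) < 2:
            break
        eig = compute_eigengenes(current, cohorts)
        cons = None
        for c in eig.cohort_names:
            corr = eig.cohort(c)[mods].corr().to_numpy()
            cons = corr if cons is None else np.minimum(cons, corr)
        np.fill_diagonal(cons, -np.inf)
        i, j = np.unravel_index(np.argmax(cons), cons.shape)
        if cons[i, j] <= merge_cor:
            break
        a, b = mods[i], mods[j]
        sizes = current.sizes()
        keep_label, drop_label = (a, b) if sizes[a] >= sizes[b] else (b, a)
        labels[labels == drop_label] = keep_label
    labels = _relabel_by_size(labels)
    return ModuleAssignment(labels, assign.min_module_size)
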