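"""Synthetic multi-cohort expression data with planted module/trait structure.

The generator is the factor model that module eigengene analysis
estimates: each planted module m has a per-sample eigengene score
ME_m ~ N(0, 1), and a member gene g with loading rho_g in (0, 1) is

    x_g = rho_g * ME_m + sqrt(1 - rho_g^2) * eps,   eps ~ N(0, 1),

so two members correlate as rho_i * rho_j.  Background genes are pure
noise; cohort-specific modules exist only in their own cohort (their
genes are background elsewhere).  Traits couple to the eigengene scores:

    phenotype ~ Bernoulli(logistic(sum_m w_m^pheno * ME_m))
    FVC, DL_CO = sum_m w_m^trait * ME_m + noise_sd * eps

By default the two disease modules' eigengene scores are drawn with a
negative mutual correlation (one module up-, one down-regulated in
disease), mirroring the mutual correlation of disease modules in real
cohorts and keeping each module's point-biserial correlation with the
binary label in the candidate range; all other modules are independent.

Everything is reproducible from a single seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import ExpressionMatrix, TraitTable
from .genesets import GeneSet

__all__ = [
    "SyntheticTruth",
    "default_truth",
    "simulate_consensus_cohorts",
    "simulate_gene_annotations",
]


@dataclass
class ModuleSpec:
    """One planted module: size, trait couplings and (optional) cohort owner."""

    name: str
    size: int
    pheno_weight: float = 0.0
    fvc_weight: float = 0.0
    dlco_weight: float = 0.0
    specific_to: int | None = None  # cohort index; None = shared


@dataclass
class SyntheticTruth:
    """Planted structure: module map, loadings, couplings and sample sizes."""

    modules: list[ModuleSpec]
    module_map: pd.Series  # gene -> module name or "background"
    loadings: pd.Series  # gene -> rho in (0,1); 0 for background
    n_samples: tuple[int, ...]
    noise_sd: float
    seed: int
    disease_me_cor: float
    lung_traits_in: tuple[int, ...]
    loading_range: tuple[float, float]

    def __post_init__(self) -> None:
        for spec in self.modules:
            if spec.size < 3:
                raise ValueError(f"module {spec.name!r} has fewer than 3 genes")
        member = self.module_map != "background"
        rho = self.loadings[member]
        if ((rho <= 0) | (rho >= 1)).any():
            raise ValueError("member loadings must lie in (0, 1)")
        if (self.loadings[~member] != 0).any():
            raise ValueError("background genes must have zero loading")

    @property
    def n_genes(self) -> int:
        return len(self.module_map)

    @property
    def shared_modules(self) -> list[str]:
        return [m.name for m in self.modules if m.specific_to is None]

    @property
    def cohort_specific_modules(self) -> list[str]:
        return [m.name for m in self.modules if m.specific_to is not None]

    @property
    def trait_coupled_modules(self) -> list[str]:
        return [
            m.name
            for m in self.modules
            if m.pheno_weight or m.fvc_weight or m.dlco_weight
        ]

    def genes_in(self, module: str) -> list[str]:
        return list(self.module_map.index[self.module_map == module])

    def top_loading_genes(self, quantile: float = 0.9) -> list[str]:
        """Member genes of trait-coupled modules in the top loading decile."""
        pool = self.module_map.isin(self.trait_coupled_modules)
        rho = self.loadings[pool]
        thr = rho.quantile(quantile)
        return list(rho.index[rho >= thr])


DEFAULT_MODULES = (
    ModuleSpec("M1", 300, pheno_weight=3.0, fvc_weight=-1.2, dlco_weight=-1.2),
    ModuleSpec("M2", 200, pheno_weight=-3.0, fvc_weight=1.2, dlco_weight=1.2),
    ModuleSpec("M3", 150),
    ModuleSpec("M4", 120),
    ModuleSpec("M5", 80),
    ModuleSpec("C1", 60, specific_to=1),
)


def default_truth(
    n_genes: int = 2000,
    n_samples: tuple[int, ...] = (120, 120),
    modules: tuple[ModuleSpec, ...] = DEFAULT_MODULES,
    loading_range: tuple[float, float] = (0.3, 0.9),
    noise_sd: float = 1.0,
    disease_me_cor: float = -0.5,
    lung_traits_in: tuple[int, ...] = (0,),
    seed: int = 42,
) -> SyntheticTruth:
    """The default study conditions: 2 cohorts x 2000 genes x 120 samples,
    5 shared planted modules (two disease-coupled, up/down) plus one
    cohort-specific module, loadings U(0.3, 0.9); lung-function traits
    exist only in the first cohort.
    """
    if modules is DEFAULT_MODULES and n_genes != 2000:
        # keep the default module/background proportions at other scales
        factor = n_genes / 2000
        modules = tuple(
            ModuleSpec(
                m.name, max(3, int(round(m.size * factor))),
                m.pheno_weight, m.fvc_weight, m.dlco_weight, m.specific_to,
            )
            for m in modules
        )
    total = sum(m.size for m in modules)
    if total > n_genes:
        raise ValueError(f"module sizes ({total}) exceed gene count ({n_genes})")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC0]))
    genes = [f"G{i:05d}" for i in range(n_genes)]
    labels = []
    for m in modules:
        labels += [m.name] * m.size
    labels += ["background"] * (n_genes - total)
    module_map = pd.Series(labels, index=genes, name="module")
    lo, hi = loading_range
    rho = np.zeros(n_genes)
    member = module_map != "background"
    rho[member.to_numpy()] = rng.uniform(lo, hi, size=int(member.sum()))
    loadings = pd.Series(rho, index=genes, name="loading")
    return SyntheticTruth(
        modules=list(modules),
        module_map=module_map,
        loadings=loadings,
        n_samples=tuple(n_samples),
        noise_sd=noise_sd,
        seed=seed,
        disease_me_cor=disease_me_cor,
        lung_traits_in=tuple(lung_traits_in),
        loading_range=loading_range,
    )


def _draw_me_scores(
    truth: SyntheticTruth, n: int, rng: np.random.Generator
) -> pd.DataFrame:
    """Eigengene scores per sample; the two disease modules are correlated."""
    names = [m.name for m in truth.modules]
    Z = rng.standard_normal((n, len(names)))
    ME = pd.DataFrame(Z, columns=names)
    coupled = truth.trait_coupled_modules
    r = truth.disease_me_cor
    if len(coupled) >= 2 and r != 0:
        a, b = coupled[0], coupled[1]
        ME[b] = r * ME[a] + np.sqrt(1 - r**2) * ME[b]
    return ME


def simulate_consensus_cohorts(
    truth: SyntheticTruth,
) -> tuple[list[ExpressionMatrix], list[TraitTable], SyntheticTruth]:
    """Draw expression and trait tables for every cohort from the truth."""
    ss = np.random.SeedSequence([truth.seed, 0xDA7A])
    cohort_seeds = ss.spawn(len(truth.n_samples))
    gene_ids = list(truth.module_map.index)
    baseline_rng = np.random.default_rng(np.random.SeedSequence([truth.seed, 0xBA5E]))
    baseline = baseline_rng.normal(8.0, 1.5, size=truth.n_genes)
    cohorts, trait_tables = [], []
    rho = truth.loadings.to_numpy()
    for ci, (n, cseed) in enumerate(zip(truth.n_samples, cohort_seeds)):
        rng = np.random.default_rng(cseed)
        ME = _draw_me_scores(truth, n, rng)
        X = np.empty((truth.n_genes, n))
        noise = rng.standard_normal((truth.n_genes, n))
        for gi, (gene, mod) in enumerate(truth.module_map.items()):
            active = mod != "background"
            if active:
                spec = next(m for m in truth.modules if m.name == mod)
                if spec.specific_to is not None and spec.specific_to != ci:
                    active = False
            if active:
                r = rho[gi]
                X[gi] = r * ME[mod].to_numpy() + np.sqrt(1 - r**2) * noise[gi]
            else:
                X[gi] = noise[gi]
        X += baseline[:, None]
        sample_ids = [f"c{ci + 1}_s{j:03d}" for j in range(n)]
        cohort_name = f"cohort{ci + 1}"
        cohorts.append(
            ExpressionMatrix(
                pd.DataFrame(X, index=gene_ids, columns=sample_ids),
                cohort_name=cohort_name,
            )
        )
        logit = np.zeros(n)
        fvc = np.zeros(n)
        dlco = np.zeros(n)
        for m in truth.modules:
            if m.specific_to is not None and m.specific_to != ci:
                continue
            me = ME[m.name].to_numpy()
            logit += m.pheno_weight * me
            fvc += m.fvc_weight * me
            dlco += m.dlco_weight * me
        phenotype = rng.binomial(1, 1.0 / (1.0 + np.exp(-logit)))
        fvc = fvc + truth.noise_sd * rng.standard_normal(n)
        dlco = dlco + truth.noise_sd * rng.standard_normal(n)
        tbl = pd.DataFrame(
            {"phenotype": phenotype, "fvc": fvc, "dlco": dlco},
            index=pd.Index(sample_ids, name="sample_id"),
        )
        if ci not in truth.lung_traits_in:
            tbl[["fvc", "dlco"]] = np.nan
        trait_tables.append(TraitTable(tbl, cohort_name=cohort_name))
    return cohorts, trait_tables, truth


DEFAULT_ANNOTATION_SIZES = {
    "secretome": 200,
    "known_disease": 400,
    "lung_function_gwa": 150,
}
DEFAULT_CELL_TYPES = ("epithelial", "fibroblast", "endothelial")


def simulate_gene_annotations(
    truth: SyntheticTruth,
    overlap_with_hubs: dict[str, float] | None = None,
    sizes: dict[str, int] | None = None,
    n_cell_types: int = 3,
    marker_size: int = 80,
    seed: int | None = None,
) -> list[GeneSet]:
    """Mock curated gene sets with controlled overlap against planted top genes.

    For each category, a fraction ``overlap_with_hubs[category]`` of the
    set is drawn from the top-loading genes of the trait-coupled modules
    (the genes hub selection should find) and the rest uniformly from the
    remaining gene universe; per-cell-type marker sets are built the same
    way.  Overlap 0 makes a category's enrichment null.
    """
    overlap_with_hubs = dict(overlap_with_hubs or {})
    sizes = dict(sizes or DEFAULT_ANNOTATION_SIZES)
    for frac in overlap_with_hubs.values():
        if not (0 <= frac <= 1):
            raise ValueError("overlap fractions must lie in [0, 1]")
    rng = np.random.default_rng(
        np.random.SeedSequence([seed if seed is not None else truth.seed, 0xA110])
    )
    top = np.array(truth.top_loading_genes())
    universe = truth.module_map.index.to_numpy()
    rest = np.array(sorted(set(universe) - set(top)))
    out = []

    def build(name: str, category: str, size: int, frac: float) -> GeneSet:
        n_top = min(int(round(frac * size)), len(top))
        n_rest = min(size - n_top, len(rest))
        if n_top + n_rest < size:
            warnings.warn(
                f"gene set {name!r} clipped to {n_top + n_rest} genes "
                "(universe too small for the configured size)"
            )
        chosen = list(rng.choice(top, size=n_top, replace=False)) if n_top else []
        chosen += list(rng.choice(rest, size=n_rest, replace=False))
        return GeneSet(name, frozenset(chosen), category=category)

    for cat, size in sizes.items():
        frac = overlap_with_hubs.get(cat, 0.0)
        out.append(build(cat, cat, size, frac))
    for t in range(n_cell_types):
        cell = (
            DEFAULT_CELL_TYPES[t] if t < len(DEFAULT_CELL_TYPES) else f"celltype{t + 1}"
        )
        frac = overlap_with_hubs.get("cell-marker", 0.0)
        out.append(build(f"{cell}_markers", "cell-marker", marker_size, frac))
    return out
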