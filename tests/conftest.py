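"""Shared fixtures: small and paper-scale synthetic runs.

The heavy end-to-end state (default study conditions: 2 cohorts x 2000
genes x 120 samples, 5 shared + 1 cohort-specific planted module) is
built once per session and shared by the module-recovery, candidate-
selection and hub-enrichment tests.
"""

import numpy as np
import pytest

import cwgcna as cw
from cwgcna.simulate import ModuleSpec


SMALL_MODULES = (
    ModuleSpec("M1", 60, pheno_weight=3.0, fvc_weight=-1.2, dlco_weight=-1.2),
    ModuleSpec("M2", 50, pheno_weight=-3.0, fvc_weight=1.2, dlco_weight=1.2),
    ModuleSpec("M3", 40),
    ModuleSpec("C1", 30, specific_to=1),
)


@pytest.fixture(scope="session")
def small_sim():
    """2 cohorts x 400 genes x 80 samples with 3 shared + 1 specific module."""
    truth = cw.default_truth(
        n_genes=400, n_samples=(80, 80), modules=SMALL_MODULES, seed=1
    )
    cohorts, traits, truth = cw.simulate_consensus_cohorts(truth)
    return cohorts, {t.cohort_name: t for t in traits}, truth


@pytest.fixture(scope="session")
def small_run(small_sim):
    """Consensus network + modules + eigengenes for the small simulation."""
    cohorts, traits, truth = small_sim
    toms = [cw.tom_similarity(cw.adjacency_matrix(c, "signed", 6)) for c in cohorts]
    ct = cw.build_consensus(toms)
    _, assign = cw.detect_modules(ct, cohorts, min_module_size=20)
    assign = cw.merge_modules(assign, cohorts)
    eig = cw.compute_eigengenes(assign, cohorts)
    return cohorts, traits, truth, ct, assign, eig


@pytest.fixture(scope="session")
def default_run():
    """The default study conditions run end-to-end through hub selection."""
    truth = cw.default_truth(seed=42)
    cohorts, trait_list, truth = cw.simulate_consensus_cohorts(truth)
    traits = {t.cohort_name: t for t in trait_list}
    power = max(cw.pick_soft_threshold(c).chosen_power for c in cohorts)
    toms = [cw.tom_similarity(cw.adjacency_matrix(c, "signed", power)) for c in cohorts]
    ct = cw.build_consensus(toms)
    _, assign = cw.detect_modules(ct, cohorts)
    assign = cw.merge_modules(assign, cohorts)
    eig = cw.compute_eigengenes(assign, cohorts)
    candidates = cw.select_candidate_modules(eig, traits)
    gs = cw.gene_significance(cohorts, traits)
    mem = cw.module_membership(assign, eig, cohorts)
    hubs = cw.select_hubs(cw.hub_score(mem, gs))
    return {
        "truth": truth,
        "cohorts": cohorts,
        "traits": traits,
        "power": power,
        "consensus": ct,
        "assignment": assign,
        "eigengenes": eig,
        "candidates": candidates,
        "hub_table": hubs,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
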