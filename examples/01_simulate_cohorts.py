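"""Generate a two-cohort synthetic dataset with planted co-expression modules.

Draws the default study conditions (2 cohorts x 2000 genes x 120 samples,
five shared modules -- two coupled to disease and lung function -- plus one
cohort-specific module) and prints what was planted.
"""

import cwgcna as cw

truth = cw.default_truth(seed=42)
cohorts, traits, truth = cw.simulate_consensus_cohorts(truth)

print(f"cohorts: {[c.cohort_name for c in cohorts]}, shapes {[c.shape for c in cohorts]}")
print(f"shared modules: {truth.shared_modules}")
print(f"cohort-specific modules: {truth.cohort_specific_modules}")
print(f"trait-coupled modules: {truth.trait_coupled_modules}")
for t in traits:
    n_case = int(t.phenotype.sum())
    print(
        f"{t.cohort_name}: {n_case} cases / {len(t.sample_ids) - n_case} controls,"
        f" lung-function traits measured: {t.has_trait('fvc')}"
    )
# Module sizes are planted; expression follows a factor model, so two genes
# with loadings rho_i, rho_j in the same module correlate as rho_i * rho_j.
print(truth.module_map.value_counts().to_string())
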