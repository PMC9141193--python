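"""Select trait-correlated candidate modules and their intramodular hubs.

Module eigengenes are correlated with disease status (both cohorts) and
with FVC / DL_CO (first cohort only); candidates need |cor| >= 0.5 and
BH-adjusted p <= 0.05 throughout.  Hubs are the top 5% of each candidate
module by HubScore = |consensus kME| x mean |trait GS|.
"""

import cwgcna as cw

truth = cw.default_truth(seed=42)
cohorts, trait_list, truth = cw.simulate_consensus_cohorts(truth)
traits = {t.cohort_name: t for t in trait_list}

power = max(cw.pick_soft_threshold(c).chosen_power for c in cohorts)
toms = [cw.tom_similarity(cw.adjacency_matrix(c, "signed", power)) for c in cohorts]
_, assign = cw.detect_modules(cw.build_consensus(toms), cohorts)
assign = cw.merge_modules(assign, cohorts)
eig = cw.compute_eigengenes(assign, cohorts)

candidates = cw.select_candidate_modules(eig, traits)
print("candidate modules:", candidates.selected)
sel = candidates.table[candidates.table["module"].isin(candidates.selected)]
print(sel[["module", "cohort", "trait", "r", "p_adj"]].round(4).to_string(index=False))

gs = cw.gene_significance(cohorts, traits)
mem = cw.module_membership(assign, eig, cohorts)
hubs = cw.select_hubs(cw.hub_score(mem, gs), q=0.95, modules=candidates.selected)
n_hubs = hubs.groupby("module")["is_hub"].sum()
# roughly 5% of each candidate module's genes pass the 95th-percentile cut
print("hubs per candidate module:", n_hubs[candidates.selected].to_dict())
top = hubs[hubs["is_hub"]].nlargest(5, "hub_score")
print(top[["module", "consensus_kME", "hub_score"]].round(3).to_string())
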