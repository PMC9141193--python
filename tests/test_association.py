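"""Correlation tests, candidate-module selection, kME/GS and hub scoring."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import cwgcna as cw
from cwgcna.association import (
    SignificanceTable,
    consensus_kme,
    correlation_test,
    hub_score,
    select_hubs,
)
from cwgcna.data_io import TraitTable
from cwgcna.modules import ModuleEigengenes


def exact_r_vectors(r, n):
    """Two mean-zero length-n vectors with sample correlation exactly r."""
    u = np.zeros(n); v = np.zeros(n)
    u[:2] = [1, -1]; v[2:4] = [1, -1]
    return u, r * u + np.sqrt(1 - r**2) * v


class TestCorrelationTest:
    @pytest.mark.parametrize("method", ["student", "fisher"])
    def test_zero_correlation_gives_p_one(self, method):
        u, y = exact_r_vectors(0.0, 12)
        res = correlation_test(u, y, method)
        assert res.r == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_student_example_r06_n27(self):
        u, y = exact_r_vectors(0.6, 27)
        res = correlation_test(u, y, "student")
        assert res.r == pytest.approx(0.6, abs=1e-12)
        assert res.n == 27
        # t = 0.6*sqrt(25/0.64) = 3.75, df = 25
        assert res.p == pytest.approx(9.388e-4, rel=1e-3)

    def test_fisher_approximates_student_for_moderate_r(self, rng):
        checked = 0
        for _ in range(30):
            n = int(rng.integers(60, 200))
            x = rng.standard_normal(n)
            y = 0.2 * x + rng.standard_normal(n)
            s = correlation_test(x, y, "student")
            f = correlation_test(x, y, "fisher")
            if abs(s.r) <= 0.4 and s.p >= 0.01:  # outside the extreme tail
                assert f.p == pytest.approx(s.p, rel=0.10)
                checked += 1
        assert checked >= 10

    def test_constant_vector_errors(self):
        with pytest.raises(ValueError, match="constant"):
            correlation_test([1, 1, 1, 1], [1, 2, 3, 4])

    def test_perfect_fisher_correlation_warns_p_zero(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        with pytest.warns(UserWarning, match="degenerates"):
            res = correlation_test(x, 2 * x, "fisher")
        assert res.p == 0.0

    def test_missing_pairs_dropped(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, np.nan])
        y = np.array([2.0, 4.0, 6.0, 8.1, 1.0])
        res = correlation_test(x, y, "student")
        assert res.n == 4


def _toy_eigengenes_and_traits(rng, coupled_r=0.8, uncoupled_r=0.05):
    """Two cohorts, two modules: 'hot' trait-coupled, 'cold' not."""
    n = 60
    eig, traits = {}, {}
    for cname in ("cohort1", "cohort2"):
        z = rng.standard_normal((3, n))
        hot = z[0]
        cold = z[1]
        latent = coupled_r * hot + np.sqrt(1 - coupled_r**2) * z[2]
        pheno = (latent > 0).astype(float)
        idx = [f"{cname}_s{i}" for i in range(n)]
        eig[cname] = pd.DataFrame({"hot": hot, "cold": cold}, index=idx)
        tbl = pd.DataFrame({"phenotype": pheno}, index=idx)
        if cname == "cohort1":
            tbl["fvc"] = -latent + 0.3 * rng.standard_normal(n)
            tbl["dlco"] = -latent + 0.3 * rng.standard_normal(n)
        traits[cname] = TraitTable(tbl, cohort_name=cname)
    me = ModuleEigengenes(eig, pd.DataFrame())
    return me, traits


class TestCandidateSelection:
    def test_coupled_module_selected_uncoupled_not(self, rng):
        me, traits = _toy_eigengenes_and_traits(rng)
        rep = cw.select_candidate_modules(me, traits)
        assert rep.selected == ["hot"]
        assert not rep.passes("cold")

    def test_conjunction_over_cohorts(self, rng):
        me, traits = _toy_eigengenes_and_traits(rng)
        # break the coupling in cohort 2 only
        me.eigengenes["cohort2"]["hot"] = rng.standard_normal(60)
        rep = cw.select_candidate_modules(me, traits)
        assert rep.selected == []

    def test_no_candidates_is_not_an_error(self, rng):
        me, traits = _toy_eigengenes_and_traits(rng, coupled_r=0.1)
        rep = cw.select_candidate_modules(me, traits)
        assert rep.selected == []

    def test_bh_adjustment_is_monotone_within_family(self, rng):
        me, traits = _toy_eigengenes_and_traits(rng)
        rep = cw.select_candidate_modules(me, traits)
        for _, sub in rep.table.groupby(["cohort", "trait"]):
            order_p = sub.sort_values("p")["p_adj"].to_numpy()
            assert (np.diff(order_p) >= -1e-15).all()


class TestGeneSignificance:
    def test_gene_identical_to_trait_has_gs_one(self, small_sim):
        cohorts, traits, _ = small_sim
        c = cohorts[0]
        tt = traits[c.cohort_name]
        df = c.values.copy()
        df.iloc[0] = tt.trait("fvc").reindex(df.columns).to_numpy()
        m = cw.data_io.ExpressionMatrix(df, cohort_name=c.cohort_name)
        st = cw.gene_significance([m], {c.cohort_name: tt})
        assert st.gs.iloc[0][f"{c.cohort_name}:fvc"] == pytest.approx(1.0)

    def test_null_gs_small_at_n200(self, rng):
        n = 200
        X = rng.standard_normal((100, n))
        cols = [f"s{i}" for i in range(n)]
        m = cw.data_io.ExpressionMatrix(
            pd.DataFrame(X, columns=cols), cohort_name="c"
        )
        tt = TraitTable(
            pd.DataFrame({"phenotype": rng.integers(0, 2, n)}, index=cols),
            cohort_name="c",
        )
        st = cw.gene_significance([m], {"c": tt})
        frac = (st.gs["c:phenotype"].abs() < 0.2).mean()
        assert frac >= 0.95

    def test_sign_matches_planted_coupling(self, small_sim):
        cohorts, traits, truth = small_sim
        st = cw.gene_significance(cohorts, traits)
        up = truth.genes_in("M1")  # positive phenotype coupling
        down = truth.genes_in("M2")
        col = "cohort1:phenotype"
        assert st.gs.loc[up, col].mean() > 0.2
        assert st.gs.loc[down, col].mean() < -0.2


class TestConsensusKME:
    @pytest.mark.parametrize(
        "row,expected",
        [([0.8, 0.6], 0.6), ([0.8, -0.4], 0.0), ([-0.7, -0.5], -0.5), ([1.0, 1.0], 1.0)],
    )
    def test_stated_rules(self, row, expected):
        assert consensus_kme(np.array([row]))[0] == pytest.approx(expected)

    def test_gene_equal_to_eigengene_has_kme_one(self, small_run):
        cohorts, _, _, _, assign, eig = small_run
        mem = cw.module_membership(assign, eig, cohorts)
        mod = mem["module"].iloc[0]
        c = cohorts[0]
        df = c.values.copy()
        gene = mem.index[mem["module"] == mod][0]
        df.loc[gene] = eig.cohort(c.cohort_name)[mod].to_numpy()
        m2 = cw.data_io.ExpressionMatrix(df, cohort_name=c.cohort_name)
        mem2 = cw.module_membership(assign, eig, [m2])
        assert mem2.loc[gene, f"kME:{c.cohort_name}"] == pytest.approx(1.0, abs=1e-8)


class TestHubScore:
    def _tables(self, kmes, gss):
        genes = [f"g{i}" for i in range(len(kmes))]
        mem = pd.DataFrame(
            {"module": "m", "kME:c1": kmes, "kME:c2": kmes, "consensus_kME": kmes},
            index=genes,
        )
        gs = pd.DataFrame(
            {f"t{j}": [row[j] for row in gss] for j in range(len(gss[0]))}, index=genes
        )
        return mem, SignificanceTable(gs, gs.copy())

    def test_perfect_gene_scores_one(self):
        mem, st = self._tables([1.0], [[1.0, -1.0, 1.0, 1.0]])
        assert hub_score(mem, st)["hub_score"].iloc[0] == pytest.approx(1.0)

    def test_zero_gs_scores_zero(self):
        mem, st = self._tables([0.9], [[0.0, 0.0]])
        assert hub_score(mem, st)["hub_score"].iloc[0] == 0.0

    def test_product_formula_arithmetic(self):
        # consensus kME 0.6, mean |GS| = (0.5+0.7+0.6+0.6)/4 = 0.6 -> 0.36
        mem, st = self._tables([0.6], [[0.5, -0.7, 0.6, 0.6]])
        assert hub_score(mem, st)["hub_score"].iloc[0] == pytest.approx(0.36)

    def test_gene_without_gs_excluded_with_warning(self):
        mem, st = self._tables([0.5, 0.6], [[0.4], [0.5]])
        st.gs.iloc[0, 0] = np.nan
        with pytest.warns(UserWarning, match="lack GS"):
            out = hub_score(mem, st)
        assert len(out) == 1


class TestSelectHubs:
    def _hub_frame(self, scores, module="m"):
        return pd.DataFrame(
            {"module": module, "hub_score": scores},
            index=[f"g{i}" for i in range(len(scores))],
        )

    def test_hundred_distinct_scores_give_five_hubs(self, rng):
        hubs = select_hubs(self._hub_frame(rng.permutation(100) / 100.0))
        assert int(hubs["is_hub"].sum()) == 5

    def test_twenty_distinct_scores_give_one_hub(self, rng):
        hubs = select_hubs(self._hub_frame(rng.permutation(20) / 20.0))
        assert int(hubs["is_hub"].sum()) == 1

    def test_threshold_ties_all_included(self):
        hubs = select_hubs(self._hub_frame([0.1] * 50 + [0.9] * 50))
        assert int(hubs["is_hub"].sum()) == 50

    def test_count_bounds_per_module(self, rng):
        for size in (5, 20, 100, 333):
            hubs = select_hubs(self._hub_frame(rng.random(size)))
            n = int(hubs["is_hub"].sum())
            assert 1 <= n <= int(np.ceil(0.05 * size)) + 1

    def test_hub_recovery_enriched_in_top_loading_genes(self, default_run):
        truth = default_run["truth"]
        hubs = default_run["hub_table"]
        cand = default_run["candidates"].selected
        hub_genes = set(hubs.index[hubs["is_hub"] & hubs["module"].isin(cand)])
        top = set(truth.top_loading_genes())
        assign = default_run["assignment"]
        universe = set(assign.labels.index[assign.labels.isin(cand)])
        k = len(hub_genes & top)
        K = len(top & universe)
        n = len(hub_genes & universe)
        N = len(universe)
        fold = (k / n) / (K / N)
        p = stats.hypergeom.sf(k - 1, N, K, n)
        assert fold >= 5
        assert p < 0.01
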