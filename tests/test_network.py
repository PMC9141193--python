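"""Adjacency, TOM, calibration, consensus and the compatibility screen."""

import numpy as np
import pandas as pd
import pytest

import cwgcna as cw
from cwgcna import network
from cwgcna.data_io import ExpressionMatrix


def tom_oracle(A):
    """O(n^3) triple-loop topological overlap, straight from the definition."""
    A = np.asarray(A, dtype=float).copy()
    np.fill_diagonal(A, 0.0)
    n = A.shape[0]
    k = A.sum(axis=1)
    T = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            l = sum(A[i, u] * A[u, j] for u in range(n) if u not in (i, j))
            T[i, j] = T[j, i] = (l + A[i, j]) / (min(k[i], k[j]) + 1 - A[i, j])
    return T


def exact_corr_matrix(pairs_r: float, n: int = 8):
    """Two mean-zero vectors with sample correlation exactly pairs_r."""
    u = np.zeros(n)
    v = np.zeros(n)
    u[:2] = [1, -1]
    v[2:4] = [1, -1]
    y = pairs_r * u + np.sqrt(1 - pairs_r**2) * v
    return u, y


class TestAdjacency:
    @pytest.mark.parametrize(
        "r,mode,power,expected",
        [
            (1.0, "signed", 6, 1.0),
            (-1.0, "signed", 3, 0.0),
            (0.5, "unsigned", 2, 0.25),
            (0.5, "signed", 1, 0.75),
        ],
    )
    def test_transform_values(self, r, mode, power, expected):
        x, y = exact_corr_matrix(r)
        m = ExpressionMatrix(pd.DataFrame([x, y], index=["g1", "g2"]))
        a = cw.adjacency_matrix(m, mode=mode, power=power)
        assert a.values[0, 1] == pytest.approx(expected, abs=1e-12)
        assert a.values[0, 0] == 0.0  # diagonal stored as 0

    def test_unsigned_entries_strictly_decrease_with_power(self, rng):
        m = ExpressionMatrix(pd.DataFrame(rng.standard_normal((10, 20))))
        a2 = cw.adjacency_matrix(m, "unsigned", 2).values
        a4 = cw.adjacency_matrix(m, "unsigned", 4).values
        off = ~np.eye(10, dtype=bool)
        assert (a4[off] < a2[off]).all()  # |r|<1 almost surely

    def test_constant_gene_warns_not_errors(self):
        df = pd.DataFrame([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]], index=["flat", "g"])
        with pytest.warns(UserWarning, match="constant"):
            a = cw.adjacency_matrix(ExpressionMatrix(df), "unsigned", 2)
        assert a.values[0, 1] == 0.0

    def test_too_few_samples_error(self):
        m = ExpressionMatrix(pd.DataFrame([[1.0, 2.0], [2.0, 1.0]]))
        with pytest.raises(ValueError, match="3 samples"):
            cw.adjacency_matrix(m, "signed", 6)


class TestTOM:
    def test_hand_computed_three_gene_example(self):
        A = np.array([[0, 0.8, 0.5], [0.8, 0, 0.4], [0.5, 0.4, 0]])
        t = cw.tom_similarity(A)
        # l_12 = 0.5*0.4; TOM_12 = (0.2+0.8)/(min(1.3,1.2)+1-0.8) = 1/1.4
        assert t.values[0, 1] == pytest.approx(1.0 / 1.4, abs=1e-12)
        assert np.allclose(np.diag(t.values), 1.0)

    def test_isolated_gene_has_zero_overlap(self):
        A = np.zeros((4, 4))
        A[1, 2] = A[2, 1] = 0.7
        t = cw.tom_similarity(A)
        assert np.all(t.values[0, 1:] == 0.0)

    @pytest.mark.parametrize("n", [10, 30, 50])
    def test_matches_triple_loop_oracle(self, n, rng):
        A = rng.uniform(0, 1, size=(n, n))
        A = (A + A.T) / 2
        np.fill_diagonal(A, 0.0)
        t = cw.tom_similarity(A)
        assert np.abs(t.values - tom_oracle(A)).max() < 1e-12


class TestCalibration:
    def _toms(self, rng, n=25):
        out = []
        for scale in (1.0, 2.0):
            A = rng.uniform(0, 1, size=(n, n)) ** scale
            A = (A + A.T) / 2
            np.fill_diagonal(A, 0.0)
            out.append(cw.tom_similarity(A))
        return out

    def test_identical_toms_unchanged_with_unit_exponents(self, rng):
        t = self._toms(rng)[0]
        t2 = network.TOMMatrix(t.gene_ids, t.values.copy())
        calibrated, exps = cw.calibrate_toms([t, t2], q=0.95)
        assert exps == [1.0, 1.0]
        assert np.allclose(calibrated[1].values, t.values)

    def test_quantiles_match_reference_after_calibration(self, rng):
        toms = self._toms(rng)
        calibrated, exps = cw.calibrate_toms(toms, q=0.95)
        quants = [np.quantile(t.off_diagonal(), 0.95, method="lower") for t in calibrated]
        assert abs(quants[0] - quants[1]) < 1e-10
        assert exps[0] == 1.0 and exps[1] != 1.0

    def test_known_exponent_maps_quantile(self):
        # Q_ref=0.2, Q_s=0.4 -> e = log(0.2)/log(0.4) ~ 1.7565 maps 0.4 to 0.2
        e = np.log(0.2) / np.log(0.4)
        assert e == pytest.approx(1.7565, abs=5e-5)
        assert 0.4**e == pytest.approx(0.2, abs=1e-12)

    def test_calibration_preserves_within_cohort_ordering(self, rng):
        toms = self._toms(rng)
        calibrated, _ = cw.calibrate_toms(toms, q=0.9)
        raw = toms[1].off_diagonal()
        cal = calibrated[1].off_diagonal()
        assert (np.argsort(raw) == np.argsort(cal)).all()

    def test_degenerate_quantile_error(self):
        z = network.TOMMatrix(["a", "b", "c"], np.eye(3))
        with pytest.raises(ValueError, match="outside"):
            cw.calibrate_toms([z, z], q=0.5)

    def test_consensus_is_elementwise_minimum(self, rng):
        toms = self._toms(rng)
        cons = cw.consensus_tom(toms)
        stack = np.stack([t.values for t in toms])
        off = ~np.eye(25, dtype=bool)
        assert np.array_equal(cons.values[off], stack.min(axis=0)[off])
        for t in toms:
            assert (cons.values[off] <= t.values[off] + 1e-15).all()

    def test_single_cohort_consensus_identity(self, rng):
        t = self._toms(rng)[0]
        cons = cw.consensus_tom([t])
        assert np.allclose(cons.values, t.values)

    def test_mismatched_gene_lists_error(self, rng):
        t1, t2 = self._toms(rng)
        t2.gene_ids = [g + "_x" for g in t2.gene_ids]
        with pytest.raises(ValueError, match="identical gene list"):
            cw.consensus_tom([t1, t2])


class TestQQDivergence:
    def test_identical_distributions_give_zero(self, rng):
        t = cw.tom_similarity(np.abs(rng.uniform(0, 1, (12, 12))))
        assert cw.tom_qq_divergence(t, t) == 0.0

    def test_strict_shrinkage_detected(self, rng):
        A = rng.uniform(0.1, 0.9, (15, 15))
        A = (A + A.T) / 2
        t1 = cw.tom_similarity(A)
        t2 = network.TOMMatrix(t1.gene_ids, t1.values**2)
        assert cw.tom_qq_divergence(t1, t2) > 0

    def test_same_generator_closer_than_disjoint_structure(self, small_sim):
        cohorts, _, _ = small_sim
        toms = [cw.tom_similarity(cw.adjacency_matrix(c, "signed", 6)) for c in cohorts]
        within = cw.tom_qq_divergence(toms[0], toms[1])
        # a structureless cohort: pure noise, no planted modules
        noise = cw.default_truth(
            n_genes=400, n_samples=(80,),
            modules=(cw.simulate.ModuleSpec("Z", 3),), seed=9,
        )
        nc, _, _ = cw.simulate_consensus_cohorts(noise)
        tn = cw.tom_similarity(cw.adjacency_matrix(nc[0], "signed", 6))
        across = cw.tom_qq_divergence(toms[0], tn)
        assert within < across


class TestSoftThreshold:
    def test_smallest_qualifying_power_chosen(self):
        p, warn = network.select_power([2, 4, 6, 8], [0.2, 0.5, 0.85, 0.9], 0.8)
        assert (p, warn) == (6, False)

    def test_fallback_to_argmax_with_warning(self):
        p, warn = network.select_power([2, 4, 6], [0.2, 0.6, 0.5], 0.8)
        assert (p, warn) == (4, True)

    def test_deterministic_and_finite_on_planted_modules(self, small_sim):
        cohorts, _, _ = small_sim
        r1 = cw.pick_soft_threshold(cohorts[0])
        r2 = cw.pick_soft_threshold(cohorts[0])
        assert r1.chosen_power == r2.chosen_power
        assert r1.chosen_power in r1.candidate_powers
        assert all(-1 <= f <= 1 for f in r1.fit_r2)

    def test_too_few_samples_error(self):
        m = ExpressionMatrix(pd.DataFrame([[1.0, 2.0], [3.0, 1.0]]))
        with pytest.raises(ValueError, match="3 samples"):
            cw.pick_soft_threshold(m)
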