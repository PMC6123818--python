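"""Per-probe RSA, permutation significance, and area x layer aggregation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import rsalign as ra
from rsalign.mapping import _LayerRDMBank
from conftest import DIAGONAL_MAP
import oracles


class TestProbeRdm:
    def test_absolute_differences(self):
        rdm = ra.probe_rdm([1.0, 3.0, 2.0])
        np.testing.assert_allclose(
            rdm.matrix, [[0, 2, 1], [2, 0, 1], [1, 1, 0]]
        )
        assert rdm.metric == "absdiff"

    def test_positive_affine_scales_rdm_only(self, rng):
        r = rng.standard_normal(12)
        a = ra.probe_rdm(r)
        b = ra.probe_rdm(2 * r + 5)
        np.testing.assert_allclose(b.matrix, 2 * a.matrix, atol=1e-12)

    def test_constant_vector_degenerate(self):
        assert ra.probe_rdm([2.0, 2.0, 2.0]).is_degenerate

    @given(st.lists(st.integers(-100, 100), min_size=3, max_size=10, unique=True),
           st.sampled_from([0.5, 1.0, 2.0, 4.0]),
           st.integers(-5, 5))
    @settings(max_examples=50, deadline=None)
    def test_rank_correlations_affine_invariant(self, values, scale, shift):
        # integer-valued responses and power-of-two scales keep the affine
        # transform exact in floating point
        r = np.asarray(values, dtype=float)
        if np.ptp(r) == 0:
            return
        layer = ra.probe_rdm(np.sort(r) + np.arange(len(r)) * 1e-6)
        if layer.is_degenerate:
            return
        rho1 = ra.rdm_spearman(ra.probe_rdm(r), layer)
        rho2 = ra.rdm_spearman(ra.probe_rdm(scale * r + shift), layer)
        assert rho1 == pytest.approx(rho2, abs=1e-12)


class TestRdmSpearman:
    def test_self_correlation_is_one(self, rng):
        rdm = ra.probe_rdm(rng.standard_normal(10))
        assert ra.rdm_spearman(rdm, rdm) == pytest.approx(1.0)

    def test_monotone_transform_invariant(self, rng):
        a = ra.probe_rdm(rng.standard_normal(10))
        b = ra.RDM(matrix=a.matrix**2, metric="absdiff")
        c = ra.probe_rdm(rng.standard_normal(10))
        assert ra.rdm_spearman(a, c) == pytest.approx(
            ra.rdm_spearman(b, c), abs=1e-12)

    def test_matches_brute_force_oracle_on_fixed_pair(self):
        """4x4 RDMs with uppers (1..6) and (2,1,3,4,6,5)."""
        from scipy.spatial.distance import squareform

        a = ra.RDM(matrix=squareform([1, 2, 3, 4, 5, 6.0]))
        b = ra.RDM(matrix=squareform([2, 1, 3, 4, 6, 5.0]))
        expected = oracles.brute_spearman([1, 2, 3, 4, 5, 6], [2, 1, 3, 4, 6, 5])
        assert ra.rdm_spearman(a, b) == pytest.approx(expected, abs=1e-12)

    def test_matches_brute_force_oracle_random_pairs(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 9))
            a = ra.probe_rdm(rng.standard_normal(n))
            b = ra.probe_rdm(rng.standard_normal(n))
            expected = oracles.brute_spearman(list(a.upper()), list(b.upper()))
            assert ra.rdm_spearman(a, b) == pytest.approx(expected, abs=1e-12)

    def test_degenerate_input_is_an_error_not_zero(self):
        good = ra.probe_rdm([1.0, 2.0, 3.0])
        bad = ra.probe_rdm([1.0, 1.0, 1.0])
        with pytest.raises(ra.DegenerateRDMError):
            ra.rdm_spearman(good, bad)


class TestPermutationLayerTest:
    def test_perfect_probe_reaches_minimum_p(self, hierarchy, layer_bank):
        u = np.random.default_rng(1).standard_normal(
            hierarchy.activations[4].shape[1])
        r = hierarchy.activations[4] @ u
        rho, p, flags = ra.permutation_layer_test(
            r, layer_bank, n_perm=999, seed=2)
        assert p[4] == pytest.approx(1 / 1000)
        # with one more permutation the minimum p drops below alpha = 0.001
        _, p2, flags2 = ra.permutation_layer_test(
            r, layer_bank, n_perm=1000, seed=2)
        assert p2[4] == pytest.approx(1 / 1001)
        assert flags2[4]

    def test_joint_permutation_identity(self, rng):
        """Permuting responses and jointly permuting the RDM leave rho fixed."""
        r = rng.standard_normal(15)
        perm = rng.permutation(15)
        layer = ra.probe_rdm(rng.standard_normal(15))
        layer_p = ra.RDM(matrix=layer.matrix[np.ix_(perm, perm)], metric="absdiff")
        rho1 = ra.rdm_spearman(ra.probe_rdm(r), layer)
        rho2 = ra.rdm_spearman(ra.probe_rdm(r[perm]), layer_p)
        assert rho1 == pytest.approx(rho2, abs=1e-12)

    def test_null_flag_rate_bounded(self, layer_bank, rng):
        null = ra.simulate_null_responses(30, 100, seed=5)
        flags = []
        for i in range(null.n_probes):
            _, _, f = ra.permutation_layer_test(
                null.values[i], layer_bank, n_perm=1000, alpha=0.001,
                seed=int(rng.integers(2**31)))
            flags.append(f)
        assert np.mean(flags) <= 0.005

    def test_observed_rho_matches_scipy(self, layer_bank, rng):
        from scipy.stats import spearmanr

        r = rng.standard_normal(100)
        rho, _, _ = ra.permutation_layer_test(r, layer_bank, n_perm=99, seed=1)
        probe = ra.probe_rdm(r)
        for l, layer_rdm in enumerate(layer_bank.rdms):
            direct = spearmanr(probe.upper(), layer_rdm.upper()).statistic
            assert rho[l] == pytest.approx(direct, abs=1e-12)

    def test_monte_carlo_p_matches_full_enumeration(self):
        """For n=6 stimuli the exact null is all 720 permutations."""
        rng = np.random.default_rng(7)
        responses = list(rng.standard_normal(6))
        layer_vals = list(rng.standard_normal(6))
        layer_upper = oracles.upper_triangle_absdiff(layer_vals)
        exact = oracles.enumerate_permutation_p(responses, layer_upper)
        bank = _LayerRDMBank([ra.probe_rdm(layer_vals)])
        n_perm = 4000
        _, p, _ = ra.permutation_layer_test(responses, bank, n_perm=n_perm, seed=8)
        se = oracles.monte_carlo_se(exact, n_perm)
        assert abs(p[0] - exact) <= 3 * se + 2 / n_perm

    def test_empirical_p_never_zero(self, layer_bank, rng):
        r = rng.standard_normal(100)
        _, p, _ = ra.permutation_layer_test(r, layer_bank, n_perm=200, seed=3)
        assert (p > 0).all() and (p <= 1).all()


class TestMapProbes:
    def test_planted_layer_recovered(self):
        """At the full 250-stimulus study scale, high-snr probes almost
        always have their own planted layer among the flagged layers."""
        hierarchy = ra.make_layer_hierarchy(n_stimuli=250, seed=11)
        bank = _LayerRDMBank.from_layers(hierarchy)
        plan, truth = ra.make_probe_plan(DIAGONAL_MAP, probes_per_area=6,
                                         snr=10.0, seed=12)
        responses = ra.simulate_band_responses(hierarchy, plan, seed=13)
        mapping = ra.map_probes(responses, bank, plan, n_perm=1000,
                                alpha=0.001, seed=14)
        hits = 0
        for pid, grp in mapping.table.groupby("probe_id"):
            sig = grp[grp["significant"]]
            if len(sig) and truth.probe_targets[pid] in set(sig["layer"]):
                hits += 1
        assert hits >= 0.9 * plan.n_probes

    def test_null_probes_rarely_flagged(self, layer_bank):
        null = ra.simulate_null_responses(30, 100, seed=9)
        m = ra.map_probes(null, layer_bank, {p: "17" for p in null.probe_ids},
                          n_perm=1000, alpha=0.001, seed=10)
        assert m.table["significant"].mean() <= 0.005

    def test_deterministic_under_master_seed(self, planted, layer_bank):
        plan, _, resp = planted
        small = ra.ResponseMatrix(values=resp.values[:5],
                                  probe_ids=list(resp.probe_ids)[:5])
        m1 = ra.map_probes(small, layer_bank, plan, n_perm=200, seed=42)
        m2 = ra.map_probes(small, layer_bank, plan, n_perm=200, seed=42)
        pd.testing.assert_frame_equal(m1.table, m2.table)

    def test_degenerate_probe_recorded(self, layer_bank):
        vals = np.vstack([np.ones(100), np.random.default_rng(1).standard_normal(100)])
        rm = ra.ResponseMatrix(values=vals, probe_ids=["flat", "ok"])
        m = ra.map_probes(rm, layer_bank, {"flat": "17", "ok": "17"},
                          n_perm=200, seed=1)
        assert m.degenerate_probes == ["flat"]
        flat_rows = m.table[m.table["probe_id"] == "flat"]
        assert not flat_rows["significant"].any()

    def test_masked_stimuli_excluded(self, layer_bank, hierarchy):
        rng = np.random.default_rng(3)
        u = rng.standard_normal(hierarchy.activations[2].shape[1])
        r = hierarchy.activations[2] @ u
        r_masked = r.copy()
        r_masked[:5] = np.nan
        rm = ra.ResponseMatrix(values=r_masked[None, :], probe_ids=["p"])
        m = ra.map_probes(rm, layer_bank, {"p": "18"}, n_perm=1000, seed=4)
        sig = m.table[m.table["significant"]]
        assert 2 in set(sig["layer"])


class TestAggregateAreaLayer:
    def _mapping(self, rows):
        df = pd.DataFrame(rows, columns=["probe_id", "area", "layer", "rho",
                                         "p", "significant"])
        return ra.ProbeMapping(table=df, layer_names=[f"l{i}" for i in range(9)])

    def test_single_probe_single_cell(self):
        m = self._mapping([("a", "19", 4, 0.5, 0.0005, True),
                           ("a", "19", 1, 0.1, 0.5, False)])
        agg = ra.aggregate_area_layer(m)
        assert agg.scores.loc["19", 4] == pytest.approx(0.5)
        assert agg.scores.loc["19"].drop(4).eq(0).all()

    def test_two_probes_averaged(self):
        m = self._mapping([("a", "18", 2, 0.4, 0.0005, True),
                           ("b", "18", 2, 0.6, 0.0005, True)])
        agg = ra.aggregate_area_layer(m)
        assert agg.scores.loc["18", 2] == pytest.approx(0.5)

    def test_multi_layer_probe_counts_once_in_denominator(self):
        """Hand-worked: probe d significant at layers 1 and 3, probe e at 1."""
        m = self._mapping([
            ("d", "17", 1, 0.2, 0.0005, True),
            ("d", "17", 3, 0.4, 0.0005, True),
            ("e", "17", 1, 0.3, 0.0005, True),
        ])
        agg = ra.aggregate_area_layer(m)
        assert agg.scores.loc["17", 1] == pytest.approx((0.2 + 0.3) / 2)
        assert agg.scores.loc["17", 3] == pytest.approx(0.4 / 2)
        assert agg.probes_significant["17"] == 2

    def test_area_without_significance_is_zero_row(self):
        m = self._mapping([("a", "20", 5, 0.3, 0.5, False)])
        agg = ra.aggregate_area_layer(m)
        assert agg.scores.loc["20"].eq(0).all()
        assert agg.probes_significant["20"] == 0

    def test_planted_diagonal_pattern(self, planted, planted_mapping):
        _, truth, _ = planted
        agg = ra.aggregate_area_layer(planted_mapping)
        for area, layer in truth.area_layer_map.items():
            assert agg.scores.loc[area].idxmax() == layer

    def test_responsive_normalization_option(self):
        m = self._mapping([
            ("a", "18", 2, 0.4, 0.0005, True),
            ("b", "18", 2, 0.2, 0.5, False),
        ])
        sig = ra.aggregate_area_layer(m, normalization="significant")
        resp = ra.aggregate_area_layer(m, normalization="responsive")
        assert sig.scores.loc["18", 2] == pytest.approx(0.4)
        assert resp.scores.loc["18", 2] == pytest.approx(0.2)
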