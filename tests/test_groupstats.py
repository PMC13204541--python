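import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

import oracles
from hdbn.groupstats import (assign_bins, bh_adjust, compare_network_params,
                             edge_ttest, edgewise_compare, enumerate_pairs,
                             log_transform, pooled_ttest, region_streamline_compare,
                             zero_filter)
from hdbn.simulate import SimulationConfig, simulate_cohort


class TestPairEnumeration:
    @pytest.mark.parametrize("n,expected", [(36, 630), (2, 1), (5, 10)])
    def test_pair_counts(self, n, expected):
        pairs = enumerate_pairs(n)
        assert len(pairs) == expected
        assert pairs == sorted(pairs)  # lexicographic
        assert len(set(pairs)) == len(pairs)

    def test_too_few_regions(self):
        with pytest.raises(ValueError):
            enumerate_pairs(1)


class TestZeroFilter:
    @pytest.mark.parametrize("values,included,frac", [
        ([0, 0, 0, 7], False, 0.75),
        ([0, 0, 5, 7], True, 0.5),   # exactly half zero is kept
        ([1, 2, 3], True, 0.0),
    ])
    def test_exclusion_rule(self, values, included, frac):
        inc, f = zero_filter(values)
        assert inc is included
        assert f == pytest.approx(frac)


class TestLogTransform:
    def test_pseudocount(self):
        assert log_transform(0) == 0.0
        assert log_transform(np.e - 1) == pytest.approx(1.0)
        assert np.allclose(log_transform([0, 9]), [0.0, np.log(10)])

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            log_transform([-1, 2])


class TestEdgeTTest:
    def test_hand_computed_pooled_t(self):
        t, df, p, sign = edge_ttest([0, 1, 2], [3, 4, 5])
        assert t == pytest.approx(-3.674, abs=1e-3)
        assert df == 4
        assert p == pytest.approx(0.0213, abs=2e-4)
        assert sign == +1

    def test_matches_textbook_oracle(self, rng):
        for _ in range(20):
            x = rng.normal(0, 1, 8)
            y = rng.normal(0.3, 1.2, 12)
            t, df, p, _ = edge_ttest(x, y)
            t0, df0, p0 = oracles.bf_pooled_t(x, y)
            assert t == pytest.approx(t0, abs=1e-10)
            assert df == df0
            assert p == pytest.approx(p0, abs=1e-12)

    def test_identical_samples(self):
        t, df, p, sign = edge_ttest([2, 2, 2], [2, 2, 2])
        assert p == 1.0 and sign == 0

    def test_label_swap_antisymmetry(self, rng):
        x, y = rng.normal(0, 1, 8), rng.normal(1, 1, 12)
        t1, _, p1, s1 = edge_ttest(x, y)
        t2, _, p2, s2 = edge_ttest(y, x)
        assert t2 == pytest.approx(-t1)
        assert p2 == pytest.approx(p1)
        assert s2 == -s1

    def test_degenerate_zero_variance_distinct_means(self):
        r = pooled_ttest([1, 1, 1], [2, 2, 2])
        assert r.degenerate
        assert r.p == np.finfo(float).tiny
        assert r.sign == +1


class TestBHAdjust:
    def test_hand_stepup_example(self):
        adj, _ = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_identity(self):
        adj, disc = bh_adjust([0.05])
        assert adj[0] == 0.05
        assert disc[0]  # discovery at adjusted <= q

    def test_adjusted_never_below_raw(self, rng):
        p = rng.uniform(1e-6, 1, 50)
        adj, _ = bh_adjust(p)
        assert (adj >= p - 1e-15).all()
        assert (adj <= 1.0).all()

    def test_matches_reference_implementation(self, rng):
        for _ in range(100):
            p = rng.uniform(1e-12, 1, int(rng.integers(1, 60)))
            adj, disc = bh_adjust(p)
            rej, expected, *_ = multipletests(p, 0.05, "fdr_bh")
            assert np.allclose(adj, expected, atol=1e-12)
            assert np.array_equal(disc, rej)

    def test_matches_bruteforce_oracle(self, rng):
        p = rng.uniform(0, 1, 25)
        adj, _ = bh_adjust(p)
        assert np.allclose(adj, oracles.bf_bh(list(p)), atol=1e-12)

    def test_empty_input(self):
        adj, disc = bh_adjust([])
        assert adj.size == 0 and disc.size == 0


class TestBins:
    def test_text_convention_partition(self):
        p = np.array([0.002, 0.03, 0.2, np.nan])
        bins = assign_bins(p)
        assert list(bins) == ["dark", "light", "none", "none"]


class TestEdgewisePipeline:
    def test_signed_matrix_symmetric_with_filtered_missing(self, small_cohort):
        res = edgewise_compare(small_cohort, "ipsilateral")
        v = res.matrix.values.to_numpy()
        assert np.allclose(v, v.T, equal_nan=True)
        excluded = ~res.table["included"]
        assert excluded.any()  # zero_prob makes some pairs all-zero
        assert res.table.loc[excluded, "p_adj"].isna().all()

    def test_planted_edge_recovered_with_positive_sign(self, small_cohort):
        res = edgewise_compare(small_cohort, "ipsilateral")
        tab = res.table
        stems = small_cohort.table.stems
        row = tab[(tab.region_a == stems[1]) & (tab.region_b == stems[5])]
        assert row["sign"].iloc[0] == +1

    def test_animal_order_invariance(self, small_cohort):
        import copy
        shuffled = copy.copy(small_cohort)
        shuffled.connectomes = list(reversed(small_cohort.connectomes))
        a = edgewise_compare(small_cohort, "ipsilateral").table
        b = edgewise_compare(shuffled, "ipsilateral").table
        pd.testing.assert_frame_equal(a, b)

    def test_all_filtered_raises(self, region_table):
        cfg = SimulationConfig(n_wt=2, n_ko=2, zero_prob=0.0, seed=0)
        cohort = simulate_cohort(cfg, with_diffusivity=False)
        for c in cohort.connectomes:
            c.counts[:] = 0.0
        with pytest.raises(ValueError, match="no testable pairs"):
            edgewise_compare(cohort, "ipsilateral")

    def test_uniform_count_scaling_leaves_t_nearly_unchanged(self):
        # scaling all animals' counts by c shifts log values by ~log c for
        # large counts, leaving the pooled t essentially unchanged
        cfg = SimulationConfig(n_wt=6, n_ko=6, baseline_log_mean=7.0,
                               zero_prob=0.0, seed=9)
        cohort = simulate_cohort(cfg, with_diffusivity=False)
        t1 = edgewise_compare(cohort, "ipsilateral").table["t"].to_numpy()
        for c in cohort.connectomes:
            c.counts = c.counts * 4.0
        t2 = edgewise_compare(cohort, "ipsilateral").table["t"].to_numpy()
        assert np.nanmax(np.abs(t1 - t2)) < 0.02


class TestRegionStreamlines:
    def test_totals_are_row_sums(self, small_cohort):
        c = small_cohort.connectomes[0]
        assert np.array_equal(c.region_totals(), c.counts.sum(axis=1))

    def test_null_cohort_few_discoveries(self):
        cfg = SimulationConfig(seed=11)
        cohort = simulate_cohort(cfg, with_diffusivity=False)
        tab = region_streamline_compare(cohort)
        assert len(tab) == 72
        assert tab["discovery"].mean() <= 0.1

    def test_region_wide_planted_effect_flagged(self):
        # triple every edge touching region 3 (both hemispheres) in KO animals
        cfg = SimulationConfig(seed=13, zero_prob=0.1)
        cohort = simulate_cohort(cfg, with_diffusivity=False)
        for c in cohort.connectomes:
            if c.group == "KO":
                for r in (3, 39):
                    c.counts[r, :] *= 3
                    c.counts[:, r] *= 3
                    c.counts[r, r] = 0
        tab = region_streamline_compare(cohort)
        assert bool(tab.loc[tab.region == cohort.table.abbreviations[3], "discovery"].iloc[0])


class TestNetworkParamComparison:
    @staticmethod
    def _frame(wt_vals, ko_vals, metric="density"):
        rows = []
        for i, v in enumerate(wt_vals):
            rows.append({"animal_id": f"WT{i}", "group": "WT", "provenance": "whole",
                         "metric": metric, "value": v})
        for i, v in enumerate(ko_vals):
            rows.append({"animal_id": f"KO{i}", "group": "KO", "provenance": "whole",
                         "metric": metric, "value": v})
        return pd.DataFrame(rows)

    def test_identical_groups_p_one(self):
        f = self._frame([1, 2, 3], [1, 2, 3])
        out = compare_network_params(f)
        assert out["p"].iloc[0] == 1.0

    def test_label_swap_flips_sign_only(self):
        f = self._frame([0.1, 0.2, 0.3], [0.4, 0.5, 0.6])
        g = self._frame([0.4, 0.5, 0.6], [0.1, 0.2, 0.3])
        a, b = compare_network_params(f), compare_network_params(g)
        assert a["sign"].iloc[0] == -b["sign"].iloc[0]
        assert a["p"].iloc[0] == pytest.approx(b["p"].iloc[0])

    def test_nan_values_dropped_and_counted(self):
        f = self._frame([0.1, 0.2, np.nan], [0.3, 0.4, 0.5])
        out = compare_network_params(f)
        assert out["n_dropped"].iloc[0] == 1
        assert out["testable"].iloc[0]

    def test_all_missing_not_testable(self):
        f = self._frame([np.nan] * 3, [0.3, 0.4, 0.5])
        out = compare_network_params(f)
        assert not out["testable"].iloc[0]
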