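"""Abundance filtering/normalization, differential hits, and enrichment."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from aggloscan import proteomics, synthetic


def table(rows: dict, columns=None):
    return pd.DataFrame.from_dict(rows, orient="index", columns=columns)


class TestFilterTable:
    def test_peptide_and_detection_criteria(self):
        ab = table(
            {
                "single_pep": [1, 2, 3, 4, 5, 6],
                "five_of_six": [1, 2, 3, 4, 5, np.nan],
                "four_of_six": [1, 2, 3, 4, np.nan, np.nan],
                "complete": [1, 2, 3, 4, 5, 6],
            }
        ).astype(float)
        pep = pd.Series({"single_pep": 1, "five_of_six": 3, "four_of_six": 5, "complete": 2})
        kept, report = proteomics.filter_table(ab, pep)
        assert set(kept.index) == {"five_of_six", "complete"}   # 5/6 = 83% passes 80%
        assert report["removed_peptides"] == 1
        assert report["removed_detection"] == 1

    def test_empty_result_warns(self):
        ab = table({"p": [1.0, np.nan, np.nan, np.nan]})
        with pytest.warns(UserWarning, match="all proteins"):
            kept, _ = proteomics.filter_table(ab, pd.Series({"p": 5}))
        assert kept.empty


class TestQuantileNormalize:
    def test_identical_columns_unchanged(self):
        ab = pd.DataFrame({"a": [1.0, 5.0, 9.0], "b": [1.0, 5.0, 9.0]})
        out = proteomics.quantile_normalize(ab)
        pd.testing.assert_frame_equal(out, ab)

    def test_hand_computed_two_column_case(self):
        ab = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0]})
        out = proteomics.quantile_normalize(ab)
        assert np.allclose(out["a"], [2.5, 3.5, 4.5])
        assert np.allclose(out["b"], [2.5, 3.5, 4.5])

    def test_single_column_is_identity(self):
        ab = pd.DataFrame({"a": [3.0, 1.0, 2.0]})
        pd.testing.assert_frame_equal(proteomics.quantile_normalize(ab), ab)

    def test_columns_share_sorted_values_when_complete(self):
        rng = np.random.default_rng(5)
        ab = pd.DataFrame(rng.lognormal(3, 1, size=(40, 4)), columns=list("abcd"))
        out = proteomics.quantile_normalize(ab)
        ref = np.sort(out["a"].to_numpy())
        for c in "bcd":
            assert np.allclose(np.sort(out[c].to_numpy()), ref)

    def test_missing_entries_stay_missing(self):
        ab = pd.DataFrame({"a": [1.0, np.nan, 3.0], "b": [4.0, 5.0, 6.0]})
        out = proteomics.quantile_normalize(ab)
        assert np.isnan(out.loc[1, "a"]) and out.notna().sum().sum() == 5


class TestImpute:
    def test_complete_table_is_identity(self):
        ab = pd.DataFrame({"a": [1.0, 2.0], "b": [3.0, 4.0]})
        pd.testing.assert_frame_equal(proteomics.impute(ab), ab)

    def test_half_min_definition(self):
        ab = pd.DataFrame([[10.0, np.nan, 12.0]], index=["p"], columns=list("abc"))
        out = proteomics.impute(ab, "half_min")
        assert out.loc["p", "b"] == 5.0

    def test_fully_missing_row_rejected(self):
        ab = pd.DataFrame([[np.nan, np.nan]], index=["p"], columns=list("ab"))
        with pytest.raises(ValueError, match="fully missing"):
            proteomics.impute(ab)

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="method"):
            proteomics.impute(pd.DataFrame({"a": [1.0]}), "magic")

    def test_knn_beats_half_min_on_missing_at_random(self):
        ab, pep, ann, truth = synthetic.simulate_abundance(
            150, 6, 0, 1.0, missing_rate=0.0, categories=2, seed=9, noise_sd_log2=0.2
        )
        rng = np.random.default_rng(10)
        mask = rng.random(ab.shape) < 0.10
        holed = ab.mask(mask)
        keep = ~holed.isna().all(axis=1)
        holed, ab_t, mask = holed[keep], ab[keep], mask[keep.to_numpy()]

        def rmse(imputed):
            truth_vals = np.log2(ab_t.to_numpy()[mask])
            got = np.log2(imputed.to_numpy()[mask])
            return np.sqrt(np.mean((truth_vals - got) ** 2))

        assert rmse(proteomics.impute(holed, "knn")) <= rmse(proteomics.impute(holed, "half_min"))


class TestDifferential:
    GROUPS = ([f"A{i}" for i in range(1, 7)], [f"B{i}" for i in range(1, 7)])

    def test_identical_groups_produce_no_hits(self):
        rng = np.random.default_rng(0)
        half = rng.lognormal(10, 1, size=(50, 6))
        ab = pd.DataFrame(np.hstack([half, half]), columns=self.GROUPS[0] + self.GROUPS[1])
        res = proteomics.differential(ab, *self.GROUPS)
        assert np.allclose(res.log2_fc, 0.0)
        assert not res.hit.any()

    def test_perfect_separation_single_protein(self):
        ab = pd.DataFrame([[2.0] * 3 + [2.0**8] * 3], index=["p"], columns=["A1", "A2", "A3", "B1", "B2", "B3"])
        res = proteomics.differential(ab, ["A1", "A2", "A3"], ["B1", "B2", "B3"])
        assert res.loc["p", "log2_fc"] == pytest.approx(-7.0)
        assert res.loc["p", "p"] < 0.05

    def test_group_size_validated(self):
        ab = pd.DataFrame({"A1": [1.0], "B1": [2.0], "B2": [3.0]})
        with pytest.raises(ValueError, match="group A"):
            proteomics.differential(ab, ["A1"], ["B1", "B2"])

    def test_spiked_fold_two_recovered_with_controlled_false_positives(self):
        ab, pep, ann, truth = synthetic.simulate_abundance(
            300, 6, 15, fold=2.0, missing_rate=0.0, categories=3, seed=12, noise_sd_log2=0.1
        )
        res = proteomics.differential(ab, *self.GROUPS)
        hits = proteomics.call_hits(res)
        assert truth["de_proteins"] <= hits
        nulls = set(ab.index) - truth["de_proteins"]
        assert len(hits & nulls) <= 0.05 * len(nulls)

    def test_null_type_one_error_control(self):
        """Under fold=1 the adjusted-hit fraction stays near the nominal rate."""
        fractions = []
        for seed in range(25):
            ab, *_ = synthetic.simulate_abundance(200, 4, 0, 1.0, 0.0, 2, seed=seed)
            groups = [c for c in ab if c[0] == "A"], [c for c in ab if c[0] == "B"]
            res = proteomics.differential(ab, *groups)
            fractions.append((res.p_adj < 0.05).mean())
        se = np.sqrt(0.05 * 0.95 / (200 * len(fractions)))
        assert np.mean(fractions) <= 0.05 + 3 * se


class TestCallHits:
    def _res(self, fc, p_adj, proteins=None):
        proteins = proteins or [f"p{i}" for i in range(len(fc))]
        return pd.DataFrame(dict(log2_fc=fc, p=p_adj, p_adj=p_adj), index=proteins)

    def test_exact_fold_boundary_is_not_a_hit(self):
        res = self._res([np.log2(1.68)], [0.001])
        assert proteomics.call_hits(res) == set()

    def test_fold_two_significant_is_a_hit(self):
        res = self._res([1.0], [0.04])
        assert proteomics.call_hits(res) == {"p0"}

    def test_downregulation_counts_in_magnitude(self):
        res = self._res([-1.0], [0.01])
        assert proteomics.call_hits(res) == {"p0"}

    def test_exclusive_rule_drops_shared_hits(self):
        a = self._res([1.0, 1.0], [0.01, 0.01], ["shared", "only_a"])
        b = self._res([1.0, 0.0], [0.01, 0.9], ["shared", "only_a"])
        only_a, only_b = proteomics.call_hits(a, b, exclusive=True)
        assert only_a == {"only_a"} and only_b == set()

    def test_exclusive_requires_both_tables(self):
        with pytest.raises(ValueError, match="both"):
            proteomics.call_hits(self._res([1.0], [0.01]), exclusive=True)


class TestBootstrapEnrichment:
    def _ann(self, membership):
        return pd.DataFrame(
            [{"protein": p, "category": c} for c, ps in membership.items() for p in ps]
        )

    def test_whole_universe_category_has_p_one(self):
        universe = [f"g{i}" for i in range(12)]
        hits = set(universe[:4])
        res = proteomics.bootstrap_enrichment(
            hits, universe, self._ann({"all": universe}), iterations=2000, seed=0
        )
        assert res[0].p == 1.0

    def test_zero_overlap_categories_untested(self):
        universe = [f"g{i}" for i in range(10)]
        res = proteomics.bootstrap_enrichment(
            {"g0"}, universe, self._ann({"other": ["g5", "g6"]}), iterations=2000, seed=0
        )
        assert res == []

    def test_hits_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="subset"):
            proteomics.bootstrap_enrichment({"x"}, ["a", "b"], self._ann({"c": ["a"]}), iterations=2000)

    def test_matches_exact_hypergeometric_enumeration(self):
        """N=20, K=5, n=4, k=3: p converges to the exhaustively enumerated
        upper tail = [C(5,3)C(15,1) + C(5,4)] / C(20,4)."""
        universe = [f"g{i}" for i in range(20)]
        category = universe[:5]
        hits = set(category[:3]) | {universe[19]}          # k = 3 of n = 4
        # independent oracle: enumerate all C(20,4) draws
        tail = sum(
            1 for draw in itertools.combinations(range(20), 4)
            if sum(i < 5 for i in draw) >= 3
        )
        p_exact = tail / 4845
        m = 40_000
        res = proteomics.bootstrap_enrichment(hits, universe, self._ann({"cat": category}), iterations=m, seed=3)
        (r,) = res
        assert r.n_hits_in_category == 3 and r.category_size == 5
        mc_se = np.sqrt(p_exact * (1 - p_exact) / m)
        assert abs(r.p - p_exact) <= 3 * mc_se
        # and the enumeration itself agrees with the library survival function
        assert p_exact == pytest.approx(stats.hypergeom.sf(2, 20, 5, 4))

    def test_unseen_exceedance_reports_upper_bound(self):
        universe = [f"g{i}" for i in range(25)]
        category = universe[:5]
        hits = set(category)  # all five: p is tiny, never resampled at m=2000
        res = proteomics.bootstrap_enrichment(hits, universe, self._ann({"cat": category}), iterations=2000, seed=1)
        (r,) = res
        assert r.p_is_upper_bound and r.p == 1.0 / 2000

    def test_low_iteration_warning(self):
        with pytest.warns(UserWarning, match="resolution"):
            proteomics.bootstrap_enrichment(
                {"a"}, ["a", "b", "c"], self._ann({"c1": ["a"]}), iterations=100, seed=0
            )


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert proteomics.bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_hand_step_up_case(self):
        assert np.allclose(proteomics.bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_all_ones_stay_one(self):
        assert np.allclose(proteomics.bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="\\[0, 1\\]"):
            proteomics.bh_adjust([0.5, 1.5])

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=2, max_size=20))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_monotone_in_raw_order(self, pvals):
        adj = proteomics.bh_adjust(pvals)
        order = np.argsort(pvals)
        assert np.all(np.diff(adj[order]) >= -1e-12)
        assert np.all((adj >= np.array(pvals) - 1e-12) & (adj <= 1.0))
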