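"""Total anticholinergic load and the Steel many-to-one rank test."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import ranksum_permutation_p, steel_maxt_exact
from aclpv.errors import ValidationError
from aclpv.tal import compute_tal, steel_test, summarize_groups, TalRecord
from conftest import make_profile


class TestComputeTal:
    def test_sums_distinct_scored_drugs(self, registry):
        p = make_profile(drugs=[("atropine", "suspect", "oral", 3),
                                ("loratadine", "concomitant", "oral", 1)])
        rec = compute_tal(p, registry)
        assert (rec.tal, rec.n_jars_drugs) == (4, 2)

    def test_same_drug_two_involvements_counted_once(self, registry):
        p = make_profile(drugs=[("atropine", "suspect", "oral", 3),
                                ("atropine", "concomitant", "oral", 3)])
        rec = compute_tal(p, registry)
        assert (rec.tal, rec.n_jars_drugs) == (3, 1)

    def test_all_involvements_contribute(self, registry):
        p = make_profile(drugs=[
            ("atropine", "suspect", "oral", 3),
            ("biperiden", "interaction", "oral", 3),
            ("amitriptyline", "concomitant", "oral", 2),
            ("loratadine", "concomitant", "transdermal", 1),
        ])
        assert compute_tal(p, registry).tal == 9

    def test_route_stratification_restricts_records(self, registry):
        p = make_profile(drugs=[("atropine", "suspect", "oral", 3),
                                ("loratadine", "concomitant",
                                 "transdermal", 1)])
        assert compute_tal(p, registry, route="oral").tal == 3
        assert compute_tal(p, registry, route="transdermal").tal == 1

    @settings(max_examples=40, derandomize=True)
    @given(st.lists(st.sampled_from(["atropine", "biperiden",
                                     "amitriptyline", "loratadine",
                                     "aspirin"]),
                    unique=True, max_size=5))
    def test_tal_decomposes_by_score(self, registry, names):
        p = make_profile(drugs=[(n, "concomitant", "oral",
                                 registry.score_of(n)) for n in names])
        rec = compute_tal(p, registry)
        scores = [registry.score_of(n) for n in names
                  if registry.score_of(n) is not None]
        assert rec.tal == (3 * scores.count(3) + 2 * scores.count(2)
                           + scores.count(1))
        assert rec.tal >= rec.n_jars_drugs
        assert (rec.tal == 0) == (rec.n_jars_drugs == 0)

    def test_adding_scored_drug_strictly_increases_tal(self, registry):
        base = make_profile(drugs=[("atropine", "suspect", "oral", 3)])
        more = make_profile(drugs=[("atropine", "suspect", "oral", 3),
                                   ("loratadine", "concomitant", "oral", 1)])
        assert compute_tal(more, registry).tal > compute_tal(base,
                                                             registry).tal


class TestSteelExact:
    def test_separated_samples_match_enumeration(self):
        # control {1,2,3} vs group {4,5,6}: C(6,3)=20 splits, the two
        # most extreme reach |z|max -> p = 2/20
        res = steel_test([[4, 5, 6]], [1, 2, 3], method="exact")
        assert res.p_adjusted[0] == pytest.approx(0.1)
        assert res.n_resamples == 20

    @pytest.mark.parametrize("groups,control", [
        ([[4.0, 5.0, 6.0]], [1.0, 2.0, 3.0]),
        ([[1.0, 3.0], [2.0, 2.0]], [2.0, 1.0, 4.0]),
        ([[5.0, 1.0, 2.0]], [2.0, 2.0, 3.0, 1.0]),
        ([[1.0, 1.0], [2.0, 3.0], [1.0, 4.0]], [2.0, 2.0]),
    ])
    def test_matches_independent_enumeration_oracle(self, groups, control):
        res = steel_test(groups, control, method="exact")
        p_adj, p_un, n_total = steel_maxt_exact(groups, control)
        assert res.n_resamples == n_total
        assert res.p_adjusted == pytest.approx(p_adj, abs=1e-12)
        assert res.p_unadjusted == pytest.approx(p_un, abs=1e-12)

    @pytest.mark.parametrize("group,control", [
        ([4.0, 5.0, 6.0], [1.0, 2.0, 3.0]),
        ([1.0, 2.0, 2.0], [2.0, 3.0, 1.0, 1.0]),
        ([2.5, 2.5], [1.0, 2.5, 4.0]),
    ])
    def test_single_group_reduces_to_ranksum_permutation(self, group,
                                                         control):
        """With k=1 the max-T adjustment is vacuous: the adjusted p is
        the two-sample permutation rank-sum p."""
        res = steel_test([group], control, method="exact")
        assert res.p_adjusted[0] == pytest.approx(
            ranksum_permutation_p(group, control), abs=1e-12
        )

    def test_all_identical_observations_give_p_one(self):
        res = steel_test([[2.0, 2.0], [2.0]], [2.0, 2.0, 2.0],
                         method="exact")
        assert np.all(res.p_adjusted == 1.0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            steel_test([[]], [1.0, 2.0])


class TestSteelProperties:
    def test_adjusted_dominates_unadjusted(self):
        rng = np.random.default_rng(4)
        groups = [rng.integers(0, 6, size=30).astype(float) for _ in range(3)]
        control = rng.integers(0, 6, size=50).astype(float)
        res = steel_test(groups, control, method="permutation",
                         n_permutations=500, seed=1)
        assert np.all(res.p_adjusted >= res.p_unadjusted - 1e-12)

    def test_invariant_under_monotone_transformation(self):
        rng = np.random.default_rng(2)
        groups = [rng.integers(0, 8, size=3).astype(float) for _ in range(2)]
        control = rng.integers(0, 8, size=4).astype(float)
        res_raw = steel_test(groups, control, method="exact")
        res_exp = steel_test([np.exp(g) for g in groups], np.exp(control),
                             method="exact")
        assert res_raw.p_adjusted == pytest.approx(res_exp.p_adjusted)

    def test_permutation_is_seed_deterministic(self):
        rng = np.random.default_rng(3)
        groups = [rng.normal(size=40)]
        control = rng.normal(size=60)
        a = steel_test(groups, control, method="permutation",
                       n_permutations=300, seed=11)
        b = steel_test(groups, control, method="permutation",
                       n_permutations=300, seed=11)
        assert np.array_equal(a.p_adjusted, b.p_adjusted)

    def test_normal_approximation_tracks_permutation(self):
        rng = np.random.default_rng(6)
        groups = [rng.normal(0.6, 1, 40), rng.normal(0, 1, 40)]
        control = rng.normal(size=60)
        perm = steel_test(groups, control, method="permutation",
                          n_permutations=4000, seed=0)
        norm = steel_test(groups, control, method="normal")
        assert perm.p_adjusted == pytest.approx(norm.p_adjusted, abs=0.05)


class TestSummaries:
    def _records(self, tals, label):
        return ([TalRecord(f"{label}{i}", t, max(1, t // 2))
                 for i, t in enumerate(tals)], [label] * len(tals))

    def test_group_mean_and_sd(self):
        recs, labels = self._records([4, 4, 4], "D")
        crecs, clabels = self._records([1, 2, 3], "OTHER")
        df = summarize_groups(recs + crecs, labels + clabels,
                              method="exact")
        row = df.set_index("group").loc["D"]
        assert row["tal_mean"] == 4.0
        assert row["tal_sd"] == 0.0

    def test_singleton_group_sd_absent(self):
        recs, labels = self._records([5], "B")
        crecs, clabels = self._records([1, 2, 4], "OTHER")
        df = summarize_groups(recs + crecs, labels + clabels, method="exact")
        assert np.isnan(df.set_index("group").loc["B", "tal_sd"])

    def test_groups_identical_to_control_give_large_p(self):
        rng = np.random.default_rng(9)
        vals = rng.integers(1, 7, size=60).astype(int)
        recs, labels = [], []
        for i, v in enumerate(vals):
            label = ["B", "C", "OTHER"][i % 3]
            recs.append(TalRecord(f"C{i}", int(v), 1))
            labels.append(label)
        df = summarize_groups(recs, labels, n_permutations=600, seed=2,
                              method="permutation")
        ps = df.set_index("group")["steel_p"]
        assert ps["B"] > 0.2 and ps["C"] > 0.2

    def test_shifted_group_detected(self):
        """A +1.5 TAL shift in one group at n=500/group is detected."""
        rng = np.random.default_rng(12)
        control = rng.poisson(3, 500)
        shifted = rng.poisson(3, 500) + 2  # integer-valued +2 shift
        same = rng.poisson(3, 500)
        recs, labels = [], []
        for arr, lab in ((control, "OTHER"), (shifted, "B"), (same, "C")):
            for i, v in enumerate(arr):
                recs.append(TalRecord(f"{lab}{i}", int(v), 1))
                labels.append(lab)
        df = summarize_groups(recs, labels, n_permutations=400, seed=3,
                              method="permutation")
        ps = df.set_index("group")["steel_p"]
        assert ps["B"] < 0.05
        assert ps["C"] > 0.05

    def test_drug_means_pooled_by_table_block(self):
        recs = [TalRecord("b1", 3, 1), TalRecord("b2", 3, 3),
                TalRecord("c1", 3, 2), TalRecord("o1", 2, 1),
                TalRecord("o2", 2, 1)]
        labels = ["B", "B", "C", "OTHER", "OTHER"]
        df = summarize_groups(recs, labels, method="exact").set_index("group")
        # single-category block pools B and C: (1+3+2)/3 = 2
        assert df.loc["B", "mean_jars_drugs"] == pytest.approx(2.0)
        assert df.loc["C", "mean_jars_drugs"] == pytest.approx(2.0)
        assert df.loc["OTHER", "mean_jars_drugs"] == pytest.approx(1.0)

    def test_empty_control_rejected(self):
        recs, labels = self._records([1, 2], "B")
        with pytest.raises(ValidationError):
            summarize_groups(recs, labels)
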