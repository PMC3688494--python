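import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2_contingency

from orgedit.differential import (DEPENDENT, EXCLUDED, INDEPENDENT,
                                  bonferroni_threshold, chisq_2x2,
                                  classify_silenced, classify_vs_wildtype,
                                  delta_ee, load_count_matrix,
                                  pool_replicates, replay_count_matrix,
                                  round_half_up, summarize_classification)


class TestPoolReplicates:
    def test_elementwise_sum(self):
        assert pool_replicates([(10, 90), (20, 80)]) == (30, 170)

    def test_single_replicate_unchanged(self):
        assert pool_replicates([(7, 3)]) == (7, 3)

    def test_order_invariance(self, rng):
        pairs = [tuple(rng.integers(0, 100, 2)) for _ in range(6)]
        perm = [pairs[i] for i in rng.permutation(6)]
        assert pool_replicates(pairs) == pool_replicates(perm)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pool_replicates([])


class TestChisq2x2:
    def test_identical_proportions_give_zero(self):
        t = chisq_2x2(100, 100, 200, 200)
        assert t.chisq == 0.0 and t.pvalue == 1.0

    def test_hand_computed_example(self):
        # expected cells 700/300/700/300
        t = chisq_2x2(500, 500, 900, 100)
        assert t.chisq == pytest.approx(380.952381, abs=1e-5)

    def test_zero_marginal_is_excluded_marker(self):
        assert chisq_2x2(0, 0, 10, 20).excluded
        assert chisq_2x2(0, 10, 0, 20).excluded

    def test_matches_scipy_pearson_on_random_tables(self, rng):
        for _ in range(1000):
            c1, t1, c2, t2 = (int(x) for x in rng.integers(1, 2000, 4))
            mine = chisq_2x2(c1, t1, c2, t2)
            ref_stat, ref_p, _, _ = chi2_contingency(
                [[c1, t1], [c2, t2]], correction=False)
            assert abs(mine.chisq - ref_stat) < 1e-9
            assert mine.pvalue == pytest.approx(ref_p, rel=1e-9)


class TestBonferroni:
    def test_mitochondrial_universe(self):
        assert f"{bonferroni_threshold(1e-3, 619):.1e}" == "1.6e-06"

    def test_plastid_universe(self):
        assert f"{bonferroni_threshold(1e-3, 37):.1e}" == "2.7e-05"

    def test_single_test_identity(self):
        assert bonferroni_threshold(0.05, 1) == 0.05

    def test_zero_tests_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(1e-3, 0)


class TestClassifyVsWildtype:
    NOMINAL = 1.6e-6

    def test_strong_relative_drop_at_poorly_edited_site(self):
        # wild-type extent 0.04, mutant 0.005 -> delta_EE 0.875; the low
        # absolute wild-type extent must not block a dependent call
        wt = (9600, 400)     # extent 0.04
        mut = (9950, 50)     # extent 0.005
        res = classify_vs_wildtype(wt, mut, self.NOMINAL)
        assert res.delta_ee == pytest.approx(0.875)
        assert res.klass == DEPENDENT

    def test_significant_but_small_delta_is_independent(self):
        wt = (100000, 100000)
        mut = (104000, 96000)  # extent 0.48, delta 0.04, p tiny
        res = classify_vs_wildtype(wt, mut, self.NOMINAL)
        assert res.test.pvalue < self.NOMINAL
        assert res.delta_ee < 0.1
        assert res.klass == INDEPENDENT

    def test_insignificant_large_delta_is_independent(self):
        wt = (90, 10)
        mut = (99, 1)  # delta 0.9 but underpowered at nominal 1.6e-6
        res = classify_vs_wildtype(wt, mut, self.NOMINAL)
        assert res.delta_ee >= 0.1
        assert res.test.pvalue > self.NOMINAL
        assert res.klass == INDEPENDENT

    def test_editing_increase_never_dependent(self):
        wt = (5000, 5000)
        mut = (2000, 8000)
        res = classify_vs_wildtype(wt, mut, self.NOMINAL)
        assert res.delta_ee < 0
        assert res.klass == INDEPENDENT

    def test_zero_wildtype_extent_excluded_with_reason(self):
        res = classify_vs_wildtype((5000, 0), (4000, 1000), self.NOMINAL)
        assert res.klass == EXCLUDED
        assert res.reason == "zero_wildtype_extent"
        assert res.delta_ee is None

    def test_raising_delta_cutoff_never_adds_dependents(self, rng):
        sites = [(tuple(rng.integers(1, 3000, 2)),
                  tuple(rng.integers(1, 3000, 2))) for _ in range(200)]
        for lo, hi in ((0.05, 0.1), (0.1, 0.3)):
            dep_lo = {i for i, (w, m) in enumerate(sites)
                      if classify_vs_wildtype(w, m, 1e-3, lo).klass
                      == DEPENDENT}
            dep_hi = {i for i, (w, m) in enumerate(sites)
                      if classify_vs_wildtype(w, m, 1e-3, hi).klass
                      == DEPENDENT}
            assert dep_hi <= dep_lo


class TestClassifySilenced:
    NOMINAL = 1.7e-6
    STRONG = (2000, 8000)    # extent 0.8
    REDUCED = (8000, 2000)   # extent 0.2

    def test_reduction_against_both_controls_is_dependent(self):
        res = classify_silenced(self.REDUCED, self.STRONG, self.STRONG,
                                self.NOMINAL)
        assert res.klass == DEPENDENT

    def test_reduction_against_one_control_only_is_independent(self):
        # sil 0.72 vs uninoc 0.80 passes the rule, but vs gfp 0.75 the
        # relative drop is only 0.04 -> not retained
        res = classify_silenced((2800, 7200), self.STRONG, (2500, 7500),
                                self.NOMINAL)
        assert res.klass == INDEPENDENT

    def test_gfp_control_itself_reduced_excludes_site(self):
        res = classify_silenced(self.REDUCED, self.STRONG, self.REDUCED,
                                self.NOMINAL)
        res2 = classify_silenced((1, 9999), self.STRONG, self.REDUCED,
                                 self.NOMINAL)
        assert res2.klass == EXCLUDED
        assert res2.reason == "gfp_control_reduced"

    def test_extents_anchored_on_uninoculated_control(self):
        res = classify_silenced(self.REDUCED, self.STRONG, (2500, 7500),
                                self.NOMINAL)
        assert res.wt_extent == pytest.approx(0.8)
        assert res.mut_extent == pytest.approx(0.2)


class TestSummaries:
    def _results(self, n_dep, n_indep, n_excl=0):
        out = []
        for i in range(n_dep):
            out.append(classify_vs_wildtype((1000, 9000), (9990, 10), 1e-3,
                                            site=i))
        for i in range(n_indep):
            out.append(classify_vs_wildtype((1000, 9000), (1000, 9000),
                                            1e-3, site=n_dep + i))
        for i in range(n_excl):
            out.append(classify_vs_wildtype((1000, 0), (1000, 10), 1e-3))
        return out

    def test_total_row_percentage(self):
        df = summarize_classification(self._results(468, 610 - 468), "all")
        assert df.loc[0, "dependent_pct"] == 77
        assert df.loc[0, "independent_pct"] == 23

    def test_mttb_style_percentage(self):
        df = summarize_classification(self._results(43, 1), "mttb")
        assert df.loc[0, "dependent_pct"] == 98

    def test_zero_dependent(self):
        df = summarize_classification(self._results(0, 10))
        assert df.loc[0, "dependent_pct"] == 0

    def test_excluded_reported_separately(self):
        df = summarize_classification(self._results(2, 3, 4))
        assert df.loc[0, "excluded"] == 4
        assert df.loc[0, "analyzed"] == 5

    def test_round_half_up(self):
        assert round_half_up(87.5) == 88
        assert round_half_up(87.49) == 87


class TestReplayCountMatrix:
    def _matrix(self):
        rows = []
        rng = np.random.default_rng(7)
        for i in range(30):
            wt_extent = rng.uniform(0.3, 0.95)
            dependent = i < 12
            mut_extent = wt_extent * (0.2 if dependent else 1.0)
            row = {"site": f"s{i}", "organelle": "mitochondrial"}
            for lib, extent in (("m1", mut_extent), ("m2", mut_extent),
                                ("w1", wt_extent), ("w2", wt_extent)):
                t = int(round(4000 * extent))
                row[f"{lib}_C"] = 4000 - t
                row[f"{lib}_T"] = t
            rows.append(row)
        return pd.DataFrame(rows)

    def test_replay_recovers_planted_classification(self):
        comparisons = [{
            "genotype": "mut", "mutant_libraries": ["m1", "m2"],
            "wildtype_libraries": ["w1", "w2"],
        }]
        results = replay_count_matrix(self._matrix(), comparisons)
        labels = {r.site: r.klass for r in results["mut"]}
        assert sum(v == DEPENDENT for v in labels.values()) == 12
        assert all(labels[f"s{i}"] == DEPENDENT for i in range(12))

    def test_pooling_equals_summed_counts(self):
        df = self._matrix()
        res_split = replay_count_matrix(df, [{
            "genotype": "g", "mutant_libraries": ["m1", "m2"],
            "wildtype_libraries": ["w1", "w2"]}])["g"]
        pooled = df.copy()
        pooled["mp_C"] = pooled["m1_C"] + pooled["m2_C"]
        pooled["mp_T"] = pooled["m1_T"] + pooled["m2_T"]
        pooled["wp_C"] = pooled["w1_C"] + pooled["w2_C"]
        pooled["wp_T"] = pooled["w1_T"] + pooled["w2_T"]
        res_pooled = replay_count_matrix(pooled, [{
            "genotype": "g", "mutant_libraries": ["mp"],
            "wildtype_libraries": ["wp"]}])["g"]
        for a, b in zip(res_split, res_pooled):
            assert a.klass == b.klass
            assert a.test.chisq == pytest.approx(b.test.chisq)

    def test_count_matrix_io(self, tmp_path):
        df = self._matrix()
        df.to_csv(tmp_path / "m.tsv", sep="\t", index=False)
        back = load_count_matrix(tmp_path / "m.tsv")
        pd.testing.assert_frame_equal(back, df)


class TestNullCalibration:
    def test_null_simulation_yields_no_dependent_calls(self, rng):
        # equal true editing in both genotypes at 619 sites, depth 5000:
        # expected dependent calls at the Bonferroni threshold < 1
        nominal = bonferroni_threshold(1e-3, 619)
        n_dep = 0
        for _ in range(619):
            theta = rng.uniform(0.05, 0.95)
            wt_t = rng.binomial(5000, theta)
            mut_t = rng.binomial(5000, theta)
            res = classify_vs_wildtype((5000 - wt_t, wt_t),
                                       (5000 - mut_t, mut_t), nominal)
            n_dep += res.klass == DEPENDENT
        assert n_dep == 0
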