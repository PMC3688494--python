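import math

import numpy as np
import pytest

from orgedit.error_model import MismatchRateTable, estimate_mismatch_rates
from orgedit.formats_io import PileupColumn, Template, TemplateSet
from orgedit.simulator import simulate_site_counts
from orgedit.site_caller import (SiteCall, UndefinedExtentError,
                                 annotate_silent, call_counts_batch,
                                 call_editing_site, call_sample,
                                 editing_extent, select_candidates,
                                 site_log_likelihood)

from conftest import make_column


class TestSiteLogLikelihood:
    def test_theta_zero_collapses_to_null(self, uniform_rates):
        col = make_column({"C": 900, "T": 100})
        expected = (900 * math.log(uniform_rates.pooled_rate("C", "C"))
                    + 100 * math.log(uniform_rates.pooled_rate("C", "T")))
        assert site_log_likelihood(col, uniform_rates, 0.0) == \
            pytest.approx(expected, rel=1e-12)

    def test_theta_one_collapses_to_edited(self, uniform_rates):
        col = make_column({"C": 900, "T": 100})
        expected = (900 * math.log(uniform_rates.pooled_rate("T", "C"))
                    + 100 * math.log(uniform_rates.pooled_rate("T", "T")))
        assert site_log_likelihood(col, uniform_rates, 1.0) == \
            pytest.approx(expected, rel=1e-12)

    def test_matches_binomial_mixture_closed_form(self, symmetric_ct_rates):
        col = make_column({"C": 900, "T": 100})
        r = symmetric_ct_rates
        theta = 0.1
        expected = (
            900 * math.log((1 - theta) * r.pooled_rate("C", "C")
                           + theta * r.pooled_rate("T", "C"))
            + 100 * math.log((1 - theta) * r.pooled_rate("C", "T")
                             + theta * r.pooled_rate("T", "T"))
        )
        assert site_log_likelihood(col, r, theta) == \
            pytest.approx(expected, rel=1e-12)

    def test_empty_column_is_zero(self, uniform_rates):
        col = PileupColumn("t", 1, "C")
        assert site_log_likelihood(col, uniform_rates, 0.3) == 0.0

    def test_ambiguous_bases_are_ignored(self, uniform_rates):
        col = make_column({"C": 500, "T": 50})
        col_n = make_column({"C": 500, "T": 50})
        col_n.add(1, "N", 20)
        assert site_log_likelihood(col, uniform_rates, 0.2) == \
            site_log_likelihood(col_n, uniform_rates, 0.2)


class TestCallEditingSite:
    def test_no_t_reads_is_null_call(self, uniform_rates):
        call = call_editing_site(make_column({"C": 5000}), uniform_rates)
        assert (call.theta_hat, call.lrt, call.pvalue) == (0.0, 0.0, 1.0)

    def test_error_free_limit_equals_count_fraction(self):
        rates = MismatchRateTable.uniform({})  # zero error, pseudocount 0
        call = call_editing_site(make_column({"C": 900, "T": 100}), rates)
        assert call.theta_hat == pytest.approx(0.100, abs=1e-6)
        assert call.t_fraction == pytest.approx(0.1)

    def test_mle_matches_closed_form_and_grid_oracle(self,
                                                     symmetric_ct_rates):
        eps = 1e-3
        col = make_column({"C": 9900, "T": 100})
        call = call_editing_site(col, symmetric_ct_rates)
        closed = (0.01 - eps) / (1 - 2 * eps)
        assert call.theta_hat == pytest.approx(closed, abs=1e-6)
        # grid-search oracle to 4 significant digits
        grid = np.linspace(0.0, 1.0, 1000001)
        lls = [site_log_likelihood(col, symmetric_ct_rates, t)
               for t in (0.0, closed)]
        # dense grid around the optimum
        local = np.linspace(closed - 1e-3, closed + 1e-3, 20001)
        ll_local = [
            sum(n * math.log((1 - t) * symmetric_ct_rates.pooled_rate("C", o)
                             + t * symmetric_ct_rates.pooled_rate("T", o))
                for o, n in (("C", 9900), ("T", 100)))
            for t in local
        ]
        grid_best = local[int(np.argmax(ll_local))]
        assert call.theta_hat == pytest.approx(grid_best, abs=1e-5)
        lrt_oracle = 2 * (max(ll_local) - lls[0])
        assert call.lrt == pytest.approx(lrt_oracle, rel=1e-4)

    def test_uncovered_column_flagged(self, uniform_rates):
        call = call_editing_site(PileupColumn("t", 1, "C"), uniform_rates)
        assert not call.covered and call.pvalue == 1.0

    def test_lrt_nonnegative_and_pvalue_monotone(self, uniform_rates, rng):
        calls = []
        for t_count in (0, 3, 10, 40, 150):
            calls.append(call_editing_site(
                make_column({"C": 5000 - t_count, "T": t_count}),
                uniform_rates))
        assert all(c.lrt >= 0 for c in calls)
        lrts = [c.lrt for c in calls]
        pvals = [c.pvalue for c in calls]
        assert lrts == sorted(lrts)
        assert pvals == sorted(pvals, reverse=True)

    def test_batch_caller_agrees_with_single_site_path(self, uniform_rates,
                                                       rng):
        counts = simulate_site_counts(20, 3000, 0.05, 1e-3, rng)
        th, lrt, p = call_counts_batch(counts, uniform_rates)
        for k, row in enumerate(counts):
            col = make_column(dict(zip("ACGT", (int(x) for x in row))))
            call = call_editing_site(col, uniform_rates)
            assert call.theta_hat == pytest.approx(th[k], abs=1e-6)
            assert call.lrt == pytest.approx(lrt[k], rel=1e-6, abs=1e-6)

    def test_power_nondecreasing_in_depth(self, uniform_rates, rng):
        detection = []
        for depth in (200, 1000, 5000):
            counts = simulate_site_counts(200, depth, 0.03, 1e-3, rng)
            _, _, p = call_counts_batch(counts, uniform_rates)
            detection.append((p < 1e-6).mean())
        assert detection == sorted(detection)


class TestCallSampleAndSelection:
    def _call(self, site, lib, pvalue, t_fraction=0.2, depth=1000):
        t = int(round(t_fraction * depth))
        return SiteCall(site[0], site[1], lib, depth - t, t, 0,
                        theta_hat=t_fraction, lrt=1.0, pvalue=pvalue)

    def test_significance_is_strictly_less_than_alpha(self, uniform_rates):
        pileup = {
            ("t", 1): make_column({"C": 4000, "T": 1000}, position=1),
            ("t", 2): make_column({"C": 5000}, position=2),
        }
        calls, sig = call_sample(pileup, uniform_rates, "lib")
        assert ("t", 1) in sig and ("t", 2) not in sig

    def test_exact_alpha_boundary_not_significant(self):
        calls_by_site = {
            ("t", 1): {"a": self._call(("t", 1), "a", pvalue=1e-6)},
            ("t", 2): {"a": self._call(("t", 2), "a", pvalue=0.99e-6)},
        }
        cand = select_candidates(calls_by_site, ["a"])
        assert ("t", 2) in cand.union and ("t", 1) not in cand.union

    def test_fraction_and_depth_filters_are_strict(self):
        calls_by_site = {
            ("t", 1): {"a": self._call(("t", 1), "a", 1e-9,
                                       t_fraction=0.04)},
            ("t", 2): {"a": self._call(("t", 2), "a", 1e-9, depth=100)},
            ("t", 3): {"a": self._call(("t", 3), "a", 1e-9, depth=101)},
        }
        cand = select_candidates(calls_by_site, ["a"])
        assert ("t", 1) not in cand.final  # max fraction 0.04 <= 0.05
        assert ("t", 2) not in cand.final  # mean depth exactly 100
        assert ("t", 3) in cand.final

    def test_mean_depth_runs_over_all_libraries(self):
        # depth 300 in one of three libraries -> mean 100, excluded
        calls_by_site = {("t", 1): {"a": self._call(("t", 1), "a", 1e-9,
                                                    depth=300)}}
        cand = select_candidates(calls_by_site, ["a", "b", "c"])
        assert ("t", 1) not in cand.final

    def test_empty_library_set_rejected(self):
        with pytest.raises(ValueError):
            select_candidates({}, [])


class TestEditingExtent:
    def test_reported_low_extent_site(self):
        # 117 edited transcripts among 12290
        assert editing_extent(12290 - 117, 117) == pytest.approx(0.009520,
                                                                 abs=5e-7)

    def test_boundaries(self):
        assert editing_extent(0, 50) == 1.0
        assert editing_extent(50, 0) == 0.0

    def test_zero_denominator_raises(self):
        with pytest.raises(UndefinedExtentError):
            editing_extent(0, 0)


class TestAnnotateSilent:
    def _template(self, seq, cds_start=1, cds_end=None):
        return Template(id="t", seq=seq, cds_start=cds_start,
                        cds_end=cds_end or len(seq))

    def test_third_position_pro_codon_is_silent(self):
        t = self._template("CCC")
        assert annotate_silent(t, 3) == "silent"

    def test_first_position_leu_to_phe_is_non_silent(self):
        t = self._template("CTT")
        assert annotate_silent(t, 1) == "non_silent"

    def test_utr_site_is_non_coding(self):
        t = self._template("CCCAAACCC", cds_start=4, cds_end=6)
        assert annotate_silent(t, 1) == "non_coding"
        t2 = Template(id="t", seq="CCC")
        assert annotate_silent(t2, 1) == "non_coding"

    def test_non_c_position_rejected(self):
        with pytest.raises(ValueError):
            annotate_silent(self._template("ACT"), 1)
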