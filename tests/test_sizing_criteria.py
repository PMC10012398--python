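"""The three sample-size criteria, their aggregation and mitigations."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.optimize import brentq
from scipy.stats import chi2, norm

from mnlr_samplesize import (
    OutcomeDistribution,
    PairwiseEvidence,
    RsqEstimates,
    SizingConfig,
    UnattainableShrinkageError,
    binary_shrinkage_size,
    criterion_i,
    criterion_i_heuristic_direct,
    criterion_ii,
    criterion_iii,
    epv_size,
    final_size,
    merge_categories,
)
from conftest import WORKED_PAIR_N, WORKED_PAIRWISE_R2


class TestBinaryShrinkageSize:
    def test_worked_pair_value(self):
        # Q=17, S=0.9, R2=0.497; frozen from an independent arithmetic evaluation
        assert binary_shrinkage_size(17, 0.9, 0.497) == pytest.approx(
            211.5854, abs=1e-3
        )

    def test_diverges_as_s_approaches_one(self):
        sizes = [binary_shrinkage_size(17, s, 0.2) for s in (0.9, 0.99, 0.999)]
        assert sizes[0] < sizes[1] < sizes[2]
        assert sizes[2] > 100 * sizes[0]

    @given(
        st.integers(1, 50),
        st.floats(0.5, 0.99),
        st.floats(0.01, 0.45),
    )
    def test_bisection_inverse_recovers_target_shrinkage(self, q, s, r2):
        """Solving the formula numerically for S at the returned m gives S back."""
        m = binary_shrinkage_size(q, s, r2)

        def f(s_try):
            return binary_shrinkage_size(q, s_try, r2) - m

        recovered = brentq(f, r2 + 1e-9, 1 - 1e-9, xtol=1e-12)
        assert recovered == pytest.approx(s, abs=1e-6)

    @given(
        st.integers(1, 50),
        st.floats(0.6, 0.95),
        st.floats(0.01, 0.5),
    )
    def test_monotonicity(self, q, s, r2):
        if r2 >= s - 0.02:
            return
        m = binary_shrinkage_size(q, s, r2)
        assert binary_shrinkage_size(q + 1, s, r2) > m
        assert binary_shrinkage_size(q, s + 0.01, r2) > m
        assert binary_shrinkage_size(q, s, r2 + 0.005) < m

    def test_unattainable_shrinkage_rejected(self):
        with pytest.raises(UnattainableShrinkageError):
            binary_shrinkage_size(10, 0.5, 0.6)


class TestCriterionI:
    def test_worked_example_pair_41(self, worked_dist, worked_cfg):
        res = criterion_i(
            worked_dist, PairwiseEvidence(r2=WORKED_PAIRWISE_R2), worked_cfg
        )
        assert res.per_pair_n[(4, 1)] == 246

    def test_worked_example_grid_within_one_percent(self, worked_dist, worked_cfg):
        """3-d.p. R² inputs reproduce the published grid to ~1% and the
        binding pair is {5,3} (the published values used unrounded R²)."""
        res = criterion_i(
            worked_dist, PairwiseEvidence(r2=WORKED_PAIRWISE_R2), worked_cfg
        )
        for pair, published in WORKED_PAIR_N.items():
            assert abs(res.per_pair_n[pair] - published) / published < 0.01
        assert res.binding == (5, 3)
        assert res.n == res.per_pair_n[(5, 3)]

    def test_k2_reduces_to_binary_formula(self):
        dist = OutcomeDistribution((300, 200))
        cfg = SizingConfig(Q=10)
        res = criterion_i(dist, PairwiseEvidence(r2={(2, 1): 0.2}), cfg)
        assert res.n == math.ceil(binary_shrinkage_size(10, 0.9, 0.2) - 1e-9)

    def test_missing_pairs_listed(self, worked_dist, worked_cfg):
        partial = {(2, 1): 0.116}
        with pytest.raises(ValueError, match=r"\(5, 4\)"):
            criterion_i(worked_dist, PairwiseEvidence(r2=partial), worked_cfg)

    def test_unattainable_pair_named(self, worked_dist):
        bad = dict(WORKED_PAIRWISE_R2)
        bad[(5, 3)] = 0.95
        with pytest.raises(ValueError, match=r"\(5,3\)|maximum"):
            criterion_i(worked_dist, PairwiseEvidence(r2=bad), SizingConfig(Q=17))

    def test_pair_relaxation_moves_binding_pair(self, worked_dist, worked_cfg):
        """Relaxing the binding pair's shrinkage target to 0.8 never raises
        any pairwise size and moves the binding pair to {3,2}."""
        base = criterion_i(
            worked_dist, PairwiseEvidence(r2=WORKED_PAIRWISE_R2), worked_cfg
        )
        relaxed_cfg = SizingConfig(Q=17, s_target_overrides={(5, 3): 0.8})
        relaxed = criterion_i(
            worked_dist, PairwiseEvidence(r2=WORKED_PAIRWISE_R2), relaxed_cfg
        )
        for pair in WORKED_PAIRWISE_R2:
            assert relaxed.per_pair_n[pair] <= base.per_pair_n[pair]
        assert relaxed.per_pair_n[(5, 3)] < base.per_pair_n[(5, 3)]
        assert relaxed.binding == (3, 2)


class TestHeuristicDirect:
    def test_worked_example_value_and_warning(self, worked_dist, worked_cfg):
        overall = RsqEstimates(r2_cs_adj=0.126, max_r2_cs=0.841)
        with pytest.warns(UserWarning, match="not necessarily"):
            n = criterion_i_heuristic_direct(worked_dist, overall, worked_cfg)
        # frozen from independent arithmetic: 68 / (0.1 * ln(1 - 0.14)) = 4508.6
        assert n == 4509

    def test_smaller_than_pairwise_criterion(self, worked_dist, worked_cfg):
        """The rejected direct approach understates the pairwise requirement."""
        overall = RsqEstimates(r2_cs_adj=0.126, max_r2_cs=0.841)
        with pytest.warns(UserWarning):
            n_direct = criterion_i_heuristic_direct(worked_dist, overall, worked_cfg)
        n_pairwise = criterion_i(
            worked_dist, PairwiseEvidence(r2=WORKED_PAIRWISE_R2), worked_cfg
        ).n
        assert n_direct < n_pairwise

    def test_k2_reduces_to_binary(self):
        dist = OutcomeDistribution((100, 100))
        cfg = SizingConfig(Q=5)
        with pytest.warns(UserWarning):
            n = criterion_i_heuristic_direct(
                dist, RsqEstimates(r2_cs_adj=0.2, max_r2_cs=0.75), cfg
            )
        assert n == math.ceil(binary_shrinkage_size(5, 0.9, 0.2) - 1e-9)


class TestCriterionII:
    def test_worked_example_printed_inputs(self, worked_cfg):
        """At the 3-d.p. inputs the unrounded bound is 1477.08, so the
        smallest integer satisfying it is 1478 (>= the published 1477)."""
        res = criterion_ii(
            5, worked_cfg, RsqEstimates(r2_cs_adj=0.126, max_r2_cs=0.841)
        )
        assert res.n == 1478
        assert res.n >= 1477

    def test_smallest_integer_semantics(self, worked_cfg):
        r2, mx, d, K, Q = 0.126, 0.841, 0.05, 5, 17
        res = criterion_ii(K, worked_cfg, RsqEstimates(r2_cs_adj=r2, max_r2_cs=mx))
        s_bound = r2 / (r2 + d * mx)
        raw = (K - 1) * Q / ((s_bound - 1) * math.log(1 - r2 - d * mx))
        assert res.n >= raw
        assert res.n - 1 < raw

    @pytest.mark.parametrize("mx", [0.3, 0.6, 0.841, 0.95])
    def test_fallback_inputs_imply_shrinkage_bound_075(self, mx):
        """With R² = 0.15·max and delta = 0.05 the implied shrinkage bound is
        0.75 for any max, so criterion (ii) equals the shrinkage formula at
        S = 0.75."""
        r2 = 0.15 * mx
        cfg = SizingConfig(Q=17)
        res = criterion_ii(5, cfg, RsqEstimates(r2_cs_adj=r2, max_r2_cs=mx))
        assert r2 / (r2 + 0.05 * mx) == pytest.approx(0.75, abs=1e-12)
        expected = 4 * 17 / ((0.75 - 1) * math.log(1 - r2 / 0.75))
        assert res.n == math.ceil(expected - 1e-9)

    def test_k2_reduces_to_binary_form(self):
        cfg = SizingConfig(Q=10)
        res = criterion_ii(2, cfg, RsqEstimates(r2_cs_adj=0.2, max_r2_cs=0.75))
        s_bound = 0.2 / (0.2 + 0.05 * 0.75)
        expected = 10 / ((s_bound - 1) * math.log(1 - 0.2 - 0.05 * 0.75))
        assert res.n == math.ceil(expected - 1e-9)

    def test_degenerate_inputs_rejected(self, worked_cfg):
        with pytest.raises(ValueError, match=">= 1"):
            criterion_ii(
                3, worked_cfg, RsqEstimates(r2_cs_adj=0.97, max_r2_cs=0.98)
            )


class TestCriterionIII:
    def test_worked_example_categories(self, worked_dist, worked_cfg):
        res = criterion_iii(worked_dist, worked_cfg)
        assert res.per_category_n == {1: 524, 2: 134, 3: 127, 4: 307, 5: 88}
        assert res.n == 524
        assert res.binding == 1

    def test_balanced_proportion_is_worst_case(self):
        cfg = SizingConfig(Q=1)
        n_half = criterion_iii(OutcomeDistribution((500, 500)), cfg).n
        for counts in ((300, 700), (100, 900), (650, 350)):
            assert criterion_iii(OutcomeDistribution(counts), cfg).n <= n_half

    def test_pointwise_escape_hatch_uses_normal_quantile(self):
        dist = OutcomeDistribution((300, 700))
        point = criterion_iii(dist, SizingConfig(Q=1, pointwise=True))
        mult = norm.ppf(0.975) ** 2
        expected = math.ceil(mult * 0.3 * 0.7 / 0.05**2 - 1e-9)
        assert point.per_category_n[1] == expected
        # simultaneous chi-squared construction is more conservative
        simul = criterion_iii(dist, SizingConfig(Q=1))
        assert simul.n > point.n

    def test_chi_squared_quantile_matches_printed_constant(self):
        assert chi2.ppf(1 - 0.05 / 5, df=1) == pytest.approx(6.635, abs=5e-4)


class TestFinalSizeAndEpv:
    def test_worked_example_binding_criterion_is_pairwise(
        self, worked_dist, worked_cfg
    ):
        ci = criterion_i(
            worked_dist, PairwiseEvidence(r2=WORKED_PAIRWISE_R2), worked_cfg
        )
        cii = criterion_ii(
            5, worked_cfg, RsqEstimates(r2_cs_adj=0.126, max_r2_cs=0.841)
        )
        ciii = criterion_iii(worked_dist, worked_cfg)
        report = final_size(ci, cii, ciii, worked_dist)
        assert report.binding_criterion == "i"
        assert report.final_n == ci.n
        assert sum(report.expected_counts) == report.final_n

    def test_small_pairwise_requirement_yields_precision_binding(self):
        dist = OutcomeDistribution((500, 500))
        cfg = SizingConfig(Q=1)
        ci = criterion_i(dist, PairwiseEvidence(r2={(2, 1): 0.5}), cfg)
        cii = criterion_ii(2, cfg, RsqEstimates(r2_cs_adj=0.5, max_r2_cs=0.75))
        ciii = criterion_iii(dist, cfg)
        report = final_size(ci, cii, ciii, dist)
        assert report.final_n == max(ci.n, cii.n, ciii.n)
        assert report.final_n == ciii.n
        assert report.binding_criterion == "iii"

    @pytest.mark.parametrize(
        "epv, q, counts, expected",
        [
            (10, 17, (2557, 186, 176, 467, 120), 4967),
            (20, 17, (2557, 186, 176, 467, 120), 9934),
            (10, 1, (100, 900), 100),  # ceil(10 * 1 / 0.1)
        ],
    )
    def test_epv_comparator(self, epv, q, counts, expected):
        assert epv_size(epv, q, OutcomeDistribution(counts)) == expected


class TestMergeCategories:
    def test_worked_example_merge(self, worked_dist):
        evidence = PairwiseEvidence(r2=WORKED_PAIRWISE_R2)
        merged, new_ev = merge_categories(worked_dist, evidence, [{3, 4}])
        assert merged.counts == (2557, 186, 643, 120)
        assert merged.K == 4
        # untouched pairs survive under relabelling (5 -> 4)
        assert new_ev.r2[(2, 1)] == WORKED_PAIRWISE_R2[(2, 1)]
        assert new_ev.r2[(4, 2)] == WORKED_PAIRWISE_R2[(5, 2)]
        # pairs touching merged categories must be re-supplied
        assert (3, 1) not in new_ev.r2
        assert len(new_ev.r2) == 3  # (2,1), (4,1)<-(5,1), (4,2)<-(5,2)

    def test_singleton_merge_is_identity(self, worked_dist):
        evidence = PairwiseEvidence(r2=WORKED_PAIRWISE_R2)
        merged, new_ev = merge_categories(worked_dist, evidence, [{2}])
        assert merged.counts == worked_dist.counts
        assert new_ev.r2 == dict(WORKED_PAIRWISE_R2)

    def test_cannot_merge_everything(self, worked_dist):
        with pytest.raises(ValueError, match="at least 2"):
            merge_categories(worked_dist, None, [{1, 2, 3, 4, 5}])

    def test_overlapping_sets_rejected(self, worked_dist):
        with pytest.raises(ValueError, match="more than one"):
            merge_categories(worked_dist, None, [{1, 2}, {2, 3}])


class TestMonotonicityBattery:
    """Criterion requirements move the right way in every input."""

    @given(
        st.integers(2, 40),
        st.floats(0.05, 0.4),
        st.floats(0.7, 0.95),
    )
    def test_criterion_i_monotone(self, q, r2, s):
        dist = OutcomeDistribution((300, 200, 100))
        ev = PairwiseEvidence(r2={(2, 1): r2, (3, 1): r2, (3, 2): r2})
        base = criterion_i(dist, ev, SizingConfig(Q=q, s_target=s))
        more_q = criterion_i(dist, ev, SizingConfig(Q=q + 1, s_target=s))
        assert more_q.n >= base.n
        better_r2 = PairwiseEvidence(
            r2={(2, 1): r2 + 0.05, (3, 1): r2 + 0.05, (3, 2): r2 + 0.05}
        )
        assert criterion_i(dist, better_r2, SizingConfig(Q=q, s_target=s)).n <= base.n

    @given(st.floats(0.05, 0.3), st.floats(0.02, 0.1))
    def test_criterion_ii_monotone_in_delta(self, r2, delta):
        est = RsqEstimates(r2_cs_adj=r2, max_r2_cs=0.8)
        tight = criterion_ii(3, SizingConfig(Q=10, delta_r2=delta), est)
        loose = criterion_ii(3, SizingConfig(Q=10, delta_r2=delta + 0.01), est)
        assert loose.n <= tight.n

    @given(st.floats(0.02, 0.1), st.floats(0.01, 0.2))
    def test_criterion_iii_monotone_in_delta_and_alpha(self, delta, alpha):
        dist = OutcomeDistribution((300, 200, 100))
        base = criterion_iii(dist, SizingConfig(Q=1, delta_precision=delta, alpha=alpha))
        looser = criterion_iii(
            dist, SizingConfig(Q=1, delta_precision=delta + 0.01, alpha=alpha)
        )
        assert looser.n <= base.n
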