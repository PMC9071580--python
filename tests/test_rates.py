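import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import lambertw

from lohscape.genome import GenomeLayout, segment_from_markers
from lohscape.rates import (
    CountTable,
    DrakeFluctuationModel,
    EstimatorConfig,
    RateEstimate,
    central_count,
    correct_detection,
    estimate_rate,
    frequency_from_counts,
    genome_extrapolate,
    segment_density,
    solve_drake,
)

N_PAPER = 2.2e7
S_PAPER = 1 / 200

TOY = GenomeLayout.from_records([("chrT", 1_000_000, 300_000)])
SEG = segment_from_markers(TOY, "chrT", 310_000, 610_000)  # d = 300 kb


def drake_bisect(f, N, iters=200):
    """Independent oracle: plain bisection on mu ln(N mu) - f over [e/N, f]."""
    lo, hi = math.e / N, f
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if mid * math.log(N * mid) - f > 0:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


class TestCentralCount:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ([2, 8], 4.0),
            ([0, 2, 8, 0], 2.0),
            ([0, 0, 0], 0.0),
            ([5, 5, 5], 5.0),
        ],
    )
    def test_examples(self, counts, expected):
        assert central_count(counts) == pytest.approx(expected)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            central_count([])

    @given(st.lists(st.integers(min_value=0, max_value=500), min_size=1, max_size=40))
    @settings(max_examples=100, deadline=None)
    def test_permutation_invariant_and_bounded(self, counts):
        c = central_count(counts)
        assert c == pytest.approx(central_count(sorted(counts)))
        assert 0 <= c <= max(counts) + 1e-9


class TestFrequency:
    def test_paper_scale_example(self):
        # C_hat back-derived from the printed f for the rDNA-bearing arm
        assert frequency_from_counts(81.4, N_PAPER, S_PAPER) == pytest.approx(
            7.4e-4, rel=1e-2
        )

    def test_zero_and_boundary(self):
        assert frequency_from_counts(0.0, N_PAPER, S_PAPER) == 0.0
        assert frequency_from_counts(N_PAPER * S_PAPER, N_PAPER, S_PAPER) == 1.0

    def test_subunit_plating_rejected(self):
        with pytest.raises(ValueError):
            frequency_from_counts(1.0, 10, 0.01)


class TestSolveDrake:
    def test_fixed_point_at_domain_edge(self):
        f = math.e / N_PAPER
        assert solve_drake(f, N_PAPER) == pytest.approx(f)

    @pytest.mark.parametrize("f", [7.8e-6, 7.4e-4])
    def test_matches_bisection_oracle_on_printed_inputs(self, f):
        mu = solve_drake(f, N_PAPER)
        assert abs(mu * math.log(N_PAPER * mu) - f) / f < 1e-9
        assert mu == pytest.approx(drake_bisect(f, N_PAPER), rel=1e-9)

    def test_derived_values(self):
        assert solve_drake(7.8e-6, N_PAPER) == pytest.approx(2.05e-6, rel=0.01)
        assert solve_drake(7.4e-4, N_PAPER) == pytest.approx(9.7e-5, rel=0.01)

    def test_nonpositive_frequency_is_nondetect_zero(self):
        assert solve_drake(0.0, N_PAPER) == 0.0
        assert solve_drake(-1.0, N_PAPER) == 0.0

    def test_below_domain_rejected(self):
        with pytest.raises(ValueError, match="Drake domain"):
            solve_drake(1e-8, N_PAPER)

    def test_residual_and_lambertw_agreement_over_domain(self, rng):
        # second independent oracle: mu = exp(W(N f)) / N on the W >= 1 branch
        Ns = 10 ** rng.uniform(5, 9, size=10_000)
        fs = np.exp(rng.uniform(np.log(np.e / Ns * 1.01), np.log(1e-2)))
        for N, f in zip(Ns, fs):
            mu = solve_drake(f, N)
            assert abs(mu * math.log(N * mu) - f) / f < 1e-9
            mu_w = float(np.exp(lambertw(N * f).real) / N)
            assert mu == pytest.approx(mu_w, rel=1e-9)


class TestEstimateRate:
    def test_all_zero_table_flagged(self):
        t = CountTable(counts=(0,) * 30, N=N_PAPER, s=S_PAPER)
        e = estimate_rate(t, EstimatorConfig(B=100, seed=1))
        assert e.nondetect and e.mu == 0.0
        assert (e.ci_low, e.ci_high) == (0.0, 0.0)
        assert e.upper_bound_zero == pytest.approx(3 / (30 * N_PAPER * S_PAPER))

    def test_identical_counts_give_zero_width_ci(self):
        t = CountTable(counts=(7,) * 20, N=N_PAPER, s=S_PAPER)
        e = estimate_rate(t, EstimatorConfig(B=500, seed=2))
        assert e.ci_low == pytest.approx(e.mu)
        assert e.ci_high == pytest.approx(e.mu)

    def test_seed_reproducible(self):
        t = CountTable(counts=(0, 1, 4, 9, 2, 0, 3, 7, 1, 5), N=N_PAPER, s=S_PAPER)
        e1 = estimate_rate(t, EstimatorConfig(B=200, seed=5))
        e2 = estimate_rate(t, EstimatorConfig(B=200, seed=5))
        assert (e1.mu, e1.ci_low, e1.ci_high) == (e2.mu, e2.ci_low, e2.ci_high)

    def test_monotone_in_counts(self):
        base = [0, 1, 4, 9, 2, 0, 3, 7, 1, 5]
        t0 = CountTable(counts=tuple(base), N=N_PAPER, s=S_PAPER)
        e0 = estimate_rate(t0, EstimatorConfig(B=1, seed=0))
        bumped = base.copy()
        bumped[3] += 10
        t1 = CountTable(counts=tuple(bumped), N=N_PAPER, s=S_PAPER)
        e1 = estimate_rate(t1, EstimatorConfig(B=1, seed=0))
        assert e1.mu >= e0.mu
        assert e1.f_hat >= e0.f_hat

    def test_replicate_order_irrelevant(self):
        counts = (0, 1, 4, 9, 2, 0, 3, 7, 1, 5)
        e1 = estimate_rate(CountTable(counts=counts, N=N_PAPER, s=S_PAPER),
                           EstimatorConfig(B=1, seed=0))
        e2 = estimate_rate(CountTable(counts=counts[::-1], N=N_PAPER, s=S_PAPER),
                           EstimatorConfig(B=1, seed=0))
        assert e1.mu == pytest.approx(e2.mu)


class TestCorrection:
    def test_doubles_rate_and_ci(self):
        e = RateEstimate(mu=1e-4, ci_low=1e-5, ci_high=3e-5 + 1e-4)
        c = correct_detection(e)
        assert c.mu == pytest.approx(2e-4)
        assert c.ci_low == pytest.approx(2e-5)
        assert c.corrected

    def test_double_correction_rejected(self):
        e = correct_detection(RateEstimate(mu=1e-4))
        with pytest.raises(ValueError, match="already"):
            correct_detection(e)


class TestDensityAndExtrapolation:
    def test_density_example(self):
        e = RateEstimate(mu=3e-5, ci_low=3e-5, ci_high=3e-5, segment=SEG)
        d = segment_density(e)
        assert d.mu == pytest.approx(1e-6)

    def test_zero_rate(self):
        e = RateEstimate(mu=0.0, ci_low=0.0, ci_high=0.0, segment=SEG)
        assert segment_density(e).mu == 0.0

    def test_halving_d_doubles_density(self):
        half = segment_from_markers(TOY, "chrT", 310_000, 460_000)
        e = RateEstimate(mu=3e-5, segment=SEG)
        assert segment_density(e, half).mu == pytest.approx(2 * segment_density(e).mu)

    def test_corrected_rate_rejected_for_density(self):
        e = correct_detection(RateEstimate(mu=3e-5, segment=SEG))
        with pytest.raises(ValueError, match="uncorrected"):
            segment_density(e)

    def test_extrapolation_paper_arithmetic(self):
        assert genome_extrapolate([5.53e-4], 0.453) == pytest.approx(1.22e-3, rel=5e-3)

    def test_full_coverage_is_identity(self):
        rates = [1e-5, 2e-5, 3e-5]
        assert genome_extrapolate(rates, 1.0) == pytest.approx(sum(rates))

    def test_uncorrected_estimates_rejected(self):
        with pytest.raises(ValueError, match="corrected"):
            genome_extrapolate([RateEstimate(mu=1e-5)], 0.5)


class TestModelFrontEnd:
    def test_fit_and_summary(self):
        m = DrakeFluctuationModel([0, 1, 4, 9, 2, 0, 3, 7, 1, 5], N=N_PAPER, s=S_PAPER,
                                  strain="BYxBY", segment=SEG)
        res = m.fit(B=200, seed=3)
        assert res.estimate.corrected
        assert res.conf_int[0] <= res.mu <= res.conf_int[1]
        text = res.summary()
        assert "x2 corrected" in text and "bootstrap CI" in text

    def test_uncorrected_fit_is_half(self):
        m = DrakeFluctuationModel([3, 5, 2, 8, 1, 4], N=N_PAPER, s=S_PAPER)
        r1 = m.fit(correct=False, B=50, seed=4)
        r2 = m.fit(correct=True, B=50, seed=4)
        assert r2.mu == pytest.approx(2 * r1.mu)
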