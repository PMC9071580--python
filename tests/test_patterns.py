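import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lohscape.patterns import (
    DensityRecord,
    build_density_records,
    distance_correlation,
    length_rank_correlation,
    stepwise_density_regression,
    strain_anova,
)


def make_records(densities, ranks):
    return [
        DensityRecord(
            segment_name=f"s{i}", strain="BYxBY", environment="SC", medium="FG",
            density=float(d), arm_length=int(1000 * r), length_rank=float(r),
        )
        for i, (d, r) in enumerate(zip(densities, ranks))
    ]


class TestLengthRankCorrelation:
    def test_perfectly_decreasing_gives_minus_one(self):
        recs = make_records([10, 8, 6, 4, 2], [1, 2, 3, 4, 5])
        r, p = length_rank_correlation(recs)
        assert r == pytest.approx(-1.0)

    def test_constant_density_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            length_rank_correlation(make_records([3, 3, 3], [1, 2, 3]))

    def test_matches_direct_covariance_formula(self, rng):
        dens = rng.random(20)
        ranks = rng.permutation(20) + 1
        recs = make_records(dens, ranks)
        r, _ = length_rank_correlation(recs)
        direct = float(
            np.cov(dens, ranks, bias=True)[0, 1] / (dens.std() * ranks.std())
        )
        assert r == pytest.approx(direct, abs=1e-12)

    def test_build_records_assigns_midranks(self, layout, panel32):
        dens = {s.name: 1.0 + i for i, s in enumerate(panel32)}
        recs = build_density_records(dens, panel32, layout)
        ranks = sorted(r.length_rank for r in recs)
        assert ranks[0] >= 1 and ranks[-1] <= len(recs)
        assert sum(ranks) == pytest.approx(len(recs) * (len(recs) + 1) / 2)


class TestDistanceCorrelation:
    def test_monotone_increasing_gives_plus_one(self):
        rates = [1, 2, 3, 5, 8]
        dist = [10, 20, 30, 40, 50]
        r, _ = distance_correlation(rates, dist, "telomere")
        assert r == pytest.approx(1.0)

    def test_reversing_distances_negates_rs(self, rng):
        rates = rng.random(15)
        dist = rng.random(15) * 1e5
        r1, _ = distance_correlation(rates, dist, "centromere")
        r2, _ = distance_correlation(rates, dist.max() - dist, "centromere")
        assert r2 == pytest.approx(-r1, abs=1e-12)

    def test_ties_agree_with_rank_then_pearson_oracle(self):
        rates = [1.0, 2.0, 2.0, 3.0, 5.0, 5.0, 7.0]
        dist = [3.0, 3.0, 10.0, 20.0, 20.0, 30.0, 40.0]
        r, _ = distance_correlation(rates, dist, "telomere")
        oracle = stats.pearsonr(stats.rankdata(rates), stats.rankdata(dist))[0]
        assert r == pytest.approx(float(oracle), abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            distance_correlation([1, 2], [1, 2, 3])

    def test_affine_transform_of_rates_invariant(self, rng):
        rates = rng.random(12)
        dist = rng.random(12)
        r1, _ = distance_correlation(rates, dist)
        r2, _ = distance_correlation(3.5 * rates + 1.0, dist)
        assert r1 == pytest.approx(r2, abs=1e-12)


class TestStepwiseRegression:
    def make_predictors(self, rng, n=32):
        return pd.DataFrame(
            {
                "ARS": rng.normal(size=n),
                "LTR_retrotransposon": rng.normal(size=n),
                "tRNA": rng.normal(size=n),
                "tandem_repeat": rng.normal(size=n),
                "meiotic_hotspot": rng.normal(size=n),
            }
        )

    def test_planted_signal_retained_with_sign(self, rng):
        X = self.make_predictors(rng)
        z = (X["ARS"] - X["ARS"].mean()) / X["ARS"].std(ddof=0)
        y = 2.0 * z + rng.normal(scale=0.01, size=len(X))
        res = stepwise_density_regression(y, X)
        assert "ARS" in res.selected
        assert res.signs["ARS"] == 1
        assert res.coefficients["ARS"] == pytest.approx(2.0, rel=0.05)
        # AIC may keep an occasional noise predictor, but only with a
        # negligible coefficient
        for other in res.selected:
            if other != "ARS":
                assert abs(res.coefficients[other]) < 0.05

    def test_null_response_full_model_rarely_significant(self):
        hits = 0
        for seed in range(100):
            r = np.random.default_rng(seed)
            X = self.make_predictors(r)
            y = r.normal(size=len(X))
            import statsmodels.api as sm

            fit = sm.OLS(y, sm.add_constant(X)).fit()
            hits += fit.f_pvalue < 0.05
        assert hits <= 10  # type-I control of the full-model F test

    def test_single_predictor_equals_simple_regression(self, rng):
        X = pd.DataFrame({"ARS": rng.normal(size=30)})
        y = 1.5 * X["ARS"].to_numpy() + rng.normal(scale=0.3, size=30)
        res = stepwise_density_regression(y, X, standardize=False)
        import statsmodels.api as sm

        simple = sm.OLS(y, sm.add_constant(X)).fit()
        if res.selected:  # AIC may drop a weak predictor; here it should not
            assert res.coefficients["ARS"] == pytest.approx(
                float(simple.params["ARS"]), rel=1e-9
            )

    def test_collinear_pair_dropped_with_warning(self, rng):
        X = self.make_predictors(rng)
        X["ARS_copy"] = X["ARS"] * 2.0
        y = rng.normal(size=len(X))
        with pytest.warns(UserWarning, match="collinear"):
            res = stepwise_density_regression(y, X)
        assert "ARS_copy" in res.dropped_collinear

    def test_intercept_equals_mean_response(self, rng):
        X = self.make_predictors(rng)
        y = rng.normal(loc=5.0, size=len(X))
        res = stepwise_density_regression(y, X)
        assert float(res.model.params["const"]) == pytest.approx(y.mean(), abs=1e-10)


class TestStrainAnova:
    def frame(self, values):
        rows = []
        for arm, by_strain in values.items():
            for strain, v in by_strain.items():
                rows.append({"arm": arm, "strain": strain, "rate": v})
        return pd.DataFrame(rows)

    def test_identical_strain_columns_give_null_strain_effect(self):
        df = self.frame(
            {f"a{i}": {"BY": v, "H1": v, "H2": v} for i, v in enumerate([1.0, 2.0, 4.0, 8.0])}
        )
        res = strain_anova(df, reference="BY")
        # identical columns: the strain factor explains nothing
        assert res.table.loc["C(strain)", "sum_sq"] == pytest.approx(0.0, abs=1e-10)
        assert (res.tukey["reject"] == False).all()  # noqa: E712

    def test_planted_strain_shift_detected(self, rng):
        arms = [f"a{i}" for i in range(16)]
        df = self.frame(
            {
                a: {
                    "BY": float(np.exp(rng.normal(0, 0.05))),
                    "H1": float(np.exp(rng.normal(0, 0.05))),
                    "H2": float(np.exp(rng.normal(2.0, 0.05))),
                }
                for a in arms
            }
        )
        res = strain_anova(df, reference="BY")
        assert res.table.loc["C(strain)", "PR(>F)"] < 1e-6
        h2 = res.reference_contrasts[
            (res.reference_contrasts["group1"] == "H2")
            | (res.reference_contrasts["group2"] == "H2")
        ]
        assert h2["reject"].all()

    def test_two_by_two_sums_of_squares_match_hand_arithmetic(self):
        # layout: arms {a,b} x strains {s,t}, y = [[1,3],[2,6]] (log off)
        df = self.frame({"a": {"s": 1.0, "t": 3.0}, "b": {"s": 2.0, "t": 6.0}})
        res = strain_anova(df, log_response=False)
        # grand mean 3; arm means 2,4; strain means 1.5,4.5
        # SS_arm = 2*((2-3)^2+(4-3)^2) = 4 ; SS_strain = 2*(1.5^2) * 2 = 9
        assert res.table.loc["C(arm)", "sum_sq"] == pytest.approx(4.0)
        assert res.table.loc["C(strain)", "sum_sq"] == pytest.approx(9.0)

    def test_missing_cell_named_in_error(self):
        df = self.frame({"a": {"s": 1.0, "t": 3.0}, "b": {"s": 2.0}})
        with pytest.raises(ValueError, match="missing arm x strain"):
            strain_anova(df)

    def test_log_response_requires_positive_rates(self):
        df = self.frame({"a": {"s": 0.0, "t": 3.0}, "b": {"s": 2.0, "t": 6.0}})
        with pytest.raises(ValueError, match="positive"):
            strain_anova(df)


class TestPanelSignRecovery:
    def test_simulated_positional_pattern_signs(self, layout, panel23):
        # generator-level property: with telomere amplification on, the
        # Spearman signs mirror the positional model
        import lohscape as L

        ok = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            tables, _ = L.simulate_genome_panel(
                layout, panel23, 1e-9, 3.0, 1e5, 0.5, 1e5, L.SimConfig(mu=0.0), r
            )
            rates = [
                L.estimate_rate(tables[s.name], L.EstimatorConfig(B=1, seed=0)).mu
                for s in panel23
            ]
            rt, _ = distance_correlation(rates, [s.dist_tel for s in panel23])
            rc, _ = distance_correlation(
                rates, [s.dist_cen for s in panel23], "centromere"
            )
            ok += (rt < 0) and (rc > 0)
        assert ok >= 19
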