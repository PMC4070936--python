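"""Point estimators, instrument strength and the IV-outcome association test."""

import math

import numpy as np
import pytest
from scipy.optimize import brentq
from scipy.stats import kstest

from ivcrr import (
    ConvergenceError,
    DegenerateDataError,
    DGPConfig,
    IVData,
    RatioIV,
    RiskRatioGMM,
    TwoStageRiskRatio,
    generate_dataset,
    instrument_strength,
    iv_outcome_association,
)
from ivcrr.estfun import mgmm_estfun


def binary_iv_dataset(seed=5, n=2000, gamma=0.5, beta0=-2.0, beta1=0.3):
    rng = np.random.default_rng(seed)
    g = rng.integers(0, 2, n).astype(float)
    x = gamma * g + rng.normal(0, 1, n)
    y = (rng.random(n) < np.minimum(np.exp(beta0 + beta1 * x), 1)).astype(int)
    return IVData(g, x, y)


class TestInstrumentStrength:
    def test_perfect_instrument(self):
        g = np.arange(10.0)
        s = instrument_strength(IVData(g, g, np.tile([0, 1], 5)))
        assert s.r2 == pytest.approx(1.0)
        assert math.isinf(s.f_stat)

    def test_matches_hand_ols(self):
        g = np.array([0.0, 1.0, 2.0])
        x = np.array([0.1, 0.8, 2.1])
        # closed-form simple regression: r2 = corr(g, x)^2
        r2_hand = float(np.corrcoef(g, x)[0, 1] ** 2)
        s = instrument_strength(IVData(g, x, np.array([0, 1, 0])))
        assert s.r2 == pytest.approx(r2_hand, rel=1e-12)
        assert s.f_stat == pytest.approx((3 - 2) * r2_hand / (1 - r2_hand), rel=1e-9)

    def test_f_r2_identity_on_simulated_data(self):
        ds = generate_dataset(DGPConfig(n=5_000, rho2=0.01, seed=2))
        s = instrument_strength(ds)
        assert s.f_stat == pytest.approx((ds.n - 2) * s.r2 / (1 - s.r2), rel=1e-10)

    def test_constant_instrument_rejected(self):
        with pytest.raises(DegenerateDataError):
            instrument_strength(IVData(np.ones(5), np.arange(5.0), np.tile([0, 1], 3)[:5]))

    def test_mean_f_near_noncentral_expectation(self):
        """Mean F over replicates tracks (n-2)(1+lambda)/(n-4) at rho2=0.01."""
        n, rho2 = 5_000, 0.01
        fs = [
            instrument_strength(
                generate_dataset(DGPConfig(n=n, rho2=rho2, seed=40_000 + r))
            ).f_stat
            for r in range(300)
        ]
        lam = n * rho2 / (1 - rho2)
        expected = (n - 2) * (1 + lam) / (n - 4)
        se = np.std(fs) / math.sqrt(len(fs))
        assert abs(np.mean(fs) - expected) < 4 * se


class TestGMMPointEstimate:
    @pytest.mark.parametrize("method", ["mgmm", "lgmm"])
    def test_strong_instrument_recovery(self, method, strong_dataset):
        res = RiskRatioGMM(strong_dataset, method).fit()
        assert res.multiplicity_flag == "UNIQUE"
        assert res.beta1 == pytest.approx(0.2, abs=0.05)
        assert res.crr == pytest.approx(math.exp(res.beta1), rel=1e-15)
        assert res.se is not None and 0 < res.se < 0.2
        lo, hi = res.crr_conf_int()
        assert lo <= res.crr <= hi

    def test_multiple_roots_reported_and_verified(self):
        # seed 0 at rho2 = 0.005, n = 5,000 has two roots (weak instrument)
        ds = generate_dataset(DGPConfig(n=5_000, rho2=0.005, seed=0))
        res = RiskRatioGMM(ds, "mgmm").fit()
        assert res.multiplicity_flag == "MULTIPLE"
        assert res.roots.size >= 2
        # the tabulated estimate is the smallest-magnitude root
        assert abs(res.beta1) == pytest.approx(min(abs(res.roots)))
        # verify every root against an independent bracketing oracle
        for r in res.roots:
            oracle = brentq(
                lambda b: mgmm_estfun(ds, b).value, r - 0.05, r + 0.05, xtol=1e-10
            )
            assert r == pytest.approx(oracle, abs=1e-6)

    def test_no_root_falls_back_to_objective_minimum(self):
        # seed 4 at rho2 = 0.005, n = 5,000 has no sign change
        ds = generate_dataset(DGPConfig(n=5_000, rho2=0.005, seed=4))
        res = RiskRatioGMM(ds, "mgmm").fit()
        assert res.multiplicity_flag == "NO_SOLUTION"
        assert res.objective_minimum is not None and res.objective_minimum > 0
        assert res.scan_result.grid[0] <= res.beta1 <= res.scan_result.grid[-1]

    def test_mgmm_and_lgmm_estimate_same_estimand(self):
        """With a strong instrument both methods' unique roots converge."""
        diffs = []
        for rep in range(11):
            ds = generate_dataset(DGPConfig(n=100_000, rho2=0.5, seed=80_000 + rep))
            rm = RiskRatioGMM(ds, "mgmm").fit()
            rl = RiskRatioGMM(ds, "lgmm").fit()
            assert rm.multiplicity_flag == rl.multiplicity_flag == "UNIQUE"
            diffs.append(abs(rm.beta1 - rl.beta1))
        assert np.median(diffs) < 0.02

    def test_summary_mentions_multiplicity(self):
        ds = generate_dataset(DGPConfig(n=5_000, rho2=0.005, seed=0))
        text = RiskRatioGMM(ds, "mgmm").fit().summary()
        assert "MULTIPLE" in text and "not trustworthy" in text


class TestTwoStageAndRatio:
    def test_binary_instrument_two_stage_equals_ratio(self):
        for seed in (5, 6, 7):
            ds = binary_iv_dataset(seed=seed)
            ts = TwoStageRiskRatio(ds).fit()
            ra = RatioIV(ds).fit()
            assert ts.beta1 == pytest.approx(ra.beta1, abs=1e-8)

    def test_null_exposure_effect_estimated_near_zero(self):
        rng = np.random.default_rng(21)
        n = 20_000
        g = rng.normal(0, 1, n)
        x = g + rng.normal(0, 1, n)
        y = (rng.random(n) < 0.05).astype(int)  # independent of g and x
        res = TwoStageRiskRatio(IVData(g, x, y)).fit()
        assert abs(res.beta1) < 3 * res.se

    def test_two_stage_unbiased_without_confounding(self):
        ests = []
        for rep in range(200):
            ds = generate_dataset(DGPConfig(n=50_000, rho2=0.1, seed=90_000 + rep))
            ests.append(TwoStageRiskRatio(ds).fit().beta1)
        assert np.mean(ests) == pytest.approx(0.2, abs=0.03)

    def test_ratio_with_unit_first_stage(self):
        rng = np.random.default_rng(31)
        n = 5_000
        g = rng.normal(0, 1, n)
        y = (rng.random(n) < np.minimum(np.exp(-2.5 + 0.3 * g), 1)).astype(int)
        res = RatioIV(IVData(g, g.copy(), y)).fit()
        # denominator slope is exactly 1, so ratio = reduced-form slope
        from ivcrr.glm import fit_log_binomial

        direct = fit_log_binomial(y, np.column_stack([np.ones(n), g])).params[1]
        assert res.beta1 == pytest.approx(direct, rel=1e-10)

    def test_ratio_saturated_binary_matches_hand_risk_ratio(self):
        """For binary g the log-link slope is ln of the risk ratio between arms."""
        ds = binary_iv_dataset(seed=11, n=4000)
        p1 = ds.y[ds.g == 1].mean()
        p0 = ds.y[ds.g == 0].mean()
        hand_num = math.log(p1 / p0)
        b_x = np.polyfit(ds.g, ds.x, 1)[0]
        res = RatioIV(ds).fit()
        assert res.beta1 == pytest.approx(hand_num / b_x, rel=1e-7)

    def test_ci_width_shrinks_with_sample_size(self):
        widths = []
        for n in (2_000, 20_000):
            ds = generate_dataset(DGPConfig(n=n, rho2=0.1, seed=55))
            lo, hi = RatioIV(ds).fit().conf_int()
            widths.append(hi - lo)
        assert widths[1] < widths[0]

    def test_weak_instrument_zero_denominator_rejected(self):
        rng = np.random.default_rng(77)
        n = 200
        g = np.tile([-1.0, 1.0], n // 2)
        x = np.full(n, 0.5)  # no exposure variation: denominator is zero
        y = (rng.random(n) < 0.3).astype(int)
        with pytest.raises(DegenerateDataError, match="weak"):
            RatioIV(IVData(g, x, y)).fit()


def test_log_binomial_matches_statsmodels_on_easy_data():
    """On well-behaved data our step-halving IRLS agrees with statsmodels'
    Binomial(log) GLM to high precision (params and standard errors)."""
    import warnings

    import statsmodels.api as sm
    from ivcrr.glm import fit_log_binomial

    ds = binary_iv_dataset(seed=5)
    X = np.column_stack([np.ones(ds.n), ds.g])
    ours = fit_log_binomial(ds.y, X)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ref = sm.GLM(
            np.asarray(ds.y, dtype=float), X,
            family=sm.families.Binomial(link=sm.families.links.Log()),
        ).fit()
    assert ours.params == pytest.approx(np.asarray(ref.params), rel=1e-6)
    assert ours.bse == pytest.approx(np.asarray(ref.bse), rel=1e-4)


class TestIVOutcomeAssociation:
    def test_type_one_error_p_values_uniform(self):
        """Under the null the Wald p-values are uniform (KS distance < 0.05)."""
        ps = []
        for rep in range(1000):
            rng = np.random.default_rng(10_000 + rep)
            g = rng.normal(0, 1, 2000)
            x = rng.normal(0, 1, 2000)
            y = (rng.random(2000) < 0.05).astype(int)
            ps.append(iv_outcome_association(IVData(g, x, y))[1])
        assert kstest(ps, "uniform").statistic < 0.05

    def test_power_against_strong_effect(self):
        hits = 0
        for rep in range(100):
            ds = generate_dataset(
                DGPConfig(n=30_000, rho2=0.1, beta0=-3.0, beta1=0.5, seed=500 + rep)
            )
            hits += iv_outcome_association(ds)[1] < 0.001
        assert hits >= 95

    def test_perfect_separation_surfaces_convergence_error(self):
        g = np.array([0.0, 0.0, 0.0, 1.0, 1.0, 1.0])
        y = np.array([0, 0, 0, 1, 1, 1])
        with pytest.raises(ConvergenceError):
            iv_outcome_association(IVData(g, g.copy(), y))
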