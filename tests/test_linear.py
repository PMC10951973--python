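"""Linear MR estimators: hand-computed oracles, simulations, invariances."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st

from stratmr import (SimConfig, egger, grs_associations, ivw, mr_presso,
                     ratio_estimate, simulate_summary_stats, weighted_median,
                     weighted_mode)
from stratmr.exceptions import (FitError, InvalidParameterError,
                                WeakInstrumentError)
from stratmr.linear import _weighted_median_point, _mode_bandwidth


def _stats(bx, by, sx=None, sy=None):
    bx = np.asarray(bx, float)
    return pd.DataFrame({
        "beta_x": bx,
        "se_x": sx if sx is not None else np.full_like(bx, 1e-8),
        "beta_y": np.asarray(by, float),
        "se_y": sy if sy is not None else np.full_like(bx, 0.01),
    })


class TestRatio:
    def test_division_and_ci(self):
        est = ratio_estimate(0.06, 0.01, 0.3, 0.0)
        assert est.theta == pytest.approx(0.2)
        assert est.ci_low < est.theta < est.ci_high
        assert est.or_per_unit == pytest.approx(np.exp(8 * 0.2))

    def test_second_order_reduces_to_first_when_se_zx_zero(self):
        first = ratio_estimate(0.06, 0.01, 0.3, 0.0, order="first")
        second = ratio_estimate(0.06, 0.01, 0.3, 0.0, order="second")
        assert first.se == pytest.approx(second.se)
        assert first.se == pytest.approx(0.01 / 0.3)

    def test_zero_instrument_rejected(self):
        with pytest.raises(WeakInstrumentError):
            ratio_estimate(0.1, 0.01, 0.0, 0.01)

    def test_equals_two_stage_least_squares(self):
        """With a continuous outcome the ratio of OLS coefficients is the
        2SLS estimator; check against the closed-form IV estimate."""
        rng = np.random.default_rng(8)
        n = 2_000
        z = rng.normal(0, 1, n)
        u = rng.normal(0, 1, n)
        x = 1.5 * z + u + rng.normal(0, 1, n)
        y = 0.7 * x + 2 * u + rng.normal(0, 1, n)
        Z = sm.add_constant(z)
        bzx = sm.OLS(x, Z).fit()
        bzy = sm.OLS(y, Z).fit()
        est = ratio_estimate(bzy.params[1], bzy.bse[1],
                             bzx.params[1], bzx.bse[1])
        zc = z - z.mean()
        iv = (zc @ y) / (zc @ x)            # single-instrument 2SLS
        assert est.theta == pytest.approx(iv, abs=1e-8)


class TestGRSAssociations:
    def test_deterministic_exposure_relation(self):
        rng = np.random.default_rng(0)
        n = 500
        g = rng.normal(0, 1, n)
        cohort = pd.DataFrame({
            "exposure": 2.0 * g,
            "outcome_all_cause": rng.integers(0, 2, n),
        })
        a = grs_associations(cohort, g, "all_cause")
        assert a.beta_zx == pytest.approx(2.0, abs=1e-10)
        assert a.se_zx == pytest.approx(0.0, abs=1e-8)

    def test_null_outcome_within_two_se(self):
        hits = 0
        reps = 30
        for r in range(reps):
            rng = np.random.default_rng(200 + r)
            n = 2_000
            g = rng.normal(0, 1, n)
            cohort = pd.DataFrame({
                "exposure": 10 + g + rng.normal(0, 3, n),
                "outcome_all_cause": rng.binomial(1, 0.1, n),
            })
            a = grs_associations(cohort, g, "all_cause")
            hits += abs(a.beta_zy) < 2 * a.se_zy
        assert hits >= 0.9 * reps

    def test_orthogonal_covariate_barely_moves_estimate(self):
        rng = np.random.default_rng(9)
        n = 5_000
        g = rng.normal(0, 1, n)
        cohort = pd.DataFrame({
            "exposure": 10 + 2 * g + rng.normal(0, 3, n),
            "outcome_all_cause": rng.binomial(1, 0.1, n),
            "noise_cov": rng.normal(0, 1, n),
        })
        a0 = grs_associations(cohort, g, "all_cause")
        a1 = grs_associations(cohort, g, "all_cause", covariates=["noise_cov"])
        assert abs(a1.beta_zx - a0.beta_zx) < 2 * a0.se_zx


class TestIVW:
    def test_equal_ratios_recovered(self):
        est = ivw(_stats([0.1, 0.2], [0.01, 0.02], sy=[0.01, 0.01]), "fixed")
        assert est.theta == pytest.approx(0.1)

    def test_single_variant_equals_ratio(self):
        s = _stats([0.3], [0.06], sx=[0.0 + 1e-12], sy=[0.01])
        est = ivw(s, "fixed", enforce_min=False)
        ref = ratio_estimate(0.06, 0.01, 0.3, 0.0)
        assert est.theta == pytest.approx(ref.theta, abs=1e-12)
        assert est.se == pytest.approx(ref.se, rel=1e-9)

    def test_matches_weighted_least_squares_oracle(self):
        rng = np.random.default_rng(3)
        s = _stats(rng.uniform(0.1, 0.5, 6),
                   rng.normal(0.02, 0.01, 6),
                   sy=rng.uniform(0.005, 0.02, 6))
        est = ivw(s, "random")
        wls = sm.WLS(s["beta_y"], s[["beta_x"]],
                     weights=1.0 / s["se_y"] ** 2).fit()
        assert est.theta == pytest.approx(wls.params.iloc[0], abs=1e-10)

    def test_minimum_variant_counts(self):
        s = _stats([0.1, 0.2], [0.01, 0.02])
        with pytest.raises(InvalidParameterError):
            ivw(s, "random")
        with pytest.raises(InvalidParameterError):
            ivw(s.iloc[:1], "fixed")

    def test_random_se_at_least_fixed(self):
        rng = np.random.default_rng(4)
        s = _stats(rng.uniform(0.1, 0.5, 8),
                   rng.normal(0.01, 0.02, 8),
                   sy=rng.uniform(0.005, 0.02, 8))
        assert ivw(s, "random").se >= ivw(s, "fixed").se - 1e-15


class TestEgger:
    def test_exact_interpolation(self):
        bx = np.array([0.1, 0.2, 0.3])
        by = 0.005 + 0.1 * bx
        est = egger(_stats(bx, by))
        assert est.theta == pytest.approx(0.1, abs=1e-10)
        assert est.extras["intercept"] == pytest.approx(0.005, abs=1e-10)

    def test_orientation_invariance(self):
        """Flipping a variant's allele coding must not change the fit."""
        bx = np.array([0.1, -0.2, 0.3, 0.25])
        by = 0.004 + 0.08 * bx
        a = egger(_stats(bx, by))
        flip = np.array([1, -1, 1, 1.0])
        b = egger(_stats(bx * flip, by * flip))
        assert a.theta == pytest.approx(b.theta, abs=1e-12)

    def test_balanced_pleiotropy_intercept_coverage(self):
        covered = 0
        reps = 60
        for r in range(reps):
            s = simulate_summary_stats(SimConfig(
                seed=5_000 + r, pleiotropy="balanced",
                pleiotropy_magnitude=0.004, pleiotropy_fraction=0.5))
            est = egger(s)
            half = 1.96 * est.extras["intercept_se"]
            covered += abs(est.extras["intercept"]) < half
        assert covered >= 0.85 * reps

    def test_directional_pleiotropy_detected_and_corrected(self):
        p_hits = 0
        err_egger, err_ivw = [], []
        reps = 40
        for r in range(reps):
            s = simulate_summary_stats(SimConfig(
                seed=6_000 + r, pleiotropy="directional",
                pleiotropy_magnitude=0.01, pleiotropy_fraction=1.0))
            e = egger(s)
            p_hits += e.extras["intercept_p"] < 0.05
            err_egger.append(abs(e.theta - 0.025))
            err_ivw.append(abs(ivw(s, "random").theta - 0.025))
        assert p_hits >= 0.8 * reps
        assert np.mean(err_egger) < np.mean(err_ivw)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(InvalidParameterError):
            egger(_stats([0.1, 0.2], [0.01, 0.02]))
        with pytest.raises(InvalidParameterError):
            egger(_stats([0.2, 0.2, 0.2], [0.01, 0.02, 0.03]))


class TestWeightedMedian:
    def test_middle_value_equal_weights(self):
        s = _stats([1.0, 1.0, 1.0], [0.1, 0.2, 0.3], sy=[0.1, 0.1, 0.1])
        est = weighted_median(s, n_boot=50, seed=1)
        assert est.theta == pytest.approx(0.2)

    def test_hand_computed_interpolation(self):
        """Ratios (.1,.2,.3), weights (.5,.25,.25): percentile points are
        (.25,.625,.875); interpolating to 0.5 between the first two gives
        0.1 + 0.1*(0.5-0.25)/(0.625-0.25)."""
        expected = 0.1 + 0.1 * (0.5 - 0.25) / (0.625 - 0.25)
        got = _weighted_median_point(np.array([0.1, 0.2, 0.3]),
                                     np.array([0.5, 0.25, 0.25]))
        assert got == pytest.approx(expected, abs=1e-12)

    def test_robust_to_minority_invalid_variants(self):
        """With <50% of weight on pleiotropic variants the median stays
        near theta while IVW is dragged away."""
        theta = 0.025
        med_ok = 0
        ivw_biased = 0
        reps = 40
        for r in range(reps):
            rng = np.random.default_rng(7_000 + r)
            j = 20
            bx = rng.uniform(0.35, 0.45, j)  # near-equal weights, so the
            sy = np.full(j, 0.002)           # invalid share stays < 50%
            by = theta * bx + rng.normal(0, sy)
            by[:4] += 0.02                  # 20% invalid, large bias
            s = _stats(bx, by, sx=np.full(j, 1e-6), sy=sy)
            m = weighted_median(s, n_boot=200, seed=r)
            med_ok += abs(m.theta - theta) < 2 * max(m.se, 1e-12)
            i = ivw(s, "fixed")
            ivw_biased += abs(i.theta - theta) > 2 * i.se
        assert med_ok >= 0.8 * reps
        assert ivw_biased >= 0.5 * reps

    def test_bootstrap_reproducible(self):
        s = _stats([0.2, 0.3, 0.4], [0.01, 0.02, 0.015])
        a = weighted_median(s, n_boot=200, seed=5)
        b = weighted_median(s, n_boot=200, seed=5)
        assert a.se == b.se


class TestWeightedMode:
    def test_point_mass(self):
        s = _stats([0.1, 0.2, 0.4], [0.1 * 0.3, 0.2 * 0.3, 0.4 * 0.3],
                   sy=[0.01, 0.01, 0.01])
        for bw in (0.3, 1.0, 3.0):
            est = weighted_mode(s, bandwidth_factor=bw, n_boot=20, seed=0)
            assert est.theta == pytest.approx(0.3, abs=1e-9)

    def test_majority_cluster_wins(self):
        bx = np.full(7, 0.4)
        ratios = np.array([0.19, 0.2, 0.2, 0.21, 0.2, 1.0, 1.0])
        s = _stats(bx, ratios * bx, sy=np.full(7, 0.01))
        est = weighted_mode(s, n_boot=50, seed=0)
        assert abs(est.theta - 0.2) < 0.05

    def test_matches_grid_argmax_oracle(self):
        rng = np.random.default_rng(11)
        bx = rng.uniform(0.2, 0.5, 12)
        by = 0.025 * bx + rng.normal(0, 0.004, 12)
        s = _stats(bx, by, sx=np.full(12, 1e-6), sy=np.full(12, 0.004))
        est = weighted_mode(s, n_boot=20, seed=0)
        # independent brute force over a fine grid
        r = s["beta_y"] / s["beta_x"]
        var = s["se_y"] ** 2 / s["beta_x"] ** 2 \
            + s["beta_y"] ** 2 * s["se_x"] ** 2 / s["beta_x"] ** 4
        w = (1.0 / var).to_numpy()
        w = w / w.sum()
        h = _mode_bandwidth(r.to_numpy(), 1.0)
        grid = np.linspace(r.min() - 3 * h, r.max() + 3 * h, 10_000)
        dens = (w[None, :]
                * np.exp(-0.5 * ((grid[:, None] - r.to_numpy()) / h) ** 2)
                ).sum(axis=1)
        oracle = grid[np.argmax(dens)]
        assert abs(est.theta - oracle) <= (grid[1] - grid[0])

    def test_zero_bandwidth_factor_rejected(self):
        s = _stats([0.2, 0.3, 0.4], [0.01, 0.02, 0.015])
        with pytest.raises(InvalidParameterError):
            weighted_mode(s, bandwidth_factor=0.0)


class TestPresso:
    def test_noiseless_collinear_global_p_one(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        s = _stats(bx, 0.025 * bx, sx=np.full(4, 1e-9), sy=np.full(4, 0.01))
        est = mr_presso(s, n_sim=200, seed=0)
        assert est.extras["global_p"] == pytest.approx(1.0)
        assert est.extras["outlier_indices"] == []

    def test_null_global_test_calibrated(self):
        hits = 0
        reps = 30
        for r in range(reps):
            s = simulate_summary_stats(SimConfig(seed=8_000 + r))
            est = mr_presso(s, n_sim=300, seed=r)
            hits += est.extras["global_p"] < 0.05
        assert hits / reps <= 0.2           # ~5% expected

    def test_planted_outlier_flagged_and_corrected(self):
        theta = 0.025
        good = 0
        reps = 25
        for r in range(reps):
            rng = np.random.default_rng(9_000 + r)
            j = 20                          # enough variants that the outlier
            bx = rng.uniform(0.2, 0.6, j)   # does not contaminate the rest
            sy = np.full(j, 0.004)
            by = theta * bx + rng.normal(0, sy)
            by[3] = 10 * theta * bx[3]      # gross outlier (ratio 10*theta)
            s = _stats(bx, by, sx=np.full(j, 1e-6), sy=sy)
            est = mr_presso(s, n_sim=400, seed=r)
            flagged = 3 in est.extras["outlier_indices"]
            closer = (abs(est.theta - theta)
                      < abs(est.extras["raw_theta"] - theta))
            good += flagged and closer
        assert good >= 0.9 * reps

    def test_too_few_variants_rejected(self):
        with pytest.raises(InvalidParameterError):
            mr_presso(_stats([0.1, 0.2, 0.3], [0.01, 0.02, 0.03]))


class TestInvariances:
    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(st.floats(min_value=0.1, max_value=10.0, allow_nan=False))
    def test_scale_equivariance(self, c):
        """Rescaling the exposure units divides every estimate by c."""
        rng = np.random.default_rng(12)
        bx = rng.uniform(0.2, 0.5, 8)
        by = 0.03 * bx + rng.normal(0, 0.003, 8)
        sx = np.full(8, 0.01)
        sy = np.full(8, 0.003)
        s1 = _stats(bx, by, sx=sx, sy=sy)
        s2 = _stats(bx * c, by, sx=sx * c, sy=sy)
        for fn in (lambda s: ivw(s, "random"), egger,
                   lambda s: weighted_median(s, n_boot=10, seed=0)):
            assert fn(s2).theta == pytest.approx(fn(s1).theta / c, rel=1e-6)

    def test_single_variant_method_agreement(self):
        """One variant: IVW reduces to the ratio estimate (Egger needs an
        intercept and is undefined)."""
        s = _stats([0.25], [0.01], sx=[1e-12], sy=[0.004])
        a = ivw(s, "fixed", enforce_min=False).theta
        b = ratio_estimate(0.01, 0.004, 0.25, 0.0).theta
        assert a == pytest.approx(b, abs=1e-12)
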