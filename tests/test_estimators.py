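"""MR estimators against hand arithmetic and independent numerical oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from mrpipe.estimators import (
    egger, ivw, or_ci, wald_ratio, weighted_median, weighted_mode,
    weighted_percentile,
)
from mrpipe.exceptions import ConfigError, EstimationError

from conftest import make_harmonized


def _random_hset(rng, J=8):
    bx = rng.normal(0, 0.3, J)
    bx[np.abs(bx) < 0.02] = 0.1  # keep instruments non-null
    by = rng.normal(0, 0.1, J)
    sx = rng.uniform(0.005, 0.05, J)
    sy = rng.uniform(0.01, 0.1, J)
    return make_harmonized(bx, by, sx, sy)


class TestWaldRatio:
    def test_hand_arithmetic(self):
        res = wald_ratio(bx=0.1, by=0.2, sx=0.01, sy=0.05)
        assert res.beta == pytest.approx(2.0)
        assert res.se == pytest.approx(0.5)

    def test_null_outcome_gives_or_one(self):
        res = wald_ratio(bx=0.1, by=0.0, sx=0.01, sy=0.05)
        assert res.beta == 0.0 and res.or_ == pytest.approx(1.0)

    def test_null_instrument_rejected(self):
        with pytest.raises(EstimationError, match="null instrument"):
            wald_ratio(bx=0.0, by=0.1, sx=0.01, sy=0.05)

    def test_se_against_delta_method_oracle(self, rng):
        """Second-order option matches the full delta-method variance; the
        first-order se underestimates it by at most the sx-term fraction."""
        for _ in range(100):
            bx = rng.uniform(0.2, 1.0) * rng.choice([-1, 1])
            by = rng.normal(0, 0.2)
            sx = rng.uniform(0.001, 0.1) * abs(bx)
            sy = rng.uniform(0.01, 0.1)
            oracle = np.sqrt(sy**2 / bx**2 + by**2 * sx**2 / bx**4)
            assert wald_ratio(bx, by, sx, sy, second_order=True).se == \
                pytest.approx(oracle, abs=1e-12)
            first = wald_ratio(bx, by, sx, sy).se
            assert first <= oracle
            # with sx/|bx| < 0.1 and a modest ratio the gap stays small
            if abs(by / bx) * (sx / sy) < 0.3:
                assert first == pytest.approx(oracle, rel=0.05)


class TestIVW:
    def test_two_snp_hand_arithmetic(self):
        # unit weights: bx = 1, sy = 1; ratios 1 and 3
        h = make_harmonized([1.0, 1.0], [1.0, 3.0])
        res = ivw(h, mode="fixed")
        assert res.beta == pytest.approx(2.0)
        assert res.se == pytest.approx(np.sqrt(0.5))

    def test_identical_ratios_random_equals_fixed(self):
        h = make_harmonized([1.0, 2.0, 0.5], [0.7, 1.4, 0.35],
                            sy=[0.1, 0.1, 0.1])
        fixed = ivw(h, mode="fixed")
        random = ivw(h, mode="random")
        assert fixed.beta == pytest.approx(0.7)
        assert random.se == pytest.approx(fixed.se)  # Q = 0 -> floor at 1
        assert fixed.extras["Q"] == pytest.approx(0.0, abs=1e-20)

    def test_matches_wls_oracle(self, rng):
        """IVW fixed equals closed-form WLS of by on bx, no intercept, w=1/sy^2."""
        for _ in range(50):
            h = _random_hset(rng)
            res = ivw(h, mode="fixed")
            w = 1.0 / h.sy**2
            slope = np.sum(w * h.bx * h.by) / np.sum(w * h.bx**2)
            se = 1.0 / np.sqrt(np.sum(w * h.bx**2))
            assert res.beta == pytest.approx(slope, abs=1e-10)
            assert res.se == pytest.approx(se, abs=1e-10)

    def test_auto_mode_records_choice(self, rng):
        h = _random_hset(rng)
        res = ivw(h, mode="auto")
        assert res.extras["mode_used"] in ("fixed", "random")
        expected = "random" if res.extras["Q_pval"] < 0.05 else "fixed"
        assert res.extras["mode_used"] == expected

    def test_single_snp_refused(self):
        h = make_harmonized([1.0], [1.0])
        with pytest.raises(EstimationError, match="wald_ratio"):
            ivw(h)


class TestEgger:
    def test_noise_free_line_recovered(self):
        bx = np.array([1.0, 2.0, 3.0])
        by = 0.5 + 1.0 * bx
        res = egger(make_harmonized(bx, by))
        assert res.beta == pytest.approx(1.0, abs=1e-10)
        assert res.extras["intercept"] == pytest.approx(0.5, abs=1e-10)

    def test_zero_intercept_variant_equals_ivw(self, rng):
        """WLS identity: pinning the intercept at 0 recovers the IVW estimate."""
        h = _random_hset(rng)
        w = 1.0 / h.sy**2
        slope_no_int = np.sum(w * h.bx * h.by) / np.sum(w * h.bx**2)
        assert ivw(h, mode="fixed").beta == pytest.approx(slope_no_int, abs=1e-12)

    def test_matches_normal_equations_oracle(self, rng):
        for _ in range(50):
            h = _random_hset(rng)
            res = egger(h)
            s = np.where(h.bx < 0, -1.0, 1.0)
            X = np.column_stack([np.ones(h.n_snp), s * h.bx])
            W = np.diag(1.0 / h.sy**2)
            coef = np.linalg.solve(X.T @ W @ X, X.T @ W @ (s * h.by))
            assert res.extras["intercept"] == pytest.approx(coef[0], abs=1e-10)
            assert res.beta == pytest.approx(coef[1], abs=1e-10)

    def test_needs_three_snps(self):
        with pytest.raises(EstimationError):
            egger(make_harmonized([1.0, 2.0], [1.0, 2.0]))


class TestWeightedMedian:
    def test_equal_weights_is_median(self):
        h = make_harmonized([1.0, 1.0, 1.0], [1.0, 2.0, 9.0])
        res = weighted_median(h, n_boot=50, seed=1)
        assert res.beta == pytest.approx(2.0)

    def test_dominant_weight_pulls_estimate(self):
        # weights ∝ bx^2/sy^2: make SNP 0 dominate
        bx = np.array([3.0, 0.5, 0.5])
        by = bx * np.array([1.0, 5.0, 9.0])
        res = weighted_median(make_harmonized(bx, by), n_boot=50, seed=1)
        assert res.beta < 5.0

    def test_equal_weights_odd_j_exact_sample_median(self, rng):
        for J in (3, 5, 7):
            ratios = rng.normal(0, 1, J)
            h = make_harmonized(np.ones(J), ratios)
            res = weighted_median(h, n_boot=10, seed=0)
            assert res.beta == pytest.approx(np.median(ratios), abs=1e-14)

    def test_matches_percentile_scan_oracle(self, rng):
        """Brute-force cumulative-weight scan with the same midpoint rule."""
        for _ in range(100):
            J = rng.integers(3, 12)
            values = rng.normal(0, 1, J)
            weights = rng.uniform(0.1, 2.0, J)
            order = np.argsort(values)
            v, w = values[order], weights[order] / weights.sum()
            target, acc, oracle = 0.5, 0.0, None
            mids = np.cumsum(w) - 0.5 * w
            for i in range(J):
                if mids[i] >= target:
                    if i == 0:
                        oracle = v[0]
                    else:
                        frac = (target - mids[i - 1]) / (mids[i] - mids[i - 1])
                        oracle = v[i - 1] + frac * (v[i] - v[i - 1])
                    break
            if oracle is None:
                oracle = v[-1]
            assert weighted_percentile(values, weights, 0.5) == pytest.approx(
                oracle, abs=1e-14)

    def test_bootstrap_reproducible(self, rng):
        h = _random_hset(rng)
        a = weighted_median(h, n_boot=100, seed=42)
        b = weighted_median(h, n_boot=100, seed=42)
        assert a.se == b.se

    def test_bad_n_boot_rejected(self, rng):
        with pytest.raises(ConfigError):
            weighted_median(_random_hset(rng), n_boot=0)


class TestWeightedMode:
    def test_dominant_cluster(self):
        bx = np.ones(4)
        by = np.array([1.0, 1.0, 1.0, 5.0])
        res = weighted_mode(make_harmonized(bx, by), n_boot=20, seed=0)
        assert res.beta == pytest.approx(1.0, abs=0.5)

    def test_tight_cluster_center(self):
        bx = np.ones(5)
        by = np.full(5, 0.7) + np.array([-1e-9, 0, 1e-9, 0, 0])
        res = weighted_mode(make_harmonized(bx, by), n_boot=20, seed=0)
        assert res.beta == pytest.approx(0.7, abs=1e-6)

    def test_matches_grid_search_oracle(self, rng):
        from mrpipe.estimators import _mode_estimate, _silverman_bandwidth
        for _ in range(20):
            J = rng.integers(4, 10)
            theta = rng.normal(0, 1, J)
            w = rng.uniform(0.1, 2.0, J)
            h_band = _silverman_bandwidth(theta, w)
            est = _mode_estimate(theta, w, 1.0)
            grid = np.linspace(theta.min() - 3 * h_band,
                               theta.max() + 3 * h_band, 20001)
            wn = w / w.sum()
            dens = (np.exp(-0.5 * ((grid[:, None] - theta[None, :]) / h_band) ** 2)
                    * wn).sum(axis=1)
            step = grid[1] - grid[0]
            assert abs(est - grid[np.argmax(dens)]) <= 2 * step

    def test_bad_phi_rejected(self, rng):
        with pytest.raises(ConfigError):
            weighted_mode(_random_hset(rng), phi=0.0)


class TestOrCi:
    def test_null_beta(self):
        or_, lo, hi, p = or_ci(0.0, 0.1)
        assert or_ == pytest.approx(1.0)
        assert lo == pytest.approx(0.822, abs=5e-4)
        assert hi == pytest.approx(1.217, abs=5e-4)

    def test_published_or_ci_reproduces_printed_p(self):
        """OR 2.055 (1.260-3.352): back-derived se gives p rounding to 0.004."""
        beta = np.log(2.055)
        se = (np.log(3.352) - np.log(1.260)) / (2 * stats.norm.ppf(0.975))
        _, _, _, p = or_ci(beta, se)
        assert round(p, 3) == 0.004

    def test_ci_width_monotone_in_se(self):
        widths = [or_ci(0.3, se)[2] - or_ci(0.3, se)[1]
                  for se in (0.05, 0.1, 0.2, 0.4)]
        assert all(a < b for a, b in zip(widths, widths[1:]))


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_outcome_recode_equivariance(seed):
    """Negating the outcome effects negates every estimator's beta.

    Deterministic estimators (IVW, Egger) keep their se exactly; the
    bootstrap se of median/mode is left out (different resampling noise).
    """
    rng = np.random.default_rng(seed)
    h = _random_hset(rng)
    h_neg = make_harmonized(h.bx, -h.by, h.sx, h.sy)
    a, b = ivw(h, mode="fixed"), ivw(h_neg, mode="fixed")
    assert a.beta == pytest.approx(-b.beta, abs=1e-12)
    assert a.se == pytest.approx(b.se, abs=1e-12)
    a, b = egger(h), egger(h_neg)
    assert a.beta == pytest.approx(-b.beta, abs=1e-10)
    assert a.se == pytest.approx(b.se, rel=1e-9)
    assert a.extras["intercept"] == pytest.approx(-b.extras["intercept"], abs=1e-10)
    a = weighted_median(h, n_boot=10, seed=7)
    b = weighted_median(h_neg, n_boot=10, seed=7)
    assert a.beta == pytest.approx(-b.beta, abs=1e-12)
    a = weighted_mode(h, n_boot=10, seed=7)
    b = weighted_mode(h_neg, n_boot=10, seed=7)
    assert a.beta == pytest.approx(-b.beta, abs=1e-5)


def test_joint_sign_flip_is_orientation_invariance(rng):
    """Flipping bx and by together (an allele recode) leaves estimates unchanged."""
    h = _random_hset(rng)
    h_flip = make_harmonized(-h.bx, -h.by, h.sx, h.sy)
    assert ivw(h, mode="fixed").beta == pytest.approx(
        ivw(h_flip, mode="fixed").beta, abs=1e-12)
    assert egger(h).beta == pytest.approx(egger(h_flip).beta, abs=1e-10)


def test_result_or_fields_consistent(rng):
    res = ivw(_random_hset(rng))
    assert res.or_ == pytest.approx(np.exp(res.beta))
    assert res.ci_low < res.or_ < res.ci_high
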