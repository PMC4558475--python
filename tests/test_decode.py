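import numpy as np
import pandas as pd
import pytest
from sklearn.covariance import ledoit_wolf_shrinkage

from impulsewm import (
    DEFAULT_SCHEMES,
    EpochSet,
    assign_bins,
    distance_difference,
    loo_discrimination,
    pooled_precision,
    univariate_discrimination,
)
from impulsewm.decode import _eig_pinv, _loo_branch, _lw_shrinkage
from conftest import make_epochs


# --------------------------------------------------------------------------
# independent oracles (deliberately naive)
# --------------------------------------------------------------------------

def quadratic_form_oracle(x, m_same, m_orth, P):
    """Element-by-element quadratic form, no linear algebra shortcuts."""
    d_orth = d_same = 0.0
    n = len(x)
    for i in range(n):
        for j in range(n):
            d_orth += (m_orth[i] - x[i]) * P[i, j] * (m_orth[j] - x[j])
            d_same += (m_same[i] - x[i]) * P[i, j] * (m_same[j] - x[j])
    return d_orth - d_same


def reference_loo_discrimination(epochs):
    """Slow, loop-based re-derivation of the LOO distance-difference
    time-course, using sklearn's Ledoit-Wolf shrinkage independently."""
    theta = epochs.trials["orientation_deg"].to_numpy()
    n, _, T = epochs.data.shape
    estimates = np.zeros((n, len(DEFAULT_SCHEMES), T))
    for s_i, scheme in enumerate(DEFAULT_SCHEMES):
        bins = scheme.assign(theta)
        for b_same, b_orth in [c for comp in scheme.comparisons for c in (comp, comp[::-1])]:
            for trial in np.flatnonzero(bins == b_same):
                own = np.flatnonzero((bins == b_same) & (np.arange(n) != trial))
                other = np.flatnonzero(bins == b_orth)
                for t in range(T):
                    X_own = epochs.data[own, :, t]
                    X_other = epochs.data[other, :, t]
                    resid = np.vstack(
                        [X_own - X_own.mean(0), X_other - X_other.mean(0)]
                    )
                    rho = ledoit_wolf_shrinkage(resid, assume_centered=True)
                    dof = len(own) - 1 + len(other) - 1
                    cov = resid.T @ resid / dof
                    p = cov.shape[0]
                    shrunk = (1 - rho) * cov + rho * np.trace(cov) / p * np.eye(p)
                    P = np.linalg.inv(shrunk)
                    x = epochs.data[trial, :, t]
                    estimates[trial, s_i, t] = quadratic_form_oracle(
                        x, X_own.mean(0), X_other.mean(0), P
                    )
    return estimates.mean(axis=(0, 1))


# --------------------------------------------------------------------------
# binning
# --------------------------------------------------------------------------

class TestAssignBins:
    @pytest.mark.parametrize(
        "theta,bin_a,bin_b",
        [
            (10.0, 0, 0),     # [0,45) and [-22.5,22.5)
            (100.0, 2, 2),    # orthogonal to 10 deg in both schemes
            (45.0, 1, 1),     # half-open boundary
            (157.5, 3, 0),    # wraps into [-22.5,22.5) in scheme B
            (0.0, 0, 0),
            (179.9, 3, 0),
        ],
    )
    def test_examples(self, theta, bin_a, bin_b):
        a, b = assign_bins(theta)
        assert (a, b) == (bin_a, bin_b)

    def test_orthogonal_orientations_land_in_paired_bins(self):
        rng = np.random.default_rng(0)
        theta = rng.uniform(0, 180, 500)
        for scheme in DEFAULT_SCHEMES:
            b1 = scheme.assign(theta)
            b2 = scheme.assign((theta + 90) % 180)
            assert np.all((b2 - b1) % 4 == 2)

    def test_every_orientation_in_exactly_one_bin(self):
        theta = np.arange(0, 180, 0.25)
        for scheme in DEFAULT_SCHEMES:
            bins = scheme.assign(theta)
            assert set(np.unique(bins)) == {0, 1, 2, 3}

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            assign_bins(180.0)
        with pytest.raises(ValueError):
            assign_bins(-0.1)


# --------------------------------------------------------------------------
# pooled precision
# --------------------------------------------------------------------------

class TestPooledPrecision:
    def test_white_data_gives_identity_precision(self):
        rng = np.random.default_rng(1)
        pp = pooled_precision(rng.standard_normal((3000, 6)), rng.standard_normal((3000, 6)))
        np.testing.assert_allclose(pp.precision, np.eye(6), atol=0.1)

    def test_fewer_trials_than_channels_still_finite_psd(self):
        rng = np.random.default_rng(2)
        pp = pooled_precision(rng.standard_normal((5, 17)), rng.standard_normal((5, 17)))
        assert np.isfinite(pp.precision).all()
        np.testing.assert_allclose(pp.precision, pp.precision.T, atol=1e-10)
        assert np.all(np.linalg.eigvalsh(pp.precision) >= -1e-10)
        assert 0 < pp.shrinkage <= 1

    def test_zero_shrinkage_matches_plain_inverse(self):
        rng = np.random.default_rng(3)
        X1, X2 = rng.standard_normal((40, 5)), rng.standard_normal((50, 5))
        pp = pooled_precision(X1, X2, shrinkage=0.0)
        R1, R2 = X1 - X1.mean(0), X2 - X2.mean(0)
        cov = (R1.T @ R1 + R2.T @ R2) / (39 + 49)
        np.testing.assert_allclose(pp.precision, np.linalg.inv(cov), atol=1e-10)

    def test_shrinkage_intensity_matches_sklearn(self):
        rng = np.random.default_rng(4)
        for n, p in [(30, 8), (10, 17), (200, 5)]:
            R = rng.standard_normal((n, p)) @ rng.standard_normal((p, p))
            assert _lw_shrinkage(R) == pytest.approx(
                ledoit_wolf_shrinkage(R, assume_centered=True), abs=1e-12
            )

    def test_undersized_bin_rejected(self):
        with pytest.raises(ValueError):
            pooled_precision(np.zeros((1, 4)), np.zeros((10, 4)))


def test_eig_pinv_matches_inverse_on_full_rank():
    rng = np.random.default_rng(5)
    A = rng.standard_normal((6, 6))
    spd = A @ A.T + 6 * np.eye(6)
    np.testing.assert_allclose(_eig_pinv(spd), np.linalg.inv(spd), atol=1e-10)


def test_eig_pinv_zeroes_null_directions():
    u = np.array([[1.0, 0.0], [0.0, 0.0]])
    pinv = _eig_pinv(u)
    np.testing.assert_allclose(pinv, u, atol=1e-12)


# --------------------------------------------------------------------------
# distance difference
# --------------------------------------------------------------------------

class TestDistanceDifference:
    def test_identity_metric_example(self):
        assert distance_difference([0, 0], [0, 0], [3, 4], np.eye(2)) == pytest.approx(25.0)

    def test_equidistant_point_scores_zero(self):
        assert distance_difference([0, 0], [1, 1], [-1, -1], np.eye(2)) == pytest.approx(0.0)

    def test_matches_bruteforce_oracle_on_17_channels(self):
        rng = np.random.default_rng(6)
        x, ms, mo = rng.standard_normal((3, 17))
        A = rng.standard_normal((17, 17))
        P = A @ A.T
        got = distance_difference(x, ms, mo, P)
        want = quadratic_form_oracle(x, ms, mo, P)
        assert got == pytest.approx(want, rel=1e-10)

    def test_nonconformable_rejected(self):
        with pytest.raises(ValueError):
            distance_difference([0, 0, 0], [0, 0], [1, 1], np.eye(2))


# --------------------------------------------------------------------------
# leave-one-trial-out machinery
# --------------------------------------------------------------------------

class TestLooBranch:
    def test_matches_explicit_exclusion(self):
        """Batched LOO stats equal a from-scratch fit with the row deleted."""
        rng = np.random.default_rng(7)
        X1 = rng.standard_normal((12, 5))
        X2 = rng.standard_normal((14, 5))
        ms, mo, prec = _loo_branch(X1, X2, np.arange(12))
        for i in range(12):
            X1_wo = np.delete(X1, i, axis=0)
            np.testing.assert_allclose(ms[i], X1_wo.mean(0), atol=1e-12)
            np.testing.assert_allclose(mo[i], X2.mean(0), atol=1e-12)
            pp = pooled_precision(X1_wo, X2)
            np.testing.assert_allclose(prec[i], pp.precision, atol=1e-9)

    def test_undersized_bins_rejected(self):
        with pytest.raises(ValueError):
            _loo_branch(np.zeros((2, 3)), np.zeros((5, 3)), [0])


class TestLooDiscrimination:
    def test_matches_independent_reference(self):
        """Full pipeline vs. slow loop/sklearn re-derivation (LOO hygiene,
        double estimates and averaging all included)."""
        ep = make_epochs(n_trials=16, n_channels=4, n_times=3, seed=8)
        # evenly spaced orientations: 4 trials per bin in both schemes
        ep.trials["orientation_deg"] = np.arange(16) * 11.25
        got = loo_discrimination(ep)
        want = reference_loo_discrimination(ep)
        np.testing.assert_allclose(got.values, want, atol=1e-8)

    def test_scale_invariance(self):
        ep = make_epochs(n_trials=20, n_channels=5, n_times=4, seed=9)
        base = loo_discrimination(ep)
        ep_scaled = ep.copy()
        ep_scaled.data *= 7.3
        scaled = loo_discrimination(ep_scaled)
        np.testing.assert_allclose(scaled.values, base.values, rtol=1e-8)

    def test_noise_only_is_null_centered(self):
        ep = make_epochs(n_trials=48, n_channels=6, n_times=40, seed=10)
        tc = loo_discrimination(ep, keep_per_trial=True)
        sem = tc.per_trial.std(axis=0, ddof=1) / np.sqrt(tc.n_trials)
        frac_within = np.mean(np.abs(tc.values) <= 3 * sem)
        assert frac_within >= 0.95

    def test_planted_pattern_is_localized(self):
        rng = np.random.default_rng(11)
        ep = make_epochs(n_trials=40, n_channels=6, n_times=30, seed=12)
        theta = ep.trials["orientation_deg"].to_numpy()
        pattern = rng.standard_normal((6, 2))
        tuning = np.stack(
            [np.cos(2 * np.deg2rad(theta)), np.sin(2 * np.deg2rad(theta))], 1
        )
        window = slice(10, 20)
        ep.data[:, :, window] += 3.0 * (tuning @ pattern.T)[:, :, None]
        tc = loo_discrimination(ep)
        assert tc.values[window].mean() > 5 * np.abs(tc.values[:10]).mean()

    def test_undersized_bin_reports_offender(self):
        ep = make_epochs(n_trials=8)
        ep.trials["orientation_deg"] = np.full(8, 10.0)  # single bin only
        with pytest.raises(ValueError, match="bin"):
            loo_discrimination(ep)


class TestUnivariateDiscrimination:
    def _patterned_epochs(self, pattern, seed=13, amp=2.0):
        ep = make_epochs(n_trials=40, n_channels=4, n_times=6, seed=seed)
        theta = ep.trials["orientation_deg"].to_numpy()
        tuning = np.cos(2 * np.deg2rad(theta))
        ep.data += amp * tuning[:, None, None] * np.asarray(pattern)[None, :, None]
        return ep

    def test_zero_sum_pattern_invisible_to_univariate(self):
        ep = self._patterned_epochs([1.0, -1.0, 1.0, -1.0])
        uni = univariate_discrimination(ep)
        multi = loo_discrimination(ep)
        assert multi.values.mean() > 10 * abs(uni.values.mean())

    def test_uniform_offset_visible_to_univariate(self):
        ep = self._patterned_epochs([1.0, 1.0, 1.0, 1.0])
        uni = univariate_discrimination(ep)
        assert uni.values.mean() > 0

    def test_noise_only_near_zero(self):
        ep = make_epochs(n_trials=60, n_channels=4, n_times=30, seed=14)
        uni = univariate_discrimination(ep, keep_per_trial=True)
        sem = uni.per_trial.std(axis=0, ddof=1) / np.sqrt(uni.n_trials)
        assert np.mean(np.abs(uni.values) <= 3 * sem) >= 0.9
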