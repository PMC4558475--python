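import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from impulsewm import (
    DiscriminationTimecourse,
    generalization_matrix,
    lag_correlation,
    loo_discrimination,
    shift_timecourse_from_matrix,
    shifted_training_timecourse,
)
from impulsewm.pipeline import prepare_participant
from impulsewm import Design
from conftest import make_epochs


def balanced_epochs(n_trials=24, n_channels=5, n_times=8, seed=0):
    ep = make_epochs(n_trials, n_channels, n_times, seed)
    ep.trials["orientation_deg"] = (np.arange(n_trials) * 180.0 / n_trials) % 180.0
    return ep


class TestGeneralizationMatrix:
    def test_diagonal_equals_loo_discrimination_exactly(self):
        ep = balanced_epochs()
        mat = generalization_matrix(ep, ep)
        tc = loo_discrimination(ep)
        # identical statistics; only the floating-point reduction order
        # differs between the two code paths
        np.testing.assert_allclose(np.diag(mat.values), tc.values, rtol=1e-12, atol=1e-14)

    def test_channel_mismatch_rejected(self):
        a = balanced_epochs(n_channels=5)
        b = balanced_epochs(n_channels=4)
        with pytest.raises(ValueError):
            generalization_matrix(a, b)

    def test_same_trials_requires_id_match(self):
        a = balanced_epochs()
        b = balanced_epochs()
        b.trials["trial_id"] += 1000
        with pytest.raises(ValueError):
            generalization_matrix(a, b, same_trials=True)

    def test_independent_mode_runs_without_exclusion(self):
        train = balanced_epochs(seed=1)
        test = balanced_epochs(seed=2)
        test.trials["trial_id"] += 1000
        mat = generalization_matrix(train, test, same_trials=False)
        assert mat.values.shape == (train.n_times, test.n_times)
        assert np.isfinite(mat.values).all()

    def test_stride_subsamples_grid(self):
        ep = balanced_epochs(n_times=12)
        mat = generalization_matrix(ep, ep, stride=3)
        assert mat.train_time_ms.size == 4

    def test_static_code_generalizes_dynamic_code_does_not(self):
        """Static synthetic patterns give a near-uniform positive block;
        dynamic (rotating) patterns give diagonal dominance."""
        stats = {}
        for dynamics in ("static", "dynamic"):
            part = prepare_participant(
                Design(n_short=0, n_early=40, n_late=40, dynamics=dynamics,
                       impulse_amplitude=0.0, seed=21)
            )
            mem = part.memory_long.crop(0.0, 400.0)
            mat = generalization_matrix(mem, mem, stride=4).values
            diag = np.diag(mat).mean()
            off_mask = ~np.eye(mat.shape[0], dtype=bool)
            # compare far-off-diagonal (>100 ms apart) to the diagonal
            ti = np.arange(mat.shape[0])
            far = np.abs(ti[:, None] - ti[None, :]) * 16.0 > 100.0
            stats[dynamics] = (diag, mat[off_mask & far].mean(), mat.min())
        d_diag, d_far, _ = stats["dynamic"]
        s_diag, s_far, _ = stats["static"]
        assert d_diag > 2.0 * max(d_far, 0.0)       # dynamic: diagonal dominant
        assert s_far > 0.5 * s_diag                 # static: block-uniform


class TestShiftedTraining:
    def test_zero_shift_reproduces_matrix_slice(self, small_participant):
        part = small_participant
        tc = shifted_training_timecourse(
            part.impulse, part.memory_long, shift_ms=0.0,
            test_times=np.arange(1300.0, 1350.0, 4.0),
        )
        mat = generalization_matrix(
            part.impulse, part.memory_long,
            train_times=np.arange(100.0, 150.0, 4.0),
            test_times=np.arange(1300.0, 1350.0, 4.0),
        )
        sliced = shift_timecourse_from_matrix(mat, 0.0)
        np.testing.assert_allclose(tc.values, sliced.values, atol=1e-12)
        np.testing.assert_array_equal(tc.time_ms, sliced.time_ms)

    def test_off_grid_shift_rejected(self, small_participant):
        with pytest.raises(ValueError):
            shifted_training_timecourse(
                small_participant.impulse, small_participant.memory_long, shift_ms=3.0
            )


class TestLagCorrelation:
    def _tc(self, values, t0=1372.0):
        t = t0 + 4.0 * np.arange(len(values))
        return DiscriminationTimecourse(time_ms=t, values=np.asarray(values, float), n_trials=1)

    def test_delayed_copy_peaks_at_delay_with_r_one(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(400)
        delay = 15  # samples = 60 ms
        # late(t) = early(t - 60 ms): shifting the late window by +60 ms
        # must recover r = 1
        early = self._tc(x[delay : delay + 230])
        late = self._tc(x[: 270])
        res = lag_correlation([early], [late], window_ms=(1372.0, 2168.0))
        assert res.peak_lag_ms == 60.0
        peak_idx = int(np.flatnonzero(res.lags_ms == 60.0)[0])
        assert res.r[0, peak_idx] == pytest.approx(1.0, abs=1e-9)

    def test_independent_noise_gives_flat_mean_z(self):
        rng = np.random.default_rng(1)
        early = [self._tc(rng.standard_normal(260)) for _ in range(40)]
        late = [self._tc(rng.standard_normal(260)) for _ in range(40)]
        res = lag_correlation(early, late)
        # mean z across 40 independent participants: SE ~ 1/sqrt(200*40)
        assert np.abs(res.mean_z).max() < 4.0 / np.sqrt(200 * 40) * 3

    def test_fisher_z_clamped_for_degenerate_r(self):
        x = np.sin(np.arange(260))
        res = lag_correlation([self._tc(x)], [self._tc(x)], lags_ms=[0.0])
        assert np.isfinite(res.z).all()

    def test_tie_breaks_toward_smaller_lag(self):
        # 8 ms-periodic signal: lag 0 and lag 8 windows are identical (r = 1
        # at both), so the tie must resolve to the smaller lag
        x = np.tile([1.0, -1.0], 150)
        res = lag_correlation([self._tc(x)], [self._tc(x)], lags_ms=[0.0, 8.0])
        assert res.peak_lag_ms == 0.0

    def test_insufficient_coverage_rejected(self):
        short = self._tc(np.arange(50.0))
        with pytest.raises(ValueError):
            lag_correlation([short], [short])


@settings(max_examples=20, deadline=None, derandomize=True)
@given(
    delay_samples=st.integers(min_value=0, max_value=30),
    seed=st.integers(min_value=0, max_value=10_000),
)
def test_lag_recovery_property(delay_samples, seed):
    """lag_correlation(x, delay(x, L)) peaks at L for random signals."""
    rng = np.random.default_rng(seed)
    base = rng.standard_normal(300)
    t0 = 1372.0
    early = DiscriminationTimecourse(
        time_ms=t0 + 4.0 * np.arange(230), values=base[30 : 30 + 230], n_trials=1
    )
    late = DiscriminationTimecourse(
        time_ms=t0 + 4.0 * np.arange(270),
        values=base[30 - delay_samples : 30 - delay_samples + 270],
        n_trials=1,
    )
    res = lag_correlation([early], [late])
    assert res.peak_lag_ms == pytest.approx(delay_samples * 4.0)
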