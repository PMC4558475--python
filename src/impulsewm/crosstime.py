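"""Cross-temporal and cross-epoch generalization, shifted-training
time-courses, and the impulse-onset lag-correlation analysis.

A generalization matrix decouples the training and testing time points:
training statistics (LOO bin means and pooled shrunk precision) at train
time Y are applied to held-out test vectors at test time X. Diagonal
entries of a within-epoch matrix reproduce the time-resolved decoding
exactly; off-diagonal entries measure how far the discriminative pattern
generalizes across time. Because memory-locked and impulse-locked epochs
contain the very same long trials, the held-out test trial is excluded
from cross-epoch training sets too.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .decode import (
    DEFAULT_SCHEMES,
    BinScheme,
    DiscriminationTimecourse,
    _check_bin_sizes,
    _comparison_members,
    _evaluate,
    _loo_branch,
    pooled_precision,
)
from .epochs import EpochSet, SAMPLE_STEP_MS

__all__ = [
    "GeneralizationMatrix",
    "LagCorrelation",
    "generalization_matrix",
    "shifted_training_timecourse",
    "shift_timecourse_from_matrix",
    "shift_profile",
    "lag_correlation",
]


@dataclass
class GeneralizationMatrix:
    """Train-time x test-time grid of mean distance differences."""

    train_time_ms: np.ndarray
    test_time_ms: np.ndarray
    values: np.ndarray  # (n_train_times, n_test_times)
    n_test_trials: int
    train_epoch: str = ""
    test_epoch: str = ""

    def __post_init__(self) -> None:
        self.train_time_ms = np.asarray(self.train_time_ms, dtype=float)
        self.test_time_ms = np.asarray(self.test_time_ms, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.train_time_ms.size, self.test_time_ms.size):
            raise ValueError("values grid does not match the two time axes")

    def diagonal(self) -> DiscriminationTimecourse:
        """Within-epoch diagonal as a time-course (train time == test time)."""
        common, tr_idx, te_idx = np.intersect1d(
            self.train_time_ms, self.test_time_ms, return_indices=True
        )
        return DiscriminationTimecourse(
            time_ms=common,
            values=self.values[tr_idx, te_idx],
            n_trials=self.n_test_trials,
        )


def _time_subset(time_ms: np.ndarray, wanted) -> np.ndarray:
    """Indices of requested times on an epoch axis (all must be on-grid)."""
    if wanted is None:
        return np.arange(time_ms.size)
    wanted = np.asarray(wanted, dtype=float)
    idx = np.searchsorted(time_ms, wanted - 1e-9)
    idx = np.clip(idx, 0, time_ms.size - 1)
    if not np.allclose(time_ms[idx], wanted, atol=1e-6):
        raise ValueError("requested times not on the epoch sample grid")
    return idx


def generalization_matrix(
    train: EpochSet,
    test: EpochSet,
    same_trials: bool = True,
    train_times=None,
    test_times=None,
    stride: int = 1,
    schemes: tuple[BinScheme, ...] = DEFAULT_SCHEMES,
    train_epoch: str = "",
    test_epoch: str = "",
) -> GeneralizationMatrix:
    """Cross-temporal (possibly cross-epoch) generalization matrix.

    ``train`` supplies the training trials; ``test`` the held-out test
    vectors. With ``same_trials`` (the within-epoch case, and the
    memory/impulse cross-epoch case on long trials) every test trial is
    matched to a training trial by ``trial_id`` and excluded from its own
    training set at every train time; the test set may be a subset of the
    training trials (the rest still contribute to training). With
    ``same_trials=False`` the trial sets are independent and no exclusion
    is applied.

    ``train_times``/``test_times`` restrict the grid (ms, on-sample);
    ``stride`` subsamples both axes for quick looks.
    """
    if train.channel_names != test.channel_names:
        raise ValueError("train and test epochs must share the channel set")
    tr_t_idx = _time_subset(train.time_ms, train_times)[::stride]
    te_t_idx = _time_subset(test.time_ms, test_times)[::stride]

    theta_train = train.trials["orientation_deg"].to_numpy(dtype=float)
    theta_test = test.trials["orientation_deg"].to_numpy(dtype=float)
    test_eval = test.data[:, :, te_t_idx]  # (n_test, C, Tte)

    if same_trials:
        train_ids = train.trials["trial_id"].to_numpy()
        test_ids = test.trials["trial_id"].to_numpy()
        pos_in_train = {tid: i for i, tid in enumerate(train_ids)}
        missing = [t for t in test_ids if t not in pos_in_train]
        if missing:
            raise ValueError("same_trials: some test trials are not in the training set")
        test_to_train = np.array([pos_in_train[t] for t in test_ids])

    total = np.zeros((tr_t_idx.size, te_t_idx.size))
    n_est = 0
    for scheme in schemes:
        bins_train = scheme.assign(theta_train)
        bins_test = scheme.assign(theta_test)
        _check_bin_sizes(bins_train, scheme)
        for comp in scheme.comparisons:
            idx1, idx2 = _comparison_members(bins_train, comp)
            te1 = np.flatnonzero(bins_test == comp[0])
            te2 = np.flatnonzero(bins_test == comp[1])
            n_est += te1.size + te2.size
            for own_tr, other_tr, te_rows in ((idx1, idx2, te1), (idx2, idx1, te2)):
                if te_rows.size == 0:
                    continue
                ev = test_eval[te_rows].transpose(0, 2, 1)  # (m, Tte, C)
                if same_trials:
                    held = test_to_train[te_rows]
                    pos = np.searchsorted(own_tr, held)
                    if not np.array_equal(own_tr[pos], held):
                        raise ValueError("test trial not in its own training bin")
                for ti, t_abs in enumerate(tr_t_idx):
                    X_own = train.data[own_tr, :, t_abs]
                    X_other = train.data[other_tr, :, t_abs]
                    if same_trials:
                        ms, mo, prec = _loo_branch(X_own, X_other, pos)
                        total[ti] += _evaluate(ms, mo, prec, ev).sum(axis=0)
                    else:
                        pp = pooled_precision(X_own, X_other)
                        u = X_other.mean(axis=0) - ev
                        v = X_own.mean(axis=0) - ev
                        d = np.einsum("mtc,cd,mtd->mt", u, pp.precision, u) - np.einsum(
                            "mtc,cd,mtd->mt", v, pp.precision, v
                        )
                        total[ti] += d.sum(axis=0)
    return GeneralizationMatrix(
        train_time_ms=train.time_ms[tr_t_idx],
        test_time_ms=test.time_ms[te_t_idx],
        values=total / n_est,
        n_test_trials=test.n_trials,
        train_epoch=train_epoch,
        test_epoch=test_epoch,
    )


def _check_on_grid(value_ms: float, what: str) -> None:
    if abs(value_ms / SAMPLE_STEP_MS - round(value_ms / SAMPLE_STEP_MS)) > 1e-9:
        raise ValueError(f"{what} must lie on the {SAMPLE_STEP_MS:g} ms sample grid")


def shifted_training_timecourse(
    train: EpochSet,
    test: EpochSet,
    shift_ms: float,
    nominal_onset_ms: float = 1200.0,
    test_times=None,
    schemes: tuple[BinScheme, ...] = DEFAULT_SCHEMES,
) -> DiscriminationTimecourse:
    """Impulse-trained decoding read out in memory-locked time.

    For each memory-locked test time t, training statistics are taken from
    the impulse-locked epoch at ``t - nominal_onset_ms + shift_ms``. The
    nominal onset anchors the alignment (default 1200 ms, the mean of the
    two scheduled impulse onsets) and a positive shift moves the training
    window later relative to it. Equivalent to a diagonal slice of the
    cross-epoch generalization matrix.
    """
    _check_on_grid(shift_ms, "shift_ms")
    te_t_idx = _time_subset(test.time_ms, test_times)
    train_t = test.time_ms[te_t_idx] - nominal_onset_ms + shift_ms
    ok = (train_t >= train.time_ms[0] - 1e-9) & (train_t <= train.time_ms[-1] + 1e-9)
    if not ok.any():
        raise ValueError("no test time maps into the training epoch at this shift")
    te_t_idx = te_t_idx[ok]
    values = np.empty(te_t_idx.size)
    for k, (te_abs, t_train) in enumerate(zip(te_t_idx, train_t[ok])):
        m = generalization_matrix(
            train,
            test,
            same_trials=True,
            train_times=[t_train],
            test_times=[test.time_ms[te_abs]],
            schemes=schemes,
        )
        values[k] = m.values[0, 0]
    return DiscriminationTimecourse(
        time_ms=test.time_ms[te_t_idx], values=values, n_trials=test.n_trials
    )


def shift_timecourse_from_matrix(
    block: GeneralizationMatrix, shift_ms: float, nominal_onset_ms: float = 1200.0
) -> DiscriminationTimecourse:
    """Slice a precomputed cross-epoch matrix at one training shift.

    Returns the time-course over all test times t for which the train time
    ``t - nominal_onset_ms + shift_ms`` is on the matrix's train axis.
    """
    _check_on_grid(shift_ms, "shift_ms")
    train_t = block.test_time_ms - nominal_onset_ms + shift_ms
    tr_idx = np.searchsorted(block.train_time_ms, train_t - 1e-9)
    tr_idx_c = np.clip(tr_idx, 0, block.train_time_ms.size - 1)
    ok = np.abs(block.train_time_ms[tr_idx_c] - train_t) < 1e-6
    if not ok.any():
        raise ValueError("shift maps no test time onto the matrix train axis")
    te_idx = np.flatnonzero(ok)
    return DiscriminationTimecourse(
        time_ms=block.test_time_ms[te_idx],
        values=block.values[tr_idx_c[te_idx], te_idx],
        n_trials=block.n_test_trials,
    )


def shift_profile(
    block: GeneralizationMatrix,
    shifts_ms,
    window_ms: tuple[float, float],
    nominal_onset_ms: float = 1200.0,
) -> np.ndarray:
    """Mean discrimination over ``window_ms`` as a function of training
    shift, from one participant's cross-epoch matrix."""
    out = np.empty(len(shifts_ms))
    for i, s in enumerate(shifts_ms):
        tc = shift_timecourse_from_matrix(block, s, nominal_onset_ms)
        sel = (tc.time_ms >= window_ms[0] - 1e-9) & (tc.time_ms <= window_ms[1] + 1e-9)
        if not sel.any():
            raise ValueError("window not covered at this shift")
        out[i] = tc.values[sel].mean()
    return out


# --------------------------------------------------------------------------
# lag correlation between early- and late-onset decoding time-courses
# --------------------------------------------------------------------------

@dataclass
class LagCorrelation:
    """Per-participant Pearson r / Fisher z between the early-onset
    time-course window and lagged windows of the late-onset time-course."""

    lags_ms: np.ndarray
    r: np.ndarray       # (n_participants, n_lags)
    z: np.ndarray       # Fisher-transformed r
    mean_z: np.ndarray  # group mean per lag
    peak_lag_ms: float  # argmax of mean z; ties -> smaller lag
    window_ms: tuple[float, float]


def _window_values(tc: DiscriminationTimecourse, start: float, stop: float) -> np.ndarray:
    sel = (tc.time_ms >= start - 1e-9) & (tc.time_ms <= stop + 1e-9)
    n_expect = int(round((stop - start) / SAMPLE_STEP_MS)) + 1
    if sel.sum() != n_expect:
        raise ValueError(
            f"time-course does not fully cover [{start}, {stop}] ms"
        )
    return tc.values[sel]


def lag_correlation(
    tc_early: list[DiscriminationTimecourse],
    tc_late: list[DiscriminationTimecourse],
    window_ms: tuple[float, float] = (1370.0, 2170.0),
    lags_ms=None,
) -> LagCorrelation:
    """Correlate early-onset decoding with lag-shifted late-onset decoding.

    Per participant, Pearson's r between the early time-course over
    ``window_ms`` and equal-length windows of the late time-course shifted
    by each lag (default 0..120 ms in 4 ms steps, 31 lags). r is clamped
    to ±(1 − 1e−12) before the Fisher transform; the peak lag is the
    argmax of the group-mean z, ties broken toward the smaller lag.
    """
    if lags_ms is None:
        lags_ms = np.arange(0.0, 124.0, SAMPLE_STEP_MS)
    lags_ms = np.asarray(lags_ms, dtype=float)
    if len(tc_early) != len(tc_late) or not tc_early:
        raise ValueError("need matching, non-empty early/late time-course lists")
    start, stop = window_ms
    # the default window starts 2 ms before a sample; snap it onto the grid
    if abs(start / SAMPLE_STEP_MS - round(start / SAMPLE_STEP_MS)) > 1e-9:
        start = float(np.ceil(start / SAMPLE_STEP_MS) * SAMPLE_STEP_MS)
        stop = start + np.floor((stop - start) / SAMPLE_STEP_MS) * SAMPLE_STEP_MS
    n_sub = len(tc_early)
    r = np.empty((n_sub, lags_ms.size))
    for p in range(n_sub):
        x = _window_values(tc_early[p], start, stop)
        for li, lag in enumerate(lags_ms):
            _check_on_grid(lag, "lag")
            y = _window_values(tc_late[p], start + lag, stop + lag)
            r[p, li] = np.corrcoef(x, y)[0, 1]
    r_c = np.clip(r, -1 + 1e-12, 1 - 1e-12)
    z = np.arctanh(r_c)
    mean_z = z.mean(axis=0)
    peak = float(lags_ms[int(np.argmax(mean_z))])
    return LagCorrelation(
        lags_ms=lags_ms, r=r, z=z, mean_z=mean_z, peak_lag_ms=peak, window_ms=(start, stop)
    )
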