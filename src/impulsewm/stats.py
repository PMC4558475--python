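"""Group-level inference: sign-permutation tests with cluster-based
multiple-comparison correction, and the pre-impulse baseline-increase test.

The null hypothesis at each time point is that the group-mean
discrimination value is 0; under it each participant's value is symmetric
about 0, so the null is built by randomly multiplying every participant's
time-course by +1 or −1. Per-time-point two-sided p-values and the
max-cluster-mass null are computed from the same set of sign-flip draws
(single pass). Clusters are maximal contiguous runs of same-sign
suprathreshold time points; cluster mass is the sum of the group-mean
values within the run (the per-time-point statistic itself).
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np

__all__ = [
    "Cluster",
    "ClusterTestResult",
    "ClusterSettings",
    "sign_permutation_cluster",
    "baseline_increase_test",
]


@dataclass(frozen=True)
class ClusterSettings:
    """Permutation-test settings (standard defaults of the analysis)."""

    n_perm: int = 10_000
    cluster_alpha: float = 0.01
    alpha: float = 0.05
    window_ms: tuple[float, float] | None = None
    seed: int = 0  # required, logged with the result


@dataclass
class Cluster:
    start_ms: float
    end_ms: float
    sign: int
    mass: float
    p: float

    @property
    def significant(self) -> bool:  # against the configured alpha, set by the test
        return self._significant

    _significant: bool = field(default=False, repr=False)


@dataclass
class ClusterTestResult:
    time_ms: np.ndarray
    group_mean: np.ndarray
    pointwise_p: np.ndarray
    clusters: list[Cluster]
    settings: ClusterSettings

    @property
    def significant_clusters(self) -> list[Cluster]:
        return [c for c in self.clusters if c.p < self.settings.alpha]


def _contiguous_runs(mask: np.ndarray):
    """(start, stop) index pairs (half-open) of True runs."""
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    return list(zip(edges[::2], edges[1::2]))


def _cluster_masses(values: np.ndarray, supra: np.ndarray):
    """Clusters of same-sign suprathreshold points and their masses."""
    out = []
    for sign in (1, -1):
        mask = supra & ((values > 0) if sign > 0 else (values < 0))
        for start, stop in _contiguous_runs(mask):
            out.append((start, stop, sign, values[start:stop].sum()))
    return out


def sign_permutation_cluster(
    data: np.ndarray,
    time_ms: np.ndarray,
    settings: ClusterSettings = ClusterSettings(),
) -> ClusterTestResult:
    """Two-sided sign-permutation test with cluster-mass correction.

    Parameters
    ----------
    data:
        Participants x time matrix of decoding values.
    time_ms:
        Time axis; ``settings.window_ms`` restricts the analysis window.
    """
    data = np.asarray(data, dtype=float)
    time_ms = np.asarray(time_ms, dtype=float)
    if data.ndim != 2 or data.shape[0] < 2:
        raise ValueError("need a participants x time matrix with >= 2 participants")
    if data.shape[1] != time_ms.size:
        raise ValueError("time axis length mismatch")
    if settings.n_perm < 100:
        warnings.warn("n_perm < 100: permutation p-values will be very coarse")

    if settings.window_ms is not None:
        lo, hi = settings.window_ms
        keep = (time_ms >= lo - 1e-9) & (time_ms <= hi + 1e-9)
        if not keep.any():
            raise ValueError(f"analysis window [{lo}, {hi}] outside the time axis")
        data = data[:, keep]
        time_ms = time_ms[keep]

    n_sub, n_time = data.shape
    rng = np.random.default_rng(settings.seed)
    signs = rng.choice([-1.0, 1.0], size=(settings.n_perm, n_sub))
    null_means = (signs @ data) / n_sub  # (n_perm, n_time)
    obs = data.mean(axis=0)

    p_floor = 1.0 / settings.n_perm
    abs_null = np.abs(null_means)
    pointwise_p = np.maximum(
        (abs_null >= np.abs(obs)[None, :]).mean(axis=0), p_floor
    )

    # cluster-forming threshold: the (1 - cluster_alpha) quantile of |null|
    # per time point, so that "p < cluster_alpha" is evaluated consistently
    # for observed and permuted data
    thresh = np.quantile(abs_null, 1.0 - settings.cluster_alpha, axis=0)

    null_max_mass = np.zeros(settings.n_perm)
    for r in range(settings.n_perm):
        masses = _cluster_masses(null_means[r], abs_null[r] > thresh)
        if masses:
            null_max_mass[r] = max(abs(m[3]) for m in masses)

    clusters = []
    for start, stop, sign, mass in _cluster_masses(obs, np.abs(obs) > thresh):
        p = max(float((null_max_mass >= abs(mass)).mean()), p_floor)
        c = Cluster(
            start_ms=float(time_ms[start]),
            end_ms=float(time_ms[stop - 1]),
            sign=sign,
            mass=float(mass),
            p=p,
        )
        c._significant = p < settings.alpha
        clusters.append(c)
    clusters.sort(key=lambda c: c.start_ms)
    return ClusterTestResult(
        time_ms=time_ms,
        group_mean=obs,
        pointwise_p=pointwise_p,
        clusters=clusters,
        settings=settings,
    )


def baseline_increase_test(
    data: np.ndarray,
    time_ms: np.ndarray,
    settings: ClusterSettings = ClusterSettings(window_ms=(0.0, 800.0)),
    baseline_ms: tuple[float, float] = (-100.0, 0.0),
) -> ClusterTestResult:
    """Test for a post-onset *increase* over the pre-impulse level.

    Per participant, the mean over ``baseline_ms`` (half-open, default
    [−100, 0) ms before impulse onset) is subtracted from the whole
    time-course; the sign-permutation cluster test then runs on the
    differences over the analysis window.
    """
    data = np.asarray(data, dtype=float)
    time_ms = np.asarray(time_ms, dtype=float)
    lo, hi = baseline_ms
    base = (time_ms >= lo - 1e-9) & (time_ms < hi - 1e-9)
    if not base.any():
        raise ValueError(f"baseline window [{lo}, {hi}) not covered by the epoch")
    diffs = data - data[:, base].mean(axis=1, keepdims=True)
    return sign_permutation_cluster(diffs, time_ms, settings)
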