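"""Trial-wise Mahalanobis distance-difference decoding.

The statistic: trials are split into four 45°-wide orientation bins, twice
(two bin schemes offset by 22.5°), and only orthogonal bins are compared.
For a held-out test trial x at one time point, with training-bin means
m_same (its own bin) and m_orth (the bin 90° away) and pC+ the
pseudoinverse of the pooled, shrinkage-regularized error covariance of the
training trials, the per-trial estimate is the squared-form distance
difference

    D_orth - D_same = (m_orth - x)' pC+ (m_orth - x)
                    - (m_same - x)' pC+ (m_same - x),

positive when the channel pattern carries orientation information. Every
training quantity (bin means, covariance, its shrinkage intensity and
pseudoinverse) is recomputed with the test trial left out; each trial
yields one estimate per scheme, and the time-course is the average over
estimates and trials.

The shrinkage intensity is the analytic optimal shrinkage toward a scaled
identity (Ledoit & Wolf), computed on the pooled within-bin residuals of
the LOO training set under the 1/n covariance normalization — the exact
convention of ``sklearn.covariance.ledoit_wolf_shrinkage`` — and applied
to the dof-normalized pooled covariance. The pseudoinverse zeroes
eigenvalues below ``max(eig) * 1e-12``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .epochs import EpochSet

__all__ = [
    "BinScheme",
    "DEFAULT_SCHEMES",
    "PooledPrecision",
    "DiscriminationTimecourse",
    "assign_bins",
    "pooled_precision",
    "distance_difference",
    "loo_discrimination",
    "univariate_discrimination",
]

_PINV_TOL = 1e-12


# --------------------------------------------------------------------------
# orientation binning
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class BinScheme:
    """One 4-bin partition of orientation space (mod 180°).

    Bins are half-open 45° intervals starting at ``offset_deg``; the two
    comparisons pit each bin against the bin 90° away.
    """

    name: str
    offset_deg: float

    #: index pairs of orthogonal bins compared against each other
    comparisons: tuple[tuple[int, int], ...] = ((0, 2), (1, 3))

    def assign(self, orientation_deg) -> np.ndarray:
        theta = np.asarray(orientation_deg, dtype=float)
        if np.any((theta < 0) | (theta >= 180.0)):
            raise ValueError("orientation must lie in [0, 180)")
        return (np.floor(((theta - self.offset_deg) % 180.0) / 45.0)).astype(int)


#: Scheme A: [0,45), [45,90), [90,135), [135,180).
#: Scheme B: [-22.5,22.5), [22.5,67.5), [67.5,112.5), [112.5,157.5) (mod 180).
DEFAULT_SCHEMES = (BinScheme("A", 0.0), BinScheme("B", -22.5))


def assign_bins(orientation_deg) -> tuple[np.ndarray, np.ndarray]:
    """Bin index of each orientation under both schemes."""
    return tuple(s.assign(orientation_deg) for s in DEFAULT_SCHEMES)


# --------------------------------------------------------------------------
# pooled shrunk covariance and its pseudoinverse
# --------------------------------------------------------------------------

@dataclass
class PooledPrecision:
    """Pooled shrunk error covariance and its pseudoinverse ("pC+")."""

    covariance: np.ndarray
    precision: np.ndarray
    shrinkage: float


def _lw_shrinkage(residuals: np.ndarray) -> float:
    """Ledoit-Wolf analytic shrinkage toward scaled identity for centered
    rows, mirroring sklearn's ledoit_wolf_shrinkage(assume_centered=True)."""
    n, p = residuals.shape
    if p == 1:
        return 0.0
    emp = residuals.T @ residuals / n
    mu = np.trace(emp) / p
    delta_ = float(np.sum(emp**2))
    beta_ = float(np.sum(np.sum(residuals**2, axis=1) ** 2))
    beta = (beta_ / n - delta_) / (p * n)
    delta = (delta_ - 2.0 * mu * np.trace(emp) + p * mu**2) / p
    if delta <= 0:
        return 0.0
    return float(min(beta, delta) / delta) if beta > 0 else 0.0


def _eig_pinv(mat: np.ndarray, tol: float = _PINV_TOL) -> np.ndarray:
    """Symmetric (batched) pseudoinverse; eigenvalues below max*tol -> 0."""
    w, v = np.linalg.eigh(mat)
    cutoff = np.max(np.abs(w), axis=-1, keepdims=True) * tol
    inv_w = np.where(np.abs(w) > cutoff, 1.0 / np.where(w == 0, 1.0, w), 0.0)
    return np.einsum("...ij,...j,...kj->...ik", v, inv_w, v)


def pooled_precision(
    train_bin1: np.ndarray,
    train_bin2: np.ndarray,
    shrinkage: float | None = None,
    tol: float = _PINV_TOL,
) -> PooledPrecision:
    """Pooled shrunk covariance of two training bins and its pseudoinverse.

    Residuals are taken about each bin's own mean; per-bin covariances are
    pooled weighted by their degrees of freedom. ``shrinkage=None`` selects
    the analytic Ledoit-Wolf intensity; pass 0.0 to force the plain pooled
    sample covariance.
    """
    X1 = np.asarray(train_bin1, dtype=float)
    X2 = np.asarray(train_bin2, dtype=float)
    if X1.shape[0] < 2 or X2.shape[0] < 2:
        raise ValueError("need at least 2 trials per bin to estimate covariance")
    if X1.shape[1] != X2.shape[1]:
        raise ValueError("bins must share the channel dimension")
    R1 = X1 - X1.mean(axis=0)
    R2 = X2 - X2.mean(axis=0)
    residuals = np.vstack([R1, R2])
    dof = (X1.shape[0] - 1) + (X2.shape[0] - 1)
    cov = residuals.T @ residuals / dof
    rho = _lw_shrinkage(residuals) if shrinkage is None else float(shrinkage)
    p = cov.shape[0]
    shrunk = (1.0 - rho) * cov + rho * (np.trace(cov) / p) * np.eye(p)
    return PooledPrecision(covariance=shrunk, precision=_eig_pinv(shrunk, tol), shrinkage=rho)


def distance_difference(test_vector, mean_bin_same, mean_bin_orth, precision) -> float:
    """Squared-form Mahalanobis distance difference (orthogonal − same)."""
    x = np.asarray(test_vector, dtype=float)
    P = precision.precision if isinstance(precision, PooledPrecision) else np.asarray(precision)
    u = np.asarray(mean_bin_orth, dtype=float) - x
    v = np.asarray(mean_bin_same, dtype=float) - x
    if u.shape[-1] != P.shape[-1] or v.shape[-1] != P.shape[-1]:
        raise ValueError("non-conformable dimensions")
    return float(u @ P @ u - v @ P @ v)


# --------------------------------------------------------------------------
# batched LOO machinery (shared with the cross-temporal module)
# --------------------------------------------------------------------------

def _loo_branch(X_own, X_other, test_idx, tol=_PINV_TOL):
    """LOO training statistics for held-out trials of one bin.

    For each held-out row index in ``test_idx`` (into ``X_own``): the
    own-bin LOO mean, the (full) other-bin mean, and the pooled shrunk
    precision computed from residuals excluding the held-out row.

    Returns (mean_same (m,C), mean_orth (m,C), precision (m,C,C)).
    """
    X_own = np.asarray(X_own, dtype=float)
    X_other = np.asarray(X_other, dtype=float)
    n_own, C = X_own.shape
    n_other = X_other.shape[0]
    if n_own < 3 or n_other < 2:
        raise ValueError("each bin needs >=3 trials for LOO estimation")
    test_idx = np.asarray(test_idx, dtype=int)
    m = test_idx.size

    mean_other = X_other.mean(axis=0)
    R_other = X_other - mean_other
    S_other = R_other.T @ R_other
    q_other_sq = float(np.sum(np.sum(R_other**2, axis=1) ** 2))

    sum_own = X_own.sum(axis=0)
    mean_loo = (sum_own - X_own[test_idx]) / (n_own - 1)          # (m, C)
    R_own = X_own[None, :, :] - mean_loo[:, None, :]              # (m, n_own, C)
    w = np.ones((m, n_own))
    w[np.arange(m), test_idx] = 0.0
    S_own = np.einsum("mnc,mnd,mn->mcd", R_own, R_own, w, optimize=True)

    n_loo = n_own - 1 + n_other
    S_total = S_own + S_other                                     # (m, C, C)

    # Ledoit-Wolf intensity on the pooled residuals (1/n normalization)
    S_lw = S_total / n_loo
    trace = np.trace(S_lw, axis1=1, axis2=2)
    mu = trace / C
    delta_ = np.sum(S_lw**2, axis=(1, 2))
    q_own = np.sum(R_own**2, axis=2)                              # (m, n_own)
    beta_ = np.sum(w * q_own**2, axis=1) + q_other_sq
    beta = (beta_ / n_loo - delta_) / (C * n_loo)
    delta = (delta_ - 2.0 * mu * trace + C * mu**2) / C
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.where(delta > 0, np.minimum(np.maximum(beta, 0.0), delta) / np.where(delta > 0, delta, 1.0), 0.0)

    dof = n_loo - 2
    S_pool = S_total / dof
    trace_pool = np.trace(S_pool, axis1=1, axis2=2)
    eye = np.eye(C)
    shrunk = (1.0 - rho)[:, None, None] * S_pool + (rho * trace_pool / C)[:, None, None] * eye
    precision = _eig_pinv(shrunk, tol)
    mean_orth = np.broadcast_to(mean_other, (m, C))
    return mean_loo, mean_orth, precision


def _evaluate(mean_same, mean_orth, precision, eval_vectors):
    """Distance differences for held-out trials at arbitrary test vectors.

    eval_vectors: (m, T, C) — one test-time series per held-out trial.
    Returns (m, T).
    """
    u = mean_orth[:, None, :] - eval_vectors
    v = mean_same[:, None, :] - eval_vectors
    d_orth = np.einsum("mtc,mcd,mtd->mt", u, precision, u, optimize=True)
    d_same = np.einsum("mtc,mcd,mtd->mt", v, precision, v, optimize=True)
    return d_orth - d_same


def _comparison_members(trials_bins: np.ndarray, comparison: tuple[int, int]):
    """Row indices of the two bins of one comparison."""
    b1, b2 = comparison
    return np.flatnonzero(trials_bins == b1), np.flatnonzero(trials_bins == b2)


# --------------------------------------------------------------------------
# time-courses
# --------------------------------------------------------------------------

@dataclass
class DiscriminationTimecourse:
    """Mean Mahalanobis distance difference per time point (arb. units)."""

    time_ms: np.ndarray
    values: np.ndarray
    n_trials: int
    per_trial: np.ndarray | None = None  # (n_trials, n_times), scheme-averaged

    def __post_init__(self) -> None:
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.time_ms.shape:
            raise ValueError("values length must match the time axis")


def _check_bin_sizes(bins: np.ndarray, scheme: BinScheme, min_per_bin: int = 3) -> None:
    for comp in scheme.comparisons:
        for b in comp:
            n = int(np.sum(bins == b))
            if n < min_per_bin:
                raise ValueError(
                    f"scheme {scheme.name} bin {b} has {n} trials; "
                    f"needs >= {min_per_bin} for leave-one-out decoding"
                )


def loo_discrimination(
    epochs: EpochSet,
    schemes: tuple[BinScheme, ...] = DEFAULT_SCHEMES,
    keep_per_trial: bool = False,
) -> DiscriminationTimecourse:
    """Leave-one-trial-out distance-difference time-course.

    At every time point, every trial is held out once per scheme from its
    orthogonal-bin comparison; training means and the pooled shrunk
    precision are recomputed without it and the squared-form distance
    difference is evaluated on the instantaneous channel vector. The
    output averages the two per-trial estimates and all trials.
    """
    X = epochs.data  # (n, C, T)
    n, _, T = X.shape
    theta = epochs.trials["orientation_deg"].to_numpy(dtype=float)
    estimates = np.zeros((n, len(schemes), T))
    for s_i, scheme in enumerate(schemes):
        bins = scheme.assign(theta)
        _check_bin_sizes(bins, scheme)
        for comp in scheme.comparisons:
            idx1, idx2 = _comparison_members(bins, comp)
            for t in range(T):
                X1 = X[idx1, :, t]
                X2 = X[idx2, :, t]
                ms, mo, prec = _loo_branch(X1, X2, np.arange(idx1.size))
                estimates[idx1, s_i, t] = _evaluate(ms, mo, prec, X1[:, None, :])[:, 0]
                ms, mo, prec = _loo_branch(X2, X1, np.arange(idx2.size))
                estimates[idx2, s_i, t] = _evaluate(ms, mo, prec, X2[:, None, :])[:, 0]
    per_trial = estimates.mean(axis=1)
    return DiscriminationTimecourse(
        time_ms=epochs.time_ms,
        values=per_trial.mean(axis=0),
        n_trials=n,
        per_trial=per_trial if keep_per_trial else None,
    )


def univariate_discrimination(
    epochs: EpochSet,
    schemes: tuple[BinScheme, ...] = DEFAULT_SCHEMES,
    keep_per_trial: bool = False,
) -> DiscriminationTimecourse:
    """Univariate control: same LOO structure on the channel-averaged
    voltage; statistic is |mean_orth − x̄| − |mean_same − x̄|."""
    V = epochs.data.mean(axis=1)  # (n, T)
    n, T = V.shape
    theta = epochs.trials["orientation_deg"].to_numpy(dtype=float)
    estimates = np.zeros((n, len(schemes), T))
    for s_i, scheme in enumerate(schemes):
        bins = scheme.assign(theta)
        _check_bin_sizes(bins, scheme)
        for comp in scheme.comparisons:
            idx1, idx2 = _comparison_members(bins, comp)
            for own, other in ((idx1, idx2), (idx2, idx1)):
                v_own = V[own]                       # (n_own, T)
                mean_other = V[other].mean(axis=0)   # (T,)
                loo_mean = (v_own.sum(axis=0) - v_own) / (own.size - 1)
                estimates[own, s_i, :] = np.abs(mean_other - v_own) - np.abs(loo_mean - v_own)
    per_trial = estimates.mean(axis=1)
    return DiscriminationTimecourse(
        time_ms=epochs.time_ms,
        values=per_trial.mean(axis=0),
        n_trials=n,
        per_trial=per_trial if keep_per_trial else None,
    )
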