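"""Synthetic EEG for the impulse-response working-memory paradigm.

Emulates the statistical structure the downstream analyses assume, so the
whole pipeline is testable without any recordings:

* 1600 trials per simulated participant (800 "short" trials whose probe
  follows the first delay, 400 "early-impulse" and 400 "late-impulse"
  long trials with a task-irrelevant impulse stimulus at 1170 or 1230 ms
  after memory-item onset),
* a randomly oriented memory grating per trial (uniform on [0, 180)),
* an orientation-tuned evoked response during encoding that decays into
  the delay, optionally with a *dynamic* (time-rotating) spatial code,
* an impulse-evoked orientation-dependent response, time-locked to each
  trial's impulse onset, carried by a spatial code that is independent of
  the encoding code unless ``shared_code=True``,
* spatially correlated Gaussian sensor noise,
* 2AFC behavioral responses from the guess/precision mixture model.

Everything is reproducible from ``Design.seed``; one root generator feeds
all randomness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .epochs import EpochSet, SAMPLE_STEP_MS, round_to_sample_grid
from .preprocess import POSTERIOR_17

__all__ = ["Design", "PROBE_DELTAS_DEG", "generate_epochs", "generate_behavior"]

#: Absolute probe-test rotations used in the task (degrees); each trial
#: draws one of the 20 signed values uniformly.
PROBE_DELTAS_DEG = (4, 5, 7, 9, 12, 15, 20, 26, 34, 45)

_EPOCH_START_MS = -200.0
_SHORT_EPOCH_END_MS = 1400.0
_LONG_EPOCH_END_MS = 2800.0


@dataclass
class Design:
    """Simulation design: trial structure, signal model and noise model.

    Amplitudes are in microvolts and may be zero (signal-free null runs);
    negative values are rejected. The orientation signal lives in a 2-D
    tuning subspace (cos 2θ, sin 2θ) projected onto random orthonormal
    channel patterns; ``dynamics='dynamic'`` rotates the encoding (and
    impulse) patterns smoothly within a 4-D channel subspace over roughly
    300 ms, which produces diagonal-dominant cross-temporal matrices.
    """

    n_channels: int = 17
    sample_rate_hz: float = 250.0
    n_short: int = 800
    n_early: int = 400
    n_late: int = 400
    memory_onset_ms: float = 0.0
    memory_duration_ms: float = 200.0
    impulse_onsets_ms: tuple[float, float] = (1170.0, 1230.0)
    encode_amplitude: float = 1.0
    impulse_amplitude: float = 0.7
    encode_decay_tau_ms: float = 300.0
    dynamics: str = "dynamic"
    shared_code: bool = False
    noise_spatial_corr: float = 0.3
    noise_sd: float = 1.0
    erp_amplitude: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_channels < 8:
            raise ValueError("need at least 8 channels for the code subspaces")
        for name in ("n_short", "n_early", "n_late"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_short + self.n_early + self.n_late == 0:
            raise ValueError("design has no trials")
        for name in ("encode_amplitude", "impulse_amplitude", "erp_amplitude"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.encode_decay_tau_ms <= 0:
            raise ValueError("encode_decay_tau_ms must be > 0")
        if self.dynamics not in ("static", "dynamic"):
            raise ValueError("dynamics must be 'static' or 'dynamic'")
        if not (0.0 <= self.noise_spatial_corr < 1.0):
            raise ValueError("noise_spatial_corr must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def n_trials(self) -> int:
        return self.n_short + self.n_early + self.n_late

    def channel_names(self) -> list[str]:
        if self.n_channels == len(POSTERIOR_17):
            return list(POSTERIOR_17)
        return [f"CH{i + 1:02d}" for i in range(self.n_channels)]


# --------------------------------------------------------------------------
# temporal envelopes and spatial codes
# --------------------------------------------------------------------------

def _encode_envelope(t_ms: np.ndarray, tau_ms: float) -> np.ndarray:
    """Encoding-response envelope: onset ~60 ms, peak 160 ms, exponential
    decay into the delay with time constant ``tau_ms``."""
    peak, rise_sd = 160.0, 50.0
    env = np.where(
        t_ms < peak,
        np.exp(-0.5 * ((t_ms - peak) / rise_sd) ** 2),
        np.exp(-(t_ms - peak) / tau_ms),
    )
    return np.where(t_ms >= 40.0, env, 0.0)


def _impulse_envelope(tau_ms: np.ndarray) -> np.ndarray:
    """Impulse-response envelope: two bumps peaking ~200 and ~360 ms after
    impulse onset, gone by ~600 ms."""
    env = np.exp(-0.5 * ((tau_ms - 200.0) / 45.0) ** 2) + 0.8 * np.exp(
        -0.5 * ((tau_ms - 360.0) / 55.0) ** 2
    )
    return np.where(tau_ms >= 80.0, env, 0.0)


def _rotation_angle(t_ms: np.ndarray, start: float, stop: float, dynamic: bool) -> np.ndarray:
    """Code-rotation angle: 0 before ``start``, linear ramp to pi/2 at
    ``stop``, frozen after (identically 0 for static codes)."""
    if not dynamic:
        return np.zeros_like(t_ms)
    frac = np.clip((t_ms - start) / (stop - start), 0.0, 1.0)
    return frac * (np.pi / 2.0)


def _code_patterns(basis4: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Time-resolved 2-column code from a 4-column orthonormal basis.

    Column pair (q0, q1) rotates toward (q2, q3) as phi goes 0 -> pi/2;
    the two code columns stay orthonormal at every time point.
    """
    q0, q1, q2, q3 = basis4.T
    c, s = np.cos(phi), np.sin(phi)
    u1 = c[:, None] * q0 + s[:, None] * q2
    u2 = c[:, None] * q1 + s[:, None] * q3
    return np.stack([u1, u2], axis=-1)  # (T, C, 2)


def _noise_cholesky(design: Design) -> np.ndarray:
    """Cholesky factor of the channel noise covariance sd^2 * rho^|i-j|."""
    idx = np.arange(design.n_channels)
    corr = design.noise_spatial_corr ** np.abs(idx[:, None] - idx[None, :])
    return np.linalg.cholesky(design.noise_sd**2 * corr + 1e-12 * np.eye(design.n_channels))


# --------------------------------------------------------------------------
# trial table
# --------------------------------------------------------------------------

def _make_trial_table(design: Design, rng: np.random.Generator) -> pd.DataFrame:
    n = design.n_trials
    onset_early = round_to_sample_grid(design.impulse_onsets_ms[0])
    onset_late = round_to_sample_grid(design.impulse_onsets_ms[1])
    trial_type = np.array(
        ["short"] * design.n_short + ["long"] * (design.n_early + design.n_late)
    )
    onsets = np.concatenate(
        [
            np.full(design.n_short, np.nan),
            np.full(design.n_early, onset_early),
            np.full(design.n_late, onset_late),
        ]
    )
    order = rng.permutation(n)  # conditions randomized across the session
    signed = np.concatenate([PROBE_DELTAS_DEG, [-d for d in PROBE_DELTAS_DEG]])
    table = pd.DataFrame(
        {
            "trial_id": np.arange(n),
            "orientation_deg": rng.uniform(0.0, 180.0, size=n),
            "trial_type": trial_type[order],
            "impulse_onset_ms": onsets[order],
            "probe_delta_deg": rng.choice(signed, size=n).astype(float),
            "response": np.full(n, "", dtype=object),
        }
    )
    return table


# --------------------------------------------------------------------------
# public operations
# --------------------------------------------------------------------------

def generate_epochs(design: Design) -> tuple[EpochSet, pd.DataFrame]:
    """Simulate memory-item-locked epochs for one participant.

    Returns an :class:`EpochSet` on the −200..2800 ms grid holding all
    trials, plus the trial table (responses unfilled; see
    :func:`generate_behavior`). Short trials are only defined by the
    paradigm up to 1400 ms — crop memory-epoch analyses there; samples
    beyond continue noise and the decayed encoding trace but never a
    probe response, which is not modelled.
    """
    rng = np.random.default_rng(design.seed)
    trials = _make_trial_table(design, rng)
    t = np.arange(_EPOCH_START_MS, _LONG_EPOCH_END_MS + SAMPLE_STEP_MS / 2, SAMPLE_STEP_MS)
    n, C, T = design.n_trials, design.n_channels, t.size

    # random orthonormal channel basis: columns 0-3 encoding subspace,
    # columns 4-7 impulse subspace (reused when shared_code)
    basis, _ = np.linalg.qr(rng.standard_normal((C, 8)))
    enc_basis = basis[:, :4]
    imp_basis = enc_basis if design.shared_code else basis[:, 4:8]
    erp_topo = rng.standard_normal(C)
    erp_topo /= np.linalg.norm(erp_topo)

    theta = np.deg2rad(trials["orientation_deg"].to_numpy())
    tuning = np.stack([np.cos(2 * theta), np.sin(2 * theta)], axis=1)  # (n, 2)

    dynamic = design.dynamics == "dynamic"
    data = np.zeros((n, C, T))

    # orientation-tuned encoding response (all trials, memory-locked)
    if design.encode_amplitude > 0:
        t_rel = t - design.memory_onset_ms
        env = _encode_envelope(t_rel, design.encode_decay_tau_ms)
        patt = _code_patterns(enc_basis, _rotation_angle(t_rel, 60.0, 360.0, dynamic))
        data += design.encode_amplitude * np.einsum(
            "nk,tck,t->nct", tuning, patt, env, optimize=True
        )

    # orientation-tuned impulse response (long trials, impulse-locked)
    if design.impulse_amplitude > 0:
        onset_vals = trials["impulse_onset_ms"].to_numpy()
        for onset in np.unique(onset_vals[~np.isnan(onset_vals)]):
            sel = np.flatnonzero(onset_vals == onset)
            tau = t - onset
            env = _impulse_envelope(tau)
            patt = _code_patterns(imp_basis, _rotation_angle(tau, 80.0, 500.0, dynamic))
            data[sel] += design.impulse_amplitude * np.einsum(
                "nk,tck,t->nct", tuning[sel], patt, env, optimize=True
            )

    # orientation-independent evoked deflections (same for every trial of
    # a condition; cancels in all bin contrasts)
    if design.erp_amplitude > 0:
        erp_env = np.exp(-0.5 * ((t - 120.0) / 60.0) ** 2) * (t >= 20.0)
        data += design.erp_amplitude * erp_topo[None, :, None] * erp_env[None, None, :]
        onset_vals = trials["impulse_onset_ms"].to_numpy()
        for onset in np.unique(onset_vals[~np.isnan(onset_vals)]):
            sel = np.flatnonzero(onset_vals == onset)
            tau = t - onset
            erp_env = np.exp(-0.5 * ((tau - 120.0) / 60.0) ** 2) * (tau >= 20.0)
            data[sel] += design.erp_amplitude * erp_topo[None, :, None] * erp_env[None, None, :]

    if design.noise_sd > 0:
        L = _noise_cholesky(design)
        noise = rng.standard_normal((n, T, C)) @ L.T
        data += noise.transpose(0, 2, 1)

    epochs = EpochSet(
        data=data, time_ms=t, channel_names=design.channel_names(), trials=trials
    )
    return epochs, trials


def generate_behavior(
    g: float, sigma: float, trials: pd.DataFrame, seed: int | np.random.Generator = 0
) -> pd.DataFrame:
    """Draw 2AFC responses from the guess/precision mixture model.

    Each trial answers "clockwise" with probability
    ``g/2 + (1 - g) * Phi(delta / sigma)`` where ``delta`` is the signed
    probe rotation: guesses (rate ``g``) are uniform over the two
    responses, remembered items carry Gaussian orientation noise with
    standard deviation ``sigma`` degrees.
    """
    if not (0.0 <= g <= 1.0):
        raise ValueError("g must be in [0, 1]")
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = trials.copy()
    delta = out["probe_delta_deg"].to_numpy(dtype=float)
    p_cw = g / 2.0 + (1.0 - g) * norm.cdf(delta / sigma)
    out["response"] = np.where(rng.uniform(size=len(out)) < p_cw, "cw", "ccw")
    return out
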