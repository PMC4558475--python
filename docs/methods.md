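# Methods

This note documents the models, conventions and numerical choices behind
`impulsewm`, in the package's own terms: what is simulated, what is
computed, where the design was genuinely open, and what the synthetic
results do and do not establish.

## Task and epoch geometry

One simulated session has 1600 trials by default: 800 "short" trials
(memory item 0–200 ms, probe at 1200 ms) and 800 "long" trials in which a
task-irrelevant high-contrast impulse appears mid-delay, scheduled at
1170 ms ("early") or 1230 ms ("late") after memory-item onset, 400 trials
each. Epochs are sampled at 250 Hz (4 ms steps): memory-locked −200..1400
ms for analyses including short trials, −200..2800 ms for long trials,
and impulse-locked −200..1400 ms after re-epoching. The scheduled onsets
fall exactly between samples; latencies are rounded to the nearest sample
with halves away from zero, giving effective onsets of 1172 and 1232 ms.
This convention preserves the designed 60 ms onset difference (banker's
rounding would stretch it to 64 ms) and is applied identically in the
generator and in re-epoching. Short trials are generated on the long
grid; the paradigm defines them only to 1400 ms and all memory-epoch
analyses crop there (no probe response is modelled).

## Synthetic signal model

The generator produces the *statistical structure the analyses assume*,
not biophysically realistic EEG:

* **Orientation tuning.** A remembered orientation θ (uniform on
  [0°, 180°)) maps to the 2-vector (cos 2θ, sin 2θ), so orientations 90°
  apart are maximally separated — matching the orthogonal-bin design.
* **Spatial codes.** The tuning vector projects onto pairs of random
  orthonormal channel patterns drawn once per participant. Encoding and
  impulse responses use disjoint 4-dimensional channel subspaces unless
  `shared_code=True`; with independent subspaces, cross-epoch
  generalization is exactly zero in expectation.
* **Dynamics.** With `dynamics="dynamic"` (default) the active pattern
  pair rotates smoothly within its 4-D subspace (encoding: over
  60–360 ms; impulse: over 80–500 ms after onset), so decoders generalize
  poorly across time — reproducing diagonal-dominant generalization
  matrices. `"static"` freezes the patterns and yields block-uniform
  matrices.
* **Envelopes.** Encoding: onset ~60 ms, peak 160 ms, exponential decay
  with `encode_decay_tau_ms` (default 300 ms) so late-delay decodability
  is near zero. Impulse: two bumps peaking ~200 and ~360 ms after the
  trial's (rounded) onset. An orientation-*independent* evoked deflection
  with a fixed random topography is added at both stimulus onsets; it
  cancels in every bin contrast and merely makes the traces ERP-like.
* **Noise.** Spatially correlated Gaussian sensor noise (channel
  correlation ρ^|i−j|, default ρ=0.3, SD 1 µV), white in time before the
  8 ms Gaussian smoothing. Amplitudes default to 1.0 µV (encoding) and
  0.7 µV (impulse): the physiological effect size of orientation
  information is not something the task design fixes, so the default SNR
  is a free parameter chosen once so that desk-scale runs (tens to
  hundreds of trials, 6–12 participants) reproduce the qualitative result
  pattern — positive encoding-epoch decoding, near-zero late delay,
  positive post-impulse decoding, no cross-epoch transfer.

All randomness flows from one `numpy` generator seeded by `Design.seed`;
identical designs give bit-identical output. Not emulated: volume
conduction/head geometry, eye movements and other artifacts, temporal
noise autocorrelation beyond the smoothing kernel, probe-evoked activity.
Passing tests therefore certify the *estimators and inference machinery*,
not claims about real recordings.

## Preprocessing conventions

Baseline correction subtracts the per-trial, per-channel mean over the
half-open window [−200, 0) ms (the onset sample is excluded). Temporal
smoothing convolves each trace with a unit-sum Gaussian (SD 8 ms = 2
samples), truncated at ±4 SD with reflected edges, so constants pass
through unchanged and no boundary amplitude is lost; smoothing is applied
last, on each final analysis epoch. Channel selection returns the 17
posterior channels (P7…O2) in the requested order. An optional
peak-to-peak amplitude threshold flags — never drops — trials, standing
in for manual screening; it is off by default.

## Decoding statistic

Orientations are binned twice into four half-open 45° bins (scheme A
starting at 0°, scheme B at −22.5°, modulo 180°); each scheme contributes
two orthogonal-pair comparisons, and every trial is held out once per
scheme. Per time point the instantaneous 17-channel vector is used (no
temporal window). Training statistics always exclude the held-out trial:
bin means by downdating, and the error covariance re-estimated from the
remaining trials' residuals about their own bin means, pooled over the
two bins weighted by degrees of freedom. Unequal bin counts are used as
they are (no subsampling). The distance difference uses the squared
quadratic form (no square root).

**Shrinkage.** The covariance is shrunk toward a scaled identity with the
analytic optimal intensity of Ledoit & Wolf, computed on the pooled
residual rows under the 1/n covariance normalization — the exact
convention of `sklearn.covariance.ledoit_wolf_shrinkage` — then applied
to the dof-normalized pooled covariance. The intensity is re-derived in
batched form for the leave-one-out inner loop; tests assert equality with
sklearn's scalar implementation to 1e−10, and the entire decoding
pipeline is cross-checked against an independent loop-based
re-derivation. **Pseudoinverse:** symmetric eigendecomposition with
eigenvalues below max(eig)·1e−12 zeroed; with nonzero shrinkage the
matrix is positive definite and this equals the plain inverse. The
statistic is exactly invariant to global rescaling of the data.

The univariate control runs the identical leave-one-out structure on the
channel-averaged voltage with |mean_orth − x̄| − |mean_same − x̄|; it sees
amplitude differences but is blind to zero-sum spatial patterns.

## Cross-temporal analyses

Generalization matrices decouple train and test times; training
statistics at train time Y are applied to held-out test vectors at test
time X. Because memory-locked and impulse-locked epochs contain the same
long trials, the held-out trial is excluded from cross-epoch training
sets too (the conservative choice; the alternative would leak the test
trial into training through the other epoch). The within-epoch diagonal
reproduces the time-resolved decoding to machine precision (shared code
path). Matrices are computed on the native 4 ms grid; a `stride`
parameter subsamples both axes for quick runs (pipeline default 8).

**Shifted training and lag correlation.** The impulse-trained decoder is
read out in memory-locked time: test time t uses train time
t − t₀ + shift, where the nominal onset anchor t₀ is exposed as a
parameter (default 1200 ms, the mean of the two scheduled onsets; the
exact anchor is a convention, not a measured quantity). The best shift
per onset condition is the argmax of group-mean discrimination over the
post-impulse window t₀ + [0, 800] ms — the full impulse response. The
narrower correlation window (1370–2170 ms, snapped onto the grid as
1372–2168 ms) is *not* used for the shift profile: it begins ~200 ms
after the early onset, truncates that condition's first response peak,
and would bias its argmax toward smaller shifts. With effective onsets
1172/1232 ms the best shifts on the 4 ms grid are +28 and −32 ms (the
grid-representable ±30). The lag correlation then takes the
per-participant best-shift time-courses, correlates the early window with
late windows lagged 0..120 ms (31 lags), Fisher-transforms r (clamped to
±(1 − 1e−12) so degenerate fixtures stay finite), averages z over
participants and reports the argmax lag, ties toward the smaller lag.
Using best-shift time-courses matters: at zero shift the shared training
envelope drags both conditions toward the nominal onset and the analytic
peak sits near half the true onset difference.

## Group statistics

Sign-permutation tests: under the null each participant's decoding value
is symmetric about zero, so the null distribution multiplies each
participant's time-course by ±1 (10,000 draws by default, seeded and
logged). Per-time two-sided p-values and the cluster null come from the
same draws. The cluster-forming threshold "p < 0.01" is implemented as
the (1 − 0.01) quantile of |null mean| per time point, applied uniformly
to observed and permuted data; clusters are maximal same-sign contiguous
runs; cluster mass is the sum of group-mean values in the run (the
per-time statistic itself — the cluster statistic is a free choice and
this matches the tested quantity; it is swappable in settings). Corrected
p = fraction of permutations whose maximal |mass| reaches the observed
one, floored at 1/n_perm. Default analysis windows: memory 0–1400 ms,
impulse 0–800 ms. The baseline-increase test subtracts each participant's
mean over [−100, 0) ms before the impulse and re-runs the cluster test on
the differences. Simulated type-I error is checked at ~5% family-wise.

## Behavioral model

P(cw | Δ) = g/2 + (1 − g)·Φ(Δ/σ): guesses are uniform over the two
responses; memory noise is Gaussian on the decision variable. Whether
noise sits on one or both compared representations only rescales σ by √2;
this package defines σ on the decision variable and uses the same
convention for generation and fitting, so self-consistency (parameter
recovery) is the testable contract. Fitting: bounded L-BFGS-B on the
negative log-likelihood with five deterministic starts; g ∈ [0, 1],
σ ∈ [0.1°, 100°]; likelihood clipped at 1e−300 before the log. When g
fits at 1, σ drops out of the likelihood and is flagged unidentifiable.
Condition comparisons use two-sided paired t-tests; identical conditions
return t = 0, p = 1 rather than 0/0.

## Problem sizes

The acceptance script uses 8 simulated participants with 200 early + 200
late long trials each for the latency analysis and 20 replicates of 800
trials for mixture recovery; the test suite uses 6 participants × 150 +
150 trials and correspondingly reduced simulation counts. These sizes put
Monte-Carlo error comfortably inside the quantities' tolerances while
keeping runs at desk scale.

## Known limitations

* The generator's SNR, envelopes and code-rotation speeds are stylized;
  only their qualitative consequences (decay, re-emergence, diagonal
  dominance, onset-locking) are asserted.
* Cluster inference assumes exchangeable participants and symmetric
  per-participant nulls; no TFCE or parametric alternatives.
* The pipeline starts from epochs: filtering, re-referencing and artifact
  screening of continuous recordings are upstream concerns.
* Real-data cluster extents are data-dependent quantities and are not
  reproduced or asserted anywhere.
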