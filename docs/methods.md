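# Methods

## The generative model

The core object is a recurrent switching linear dynamical system (rSLDS)
with `K` discrete states and `D` continuous latent dimensions:

- transitions: `p(z_{t+1} | z_t = k, x_t) = softmax(R_k x_t + r_k)` with
  `R_k ∈ R^{K×D}`, `r_k ∈ R^K` (the recurrent dependence on the latent
  position is what lets a 2-D model carve state space into regimes);
- dynamics: `x_t = A_{z_t} x_{t-1} + b_{z_t} + B_{z_t} u_t + ε_t`,
  `ε_t ~ N(0, Q_{z_t})`, with optional inputs `u_t` (intruder presence);
- emissions: `y_t = C x_t + d + δ_t`, `δ_t ~ N(0, S)` with diagonal `S`
  (per-neuron observation variances; a full covariance adds nothing for
  calcium noise and would cost `N²` parameters).

A line attractor in this language is a dynamics matrix with one eigenvalue
very close to 1 (time constant `τ = |1/log|λ||` of hundreds of frames) and
the rest fast. Time constants are converted frames → seconds at the imaging
frame rate (10 Hz default); natural log is used throughout.

## Fitting: structured variational EM

No external state-space package is used; the fitter is implemented here.

- **Posterior factorization** `q(x) q(z)`. Given discrete-state marginals,
  `q(x)` is the exact Gaussian chain posterior: the block-tridiagonal
  precision is assembled from state-averaged dynamics terms plus the
  emission terms and solved by a forward elimination / backward substitution
  pass (Thomas algorithm; numba-compiled). Means, marginal covariances and
  lag-one cross-covariances feed the M-steps; the chain log-determinant
  gives the Gaussian entropy.
- Given `q(x)`, `q(z)` comes from forward–backward over the discrete chain
  with state log-likelihoods `E_q(x)[log N(x_t; A_k x_{t-1}+…)]` (including
  the posterior-covariance trace corrections) and transition probabilities
  evaluated at the posterior latent means. Evaluating the softmax at the
  mean rather than integrating over `q(x)` is the one approximation in the
  scheme; it is standard for recurrent SLDS and in practice the reported
  objective is monotone to ~1e-6 relative (asserted in the tests).
- **M-steps** are closed-form weighted regressions for `{A_k, b_k, B_k,
  Q_k}` (with a small ridge and an eigenvalue floor of 1e-8 on `Q`) and for
  `{C, d, S}` (variance floor 1e-6); `{R_k, r_k}` are refit by weighted
  multinomial logistic regression on the pairwise state marginals.
- **Initialization**: factor analysis for `C, d, S` and the latent
  trajectory; k-means on those latents for discrete states; per-state ridge
  regression for the dynamics; near-diagonal empirical transitions with
  `R = 0`.
- **Objective**: the structured mean-field evidence lower bound (emission
  and dynamics expectations under `q`, transition term at the latent means,
  plus both entropies), reported per iteration in `FitDiagnostics`.

**Cross-validation.** Five contiguous time blocks. For each fold the model
is fit on the remaining blocks as *separate segments* (the smoother never
bridges the cut, so no spurious discontinuity enters the dynamics
estimates). Held-out activity is reconstructed as `C x̂ + d` from latents
inferred under the train-fold parameters, and cvR² pools residuals over all
folds. This "reconstruction" definition measures how well the model's
low-dimensional subspace and dynamics explain unseen data; it is the
definition used for the 70% quality gate.

**Identifiability.** Latents are defined up to an invertible linear map, so
nothing downstream depends on the latent basis: time constants come from
eigenvalues (basis-invariant), neuron-to-dimension assignment from the
columns of `C`, and tests align fitted to planted latents by correlation
where needed.

## How precisely can a 100-second time constant be estimated?

A per-frame eigenvalue `λ ≈ exp(-1/τ_frames)` near 1 is hard to pin down:
the relative error of `τ` is roughly `τ_frames × SE(λ)`, and a Fisher
calculation for the well-observed regime gives
`SE(λ) ≈ sqrt(σ_q² + 2 σ_x̂²) / (sqrt(T)·SD(x))`, where `σ_x̂` is the
per-frame latent estimation error set by emission noise and neuron count.
Both noise terms scale with the signal, so effectively
`SE(λ) ≈ noise_frac · sqrt(2/(N_dim·T))`. At the default session size
(N = 60, T = 3000, 20% emission noise) a planted 100-s constant is
recovered with ~70% scatter per session — single-session estimates of such
slow constants are intrinsically noisy. The parameter-recovery test
therefore uses N = 100 neurons, T = 6000 frames and a planted 50-s slow
constant, and asserts the *median* over ten seeded sessions within 25%;
these sizes were fixed by the power analysis above before any fitting was
run. The fast time constant (1 s) is recovered tightly per session.

## Synthetic sessions

The generator plants the study conditions rather than serving as a tuning
knob:

- 2-D latents, slow τ = 100 s and fast τ = 1 s at 10 Hz (diagonal dynamics,
  no rotation, for interpretability); two discrete states sharing the
  dynamics but switching on the slow latent (intruder-absent vs. ramping).
- Binary intruder-presence input drives the slow dimension only; its gain is
  self-calibrated so the slow latent spans ~3 of its stationary SDs over the
  first bout (slow innovation SD 0.015/frame, fast 0.1/frame).
- Emissions: disjoint dominant-weight groups (40% x1, 40% x2 with weights
  U(0.5, 1.5), 20% near-zero "neither"), offsets N(0, 0.1), and additive
  Gaussian noise at 20% of each neuron's signal SD (SNR 5) by default.
- Bout annotations are derived from the input schedule, so behavior and
  dynamics are consistent by construction. Cell positions are uniform in
  the FOV (no spatial clustering, matching the data regime emulated);
  clustered positions are available for decoder positive controls.
- All randomness descends from one session seed split into named substreams.

What passing tests on these sessions do **not** show: robustness to
non-Gaussian calcium noise, photobleaching drift, nonlinear fluorescence,
imperfect source extraction, or behavior–input misalignment — none of which
the generator emulates.

## Simulated targeted stimulation

Stimulation drive enters the latent update through the normalized sum of the
targeted neurons' emission rows (`Cᵀ` weighting): stimulating x1-weighted
cells pushes the slow latent. Because the planted dynamics matrix is shared
across discrete states, the perturbation superposes exactly on the
unperturbed latents (zero gain returns the session bit-identically). The
line attractor occupies a finite extent of state space; this is modelled by
scaling drive effectiveness down linearly as the stimulation-driven slow
displacement approaches a bound (default 2.5 latent units), which leaves the
decay time constant untouched while making integration saturate. The
per-frame drive scale (0.06) and bound were calibrated once so that the
evoked response integrates strictly over pulses 1–3 and saturates at pulse
3–4 under the standard protocol (2-s pulses, 20-s ISI, five targets), the
qualitative behavior the pipeline is meant to quantify.

Single-session ISI means ride on slow background drift of the latent state,
so integration/saturation flags are computed on the **evoked** projection
(stimulated minus unstimulated session) — the same role averaging across
animals plays in vivo. Influence scores z-score each neuron against the
pre-stimulation baseline and average over ISI windows, excluding the first
1 s after each pulse (transient contamination) and all followers within the
50 µm exclusion radius of the target; "photoactivated" followers would be
defined as z > 2 versus baseline. The connectivity fraction is the
proportion of x1→x1 scores strictly above the largest x1→x2 score.

## Mechanistic LIF network

Current-based LIF neurons: `τ_m dx/dt = −x + g(Σ W p − g_inh I_inh) + w s`,
threshold θ = 0.1 with reset to zero and a one-timestep unit impulse into
the synaptic current `τ_s dp/dt = −p + r`. Euler integration at dt = 1 ms
with `η ~ N(0,1)/5` added to each membrane at every step — read literally as
a per-step additive term, this sets a fluctuation-driven spontaneous firing
regime on which recurrence operates (the alternative reading, noise inside
the current, yields near-silent networks where recurrent effects are
invisible). Weights: subnetwork block (first 200 of 1000 neurons) nonzero
with probability σ, drawn U(0, 1/√200); background density 1% (unspecified
upstream; at 1% the background contributes ≈ 0.16 to the spectral radius, so
the subnetwork dominates and τ_n → τ_s as σ → 0), drawn U(0, 1/√1000); zero
diagonal. λ_max by power iteration (tolerance 1e-8; dense fallback), on the
full matrix by default with a subnetwork-only mode available.

The analytic constant `τ_n = τ_s/|1 − λ_max|` is validated against the
slowest decay mode of the linearized no-reset rate model (agreement well
inside 10%). Phase diagrams average τ_n per (σ, τ_s) cell over seeds and
mask a cell unstable if any seed reaches λ_max ≥ 1. Inhibition is one
graded unit integrating the population-mean rate (τ_I = 50 ms) subtracted
from every membrane with gain g_inh.

Input pulses are smoothed steps (100 ms Gaussian), four pulses at 20-s ISI,
driving a random 25% of neurons; amplitude 0.3 makes driven cells spike
during pulses. Rate-to-calcium conversion convolves firing rates with a
causal exponential kernel (default τ = 1.5 s, GCaMP7s-like) as a leaky
integrator — a constant rate ρ plateaus at ρ·τ; a unit-integral
normalization flag is provided.

## Decoders

The 1-D "SVM" is an exhaustive threshold search over both polarities
maximizing accuracy — equivalent to a maximal-margin separator in one
dimension and fully deterministic. Bouts separated by < 5 s are merged into
trials; balancing samples duration-matched out-of-bout negative frame sets
(seeded). Reported accuracy is the leave-one-trial-out average; the frozen
threshold for cross-condition testing is refit on all balanced frames. The
shuffle null keeps the trial structure fixed, randomly reassigns positive
labels, fits the threshold on a balanced half of the shuffled trials and
scores the held-out balanced half, making the null mean exactly 0.5 in
expectation. The spatial decoder is a linear SVM on standardized (x, y)
with stratified cross-validation and 20 label-shuffle repeats. The motion
GLM uses a lagged design (10 features × lags over 10 s), contiguous 10-fold
cross-validation and per-fold generalized-cross-validated ridge.

Note on a closed form used in the tests: a 2-SD in-bout elevation with unit
noise gives an optimal frame-wise accuracy of Φ(1) ≈ 0.84 (Gaussian class
overlap), which is the band the planted-effect test asserts.

## Problem sizes and numerical choices

Default test/acceptance problem sizes: sessions of 3000–6000 frames with
60–100 neurons; LIF simulations of ~100 s at 1 ms resolution; 20 seeds for
spectral averages; 1000 shuffles for the decoder null. Tolerances: ELBO
monotonicity to 1e-6 relative; Q floor 1e-8, S floor 1e-6; power-iteration
tolerance 1e-8; ACHW uses the 0.5 crossing of r_k with linear interpolation
between integer lags (censored at the maximum computed lag when never
reached); the biased (1/T) autocovariance estimator is used as is standard.
When K > 1, reported time constants and the line-attractor score come from
the state with the largest leading tau (the attractor-expressing state),
with per-state values also available.

## Known limitations

- The recurrent-softmax-at-the-mean approximation can in principle break
  ELBO monotonicity; observed violations are below the asserted tolerance.
- Slow-τ estimates from single short sessions are wide (see the power
  analysis); cohort-level medians are the reliable quantity.
- The stimulation model is a low-dimensional surrogate: no optics, no
  per-cell photoactivation variability beyond the fixed radii, and
  saturation is imposed through a single bound rather than emerging from a
  fitted nonlinear flow.
- The LIF model's high-noise spontaneous regime makes "runaway excitation"
  appear as persistent, growing elevation rather than divergence; the
  spiking ceiling bounds rates.
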