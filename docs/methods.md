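# Methods

This note documents the models and procedures implemented in `hippostate`,
the choices made where the design was genuinely open, and what the
synthetic-data tests do and do not establish about real recordings.

## Current-source density estimation

Laminar CSD is estimated with the one-dimensional cubic-spline inverse
method: the depth profile of the CSD is parameterised by its values at the
electrode depths, interpolated between them by a natural cubic spline, and
each depth slice is treated as a planar disk source of finite lateral
extent.  The forward matrix `F` maps spline node values to electrode
potentials via the disk kernel
`(sqrt(dz² + R²) − |dz|) / 2σ`; inversion solves
`min_c ‖F c − V‖² + λ‖c‖²` per time sample with one shared λ.

Open choices: lateral source diameter 500 µm and homogeneous conductivity
0.3 (both configurable; they scale, but do not reshape, the estimate).
λ is selected by leave-one-channel-out cross-validation over a 25-point
log grid spanning `[1e−8, 1e2]·trace(FᵀF)/n`; the CV error is evaluated on
at most 20 000 time samples, which estimates a per-sample average
accurately at a fraction of the cost.  No spatial smoothing is applied
beyond what λ induces.  The noiseless forward→inverse round trip at λ=0 is
exact to <1e−6 relative error (tested).

**DG CSD activity** — the proxy for entorhinal input — is the rectified
CSD averaged over the molecular-layer depth rows, median-filtered with a
1 s window, and z-scored.  Median and boxcar filters use reflect padding
so the session edges carry no transient.  In synthetic sessions the layer
rows come from generator truth; on real data they are a user-supplied
channel range (histological localisation is out of scope).

## UP/DOWN segmentation

A two-component Gaussian mixture is fitted to the activity distribution
(EM, deterministic percentile initialisation, no random restarts).  The
mixture initialises a two-state Gaussian HMM whose transition and emission
parameters are re-estimated by Baum–Welch; the Viterbi path is decoded on
the activity downsampled to 4 Hz, and the higher-mean state is UP.
Downsampling to the 4 Hz frame grid uses per-frame averaging
(integrate-and-dump) rather than a long FIR: frame-local averaging
suppresses out-of-band noise without smearing state transitions across
frames, which measurably biases recovered epoch durations upward.

The minimum representable epoch is one frame (0.25 s); no further pruning
is applied.  Epochs clipped at exactly one frame are phase-random relative
to the frame grid and are sometimes invisible to the Viterbi path, which
merges their neighbours; on sessions with ~3 s mean epochs this inflates
recovered mean durations by roughly 3–4%.  This is a property of the 4 Hz
decoding itself, and therefore also present in any duration statistics
derived from such a segmentation.

**Phase convention**: each UP epoch maps linearly onto [0, π) (0 at the
DOWN→UP transition) and each DOWN epoch onto [π, 2π).  Boundary epochs use
the trace edges as pseudo-transitions so phase is defined everywhere.
Event–phase densities use 40 bins, are occupancy-corrected by the time
spent per phase bin, and normalised to unit integral over one cycle.

## Ripple detection

Ripple power is the square root of the 80–250 Hz band-passed (zero-phase
FIR, so onsets carry no group delay), squared, 10 ms-Gaussian-smoothed
LFP.  Candidate events exceed mean + 3 SD of the whole-session envelope;
segments closer than 55 ms are merged, merged segments shorter than 20 ms
are dropped, and events that temporally intersect a supra-threshold
segment detected by the same procedure on a reference channel are rejected
as artifacts (the strictest reading of simultaneous detection; the
reference threshold is the same 3 SD).  Sharp-wave size is the peak
magnitude of the radiatum sink within [onset − 50 ms, offset], measured
against the session median; events are split big/small at the session
median (mean splitting available).  Doublet classification uses a 200 ms
onset-to-onset gap by default (configurable) — generous enough to capture
~100 ms ripple doublets.

Note that a pure z-threshold detector always crosses somewhere on a finite
noise envelope, so a handful of brief spurious detections on ripple-free
channels is expected behaviour rather than a defect; the minimum-duration
and reference rules remove most of them.

## V_m processing

Spikes are local maxima with prominence ≥ 15 mV and width ≤ 10 ms; cells
with a median spike threshold above −37 mV are flagged for exclusion
(−37.0 exactly is kept).  The spike threshold is measured as the V_m at
the maximum of the second derivative within 3 ms before the peak — a
conventional operationalisation, exposed as a parameter.  Spike intervals
[−3 ms, +5 ms] are linearly interpolated (overlapping windows merged
first).  The subthreshold trace is low-pass filtered with a
Parks–McClellan equiripple FIR (250–350 Hz transition band, <1% passband
ripple, ≥40 dB at 500 Hz), applied forward-backward for zero phase, and
resampled to 2083 Hz.  The decomposition is

    slow_raw = median_1s(V);  fast = V − slow_raw;
    drift = boxcar_60s(slow_raw);  slow = slow_raw − drift,

so `fast + slow + drift == V` exactly at every sample.  On traces shorter
than the boxcar the drift window truncates and the result is flagged.

## Transfer models

The slow V_m of a cell is modelled as the output of a 75-tap FIR filter
driven by the z-scored DG CSD activity at a model rate of 20.83 Hz
(2083/100), spanning 3.6 s with 18 negative-lag taps down to −0.86 s —
the unique tap split consistent with all three printed figures (75 taps,
3.6 s, −0.86 s).  Negative lags let the output lead the input, which is a
physiological signature (CA1/CA3), not an error.  The coefficients carry a
first-order stable-spline ("TC") Gaussian prior `K(i,j) = c·ρ^max(i,j)`,
indexed from the most negative lag; `(c, ρ, σ²)` are chosen by
marginal-likelihood maximisation (L-BFGS-B on the log parameters, 3
starts; the likelihood is evaluated with 75×75 matrices via the standard
low-rank determinant/quadratic-form identities, so fits take well under a
second).  The posterior-mean filter equals the ridge-type estimate
`(XᵀX + σ²K⁻¹)⁻¹Xᵀy`.

Because the prior variance is largest at the most negative lag, the edge
taps can absorb residual low-frequency mismatch between the estimated and
the true input on short sessions; downstream summaries that look for the
physiological extremum should skip the first few edge taps (the pipeline
tests do).

Cross-covariances are computed over 30 s sliding windows with 50% overlap
on z-scored signals (i.e., correlations; a raw-covariance mode exists),
with positive lag meaning V_m follows the activity.  Coherence is
Welch-averaged with an analytic significance floor `1 − α^(1/(L−1))` for
L segments.

## Event statistics

Ripple-triggered averages use [−1, +1] s windows for fast components and
[−5, +5] s for slow components (slow trends around ripples evolve over
seconds); events without full window coverage are dropped; SEM is the
per-lag sample SD over events divided by √n.  RTA additivity
(fast + slow = total) is exact by linearity and asserted in tests.

The UDS significance battery follows the sampling scheme that removes
serial correlation: total (slow+fast) V_m sampled every 2 s for the mean
tests (Welch t and Wilcoxon rank-sum), fast V_m sampled every 1 s for the
variance tests (F and Ansari–Bradley), a χ² goodness-of-fit of state spike
counts against the session mean rate, and one-sample Z-tests of the 20
phase-bin means against zero at α/20, with phase modulation declared when
≥5 of 20 bins are significant.  The Z-test SD comes from the cell's
overall subsampled V_m (the variance source is not otherwise pinned down);
the tests apply to the detrended total V_m.  Type-I error of every test is
calibrated within the binomial 95% interval of nominal α on 500 null
simulations (tested), and power at a 2 SD state shift exceeds 0.9.

Big/small sharp-wave comparisons use pointwise paired t-tests across cells
at p < 0.01, with exact ties assigned p = 1, and contiguous significant
runs reported as (onset, duration).  Population images order cells by
their loading on the first principal component of the stacked response
matrix, with the component sign fixed so the mean loading of the top
quartile is positive.

## Adapting two-population rate model

Both populations follow `τ_r ṙ = −r + R∞(wr − ba + I + ξ)`,
`τ_a ȧ = −a + A∞(r)` with logistic activations (R∞: k=1, x₀=5; A∞: k=15,
x₀=0.5), τ_r=1, τ_a=25 (dimensionless AU), and Ornstein–Uhlenbeck noise
`dξ = −θξ dt + σ√(2θ) dW` (θ=0.05, stationary SD σ).  EC parameters:
w=6.8, b=1, I=2.1, σ=0.1.  CA3 receives `I = 2.5 − 0.6·r_ec` (net
inhibition from EC activity) and `w = 3.5 + 2.5·a_ec` (recurrent
potentiation tracking the slow EC state), with σ=0.25 and an independent
noise stream.  Integration is Euler–Maruyama at dt=0.01 (state-conditional
medians change by <2% when dt is halved); the OU noise uses its exact
discretisation.  Runs start at the EC DOWN fixed point.

Fixed points are the roots of `−r + R∞(wr − bA∞(r) + I)`, bracketed on a
dense grid and refined by bisection, with stability from the 2×2 Jacobian.
At the printed parameters the EC system is bistable with **five** fixed
points: two stable nodes, two saddles, and one fully unstable node at the
exact-symmetry point r = a = 0.5 (where R∞(5) = 0.5).  Clamping the EC at
its DOWN (UP) state leaves CA3 with a single stable fixed point, at a
lower rate in the UP regime — inhibited but excitable.

**Model UP/DOWN labels.**  The CA3 population does not see the raw EC rate:
its drive and recurrent gain follow `r_ec` through the adaptation variable
on the τ_a timescale, so CA3 excitability outlasts a rapid EC rate drop by
a few tens of AU.  Immediately after an UP→DOWN rate transition the CA3
field transiently combines near-UP recurrence (w ≈ 6) with DOWN-level
disinhibition (I ≈ 2.44), its low fixed point disappears, and a population
burst follows nearly deterministically within ~10 AU.  Labels derived from
the raw rate would therefore assign a visible fraction of bursts to
"DOWN" even though they are produced by the UP-state machinery.  `model_uds`
consequently thresholds the causally τ_a-smoothed EC rate by default
(threshold at the unstable fixed point nearest the stable-pair midpoint,
hysteresis ±10% of the stable separation); with these labels CA3 bursts
are fully contained in UP segments over long runs while the median CA3
rate remains higher in DOWN than UP.  Raw-rate labelling remains available
(`gate_tau=None`).  Burst detection uses upward crossings of 0.5 with a
τ_a refractory period; both are free choices exposed in the API.

## Pupil analysis

Circles are fitted to landmark points with the Taubin SVD algebraic
method, which is exact on noiseless circles and agrees with geometric
least squares to well under the landmark noise level.  A frame is valid
iff it has more than 3 points with likelihood > 0.7; a session passes QC
iff the mean likelihood across detected points exceeds 0.95 and more than
97% of frames are valid.  Diameter is 2r with gaps up to 0.5 s linearly
interpolated.  Blink detection — described only qualitatively in the
source analyses — is operationalised as frames whose mean landmark
likelihood falls more than 0.5 below its 1 s rolling median, and is
flagged experimental.

## Synthetic sessions

The generator produces the statistical structure the analysis assumes,
with full ground truth:

* **UDS**: alternating epochs with exponential durations (defaults: UP
  mean 3.06 s, DOWN mean 3.25 s), clipped below at one 4 Hz frame.
  Clipping (rather than resampling) preserves the configured mean to
  ~0.5%: `E[max(X, c)] = c + m·e^{−c/m}`.  Sessions open in DOWN.
* **DG events**: biexponential current dipoles (2 ms rise, 8 ms decay) in
  the molecular layer, forward-projected through the *same* spline iCSD
  forward matrix the estimator uses — making the forward→inverse oracle
  exact.  State-conditional Poisson rates default to 25 s⁻¹ (UP) and
  4 s⁻¹ (DOWN): dense enough that the 1 s running median of the rectified
  CSD sits on the event amplitudes during UP and near zero during DOWN,
  which is what makes the activity distribution bimodal.  The source
  analyses do not quantify these rates; they are free parameters.
* **Ripples**: 150 Hz, ~70 ms Hanning-windowed bursts on the CA1
  pyramidal-layer channel, only inside UP epochs, with lognormal radiatum
  sharp waves.  The occurrence rate ramps up through each UP epoch
  (thinning with a 0.5 s time constant) and terminates at the UP→DOWN
  edge, matching the observed within-state rate profile.
* **V_m**: slow component = subfield kernel ⊛ true activity.  Kernels are
  Gaussian bumps in mV·s⁻¹ per activity-z with extrema at the reported
  subfield medians: DG +37 ms, CA3 trough +296 ms (negative), CA1 −225 ms
  (leading).  Peri-ripple fast templates: DG/CA1 pre-ripple (−100 ms) and
  post-onset depolarisation bumps, CA3 post-onset trough.  Spiking is an
  inhomogeneous Poisson process with λ(t) = λ₀·exp(ΔV_m/2 mV), 5 ms
  refractory, rendered as 2 ms, 60 mV stereotyped transients that the
  spike detector finds.  White Gaussian noise (0.3 mV) and a slow drift
  ride on a −60 mV resting potential.
* **Pupil**: exponential relaxation (τ = 1 s) toward a state-dependent set
  point — dilated in DOWN, constricted through UP — with DOWN-only blinks;
  landmark point sets are emitted for the pupil module.

All randomness derives from one seed through `numpy.random.SeedSequence`
substreams spawned in a fixed order (UDS, events, ripples, LFP noise, one
per cell, pupil), so each component is independently reproducible.

What the generator does **not** emulate: 1/f LFP background, theta
epochs, conductance-based spike shapes, electrode drift, access-resistance
artifacts, correlated multi-channel noise, or anatomical gradients within
subfields.  Passing tests therefore establish that the pipeline recovers
known structure under the stated statistical assumptions — not that those
assumptions exhaust real recordings.

## Problem sizes and numerical defaults

Test and acceptance workloads use 3000 s activity-only sessions for
duration recovery (≈450 epochs per state), 600 s for lag recovery, 120 s
full sessions (10 seeds) for end-to-end ripple/UDS containment, 10⁴ AU ×
10 seeds for the rate model, and 500 replicates for test calibration —
sizes at which the recovered quantities' sampling error is comfortably
inside the tolerances being checked.  The acceptance script averages
duration recovery over five independent 3000 s sessions to report the
estimator's value rather than one session's sampling noise.  Matrix
inversions add `1e−12`-scale jitter before Cholesky factorisation;
degenerate inputs (constant activity, zero-variance signals, rank-0
response matrices) return flagged results or raise with diagnostics rather
than propagating NaNs.

## Known limitations

* Epoch-duration recovery inherits the ~3–4% upward bias of 4 Hz Viterbi
  decoding described above.
* The CSD inverse assumes cylindrical symmetry and homogeneous
  conductivity; λ chosen by channel-wise CV under-regularises if channel
  noise is strongly correlated.
* The TC-prior FIR can place spurious mass on the extreme negative-lag
  taps when input and output disagree at very low frequencies (short
  sessions, drift-removal mismatch).
* The marginal-likelihood surface for (c, ρ, σ²) can be multi-modal;
  three restarts have sufficed in testing but are not a guarantee.
* `hmmlearn`'s EM monitor occasionally reports a last-step likelihood
  decrease of ~1e−4; this is a convergence-tolerance artifact without
  effect on the decoded path.
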