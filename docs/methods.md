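# Methods

This note documents the models, estimators and numerical choices behind
`spikeconn`, and what the synthetic study conditions do and do not show
about real recordings.

## The inference problem

Given parallel spike trains, the cross-correlogram (CC) of an ordered
pair (reference *i*, target *j*) histograms the lags `t_tgt − t_ref` of
all spike pairs within ±W (default W = 50 ms, 1-ms bins).  A
monosynaptic connection appears as a hump (excitatory) or dip
(inhibitory) a few milliseconds to one side of the origin.  The
difficulty is that *unconnected* pairs also show CC structure whenever
the two neurons share background drive: smooth oscillations produce
smooth undulation, and background rate processes that are not
mean-square differentiable produce a *cusp* — a peak that is continuous
but not differentiable at zero lag.  The package implements three
estimators of increasing robustness to such structure, plus the
generative models needed to validate them with known ground truth.

Lag-bin convention: bins are mirror-symmetric about zero
(`[kΔ,(k+1)Δ)` on the positive side, `(−(k+1)Δ,−kΔ]` on the negative
side, zero lag in `[0,Δ)`), which makes the reversal identity
`c_ij(t) = c_ji(−t)` exact at the bin level for every input.  Pairs with
|lag| ≥ W are never counted and no edge correction is applied.

## Rate models (what the null looks like)

Pairs of conditionally independent Poisson trains driven by a shared
rate path:

- **sinusoid** `r(t) = r + a sin(ωt)` (phase lag φ and/or time lag for
  the second unit).  Analytic CC: `r1 r2 + (a1 a2 / 2) cos(ωt + φ)`.
- **gabor**: frequencies drawn per 10-s window from a normal around ω
  with SD 1/δ, giving the damped CC
  `r1 r2 + (a1 a2/2) e^{−t²/2δ²} cos(ωt + φ)`.
- **ou**: Ornstein–Uhlenbeck rate with mean μ, stationary SD σ and
  relaxation rate 2/τr, sampled by its exact Gaussian transition and
  clipped at 0 (tests use μ ≥ 2σ so clipping is negligible).  CC:
  `μ² + σ² e^{−2|t|/τr}` — an exponential cusp.
- **telegraph**: rate switching between μ±σ with exponential holding
  times of mean τr.  Same CC as the OU process: the correlogram does not
  identify the underlying rate process, only its autocovariance.
- **mixture**: sinusoid riding on an OU fluctuation (no closed form is
  exposed).

Sampling uses thinning against the path maximum on a grid with
dt ≤ τr/10.  `inject_synaptic_pair` is the generative twin of the GLM
observation model: the postsynaptic intensity is
`r_post(t)·exp(J Σ_k f(t−t_k))` with the same synaptic kernel the
estimator fits, computed by exact exponential recursion on the grid and
capped (default 1000 spikes/s) to guard against runaway excitation.

## Estimators

**Classical CC**: baseline = mean count at |lag| ∈ (10, 50] ms; exact
Poisson two-sided band at level α Bonferroni-corrected over the
detection-window bins (default [1, 5] ms, per direction); any bin above
(below) the band ⇒ excitatory (inhibitory).  The flat-null assumption is
exactly what common background drive violates, so this method's
false-positive rate on common-input pairs is the documented failure mode
(measured ~1 per direction at α = 10⁻⁴ on strong OU-cusp nulls).

**GLMCC / ShinGLMCC**: the CC counts are modelled as Poisson on the lag
axis with intensity `λ(t) = exp(a(t) + J_pos f(t) + J_neg f(−t))`,
`f(t) = e^{−(t−d)/τs}` for t > d else 0.  Discretization: one value of
a(t) per 1-ms bin; the expected count per bin is
`Δ·exp(a_b + J·F̄_b)` where F̄_b is the *exact* integral of f over the
bin divided by Δ.  This keeps the penalized objective concave.  Priors:

- glmcc: gradient penalty `(1/γ) Σ (Δa)²/Δt` over all adjacent bins
  (γ = 5×10⁻⁴ /ms);
- shin: curvature penalty `(β/2) Σ w·(second divided difference)²`
  computed separately within each half of the lag axis (β = 10⁶ ms³),
  with one shared origin-knot ordinate enforcing continuity at zero lag.
  Divided differences use the true knot spacings (half a bin next to the
  origin), so any continuous piecewise-linear V-shape has exactly zero
  penalty: the background may bend at the origin but nowhere else.

Fitting is damped Newton with backtracking on the concave penalized
objective (init a = log mean count, J = 0; convergence at relative
objective change < 10⁻⁸ or gradient sup-norm < 10⁻⁶; non-convergence is
flagged, never silently returned).  A 10-bin toy optimum matches a
derivative-free (Powell) optimizer to 10⁻⁶.

**Detection** is a per-direction Wilks likelihood-ratio test:
`D = logL(Ĵ) − logL(J=0)` using *unpenalized* data log-likelihoods of
the full fit and the J-fixed refit, detected iff `2D > χ²₁(1−α)`
(α = 10⁻⁴ by default, threshold ≈ 15.14), labelled by the sign of Ĵ.
D is evaluated at a fixed reference kernel (τs = 1 ms, d = 2 ms).  This
is deliberate twice over.  First, selecting the best-fitting grid point
and then testing there would test a data-chosen hypothesis and inflates
the null detection rate several-fold (measured 0.10–0.18 instead of
0.05 at α = 0.05 over 12 grid points); at a fixed kernel the test is
calibrated.  Second, the reference kernel's shape matters: the sharpest
grid timescale (τs = 1 ms) is the direction least representable by
either penalized background, which keeps the null 2D at its Wilks
reference (broader kernels are partially absorbed by the restricted
refit's background and drift conservative), while centring the kernel
at the typical transmission delay (d = 2 ms, the middle of the delay
grid) maximizes power over the few-millisecond effect window.  The
cost is reduced sensitivity to synapses with a 1-ms delay, whose first
effect bin lies outside the detection kernel's support.  When a connection is
detected, (τs, d) ∈ {1,2,3,4}×{1,2,3} ms is then grid-searched by the
full-model penalized objective (ties toward smaller d, then smaller τs)
and the reported J comes from the best grid point; on injected ground
truth this recovers the true kernel modally and the mean Ĵ within
±0.15.

Two calibration caveats, measured and documented rather than hidden:
(i) the glmcc variant becomes mildly *conservative* as counts grow,
because its relatively weak gradient prior lets the background absorb
part of the kernel-direction noise in the restricted refit; (ii) at the
printed hyperparameter values the gradient prior is overall more
flexible than the shin curvature prior for per-bin counts above a few,
so on OU-cusp nulls at desk scale *both* GLM variants absorb the cusp
and neither produces false positives, while the classical test fails
almost always — the comparative ordering (shin ≤ glmcc ≪ classical)
holds, with the two GLM rates at zero.  Shin's distinctive freedom — a
background that can bend at the origin while staying stiff elsewhere —
is verified structurally through its penalty nullspace and its exact
V-shape invariance.

`estimate_connectivity` evaluates each unordered pair once (one CC
serves both directions), is deterministic given dataset and
hyperparameters, records per-pair failures instead of aborting, and can
process pairs in parallel (joblib) with results identical to sequential
execution.  The E–I dominance index of a unit is
`d_ei = (n_e − n_i)/(n_e + n_i)` over its outgoing detected edges,
undefined (NaN) when it has none.

## MAT network simulator

Neurons are leaky integrators *without* voltage reset whose threshold
jumps by α₁+α₂ after each spike and relaxes on τ₁ = 10 ms and
τ₂ = 200 ms; membrane, synaptic and background-conductance equations and
all parameter values (membrane time constants, reversal potentials,
weight and delay distributions, OU background parameters) follow the
reference configuration: 1,000 neurons (800 E innervating 12.5% of
others with log-normal conductances, log-mean −5.543, log-SD 1.30;
200 I innervating 25% with normal conductances 0.0217 ± 0.00171,
negative draws resampled), delays uniform [3,5] ms (E) and [2,4] ms (I),
the whole matrix multiplied once at build time by a strength constant A.
Integration is Euler–Maruyama at dt = 0.1 ms with exact exponential
decay for conductances and threshold states, exact OU transitions for
the background conductances (clipped at 0), a per-target delay ring
buffer, and a 2-ms absolute refractory period (the model family's
standard choice; without it a supra-threshold membrane would re-trigger
every step).  The membrane equation divides the background term by τm
but not the recurrent conductance term, exactly as specified for this
model.  Simulations are bitwise reproducible given (config, seed), abort
with a diagnostic on |v| > 10³ mV, and halving dt changes total spike
output by < 5% in the asynchronous regime.

**Downscaling.** Tests and the regime demonstration use N = 100 (80 E /
20 I) for tractability, multiplying synaptic weights by 1000/N so each
neuron keeps the full-size network's expected recurrent drive (standard
downscaling compensation; `scaled_config`).  Sweeping A over
{0.6, 1.2, 1.8} at 200 s reproduces the asynchronous → bursting →
oscillatory-bursting transition: the population Fano factor (10-ms bins
of the summed train) rises ≈ 2.8 → 9.0 → 12.8, and the summed-train
autocorrelogram envelope decays exponentially from the origin (τ ≈ 12 ms
at A = 1.8) — the cusp signature.  One downscaling artifact matters: the
strong compensated synapses lock population bursts into ~4–5 ms volleys
(set by the excitatory delay band), putting a fast ripple on the 1-ms
autocorrelogram that neither cusp nor hump candidate models.  The
regime diagnostic therefore compares the two peak models on 5-ms
coarse-grained lags over ±40 ms, where the question is about the
envelope's shape; at 1-ms resolution with high counts the ripple
dominates the likelihoods.  What these tests show is that the estimators
and the regime phenomenology behave correctly at reduced scale; they do
not reproduce the full-size network's counts, nor biological numbers,
which require the original recordings.

## Cusp-vs-smooth diagnostic

`cusp_vs_smooth_test` fits `baseline + A·e^{−|t|/τ}` against
`baseline + A·e^{−t²/2s²}` (equal parameter counts) to the central
±10 ms of a self-count-free autocorrelogram by maximum Poisson
likelihood (Nelder–Mead over log-parameters, three scale starts) and
reports the log-likelihood difference; on synthetic counts from either
family the correct form is preferred in ≥ 90% of replicates, and flat
counts give |Δ| < 2.  These two forms are the minimal representatives of
the piecewise-nondifferentiable and everywhere-smooth classes; richer
families would change Δ's magnitude but not the sign logic.

## Evaluation

Estimates are scored per category (excitatory / inhibitory) as binary
classification over all N(N−1) ordered pairs.  True excitatory edges
with raw conductance ≤ 0.01 (before the A multiplier) are excluded from
the excitatory universe entirely — neither positives nor negatives —
because they are undetectable in principle at these durations.  A
sign-flipped detection counts as FN in the true category and FP in the
reported one.  MCC uses the standard binary formula with the
zero-denominator convention MCC := 0; the headline score is the macro
average `(MCC_e + MCC_i)/2`.

## Surrogates

`jitter_surrogate` displaces each spike independently and uniformly on
±half-width (clipped to the recording span).  Note the intrinsic limit
of jitter as a cusp probe: ±2 ms jitter smears lags by a triangular
±4 ms kernel, which still leaves 44% of an arbitrarily sharp cusp's mass
within |lag| ≤ 1 ms, so the central excess of a sharp cusp flattens to
just under half — broader cusps flatten less.  `shuffle_surrogate`
permutes each unit's inter-spike intervals and re-accumulates from its
first spike, preserving per-unit rate and ISI statistics while
destroying cross-unit timing; it serves as the temporal-variability
reference for population rasters.

## Study conditions used by the validation suite

All stochastic operations take explicit integer seeds and are
deterministic given them.  The suite's problem sizes: analytic-CC
recovery at T = 3600 s; OU/telegraph equivalence pooled over six
3600-s pairs (recovered τr within 4% pooled); Wilks calibration on
1000 null pairs at 5 spikes/s × 3600 s (the rate of the power example
and the standard recording duration); coupling recovery on 50 injected
pairs at 10 spikes/s × 1800 s; comparative cusp robustness on 200 OU
pairs at 600 s; the network sweep at N = 100 × 200 s.  These choices
put the asymptotic tests in their asymptotic regime while keeping the
full suite within ordinary desk runtimes.

## Known limitations

- The LR test's null calibration is asymptotic; at very low counts
  (per-bin counts ≲ 20) it drifts conservative, more so for glmcc.
- The penalized backgrounds make the two GLM variants' *relative*
  goodness-of-fit scale-dependent; claims about which variant "fits a
  cusp better" only make sense at fixed counts and hyperparameters.
- The generators produce stationary (or piecewise-stationary)
  backgrounds; real recordings add nonstationarity, refractoriness and
  sorting artifacts that none of the synthetic conditions emulate, so a
  green suite validates the estimators' statistical machinery, not
  their field performance.
- The network demonstration is a downscaled surrogate of the full-size
  simulation; edge-level recovery rates at N = 100, short T are far
  from the full-scale FPR/FNR curves.
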