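# Methods

This note records the model, the estimators, the numerical choices and the
known limitations of the package, in the package's own terms.  Symbols
follow `README.md`.

## Data model and conventions

A session is `M` trials × `N` neurons of sorted spike times in
trial-relative seconds, with three contiguous behavioral epochs
(sample → delay → response) shared by all trials.  Everything downstream
uses two grids:

* the **latent grid**: bins of `S_bin = 67.4 ms`, half-open
  `[T·S_bin, (T+1)·S_bin)`, 0-based, 20 bins per epoch by default (the
  epoch lengths are configurable; only the classification step depends on
  the 20-bin convention);
* the **fine grid**: `δt = S_bin/60 ≈ 1.12 ms`, 60 steps per bin.

A spike exactly on an edge belongs to the later bin/step.  Correlogram lag
`k > 0` covers `[t_ref+(k−1)τ, t_ref+kτ)` and negative lags mirror it;
a target spike at exactly the reference time counts at lag +1.
Autocorrelations (`i = j`) are excluded throughout.

## Latent model (SNA)

Epoch-switched linear-Gaussian state space on the latent grid:
`x_T = A(s_T) x_{T−1} + w_T`, `w ~ N(0, Q)`;
`y_T = C(s_T) x_T + d + v_T`, `v ~ N(0, diag(R))`, with `x_1 ~ N(μ0, P0)`.
Parameters switch at the cued epoch boundaries; the latent state is
continuous across switches.

**Observation scale.**  `y = counts/S_bin`, i.e. the additive-Gaussian
model acts on the natural rate scale.  At the sub-spike-per-bin counts
typical of cortical data (≈0.5 spikes/bin at 8 Hz), a square-root
variance-stabilizing transform would make the back-transformed smoothed
rate biased low by a factor ≈2.4, which in turn biases the ECCG and breaks
the DCCG's null (CCG−ECCG must average to zero for purely latent-driven
data).  The rate-scale model keeps the smoothed estimate unbiased; the
sqrt alternative remains available (`fit_edlds(..., transform="sqrt-rate")`)
for settings where variance stabilization matters more than ECCG
calibration.

**Fitting.**  Plain EM.  The E-step is an exact Kalman filter/RTS smoother;
because every trial shares the schedule and noise model, all covariance
recursions and gains are trial-independent and only the means are
propagated per trial, which makes the fit linear in `M`.  The M-step is in
closed form: per-epoch `A(s)` from the transition moments of bins whose
*target* bin lies in the epoch, a joint block solve for the per-epoch
projections `C(s)` and the shared offset `d`, shared `Q` and diagonal `R`,
and `μ0, P0` from the first-bin posterior.  The marginal log-likelihood is
recorded every iteration and is non-decreasing; covariance eigenvalue
clipping and observation-variance flooring (`1e-8`) trigger only on
degeneracy and are logged as warnings.

**Initialization.**  Factor analysis per epoch for `C(s)` (fixed
`random_state`), shrunk identity `A = 0.9·I`, `Q = (1−0.81)·I`, data mean
for `d`.  Defaults: `max_iter = 100`, relative tolerance `1e-6`.  The
latent dimension defaults to 8 for real data and is overridable; held-out
`model_loglik` supports selection.  Analyses of generated sessions in the
tests and the acceptance script use the generator's own dimension (2),
which is part of the simulation's ground truth.

**SNA.**  The smoothed projection `C(s) x̂ + d`, rectified at
`ε_r = 0.1 spikes/s` so every downstream probability is strictly positive.
Piecewise-constant within each bin.

## Correlograms

CCG: per ordered pair, the trial average of per-reference-spike lagged
target counts divided by `τ` (default 25 ms; the 15–45 ms range behaves
similarly).  A trial without reference spikes contributes zero to the
average and stays in the trial count; a pair with no reference spikes in
the entire scope is flagged undefined, never silently zero.  ECCG replaces
the target count with the time-average of the target's piecewise-constant
SNA over the same window (length-weighted across bin edges, truncated at
trial boundaries; a reference spike whose window lies entirely outside the
trial is dropped from that lag's average).  DCCG = CCG − ECCG elementwise,
undefined flags propagating.

**Windowed estimation** (for the transient correction): centered windows
of 20 bins × 20 trials around each (bin, trial), truncated at session
edges with the denominator adjusted to the spikes actually used; the SNA
is fit once per session and reused in every window.  Centered windows were
chosen for symmetry.  The all-centers path computes identical values via
cumulative sums over bins and trials and is tested against the per-center
path.

## Transient correction and mixing (TSNA / ONA)

Within bin `T`, the corrected rate at fine step `t` is
`r_C(t) = Σ_{j≠i} [1{after_j}(t)·C_ij(τ) + 1{ahead_j}(t)·C_ij(−τ)] · r_i^T
/ Σ_{j≠i} C^E_ij(±τ)` — each reference's contribution is its windowed CCG
weighted by the population's summed windowed ECCG at the matching lag.
The forward weight `C_ij(τ)` acts on steps within `τ` *after* a reference
spike and the backward weight on steps within `τ` *ahead of* one, so each
lag's weight is applied to the steps that lag describes; this is the
reading consistent with the pairwise measure ("the target firing after the
reference's firing") and it is what makes injected couplings visible at
the read-off steps.  A zero ECCG denominator, or a corrected trace with
zero mean, falls back to the constant SNA for that bin and is flagged.

TSNA rescales the corrected trace so its bin mean equals `r_i^T` exactly
(asserted at `1e-9`); consequently every mixture `α·TSNA + (1−α)·SNA`
preserves the bin mean.

**Mixing objective.**  `P(t) = (α·TSNA(t) + (1−α)·r_i^T)·δt`, clipped to
`[ε_p, 1−ε_p]`, `ε_p = 1e-6`.  The default objective is the log-Bernoulli
likelihood `Σ_t [δ_t log P + (1−δ_t) log(1−P)]`, concave in `α`, which
yields interior, evidence-weighted mixtures: bins without target spikes
drive `α → 0` (no evidence for transient structure), bins whose spikes sit
on TSNA peaks drive `α → 1`.  An additive score
`Σ_t [δ_t P + (1−δ_t)(1−P)]` is available as `objective="sum"`; because
the TSNA normalization fixes `Σ_t P`, that score is exactly linear in `α`
(slope `2δt·Σ_{spike steps}(TSNA−SNA)`), so its optimum is always an
interval endpoint and every spikeless bin is exactly flat — it cannot
express graded mixtures, which is why it is not the default.

**Optimization.**  `Q = logit(α)` is searched on `[−10, 10]`
(`α ∈ [4.5e-5, 1−4.5e-5]`).  The additive score is maximized exactly by
enumerating the interval endpoints and clipping breakpoints of the
piecewise-linear objective.  The log-likelihood is maximized on a logit
lattice of resolution 0.01 (coarse step 0.5, then a fine pass over the
bracketing interval) — the optimizer's stated resolution; differences
below it change the objective by ≪1e-6.  A flat objective (TSNA ≡ SNA)
tie-breaks at `Q* = 0` (`α* = 0.5`) and is flagged.  Per-(neuron, trial,
bin) optimization is independent; the batched session path is tested to
agree with the single-bin optimizer.

## Divergence measures

**DONA** (per neuron, trial, bin): `Σ_t P_ONA(t)·log(P_ONA(t)/P_SNA)` over
the 60 steps, natural log, probabilities clipped as above and *not*
renormalized within the bin (the literal per-step firing probabilities).
Non-negative whenever the bin mean is preserved.

**PDONA** (per ordered pair, trial, bin): the `n = 6` consecutive
reference spikes whose mean time is nearest the bin center (ties toward
earlier spikes, same trial) define read-off steps one `δt` after each
spike; the target's ONA- and SNA-implied Bernoulli probabilities there
define two distributions over the `2^n` firing patterns (normalized per
the pattern-probability definition — the normalizer is exactly 1 for
probabilities in (0,1)), and PDONA is their KL divergence.  The session
path uses the algebraically identical sum of per-spike Bernoulli KLs; the
single-pair function enumerates the patterns literally, and the two are
tested against each other.  A reference spike whose read-off step falls
past the trial end reads the containing bin's SNA value for both sources.
Pairs whose reference fired fewer than 10 times in the trial (or fewer
than `n`) are excluded with a reason code, never silent zeros.
`n ∈ {5,7,8}` is supported.

## Statistics

* **Epoch preference**: series are trial-averaged first; for each unit,
  each epoch's 20 bin values are compared against each other epoch's by
  one-sided Wilcoxon rank-sum tests at raw `p < 0.05` with a
  larger-median requirement.  An epoch that beats both others labels the
  unit; beating exactly one yields the residual "two-epoch" label; none,
  "none".  The raw-p convention (no multiple-testing correction) is the
  procedure's definition; Benjamini–Hochberg can be applied externally to
  the returned p-value table.
* **Proportion tests**: χ² on 2×2 preferred/not tables without continuity
  correction; Fisher's exact test (flagged) when an expected cell is
  below 5.
* **Decoding**: per neuron, `logit P(ipsi) = c_0 + c_sp·log(N_sp+ε) +
  c_DONA·log(DONA+ε)` with `ε = 1e-6` guarding zeros, fitted by maximum
  likelihood (statsmodels); the reduced model drops the interaction term;
  AICs are compared on identical trials.  Suspected separation falls back
  to an L2-penalized fit and is flagged.  Predictors default to the delay
  epoch's per-trial totals (configurable).
* **NCC**: `ρ_ij` is the across-trial Pearson correlation of the two
  neurons' counts in the bin — the only construction that yields one
  coefficient per bin — and `ρ_i` the root mean square over valid
  pairings; zero-variance neurons are excluded with the denominator
  adjusted and flagged.

## Synthetic sessions

The generator emulates the assumed data-generating process: a latent
trajectory with per-epoch rotation/decay dynamics (stationary variance ≈1
per coordinate), unit-norm projections scaled so latent-driven rate
fluctuations have sd ≈ 35% of baseline, baselines drawn once per neuron
from U(4, 12) Hz (a realistic cortical range), rates rectified at
0.5 spikes/s, and spikes drawn by per-`δt` Bernoulli thinning (consistent
with the analysis's probability model).  Directed couplings multiply the
target's rate by a gain for a fixed kernel (default `τ`) after each
reference spike, gated by the current epoch — the simplest mechanism that
produces the transient short-lag DCCG signature while leaving slow shared
dynamics untouched.  Couplings are applied causally step by step; spike
times sit at step centers so they never coincide with bin edges.  Presets:
`tiny` (3 neurons × 5 trials), `null` (20 × 100, uncoupled), `recovery`
(20 × 100 with ten gain-2 response-gated couplings, refs 0–9 → targets
10–19).

What the generator does **not** emulate: refractoriness beyond one spike
per `δt` step, bursting, non-Poisson dispersion, epoch-locked stimulus
transients, electrode drift, or sorting errors.  Passing tests therefore
demonstrate correctness of the estimators under the model's own
assumptions, not robustness to real-data violations of them.

## Sensitivity of the pairwise measure

The correction expresses a pair's transient effect through the weight
`C_ij/Σ_j C^E_ij`, i.e. diluted by the population's summed expected rate.
With 20 neurons at 4–12 Hz, a coupling that truly doubles the target's
conditional rate appears as only a ~13% vs ~6% (coupled vs uncoupled)
conditional TSNA elevation, further scaled by the fitted `α`; and the KL
floor of PDONA scales with the target's rate, so absolute PDONA values are
not comparable across pairs with very different rates.  In simulation the
pipeline cleanly recovers and epoch-localizes couplings of gain ≈3 and
separates coupled from uncoupled pairs by raw PDONA at gain ≈5; gain-2
couplings sit near the detection threshold of the per-epoch rank-sum
procedure and below the threshold of absolute cross-pair PDONA
comparisons.  Within-pair contrasts (the same pair across epochs, or
references onto the same target) are the reliable comparisons; the
epoch-classification procedure is of this kind.

## Reproducibility and problem sizes

Every stochastic component takes a `numpy` `Generator` seed; pipeline runs
serialize their full configuration, seed and flags to `manifest.json`, and
identical configurations reproduce outputs bit-for-bit.  Tests and the
acceptance script analyze the preset sizes above (20 neurons × 100 trials
for the null/recovery studies; 200 trials for subspace and decoder
recovery; 50 random small sessions for the estimator oracle), with EM
capped at 60 iterations for generated sessions — past that point parameter
changes are below the tolerance at these sizes.

## Known limitations

* The per-bin `α` is estimated from ≈0.5 expected spikes per bin; it is a
  noisy, heavily shrunk quantity, and DONA inherits a selection-driven
  noise floor from it.
* Session-level exchangeability of trials is assumed by the windowed
  estimators and by the trial-shuffled null; slow drift across trials
  violates it.
* The NWB container is not read directly; sessions enter through the
  native delimited-text tables (or the in-memory API).
* Nonlinear or state-switching latent models and learned (GLM-style)
  coupling kernels are out of scope; the correction is ratio-based by
  construction.
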