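# Methods

This note documents the models, conventions and defaults implemented in
`tempoprep`, the choices made where a convention was genuinely open, and what
the synthetic-data tests do and do not establish.

## Foreperiod distributions

A block's foreperiod (FP) distribution is represented as probability mass on a
1-ms grid over the admissible range, 1250–2750 ms by default.

- **Baseline (B)**: Gaussian with mean at the anchor (1600 or 2400 ms) and SD
  equal to the display's technical jitter (default 5 ms); `jitter_sd = 0`
  yields an exact point mass.
- **Uncertain (U)**: Gaussian with SD 120 ms (the anchor convolved with the
  uncertainty kernel).

Discretisation integrates the Gaussian density over each 1-ms cell (CDF
differences, exact at any kernel width). Mass outside the range is *cut and
the distribution renormalised*; the range endpoints are part of the design,
but the truncation rule itself is this package's convention. Truncation
preserves unimodality up to floating-point underflow in the far tails
(~1e-15 relative). For reporting and for trial-level regressors, mass is
aggregated into 50-ms half-open bins `[lo, hi)` on the absolute 50-ms lattice
(which passes through the 1250-ms range start); the range maximum closes the
final bin. In simulated designs the baseline block's range is additionally
tightened to anchor ± 3 jitter SDs so that every baseline trial stays in that
window.

Whether the original experiment drew U durations from a continuous or
pre-binned grid is unknown; the 1-ms grid is an assumption and is fine enough
that the 50-ms binned statistics are insensitive to it.

## Hazard-rate variants

On the binned support restricted to bins with positive mass:

    HR_classic(t_i) = p_i / S(t_i),   S(t_i) = Σ_{j ≥ i} p_j

Survival is evaluated *before* the current bin (computed by reverse
accumulation, so no cancellation), which makes the hazard at the final
occupied bin exactly 1 — the terminal-certainty property of a bounded FP
range. Two derived variants serve as alternative regressors:

- `HR_mirror = 2·mean(HR_classic) − HR_classic` (value reflection about the
  mean). "Mirrored around its mean" could in principle also mean time
  reversal; value reflection is implemented because it produces the described
  decreasing trend with a local minimum at the anchor, and the reflection is
  an involution that preserves the mean.
- `HR_rec = 1 / HR_classic` (defined because the support excludes zero-mass
  bins); equals 1 at the final bin.

The exact conditional-CDF formula behind the published hazard curves is cited
rather than printed in the source literature; the convention above is flagged
here so users can compare against their own.

**Subjective (blurred) hazard.** Scalar expectancy is modelled by spreading
each mass point at time τ as a Gaussian `N(τ, φ·τ)` before computing the
hazard (each source kernel integrated over destination cells, so the φ → 0
limit is exact). The blur coefficient φ defaults to 0.26, a Weber-like
fraction typical of interval-timing calibrations; it is a free parameter of
the package, not an estimated quantity, and every function exposing it
accepts other values.

## Preparation models and predicted curves

All latency mappings are affine (`a` ms intercept, slope `b`), because the
hypotheses are compared on curve *shape*; defaults for the hazard mapping
(`a = 217.924`, `b = 0.371`) come from the fitted latency ~ reciprocal-hazard
relation of the short-anchor uncertain condition. The model set:

| name | mean latency | SD over FP |
|---|---|---|
| `hr_classic` | `a + b/HR` | affine decreasing in `HR_classic` (the empirical pattern) |
| `hr_subjective` | `a + b/HR_subj` | grows with FP (`sqrt((k·t)² + baseline_sd²)`) |
| `pdf` | `a − b·f(t)/max f` | valley at the mode |
| `fmtp_trace` | `a − b·preparation(t)` | grows with FP |
| `scalar_noise` | flat `a` | `sqrt(k²·t² + c)` |
| `linear_fp` | `a + b·t` | constant |

`fmtp_trace` implements only the trace-plus-smearing core of multiple-trace
preparation: each past FP contributes a Gaussian density (`sd = smear_k·FP`)
weighted by `decay^j` over trial lag `j`. It is deliberately "fMTP-like": the
full published model's activation/inhibition dynamics are out of scope, and
no canonical `decay` default exists, so it is a config knob (default 1 = no
forgetting). `linear_fp` (latency affine in FP) is included as a generative
convenience for parameter-recovery work; it is not one of the competing
hypotheses.

On the PDF account, the predicted variability curve has its *minimum* at the
distribution mode and rises on both flanks (the inverse of the bump-shaped
pmf).

## Synthetic experiment

`build_design` reproduces the design skeleton: per subject, four blocks of
`n_trials_per_block` trials; within an anchor the B block always precedes the
U block (to keep the baseline uncontaminated by carry-over), and half the
subjects start with the short-anchor pair (odd subject counts are
counterbalanced as evenly as possible, with a warning). Target side is
left/right with p = 0.5. Defaults are the study's scale: 42 subjects × 100
trials/block = 16 800 trials.

`simulate_latencies` adds `latency = model mean + subject intercept + ε` with
subject SD 33.571 ms and residual SD 51.905 ms by default — the random-term
SDs of the fitted short-anchor mixed model, used as generator truth so that
parameter-recovery tests run at realistic noise. Latencies below 100 ms /
above 1000 ms are flagged anticipatory/late. `apply_dropout` flags a
Bernoulli artifact subset, default rate 5.07% (the published blink/lost-signal
loss). The anticipatory/late/off-target rates are not separately published;
they are independent knobs (`off_target_rate` default 0.05 in pipeline runs),
so the default pipeline does not — and is not meant to — reproduce the
published 69.5% visually-guided rate, which depends on those unpublished
rates. The accounting arithmetic itself is exact (see below).

Gaze traces are cyclopean 500 Hz x/y in degrees: fixation noise (0.04° SD), a
minimum-jerk saccade of 9.5° amplitude and 48 ms duration at IS onset +
latency (peak velocity ≈ 370°/s, peak acceleration ≈ 25 000°/s², comfortably
above the detection thresholds), optional ≥100 ms NaN blink gaps. Only the
detector-facing properties are contractual; the kinematic profile is not a
physiological model. First trials of a block have missing `fp_prev` (not
zero); sequence-based fits exclude them.

One master seed spawns per-stage child seeds (design, latencies, dropout) via
`numpy` SeedSequence, so runs are reproducible end to end and stages can be
re-run in isolation.

## Preprocessing

Velocity and acceleration come from central differences with a 3-sample
moving-average smoother (the original detection was vendor software; the
thresholds are the only published contract). A saccade is a contiguous
supra-22°/s episode with peak acceleration > 3800°/s² and displacement > 1°;
episodes touching NaN samples are discarded. Artifact rejection drops trials
with a blink gap at or after the warning stimulus, and trials whose recording
continuity is broken: a sample-to-sample jump > 2° outside detected saccades,
or a detected episode that is not a plausible eye movement (peak velocity
> 800°/s — beyond the saccadic main sequence for these amplitudes — or
duration < 10 ms). Visually-guided selection takes the first saccade with
latency in [100, 1000] ms after IS onset — endpoints *inclusive*, a
convention this package fixes because "between 100 and 1000 ms" does not
specify endpoint handling — landing within the 3 × 3° target box. Percentages
in the accounting table are computed on the total trial count and rounded
half-up to two decimals, matching the published table's rendering (16 800 /
15 948 / 11 676 → 100.00 / 94.93 / 69.50, blink loss 5.07).

## Statistical battery

- **Mixed models** (`LatencyMixedModel`, backed by statsmodels MixedLM):
  Gaussian-identity, latency on one predictor (`fp_n`, `fp_prev`, `sequence`,
  `hr_rec`), subject random intercept (`rs1`) by default; `rs2`–`rs4`
  (slope-only, uncorrelated intercept+slope, correlated intercept+slope) are
  reconstructions of the unpublished random-slope candidates. REML for
  reported fits; ML for fixed-structure comparison. Wald 95% CIs (the CI
  method is not named in the source; Wald is the default here). BIC is
  lme4-style, `−2 logLik + npar·log(n_obs)` with npar = fixed effects +
  covariance parameters + residual. Singular/non-convergent candidates are
  reported as such with infinite BIC, never silently simplified. For the
  structure-selection step the predictor is standardised (the likelihood is
  invariant to linear predictor rescaling; raw millisecond scales make slope
  variances numerically tiny). The sequence predictor is
  `fp_prev − fp_n`; the Methods-style sign convention is recorded in each
  result's metadata because the source describes it both ways.
- **Binned linear models**: latencies averaged within 50-ms FP bins (bins
  with ≥ 2 trials), OLS of bin means on FP or on the reciprocal hazard,
  adjusted R² reported.
- **Weber slope analysis**: OLS of bin variance on FP²; slope = k², intercept
  = c; `weber_obeyed = (k² > 0)`. Unweighted by default (whether the original
  analysis weighted bins is unstated); an optional weights argument supports
  precision weighting (the variance of a sample variance scales with σ⁴).
- **Paired SD test**: two-sided paired t on per-subject latency SDs; degenerate
  zero-variance differences are rejected, not silently passed.
- **TOST, paired (d_z bounds)**: because the bounds are standardised, the
  observed `t = d_z·√n` follows a *noncentral* t under either boundary null
  (noncentrality ±sesoi·√n). The one-sided p-values use that exact
  distribution — so the rejection rate at the bound equals α — and the
  (1 − 2α) CI inverts the same tests, making "equivalent" exactly "CI inside
  bounds". The common central-t shortcut on sample-SD-converted bounds is
  conservative at small n (size ≈ α/2 at n = 12). α = 0.01 and the d_z bounds
  ±1.125 are the study's values.
- **TOST, coefficient (f² bounds)**: the published bounds (±0.09 short,
  ±0.02 long anchor) are on Cohen's f² without a printed conversion. The
  implemented reconstruction scales the coefficient to a signed f via
  `f = β·sd(x)/σ_resid`, translates ±sesoi_f² to a raw-coefficient bound
  `√(sesoi_f²)·σ_resid/sd(x)`, and runs two one-sided Wald t-tests on β.
- **Family diagnostics**: gamma / inverse-Gaussian / log-Gaussian fits are
  available only as residual-summary diagnostics; the Gaussian identity model
  is the single inferential family (the original model comparison retained
  it).

The study-wide significance level is 0.01 throughout.

## What the synthetic tests show — and what they do not

Test problem sizes were chosen to exercise each statistical property at
adequate power while keeping the default suite fast: parameter recovery runs
100 replicates of the full 42 × 100 single-block design; TOST calibration
uses 10 000 replicates at n = 12 with bound 0.5 (exact size does not depend
on n); Weber recovery uses 30 bins × 10 000 trials with k² = 0.01 and
c = 51.905² (the residual-variance floor), where the estimator's sampling
error is comfortably inside 20%; the sampling-oracle hazard check uses 10⁶
draws.

The generator draws Gaussian residuals with a constant (or model-prescribed)
SD, independent trials apart from the explicit trace model, no learning, no
fatigue, no calibration drift, and clean parametric saccades. Passing tests
therefore establish that the *machinery* is correct — hazard arithmetic,
model fitting, selection, calibration of the equivalence tests, detector
behaviour on its contractual features — not that real saccadic latencies obey
any particular model. Empirically shaped features of real data (skewed
latency distributions, express saccades, drift) are out of scope, and the
published coefficient values cannot be reproduced here because the original
dataset is available only on request; where those values appear as defaults
they are generator inputs, not results.

## Known limitations

- The fMTP-like model is a two-parameter summary; conclusions about the full
  multiple-trace model do not transfer.
- Hazard variants are defined only on bins with positive mass; regressor
  lookups outside the occupied support raise rather than extrapolate.
- Reciprocal hazards become numerically huge in far-tail bins (mass ~1e-10);
  such bins are never sampled in practice but curves over the full support
  should be read with that in mind.
- MixedLM Wald p-values are asymptotic; no small-sample df corrections
  (Kenward–Roger/Satterthwaite) are provided.
- The trace simulator is monocular ("cyclopean"); binocular disparity and
  calibration drift are not modelled.
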