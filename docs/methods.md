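# Methods

This note documents the models, defaults and numerical choices behind
`revlearn`, and what the synthetic-data tests do and do not establish about
real recordings.

## Trial structure

All analysis is organised around a `TrialSchedule`: 1-minute trials of which
only the first 20 s are imaged (5 fps, 100 frames), odor on at t = 5 s for
5 s, shock (when present) 4 s after odor onset for 100 ms. The standard
protocol is five acquisition rounds (CS+ shocked, CS− not) followed by two
reversal rounds (CS+ unshocked, CS− shocked), odors alternating CS+/CS−
within each round — 14 trials. Mock variants keep the structure and disable
every shock. Time is zero at imaging onset *within each trial*; every trial
is processed independently because the excitation lights (and therefore
bleaching) are only on during the imaging window and the baseline R₀ is
defined per recording.

## Generative model (synthetic data)

Per trial, with local time t and cumulative illuminated time t_cum:

```
G(t) = [B_G + A·k(t − t_odor) + A_s·k(t − t_shock)] · bleach_G(t_cum) · M(t) + ε_G
T(t) =  B_T                                         · bleach_T(t_cum) · M(t) + ε_T
```

* `k` — peak-normalized difference of exponentials (rise 0.2 s, decay
  1.5 s), a generic smooth causal calcium-indicator kernel; any such kernel
  suffices for recovery testing since the pipeline never assumes its shape.
* `bleach` — double exponential `a₁e^(−t/τ₁) + a₂e^(−t/τ₂) + c`, default
  (0.3, 30 s, 0.1, 300 s, 0.6) on both channels. The clock is cumulative
  illuminated time, so per-trial segments remain exactly in the
  double-exponential family with rescaled amplitudes. Shared bleach makes
  the ratio trend-free by construction; per-channel overrides exist to
  exercise the detrender, since whether the two fluorophores bleach equally
  in a given preparation is an empirical question.
* `M` — motion artifact: exponential of low-pass-filtered white noise
  (0.5 s smoothing, log-sd 0.05), the *same realization on both channels*.
  This encodes the design assumption that justifies ratiometric imaging;
  its cancellation in G/T is exact, and tests assert that.
* `ε` — i.i.d. Gaussian sensor noise, default 1.5 a.u. per channel per frame
  against 100 a.u. baselines (≈2% per-frame ratio noise; peak-response SNR
  ≈14, chosen to emulate ROI-averaged GCaMP6f recordings in which
  single-trial transients are cleanly visible, as they are in this
  preparation).
* Response amplitude A = 30 a.u. × a per-trial multiplier from a declarative
  plasticity profile; shock response A_s = 40 a.u., constant. Profiles are
  tables, not update rules — the study quantifies trial-wise changes and
  prescribes no plasticity dynamics. The `PAM-b'2a` preset drops the CS+
  multiplier 1.0 → 0.4 linearly across acquisition and rebounds to 0.7 on
  reversal trial 2 (the omission experienced on reversal trial 1 takes
  effect on the next trial); CS− stays at 1.0. The real cells also show a
  small CS− decrease after one reversal trial, which the default preset
  deliberately omits so that CS− differences are a true null. Presets for
  `MBON-g2a'1` (same sign pattern) and `MBON-g5b'2a` (potentiates during
  acquisition, depresses after reversal) are included; `flat` is the
  no-plasticity control.

Every simulated trace carries its ground truth (per-trial multipliers,
amplitudes in ΔR/R₀ units, and the expected windowed response mean computed
from the kernel), so recovery tests need no external reference.

Quadrant occupancy is Binomial(n, p) per configuration; synapse tables draw
per-pair counts from Poisson(mean) or take exact counts, with uniform
coordinates in a unit box.

## Trace processing

* **Ratio** G/T, with a hard error naming the first frame where T ≤ 0.
* **Detrend**: fit the double exponential to frames outside the stimulus
  mask and subtract it, preserving the initial level
  (R_d = R − f(t) + f(t₀)). Subtractive rather than divisive correction
  keeps ΔR/R₀ well defined and reduces to the identity when there is no
  bleach; which variant the original analysis used is not determinable, so
  the choice is fixed here and documented. The mask covers
  [odor onset, odor offset + 6 s): the pad spans four decay constants past
  the shock transient — with a shorter pad the shock tail measurably biases
  the fitted trend and hence the odor metric on shock trials.
* **Fit numerics**: variable projection (amplitudes solved linearly) over
  the τ start grid {5, 30, 100, 300} s, then one bounded trust-region
  polish with analytic Jacobian, τ ∈ [1 s, 100 × record length], at most 30
  function evaluations. The cap matters: identifiable trends converge in
  ~15 evaluations, while flat traces (nothing to remove) have unidentifiable
  τ and would iterate forever without ever changing the result. Hitting the
  cap is therefore not a failure; only non-finite solutions trigger the
  linear-detrend fallback (`fit_ok=False`). The fit needs ≥ 20 unmasked
  frames. On noise-free double-exponential inputs the recovered τ agree
  with an independently coded grid + Nelder–Mead oracle to ≪1%.
* **ΔR/R₀**: R₀ is the mean of the *detrended* trace over t ∈ [0, 5) s
  (exactly 25 frames at 5 fps) — normalization follows detrending, matching
  the stated processing order. R₀ ≤ 0 is an error, not a NaN.
* **Windows** are half-open in seconds, a frame belonging to a window iff
  its timestamp lies inside it (10⁻⁶ s tolerance against float jitter, far
  below half a frame). Odor: [onset, onset+4) — 20 frames, ending exactly
  at shock onset. Shock: [onset+4, onset+4.8) — 4 frames, ending before
  odor offset at 5 s. Incomplete coverage raises a truncated-window error.

## Learning metrics and statistics

Per fly and odor: `diff_acquisition` (last − first acquisition trial),
`diff_reversal` (second − first reversal trial), and the per-trial
trajectory relative to acquisition trial 1 (zero there by construction).
Positive differences mean the response increased. Both metrics are
shift-invariant and antisymmetric under trial-order reversal; tests assert
these properties.

The test battery:

* **paired_compare** — D'Agostino–Pearson omnibus on the paired differences
  at α = 0.05 decides paired t (normal) vs Wilcoxon signed-rank
  (non-normal). The gate runs on the differences, the quantity actually
  tested. For n < 8 the omnibus is undefined and the t-test is used with
  `normality_p = NaN`. Wilcoxon drops zero differences and uses the exact
  null for n ≤ 25 without ties, else the normal approximation with
  continuity correction. All-zero differences return a flagged degenerate
  result with p = 1. Null simulations put the empirical size at ≈0.050.
* **rm_anova_dunnett** — one-way repeated-measures ANOVA over trials (or
  fully within-subject two-way trial × odor when both odors are present,
  headline effect = the interaction, i.e. the learning effect). Sums of
  squares, Greenhouse–Geisser ε (Box's formula on the contrasted
  covariance) and Mauchly's W (with the second-order chi-square correction)
  are computed directly and cross-checked against pingouin in the test
  suite. `apply_gg` ∈ {True, False, "auto"}; the default "auto" applies the
  GG df correction only when Mauchly rejects sphericity at 0.05 — the
  conditional usage that keeps the test calibrated (empirical size 0.050
  under sphericity, versus 0.026 when GG is forced on). Unbalanced designs
  raise; nothing is imputed.
* **Dunnett post-hoc** — each later trial vs trial 1 as paired contrasts
  (df = n−1), family-wise adjusted with the equicorrelated (ρ = 0.5)
  multivariate-t distribution evaluated by deterministic tensor quadrature
  (96-node Gauss–Hermite × 96-node Gauss–Legendre in chi probability
  space; absolute accuracy well below 10⁻⁶, and it reproduces scipy's
  independent-groups Dunnett test on balanced designs).

## Behavioral indices

Avoidance index (N_CS− − N_CS+)/N_total ∈ [−1, 1]; reciprocal balancing is
the arithmetic mean over the two odor-swapped cohorts; red-light preference
is the per-configuration (N_light − N_dark)/N_total averaged over the two
alternating illumination patterns; single-fly preference is percent of
frames per quadrant class. Flies that cannot be assigned to a class (e.g.
on a quadrant border) are excluded from numerator *and* denominator —
totals count classified flies only. Degenerate totals raise rather than
return NaN.

## Connectome summaries

Operates on synapse CSVs (one row per contact: pre/post cell id and type,
ROI, coordinates, optional tracing flags and hemisphere). Filters:
fully-traced-only, ROI whitelist (the "dendritic" restriction is an ROI
list supplied by the caller — no geometric inference), hemisphere via a
`side` column. A requested filter whose column is absent warns and is a
no-op. Pair counts group by (pre cell, post cell); with a cell roster,
zero-synapse candidate pairs enter the type-pair mean (the convention
behind "an average of N synapses onto each of the ten cells"); without a
roster only observed pairs are averaged, and asking for zero-inclusion
without a roster is an error. No network I/O: a live neuPrint query is
just another producer of the same CSV schema.

## Problem sizes used in the automated checks

Motion invariance: 100 artifact paths on a 2-trial schedule, exact to
≤10⁻⁹. Bleach recovery: 20 parameter draws on 120-s records (τ₁ ∈ [3, 10] s,
τ₂ ∈ [30, 80] s — both identifiable within the record). Plasticity
recovery: 200 flies × 14 trials at default noise; the sign of
diff_acquisition and diff_reversal is recovered for ≈98% of flies and CS−
means sit within ±0.003 of zero. Calibration: 2000-replicate null
simulations for both test paths; power for the CS+ vs CS− acquisition
contrast at n = 9 flies over 500 full-pipeline replicates (5-acquisition
schedule — the contrast involves no reversal trials). Connectome: 50 random
fixtures against nested-loop enumeration plus the structured 2 × 10
exact-5 fixture. Binomial consistency: 10⁴ draws at p ∈ {0.1, 0.5, 0.9}.

## What the synthetic tests do not show

The generator produces Gaussian, stationary noise, a single ROI per fly,
no odor-offset responses, no slow drift other than bleaching, and
transients that follow one fixed kernel. Passing recovery tests therefore
demonstrates correctness of the *analysis* under the stated generative
assumptions — not robustness to segmentation errors, z-drift,
odor-delivery variability, breathing artifacts that differ between
channels, or indicator nonlinearity. The shock-trial trend bias discussed
above is an example of how stimulus tails interact with trend fitting;
with real kernels slower than ~2 s the mask pad should be widened
accordingly (it is a parameter).

## Known limitations

* The two-way RM-ANOVA uses the univariate GG-corrected approach only; no
  multivariate or mixed-model fallback.
* Kruskal–Wallis/Dunn and Mann–Whitney paths used by some behavioral
  panels elsewhere are out of scope.
* The Wilcoxon zero/tie policy and the normality α are conventions, both
  exposed as parameters.
* `diff_acquisition` is defined as last-minus-first within the phase, so
  protocols with a different acquisition count than five remain valid but
  are no longer literally "trial 5 − trial 1".
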