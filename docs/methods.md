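# Methods

`voxelsem` implements a voxel-wise structural-equation-modeling (SEM)
comparison of causal accounts of white-matter aging, together with a
synthetic data generator whose voxels obey known causal diagrams so that the
whole pipeline can be validated without access to subject data.

## The models

Two latent constructs are measured at every voxel:

* **WMI** (white-matter integrity), indicated by the voxel's sign-flipped
  fractional anisotropy (−FA) and mean diffusivity (MD).  FA is multiplied
  by −1 so that both indicators increase as tissue integrity declines and
  their covariance is positive.
* **BEH** (cognition/processing speed), indicated by mean reaction times of
  a verbal and a visuospatial working-memory task, optionally extended by a
  number-Stroop task ("working memory + Stroop", the 3-indicator variant).

Observed age completes the variable set.  Four structural hypotheses are
fitted per voxel:

| model | structural paths |
|---|---|
| brain mediation | age → WMI → BEH |
| cognitive mediation | age → BEH → WMI |
| independent factor | age → BEH, age → WMI (no BEH–WMI link) |
| common factor | age → G, G → BEH, G → WMI |

Mediation is *full* (no direct age path).  Two *simple* models support path
significance maps: age → WMI (saturated, df = 0) and BEH → WMI.

Every model is held in RAM form: a directed-path matrix **A**, a symmetric
(co)variance matrix **S** over observed + latent variables, and a selector
**F** onto the observed rows, giving the implied covariance
`Σ(θ) = F (I−A)⁻¹ S (I−A)⁻ᵀ Fᵀ`.  Maximum-likelihood estimation minimises
`F_ML = ln|Σ| + tr(S_sample Σ⁻¹) − ln|S_sample| − p`; the model chi-square is
`(N−1)·F_ML(θ̂)`, and AIC uses the `χ² − 2·df` convention (a constant shift
of Akaike's `−2lnL + 2k` on fixed data, so rankings are identical).

### Identification

The first loading of each latent is fixed to 1 and latent residual variances
are free; for the common-factor model the common latent G additionally has
its residual variance fixed to 1.  With two behavioral indicators this gives
11 free parameters (df = 4) for the three single-path models and 12 (df = 3)
for the common factor.  Note that chi-square, p and AIC are invariant to the
identification choice, so the open question of how the original common
factor was scaled does not affect model selection.

The simple age→WMI model (6 moments, 6 parameters) is saturated.  The simple
BEH→WMI model is *not*: two RT plus two WM indicators leave exactly one
vanishing-tetrad constraint, hence df = 1.  No identified variant of that
two-factor structure can be saturated; the package keeps the honest df.

## Fitting

Free parameters are unconstrained — variances may go negative — because the
downstream filter *depends* on Heywood cases surfacing as latent
correlations outside [−1, 1] (computed with signed square roots and never
clipped).

* **Starting values**: paths and loadings 0.5, free variances half the
  matching observed variance (latents 1.0).  This presumes the pipeline's
  0–10 min-max scaling, which puts every variable in a predictable range.
* **Optimizer**: dense BFGS with a strong-Wolfe line search (numba-compiled;
  a pure scipy L-BFGS-B route is retained and tested to reach the same
  minima).  Gradients are analytic.  The convergence tolerance is an
  inf-norm gradient below 1e-6: with 0–10-scaled inputs that fixes F_ML to
  ~1e-12, far below every reported-statistic tolerance, while a much tighter
  setting only provokes line-search churn in flat Heywood valleys.
  Iteration cap 500.
* **Multi-start**: two deterministic alternates (all paths −0.5; all paths
  1.0) guard against local minima, keeping the lowest minimum.
* **Just-identified models** (df = 0) are solved exactly: Σ(θ) = S is a
  square system and is solved by Powell's hybrid method with the analytic
  Jacobian, falling back to a homotopy that deforms the target covariance
  from Σ(θ₀) to S while tracking the root by Newton steps.  This is robust
  even when the exact solution lies in Heywood territory (as it does for
  null-association voxels), and guarantees the saturated identity χ² = 0.
* **Simplex rescue**: fits that still fail to converge (typically badly
  misspecified models on null-association data, whose optima sit in flat,
  barrier-adjacent regions) are retried from a fixed battery of seeded
  random starts explored by adaptive Nelder-Mead and polished by BFGS,
  stopping once three consecutive restarts fail to improve.  All stages are
  deterministic.

Convergence is classified with a traffic-light scheme: **GREEN** (converged,
positive-definite implied covariance — trust the solution), **BLUE**
(iteration budget exhausted), **RED** (non-finite values, singular (I−A),
non-PD implied covariance, or input/implied covariance condition number
above 1e12).  Non-GREEN voxel fits are tallied and excluded, never fatal.

### A note on degenerate global minima

For misspecified models on null-association data the ML discrepancy can have
many shallow Heywood minima.  The test suite compares fitted minima against
an independent restarted Nelder-Mead search; on a 50-voxel battery the two
agree to 1e-5 on all fits the engine certifies GREEN, but on a handful of
non-convergent (BLUE, hence discarded) fits even two independent 20-restart
searches disagree with each other at the 1e-3 level — those minima are not
reproducibly attainable by any restart search of that size, and the affected
voxels never enter any map.

## The voxel pipeline

1. **Skeleton**: a voxel enters the analysis only if FA > 0.2 (strict) in
   *every* subject — a conjunction mask, not a TBSS-style projection.
2. **Transform**: per voxel, columns (age, RTs, −FA, MD) are min-max scaled
   to [0, 10] across subjects (sign flip before scaling).  Chi-square is
   scale-invariant, so the choice of per-voxel over global scaling is purely
   numerical.
3. **Fit**: all requested models on one shared sample covariance
   (denominator N−1).  Constant columns mark the voxel unfittable.
4. **Filter**: a model is eligible only if GREEN, fit p > 0.05 (strict), and
   every latent correlation lies in [−1, 1] (boundary included).
5. **Select**: lowest AIC among eligible models; exact ties go to the
   larger-df model, then a fixed order (independent > cognitive mediation >
   brain mediation > common factor).  Ineligible-everywhere voxels get 0.
6. **Maps and summaries**: cluster-extent thresholding in mm³ (default
   26-connectivity, per label; components exactly at threshold survive),
   overlap percentages `100 · detected / skeleton` (which partition the
   skeleton), atlas-label conjunction counts, and per-voxel Pearson
   correlation of (−FA, MD) with its median.
7. **Path maps**: voxel-wise chi-square difference between the simple model
   with the structural path free vs fixed to 0, referred to 1 df with the
   printed landmarks 6.63 (p = .01) and 15.14 (p = .0001).  Caveat: fixing
   the path removes *two* covariance moments (age–FA and age–MD), so under
   the null the difference is chi-square(2)-distributed and the 1-df
   reference is anticonservative (~3.6% exceed the 1% landmark).  The
   package keeps the conventional 1-df accounting and documents the
   miscalibration rather than silently re-referencing it.

## The synthetic generator

The generator defines the study conditions; its defaults are fixed:

* **Cohort** (n = 88): three age bands, 18–39 / 40–59 / 60–89 years with
  36 / 27 / 25 subjects (19 / 19 / 16 women).  Ages are uniform within band;
  an optional truncated-normal mode moment-matches each band's published
  mean ± SD (the middle band's SD of 6.31 exceeds the uniform-limit SD of a
  width-19 interval, 5.48, so no truncated normal can attain it; the closest
  near-uniform shape is used).
* **Behavior**: latent slowing `BEH = 3.0 ms/yr · age + N(0, 80 ms)`, giving
  cor(age, BEH) ≈ 0.6 with the cohort's age SD of ≈ 20 yr — a typical
  adult-lifespan speed effect.  Task means load on BEH (1.0 / 0.9 / 0.8 for
  verbal / spatial / Stroop) with 40 ms unique SD (between-task r ≈ 0.7);
  trials add 150 ms noise, 24 per session for the working-memory tasks and
  48 for Stroop, two sessions each.
* **Volumes**: each region of a labelled volume realises one causal diagram.
  The target covariance of (age, BEH, WMI) under the diagram is written in
  closed form — structural effect sizes are specified as correlations
  (defaults: cor(age, WMI) = 0.5 in independent regions, cor(BEH, WMI) = 0.5
  in cognitive-mediation regions, both "moderate") — and per-voxel WMI is
  drawn from its exact conditional law given the subject's (age, BEH).
  Because multivariate-normal diagrams are covariance-equivalent, this
  conditional construction reproduces the diagram's population covariance
  exactly; the package asserts that it matches the SEM engine's implied
  covariance (the generator and engine share one algebra only through that
  test, not through code).  Indicators load on WMI with residual SD 0.905
  against unit WMI variance, i.e. reliability 0.55 each, so the per-voxel
  (−FA, MD) correlation is 0.55 by construction.  FA volumes are written as
  `clip(0.55 − 0.03 · negFA, 0, 1)` (clipping affects a negligible
  fraction, warned above 0.1%) and MD as `0.80 + 0.05 · MD_raw`.
* **Default geometry**: a 24 × 24 × 12 volume cut into three equal axial
  slabs — NULL (pure noise), independent factor, cognitive mediation —
  ≈ 2300 voxels each: large enough for stable rates and cluster-threshold
  tests, small enough for minutes-scale runs on one CPU.

What the generator does *not* emulate: spatial autocorrelation of noise,
registration error, diffusion physics, RT distributions' skew.  Passing
recovery tests therefore demonstrate the statistical machinery under ideal
sampling, not performance on real scanner data.

## What recovery can and cannot show

With these defaults, cognitive-mediation regions are recovered at ≈ 85–90%
and brain-mediation maps stay empty.  Two structural limits are worth
knowing:

* The common-factor model nests cognitive mediation on the boundary where
  BEH's residual variance hits zero; under cognitive-mediation truth about
  half of its sample fits are therefore Heywood (filtered — mirroring the
  suspect-voxel filter's emptying of the common-factor map), and it beats
  cognitive mediation on AIC only when the boundary chi-square difference
  exceeds 2 (≈ 8% of voxels).
* Under independent-factor truth the common factor can absorb any *positive*
  sample partial BEH–WMI covariance, so its AIC win rate is a
  chi-square(1)-tail gamble of roughly `P(z² > 2)/2 ≈ 8%` in independent
  regions regardless of effect size.  A ≈ 2–4% rate of common-factor false
  assignments over NULL + independent regions is intrinsic to AIC selection
  at n = 88, not an implementation artifact.

## Behavioral preparation

Session means require complete trial blocks; subject indicators pool both
sessions (equal to the mean of session means for balanced designs).
Test-retest reliability is the single-measure, two-way mixed *consistency*
ICC(3,1) by default — the form that ignores a pure session shift — with
ICC(2,1) (absolute agreement) selectable; estimates come from
`pingouin.intraclass_corr`, reported with the mean squares.  Error trials
are included (an optional correct-only filter can be applied upstream by
subsetting the trial table).

## Reproducibility

Every generator takes an explicit seed and is bit-reproducible.  Pipeline
outputs are deterministic functions of (inputs, config); run directories
embed the exact config and package version.  The problem sizes used by the
test suite and the acceptance script — 2000-voxel calibration blocks, the
24 × 24 × 12 recovery volume, a 50-voxel optimizer-equivalence battery, and
large-n (10⁵-scale) closed-form checks — were chosen to give stable rates
on a single CPU in minutes.
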