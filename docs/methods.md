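# Methods

## The study design being modelled

Goldfish held under a 12L:12D photocycle (lights on at ZT-0, scheduled
feeding at ZT-4) were sampled every 4 h across one full daily cycle —
seven sampling times ZT 0, 4, 8, 12, 16, 20, 24, six fish per time — and
*preproghrelin* and *ghs-r1* mRNA was measured by RT-qPCR in forebrain,
hypothalamus, hindbrain, pituitary and gastrointestinal tract.  Each fish
contributes a single cross-sectional observation; there are no repeated
measures.  ZT-24 is kept as its own sampling group: its cosinor
regressors coincide with ZT-0 by periodicity, which is the correct
behaviour, while the ANOVA treats it as a seventh group.

The raw per-fish measurements for this design were never deposited, so
the package ships a generator (`simulate`) that reproduces the design's
statistical structure from published rhythm parameters, and every
downstream stage is validated against it.

## Relative quantification (2^-ddCt)

Per sample, dCt = Ct_target − Ct_ref, where Ct_ref is the arithmetic mean
of the configured reference genes' Cts — equivalent to normalizing
expression by the geometric mean of the reference genes' expression
levels, the standard multi-reference practice.  Technical replicates are
averaged at the Ct level before dCt.  Amplification efficiency is assumed
to be 100% for all genes (the assays were validated to ~100%); no
Pfaffl-style efficiency correction is applied.

Calibration is per tissue × gene panel.  Per-sample relative expression
2^-dCt is divided by the mean of the sampling-time group with the lowest
group-mean expression, so that the lowest-expression time has mean
relative expression exactly 1.  Note this is calibration on the
*expression* scale: subtracting the calibrator group's mean dCt instead
(a common shortcut) fixes the calibrator's *geometric* mean at 1 and, by
Jensen's inequality, leaves its arithmetic mean above 1 whenever there is
within-group noise.  The two coincide when within-group dCt is constant.
Ties in the lowest group mean resolve to the earliest ZT and are logged.

## Cosinor rhythmometry

The single-component cosinor with the period fixed at 24 h:

    y(t) = M + A·cos(ωt − φ) + ε,   ω = π/12 rad/h,

with mesor M (rhythm-adjusted mean), amplitude A ≥ 0 (half
peak-to-trough) and acrophase φ, reported in hours (φ_h = φ·12/π mod 24),
i.e. the ZT clock time of the fitted peak.  The model is estimated by
ordinary least squares through the exact reparameterization

    y(t) = M + β·cos(ωt) + γ·sin(ωt),   β = A·cos φ, γ = A·sin φ,

which minimizes the same residual sum of squares as iterative nonlinear
regression on (M, A, φ) — the equivalence is asserted against a
brute-force SSE grid-plus-refinement oracle in the test suite — but is
closed-form and numerically stable.  No observation weighting is applied.

Standard errors: the linear model's covariance with σ̂² = RSS/(n−3) gives
se(M), var(β), var(γ), cov(β,γ); the delta method then gives

    se(A)² = (β²·var β + γ²·var γ + 2βγ·cov)/A²
    se(φ)² = (γ²·var β + β²·var γ − 2βγ·cov)/A⁴      (radians)

The amplitude interval is Student-t: A ± t_{(1+c)/2, n−3}·se(A) at level
c = 0.99 by default, floored at 0.  A Fieller-type or normal-based
interval would be equally defensible; the t-based choice is documented in
the fit object and no claim is made that it reproduces any particular
published bracket exactly.

The zero-amplitude test compares the cosinor against the intercept-only
model: F = ((RSS₀ − RSS)/2)/(RSS/(n−3)) on (2, n−3) df, with n the number
of per-fish observations (the fit is to all individual values, not group
means).  Degenerate inputs: an exact rhythmic fit (RSS numerically zero,
spread nonzero) reports F = ∞, p = 0 with a perfect-fit flag; constant
data reports A = 0 exactly, an undefined (NaN) acrophase, F = 0, p = 1.
A harmonic component below 10⁻¹² of the data scale is snapped to exactly
zero so that constant input behaves identically regardless of float
residue.

## ANOVA, SNK and the dual criterion

One-way fixed-effects ANOVA across sampling times uses the classical sums
of squares; zero within-group variance with unequal means (possible with
noiseless synthetic data) is flagged and reported as F = ∞, p = 0, with
degeneracy judged relative to the data's scale.  No normality or
homoscedasticity gating is applied.

The Student–Newman–Keuls post-hoc sorts the k group means and tests each
stretch of r ordered means with the studentized range: the stretch is
significant when q = (max−min)/√(MS_within/ñ) exceeds q(α, r, df_within),
with ñ the harmonic mean of the stretch's group sizes (Kramer-style
adjustment; the design here is balanced so it only adds robustness).  A
non-significant stretch is declared homogeneous and never subdivided (the
classical containment rule).  Maximal homogeneous stretches are swept
into compact letters — shared letter = not significantly different — with
ties broken by ascending mean then ZT; the letter display is
presentation-only.  Critical values come from scipy's studentized-range
distribution function (numerical, well below 10⁻⁶ quantile error; values
cached per (α, r, df)).  The post-hoc is protected: it is only run when
the omnibus ANOVA is significant.

A series is declared rhythmic by the conjunction used throughout:

    ANOVA p < 0.05   AND   zero-amplitude p < 0.005.

Because it is an intersection of events its null firing rate is bounded
by the zero-amplitude rate; the null-calibration analysis
(analysis/05) measures ≈ 0.004–0.005 over 10,000 arrhythmic 7×6 studies.
No multiple-testing correction is applied across the ten tissue × gene
panels (none was applied in the original analysis).

## The synthetic-data generator

Each series draws per-fish values around the cosinor mean
M + A·cos(ωt − ωφ_h) at the seven design time points.  Defaults encode
the study conditions: 7 time points at 4-h spacing, n = 6 per time, and
additive Gaussian noise with sd 1.0 relative-expression units — additive
because the study's figures display mean ± SEM on the relative-expression
scale.  A lognormal (multiplicative) mode is available since true
relative expression is strictly positive; its `noise_sd` is the SD on the
natural-log scale.  The five rhythmic panels' generative parameters are
the published (mesor, amplitude, acrophase) triples; the five flat panels
use amplitude 0 and a mesor of 1.5 (not published; comparable to the
rhythmic panels' troughs).

Additive-mode values are clipped at 10⁻⁶ (flagged per record) so the Ct
back-transform Ct = ct_baseline − log₂(expression) is always defined.
This censoring matters quantitatively: for panels whose trough approaches
the noise scale (e.g. amplitude 0.9 on mesor 1.5 at sd 1.0) the clipped
lower tail biases the mean *recovered mesor* upward by ~0.06 and
attenuates the recovered amplitude by ~1%; the acrophase is unaffected
because clipping is symmetric in phase.  The parameter-recovery tests
account for this analytically (closed-form mean of a floored Gaussian)
rather than pretending the estimator is unbiased under censoring.

Randomness: one master seed; each tissue × gene series draws from a child
stream keyed by (seed, CRC32(tissue), CRC32(gene)), so a series'
values are identical whatever other series share the panel, and identical
seeds give byte-identical datasets across runs and platforms.

What the generator does *not* emulate: plate effects, primer-efficiency
deviations from 100%, reference-gene instability, fluorescence-curve
artefacts, between-fish covariance across tissues (each tissue × gene
series is drawn independently), or heteroscedasticity across time points.
Passing recovery tests therefore show the estimators are correct for
cosinor-structured means with i.i.d. additive (or lognormal) noise — not
that real qPCR data meet those assumptions.

## Problem sizes and numerical choices

Parameter-recovery analyses use 500 replicate studies per panel and
null-calibration uses 10,000 replicates — enough for Monte-Carlo SEs of
~0.01 h (acrophase), ~0.01 (amplitude) and ~0.0007 (null rate).
Tolerances in tests are 3 Monte-Carlo SEs for simulated quantities and
10⁻⁹ (or machine precision) for exact identities.  The ddCt route
re-anchors each panel's scale to its noisy lowest-expression group; all
reported p-values, acrophases and letter displays are invariant to that
scaling.

## Known limitations

- The acrophase SE is a delta-method (linearization) approximation; it is
  accurate when A/se(A) ≳ 3 and degrades for weak rhythms.
- The amplitude estimator carries the positive Rice bias ≈ σ_A²/(2A) in
  the same regime; tests bound it explicitly.
- Protected SNK is one of several SNK variants in circulation; with the
  balanced n = 6 design the choice only affects edge cases.
- Fitting per-fish values from a cross-sectional design estimates the
  population-mean rhythm; individual-fish rhythm parameters are not
  identifiable from one observation per fish.
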