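# Methods

This note records the models implemented in `dragonmorph`, the defaults and
why they were chosen, what the synthetic generators do and do not emulate,
and the numerical conventions.

## Receptor-noise-limited discrimination (`vision`)

The model assumes colour discrimination is limited by independent noise in
each photoreceptor channel. For receptor class *i* with spectral sensitivity
*S_i(λ)*, the quantum catch of a surface with reflectance *R(λ)* under
irradiance *I(λ)* is

    q_i = Σ_λ R(λ) · I(λ) · S_i(λ) · Δλ,

evaluated by rectangle-rule summation on a 1-nm grid over 300–700 nm (the
visual range of diurnal lizards; 1 nm matches spectrometer resolution, and
the difference from trapezoidal integration is orders of magnitude below any
tolerance used here). Contrast between stimuli A and B uses log catch ratios
Δf_i = ln(q_i^A/q_i^B). Chromatic distance is the receptor-noise quadratic
form, implemented for any n ≥ 2 receptor classes as

    ΔS² = Σ_{i<j} (Π_{k≠i,j} ω_k)² (Δf_j − Δf_i)² / Σ_i (Π_{k≠i} ω_k)²,

which reduces to the familiar dichromat (|Δf₁−Δf₂|/√(ω₁²+ω₂²)), trichromat
and tetrachromat expressions. Achromatic (luminance) distance is
ΔL = |Δf_ach|/ω_ach. Both are in JND: 1 JND is the discrimination threshold.

**Visual system default.** An agamid tetrachromat: λmax 365 (UVS), 440
(SWS), 493 (MWS), 571 (LWS) nm; relative cone abundances η = 1 : 1 : 3.5 : 6;
Weber fraction ω = 0.05 for the most abundant (LWS) class, remaining
channels derived as ω_i = ω_LWS √(η_LWS/η_i) (noise scales with the inverse
square root of receptor number). The achromatic channel is the LWS catch
with ω = 0.05 — the natural choice given LWS is the reference class whose
noise is fixed; a double-cone mechanism would only rescale ΔL.

**Design choices where the biology under-determines the model.**

* *Sensitivity shape*: only λmax values are known for this visual system, so
  sensitivities use the Govardovskii vitamin-A1 absorbance template (α band
  plus the 0.26-amplitude Gaussian β band), peak-normalised on the analysis
  grid. This is standard practice for lizard visual modelling.
* *Illuminant*: "full sunlight" is represented by the CIE D65 relative
  spectral power distribution (typed from the public 10-nm CIE table),
  interpolated to 1 nm, multiplied by λ to convert energy to photon flux,
  and normalised to unit mean. Because both stimuli in a contrast share the
  illuminant, ΔS is invariant to its overall scale; the choice affects only
  the absolute JND scale mildly through its spectral shape.
* *No ocular-media correction* and *no von Kries adaptation*: the former
  cannot be parameterised for this species; the latter cancels exactly in
  log catch ratios of two stimuli under one illuminant, so omitting it
  changes nothing — noted for transparency.

Degenerate inputs: identically-zero reflectance is rejected (log ratios
undefined); catch sets from different systems cannot be compared.

## Image calibration and segmentation (`imaging`)

Calibration follows the two-step convention of calibrated animal-coloration
photography. (1) *Linearization*: per-channel power law
`reflectance = a_c · response^γ_c`, least squares in log–log space on the
six grey-ramp squares. Six points over-determine the two parameters; RMS
log-residuals are stored. Responses that are not monotone in reflectance
trigger a warning and an isotonic-regression projection before fitting.
(2) *Equalization*: per-channel gain set so the in-frame 30 %-reflectance
grey standard reads exactly 0.30 per channel, removing frame-to-frame
lighting variation (the standard region's means equal the target exactly
afterwards, by construction).

Segmentation normalises each pixel by luminance, (r,g,b) = (R,G,B)/(R+G+B),
then applies thresholds: **red** if r − g ≥ 0.20, else **yellow** if
min(r,g) − b ≥ 0.15, else **grey**. The score functions are a documented
reconstruction — the per-pixel metric of the original MATLAB scripts is not
published — chosen so that (a) the scores are dimensionless chromaticity
differences compatible with thresholds of 0.20/0.15, (b) red is tested
first, reflecting the deliberately conservative red threshold that keeps
orange distinct from yellow, and (c) the result is invariant to uniform
brightness scaling. Thresholds and precedence are config-overridable.
Zero-sum pixels carry no chromatic information and are counted as grey.
Proportions always sum to 1 (grey is the remainder class).

## Canonical discriminant analysis (`classify`)

Between-group (B) and within-group (W) scatter matrices feed the
generalized symmetric eigenproblem B·v = λ·W·v (solved with `scipy`'s
`eigh`, which guarantees real nonnegative eigenvalues for positive-definite
W). min(p, g−1) axes are kept; coefficient vectors are scaled to unit pooled
within-group variance. Wilks' Λ = Π 1/(1+λᵢ) (identically det(W)/det(W+B)),
tested with Rao's F approximation: df1 = p(g−1), df2 = m·s − df1/2 + 1 with
m = n − 1 − (p+g)/2 and s = √((p²(g−1)²−4)/(p²+(g−1)²−5)); df2 is reported
fractional, not rounded. For the study design (n = 35, p = 7, g = 4) this
gives df1 = 21 and df2 ≈ 72.3.

Classification uses linear discriminant scores with the pooled covariance
and equal priors (proportional priors are an option); ties are broken by the
fixed morph order orange, yellow, grey, orange+yellow. The linear (not
quadratic) rule follows from the homogeneous-covariance framing of a
canonical analysis. Leave-one-out cross-validation refits the discriminant
for every held-out row and is fully deterministic; a morph with a single
observation cannot be held out and is rejected, while a held-out member of a
size-2 morph leaves a singleton group that still defines a centroid.
Features are used unscaled — the analysis is affine-invariant, which the
test suite verifies numerically.

## Hormone and time-course statistics (`stats`)

**Hormone ANOVA.** The testosterone comparison across pre-implant, week 1
and week 4 is reported in the field as a "one-way ANOVA", but with repeated
samples per female and 44 records from 18 females the only design consistent
with (2, 24) error df is a female-blocked additive model
`testosterone ~ female + timepoint`. That model is what `anova_time` fits
(OLS; timepoint tested by its partial sum of squares; error df
N − 1 − (n_females − 1) − (n_timepoints − 1)). Timepoint least-squares means
average the predictions over female levels. Missing cells are handled
listwise: a female contributes whichever timepoints exist.

**Pairwise contrasts** are differences of timepoint LS means on the ANOVA
error df, adjusted with the Tukey–Kramer studentized range (k = number of
timepoints) — the adjustment consistent with the magnitude of the study's
reported adjusted p values; the unadjusted value is also reported.

**Exact frequency test.** The Freeman–Halton extension of Fisher's exact
test enumerates every r×c table with the observed margins (recursive
enumeration; multivariate hypergeometric probabilities via log-gamma) and
sums the mass of tables no more probable than the observed one; ties within
a relative 1e-12 count as "as extreme". Totals above 200 require the seeded
Monte-Carlo mode (Patefield sampling via `scipy.stats.random_table`, with
the +1/(m+1) finite-sample correction).

**FDR.** Benjamini–Hochberg step-up adjustment (delegated to
`statsmodels.stats.multitest`), validated in the tests against a hand
step-up computation and the rejection-set equivalence.

**Mixed models.** Each colour variable is modelled by REML (`statsmodels`
`MixedLM`) with fixed effects time, time², morph, morph×time, morph×time²
and a random per-female intercept. Morph uses sum-to-zero coding so the
`time`/`time²` main effects test the slope averaged over morphs. Term F
tests are Wald tests on the REML fit with a residual-style denominator df
(N − rank(X)); the original analysis's denominator-df method is unstated, so
exact reproduction of its F table is not a goal — the package documents its
own convention. Boundary fits (zero intercept variance) are legitimate and
reduce to OLS, which the tests verify; zero residual variance is reported as
degenerate rather than fitted. `per_morph_trend` refits the same model
without morph terms within one morph, for responses whose morph×time²
interaction is significant.

## Synthetic data (`simulate`)

The generators encode the study conditions as defaults and are pure
functions of parameters + seed:

* **Spectra**: logistic long-pass reflectance edges (midpoint 580 nm for
  orange, 500 nm for yellow), flat 30 % cream/grey, all tapered to a low UV
  floor below ~380 nm, with lognormal multiplicative noise (sd 0.02). These
  are parametric idealizations of measured throat spectra shapes, not
  digitized curves.
* **Images**: patch compositions with chromaticity scores placed clearly
  across the 0.20/0.15 thresholds (orange r−g = 0.30, yellow
  min(r,g)−b = 0.25), an embedded 30 % grey standard and six-step grey ramp
  (reflectances 0.05–0.80), per-channel gamma distortion (default 2.2) and
  additive sensor noise. Default frame 60×60 px — small enough for
  simulation studies, structurally identical to larger frames.
* **Feature tables**: multivariate normal per morph around plausible mean
  vectors at the study counts 10/7/7/11 (n = 35), shared diagonal
  covariance (sd 0.06–0.07 for proportions, 1 JND for contrasts).
* **Hormone panels**: lognormal concentrations (positive, right-skewed)
  around geometric means 55.95 / 262.16 / 134.02 ng/mL with per-female
  intercept sd 0.25 and residual sd 0.35 on the log scale; availability
  fixed at 18/11/15 records, reproducing the (2, 24) design.
* **Time courses**: quadratic mean trajectories per morph over weeks
  1–6, 10, 12 — rising for orange and orange+yellow, flat for yellow and
  grey — plus a per-female random intercept (sd 0.03) and residual noise
  (sd 0.05). Effect sizes give power ≥ 0.9 for the qualitative pattern at
  study-scale n.

What the generators deliberately do **not** emulate: spatial structure of
real throats (patches are blocks, not blobs), UV photography, chromatic
aberration or demosaicing artefacts, assay nonlinearity, within-female
correlation beyond a random intercept, and colour reversion after peak
expression. Passing recovery tests therefore demonstrates correctness of
the computational chain under the stated statistical structure, not
robustness to every property of real photographs.

## Known limitations

* The per-pixel segmentation scores are a reconstruction (see above);
  absolute proportion values on real photographs depend on that choice,
  though threshold monotonicity and invariances hold regardless.
* JND values depend on the bundled daylight spectrum and the A1 template;
  other illuminants can be passed explicitly.
* Mixed-model denominator df are residual-style; software using
  Satterthwaite or Kenward–Roger df will report different p values for the
  same fit.
* The exact test enumerates tables only up to total 200; beyond that the
  seeded Monte-Carlo mode returns a simulation estimate.
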