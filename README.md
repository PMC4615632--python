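# dragonmorph

Objective quantification and classification of throat colour morphs in the
tawny dragon lizard (*Ctenophorus decresii*) — and, more generally, a tested
pipeline for studies that score discrete colour phenotypes from calibrated
photographs and reflectance spectra and track their hormonal induction over
time.

Male tawny dragons carry four discrete throat morphs (orange, yellow, grey,
and an orange centre surrounded by yellow). When testosterone is
experimentally elevated in females, they express the same morphs; verifying
that claim objectively requires (i) measuring how much red, yellow and grey
each throat carries, (ii) asking whether the morph classes separate
statistically, and (iii) modelling how colour and plasma testosterone change
over the weeks after the implant. `dragonmorph` implements each step as a
reusable library with a thin CLI, plus synthetic-data generators so every
stage is testable without the original measurements.

## What it computes

**Receptor-noise-limited colour contrast.** Quantum catches are
`q_i = Σ_λ R(λ) I(λ) S_i(λ) Δλ` on a 1-nm grid over 300–700 nm, with
sensitivities from the vitamin-A1 pigment template at λmax = 365/440/493/571
nm (UVS/SWS/MWS/LWS) and a bundled daylight (D65) illuminant in quantal
units. With log catch ratios `Δf_i = ln(q_i^A/q_i^B)` and Weber fractions
`ω_i = ω_LWS √(η_LWS/η_i)` (cone ratio 1:1:3.5:6, ω_LWS = 0.05), chromatic
distance ΔS is the standard receptor-noise quadratic form (implemented for
any number of receptor classes) and achromatic distance is
`ΔL = |Δf_LWS|/ω_LWS`, both in just-noticeable differences (JND) against a
30 % grey background.

**Calibrated segmentation.** Per-channel power-law linearization fitted to a
six-step grey ramp, channel equalization to an in-frame 30 % grey standard,
then per-pixel classification on luminance-normalised chromaticities
`(r,g,b) = (R,G,B)/(R+G+B)`: red if `r − g ≥ 0.20`, else yellow if
`min(r,g) − b ≥ 0.15`, else grey.

**Morph classification.** Canonical discriminant analysis of the seven
colour variables (three cover proportions plus throat/bib chromatic and
achromatic JND): eigenvalues of `W⁻¹B`, per-axis variance shares, Wilks'
Λ = Π 1/(1+λᵢ) with Rao's F approximation, and leave-one-out cross-validated
assignment with pooled-covariance linear scores.

**Hormone and time-course statistics.** Female-blocked ANOVA of plasma
testosterone across pre/week-1/week-4 with Tukey–Kramer pairwise contrasts;
Freeman–Halton exact test for r×c morph-frequency tables;
Benjamini–Hochberg FDR; and REML mixed models of each colour variable with
linear + quadratic time, morph, their interactions, and a per-female random
intercept.

## Worked example

```python
from dragonmorph import simulate, vision, stats
from dragonmorph.classify import canonical_discriminant, cross_validate_loo

# JND contrast of a synthetic orange throat against the 30% grey background
spec = simulate.gen_reflectance(simulate.MORPH_ARCHETYPES["orange"], seed=1)
res = vision.contrast_vs_background(spec)
print(f"chromatic {res.chromatic_jnd:.2f} JND, achromatic {res.achromatic_jnd:.2f} JND")
# -> chromatic 19.67 JND, achromatic 6.03 JND

# four-morph discriminant analysis at the study's 10/7/7/11 sample sizes
table = simulate.gen_feature_table(seed=1)
fit = canonical_discriminant(table)
print(f"Wilks lambda = {fit.wilks_lambda:.4f}, "
      f"F({fit.df1}, {fit.df2:.1f}) = {fit.f_statistic:.2f}")
# -> Wilks lambda = 0.0005, F(21, 72.3) = 44.76

# hormone response across the three sampling timepoints (44 records)
panel = simulate.gen_hormone_panel(seed=1)
a = stats.anova_time(panel)
print(f"F({a.df_num}, {a.df_den}) = {a.f_statistic:.2f}")
# -> F(2, 24) = 69.63
```

The chromatic contrast (≈20 JND) says an orange throat is far above the
1-JND discrimination threshold for a lizard viewer against neutral grey; the
tiny Wilks' Λ on 21 numerator df says the four morph centroids are strongly
separated relative to within-morph spread; and the (2, 24)-df F is the
signature of the blocked hormone design (44 records, 18 females, 3
timepoints).

A CLI mirrors the stages (`dragonmorph simulate | calibrate | segment |
contrast | classify | stats | run`); `dragonmorph run --config config.yaml`
executes the full pipeline and writes a provenance-stamped JSON bundle.

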