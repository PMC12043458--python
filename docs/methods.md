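# Methods

`ofswheat` implements the computational chain of a multi-site wheat
organic-fertilizer-substitution (OFS) assessment: plot-level trial
statistics, nutritional yield, phytate-based mineral bioavailability, and an
ex-ante DALY health/economic impact model, together with a synthetic trial
generator that stands in for field data.

## Data model and units

A trial is a flat collection of plot records: site, treatment
(CK = unfertilized control, FP = farmers' practice, OPT = optimized
fertilization, OF15/OF30 = 15%/30% organic substitution of chemical N),
replicate, dry grain yield (Mg ha⁻¹), grain Fe/Mn/Cu/Zn (mg kg⁻¹), phytic
acid (g kg⁻¹), and optional soil covariates carried for description only.
Units are fixed per column and never inferred — silent unit drift is the
dominant failure mode for this arithmetic. Yields are dry grain mass; an
optional moisture fraction converts fresh weights at read time and defaults
to zero (yields assumed already dry, since trial reports rarely state the
moisture basis).

## Synthetic trial generator

The generator emulates a 5-site × 5-treatment × 3-replicate randomized
design. For plot (s, t, r):

    yield   = site_mean_s · f_t / mean(f) · ε_y
    content = analyte_mean · g_{a,t} / mean(g_a) · ε_a

* **Treatment effects** f (yield) and g (per analyte) are multiplicative
  factors relative to CK, normalized by their mean so the configured
  marginal means are the expected sample means. Defaults are calibrated to
  the reference trial: treatment mean yields 8.00/8.95/9.30/9.58/9.47
  Mg ha⁻¹ (grand mean 9.06, 15%OF +19.75% over CK), Fe and Zn contents
  raised ~24.69% and ~19.19% over CK (~10.59%/~13.99% over FP) under OFS,
  Mn and Cu essentially flat (back-derived from treatment-level nutritional
  yields divided by yields), phytic acid mildly depressed under OFS so
  treatment means span ≈ 8.2–8.9 g kg⁻¹ around the 8.5 g kg⁻¹ grand mean.
* **Site effects** are multiplicative on yield only (site means
  7.07–9.85 Mg ha⁻¹); grain composition has no site component by default,
  so regional composition contrasts are not emulated.
* **Noise** ε is mean-one and strictly positive: log-normal by default
  (concentrations are positive and total CVs reach 27.6%), with a
  reflected truncated-normal alternative (slight positive mean bias at
  extreme CVs). Configured CVs are *totals* across all plots, as printed in
  trial descriptive tables (yield 15.08%; Fe 27.56%, Mn 17.64%, Cu 23.60%,
  Zn 10.16%; phytic acid 12%, a chosen value — no CV is published for it).
  The residual plot-level CV is backed out in closed form from
  1 + CV²_total = Π(1 + CV²_component) over the fixed site and treatment
  structures, clipped at zero. Residual CVs can also be pinned explicitly;
  then the plot noise scale is independent of the site list, and because
  each site consumes its own child PRNG stream spawned from the root seed,
  appending a site never perturbs earlier sites (under the default
  total-CV calibration the derived *yield* noise scale does depend on the
  site-mean spread, so only composition is guaranteed untouched).
* **Dilution.** Yield and composition noise share a latent plot factor
  with log-scale correlation −0.3 by default (negative yield–mineral
  correlations are a robust agronomic observation; no functional form or
  value is published, so the mechanism and loading are this package's
  choice). Contents are mutually correlated at ρ² through the shared
  factor. The recovery routine estimates the correlation from residuals
  within site × treatment cells, removing the design structure.

What passing generator-based tests show: the downstream arithmetic and
inference behave correctly on data with realistic means, CVs, effect sizes
and design structure. What they do not show: robustness to real-data
features the generator omits — site × treatment interactions, spatial block
effects, non-multiplicative site effects on composition, measurement
outliers, missing plots.

## Statistics

One-way ANOVA is computed from textbook sums of squares; with zero
within-group variance F is 0 (equal means, p = 1) or +∞ (p = 0). Fisher's
LSD declares a pair different iff |m_i − m_j| > t(1−α/2, df_w)·√(MS_w(1/n_i
+ 1/n_j)), α = 0.05 two-tailed by default. The compact letter display uses
insert-and-absorb (split every column containing a significant pair, then
drop columns contained in others), which encodes the decision matrix
exactly: two groups share a letter iff not declared different. Letters are
ranked by descending mean; ties break by input order (conventionally CK,
FP, OPT, OF15, OF30). LSD is unprotected by default with a `protected`
option (omnibus p < α required), since trial reports typically do not state
which variant they use. Analyses pool sites (one letter set per treatment,
n = sites × replicates), matching how such trials present treatment
comparisons; per-site analysis is available by filtering records.
p-values always come from distribution functions, never tables.

## Nutritional yield and bioavailability

NY = C·GY/DRI/365 (adults ha⁻¹): content mg kg⁻¹ × yield kg ha⁻¹ gives mg
ha⁻¹, divided by the adult daily reference intake and 365 days. DRIs:
energy 8.47 MJ day⁻¹, Fe 13.00, Mn 2.05, Cu 0.90, Zn 9.50 mg day⁻¹. Energy
NY uses 339 kcal per 100 g wheat and the thermochemical calorie
4.184 kJ kcal⁻¹ (the conversion factor is rarely stated in assessments;
this one is fixed and documented). NY is computed per plot and averaged per
treatment (matching mean ± SD table presentation); an `of_means` mode
applies the formula to treatment means instead — with negatively correlated
content and yield the two differ by roughly the covariance term, about 1%
at the default settings.

Molar ratios use fixed masses: phytic acid (C₆H₁₈O₂₄P₆) 660.04, Fe 55.845,
Zn 65.38, Mn 54.938, Cu 63.546 g mol⁻¹. Bioavailability flags apply the
standard absorption-friendly thresholds PA/Zn < 15 and PA/Fe < 1; other
minerals have no established threshold and raise an error.

## Health and economic impact

For each nutrient (Zn, Fe), OFS treatment and demographic group:

1. Δcontent = OFS grain content − reference (default OPT) content.
2. additional intake = Δcontent × wheat intake (kg day⁻¹) × milling
   recovery (0.310 Zn, 0.217 Fe; both minerals concentrate in the bran
   removed during flour production).
3. gap closure = min(1, additional / (RNI − baseline intake)); groups at or
   above the RNI have no gap. This linear capped form is this package's
   choice — published assessments delegate it to earlier DALY methodology
   papers without restating it — and it is the simplest form consistent
   with the reproducible structure of published results (exact 3× scaling
   between 20% and 60% coverage scenarios). It is isolated in one function
   so saturating dose-response curves can be swapped in.
4. DALYs saved = group burden × coverage × gap closure.
5. % burden reduction = 100 × Σ saved / burden denominator. The
   denominator defaults to the sum of group burdens (so the reduction is
   capped at 100% by construction); the packaged fixture overrides it with
   the published denominators, which cover a wider aggregate.
6. Economic benefit = total DALYs saved × PCNI − fertilizer cost
   (900 RMB ha⁻¹, flat — labor is comparable across regimes) × area
   (4.0 × 10⁶ ha). Reported per treatment × scenario with DALYs summed
   over nutrients, so the single fertilizer cost is not double-counted.

A generic DALY burden routine is included: population × (m·L_disc +
Σ I·D·w) with L_disc = (1 − e^(−rL))/r for discount rate r > 0; discounting
and age weighting default to off (r = 0), with the 3% option conventional
in such analyses available.

All demographic parameters live in an editable YAML fixture
(`src/ofswheat/data/health_params.yaml`). It is a **synthetic,
back-solved** set: the underlying provincial survey inputs are not public,
so RNIs, group burdens and treatment content differences were back-solved
from the internally consistent published 15%OF impact column (the
back-solving arithmetic is shown in the file's comments). The 30%OF column
is not consistent with any single content difference under the linear
model, so its contents are anchored on two rows (infant Zn, adult-male Fe)
and other 30%OF cells deviate from print by up to ~8%. Published RMB
impacts cannot be reconciled with a single PCNI and the stated flat cost;
the fixture's PCNI (8758 RMB) is back-solved assuming a negligible cost
term, and monetary outputs are exercised by property tests, not
reproduction tests.

## Numerical and reporting choices

* Report files round to 2 decimals (matching conventional tables); all
  internal computation keeps full precision. Plot CSVs use shortest
  round-trip float formatting, so write → read is bit-exact.
* Report bundles contain no timestamps; a rerun with identical config and
  inputs is byte-identical. Every output file's first line declares units.
* Degenerate inputs: single-treatment datasets produce all outputs with
  the letters column marked "not applicable"; zero within-group variance
  is handled as above; empty record sets are rejected with explicit errors.

## Problem sizes in the test suite

Monte-Carlo checks use sizes chosen for tight yet fast verification:
generator calibration at 200 replicates/site (5,000 plots; means within 3
SE, CVs within 15% relative), ANOVA type-I error over 10,000 null
repetitions (5 groups × 3), letter-display/brute-force equivalence over 200
random instances, dilution-correlation recovery at 400 replicates/site.

## Known limitations

* No site-block or mixed-effects modelling; treatments are compared pooled
  over sites.
* No absorption models beyond the molar-ratio proxy (no Miller/WHO
  absorption equations), and no uncertainty propagation over DALY
  parameters.
* The generator does not simulate weather, soil processes, spatial layout,
  or site effects on grain composition.
* The health fixture reproduces the published 15%OF column by
  construction; it is a calibration vehicle, not an independent estimate.
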