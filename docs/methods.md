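# Methods

This note documents the model implemented by `mammodose`: its assumptions,
parameters, numerical choices, and the limits of what the synthetic test
harness demonstrates.

## The model

The package projects, from a woman's **first** screening-mammography visit,
her mean glandular dose (MGD) at every potential screening age 40–75, and
from that a population-level lifetime risk of radiation-induced breast
cancer for any screening regimen. The chain has four stages.

### 1. Percentile growth curves

Mammographic breast density (MBD, %) and compressed breast thickness
(CBT, mm) evolve with age; tube loading (mAs) tracks CBT. Each relationship
is modelled as a family of 20 percentile curves (levels 1, 5, 10, …, 95):
quadratics in age for MBD and CBT,

    MBD(A) = a A² + b A + c,      CBT(A) = a A² + b A + c,

and a cubic in thickness for mAs,

    mAs(C) = a C³ + b C² + c C + d.

The woman's observed first-visit value selects the curve whose evaluation at
her presenting age (or CBT, for mAs) is **closest in absolute difference**;
that curve then predicts the quantity at every other age. Ties break toward
the lower percentile (the lower-dose direction); observations outside the
1st–95th envelope clamp to the extreme curve rather than extrapolating a new
percentile — only 20 curves are defined. Selection is idempotent: selecting
with a value read off a curve re-selects that curve.

The published coefficient set ships with the package at full printed
precision (up to 18 decimals), so the published curves are reproduced
exactly. Families can also be re-fitted from cohort data: samples are
grouped into 1-year age bins (1 mm CBT bins for mAs), the empirical
percentile of y in each bin is taken by linear interpolation of order
statistics (the "type 7" convention — the source tables do not state an
estimator, so the most common one is used), under-populated bins (default
minimum 10 samples) are dropped with a warning, and each level is fitted by
least squares against the mean x of its bins. Fitting fewer than order+1
bins is an error.

Predictions are clipped to physical bounds — MBD to [0, 100] %, CBT to
[20, 110] mm, mAs floored at 1 mAs (the cubics can go negative outside the
fitted range). The published 5th-percentile CBT curve crosses its
neighbours at mid ages; the family is embedded as printed and deliberately
not monotonised.

### 2. Acquisition prediction

Hologic Selenia Dimensions units select kVp and target/filter (T/F) from
CBT: W/Rh for 20–69 mm, W/Ag for 70–110 mm, with kVp stepping from 25 to 37
across 16 CBT bands. The packaged lookup table encodes this; fractional
predicted CBT rounds half-up to integer mm and clamps to [20, 110] before
the bin match (the mapping of fractional thickness to integer bins is a
package choice; the source defines only integer bands). The table can be
re-derived from cohort data as the per-mm modal (kVp, T/F) pair, with
interior gaps filled from the nearest populated millimetre and identical
neighbouring pairs merged into bands.

An *exposure plan* holds, for each age 40–75, predicted MBD and CBT (from
the selected age curves), kVp/T-F (lookup on predicted CBT), and mAs
(selected mAs curve at predicted CBT). At the presenting age the observed
values replace the predictions, since the actual acquisition is known; if
observed kVp/T-F disagree with the lookup, the observation wins and the
disagreement is logged.

### 3. Dosimetry

Per exposure, MGD = K·g·c·s with incident air kerma

    K = mAs · A · kVp^n / (SID − ISD − CBT)² ,

A and n being tube-output constants from the unit's QA survey and SID/ISD
the source-to-image and image-to-support-plate distances. All distances are
millimetres; QA configs must declare `distance_units: mm` explicitly and
anything else is refused rather than converted (the inverse-square form
makes a silent unit error a ~100× dose error). The g/c/s conversion factors
are multilinearly interpolated from user-supplied grids in (HVL, CBT) and
(HVL, CBT, glandularity); the predicted MBD serves as the glandularity
input. Queries outside a grid raise an error — extrapolating dosimetric
factors silently is unsafe. Beam HVL is modelled as linear in kVp per
target/filter with QA-configurable intercept and slope (a per-image
measured HVL column can override it).

A visit dose assumes 2 identical projections per breast (1 MLO + 1 CC,
configurable): with both breasts imaged the two per-breast dose sums are
averaged (the breasts jointly form one organ); with a single laterality the
sum is reported unaveraged, treating the woman as post-mastectomy. The
result is 36 per-age visit doses; their median is the **median MGD per
screening round** (MGD_MSR; even-length medians average the central pair).

### 4. Categorisation and risk

MGD_MSR maps to a low/medium/high dose category by tertile boundaries of a
training cohort's MGD_MSR distribution; the published boundaries 3.413 and
4.346 mGy ship as defaults and are consumed as constants (the underlying
cohort is not reproducible here). Bands are half-open: [0, 3.413) low,
[3.413, 4.346) medium, [4.346, ∞) high — the printed ranges list the
boundary in both bands, so a convention had to be chosen. Boundaries can be
recomputed from any cohort with the same type-7 quantile estimator.

Risk is projected at the category level. Each category carries a published
table of median MGD per age 40–75. The lifetime attributable risk (LAR) of
breast cancer per 100,000 women per mGy at exposure age A is a cubic

    LAR(A) = a A³ + b A² + c A + d

fitted through the BEIR VII female-breast anchors (ages 40–80), per
endpoint (incidence, mortality) and DDREF ∈ {1, 1.5, 2}; DDREF scaling is
the exact ratio 1 : 2/3 : 1/2. The cubic is refused outside ages 40–80
rather than extrapolated. The lifetime effective risk of a regimen is

    LER = Σ_ages MGD_category(age) · LAR(age) ,

in cases per 100,000; percent presentation divides by 1000 and is rounded
to 3 decimals in summaries. Regimen presets: Australia full (annual 40–49 +
biennial 50–74, 23 visits), Australia biennial (50–74, 13), UK (triennial
from 50, 7 visits, ages 50–68), USA (annual 45–54 + biennial 55–75, 21).
The UK programme is sometimes described as "50 to 74", but seven triennial
invitations span ages 50–68, and only that reading reproduces the published
regimen sums; the preset uses it.

The LAR is a population parameter, so the headline output is the
category-level projection; a per-woman profile mode exists but is flagged
exploratory in its output.

## Synthetic data

`mammodose.synthetic` generates seeded cohorts with exactly the structure
the model assumes: each woman has a uniform age in 40–75 and occupies one
of the 20 percentile levels (uniformly by default, configurable weights);
her images carry the level's curve values plus additive Gaussian noise on
MBD (σ = 1 percentage point) and CBT (σ = 2 mm), truncated to physical
bounds, and multiplicative log-normal noise on mAs (σ = 0.05); kVp/T-F
follow the lookup on the noisy CBT, with optional contamination. All
randomness flows from one seed. `simulate_exposures_from_lookup` draws
CBT uniformly over the full 20–110 mm range so every lookup band is
exercised — the round-trip oracle for table derivation.

What this does and does not show: passing parameter-recovery tests
demonstrates that the fitting and derivation code inverts its own
generative assumptions at realistic sample sizes (20,000 images recover
the median curves within 10 % and the lookup bin-for-bin under 10 % kVp
contamination). Real screening data violate these assumptions — women drift
across percentile levels between visits, density estimates carry
software-specific bias, AEC behaviour varies with unit calibration — so
recovery on synthetic cohorts bounds code correctness, not clinical
accuracy. Because women sit on 20 discrete levels, bin percentiles are
biased by up to half a level gap, which dominates the few-percent error
seen in recovery tests.

The fixture factor tables are smooth, positive, physically shaped grids
(g decreasing with CBT, c ≡ 1 at 50 % glandularity, s near 1) but
synthetic: real work requires the published factor grids, supplied in the
same CSV format. The fixture QA constants (A = 0.85, n = 3, SID 700 mm,
ISD 25 mm) are calibrated so a median woman's visit doses land in the
low-mGy range seen in screening dose audits.

## Numerical and design choices

- Polynomials are evaluated with Horner's rule (`numpy.polyval`) on
  coefficients stored highest-degree-first.
- Curve selection scans levels in ascending order with a strict `<`, which
  implements the lower-percentile tie-break without a separate pass.
- Quantiles and medians use NumPy's default linear interpolation
  throughout (curve fitting, tertiles, MGD_MSR, category medians).
- Visit summaries average MBD/CBT/mAs arithmetically across images and take
  the modal kVp (ties to the lower kVp) and modal T/F (ties to W/Rh).
- The per-visit pipeline orders women lexicographically and writes no
  timestamps, so repeated runs are byte-identical.
- Validation errors carry the offending field, age, or axis by name.

## Problem sizes

The test suite runs cohorts of up to 5,000 women × 4 images (20,000
samples) for parameter recovery and 20,000 draws for lookup derivation;
these sizes were chosen as the point where recovery tolerances stabilise.
The acceptance script's quantities are closed-form sums over at most 23
regimen ages and run in milliseconds.

## Known limitations

- Hologic-specific: the kVp/T-F lookup and mAs curves encode one vendor's
  exposure control; other vendors need their own derived tables.
- The category boundaries and category median-dose table are consumed as
  published constants; they cannot be re-derived without the original
  cohort.
- No non-radiation risk modifiers (ethnicity, BMI, HRT, parity) enter the
  risk projection.
- The linear HVL-vs-kVp model is a configurable simplification of measured
  beam quality; supply per-image HVL where available.
- Percentile-curve crossings present in the published coefficients are
  preserved, so predicted series from adjacent levels can invert order at
  some ages.
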