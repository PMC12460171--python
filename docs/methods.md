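# Methods

This note records the models implemented by tracequant, their
assumptions, the defaults that matter, and the design choices made
where more than one reasonable convention exists. Nothing here states a
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Natural-abundance correction

A metabolite with *n* atoms of the tracer element and *j* tracer labels
produces a measured isotopologue distribution equal to the convolution
of (a) the binomial natural-abundance distribution of its *n − j*
unlabelled positions and (b) the binomial tracer-purity distribution of
its *j* labelled positions. Stacking these as columns gives the
forward matrix **A** (lower-triangular at purity 1); the measured MID is
**A·x** for labelling MID **x**. Correction solves
min ‖**A·x** − measured‖₂ subject to **x** ≥ 0 (scipy NNLS) and
renormalizes to the simplex. NNLS rather than direct inversion because
multiplicative intensity noise routinely drives naive inverses negative
at low-abundance isotopologues; the residual norm is kept as a fit
diagnostic (config threshold `na_correction.residual_warn_threshold`,
default 0.01).

Only the tracer element is corrected (¹³C for carbon tracing, ²H for
deuterium tracing). This is the high-resolution assumption: at
orbitrap resolving powers the isotopologues of other elements are
mass-separated from the tracer series. Defaults: ¹³C natural abundance
0.011, ²H 0.000156, tracer purity 1.0 (no purity correction is applied
unless configured, since tracer purity is rarely reported for ²H₂O
dosing); all are configurable.

## Deuterium enrichment and its truncation bias

Palmitate ²H enrichment is the weighted sum H₁ + 2·H₂ + 3·H₃ over the
corrected isotopologue fractions, hard-truncated at M3. For binomial
labelling of *n* sites at probability *p* the untruncated weighted sum
is exactly *n·p*, so the truncation attenuates the estimate by a factor
computable by direct binomial enumeration: ≈0.9852 at *p* = 0.025,
*n* = 22, and 0.9760 at *p* = 0.03. The implementation reports the
untruncated sum alongside the truncated estimator so the bias is always
visible; the truncated form is the headline value because it is the
estimator the downstream lipogenesis equation is defined with.

## Body-water calibration

²H in body water exchanges into acetone under base catalysis; the
²H₁-acetone fraction is linear in the water ²H fraction. The standard
curve is ordinary least squares *with* an intercept — natural ²H
background produces a nonzero blank — over a serial dilution spanning
0–4% ²H₂O (the physiological range after a 30 µl g⁻¹ intraperitoneal
dose; synthetic defaults use slope 0.75, intercept 0.005). Serum
samples are inverted through the line; values below the blank are
clamped to 0 with a logged warning rather than erroring, because blanks
scatter.

## De novo lipogenesis

Under the two-population model — a fraction *f* of the palmitate pool
synthesized during exposure with each of its *n* exchangeable hydrogens
drawn from body water at ²H fraction BW, the rest pre-existing and
unlabelled — the isotopomer ratio identity
H₂/H₁ = ((n−1)/2)·BW/(1−BW) holds exactly, independent of *f*.
*n* is therefore estimated per animal from that animal's corrected
H₂/H₁ ratio and body water (not pooled across the cohort, matching
per-animal reporting), and DNL = enrichment/(BW·n). Samples with
H₁ ≈ 0 have an undefined ratio and are excluded with a logged reason.
Estimates above 1 are physically impossible and are flagged
(`dnl_fraction>1`) but never clamped, so calibration errors remain
visible in QC. *n* is not capped at palmitate's theoretical maximum;
the estimate is reported as-is. The hourly rate divides by the time
between dose and collection (15 h in the overnight protocol the
synthetic metadata emulates). The rate unit is fraction·h⁻¹ and is
documented as such wherever reported.

## Fatty-acid oxidation

The calorimetry instrument is calibrated to 1.1% ¹³CO₂ (natural ¹³C
abundance), so the oxidation signal is the excess above that constant
baseline; a per-animal pre-dose baseline mode is available behind
config but is not the default, because calibration to the constant is
the stated instrument setup. Negative excess is floored at zero with a
count of floored points.

Two readouts per animal:

* slope-to-max — OLS slope of excess against time from dosing through
  the earliest maximum (ties break to the earliest time; a maximum at
  the first point means no rising phase and is an error);
* normalized oxidation — excess divided by circulating un-esterified
  ¹³C-substrate enrichment linearly interpolated to the CO₂ time points.
  Per-timepoint normalization is the default (an AUC-ratio mode would
  be the alternative); extrapolation beyond the measured substrate span
  is refused, and points with interpolated enrichment ≤ 0.001 (config
  `enrichment_floor`) are dropped with a warning since the quotient
  would be noise-dominated.

## Quantitation

Concentration curves are OLS with intercept over authentic standards
with inverse prediction for unknowns (weighted 1/x regression is left
to future work; the defaults match unweighted practice). Tissue
amounts use the extraction formula concentration(µM) × volume(µl) /
mass(mg). That expression is dimensionally nmol g⁻¹, which is the
default unit label; because the formula is sometimes quoted with a
µmol g⁻¹ label, the label (not the number) can be overridden. Labelled
fatty-acid readouts can be divided by the hepatic ¹³C-acetyl-CoA
fractional labelling, which cancels precursor-pool enrichment
differences between animals.

## Group statistics

Outliers are values beyond 1.5×IQR below Q1 or above Q3, with quartiles
by linear interpolation (the type-7 convention, fixed and documented
because "IQR" alone underdetermines the quartile estimator); flagging
is applied per metric per group before testing, and flagged values are
excluded and reported. Multi-group comparisons are one-way ANOVA with
Tukey's HSD (statsmodels); the unadjusted pairwise p uses the same
pooled-MSE t statistic and error df as the Tukey adjustment so that
adjusted ≥ unadjusted always holds. Two-group tests are Student's t
with pooled variance (Welch is available via config); one-sided tests
require the direction explicitly — it is never inferred. FDR
correction is Benjamini–Hochberg step-up.

## Synthetic data

The generators produce exactly the structures the estimators assume,
which is what makes them useful for validation and is also their
limitation:

* DNL cohorts: two-population binomial-mixture labelling convolved with
  ²H natural abundance over all 31 palmitate hydrogens, scaled to 10⁶
  total counts, with multiplicative log-normal noise (mean-one
  parameterization) at a configurable CV. Defaults mirror the study
  shape: groups CF/IF/CIF with f = 0.5/0.25/0.3, 10 animals/group,
  n = 22 exchangeable hydrogens, body water 2.5%, 5% CV, 18:00 dose /
  09:00 collection. The group f values are plausible effect directions,
  not claims about measured values.
* CO₂ traces: excess A·(1−e^(−k_a t))·e^(−k_e t) on the 1.1% baseline,
  sampled at 40-min intervals over 8 h (defaults A = 0.006/0.004 for a
  1.5× two-group contrast, k_a = 0.02 min⁻¹, k_e = 0.004 min⁻¹, 10%
  multiplicative noise), plus an exponentially decaying substrate
  enrichment series (15% initial, 0.003 min⁻¹).
* Body-water standards: points on the acetone line with Gaussian
  response noise.

Real LC–MS data additionally contain peak-integration errors,
background, matrix effects, drift, and deviations from binomial
labelling (positional enrichment differences, elongation vs de-novo
pools). Passing tests therefore demonstrate correctness of the
arithmetic and robustness to multiplicative noise, not robustness to
those instrument artefacts.

## Numerical choices and problem sizes

All randomness flows through `numpy.random.default_rng` seeds;
generators are byte-reproducible. Validation runs use 200 random MIDs
for the correction round-trip, the full n ∈ 2..40 × p ∈ 0.005..0.06
grid for the ratio identity, 100 replicate cohorts of 10/group for
noisy DNL recovery and detection, 500 seeds for calibration coverage,
100 seeds for FAO ordering, and 2,000 null simulations for the t-test
type-I error — sizes chosen so each check has narrow Monte-Carlo error
while the whole suite completes in about half a minute.

## Known limitations

Single-tracer correction only (no dual-tracer or multi-element joint
correction); no isotopomer spectral analysis or multi-compartment
precursor modelling; absolute oxidation flux (µmol min⁻¹) is out of
scope because it requires VCO₂ volumes and bicarbonate-pool recovery
factors; no derivatization-efficiency or matrix-effect modelling in
quantitation.
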