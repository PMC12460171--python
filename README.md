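# tracequant

Quantitative analysis of stable-isotope tracer studies from LC–MS
isotopologue peak tables and indirect-calorimetry breath traces. The
package implements the full quantitation chain used in in-vivo studies
of hepatic lipid metabolism:

* **Natural-abundance correction** of measured mass-isotopomer
  distributions (MIDs) by non-negative least squares against the
  binomial convolution matrix of the tracer element (¹³C at 1.1%, ²H at
  0.0156%), under the high-resolution assumption that non-tracer
  isotopologues are mass-resolved.
* **²H₂O de novo lipogenesis (DNL)**. After a deuterated-water dose, the
  fraction of palmitate newly synthesized is

  ```
  DNL = ²H enrichment / (BW × n)
  ²H enrichment = ²H₁ + 2·²H₂ + 3·²H₃
  ²H₂/²H₁ = ((n − 1)/2) · BW/(1 − BW)
  ```

  where BW is the body-water ²H fraction (calibrated through an
  acetone-exchange standard curve) and *n* the number of exchangeable
  hydrogens, estimated per animal by inverting the binomial isotopomer
  ratio identity. Dividing by hours since dosing gives the hourly rate.
* **¹³CO₂ fatty-acid oxidation**: excess ¹³CO₂ above the 1.1% natural
  baseline, the OLS slope of the rise up to the trace maximum, and
  per-timepoint normalization to circulating ¹³C-substrate enrichment.
* **Calibration-curve quantitation**: external standards, inverse
  prediction, tissue amounts (µM × µl / mg), and acetyl-CoA-normalized
  lipogenesis readouts.
* **Group statistics**: 1.5×IQR outlier flagging, one-way ANOVA with
  Tukey's HSD, pooled-variance Student's t, Benjamini–Hochberg FDR.
* **Synthetic-data generators** that emit cohorts with the exact
  statistical structure the estimators assume (binomial-mixture ²H
  labelling, rise-then-decay CO₂ excess, log-normal intensity noise),
  so every stage can be validated without instrument data.

Intended users: metabolism researchers processing isotope-tracing
experiments, and method developers who need a transparent, tested
reference for the DNL/FAO arithmetic.

## Worked example

Simulate a three-group ²H₂O cohort (CF = fructose control, IF = inulin
+ fructose, CIF = delayed inulin; true synthesis fractions 0.5 / 0.25 /
0.3, body water 2.5%, 5% intensity CV) and run the DNL pipeline:

```sh
tracequant simulate dnl --out demo_data --seed 7
cat > run.yaml <<EOF
pipeline: dnl
peak_table: demo_data/peaks.csv
metadata: demo_data/metadata.csv
body_water_standards: demo_data/standards.csv
output_dir: demo_run
EOF
tracequant dnl --config run.yaml
cat demo_run/summary.txt
```

```
tracequant DNL pipeline summary
================================

Per-group DNL fraction (outliers excluded):
  CF: mean 0.5078  sd 0.0391  n 10
  IF: mean 0.2489  sd 0.0124  n 9
  CIF: mean 0.2758  sd 0.0230  n 10

Group comparisons:
  CF vs CIF: p 1.14e-16  adj p 1.332e-15
  CF vs IF: p 1.509e-17  adj p 1.11e-15
  CIF vs IF: p 0.043  adj p 0.1037
```

The group means recover the designed synthesis fractions (0.5 / 0.25 /
0.3) to within a few percent — the small shortfall of the noise-free
estimate (−1.5% at 2.5% body water) is the documented M3-truncation
bias of the enrichment sum. One IF animal was excluded by the 1.5×IQR
rule; the fructose-only group separates from both inulin groups at
Tukey-adjusted p < 0.001. Every intermediate (raw MIDs, corrected MIDs,
enrichments, body-water inversions, per-sample DNL, outlier flags) is
written to `demo_run/` as a numbered CSV.

The analogous `tracequant simulate fao` / `tracequant fao` pair runs
the breath-trace pipeline (per-animal slope-to-max, normalized
oxidation, group tests).

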