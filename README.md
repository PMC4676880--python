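# mrmqc

Assay-characterization engine for targeted proteomics. Given per-run,
per-transition chromatographic peak areas from SRM/MRM assay-development
experiments (a Skyline-style tab-delimited transition-results export),
`mrmqc` computes the CPTAC Assay Development Working Group "Tier 2"
performance measures:

* **Response curve** — limit of detection (LOD), lower limit of
  quantification (LLOQ), upper limit of quantification / linear range,
  calibration-curve linearity (slope, intercept, R², slope standard error),
  and carry-over;
* **Mini-validation of repeatability** — intra-assay, inter-assay and total
  coefficients of variation at low/medium/high concentration levels, the
  validated LLOQ level, and partial validation of specificity via transition
  ratios.

Every measure is reported at two levels per peptide: for each monitored
transition individually and for the summed transition signal. It is written
for mass-spectrometry method developers who already integrate peaks in
Skyline and need standardized, auditable performance numbers for each assay.

## The statistics in brief

**Calibration.** Peak area *y* is regressed on theoretical concentration *x*
by least squares over individual replicate observations, *y = a·x + b*
(optionally 1/x- or 1/x²-weighted). Reported: *a*, *b*, R², and
100·SE(*a*)/|*a*| (`Curve.SlopeStdErr(%)`). The **linear range** is the
widest contiguous window of calibration points in which every point has
replicate CV ≤ 20 % and back-calculated accuracy within ±20 % of nominal;
its top point is the **ULOQ**. The **LLOQ** is the lowest point from which
all-replicate detectability and CV ≤ 20 % hold unbroken up to the ULOQ.

**LOD.** With ≥2 detectable blank runs, LOD = (mean(blank) + 3·sd(blank) −
b)/a. When blanks report nothing — the usual case on modern instruments —
the spiked-in fallback LOD = 3·sd(lowest calibration point)/a is used and
flagged in `LOD.usedSpiked`.

**CV decomposition.** For each concentration level, a one-way
random-effects (day) ANOVA: σ²_within = MS_within, σ²_between =
max(0, (MS_between − MS_within)/n₀) with the unbalanced-design
n₀ = (N − Σn_d²/N)/(D − 1). intraCV, interCV and totalCV are the component
standard deviations (and their root sum of squares) as a percentage of the
grand mean.

**Specificity.** For all samples above the validated LLOQ, each ratio of
peak areas between transitions of the same peptide is compared with its
across-sample mean; a transition whose maximum deviation exceeds 30 % is
flagged non-specific (`PVSpec.*` columns). Summed-transition rows carry NA
here — ratios are undefined for a sum.

## Worked example

`mrmqc demo` generates a seeded synthetic study (15 peptides × 3
transitions; seven-point calibration curves in triplicate; low/medium/high
QC levels over five days in triplicate) and runs both engines on it:

```
$ mrmqc demo --seed 7 --out demo
demo outputs written under demo
```

`demo/response_curve_results/response_curve_report.tsv` begins:

```
Peptide      Transition  LOD.value    LOD.usedSpiked  LLOQ.CaliPoint  ULOQ.CaliPoint  Curve.Slope  Curve.Intercept  Curve.Rsquared  Curve.SlopeStdErr(%)
WPQVNSTFCHK  2.y3.1      0.000636703  TRUE            1               5               15365.4      -108.504         0.996203        1.9523
WPQVNSTFCHK  2.y4.1      0.00134001   TRUE            1               6               23510.3      1242.49          0.999208        0.8903
```

Reading the first row: transition y3 (2+ precursor, 1+ product) of peptide
WPQVNSTFCHK responds linearly (R² = 0.996, slope SE 1.95 % of the slope)
with a response factor of ~15 365 area units per concentration unit;
quantification is reliable from calibration point 1 up to point 5, and the
detection limit of 6.4·10⁻⁴ concentration units was estimated from the
spiked-in fallback because the blank runs showed no signal (`TRUE`).

The repeatability report gives, per transition, the CV trio at each level,
e.g. `intraCV.low 4.3651  interCV.low 6.7952  totalCV.low 8.0764`, the
validated LLOQ level (`low`) with its median-based total CV
(`totalCV.Me 6.9005`), and the specificity fields — here a maximum
transition-ratio deviation of 20.46 % in a day-5 low sample, below the 30 %
threshold, so `PVSpec.specific TRUE`.

For real data, supply your own three files:

```
mrmqc run --mode both --skyline export.tsv --metadata metadata.tsv \
          --dilution dilution.tsv --out results --visualize
```

`--visualize` adds per-peptide response-curve and repeatability figures plus
an eight-panel global overview.

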