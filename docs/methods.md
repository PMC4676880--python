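# Methods

This note documents the statistical procedures, the defaults and why they
were chosen, what the synthetic-data generator does and does not emulate,
and the numerical edge-case policies.

## Inputs and assembly

Three tab-delimited files define an experiment: the Skyline-style transition
export (peptide sequence, precursor charge, fragment ion, product charge,
replicate name, peak area), the run metadata (sample type ∈ {blank,
calibration, qc}, day, replicate index, calibration point or concentration
level), and the serial-dilution map (calibration point → theoretical
concentration, strictly increasing). Header matching is case-insensitive
and separator-tolerant, with a user column map as the escape hatch, because
Skyline report templates are user-defined. Missing areas may be spelled
`""`, `#N/A`, `NA` or `NaN` on input; output uses `NA` only. A peptide is
keyed by (sequence, precursor charge); modified-sequence strings are used
verbatim as the sequence key.

Measurements are assembled per transition; the summed-transition series adds
the non-missing areas per run (missing treated as absent, not zero — zero
filling would bias the curve's low end, where dropout concentrates; a run
with every transition missing stays missing). An export run without
metadata is an error; a metadata run without export rows is only a warning.
Unbalanced designs are accepted throughout; all statistics use per-group
counts.

The metadata file's row order is read as acquisition order. Blank runs
listed after the last run of the highest calibration point are carry-over
(post-high) blanks; all other blanks are pre-curve blanks. This is the one
place where file order is semantic, and it is documented in the CLI help.

## Response curve

"Detectable" means present and strictly > 0 throughout.

**Calibration fit.** Least squares of area on concentration over individual
replicate observations (replicates are not averaged, so SE(slope) keeps the
replicate information), computed with statsmodels WLS. Default weighting is
none; 1/x and 1/x² are available because bioanalytical calibration
variance commonly grows with concentration. R² is the ordinary coefficient
of determination, clipped to [0, 1] against floating-point excursions.

**Linear range / ULOQ.** Brute force over all contiguous calibration-point
windows of ≥3 points, widest first, ties preferring the higher top point and
then the lower bottom point (deterministic and auditable). A window passes
when every point has ≥2 detectable replicates with CV ≤ the CV threshold
(default 20 %) and the window's own fit back-calculates each point's mean
area to within the accuracy tolerance (default ±20 %) of nominal. The
reported curve statistics come from the winning window's fit; without a
passing window the fit falls back to all points with detectable signal so
LOD conversion still has a curve.

**LLOQ.** The lowest point p such that every point in [p, ULOQ] has all
replicates detectable and CV ≤ threshold; "not estimable" is a legal,
rendered outcome. By construction LLOQ ≤ ULOQ when both exist.

**LOD.** The classical k·sigma convention (k = 3, configurable). With ≥2
detectable blank runs: signal mean(blank) + k·sd(blank) converted through
the fitted curve and floored at zero. Otherwise the spiked-in fallback
k·sd(areas at the lowest calibration point with ≥2 detectable
replicates)/slope, flagged via `LOD.usedSpiked`. LOD is reported in the
dilution file's concentration units, whatever they are.

**Carry-over.** 100·mean(post-high blanks)/mean(highest point), with
missing blank areas counted as zero signal; additionally flagged when the
blank mean exceeds 20 % of the LLOQ point's mean signal. Without post-high
blanks the cell is NA.

## Repeatability

**CV decomposition.** Method-of-moments one-way ANOVA with day as the
random factor, per concentration level: σ²_w = MS_within, σ²_b = max(0,
(MS_between − MS_within)/n₀), n₀ = (N − Σn_d²/N)/(D−1) for unbalanced day
sizes; CVs are 100·σ/grand mean, totalCV uses σ²_w + σ²_b. This closed-form
estimator was chosen over an iterative REML fit because it is exact,
dependency-free and the standard in assay-validation practice; the clamp at
zero is the usual non-negativity repair. Days with <2 detectable replicates
are dropped with a logged warning; <2 usable days or a non-positive grand
mean make the level not estimable.

**Validated LLOQ.** The lowest level (low < medium < high) with totalCV ≤
the validation threshold (default 20 %) and every replicate detectable on
every day. `totalCV.Me` is a median-based summary at that level: the CV of
the per-day medians of replicate measurements (medians-per-day is also what
the repeatability figure plots). The plain ANOVA totalCV per level is
reported alongside, so both estimators are visible.

**Specificity.** Samples qualify when their concentration level is at or
above the summed series' validated LLOQ level (all samples qualify, with a
warning, when no level validates — a deterministic link between the two
computations). Within each qualifying sample in which every transition is
detectable, transition ratios are formed; each ratio series is compared to
its across-sample mean, and a transition's `PVSpec.maxDeviation` is its
largest percent deviation, with the maximizing sample's day and level
reported. `specific` is maxDeviation ≤ 30 % (configurable). The default
ratio definition is **pairwise** — area_t/area_t′ for every ordered pair —
which is the literal reading of "ratios of peak areas of different
transitions of the same peptide" and has the property that inflating one
transition by a factor f in one of M samples produces a deviation of
exactly 100·(f·M/(M−1+f) − 1) for that transition (≈ 100·(f−1) for large
M). Fraction-of-sum and ratio-to-most-intense definitions are available via
`ratio_mode`; note the sum denominator dilutes an interference (a 1.4×
inflation on one of three transitions yields only ≈ 23 % deviation), so it
is not the default. Summed rows never carry PVSpec values.

## Synthetic data

The generator emulates the canonical Tier 2 study design: 15 peptides × 3
transitions; seven-point serial dilution spanning 0.01–100 concentration
units in triplicate with three pre-curve blanks; low/medium/high QC levels
(1/10/100 units) over five days in triplicate. Signal is linear in
concentration with per-transition response factors drawn log-uniformly over
10^2.5–10^4.5 area units per concentration unit. Noise is multiplicative
log-normal — the empirical regime of integrated MRM peak areas — with
σ² = ln(1 + (CV/100)²) so the generated CV equals the configured one
exactly; defaults are 5 % within-replicate and 10 % between-day, typical of
a well-behaved targeted assay. The day effect is shared across a peptide's
transitions (same sample handling). Blanks default to zero signal, matching
instruments whose blanks report nothing; dropout below a configurable
concentration writes `#N/A`; carry-over writes post-high blanks carrying a
configured fraction of the top-point signal; an interference option
multiplies one transition's area in one chosen sample by a known factor.
Ground truth is written to a JSON sidecar so tests never reach into the
generator's internals.

What it does **not** emulate: chromatographic peak shapes and integration
error, retention-time drift, matrix interference at the signal level,
heavy/light internal-standard structure, heteroscedastic additive noise at
the low end, or missingness that is stochastic rather than a hard
concentration threshold. Passing tests therefore demonstrate correctness of
the estimators and decision rules under the stated noise model, not
robustness to every pathology of real acquisitions.

## Numerical and reporting choices

Sample standard deviations use ddof = 1 everywhere. Percent-scaled cells
print with 4 decimals, everything else with 6 significant figures; booleans
print TRUE/FALSE; not-applicable/not-estimable cells print NA. Reports are
deterministic (no timestamps), so identical inputs and configuration
reproduce them byte-for-byte. Test problem sizes were chosen to keep the
whole suite under about half a minute while leaving Monte-Carlo bounds
comfortably wide: the variance-recovery check uses ~500 simulated
transitions (5 days × 3 replicates each), for which the mean estimated
intra-/inter-assay CVs at truth 5 %/10 % fall within [4, 6] % and
[7.5, 12.5] %.

## Known limitations

* LOD/LLOQ carry no confidence intervals; detection-probability (logistic)
  LOD modeling is out of scope.
* The carry-over assessment depends on metadata row order encoding
  acquisition order; shuffled metadata silently reclassifies blanks.
* The engine is agnostic to whether the area column is light, heavy or a
  ratio; heavy/light processing must happen upstream.
* With very wide dynamic ranges and unweighted regression, back-calculated
  accuracy at the lowest points is intercept-dominated and the linear-range
  search may trim low points; 1/x² weighting is the standard remedy and is
  one config key away.
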