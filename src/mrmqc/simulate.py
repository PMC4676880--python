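"""Seeded synthetic assay-development experiments.

Generates the three tab-delimited inputs the engine reads — a Skyline-style
transition export, run metadata, and a dilution map — plus a machine-readable
ground-truth sidecar, for both experiment designs:

* response curve: a serial dilution (default seven points spanning
  0.01–100 concentration units, in triplicate) with linear signal,
  multiplicative (log-normal) replicate noise, optional blank signal,
  low-concentration dropout and carry-over into post-high blanks;
* repeatability: low/medium/high QC levels measured in replicate over
  several days (default 3 × 5 × 3), with separate within-day and between-day
  log-normal variance components and an optional interference that inflates
  one transition's area in chosen samples by a known factor (a manufactured
  specificity violation).

Noise is multiplicative because SRM peak-area variability is empirically
proportional to signal; the log-normal sigma is chosen as
sigma² = ln(1 + (CV/100)²) so the generated coefficient of variation equals
the configured one exactly. Defaults mirror a typical CPTAC-style Tier 2
assay-development study: 15 peptides, 3 transitions each, 7-point curves in
triplicate, and 5-day triplicate mini-validation, with 5 % within-day and
10 % between-day CV.

Determinism: the same :class:`SimulationConfig` (including seed) produces
byte-identical files.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

EXPORT_HEADER = ("Peptide Sequence", "Precursor Charge", "Fragment Ion",
                 "Product Charge", "Replicate Name", "Area")
METADATA_HEADER = ("Replicate Name", "Sample Type", "Day", "Replicate Index",
                   "Concentration Level", "Calibration Point")
DILUTION_HEADER = ("Calibration Point", "Theoretical Concentration")

_AMINO = "ACDEFGHIKLMNPQRSTVWY"

DEFAULT_CALIBRATION_POINTS = (0.01, 0.0464, 0.215, 1.0, 4.64, 21.5, 100.0)


@dataclass(frozen=True)
class Interference:
    """Inflate one transition's area in one QC sample by ``factor``."""

    transition_index: int
    level: str
    day: int
    replicate: int
    factor: float


@dataclass
class SimulationConfig:
    seed: int = 0
    n_peptides: int = 15
    n_transitions_per_peptide: int = 3
    calibration_points: Sequence[float] = DEFAULT_CALIBRATION_POINTS
    n_replicates: int = 3
    n_days: int = 5
    qc_concentrations: dict = field(default_factory=lambda: {
        "low": 1.0, "medium": 10.0, "high": 100.0})
    slope_per_transition: Sequence[Sequence[float]] | None = None
    proportional_cv: float = 5.0      # within-replicate CV, percent
    between_day_cv: float = 10.0      # day-to-day CV, percent
    blank_mean: float = 0.0
    blank_sd: float = 0.0
    n_blanks_pre: int = 3
    n_blanks_post: int = 2
    dropout_below: float = 0.0        # concentrations below this go missing
    carryover_fraction: float = 0.0   # post-high blank signal / high signal
    interference: Interference | None = None

    def __post_init__(self) -> None:
        pts = list(self.calibration_points)
        if any(b <= a for a, b in zip(pts, pts[1:])):
            raise ValueError("calibration_points must strictly increase")
        for name in ("proportional_cv", "between_day_cv", "blank_mean",
                     "blank_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.carryover_fraction < 1:
            raise ValueError("carryover_fraction must be in [0, 1)")
        if min(self.n_peptides, self.n_transitions_per_peptide,
               self.n_replicates, self.n_days) < 1:
            raise ValueError("counts must be >= 1")
        if self.interference is not None:
            i = self.interference
            if i.level not in self.qc_concentrations:
                raise ValueError(f"interference level {i.level!r} unknown")
            if not 0 <= i.transition_index < self.n_transitions_per_peptide:
                raise ValueError("interference transition_index out of range")


@dataclass
class SimulatedExperiment:
    export_path: Path
    metadata_path: Path
    dilution_path: Path | None
    ground_truth_path: Path
    ground_truth: dict


def _lognormal_sigma(cv_percent: float) -> float:
    return math.sqrt(math.log(1.0 + (cv_percent / 100.0) ** 2))


def _peptides(config: SimulationConfig, rng: np.random.Generator
              ) -> list[tuple[str, int, list[str]]]:
    """(sequence, precursor charge, fragment ions) per peptide."""
    out = []
    seen: set[str] = set()
    for _ in range(config.n_peptides):
        while True:
            seq = "".join(_AMINO[i] for i in
                          rng.integers(0, len(_AMINO), size=10)) + "K"
            if seq not in seen:
                seen.add(seq)
                break
        ions = [f"y{3 + t}" for t in range(config.n_transitions_per_peptide)]
        out.append((seq, 2, ions))
    return out


def _slopes(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    if config.slope_per_transition is not None:
        arr = np.asarray(config.slope_per_transition, dtype=float)
        if arr.shape != (config.n_peptides, config.n_transitions_per_peptide):
            raise ValueError("slope_per_transition has the wrong shape")
        if (arr <= 0).any():
            raise ValueError("slopes must be positive")
        return arr
    # peak-area response factors spanning a few orders of magnitude
    return 10.0 ** rng.uniform(
        2.5, 4.5, size=(config.n_peptides, config.n_transitions_per_peptide))


def _write_tsv(path: Path, header: Sequence[str],
               rows: Sequence[Sequence[str]]) -> None:
    lines = ["\t".join(header)]
    lines += ["\t".join(r) for r in rows]
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def _fmt_area(area: float | None) -> str:
    return "#N/A" if area is None else f"{area:.6f}"


def simulate_response_curve(config: SimulationConfig,
                            outdir: str | Path) -> SimulatedExperiment:
    """Write a serial-dilution experiment; returns paths and ground truth.

    Pre-curve blanks are drawn Normal(blank_mean, blank_sd) truncated at 0;
    post-high (carry-over) blanks are written only when carryover_fraction is
    positive, carrying that fraction of the high-point signal. Calibration
    areas at concentrations below ``dropout_below`` are exported as missing.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    peptides = _peptides(config, rng)
    slopes = _slopes(config, rng)
    sigma = _lognormal_sigma(config.proportional_cv)
    points = list(config.calibration_points)

    meta_rows: list[tuple[str, ...]] = []
    run_specs: list[tuple[str, str, float | None]] = []  # (run, kind, conc)
    for b in range(config.n_blanks_pre):
        run = f"blank_pre_{b + 1:02d}"
        meta_rows.append((run, "blank", "", str(b + 1), "", ""))
        run_specs.append((run, "blank_pre", None))
    for p_idx, conc in enumerate(points, start=1):
        for rep in range(1, config.n_replicates + 1):
            run = f"cal_p{p_idx}_r{rep}"
            meta_rows.append((run, "calibration", "", str(rep), "", str(p_idx)))
            run_specs.append((run, "calibration", conc))
    n_post = config.n_blanks_post if config.carryover_fraction > 0 else 0
    for b in range(n_post):
        run = f"blank_post_{b + 1:02d}"
        meta_rows.append((run, "blank", "", str(b + 1), "", ""))
        run_specs.append((run, "blank_post", None))

    export_rows: list[tuple[str, ...]] = []
    top_conc = points[-1]
    for (seq, z, ions), pep_slopes in zip(peptides, slopes):
        for ion, slope in zip(ions, pep_slopes):
            for run, kind, conc in run_specs:
                if kind == "calibration":
                    if conc < config.dropout_below:
                        area = None
                    else:
                        noise = math.exp(rng.normal(0.0, sigma)) if sigma else 1.0
                        area = slope * conc * noise
                elif kind == "blank_pre":
                    area = max(0.0, rng.normal(config.blank_mean,
                                               config.blank_sd)) \
                        if (config.blank_mean or config.blank_sd) else 0.0
                else:  # blank_post: carry-over from the top point
                    carried = config.carryover_fraction * slope * top_conc
                    extra = max(0.0, rng.normal(config.blank_mean,
                                                config.blank_sd)) \
                        if (config.blank_mean or config.blank_sd) else 0.0
                    area = carried + extra
                export_rows.append((seq, str(z), ion, "1", run,
                                    _fmt_area(area)))

    dilution_rows = [(str(i + 1), f"{c:g}") for i, c in enumerate(points)]

    export_path = outdir / "export.tsv"
    metadata_path = outdir / "metadata.tsv"
    dilution_path = outdir / "dilution.tsv"
    truth_path = outdir / "ground_truth.json"
    _write_tsv(export_path, EXPORT_HEADER, export_rows)
    _write_tsv(metadata_path, METADATA_HEADER, meta_rows)
    _write_tsv(dilution_path, DILUTION_HEADER, dilution_rows)

    first_kept = next((i + 1 for i, c in enumerate(points)
                       if c >= config.dropout_below), None)
    truth = {
        "design": "response_curve",
        "peptides": [{"sequence": s, "precursor_charge": z, "fragment_ions": f}
                     for s, z, f in peptides],
        "true_slopes": slopes.tolist(),
        "calibration_points": points,
        "proportional_cv": config.proportional_cv,
        "blank_mean": config.blank_mean,
        "blank_sd": config.blank_sd,
        "dropout_below": config.dropout_below,
        "first_detectable_point": first_kept,
        "carryover_fraction": config.carryover_fraction,
        "seed": config.seed,
    }
    truth_path.write_text(json.dumps(truth, indent=2) + "\n", encoding="utf-8")
    return SimulatedExperiment(export_path, metadata_path, dilution_path,
                               truth_path, truth)


def simulate_repeatability(config: SimulationConfig,
                           outdir: str | Path) -> SimulatedExperiment:
    """Write a mini-validation-of-repeatability experiment.

    Per peptide, a shared day effect exp(delta_d), delta ~ N(0, sigma_b),
    multiplies every transition's level mean; replicate noise exp(eps),
    eps ~ N(0, sigma_w), is drawn per measurement. The optional interference
    multiplies one transition's area in one (level, day, replicate) sample.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    peptides = _peptides(config, rng)
    slopes = _slopes(config, rng)
    sigma_w = _lognormal_sigma(config.proportional_cv)
    sigma_b = _lognormal_sigma(config.between_day_cv)
    levels = list(config.qc_concentrations)

    meta_rows: list[tuple[str, ...]] = []
    samples: list[tuple[str, str, int, int]] = []  # (run, level, day, rep)
    for day in range(1, config.n_days + 1):
        for level in levels:
            for rep in range(1, config.n_replicates + 1):
                run = f"d{day}_{level}_r{rep}"
                meta_rows.append((run, "qc", str(day), str(rep), level, ""))
                samples.append((run, level, day, rep))

    day_effects = {
        (p, d): (math.exp(rng.normal(0.0, sigma_b)) if sigma_b else 1.0)
        for p in range(config.n_peptides)
        for d in range(1, config.n_days + 1)}

    export_rows: list[tuple[str, ...]] = []
    for p, ((seq, z, ions), pep_slopes) in enumerate(zip(peptides, slopes)):
        for t, (ion, slope) in enumerate(zip(ions, pep_slopes)):
            for run, level, day, rep in samples:
                mu = slope * config.qc_concentrations[level]
                noise = math.exp(rng.normal(0.0, sigma_w)) if sigma_w else 1.0
                area = mu * day_effects[p, day] * noise
                intf = config.interference
                if (intf is not None and intf.transition_index == t
                        and (level, day, rep) == (intf.level, intf.day,
                                                  intf.replicate)):
                    area *= intf.factor
                export_rows.append((seq, str(z), ion, "1", run,
                                    _fmt_area(area)))

    export_path = outdir / "export.tsv"
    metadata_path = outdir / "metadata.tsv"
    truth_path = outdir / "ground_truth.json"
    _write_tsv(export_path, EXPORT_HEADER, export_rows)
    _write_tsv(metadata_path, METADATA_HEADER, meta_rows)

    truth = {
        "design": "repeatability",
        "peptides": [{"sequence": s, "precursor_charge": z, "fragment_ions": f}
                     for s, z, f in peptides],
        "true_slopes": slopes.tolist(),
        "qc_concentrations": dict(config.qc_concentrations),
        "within_day_cv": config.proportional_cv,
        "between_day_cv": config.between_day_cv,
        "n_days": config.n_days,
        "n_replicates": config.n_replicates,
        "interference": asdict(config.interference)
        if config.interference else None,
        "seed": config.seed,
    }
    truth_path.write_text(json.dumps(truth, indent=2) + "\n", encoding="utf-8")
    return SimulatedExperiment(export_path, metadata_path, None,
                               truth_path, truth)
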