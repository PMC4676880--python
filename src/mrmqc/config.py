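"""Runtime configuration.

A flat key=value text file (mirroring the classic ``*.config`` style of
desktop assay tools) can seed an :class:`EngineConfig`; command-line flags
override file values.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path

MODES = ("response_curve", "repeatability", "both")
RATIO_MODES = ("pairwise", "sum", "max_transition")
WEIGHTINGS = ("none", "inv_x", "inv_x2")


@dataclass
class EngineConfig:
    """Thresholds and options of the characterization engine.

    lod_multiplier
        k in the "mean blank + k·sd" detection-limit rule (default 3,
        the classical 3-sigma convention).
    lloq_cv_threshold
        maximum replicate CV (%) for a calibration point to quantify
        (default 20).
    accuracy_tolerance
        maximum back-calculated accuracy error (%) of a point's mean for the
        linear-range search (default 20).
    specificity_threshold
        maximum transition-ratio deviation (%) from its mean before a
        transition is called non-specific (default 30).
    ratio_mode
        how transition ratios are formed: "pairwise" (each transition against
        each other transition of the peptide), "sum" (fraction of the summed
        signal) or "max_transition" (against the most intense transition).
    weighting
        calibration-regression weighting: "none" (OLS), "inv_x" (1/x) or
        "inv_x2" (1/x²).
    """

    mode: str = "both"
    lod_multiplier: float = 3.0
    lloq_cv_threshold: float = 20.0
    accuracy_tolerance: float = 20.0
    specificity_threshold: float = 30.0
    ratio_mode: str = "pairwise"
    weighting: str = "none"
    visualize: bool = False
    output_dir: str = "."
    column_map: dict | None = None

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.ratio_mode not in RATIO_MODES:
            raise ValueError(f"ratio_mode must be one of {RATIO_MODES}")
        if self.weighting not in WEIGHTINGS:
            raise ValueError(f"weighting must be one of {WEIGHTINGS}")
        for name in ("lod_multiplier", "lloq_cv_threshold",
                     "accuracy_tolerance", "specificity_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


def load_config(path: str | Path, **overrides) -> EngineConfig:
    """Read a flat key=value config file; keyword overrides win on conflict."""
    values: dict[str, object] = {}
    known = {f.name: f.type for f in fields(EngineConfig)}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"{path} line {lineno}: expected key=value")
        key, _, raw = line.partition("=")
        key, raw = key.strip(), raw.strip()
        if key not in known:
            raise ValueError(f"{path} line {lineno}: unknown key {key!r}")
        if key == "visualize":
            values[key] = raw.lower() in ("true", "1", "yes")
        elif key in ("mode", "ratio_mode", "weighting", "output_dir"):
            values[key] = raw
        else:
            values[key] = float(raw)
    values.update({k: v for k, v in overrides.items() if v is not None})
    return EngineConfig(**values)
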