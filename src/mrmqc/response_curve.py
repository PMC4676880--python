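"""Response-curve characterization.

From a multipoint serial-dilution experiment this module estimates, per
transition (and per summed-transition series):

* the calibration regression — peak area on theoretical concentration,
  ordinary (optionally 1/x- or 1/x²-weighted) least squares over individual
  replicate observations inside the linear range;
* the linear range / upper limit of quantification — the widest contiguous
  calibration-point window whose fit back-calculates every point's mean to
  within the accuracy tolerance and whose replicate CVs stay under the CV
  threshold;
* the lower limit of quantification — the lowest calibration point from which
  compliance (all replicates detectable, CV under threshold) holds unbroken
  up to the ULOQ;
* the limit of detection — mean + k·sd of the blank signal mapped through the
  calibration curve; when fewer than two blank runs show detectable signal
  (the common situation on modern instruments: pre-curve blanks report
  nothing) the spiked-in fallback k·sd(lowest detectable point)/slope is used
  and flagged;
* carry-over — the mean signal of blanks acquired after the highest
  calibration point, as a percentage of the high-point mean, flagged when it
  exceeds 20 % of the LLOQ-point signal.

An area counts as "detectable" iff it is present and strictly positive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm

from .config import EngineConfig
from .io import DilutionRow
from .model import MeasurementSet, ResponseCurveGroups, TransitionKey, group_by_design

logger = logging.getLogger(__name__)


def detectable(areas: Sequence[float | None]) -> list[float]:
    """Non-missing, strictly positive areas."""
    return [a for a in areas if a is not None and a > 0]


def replicate_cv(areas: Sequence[float]) -> float:
    """Percent coefficient of variation (sample sd / mean)."""
    arr = np.asarray(areas, dtype=float)
    m = arr.mean()
    if m <= 0:
        return float("inf")
    return float(100.0 * arr.std(ddof=1) / m)


# ---------------------------------------------------------------------------
# calibration regression
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CurveFit:
    slope: float
    intercept: float
    rsquared: float
    slope_stderr_pct: float
    n_obs: int

    def inverse(self, signal: float) -> float:
        """Back-calculate the concentration that yields *signal*."""
        return (signal - self.intercept) / self.slope


def fit_curve(observations: Sequence[tuple[float, float]],
              weighting: str = "none") -> CurveFit | None:
    """Least-squares fit of area on concentration, replicates individually.

    ``weighting`` "inv_x"/"inv_x2" applies 1/x resp. 1/x² weights (a common
    bioanalytical choice when variance grows with concentration); "none" is
    plain OLS. Returns None when fewer than three distinct concentrations are
    available; raises ValueError on zero concentration variance.
    """
    xs = np.array([c for c, _ in observations], dtype=float)
    ys = np.array([a for _, a in observations], dtype=float)
    if len(set(xs.tolist())) < 3:
        return None
    if np.ptp(xs) == 0:
        raise ValueError("zero variance in concentrations")
    if weighting == "none":
        w = np.ones_like(xs)
    elif weighting == "inv_x":
        w = 1.0 / xs
    elif weighting == "inv_x2":
        w = 1.0 / xs ** 2
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    res = sm.WLS(ys, sm.add_constant(xs), weights=w).fit()
    intercept, slope = res.params
    se = res.bse[1]
    return CurveFit(
        slope=float(slope),
        intercept=float(intercept),
        rsquared=float(min(max(res.rsquared, 0.0), 1.0)),
        slope_stderr_pct=float(100.0 * se / abs(slope)) if slope != 0 else float("inf"),
        n_obs=len(xs),
    )


# ---------------------------------------------------------------------------
# limits
# ---------------------------------------------------------------------------

def estimate_lod(blank_areas: Sequence[float | None],
                 lowest_point_areas: Sequence[float | None],
                 curve: CurveFit | None,
                 multiplier: float = 3.0,
                 ) -> tuple[float | None, bool | None]:
    """Limit of detection, in concentration units: (LOD.value, LOD.usedSpiked).

    With >=2 detectable blank runs: signal = mean(blank) + k·sd(blank), mapped
    through the calibration curve (usedSpiked False). Otherwise the spiked-in
    fallback k·sd(lowest point areas)/slope is used (usedSpiked True).
    Returns (None, None) when neither route is estimable or the curve has a
    non-positive slope.
    """
    if curve is None or curve.slope <= 0:
        if curve is not None:
            logger.warning("non-positive calibration slope; LOD not estimable")
        return None, None
    blanks = detectable(blank_areas)
    if len(blanks) >= 2:
        signal = float(np.mean(blanks) + multiplier * np.std(blanks, ddof=1))
        return max(0.0, curve.inverse(signal)), False
    spiked = [a for a in lowest_point_areas if a is not None]
    if len(spiked) >= 2:
        sd = float(np.std(spiked, ddof=1))
        return multiplier * sd / curve.slope, True
    return None, None


def _point_complies(areas: Sequence[float | None], cv_threshold: float) -> bool:
    """All replicates detectable and replicate CV under threshold."""
    if not areas or any(a is None or a <= 0 for a in areas):
        return False
    if len(areas) < 2:
        return True
    return replicate_cv(list(areas)) <= cv_threshold


def estimate_lloq(groups: dict[int, list[float | None]],
                  cv_threshold: float = 20.0,
                  uloq_point: int | None = None) -> int | None:
    """Lowest calibration point quantifying reliably.

    The LLOQ point is the lowest point such that it, and every higher point up
    to the ULOQ, has all replicates detectable with replicate CV under the
    threshold. None when no point qualifies.
    """
    points = sorted(groups)
    if uloq_point is not None:
        points = [p for p in points if p <= uloq_point]
    lloq = None
    for p in reversed(points):
        if _point_complies(groups[p], cv_threshold):
            lloq = p
        else:
            break
    return lloq


def find_linear_range(groups: dict[int, list[float | None]],
                      dilution: Sequence[DilutionRow],
                      cv_threshold: float = 20.0,
                      accuracy_tolerance: float = 20.0,
                      weighting: str = "none",
                      ) -> tuple[tuple[int, int] | None, CurveFit | None]:
    """Widest contiguous calibration-point window with a linear fit.

    A window passes when every point in it has >=2 detectable replicates with
    CV under ``cv_threshold`` and the window's own least-squares fit
    back-calculates each point's mean area to within ``accuracy_tolerance`` %
    of the nominal concentration. Ties between equally wide windows prefer
    the higher top point, then the lower bottom point. Returns
    ((low_point, high_point), fit) or (None, fallback_fit) when no window of
    >=3 points passes; the fallback fit pools every point with a detectable
    replicate, so downstream estimates still have a curve when possible.
    """
    conc = {d.calibration_point: d.theoretical_concentration for d in dilution}
    points = sorted(p for p in groups if p in conc)

    def observations(window: Sequence[int]) -> list[tuple[float, float]]:
        return [(conc[p], a) for p in window for a in detectable(groups[p])]

    windows = []
    n = len(points)
    for width in range(n, 2, -1):
        for lo_idx in range(n - width, -1, -1):  # higher windows first
            windows.append(points[lo_idx:lo_idx + width])
    # sort: widest first, then higher top point, then lower bottom point
    windows.sort(key=lambda w: (-len(w), -w[-1], w[0]))

    for window in windows:
        ok = True
        for p in window:
            reps = detectable(groups[p])
            if len(reps) < 2 or replicate_cv(reps) > cv_threshold:
                ok = False
                break
        if not ok:
            continue
        fit = fit_curve(observations(window), weighting)
        if fit is None or fit.slope <= 0:
            continue
        for p in window:
            back = fit.inverse(float(np.mean(detectable(groups[p]))))
            nominal = conc[p]
            if nominal <= 0 or abs(back - nominal) / nominal * 100 > accuracy_tolerance:
                ok = False
                break
        if ok:
            return (window[0], window[-1]), fit
    fallback = fit_curve(observations([p for p in points if detectable(groups[p])]),
                         weighting)
    return None, fallback


def assess_carryover(blank_after_high: Sequence[float | None],
                     high_point_areas: Sequence[float | None],
                     lloq_area: float | None,
                     ) -> tuple[float | None, bool | None]:
    """Carry-over: post-high blank signal as % of the high-point mean.

    Missing blank areas count as zero signal (nothing detected). The flag
    marks blank signal above 20 % of the LLOQ-point signal; it is None when
    the LLOQ signal is unknown. Returns (None, None) without post-high blanks.
    """
    if not blank_after_high:
        return None, None
    high = [a for a in high_point_areas if a is not None]
    if not high or np.mean(high) <= 0:
        return None, None
    blank_mean = float(np.mean([a if a is not None else 0.0
                                for a in blank_after_high]))
    percent = 100.0 * blank_mean / float(np.mean(high))
    flag = (blank_mean > 0.2 * lloq_area) if lloq_area is not None else None
    return percent, flag


# ---------------------------------------------------------------------------
# report row + per-transition pipeline
# ---------------------------------------------------------------------------

@dataclass
class ResponseCurveResult:
    """One row of the response-curve report."""

    key: TransitionKey
    lod_value: float | None = None
    lod_used_spiked: bool | None = None
    lloq_cali_point: int | None = None
    uloq_cali_point: int | None = None
    curve_slope: float | None = None
    curve_intercept: float | None = None
    curve_rsquared: float | None = None
    curve_slope_stderr_pct: float | None = None
    carryover_percent: float | None = None
    carryover_flag: bool | None = None

    @staticmethod
    def columns() -> list[str]:
        return ["Peptide", "Transition", "LOD.value", "LOD.usedSpiked",
                "LLOQ.CaliPoint", "ULOQ.CaliPoint", "Curve.Slope",
                "Curve.Intercept", "Curve.Rsquared", "Curve.SlopeStdErr(%)",
                "Carryover.percent", "Carryover.flag"]

    def to_record(self) -> dict[str, object]:
        return {
            "Peptide": self.key.peptide_sequence,
            "Transition": self.key.label,
            "LOD.value": self.lod_value,
            "LOD.usedSpiked": self.lod_used_spiked,
            "LLOQ.CaliPoint": self.lloq_cali_point,
            "ULOQ.CaliPoint": self.uloq_cali_point,
            "Curve.Slope": self.curve_slope,
            "Curve.Intercept": self.curve_intercept,
            "Curve.Rsquared": self.curve_rsquared,
            "Curve.SlopeStdErr(%)": self.curve_slope_stderr_pct,
            "Carryover.percent": self.carryover_percent,
            "Carryover.flag": self.carryover_flag,
        }


def characterize_response_curve(mset: MeasurementSet,
                                dilution: Sequence[DilutionRow],
                                config: EngineConfig | None = None,
                                ) -> ResponseCurveResult:
    """Full response-curve characterization of one transition."""
    config = config or EngineConfig()
    groups: ResponseCurveGroups = group_by_design(mset, "response_curve")

    window, fit = find_linear_range(
        groups.calibration, dilution,
        cv_threshold=config.lloq_cv_threshold,
        accuracy_tolerance=config.accuracy_tolerance,
        weighting=config.weighting)
    uloq = window[1] if window else None
    lloq = estimate_lloq(groups.calibration,
                         cv_threshold=config.lloq_cv_threshold,
                         uloq_point=uloq)

    # spiked fallback uses the lowest point with >=2 detectable replicates
    lowest_areas: list[float | None] = []
    for p in sorted(groups.calibration):
        if len(detectable(groups.calibration[p])) >= 2:
            lowest_areas = groups.calibration[p]
            break
    lod_value, used_spiked = estimate_lod(
        groups.blanks_pre, lowest_areas, fit, config.lod_multiplier)

    lloq_area = (float(np.mean(detectable(groups.calibration[lloq])))
                 if lloq is not None else None)
    top = max(groups.calibration) if groups.calibration else None
    carry, carry_flag = assess_carryover(
        groups.blanks_post_high,
        groups.calibration.get(top, []) if top is not None else [],
        lloq_area)

    return ResponseCurveResult(
        key=mset.key,
        lod_value=lod_value,
        lod_used_spiked=used_spiked,
        lloq_cali_point=lloq,
        uloq_cali_point=uloq,
        curve_slope=fit.slope if fit else None,
        curve_intercept=fit.intercept if fit else None,
        curve_rsquared=fit.rsquared if fit else None,
        curve_slope_stderr_pct=fit.slope_stderr_pct if fit else None,
        carryover_percent=carry,
        carryover_flag=carry_flag,
    )
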