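"""Assay-performance figures.

Per peptide: a response-curve figure (one panel per monitored transition plus
one for the summed series, points and fitted line on log-log axes) and a
repeatability figure (per-day medians of replicate measurements at the low,
medium and high levels, for the summed series). Globally: an eight-panel
overview across all assayed transitions — distributions of LOD, LLOQ point,
R², slope standard error, the three per-level CV summaries, and the maximum
specificity deviation.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402

from .io import DilutionRow  # noqa: E402
from .model import MeasurementSet, group_by_design  # noqa: E402
from .repeatability import LEVEL_ORDER, RepeatabilityResult  # noqa: E402
from .response_curve import ResponseCurveResult, detectable  # noqa: E402


def response_curve_figure(transition_sets: Sequence[MeasurementSet],
                          summed_set: MeasurementSet,
                          dilution: Sequence[DilutionRow],
                          results: Sequence[ResponseCurveResult],
                          path: str | Path) -> Path:
    """One panel per transition + one for the summed series."""
    conc = {d.calibration_point: d.theoretical_concentration for d in dilution}
    sets = list(transition_sets) + [summed_set]
    by_key = {r.key: r for r in results}
    n = len(sets)
    ncols = min(n, 2)
    nrows = -(-n // ncols)
    fig, axes = plt.subplots(nrows, ncols, figsize=(4.5 * ncols, 3.5 * nrows),
                             squeeze=False)
    peptide = summed_set.key.peptide_sequence
    for ax, mset in zip(axes.flat, sets):
        groups = group_by_design(mset, "response_curve")
        xs, ys = [], []
        for p, areas in groups.calibration.items():
            for a in detectable(areas):
                xs.append(conc[p])
                ys.append(a)
        ax.plot(xs, ys, "o", ms=4, alpha=0.7)
        res = by_key.get(mset.key)
        if res and res.curve_slope is not None and xs:
            grid = np.linspace(min(xs), max(xs), 50)
            ax.plot(grid, res.curve_slope * grid + res.curve_intercept, "-",
                    lw=1)
            ax.set_title(f"{mset.key.label}  R²="
                         f"{res.curve_rsquared:.4f}", fontsize=9)
        else:
            ax.set_title(mset.key.label, fontsize=9)
        if xs and min(xs) > 0:
            ax.set_xscale("log")
            ax.set_yscale("log")
        ax.set_xlabel("concentration")
        ax.set_ylabel("peak area")
    for ax in axes.flat[n:]:
        ax.set_visible(False)
    fig.suptitle(f"Response curve — {peptide}", fontsize=11)
    fig.tight_layout(rect=(0, 0, 1, 0.96))
    path = Path(path)
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return path


def repeatability_figure(summed_set: MeasurementSet,
                         path: str | Path) -> Path:
    """Per-day medians of replicate measurements, one panel per level."""
    groups = group_by_design(summed_set, "repeatability")
    fig, axes = plt.subplots(1, 3, figsize=(11, 3.2))
    for ax, level in zip(axes, LEVEL_ORDER):
        days = sorted(d for (lvl, d) in groups if lvl == level)
        medians = [np.median([a for a in groups[(level, d)] if a is not None])
                   for d in days]
        ax.plot(days, medians, "o-", ms=5)
        ax.set_title(f"{level}", fontsize=10)
        ax.set_xlabel("day")
        ax.set_ylabel("median peak area")
        ax.set_xticks(days)
    fig.suptitle(f"Repeatability — {summed_set.key.peptide_sequence} (summed)",
                 fontsize=11)
    fig.tight_layout(rect=(0, 0, 1, 0.94))
    path = Path(path)
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return path


def _hist(ax, values, title, xlabel):
    values = [v for v in values if v is not None]
    if values:
        ax.hist(values, bins=min(20, max(5, len(values) // 3)),
                color="#4878a8", edgecolor="white")
    ax.set_title(title, fontsize=9)
    ax.set_xlabel(xlabel, fontsize=8)


def global_overview(rc_results: Sequence[ResponseCurveResult],
                    rep_results: Sequence[RepeatabilityResult],
                    path: str | Path) -> Path:
    """Eight-panel summary of assay performance across all transitions."""
    fig, axes = plt.subplots(2, 4, figsize=(16, 7))
    ax = axes.flat
    _hist(ax[0], [np.log10(r.lod_value) for r in rc_results
                  if r.lod_value], "LOD distribution", "log10 LOD")
    _hist(ax[1], [r.lloq_cali_point for r in rc_results],
          "LLOQ calibration point", "point")
    _hist(ax[2], [r.curve_rsquared for r in rc_results], "Curve R²", "R²")
    _hist(ax[3], [r.curve_slope_stderr_pct for r in rc_results],
          "Slope std. error", "% of slope")
    for i, stat in enumerate(("intra_cv", "inter_cv", "total_cv")):
        data, labels = [], []
        for level in LEVEL_ORDER:
            vals = [getattr(r.per_level.get(level), stat)
                    for r in rep_results if r.per_level.get(level)]
            if vals:
                data.append(vals)
                labels.append(level)
        if data:
            ax[4 + i].boxplot(data, tick_labels=labels)
        ax[4 + i].set_title(stat.replace("_", " ") + " (%)", fontsize=9)
    _hist(ax[7], [r.pvspec.max_deviation for r in rep_results
                  if r.pvspec.max_deviation is not None],
          "Specificity max deviation", "% deviation")
    fig.suptitle("Assay performance overview", fontsize=12)
    fig.tight_layout(rect=(0, 0, 1, 0.95))
    path = Path(path)
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return path
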