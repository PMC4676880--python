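"""Mini-validation of repeatability.

A repeatability experiment measures each transition at three concentration
levels (low / medium / high), in replicate, on several days. This module
computes, per transition and per summed-transition series:

* the intra-assay, inter-assay and total coefficients of variation at each
  level, from a one-way random-effects (day) variance decomposition;
* the validated lower limit of quantification — the lowest level whose total
  CV stays under the validation threshold with every replicate detectable on
  every day — together with ``totalCV.Me``, a median-based total CV at that
  level (CV of the per-day medians of the replicate measurements);
* partial validation of specificity — whether each transition's ratios of
  peak areas against the peptide's other transitions stay within the
  deviation threshold of their across-sample mean, over all samples above the
  validated LLOQ.

The variance decomposition is the standard method-of-moments one-way ANOVA:
with day mean squares MS_between and pooled within-day MS_within,
sigma²_within = MS_within and sigma²_between = max(0, (MS_between −
MS_within)/n0), n0 = (N − Σn_d²/N)/(D−1) for unbalanced day sizes. CVs are
the component standard deviations as a percentage of the grand mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .config import EngineConfig
from .model import MeasurementSet, TransitionKey, group_by_design

logger = logging.getLogger(__name__)

LEVEL_ORDER = ("low", "medium", "high")


# ---------------------------------------------------------------------------
# variance components
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CVComponents:
    intra_cv: float
    inter_cv: float
    total_cv: float
    grand_mean: float
    n_days: int
    n_obs: int


def cv_components(day_groups: Mapping[int, Sequence[float | None]]
                  ) -> CVComponents | None:
    """Intra-/inter-/total CV from replicate areas grouped by day.

    Days keeping fewer than two detectable replicates are dropped (logged);
    returns None with fewer than two usable days or a non-positive grand
    mean. A negative between-day moment estimate is clamped to zero.
    """
    days: dict[int, np.ndarray] = {}
    for day, areas in day_groups.items():
        vals = np.array([a for a in areas if a is not None and a > 0],
                        dtype=float)
        if len(vals) >= 2:
            days[day] = vals
        else:
            logger.warning("day %s dropped from CV decomposition "
                           "(<2 detectable replicates)", day)
    if len(days) < 2:
        return None

    all_vals = np.concatenate(list(days.values()))
    n_total = len(all_vals)
    n_days = len(days)
    grand_mean = float(all_vals.mean())
    if grand_mean <= 0:
        return None

    ss_within = sum(float(((v - v.mean()) ** 2).sum()) for v in days.values())
    ms_within = ss_within / (n_total - n_days)
    ss_between = sum(len(v) * (float(v.mean()) - grand_mean) ** 2
                     for v in days.values())
    ms_between = ss_between / (n_days - 1)
    n0 = (n_total - sum(len(v) ** 2 for v in days.values()) / n_total) \
        / (n_days - 1)
    var_within = ms_within
    var_between = max(0.0, (ms_between - ms_within) / n0)

    return CVComponents(
        intra_cv=100.0 * var_within ** 0.5 / grand_mean,
        inter_cv=100.0 * var_between ** 0.5 / grand_mean,
        total_cv=100.0 * (var_within + var_between) ** 0.5 / grand_mean,
        grand_mean=grand_mean,
        n_days=n_days,
        n_obs=n_total,
    )


# ---------------------------------------------------------------------------
# validated LLOQ
# ---------------------------------------------------------------------------

def validated_lloq(per_level: Mapping[str, CVComponents | None],
                   day_groups_by_level: Mapping[str, Mapping[int, Sequence[float | None]]],
                   cv_threshold: float = 20.0,
                   ) -> tuple[str | None, float | None]:
    """(ValidatedLLOQ.concLevel, totalCV.Me).

    The validated level is the lowest (low < medium < high) whose total CV is
    under the threshold with all replicates detectable on all days.
    totalCV.Me is the CV of the per-day medians at that level.
    """
    for level in LEVEL_ORDER:
        comp = per_level.get(level)
        if comp is None or comp.total_cv > cv_threshold:
            continue
        groups = day_groups_by_level.get(level, {})
        if not groups:
            continue
        if any(a is None or a <= 0 for areas in groups.values() for a in areas):
            continue
        medians = np.array([np.median(np.asarray(areas, dtype=float))
                            for areas in groups.values()])
        me = float(100.0 * medians.std(ddof=1) / medians.mean()) \
            if len(medians) >= 2 and medians.mean() > 0 else None
        return level, me
    return None, None


# ---------------------------------------------------------------------------
# partial validation of specificity
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PVSpec:
    max_deviation: float | None = None
    mean_at_max_dev: float | None = None
    day_at_max_dev: int | None = None
    conc_level_at_max_dev: str | None = None
    specific: bool | None = None


def transition_ratios(areas_by_transition: Mapping[TransitionKey, float],
                      mode: str = "sum",
                      reference: TransitionKey | None = None,
                      ) -> dict[TransitionKey, float]:
    """Single-sample transition ratios under the "sum" / "max_transition" modes.

    "sum" ratios are fractions of the summed signal (they sum to 1);
    "max_transition" divides by the reference transition's area.
    """
    if mode == "sum":
        total = sum(areas_by_transition.values())
        if total <= 0:
            raise ValueError("non-positive total area")
        return {k: a / total for k, a in areas_by_transition.items()}
    if mode == "max_transition":
        if reference is None:
            reference = max(areas_by_transition, key=areas_by_transition.get)
        ref = areas_by_transition[reference]
        if ref <= 0:
            raise ValueError("non-positive reference area")
        return {k: a / ref for k, a in areas_by_transition.items()}
    raise ValueError(f"unknown ratio mode {mode!r}")


def specificity_deviation(transition_sets: Sequence[MeasurementSet],
                          qualifying_runs: Sequence[str],
                          ratio_mode: str = "pairwise",
                          threshold: float = 30.0,
                          ) -> dict[TransitionKey, PVSpec]:
    """Per-transition maximum ratio deviation over the qualifying samples.

    For every qualifying run in which all transitions are detectable, ratio
    series are formed per the chosen mode — "pairwise" builds one series per
    ordered transition pair (area_t / area_t'), the others one series per
    transition. Each series is compared against its across-sample mean; a
    transition's PVSpec.maxDeviation is the largest percent deviation over
    its series and samples, and it is specific iff that maximum stays at or
    under the threshold.
    """
    if len(transition_sets) < 2:
        raise ValueError("specificity needs >=2 transitions of one peptide")
    keys = [s.key for s in transition_sets]
    usable: list[str] = []
    for run in qualifying_runs:
        areas = [s.measurements[run].area for s in transition_sets]
        if all(a is not None and a > 0 for a in areas):
            usable.append(run)
        else:
            logger.warning("specificity: run %r skipped (missing transition "
                           "area)", run)
    if not usable:
        return {k: PVSpec() for k in keys}

    area = {(s.key, run): s.measurements[run].area
            for s in transition_sets for run in usable}

    # series id → (owner transition, run → ratio)
    series: dict[object, tuple[TransitionKey, dict[str, float]]] = {}
    if ratio_mode == "pairwise":
        for t in keys:
            for t2 in keys:
                if t2 == t:
                    continue
                series[(t, t2)] = (t, {r: area[t, r] / area[t2, r]
                                       for r in usable})
    else:
        reference = None
        if ratio_mode == "max_transition":
            means = {t: np.mean([area[t, r] for r in usable]) for t in keys}
            reference = max(means, key=means.get)
        for r in usable:
            ratios = transition_ratios({t: area[t, r] for t in keys},
                                       mode=ratio_mode, reference=reference)
            for t, v in ratios.items():
                series.setdefault(t, (t, {}))[1][r] = v

    best: dict[TransitionKey, tuple[float, float, str]] = {}
    annotations = {r: transition_sets[0].measurements[r].annotation
                   for r in usable}
    for _, (owner, by_run) in series.items():
        vals = np.array([by_run[r] for r in usable])
        mean = float(vals.mean())
        if mean <= 0:
            logger.warning("specificity: zero mean ratio for %s", owner.label)
            continue
        devs = 100.0 * np.abs(vals - mean) / mean
        i = int(np.argmax(devs))
        cand = (float(devs[i]), mean, usable[i])
        if owner not in best or cand[0] > best[owner][0]:
            best[owner] = cand

    out: dict[TransitionKey, PVSpec] = {}
    for t in keys:
        if t not in best:
            out[t] = PVSpec()
            continue
        max_dev, mean, run = best[t]
        ann = annotations[run]
        out[t] = PVSpec(
            max_deviation=max_dev,
            mean_at_max_dev=mean,
            day_at_max_dev=ann.day,
            conc_level_at_max_dev=ann.concentration_level,
            specific=max_dev <= threshold,
        )
    return out


# ---------------------------------------------------------------------------
# report row + per-peptide pipeline
# ---------------------------------------------------------------------------

@dataclass
class RepeatabilityResult:
    """One row of the repeatability report."""

    key: TransitionKey
    per_level: dict[str, CVComponents | None] = field(default_factory=dict)
    validated_level: str | None = None
    total_cv_me: float | None = None
    pvspec: PVSpec = field(default_factory=PVSpec)

    @staticmethod
    def columns() -> list[str]:
        cols = ["Peptide", "Transition"]
        for level in LEVEL_ORDER:
            cols += [f"intraCV.{level}", f"interCV.{level}", f"totalCV.{level}"]
        cols += ["ValidatedLLOQ.concLevel", "totalCV.Me",
                 "PVSpec.maxDeviation", "PVSpec.meanAtMaxDev",
                 "PVSpec.dayAtMaxDev", "PVSpec.concLevelAtMaxDev",
                 "PVSpec.specific"]
        return cols

    def to_record(self) -> dict[str, object]:
        rec: dict[str, object] = {
            "Peptide": self.key.peptide_sequence,
            "Transition": self.key.label,
        }
        for level in LEVEL_ORDER:
            comp = self.per_level.get(level)
            rec[f"intraCV.{level}"] = comp.intra_cv if comp else None
            rec[f"interCV.{level}"] = comp.inter_cv if comp else None
            rec[f"totalCV.{level}"] = comp.total_cv if comp else None
        rec["ValidatedLLOQ.concLevel"] = self.validated_level
        rec["totalCV.Me"] = self.total_cv_me
        rec["PVSpec.maxDeviation"] = self.pvspec.max_deviation
        rec["PVSpec.meanAtMaxDev"] = self.pvspec.mean_at_max_dev
        rec["PVSpec.dayAtMaxDev"] = self.pvspec.day_at_max_dev
        rec["PVSpec.concLevelAtMaxDev"] = self.pvspec.conc_level_at_max_dev
        rec["PVSpec.specific"] = self.pvspec.specific
        return rec


def _by_level(mset: MeasurementSet) -> dict[str, dict[int, list[float | None]]]:
    """(level, day) grouping reshaped to level → day → areas."""
    groups = group_by_design(mset, "repeatability")
    out: dict[str, dict[int, list[float | None]]] = {}
    for (level, day), areas in groups.items():
        out.setdefault(level, {})[day] = areas
    return out


def _characterize_one(mset: MeasurementSet, cv_threshold: float
                      ) -> RepeatabilityResult:
    by_level = _by_level(mset)
    per_level = {level: cv_components(days)
                 for level, days in by_level.items()}
    level, me = validated_lloq(per_level, by_level, cv_threshold)
    return RepeatabilityResult(key=mset.key, per_level=per_level,
                               validated_level=level, total_cv_me=me)


def characterize_repeatability(transition_sets: Sequence[MeasurementSet],
                               summed_set: MeasurementSet,
                               config: EngineConfig | None = None,
                               ) -> list[RepeatabilityResult]:
    """Repeatability report rows for one peptide: transitions then the sum.

    The specificity sample filter keeps qc runs at or above the summed
    series' validated LLOQ level; without a validated level every sample
    qualifies (logged). Summed rows carry no PVSpec values — transition
    ratios are meaningless for a sum.
    """
    config = config or EngineConfig()
    results = [_characterize_one(s, config.lloq_cv_threshold)
               for s in transition_sets]
    summed_result = _characterize_one(summed_set, config.lloq_cv_threshold)

    if len(transition_sets) >= 2:
        floor = summed_result.validated_level
        if floor is None:
            logger.warning(
                "%s: no validated LLOQ for the summed series; all samples "
                "qualify for the specificity check",
                summed_set.key.peptide_sequence)
            min_rank = 0
        else:
            min_rank = LEVEL_ORDER.index(floor)
        qualifying = [
            run for run, m in summed_set.measurements.items()
            if m.annotation.sample_type == "qc"
            and LEVEL_ORDER.index(m.annotation.concentration_level) >= min_rank
        ]
        pvspec = specificity_deviation(
            transition_sets, qualifying,
            ratio_mode=config.ratio_mode,
            threshold=config.specificity_threshold)
        for res in results:
            res.pvspec = pvspec.get(res.key, PVSpec())

    return results + [summed_result]
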