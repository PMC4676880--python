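"""Variance-component CVs, validated LLOQ, and transition-ratio specificity."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mrmqc import (
    CVComponents,
    EngineConfig,
    Interference,
    MetadataRow,
    SimulationConfig,
    SkylineExportRow,
    assemble,
    characterize_repeatability,
    cv_components,
    group_by_peptide,
    parse_metadata,
    parse_skyline_export,
    simulate_repeatability,
    specificity_deviation,
    sum_transitions,
    transition_ratios,
    validated_lloq,
)
from mrmqc.model import TransitionKey


def anova_oracle(day_groups):
    """Explicit mean-square arithmetic, independent of the implementation."""
    days = [np.asarray(v, dtype=float) for v in day_groups.values()]
    all_vals = np.concatenate(days)
    n, d = len(all_vals), len(days)
    gm = all_vals.mean()
    msw = sum(((v - v.mean()) ** 2).sum() for v in days) / (n - d)
    msb = sum(len(v) * (v.mean() - gm) ** 2 for v in days) / (d - 1)
    n0 = (n - sum(len(v) ** 2 for v in days) / n) / (d - 1)
    vb = max(0.0, (msb - msw) / n0)
    return (100 * np.sqrt(msw) / gm, 100 * np.sqrt(vb) / gm,
            100 * np.sqrt(msw + vb) / gm)


class TestCvComponents:
    def test_hand_computed_two_day_instance(self):
        # MS_within=2, MS_between=16, sigma2_between=7, grand mean 13
        comp = cv_components({1: [10.0, 12.0], 2: [14.0, 16.0]})
        assert comp.intra_cv == pytest.approx(100 * np.sqrt(2) / 13, rel=1e-12)
        assert comp.inter_cv == pytest.approx(100 * np.sqrt(7) / 13, rel=1e-12)
        assert comp.total_cv == pytest.approx(300 / 13, rel=1e-12)
        assert comp.intra_cv == pytest.approx(10.8786, abs=1e-3)
        assert comp.inter_cv == pytest.approx(20.3519, abs=1e-3)
        assert comp.total_cv == pytest.approx(23.0769, abs=1e-3)

    def test_identical_values_give_zero_cvs(self):
        comp = cv_components({d: [50.0] * 3 for d in range(1, 6)})
        assert (comp.intra_cv, comp.inter_cv, comp.total_cv) == (0.0, 0.0, 0.0)

    def test_pure_between_day_structure(self):
        comp = cv_components({1: [10.0, 10.0], 2: [20.0, 20.0]})
        assert comp.intra_cv == 0.0
        assert comp.inter_cv > 0.0

    def test_negative_between_day_moment_clamps_to_zero(self):
        # day means identical, within-day spread large -> MSB < MSW
        comp = cv_components({1: [5.0, 15.0], 2: [5.0, 15.0]})
        assert comp.inter_cv == 0.0
        assert comp.total_cv == pytest.approx(comp.intra_cv)

    def test_day_with_single_replicate_is_dropped(self, caplog):
        with caplog.at_level("WARNING"):
            comp = cv_components({1: [10.0, 12.0], 2: [14.0, 16.0],
                                  3: [99.0]})
        assert comp.n_days == 2
        assert "dropped" in caplog.text

    def test_fewer_than_two_days_not_estimable(self):
        assert cv_components({1: [10.0, 12.0]}) is None

    def test_agrees_with_mean_square_oracle_on_unbalanced_designs(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            n_days = int(rng.integers(2, 7))
            groups = {d: list(rng.lognormal(np.log(100) + rng.normal(0, 0.1),
                                            0.05, size=rng.integers(2, 6)))
                      for d in range(n_days)}
            comp = cv_components(groups)
            intra, inter, total = anova_oracle(groups)
            assert comp.intra_cv == pytest.approx(intra, rel=1e-9)
            assert comp.inter_cv == pytest.approx(inter, rel=1e-9, abs=1e-9)
            assert comp.total_cv == pytest.approx(total, rel=1e-9)

    def test_total_cv_dominates_each_component(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            groups = {d: list(rng.lognormal(4, 0.2, size=3)) for d in range(4)}
            comp = cv_components(groups)
            tol = 1e-9
            assert comp.total_cv ** 2 + tol >= comp.intra_cv ** 2
            assert comp.total_cv ** 2 + tol >= comp.inter_cv ** 2


def _comp(total):
    return CVComponents(intra_cv=total / 2, inter_cv=total / 2,
                        total_cv=total, grand_mean=100.0, n_days=5, n_obs=15)


def _clean_groups(mean):
    return {d: [mean * 0.98, mean, mean * 1.02] for d in range(1, 6)}


class TestValidatedLloq:
    def test_lowest_level_under_threshold(self):
        per_level = {"low": _comp(35.0), "medium": _comp(12.0),
                     "high": _comp(8.0)}
        groups = {lvl: _clean_groups(100 * (i + 1))
                  for i, lvl in enumerate(("low", "medium", "high"))}
        level, me = validated_lloq(per_level, groups)
        assert level == "medium"
        assert me is not None

    def test_all_levels_pass_picks_low(self):
        per_level = {lvl: _comp(5.0) for lvl in ("low", "medium", "high")}
        groups = {lvl: _clean_groups(100.0) for lvl in per_level}
        assert validated_lloq(per_level, groups)[0] == "low"

    def test_no_level_passes(self):
        per_level = {lvl: _comp(40.0) for lvl in ("low", "medium", "high")}
        groups = {lvl: _clean_groups(100.0) for lvl in per_level}
        assert validated_lloq(per_level, groups) == (None, None)

    def test_undetectable_replicate_disqualifies_a_level(self):
        per_level = {"low": _comp(5.0), "medium": _comp(5.0),
                     "high": _comp(5.0)}
        groups = {lvl: _clean_groups(100.0) for lvl in per_level}
        groups["low"][3][1] = None
        assert validated_lloq(per_level, groups)[0] == "medium"

    def test_total_cv_me_is_cv_of_day_medians(self):
        per_level = {"low": _comp(5.0)}
        groups = {"low": {1: [9.0, 10.0, 11.0], 2: [19.0, 20.0, 21.0]}}
        _, me = validated_lloq(per_level, groups)
        medians = np.array([10.0, 20.0])
        assert me == pytest.approx(100 * medians.std(ddof=1) / medians.mean())


def _qc_sets(area_fn, n_transitions=3, n_days=5, n_reps=3):
    """Build transition sets over a full qc design; area_fn(t, level, day, rep)."""
    metadata, export = [], []
    for level in ("low", "medium", "high"):
        for day in range(1, n_days + 1):
            for rep in range(1, n_reps + 1):
                run = f"{level}{day}r{rep}"
                metadata.append(MetadataRow(run, "qc", day=day,
                                            replicate_index=rep,
                                            concentration_level=level))
                for t in range(n_transitions):
                    export.append(SkylineExportRow(
                        "PEPK", 2, f"y{4 + t}", 1, run,
                        area_fn(t, level, day, rep)))
    sets = assemble(export, metadata)
    runs = [m.replicate_name for m in metadata]
    return sets, runs


class TestSpecificity:
    def test_constant_ratios_are_specific(self):
        sets, runs = _qc_sets(lambda t, level, day, rep:
                              [100.0, 200.0, 400.0][t])
        pvspec = specificity_deviation(sets, runs)
        for spec in pvspec.values():
            assert spec.max_deviation == pytest.approx(0.0, abs=1e-9)
            assert spec.specific is True

    def test_inflated_sample_deviation_matches_closed_form(self):
        factor, m = 1.4, 45

        def area(t, level, day, rep):
            base = [100.0, 200.0, 400.0][t]
            if (t, level, day, rep) == (0, "high", 3, 2):
                return base * factor
            return base

        sets, runs = _qc_sets(area)
        pvspec = specificity_deviation(sets, runs)
        # pairwise ratio of the inflated transition against either partner is
        # f x base in one of m samples: deviation = 100*(f*m/(m-1+f) - 1)
        expected = 100 * (factor * m / (m - 1 + factor) - 1)
        inflated = pvspec[TransitionKey("PEPK", 2, "y4", 1)]
        assert inflated.max_deviation == pytest.approx(expected, abs=1e-9)
        assert inflated.specific is False
        assert inflated.day_at_max_dev == 3
        assert inflated.conc_level_at_max_dev == "high"
        # the partners see the reciprocal dip, below the 30 % threshold
        for ion in ("y5", "y6"):
            partner = pvspec[TransitionKey("PEPK", 2, ion, 1)]
            recip = 100 * (1 - m / ((m - 1 + 1 / factor) * factor))
            assert partner.max_deviation == pytest.approx(recip, abs=1e-9)
            assert partner.specific is True

    def test_samples_with_missing_transitions_are_skipped(self, caplog):
        def area(t, level, day, rep):
            if (t, level, day, rep) == (1, "low", 1, 1):
                return None
            return [100.0, 200.0, 400.0][t]

        sets, runs = _qc_sets(area)
        with caplog.at_level("WARNING"):
            pvspec = specificity_deviation(sets, runs)
        assert "skipped" in caplog.text
        assert all(s.max_deviation == pytest.approx(0.0, abs=1e-9)
                   for s in pvspec.values())

    @given(st.lists(st.floats(min_value=1.0, max_value=1e6), min_size=2,
                    max_size=6))
    def test_sum_mode_ratios_sum_to_one(self, areas):
        keys = [TransitionKey("PEPK", 2, f"y{i}", 1)
                for i in range(len(areas))]
        ratios = transition_ratios(dict(zip(keys, areas)), mode="sum")
        assert sum(ratios.values()) == pytest.approx(1.0, abs=1e-12)


class TestCharacterizeRepeatability:
    def _run(self, config, sim_config, tmp_path):
        sim = simulate_repeatability(sim_config, tmp_path / "rep")
        sets = assemble(parse_skyline_export(sim.export_path),
                        parse_metadata(sim.metadata_path))
        by_pep = group_by_peptide(sets)
        results = []
        for transition_sets in by_pep.values():
            results.extend(characterize_repeatability(
                transition_sets, sum_transitions(transition_sets), config))
        return results

    def test_summed_rows_carry_no_pvspec(self, tmp_path):
        results = self._run(
            EngineConfig(mode="repeatability"),
            SimulationConfig(seed=3, n_peptides=2), tmp_path)
        summed = [r for r in results if r.key.is_summed]
        assert len(summed) == 2
        for row in summed:
            assert row.pvspec.max_deviation is None
            assert row.pvspec.specific is None

    def test_zero_between_day_noise_gives_small_inter_cv(self, tmp_path):
        results = self._run(
            EngineConfig(mode="repeatability"),
            SimulationConfig(seed=4, n_peptides=3, between_day_cv=0.0,
                             proportional_cv=5.0), tmp_path)
        inter = [c.inter_cv for r in results
                 for c in r.per_level.values() if c is not None]
        # moment estimator clamps at 0; sampling noise keeps it small
        assert np.mean(inter) < 4.0

    def test_variance_component_recovery(self, tmp_path):
        """~500 simulated transitions at 5 % within- / 10 % between-day CV:
        the mean estimated components land near their targets."""
        results = self._run(
            EngineConfig(mode="repeatability"),
            SimulationConfig(seed=6, n_peptides=167,
                             n_transitions_per_peptide=3,
                             proportional_cv=5.0, between_day_cv=10.0),
            tmp_path)
        per_transition = [r for r in results if not r.key.is_summed]
        assert len(per_transition) == 501
        intra = [r.per_level["medium"].intra_cv for r in per_transition]
        inter = [r.per_level["medium"].inter_cv for r in per_transition]
        assert 4.0 <= np.mean(intra) <= 6.0
        assert 7.5 <= np.mean(inter) <= 12.5
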