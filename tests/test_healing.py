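import numpy as np
import pytest

from osteolattice.healing import (DEFAULT_STAGES, FrequencyBins,
                                  FrequencyReport, evaluate_criteria,
                                  frequency_analysis, reports_to_csv)
from osteolattice.optimizer import CriteriaConfig


class TestFrequencyAnalysis:
    def test_hand_counted_example(self):
        # {10, 60, 60, 400} against the eight stress intervals
        bins = FrequencyBins()
        pct = frequency_analysis([10.0, 60.0, 60.0, 400.0],
                                 bins.stress_edges)
        assert list(pct) == [25.0, 50.0, 0.0, 0.0, 0.0, 0.0, 0.0, 25.0]

    def test_all_in_one_bin(self):
        bins = FrequencyBins()
        pct = frequency_analysis(np.full(17, 120.0), bins.stress_edges)
        assert pct[2] == 100.0
        assert pct.sum() == pytest.approx(100.0, abs=1e-9)

    def test_half_open_boundaries(self):
        pct = frequency_analysis([50.0], FrequencyBins().stress_edges)
        assert pct[1] == 100.0  # 50 belongs to [50, 100), not <50

    def test_binomial_oracle(self):
        # 10,000 seeded uniforms on [0, 400]: per-bin count within 3 sigma
        rng = np.random.default_rng(12345)
        vals = rng.uniform(0.0, 400.0, 10_000)
        bins = FrequencyBins()
        pct = frequency_analysis(vals, bins.stress_edges)
        p = 50.0 / 400.0  # each interior bin spans 50 of 400
        sigma = np.sqrt(10_000 * p * (1 - p)) / 10_000 * 100.0
        for observed in pct:
            assert abs(observed - 100.0 * p) < 3.0 * sigma

    def test_percentages_sum_to_100(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            vals = rng.exponential(100.0, 500)
            for edges in (FrequencyBins().stress_edges,
                          FrequencyBins().strain_edges):
                pct = frequency_analysis(vals, edges)
                assert pct.sum() == pytest.approx(100.0, abs=1e-6)

    def test_empty_field_raises(self):
        with pytest.raises(ValueError):
            frequency_analysis([], FrequencyBins().stress_edges)

    def test_bad_edges_raise(self):
        with pytest.raises(ValueError):
            frequency_analysis([1.0], [10.0, 5.0])


def _report(stage, max_stress, adaptation=50.0):
    stress_p = np.zeros(8)
    stress_p[0] = 100.0
    strain_p = np.array([adaptation, 100.0 - adaptation, 0.0, 0.0])
    return FrequencyReport(stage, stress_p, strain_p, max_stress,
                           5000.0, adaptation)


class TestCriteria:
    def test_passes_below_yield(self):
        # stage maxima 697.35 / 398.36 / 293.40 all clear 897
        reports = [_report("G-T", 697.35), _report("IM-B", 398.36),
                   _report("M-B", 293.40)]
        status = evaluate_criteria(reports, CriteriaConfig())
        assert status.stress_pass
        assert status.worst_stage == "G-T"

    def test_fails_at_gt(self):
        reports = [_report("G-T", 1036.30), _report("IM-B", 739.22),
                   _report("M-B", 594.05)]
        status = evaluate_criteria(reports, CriteriaConfig())
        assert not status.stress_pass
        assert status.max_stress == pytest.approx(1036.30)

    def test_boundary_inclusive(self):
        reports = [_report("G-T", 897.0)]
        assert evaluate_criteria(reports, CriteriaConfig()).stress_pass

    def test_adaptation_equals_first_strain_bin(self):
        r = _report("G-T", 100.0, adaptation=35.79)
        assert r.adaptation_fraction == pytest.approx(
            r.strain_percentages[0])


class TestStages:
    def test_default_stage_materials(self):
        by_label = {s.label: s.graft_material for s in DEFAULT_STAGES}
        assert by_label["G-T"].E == 0.2
        assert by_label["G-T"].nu == 0.167
        assert by_label["IM-B"].E == 1000.0
        assert by_label["M-B"].E == 5000.0

    def test_default_bins_match_published_intervals(self):
        bins = FrequencyBins()
        assert list(bins.stress_edges) == [50, 100, 150, 200, 250, 300, 350]
        assert list(bins.strain_edges) == [3000, 6000, 10000]
        assert len(bins.stress_labels()) == 8
        assert len(bins.strain_labels()) == 4

    def test_csv_layout(self):
        text = reports_to_csv([_report("G-T", 123.0)])
        lines = text.strip().splitlines()
        assert lines[0] == "stage,field,bin,percent"
        assert len([l for l in lines if l.startswith("G-T,stress")]) == 8
        assert len([l for l in lines if l.startswith("G-T,strain")]) == 4


class TestSweepOnSmallModel:
    def test_identical_materials_identical_reports(self, small_problem):
        from osteolattice.healing import HealingStage, run_stage_sweep
        from osteolattice.materials import DEFAULT_MATERIALS
        design, load = small_problem
        stage = HealingStage("G-T", DEFAULT_MATERIALS["granulation"])
        stages = [stage,
                  HealingStage("IM-B", DEFAULT_MATERIALS["granulation"]),
                  HealingStage("M-B", DEFAULT_MATERIALS["granulation"])]
        reports = run_stage_sweep(design, stages, load)
        for r in reports[1:]:
            assert np.allclose(r.stress_percentages,
                               reports[0].stress_percentages)
            assert r.max_stress == pytest.approx(reports[0].max_stress)
            assert r.adaptation_fraction == pytest.approx(
                reports[0].adaptation_fraction)

    def test_stage_maxima_non_increasing(self, small_problem):
        from osteolattice.healing import run_stage_sweep
        design, load = small_problem
        reports = run_stage_sweep(design, DEFAULT_STAGES, load)
        ms = [r.max_stress for r in reports]
        mn = [r.max_strain for r in reports]
        assert ms[0] >= ms[1] >= ms[2]
        assert mn[0] >= mn[2]

    def test_adaptation_monotone_in_bite_force(self, small_problem):
        # linearity: doubling the bite force scales strains up, so the
        # fraction inside [0, 3000] ue cannot grow
        from osteolattice.healing import run_stage_sweep
        from osteolattice.model import build_load_case
        design, _ = small_problem
        fx = design.fixture
        fractions = []
        for bite in (400.0, 800.0, 1600.0):
            load = build_load_case(fx, bite_force=bite)
            reports = run_stage_sweep(design, DEFAULT_STAGES[2:], load)
            fractions.append(reports[0].adaptation_fraction)
        assert fractions[0] >= fractions[1] >= fractions[2]
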