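"""Healing-stage sweep and binned stress/strain frequency statistics.

The graft space is evaluated at three regeneration stages by swapping its
material: granulation tissue (G-T) early, immature bone (IM-B) mid, mature
bone (M-B) late.  For each stage the implant stress and graft strain fields
are binned into fixed intervals and reported as percentages together with
the field maxima, plus the fraction of graft nodes inside the bone
strain-adaptation window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import fe
from .materials import DEFAULT_MATERIALS, LoadCase, MaterialProperties
from .model import DesignModel


@dataclass(frozen=True)
class HealingStage:
    label: str                      # 'G-T' | 'IM-B' | 'M-B'
    graft_material: MaterialProperties


DEFAULT_STAGES: tuple[HealingStage, ...] = (
    HealingStage("G-T", DEFAULT_MATERIALS["granulation"]),
    HealingStage("IM-B", DEFAULT_MATERIALS["immature"]),
    HealingStage("M-B", DEFAULT_MATERIALS["mature"]),
)


@dataclass
class FrequencyBins:
    """Interior bin edges; first bin is open below, last open above."""

    stress_edges: tuple = (50.0, 100.0, 150.0, 200.0, 250.0, 300.0, 350.0)
    strain_edges: tuple = (3_000.0, 6_000.0, 10_000.0)

    def stress_labels(self) -> list[str]:
        return _bin_labels(self.stress_edges, "MPa")

    def strain_labels(self) -> list[str]:
        return _bin_labels(self.strain_edges, "ue", zero_floor=True)


def _bin_labels(edges, unit, zero_floor=False):
    first = (f"0-{edges[0]:g} {unit}" if zero_floor
             else f"<{edges[0]:g} {unit}")
    labels = [first]
    for a, b in zip(edges[:-1], edges[1:]):
        labels.append(f"{a:g}-{b:g} {unit}")
    labels.append(f">{edges[-1]:g} {unit}")
    return labels


@dataclass
class FrequencyReport:
    stage: str
    stress_percentages: np.ndarray
    strain_percentages: np.ndarray
    max_stress: float               # MPa, implant field
    max_strain: float               # ue, graft field
    adaptation_fraction: float      # % of graft nodes in [0, window]

    def validate(self):
        for p in (self.stress_percentages, self.strain_percentages):
            if abs(float(np.sum(p)) - 100.0) > 1e-6:
                raise AssertionError("bin percentages must sum to 100")


@dataclass
class CriteriaStatus:
    stress_pass: bool
    max_stress: float                       # worst over stages
    worst_stage: str
    per_stage_max_stress: dict[str, float]
    per_stage_adaptation: dict[str, float]  # %


def frequency_analysis(field_values: np.ndarray, edges) -> np.ndarray:
    """Percentage of values per bin; bins are [lo, hi) with open ends."""
    field_values = np.asarray(field_values, dtype=np.float64)
    if field_values.size == 0:
        raise ValueError("empty field passed to frequency analysis")
    edges = np.asarray(edges, dtype=np.float64)
    if np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    full = np.concatenate([[-np.inf], edges, [np.inf]])
    counts, _ = np.histogram(field_values, bins=full)
    return 100.0 * counts / field_values.size


def run_stage_sweep(design: DesignModel, stages, load: LoadCase,
                    bins: FrequencyBins | None = None
                    ) -> list[FrequencyReport]:
    """One independent solve per stage; only the graft material changes."""
    reports, _ = run_stage_sweep_detailed(design, stages, load, bins)
    return reports


def run_stage_sweep_detailed(design: DesignModel, stages, load: LoadCase,
                             bins: FrequencyBins | None = None):
    """Stage sweep that also returns the raw solved fields per stage."""
    stages = list(stages)
    if not stages:
        raise ValueError("at least one healing stage required")
    bins = bins or FrequencyBins()
    reports, results = [], []
    for stage in stages:
        try:
            fem, meta = design.assemble_stage(stage.graft_material, load)
            result = fe.solve(fem)
        except Exception as exc:
            raise RuntimeError(
                f"stage {stage.label}: solve failed ({exc})") from exc
        stress_field = design.implant_stress_field(result)
        strain_field = design.graft_strain_field(result, meta)
        strain_pct = frequency_analysis(strain_field, bins.strain_edges)
        report = FrequencyReport(
            stage=stage.label,
            stress_percentages=frequency_analysis(stress_field,
                                                  bins.stress_edges),
            strain_percentages=strain_pct,
            max_stress=float(stress_field.max()),
            max_strain=float(strain_field.max()),
            adaptation_fraction=float(strain_pct[0]),
        )
        report.validate()
        reports.append(report)
        results.append((result, meta))
    return reports, results


def evaluate_criteria(reports: list[FrequencyReport], criteria
                      ) -> CriteriaStatus:
    """Yield criterion across all stages; inclusive comparison (<= yield)."""
    per_stress = {r.stage: r.max_stress for r in reports}
    per_adapt = {r.stage: r.adaptation_fraction for r in reports}
    worst = max(reports, key=lambda r: r.max_stress)
    return CriteriaStatus(
        stress_pass=bool(worst.max_stress <= criteria.yield_strength),
        max_stress=worst.max_stress,
        worst_stage=worst.stage,
        per_stage_max_stress=per_stress,
        per_stage_adaptation=per_adapt)


def reports_to_csv(reports: list[FrequencyReport],
                   bins: FrequencyBins | None = None) -> str:
    """One row per stage per bin, plus per-stage summary rows."""
    bins = bins or FrequencyBins()
    lines = ["stage,field,bin,percent"]
    for r in reports:
        for label, pct in zip(bins.stress_labels(), r.stress_percentages):
            lines.append(f"{r.stage},stress,{label},{pct:.6f}")
        for label, pct in zip(bins.strain_labels(), r.strain_percentages):
            lines.append(f"{r.stage},strain,{label},{pct:.6f}")
        lines.append(f"{r.stage},max_stress_MPa,,{r.max_stress:.6f}")
        lines.append(f"{r.stage},max_strain_ue,,{r.max_strain:.6f}")
        lines.append(f"{r.stage},adaptation_pct,,"
                     f"{r.adaptation_fraction:.6f}")
    return "\n".join(lines) + "\n"
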