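"""Strut-diameter size optimization against yield and strain-window criteria.

A fully-stressed-design loop: solve the worst (softest-graft) stage,
thicken struts where equivalent stress concentrates, thin clearly shielded
struts, re-voxelize the graft on the same grid, repeat.  Stops once the
yield criterion holds at every stage and the graft strain-adaptation
fraction stops improving; returns the best design seen under a
lexicographic (stress feasibility, adaptation fraction) objective.
The loop is fully deterministic; hotspot ties break by ascending strut id.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .healing import (DEFAULT_STAGES, FrequencyBins, evaluate_criteria,
                      run_stage_sweep_detailed)
from .lattice import LatticeModel, StrutSpec
from .materials import LoadCase
from .model import DesignModel


@dataclass
class CriteriaConfig:
    yield_strength: float = 897.0          # MPa
    strain_window_upper: float = 3_000.0   # ue
    max_iterations: int = 20
    improvement_tolerance: float = 0.5     # percentage points
    hotspot_quantile: float = 0.90

    def __post_init__(self):
        if min(self.yield_strength, self.strain_window_upper,
               self.max_iterations, self.improvement_tolerance) <= 0:
            raise ValueError("criteria parameters must be positive")


@dataclass
class IterationRecord:
    iteration: int
    max_stress: dict[str, float]
    adaptation_fraction: dict[str, float]
    struts_modified: int
    feasible: bool


@dataclass
class OptimizationTrace:
    records: list[IterationRecord] = field(default_factory=list)
    converged: bool = False
    reason: str = "not run"

    def to_csv(self) -> str:
        stages = list(self.records[0].max_stress) if self.records else []
        head = ["iteration"] + [f"max_stress_{s}" for s in stages] \
            + [f"adaptation_{s}" for s in stages] \
            + ["struts_modified", "feasible"]
        lines = [",".join(head)]
        for r in self.records:
            row = [str(r.iteration)]
            row += [f"{r.max_stress[s]:.6f}" for s in stages]
            row += [f"{r.adaptation_fraction[s]:.6f}" for s in stages]
            row += [str(r.struts_modified), str(int(r.feasible))]
            lines.append(",".join(row))
        lines.append(f"# converged={self.converged} reason={self.reason}")
        return "\n".join(lines) + "\n"


def identify_hotspots(beam_stress: np.ndarray, quantile: float,
                      yield_strength: float = 897.0) -> np.ndarray:
    """Strut ids whose stress exceeds max(q-quantile, yield/2); ascending."""
    beam_stress = np.asarray(beam_stress, dtype=np.float64)
    if beam_stress.size == 0:
        return np.empty(0, dtype=np.int64)
    cutoff = max(float(np.quantile(beam_stress, quantile)),
                 yield_strength / 2.0)
    return np.where(beam_stress > cutoff)[0].astype(np.int64)


def update_diameters(lattice: LatticeModel, hotspots: np.ndarray,
                     beam_stress: np.ndarray, spec: StrutSpec,
                     yield_strength: float = 897.0) -> LatticeModel:
    """Fully-stressed multiplicative resizing with per-step clamps.

    Hotspot struts: d <- clip(d * (sigma/sigma_t)^(1/2), 0.9 d, 1.25 d),
    sigma_t = yield/1.5, then clipped to [d_min, d_max].  Struts loafing
    below sigma_t/4 are thinned by 5% (stress-shielding relief).  Fixation
    struts (retainer/screw) are never resized.
    """
    hotspots = np.asarray(hotspots, dtype=np.int64)
    if len(hotspots) and (hotspots.max() >= lattice.n_struts
                          or hotspots.min() < 0):
        raise IndexError("hotspot id outside lattice")
    out = lattice.copy()
    sigma_t = yield_strength / 1.5
    resizable = np.array([t in ("trabecular", "grid") for t in out.tags])
    d = out.diameters
    for i in hotspots:
        if not resizable[i]:
            continue
        factor = np.sqrt(beam_stress[i] / sigma_t)
        new = np.clip(d[i] * factor, 0.9 * d[i], 1.25 * d[i])
        d[i] = np.clip(new, spec.d_min, spec.d_max)
    shielded = resizable & (np.asarray(beam_stress) < sigma_t / 4.0)
    shielded[hotspots] = False
    d[shielded] = np.maximum(d[shielded] * 0.95, spec.d_min)
    return out


def optimize(design: DesignModel, load: LoadCase, criteria: CriteriaConfig,
             spec: StrutSpec | None = None, stages=DEFAULT_STAGES,
             bins: FrequencyBins | None = None
             ) -> tuple[DesignModel, OptimizationTrace]:
    """Iterate solve -> hotspot -> resize -> re-voxelize until criteria hold.

    The worst-case (first, G-T) stage drives the stress update and scores
    the adaptation fraction.  Returns the best-so-far design by
    (feasibility, G-T adaptation) and a per-iteration trace; a
    non-convergence reason is recorded when the yield criterion cannot be
    met within ``max_iterations``.
    """
    spec = spec or _spec_from_provenance(design.lattice)
    if bins is None:
        if criteria.strain_window_upper == 3000.0:
            bins = FrequencyBins()
        else:  # customised window: scale the strain bins with it
            w = criteria.strain_window_upper
            bins = FrequencyBins(strain_edges=(w, 2.0 * w, 10.0 * w / 3.0))

    trace = OptimizationTrace()
    best = None        # (feasible, adaptation, -iteration, design)
    prev_adapt = None
    current = design
    stages = list(stages)
    gt_label = stages[0].label

    for it in range(criteria.max_iterations):
        reports, results = run_stage_sweep_detailed(current, stages, load,
                                                    bins)
        status = evaluate_criteria(reports, criteria)
        gt_adapt = status.per_stage_adaptation[gt_label]
        trace.records.append(IterationRecord(
            iteration=it,
            max_stress=dict(status.per_stage_max_stress),
            adaptation_fraction=dict(status.per_stage_adaptation),
            struts_modified=0,
            feasible=status.stress_pass))

        key = (status.stress_pass, gt_adapt)
        if best is None or key > best[0]:
            best = (key, current)

        if status.stress_pass:
            if gt_adapt >= 100.0 - 1e-9:
                trace.converged = True
                trace.reason = "criteria met (full adaptation)"
                break
            if (prev_adapt is not None
                    and gt_adapt - prev_adapt
                    < criteria.improvement_tolerance):
                trace.converged = True
                trace.reason = "criteria met (adaptation plateau)"
                break
        prev_adapt = gt_adapt

        if it == criteria.max_iterations - 1:
            break
        gt_result, _ = results[0]
        hot = identify_hotspots(gt_result.beam_stress,
                                criteria.hotspot_quantile,
                                criteria.yield_strength)
        new_lattice = update_diameters(current.lattice, hot,
                                       gt_result.beam_stress, spec,
                                       criteria.yield_strength)
        changed = int(np.sum(~np.isclose(new_lattice.diameters,
                                         current.lattice.diameters)))
        trace.records[-1].struts_modified = changed
        if changed == 0 and status.stress_pass:
            trace.converged = True
            trace.reason = "criteria met (no further resizing possible)"
            break
        current = current.with_lattice(new_lattice)
        _assert_bounds(new_lattice, spec)

    if not trace.converged:
        feasible = best is not None and best[0][0]
        trace.reason = ("max iterations reached (feasible)" if feasible
                        else "non-convergence: yield criterion not met "
                             "within max_iterations")
        trace.converged = False
    return best[1], trace


def _spec_from_provenance(lattice: LatticeModel) -> StrutSpec:
    p = lattice.provenance.get("strut_spec")
    if p:
        return StrutSpec(p["d_min"], p["d_max"],
                         np.asarray(p["gradient_axis"]))
    return StrutSpec()


def _assert_bounds(lattice: LatticeModel, spec: StrutSpec):
    mask = np.array([t in ("trabecular", "grid") for t in lattice.tags])
    d = lattice.diameters[mask]
    if len(d) and (d.min() < spec.d_min - 1e-12
                   or d.max() > spec.d_max + 1e-12):
        raise AssertionError("strut diameter bounds violated during update")
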