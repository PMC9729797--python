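"""End-to-end pipeline: fixture -> lattice -> FE sweep -> optimization -> files.

All randomness flows from the single config seed; two runs with the same
config produce byte-identical numeric outputs.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np

from . import fe
from .config import PipelineConfig
from .fixtures import DefectFixture, make_defect_fixture
from .geometry import load_stl
from .healing import reports_to_csv, run_stage_sweep_detailed
from .lattice import (LatticeModel, assign_gradient_diameters,
                      build_grid_shell, lattice_to_surface, merge_components,
                      place_fixation, tessellate_trabecular)
from .model import DesignModel, build_load_case
from .optimizer import optimize

log = logging.getLogger("osteolattice")


def build_fixture(config: PipelineConfig) -> DefectFixture:
    if config.geometry_source != "fixture":
        raise NotImplementedError(
            "STL geometry sources supply only the defect region; the "
            "labeled fixture sets require the synthetic fixture")
    return make_defect_fixture(config.span_mm, config.height_mm,
                               config.width_mm, config.curvature,
                               config.seed,
                               defect_fraction=config.defect_fraction)


def build_lattice(fixture: DefectFixture,
                  config: PipelineConfig) -> LatticeModel:
    """Trabecular core + grid shell + gradient diameters + fixation."""
    cell = config.unit_cell_spec()
    region = fixture.defect_region
    if config.geometry_source == "stl":
        region = load_stl(config.stl_path)
    trab = tessellate_trabecular(region, cell)
    grid = build_grid_shell(region, cell)
    lat = merge_components(trab, grid)
    lat = assign_gradient_diameters(lat, config.strut_spec())
    lat = place_fixation(lat, fixture, config.fixation_spec())
    return lat


def build_design(fixture: DefectFixture, lat: LatticeModel,
                 config: PipelineConfig) -> DesignModel:
    return DesignModel.build(
        fixture, lat, voxel_mm=config.voxel_mm, shell_mm=config.shell_mm,
        tooth_radius_mm=config.tooth_radius_mm, disc_mm=config.disc_mm,
        materials=config.materials_table(),
        strain_measure=config.strain_measure)


def run_pipeline(config: PipelineConfig, outdir=None) -> dict[str, Path]:
    """Run every stage and write all artifacts; returns path map.

    Partial outputs are retained on failure; the failing stage name is
    attached to the raised error.
    """
    outdir = Path(outdir if outdir is not None else config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    t0 = time.time()
    stage = "configure"
    try:
        paths["config"] = outdir / "config.yaml"
        config.save(paths["config"])

        stage = "fixture"
        fixture = build_fixture(config)
        fixture.export(outdir)
        paths["outer_stl"] = outdir / "outer_surface.stl"
        paths["defect_stl"] = outdir / "defect_region.stl"
        paths["fixture_sets"] = outdir / "fixture_sets.json"

        stage = "generate"
        lat = build_lattice(fixture, config)
        paths["lattice_initial"] = outdir / "lattice_initial.json"
        paths["lattice_initial"].write_text(lat.to_json())
        paths["implant_initial_stl"] = outdir / "implant_initial.stl"
        lattice_to_surface(lat, segments_per_circle=6).save_stl(
            paths["implant_initial_stl"])

        stage = "solve/analyze (initial)"
        design = build_design(fixture, lat, config)
        load = build_load_case(fixture, config.bite_force_n,
                               config.materials_table())
        reports0, _ = run_stage_sweep_detailed(design, config.stages(), load,
                                               config.bins())
        paths["reports_initial"] = outdir / "reports_initial.csv"
        paths["reports_initial"].write_text(
            reports_to_csv(reports0, config.bins()))

        stage = "optimize"
        best, trace = optimize(design, load, config.criteria(),
                               spec=config.strut_spec(),
                               stages=config.stages(), bins=config.bins())
        paths["trace"] = outdir / "trace.csv"
        paths["trace"].write_text(trace.to_csv())
        paths["lattice_final"] = outdir / "lattice_final.json"
        paths["lattice_final"].write_text(best.lattice.to_json())

        stage = "analyze (final)"
        reports1, results1 = run_stage_sweep_detailed(
            best, config.stages(), load, config.bins())
        paths["reports_final"] = outdir / "reports_final.csv"
        paths["reports_final"].write_text(
            reports_to_csv(reports1, config.bins()))
        paths["summary"] = outdir / "summary.json"
        paths["summary"].write_text(json.dumps({
            phase: {r.stage: {"max_stress_MPa": r.max_stress,
                              "max_strain_ue": r.max_strain,
                              "adaptation_pct": r.adaptation_fraction}
                    for r in reps}
            for phase, reps in (("initial", reports0), ("final", reports1))
        }, indent=1, sort_keys=True))

        stage = "export"
        paths["implant_final_stl"] = outdir / "implant_final.stl"
        lattice_to_surface(best.lattice, segments_per_circle=6).save_stl(
            paths["implant_final_stl"])
        for st, (result, _meta) in zip(config.stages(), results1):
            fem, _ = best.assemble_stage(st.graft_material, load)
            p = outdir / f"result_{st.label}.vtk"
            fe.export_vtk(fem, result, p)
            paths[f"result_{st.label}"] = p

        paths["run_log"] = outdir / "run_log.json"
        paths["run_log"].write_text(json.dumps({
            "config_hash": config.content_hash(),
            "seed": config.seed,
            "elapsed_s": round(time.time() - t0, 2),
            "converged": trace.converged,
            "reason": trace.reason,
            "n_iterations": len(trace.records),
        }, indent=1, sort_keys=True))
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") \
            from exc
    log.info("pipeline finished in %.1f s; %d artifacts",
             time.time() - t0, len(paths))
    return paths
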