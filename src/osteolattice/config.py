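"""Pipeline configuration: defaults, YAML round-trip, content hashing.

Every tunable of the pipeline lives here as a plain scalar/list/dict field
so that ``parse(serialize(c)) == c`` holds exactly and a content hash can
be computed over the canonical JSON form.  Missing fields in a user file
are filled from the package defaults.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields

import numpy as np
import yaml

from .fixtures import MUSCLE_DIRECTIONS
from .healing import DEFAULT_STAGES, FrequencyBins, HealingStage
from .lattice import FixationSpec, StrutSpec, UnitCellSpec
from .materials import DEFAULT_MATERIALS, MaterialProperties
from .optimizer import CriteriaConfig


def _default_materials() -> dict:
    out = {}
    for name, m in DEFAULT_MATERIALS.items():
        out[name] = {"E": m.E, "nu": m.nu}
        if m.yield_strength is not None:
            out[name]["yield_strength"] = m.yield_strength
    return out


@dataclass
class PipelineConfig:
    # geometry source: the seeded synthetic fixture or a user STL
    geometry_source: str = "fixture"
    stl_path: str | None = None
    span_mm: float = 40.0
    height_mm: float = 20.0
    width_mm: float = 10.0
    curvature: float = 0.15
    defect_fraction: float = 0.4
    seed: int = 42

    # unit cell / struts / fixation
    cell_kind: str = "rhombic_dodecahedron"
    pore_diameter_mm: float = 5.0
    orientation: list = field(default_factory=lambda: [0.0, 0.0, 1.0])
    d_min_mm: float = 0.2
    d_max_mm: float = 0.8
    gradient_axis: list = field(default_factory=lambda: [0.0, 0.0, -1.0])
    retainer_thickness_mm: float = 2.0
    screw_length_mm: float = 8.0
    screws_per_side: int = 5
    screw_diameter_mm: float = 2.0

    # discretization
    voxel_mm: float = 1.25
    shell_mm: float = 1.5
    tooth_radius_mm: float = 3.0
    disc_mm: float = 2.0
    strain_measure: str = "equivalent"

    # loads
    bite_force_n: float = 800.0
    bite_direction: list = field(default_factory=lambda: [0.0, 0.0, -1.0])
    muscle_directions: dict = field(
        default_factory=lambda: {k: list(v)
                                 for k, v in MUSCLE_DIRECTIONS.items()})

    # materials (Young's modulus MPa / Poisson ratio / optional yield)
    materials: dict = field(default_factory=_default_materials)

    # frequency bins
    stress_edges: list = field(
        default_factory=lambda: [50.0, 100.0, 150.0, 200.0, 250.0,
                                 300.0, 350.0])
    strain_edges: list = field(
        default_factory=lambda: [3_000.0, 6_000.0, 10_000.0])

    # criteria / optimizer
    yield_strength_mpa: float = 897.0
    strain_window_ue: float = 3_000.0
    max_iterations: int = 20
    improvement_tolerance: float = 0.5
    hotspot_quantile: float = 0.90

    output_dir: str = "out"

    # -- serialization --------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(text) or {})

    def save(self, path):
        with open(path, "w") as fh:
            fh.write(self.to_yaml())

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_yaml(fh.read())

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()

    # -- adapters into the domain objects -------------------------------

    def unit_cell_spec(self) -> UnitCellSpec:
        return UnitCellSpec(self.cell_kind, self.pore_diameter_mm,
                            np.asarray(self.orientation, dtype=np.float64))

    def strut_spec(self) -> StrutSpec:
        return StrutSpec(self.d_min_mm, self.d_max_mm,
                         np.asarray(self.gradient_axis, dtype=np.float64))

    def fixation_spec(self) -> FixationSpec:
        return FixationSpec(self.retainer_thickness_mm, self.screw_length_mm,
                            self.screws_per_side, self.screw_diameter_mm)

    def criteria(self) -> CriteriaConfig:
        return CriteriaConfig(self.yield_strength_mpa, self.strain_window_ue,
                              self.max_iterations,
                              self.improvement_tolerance,
                              self.hotspot_quantile)

    def bins(self) -> FrequencyBins:
        return FrequencyBins(tuple(self.stress_edges),
                             tuple(self.strain_edges))

    def materials_table(self) -> dict[str, MaterialProperties]:
        out = {}
        for name, spec in self.materials.items():
            out[name] = MaterialProperties(name, spec["E"], spec["nu"],
                                           spec.get("yield_strength"))
        return out

    def stages(self) -> tuple[HealingStage, ...]:
        mats = self.materials_table()
        return (HealingStage("G-T", mats["granulation"]),
                HealingStage("IM-B", mats["immature"]),
                HealingStage("M-B", mats["mature"]))
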