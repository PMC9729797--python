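"""Material constants, masticatory muscle loads and the load case.

All values are in the mm-N-MPa unit system. The tissue/metal constants and
the muscle force table are package defaults; every one of them can be
overridden through the pipeline configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class MaterialProperties:
    """Isotropic linear-elastic constants; yield strength only for metals."""

    name: str
    E: float                      # Young's modulus, MPa
    nu: float                     # Poisson's ratio
    yield_strength: float | None = None

    def __post_init__(self):
        if self.E <= 0:
            raise ValueError(f"{self.name}: Young's modulus must be positive")
        if not 0.0 < self.nu < 0.5:
            raise ValueError(f"{self.name}: Poisson's ratio must be in (0, 0.5)")

    @property
    def G(self) -> float:
        """Shear modulus."""
        return self.E / (2.0 * (1.0 + self.nu))


#: Default tissue/metal properties.
DEFAULT_MATERIALS: dict[str, MaterialProperties] = {
    "cortical": MaterialProperties("cortical", 15_000.0, 0.3),
    "cancellous": MaterialProperties("cancellous", 1_500.0, 0.3),
    "disc": MaterialProperties("disc", 44.1, 0.4),
    "tooth": MaterialProperties("tooth", 20_000.0, 0.3),
    "Ti6Al4V": MaterialProperties("Ti6Al4V", 110_000.0, 0.3,
                                  yield_strength=897.0),
    "granulation": MaterialProperties("granulation", 0.2, 0.167),
    "immature": MaterialProperties("immature", 1_000.0, 0.3),
    "mature": MaterialProperties("mature", 5_000.0, 0.3),
}

#: Muscle forces (N) under maximum-force bite, per side.
MUSCLE_FORCES: dict[str, dict[str, float]] = {
    "left": {
        "anterior temporalis": 222.3,
        "posterior temporalis": 158.6,
        "superior lateral pterygoid": 5.1,
        "inferior lateral pterygoid": 65.5,
        "medial pterygoid": 170.8,
        "superficial masseter": 196.3,
        "deep anterior masseter": 37.9,
        "deep posterior masseter": 44.9,
    },
    "right": {
        "anterior temporalis": 221.5,
        "posterior temporalis": 156.5,
        "superior lateral pterygoid": 5.3,
        "inferior lateral pterygoid": 76.1,
        "medial pterygoid": 170.7,
        "superficial masseter": 196.3,
        "deep anterior masseter": 37.9,
        "deep posterior masseter": 44.2,
    },
}

#: Grounded-spring stiffness (N/mm) per muscle group.
MUSCLE_SPRING_STIFFNESS: dict[str, float] = {
    "temporalis": 14.0,
    "masseter": 16.35,
    "lateral pterygoid": 12.0,
    "medial pterygoid": 15.0,
}

MUSCLE_NAMES: tuple[str, ...] = tuple(MUSCLE_FORCES["left"])


def muscle_stiffness(name: str) -> float:
    """Map a muscle row label onto its group spring stiffness."""
    low = name.lower()
    if "lateral pterygoid" in low:
        return MUSCLE_SPRING_STIFFNESS["lateral pterygoid"]
    if "medial pterygoid" in low:
        return MUSCLE_SPRING_STIFFNESS["medial pterygoid"]
    if "masseter" in low:
        return MUSCLE_SPRING_STIFFNESS["masseter"]
    if "temporalis" in low:
        return MUSCLE_SPRING_STIFFNESS["temporalis"]
    raise KeyError(f"unknown muscle group for '{name}'")


@dataclass
class MuscleLoad:
    """One muscle: a point force plus a grounded spring at the attachment."""

    name: str
    side: str                       # 'left' | 'right'
    force: float                    # N
    direction: np.ndarray           # unit vector
    spring_stiffness: float         # N/mm
    attachment: int                 # node id (resolved at assembly time)

    def __post_init__(self):
        self.direction = np.asarray(self.direction, dtype=np.float64)
        n = np.linalg.norm(self.direction)
        if not np.isfinite(n) or n == 0:
            raise ValueError("muscle direction must be a non-zero vector")
        self.direction = self.direction / n
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be left/right, got {self.side!r}")


@dataclass
class LoadCase:
    """Bite force, muscle loads, and support sets for one solve."""

    bite_force: float = 800.0
    bite_direction: np.ndarray = field(
        default_factory=lambda: np.array([0.0, 0.0, -1.0]))
    occlusal_nodes: np.ndarray = field(
        default_factory=lambda: np.empty(0, dtype=np.int64))
    muscles: list[MuscleLoad] = field(default_factory=list)
    fixed_nodes: np.ndarray = field(
        default_factory=lambda: np.empty(0, dtype=np.int64))

    def __post_init__(self):
        if self.bite_force <= 0:
            raise ValueError("bite force must be positive")
        self.occlusal_nodes = np.asarray(self.occlusal_nodes, dtype=np.int64)
        self.fixed_nodes = np.asarray(self.fixed_nodes, dtype=np.int64)
        if self.occlusal_nodes.size and self.fixed_nodes.size:
            if np.intersect1d(self.occlusal_nodes, self.fixed_nodes).size:
                raise ValueError("occlusal and fixed node sets must be disjoint")
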