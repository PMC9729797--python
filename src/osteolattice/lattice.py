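"""Lattice implant generation.

Two components make up the implant, mirroring trabecular and cortical bone:

* an interior strut wireframe built from space-filling rhombic-dodecahedron
  cells (a regular-dodecahedron wireframe with vertex snapping is available
  as a non-tessellating option), clipped to the target region;
* a quadrilateral grid shell traced on the region surface by slicing it
  with three orthogonal families of planes spaced one pore apart, plus the
  region's sharp feature edges.

Strut solids are capsules (cylinder + spherical caps) throughout, which
gives a closed-form signed distance for the Boolean graft region and for
surface export.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .errors import EmptyLatticeError, InvalidParameterError, ResolutionError
from .geometry import TriMesh, simplify_polyline

_NODE_DECIMALS = 6


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

@dataclass
class UnitCellSpec:
    cell_kind: str = "rhombic_dodecahedron"
    pore_diameter: float = 5.0
    orientation: np.ndarray = field(
        default_factory=lambda: np.array([0.0, 0.0, 1.0]))

    def __post_init__(self):
        if self.pore_diameter <= 0:
            raise InvalidParameterError("pore_diameter must be positive")
        if self.cell_kind not in ("rhombic_dodecahedron",
                                  "regular_dodecahedron_wireframe"):
            raise InvalidParameterError(f"unknown cell kind {self.cell_kind!r}")
        self.orientation = np.asarray(self.orientation, dtype=np.float64)
        if self.orientation.shape == (3,):
            n = np.linalg.norm(self.orientation)
            if abs(n - 1.0) > 1e-9:
                if n == 0:
                    raise InvalidParameterError("orientation must be non-zero")
                self.orientation = self.orientation / n
        elif self.orientation.shape != (3, 3):
            raise InvalidParameterError(
                "orientation must be a unit vector or a 3x3 rotation")

    def rotation(self) -> np.ndarray:
        """Rows are the cell axes expressed in world coordinates."""
        if self.orientation.shape == (3, 3):
            return self.orientation
        v = self.orientation
        z = np.array([0.0, 0.0, 1.0])
        c = float(z @ v)
        if c > 1.0 - 1e-12:
            return np.eye(3)
        if c < -1.0 + 1e-12:
            return np.diag([1.0, -1.0, -1.0])
        axis = np.cross(z, v)
        s = np.linalg.norm(axis)
        axis = axis / s
        K = np.array([[0, -axis[2], axis[1]],
                      [axis[2], 0, -axis[0]],
                      [-axis[1], axis[0], 0]])
        R = np.eye(3) + s * K + (1 - c) * (K @ K)
        return R.T  # rows map world -> cell


@dataclass
class StrutSpec:
    d_min: float = 0.2
    d_max: float = 0.8
    gradient_axis: np.ndarray = field(
        default_factory=lambda: np.array([0.0, 0.0, -1.0]))

    def __post_init__(self):
        if not 0 < self.d_min <= self.d_max:
            raise InvalidParameterError("need 0 < d_min <= d_max")
        self.gradient_axis = np.asarray(self.gradient_axis, dtype=np.float64)
        self.gradient_axis = self.gradient_axis / np.linalg.norm(
            self.gradient_axis)


@dataclass
class FixationSpec:
    retainer_thickness: float = 2.0
    screw_length: float = 8.0
    screws_per_side: int = 5
    screw_diameter: float = 2.0

    def __post_init__(self):
        if self.retainer_thickness <= 0 or self.screw_length <= 0:
            raise InvalidParameterError("fixation dimensions must be positive")
        if not 5 <= self.screws_per_side <= 7:
            raise InvalidParameterError(
                f"screws_per_side must be within [5, 7], "
                f"got {self.screws_per_side}")


# ---------------------------------------------------------------------------
# lattice model
# ---------------------------------------------------------------------------

class LatticeModel:
    """Strut graph: node coordinates, edges, per-strut diameters and tags."""

    TAGS = ("trabecular", "grid", "retainer", "screw")

    def __init__(self, nodes=None, edges=None, diameters=None, tags=None,
                 provenance: dict | None = None):
        self.nodes = (np.asarray(nodes, dtype=np.float64).reshape(-1, 3)
                      if nodes is not None else np.empty((0, 3)))
        self.edges = (np.asarray(edges, dtype=np.int64).reshape(-1, 2)
                      if edges is not None else np.empty((0, 2), np.int64))
        self.diameters = (np.asarray(diameters, dtype=np.float64)
                          if diameters is not None
                          else np.empty(0))
        self.tags = list(tags) if tags is not None else []
        self.provenance = provenance or {}

    # -- queries --------------------------------------------------------

    @property
    def n_struts(self) -> int:
        return len(self.edges)

    def lengths(self) -> np.ndarray:
        a = self.nodes[self.edges[:, 0]]
        b = self.nodes[self.edges[:, 1]]
        return np.linalg.norm(b - a, axis=1)

    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.nodes[self.edges[:, 0]]
                      + self.nodes[self.edges[:, 1]])

    def segments(self):
        """(start points, end points, radii) of all strut capsules."""
        return (self.nodes[self.edges[:, 0]], self.nodes[self.edges[:, 1]],
                self.diameters / 2.0)

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(len(self.nodes)))
        g.add_edges_from(map(tuple, self.edges))
        return g

    def is_connected(self) -> bool:
        g = self.graph()
        g.remove_nodes_from(list(nx.isolates(g)))
        return g.number_of_nodes() > 0 and nx.is_connected(g)

    def strut_volume(self) -> float:
        """Sum of capsule volumes (junction overlaps not subtracted)."""
        r = self.diameters / 2.0
        return float(np.sum(np.pi * r ** 2 * self.lengths()
                            + 4.0 / 3.0 * np.pi * r ** 3))

    def copy(self) -> "LatticeModel":
        return LatticeModel(self.nodes.copy(), self.edges.copy(),
                            self.diameters.copy(), list(self.tags),
                            dict(self.provenance))

    # -- mutation helpers ----------------------------------------------

    def _validate(self):
        if len(self.edges):
            a, b = self.edges[:, 0], self.edges[:, 1]
            if np.any(a == b):
                raise InvalidParameterError("zero-length strut (a == b)")
            key = np.sort(self.edges, axis=1)
            if len(np.unique(key, axis=0)) != len(key):
                raise InvalidParameterError("duplicate strut node pair")

    def append(self, other: "LatticeModel", snap_tol: float = 0.0):
        """Merge another lattice in, snapping its nodes to nearby existing
        nodes within ``snap_tol`` and dropping duplicate struts."""
        if other.n_struts == 0:
            return self
        remap = np.arange(len(other.nodes)) + len(self.nodes)
        nodes = [self.nodes]
        if snap_tol > 0 and len(self.nodes):
            tree = cKDTree(self.nodes)
            d, idx = tree.query(other.nodes)
            new_mask = d > snap_tol
        else:
            new_mask = np.ones(len(other.nodes), dtype=bool)
            idx = np.zeros(len(other.nodes), dtype=np.int64)
        new_ids = {}
        counter = len(self.nodes)
        for i in range(len(other.nodes)):
            if new_mask[i]:
                new_ids[i] = counter
                counter += 1
            else:
                remap[i] = idx[i]
        for i, nid in new_ids.items():
            remap[i] = nid
        nodes.append(other.nodes[new_mask])
        self.nodes = np.vstack(nodes)
        edges = remap[other.edges]
        keep = edges[:, 0] != edges[:, 1]
        existing = {tuple(sorted(e)) for e in self.edges.tolist()}
        add_e, add_d, add_t = [], [], []
        for e, d_, t in zip(edges[keep], other.diameters[keep],
                            [t for t, k in zip(other.tags, keep) if k]):
            key = tuple(sorted(e.tolist()))
            if key in existing:
                continue
            existing.add(key)
            add_e.append(e)
            add_d.append(d_)
            add_t.append(t)
        if add_e:
            self.edges = np.vstack([self.edges, np.array(add_e)])
            self.diameters = np.concatenate([self.diameters, add_d])
            self.tags.extend(add_t)
        return self

    def collapse_short_struts(self, min_length: float) -> "LatticeModel":
        """Merge node pairs joined by struts shorter than ``min_length``.

        Deterministic union-find (cluster representative = smallest id,
        position = cluster mean); repeats until no short strut remains.
        """
        for _ in range(12):
            L = self.lengths()
            short = np.where(L < min_length)[0]
            if not len(short):
                break
            parent = np.arange(len(self.nodes))

            def find(i):
                while parent[i] != i:
                    parent[i] = parent[parent[i]]
                    i = parent[i]
                return i

            for e in short:
                a, b = sorted((find(self.edges[e, 0]),
                               find(self.edges[e, 1])))
                parent[b] = a
            roots = np.array([find(i) for i in range(len(self.nodes))])
            # cluster means
            sums = np.zeros_like(self.nodes)
            cnt = np.zeros(len(self.nodes))
            np.add.at(sums, roots, self.nodes)
            np.add.at(cnt, roots, 1.0)
            used = sorted(set(roots.tolist()))
            remap = {r: i for i, r in enumerate(used)}
            new_nodes = sums[used] / cnt[used, None]
            new_edges, new_d, new_t = [], [], []
            seen = set()
            for e, d_, t in zip(self.edges, self.diameters, self.tags):
                a, b = remap[roots[e[0]]], remap[roots[e[1]]]
                if a == b:
                    continue
                key = (min(a, b), max(a, b))
                if key in seen:
                    continue
                seen.add(key)
                new_edges.append((a, b))
                new_d.append(d_)
                new_t.append(t)
            self.nodes = new_nodes
            self.edges = (np.array(new_edges, dtype=np.int64)
                          if new_edges else np.empty((0, 2), np.int64))
            self.diameters = np.array(new_d)
            self.tags = new_t
        return self

    def connect_components(self, tag: str = "grid",
                           diameter: float | None = None):
        """Add shortest tie struts until the graph is one component."""
        g = self.graph()
        g.remove_nodes_from(list(nx.isolates(g)))
        comps = [sorted(c) for c in nx.connected_components(g)]
        comps.sort(key=lambda c: (-len(c), c[0]))
        if diameter is None:
            diameter = float(self.diameters.max()) if len(self.diameters) \
                else 0.5
        while len(comps) > 1:
            main = comps[0]
            tree = cKDTree(self.nodes[main])
            best = None
            for ci, comp in enumerate(comps[1:], start=1):
                d, idx = tree.query(self.nodes[comp])
                j = int(d.argmin())
                cand = (float(d[j]), ci, comp[j], main[int(idx[j])])
                if best is None or cand < best:
                    best = cand
            dist, ci, na, nb = best
            if dist < 1e-6:
                # coincident nodes across components: merge, don't bridge
                self.edges[self.edges == na] = nb
                self._drop_degenerate()
            else:
                self.edges = np.vstack([self.edges, [[na, nb]]])
                self.diameters = np.concatenate([self.diameters, [diameter]])
                self.tags.append(tag)
            merged = set(comps[0]) | set(comps.pop(ci))
            if dist < 1e-6:
                merged.discard(na)
            comps[0] = sorted(merged)
        return self

    def _drop_degenerate(self):
        """Remove self-loops and duplicate node pairs in place."""
        keep, seen = [], set()
        for i, e in enumerate(self.edges):
            if e[0] == e[1]:
                continue
            key = (min(e), max(e))
            if key in seen:
                continue
            seen.add(key)
            keep.append(i)
        if len(keep) != len(self.edges):
            self.edges = self.edges[keep]
            self.diameters = self.diameters[keep]
            self.tags = [self.tags[i] for i in keep]

    def largest_component(self) -> "LatticeModel":
        g = self.graph()
        g.remove_nodes_from(list(nx.isolates(g)))
        if g.number_of_nodes() == 0:
            raise EmptyLatticeError("lattice has no struts")
        comp = max(nx.connected_components(g), key=lambda c: (len(c), -min(c)))
        keep = np.array([i for i, e in enumerate(self.edges)
                         if e[0] in comp and e[1] in comp])
        used = sorted(comp)
        remap = {n: i for i, n in enumerate(used)}
        edges = np.array([[remap[a], remap[b]] for a, b in self.edges[keep]])
        return LatticeModel(self.nodes[used], edges, self.diameters[keep],
                            [self.tags[i] for i in keep],
                            dict(self.provenance))

    # -- serialization --------------------------------------------------

    def to_json(self) -> str:
        return json.dumps({
            "nodes": self.nodes.tolist(),
            "edges": self.edges.tolist(),
            "diameters": self.diameters.tolist(),
            "tags": self.tags,
            "provenance": self.provenance,
        }, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "LatticeModel":
        d = json.loads(text)
        return cls(np.array(d["nodes"]).reshape(-1, 3),
                   np.array(d["edges"], dtype=np.int64).reshape(-1, 2),
                   np.array(d["diameters"]), d["tags"], d.get("provenance"))


def _dedup_edges(points: list, raw_edges: list) -> tuple[np.ndarray, np.ndarray]:
    """Merge coincident nodes (rounded keys) and drop duplicate edges."""
    keys = {}
    nodes = []
    ids = np.empty(len(points), dtype=np.int64)
    for i, p in enumerate(points):
        k = tuple(np.round(p, _NODE_DECIMALS))
        if k not in keys:
            keys[k] = len(nodes)
            nodes.append(p)
        ids[i] = keys[k]
    edges = set()
    for a, b in raw_edges:
        ia, ib = int(ids[a]), int(ids[b])
        if ia != ib:
            edges.add((min(ia, ib), max(ia, ib)))
    return np.array(nodes), np.array(sorted(edges), dtype=np.int64)


# ---------------------------------------------------------------------------
# trabecular tessellation
# ---------------------------------------------------------------------------

# rhombic dodecahedron wireframe: 8 degree-3 "cube corner" vertices, each
# joined to the 3 nearest degree-4 axis vertices; 24 edges per cell
_RD_CORNERS = np.array([[sx, sy, sz] for sx in (-1, 1) for sy in (-1, 1)
                        for sz in (-1, 1)], dtype=np.float64)
#: opening factor: (in-cell wireframe opening) / s for the unit above
OPENING_FACTOR = 4.0 * np.sqrt(6.0) / 3.0
_FCC_OFFSETS = np.array([[0, 0, 0], [2, 2, 0], [2, 0, 2], [0, 2, 2]],
                        dtype=np.float64)

# regular dodecahedron wireframe (non-tessellating option)
_PHI = (1 + np.sqrt(5.0)) / 2.0


def _regular_dodecahedron() -> tuple[np.ndarray, np.ndarray]:
    v = []
    for sx in (-1, 1):
        for sy in (-1, 1):
            for sz in (-1, 1):
                v.append((sx, sy, sz))
    for s1 in (-1, 1):
        for s2 in (-1, 1):
            v.append((0, s1 / _PHI, s2 * _PHI))
            v.append((s1 / _PHI, s2 * _PHI, 0))
            v.append((s1 * _PHI, 0, s2 / _PHI))
    v = np.array(v, dtype=np.float64)
    d = np.linalg.norm(v[:, None] - v[None], axis=2)
    edge_len = 2.0 / _PHI
    e = np.argwhere((d > 1e-9) & (np.abs(d - edge_len) < 1e-9))
    e = np.unique(np.sort(e, axis=1), axis=0)
    return v, e


def _cell_edges(kind: str, s: float) -> tuple[np.ndarray, np.ndarray]:
    """Local wireframe (vertices, edge index pairs) for one cell."""
    if kind == "rhombic_dodecahedron":
        verts = [tuple(c) for c in _RD_CORNERS]
        for ax in range(3):
            for sign in (-2.0, 2.0):
                p = [0.0, 0.0, 0.0]
                p[ax] = sign
                verts.append(tuple(p))
        verts = np.array(verts)
        edges = []
        for i, corner in enumerate(_RD_CORNERS):
            for ax in range(3):
                target = [0.0, 0.0, 0.0]
                target[ax] = 2.0 * corner[ax]
                j = next(k for k in range(8, 14)
                         if np.allclose(verts[k], target))
                edges.append((i, j))
        return verts * s, np.array(edges, dtype=np.int64)
    verts, edges = _regular_dodecahedron()
    # scale so the in-cell opening is comparable to the rhombic cell's
    return verts * (s * 1.35), edges


def tessellate_trabecular(region: TriMesh, cell: UnitCellSpec,
                          default_diameter: float = 0.5) -> LatticeModel:
    """Fill a closed region with the trabecular-like strut wireframe.

    Cells sit on an FCC grid in the (possibly rotated) cell frame anchored
    at the region centroid; edges are kept when both endpoints fall inside
    the region, and the largest connected component is returned.
    """
    if not region.is_watertight():
        raise InvalidParameterError("region mesh must be watertight")
    s = cell.pore_diameter / OPENING_FACTOR
    pitch = 4.0 * s
    R = cell.rotation()
    centroid = region.centroid()
    local = (region.vertices - centroid) @ R.T
    lo = local.min(axis=0) - 0.75 * pitch
    hi = local.max(axis=0) + 0.75 * pitch
    if np.any(hi - lo < pitch):
        raise EmptyLatticeError("region smaller than one cell pitch")

    base_lo = np.floor(lo / pitch).astype(int)
    base_hi = np.ceil(hi / pitch).astype(int)
    cell_verts, cell_edge_idx = _cell_edges(cell.cell_kind, s)

    points: list[np.ndarray] = []
    raw_edges: list[tuple[int, int]] = []
    for i in range(base_lo[0], base_hi[0] + 1):
        for j in range(base_lo[1], base_hi[1] + 1):
            for k in range(base_lo[2], base_hi[2] + 1):
                for off in _FCC_OFFSETS:
                    center = (np.array([i, j, k], dtype=np.float64) * pitch
                              + off * s)
                    if np.any(center < lo) or np.any(center > hi):
                        continue
                    base = len(points)
                    world = (cell_verts + center) @ R + centroid
                    points.extend(world)
                    raw_edges.extend((base + a, base + b)
                                     for a, b in cell_edge_idx)
    if not points:
        raise EmptyLatticeError("no cells generated")
    if cell.cell_kind == "regular_dodecahedron_wireframe":
        points, raw_edges = _snap_points(points, raw_edges,
                                         cell.pore_diameter / 10.0)
    nodes, edges = _dedup_edges(points, raw_edges)

    inside = region.contains(nodes)
    mids = 0.5 * (nodes[edges[:, 0]] + nodes[edges[:, 1]])
    keep = region.contains(mids)
    edges = edges[keep]
    if not len(edges):
        raise EmptyLatticeError("region too small to host one cell")
    nodes, edges = _clip_edges_to_region(region, nodes, edges, inside)
    lat = LatticeModel(nodes, edges,
                       np.full(len(edges), default_diameter),
                       ["trabecular"] * len(edges),
                       provenance={"cell_kind": cell.cell_kind,
                                   "pore_diameter": cell.pore_diameter})
    return lat.largest_component()


def _clip_edges_to_region(region: TriMesh, nodes: np.ndarray,
                          edges: np.ndarray, inside: np.ndarray,
                          iters: int = 20) -> tuple[np.ndarray, np.ndarray]:
    """Pull strut endpoints that poke outside the region back onto its
    surface by bisecting along the strut toward its (interior) midpoint."""
    mids = 0.5 * (nodes[edges[:, 0]] + nodes[edges[:, 1]])
    new_nodes = list(nodes)
    new_edges = edges.copy()
    # collect all (edge, end) pairs needing a clip, bisect them as a batch
    jobs = []
    for col in (0, 1):
        for ei in np.where(~inside[edges[:, col]])[0]:
            jobs.append((int(ei), col))
    if jobs:
        lo = np.array([mids[ei] for ei, _ in jobs])           # inside
        hi = np.array([nodes[edges[ei, col]] for ei, col in jobs])  # outside
        for _ in range(iters):
            mid = 0.5 * (lo + hi)
            isin = region.contains(mid)
            lo[isin] = mid[isin]
            hi[~isin] = mid[~isin]
        for (ei, col), p in zip(jobs, 0.5 * (lo + hi)):
            new_edges[ei, col] = len(new_nodes)
            new_nodes.append(p)
    nodes = np.array(new_nodes)
    # clipping may have split shared outside vertices; merge coincident ones
    pts = [nodes[i] for i in range(len(nodes))]
    raw = [tuple(e) for e in new_edges]
    return _dedup_edges(pts, raw)


def _snap_points(points, raw_edges, tol):
    """Cluster nearby points (vertex snapping for non-tessellating cells)."""
    pts = np.asarray(points)
    tree = cKDTree(pts)
    groups = tree.query_ball_point(pts, tol)
    canon = np.arange(len(pts))
    for i, grp in enumerate(groups):
        canon[i] = min(grp + [canon[i]])
    merged = pts.copy()
    for i in range(len(pts)):
        merged[i] = pts[canon[i]]
    return list(merged), raw_edges


def cell_openings(lattice: LatticeModel, cell: UnitCellSpec,
                  region: TriMesh) -> np.ndarray:
    """In-cell pore opening (2x clearance from cell centre to the nearest
    strut axis) for every interior cell; used to verify the pore scale."""
    from .geometry import segment_point_distance
    s = cell.pore_diameter / OPENING_FACTOR
    pitch = 4.0 * s
    R = cell.rotation()
    centroid = region.centroid()
    local = (region.vertices - centroid) @ R.T
    lo, hi = local.min(axis=0), local.max(axis=0)
    centers = []
    rng0 = np.floor(lo / pitch).astype(int)
    rng1 = np.ceil(hi / pitch).astype(int)
    for i in range(rng0[0], rng1[0] + 1):
        for j in range(rng0[1], rng1[1] + 1):
            for k in range(rng0[2], rng1[2] + 1):
                for off in _FCC_OFFSETS:
                    centers.append(np.array([i, j, k]) * pitch + off * s)
    centers = np.array(centers) @ R + centroid
    # interior cells only: centre at least one pitch from the surface
    inside = region.contains(centers)
    margin = region.distance_to_surface(centers) > 0.5 * pitch
    centers = centers[inside & margin]
    a, b, _ = lattice.segments()
    out = []
    for c in centers:
        d = np.inf
        for i in range(len(a)):
            d = min(d, float(segment_point_distance(c[None], a[i], b[i])[0]))
        if np.isfinite(d):
            out.append(2.0 * d)
    return np.array(out)


# ---------------------------------------------------------------------------
# grid shell
# ---------------------------------------------------------------------------

def _polyline_crossings(poly: np.ndarray, axis: int,
                        values: np.ndarray) -> list[tuple[float, np.ndarray]]:
    """(arc-length parameter, point) where the polyline crosses each plane."""
    out = []
    seg = np.linalg.norm(np.diff(poly, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    coord = poly[:, axis]
    for v in values:
        d = coord - v
        for i in range(len(poly) - 1):
            if d[i] == 0.0:
                out.append((arc[i], poly[i].copy()))
            elif d[i] * d[i + 1] < 0:
                t = d[i] / (d[i] - d[i + 1])
                out.append((arc[i] + t * seg[i],
                            poly[i] + t * (poly[i + 1] - poly[i])))
    return out


def _arc_between(poly, arc, s0, s1):
    """Sub-polyline of `poly` between arc-length parameters s0 < s1."""
    pts = []
    for i in range(len(poly)):
        if s0 < arc[i] < s1:
            pts.append(poly[i])
    p0 = _interp_at(poly, arc, s0)
    p1 = _interp_at(poly, arc, s1)
    return np.vstack([p0, *pts, p1]) if pts else np.vstack([p0, p1])


def _interp_at(poly, arc, s):
    i = int(np.searchsorted(arc, s, side="right")) - 1
    i = min(max(i, 0), len(poly) - 2)
    denom = arc[i + 1] - arc[i]
    t = 0.0 if denom <= 0 else (s - arc[i]) / denom
    return poly[i] + t * (poly[i + 1] - poly[i])


def build_grid_shell(region: TriMesh, cell: UnitCellSpec,
                     default_diameter: float = 0.5,
                     simplify_tol: float = 0.08,
                     feature_angle: float = 40.0) -> LatticeModel:
    """Trace a quadrilateral strut grid on the region's outer surface.

    Three orthogonal families of slicing planes spaced one pore apart cut
    the surface into on-surface curves; sharp feature edges are added as a
    fourth curve set.  Curve/curve crossings become grid nodes and the arcs
    between them become struts (polyline-subdivided so they stay on the
    surface, then simplified).
    """
    if not region.is_watertight():
        raise InvalidParameterError("region mesh must be watertight")
    pore = cell.pore_diameter
    bmin, bmax = region.bounds()

    plane_values = []
    for ax in range(3):
        vals = np.arange(bmin[ax] + pore, bmax[ax] - 0.1 * pore, pore)
        vals = vals[vals > bmin[ax] + 0.1 * pore]
        plane_values.append(vals)

    curves = []  # (points, closed, kind, axis)
    for ax in range(3):
        for v in plane_values[ax]:
            for poly in region.slice_plane(ax, float(v)):
                closed = bool(np.allclose(poly[0], poly[-1]))
                if len(poly) >= 2:
                    curves.append([poly, closed, "slice", ax])

    # feature chains
    feat = region.feature_edges(feature_angle)
    for chain, closed in _chain_feature_edges(region, feat):
        curves.append([chain, closed, "feature", -1])

    # collect crossing points per curve
    crossing_records = []          # (curve index, arc parameter, point)
    all_points = []
    for ci, (poly, closed, kind, ax) in enumerate(curves):
        hits = []
        for other_ax in range(3):
            if other_ax == ax:
                continue
            hits.extend(_polyline_crossings(poly, other_ax,
                                            plane_values[other_ax]))
        if not closed:
            seg = np.linalg.norm(np.diff(poly, axis=0), axis=1)
            arc = np.concatenate([[0.0], np.cumsum(seg)])
            hits.append((0.0, poly[0].copy()))
            hits.append((float(arc[-1]), poly[-1].copy()))
        for s, p in hits:
            crossing_records.append((ci, s, p))
            all_points.append(p)

    if not all_points:
        raise EmptyLatticeError("no grid curves generated on the surface")

    # cluster crossing points into canonical nodes
    all_points = np.array(all_points)
    tol = 0.05 * pore
    tree = cKDTree(all_points)
    pairs = tree.query_pairs(tol)
    parent = list(range(len(all_points)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in sorted(pairs):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)
    canonical = {}
    for i in range(len(all_points)):
        r = find(i)
        canonical.setdefault(r, all_points[r])

    points: list[np.ndarray] = []
    raw_edges: list[tuple[int, int]] = []

    def add_point(p) -> int:
        points.append(np.asarray(p, dtype=np.float64))
        return len(points) - 1

    rec_by_curve: dict[int, list[tuple[float, int]]] = {}
    for ri, (ci, s, _p) in enumerate(crossing_records):
        rec_by_curve.setdefault(ci, []).append((s, find(ri)))

    root_node: dict[int, int] = {}

    def node_for(root) -> int:
        if root not in root_node:
            root_node[root] = add_point(canonical[root])
        return root_node[root]

    for ci, (poly, closed, kind, ax) in enumerate(curves):
        seg = np.linalg.norm(np.diff(poly, axis=0), axis=1)
        arc = np.concatenate([[0.0], np.cumsum(seg)])
        total = float(arc[-1])
        if total <= 0:
            continue
        recs = sorted(set(rec_by_curve.get(ci, [])))
        # drop parameter-duplicates mapping to the same canonical node
        cleaned = []
        for s, root in recs:
            if cleaned and (s - cleaned[-1][0] < tol
                            and root == cleaned[-1][1]):
                continue
            cleaned.append((s, root))
        recs = cleaned
        if not recs:
            if closed:  # free ring: keep as a closed strut loop
                ring = simplify_polyline(poly, simplify_tol)
                ids = [add_point(p) for p in ring[:-1]]
                for i in range(len(ids)):
                    raw_edges.append((ids[i], ids[(i + 1) % len(ids)]))
            continue
        spans = []
        for i in range(len(recs) - 1):
            spans.append((recs[i], recs[i + 1]))
        if closed and len(recs) >= 1:
            spans.append((recs[-1], (recs[0][0] + total, recs[0][1])))
        for (s0, r0), (s1, r1) in spans:
            if s1 - s0 < tol:
                if r0 != r1:
                    raw_edges.append((node_for(r0), node_for(r1)))
                continue
            if s1 <= total:
                piece = _arc_between(poly, arc, s0, s1)
            else:  # wrap-around span on a closed curve
                a1 = _arc_between(poly, arc, s0, total)
                a2 = _arc_between(poly, arc, 0.0, s1 - total)
                piece = np.vstack([a1, a2[1:]])
            piece = simplify_polyline(piece, simplify_tol)
            ids = [node_for(r0)]
            for p in piece[1:-1]:
                ids.append(add_point(p))
            ids.append(node_for(r1))
            for i in range(len(ids) - 1):
                raw_edges.append((ids[i], ids[i + 1]))

    nodes, edges = _dedup_edges(points, raw_edges)
    if not len(edges):
        raise EmptyLatticeError("grid shell generation produced no struts")
    lat = LatticeModel(nodes, edges, np.full(len(edges), default_diameter),
                       ["grid"] * len(edges),
                       provenance={"pore_diameter": pore})
    lat.collapse_short_struts(0.06 * pore)
    lat.connect_components(tag="grid", diameter=default_diameter)
    return lat


def _chain_feature_edges(region: TriMesh, feat: np.ndarray):
    """Chain feature mesh edges into polylines, breaking at junctions."""
    if not len(feat):
        return []
    g = nx.Graph()
    g.add_edges_from(map(tuple, feat))
    chains = []
    visited = set()

    def emit(path):
        pts = region.vertices[np.array(path)]
        closed = path[0] == path[-1]
        chains.append((pts, closed))

    breakpoints = [n for n in g if g.degree(n) != 2]
    for start in sorted(breakpoints):
        for nb in sorted(g.neighbors(start)):
            if (start, nb) in visited or (nb, start) in visited:
                continue
            path = [start, nb]
            visited.add((start, nb))
            while g.degree(path[-1]) == 2:
                nxts = [m for m in g.neighbors(path[-1]) if m != path[-2]]
                if not nxts:
                    break
                visited.add((path[-1], nxts[0]))
                path.append(nxts[0])
                if path[-1] == start:
                    break
            emit(path)
    # pure loops (all degree 2)
    for comp in nx.connected_components(g):
        if any(n in breakpoints for n in comp):
            continue
        comp = sorted(comp)
        cycle = nx.cycle_basis(g.subgraph(comp))
        for cyc in cycle:
            emit(cyc + [cyc[0]])
    return chains


def merge_components(trabecular: LatticeModel, grid: LatticeModel,
                     snap_tol: float | None = None) -> LatticeModel:
    """Merge the trabecular core and grid shell into one connected lattice."""
    pore = trabecular.provenance.get("pore_diameter", 5.0)
    if snap_tol is None:
        snap_tol = pore / 10.0
    merged = trabecular.copy()
    merged.append(grid, snap_tol=snap_tol)
    merged.provenance.update(grid.provenance)
    merged.collapse_short_struts(0.06 * pore)
    merged.connect_components(tag="grid")
    merged._validate()
    return merged


# ---------------------------------------------------------------------------
# gradient diameters and fixation
# ---------------------------------------------------------------------------

def assign_gradient_diameters(lattice: LatticeModel,
                              spec: StrutSpec) -> LatticeModel:
    """Linear diameter law along the gradient axis.

    d(t) = d_min + (d_max - d_min) * t with t the strut midpoint's
    normalised coordinate measured from the top (t = 0) to the bottom
    (t = 1) of the lattice along ``spec.gradient_axis``.  Applies to
    trabecular and grid struts; fixation struts are left untouched.
    """
    if lattice.n_struts == 0:
        raise EmptyLatticeError("cannot grade an empty lattice")
    out = lattice.copy()
    mask = np.array([t in ("trabecular", "grid") for t in out.tags])
    proj = out.midpoints() @ spec.gradient_axis
    lo, hi = proj[mask].min(), proj[mask].max()
    if hi - lo < 1e-12:
        out.diameters[mask] = 0.5 * (spec.d_min + spec.d_max)
    else:
        t = (proj - lo) / (hi - lo)
        d = spec.d_min + (spec.d_max - spec.d_min) * t
        out.diameters[mask] = d[mask]
    out.provenance["strut_spec"] = {"d_min": spec.d_min, "d_max": spec.d_max,
                                    "gradient_axis":
                                        spec.gradient_axis.tolist()}
    return out


def place_fixation(lattice: LatticeModel, fixture, spec: FixationSpec
                   ) -> LatticeModel:
    """Add two retainer strut frames and the fixation screws.

    Retainer frames trace each stump cut plane's perimeter with spokes to
    its centre; screws are 8 mm struts driven outward (into residual bone)
    from evenly spaced perimeter nodes.  Retainer struts take the largest
    lattice diameter; screws take ``spec.screw_diameter``.
    """
    out = lattice.copy()
    d_ret = float(out.diameters.max()) if len(out.diameters) else 0.8
    n_lattice_nodes = len(out.nodes)
    pore = out.provenance.get("pore_diameter", 5.0)
    dv = fixture.defect_region.vertices
    for side, ids in enumerate(fixture.stump_faces):
        pts = dv[ids]
        center = pts.mean(axis=0)
        radial = np.linalg.norm(pts - center, axis=1)
        ring_ids = ids[radial > 1e-6]
        ring = dv[ring_ids]
        ang = np.arctan2(ring[:, 2] - center[2], ring[:, 1] - center[1])
        order = np.argsort(ang, kind="stable")
        ring = ring[order]
        n_ring = len(ring)

        base = len(out.nodes)
        out.nodes = np.vstack([out.nodes, ring, center[None]])
        new_edges, new_d, new_t = [], [], []
        for i in range(n_ring):
            new_edges.append((base + i, base + (i + 1) % n_ring))
            new_d.append(d_ret)
            new_t.append("retainer")
        for i in range(0, n_ring, max(1, n_ring // 6)):
            new_edges.append((base + i, base + n_ring))
            new_d.append(d_ret)
            new_t.append("retainer")

        n_screws = spec.screws_per_side
        if n_ring < n_screws:
            warnings.warn(f"stump face {side}: only {n_ring} perimeter nodes "
                          f"for {n_screws} screws; reducing", stacklevel=2)
            n_screws = max(1, n_ring)
        direction = np.array([-1.0, 0.0, 0.0]) if side == 0 \
            else np.array([1.0, 0.0, 0.0])
        picks = np.linspace(0, n_ring, n_screws, endpoint=False).astype(int)
        for p in picks:
            head = base + int(p)
            tip = out.nodes[head] + spec.screw_length * direction
            out.nodes = np.vstack([out.nodes, tip[None]])
            new_edges.append((head, len(out.nodes) - 1))
            new_d.append(spec.screw_diameter)
            new_t.append("screw")
        # distribute stump load into the lattice: every ring node gets short
        # transfer struts to its two nearest lattice nodes
        tree = cKDTree(out.nodes[:n_lattice_nodes])
        dist, near = tree.query(ring, k=2)
        for i in range(n_ring):
            for j in range(2):
                if dist[i, j] < pore:
                    new_edges.append((base + i, int(near[i, j])))
                    new_d.append(d_ret)
                    new_t.append("retainer")
        out.edges = np.vstack([out.edges, np.array(new_edges)])
        out.diameters = np.concatenate([out.diameters, new_d])
        out.tags.extend(new_t)
    out.collapse_short_struts(0.05)
    out.connect_components(tag="retainer", diameter=d_ret)
    out.provenance["fixation"] = {
        "retainer_thickness": spec.retainer_thickness,
        "screw_length": spec.screw_length,
        "screws_per_side": spec.screws_per_side}
    return out


# ---------------------------------------------------------------------------
# boolean graft region and surface export
# ---------------------------------------------------------------------------

@dataclass
class VoxelGrid:
    """Hexahedral voxel partition of a region with respect to a lattice."""

    origin: np.ndarray
    voxel_mm: float
    shape: tuple[int, int, int]
    region_mask: np.ndarray        # (nx, ny, nz) inside the region
    strut_mask: np.ndarray         # inside region AND inside a capsule

    @property
    def graft_mask(self) -> np.ndarray:
        return self.region_mask & ~self.strut_mask

    def centers(self, mask: np.ndarray) -> np.ndarray:
        ijk = np.argwhere(mask)
        return self.origin + (ijk + 0.5) * self.voxel_mm

    def graft_volume(self) -> float:
        return float(self.graft_mask.sum()) * self.voxel_mm ** 3

    def region_volume(self) -> float:
        return float(self.region_mask.sum()) * self.voxel_mm ** 3


def capsule_union_mask(points: np.ndarray, a: np.ndarray, b: np.ndarray,
                       radii: np.ndarray) -> np.ndarray:
    """Boolean membership of each point in the union of strut capsules.

    Prunes by per-capsule bounding box, so cost scales with the occupied
    volume rather than points x struts.
    """
    points = np.atleast_2d(points)
    inside = np.zeros(len(points), dtype=bool)
    for i in range(len(a)):
        lo = np.minimum(a[i], b[i]) - radii[i]
        hi = np.maximum(a[i], b[i]) + radii[i]
        cand = np.where(~inside
                        & np.all((points >= lo) & (points <= hi), axis=1))[0]
        if not len(cand):
            continue
        ab = b[i] - a[i]
        l2 = float(ab @ ab)
        rel = points[cand] - a[i]
        if l2 < 1e-300:
            d2 = np.einsum("ij,ij->i", rel, rel)
        else:
            t = np.clip(rel @ ab / l2, 0.0, 1.0)
            dd = rel - t[:, None] * ab
            d2 = np.einsum("ij,ij->i", dd, dd)
        inside[cand[d2 <= radii[i] ** 2]] = True
    return inside


def boolean_graft_region(region: TriMesh, lattice: LatticeModel,
                         voxel_mm: float) -> VoxelGrid:
    """Voxelize the graft space: inside the region, outside every capsule."""
    if voxel_mm <= 0:
        raise InvalidParameterError("voxel_mm must be positive")
    pore = lattice.provenance.get("pore_diameter")
    if pore is not None and voxel_mm > pore / 4.0 + 1e-12:
        raise ResolutionError(
            f"voxel {voxel_mm} mm too coarse; must be <= pore/4 "
            f"= {pore / 4.0} mm")
    bmin, bmax = region.bounds()
    shape = tuple(int(np.ceil((bmax[i] - bmin[i]) / voxel_mm))
                  for i in range(3))
    if min(shape) < 2:
        raise ResolutionError("voxel grid degenerate along one axis")
    ijk = np.stack(np.meshgrid(*[np.arange(s) for s in shape],
                               indexing="ij"), axis=-1).reshape(-1, 3)
    centers = bmin + (ijk + 0.5) * voxel_mm
    region_mask = region.contains(centers).reshape(shape)
    strut_mask = np.zeros(shape, dtype=bool)
    if lattice.n_struts:
        a, b, r = lattice.segments()
        inside_caps = capsule_union_mask(centers, a, b, r).reshape(shape)
        strut_mask = region_mask & inside_caps
    return VoxelGrid(np.asarray(bmin, dtype=np.float64), float(voxel_mm),
                     shape, region_mask, strut_mask)


def lattice_to_surface(lattice: LatticeModel,
                       segments_per_circle: int = 12) -> TriMesh:
    """Triangulated capsule-union surface, watertight, for STL export.

    Extracted by marching cubes from the union signed-distance field; the
    sampling pitch follows ``segments_per_circle`` (arc length of the
    thinnest strut circle), floored to keep the grid tractable.
    """
    from skimage.measure import marching_cubes

    if segments_per_circle < 6:
        raise InvalidParameterError("segments_per_circle must be >= 6")
    if lattice.n_struts == 0:
        raise EmptyLatticeError("cannot surface an empty lattice")
    a, b, r = lattice.segments()
    d_min = float(lattice.diameters.min())
    lo = np.minimum(a, b).min(axis=0) - r.max() * 2
    hi = np.maximum(a, b).max(axis=0) + r.max() * 2
    pitch = np.pi * d_min / segments_per_circle
    pitch = max(pitch, float(np.max(hi - lo)) / 400.0)
    nsteps = np.maximum(((hi - lo) / pitch).astype(int) + 2, 4)
    xs = [lo[i] + np.arange(nsteps[i]) * pitch for i in range(3)]
    vol = np.full(tuple(nsteps), 10.0 * pitch)
    # update the field strut by strut on its bounding sub-grid only
    for i in range(len(a)):
        margin = r[i] + 3 * pitch
        blo = np.minimum(a[i], b[i]) - margin
        bhi = np.maximum(a[i], b[i]) + margin
        i0 = np.maximum(((blo - lo) / pitch).astype(int), 0)
        i1 = np.minimum(((bhi - lo) / pitch).astype(int) + 2, nsteps)
        if np.any(i1 <= i0):
            continue
        sub = np.meshgrid(xs[0][i0[0]:i1[0]], xs[1][i0[1]:i1[1]],
                          xs[2][i0[2]:i1[2]], indexing="ij")
        pts = np.stack([s.ravel() for s in sub], axis=1)
        ab = b[i] - a[i]
        l2 = float(ab @ ab)
        rel = pts - a[i]
        t = np.clip(rel @ ab / l2, 0.0, 1.0) if l2 > 0 else np.zeros(len(pts))
        dd = rel - t[:, None] * ab
        d = (np.sqrt(np.einsum("ij,ij->i", dd, dd)) - r[i]).reshape(
            sub[0].shape)
        view = vol[i0[0]:i1[0], i0[1]:i1[1], i0[2]:i1[2]]
        np.minimum(view, d, out=view)
    verts, faces, _, _ = marching_cubes(vol, level=0.0, spacing=(pitch,) * 3)
    verts = verts + lo
    mesh = TriMesh(verts, faces.astype(np.int64))
    if mesh.volume() < 0:
        mesh.faces = mesh.faces[:, ::-1]
    return mesh


def porosity(lattice: LatticeModel, region: TriMesh) -> float:
    """1 - strut volume / region volume (capsule-sum approximation)."""
    return 1.0 - lattice.strut_volume() / region.volume()
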