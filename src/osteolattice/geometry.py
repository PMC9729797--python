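"""Triangle-mesh primitives: STL I/O, watertightness, volume, containment, slicing.

Everything works in a consistent mm unit system on plain numpy arrays.
The mesh class is deliberately minimal — it is a data carrier with the
handful of geometric queries the lattice generator and the fixtures need,
not a general mesh-processing library.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field

import numpy as np


class STLParseError(ValueError):
    """Malformed STL input; carries the byte offset where parsing failed."""

    def __init__(self, message: str, offset: int = 0):
        super().__init__(f"{message} (byte offset {offset})")
        self.offset = offset


@dataclass
class TriMesh:
    """Indexed triangle surface mesh (vertices in mm, 0-based faces)."""

    vertices: np.ndarray  # (n, 3) float64
    faces: np.ndarray     # (m, 3) int64

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)

    # -- basic measures -------------------------------------------------

    @property
    def triangles(self) -> np.ndarray:
        """(m, 3, 3) corner coordinates."""
        return self.vertices[self.faces]

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        return self.vertices.min(axis=0), self.vertices.max(axis=0)

    def centroid(self) -> np.ndarray:
        return self.vertices.mean(axis=0)

    def edge_counts(self) -> dict[tuple[int, int], int]:
        e = np.concatenate([self.faces[:, [0, 1]], self.faces[:, [1, 2]],
                            self.faces[:, [2, 0]]])
        e = np.sort(e, axis=1)
        keys, counts = np.unique(e, axis=0, return_counts=True)
        return {tuple(k): int(c) for k, c in zip(keys, counts)}

    def is_watertight(self) -> bool:
        """Every undirected edge shared by exactly two triangles."""
        counts = np.fromiter(self.edge_counts().values(), dtype=np.int64)
        return bool(counts.size) and bool(np.all(counts == 2))

    def euler_characteristic(self) -> int:
        used = np.unique(self.faces)
        n_edges = len(self.edge_counts())
        return int(len(used) - n_edges + len(self.faces))

    def volume(self) -> float:
        """Enclosed volume via the divergence theorem (signed tet sum)."""
        t = self.triangles
        return float(np.einsum("ij,ij->i", t[:, 0],
                               np.cross(t[:, 1], t[:, 2])).sum() / 6.0)

    def area(self) -> float:
        t = self.triangles
        return float(0.5 * np.linalg.norm(
            np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0]), axis=1).sum())

    def face_normals(self) -> np.ndarray:
        t = self.triangles
        n = np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0])
        norms = np.linalg.norm(n, axis=1)
        norms[norms == 0] = 1.0
        return n / norms[:, None]

    # -- point queries --------------------------------------------------

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Even-odd ray-cast containment test for a batch of points.

        Uses a fixed irrational ray direction to dodge edge/vertex grazing;
        adequate for the well-shaped closed meshes produced by this package.
        """
        points = np.atleast_2d(np.asarray(points, dtype=np.float64))
        direction = np.array([0.2938541, 0.5583272, 0.7759341])
        direction /= np.linalg.norm(direction)
        tri = self.triangles
        v0, e1, e2 = tri[:, 0], tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]
        h = np.cross(direction, e2)
        a = np.einsum("ij,ij->i", e1, h)
        valid = np.abs(a) > 1e-12
        inv_a = np.where(valid, 1.0 / np.where(valid, a, 1.0), 0.0)
        out = np.zeros(len(points), dtype=bool)
        chunk = max(1, int(4_000_000 / max(len(tri), 1)))
        for s in range(0, len(points), chunk):
            p = points[s:s + chunk]
            sv = p[:, None, :] - v0[None, :, :]            # (p, m, 3)
            u = np.einsum("pmi,mi->pm", sv, h) * inv_a
            q = np.cross(sv, e1[None, :, :])
            v = np.einsum("pmi,i->pm", q, direction) * inv_a
            t = np.einsum("pmi,mi->pm", q, e2) * inv_a
            hit = (valid[None, :] & (u >= 0) & (v >= 0) & (u + v <= 1)
                   & (t > 1e-10))
            out[s:s + chunk] = (hit.sum(axis=1) % 2) == 1
        return out

    def distance_to_surface(self, points: np.ndarray) -> np.ndarray:
        """Unsigned distance from each point to the closest triangle."""
        points = np.atleast_2d(np.asarray(points, dtype=np.float64))
        best = np.full(len(points), np.inf)
        tri = self.triangles
        chunk = max(1, int(2_000_000 / max(len(tri), 1)))
        for s in range(0, len(points), chunk):
            d = _point_triangle_distance(points[s:s + chunk], tri)
            best[s:s + chunk] = d.min(axis=1)
        return best

    def closest_point(self, points: np.ndarray) -> np.ndarray:
        """Closest point on the surface for each query point."""
        points = np.atleast_2d(np.asarray(points, dtype=np.float64))
        tri = self.triangles
        out = np.empty_like(points)
        chunk = max(1, int(1_000_000 / max(len(tri), 1)))
        for s in range(0, len(points), chunk):
            d, cp = _point_triangle_distance(points[s:s + chunk], tri,
                                             return_points=True)
            idx = d.argmin(axis=1)
            out[s:s + chunk] = cp[np.arange(len(idx)), idx]
        return out

    # -- slicing and feature extraction ---------------------------------

    def slice_plane(self, axis: int, value: float) -> list[np.ndarray]:
        """Intersect with the plane ``x[axis] == value``.

        Returns a list of polylines, each an (k, 3) array; closed loops
        repeat their first point at the end.  Crossing points are computed
        once per mesh edge, so adjacent triangles chain exactly.
        """
        d = self.vertices[:, axis] - value
        # nudge vertices sitting exactly on the plane to keep crossings simple
        eps = 1e-9 * max(1.0, abs(value))
        d = np.where(np.abs(d) < eps, eps, d)
        fd = d[self.faces]
        crossing = ~(np.all(fd > 0, axis=1) | np.all(fd < 0, axis=1))
        segments = []
        for f in self.faces[crossing]:
            pts = []
            for i, j in ((0, 1), (1, 2), (2, 0)):
                a, b = f[i], f[j]
                if d[a] * d[b] < 0:
                    lo, hi = (a, b) if a < b else (b, a)
                    t = d[lo] / (d[lo] - d[hi])
                    pts.append((lo, hi, tuple(self.vertices[lo]
                                              + t * (self.vertices[hi]
                                                     - self.vertices[lo]))))
            if len(pts) == 2:
                segments.append((pts[0][:2], pts[1][:2],
                                 pts[0][2], pts[1][2]))
        return _chain_segments(segments)

    def feature_edges(self, angle_deg: float = 40.0) -> np.ndarray:
        """Mesh edges whose dihedral angle exceeds ``angle_deg``; (k, 2) ids."""
        e = np.concatenate([self.faces[:, [0, 1]], self.faces[:, [1, 2]],
                            self.faces[:, [2, 0]]])
        owner = np.tile(np.arange(len(self.faces)), 3)
        order = np.lexsort((np.sort(e, axis=1)[:, 1], np.sort(e, axis=1)[:, 0]))
        e_sorted = np.sort(e, axis=1)[order]
        owner = owner[order]
        normals = self.face_normals()
        out = []
        i = 0
        cos_thresh = np.cos(np.radians(angle_deg))
        while i + 1 < len(e_sorted):
            if np.array_equal(e_sorted[i], e_sorted[i + 1]):
                c = float(normals[owner[i]] @ normals[owner[i + 1]])
                if c < cos_thresh:
                    out.append(e_sorted[i])
                i += 2
            else:
                i += 1
        return (np.array(out, dtype=np.int64) if out
                else np.empty((0, 2), dtype=np.int64))

    # -- I/O ------------------------------------------------------------

    def save_stl(self, path, ascii: bool = False, name: str = "osteolattice"):
        tri = self.triangles.astype(np.float32)
        normals = self.face_normals().astype(np.float32)
        if ascii:
            with open(path, "w") as fh:
                fh.write(f"solid {name}\n")
                for n, t in zip(normals, tri):
                    fh.write(f"  facet normal {n[0]:.9e} {n[1]:.9e} {n[2]:.9e}\n")
                    fh.write("    outer loop\n")
                    for v in t:
                        fh.write(f"      vertex {v[0]:.9e} {v[1]:.9e} {v[2]:.9e}\n")
                    fh.write("    endloop\n  endfacet\n")
                fh.write(f"endsolid {name}\n")
        else:
            with open(path, "wb") as fh:
                fh.write(name.encode().ljust(80, b"\0")[:80])
                fh.write(struct.pack("<I", len(tri)))
                rec = np.zeros(len(tri), dtype=[("n", "<f4", 3),
                                                ("v", "<f4", (3, 3)),
                                                ("attr", "<u2")])
                rec["n"], rec["v"] = normals, tri
                fh.write(rec.tobytes())


def load_stl(path) -> TriMesh:
    """Read a binary or ASCII STL file into an indexed TriMesh.

    Duplicate vertices are merged exactly (bitwise), which is sufficient to
    reconstruct topology for meshes written by this package.
    """
    with open(path, "rb") as fh:
        data = fh.read()
    if len(data) < 15:
        raise STLParseError("file too short to be STL", len(data))
    is_ascii = data.lstrip()[:5] == b"solid"
    if is_ascii:
        # heuristic guard: binary files may also start with 'solid'
        try:
            text = data.decode("ascii")
        except UnicodeDecodeError:
            is_ascii = False
        else:
            if "facet" not in text and "endsolid" not in text:
                is_ascii = False
    if is_ascii:
        tri = _parse_ascii_stl(data.decode("ascii"))
    else:
        if len(data) < 84:
            raise STLParseError("binary STL truncated before facet count", len(data))
        (n_facets,) = struct.unpack_from("<I", data, 80)
        expected = 84 + 50 * n_facets
        if len(data) < expected:
            raise STLParseError(
                f"facet count {n_facets} implies {expected} bytes, got {len(data)}",
                len(data))
        rec = np.frombuffer(data, dtype=[("n", "<f4", 3), ("v", "<f4", (3, 3)),
                                         ("attr", "<u2")], count=n_facets,
                            offset=84)
        tri = rec["v"].astype(np.float64)
    return _soup_to_mesh(tri)


def _parse_ascii_stl(text: str) -> np.ndarray:
    tri, current = [], []
    offset = 0
    for line in text.splitlines(keepends=True):
        stripped = line.strip()
        if stripped.startswith("vertex"):
            parts = stripped.split()
            if len(parts) != 4:
                raise STLParseError("malformed vertex line", offset)
            try:
                current.append([float(p) for p in parts[1:]])
            except ValueError:
                raise STLParseError("non-numeric vertex coordinate", offset)
        elif stripped.startswith("endfacet"):
            if len(current) != 3:
                raise STLParseError(
                    f"facet with {len(current)} vertices", offset)
            tri.append(current)
            current = []
        offset += len(line)
    if current:
        raise STLParseError("dangling facet at end of file", offset)
    return np.array(tri, dtype=np.float64).reshape(-1, 3, 3)


def _soup_to_mesh(tri: np.ndarray) -> TriMesh:
    flat = tri.reshape(-1, 3)
    verts, inv = np.unique(flat, axis=0, return_inverse=True)
    return TriMesh(verts, inv.reshape(-1, 3))


def _point_triangle_distance(points, tri, return_points=False):
    """Distance from each point to each triangle; (p, m) matrix.

    Vectorised Ericson-style closest-point-on-triangle.
    """
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab, ac = b - a, c - a
    p = points[:, None, :]
    ap = p - a[None]
    d1 = np.einsum("mi,pmi->pm", ab, ap)
    d2 = np.einsum("mi,pmi->pm", ac, ap)
    bp = p - b[None]
    d3 = np.einsum("mi,pmi->pm", ab, bp)
    d4 = np.einsum("mi,pmi->pm", ac, bp)
    cp = p - c[None]
    d5 = np.einsum("mi,pmi->pm", ab, cp)
    d6 = np.einsum("mi,pmi->pm", ac, cp)

    va = d3 * d6 - d5 * d4
    vb = d5 * d2 - d1 * d6
    vc = d1 * d4 - d3 * d2
    denom = va + vb + vc
    denom = np.where(np.abs(denom) < 1e-300, 1.0, denom)
    v = vb / denom
    w = vc / denom
    # interior projection
    closest = a[None] + v[..., None] * ab[None] + w[..., None] * ac[None]

    # vertex regions
    closest = np.where(((d1 <= 0) & (d2 <= 0))[..., None],
                       np.broadcast_to(a[None], closest.shape), closest)
    closest = np.where(((d3 >= 0) & (d4 <= d3))[..., None],
                       np.broadcast_to(b[None], closest.shape), closest)
    closest = np.where(((d6 >= 0) & (d5 <= d6))[..., None],
                       np.broadcast_to(c[None], closest.shape), closest)
    # edge AB
    t_ab = np.clip(np.where(np.abs(d1 - d3) > 1e-300, d1 / (d1 - d3), 0.0), 0, 1)
    on_ab = (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    closest = np.where(on_ab[..., None],
                       a[None] + t_ab[..., None] * ab[None], closest)
    # edge AC
    t_ac = np.clip(np.where(np.abs(d2 - d6) > 1e-300, d2 / (d2 - d6), 0.0), 0, 1)
    on_ac = (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    closest = np.where(on_ac[..., None],
                       a[None] + t_ac[..., None] * ac[None], closest)
    # edge BC
    num = d4 - d3
    den = (d4 - d3) + (d5 - d6)
    t_bc = np.clip(np.where(np.abs(den) > 1e-300, num / den, 0.0), 0, 1)
    on_bc = (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
    closest = np.where(on_bc[..., None],
                       b[None] + t_bc[..., None] * (c - b)[None], closest)

    dist = np.linalg.norm(p - closest, axis=2)
    if return_points:
        return dist, closest
    return dist


def _chain_segments(segments) -> list[np.ndarray]:
    """Chain (edge-keyed) segments into polylines.

    Each segment carries the mesh-edge keys of its endpoints, so matching is
    exact (no floating-point tolerance needed).
    """
    if not segments:
        return []
    adjacency: dict = {}
    coords: dict = {}
    for ka, kb, pa, pb in segments:
        coords[ka] = pa
        coords[kb] = pb
        adjacency.setdefault(ka, []).append(kb)
        adjacency.setdefault(kb, []).append(ka)
    visited = set()
    polylines = []
    for start in sorted(adjacency):
        if start in visited:
            continue
        # walk to an end (open chain) or loop back
        chain = [start]
        visited.add(start)
        cur = start
        extended = True
        while extended:
            extended = False
            for nxt in adjacency[cur]:
                if nxt not in visited:
                    chain.append(nxt)
                    visited.add(nxt)
                    cur = nxt
                    extended = True
                    break
        # try extending backwards (open chains)
        cur = start
        extended = True
        while extended:
            extended = False
            for nxt in adjacency[cur]:
                if nxt not in visited:
                    chain.insert(0, nxt)
                    visited.add(nxt)
                    cur = nxt
                    extended = True
                    break
        pts = np.array([coords[k] for k in chain])
        if len(chain) > 2 and chain[0] in adjacency[chain[-1]]:
            pts = np.vstack([pts, pts[:1]])  # close the loop
        polylines.append(pts)
    return polylines


def simplify_polyline(points: np.ndarray, tol: float) -> np.ndarray:
    """Douglas-Peucker simplification; keeps endpoints, tolerance in mm."""
    points = np.asarray(points, dtype=np.float64)
    if len(points) < 3:
        return points
    keep = np.zeros(len(points), dtype=bool)
    keep[0] = keep[-1] = True
    stack = [(0, len(points) - 1)]
    while stack:
        i, j = stack.pop()
        if j <= i + 1:
            continue
        a, b = points[i], points[j]
        ab = b - a
        l2 = ab @ ab
        seg = points[i + 1:j]
        if l2 < 1e-300:
            d = np.linalg.norm(seg - a, axis=1)
        else:
            t = np.clip((seg - a) @ ab / l2, 0, 1)
            d = np.linalg.norm(seg - a - t[:, None] * ab, axis=1)
        k = int(d.argmax())
        if d[k] > tol:
            keep[i + 1 + k] = True
            stack.append((i, i + 1 + k))
            stack.append((i + 1 + k, j))
    return points[keep]


def segment_point_distance(points: np.ndarray, a: np.ndarray,
                           b: np.ndarray) -> np.ndarray:
    """Distance from each point to segment ab."""
    points = np.atleast_2d(points)
    ab = b - a
    l2 = float(ab @ ab)
    if l2 < 1e-300:
        return np.linalg.norm(points - a, axis=1)
    t = np.clip((points - a) @ ab / l2, 0.0, 1.0)
    return np.linalg.norm(points - a - t[:, None] * ab, axis=1)


def min_capsule_distance(points: np.ndarray, seg_a: np.ndarray,
                         seg_b: np.ndarray, radii: np.ndarray) -> np.ndarray:
    """Signed distance from points to a union of capsules (< 0 inside)."""
    points = np.atleast_2d(points)
    best = np.full(len(points), np.inf)
    for a, b, r in zip(seg_a, seg_b, radii):
        d = segment_point_distance(points, a, b) - r
        np.minimum(best, d, out=best)
    return best
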