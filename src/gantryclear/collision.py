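"""Minimum-distance and intersection queries between triangle meshes.

The clearance quantity driving the whole safety check is the exact
surface-to-surface Euclidean distance between two triangle meshes.  It is
computed from closed-form triangle-triangle distance (the minimum over
edge-edge and vertex-face candidates, zero when the triangles cross) in two
flavours:

* :func:`brute_force_distance` — exhaustive over all triangle pairs; the
  reference oracle used by the property tests and by fixture labelling;
* :func:`min_distance` — the same primitive accelerated by axis-aligned
  bounding-box trees with branch-and-bound pruning, seeded with the closest
  vertex-pair distance as an upper bound.

Both operate on ``trimesh.Trimesh`` objects with coordinates in mm.
"""

from __future__ import annotations

import enum
import heapq
from dataclasses import dataclass

import numpy as np
import trimesh

__all__ = [
    "CollisionType",
    "ClearancePair",
    "NotMonitoredError",
    "min_distance",
    "intersects",
    "brute_force_distance",
    "classify_pair",
    "point_mesh_distance",
]

_EPS = 1e-12
_CHUNK = 32768


class CollisionType(enum.Enum):
    """The four collision scenarios monitored for a half-gantry system."""

    type1_gantry_vs_couch = 1
    type2_gantry_vs_patient = 2
    type3_gantry_vs_pps_arm = 3
    type4_gantry_vs_immobilization = 4


class NotMonitoredError(ValueError):
    """Raised when a component pair is not part of the monitored set."""


@dataclass(frozen=True)
class ClearancePair:
    """Closest approach between two named components."""

    component_a: str
    component_b: str
    distance: float  # mm, >= 0
    point_a: np.ndarray
    point_b: np.ndarray
    type: CollisionType | None = None


# gantry-side hazards vs. the surfaces they are checked against
_GANTRY_SIDE = {"gantry_head", "touch_guard", "range_shifter"}
_PPS_KINDS = {"pps_base_lower_arm", "pps_upper_arm_knuckle"}


def classify_pair(kind_a: str, role_or_kind_b: str) -> CollisionType:
    """Map a monitored (gantry-side, obstacle) pair to its collision type.

    ``kind_a`` must be a gantry-side component kind; ``role_or_kind_b`` is
    either a machine component kind (couch top, PPS arms) or a patient
    structure role (body, immobilization, bolus_device).
    """
    if kind_a not in _GANTRY_SIDE:
        raise NotMonitoredError(
            f"pair ({kind_a!r}, {role_or_kind_b!r}) is not monitored: "
            f"first element must be one of {sorted(_GANTRY_SIDE)}"
        )
    b = role_or_kind_b
    if b == "couch_top":
        return CollisionType.type1_gantry_vs_couch
    if b == "body":
        return CollisionType.type2_gantry_vs_patient
    if b in _PPS_KINDS:
        return CollisionType.type3_gantry_vs_pps_arm
    if b in ("immobilization", "bolus_device"):
        return CollisionType.type4_gantry_vs_immobilization
    raise NotMonitoredError(f"pair ({kind_a!r}, {b!r}) is not monitored")


# ---------------------------------------------------------------------------
# vectorized primitives
# ---------------------------------------------------------------------------

def _dot(a, b):
    return np.einsum("...i,...i->...", a, b)


def closest_point_on_triangles(p: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Closest point on triangle ``tri[k]`` to point ``p[k]``, vectorized.

    Region classification after Ericson's real-time collision detection
    formulation, written with masks instead of branches.
    """
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab = b - a
    ac = c - a
    ap = p - a
    d1 = _dot(ab, ap)
    d2 = _dot(ac, ap)
    bp = p - b
    d3 = _dot(ab, bp)
    d4 = _dot(ac, bp)
    cp = p - c
    d5 = _dot(ab, cp)
    d6 = _dot(ac, cp)

    out = np.empty_like(p)
    done = np.zeros(len(p), dtype=bool)

    # vertex regions
    m = (d1 <= 0) & (d2 <= 0)
    out[m] = a[m]
    done |= m
    m = (~done) & (d3 >= 0) & (d4 <= d3)
    out[m] = b[m]
    done |= m
    m = (~done) & (d6 >= 0) & (d5 <= d6)
    out[m] = c[m]
    done |= m

    # edge AB
    vc = d1 * d4 - d3 * d2
    m = (~done) & (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    v = np.where(np.abs(d1 - d3) > _EPS, d1 / np.where(m, d1 - d3, 1.0), 0.0)
    out[m] = a[m] + np.clip(v[m], 0, 1)[:, None] * ab[m]
    done |= m

    # edge AC
    vb = d5 * d2 - d1 * d6
    m = (~done) & (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    w = np.where(np.abs(d2 - d6) > _EPS, d2 / np.where(m, d2 - d6, 1.0), 0.0)
    out[m] = a[m] + np.clip(w[m], 0, 1)[:, None] * ac[m]
    done |= m

    # edge BC
    va = d3 * d6 - d5 * d4
    m = (~done) & (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
    denom = (d4 - d3) + (d5 - d6)
    w = np.where(np.abs(denom) > _EPS, (d4 - d3) / np.where(np.abs(denom) > _EPS, denom, 1.0), 0.0)
    out[m] = b[m] + np.clip(w[m], 0, 1)[:, None] * (c[m] - b[m])
    done |= m

    # face interior
    m = ~done
    if m.any():
        denom = va + vb + vc
        denom = np.where(np.abs(denom) > _EPS, denom, 1.0)
        v = vb / denom
        w = vc / denom
        out[m] = a[m] + v[m, None] * ab[m] + w[m, None] * ac[m]
    return out


def closest_points_segments(p1, q1, p2, q2):
    """Closest points between segments ``[p1,q1]`` and ``[p2,q2]`` (batched)."""
    d1 = q1 - p1
    d2 = q2 - p2
    r = p1 - p2
    a = _dot(d1, d1)
    e = _dot(d2, d2)
    f = _dot(d2, r)
    c = _dot(d1, r)
    b = _dot(d1, d2)
    denom = a * e - b * b

    s = np.where(denom > _EPS, np.clip((b * f - c * e) / np.where(denom > _EPS, denom, 1.0), 0, 1), 0.0)
    t = np.where(e > _EPS, (b * s + f) / np.where(e > _EPS, e, 1.0), 0.0)
    t_cl = np.clip(t, 0, 1)
    redo = t != t_cl
    s_new = np.clip((b * t_cl - c) / np.where(a > _EPS, a, 1.0), 0, 1)
    s = np.where(redo & (a > _EPS), s_new, s)
    # degenerate first segment: point
    s = np.where(a > _EPS, s, 0.0)
    c1 = p1 + s[:, None] * d1
    c2 = p2 + t_cl[:, None] * d2
    return c1, c2


def _segments_cross_triangles(p, q, tri):
    """True where segment ``[p,q]`` pierces triangle ``tri`` (batched)."""
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    d = q - p
    e1 = b - a
    e2 = c - a
    h = np.cross(d, e2)
    det = _dot(e1, h)
    ok = np.abs(det) > _EPS
    inv = 1.0 / np.where(ok, det, 1.0)
    s = p - a
    u = _dot(s, h) * inv
    qv = np.cross(s, e1)
    v = _dot(d, qv) * inv
    t = _dot(e2, qv) * inv
    tol = 1e-12
    return ok & (u >= -tol) & (v >= -tol) & (u + v <= 1 + tol) & (t >= -tol) & (t <= 1 + tol)


def triangle_pair_distance(tri_a: np.ndarray, tri_b: np.ndarray):
    """Exact distance and closest points for each triangle pair.

    ``tri_a``, ``tri_b``: arrays of shape (k, 3, 3).  Returns
    ``(dist (k,), pa (k,3), pb (k,3))``; crossing pairs report distance 0.
    """
    k = len(tri_a)
    cand_pa = []
    cand_pb = []
    # 9 edge-edge pairs
    for i in range(3):
        p1 = tri_a[:, i]
        q1 = tri_a[:, (i + 1) % 3]
        for j in range(3):
            p2 = tri_b[:, j]
            q2 = tri_b[:, (j + 1) % 3]
            c1, c2 = closest_points_segments(p1, q1, p2, q2)
            cand_pa.append(c1)
            cand_pb.append(c2)
    # vertices of A vs face B, and vice versa
    for i in range(3):
        v = tri_a[:, i]
        cp = closest_point_on_triangles(v, tri_b)
        cand_pa.append(v)
        cand_pb.append(cp)
    for j in range(3):
        v = tri_b[:, j]
        cp = closest_point_on_triangles(v, tri_a)
        cand_pa.append(cp)
        cand_pb.append(v)

    pa = np.stack(cand_pa, axis=1)  # (k, 15, 3)
    pb = np.stack(cand_pb, axis=1)
    d2 = np.sum((pa - pb) ** 2, axis=2)
    best = np.argmin(d2, axis=1)
    idx = np.arange(k)
    out_pa = pa[idx, best]
    out_pb = pb[idx, best]
    dist = np.sqrt(d2[idx, best])

    # crossing triangles have zero distance regardless of the candidates
    crossing = np.zeros(k, dtype=bool)
    for i in range(3):
        crossing |= _segments_cross_triangles(tri_a[:, i], tri_a[:, (i + 1) % 3], tri_b)
    for j in range(3):
        crossing |= _segments_cross_triangles(tri_b[:, j], tri_b[:, (j + 1) % 3], tri_a)
    if crossing.any():
        mid = 0.5 * (out_pa[crossing] + out_pb[crossing])
        out_pa[crossing] = mid
        out_pb[crossing] = mid
        dist[crossing] = 0.0
    return dist, out_pa, out_pb


# ---------------------------------------------------------------------------
# AABB tree
# ---------------------------------------------------------------------------

class _AABBTree:
    """Static median-split AABB tree over a triangle soup."""

    __slots__ = ("lo", "hi", "left", "right", "start", "count", "order", "tris")

    def __init__(self, tris: np.ndarray, leaf_size: int = 8):
        n = len(tris)
        self.tris = tris
        tlo = tris.min(axis=1)
        thi = tris.max(axis=1)
        cent = tris.mean(axis=1)
        order = np.arange(n)

        lo, hi, left, right, start, count = [], [], [], [], [], []

        def build(idx: np.ndarray) -> int:
            node = len(lo)
            lo.append(tlo[idx].min(axis=0))
            hi.append(thi[idx].max(axis=0))
            left.append(-1)
            right.append(-1)
            start.append(-1)
            count.append(0)
            if len(idx) <= leaf_size:
                start[node] = len(build.leaf_order)
                count[node] = len(idx)
                build.leaf_order.extend(idx.tolist())
                return node
            ext = hi[node] - lo[node]
            axis = int(np.argmax(ext))
            keys = cent[idx, axis]
            med = np.median(keys)
            mask = keys <= med
            if mask.all() or not mask.any():
                half = len(idx) // 2
                part = np.argsort(keys, kind="stable")
                l_idx, r_idx = idx[part[:half]], idx[part[half:]]
            else:
                l_idx, r_idx = idx[mask], idx[~mask]
            left[node] = build(l_idx)
            right[node] = build(r_idx)
            return node

        build.leaf_order = []
        build(order)
        self.lo = np.array(lo)
        self.hi = np.array(hi)
        self.left = np.array(left)
        self.right = np.array(right)
        self.start = np.array(start)
        self.count = np.array(count)
        self.order = np.array(build.leaf_order, dtype=int)

    def leaf_triangles(self, node: int) -> np.ndarray:
        s, c = self.start[node], self.count[node]
        return self.order[s : s + c]


def _aabb_distance(lo1, hi1, lo2, hi2) -> float:
    gap = np.maximum(0.0, np.maximum(lo1 - hi2, lo2 - hi1))
    return float(np.sqrt(np.sum(gap * gap)))


def _triangles(mesh: trimesh.Trimesh) -> np.ndarray:
    if mesh.is_empty or len(mesh.faces) == 0:
        raise ValueError("empty mesh in distance query")
    return mesh.vertices.view(np.ndarray)[mesh.faces]


def _closest_vertex_pair(mesh_a, mesh_b):
    """Upper bound for the surface distance from the closest vertex pair."""
    from scipy.spatial import cKDTree

    va = mesh_a.vertices.view(np.ndarray)
    vb = mesh_b.vertices.view(np.ndarray)
    tree = cKDTree(vb)
    d, j = tree.query(va)
    i = int(np.argmin(d))
    return float(d[i]), va[i], vb[int(j[i])]


def _candidate_pairs(ta, tb, bound):
    """Leaf triangle pairs whose AABB lower bound is within ``bound``."""
    tree_a = _AABBTree(ta)
    tree_b = _AABBTree(tb)
    pairs_a, pairs_b = [], []
    heap = [(_aabb_distance(tree_a.lo[0], tree_a.hi[0], tree_b.lo[0], tree_b.hi[0]), 0, 0)]
    while heap:
        d, na, nb = heapq.heappop(heap)
        if d > bound:
            continue
        leaf_a = tree_a.left[na] < 0
        leaf_b = tree_b.left[nb] < 0
        if leaf_a and leaf_b:
            ia = tree_a.leaf_triangles(na)
            ib = tree_b.leaf_triangles(nb)
            g = np.meshgrid(ia, ib, indexing="ij")
            pairs_a.append(g[0].ravel())
            pairs_b.append(g[1].ravel())
            continue
        # split the node with the larger box
        if leaf_b or (
            not leaf_a
            and np.prod(tree_a.hi[na] - tree_a.lo[na]) >= np.prod(tree_b.hi[nb] - tree_b.lo[nb])
        ):
            for child in (tree_a.left[na], tree_a.right[na]):
                dd = _aabb_distance(tree_a.lo[child], tree_a.hi[child], tree_b.lo[nb], tree_b.hi[nb])
                if dd <= bound:
                    heapq.heappush(heap, (dd, int(child), nb))
        else:
            for child in (tree_b.left[nb], tree_b.right[nb]):
                dd = _aabb_distance(tree_a.lo[na], tree_a.hi[na], tree_b.lo[child], tree_b.hi[child])
                if dd <= bound:
                    heapq.heappush(heap, (dd, na, int(child)))
    if not pairs_a:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    return np.concatenate(pairs_a), np.concatenate(pairs_b)


def _point_in_mesh(point: np.ndarray, tris: np.ndarray) -> bool:
    """Ray-crossing parity test; direction chosen off-axis to dodge edges."""
    d = np.array([0.577350269189626, 0.577350269189626, 0.577350269189626])
    a, b, c = tris[:, 0], tris[:, 1], tris[:, 2]
    e1 = b - a
    e2 = c - a
    h = np.cross(d, e2)
    det = _dot(e1, h)
    ok = np.abs(det) > _EPS
    inv = 1.0 / np.where(ok, det, 1.0)
    s = point - a
    u = _dot(s, h) * inv
    qv = np.cross(s, e1)
    v = np.einsum("i,ki->k", d, qv) * inv
    t = _dot(e2, qv) * inv
    hits = ok & (u >= 0) & (v >= 0) & (u + v <= 1) & (t > _EPS)
    return bool(np.count_nonzero(hits) % 2)


def _contained(mesh_a: trimesh.Trimesh, mesh_b: trimesh.Trimesh) -> bool:
    """One solid fully inside the other (surfaces disjoint but overlapping)."""
    if mesh_b.is_watertight and _point_in_mesh(
        mesh_a.vertices.view(np.ndarray)[0], _triangles(mesh_b)
    ):
        return True
    if mesh_a.is_watertight and _point_in_mesh(
        mesh_b.vertices.view(np.ndarray)[0], _triangles(mesh_a)
    ):
        return True
    return False


def min_distance(mesh_a: trimesh.Trimesh, mesh_b: trimesh.Trimesh, cutoff: float | None = None):
    """Exact minimum surface-to-surface distance between two meshes.

    Returns ``(distance_mm, point_a, point_b)``.  With ``cutoff`` given, any
    result greater than the cutoff may be the (still valid, but not minimal)
    closest-vertex-pair distance rather than the exact surface distance.
    Overlapping or touching meshes return 0.
    """
    ta = _triangles(mesh_a)
    tb = _triangles(mesh_b)
    ub, pa, pb = _closest_vertex_pair(mesh_a, mesh_b)
    bound = ub if cutoff is None else min(ub, cutoff)
    ia, ib = _candidate_pairs(ta, tb, bound + 1e-9)
    best = ub
    best_pa, best_pb = pa, pb
    for s in range(0, len(ia), _CHUNK):
        d, cpa, cpb = triangle_pair_distance(ta[ia[s : s + _CHUNK]], tb[ib[s : s + _CHUNK]])
        k = int(np.argmin(d))
        if d[k] < best:
            best = float(d[k])
            best_pa, best_pb = cpa[k], cpb[k]
            if best == 0.0:
                break
    if best > 0.0 and _contained(mesh_a, mesh_b):
        mid = 0.5 * (best_pa + best_pb)
        return 0.0, mid, mid
    return best, np.asarray(best_pa, dtype=float), np.asarray(best_pb, dtype=float)


def intersects(mesh_a: trimesh.Trimesh, mesh_b: trimesh.Trimesh) -> bool:
    """True iff the two meshes touch, cross, or one contains the other."""
    ta = _triangles(mesh_a)
    tb = _triangles(mesh_b)
    ia, ib = _candidate_pairs(ta, tb, 1e-9)
    for s in range(0, len(ia), _CHUNK):
        d, _, _ = triangle_pair_distance(ta[ia[s : s + _CHUNK]], tb[ib[s : s + _CHUNK]])
        if (d <= 1e-9).any():
            return True
    return _contained(mesh_a, mesh_b)


def brute_force_distance(mesh_a: trimesh.Trimesh, mesh_b: trimesh.Trimesh) -> float:
    """Exhaustive all-pairs triangle distance; the oracle for property tests.

    Guarded to small meshes (<= 2,000 triangles total) since it is O(n*m).
    """
    ta = _triangles(mesh_a)
    tb = _triangles(mesh_b)
    if len(ta) + len(tb) > 2000:
        raise ValueError(
            f"brute_force_distance limited to 2000 triangles total, got {len(ta) + len(tb)}"
        )
    ia, ib = np.meshgrid(np.arange(len(ta)), np.arange(len(tb)), indexing="ij")
    ia, ib = ia.ravel(), ib.ravel()
    best = np.inf
    for s in range(0, len(ia), _CHUNK):
        d, _, _ = triangle_pair_distance(ta[ia[s : s + _CHUNK]], tb[ib[s : s + _CHUNK]])
        best = min(best, float(d.min()))
        if best == 0.0:
            break
    if best > 0.0 and _contained(mesh_a, mesh_b):
        return 0.0
    return best


def contains_point(mesh: trimesh.Trimesh, point) -> bool:
    """True if ``point`` lies inside the (watertight) mesh."""
    return _point_in_mesh(np.asarray(point, dtype=float), _triangles(mesh))


def point_mesh_distance(point, mesh: trimesh.Trimesh) -> float:
    """Distance from a single point to a mesh surface (brute over faces)."""
    tris = _triangles(mesh)
    p = np.broadcast_to(np.asarray(point, dtype=float), (len(tris), 3))
    cp = closest_point_on_triangles(np.ascontiguousarray(p), tris)
    return float(np.sqrt(np.min(np.sum((cp - p) ** 2, axis=1))))
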