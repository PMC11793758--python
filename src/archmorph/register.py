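"""Best-fit rigid alignment by iterative nearest-point matching (ICP).

The correspondence primitive is the exact nearest point on the reference
triangle surface (vertex, edge or interior), found through a KD-tree
candidate search that is provably global: an upper bound from the nearest
vertex is tightened on its incident faces, then every triangle that could
possibly beat the bound is tested.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .errors import ValidationError
from .mesh import TriangleMesh

__all__ = [
    "RigidTransform",
    "AlignmentReport",
    "ICPConfig",
    "SurfaceIndex",
    "closest_point_on_triangles",
    "apply_transform",
    "best_fit_align",
]


@dataclass(frozen=True)
class RigidTransform:
    """Rotation + translation, acting as ``R @ v + t``."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.rotation, dtype=np.float64)
        t = np.asarray(self.translation, dtype=np.float64)
        if r.shape != (3, 3) or t.shape != (3,):
            raise ValidationError("rotation must be (3,3), translation (3,)")
        if not np.allclose(r @ r.T, np.eye(3), atol=1e-9):
            raise ValidationError("rotation is not orthonormal within 1e-9")
        if not np.isclose(np.linalg.det(r), 1.0, atol=1e-9):
            raise ValidationError("rotation determinant is not +1 (reflection?)")
        object.__setattr__(self, "rotation", r)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_axis_angle(
        cls, axis: np.ndarray, angle_rad: float, translation: np.ndarray | None = None
    ) -> "RigidTransform":
        axis = np.asarray(axis, dtype=np.float64)
        axis = axis / np.linalg.norm(axis)
        k = np.array(
            [
                [0.0, -axis[2], axis[1]],
                [axis[2], 0.0, -axis[0]],
                [-axis[1], axis[0], 0.0],
            ]
        )
        r = np.eye(3) + np.sin(angle_rad) * k + (1.0 - np.cos(angle_rad)) * (k @ k)
        # re-orthonormalise to keep the 1e-9 invariant exactly
        u, _, vt = np.linalg.svd(r)
        r = u @ vt
        t = np.zeros(3) if translation is None else np.asarray(translation, float)
        return cls(r, t)

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=np.float64) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying ``other`` first, then self."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation)

    def to_dict(self) -> dict:
        return {
            "rotation": self.rotation.tolist(),
            "translation": self.translation.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(np.array(d["rotation"]), np.array(d["translation"]))


@dataclass
class AlignmentReport:
    """Convergence diagnostics of one best-fit alignment."""

    transform: RigidTransform
    rms_history: list[float]
    iterations: int
    converged: bool
    sample_size: int


@dataclass
class ICPConfig:
    max_iter: int = 200
    rms_tol: float = 1e-6
    sample_size: int = 50_000
    seed: int | None = None
    trim_fraction: float = 0.0  # fraction of worst correspondences dropped
    pre_align_centroids: bool = False


def apply_transform(mesh: TriangleMesh, transform: RigidTransform) -> TriangleMesh:
    """Map every vertex by ``R v + t``; faces unchanged, normals rotated."""
    normals = mesh.vertex_normals
    if normals is not None:
        normals = normals @ transform.rotation.T
    return TriangleMesh(transform.apply(mesh.vertices), mesh.faces.copy(), normals)


# -- exact point-to-triangle distance -----------------------------------

def closest_point_on_triangles(points: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    """Closest point on each (closed) triangle to each paired query point.

    points: (k, 3); triangles: (k, 3, 3).  Vectorised Ericson region test.
    """
    p = np.asarray(points, dtype=np.float64)
    a = triangles[:, 0]
    b = triangles[:, 1]
    c = triangles[:, 2]
    ab = b - a
    ac = c - a
    ap = p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    out = np.empty_like(p)
    done = np.zeros(len(p), dtype=bool)

    def settle(mask: np.ndarray, value: np.ndarray) -> None:
        m = mask & ~done
        out[m] = value[m]
        done[m] = True

    settle((d1 <= 0) & (d2 <= 0), a)  # vertex A
    settle((d3 >= 0) & (d4 <= d3), b)  # vertex B

    vc = d1 * d4 - d3 * d2
    with np.errstate(divide="ignore", invalid="ignore"):
        v_ab = d1 / (d1 - d3)
    settle((vc <= 0) & (d1 >= 0) & (d3 <= 0), a + np.nan_to_num(v_ab)[:, None] * ab)

    settle((d6 >= 0) & (d5 <= d6), c)  # vertex C

    vb = d5 * d2 - d1 * d6
    with np.errstate(divide="ignore", invalid="ignore"):
        w_ac = d2 / (d2 - d6)
    settle((vb <= 0) & (d2 >= 0) & (d6 <= 0), a + np.nan_to_num(w_ac)[:, None] * ac)

    va = d3 * d6 - d5 * d4
    with np.errstate(divide="ignore", invalid="ignore"):
        w_bc = (d4 - d3) / ((d4 - d3) + (d5 - d6))
    settle(
        (va <= 0) & ((d4 - d3) >= 0) & ((d5 - d6) >= 0),
        b + np.nan_to_num(w_bc)[:, None] * (c - b),
    )

    # interior
    if not done.all():
        m = ~done
        denom = va[m] + vb[m] + vc[m]
        denom[denom == 0.0] = 1.0
        v = vb[m] / denom
        w = vc[m] / denom
        out[m] = a[m] + v[:, None] * ab[m] + w[:, None] * ac[m]
    return out


def barycentric_coordinates(
    points: np.ndarray, triangles: np.ndarray
) -> np.ndarray:
    """Barycentric coords of points assumed to lie on their paired triangles."""
    a = triangles[:, 0]
    ab = triangles[:, 1] - a
    ac = triangles[:, 2] - a
    ap = np.asarray(points, dtype=np.float64) - a
    d00 = np.einsum("ij,ij->i", ab, ab)
    d01 = np.einsum("ij,ij->i", ab, ac)
    d11 = np.einsum("ij,ij->i", ac, ac)
    d20 = np.einsum("ij,ij->i", ap, ab)
    d21 = np.einsum("ij,ij->i", ap, ac)
    denom = d00 * d11 - d01 * d01
    denom = np.where(denom == 0.0, 1.0, denom)
    v = (d11 * d20 - d01 * d21) / denom
    w = (d00 * d21 - d01 * d20) / denom
    bary = np.stack([1.0 - v - w, v, w], axis=1)
    return np.clip(bary, 0.0, 1.0)


class SurfaceIndex:
    """Spatial index over a triangle surface for exact nearest-point queries."""

    def __init__(self, mesh: TriangleMesh):
        if mesh.n_faces == 0:
            raise ValidationError("cannot index an empty mesh")
        self.mesh = mesh
        self._tree = cKDTree(mesh.vertices)
        tri = mesh.triangles()
        self._tri = tri
        edges = np.stack(
            [
                np.linalg.norm(tri[:, 1] - tri[:, 0], axis=1),
                np.linalg.norm(tri[:, 2] - tri[:, 1], axis=1),
                np.linalg.norm(tri[:, 0] - tri[:, 2], axis=1),
            ]
        )
        self.max_edge = float(edges.max())
        centroids = tri.mean(axis=1)
        self._ctree = cKDTree(centroids)
        # max distance from any triangle centroid to its own vertices
        self._spread = float(
            np.linalg.norm(tri - centroids[:, None, :], axis=2).max()
        )
        # vertex -> incident faces adjacency in CSR layout
        flat = mesh.faces.ravel()
        order = np.argsort(flat, kind="stable")
        self._adj_faces = order // 3
        counts = np.bincount(flat, minlength=mesh.n_vertices)
        self._adj_start = np.concatenate([[0], np.cumsum(counts)])

    def faces_of_vertices(
        self, owners: np.ndarray, vertex_ids: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        """Expand (owner, vertex) pairs into deduplicated (owner, face) pairs."""
        owners = np.asarray(owners, dtype=np.int64)
        vertex_ids = np.asarray(vertex_ids, dtype=np.int64)
        if len(owners) == 0:
            return owners, vertex_ids
        starts = self._adj_start[vertex_ids]
        stops = self._adj_start[vertex_ids + 1]
        counts = stops - starts
        o = np.repeat(owners, counts)
        f = self._adj_faces[_ragged_range(starts, stops)]
        key = o * self.mesh.n_faces + f
        uniq = np.unique(key)
        return uniq // self.mesh.n_faces, uniq % self.mesh.n_faces

    def query(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Globally nearest surface point for each query.

        Returns (closest_points (k,3), face_ids (k,), distances (k,)).
        """
        p = np.asarray(points, dtype=np.float64)
        if p.ndim == 1:
            cp, fid, d = self.query(p[None, :])
            return cp[0], int(fid[0]), float(d[0])
        k = len(p)
        tri = self._tri
        best_d = np.full(k, np.inf)
        best_face = np.full(k, -1, dtype=np.int64)
        best_point = np.zeros((k, 3))

        def consider(owners: np.ndarray, faces: np.ndarray) -> None:
            if len(owners) == 0:
                return
            cp = closest_point_on_triangles(p[owners], tri[faces])
            d = np.linalg.norm(cp - p[owners], axis=1)
            np.minimum.at(best_d, owners, d)
            hit = d <= best_d[owners]
            best_face[owners[hit]] = faces[hit]
            best_point[owners[hit]] = cp[hit]

        # stage 1: upper bound from the faces around the nearest vertex
        _, nearest_v = self._tree.query(p)
        consider(*self.faces_of_vertices(np.arange(k), nearest_v))

        # stage 2: any triangle containing a point closer than best_d has
        # its centroid within best_d + spread of the query — an exhaustive
        # centroid-ball sweep makes the result provably global
        radii = best_d + self._spread * (1.0 + 1e-12) + 1e-12
        balls = self._ctree.query_ball_point(p, radii)
        owners2 = np.repeat(
            np.arange(k, dtype=np.int64),
            np.fromiter((len(b) for b in balls), dtype=np.int64, count=k),
        )
        cands = (
            np.concatenate([np.asarray(b, dtype=np.int64) for b in balls])
            if owners2.size
            else np.empty(0, dtype=np.int64)
        )
        consider(owners2, cands)
        return best_point, best_face, best_d


def _ragged_range(starts: np.ndarray, stops: np.ndarray) -> np.ndarray:
    """Concatenated arange(start, stop) without a Python loop."""
    counts = stops - starts
    total = int(counts.sum())
    if total == 0:
        return np.empty(0, dtype=np.int64)
    offsets = np.concatenate([[0], np.cumsum(counts)[:-1]])
    return np.repeat(starts - offsets, counts) + np.arange(total)


def nearest_point_on_surface(
    reference: TriangleMesh | SurfaceIndex, point: np.ndarray
) -> tuple[np.ndarray, int, float]:
    """Closest point on the reference surface to a single query point."""
    index = reference if isinstance(reference, SurfaceIndex) else SurfaceIndex(reference)
    return index.query(np.asarray(point, dtype=np.float64))


def solve_rigid(source: np.ndarray, target: np.ndarray) -> RigidTransform:
    """Least-squares rigid motion mapping source onto target (Kabsch/SVD).

    The reflection case is guarded by flipping the smallest singular axis.
    """
    src = np.asarray(source, dtype=np.float64)
    tgt = np.asarray(target, dtype=np.float64)
    cs = src.mean(axis=0)
    ct = tgt.mean(axis=0)
    h = (src - cs).T @ (tgt - ct)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    s = np.diag([1.0, 1.0, d])
    r = vt.T @ s @ u.T
    # polish orthonormality to satisfy the 1e-9 invariant
    uu, _, vvt = np.linalg.svd(r)
    r = uu @ vvt
    t = ct - r @ cs
    return RigidTransform(r, t)


def best_fit_align(
    test: TriangleMesh,
    reference: TriangleMesh,
    config: ICPConfig | None = None,
) -> tuple[RigidTransform, AlignmentReport]:
    """Iteratively align ``test`` onto ``reference`` by nearest-point matching.

    Returns the cumulative rigid transform (to be applied to ``test``) and a
    convergence report.  Non-convergence is reported, not raised.
    """
    cfg = config or ICPConfig()
    if test.n_vertices == 0 or reference.n_faces == 0:
        raise ValidationError("both meshes must be non-empty")
    if not (np.all(np.isfinite(test.vertices)) and np.all(np.isfinite(reference.vertices))):
        raise ValidationError("non-finite geometry")

    source = test.vertices
    if len(source) > cfg.sample_size:
        if cfg.seed is None:
            raise ValidationError("seed required when sampling test vertices")
        rng = np.random.default_rng(cfg.seed)
        pick = rng.choice(len(source), size=cfg.sample_size, replace=False)
        source = source[np.sort(pick)]

    index = SurfaceIndex(reference)
    transform = RigidTransform.identity()
    if cfg.pre_align_centroids:
        shift = reference.vertices.mean(axis=0) - source.mean(axis=0)
        transform = RigidTransform(np.eye(3), shift)

    rms_history: list[float] = []
    converged = False
    for _ in range(cfg.max_iter):
        moved = transform.apply(source)
        closest, _, dist = index.query(moved)
        if cfg.trim_fraction > 0.0:
            cut = np.quantile(dist, 1.0 - cfg.trim_fraction)
            keep = dist <= cut
        else:
            keep = slice(None)
        rms = float(np.sqrt(np.mean(dist[keep] ** 2)))
        rms_history.append(rms)
        if len(rms_history) >= 2 and abs(rms_history[-2] - rms) < cfg.rms_tol:
            converged = True
            break
        if rms == 0.0:
            converged = True
            break
        step = solve_rigid(moved[keep], closest[keep])
        transform = step.compose(transform)

    report = AlignmentReport(
        transform=transform,
        rms_history=rms_history,
        iterations=len(rms_history),
        converged=converged,
        sample_size=len(source),
    )
    return transform, report
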