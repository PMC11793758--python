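"""Synthetic appliance-like specimens with known, parametric deformations.

The generator produces a horseshoe-shaped band surface (open channel:
outer wall, occlusal top, inner wall) swept along a parabolic arch.
Coordinate convention: z is occlusal (up), the anterior apex points to
-y after centering, the two posterior arm ends sit at +y, and the
palatal (inner) side faces the arch midline.

Deformation fields use cosine-tapered weights that reach an exact
plateau of 1, so the configured magnitude is attained exactly at the
extreme of the targeted region — which is what makes downstream
parameter-recovery tests meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .errors import ValidationError
from .mesh import TriangleMesh, compute_vertex_normals, merge_duplicate_vertices

__all__ = [
    "ArchParams",
    "DeformationScenario",
    "SpherePointCloud",
    "generate_arch_appliance",
    "apply_deformation",
    "apply_scan_noise",
    "generate_sphere_scan",
]


@dataclass(frozen=True)
class ArchParams:
    """Geometry of the synthetic arch appliance (all mm)."""

    span: float = 50.0
    depth: float = 40.0
    band_width: float = 8.0
    occlusal_height: float = 3.0
    resolution: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        problems = []
        for name in ("span", "depth", "band_width", "occlusal_height", "resolution"):
            if getattr(self, name) <= 0:
                problems.append(f"{name} must be positive")
        if self.resolution > self.band_width / 4.0:
            problems.append(
                f"resolution {self.resolution} exceeds band_width/4 "
                f"= {self.band_width / 4.0}"
            )
        if problems:
            raise ValidationError("; ".join(problems))


@dataclass(frozen=True)
class DeformationScenario:
    """Magnitudes (mm) of the three deformation components."""

    posterior_shrink: float = 0.0
    palatal_lift: float = 0.0
    buccal_retraction: float = 0.0
    smoothness: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        problems = []
        for name in ("posterior_shrink", "palatal_lift", "buccal_retraction"):
            if getattr(self, name) < 0:
                problems.append(f"{name} must be >= 0")
        if self.smoothness <= 0:
            problems.append("smoothness must be > 0")
        if problems:
            raise ValidationError("; ".join(problems))

    @property
    def is_identity(self) -> bool:
        return (
            self.posterior_shrink == 0.0
            and self.palatal_lift == 0.0
            and self.buccal_retraction == 0.0
        )


@dataclass
class SpherePointCloud:
    """Scanned calibration-sphere point cloud with known ground truth."""

    points: np.ndarray
    true_radius: float
    center: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=np.float64)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValidationError("points must be (n, 3)")
        if self.true_radius <= 0:
            raise ValidationError("true_radius must be positive")
        self.points = pts
        self.center = np.asarray(self.center, dtype=np.float64)

    def __len__(self) -> int:
        return len(self.points)


# -- arch construction ---------------------------------------------------

def _centerline(params: ArchParams, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Centerline points and unit inward normals in the xy-plane.

    Parabola x = a*t, y = depth*t^2, t in [-1, 1]; the inward normal
    points toward the concave (arch-midline) side.
    """
    a = (params.span - params.band_width) / 2.0
    x = a * t
    y = params.depth * t * t
    pts = np.stack([x, y], axis=1)
    # tangent (a, 2*depth*t); inward normal is its +90 deg rotation
    tx = np.full_like(t, a)
    ty = 2.0 * params.depth * t
    norm = np.hypot(tx, ty)
    normals = np.stack([-ty / norm, tx / norm], axis=1)
    return pts, normals


def _cross_section(params: ArchParams) -> np.ndarray:
    """(n, 2) polyline (lateral s, height z): outer wall up, top across,
    inner wall down.  s is negative on the buccal (outer) side."""
    w = params.band_width / 2.0
    h = params.occlusal_height
    res = params.resolution
    n_h = max(1, int(np.ceil(h / res)))
    n_w = max(1, int(np.ceil(params.band_width / res)))
    outer = np.stack(
        [np.full(n_h, -w), np.linspace(0.0, h, n_h + 1)[:-1]], axis=1
    )
    top = np.stack(
        [np.linspace(-w, w, n_w + 1)[:-1], np.full(n_w, h)], axis=1
    )
    inner = np.stack(
        [np.full(n_h + 1, w), np.linspace(h, 0.0, n_h + 1)], axis=1
    )
    return np.concatenate([outer, top, inner], axis=0)


def _build_arch(params: ArchParams) -> tuple[np.ndarray, np.ndarray]:
    """Uncentered vertex grid and faces of the swept band surface."""
    # arc length of the centerline, for the along-arch sample count
    t_dense = np.linspace(-1.0, 1.0, 2049)
    pts_dense, _ = _centerline(params, t_dense)
    seg = np.linalg.norm(np.diff(pts_dense, axis=0), axis=1)
    arc_len = float(seg.sum())
    n_u = int(np.ceil(arc_len / params.resolution))
    if n_u < 4:
        raise ValidationError("resolution too coarse for the arch length")

    # sample t so points are (approximately) equally spaced along the arc
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    t = np.interp(np.linspace(0.0, arc_len, n_u + 1), cum, t_dense)
    centers, normals = _centerline(params, t)

    cs = _cross_section(params)
    n_c = len(cs)
    # vertex grid: (along arch, along cross-section)
    cx = centers[:, None, 0] + normals[:, None, 0] * cs[None, :, 0]
    cy = centers[:, None, 1] + normals[:, None, 1] * cs[None, :, 0]
    cz = np.broadcast_to(cs[None, :, 1], cx.shape)
    vertices = np.stack([cx, cy, cz], axis=2).reshape(-1, 3)

    i = np.arange(n_u)[:, None]
    j = np.arange(n_c - 1)[None, :]
    v00 = (i * n_c + j).ravel()
    v10 = ((i + 1) * n_c + j).ravel()
    v01 = (i * n_c + j + 1).ravel()
    v11 = ((i + 1) * n_c + j + 1).ravel()
    faces = np.concatenate(
        [
            np.stack([v00, v10, v11], axis=1),
            np.stack([v00, v11, v01], axis=1),
        ],
        axis=0,
    )
    return vertices, faces


def _centering_shift(params: ArchParams) -> np.ndarray:
    vertices, _ = _build_arch(params)
    return (vertices.min(axis=0) + vertices.max(axis=0)) / 2.0


def arch_frame(params: ArchParams, n_samples: int = 4097) -> tuple[np.ndarray, np.ndarray]:
    """Densely sampled centerline (xy) and inward normals, in the centered
    coordinate frame of generate_arch_appliance's output."""
    t = np.linspace(-1.0, 1.0, n_samples)
    pts, normals = _centerline(params, t)
    return pts - _centering_shift(params)[:2], normals


def generate_arch_appliance(params: ArchParams) -> TriangleMesh:
    """Build the horseshoe band surface, centered at the origin.

    Deterministic for fixed params; the winding makes the occlusal top
    face +z, the outer wall face away from the arch and the inner wall
    face the midline.
    """
    vertices, faces = _build_arch(params)
    vertices, faces, _ = merge_duplicate_vertices(vertices, faces)
    mesh = TriangleMesh(vertices, faces)
    box = mesh.bounds()
    mesh.vertices -= (box.min_corner + box.max_corner) / 2.0
    return mesh


# -- deformation ---------------------------------------------------------

def _cosine_ramp(u: np.ndarray) -> np.ndarray:
    """0 for u<=0, smooth rise, exactly 1 for u>=1."""
    u = np.clip(u, 0.0, 1.0)
    return 0.5 * (1.0 - np.cos(np.pi * u))


def _lateral_frame(
    mesh: TriangleMesh, params: ArchParams | None
) -> tuple[np.ndarray, np.ndarray]:
    """Per-vertex signed lateral offset from the arch midcurve and the
    inward (palatal) unit direction in the xy-plane.

    s > 0 on the inner (palatal) side, s < 0 on the outer (buccal) side.
    With ``params`` the generator's analytic centerline is used (exact);
    without it a quadratic y = q(x) fit of the vertex cloud stands in,
    which is adequate away from the steep posterior arms because the
    downstream weight ramps have flat plateaus.
    """
    x = mesh.vertices[:, 0]
    y = mesh.vertices[:, 1]
    if params is not None:
        curve, normals = arch_frame(params)
    else:
        coeffs = np.polyfit(x, y, 2)
        xs = np.linspace(x.min(), x.max(), 2048)
        ys = np.polyval(coeffs, xs)
        curve = np.stack([xs, ys], axis=1)
        slope = 2.0 * coeffs[0] * xs + coeffs[1]
        norm = np.hypot(1.0, slope)
        normals = np.stack([-slope / norm, 1.0 / norm], axis=1)
    tree = cKDTree(curve)
    _, idx = tree.query(np.stack([x, y], axis=1))
    n = normals[idx]
    s = (x - curve[idx, 0]) * n[:, 0] + (y - curve[idx, 1]) * n[:, 1]
    return s, n


def deformation_displacement(
    mesh: TriangleMesh,
    scenario: DeformationScenario,
    params: ArchParams | None = None,
) -> np.ndarray:
    """Per-vertex displacement (mm) of the deformation field."""
    v = mesh.vertices
    disp = np.zeros_like(v)
    ell = scenario.smoothness
    y_max = v[:, 1].max()

    if scenario.posterior_shrink > 0.0:
        w = _cosine_ramp((v[:, 1] - (y_max - ell)) / ell)
        disp[:, 1] -= scenario.posterior_shrink * w

    if scenario.palatal_lift > 0.0 or scenario.buccal_retraction > 0.0:
        s, inward = _lateral_frame(mesh, params)
        if params is not None:
            half_width = params.band_width / 2.0
        else:
            half_width = float(np.percentile(np.abs(s), 97.5))
        ramp = 0.6 * half_width  # weight hits exactly 1 well inside the walls
        # lift and retraction act on the molar (posterior-arm) region only,
        # so the rigid best-fit downstream cannot absorb them
        w_molar = _cosine_ramp((v[:, 1] - (y_max - 1.5 * ell)) / ell)
        if scenario.palatal_lift > 0.0:
            disp[:, 2] += scenario.palatal_lift * _cosine_ramp(s / ramp) * w_molar
        if scenario.buccal_retraction > 0.0:
            w = scenario.buccal_retraction * _cosine_ramp(-s / ramp) * w_molar
            disp[:, 0] += w * inward[:, 0]
            disp[:, 1] += w * inward[:, 1]

    return disp


def apply_deformation(
    mesh: TriangleMesh,
    scenario: DeformationScenario,
    params: ArchParams | None = None,
) -> TriangleMesh:
    """Displace vertices by the smooth parametric deformation field.

    Topology is unchanged.  A zero scenario returns an exact copy.
    ``params`` (the generator parameters, when known) makes the lateral
    coordinate analytic instead of fitted.  Raises if the displacement
    inverts any triangle.
    """
    if scenario.is_identity:
        return mesh.copy()
    disp = deformation_displacement(mesh, scenario, params)
    out = TriangleMesh(mesh.vertices + disp, mesh.faces.copy())
    before = mesh.face_cross()
    after = out.face_cross()
    flipped = np.einsum("ij,ij->i", before, after) < 0.0
    if flipped.any():
        bad = np.flatnonzero(flipped)[:20].tolist()
        raise ValidationError(
            f"deformation inverts {int(flipped.sum())} faces, e.g. {bad}"
        )
    return out


def apply_scan_noise(mesh: TriangleMesh, sigma_mm: float, seed: int) -> TriangleMesh:
    """Displace each vertex along its normal by iid N(0, sigma) noise."""
    if sigma_mm < 0:
        raise ValidationError("sigma must be >= 0")
    if sigma_mm == 0.0:
        return mesh.copy()
    normals = (
        mesh.vertex_normals
        if mesh.vertex_normals is not None
        else compute_vertex_normals(mesh)
    )
    rng = np.random.default_rng(seed)
    offsets = rng.normal(0.0, sigma_mm, size=mesh.n_vertices)
    return TriangleMesh(mesh.vertices + offsets[:, None] * normals, mesh.faces.copy())


def generate_sphere_scan(
    radius_mm: float,
    center: np.ndarray | tuple = (0.0, 0.0, 0.0),
    n_points: int = 10_000,
    sigma_mm: float = 0.0,
    seed: int = 0,
) -> SpherePointCloud:
    """Area-uniform points on a sphere, perturbed radially by N(0, sigma)."""
    if n_points < 4:
        raise ValidationError("need at least 4 points")
    if radius_mm <= 0:
        raise ValidationError("radius must be positive")
    rng = np.random.default_rng(seed)
    dirs = rng.normal(size=(n_points, 3))
    norms = np.linalg.norm(dirs, axis=1)
    # resample the (measure-zero) degenerate draws
    while (norms == 0.0).any():
        bad = norms == 0.0
        dirs[bad] = rng.normal(size=(int(bad.sum()), 3))
        norms = np.linalg.norm(dirs, axis=1)
    dirs /= norms[:, None]
    radii = radius_mm + (
        rng.normal(0.0, sigma_mm, size=n_points) if sigma_mm > 0.0 else 0.0
    )
    center = np.asarray(center, dtype=np.float64)
    return SpherePointCloud(center + dirs * np.atleast_1d(radii)[:, None], radius_mm, center)
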