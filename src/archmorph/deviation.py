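"""Signed deviation fields, cutoff classification, outcome summaries,
cross-sections and color-map export.

Sign convention: a test vertex lying on the side the reference surface
normal points to gets a positive deviation ("above" the reference),
the opposite side negative.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import EmptyResultError, MeshIOError, ValidationError
from .mesh import TriangleMesh, compute_vertex_normals
from .register import SurfaceIndex, barycentric_coordinates

log = logging.getLogger(__name__)

DEFAULT_CUTOFF_MM = 0.040
DEFAULT_DISPLAY_LIMIT_MM = 0.15


@dataclass
class DeviationField:
    """Per-vertex signed deviation (mm) of a test mesh from a reference."""

    values: np.ndarray
    mesh: TriangleMesh

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 1 or len(v) != self.mesh.n_vertices:
            raise ValidationError("field length must equal vertex count")
        if not np.all(np.isfinite(v)):
            raise ValidationError("deviation values must be finite")
        self.values = v


@dataclass
class DeviationClass:
    """Per-vertex three-way label: +1 (plus), 0 (neutral), -1 (minus)."""

    labels: np.ndarray
    cutoff: float

    @property
    def plus(self) -> np.ndarray:
        return self.labels == 1

    @property
    def minus(self) -> np.ndarray:
        return self.labels == -1

    @property
    def neutral(self) -> np.ndarray:
        return self.labels == 0


@dataclass(frozen=True)
class DeformationSummary:
    """The six per-specimen outcomes (all non-negative)."""

    max_plus: float
    max_minus: float
    area_plus: float
    area_minus: float
    volume_plus: float
    volume_minus: float
    cutoff: float

    OUTCOME_NAMES = (
        "max_minus",
        "max_plus",
        "area_minus",
        "area_plus",
        "volume_minus",
        "volume_plus",
    )

    def to_dict(self) -> dict:
        return {
            "max_plus_mm": self.max_plus,
            "max_minus_mm": self.max_minus,
            "area_plus_mm2": self.area_plus,
            "area_minus_mm2": self.area_minus,
            "volume_plus_mm3": self.volume_plus,
            "volume_minus_mm3": self.volume_minus,
            "cutoff_mm": self.cutoff,
        }

    def as_row(self) -> dict:
        return {name: getattr(self, name) for name in self.OUTCOME_NAMES}


@dataclass(frozen=True)
class Plane:
    """Cutting plane given by a point and a normal."""

    point: np.ndarray
    normal: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.point, dtype=np.float64)
        n = np.asarray(self.normal, dtype=np.float64)
        if np.linalg.norm(n) == 0.0:
            raise ValidationError("plane normal must be nonzero")
        object.__setattr__(self, "point", p)
        object.__setattr__(self, "normal", n / np.linalg.norm(n))


@dataclass
class CrossSection:
    """Plane-mesh intersection polylines annotated with deviation."""

    plane: Plane
    polylines: list  # list of dicts: points (k,3), arc_length (k,), deviation (k,)

    @property
    def longest(self) -> dict:
        return self.polylines[0]


def signed_deviation_field(
    test_aligned: TriangleMesh,
    reference: TriangleMesh,
    index: SurfaceIndex | None = None,
) -> DeviationField:
    """Signed distance from each test vertex to the reference surface.

    The sign comes from the barycentrically interpolated reference vertex
    normal at the closest point, falling back to the face normal where
    the interpolated normal vanishes.
    """
    idx = index if index is not None else SurfaceIndex(reference)
    closest, face_ids, dist = idx.query(test_aligned.vertices)
    ref_normals = (
        reference.vertex_normals
        if reference.vertex_normals is not None
        else compute_vertex_normals(reference)
    )
    tri = reference.triangles()[face_ids]
    bary = barycentric_coordinates(closest, tri)
    corner_normals = ref_normals[reference.faces[face_ids]]  # (k, 3, 3)
    n_interp = np.einsum("kc,kcj->kj", bary, corner_normals)
    lengths = np.linalg.norm(n_interp, axis=1)
    degenerate = lengths < 1e-12
    if degenerate.any():
        log.info(
            "%d interpolated normals degenerate; using face normals",
            int(degenerate.sum()),
        )
        n_interp[degenerate] = reference.face_normals()[face_ids[degenerate]]
        lengths = np.linalg.norm(n_interp, axis=1)
        lengths[lengths == 0.0] = 1.0
    n_interp /= lengths[:, None]
    side = np.einsum("ij,ij->i", test_aligned.vertices - closest, n_interp)
    values = np.where(side >= 0.0, dist, -dist)
    return DeviationField(values, test_aligned)


def classify_deviation(field: DeviationField, cutoff_mm: float) -> DeviationClass:
    """Three-way strict-inequality labeling at +-cutoff."""
    if cutoff_mm <= 0.0:
        raise ValidationError("cutoff must be > 0")
    v = field.values
    labels = (v > cutoff_mm).astype(np.int8) - (v < -cutoff_mm).astype(np.int8)
    return DeviationClass(labels, float(cutoff_mm))


def deformation_summary(
    field: DeviationField,
    classes: DeviationClass,
    area_mode: str = "surface",
) -> DeformationSummary:
    """Six outcomes from a classified deviation field.

    A triangle belongs to a sign's region when the mean of its vertex
    deviations exceeds the cutoff in that direction; its area contributes
    to the region area and area * mean |vertex deviation| to the volume.
    ``area_mode='projected_z'`` measures areas projected to the xy-plane
    instead of on the surface.
    """
    if area_mode not in ("surface", "projected_z"):
        raise ValidationError(f"unknown area_mode {area_mode!r}")
    v = field.values
    mesh = field.mesh
    cutoff = classes.cutoff

    max_plus = float(v[classes.plus].max()) if classes.plus.any() else 0.0
    max_minus = float(-v[classes.minus].min()) if classes.minus.any() else 0.0

    face_vals = v[mesh.faces]  # (m, 3)
    mean_dev = face_vals.mean(axis=1)
    mean_abs = np.abs(face_vals).mean(axis=1)
    if area_mode == "surface":
        areas = mesh.face_areas()
    else:
        t = mesh.triangles()[:, :, :2]
        areas = 0.5 * np.abs(
            (t[:, 1, 0] - t[:, 0, 0]) * (t[:, 2, 1] - t[:, 0, 1])
            - (t[:, 2, 0] - t[:, 0, 0]) * (t[:, 1, 1] - t[:, 0, 1])
        )

    in_plus = mean_dev > cutoff
    in_minus = mean_dev < -cutoff
    area_plus = float(areas[in_plus].sum())
    area_minus = float(areas[in_minus].sum())
    volume_plus = float((areas[in_plus] * mean_abs[in_plus]).sum())
    volume_minus = float((areas[in_minus] * mean_abs[in_minus]).sum())

    return DeformationSummary(
        max_plus=max_plus,
        max_minus=max_minus,
        area_plus=area_plus,
        area_minus=area_minus,
        volume_plus=volume_plus,
        volume_minus=volume_minus,
        cutoff=cutoff,
    )


# -- cross sections ------------------------------------------------------

def cross_section_deviation(
    test_aligned: TriangleMesh,
    reference: TriangleMesh,
    plane: Plane,
    field: DeviationField | None = None,
) -> CrossSection:
    """Plane-mesh intersection polylines with interpolated deviations.

    The polylines live on the test mesh; the longest is returned first.
    """
    if field is None:
        field = signed_deviation_field(test_aligned, reference)
    mesh = test_aligned
    sd = (mesh.vertices - plane.point) @ plane.normal
    # nudge exact-zero vertices off the plane for a robust sign test
    eps = 1e-12 * max(1.0, float(np.abs(sd).max()))
    sd = np.where(sd == 0.0, eps, sd)

    f = mesh.faces
    s = sd[f]  # (m, 3)
    crossing = ~((s > 0).all(axis=1) | (s < 0).all(axis=1))
    if not crossing.any():
        raise EmptyResultError("plane does not intersect the mesh")

    segments = []  # (edge_key_a, edge_key_b, point_a, point_b, dev_a, dev_b)
    dev = field.values
    for fi in np.flatnonzero(crossing):
        ids = f[fi]
        pts = []
        keys = []
        devs = []
        for a, b in ((0, 1), (1, 2), (2, 0)):
            ia, ib = ids[a], ids[b]
            if sd[ia] * sd[ib] < 0.0:
                t = sd[ia] / (sd[ia] - sd[ib])
                pts.append(mesh.vertices[ia] + t * (mesh.vertices[ib] - mesh.vertices[ia]))
                devs.append(dev[ia] + t * (dev[ib] - dev[ia]))
                keys.append((min(ia, ib), max(ia, ib)))
        if len(pts) == 2:
            segments.append((keys[0], keys[1], pts[0], pts[1], devs[0], devs[1]))

    if not segments:
        raise EmptyResultError("plane touches the mesh but produces no segments")

    polylines = _chain_segments(segments)
    polylines.sort(key=lambda d: -d["arc_length"][-1])
    return CrossSection(plane, polylines)


def _chain_segments(segments: list) -> list:
    """Join per-triangle segments sharing edge keys into ordered polylines."""
    from collections import defaultdict

    adjacency: dict = defaultdict(list)
    for si, (ka, kb, *_rest) in enumerate(segments):
        adjacency[ka].append(si)
        adjacency[kb].append(si)

    data = {}
    for ka, kb, pa, pb, da, db in segments:
        data.setdefault(ka, (pa, da))
        data.setdefault(kb, (pb, db))

    visited = set()
    polylines = []
    # open chains first (endpoints have degree 1), then closed loops
    endpoints = [k for k, lst in adjacency.items() if len(lst) == 1]
    seeds = endpoints + list(adjacency.keys())
    for seed in seeds:
        if all(si in visited for si in adjacency[seed]):
            continue
        chain_keys = [seed]
        current = seed
        while True:
            nxt_seg = next(
                (si for si in adjacency[current] if si not in visited), None
            )
            if nxt_seg is None:
                break
            visited.add(nxt_seg)
            ka, kb, *_ = segments[nxt_seg]
            current = kb if ka == current else ka
            chain_keys.append(current)
        if len(chain_keys) < 2:
            continue
        pts = np.array([data[k][0] for k in chain_keys])
        devs = np.array([data[k][1] for k in chain_keys])
        arc = np.concatenate(
            [[0.0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))]
        )
        polylines.append({"points": pts, "arc_length": arc, "deviation": devs})
    return polylines


# -- export --------------------------------------------------------------

def deviation_to_rgb(values: np.ndarray, display_limit: float) -> np.ndarray:
    """Diverging blue -> green -> red scale clamped at +-display_limit."""
    u = np.clip(np.asarray(values, dtype=np.float64) / display_limit, -1.0, 1.0)
    r = np.where(u > 0, np.rint(255 * u), 0)
    b = np.where(u < 0, np.rint(255 * -u), 0)
    g = np.rint(255 * (1.0 - np.abs(u)))
    return np.stack([r, g, b], axis=1).astype(np.uint8)


def export_color_map(
    test_aligned: TriangleMesh,
    field: DeviationField,
    cutoff: float,
    path: str | Path,
    display_limit: float = DEFAULT_DISPLAY_LIMIT_MM,
) -> tuple[Path, Path]:
    """Write an ASCII PLY with per-vertex colors + deviation scalar, and a
    CSV table (vertex id, x, y, z, deviation, class) alongside.

    Returns (ply_path, csv_path).
    """
    path = Path(path)
    csv_path = path.with_suffix(".csv")
    mesh = test_aligned
    colors = deviation_to_rgb(field.values, display_limit)
    classes = classify_deviation(field, cutoff)
    label_names = {1: "plus", 0: "neutral", -1: "minus"}
    try:
        with open(path, "w") as fh:
            fh.write("ply\nformat ascii 1.0\n")
            fh.write(f"element vertex {mesh.n_vertices}\n")
            fh.write(
                "property float x\nproperty float y\nproperty float z\n"
                "property uchar red\nproperty uchar green\nproperty uchar blue\n"
                "property float deviation\n"
            )
            fh.write(f"element face {mesh.n_faces}\n")
            fh.write("property list uchar int vertex_indices\nend_header\n")
            for v, c, d in zip(mesh.vertices, colors, field.values):
                fh.write(
                    f"{v[0]:.9g} {v[1]:.9g} {v[2]:.9g} "
                    f"{c[0]} {c[1]} {c[2]} {d:.9g}\n"
                )
            for face in mesh.faces:
                fh.write(f"3 {face[0]} {face[1]} {face[2]}\n")
        with open(csv_path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["vertex_id", "x", "y", "z", "deviation", "class"])
            for i, (v, d, lab) in enumerate(
                zip(mesh.vertices, field.values, classes.labels)
            ):
                writer.writerow(
                    [
                        i,
                        repr(float(v[0])),
                        repr(float(v[1])),
                        repr(float(v[2])),
                        repr(float(d)),
                        label_names[int(lab)],
                    ]
                )
    except OSError as exc:
        raise MeshIOError(f"cannot write color map: {exc}") from exc
    return path, csv_path


def load_deviation_csv(csv_path: str | Path) -> np.ndarray:
    """Reload the deviation column written by export_color_map, bitwise."""
    out = []
    with open(csv_path, newline="") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            out.append(float(row["deviation"]))
    return np.array(out, dtype=np.float64)
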