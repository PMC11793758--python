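"""Core triangle-mesh types and STL / XYZ input-output.

All coordinates are millimetres by contract.  Meshes are open surfaces:
no watertightness is required or checked.  Orientation is taken from the
face winding in the file; no global reorientation pass is applied.
"""

from __future__ import annotations

import logging
import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import MeshIOError, ValidationError

log = logging.getLogger(__name__)

#: duplicate vertices closer than this (per coordinate, after rounding to
#: 9 decimals) are merged into a shared index at load time
MERGE_DECIMALS = 9


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned bounding box in mm."""

    min_corner: np.ndarray
    max_corner: np.ndarray

    def __post_init__(self) -> None:
        lo = np.asarray(self.min_corner, dtype=float)
        hi = np.asarray(self.max_corner, dtype=float)
        if lo.shape != (3,) or hi.shape != (3,):
            raise ValidationError("bounding box corners must be 3-vectors")
        if np.any(lo > hi):
            raise ValidationError("bounding box min corner exceeds max corner")
        object.__setattr__(self, "min_corner", lo)
        object.__setattr__(self, "max_corner", hi)

    @property
    def extent(self) -> np.ndarray:
        return self.max_corner - self.min_corner


@dataclass
class TriangleMesh:
    """Indexed triangle surface.

    Parameters
    ----------
    vertices : (n, 3) float array, mm
    faces : (m, 3) int array of vertex indices
    vertex_normals : optional (n, 3) unit vectors
    """

    vertices: np.ndarray
    faces: np.ndarray
    vertex_normals: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        v = np.ascontiguousarray(np.asarray(self.vertices, dtype=np.float64))
        f = np.ascontiguousarray(np.asarray(self.faces, dtype=np.int64))
        if v.ndim != 2 or v.shape[1] != 3:
            raise ValidationError(f"vertices must be (n, 3), got {v.shape}")
        if f.size and (f.ndim != 2 or f.shape[1] != 3):
            raise ValidationError(f"faces must be (m, 3), got {f.shape}")
        if f.size == 0:
            f = f.reshape(0, 3)
        if not np.all(np.isfinite(v)):
            raise ValidationError("vertex coordinates must be finite")
        if f.size and (f.min() < 0 or f.max() >= len(v)):
            raise ValidationError("face indices out of range")
        self.vertices = v
        self.faces = f
        if self.vertex_normals is not None:
            n = np.asarray(self.vertex_normals, dtype=np.float64)
            if n.shape != v.shape:
                raise ValidationError("vertex_normals shape mismatch")
            self.vertex_normals = n

    # -- basic queries ---------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def bounds(self) -> BoundingBox:
        if self.n_vertices == 0:
            raise ValidationError("empty mesh has no bounds")
        return BoundingBox(self.vertices.min(axis=0), self.vertices.max(axis=0))

    def triangles(self) -> np.ndarray:
        """(m, 3, 3) array of triangle corner coordinates."""
        return self.vertices[self.faces]

    def face_cross(self) -> np.ndarray:
        """Un-normalised face normals (cross products); |.| = 2 * area."""
        t = self.triangles()
        return np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0])

    def face_normals(self) -> np.ndarray:
        c = self.face_cross()
        norm = np.linalg.norm(c, axis=1, keepdims=True)
        norm[norm == 0.0] = 1.0
        return c / norm

    def face_areas(self) -> np.ndarray:
        return 0.5 * np.linalg.norm(self.face_cross(), axis=1)

    def copy(self) -> "TriangleMesh":
        return TriangleMesh(
            self.vertices.copy(),
            self.faces.copy(),
            None if self.vertex_normals is None else self.vertex_normals.copy(),
        )


def surface_area(mesh: TriangleMesh) -> float:
    """Total surface area in mm^2 (sum of triangle areas)."""
    return float(mesh.face_areas().sum())


def compute_vertex_normals(mesh: TriangleMesh) -> np.ndarray:
    """Area-weighted per-vertex unit normals following the face winding.

    Isolated vertices (referenced by no face) get a zero normal and are
    counted in a log warning.
    """
    if mesh.n_vertices == 0:
        raise ValidationError("cannot compute normals of an empty mesh")
    acc = np.zeros_like(mesh.vertices)
    # cross product magnitude is proportional to face area, so summing the
    # raw cross products is the area-weighted mean up to normalisation
    cross = mesh.face_cross()
    for k in range(3):
        np.add.at(acc, mesh.faces[:, k], cross)
    norms = np.linalg.norm(acc, axis=1)
    isolated = norms == 0.0
    if isolated.any():
        log.warning("%d isolated/degenerate-normal vertices flagged", int(isolated.sum()))
    safe = norms.copy()
    safe[isolated] = 1.0
    return acc / safe[:, None]


def merge_duplicate_vertices(
    vertices: np.ndarray, faces: np.ndarray
) -> tuple[np.ndarray, np.ndarray, int]:
    """Merge vertices identical after rounding to MERGE_DECIMALS decimals.

    Returns (vertices, faces, n_merged).
    """
    rounded = np.round(np.asarray(vertices, dtype=np.float64), MERGE_DECIMALS)
    # normalise -0.0 so it hashes like +0.0
    rounded[rounded == 0.0] = 0.0
    uniq, index, inverse = np.unique(
        rounded, axis=0, return_index=True, return_inverse=True
    )
    inverse = inverse.reshape(-1)
    n_merged = len(vertices) - len(uniq)
    new_vertices = np.asarray(vertices, dtype=np.float64)[np.sort(index)]
    # remap through sorted-order indices so first occurrence order is kept
    order = np.argsort(index)
    rank = np.empty_like(order)
    rank[order] = np.arange(len(order))
    new_faces = rank[inverse][np.asarray(faces, dtype=np.int64)]
    return new_vertices, new_faces, n_merged


def drop_degenerate_faces(
    vertices: np.ndarray, faces: np.ndarray
) -> tuple[np.ndarray, int]:
    """Remove faces with repeated indices or zero area."""
    faces = np.asarray(faces, dtype=np.int64)
    if faces.size == 0:
        return faces.reshape(0, 3), 0
    repeated = (
        (faces[:, 0] == faces[:, 1])
        | (faces[:, 1] == faces[:, 2])
        | (faces[:, 0] == faces[:, 2])
    )
    t = vertices[faces]
    areas = 0.5 * np.linalg.norm(np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0]), axis=1)
    bad = repeated | (areas == 0.0)
    return faces[~bad], int(bad.sum())


def _clean(vertices: np.ndarray, faces: np.ndarray, origin: str) -> TriangleMesh:
    v, f, n_merged = merge_duplicate_vertices(vertices, faces)
    f, n_dropped = drop_degenerate_faces(v, f)
    if n_merged or n_dropped:
        log.info(
            "%s: merged %d duplicate vertices, dropped %d degenerate faces",
            origin,
            n_merged,
            n_dropped,
        )
    if len(f) == 0:
        raise ValidationError(f"{origin}: no valid faces after cleaning")
    return TriangleMesh(v, f)


# -- STL ----------------------------------------------------------------

_BINARY_FACET = struct.Struct("<12fH")


def _looks_ascii(path: Path) -> bool:
    with open(path, "rb") as fh:
        head = fh.read(512)
        size = path.stat().st_size
    # binary files state the facet count at byte 80; trust it when the
    # size matches exactly, otherwise fall back to keyword heuristics
    if size >= 84:
        (n_facets,) = struct.unpack("<I", head[80:84])
        if size == 84 + 50 * n_facets:
            return False
    return head.lstrip().lower().startswith(b"solid") and b"facet" in head.lower()


def _read_ascii_stl(path: Path) -> tuple[np.ndarray, np.ndarray]:
    coords: list[float] = []
    with open(path, "r", errors="replace") as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if len(parts) >= 4 and parts[0].lower() == "vertex":
                try:
                    coords.extend(float(x) for x in parts[1:4])
                except ValueError as exc:
                    raise MeshIOError(
                        f"{path}: bad vertex at line {lineno}: {line.strip()!r}"
                    ) from exc
    if not coords or len(coords) % 9 != 0:
        raise MeshIOError(
            f"{path}: truncated ASCII STL ({len(coords)} coordinates, "
            "expected a multiple of 9)"
        )
    vertices = np.array(coords, dtype=np.float64).reshape(-1, 3)
    faces = np.arange(len(vertices), dtype=np.int64).reshape(-1, 3)
    return vertices, faces


def _read_binary_stl(path: Path) -> tuple[np.ndarray, np.ndarray]:
    raw = path.read_bytes()
    if len(raw) < 84:
        raise MeshIOError(f"{path}: truncated binary STL header at byte {len(raw)}")
    (n_facets,) = struct.unpack("<I", raw[80:84])
    expected = 84 + 50 * n_facets
    if len(raw) < expected:
        raise MeshIOError(
            f"{path}: truncated binary STL at byte {len(raw)}, expected {expected}"
        )
    body = np.frombuffer(raw, dtype=np.uint8, count=50 * n_facets, offset=84)
    body = body.reshape(n_facets, 50)
    floats = body[:, :48].copy().view("<f4").reshape(n_facets, 12)
    vertices = floats[:, 3:12].astype(np.float64).reshape(-1, 3)
    faces = np.arange(len(vertices), dtype=np.int64).reshape(-1, 3)
    return vertices, faces


def read_stl(path: str | Path) -> TriangleMesh:
    """Read a binary or ASCII STL file into a cleaned TriangleMesh.

    Duplicate corner coordinates are merged into shared vertex indices;
    degenerate (zero-area) faces are dropped; counts are logged.
    """
    path = Path(path)
    if not path.is_file():
        raise MeshIOError(f"{path}: no such file")
    if path.stat().st_size == 0:
        raise ValidationError(f"{path}: empty file")
    if _looks_ascii(path):
        vertices, faces = _read_ascii_stl(path)
    else:
        vertices, faces = _read_binary_stl(path)
    return _clean(vertices, faces, str(path))


def write_stl(mesh: TriangleMesh, path: str | Path, dialect: str = "binary") -> Path:
    """Write ``mesh`` as STL.  ``dialect`` is 'binary' or 'ascii'.

    The binary dialect is byte-stable: identical meshes produce identical
    files (fixed header, no timestamps).
    """
    if dialect not in ("binary", "ascii"):
        raise ValidationError(f"unknown STL dialect {dialect!r}")
    path = Path(path)
    tri = mesh.triangles()
    normals = mesh.face_normals()
    try:
        if dialect == "ascii":
            with open(path, "w") as fh:
                fh.write("solid archmorph\n")
                for n, t in zip(normals, tri):
                    fh.write(f"  facet normal {n[0]:.9e} {n[1]:.9e} {n[2]:.9e}\n")
                    fh.write("    outer loop\n")
                    for v in t:
                        fh.write(f"      vertex {v[0]:.9e} {v[1]:.9e} {v[2]:.9e}\n")
                    fh.write("    endloop\n")
                    fh.write("  endfacet\n")
                fh.write("endsolid archmorph\n")
        else:
            header = b"archmorph binary STL".ljust(80, b"\0")
            with open(path, "wb") as fh:
                fh.write(header)
                fh.write(struct.pack("<I", mesh.n_faces))
                block = np.zeros((mesh.n_faces, 50), dtype=np.uint8)
                data = np.concatenate(
                    [normals.astype("<f4"), tri.reshape(-1, 9).astype("<f4")], axis=1
                )
                block[:, :48] = data.view(np.uint8).reshape(mesh.n_faces, 48)
                fh.write(block.tobytes())
    except OSError as exc:
        raise MeshIOError(f"cannot write {path}: {exc}") from exc
    return path


# -- XYZ point clouds ---------------------------------------------------

def read_xyz(path: str | Path) -> np.ndarray:
    """Read a whitespace-separated XYZ text file into an (n, 3) array."""
    path = Path(path)
    if not path.is_file():
        raise MeshIOError(f"{path}: no such file")
    try:
        pts = np.loadtxt(path, dtype=np.float64, ndmin=2)
    except ValueError as exc:
        raise MeshIOError(f"{path}: unparsable XYZ file: {exc}") from exc
    if pts.shape[1] < 3:
        raise MeshIOError(f"{path}: expected >= 3 columns, got {pts.shape[1]}")
    return pts[:, :3]


def write_xyz(points: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    np.savetxt(path, np.asarray(points, dtype=np.float64), fmt="%.9e")
    return path
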