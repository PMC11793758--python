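import numpy as np
import pytest

from archmorph import ArchParams, TriangleMesh, generate_arch_appliance


def make_grid_patch(n: int = 11, size: float = 10.0) -> TriangleMesh:
    """Flat square patch in z=0, counter-clockwise winding seen from +z."""
    g = np.linspace(0.0, size, n)
    xx, yy = np.meshgrid(g, g)
    v = np.column_stack([xx.ravel(), yy.ravel(), np.zeros(n * n)])
    f = []
    for i in range(n - 1):
        for j in range(n - 1):
            a = i * n + j
            f += [(a, a + 1, a + n + 1), (a, a + n + 1, a + n)]
    return TriangleMesh(v, np.array(f))


def make_icosphere(radius: float = 1.0, subdivisions: int = 3) -> TriangleMesh:
    """Subdivided icosahedron with vertices projected onto the sphere."""
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    verts = np.array(
        [
            [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
            [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
            [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1],
        ],
        dtype=float,
    )
    verts /= np.linalg.norm(verts, axis=1, keepdims=True)
    faces = np.array(
        [
            [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
            [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
            [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
            [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
        ]
    )
    for _ in range(subdivisions):
        edge_mid: dict = {}
        new_faces = []
        verts_list = list(verts)

        def midpoint(a: int, b: int) -> int:
            key = (min(a, b), max(a, b))
            if key not in edge_mid:
                m = verts_list[a] + verts_list[b]
                m /= np.linalg.norm(m)
                verts_list.append(m)
                edge_mid[key] = len(verts_list) - 1
            return edge_mid[key]

        for a, b, c in faces:
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            new_faces += [[a, ab, ca], [b, bc, ab], [c, ca, bc], [ab, bc, ca]]
        verts = np.array(verts_list)
        faces = np.array(new_faces)
    return TriangleMesh(verts * radius, faces)


def random_smooth_field(mesh: TriangleMesh, rng: np.random.Generator, scale: float = 0.1) -> np.ndarray:
    """Spatially smooth random scalar field: a few low-frequency waves."""
    v = mesh.vertices
    extent = np.linalg.norm(v.max(axis=0) - v.min(axis=0))
    out = np.zeros(len(v))
    for _ in range(4):
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        wavelength = rng.uniform(0.3, 1.0) * extent
        phase = rng.uniform(0, 2 * np.pi)
        amp = rng.uniform(0.2, 1.0) * scale
        out += amp * np.sin(2 * np.pi * (v @ direction) / wavelength + phase)
    return out


@pytest.fixture(scope="session")
def arch_params() -> ArchParams:
    return ArchParams(resolution=0.8)


@pytest.fixture(scope="session")
def base_arch(arch_params):
    return generate_arch_appliance(arch_params)


@pytest.fixture()
def patch():
    return make_grid_patch()
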