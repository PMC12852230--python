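"""Labeled tetrahedral meshes of synthetic breast geometries.

The generalized (low-fidelity) geometry is a hemispherical breast resting on
the chest-wall plane ``z = 0`` with a spherical excision cavity centered on
the apex axis.  Because the hemisphere is convex, a Delaunay tessellation of
points placed on its boundary and interior tessellates the solid exactly
(no concave pockets), which lets :mod:`scipy.spatial` do the meshing.

Units are mm throughout.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay

__all__ = [
    "BreastMesh",
    "MeshError",
    "build_breast_mesh",
    "tet_volumes",
    "extract_boundary",
    "write_vtu",
    "write_stl",
]

TISSUE, CAVITY = 0, 1
SKIN, CHEST_WALL = 0, 1

# interior grid resolution (points across the hemisphere radius) per fidelity;
# the cube-root ratio 5/7.5 puts the low-fidelity element count near 30 % of
# the high-fidelity one
_RESOLUTION = {"low": 4.0, "high": 6.0}
# cavity-surface point budget per fidelity
_N_CAVITY_SURF = {"low": 72, "high": 150}


class MeshError(RuntimeError):
    """Raised when mesh generation produces an invalid tessellation."""


@dataclass
class BreastMesh:
    """Labeled tetrahedral breast domain.

    Attributes
    ----------
    points : (n, 3) float array, mm
    tets : (m, 4) int array, positively oriented
    region : (m,) int array, ``TISSUE`` or ``CAVITY``
    boundary_faces : (k, 3) int array of boundary triangles
    boundary_label : (k,) int array, ``SKIN`` or ``CHEST_WALL``
    fidelity : ``"low"`` or ``"high"``
    cavity_center : (3,) requested cavity-sphere center
    cavity_radius : requested (margin-expanded) cavity-sphere radius
    """

    points: np.ndarray
    tets: np.ndarray
    region: np.ndarray
    boundary_faces: np.ndarray
    boundary_label: np.ndarray
    fidelity: str = "low"
    cavity_center: np.ndarray = field(default_factory=lambda: np.zeros(3))
    cavity_radius: float = 0.0

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    @property
    def n_tets(self) -> int:
        return self.tets.shape[0]

    def volumes(self) -> np.ndarray:
        return tet_volumes(self.points, self.tets)

    def breast_volume(self) -> float:
        return float(self.volumes().sum())

    def cavity_volume(self) -> float:
        return float(self.volumes()[self.region == CAVITY].sum())

    def skin_vertices(self) -> np.ndarray:
        return np.unique(self.boundary_faces[self.boundary_label == SKIN])

    def chest_wall_vertices(self) -> np.ndarray:
        return np.unique(self.boundary_faces[self.boundary_label == CHEST_WALL])


def tet_volumes(points: np.ndarray, tets: np.ndarray) -> np.ndarray:
    """Signed volumes of tetrahedra (positive for correct orientation)."""
    p = points[tets]
    e = p[:, 1:] - p[:, :1]
    return np.einsum("ij,ij->i", e[:, 0], np.cross(e[:, 1], e[:, 2])) / 6.0


def extract_boundary(tets: np.ndarray) -> np.ndarray:
    """Triangular faces that belong to exactly one tetrahedron."""
    faces = tets[:, [[1, 2, 3], [0, 3, 2], [0, 1, 3], [0, 2, 1]]].reshape(-1, 3)
    key = np.sort(faces, axis=1)
    _, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
    return faces[counts[inv] == 1]


def _fibonacci_sphere(n: int, rng: np.random.Generator) -> np.ndarray:
    """Near-uniform points on the unit sphere (golden-angle spiral)."""
    i = np.arange(n, dtype=float) + 0.5
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    # seeded azimuthal offset decorrelates meshes between patients
    phi = np.pi * (1 + 5**0.5) * i + rng.uniform(0, 2 * np.pi)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _hemisphere_points(R: float, h: float, rng: np.random.Generator) -> np.ndarray:
    """Boundary points of a radius-``R`` hemisphere (z >= 0): dome latitude
    rings from apex to the equatorial rim, a sub-surface witness layer, and
    concentric base-disk rings."""
    n_lat = max(3, int(np.ceil(0.5 * np.pi * R / h)))
    dth = 0.5 * np.pi / n_lat
    dome = [np.array([[0.0, 0.0, R]])]
    for i in range(1, n_lat + 1):
        th = i * dth
        rr = R * np.sin(th)
        ni = max(6, int(np.ceil(2.0 * np.pi * rr / h)))
        t = 2.0 * np.pi * (np.arange(ni) + rng.uniform()) / ni
        ring = np.column_stack([rr * np.cos(t), rr * np.sin(t), np.full(ni, R * np.cos(th))])
        if i < n_lat:
            # slight inward radial jitter de-cosphericalizes boundary point
            # quadruples (outward-bulging slivers have no interior witness)
            ring *= (1.0 - rng.uniform(0.0, 0.12 * h / R, size=ni))[:, None]
        dome.append(ring)
    # sub-surface witness layer against near-coplanar boundary circumspheres
    n_sub = max(20, int(np.ceil(np.pi * ((R - 0.7 * h) / h) ** 2)))
    sub = _fibonacci_sphere(2 * n_sub, rng)
    sub = (R - 0.7 * h) * sub[sub[:, 2] > 0.15]

    base = []
    n_rings = max(2, int(np.round(R / h)))
    for k in range(1, n_rings):
        rk = R * k / n_rings
        nk = max(6, int(np.ceil(2 * np.pi * rk / h)))
        t = 2 * np.pi * (np.arange(nk) + rng.uniform()) / nk
        base.append(np.column_stack([rk * np.cos(t), rk * np.sin(t), np.zeros(nk)]))
    base.append(np.zeros((1, 3)))
    return np.vstack([*dome, *base]), sub


def _interior_grid(
    R: float, h: float, center: np.ndarray, r_cav: float, rng: np.random.Generator
) -> np.ndarray:
    # body-centered cubic lattice: its Delaunay tessellation is far better
    # conditioned than a perturbed cubic grid (no slivers in the bulk)
    ax = np.arange(-R + h / 2, R, h)
    az = np.arange(h / 2, R, h)
    X, Y, Z = np.meshgrid(ax, ax, az, indexing="ij")
    cubic = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    pts = np.vstack([cubic, cubic + h / 2.0])
    pts = pts + rng.uniform(-0.05 * h, 0.05 * h, size=pts.shape)
    rad = np.linalg.norm(pts, axis=1)
    d_cav = np.linalg.norm(pts - center, axis=1)
    keep = (rad < R - 0.95 * h) & (pts[:, 2] > 0.4 * h) & (d_cav > r_cav + 0.55 * h)
    return pts[keep]


def _cavity_points(
    center: np.ndarray, r: float, n_surf: int, rng: np.random.Generator
):
    """Cavity-sphere surface + interior points, and graded tissue shells just
    outside the cavity that resolve the peri-cavity healing band (returned
    separately; they are tissue, not cavity)."""
    surf = center + r * _fibonacci_sphere(n_surf, rng)
    inner = [center[None, :]]
    if r > 3.0:
        n_in = max(12, n_surf // 4)
        inner.append(center + 0.55 * r * _fibonacci_sphere(n_in, rng))
    s = r * np.sqrt(4.0 * np.pi / n_surf)  # cavity-surface point spacing
    band = center + (r + 0.55 * s) * _fibonacci_sphere(n_surf, rng)
    return np.vstack([surf, *inner]), band


def _ellipsoidal_perturbation(
    pts: np.ndarray, R: float, center: np.ndarray, r_cav: float, rng: np.random.Generator
) -> np.ndarray:
    """Smooth, volume-preserving in-plane scaling applied away from the cavity.

    Gives the high-fidelity geometry a patient-specific deviation from the
    ideal hemisphere while leaving the cavity sphere and the apex depth line
    untouched (the blend weight vanishes within two cavity radii).
    """
    ax = rng.uniform(0.93, 1.07)
    ay = rng.uniform(0.99, 1.01) / ax
    d = np.linalg.norm(pts - center, axis=1)
    w = np.clip((d - 1.4 * r_cav) / (1.2 * r_cav), 0.0, 1.0)
    w = w * w * (3 - 2 * w)  # smoothstep
    out = pts.copy()
    out[:, 0] = pts[:, 0] * (1 + w * (ax - 1))
    out[:, 1] = pts[:, 1] * (1 + w * (ay - 1))
    return out


def _tessellate(points: np.ndarray, cavity_flag: np.ndarray, outer_flag: np.ndarray):
    tri = Delaunay(points, qhull_options="QJ")
    tets = tri.simplices
    vol = tet_volumes(points, tets)
    flip = vol < 0
    tets[flip] = tets[flip][:, [0, 1, 3, 2]]
    vol = np.abs(vol)
    # discard boundary-flat slivers: tets with all four vertices on the outer
    # surface and near-zero height (their circumsphere bulges outside the
    # hull, so Delaunay cannot avoid them); removing them dents the surface
    # by a negligible volume and leaves a consistent boundary
    edges = points[tets]
    longest = np.linalg.norm(
        edges[:, :, None, :] - edges[:, None, :, :], axis=-1
    ).max(axis=(1, 2))
    q = vol / longest**3
    flat = outer_flag[tets].all(axis=1) & (q < 1e-3)
    good = (vol > 1e-12 * vol.max()) & ~flat
    tets, vol = tets[good], vol[good]
    region = np.where(cavity_flag[tets].all(axis=1), CAVITY, TISSUE)
    return tets, vol, region


def build_breast_mesh(
    breast_volume: float,
    cavity_volume: float,
    cavity_depth: float,
    margin_width: float = 0.0,
    fidelity: str = "low",
    seed: int = 0,
) -> BreastMesh:
    """Mesh a hemispherical breast with an interior spherical cavity.

    The hemisphere radius follows from the requested breast volume,
    ``R = (3 V / 2 pi)^(1/3)``; the cavity sphere radius from the cavity
    (tumor) volume plus the surgical margin.  The cavity sits on the apex
    axis at the prescribed depth below the skin.  A single corrective
    rebuild rescales the polyhedral surfaces so that both the meshed breast
    and cavity volumes land within tolerance of their targets.
    """
    from .cohort import cavity_radius as _cavity_radius  # local import, no cycle at module load

    if fidelity not in _RESOLUTION:
        raise ValueError(f"fidelity must be 'low' or 'high', got {fidelity!r}")
    R = (3.0 * breast_volume / (2.0 * np.pi)) ** (1.0 / 3.0)
    r_cav = _cavity_radius(cavity_volume, margin_width)
    center = np.array([0.0, 0.0, R - cavity_depth])
    if cavity_depth < r_cav or center[2] < r_cav:
        raise MeshError(
            f"cavity (r={r_cav:.2f} mm) breaches the surface at depth "
            f"{cavity_depth:.2f} mm in a breast of radius {R:.2f} mm"
        )

    rng = np.random.default_rng(seed)
    h = R / _RESOLUTION[fidelity]
    n_cav = _N_CAVITY_SURF[fidelity]
    v_cav_target = 4.0 * np.pi / 3.0 * r_cav**3

    # polyhedral surfaces under-estimate the enclosed volume; one corrective
    # pass rescales the surface point radii to hit the volume targets
    R_eff, r_eff = R, r_cav
    mesh = None
    for _ in range(2):
        rng_pass = np.random.default_rng(seed)
        hemi, sub = _hemisphere_points(R_eff, h, rng_pass)
        cav, band = _cavity_points(center, r_eff, n_cav, rng_pass)
        grid = _interior_grid(R_eff, h, center, r_eff, rng_pass)
        # drop lattice/band points that collide with the graded shells
        from scipy.spatial import cKDTree
        tree = cKDTree(band)
        s_band = 0.45 * r_eff * np.sqrt(4.0 * np.pi / n_cav)
        grid = grid[tree.query(grid)[0] > s_band]
        pts = np.vstack([hemi, sub, cav, band, grid])
        if fidelity == "high":
            pts = _ellipsoidal_perturbation(pts, R_eff, center, r_eff, rng_pass)
        outer_flag = np.zeros(len(pts), dtype=bool)
        outer_flag[: len(hemi)] = True
        cavity_flag = np.zeros(len(pts), dtype=bool)
        cavity_flag[len(hemi) + len(sub) : len(hemi) + len(sub) + len(cav)] = True
        tets, vol, region = _tessellate(pts, cavity_flag, outer_flag)
        v_total = vol.sum()
        v_cavity = vol[region == CAVITY].sum()
        mesh = (pts, tets, region)
        if v_cavity <= 0:
            raise MeshError("cavity region empty after tessellation")
        r_eff *= (v_cav_target / v_cavity) ** (1.0 / 3.0)
        # breast correction: inflate the outer surface only (cavity handled above)
        R_eff *= ((breast_volume - v_cav_target) / max(v_total - v_cavity, 1.0)) ** (1.0 / 3.0)

    pts, tets, region = mesh
    faces = extract_boundary(tets)
    on_base = np.abs(pts[:, 2]) < 1e-9 * max(R, 1.0)
    label = np.where(on_base[faces].all(axis=1), CHEST_WALL, SKIN)

    out = BreastMesh(
        points=np.ascontiguousarray(pts),
        tets=np.ascontiguousarray(tets),
        region=region,
        boundary_faces=faces,
        boundary_label=label,
        fidelity=fidelity,
        cavity_center=center,
        cavity_radius=r_cav,
    )
    _validate(out, breast_volume, v_cav_target)
    return out


def _validate(mesh: BreastMesh, v_breast: float, v_cavity: float) -> None:
    vol = mesh.volumes()
    if (vol <= 0).any():
        raise MeshError(f"{int((vol <= 0).sum())} non-positive tetrahedra")
    vb, vc = vol.sum(), vol[mesh.region == CAVITY].sum()
    if abs(vb - v_breast) > 0.05 * v_breast:
        raise MeshError(f"meshed breast volume {vb:.0f} vs requested {v_breast:.0f} mm^3")
    if abs(vc - v_cavity) > 0.05 * v_cavity:
        raise MeshError(f"meshed cavity volume {vc:.1f} vs requested {v_cavity:.1f} mm^3")
    if len(mesh.boundary_faces) != (mesh.boundary_label >= 0).sum():
        raise MeshError("boundary labeling incomplete")


# ---------------------------------------------------------------------------
# plain-text writers (ASCII VTU / STL)


def write_vtu(path, mesh: BreastMesh, point_data=None, cell_data=None, points=None):
    """Write the mesh as an ASCII XML VTK unstructured grid (.vtu)."""
    pts = mesh.points if points is None else points
    point_data = point_data or {}
    cell_data = dict(cell_data or {})
    cell_data.setdefault("region", mesh.region)
    n, m = len(pts), len(mesh.tets)
    buf = io.StringIO()
    w = buf.write
    w('<?xml version="1.0"?>\n<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">\n')
    w(f'<UnstructuredGrid>\n<Piece NumberOfPoints="{n}" NumberOfCells="{m}">\n')
    w('<Points>\n<DataArray type="Float64" NumberOfComponents="3" format="ascii">\n')
    np.savetxt(buf, pts, fmt="%.9g")
    w("</DataArray>\n</Points>\n<Cells>\n")
    w('<DataArray type="Int64" Name="connectivity" format="ascii">\n')
    np.savetxt(buf, mesh.tets, fmt="%d")
    w('</DataArray>\n<DataArray type="Int64" Name="offsets" format="ascii">\n')
    np.savetxt(buf, 4 * np.arange(1, m + 1)[:, None], fmt="%d")
    w('</DataArray>\n<DataArray type="UInt8" Name="types" format="ascii">\n')
    np.savetxt(buf, np.full((m, 1), 10), fmt="%d")
    w("</DataArray>\n</Cells>\n<PointData>\n")
    for name, arr in point_data.items():
        arr = np.asarray(arr)
        nc = 1 if arr.ndim == 1 else arr.shape[1]
        w(f'<DataArray type="Float64" Name="{name}" NumberOfComponents="{nc}" format="ascii">\n')
        np.savetxt(buf, arr.reshape(n, -1), fmt="%.9g")
        w("</DataArray>\n")
    w("</PointData>\n<CellData>\n")
    for name, arr in cell_data.items():
        arr = np.asarray(arr, dtype=float)
        nc = 1 if arr.ndim == 1 else arr.shape[1]
        w(f'<DataArray type="Float64" Name="{name}" NumberOfComponents="{nc}" format="ascii">\n')
        np.savetxt(buf, arr.reshape(m, -1), fmt="%.9g")
        w("</DataArray>\n")
    w("</CellData>\n</Piece>\n</UnstructuredGrid>\n</VTKFile>\n")
    with open(path, "w") as f:
        f.write(buf.getvalue())


def write_stl(path, points: np.ndarray, faces: np.ndarray, name: str = "surface"):
    """Write a triangulated surface as ASCII STL."""
    p = points[faces]
    nrm = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
    norm = np.linalg.norm(nrm, axis=1, keepdims=True)
    nrm = np.divide(nrm, norm, out=np.zeros_like(nrm), where=norm > 0)
    with open(path, "w") as f:
        f.write(f"solid {name}\n")
        for tri, nv in zip(p, nrm):
            f.write(f"facet normal {nv[0]:.6e} {nv[1]:.6e} {nv[2]:.6e}\n outer loop\n")
            for v in tri:
                f.write(f"  vertex {v[0]:.6e} {v[1]:.6e} {v[2]:.6e}\n")
            f.write(" endloop\nendfacet\n")
        f.write(f"endsolid {name}\n")
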