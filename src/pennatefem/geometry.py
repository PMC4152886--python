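"""Reference geometry and structured hexahedral mesh of the muscle belly.

The belly is a unipennate parallelepiped: in any x-slice the muscle tissue is
a parallelogram whose short sides (length = fiber length, 65 mm) make the
initial pennation angle (15 deg) with the two long sides, which are covered
by flat aponeurosis slabs (210 x 3 mm).  The muscle coordinate frame has its
origin at the bottom-right corner of the deep aponeurosis with x = width,
y = thickness, z = belly length.  Because the two aponeuroses are staggered
by L_f cos(theta0) along z, the total z extent is
apo_length + L_f cos(theta0) (about 272.8 mm for the defaults).

The mesh is a structured grid in (x, y, z_param) with a y-dependent shear
applied to z, so every cell is an affine (sheared-box) hexahedron and the
muscle/aponeurosis interfaces are exact mesh surfaces.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Tuple

import numpy as np

__all__ = [
    "GeometryParams",
    "Resolution",
    "RegionLayout",
    "HexMesh",
    "Region",
    "build_reference_geometry",
    "generate_hex_mesh",
    "assign_fiber_directions",
    "mark_boundaries",
]


class Region:
    """Cell region codes."""
    MUSCLE = 0
    APO_DEEP = 1
    APO_SUPERFICIAL = 2
    NAMES = {0: "muscle", 1: "apo_deep", 2: "apo_superficial"}


@dataclass(frozen=True)
class GeometryParams:
    """Belly dimensions in mm / degrees (lateral-gastrocnemius defaults)."""

    fiber_length: float = 65.0
    pennation_initial: float = 15.0
    belly_width: float = 55.0
    apo_length: float = 210.0
    apo_thickness: float = 3.0

    def __post_init__(self):
        for name in ("fiber_length", "belly_width", "apo_length",
                     "apo_thickness"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.pennation_initial < 90.0:
            raise ValueError("pennation_initial must lie in (0, 90) degrees")

    @property
    def theta0(self) -> float:
        """Initial pennation in radians."""
        return np.deg2rad(self.pennation_initial)

    @property
    def muscle_thickness(self) -> float:
        """y-extent of the muscle layer, L_f sin(theta0)."""
        return self.fiber_length * np.sin(self.theta0)

    @property
    def z_stagger(self) -> float:
        """z offset between deep and superficial slabs, L_f cos(theta0)."""
        return self.fiber_length * np.cos(self.theta0)

    @property
    def z_extent(self) -> float:
        return self.apo_length + self.z_stagger

    @property
    def total_thickness(self) -> float:
        return 2.0 * self.apo_thickness + self.muscle_thickness

    @property
    def volume(self) -> float:
        """Analytic reference volume, mm^3."""
        return self.belly_width * self.apo_length * (
            2.0 * self.apo_thickness + self.muscle_thickness)


@dataclass(frozen=True)
class Resolution:
    """Cells per direction: x, deep/superficial aponeurosis y, muscle y, z."""

    nx: int = 8
    ny_apo: int = 2
    ny_muscle: int = 6
    nz: int = 48

    def __post_init__(self):
        for name in ("nx", "ny_apo", "ny_muscle", "nz"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    @property
    def ny_total(self) -> int:
        return 2 * self.ny_apo + self.ny_muscle

    @property
    def n_cells(self) -> int:
        return self.nx * self.ny_total * self.nz


@dataclass(frozen=True)
class RegionLayout:
    """Closed-form region boundaries of the reference geometry."""

    params: GeometryParams
    y_deep: Tuple[float, float]
    y_muscle: Tuple[float, float]
    y_superficial: Tuple[float, float]
    z_param_range: Tuple[float, float]
    z_extent: float

    def shear(self, y):
        """z shift of the parametric grid at thickness coordinate y."""
        p = self.params
        t = np.clip((np.asarray(y, dtype=float) - p.apo_thickness)
                    / p.muscle_thickness, 0.0, 1.0)
        return t * p.z_stagger

    def region_of(self, y):
        """Region code from the thickness coordinate."""
        y = np.asarray(y, dtype=float)
        p = self.params
        out = np.full(y.shape, Region.MUSCLE, dtype=np.int8)
        out[y < p.apo_thickness] = Region.APO_DEEP
        out[y > p.apo_thickness + p.muscle_thickness] = Region.APO_SUPERFICIAL
        return out


def build_reference_geometry(params: GeometryParams) -> RegionLayout:
    """Analytic description of the deep slab, muscle parallelogram and
    superficial slab.

    Rejects parameter sets where the stagger exceeds the aponeurosis length
    (the slabs would no longer overlap the muscle long sides).
    """
    if params.z_stagger >= params.apo_length:
        raise ValueError(
            "fiber_length*cos(pennation) exceeds apo_length: aponeuroses "
            "would not overlap the muscle long sides")
    t = params.apo_thickness
    tm = params.muscle_thickness
    return RegionLayout(
        params=params,
        y_deep=(0.0, t),
        y_muscle=(t, t + tm),
        y_superficial=(t + tm, 2.0 * t + tm),
        z_param_range=(0.0, params.apo_length),
        z_extent=params.z_extent,
    )


# VTK hexahedron local node order: bottom quad (z-) counterclockwise, then top.
_HEX_CORNERS = np.array([
    [0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
    [0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1]], dtype=int)

# Local faces by axis/side, as node index quadruples of _HEX_CORNERS order.
HEX_FACES = {
    "x-": (0, 3, 7, 4), "x+": (1, 2, 6, 5),
    "y-": (0, 1, 5, 4), "y+": (3, 2, 6, 7),
    "z-": (0, 1, 2, 3), "z+": (4, 5, 6, 7),
}


@dataclass
class HexMesh:
    """Structured sheared-box hexahedral mesh with region labels."""

    params: GeometryParams
    resolution: Resolution
    layout: RegionLayout
    node_coords: np.ndarray          # (n_nodes, 3) mm
    hexes: np.ndarray                # (n_cells, 8) node indices
    cell_region: np.ndarray          # (n_cells,) Region codes
    cell_ijk: np.ndarray             # (n_cells, 3) structured indices
    node_grid: np.ndarray            # (nx+1, ny+1, nz+1) node indices
    facet_sets: Dict[str, np.ndarray] = field(default_factory=dict)
    fiber_a0: np.ndarray | None = None  # (n_cells, 3)

    @property
    def n_nodes(self) -> int:
        return self.node_coords.shape[0]

    @property
    def n_cells(self) -> int:
        return self.hexes.shape[0]

    def cell_volumes(self) -> np.ndarray:
        """Exact cell volumes via 2x2x2 Gauss quadrature (affine cells)."""
        from .solver import quadrature_data
        _, detJ, _ = quadrature_data(self)
        return detJ.sum(axis=1)


def generate_hex_mesh(params: GeometryParams,
                      resolution: Resolution = Resolution()) -> HexMesh:
    """Structured mesh conforming to the region interfaces."""
    layout = build_reference_geometry(params)
    res = resolution
    p = params

    xs = np.linspace(0.0, p.belly_width, res.nx + 1)
    y_deep = np.linspace(0.0, p.apo_thickness, res.ny_apo + 1)
    y_mus = np.linspace(p.apo_thickness, p.apo_thickness + p.muscle_thickness,
                        res.ny_muscle + 1)
    y_sup = np.linspace(p.apo_thickness + p.muscle_thickness,
                        p.total_thickness, res.ny_apo + 1)
    ys = np.concatenate([y_deep, y_mus[1:], y_sup[1:]])
    zp = np.linspace(0.0, p.apo_length, res.nz + 1)

    nyn = ys.size
    node_grid = np.arange(xs.size * nyn * zp.size).reshape(
        xs.size, nyn, zp.size)
    X, Y, Zp = np.meshgrid(xs, ys, zp, indexing="ij")
    Z = Zp + layout.shear(Y)
    node_coords = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)

    cells = []
    regions = []
    ijk = []
    for i in range(res.nx):
        for j in range(res.ny_total):
            for k in range(res.nz):
                corners = _HEX_CORNERS + np.array([i, j, k])
                cells.append([node_grid[tuple(c)] for c in corners])
                y_mid = 0.5 * (ys[j] + ys[j + 1])
                regions.append(int(layout.region_of(y_mid)))
                ijk.append((i, j, k))
    mesh = HexMesh(
        params=params, resolution=res, layout=layout,
        node_coords=node_coords,
        hexes=np.asarray(cells, dtype=np.int64),
        cell_region=np.asarray(regions, dtype=np.int8),
        cell_ijk=np.asarray(ijk, dtype=np.int64),
        node_grid=node_grid,
    )
    mark_boundaries(mesh)
    assign_fiber_directions(mesh, params)
    return mesh


def assign_fiber_directions(mesh: HexMesh, params: GeometryParams) -> np.ndarray:
    """Unit reference fiber directions per cell.

    Muscle fibers lie in the y-z plane at the initial pennation angle to z;
    aponeurosis collagen runs along +z.
    """
    th = params.theta0
    a0 = np.zeros((mesh.n_cells, 3))
    muscle = mesh.cell_region == Region.MUSCLE
    a0[muscle] = (0.0, np.sin(th), np.cos(th))
    a0[~muscle] = (0.0, 0.0, 1.0)
    mesh.fiber_a0 = a0
    return a0


def mark_boundaries(mesh: HexMesh) -> Dict[str, np.ndarray]:
    """Boundary facet sets: the two fixed aponeurosis ends, the measurement
    plane (= the z = 0 cross-section of the deep aponeurosis) and the free
    remainder.  Facets are (cell_index, face_name) pairs.
    """
    res = mesh.resolution
    deep_j = range(0, res.ny_apo)
    sup_j = range(res.ny_apo + res.ny_muscle, res.ny_total)

    idx = {tuple(v): c for c, v in enumerate(map(tuple, mesh.cell_ijk))}

    def cid(i, j, k):
        return idx[(i, j, k)]

    fixed_deep, fixed_sup, free = [], [], []
    for i in range(res.nx):
        for j in range(res.ny_total):
            for k in range(res.nz):
                c = cid(i, j, k)
                if i == 0:
                    free.append((c, "x-"))
                if i == res.nx - 1:
                    free.append((c, "x+"))
                if j == 0:
                    free.append((c, "y-"))
                if j == res.ny_total - 1:
                    free.append((c, "y+"))
                if k == 0:
                    (fixed_deep if j in deep_j else free).append((c, "z-"))
                if k == res.nz - 1:
                    (fixed_sup if j in sup_j else free).append((c, "z+"))
    if not fixed_deep or not fixed_sup:
        raise ValueError("fixed facet sets must be non-empty")
    sets = {
        "fixed_deep_end": np.array(fixed_deep, dtype=object),
        "fixed_superficial_end": np.array(fixed_sup, dtype=object),
        "measurement_plane": np.array(fixed_deep, dtype=object),
        "free": np.array(free, dtype=object),
    }
    mesh.facet_sets = sets
    return sets


def fixed_node_ids(mesh: HexMesh) -> np.ndarray:
    """Node indices with zero prescribed displacement (both fixed ends)."""
    ids = set()
    for name in ("fixed_deep_end", "fixed_superficial_end"):
        for c, face in mesh.facet_sets[name]:
            ids.update(mesh.hexes[c][list(HEX_FACES[face])])
    return np.array(sorted(ids), dtype=np.int64)
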