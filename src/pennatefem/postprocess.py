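"""Derived outputs: plane tractions, whole-muscle force and center of
force, pennation, strain extrema, belly width/thickness changes and fiber
trajectories.

The whole-muscle force is the resultant of the Cauchy tractions across the
transverse plane bounding the deep aponeurosis (z = 0, the fixed face, so
reference and deformed configurations coincide there).  The center of
force is the normal-traction (sigma_zz) weighted centroid on that plane.
Pennation is the volume-weighted angle between the deformed fiber
direction and the locally convected deep-aponeurosis plane, the convention
that returns the initial 15 degrees in the reference state and is invariant
under rigid rotations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional

import numpy as np

from . import materials as mat
from .geometry import HexMesh, Region
from .solver import ThreeFieldState, quadrature_data, _shape_functions

__all__ = [
    "ForceReport",
    "ArchitectureReport",
    "architecture_report",
    "plane_traction",
    "force_vector",
    "pennation_angle",
    "strain_metrics",
    "fiber_trajectories",
    "report_run",
]

_G = 1.0 / np.sqrt(3.0)
_FACE_QP2 = np.array([[-_G, -_G], [_G, -_G], [_G, _G], [-_G, _G]])


@dataclass
class ForceReport:
    """Resultant force on the z = 0 measurement plane."""

    F_vec: np.ndarray          # N, 3-vector
    magnitude: float           # N
    dir_cosines: np.ndarray    # unit 3-vector
    COFx: float                # mm
    COFy: float                # mm


@dataclass
class ArchitectureReport:
    pennation_deformed: float          # degrees (volume-weighted, muscle)
    pennation_active: float            # degrees (activation-weighted)
    max_fiber_strain: float            # % shortening, muscle
    apo_strain_max: float              # % stretch, aponeurosis
    width_change: float                # %
    thickness_profile: np.ndarray      # (n, 2): z (mm), thickness (mm)


def architecture_report(state: "ThreeFieldState", mesh: HexMesh
                        ) -> ArchitectureReport:
    """Fiber-architecture summary of a converged state."""
    sm = strain_metrics(state, mesh)
    return ArchitectureReport(
        pennation_deformed=pennation_angle(state, mesh, "muscle"),
        pennation_active=pennation_angle(state, mesh, "active"),
        max_fiber_strain=sm["max_fiber_strain"],
        apo_strain_max=sm["apo_strain_max"],
        width_change=sm["width_change"],
        thickness_profile=sm["thickness_profile"])


def _face_local_coords(face: str):
    """Map 2D face quadrature to 3D local coords and in-face axes."""
    axis = {"x": 0, "y": 1, "z": 2}[face[0]]
    val = -1.0 if face[1] == "-" else 1.0
    others = [d for d in range(3) if d != axis]
    return axis, val, others


def plane_traction(state: ThreeFieldState, mesh: HexMesh,
                   params: mat.MaterialParams, plane: str = "measurement_plane"):
    """Cauchy traction t = sigma . n on the facets of ``plane``.

    Returns dict with facet-qp positions (mm), area weights (mm^2),
    tractions (Pa) and the stress components sigma_xz, sigma_yz, sigma_zz.
    The measurement-plane outward normal is -e_z; tractions are reported
    for the internal force the tissue at z > 0 transmits across the plane
    (i.e. sigma . e_z).
    """
    facets = mesh.facet_sets[plane]
    if facets is None or len(facets) == 0:
        raise ValueError(f"plane {plane!r} not found or empty")
    muscle = mesh.cell_region == Region.MUSCLE
    pos, wts, trac = [], [], []
    for cell, face in facets:
        cell = int(cell)
        axis, val, others = _face_local_coords(face)
        Xe = mesh.node_coords[mesh.hexes[cell]]
        ue = state.u[mesh.hexes[cell]]
        for fq in _FACE_QP2:
            xi = np.zeros(3)
            xi[axis] = val
            xi[others[0]], xi[others[1]] = fq
            N, dN = _shape_functions(xi)
            Jac = Xe.T @ dN                    # dX/dxi
            dNdX = dN @ np.linalg.inv(Jac)     # dN/dxi . dxi/dX
            F = np.eye(3) + ue.T @ dNdX
            J = np.linalg.det(F)
            a0 = mesh.fiber_a0[cell]
            alpha = 0.0 if not muscle[cell] else float(
                state.alpha_qp[cell].mean())
            sig = mat.total_cauchy_stress(
                F, a0, alpha, bool(muscle[cell]), params,
                pressure=np.asarray(state.p_tilde[cell]))
            # reference face area element (face is material and fixed)
            t1 = Jac[:, others[0]]
            t2 = Jac[:, others[1]]
            da = np.linalg.norm(np.cross(t1, t2))
            pos.append(Xe.T @ N)
            wts.append(da)  # unit face-qp weight = 1 for 2x2 Gauss
            trac.append(sig @ np.array([0.0, 0.0, 1.0]))
    pos = np.array(pos)
    wts = np.array(wts)
    trac = np.array(trac)
    return {"points": pos, "weights": wts, "traction": trac,
            "sigma_xz": trac[:, 0], "sigma_yz": trac[:, 1],
            "sigma_zz": trac[:, 2]}


def force_vector(traction: Dict[str, np.ndarray]) -> ForceReport:
    """Resultant force, direction cosines and center of force.

    Forces integrate Pa over mm^2 and are converted to N; the COF uses
    normal-traction (sigma_zz) weighting.
    """
    w = traction["weights"]
    t = traction["traction"]
    F = (t * w[:, None]).sum(axis=0) * 1e-6   # Pa mm^2 -> N
    magnitude = float(np.linalg.norm(F))
    if magnitude == 0.0:
        raise ValueError("degenerate force report: |F| = 0")
    tz = traction["sigma_zz"] * w
    denom = tz.sum()
    cof = (traction["points"][:, :2] * tz[:, None]).sum(axis=0) / denom
    return ForceReport(F_vec=F, magnitude=magnitude,
                       dir_cosines=F / magnitude,
                       COFx=float(cof[0]), COFy=float(cof[1]))


def _muscle_qp_state(state: ThreeFieldState, mesh: HexMesh):
    qp_coords, wdet, dNdX = quadrature_data(mesh)
    ue = state.u[mesh.hexes]
    F = np.einsum("cai,cqaJ->cqiJ", ue, dNdX) + np.eye(3)
    return qp_coords, wdet, F


def pennation_angle(state: ThreeFieldState, mesh: HexMesh,
                    region: str = "muscle") -> float:
    """Mean fiber angle to the convected deep-aponeurosis plane, degrees.

    ``region`` = 'muscle' (volume-weighted over all muscle tissue) or
    'active' (activation-weighted, the mean over the active region).
    """
    _, wdet, F = _muscle_qp_state(state, mesh)
    muscle = mesh.cell_region == Region.MUSCLE
    Fm = F[muscle]
    a0 = mesh.fiber_a0[muscle][:, None, :]
    a = np.einsum("cqiJ,cqJ->cqi", Fm, np.broadcast_to(a0, Fm.shape[:2] + (3,)))
    a /= np.linalg.norm(a, axis=-1, keepdims=True)
    # convected aponeurosis plane: push e_x, e_z through the local F
    px = Fm[..., :, 0]
    pz = Fm[..., :, 2]
    n = np.cross(px, pz)
    n /= np.linalg.norm(n, axis=-1, keepdims=True)
    ang = np.degrees(np.arcsin(np.abs(np.einsum("cqi,cqi->cq", a, n))))
    if region == "active":
        wts = wdet[muscle] * state.alpha_qp[muscle]
        if wts.sum() == 0:
            wts = wdet[muscle]
    else:
        wts = wdet[muscle]
    return float((ang * wts).sum() / wts.sum())


def strain_metrics(state: ThreeFieldState, mesh: HexMesh) -> dict:
    """Fiber-strain extrema and belly shape changes.

    Returns max muscle fiber shortening and max aponeurosis stretch (both
    % over quadrature points), the % width change of the deformed muscle
    surface at mid-length / mid-thickness, and the thickness profile
    between the aponeurosis-muscle interfaces along z.
    """
    qp_coords, wdet, F = _muscle_qp_state(state, mesh)
    a0 = mesh.fiber_a0[:, None, :]
    Fa = np.einsum("cqiJ,cqJ->cqi", F, np.broadcast_to(a0, F.shape[:2] + (3,)))
    lam = np.linalg.norm(Fa, axis=-1)
    muscle = mesh.cell_region == Region.MUSCLE
    apo = ~muscle
    max_short = float((1.0 - lam[muscle]).max() * 100.0)
    max_apo = float((lam[apo] - 1.0).max() * 100.0)
    # centroid (volume-weighted) position of the greatest shortening
    iflat = int(np.argmax(1.0 - lam[muscle]))
    short_loc = qp_coords[muscle].reshape(-1, 3)[iflat]

    width_now, width_ref = _mid_width(state, mesh)
    thickness = _thickness_profile(state, mesh)
    return {
        "max_fiber_strain": max_short,
        "apo_strain_max": max_apo,
        "max_shortening_location": short_loc,
        "width_change": (width_now / width_ref - 1.0) * 100.0,
        "thickness_profile": thickness,
    }


def _mid_width(state: ThreeFieldState, mesh: HexMesh):
    """Deformed vs reference extremal-x width of the muscle surface at the
    mid-length, mid-thickness section."""
    res = mesh.resolution
    grid = mesh.node_grid
    jm = res.ny_apo + res.ny_muscle // 2          # mid-muscle node layer
    km = res.nz // 2
    ids = [grid[0, jm, km], grid[-1, jm, km]]
    x_def = state.u[ids, 0] + mesh.node_coords[ids, 0]
    x_ref = mesh.node_coords[ids, 0]
    return float(x_def.max() - x_def.min()), float(x_ref.max() - x_ref.min())


def _thickness_profile(state: ThreeFieldState, mesh: HexMesh):
    """Deformed belly thickness (y distance between the two muscle-
    aponeurosis interfaces) vs z at mid-width.

    The interfaces are staggered along z, so the superficial interface is
    interpolated at the physical z of each deep-interface sample; the
    profile covers the z range where both interfaces exist.
    """
    res = mesh.resolution
    grid = mesh.node_grid
    im = res.nx // 2
    j_deep = res.ny_apo
    j_sup = res.ny_apo + res.ny_muscle
    lo = grid[im, j_deep, :]
    hi = grid[im, j_sup, :]
    plo = mesh.node_coords[lo] + state.u[lo]
    phi = mesh.node_coords[hi] + state.u[hi]
    zmin, zmax = phi[:, 2].min(), plo[:, 2].max()
    zs = np.linspace(zmin, zmax, max(res.nz // 2, 8))
    y_lo = np.interp(zs, plo[:, 2], plo[:, 1])
    y_hi = np.interp(zs, phi[:, 2], phi[:, 1])
    return np.column_stack([zs, y_hi - y_lo])


def _interp_displacement(mesh: HexMesh, u: np.ndarray, X: np.ndarray):
    """Trilinear interpolation of u at reference points (n, 3) using the
    structured parametrisation (y layer + sheared z)."""
    res = mesh.resolution
    p = mesh.params
    layout = mesh.layout
    X = np.atleast_2d(X)
    out = np.empty_like(X)
    xs = np.linspace(0.0, p.belly_width, res.nx + 1)
    # y node levels
    ys = np.unique(mesh.node_coords[:, 1])
    zp_nodes = np.linspace(0.0, p.apo_length, res.nz + 1)
    for n, pt in enumerate(X):
        x, y, z = pt
        zp = z - layout.shear(y)
        i = np.clip(np.searchsorted(xs, x) - 1, 0, res.nx - 1)
        j = np.clip(np.searchsorted(ys, y + 1e-12) - 1, 0, res.ny_total - 1)
        k = np.clip(np.searchsorted(zp_nodes, zp) - 1, 0, res.nz - 1)
        xi = np.array([
            2.0 * (x - xs[i]) / (xs[i + 1] - xs[i]) - 1.0,
            2.0 * (y - ys[j]) / (ys[j + 1] - ys[j]) - 1.0,
            2.0 * (zp - zp_nodes[k]) / (zp_nodes[k + 1] - zp_nodes[k]) - 1.0,
        ])
        xi = np.clip(xi, -1.0, 1.0)
        N, _ = _shape_functions(xi)
        grid = mesh.node_grid
        corners = [grid[i, j, k], grid[i + 1, j, k], grid[i + 1, j + 1, k],
                   grid[i, j + 1, k], grid[i, j, k + 1], grid[i + 1, j, k + 1],
                   grid[i + 1, j + 1, k + 1], grid[i, j + 1, k + 1]]
        out[n] = N @ u[corners]
    return out


def fiber_trajectories(state: ThreeFieldState, mesh: HexMesh,
                       seeds: Optional[np.ndarray] = None,
                       n_points: int = 41) -> List[dict]:
    """Deformed images of material fiber lines.

    Reference fibers are straight lines along a0 from seed points on the
    deep muscle-aponeurosis interface; their deformed trajectories are
    sampled with the trilinear displacement field.  Curvature comes from
    second differences along arclength; ``deviation`` is the signed lateral
    deviation from the end-to-end chord (its single sign change is the
    S-shape signature).
    """
    p = mesh.params
    th = p.theta0
    a0 = np.array([0.0, np.sin(th), np.cos(th)])
    if seeds is None:
        zs = np.linspace(0.15, 0.55, 5) * p.apo_length
        seeds = np.array([[p.belly_width / 2, p.apo_thickness, z] for z in zs])
    s = np.linspace(0.0, p.fiber_length, n_points)
    out = []
    for seed in np.atleast_2d(seeds):
        ref = seed[None, :] + s[:, None] * a0[None, :]
        disp = _interp_displacement(mesh, state.u, ref)
        cur = ref + disp
        d1 = np.gradient(cur, s, axis=0)
        d2 = np.gradient(d1, s, axis=0)
        speed = np.linalg.norm(d1, axis=1)
        kappa = np.linalg.norm(np.cross(d1, d2), axis=1) / speed**3
        # pointwise curvature of the interpolated path concentrates at
        # element interfaces; a low-order polynomial fit gives the
        # macroscopic curvature profile of the fiber line
        fits = [np.polyfit(s, cur[:, c], 6) for c in range(3)]
        ss = np.linspace(0.0, s[-1], 400)
        f1 = np.stack([np.polyval(np.polyder(f, 1), ss) for f in fits],
                      axis=1)
        f2 = np.stack([np.polyval(np.polyder(f, 2), ss) for f in fits],
                      axis=1)
        sp = np.linalg.norm(f1, axis=1)
        kappa_smooth = np.linalg.norm(np.cross(f1, f2), axis=1) / sp**3
        chord = cur[0] + np.outer(s / s[-1], cur[-1] - cur[0])
        dev_vec = cur - chord
        imax = int(np.argmax(np.linalg.norm(dev_vec, axis=1)))
        e = dev_vec[imax]
        norm_e = np.linalg.norm(e)
        dev = dev_vec @ (e / norm_e) if norm_e > 1e-12 else np.zeros(len(s))
        out.append({"arclength": s, "reference": ref, "deformed": cur,
                    "curvature": kappa, "curvature_smooth": kappa_smooth,
                    "curvature_smooth_argmax_frac":
                        float(ss[int(np.argmax(kappa_smooth))] / s[-1]),
                    "deviation": dev})
    return out


def deviation_sign_changes(dev: np.ndarray, rel_tol: float = 0.02) -> int:
    """Count sign changes of the chord deviation, ignoring noise below
    rel_tol * max |deviation|."""
    m = np.max(np.abs(dev))
    if m == 0:
        return 0
    d = dev[np.abs(dev) > rel_tol * m]
    return int(np.count_nonzero(np.diff(np.sign(d)) != 0))


def report_run(states: List[ThreeFieldState], mesh: HexMesh,
               params: mat.MaterialParams, act, metadata: dict | None = None
               ) -> dict:
    """One summary row for a completed run (end-state quantities)."""
    end = states[-1]
    trac = plane_traction(end, mesh, params)
    fr = force_vector(trac)
    sm = strain_metrics(end, mesh)
    thick = sm["thickness_profile"]
    row = {
        "pattern": act.pattern,
        "variant": params.apo_variant,
        "alpha_max": act.alpha_max,
        "force_N": fr.magnitude,
        "delta_x": fr.dir_cosines[0],
        "delta_y": fr.dir_cosines[1],
        "delta_z": fr.dir_cosines[2],
        "COFx_mm": fr.COFx,
        "COFy_mm": fr.COFy,
        "pennation_deg": pennation_angle(end, mesh, "muscle"),
        "pennation_active_deg": pennation_angle(end, mesh, "active"),
        "max_fiber_strain_pct": sm["max_fiber_strain"],
        "apo_strain_max_pct": sm["apo_strain_max"],
        "width_change_pct": sm["width_change"],
        "min_thickness_mm": float(thick[:, 1].min()),
    }
    if metadata:
        row.update(metadata)
    return row
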