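"""Three-field finite-element solver for the quasi-static contraction.

The stationary-potential-energy problem couples the displacement u with a
cell-wise constant pressure p~ and dilation J~ (Q1/P0/P0).  Because both
auxiliary fields are discontinuous they are condensed cell-by-cell: at a
stationary point J~ equals the cell-mean of J(u) and p~ = dW_vol/dJ at J~,
which turns the problem into a displacement-only "mean dilatation"
formulation whose Newton tangent carries one rank-one volumetric coupling
block per cell.  Trilinear hexahedra with 2x2x2 Gauss quadrature are used
throughout.

Activation is ramped in quasi-static load steps (elastostatics at each
step, warm-started from the previous one); each step is solved by
Newton-Raphson with backtracking line search and a direct or
preconditioned-CG linear solve.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import materials as mat
from .activation import ActivationField, alpha_at
from .geometry import HexMesh, Region, fixed_node_ids

__all__ = [
    "SolverConfig",
    "ThreeFieldState",
    "quadrature_data",
    "assemble_system",
    "newton_solve",
    "run_quasistatic",
    "NonConvergenceError",
    "InvertedElementError",
]

# 2x2x2 Gauss points / weights on [-1, 1]^3 and trilinear shape data.
_G = 1.0 / np.sqrt(3.0)
_QP = np.array([[sx * _G, sy * _G, sz * _G]
                for sz in (-1, 1) for sy in (-1, 1) for sx in (-1, 1)])
_QW = np.ones(8)
_CORNER_SIGNS = np.array([
    [-1, -1, -1], [1, -1, -1], [1, 1, -1], [-1, 1, -1],
    [-1, -1, 1], [1, -1, 1], [1, 1, 1], [-1, 1, 1]], dtype=float)


def _shape_functions(xi):
    """Trilinear N (8,) and dN/dxi (8, 3) at local point xi."""
    s = _CORNER_SIGNS
    N = 0.125 * np.prod(1.0 + s * xi, axis=1)
    dN = np.empty((8, 3))
    for d in range(3):
        terms = 1.0 + s * xi
        terms = terms.copy()
        terms[:, d] = s[:, d]
        dN[:, d] = 0.125 * np.prod(terms, axis=1)
    return N, dN


_N_ALL = np.stack([_shape_functions(xi)[0] for xi in _QP])     # (8qp, 8)
_DN_ALL = np.stack([_shape_functions(xi)[1] for xi in _QP])    # (8qp, 8, 3)

def quadrature_data(mesh: HexMesh):
    """Per-cell quadrature: physical qp coords (C, 8, 3), weights
    w*det(J0) (C, 8), and shape gradients dN/dX (C, 8, 8, 3).

    Cached on the mesh object (the reference mesh never changes)."""
    hit = getattr(mesh, "_quad_cache", None)
    if hit is not None:
        return hit
    Xe = mesh.node_coords[mesh.hexes]                     # (C, 8, 3)
    # Jacobian dX/dxi at each qp: (C, 8qp, 3, 3)
    Jac = np.einsum("caD,qad->cqDd", Xe, _DN_ALL)
    detJ = np.linalg.det(Jac)
    if np.any(detJ <= 0):
        raise ValueError("mesh contains inverted hexahedra")
    Jinv = np.linalg.inv(Jac)                             # (C, 8, 3, 3)
    dNdX = np.einsum("qad,cqdD->cqaD", _DN_ALL, Jinv)
    qp_coords = np.einsum("qa,caD->cqD", _N_ALL, Xe)
    out = (qp_coords, detJ * _QW[None, :], dNdX)
    object.__setattr__(mesh, "_quad_cache", out)
    return out


class NonConvergenceError(RuntimeError):
    pass


class InvertedElementError(RuntimeError):
    pass


@dataclass(frozen=True)
class SolverConfig:
    """Newton / linear-solver settings."""

    n_load_steps: int = 10
    newton_rtol: float = 1.0e-8
    newton_atol: float = 1.0e-10
    max_newton_iters: int = 60
    linear_solver: str = "direct"      # 'direct' (sparse LU) or 'cg'
    cg_tol: float = 1.0e-6
    line_search: bool = True
    max_backtracks: int = 12

    def __post_init__(self):
        if min(self.newton_rtol, self.newton_atol, self.cg_tol) <= 0:
            raise ValueError("tolerances must be positive")
        if self.linear_solver not in ("direct", "cg"):
            raise ValueError("linear_solver must be 'direct' or 'cg'")


@dataclass
class ThreeFieldState:
    """Discrete solution of one load step.

    ``u`` is the nodal displacement (mm); ``p_tilde`` / ``J_tilde`` are the
    condensed cell-wise pressure (Pa) and dilation recovered at convergence.
    """

    u: np.ndarray
    p_tilde: np.ndarray
    J_tilde: np.ndarray
    load_step: int
    activation_time: float
    alpha_qp: np.ndarray
    newton_iters: int = 0
    residual_history: list = field(default_factory=list)


def _cell_arrays(mesh: HexMesh, params: mat.MaterialParams):
    muscle = mesh.cell_region == Region.MUSCLE
    kappa = np.where(muscle, params.kappa_muscle, params.kappa_apo)
    return muscle, kappa


def _deformation_gradients(mesh, dNdX, u):
    ue = u[mesh.hexes]                                    # (C, 8, 3)
    F = np.einsum("cai,cqaJ->cqiJ", ue, dNdX)
    F += np.eye(3)
    return F


def cell_mean_dilation(mesh: HexMesh, u: np.ndarray):
    """Cell volume-mean of J(u) and the cell reference volumes."""
    _, wdet, dNdX = quadrature_data(mesh)
    F = _deformation_gradients(mesh, dNdX, u)
    J = np.linalg.det(F)
    V = wdet.sum(axis=1)
    return (J * wdet).sum(axis=1) / V, V


def assemble_system(mesh: HexMesh, alpha_qp: np.ndarray,
                    params: mat.MaterialParams, u: np.ndarray,
                    want_tangent: bool = True):
    """Residual (and tangent) of the condensed three-field energy.

    Returns ``(R, K, info)``; ``R`` has shape (n_nodes*3,), ``K`` is CSR (or
    None), and ``info`` carries p~, J~, per-qp J and fiber stretch.  Raises
    ``InvertedElementError`` if any quadrature point has J <= 0.
    """
    qp_coords, wdet, dNdX = quadrature_data(mesh)
    muscle, kappa = _cell_arrays(mesh, params)
    a0 = mesh.fiber_a0
    F = _deformation_gradients(mesh, dNdX, u)
    J = np.linalg.det(F)
    if np.any(J <= 0):
        raise InvertedElementError("inverted element: J <= 0 at a "
                                   "quadrature point")
    V = wdet.sum(axis=1)
    J_tilde = (J * wdet).sum(axis=1) / V
    p_tilde = mat.dw_vol(J_tilde, kappa)
    dp = mat.d2w_vol(J_tilde, kappa)

    a0q = np.broadcast_to(a0[:, None, :], F.shape[:2] + (3,))
    musq = np.broadcast_to(muscle[:, None], F.shape[:2])
    P = mat.first_piola(F, a0q, alpha_qp, musq, params,
                        pressure=np.broadcast_to(p_tilde[:, None], F.shape[:2]))

    # element residual r[c, a, i] = sum_q w P_iJ dN_a/dX_J
    r = np.einsum("cq,cqiJ,cqaJ->cai", wdet, P, dNdX)
    ndof = mesh.n_nodes * 3
    R = np.zeros(ndof)
    np.add.at(R, (mesh.hexes[:, :, None] * 3
                  + np.arange(3)[None, None, :]), r)

    K = None
    if want_tangent:
        A = mat.tangent_modulus(
            F, a0q, alpha_qp, musq, params,
            pressure=np.broadcast_to(p_tilde[:, None], F.shape[:2]),
            dpressure_dJ=None)
        Ke = np.einsum("cq,cqaJ,cqiJkL,cqbL->caibk", wdet, dNdX, A, dNdX,
                       optimize=True)
        # rank-one volumetric coupling: g[c, a, i] = d(V J~)/du
        H = np.swapaxes(np.linalg.inv(F), -1, -2)
        JH = J[..., None, None] * H
        g = np.einsum("cq,cqiJ,cqaJ->cai", wdet, JH, dNdX)
        Ke += (dp / V)[:, None, None, None, None] * np.einsum(
            "cai,cbk->caibk", g, g)
        dofs = (mesh.hexes[:, :, None] * 3 + np.arange(3)[None, None, :]
                ).reshape(mesh.n_cells, 24)
        rows = np.repeat(dofs, 24, axis=1).ravel()
        cols = np.tile(dofs, (1, 24)).ravel()
        K = sp.coo_matrix(
            (Ke.reshape(mesh.n_cells, 24, 24).ravel(), (rows, cols)),
            shape=(ndof, ndof)).tocsr()

    lam = np.sqrt(np.einsum("cqiJ,cJ,cqiK,cK->cq", F, a0, F, a0))
    info = {"p_tilde": p_tilde, "J_tilde": J_tilde, "J_qp": J, "lam_qp": lam,
            "F_qp": F}
    return R, K, info


def total_energy(mesh: HexMesh, alpha_qp: np.ndarray,
                 params: mat.MaterialParams, u: np.ndarray,
                 table: "mat.FiberEnergyTable") -> float:
    """Condensed three-field potential energy (Pa mm^3).

    Volumetric part at the cell-mean dilation, isochoric base part at the
    quadrature points, fiber part from the tabulated stress integral.
    Raises ``InvertedElementError`` on J <= 0.
    """
    _, wdet, dNdX = quadrature_data(mesh)
    muscle, kappa = _cell_arrays(mesh, params)
    F = _deformation_gradients(mesh, dNdX, u)
    J = np.linalg.det(F)
    if np.any(J <= 0):
        raise InvertedElementError("inverted element in trial state")
    V = wdet.sum(axis=1)
    J_tilde = (J * wdet).sum(axis=1) / V
    U = float((V * mat.w_vol(J_tilde, kappa)).sum())
    I1b = J ** (-2.0 / 3.0) * np.einsum("cqiJ,cqiJ->cq", F, F)
    wb = np.where(muscle[:, None], mat.w_base_muscle(I1b, params),
                  mat.w_base_apo(I1b, params))
    lam = np.sqrt(np.einsum("cqiJ,cJ,cqiK,cK->cq", F, mesh.fiber_a0,
                            F, mesh.fiber_a0))
    wf = table(lam, alpha_qp, muscle[:, None])
    return U + float((wdet * (wb + wf)).sum())


def _free_dofs(mesh: HexMesh):
    fixed = fixed_node_ids(mesh)
    mask = np.ones(mesh.n_nodes * 3, dtype=bool)
    mask[(fixed[:, None] * 3 + np.arange(3)).ravel()] = False
    return np.flatnonzero(mask)


def _solve_linear(K, rhs, config: SolverConfig):
    if config.linear_solver == "direct":
        return spla.spsolve(K.tocsc(), rhs)
    # symmetric Jacobi-preconditioned conjugate gradients
    d = K.diagonal()
    d = np.where(np.abs(d) > 0, d, 1.0)
    M = spla.LinearOperator(K.shape, matvec=lambda x: x / d)
    x, flag = spla.cg(K, rhs, rtol=config.cg_tol, maxiter=20 * K.shape[0],
                      M=M)
    if flag != 0:
        raise NonConvergenceError(f"CG failed to converge (flag={flag})")
    return x


def newton_solve(mesh: HexMesh, alpha_qp: np.ndarray,
                 params: mat.MaterialParams, config: SolverConfig,
                 u0: Optional[np.ndarray] = None,
                 log: Optional[list] = None, step: int = 0,
                 fixed_dofs: Optional[np.ndarray] = None):
    """Damped Newton-Raphson solve of one load step.

    The problem is a stationary point of the potential energy, so the line
    search is Armijo backtracking on the energy (the exponential tissue
    curves stiffen much faster than the reference tangent predicts, and a
    residual-norm merit stalls on the resulting overshoot).  When even the
    damped step fails to decrease the energy, a Levenberg-style diagonal
    regularization of the tangent is increased until progress resumes.

    Returns ``(u, info, history)``.
    """
    u = np.zeros((mesh.n_nodes, 3)) if u0 is None else u0.copy()
    if fixed_dofs is None:
        free = _free_dofs(mesh)
    else:
        mask = np.ones(mesh.n_nodes * 3, dtype=bool)
        mask[np.asarray(fixed_dofs, dtype=int)] = False
        free = np.flatnonzero(mask)
    table = mat.fiber_energy_table(params)
    history = []
    r_ref = None
    tau = 0.0  # Levenberg damping, relative to diag(K)

    def energy(uu):
        return total_energy(mesh, alpha_qp, params, uu, table)

    for it in range(config.max_newton_iters + 1):
        R, K, info = assemble_system(mesh, alpha_qp, params, u,
                                     want_tangent=True)
        rnorm = float(np.linalg.norm(R[free]))
        history.append(rnorm)
        if log is not None:
            log.append({"step": step, "iter": it, "residual": rnorm})
        if r_ref is None:
            r_ref = max(rnorm, 1e-30)
        if rnorm <= config.newton_rtol * r_ref + config.newton_atol:
            return u, info, history
        if it == config.max_newton_iters:
            break

        Kff = K[free][:, free]
        dK = sp.diags(np.abs(Kff.diagonal()) + 1e-30)
        U0 = energy(u)
        accepted = False
        for _damp in range(8):
            Ksys = Kff if tau == 0.0 else (Kff + tau * dK).tocsr()
            du = np.zeros(mesh.n_nodes * 3)
            du[free] = _solve_linear(Ksys, -R[free], config)
            slope = float(R[free] @ du[free])  # dU along du (should be < 0)
            du = du.reshape(-1, 3)
            # near the solution the energy decrease drowns in roundoff;
            # accept a residual-reducing full step first
            try:
                R_full, _, _ = assemble_system(mesh, alpha_qp, params,
                                               u + du, want_tangent=False)
                if np.linalg.norm(R_full[free]) < 0.9 * rnorm:
                    u = u + du
                    accepted = True
            except InvertedElementError:
                pass
            if not accepted and slope < 0:
                scale = 1.0
                for _bt in range(config.max_backtracks + 1):
                    try:
                        U_trial = energy(u + scale * du)
                        if (U_trial <= U0 + 1e-4 * scale * slope
                                or not config.line_search):
                            # guard: an energy-accepted step must not let
                            # the residual explode into a region Newton
                            # cannot recover from
                            R_t, _, _ = assemble_system(
                                mesh, alpha_qp, params, u + scale * du,
                                want_tangent=False)
                            if (np.linalg.norm(R_t[free]) <= 30.0 * rnorm
                                    or not config.line_search):
                                u = u + scale * du
                                accepted = True
                                break
                    except InvertedElementError:
                        pass
                    scale *= 0.5
            if accepted:
                tau = tau / 3.0 if tau > 1e-12 else 0.0
                break
            tau = max(10.0 * tau, 1e-6)
        if not accepted:
            if rnorm <= max(1e-4 * r_ref, 10 * config.newton_atol):
                # converged to achievable precision for this conditioning
                return u, info, history
            raise NonConvergenceError(
                f"line search failed at iteration {it} "
                f"(residual {rnorm:.3e}); try more load steps")
    raise NonConvergenceError(
        f"Newton did not converge in {config.max_newton_iters} iterations "
        f"(residual {history[-1]:.3e}); try more load steps")


def run_quasistatic(mesh: HexMesh, params: mat.MaterialParams,
                    act: ActivationField, config: SolverConfig = SolverConfig(),
                    ) -> tuple[List[ThreeFieldState], list]:
    """Ramp activation over n_load_steps quasi-static solves.

    Returns ``n_load_steps + 1`` states (including the stress-free
    reference) and the convergence log (list of dict rows).
    """
    if act.pattern != "uniform" and not act.calibrated:
        raise ValueError("regionalized activation field must be calibrated "
                         "against the mesh before solving")
    qp_coords, _, _ = quadrature_data(mesh)
    muscle_qp = np.broadcast_to(
        (mesh.cell_region == Region.MUSCLE)[:, None], qp_coords.shape[:2])
    flat_pts = qp_coords.reshape(-1, 3)

    log: list = []
    states: List[ThreeFieldState] = []
    u = np.zeros((mesh.n_nodes, 3))
    zero_alpha = np.zeros(qp_coords.shape[:2])
    _, _, info0 = assemble_system(mesh, zero_alpha, params, u,
                                  want_tangent=False)
    states.append(ThreeFieldState(
        u=u.copy(), p_tilde=info0["p_tilde"], J_tilde=info0["J_tilde"],
        load_step=0, activation_time=0.0, alpha_qp=zero_alpha))

    def alpha_field(t):
        a = alpha_at(flat_pts, t, act).reshape(qp_coords.shape[:2])
        return np.where(muscle_qp, a, 0.0)

    def solve_to(u_start, t_from, t_to, step_index, depth=0):
        """Solve at t_to from u_start, bisecting the increment on
        non-convergence (exponential tissue curves can put the first
        Newton iterate far outside the convergence basin)."""
        try:
            return newton_solve(mesh, alpha_field(t_to), params, config,
                                u0=u_start, log=log, step=step_index)
        except (NonConvergenceError, InvertedElementError):
            if depth >= 4:
                raise
            t_mid = 0.5 * (t_from + t_to)
            u_mid, _, _ = solve_to(u_start, t_from, t_mid, step_index,
                                   depth + 1)
            return solve_to(u_mid, t_mid, t_to, step_index, depth + 1)

    for i in range(1, config.n_load_steps + 1):
        t = act.ramp_duration * i / config.n_load_steps
        t_prev = act.ramp_duration * (i - 1) / config.n_load_steps
        alpha = alpha_field(t)
        try:
            u, info, hist = solve_to(u, t_prev, t, i)
        except (NonConvergenceError, InvertedElementError) as err:
            raise NonConvergenceError(
                f"load step {i}/{config.n_load_steps} (t={t:.3f} s) "
                f"failed: {err}") from err
        states.append(ThreeFieldState(
            u=u.copy(), p_tilde=info["p_tilde"], J_tilde=info["J_tilde"],
            load_step=i, activation_time=t, alpha_qp=alpha,
            newton_iters=len(hist) - 1, residual_history=hist))
    return states, log
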