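"""Coupled finite-element solver for post-surgical cavity healing.

Linear tetrahedra carry the displacement and the nodal fibroblast/cytokine
fields; microstructure (collagen fraction, fiber dispersion and direction,
plastic stretches) lives at one quadrature point per element.  Each healing
step is an operator split: (i) backward-Euler reaction-diffusion update of
the biochemical fields with coefficients frozen at the start-of-step state,
(ii) quadrature-point remodeling ODE update, (iii) quasi-static mechanical
re-equilibration with total stress = passive + active.

Quasi-static equilibrium is solved by Newton's method with a finite-
difference consistent tangent (12 directional derivatives per element,
evaluated vectorized over all elements), incremental loading for gravity,
and backtracking that rejects steps producing element inversion.

Units: mm, days, kPa.  Body-force density for gravity stages is
``rho_tissue g = 9.81e-3 kPa/mm``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import constitutive as con
from . import kinetics as kin
from .mesh import BreastMesh, CAVITY, TISSUE

log = logging.getLogger(__name__)

__all__ = [
    "SolverConfig",
    "Microstructure",
    "HealingState",
    "FEModel",
    "SolverError",
    "initial_fields",
    "gravity_materials",
    "healing_materials",
    "apply_gravity",
    "find_unloaded_configuration",
    "step_healing",
    "run_healing",
    "simulate_patient",
]

BODY_FORCE = 9.81e-3  # kPa/mm, tissue density 1e-6 kg/mm^3 times g
PHI_MIN = 1e-3  # collagen floor in the fresh cavity (initial field)
PHI_FLOOR_MECH = 0.25  # stiffness floor in the mechanical solve: the fresh
# cavity (seroma + provisional fibrin matrix) retains a small fraction of
# tissue stiffness, which also regularizes the crushed-element kinematics


def _det3(A):
    """Determinant of stacked 3x3 matrices (closed form, faster than LAPACK
    dispatch for many small matrices)."""
    return (
        A[..., 0, 0] * (A[..., 1, 1] * A[..., 2, 2] - A[..., 1, 2] * A[..., 2, 1])
        - A[..., 0, 1] * (A[..., 1, 0] * A[..., 2, 2] - A[..., 1, 2] * A[..., 2, 0])
        + A[..., 0, 2] * (A[..., 1, 0] * A[..., 2, 1] - A[..., 1, 1] * A[..., 2, 0])
    )


def _inv3(A, det=None):
    """Inverse of stacked 3x3 matrices via the adjugate."""
    if det is None:
        det = _det3(A)
    inv = np.empty_like(A)
    inv[..., 0, 0] = A[..., 1, 1] * A[..., 2, 2] - A[..., 1, 2] * A[..., 2, 1]
    inv[..., 0, 1] = A[..., 0, 2] * A[..., 2, 1] - A[..., 0, 1] * A[..., 2, 2]
    inv[..., 0, 2] = A[..., 0, 1] * A[..., 1, 2] - A[..., 0, 2] * A[..., 1, 1]
    inv[..., 1, 0] = A[..., 1, 2] * A[..., 2, 0] - A[..., 1, 0] * A[..., 2, 2]
    inv[..., 1, 1] = A[..., 0, 0] * A[..., 2, 2] - A[..., 0, 2] * A[..., 2, 0]
    inv[..., 1, 2] = A[..., 0, 2] * A[..., 1, 0] - A[..., 0, 0] * A[..., 1, 2]
    inv[..., 2, 0] = A[..., 1, 0] * A[..., 2, 1] - A[..., 1, 1] * A[..., 2, 0]
    inv[..., 2, 1] = A[..., 0, 1] * A[..., 2, 0] - A[..., 0, 0] * A[..., 2, 1]
    inv[..., 2, 2] = A[..., 0, 0] * A[..., 1, 1] - A[..., 0, 1] * A[..., 1, 0]
    return inv / det[..., None, None]


class SolverError(RuntimeError):
    pass


@dataclass
class SolverConfig:
    dt: float = 0.5  # days
    horizon: float = 28.0  # days
    newton_tol: float = 1e-6  # relative to the driving-force scale
    newton_max_iter: int = 30
    n_load_steps: int = 4
    min_load_factor: float = 1.0 / 64.0
    output_cadence: float = 2.0  # days
    min_dt: float = 0.2

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        n = self.output_cadence / self.dt
        if abs(n - round(n)) > 1e-9:
            raise ValueError("output_cadence must be a multiple of dt")


@dataclass
class Microstructure:
    """Per-element microstructural state (one quadrature point per tet)."""

    phi: np.ndarray  # (m,)
    kappa: np.ndarray  # (m,)
    a0: np.ndarray  # (m,3) unit fiber direction
    lam_p: np.ndarray  # (m,3) plastic stretches along basis rows
    basis: np.ndarray  # (m,3,3) rows a0, s0, n0

    @classmethod
    def isotropic(cls, m: int, phi=1.0):
        ms = cls(
            phi=np.full(m, float(phi)),
            kappa=np.full(m, 1.0 / 3.0),
            a0=np.tile(np.array([1.0, 0.0, 0.0]), (m, 1)),
            lam_p=np.ones((m, 3)),
            basis=np.zeros((m, 3, 3)),
        )
        ms.rebuild_basis()
        return ms

    def rebuild_basis(self):
        """Complete {a0, s0, n0} by Gram-Schmidt of a0 against the global z
        axis (y axis where a0 is nearly parallel to z — deterministic
        tie-break)."""
        a = self.a0
        ref = np.tile(np.array([0.0, 0.0, 1.0]), (len(a), 1))
        ref[np.abs(a[:, 2]) > 0.9] = [0.0, 1.0, 0.0]
        s = ref - np.einsum("ij,ij->i", ref, a)[:, None] * a
        s /= np.linalg.norm(s, axis=1, keepdims=True)
        n = np.cross(a, s)
        self.basis = np.stack([a, s, n], axis=1)

    def copy(self):
        return Microstructure(
            self.phi.copy(), self.kappa.copy(), self.a0.copy(), self.lam_p.copy(), self.basis.copy()
        )


@dataclass
class HealingState:
    """Displacement + biochemical fields + microstructure at one time."""

    time: float
    u: np.ndarray  # (n,3) nodal displacement from the reference mesh
    rho: np.ndarray  # (n,) fibroblast density
    c: np.ndarray  # (n,) cytokine concentration
    micro: Microstructure
    residual_norm: float = 0.0

    def copy(self):
        return HealingState(self.time, self.u.copy(), self.rho.copy(), self.c.copy(),
                            self.micro.copy(), self.residual_norm)


def gravity_materials(mesh: BreastMesh, breast_density: float):
    """(k0, k1, kf, k2) per element for prone/upright repositioning.

    Tissue: neo-Hookean with the rule-of-mixtures modulus from the 1.5/6 kPa
    adipose/fibroglandular pair.  Cavity: zero-shear (regularized) with a
    300 kPa bulk modulus (seroma, nearly incompressible).
    """
    E = con.rule_of_mixtures(breast_density, con.E_ADIPOSE_GRAVITY, con.E_FIBROGLANDULAR_GRAVITY)
    k0_t, k1_t = con.elastic_constants(E)
    k0 = np.full(mesh.n_tets, k0_t)
    k1 = np.full(mesh.n_tets, k1_t)
    cav = mesh.region == CAVITY
    k0[cav] = con.CAVITY_SHEAR_REG
    k1[cav] = con.CAVITY_BULK
    return k0, k1, np.zeros(mesh.n_tets), np.ones(mesh.n_tets)


def healing_materials(mesh: BreastMesh, breast_density: float, kf: float = 2.0, k2: float = 1.0):
    """(k0, k1, kf, k2) per element for the healing stage (10/40 kPa pair).

    The same moduli apply in the cavity: its compliance immediately after
    surgery comes from the collagen fraction ``phi`` scaling the strain
    energy, not from a separate material law.
    """
    E = con.rule_of_mixtures(breast_density, con.E_ADIPOSE_HEALING, con.E_FIBROGLANDULAR_HEALING)
    k0_t, k1_t = con.elastic_constants(E)
    return (
        np.full(mesh.n_tets, k0_t),
        np.full(mesh.n_tets, k1_t),
        np.full(mesh.n_tets, kf),
        np.full(mesh.n_tets, k2),
    )


def initial_fields(mesh: BreastMesh) -> HealingState:
    """Post-excision initial state: homeostatic tissue, seroma-filled cavity.

    Nodal fields interpolate by adjacent-element volume fraction, so
    interface nodes carry intermediate values; element microstructure is
    collagen-depleted (``phi = PHI_MIN``) and isotropic (``kappa = 1/3``)
    in the cavity.
    """
    if mesh.region is None or len(mesh.region) != mesh.n_tets:
        raise ValueError("mesh has no complete region labeling")
    vol = mesh.volumes()
    w_cav = np.zeros(mesh.n_points)
    w_all = np.zeros(mesh.n_points)
    for k in range(4):
        np.add.at(w_all, mesh.tets[:, k], vol)
        np.add.at(w_cav, mesh.tets[:, k], vol * (mesh.region == CAVITY))
    frac = w_cav / w_all
    micro = Microstructure.isotropic(mesh.n_tets)
    micro.phi[mesh.region == CAVITY] = PHI_MIN
    return HealingState(
        time=0.0,
        u=np.zeros((mesh.n_points, 3)),
        rho=1.0 - frac,
        c=frac.copy(),
        micro=micro,
    )


class FEModel:
    """Assembly and solution on one labeled tetrahedral mesh.

    Reference coordinates are taken from ``points`` (default: the mesh
    nodes); Dirichlet conditions fix the chest-wall vertices.
    """

    def __init__(
        self,
        mesh: BreastMesh,
        k0,
        k1,
        kf=None,
        k2=None,
        active: con.ActiveStressParams | None = None,
        mech: con.MechanosensingParams | None = None,
        points: np.ndarray | None = None,
    ):
        self.mesh = mesh
        self.X = mesh.points if points is None else np.asarray(points, dtype=float)
        self.k0 = np.asarray(k0, dtype=float)
        self.k1 = np.asarray(k1, dtype=float)
        self.kf = np.zeros(mesh.n_tets) if kf is None else np.asarray(kf, dtype=float)
        self.k2 = np.ones(mesh.n_tets) if k2 is None else np.asarray(k2, dtype=float)
        self.active = active or con.ActiveStressParams()
        self.mech = mech or con.MechanosensingParams()

        conn = mesh.tets
        p = self.X[conn]
        J = np.stack([p[:, 1] - p[:, 0], p[:, 2] - p[:, 0], p[:, 3] - p[:, 0]], axis=1)
        detJ = np.linalg.det(J)
        if np.any(detJ <= 0):
            raise SolverError("reference configuration contains inverted elements")
        self.V0 = detJ / 6.0
        Jinv = np.linalg.inv(J)
        # gradient of the barycentric shape functions, (m, 4, 3)
        g = np.swapaxes(Jinv, 1, 2)  # rows: grad of N1..N3 coefficients
        self.DN = np.concatenate([-g.sum(axis=1, keepdims=True), g], axis=1)

        # scatter indices for the 12x12 element stiffness
        dof = (3 * conn[:, :, None] + np.arange(3)).reshape(-1, 12)
        self.K_rows = np.repeat(dof, 12, axis=1).ravel()
        self.K_cols = np.tile(dof, (1, 12)).ravel()
        self.ndof = 3 * mesh.n_points

        fixed = mesh.chest_wall_vertices()
        self.fixed_dofs = (3 * fixed[:, None] + np.arange(3)).ravel()
        self.free = np.setdiff1d(np.arange(self.ndof), self.fixed_dofs)
        # precomputed reduced (free-free) assembly pattern
        red = -np.ones(self.ndof, dtype=np.int64)
        red[self.free] = np.arange(len(self.free))
        rr, cc = red[self.K_rows], red[self.K_cols]
        self._keep = (rr >= 0) & (cc >= 0)
        self._red_rows, self._red_cols = rr[self._keep], cc[self._keep]

        # diffusion element matrices V0 * DN DN^T and lumped mass
        self.B_diff = self.V0[:, None, None] * np.einsum("eai,ebi->eab", self.DN, self.DN)
        self.M_lumped = np.zeros(mesh.n_points)
        for k in range(4):
            np.add.at(self.M_lumped, conn[:, k], self.V0 / 4.0)
        rows = np.repeat(conn, 4, axis=1).ravel()
        cols = np.tile(conn, (1, 4)).ravel()
        self._diff_rows, self._diff_cols = rows, cols
        self._lu_c = None  # cached factorization for the cytokine solve
        self._mech_lu = None  # cached mechanical tangent factorization

    # -- mechanics ---------------------------------------------------------

    def deformation_gradient(self, u_elem):
        return np.eye(3) + np.einsum("eai,eaj->eij", u_elem, self.DN)

    def _piola(self, u_elem, micro: Microstructure, rho_e, c_e, phi_floor=None):
        """First Piola-Kirchhoff stress of the total (passive+active) Cauchy
        stress, per element.  Returns (P, J, Fe)."""
        F = self.deformation_gradient(u_elem)
        J = _det3(F)
        if np.any(J <= 0):
            return None, J, None
        if phi_floor is None:
            phi_floor = PHI_FLOOR_MECH
        Fe = F @ con.plastic_inverse(micro.lam_p, micro.basis)
        Je = _det3(Fe)
        if np.any(Je <= 0):
            return None, Je, None
        phi = np.maximum(micro.phi, phi_floor)
        sig = con.passive_stress(Fe, phi, micro.kappa, micro.a0, self.k0, self.k1, self.kf, self.k2)
        if rho_e is not None:
            a = np.einsum("eij,ej->ei", Fe, micro.a0)
            sig = sig + con.active_stress(rho_e, c_e, micro.phi, micro.kappa, a, self.active)
        Finv_T = np.swapaxes(_inv3(F, J), 1, 2)
        return J[:, None, None] * sig @ Finv_T, J, Fe

    def _element_internal(self, u_elem, micro, rho_e, c_e):
        P, J, _ = self._piola(u_elem, micro, rho_e, c_e)
        if P is None:
            return None
        return self.V0[:, None, None] * np.einsum("eij,eaj->eai", P, self.DN)

    def internal_force(self, u, micro, rho_e=None, c_e=None):
        f_el = self._element_internal(u[self.mesh.tets], micro, rho_e, c_e)
        if f_el is None:
            return None
        f = np.zeros((self.mesh.n_points, 3))
        np.add.at(f, self.mesh.tets, f_el)
        return f

    def _tangent(self, u_elem, micro, rho_e, c_e, base):
        h = 1e-6 * max(1.0, float(np.abs(self.X).max()))
        K = np.empty((len(u_elem), 12, 12))
        for a in range(4):
            for i in range(3):
                up = u_elem.copy()
                up[:, a, i] += h
                fp = self._element_internal(up, micro, rho_e, c_e)
                if fp is None:  # perturbed state inverted: one-sided other way
                    up[:, a, i] -= 2 * h
                    fp = self._element_internal(up, micro, rho_e, c_e)
                    if fp is None:
                        raise SolverError("tangent evaluation hit element inversion")
                    K[:, :, 3 * a + i] = -(fp - base).reshape(-1, 12) / h
                else:
                    K[:, :, 3 * a + i] = (fp - base).reshape(-1, 12) / h
        return K

    def solve_equilibrium(
        self,
        u0,
        micro: Microstructure,
        rho_e=None,
        c_e=None,
        f_ext=None,
        tol=1e-6,
        max_iter=30,
        force_scale=None,
    ):
        """Newton solve of ``f_int(u) = f_ext`` on the free dofs.

        Returns ``(u, residual_norm)``; raises :class:`SolverError` on
        non-convergence.
        """
        mesh = self.mesh
        u = u0.copy()
        fe = np.zeros((mesh.n_points, 3)) if f_ext is None else f_ext
        if force_scale is None:
            scale = max(float(np.linalg.norm(fe)), 1e-3 * float(self.V0.sum() ** (2.0 / 3.0)))
        else:
            scale = force_scale

        def residual(u_arr):
            f_el = self._element_internal(u_arr[mesh.tets], micro, rho_e, c_e)
            if f_el is None:
                return None, None, np.inf
            f_int = np.zeros((mesh.n_points, 3))
            np.add.at(f_int, mesh.tets, f_el)
            R = (f_int - fe).ravel()[self.free]
            return f_el, R, float(np.linalg.norm(R))

        f_el, R, rn = residual(u)
        if f_el is None:
            raise SolverError("element inversion in initial state")

        def factorize(lam_reg):
            K_el = self._tangent(u[mesh.tets], micro, rho_e, c_e, f_el)
            vals = K_el.reshape(-1, 144).ravel()[self._keep]
            K = sp.coo_matrix(
                (vals, (self._red_rows, self._red_cols)),
                shape=(len(self.free), len(self.free)),
            ).tocsc()
            if lam_reg > 0.0:
                dscale = float(np.abs(K.diagonal()).mean())
                K = K + sp.identity(K.shape[0], format="csc") * (lam_reg * dscale)
            try:
                return spla.splu(K)
            except RuntimeError as exc:
                self._mech_lu = None
                raise SolverError(f"singular tangent: {exc}") from exc

        # the factorized tangent persists across calls (the state changes
        # little between healing steps); it is refreshed whenever the
        # residual stops contracting.  On line-search failure the solve
        # falls back to pseudo-transient continuation: an adaptive diagonal
        # regularization walks a pseudo-dynamic path through snap-through
        # states while still converging to the exact equilibrium.
        lu, fresh = self._mech_lu, False
        lam_reg = 0.0
        rn_prev = np.inf
        it_budget = 3 * max_iter
        for it in range(it_budget):
            if rn <= tol * scale:
                self._mech_lu = lu if lam_reg == 0.0 else None
                return u, rn
            if lu is None or (rn > 0.5 * rn_prev and not fresh) or lam_reg > 0.0:
                lu = factorize(lam_reg)
                fresh = True
            du = lu.solve(-R)
            # backtracking guards against element inversion / divergence
            alpha, accepted = 1.0, False
            for _ in range(8):
                u_try = u.copy()
                u_try.reshape(-1)[self.free] += alpha * du
                f_try, R_try, rn_try = residual(u_try)
                if f_try is not None and rn_try < rn:
                    u, f_el, R, rn_prev, rn = u_try, f_try, R_try, rn, rn_try
                    accepted = True
                    break
                alpha *= 0.5
            if accepted:
                fresh = False
                lam_reg *= 0.5
                if lam_reg < 1e-4:
                    lam_reg = 0.0
            else:
                if not fresh:
                    lu = None  # stale tangent: rebuild and retry
                    continue
                lam_reg = max(4.0 * lam_reg, 0.03)
                if lam_reg > 1e4:
                    self._mech_lu = None
                    raise SolverError(
                        f"no progress under pseudo-transient continuation (|R|={rn:.3e})"
                    )
                lu = None
        self._mech_lu = None
        raise SolverError(f"Newton did not converge in {it_budget} iterations (|R|={rn:.3e})")

    # -- biochemical fields -------------------------------------------------

    def _assemble_diffusion(self, D_e):
        vals = (D_e[:, None, None] * self.B_diff).ravel()
        return sp.coo_matrix(
            (vals, (self._diff_rows, self._diff_cols)),
            shape=(self.mesh.n_points, self.mesh.n_points),
        ).tocsr()

    def element_means(self, nodal):
        return nodal[self.mesh.tets].mean(axis=1)

    def nodal_projection(self, elem_values):
        """Volume-weighted projection of element values onto nodes."""
        num = np.zeros(self.mesh.n_points)
        for k in range(4):
            np.add.at(num, self.mesh.tets[:, k], elem_values * self.V0 / 4.0)
        return num / self.M_lumped

    def update_fields(self, state: HealingState, dt, params: kin.KineticParams, H_n):
        """Backward-Euler reaction-diffusion update of rho and c.

        Diffusion and the linear decay terms are implicit (lumped mass keeps
        the system an M-matrix, preserving positivity); the nonnegative
        production terms are explicit at the start-of-step state.
        """
        mesh = self.mesh
        rho, c = state.rho, state.c
        phi_e = state.micro.phi
        D_rho_e = kin.fibroblast_diffusivity(phi_e, self.element_means(c), params)
        K_rho = self._assemble_diffusion(D_rho_e)
        M = sp.diags(self.M_lumped)
        s_rho, s_c = kin.field_sources(rho, c, H_n, params)
        # split: implicit linear decay, explicit remainder (production)
        prod_rho = s_rho + params.d_rho * rho
        prod_c = s_c + params.d_c * c
        A_rho = (M / dt + K_rho + params.d_rho * M).tocsc()
        rho_new = spla.spsolve(A_rho, self.M_lumped * (rho / dt + prod_rho))
        if self._lu_c is None or self._lu_c[0] != dt:
            K_c = self._assemble_diffusion(np.full(mesh.n_tets, params.D_c))
            self._lu_c = (dt, spla.splu((M / dt + K_c + params.d_c * M).tocsc()))
        c_new = self._lu_c[1].solve(self.M_lumped * (c / dt + prod_c))
        # small negative undershoots can appear where obtuse tetrahedra break
        # the discrete maximum principle; clip those, fail on real violations
        tol_rho = 0.05 * max(1.0, float(np.abs(rho_new).max()))
        tol_c = 0.05 * max(1.0, float(np.abs(c_new).max()))
        if rho_new.min() < -tol_rho or c_new.min() < -tol_c:
            raise SolverError("positivity violated in field update")
        return np.maximum(rho_new, 0.0), np.maximum(c_new, 0.0)


def solve_with_active_ramp(model: FEModel, u0, micro, rho_e, c_e, cfg: SolverConfig,
                           force_scale, n_ramp: int = 8):
    """Equilibrium solve with load continuation on the active stress.

    Tries the full active stress first; on failure, ramps the cell density
    (the active stress is linear in it) in increments, warm-starting each
    stage — needed for the excision shock at t = 0.
    """
    try:
        return model.solve_equilibrium(
            u0, micro, rho_e, c_e, tol=cfg.newton_tol,
            max_iter=cfg.newton_max_iter, force_scale=force_scale,
        )
    except SolverError:
        u = u0.copy()
        budget = max(12, cfg.newton_max_iter // 2)
        for f in np.linspace(1.0 / n_ramp, 1.0, n_ramp):
            u, rn = model.solve_equilibrium(
                u, micro, rho_e * f, c_e, tol=cfg.newton_tol,
                max_iter=budget if f < 1.0 else cfg.newton_max_iter,
                force_scale=force_scale,
            )
        return u, rn


# ---------------------------------------------------------------------------
# gravity staging


def _gravity_f_ext(model: FEModel, gravity_vector):
    f = np.zeros((model.mesh.n_points, 3))
    load = np.outer(model.V0 / 4.0, gravity_vector)  # kPa/mm * mm^3
    for k in range(4):
        np.add.at(f, model.mesh.tets[:, k], load)
    return f


def apply_gravity(
    mesh: BreastMesh,
    materials,
    gravity_vector,
    points=None,
    config: SolverConfig | None = None,
):
    """Quasi-static equilibrium under a body force (kPa/mm vector).

    Load is applied incrementally with automatic halving on Newton failure
    (floor ``min_load_factor``).  Returns nodal displacement (n, 3).
    """
    cfg = config or SolverConfig()
    k0, k1, kf, k2 = materials
    model = FEModel(mesh, k0, k1, kf, k2, points=points)
    micro = Microstructure.isotropic(mesh.n_tets)
    g = np.asarray(gravity_vector, dtype=float)
    if np.linalg.norm(g) == 0.0:
        return np.zeros((mesh.n_points, 3))
    f_full = _gravity_f_ext(model, g)
    scale = np.linalg.norm(f_full)
    u = np.zeros((mesh.n_points, 3))
    lam, step = 0.0, 1.0 / cfg.n_load_steps
    while lam < 1.0 - 1e-12:
        target = min(1.0, lam + step)
        try:
            u, _ = model.solve_equilibrium(
                u, micro, f_ext=target * f_full, tol=cfg.newton_tol,
                max_iter=cfg.newton_max_iter, force_scale=scale,
            )
            lam = target
        except SolverError:
            step /= 2.0
            if step < cfg.min_load_factor:
                raise SolverError(
                    f"gravity loading failed below load-step floor at lambda={lam:.3f}"
                )
    return u


def find_unloaded_configuration(
    mesh: BreastMesh,
    materials,
    gravity_vector,
    config: SolverConfig | None = None,
    tol_mm: float = 0.5,
    max_iter: int = 15,
):
    """Inverse-equilibrium (Sellier fixed point) recovery of the gravity-free
    shape: iteratively corrects candidate unloaded coordinates until forward
    gravity reproduces the loaded surface within ``tol_mm``.

    Returns ``(unloaded_points, mismatch_history)``.
    """
    x_target = mesh.points.copy()
    X = x_target.copy()
    history = []
    for _ in range(max_iter):
        u = apply_gravity(mesh, materials, gravity_vector, points=X, config=config)
        mismatch = X + u - x_target
        err = float(np.abs(mismatch).max())
        history.append(err)
        if err <= tol_mm:
            return X, history
        X = X - mismatch
    raise SolverError(f"unloaded-configuration iteration stalled; mismatch history {history}")


# ---------------------------------------------------------------------------
# healing time integration


def _active_force_scale(model: FEModel, state: HealingState, rho_e, c_e):
    u_elem = state.u[model.mesh.tets]
    F = model.deformation_gradient(u_elem)
    Fe = F @ con.plastic_inverse(state.micro.lam_p, state.micro.basis)
    a = np.einsum("eij,ej->ei", Fe, state.micro.a0)
    sig_act = con.active_stress(rho_e, c_e, state.micro.phi, state.micro.kappa, a, model.active)
    P = np.linalg.det(F)[:, None, None] * sig_act @ np.swapaxes(np.linalg.inv(F), 1, 2)
    f_el = model.V0[:, None, None] * np.einsum("eij,eaj->eai", P, model.DN)
    f = np.zeros((model.mesh.n_points, 3))
    np.add.at(f, model.mesh.tets, f_el)
    return max(float(np.linalg.norm(f)), 1e-6)


def step_healing(
    model: FEModel, state: HealingState, dt: float, params: kin.KineticParams,
    config: SolverConfig | None = None,
) -> HealingState:
    """One operator-split healing step; recursively halves ``dt`` (down to
    ``config.min_dt``) if the mechanical solve fails."""
    cfg = config or SolverConfig()
    try:
        return _step_healing_once(model, state, dt, params, cfg)
    except SolverError:
        if dt / 2.0 < cfg.min_dt:
            raise
        log.warning("healing step at t=%.2f failed; halving dt to %.3f", state.time, dt / 2)
        half = _step_healing_once(model, state, dt / 2.0, params, cfg)
        return step_healing(model, half, dt / 2.0, params, cfg)


def _step_healing_once(model, state, dt, params, cfg) -> HealingState:
    mesh = model.mesh
    new = state.copy()
    # start-of-step elastic volume change -> mechanosensing
    u_elem = state.u[mesh.tets]
    F = model.deformation_gradient(u_elem)
    Fe = F @ con.plastic_inverse(state.micro.lam_p, state.micro.basis)
    Je = np.linalg.det(Fe)
    H_e = con.mechanosensing(Je, model.mech)
    H_n = model.nodal_projection(H_e)

    # (i) reaction-diffusion fields
    new.rho, new.c = model.update_fields(state, dt, params, H_n)

    # (ii) quadrature-point remodeling at the frozen configuration
    rho_e = model.element_means(new.rho)
    c_e = model.element_means(new.c)
    Ce = np.swapaxes(Fe, 1, 2) @ Fe
    kin.remodel_step(new.micro, rho_e, c_e, H_e, Ce, dt, params)

    # (iii) mechanical re-equilibration; on failure, ramp the activation
    # from the warm start, then from scratch (a bad warm start can trap the
    # Newton path even when a nearby equilibrium exists)
    scale = _active_force_scale(model, new, rho_e, c_e)
    try:
        new.u, new.residual_norm = model.solve_equilibrium(
            state.u, new.micro, rho_e, c_e,
            tol=cfg.newton_tol, max_iter=cfg.newton_max_iter, force_scale=scale,
        )
    except SolverError:
        try:
            new.u, new.residual_norm = solve_with_active_ramp(
                model, state.u, new.micro, rho_e, c_e, cfg, scale, n_ramp=8
            )
        except SolverError:
            model._mech_lu = None
            new.u, new.residual_norm = solve_with_active_ramp(
                model, np.zeros_like(state.u), new.micro, rho_e, c_e, cfg, scale,
                n_ramp=12,
            )
    new.time = state.time + dt
    return new


def run_healing(
    model: FEModel,
    state0: HealingState,
    params: kin.KineticParams,
    config: SolverConfig | None = None,
    callback=None,
):
    """March the healing problem over the horizon, archiving states at the
    output cadence.  Returns ``(times, states)`` with ``states[0]`` the
    (equilibrated) initial state."""
    cfg = config or SolverConfig()
    state = state0
    states = [state.copy()]
    times = [state.time]
    n_steps = int(round(cfg.horizon / cfg.dt))
    per_out = int(round(cfg.output_cadence / cfg.dt))
    for k in range(1, n_steps + 1):
        state = step_healing(model, state, cfg.dt, params, cfg)
        if k % per_out == 0:
            states.append(state.copy())
            times.append(state.time)
            if callback is not None:
                callback(state)
    return np.array(times), states


# ---------------------------------------------------------------------------
# patient-level convenience


def simulate_patient(
    chars,
    fidelity: str = "low",
    params: kin.KineticParams | None = None,
    config: SolverConfig | None = None,
    active: con.ActiveStressParams | None = None,
    mech: con.MechanosensingParams | None = None,
):
    """Full healing simulation for one synthetic patient.

    Builds the geometry (taken as the upright pre-excision reference),
    solves the homeostatic pre-excision equilibrium (the %BSD reference
    surface), equilibrates the post-excision state, then integrates the
    4-week healing problem.  Returns a dict with the mesh, reference
    displacement, output times, archived states, and cavity-center node.
    """
    from .cohort import build_geometry

    params = params or kin.default_params()
    cfg = config or SolverConfig()
    mesh = build_geometry(chars, fidelity)
    mats = healing_materials(mesh, chars.breast_density)
    model = FEModel(mesh, *mats, active=active, mech=mech)

    # pre-excision reference: homeostatic fields everywhere (tumor ~ tissue)
    micro_ref = Microstructure.isotropic(mesh.n_tets)
    rho_ref = np.ones(mesh.n_points)
    c_ref = np.zeros(mesh.n_points)
    rho_e = model.element_means(rho_ref)
    c_e = model.element_means(c_ref)
    ref_state = HealingState(0.0, np.zeros((mesh.n_points, 3)), rho_ref, c_ref, micro_ref)
    scale = _active_force_scale(model, ref_state, rho_e, c_e)
    u_ref, _ = solve_with_active_ramp(model, ref_state.u, micro_ref, rho_e, c_e, cfg, scale)

    # post-excision equilibrium at t = 0
    state0 = initial_fields(mesh)
    rho_e0 = model.element_means(state0.rho)
    c_e0 = model.element_means(state0.c)
    scale = max(_active_force_scale(model, state0, rho_e0, c_e0), scale)
    state0.u, state0.residual_norm = solve_with_active_ramp(
        model, u_ref, state0.micro, rho_e0, c_e0, cfg, scale)

    times, states = run_healing(model, state0, params, cfg)
    center_node = int(np.argmin(np.linalg.norm(mesh.points - mesh.cavity_center, axis=1)))
    return {
        "chars": chars,
        "mesh": mesh,
        "model": model,
        "u_ref": u_ref,
        "times": times,
        "states": states,
        "center_node": center_node,
    }
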