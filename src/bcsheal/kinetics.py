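"""Local healing kinetics: reaction-diffusion coefficients and sources for
fibroblasts and cytokine, and quadrature-point remodeling ODEs for collagen
fraction, plastic stretch, fiber orientation, and fiber dispersion.

All fields are normalized (healthy tissue baseline 1); rates are per day,
diffusivities mm^2/day.  Every function is vectorized over points.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, fields as dc_fields
from importlib import resources

import numpy as np

__all__ = [
    "KineticParams",
    "load_params",
    "default_params",
    "fibroblast_velocity",
    "fibroblast_diffusivity",
    "field_sources",
    "collagen_rate",
    "plastic_stretch_rate",
    "fiber_reorientation_rate",
    "dispersion_rate",
    "update_collagen",
    "remodel_step",
]


@dataclass(frozen=True)
class KineticParams:
    # fibroblast diffusivity: D = d_rho_phi v(phi)^2/6 + d_rho_c c/(K_rho_c+c) + d_rho_0
    d_rho_phi: float  # day (scales the collagen-dependent motility term)
    v_max: float  # mm/day, peak crawling speed of the biphasic v(phi)
    K_v: float  # dimensionless, collagen level of peak motility
    d_rho_c: float  # mm^2/day, chemokinetic ceiling
    K_rho_c: float  # dimensionless, cytokine saturation (shared with the source term)
    d_rho_0: float  # mm^2/day, baseline motility
    # cytokine diffusivity
    D_c: float  # mm^2/day
    # fibroblast source
    p_rho: float  # 1/day
    p_rho_c: float  # 1/day
    p_rho_e: float  # 1/day (mechanosensing-gated)
    K_rho_rho: float  # carrying capacity
    d_rho: float  # 1/day
    # cytokine source
    p_c_rho: float  # 1/day
    p_c_e: float  # 1/day
    K_c_c: float  # dimensionless
    d_c: float  # 1/day
    # collagen
    p_phi: float  # 1/day
    p_phi_c: float  # 1/day
    K_phi_c: float  # dimensionless
    p_phi_e: float  # 1/day
    K_phi_rho: float  # dimensionless
    d_phi: float  # 1/day
    d_phi_c: float  # 1/day
    # plastic stretch
    tau_lambda_p: float  # dimensionless relaxation scale (divides phi_dot_plus)
    delta_crit: float  # dead-zone half width: lambda_crit_± = 1 ± delta_crit
    one_sided_plasticity: bool  # tension-only variant (no compressive branch) if True
    # fiber reorientation / dispersion
    tau_omega: float
    tau_kappa: float
    gamma_kappa: float
    # whether phi_dot_plus is the production term (default) or max(phi_dot, 0)
    phi_plus_is_production: bool = True

    def __post_init__(self):
        for f in dc_fields(self):
            v = getattr(self, f.name)
            if isinstance(v, bool):
                continue
            if v < 0:
                raise ValueError(f"{f.name} must be nonnegative, got {v}")
        for k in ("K_v", "K_rho_c", "K_rho_rho", "K_c_c", "K_phi_c", "K_phi_rho"):
            if getattr(self, k) <= 0:
                raise ValueError(f"{k} must be positive")


def load_params(path) -> KineticParams:
    """Load kinetic parameters from a TOML file, validating completeness."""
    with open(path, "rb") as f:
        raw = tomllib.load(f)
    names = {f.name for f in dc_fields(KineticParams)}
    missing = names - raw.keys()
    extra = raw.keys() - names
    if missing:
        raise KeyError(f"parameter file missing keys: {sorted(missing)}")
    if extra:
        raise KeyError(f"parameter file has unknown keys: {sorted(extra)}")
    return KineticParams(**raw)


def default_params() -> KineticParams:
    """The package's calibrated default parameter set."""
    ref = resources.files("bcsheal").joinpath("params/default.toml")
    with resources.as_file(ref) as path:
        return load_params(path)


def fibroblast_velocity(phi, p: KineticParams):
    """Biphasic crawling speed ``v(phi) = v_max phi / (K_v^2 + phi^2)``:
    slow in both the void (no substrate) and dense matrix (steric)."""
    phi = np.asarray(phi, dtype=float)
    return p.v_max * phi / (p.K_v**2 + phi**2)


def fibroblast_diffusivity(phi, c, p: KineticParams):
    """``D_rho = d_rho_phi v(phi)^2 / 6 + d_rho_c c/(K_rho_c + c) + d_rho_0``."""
    c = np.asarray(c, dtype=float)
    return (
        p.d_rho_phi * fibroblast_velocity(phi, p) ** 2 / 6.0
        + p.d_rho_c * c / (p.K_rho_c + c)
        + p.d_rho_0
    )


def field_sources(rho, c, H, p: KineticParams):
    """Source terms ``(s_rho, s_c)`` of the fibroblast / cytokine fields.

    ``s_rho = (p_rho + p_rho_c c/(K_rho_c + c) + p_rho_e H)(1 - rho/K_rho_rho) rho - d_rho rho``
    ``s_c   = (p_c_rho c + p_c_e H)(rho/(K_c_c + c)) - d_c c``
    """
    rho = np.asarray(rho, dtype=float)
    c = np.asarray(c, dtype=float)
    H = np.asarray(H, dtype=float)
    s_rho = (p.p_rho + p.p_rho_c * c / (p.K_rho_c + c) + p.p_rho_e * H) * (
        1.0 - rho / p.K_rho_rho
    ) * rho - p.d_rho * rho
    s_c = (p.p_c_rho * c + p.p_c_e * H) * (rho / (p.K_c_c + c)) - p.d_c * c
    return s_rho, s_c


def _collagen_production_coef(c, H, p: KineticParams):
    c = np.asarray(c, dtype=float)
    return p.p_phi + p.p_phi_c * c / (p.K_phi_c + c) + p.p_phi_e * np.asarray(H, dtype=float)


def collagen_rate(rho, c, phi, H, p: KineticParams):
    """Collagen rate and its deposition (positive) part.

    ``phi_dot = P(c, H) rho/(K_phi_rho + phi) - (d_phi + c rho d_phi_c) phi``
    with ``P = p_phi + p_phi_c c/(K_phi_c + c) + p_phi_e H``.  Returns
    ``(phi_dot, phi_dot_plus)`` where the deposition rate is the production
    term (or ``max(phi_dot, 0)`` if so configured).
    """
    rho = np.asarray(rho, dtype=float)
    phi = np.asarray(phi, dtype=float)
    prod = _collagen_production_coef(c, H, p) * rho / (p.K_phi_rho + phi)
    rate = prod - (p.d_phi + np.asarray(c) * rho * p.d_phi_c) * phi
    plus = prod if p.phi_plus_is_production else np.maximum(rate, 0.0)
    return rate, plus


def plastic_stretch_rate(lam_e, phi_dot_plus, p: KineticParams):
    """Dead-zone plastic flow rate per microstructural axis.

    ``lam_p_dot = (phi_dot_plus / tau) [ <lam_e - (1+delta)>_+ - <(1-delta) - lam_e>_+ ]``;
    remodeling (new collagen) converts elastic stretch beyond the dead zone
    into permanent stretch.  With ``one_sided_plasticity`` the compressive
    branch is disabled (tension-only variant).
    """
    lam_e = np.asarray(lam_e, dtype=float)
    up = np.maximum(lam_e - (1.0 + p.delta_crit), 0.0)
    dn = np.maximum((1.0 - p.delta_crit) - lam_e, 0.0)
    if p.one_sided_plasticity:
        dn = 0.0
    return np.asarray(phi_dot_plus)[..., None] / p.tau_lambda_p * (up - dn)


def fiber_reorientation_rate(a0, e1, lam1, phi_dot_plus, tau_omega):
    """``a0_dot = lam1 (2 pi phi_dot_plus / tau_omega)(I - a0 a0) e1`` —
    tangent to the unit sphere, driving ``a0`` toward the maximum-stretch
    eigenvector ``e1``."""
    a0 = np.asarray(a0, dtype=float)
    e1 = np.asarray(e1, dtype=float)
    proj = e1 - np.einsum("...i,...i->...", a0, e1)[..., None] * a0
    coef = np.asarray(lam1) * (2.0 * np.pi * np.asarray(phi_dot_plus) / tau_omega)
    return coef[..., None] * proj


def dispersion_rate(kappa, lam1, lam2, phi_dot_plus, p: KineticParams):
    """``kappa_dot = (phi_dot_plus / tau_kappa)((1/3)(lam2/lam1)^gamma - kappa)``."""
    lam1 = np.asarray(lam1, dtype=float)
    lam2 = np.asarray(lam2, dtype=float)
    if np.any(lam2 > lam1 * (1 + 1e-12)):
        raise ValueError("eigenvalue ordering violated: lam2 > lam1")
    target = (lam2 / lam1) ** p.gamma_kappa / 3.0
    return np.asarray(phi_dot_plus) / p.tau_kappa * (target - np.asarray(kappa))


def update_collagen(rho, c, phi, H, dt, p: KineticParams, tol=1e-10, max_iter=25):
    """Backward-Euler collagen update with vectorized scalar Newton.

    Solves ``g(x) = x - phi - dt [ P rho/(K+x) - (d_phi + c rho d_phi_c) x ] = 0``
    for the end-of-step collagen fraction; falls back to bisection-safe
    clamping at zero.  Returns ``(phi_new, phi_dot_plus)`` with the
    deposition rate evaluated at the end-of-step state.
    """
    rho = np.asarray(rho, dtype=float)
    c = np.asarray(c, dtype=float)
    phi = np.asarray(phi, dtype=float)
    P = _collagen_production_coef(c, H, p)
    dcoef = p.d_phi + c * rho * p.d_phi_c
    x = np.maximum(phi, 0.0)
    for _ in range(max_iter):
        g = x - phi - dt * (P * rho / (p.K_phi_rho + x) - dcoef * x)
        dg = 1.0 + dt * (P * rho / (p.K_phi_rho + x) ** 2 + dcoef)
        step = g / dg
        x = np.maximum(x - step, 0.0)
        if np.max(np.abs(step)) < tol:
            break
    prod = P * rho / (p.K_phi_rho + x)
    plus = prod if p.phi_plus_is_production else np.maximum(prod - dcoef * x, 0.0)
    return x, plus


def remodel_step(state, rho, c, H, Ce, dt, p: KineticParams, eig_gap_tol=1e-8):
    """Advance the quadrature-point microstructure by one time step.

    ``state`` carries arrays ``phi (m,)``, ``kappa (m,)``, ``a0 (m,3)``,
    ``lam_p (m,3)``, ``basis (m,3,3)`` (rows ``a0, s0, n0``); ``Ce`` is the
    elastic right Cauchy-Green tensor per point.  The collagen fraction is
    updated implicitly, the dispersion by its exact exponential relaxation,
    and the plastic stretches / fiber direction explicitly (their rates are
    slow on the 0.1-0.5 day step used here); ``a0`` is renormalized and the
    orthonormal basis rebuilt after every step.  Returns ``phi_dot_plus``.
    """
    phi_new, phi_plus = update_collagen(rho, c, state.phi, H, dt, p)
    state.phi = phi_new

    # elastic stretches along the microstructural axes
    lam_ax = np.sqrt(
        np.maximum(np.einsum("...ki,...ij,...kj->...k", state.basis, Ce, state.basis), 1e-12)
    )
    dlam = dt * plastic_stretch_rate(lam_ax, phi_plus, p)
    # cap the increment at 80 % of the excess beyond the dead zone: plastic
    # relief can approach the threshold within a step but never overshoot it
    # (keeps the explicit update stable for fast remodeling rates)
    excess = np.where(
        dlam > 0, np.maximum(lam_ax - (1.0 + p.delta_crit), 0.0),
        np.maximum((1.0 - p.delta_crit) - lam_ax, 0.0),
    )
    dlam = np.clip(dlam, -0.8 * excess, 0.8 * excess)
    state.lam_p = np.maximum(state.lam_p + dlam, 0.05)

    w, V = np.linalg.eigh(Ce)  # ascending
    lam1 = np.sqrt(np.maximum(w[..., 2], 1e-12))
    lam2 = np.sqrt(np.maximum(w[..., 1], 1e-12))
    e1 = V[..., :, 2]
    # sign convention e1 . a0 >= 0; freeze reorientation on degenerate spectra
    sgn = np.sign(np.einsum("...i,...i->...", e1, state.a0))
    sgn[sgn == 0] = 1.0
    e1 = e1 * sgn[..., None]
    live = (w[..., 2] - w[..., 1]) > eig_gap_tol
    da = fiber_reorientation_rate(state.a0, e1, lam1, phi_plus, p.tau_omega)
    state.a0 = state.a0 + dt * da * live[..., None]
    state.a0 /= np.linalg.norm(state.a0, axis=-1, keepdims=True)

    # kappa relaxes linearly toward its fixed point -> integrate exactly
    target = (lam2 / lam1) ** p.gamma_kappa / 3.0
    decay = np.exp(-dt * phi_plus / p.tau_kappa)
    state.kappa = np.clip(target + (state.kappa - target) * decay, 1e-6, 1.0 / 3.0)

    state.rebuild_basis()
    return phi_plus
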