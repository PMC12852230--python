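"""Point-wise tissue mechanics, vectorized over quadrature points.

Kinematics use the multiplicative elastic-plastic split ``F = Fe Fp`` with
the plastic part diagonal in an orthonormal microstructural basis
``{a0, s0, n0}``.  The passive response is a compressible neo-Hookean
matrix plus a Gasser-Ogden-Holzapfel (GOH) dispersed-fiber term scaled by
the collagen volume fraction ``phi``; the active response is a
fibroblast/myofibroblast traction aligned with the (dispersion-weighted)
deformed fiber structure tensor.

All stress routines accept stacked arrays: shapes ``(..., 3, 3)`` for
tensors and ``(...,)`` for scalar fields.  Stresses are Cauchy, in kPa.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ActiveStressParams",
    "MechanosensingParams",
    "rule_of_mixtures",
    "elastic_constants",
    "mechanosensing",
    "compose_kinematics",
    "strain_energy",
    "passive_stress",
    "active_stress",
    "structure_tensor",
]

# gravity-stage (prone/upright repositioning) tissue moduli, kPa
E_ADIPOSE_GRAVITY = 1.5
E_FIBROGLANDULAR_GRAVITY = 6.0
# healing-stage tissue moduli, kPa
E_ADIPOSE_HEALING = 10.0
E_FIBROGLANDULAR_HEALING = 40.0
# fresh cavity (seroma): zero shear, 300 kPa bulk; a tiny shear
# regularization keeps the tangent nonsingular
CAVITY_BULK = 300.0
CAVITY_SHEAR_REG = 1e-3

POISSON = 0.35  # mildly compressible tissue (interstitial fluid drainage)


@dataclass(frozen=True)
class ActiveStressParams:
    """Fibroblast traction model (Cauchy stress magnitude, kPa)."""

    t_rho: float = 0.2  # baseline cell traction, kPa
    t_rho_c: float = 160.0  # additional cytokine-activated (myofibroblast) traction, kPa
    K_t_c: float = 0.4  # cytokine saturation constant, dimensionless
    K_t: float = 0.1  # collagen level of peak traction (force saturates in dense scar)
    sigma_max: float = 100.0  # kPa; smooth ceiling on the total traction magnitude
    # (cells cannot exert unbounded stress; only bites in the extreme regime)


@dataclass(frozen=True)
class MechanosensingParams:
    """Sigmoid gating of cell activity by elastic volume change."""

    gamma_e: float = 50.0  # sensitivity
    theta_e: float = 1.10  # Je threshold (H ~ 0 at Je = 1: homeostasis preserved)


def rule_of_mixtures(density: float, E_a: float, E_f: float) -> float:
    """Effective Young's modulus from the fibroglandular volume fraction."""
    density = np.asarray(density, dtype=float)
    if np.any(density < 0) or np.any(density > 1):
        raise ValueError("breast density must lie in [0, 1]")
    return density * E_f + (1.0 - density) * E_a


def elastic_constants(E, nu: float = POISSON):
    """Convert Young's modulus to ``(k0, k1)``.

    ``k0`` multiplies ``I1 - 3`` (half-shear-modulus convention: mu = 2 k0)
    and ``k1`` the volumetric penalty.  Linearizing the energy about the
    reference gives ``sigma = 4 k0 eps + k1 tr(eps) I``, so ``k1`` is the
    first Lame parameter — this choice makes the small-strain response
    reproduce (E, nu) exactly.
    """
    E = np.asarray(E, dtype=float)
    mu = E / (2.0 * (1.0 + nu))
    k0 = mu / 2.0
    k1 = E * nu / ((1.0 + nu) * (1.0 - 2.0 * nu))
    return k0, k1


def mechanosensing(Je, p: MechanosensingParams = MechanosensingParams()):
    """Activation ``H(Je) = 1 / (1 + exp(-gamma_e (Je - theta_e)))`` in (0, 1)."""
    return 1.0 / (1.0 + np.exp(-p.gamma_e * (np.asarray(Je, dtype=float) - p.theta_e)))


def plastic_inverse(lam_p: np.ndarray, basis: np.ndarray) -> np.ndarray:
    """``(Fp)^-1`` from plastic stretches (..., 3) and basis rows (..., 3, 3)."""
    return np.einsum("...k,...ki,...kj->...ij", 1.0 / lam_p, basis, basis)


def compose_kinematics(F: np.ndarray, lam_p: np.ndarray, basis: np.ndarray, tol: float = 1e-8):
    """Elastic deformation gradient ``Fe = F (Fp)^-1``.

    ``basis`` rows are ``a0, s0, n0``; must be orthonormal to within ``tol``.
    Returns ``(Fe, Jp)``.
    """
    gram = np.einsum("...ik,...jk->...ij", basis, basis)
    if not np.allclose(gram, np.broadcast_to(np.eye(3), gram.shape), atol=tol):
        raise ValueError("plastic basis is not orthonormal")
    lam_p = np.asarray(lam_p, dtype=float)
    if np.any(lam_p <= 0):
        raise ValueError("plastic stretches must be positive")
    Fe = F @ plastic_inverse(lam_p, basis)
    return Fe, np.prod(lam_p, axis=-1)


def _det3(A):
    return (
        A[..., 0, 0] * (A[..., 1, 1] * A[..., 2, 2] - A[..., 1, 2] * A[..., 2, 1])
        - A[..., 0, 1] * (A[..., 1, 0] * A[..., 2, 2] - A[..., 1, 2] * A[..., 2, 0])
        + A[..., 0, 2] * (A[..., 1, 0] * A[..., 2, 1] - A[..., 1, 1] * A[..., 2, 0])
    )


def _invariants(Fe: np.ndarray, a0: np.ndarray):
    Je = _det3(Fe)
    be = Fe @ np.swapaxes(Fe, -1, -2)
    I1e = np.trace(be, axis1=-2, axis2=-1)
    a = np.einsum("...ij,...j->...i", Fe, a0)
    I4e = np.einsum("...i,...i->...", a, a)
    return Je, be, I1e, a, I4e


def _fiber_strain(I1e, I4e, kappa, legacy_exponent: bool):
    """GOH fiber strain measure (or the legacy exponent argument)."""
    if legacy_exponent:
        return kappa * I1e + (1.0 - 3.0 * kappa) * I4e - 1.0
    return kappa * (I1e - 3.0) + (1.0 - 3.0 * kappa) * (I4e - 1.0)


def strain_energy(
    Fe, phi, kappa, a0, k0, k1, kf=0.0, k2=1.0, tension_only=True, legacy_exponent=False
):
    """Strain-energy density (kPa), linear in the collagen fraction ``phi``.

    ``Psi = phi [ k0 (I1e - 3) + k1/2 (Je - 1)^2 - 2 k0 log Je
    + kf/(2 k2) (exp(k2 E^2) - 1) ]`` with the GOH fiber strain
    ``E = kappa (I1e - 3) + (1 - 3 kappa)(I4e - 1)``, which is stress-free
    at ``Fe = I``.  ``legacy_exponent=True`` switches to the variant
    ``E = kappa I1e + (1 - 3 kappa) I4e - 1``, which carries stress at the
    reference state unless ``k2 = 1``; retained as a comparison switch.
    """
    Je, _, I1e, _, I4e = _invariants(np.asarray(Fe, dtype=float), np.asarray(a0, dtype=float))
    if np.any(Je <= 0):
        raise ValueError("element inversion: det(Fe) <= 0")
    E = _fiber_strain(I1e, I4e, np.asarray(kappa, dtype=float), legacy_exponent)
    if tension_only and not legacy_exponent:
        # gate on E > 0: the energy is C1 there (zero slope), so the stress
        # stays continuous across the tension/compression switch
        E = np.maximum(E, 0.0)
    kf = np.asarray(kf, dtype=float)
    k2 = np.asarray(k2, dtype=float)
    if legacy_exponent:
        fiber = kf / (2.0 * k2) * np.exp(k2 * E**2)
    else:
        fiber = kf / (2.0 * k2) * np.expm1(np.minimum(k2 * E**2, 50.0))
    return phi * (k0 * (I1e - 3.0) + 0.5 * k1 * (Je - 1.0) ** 2 - 2.0 * k0 * np.log(Je) + fiber)


def passive_stress(Fe, phi, kappa, a0, k0, k1, kf=0.0, k2=1.0, tension_only=True):
    """Passive Cauchy stress ``(2/Je) Fe dPsi/dCe Fe^T`` (kPa, symmetric).

    Closed form: ``sigma = (2 phi / Je) [ k0 (be - I) + (k1/2) Je (Je - 1) I
    + kf exp(k2 E^2) E (kappa be + (1 - 3 kappa) ae x ae) ]``.
    """
    Fe = np.asarray(Fe, dtype=float)
    Je, be, I1e, a, I4e = _invariants(Fe, np.asarray(a0, dtype=float))
    if np.any(Je <= 0):
        raise ValueError("element inversion: det(Fe) <= 0")
    kappa = np.asarray(kappa, dtype=float)
    k0 = np.asarray(k0, dtype=float)[..., None, None]
    phi_ = np.asarray(phi, dtype=float)[..., None, None]
    Je_ = Je[..., None, None]
    eye = np.broadcast_to(np.eye(3), be.shape)
    sig = k0 * (be - eye) + (0.5 * np.asarray(k1, dtype=float) * Je * (Je - 1.0))[
        ..., None, None
    ] * eye
    kf = np.asarray(kf, dtype=float)
    if np.any(kf > 0):
        E = _fiber_strain(I1e, I4e, kappa, legacy_exponent=False)
        if tension_only:
            E = np.maximum(E, 0.0)
        coef = kf * np.exp(np.minimum(np.asarray(k2) * E**2, 50.0)) * E
        H = kappa[..., None, None] * be + (1.0 - 3.0 * kappa)[..., None, None] * np.einsum(
            "...i,...j->...ij", a, a
        )
        sig = sig + coef[..., None, None] * H
    return (2.0 * phi_ / Je_) * sig


def structure_tensor(kappa, a):
    """Normalized active-stress direction tensor ``A/tr(A)``,
    ``A = I + (1 - 3 kappa) a x a``; ``tr(Ahat) = 1`` exactly."""
    kappa = np.asarray(kappa, dtype=float)
    a = np.asarray(a, dtype=float)
    A = np.broadcast_to(np.eye(3), a.shape + (3,)).copy()
    A += (1.0 - 3.0 * kappa)[..., None, None] * np.einsum("...i,...j->...ij", a, a)
    tr = np.trace(A, axis1=-2, axis2=-1)
    return A / tr[..., None, None]


def active_stress(rho, c, phi, kappa, a, p: ActiveStressParams):
    """Active Cauchy stress ``rho (t_rho + t_rho_c c/(K_t_c + c))
    (phi / (K_t^2 + phi^2)) Ahat`` (kPa, symmetric PSD)."""
    rho = np.asarray(rho, dtype=float)
    c = np.asarray(c, dtype=float)
    phi = np.asarray(phi, dtype=float)
    mag = rho * (p.t_rho + p.t_rho_c * c / (p.K_t_c + c)) * phi / (p.K_t**2 + phi**2)
    if p.sigma_max > 0:
        mag = p.sigma_max * np.tanh(mag / p.sigma_max)
    return mag[..., None, None] * structure_tensor(kappa, a)
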