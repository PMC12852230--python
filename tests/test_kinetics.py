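"""Reaction-diffusion coefficients, sources, and remodeling ODE laws."""

import dataclasses

import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from bcsheal import kinetics as kin
from bcsheal.fem import Microstructure

P = kin.default_params()
RNG = np.random.default_rng(7)


def _unit_params(**over):
    """All rates/saturations set to 1 (symbolic-oracle convenience)."""
    names = [f.name for f in dataclasses.fields(kin.KineticParams)]
    vals = {n: 1.0 for n in names}
    vals["one_sided_plasticity"] = False
    vals["phi_plus_is_production"] = True
    vals["delta_crit"] = 0.1
    vals.update(over)
    return kin.KineticParams(**vals)


class TestParameterFile:
    def test_default_loads_and_validates(self):
        assert P.D_c > 0 and P.tau_lambda_p > 0

    def test_missing_key_fails_loudly(self, tmp_path):
        f = tmp_path / "bad.toml"
        f.write_text("D_c = 1.0\n")
        with pytest.raises(KeyError, match="missing"):
            kin.load_params(f)

    def test_unknown_key_fails_loudly(self, tmp_path):
        ref = dataclasses.asdict(P)
        lines = [f"{k} = {str(v).lower() if isinstance(v, bool) else v}" for k, v in ref.items()]
        lines.append("mystery_rate = 3.0")
        f = tmp_path / "extra.toml"
        f.write_text("\n".join(lines))
        with pytest.raises(KeyError, match="unknown"):
            kin.load_params(f)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            dataclasses.replace(P, d_c=-0.1)

    def test_tissue_homeostasis(self):
        """At the healthy baseline (rho=1, c=0, phi=1, H~0) the net rates
        vanish, so healthy tissue far from the wound stays put."""
        s_rho, s_c = kin.field_sources(1.0, 0.0, 0.0, P)
        assert abs(s_rho) < 1e-12 and abs(s_c) < 1e-12
        rate, _ = kin.collagen_rate(1.0, 0.0, 1.0, 0.0, P)
        assert abs(rate) < 1e-3


class TestFibroblastDiffusivity:
    def test_no_cytokine_leaves_motility_term(self):
        phi = 0.7
        expect = P.d_rho_phi * kin.fibroblast_velocity(phi, P) ** 2 / 6 + P.d_rho_0
        assert kin.fibroblast_diffusivity(phi, 0.0, P) == pytest.approx(expect)

    def test_chemokinetic_saturation(self):
        d_inf = kin.fibroblast_diffusivity(0.5, 1e9, P) - kin.fibroblast_diffusivity(0.5, 0.0, P)
        assert d_inf == pytest.approx(P.d_rho_c, rel=1e-6)

    def test_monotone_in_cytokine(self):
        c = np.linspace(0, 5, 40)
        D = kin.fibroblast_diffusivity(0.8, c, P)
        assert (np.diff(D) > 0).all()

    def test_velocity_biphasic(self):
        """Crawling speed is low in both the void and dense matrix."""
        phi = np.array([1e-3, P.K_v, 50.0])
        v = kin.fibroblast_velocity(phi, P)
        assert v[1] > v[0] and v[1] > v[2]
        assert v[1] == pytest.approx(P.v_max / (2 * P.K_v))


class TestFieldSources:
    def test_carrying_capacity(self):
        s_rho, _ = kin.field_sources(P.K_rho_rho, 0.3, 0.5, P)
        assert s_rho == pytest.approx(-P.d_rho * P.K_rho_rho)

    def test_no_cells_no_production(self):
        s_rho, s_c = kin.field_sources(0.0, 0.7, 0.5, P)
        assert s_rho == 0.0
        assert s_c == pytest.approx(-P.d_c * 0.7)

    def test_symbolic_oracle(self):
        """Rate laws agree with an independent sympy evaluation on random
        states (relative error < 1e-10)."""
        import sympy as sp

        rho, c, H = sp.symbols("rho c H")
        p = _unit_params()
        s_rho_sym = (1 + c / (1 + c) + H) * (1 - rho / 1) * rho - rho
        s_c_sym = (c + H) * (rho / (1 + c)) - c
        f_rho = sp.lambdify((rho, c, H), s_rho_sym)
        f_c = sp.lambdify((rho, c, H), s_c_sym)
        for _ in range(100):
            r, cc, h = RNG.uniform(0, 2, 3)
            got_r, got_c = kin.field_sources(r, cc, h, p)
            assert got_r == pytest.approx(f_rho(r, cc, h), rel=1e-10, abs=1e-12)
            assert got_c == pytest.approx(f_c(r, cc, h), rel=1e-10, abs=1e-12)


class TestCollagen:
    def test_pure_degradation(self):
        rate, plus = kin.collagen_rate(0.0, 0.0, 0.8, 0.0, P)
        assert rate == pytest.approx(-P.d_phi * 0.8)
        assert plus == 0.0

    def test_steady_state_matches_bisection(self):
        """The root of phi_dot(phi) at fixed fields agrees with a bracketing
        root finder to 1e-8."""
        rho, c, H = 1.0, 0.4, 0.3

        def f(phi):
            return kin.collagen_rate(rho, c, phi, H, P)[0]

        root = brentq(f, 1e-6, 100.0, xtol=1e-12)
        assert abs(f(root)) < 1e-10
        # implicit update converges to the same steady state
        phi = 0.5
        for _ in range(4000):
            phi, _ = kin.update_collagen(rho, c, phi, H, 0.5, P)
        assert phi == pytest.approx(root, abs=1e-8)

    def test_deposition_rate_is_production_term(self):
        _, plus = kin.collagen_rate(0.5, 0.2, 3.0, 0.1, P)
        prod = (P.p_phi + P.p_phi_c * 0.2 / (P.K_phi_c + 0.2) + P.p_phi_e * 0.1) * 0.5 / (
            P.K_phi_rho + 3.0)
        assert plus == pytest.approx(prod)

    def test_implicit_update_matches_ode_oracle(self):
        """Backward-Euler collagen update tracks a high-accuracy integration
        of the same ODE."""
        rho, c, H = 0.8, 0.6, 0.2
        sol = solve_ivp(lambda t, y: kin.collagen_rate(rho, c, y, H, P)[0],
                        (0, 10), [0.01], rtol=1e-10, atol=1e-12)
        phi = 0.01
        for _ in range(200):
            phi, _ = kin.update_collagen(rho, c, phi, H, 0.05, P)
        assert phi == pytest.approx(sol.y[0, -1], rel=2e-2)


class TestPlasticStretch:
    def test_dead_zone(self):
        p = _unit_params(delta_crit=0.1)
        lam = np.array([[0.95, 1.0, 1.05]])
        rate = kin.plastic_stretch_rate(lam, np.array([1.0]), p)
        np.testing.assert_allclose(rate, 0.0)

    def test_no_remodeling_without_deposition(self):
        p = _unit_params()
        rate = kin.plastic_stretch_rate(np.array([[1.5, 0.5, 1.0]]), np.array([0.0]), p)
        np.testing.assert_allclose(rate, 0.0)

    def test_direct_rate_value(self):
        p = _unit_params(delta_crit=0.1, tau_lambda_p=1.0)
        rate = kin.plastic_stretch_rate(np.array([[1.2]]), np.array([0.5]), p)
        assert rate[0, 0] == pytest.approx(0.05)

    def test_one_sided_disables_compression(self):
        p = _unit_params(delta_crit=0.1, one_sided_plasticity=True)
        rate = kin.plastic_stretch_rate(np.array([[0.5]]), np.array([1.0]), p)
        assert rate[0, 0] == 0.0


class TestFiberReorientation:
    def test_aligned_fixed_point(self):
        a0 = np.array([[0.0, 0.0, 1.0]])
        da = kin.fiber_reorientation_rate(a0, a0, 1.2, 0.5, 1.0)
        np.testing.assert_allclose(da, 0.0, atol=1e-14)

    def test_rate_tangent_to_sphere(self):
        a0 = RNG.standard_normal((40, 3))
        a0 /= np.linalg.norm(a0, axis=1, keepdims=True)
        e1 = RNG.standard_normal((40, 3))
        e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
        da = kin.fiber_reorientation_rate(a0, e1, np.full(40, 1.1), np.full(40, 0.3), 2.0)
        np.testing.assert_allclose(np.einsum("ij,ij->i", da, a0), 0.0, atol=1e-12)

    def test_converges_to_principal_direction(self):
        """Small-step integration on the unit sphere drives a0 to +-e1."""
        a0 = np.array([[1.0, 0.0, 0.0]])
        a0 = a0 + 1e-3  # break exact orthogonality (unstable equilibrium)
        a0 /= np.linalg.norm(a0)
        e1 = np.array([[0.0, 0.0, 1.0]])
        for _ in range(4000):
            da = kin.fiber_reorientation_rate(a0, e1, 1.2, 0.5, 5.0)
            a0 = a0 + 0.01 * da
            a0 /= np.linalg.norm(a0)
        assert abs(abs(a0[0] @ e1[0]) - 1.0) < 1e-6


class TestDispersion:
    def test_isotropy_preserved(self):
        rate = kin.dispersion_rate(1 / 3, 1.2, 1.2, 0.5, P)
        assert rate == pytest.approx(0.0, abs=1e-14)

    def test_alignment_develops_under_anisotropic_stretch(self):
        rate = kin.dispersion_rate(1 / 3, 1.5, 1.0, 0.5, P)
        assert rate < 0.0

    def test_eigenvalue_ordering_enforced(self):
        with pytest.raises(ValueError):
            kin.dispersion_rate(0.2, 1.0, 1.5, 0.5, P)

    def test_relaxes_to_fixed_point(self):
        """Long-time integration reaches kappa* = (1/3)(lam2/lam1)^gamma."""
        lam1, lam2 = 1.4, 1.1
        target = (lam2 / lam1) ** P.gamma_kappa / 3.0
        sol = solve_ivp(lambda t, k: kin.dispersion_rate(k, lam1, lam2, 1.0, P),
                        (0, 2000), [1 / 3], rtol=1e-12, atol=1e-14)
        assert sol.y[0, -1] == pytest.approx(target, abs=1e-6)


class TestRemodelStep:
    def test_invariants_after_update(self):
        """Unit fiber direction, kappa in (0, 1/3], positive plastic
        stretches, orthonormal basis — after every step."""
        m = 60
        micro = Microstructure.isotropic(m)
        micro.phi = RNG.uniform(0.01, 2.0, m)
        rho = RNG.uniform(0, 1.2, m)
        c = RNG.uniform(0, 1.0, m)
        H = RNG.uniform(0, 1, m)
        F = np.eye(3) + 0.2 * RNG.standard_normal((m, 3, 3))
        F[np.linalg.det(F) < 0.3] = np.eye(3)
        Ce = np.swapaxes(F, 1, 2) @ F
        for _ in range(5):
            kin.remodel_step(micro, rho, c, H, Ce, 0.5, P)
            np.testing.assert_allclose(np.linalg.norm(micro.a0, axis=1), 1.0, rtol=1e-12)
            assert (micro.kappa > 0).all() and (micro.kappa <= 1 / 3 + 1e-12).all()
            assert (micro.lam_p > 0).all() and (micro.phi >= 0).all()
            gram = np.einsum("eik,ejk->eij", micro.basis, micro.basis)
            np.testing.assert_allclose(gram, np.broadcast_to(np.eye(3), gram.shape),
                                       atol=1e-10)

    def test_homeostatic_state_is_stationary(self):
        micro = Microstructure.isotropic(4)
        Ce = np.tile(np.eye(3), (4, 1, 1))
        kin.remodel_step(micro, np.ones(4), np.zeros(4), np.zeros(4), Ce, 0.5, P)
        np.testing.assert_allclose(micro.lam_p, 1.0)
        np.testing.assert_allclose(micro.phi, 1.0, atol=2e-3)
        np.testing.assert_allclose(micro.kappa, 1 / 3)
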