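"""Disc geometry, Gaussian form functions, elliptic potential, transport."""

import numpy as np
import pytest
from scipy.integrate import quad

from tumimm import (
    GaussianSpec,
    ScalarField,
    TransportCoefficients,
    advance_field,
    gaussian_field,
    integrate_weighted,
    make_disc_grid,
    solve_potential,
)
from tumimm.spatial_fields import advection_cfl_dt, advection_matrix

COEFFS = TransportCoefficients(chi=0.864, D=0.05, K=1.0)


class TestDiscGrid:
    def test_area_converges_to_pi(self):
        for n_axis in (16, 64, 128):
            g = make_disc_grid(n_axis)
            assert abs(g.n_active * g.cell_area - np.pi) <= 4.0 / n_axis

    def test_origin_in_corner_out(self, disc64):
        r = np.hypot(disc64.xy[:, 0], disc64.xy[:, 1])
        assert r.min() < disc64.h  # a cell at the origin is active
        assert r.max() < 1.0       # nothing outside the disc

    def test_too_small(self):
        with pytest.raises(ValueError):
            make_disc_grid(4)


class TestGaussianField:
    def test_center_value_and_zero_amplitude(self, disc64):
        f = gaussian_field(GaussianSpec(1.0, 0.02), disc64)
        # the peak sits at the cell center nearest the origin
        d2 = (disc64.xy ** 2).sum(axis=1).min()
        peak = 1.0 / (2 * np.pi * 0.02) * np.exp(-d2 / 0.04)
        assert f.values.max() == pytest.approx(peak, rel=1e-12)
        z = gaussian_field(GaussianSpec(0.0, 0.02), disc64)
        assert np.all(z.values == 0.0)

    def test_integral_close_to_amplitude(self, disc64):
        # the printed kill-weight Gaussian: essentially all mass in the disc
        f = gaussian_field(GaussianSpec(1.0, 0.02), disc64)
        assert f.integral() == pytest.approx(1.0, rel=1e-3)


class TestPotential:
    def test_zero_strength_and_gauge(self, disc64):
        sig = gaussian_field(GaussianSpec(0.002, 0.05), disc64)
        phi0 = solve_potential(sig, COEFFS, 0.0, disc64)
        assert np.all(phi0.values == 0.0)
        phi = solve_potential(sig, COEFFS, 0.7, disc64)
        assert abs(phi.values.mean()) <= 1e-14 * np.abs(phi.values).max()

    def test_radial_oracle(self, disc64):
        """Centered Gaussian source: match the 1-D radial two-point BVP
        solved by independent quadrature."""
        spec = GaussianSpec(0.002, 0.05)
        s, K = 0.7, COEFFS.K
        sig = gaussian_field(spec, disc64)
        phi = solve_potential(sig, COEFFS, s, disc64)
        mean_sig = sig.values.mean()

        def sig_tilde(rho):
            raw = spec.amplitude / (2 * np.pi * spec.xi2) * np.exp(
                -rho ** 2 / (2 * spec.xi2))
            return s * (raw - mean_sig)

        def dphi(r):
            if r < 1e-12:
                return 0.0
            val, _ = quad(lambda rho: sig_tilde(rho) * rho, 0.0, r)
            return -val / (K * r)

        rs = np.linspace(0.0, 1.0, 201)
        incr = [quad(dphi, rs[i], rs[i + 1])[0] for i in range(200)]
        phir = np.concatenate([[0.0], np.cumsum(incr)])
        phir -= 2.0 * np.trapezoid(phir * rs, rs)  # disc mean of a radial field
        r_cells = np.hypot(disc64.xy[:, 0], disc64.xy[:, 1])
        oracle = np.interp(r_cells, rs, phir)
        span = phir.max() - phir.min()
        assert np.abs(phi.values - oracle).max() <= 0.02 * span


class TestAdvanceField:
    def test_zero_stays_zero(self, disc64):
        u = ScalarField.zeros(disc64)
        phi = ScalarField.zeros(disc64)
        out = advance_field(u, phi, COEFFS, np.zeros(disc64.n_active),
                            np.full(disc64.n_active, 0.18), 0.01)
        assert np.all(out.values == 0.0)

    def test_reaction_ode_limit(self, disc32):
        """No drift, tiny diffusion: each interior cell follows
        u' = g S - gamma u toward (g S / gamma)(1 - e^{-gamma t})."""
        slow = TransportCoefficients(chi=0.864, D=1e-6, K=1.0)
        phi = ScalarField.zeros(disc32)
        gS, gamma = 2.5, 0.5
        u = ScalarField.zeros(disc32)
        dt, t_end = 2e-3, 2.0
        for _ in range(round(t_end / dt)):
            u = advance_field(u, phi, slow, np.full(disc32.n_active, gS),
                              np.full(disc32.n_active, gamma), dt)
        expected = gS / gamma * (1.0 - np.exp(-gamma * t_end))
        r = np.hypot(disc32.xy[:, 0], disc32.xy[:, 1])
        interior = r < 0.5  # away from the Dirichlet boundary layer
        assert np.abs(u.values[interior] - expected).max() <= 2e-3 * expected

    def test_sup_norm_non_increasing(self, disc32):
        """Pure diffusion + decay with zero boundary obeys the maximum
        principle."""
        rng = np.random.default_rng(11)
        u = ScalarField(disc32, rng.random(disc32.n_active))
        phi = ScalarField.zeros(disc32)
        sup = u.values.max()
        for _ in range(20):
            u = advance_field(u, phi, COEFFS, np.zeros(disc32.n_active),
                              np.full(disc32.n_active, 0.1), 0.02)
            new_sup = u.values.max()
            assert new_sup <= sup * (1 + 1e-12)
            sup = new_sup

    def test_positivity_with_drift(self, disc32):
        rng = np.random.default_rng(5)
        sig = gaussian_field(GaussianSpec(0.02, 0.05), disc32)
        phi = solve_potential(sig, COEFFS, 1.0, disc32)
        u = ScalarField(disc32, rng.random(disc32.n_active))
        dt = min(0.02, advection_cfl_dt(phi, COEFFS))
        for _ in range(30):
            u = advance_field(u, phi, COEFFS, np.zeros(disc32.n_active),
                              np.zeros(disc32.n_active), dt)
            assert np.all(u.values >= 0.0)

    def test_cfl_violation_raises(self, disc32):
        sig = gaussian_field(GaussianSpec(0.02, 0.05), disc32)
        phi = solve_potential(sig, COEFFS, 1.0, disc32)
        u = ScalarField.constant(disc32, 1.0)
        dt_adm = advection_cfl_dt(phi, COEFFS)
        with pytest.raises(ValueError, match="admissible dt"):
            advance_field(u, phi, COEFFS, np.zeros(disc32.n_active),
                          np.zeros(disc32.n_active), 10 * dt_adm)


class TestIntegrateWeighted:
    def test_zero_and_linearity(self, disc64):
        delta = gaussian_field(GaussianSpec(1.0, 0.02), disc64)
        zero = ScalarField.zeros(disc64)
        assert integrate_weighted(zero, delta) == 0.0
        k = 3.7
        const = ScalarField.constant(disc64, k)
        assert integrate_weighted(const, delta) == pytest.approx(
            k * delta.integral(), rel=1e-12)

    def test_gaussian_product_closed_form(self, disc64):
        """Two centered Gaussians: ∫ G1 G2 = A1 A2 / (2 pi (xi1^2 + xi2^2))
        over the plane, nearly all inside the disc."""
        g1 = gaussian_field(GaussianSpec(1.0, 0.02), disc64)
        g2 = gaussian_field(GaussianSpec(0.5, 0.05), disc64)
        exact = 1.0 * 0.5 / (2 * np.pi * (0.02 + 0.05))
        assert integrate_weighted(g1, g2) == pytest.approx(exact, rel=5e-3)

    def test_grid_mismatch(self, disc64, disc32):
        with pytest.raises(ValueError):
            integrate_weighted(ScalarField.zeros(disc64),
                               ScalarField.zeros(disc32))


def test_grid_convergence_of_weighted_kill():
    """Halving the cell size changes ∫ delta c at fixed time by O(h)."""
    delta_spec = GaussianSpec(1.0, 0.05)
    vals = []
    for n_axis in (24, 48, 96):
        g = make_disc_grid(n_axis)
        delta = gaussian_field(delta_spec, g)
        sig = gaussian_field(GaussianSpec(0.02, 0.05), g)
        phi = solve_potential(sig, COEFFS, 1.0, g)
        u = ScalarField.zeros(g)
        dt, t_end = 0.01, 0.5
        for _ in range(round(t_end / dt)):
            u = advance_field(u, phi, COEFFS, np.full(g.n_active, 1.0),
                              np.full(g.n_active, 0.18), dt)
        vals.append(integrate_weighted(u, delta))
    err_coarse = abs(vals[0] - vals[2])
    err_fine = abs(vals[1] - vals[2])
    assert err_fine <= 0.75 * err_coarse  # at least first-order decay


def test_advection_matrix_matches_stepper(disc32):
    """The sparse advection operator equals the matrix-free upwind update."""
    rng = np.random.default_rng(2)
    sig = gaussian_field(GaussianSpec(0.02, 0.05), disc32)
    phi = solve_potential(sig, COEFFS, 1.0, disc32)
    u = ScalarField(disc32, rng.random(disc32.n_active))
    tiny = TransportCoefficients(chi=0.864, D=1e-14, K=1.0)
    dt = 0.5 * advection_cfl_dt(phi, COEFFS)
    stepped = advance_field(u, phi, tiny, np.zeros(disc32.n_active),
                            np.zeros(disc32.n_active), dt)
    A = advection_matrix(phi, 0.864)
    explicit = u.values - dt * (A @ u.values)
    assert np.abs(stepped.values - explicit).max() <= 1e-9
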