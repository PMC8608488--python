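"""Growth law, binary division operator, moments, stepper and eigenpairs."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tumimm import (
    DivisionModel,
    GrowthLaw,
    SizeGrid,
    TumorDensity,
    division_apply,
    growth_rate,
    leading_eigenpair,
    moments,
    tumor_step,
)
from tumimm.size_dynamics import admissible_dt


class TestGrowthRate:
    def test_gompertz_vanishes_at_endpoints(self, gompertz_law):
        assert growth_rate(0.0, gompertz_law) == 0.0
        assert growth_rate(10.0, gompertz_law) == 0.0
        assert growth_rate(1e-12, gompertz_law) == pytest.approx(0.0, abs=1e-9)

    def test_gompertz_closed_form(self, gompertz_law):
        assert growth_rate(1.0, gompertz_law) == pytest.approx(0.616 * math.log(10.0))

    def test_constant(self, constant_law):
        z = np.linspace(0, 50, 7)
        assert np.all(growth_rate(z, constant_law) == 0.616)

    def test_gompertz_domain_error(self, gompertz_law):
        with pytest.raises(ValueError):
            growth_rate(10.5, gompertz_law)
        with pytest.raises(ValueError):
            growth_rate(-0.1, gompertz_law)


class TestDivisionOperator:
    def test_zero_density(self, size_grid, constant_division):
        q = division_apply(TumorDensity(size_grid, np.zeros(256)), constant_division)
        assert np.all(q == 0.0)

    @given(seed=st.integers(0, 100))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_first_moment_conserved(self, seed):
        """Division never changes the total tumor mass: ∫ z Q(n) dz = 0."""
        rng = np.random.default_rng(seed)
        grid = SizeGrid(z_max=10.0, n_cells=128)
        n = TumorDensity(grid, rng.random(128))
        for model in (DivisionModel(rate_kind="constant", a=0.8),
                      DivisionModel(rate_kind="threshold", a=0.8, z0=1.0)):
            q = division_apply(n, model)
            m1_q = np.sum(grid.widths * grid.centers * q)
            _, mu1 = moments(n)
            assert abs(m1_q) <= 1e-10 * mu1

    def test_zeroth_moment_gains_cells(self, size_grid, constant_division):
        """∫ Q(n) dz = a mu0: division increases the number of cells."""
        rng = np.random.default_rng(3)
        vals = np.zeros(256)
        vals[: 90] = rng.random(90)  # support in the lower half of the grid
        n = TumorDensity(size_grid, vals)
        mu0, _ = moments(n)
        q = division_apply(n, constant_division)
        # the exact-first-moment correction shifts the zeroth moment at O(h)
        assert np.sum(size_grid.widths * q) == pytest.approx(0.8 * mu0, rel=5e-3)

    def test_brute_force_quadrature_oracle(self):
        """Cell averages of 4 a(2z) n(2z) - a(z) n(z) by fine subsampling."""
        rng = np.random.default_rng(7)
        grid = SizeGrid(z_max=8.0, n_cells=64)
        vals = rng.random(64)
        n = TumorDensity(grid, vals)

        def n_of(z):
            idx = np.clip((z // (grid.z_max / 64)).astype(int), 0, 63)
            out = vals[idx]
            out[(z < 0) | (z >= grid.z_max)] = 0.0
            return out

        for model in (DivisionModel(rate_kind="constant", a=0.8),
                      DivisionModel(rate_kind="threshold", a=0.8, z0=1.0)):
            sub = np.linspace(-0.5, 0.5, 201)[:-1] + 0.0025
            oracle = np.empty(64)
            for i, (zc, w) in enumerate(zip(grid.centers, grid.widths)):
                zz = zc + sub * w
                oracle[i] = np.mean(4 * model.rate(2 * zz) * n_of(2 * zz)
                                    - model.rate(zz) * n_of(zz))
            q = division_apply(n, model)
            # piecewise-constant quadrature vs interpolated conservative form
            scale = np.abs(oracle).max()
            assert np.abs(q - oracle).max() <= 0.15 * scale
            # and the integrals agree tightly
            assert np.sum(grid.widths * q) == pytest.approx(
                np.sum(grid.widths * oracle), rel=2e-2)


class TestMoments:
    def test_zero(self, size_grid):
        assert moments(TumorDensity(size_grid, np.zeros(256))) == (0.0, 0.0)

    def test_indicator_closed_form(self, size_grid):
        """The standard initial datum 1_{[0.125, 5]} has mu0 = 4.875 and
        mu1 = (5^2 - 0.125^2)/2."""
        n0 = TumorDensity.indicator(size_grid, 0.125, 5.0)
        mu0, mu1 = moments(n0)
        assert mu0 == pytest.approx(4.875, rel=1e-12)
        # partially covered edge cells carry their mass at the cell center,
        # so the first moment matches the continuum value at O(h^2)
        assert mu1 == pytest.approx((25.0 - 0.125 ** 2) / 2.0, rel=1e-4)

    def test_eigenprofile_unit_mass(self, constant_law, constant_division):
        grid = SizeGrid(z_max=6.0, n_cells=200)
        pair = leading_eigenpair(constant_law, constant_division, grid, tol=1e-7)
        mu0, _ = moments(pair.profile)
        assert mu0 == pytest.approx(1.0, rel=1e-12)
        assert np.all(pair.profile.values >= 0)


class TestTumorStep:
    def test_zero_stays_zero(self, size_grid, constant_law, constant_division):
        n = TumorDensity(size_grid, np.zeros(256))
        out = tumor_step(n, 0.01, 0.0, 0.0, constant_law, constant_division)
        assert np.all(out.values == 0.0)

    def test_cfl_violation_names_admissible_dt(self, size_grid, constant_law,
                                               constant_division):
        n = TumorDensity.indicator(size_grid, 0.125, 5.0)
        dt_adm = admissible_dt(size_grid, 0.0, 0.0, constant_law, constant_division)
        with pytest.raises(ValueError, match="admissible dt"):
            tumor_step(n, 2 * dt_adm, 0.0, 0.0, constant_law, constant_division)

    def test_transport_mass_growth_rate(self, constant_law):
        """With pure transport, d(mu1)/dt = V (1+beta) mu0 to first order."""
        grid = SizeGrid(z_max=20.0, n_cells=400)
        n = TumorDensity.indicator(grid, 1.0, 4.0)
        model = DivisionModel(rate_kind="threshold", a=0.8, z0=100.0)  # a(z)=0 here
        beta = 0.3
        dt = 1e-3
        out = tumor_step(n, dt, beta, 0.0, constant_law, model)
        mu0_0, mu1_0 = moments(n)
        _, mu1_1 = moments(out)
        rate = (mu1_1 - mu1_0) / dt
        assert rate == pytest.approx(0.616 * (1 + beta) * mu0_0, rel=1e-6)

    def test_exponential_cell_number(self, constant_law, constant_division):
        """mu0 grows like exp((a - ell) t) for constant rates."""
        grid = SizeGrid(z_max=60.0, n_cells=600)
        n = TumorDensity.indicator(grid, 0.125, 5.0)
        ell = 0.3
        dt, t_end = 5e-4, 0.5
        steps = round(t_end / dt)
        for _ in range(steps):
            n = tumor_step(n, dt, 0.0, ell, constant_law, constant_division)
        mu0, _ = moments(n)
        assert mu0 == pytest.approx(4.875 * math.exp((0.8 - ell) * t_end), rel=1e-3)

    @given(seed=st.integers(0, 50))
    @settings(max_examples=15, deadline=None, derandomize=True)
    def test_positivity(self, seed):
        rng = np.random.default_rng(seed)
        grid = SizeGrid(z_max=10.0, n_cells=64)
        n = TumorDensity(grid, rng.random(64))
        law = GrowthLaw(kind="gompertz", r=0.616, b=10.0)
        model = DivisionModel(rate_kind="threshold", a=0.8, z0=1.0)
        dt = admissible_dt(grid, 0.0, 0.5, law, model)
        out = tumor_step(n, dt, 0.0, 0.5, law, model)
        assert np.all(out.values >= 0.0)


class TestLeadingEigenpair:
    def test_constant_rates_lambda_equals_a(self, constant_law, constant_division):
        """For constant V and constant binary division the Malthus eigenvalue
        is the division frequency itself."""
        grid = SizeGrid(z_max=6.0, n_cells=480)
        pair = leading_eigenpair(constant_law, constant_division, grid, tol=1e-8)
        assert abs(pair.lam - 0.8) / 0.8 <= 1e-2

    def test_rate_rescaling_doubles_lambda(self, gompertz_law):
        """(a, r) -> (2a, 2r) is a time rescaling: lambda doubles, the
        normalized profile is unchanged."""
        grid = SizeGrid(z_max=10.0, n_cells=300)
        model1 = DivisionModel(rate_kind="threshold", a=0.8, z0=1.0)
        law2 = GrowthLaw(kind="gompertz", r=2 * 0.616, b=10.0)
        model2 = DivisionModel(rate_kind="threshold", a=1.6, z0=1.0)
        p1 = leading_eigenpair(gompertz_law, model1, grid, tol=1e-9)
        p2 = leading_eigenpair(law2, model2, grid, tol=1e-9)
        assert p2.lam == pytest.approx(2 * p1.lam, rel=1e-5)
        assert np.abs(p1.profile.values - p2.profile.values).max() <= 1e-5

    def test_beta_rescaling_of_profile(self, constant_law, constant_division):
        """With constant rates, enhancing growth by (1+beta) keeps lambda and
        rescales the profile to N(z/(1+beta))/(1+beta)."""
        beta = 0.5
        n_cells = 480
        grid1 = SizeGrid(z_max=6.0, n_cells=n_cells)
        law_beta = GrowthLaw(kind="constant", V_const=0.616 * (1 + beta))
        grid2 = SizeGrid(z_max=6.0 * (1 + beta), n_cells=n_cells)
        p1 = leading_eigenpair(constant_law, constant_division, grid1, tol=1e-9)
        p2 = leading_eigenpair(law_beta, constant_division, grid2, tol=1e-9)
        assert p2.lam == pytest.approx(p1.lam, rel=1e-6)
        ref = np.interp(grid2.centers / (1 + beta), grid1.centers,
                        p1.profile.values) / (1 + beta)
        l1 = np.sum(grid2.widths * np.abs(p2.profile.values - ref))
        assert l1 <= 2e-2  # profiles have unit mass; discretization-level gap
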