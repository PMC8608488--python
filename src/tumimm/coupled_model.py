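"""The coupled size/space tumor-immune system and its long-time behavior.

The model couples, through a handful of scalar functionals, four unknowns:

* ``n(t, z)`` -- the size-structured tumor cell density (growth, binary
  division, and a kill term proportional to the immune strength
  ``mubar_c = ∫ delta c dx``);
* ``c(t, x)`` -- antitumor effector cells on the unit disc, recruited at rate
  ``g(mu1) S``, dying at rate ``gamma``, converted into protumor cells at
  rate ``k_r I theta`` and suppressed by protumor cells at rate ``k_c c_r``;
* ``c_r(t, x)`` -- protumor cells, recruited by the cytokine signal ``I``
  from a distant source ``S_r`` and by conversion of effectors; they enhance
  the tumor growth velocity by the factor ``1 + beta`` with
  ``beta = ∫ b1 c_r dx``;
* ``I(t)`` -- a lumped immunosuppressive cytokine, produced above the
  critical tumor mass ``m`` (threshold law ``psi``) and damped at rate ``tau``.

Both immune species drift up the chemotactic potential ``phi``, which solves
a Neumann elliptic problem whose strength follows the Michaelis-Menten
response ``f(mu1) = mu1 / (eta + mu1)``.

Long runs end in one of two regimes: an *equilibrium* where the immune
strength balances the Malthus eigenvalue of the growth-fragmentation
operator and a residual tumor persists, or an *escape* where the tumor mass
grows without bound.  The module also provides a stationary-state predictor
of the equilibrium tumor mass, independent of time stepping.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .size_dynamics import (
    DivisionModel,
    GrowthLaw,
    SizeGrid,
    TumorDensity,
    admissible_dt,
    leading_eigenpair,
    moments,
    tumor_step,
)
from .spatial_fields import (
    DiscGrid,
    GaussianSpec,
    ScalarField,
    TransportCoefficients,
    advection_cfl_dt,
    advection_matrix,
    advance_field,
    gaussian_field,
    integrate_weighted,
    make_disc_grid,
    solve_potential,
)
from . import therapy as _therapy

__all__ = [
    "ModelParams",
    "Numerics",
    "SystemState",
    "SimulationResult",
    "OutcomeLabel",
    "OutcomeCriteria",
    "CoupledSimulation",
    "response_f",
    "activation_g",
    "psi",
    "cytokine_step",
    "coupled_step",
    "run",
    "classify_outcome",
    "equilibrium_mass_predictor",
    "NoEquilibriumError",
]


# --------------------------------------------------------------------------
# parameters

@dataclass(frozen=True)
class ModelParams:
    """Full parameter set of the coupled model.

    The printed simulation values (Gaussian kill/signal amplitudes, division
    and growth rates, chemotactic sensitivity, effector source and death
    rate) are the defaults of the corresponding fields; every remaining rate
    is a documented package default, flagged as such in run manifests.
    """

    growth: GrowthLaw = GrowthLaw(kind="gompertz", r=0.616, b=10.0, V_const=0.616)
    division: DivisionModel = DivisionModel(rate_kind="threshold", a=0.8, z0=1.0)
    transport: TransportCoefficients = TransportCoefficients(chi=0.864, D=0.05, K=1.0)
    delta: GaussianSpec = GaussianSpec(amplitude=1.0, xi2=0.02)       # kill weight
    sigma: GaussianSpec = GaussianSpec(amplitude=0.002, xi2=0.05)     # chemo signal
    theta: GaussianSpec = GaussianSpec(amplitude=1.0, xi2=0.05)       # conversion site
    b1: GaussianSpec = GaussianSpec(amplitude=0.05, xi2=0.02)         # growth boost
    S: float = 5.0               # homogeneous effector source amplitude
    Sr_amplitude: float = 15.0   # per-spot protumor source amplitude
    Sr_xi2: float = 0.02
    Sr_scale: float = 0.2        # global protumor source factor (1/5)
    Sr_radius: float = 0.7
    Sr_angles_deg: tuple[float, ...] = (90.0, 210.0, 330.0)
    gamma: float = 0.18          # effector death rate
    gamma_r: float = 1.0         # protumor death rate
    gamma_a: float = 0.18        # exhausted-cell death rate (defaults to gamma)
    tau: float = 0.2             # cytokine damping rate (slow: delayed protumor response)
    k_c: float = 1.0             # suppression of effectors by protumor cells
    k_r: float = 0.1             # cytokine-driven conversion rate
    m: float = 2.0               # critical tumor mass for cytokine activation
    psi_bar: float = 4.0         # cytokine production slope above threshold
    eta: float = 1.0             # Michaelis-Menten half-saturation mass
    g_mode: str = "linear"       # effector activation law: mu1 or mu1**2
    alpha: float = 0.5           # exhausted fraction of suppressed effectors

    def __post_init__(self):
        for name in ("S", "gamma", "gamma_r", "gamma_a", "tau", "k_c", "k_r",
                     "m", "Sr_amplitude", "Sr_scale"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.tau <= 0 or self.psi_bar <= 0 or self.eta <= 0:
            raise ValueError("tau, psi_bar and eta must be positive")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.g_mode not in ("linear", "quadratic"):
            raise ValueError("g_mode must be 'linear' or 'quadratic'")


@dataclass(frozen=True)
class Numerics:
    """Resolutions, step policy and stopping rules for the coupled runs."""

    n_axis: int = 64
    n_size_cells: int = 256
    z_max: float | None = None          # None: b (Gompertz) or 10 x initial support
    z_truncation_factor: float = 10.0
    dt_max: float = 0.1
    init_lo: float = 0.125              # initial tumor datum: indicator of [lo, hi]
    init_hi: float = 5.0
    init_height: float = 1.0
    I0: float = 0.0
    escape_stop_factor: float = 1e6
    snapshot_times: tuple[float, ...] = ()
    eigen_tol: float = 1e-8

    def size_domain(self, growth: GrowthLaw) -> float:
        if self.z_max is not None:
            return self.z_max
        if growth.kind == "gompertz":
            return growth.b
        return self.z_truncation_factor * self.init_hi


# --------------------------------------------------------------------------
# state and results

@dataclass
class SystemState:
    """The unknowns advanced by the coupled stepper."""

    t: float
    n: TumorDensity
    c: ScalarField
    c_r: ScalarField
    I: float
    phi: ScalarField | None = None
    c_a: ScalarField | None = None      # exhausted cells (therapy runs)
    T_react: float = 0.0
    T_block: float = 0.0


@dataclass
class OutcomeLabel:
    label: str                  # equilibrium | escape | undecided
    evidence: str
    time: float


@dataclass(frozen=True)
class OutcomeCriteria:
    escape_factor: float = 1e3
    rel_tol: float = 1e-5
    window_fraction: float = 0.1
    eps: float = 1e-12


@dataclass
class SimulationResult:
    """Time series and metadata of a coupled run."""

    series: dict[str, np.ndarray]
    outcome: OutcomeLabel | None
    manifest: dict
    snapshots: list = field(default_factory=list)
    final_state: SystemState | None = None

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.series)


# --------------------------------------------------------------------------
# scalar couplings

def response_f(mu1: float, eta: float) -> float:
    """Michaelis-Menten chemotactic response ``mu1 / (eta + mu1)``."""
    if eta <= 0:
        raise ValueError("eta must be positive")
    if mu1 < 0:
        raise ValueError("mu1 must be nonnegative")
    return mu1 / (eta + mu1)


def activation_g(mu1: float, mode: str = "linear") -> float:
    """Effector activation law: ``mu1`` (linear) or ``mu1**2`` (quadratic)."""
    if mu1 < 0:
        raise ValueError("mu1 must be nonnegative")
    if mode == "linear":
        return mu1
    if mode == "quadratic":
        return mu1 * mu1
    raise ValueError(f"unknown activation mode {mode!r}")


def psi(mu1: float, m: float, psi_bar: float) -> float:
    """Threshold cytokine production: ``psi_bar (mu1 - m)`` above the
    critical mass ``m``, zero below (so ``psi(0) = psi'(0) = 0`` when
    ``m > 0``)."""
    if m < 0:
        raise ValueError("m must be nonnegative")
    if psi_bar <= 0:
        raise ValueError("psi_bar must be positive")
    return psi_bar * (mu1 - m) if mu1 > m else 0.0


def cytokine_step(I: float, mu1: float, params: ModelParams, dt: float) -> float:
    """Exact exponential-integrator step of ``dI/dt = psi(mu1) - tau I``
    with the tumor mass frozen over the step."""
    if I < 0:
        raise ValueError("I must be nonnegative")
    p = psi(mu1, params.m, params.psi_bar)
    decay = math.exp(-params.tau * dt)
    return I * decay + (p / params.tau) * (1.0 - decay)


# --------------------------------------------------------------------------
# the coupled stepper

class CoupledSimulation:
    """Precomputed grids, fields and factorizations for one model setup.

    Therapy schedules are optional: when either one is present the exhausted
    cell field ``c_a`` is tracked, the reactivation drug returns exhausted
    cells to the effector pool, and the blockade drug clamps the
    cytokine-driven recruitment of protumor cells by ``max(0, 1 - T_block)``.
    """

    def __init__(self, params: ModelParams, numerics: Numerics = Numerics(),
                 sched_react=None, sched_block=None):
        self.params = params
        self.numerics = numerics
        self.sched_react = sched_react
        self.sched_block = sched_block
        self.therapy_on = sched_react is not None or sched_block is not None
        self.grid = make_disc_grid(numerics.n_axis)
        z_max = numerics.size_domain(params.growth)
        self.size_grid = SizeGrid(z_max=z_max, n_cells=numerics.n_size_cells)
        g = self.grid
        self.delta_f = gaussian_field(params.delta, g)
        self.sigma_f = gaussian_field(params.sigma, g)
        self.theta_f = gaussian_field(params.theta, g)
        self.b1_f = gaussian_field(params.b1, g)
        self.S_f = ScalarField.constant(g, params.S)
        sr = np.zeros(g.n_active)
        for ang in params.Sr_angles_deg:
            ctr = (params.Sr_radius * math.cos(math.radians(ang)),
                   params.Sr_radius * math.sin(math.radians(ang)))
            spot = GaussianSpec(params.Sr_amplitude, params.Sr_xi2, ctr)
            sr += gaussian_field(spot, g).values
        self.Sr_f = ScalarField(g, params.Sr_scale * sr)
        self._outflux_m1 = 0.0
        self._outflux_warned = False

    # -- state construction --------------------------------------------

    def initial_state(self) -> SystemState:
        nm = self.numerics
        n0 = TumorDensity.indicator(self.size_grid, nm.init_lo, nm.init_hi,
                                    nm.init_height)
        state = SystemState(
            t=0.0,
            n=n0,
            c=ScalarField.zeros(self.grid),
            c_r=ScalarField.zeros(self.grid),
            I=nm.I0,
        )
        if self.therapy_on:
            state.c_a = ScalarField.zeros(self.grid)
        return state

    # -- stepping -------------------------------------------------------

    def couplings(self, state: SystemState):
        mu0, mu1 = moments(state.n)
        ell = integrate_weighted(state.c, self.delta_f)
        beta = integrate_weighted(state.c_r, self.b1_f)
        return mu0, mu1, ell, beta

    def admissible_dt(self, state: SystemState, phi: ScalarField,
                      ell: float, beta: float) -> float:
        p, nm = self.params, self.numerics
        dt = min(
            admissible_dt(self.size_grid, beta, ell, p.growth, p.division),
            advection_cfl_dt(phi, p.transport),
            nm.dt_max,
        )
        # snap down to a dyadic ladder so the implicit-diffusion
        # factorizations are reused across steps
        k = max(0, math.ceil(math.log2(nm.dt_max / dt)))
        return nm.dt_max / 2 ** k

    DT_FLOOR_EXPONENT = 24   # dt below dt_max / 2**24 aborts the run loop
    DT_SOFT_EXPONENT = 10    # collapsed-step stop once escape is certain

    def step(self, state: SystemState, dt: float | None = None) -> SystemState:
        """One operator-splitting step; all couplings frozen at step start."""
        p = self.params
        mu0, mu1, ell, beta = self.couplings(state)
        phi = solve_potential(self.sigma_f, p.transport,
                              response_f(mu1, p.eta), self.grid)
        if dt is None:
            dt = self.admissible_dt(state, phi, ell, beta)
        t = state.t

        # drug effects, exact over [t, t+dt]
        T_react, T_block = state.T_react, state.T_block
        if self.sched_react is not None:
            T_react = _therapy.drug_step(T_react, t, dt, self.sched_react)
        if self.sched_block is not None:
            T_block = _therapy.drug_step(T_block, t, dt, self.sched_block)
        clamp = max(0.0, 1.0 - state.T_block) if self.sched_block is not None else 1.0

        c, c_r, I = state.c, state.c_r, state.I
        theta, Sr = self.theta_f.values, self.Sr_f.values

        # effector cells
        gain_c = activation_g(mu1, p.g_mode) * self.S_f.values
        if self.sched_react is not None and state.c_a is not None:
            gain_c = gain_c + state.T_react * state.c_a.values
        loss_c = p.gamma + p.k_r * I * clamp * theta + p.k_c * c_r.values
        c_new = advance_field(c, phi, p.transport, gain_c, loss_c, dt)

        # protumor cells
        gain_cr = I * clamp * (Sr + p.k_r * theta * c.values)
        c_r_new = advance_field(c_r, phi, p.transport, gain_cr,
                                np.full(self.grid.n_active, p.gamma_r), dt)

        # exhausted cells (therapy runs only)
        c_a_new = state.c_a
        if self.therapy_on and state.c_a is not None:
            gain_ca = p.alpha * p.k_c * c.values * c_r.values
            loss_ca = p.gamma_a + (state.T_react if self.sched_react is not None else 0.0)
            c_a_new = advance_field(state.c_a, phi, p.transport, gain_ca,
                                    np.full(self.grid.n_active, loss_ca), dt)

        I_new = cytokine_step(I, mu1, p, dt)
        n_new, outflux = tumor_step(state.n, dt, beta, ell, p.growth, p.division,
                                    return_outflux=True)
        self._outflux_m1 += outflux * self.size_grid.z_max
        if (not self._outflux_warned and mu1 > 0
                and self._outflux_m1 > 1e-6 * mu1):
            warnings.warn(
                "more than 1e-6 of the tumor mass left through z_max; "
                "consider enlarging the size domain"
            )
            self._outflux_warned = True

        return SystemState(t=t + dt, n=n_new, c=c_new, c_r=c_r_new, I=I_new,
                           phi=phi, c_a=c_a_new, T_react=T_react, T_block=T_block)

    # -- full run ---------------------------------------------------------

    def run(self, horizon: float, crit: OutcomeCriteria = OutcomeCriteria()
            ) -> SimulationResult:
        state = self.initial_state()
        cols = ["t", "mu0", "mu1", "mubar_c", "mu_cr", "I", "beta"]
        if self.therapy_on:
            cols += ["T_react", "T_block", "mu_ca"]
        series = {k: [] for k in cols}
        snapshots = []
        snap_left = sorted(self.numerics.snapshot_times)
        mu1_0 = None
        stopped_early = False

        def record(st: SystemState):
            mu0, mu1, ell, beta = self.couplings(st)
            series["t"].append(st.t)
            series["mu0"].append(mu0)
            series["mu1"].append(mu1)
            series["mubar_c"].append(ell)
            series["mu_cr"].append(st.c_r.integral())
            series["I"].append(st.I)
            series["beta"].append(beta)
            if self.therapy_on:
                series["T_react"].append(st.T_react)
                series["T_block"].append(st.T_block)
                series["mu_ca"].append(st.c_a.integral() if st.c_a else 0.0)
            return mu1

        mu1 = record(state)
        mu1_0 = max(mu1, 1e-300)
        dt_floor = self.numerics.dt_max / 2 ** self.DT_FLOOR_EXPONENT
        while state.t < horizon * (1 - 1e-12):
            t_prev = state.t
            state = self.step(state)
            mu1 = record(state)
            dt_taken = state.t - t_prev
            soft_floor = self.numerics.dt_max / 2 ** self.DT_SOFT_EXPONENT
            if dt_taken < dt_floor or (
                    dt_taken < soft_floor and mu1 > crit.escape_factor * mu1_0):
                # the stability bound collapsed (runaway growth enhancement
                # near escape); further integration is pointless
                warnings.warn("stable time step collapsed; stopping early")
                stopped_early = True
                break
            while snap_left and state.t >= snap_left[0]:
                snap_left.pop(0)
                snapshots.append({
                    "t": state.t,
                    "n": state.n.values.copy(),
                    "c": state.c.values.copy(),
                    "c_r": state.c_r.values.copy(),
                })
            if mu1 > self.numerics.escape_stop_factor * mu1_0:
                stopped_early = True
                break
        series = {k: np.asarray(v) for k, v in series.items()}
        result = SimulationResult(
            series=series,
            outcome=None,
            manifest=self._manifest(horizon, stopped_early),
            snapshots=snapshots,
            final_state=state,
        )
        result.outcome = classify_outcome(result, crit)
        return result

    def _manifest(self, horizon: float, stopped_early: bool) -> dict:
        from . import __version__

        return {
            "package": "tumimm",
            "version": __version__,
            "horizon": horizon,
            "stopped_early": bool(stopped_early),
            "n_axis": self.numerics.n_axis,
            "n_size_cells": self.numerics.n_size_cells,
            "z_max": self.size_grid.z_max,
            "therapy": self.therapy_on,
        }


def coupled_step(state: SystemState, params: ModelParams,
                 numerics: Numerics = Numerics(), dt: float | None = None
                 ) -> SystemState:
    """One splitting step of the coupled system (convenience wrapper).

    Repeated stepping should go through :class:`CoupledSimulation`, which
    reuses grids and matrix factorizations.
    """
    return CoupledSimulation(params, numerics).step(state, dt)


def run(params: ModelParams, numerics: Numerics = Numerics(),
        horizon: float = 100.0, crit: OutcomeCriteria = OutcomeCriteria()
        ) -> SimulationResult:
    """Simulate the untreated coupled system up to ``horizon`` (or escape)."""
    return CoupledSimulation(params, numerics).run(horizon, crit)


# --------------------------------------------------------------------------
# outcome classification

def classify_outcome(result: SimulationResult,
                     crit: OutcomeCriteria = OutcomeCriteria()) -> OutcomeLabel:
    """Label a run *escape*, *equilibrium* or *undecided*.

    Escape: the tumor mass exceeds ``escape_factor`` times its initial value
    while still increasing.  Equilibrium: the relative derivative of the
    tumor mass stays below ``rel_tol`` over the trailing window.
    """
    t = result.series["t"]
    mu1 = result.series["mu1"]
    if t.size < 3:
        raise ValueError("series too short to classify")
    mu1_0 = max(mu1[0], crit.eps)
    dmu = np.gradient(mu1, t)
    above = np.nonzero((mu1 > crit.escape_factor * mu1_0) & (dmu > 0))[0]
    if above.size:
        i = above[0]
        return OutcomeLabel(
            "escape",
            f"mu1 exceeded {crit.escape_factor:g} x mu1(0) while increasing",
            float(t[i]),
        )
    t_win = t[-1] - crit.window_fraction * (t[-1] - t[0])
    win = t >= t_win
    if win.sum() < 3:
        win = np.zeros_like(win)
        win[-3:] = True  # trailing window never shorter than 3 samples
    rel = np.abs(dmu[win]) / np.maximum(mu1[win], crit.eps)
    if rel.max() < crit.rel_tol:
        return OutcomeLabel(
            "equilibrium",
            f"max |dmu1/dt|/mu1 = {rel.max():.3e} < {crit.rel_tol:g} over the "
            "trailing window",
            float(t[-1]),
        )
    return OutcomeLabel("undecided", "neither escape nor settled tumor mass",
                        float(t[-1]))


# --------------------------------------------------------------------------
# stationary equilibrium-mass predictor

class NoEquilibriumError(ValueError):
    """The stationary kill-rate map never reaches the Malthus eigenvalue."""


def _stationary_fields(mu1: float, sim: CoupledSimulation,
                       tol: float = 1e-12, max_iter: int = 200):
    """Solve the stationary immune equations at frozen tumor mass ``mu1``.

    Damped fixed-point iteration on the nonlinear couplings (the suppression
    term ``k_c C C_r`` and the conversion source ``k_r theta C``); each inner
    problem is a sparse upwind advection-diffusion-reaction solve.
    """
    p, g = sim.params, sim.grid
    phi = solve_potential(sim.sigma_f, p.transport, response_f(mu1, p.eta), g)
    adv = advection_matrix(phi, p.transport.chi)
    diff = p.transport.D * g.lap_dirichlet
    I = psi(mu1, p.m, p.psi_bar) / p.tau
    theta = sim.theta_f.values
    src_c = activation_g(mu1, p.g_mode) * sim.S_f.values
    C_r = np.zeros(g.n_active)
    C = np.zeros(g.n_active)
    for _ in range(max_iter):
        loss_c = p.gamma + p.k_r * I * theta + p.k_c * C_r
        M_c = (adv + diff + sp.diags(loss_c)).tocsc()
        C_new = spla.spsolve(M_c, src_c)
        M_cr = (adv + diff + p.gamma_r * sp.identity(g.n_active)).tocsc()
        C_r_new = spla.spsolve(M_cr, I * (sim.Sr_f.values + p.k_r * theta * C_new))
        if I == 0.0:
            C, C_r = C_new, C_r_new
            break
        C_half = 0.5 * C + 0.5 * C_new
        C_r_half = 0.5 * C_r + 0.5 * C_r_new
        change = (np.abs(C_half - C).max() + np.abs(C_r_half - C_r).max())
        scale = np.abs(C_half).max() + np.abs(C_r_half).max() + 1e-300
        C, C_r = C_half, C_r_half
        if change < tol * scale:
            break
    return C, C_r, I


def equilibrium_mass_predictor(params: ModelParams,
                               numerics: Numerics = Numerics(),
                               lam: float | None = None,
                               mu1_max: float = 1e4) -> float:
    """Predict the equilibrium tumor mass from the stationary equations.

    At equilibrium the immune kill rate ``∫ delta C dx`` must equal the
    Malthus eigenvalue ``lam`` of the growth-fragmentation operator; the
    stationary immune fields are solved at frozen tumor mass and the smallest
    positive root of ``mu1 -> ∫ delta C_mu1 dx - lam`` is bracketed from 0.
    Requires ``b1 = 0`` (otherwise the eigenvalue is not decoupled from the
    protumor enhancement).
    """
    if params.b1.amplitude != 0.0:
        raise ValueError("the predictor requires a vanishing growth boost (b1 = 0)")
    sim = CoupledSimulation(params, numerics)
    if lam is None:
        lam = leading_eigenpair(params.growth, params.division, sim.size_grid,
                                tol=numerics.eigen_tol).lam

    from scipy.optimize import brentq

    def F(mu1: float) -> float:
        C, _, _ = _stationary_fields(mu1, sim)
        return float(np.sum(sim.delta_f.values * C) * sim.grid.cell_area) - lam

    if lam <= 0:
        return 0.0
    # F(0) = -lam < 0; scan a geometric ladder for the first sign change
    lo, f_lo = 0.0, -lam
    mu1 = 1e-3
    while mu1 <= mu1_max:
        f_hi = F(mu1)
        if f_hi >= 0:
            return float(brentq(F, lo, mu1, xtol=1e-12, rtol=1e-12))
        lo, f_lo = mu1, f_hi
        mu1 *= 2.0
    raise NoEquilibriumError(
        "no admissible equilibrium: the stationary kill rate stays below the "
        f"eigenvalue {lam:g} for all tumor masses up to {mu1_max:g}"
    )
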