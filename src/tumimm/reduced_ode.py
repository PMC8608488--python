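"""Space-homogeneous reduction of the tumor-immune model: a 5-state ODE.

Neglecting space and taking constant growth and division rates collapses the
PDE system to ordinary differential equations for the tumor cell number
``mu0``, the tumor mass ``mu1``, the effector concentration ``c``, the
protumor concentration ``c_r`` and the cytokine level ``I``::

    mu0' = mu0 (a - delta c)
    mu1' = V (1 + b1 c_r) mu0 - delta mu1 c
    c'   = g(mu1) S - gamma c - k_r c I - k_c c c_r
    c_r' = k_r c I - gamma_r c_r
    I'   = psi(mu1) - tau I

Three equilibria organize the dynamics: the healthy state ``H = 0`` (always
linearly unstable -- a nascent tumor grows), the protumor-free state ``NP``
with a residual tumor controlled by effectors (linearly stable whenever
admissible, damped for ``gamma > 4a`` and oscillatory for ``gamma < 4a``),
and a state ``P`` with all three cell populations present.  Which equilibria
are admissible is decided by the competitiveness ratio ``x = a/delta``
against the thresholds ``m S / gamma`` and the root ``X2`` of
``S - Q1 x - Q2 x^2``; beyond both thresholds no equilibrium exists and the
tumor mass blows up.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "OdeParams",
    "OdeState",
    "EquilibriumSet",
    "OdeTrajectory",
    "rhs",
    "equilibria",
    "x2_threshold",
    "regime_table",
    "stability",
    "numerical_jacobian",
    "integrate",
]

BLOWUP_FACTOR = 1e6


@dataclass(frozen=True)
class OdeParams:
    """Scalar rates of the reduced model.

    Defaults follow the printed reduced-model scenario (``V = 0.616``,
    ``delta = 1``, ``S = 1.5``, ``k_r = 1.25``, ``k_c = 0.1``, ``m = 2``)
    completed with the effector death rate ``gamma = 0.18`` and unit
    ``gamma_r``, ``tau``, ``psi_bar`` as package defaults; ``b1`` defaults
    to zero (no protumor growth enhancement).
    """

    a: float = 0.8
    V: float = 0.616
    delta: float = 1.0
    S: float = 1.5
    gamma: float = 0.18
    gamma_r: float = 1.0
    tau: float = 1.0
    k_r: float = 1.25
    k_c: float = 0.1
    b1: float = 0.0
    m: float = 2.0
    psi_bar: float = 1.0
    g_mode: str = "linear"

    def __post_init__(self):
        for name in ("a", "V", "delta", "S", "gamma", "gamma_r", "tau",
                     "k_r", "k_c", "psi_bar"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.b1 < 0 or self.m < 0:
            raise ValueError("b1 and m must be nonnegative")
        if self.g_mode not in ("linear", "quadratic"):
            raise ValueError("g_mode must be 'linear' or 'quadratic'")

    def psi(self, mu1: float) -> float:
        return self.psi_bar * (mu1 - self.m) if mu1 > self.m else 0.0

    def g(self, mu1: float) -> float:
        return mu1 * mu1 if self.g_mode == "quadratic" else mu1


@dataclass(frozen=True)
class OdeState:
    mu0: float = 0.0
    mu1: float = 0.0
    c: float = 0.0
    c_r: float = 0.0
    I: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.mu0, self.mu1, self.c, self.c_r, self.I])

    @classmethod
    def from_array(cls, y) -> "OdeState":
        return cls(*map(float, y))


@dataclass
class EquilibriumSet:
    """Closed-form equilibria with admissibility flags and reasons."""

    H: OdeState
    NP: OdeState
    NP_admissible: bool
    NP_reason: str
    P: OdeState | None
    P_admissible: bool
    P_reason: str
    Q_const: float
    Q1: float
    Q2: float
    X2: float


@dataclass
class OdeTrajectory:
    t: np.ndarray
    y: np.ndarray                 # shape (5, len(t)); rows mu0, mu1, c, c_r, I
    escaped: bool
    params: OdeParams

    def state(self, i: int = -1) -> OdeState:
        return OdeState.from_array(self.y[:, i])


def rhs(state: OdeState | np.ndarray, params: OdeParams) -> np.ndarray:
    """Right-hand side of the reduced system."""
    if isinstance(state, OdeState):
        mu0, mu1, c, c_r, I = state.as_array()
    else:
        mu0, mu1, c, c_r, I = state
    p = params
    return np.array([
        mu0 * (p.a - p.delta * c),
        p.V * (1.0 + p.b1 * c_r) * mu0 - p.delta * mu1 * c,
        p.g(mu1) * p.S - p.gamma * c - p.k_r * c * I - p.k_c * c * c_r,
        p.k_r * c * I - p.gamma_r * c_r,
        p.psi(mu1) - p.tau * I,
    ])


def equilibria(params: OdeParams) -> EquilibriumSet:
    """Closed-form equilibria H, NP and P with admissibility flags.

    NP exists (nonnegative, consistent with a silent cytokine signal) iff
    its tumor mass ``gamma a / (delta S)`` does not exceed the critical mass
    ``m``.  P requires its tumor mass to exceed ``m`` and the positivity
    constraint on the closed-form quotient (both numerator and denominator
    of the same sign).
    """
    p = params
    x = p.a / p.delta
    Q = p.k_r * p.a / (p.delta * p.tau)
    Q1 = p.psi_bar * p.k_r / p.tau
    Q2 = p.psi_bar * p.k_c * p.k_r / (p.gamma_r * p.tau)
    X2 = x2_threshold(params)

    H = OdeState()
    mu1_np = p.gamma * p.a / (p.delta * p.S)
    NP = OdeState(
        mu0=p.gamma * p.a ** 2 / (p.delta * p.V * p.S),
        mu1=mu1_np,
        c=p.a / p.delta,
        c_r=0.0,
        I=0.0,
    )
    np_ok = mu1_np <= p.m
    np_reason = ("mu1_NP <= m" if np_ok
                 else f"mu1_NP = {mu1_np:g} exceeds the critical mass m = {p.m:g}")

    # protumor equilibrium; psi_bar generalizes the printed closed form
    B = 1.0 + p.k_c * p.a / (p.gamma_r * p.delta)
    num = p.gamma * x - p.psi_bar * Q * p.m * B
    den = p.S - p.psi_bar * Q * B
    pos_ok = (num > 0 and den > 0) or (num < 0 and den < 0)
    if den == 0 or not pos_ok:
        P = None
        p_ok = False
        p_reason = "positivity constraint fails (numerator/denominator signs differ)"
    else:
        mu1_p = num / den
        c_p = p.a / p.delta
        I_p = p.psi(mu1_p) / p.tau
        cr_p = Q * p.psi(mu1_p) / p.gamma_r
        mu0_p = p.a * mu1_p / (p.V * (1.0 + p.b1 * cr_p))
        P = OdeState(mu0=mu0_p, mu1=mu1_p, c=c_p, c_r=cr_p, I=I_p)
        p_ok = mu1_p > p.m
        p_reason = ("mu1_P > m" if p_ok
                    else f"mu1_P = {mu1_p:g} does not exceed the critical mass")
    return EquilibriumSet(H=H, NP=NP, NP_admissible=np_ok, NP_reason=np_reason,
                          P=P, P_admissible=p_ok, P_reason=p_reason,
                          Q_const=Q, Q1=Q1, Q2=Q2, X2=X2)


def x2_threshold(params: OdeParams) -> float:
    """Nonnegative root of ``S - Q1 x - Q2 x^2`` (upper competitiveness bound)."""
    p = params
    Q1 = p.psi_bar * p.k_r / p.tau
    Q2 = p.psi_bar * p.k_c * p.k_r / (p.gamma_r * p.tau)
    ratio = Q1 / Q2
    return 0.5 * (-ratio + math.sqrt(ratio * ratio + 4.0 * p.S / Q2))


def regime_table(params: OdeParams) -> dict:
    """Admissibility pattern of the equilibria as a function of ``x = a/delta``.

    Two cases, split by the size of the critical mass ``m`` against
    ``gamma X2 / S``: for a relatively small critical mass NP and P occupy
    disjoint ranges of ``x``; for a large critical mass they coexist on
    ``(X2, m S / gamma)``.  Beyond the last threshold no equilibrium exists.
    """
    p = params
    X2 = x2_threshold(params)
    x_np = p.m * p.S / p.gamma
    if p.m < p.gamma * X2 / p.S:
        intervals = [
            ((0.0, x_np), frozenset({"NP"})),
            ((x_np, X2), frozenset({"P"})),
            ((X2, math.inf), frozenset()),
        ]
        case = "small_critical_mass"
    else:
        intervals = [
            ((0.0, X2), frozenset({"NP"})),
            ((X2, x_np), frozenset({"NP", "P"})),
            ((x_np, math.inf), frozenset()),
        ]
        case = "large_critical_mass"
    return {"case": case, "X2": X2, "x_NP": x_np, "intervals": intervals}


def numerical_jacobian(state: OdeState, params: OdeParams,
                       eps: float = 1e-7) -> np.ndarray:
    """Central finite-difference Jacobian of :func:`rhs`."""
    y0 = state.as_array()
    J = np.empty((5, 5))
    for j in range(5):
        h = eps * max(1.0, abs(y0[j]))
        yp, ym = y0.copy(), y0.copy()
        yp[j] += h
        ym[j] -= h
        J[:, j] = (rhs(yp, params) - rhs(ym, params)) / (2.0 * h)
    return J


def stability(params: OdeParams, which: str) -> dict:
    """Eigenvalues and linear classification at an equilibrium.

    ``H``: eigenvalues ``{a, 0, -gamma, -gamma_r, -tau}`` -- unstable.
    ``NP``: eigenvalues ``{-gamma_r, -tau, -a, (-gamma +/- sqrt(gamma
    (gamma - 4a)))/2}`` -- stable; all real (damped) when ``gamma > 4a``,
    a complex pair (oscillatory) when ``gamma < 4a``.
    ``P``: no closed form; eigenvalues of the finite-difference Jacobian.
    """
    p = params
    if which == "H":
        eig = np.array([p.a, 0.0, -p.gamma, -p.gamma_r, -p.tau],
                       dtype=complex)
        return {"eigenvalues": eig, "classification": "unstable"}
    if which == "NP":
        disc = p.gamma * (p.gamma - 4.0 * p.a)
        root = (math.sqrt(disc) if disc >= 0 else 1j * math.sqrt(-disc))
        eig = np.array([
            -p.gamma_r, -p.tau, -p.a,
            0.5 * (-p.gamma - root), 0.5 * (-p.gamma + root),
        ], dtype=complex)
        kind = "stable, damped" if p.gamma > 4.0 * p.a else "stable, oscillatory"
        return {"eigenvalues": eig, "classification": kind}
    if which == "P":
        eqs = equilibria(params)
        if not eqs.P_admissible or eqs.P is None:
            raise ValueError(f"P is not admissible: {eqs.P_reason}")
        eig = np.linalg.eigvals(numerical_jacobian(eqs.P, params))
        kind = "stable" if np.all(eig.real < 0) else "unstable"
        return {"eigenvalues": eig, "classification": kind}
    raise ValueError("which must be one of 'H', 'NP', 'P'")


def integrate(params: OdeParams, init: OdeState, horizon: float,
              rtol: float = 1e-9, atol: float = 1e-12,
              max_step: float = np.inf) -> OdeTrajectory:
    """Adaptive integration of the reduced system with blow-up detection.

    Integration stops (flagged as escape) once the tumor mass exceeds
    ``1e6 x max(1, mu1(0))``, a finite proxy for unbounded growth.
    """
    y0 = init.as_array()
    if np.any(y0 < 0):
        raise ValueError("initial state must be nonnegative")
    blow = BLOWUP_FACTOR * max(1.0, y0[1])

    def event(t, y):
        return y[1] - blow

    event.terminal = True
    event.direction = 1.0

    sol = solve_ivp(lambda t, y: rhs(y, params), (0.0, horizon), y0,
                    method="LSODA", rtol=rtol, atol=atol, max_step=max_step,
                    events=[event], dense_output=False)
    escaped = bool(sol.t_events[0].size)
    y = np.maximum(sol.y, 0.0)  # clip integrator-level negatives
    return OdeTrajectory(t=sol.t, y=y, escaped=escaped, params=params)
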