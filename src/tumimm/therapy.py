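"""Pulsed immunotherapy protocols and the treatment-extended simulations.

Two treatment modes act on the immune response:

* *reactivation* (checkpoint-inhibitor-like): a drug effect ``T_react``
  returns exhausted effector cells ``c_a`` to the active pool at rate
  ``T_react * c_a`` (and drains ``c_a`` by the same amount);
* *blockade* (cytokine-trap-like): a drug effect ``T_block`` clamps every
  cytokine-driven recruitment of protumor cells by the factor
  ``max(0, 1 - T_block)``.

Each drug effect follows the linear kinetics ``dT/dt = kappa(t) - decay T``
where ``kappa`` is a pulsed administration protocol: nothing before the
start time ``t0``, then a dose plateau of length ``pulse_len`` at the start
of every ``period``.  Exhausted cells are produced as a fraction ``alpha``
of the effectors suppressed by protumor cells and are transported exactly
like the other immune species.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

__all__ = ["DoseSchedule", "dose_rate", "drug_step", "run_with_therapy"]


@dataclass(frozen=True)
class DoseSchedule:
    """Pulsed administration: dose plateaus of length ``pulse_len`` every
    ``period``, starting at ``t0``; the drug effect decays at rate ``decay``."""

    t0: float = 0.0
    pulse_len: float = 1.0
    period: float = 7.0
    dose: float = 0.0
    decay: float = 0.05

    def __post_init__(self):
        if not 0 < self.pulse_len <= self.period:
            raise ValueError("need 0 < pulse_len <= period")
        if self.dose < 0:
            raise ValueError("dose must be nonnegative")
        if self.decay <= 0:
            raise ValueError("decay must be positive")
        if self.t0 < 0:
            raise ValueError("t0 must be nonnegative")


def dose_rate(t: float, sched: DoseSchedule) -> float:
    """Administration rate at time ``t``: ``dose`` inside a pulse, else 0."""
    if t < 0:
        raise ValueError("t must be nonnegative")
    if t < sched.t0:
        return 0.0
    phase = (t - sched.t0) % sched.period
    return sched.dose if phase < sched.pulse_len else 0.0


def _next_edge(t: float, sched: DoseSchedule) -> float:
    """First pulse edge (onset or offset) strictly after ``t``."""
    if t < sched.t0:
        return sched.t0
    phase = (t - sched.t0) % sched.period
    k = math.floor((t - sched.t0) / sched.period)
    base = sched.t0 + k * sched.period
    if phase < sched.pulse_len:
        return base + sched.pulse_len
    return base + sched.period


def drug_step(T: float, t: float, dt: float, sched: DoseSchedule) -> float:
    """Advance ``dT/dt = kappa(t) - decay T`` exactly from ``t`` to ``t+dt``.

    The interval is split at pulse edges so ``kappa`` is constant on every
    sub-interval, where the update is the exact exponential integrator
    ``T <- T e^{-decay h} + (kappa/decay)(1 - e^{-decay h})``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if T < 0:
        raise ValueError("T must be nonnegative")
    t_end = t + dt
    while t < t_end * (1 - 1e-15) :
        t_next = min(_next_edge(t, sched), t_end)
        h = t_next - t
        kappa = dose_rate(0.5 * (t + t_next), sched)
        e = math.exp(-sched.decay * h)
        T = T * e + (kappa / sched.decay) * (1.0 - e)
        t = t_next
    return T


def run_with_therapy(params, sched_react: DoseSchedule | None = None,
                     sched_block: DoseSchedule | None = None,
                     numerics=None, horizon: float = 100.0, crit=None):
    """Simulate the treatment-extended system (reactivation, blockade or both).

    The exhausted-cell field is tracked whenever a schedule is present; with
    zero doses the tumor/immune trajectories coincide with the untreated run
    (the extra field is passive).
    """
    from .coupled_model import CoupledSimulation, Numerics, OutcomeCriteria

    if sched_react is None and sched_block is None:
        raise ValueError("at least one dose schedule must be provided")
    for sched in (sched_react, sched_block):
        if sched is not None and sched.t0 >= horizon:
            warnings.warn(f"schedule starts at t0={sched.t0:g}, after the "
                          f"horizon {horizon:g}; the drug is never given")
    numerics = numerics if numerics is not None else Numerics()
    crit = crit if crit is not None else OutcomeCriteria()
    sim = CoupledSimulation(params, numerics,
                            sched_react=sched_react, sched_block=sched_block)
    return sim.run(horizon, crit)
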