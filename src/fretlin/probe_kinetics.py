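"""Steady states of the FRET-probe activation cycle.

A unimolecular probe P is converted to its active, FRET-competent state P* by a
forward enzyme F (activity ``F_a``, Michaelis constant ``K_MF``) and back by a
reverse enzyme R (activity ``R_a``, Michaelis constant ``K_MR``); total probe
``P_TOT`` is conserved.  This is the classic covalent-modification
(Goldbeter–Koshland) cycle.  The module provides:

* closed-form steady states in the three operating-limit regimes
  (forward enzyme saturated, reverse enzyme saturated, both linear),
* the full Michaelis–Menten steady state (positive root of a quadratic),
* two independent oracles (bisection of the rate balance; ODE time
  integration) used to validate the closed forms, and
* a diagnostic for how far P*(F_a) deviates from an affine law — only the
  forward-saturated regime gives active probe strictly proportional to the
  forward activity.

Activities are Vmax-type maximal rates (concentration / time); this makes the
saturated-forward balance ``F_a = R_a P*/K_MR`` dimensionally consistent.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from enum import Enum
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .errors import (
    ConvergenceError,
    DegenerateGridError,
    DegenerateParameterError,
    InvalidParameterError,
    RegimeInconsistencyError,
)

__all__ = [
    "Regime",
    "ProbeCycleParams",
    "SteadyState",
    "steady_state_limit",
    "steady_state_mm",
    "bisection_steady_state",
    "ode_steady_state_oracle",
    "linearity_deviation",
    "rate_imbalance",
]


class Regime(str, Enum):
    """Operating regime of the two enzymes of the activation cycle."""

    FORWARD_SATURATED = "forward_saturated"  # F saturated, R linear
    REVERSE_SATURATED = "reverse_saturated"  # R saturated, F linear
    BOTH_LINEAR = "both_linear"              # both enzymes first-order
    MICHAELIS = "michaelis"                  # full Michaelis-Menten kinetics


@dataclass(frozen=True)
class ProbeCycleParams:
    """Parameters of the probe activation cycle.

    F_a, R_a : maximal forward / reverse enzyme activities (conc/time), >= 0
    K_MF, K_MR : Michaelis constants (conc), > 0
    P_TOT : total probe concentration (conc), > 0
    """

    F_a: float
    R_a: float
    K_MF: float
    K_MR: float
    P_TOT: float

    def __post_init__(self) -> None:
        if not (self.F_a >= 0 and self.R_a >= 0):
            raise InvalidParameterError("enzyme activities must be non-negative")
        if not (self.K_MF > 0 and self.K_MR > 0):
            raise InvalidParameterError("Michaelis constants must be positive")
        if not self.P_TOT > 0:
            raise InvalidParameterError("total probe concentration must be positive")

    def replace(self, **kw: float) -> "ProbeCycleParams":
        return dataclasses.replace(self, **kw)


@dataclass(frozen=True)
class SteadyState:
    """Steady-state active probe concentration and the regime it was solved in."""

    p_star: float
    regime: Regime


def rate_imbalance(params: ProbeCycleParams, p_star: float) -> float:
    """Net production rate dP*/dt at active-probe level ``p_star`` under full
    Michaelis-Menten kinetics for both enzymes."""
    p = params
    inactive = p.P_TOT - p_star
    forward = p.F_a * inactive / (p.K_MF + inactive)
    reverse = p.R_a * p_star / (p.K_MR + p_star)
    return forward - reverse


def steady_state_limit(params: ProbeCycleParams, regime: Regime | str) -> SteadyState:
    """Closed-form steady state in one of the three operating-limit regimes.

    forward_saturated : F_a = R_a P*/K_MR            =>  P* = F_a K_MR / R_a
    reverse_saturated : (F_a/K_MF)(P_TOT - P*) = R_a =>  P* = P_TOT - R_a K_MF / F_a
    both_linear       : (F_a/K_MF)(P_TOT - P*) = (R_a/K_MR) P*

    Raises :class:`RegimeInconsistencyError` when the closed form leaves
    [0, P_TOT] — the limit assumption cannot hold for those parameters.
    """
    regime = Regime(regime)
    p = params
    if regime is Regime.FORWARD_SATURATED:
        if p.R_a == 0:
            raise DegenerateParameterError(
                "forward_saturated balance needs R_a > 0 (else no steady state)"
            )
        p_star = p.F_a * p.K_MR / p.R_a
    elif regime is Regime.REVERSE_SATURATED:
        if p.F_a == 0:
            raise DegenerateParameterError(
                "reverse_saturated balance needs F_a > 0 (else no steady state)"
            )
        p_star = p.P_TOT - p.R_a * p.K_MF / p.F_a
    elif regime is Regime.BOTH_LINEAR:
        kf = p.F_a / p.K_MF
        kr = p.R_a / p.K_MR
        if kf + kr == 0:
            raise DegenerateParameterError("both enzyme activities are zero")
        p_star = p.P_TOT * kf / (kf + kr)
    else:
        raise InvalidParameterError(f"{regime} is not a limit regime; use steady_state_mm")

    if not (0.0 <= p_star <= p.P_TOT):
        raise RegimeInconsistencyError(
            f"{regime.value} closed form gives P* = {p_star:g}, outside "
            f"[0, {p.P_TOT:g}]; the assumed regime cannot hold"
        )
    return SteadyState(p_star=float(p_star), regime=regime)


def steady_state_mm(params: ProbeCycleParams) -> SteadyState:
    """Full Michaelis-Menten steady state (Goldbeter-Koshland root).

    Solves F_a (P_TOT-P*)/(K_MF+P_TOT-P*) = R_a P*/(K_MR+P*), a quadratic in
    P*, and returns its unique root in [0, P_TOT].
    """
    p = params
    if p.F_a == 0 and p.R_a == 0:
        raise DegenerateParameterError("F_a = R_a = 0: every P* is stationary")
    if p.F_a == 0:
        return SteadyState(0.0, Regime.MICHAELIS)
    if p.R_a == 0:
        return SteadyState(float(p.P_TOT), Regime.MICHAELIS)

    u, r = p.F_a, p.R_a
    # (r-u) P^2 + (u P_TOT - u K_MR - r K_MF - r P_TOT) P + u P_TOT K_MR = 0
    a = r - u
    b = u * p.P_TOT - u * p.K_MR - r * p.K_MF - r * p.P_TOT
    c = u * p.P_TOT * p.K_MR

    scale = max(abs(b), abs(a) * p.P_TOT, c / p.P_TOT)
    if abs(a) * p.P_TOT < 1e-14 * scale:
        roots = [-c / b]
    else:
        disc = b * b - 4 * a * c
        disc = max(disc, 0.0)
        sq = math.sqrt(disc)
        # numerically stable pair
        q = -0.5 * (b + math.copysign(sq, b))
        roots = [q / a, c / q] if q != 0 else [0.0]

    eps = 1e-9 * p.P_TOT
    inside = [x for x in roots if -eps <= x <= p.P_TOT + eps]
    if not inside:
        raise ConvergenceError("no quadratic root in [0, P_TOT]; parameters pathological")
    # uniqueness is analytic; a second in-range root is floating-point noise
    best = min(inside, key=lambda x: abs(rate_imbalance(p, min(max(x, 0.0), p.P_TOT))))
    return SteadyState(float(min(max(best, 0.0), p.P_TOT)), Regime.MICHAELIS)


def bisection_steady_state(params: ProbeCycleParams, xtol: float = 1e-14) -> SteadyState:
    """Independent oracle: bracketed root of the rate balance on [0, P_TOT]."""
    p = params
    if p.F_a == 0 and p.R_a == 0:
        raise DegenerateParameterError("F_a = R_a = 0: every P* is stationary")
    if p.F_a == 0:
        return SteadyState(0.0, Regime.MICHAELIS)
    if p.R_a == 0:
        return SteadyState(float(p.P_TOT), Regime.MICHAELIS)
    root = brentq(lambda x: rate_imbalance(p, x), 0.0, p.P_TOT,
                  xtol=xtol * p.P_TOT, rtol=8.9e-16)
    return SteadyState(float(root), Regime.MICHAELIS)


def ode_steady_state_oracle(
    params: ProbeCycleParams,
    tol: float = 1e-8,
    max_chunks: int = 60,
    return_trajectory: bool = False,
):
    """Independent oracle: integrate dP*/dt from P*(0) = 0 to steady state.

    Integration proceeds in geometrically growing chunks (the relaxation time
    near a zero-order-ultrasensitive steady state can exceed the naive
    P_TOT/rate scale by many orders of magnitude) until
    |dP*/dt| < tol * max(F_a, R_a).  The inactive concentration is
    P_TOT - P* at every step by construction, so probe conservation is exact.

    Returns a :class:`SteadyState`, or ``(state, t, p_star, p_inactive)``
    arrays when ``return_trajectory`` is true.
    """
    p = params
    if p.F_a == 0 and p.R_a == 0:
        raise DegenerateParameterError("F_a = R_a = 0: every P* is stationary")
    rate_scale = max(p.F_a, p.R_a)
    t_chunk = p.P_TOT / rate_scale

    y0 = 0.0
    ts_all = [0.0]
    ys_all = [0.0]
    t0 = 0.0
    for _ in range(max_chunks):
        sol = solve_ivp(
            lambda t, y: [rate_imbalance(p, y[0])],
            (t0, t0 + t_chunk),
            [y0],
            method="LSODA",
            rtol=1e-12,
            atol=1e-14 * p.P_TOT,
            dense_output=False,
        )
        ts_all.extend(sol.t[1:].tolist())
        ys_all.extend(sol.y[0, 1:].tolist())
        t0 = sol.t[-1]
        y0 = float(sol.y[0, -1])
        t_chunk *= 2.0
        if abs(rate_imbalance(p, y0)) < tol * rate_scale:
            state = SteadyState(float(min(max(y0, 0.0), p.P_TOT)), Regime.MICHAELIS)
            if return_trajectory:
                p_star = np.asarray(ys_all)
                return state, np.asarray(ts_all), p_star, p.P_TOT - p_star
            return state
    raise ConvergenceError(
        f"ODE oracle did not converge within {max_chunks} chunks (tol={tol:g})"
    )


def linearity_deviation(
    params: ProbeCycleParams,
    f_a_grid: Sequence[float],
    regime: Regime | str = Regime.MICHAELIS,
    solver: Callable[[ProbeCycleParams], SteadyState] | None = None,
) -> float:
    """Maximum relative deviation of P*(F_a) from its best affine fit.

    Evaluates the steady state over ``f_a_grid`` (holding everything else in
    ``params`` fixed), least-squares fits a line, and returns
    ``max |residual| / (max P* - min P*)``.  Zero iff the map is affine on the
    grid: the hallmark of the forward-saturated regime, where active probe is
    proportional to the forward enzyme activity.
    """
    grid = np.asarray(list(f_a_grid), dtype=float)
    if np.unique(grid).size < 3:
        raise DegenerateGridError("need at least 3 distinct F_a values")

    regime = Regime(regime)
    if solver is None:
        if regime is Regime.MICHAELIS:
            solver = steady_state_mm
        else:
            solver = lambda q: steady_state_limit(q, regime)  # noqa: E731

    p_star = np.array([solver(params.replace(F_a=fa)).p_star for fa in grid])
    span = float(np.ptp(p_star))
    if span == 0.0:
        return 0.0
    coef = np.polyfit(grid, p_star, 1)
    resid = p_star - np.polyval(coef, grid)
    return float(np.max(np.abs(resid)) / span)
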