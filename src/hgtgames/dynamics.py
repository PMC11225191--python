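"""Numerical integration of the exact and coarse-grained dynamics.

``integrate_full`` solves the non-autonomous replicator system with the
time-dependent rates evaluated at the fast time ``tau = omega t``;
``integrate_coarse`` solves the autonomous averaged system in which each
fitness gains its surplus term ``phi_i``.  The two descriptions are compared
through period averages of the fraction and total abundance: the Euclidean
distance of the time-averaged fractions and the relative error of the
time-averaged total abundances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from scipy.integrate import solve_ivp

from .environment import EffectivePayoffs, EnvironmentSpec, effective_payoffs, effective_rates
from .model import FixedRates, fitness, rhs_replicator

__all__ = [
    "Trajectory",
    "ComparisonMetrics",
    "DivergenceError",
    "InvalidWindowError",
    "integrate_full",
    "integrate_coarse",
    "period_average",
    "compare_full_vs_coarse",
    "probe_regime",
]

DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-10
DEFAULT_CEILING = 1e6
SAMPLES_PER_PERIOD = 40


class DivergenceError(RuntimeError):
    """Total abundance exceeded the blow-up ceiling (N/A regime)."""


class InvalidWindowError(ValueError):
    """Averaging window not covered by the trajectory."""


@dataclass(frozen=True)
class Trajectory:
    """Sampled solution (t, p_A(t), N(t)) plus solver metadata.

    Samples violating 0 <= p_A <= 1 or N >= 0 by more than 1e-6 raise at
    construction; smaller violations (solver tolerance) are clipped.
    """

    t: np.ndarray
    p_A: np.ndarray
    N: np.ndarray
    meta: dict = field(default_factory=dict)
    diverged: bool = False

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        p = np.asarray(self.p_A, dtype=float)
        N = np.asarray(self.N, dtype=float)
        if t.ndim != 1 or np.any(np.diff(t) <= 0):
            raise ValueError("sample times must be strictly increasing")
        if np.any(p < -1e-6) or np.any(p > 1.0 + 1e-6) or np.any(N < -1e-6):
            raise ValueError("state left the physical domain beyond solver tolerance")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "p_A", np.clip(p, 0.0, 1.0))
        object.__setattr__(self, "N", np.maximum(N, 0.0))

    @property
    def p_B(self) -> np.ndarray:
        return 1.0 - self.p_A

    def final(self) -> Tuple[float, float]:
        return float(self.p_A[-1]), float(self.N[-1])


@dataclass(frozen=True)
class ComparisonMetrics:
    """Full-vs-coarse agreement over matched averaging windows."""

    frac_distance: float
    abundance_rel_error: float
    window: Tuple[float, float]
    full_mean: Tuple[float, float]
    coarse_mean: Tuple[float, float]
    diverged: bool = False


def _check_init(init: Tuple[float, float]) -> Tuple[float, float]:
    p0, N0 = float(init[0]), float(init[1])
    if not 0.0 <= p0 <= 1.0:
        raise ValueError("initial p_A must lie in [0, 1]")
    if N0 < 0:
        raise ValueError("initial N must be non-negative")
    return p0, N0


def _solve(rhs, init, t_end, t_eval, max_step, rtol, atol, ceiling, meta):
    def blow_up(t, y):
        return y[1] - ceiling

    blow_up.terminal = True
    blow_up.direction = 1.0
    sol = solve_ivp(
        rhs,
        (0.0, t_end),
        list(init),
        method="LSODA",
        t_eval=t_eval,
        max_step=max_step,
        rtol=rtol,
        atol=atol,
        events=blow_up,
    )
    diverged = bool(sol.t_events[0].size)
    if not sol.success and not diverged:
        raise RuntimeError(f"ODE solver failed: {sol.message}")
    if diverged:
        meta = dict(meta, divergence_time=float(sol.t_events[0][0]), ceiling=ceiling)
    if sol.t.size < 2:
        raise DivergenceError(
            f"trajectory blew up immediately (t = {meta.get('divergence_time')})"
        )
    return Trajectory(t=sol.t, p_A=sol.y[0], N=sol.y[1], meta=meta, diverged=diverged)


def integrate_full(
    env: EnvironmentSpec,
    init: Tuple[float, float],
    t_end: float,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    samples_per_period: int = SAMPLES_PER_PERIOD,
    ceiling: float = DEFAULT_CEILING,
) -> Trajectory:
    """Integrate the exact oscillating-environment dynamics.

    The solver max step is capped at a twentieth of the environmental
    period so every oscillation is resolved; output is sampled on a uniform
    grid of ``samples_per_period`` points per period.
    """
    p0, N0 = _check_init(init)
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    base = env.base

    def rhs(t, y):
        p, N = y
        r_A, r_B, g = env.rates_at(t)
        pB = 1.0 - p
        f_A = r_A - base.a_AA * N * p - (base.a_AB - g) * N * pB
        f_B = r_B - (base.a_BA + g) * N * p - base.a_BB * N * pB
        f_mean = p * f_A + pB * f_B
        return [p * (f_A - f_mean), N * f_mean]

    period = env.period
    dt = period / samples_per_period
    t_eval = np.arange(0.0, t_end + 0.5 * dt, dt)
    t_eval = t_eval[t_eval <= t_end]
    meta = {
        "kind": "full",
        "omega": env.omega,
        "period": period,
        "rtol": rtol,
        "atol": atol,
        "t_end": t_end,
        "init": (p0, N0),
    }
    return _solve(rhs, (p0, N0), t_end, t_eval, period / 20.0, rtol, atol, ceiling, meta)


def integrate_coarse(
    base: FixedRates,
    eff: EffectivePayoffs,
    init: Tuple[float, float],
    t_end: float,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    period: Optional[float] = None,
    samples_per_period: int = SAMPLES_PER_PERIOD,
    ceiling: float = DEFAULT_CEILING,
) -> Trajectory:
    """Integrate the autonomous coarse-grained dynamics.

    Fitness of each population is ``f_i + phi_i``; algebraically this is
    the plain replicator flow on the effective rates, which the test suite
    verifies as an invariant.  ``period`` (if given) fixes the sampling
    grid so full and coarse trajectories can be compared point-wise.
    """
    p0, N0 = _check_init(init)
    if t_end <= 0:
        raise ValueError("t_end must be positive")

    def rhs(t, y):
        # solver steps may overshoot the domain by ~tolerance; clamp
        p = min(max(y[0], 0.0), 1.0)
        N = max(y[1], 0.0)
        f = fitness(base, p, N)
        fa = f.f_A + eff.phi_A(p, N)
        fb = f.f_B + eff.phi_B(p, N)
        fm = p * fa + (1.0 - p) * fb
        return [p * (fa - fm), N * fm]

    dt = period / samples_per_period if period else t_end / 4000.0
    t_eval = np.arange(0.0, t_end + 0.5 * dt, dt)
    t_eval = t_eval[t_eval <= t_end]
    meta = {
        "kind": "coarse",
        "xi": eff.xi,
        "kappa": eff.kappa,
        "period": period,
        "rtol": rtol,
        "atol": atol,
        "t_end": t_end,
        "init": (p0, N0),
    }
    max_step = period / 20.0 if period else np.inf
    return _solve(rhs, (p0, N0), t_end, t_eval, max_step, rtol, atol, ceiling, meta)


def period_average(
    traj: Trajectory,
    n_periods: Optional[int] = None,
    period: Optional[float] = None,
) -> Tuple[float, float]:
    """Time average of (p_A, N) over whole periods taken from the end.

    The default window is the last quarter of the trajectory rounded down
    to an integer number of periods, but never fewer than 10 periods.
    """
    period = period or traj.meta.get("period")
    if not period:
        raise InvalidWindowError("no environmental period available for alignment")
    span = traj.t[-1] - traj.t[0]
    if n_periods is None:
        n_periods = max(10, int(math.floor(0.25 * span / period)))
    window = n_periods * period
    if window > span * (1.0 + 1e-9):
        raise InvalidWindowError(
            f"trajectory spans {span:.3g} < requested window {window:.3g}"
        )
    t0 = traj.t[-1] - window
    mask = traj.t >= t0 - 1e-12
    t = traj.t[mask]
    p_bar = float(np.trapezoid(traj.p_A[mask], t) / (t[-1] - t[0]))
    N_bar = float(np.trapezoid(traj.N[mask], t) / (t[-1] - t[0]))
    return p_bar, N_bar


def compare_full_vs_coarse(
    env: EnvironmentSpec,
    init: Tuple[float, float],
    t_end: float,
    n_periods: Optional[int] = None,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> ComparisonMetrics:
    """Euclidean distance of time-averaged fractions and relative error of
    time-averaged abundance between the exact and averaged dynamics."""
    eff = effective_payoffs(env)
    full = integrate_full(env, init, t_end, rtol=rtol, atol=atol)
    coarse = integrate_coarse(
        env.base, eff, init, t_end, rtol=rtol, atol=atol, period=env.period
    )
    if full.diverged or coarse.diverged:
        return ComparisonMetrics(
            frac_distance=float("nan"),
            abundance_rel_error=float("nan"),
            window=(float("nan"), float("nan")),
            full_mean=(float("nan"), float("nan")),
            coarse_mean=(float("nan"), float("nan")),
            diverged=True,
        )
    if n_periods is None:
        span = full.t[-1] - full.t[0]
        n_periods = max(10, int(math.floor(0.25 * span / env.period)))
    pf, Nf = period_average(full, n_periods=n_periods)
    pc, Nc = period_average(coarse, n_periods=n_periods, period=env.period)
    frac_distance = math.sqrt(2.0) * abs(pf - pc)  # p_B differences mirror p_A
    return ComparisonMetrics(
        frac_distance=frac_distance,
        abundance_rel_error=abs(Nf - Nc) / abs(Nf),
        window=(float(full.t[-1] - n_periods * env.period), float(full.t[-1])),
        full_mean=(pf, Nf),
        coarse_mean=(pc, Nc),
    )


def probe_regime(
    base: FixedRates,
    eff: EffectivePayoffs,
    t_end: float = 400.0,
    lattice: int = 5,
    tol: float = 1e-3,
) -> str:
    """Asymptotic regime of the coarse-grained flow probed from a lattice of
    initial conditions: 'coexistence', 'A_wins', 'B_wins' or 'bistable'."""
    outcomes = set()
    for p0 in np.linspace(0.1, 0.9, lattice):
        for N0 in np.linspace(0.5, 2.0 * max(base.r_A, base.r_B) / base.a_AA, lattice):
            traj = integrate_coarse(base, eff, (p0, N0), t_end, ceiling=1e7)
            if traj.diverged:
                outcomes.add("divergent")
                continue
            p_end, _ = traj.final()
            if p_end > 1.0 - tol:
                outcomes.add("A_wins")
            elif p_end < tol:
                outcomes.add("B_wins")
            else:
                outcomes.add("coexistence")
    if outcomes == {"A_wins", "B_wins"}:
        return "bistable"
    if len(outcomes) == 1:
        return outcomes.pop()
    return "mixed:" + ",".join(sorted(outcomes))
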