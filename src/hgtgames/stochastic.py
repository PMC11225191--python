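"""Exact stochastic simulation of the elementary birth/death/transfer events.

The continuous model is the large-system limit of six elementary event
channels acting on integer counts (n_A, n_B):

==================  =========================================  ==========
event               propensity                                 effect
==================  =========================================  ==========
birth of A          r_A n_A                                    n_A += 1
birth of B          r_B n_B                                    n_B += 1
death of A          (a_AA n_A + a_AB n_B) n_A / Omega          n_A -= 1
death of B          (a_BA n_A + a_BB n_B) n_B / Omega          n_B -= 1
HGT  B -> A         gamma_AB n_A n_B / Omega                   (+1, -1)
HGT  A -> B         gamma_BA n_A n_B / Omega                   (-1, +1)
==================  =========================================  ==========

Competition and transfer propensities scale with 1/Omega (system size) so
the concentrations x_i = n_i/Omega obey the deterministic equations in the
large-Omega limit.  Only the *difference* gamma_AB - gamma_BA = gamma enters
the drift; the symmetric baseline gamma_0 adds exchange noise without
changing the mean field.  Transfer events conserve n_A + n_B.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from numba import njit

from .model import FixedRates

__all__ = [
    "EventRateSpec",
    "decompose_gamma",
    "gillespie_run",
    "gillespie_ensemble",
]


def decompose_gamma(gamma: float, gamma0: float = 0.0) -> Tuple[float, float]:
    """Split the net balance into directional rates.

    ``gamma_AB = max(gamma, 0) + gamma0`` (B->A conversions) and
    ``gamma_BA = max(-gamma, 0) + gamma0``; the difference equals ``gamma``
    for every baseline ``gamma0 >= 0``.
    """
    if gamma0 < 0:
        raise ValueError("baseline transfer rate gamma0 must be >= 0")
    return max(gamma, 0.0) + gamma0, max(-gamma, 0.0) + gamma0


@dataclass(frozen=True)
class EventRateSpec:
    """Parameters of the six event channels."""

    r_A: float
    r_B: float
    a_AA: float
    a_AB: float
    a_BA: float
    a_BB: float
    gamma_AB: float
    gamma_BA: float
    Omega: float

    def __post_init__(self) -> None:
        if self.Omega <= 0:
            raise ValueError("system size Omega must be positive")
        if self.gamma_AB < 0 or self.gamma_BA < 0:
            raise ValueError("directional transfer rates must be >= 0")
        if min(self.r_A, self.r_B, self.a_AA, self.a_AB, self.a_BA, self.a_BB) < 0:
            raise ValueError("birth and competition rates must be >= 0")

    @classmethod
    def from_rates(
        cls, rates: FixedRates, Omega: float, gamma0: float = 0.0
    ) -> "EventRateSpec":
        g_AB, g_BA = decompose_gamma(rates.gamma, gamma0)
        return cls(
            r_A=rates.r_A,
            r_B=rates.r_B,
            a_AA=rates.a_AA,
            a_AB=rates.a_AB,
            a_BA=rates.a_BA,
            a_BB=rates.a_BB,
            gamma_AB=g_AB,
            gamma_BA=g_BA,
            Omega=Omega,
        )

    def _params(self) -> np.ndarray:
        return np.array(
            [
                self.r_A,
                self.r_B,
                self.a_AA,
                self.a_AB,
                self.a_BA,
                self.a_BB,
                self.gamma_AB,
                self.gamma_BA,
                self.Omega,
            ],
            dtype=np.float64,
        )


@njit(cache=False)
def _propensities(nA, nB, par, out):  # pragma: no cover - jitted
    rA, rB, aAA, aAB, aBA, aBB, gAB, gBA, Om = (
        par[0], par[1], par[2], par[3], par[4], par[5], par[6], par[7], par[8],
    )
    out[0] = rA * nA
    out[1] = rB * nB
    out[2] = (aAA * nA + aAB * nB) * nA / Om
    out[3] = (aBA * nA + aBB * nB) * nB / Om
    out[4] = gAB * nA * nB / Om
    out[5] = gBA * nA * nB / Om


@njit(cache=False)
def _apply(channel, nA, nB):  # pragma: no cover - jitted
    if channel == 0:
        nA += 1
    elif channel == 1:
        nB += 1
    elif channel == 2:
        nA -= 1
    elif channel == 3:
        nB -= 1
    elif channel == 4:
        nA += 1
        nB -= 1
    else:
        nA -= 1
        nB += 1
    return nA, nB


@njit(cache=False)
def _ssa_checkpoints(par, nA0, nB0, t_grid, seed):  # pragma: no cover - jitted
    np.random.seed(seed)
    nA, nB = nA0, nB0
    t = 0.0
    prop = np.empty(6)
    out = np.empty((t_grid.size, 2), dtype=np.int64)
    gi = 0
    while gi < t_grid.size:
        _propensities(nA, nB, par, prop)
        total = prop.sum()
        if total <= 0.0:
            break  # absorbing state: counts frozen for all later checkpoints
        dt = -np.log(np.random.random()) / total
        t_next = t + dt
        while gi < t_grid.size and t_grid[gi] < t_next:
            out[gi, 0] = nA
            out[gi, 1] = nB
            gi += 1
        t = t_next
        u = np.random.random() * total
        acc = 0.0
        ch = 5
        for i in range(6):
            acc += prop[i]
            if u < acc:
                ch = i
                break
        nA, nB = _apply(ch, nA, nB)
    while gi < t_grid.size:
        out[gi, 0] = nA
        out[gi, 1] = nB
        gi += 1
    return out


@njit(cache=False)
def _ssa_events(par, nA0, nB0, t_end, seed, max_events):  # pragma: no cover - jitted
    np.random.seed(seed)
    nA, nB = nA0, nB0
    t = 0.0
    prop = np.empty(6)
    times = np.empty(max_events + 1)
    As = np.empty(max_events + 1, dtype=np.int64)
    Bs = np.empty(max_events + 1, dtype=np.int64)
    times[0] = 0.0
    As[0] = nA
    Bs[0] = nB
    n = 1
    while t < t_end and n <= max_events:
        _propensities(nA, nB, par, prop)
        total = prop.sum()
        if total <= 0.0:
            break
        t += -np.log(np.random.random()) / total
        if t > t_end:
            break
        u = np.random.random() * total
        acc = 0.0
        ch = 5
        for i in range(6):
            acc += prop[i]
            if u < acc:
                ch = i
                break
        nA, nB = _apply(ch, nA, nB)
        times[n] = t
        As[n] = nA
        Bs[n] = nB
        n += 1
    return times[:n], As[:n], Bs[:n]


def _seed_for(master: int, index: int = 0) -> int:
    # one master seed, per-replicate streams derived deterministically
    ss = np.random.SeedSequence([int(master), int(index)])
    return int(ss.generate_state(1, dtype=np.uint32)[0])


def gillespie_run(
    spec: EventRateSpec,
    init: Tuple[int, int],
    t_end: float,
    seed: int,
    t_grid: Optional[np.ndarray] = None,
    max_events: int = 5_000_000,
):
    """One exact stochastic realisation.

    With ``t_grid`` given, returns an ``(len(t_grid), 2)`` array of counts
    sampled at those times (memory-bounded, suited to ensembles); otherwise
    returns the full event-time trajectory ``(times, n_A, n_B)``.  The state
    (0, 0) is absorbing.  Identical seeds reproduce identical event
    sequences.
    """
    nA0, nB0 = int(init[0]), int(init[1])
    if nA0 < 0 or nB0 < 0:
        raise ValueError("initial counts must be non-negative integers")
    par = spec._params()
    s = _seed_for(seed)
    if t_grid is not None:
        t_grid = np.asarray(t_grid, dtype=float)
        if np.any(np.diff(t_grid) <= 0) or t_grid[0] < 0:
            raise ValueError("t_grid must be non-negative and strictly increasing")
        return _ssa_checkpoints(par, nA0, nB0, t_grid, s)
    times, As, Bs = _ssa_events(par, nA0, nB0, float(t_end), s, max_events)
    if times.size > max_events:
        raise RuntimeError("event budget exhausted before t_end")
    return times, As, Bs


def gillespie_ensemble(
    spec: EventRateSpec,
    init: Tuple[int, int],
    t_grid: np.ndarray,
    n_replicates: int,
    seed: int,
) -> np.ndarray:
    """Ensemble of replicates sampled on a common grid.

    Returns an ``(n_replicates, len(t_grid), 2)`` integer array.  Replicate
    streams are derived deterministically from the master seed.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    par = spec._params()
    nA0, nB0 = int(init[0]), int(init[1])
    out = np.empty((n_replicates, t_grid.size, 2), dtype=np.int64)
    for rep in range(n_replicates):
        out[rep] = _ssa_checkpoints(par, nA0, nB0, t_grid, _seed_for(seed, rep))
    return out
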