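"""Two-population competition model with horizontal gene transfer (HGT).

Two microbial populations A and B differ by a single gene allele and compete
for the same resources.  HGT copies the allele of the donor into the
recipient, converting its type, so the net effect of transfer is captured by
a single *gene transfer balance* rate ``gamma``: positive values mean B
entities are converted to A faster than the reverse.

The model is implemented in two equivalent representations:

* **count space** -- ODEs for the abundances ``(n_A, n_B)``::

      dn_A/dt = n_A (r_A - a_AA n_A - a_AB n_B) + gamma n_A n_B
      dn_B/dt = n_B (r_B - a_BA n_A - a_BB n_B) - gamma n_A n_B

* **replicator space** -- ODEs for the fraction ``p_A = n_A/N`` and the total
  abundance ``N = n_A + n_B``, driven by density-dependent fitnesses that are
  the row expectations of a 2x2 payoff matrix (competition rates scaled by
  ``N``, with ``gamma`` folded into the off-diagonal entries).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np

__all__ = [
    "FixedRates",
    "PopulationState",
    "FitnessVector",
    "ExtinctStateError",
    "rhs_counts",
    "payoff_matrix",
    "fitness",
    "rhs_replicator",
]


class ExtinctStateError(ValueError):
    """Fraction view requested at total abundance N = 0 (both extinct)."""


_RATE_KEYS = ("r_A", "r_B", "a_AA", "a_AB", "a_BA", "a_BB", "gamma")


@dataclass(frozen=True)
class FixedRates:
    """Constant-environment parameter set.

    Parameters
    ----------
    r_A, r_B : float
        Reproduction rates (per unit time); must be positive.
    a_AA, a_AB, a_BA, a_BB : float
        Within- and between-population competition rates (per individual per
        unit time).  Raw ecological rates must be positive (purely
        competitive ecosystem); *effective* rates produced by the
        oscillating-environment substitution may be negative and are
        exempted via ``effective=True``.
    gamma : float
        Gene transfer balance (per individual per unit time); any sign,
        ``gamma = 0`` is balanced transfer.
    effective : bool
        Marks rates carrying the emergent-game substitution
        ``a_AB -> a_AB - xi``, ``a_BA -> a_BA + kappa``.
    """

    r_A: float
    r_B: float
    a_AA: float
    a_AB: float
    a_BA: float
    a_BB: float
    gamma: float = 0.0
    effective: bool = False

    def __post_init__(self) -> None:
        vals = [getattr(self, k) for k in _RATE_KEYS]
        if not all(np.isfinite(vals)):
            raise ValueError("all rates must be finite")
        if self.r_A <= 0 or self.r_B <= 0:
            raise ValueError("reproduction rates must be positive")
        if not self.effective:
            for k in ("a_AA", "a_AB", "a_BA", "a_BB"):
                if getattr(self, k) <= 0:
                    raise ValueError(
                        f"competition rate {k} must be positive "
                        "(purely competitive ecosystem)"
                    )

    @classmethod
    def symmetric(cls, r_A: float, r_B: float, a: float, gamma: float = 0.0) -> "FixedRates":
        """Equal competition rates ``a_ij = a`` for all pairs."""
        return cls(r_A=r_A, r_B=r_B, a_AA=a, a_AB=a, a_BA=a, a_BB=a, gamma=gamma)

    def to_dict(self) -> dict:
        return {k: float(getattr(self, k)) for k in _RATE_KEYS}

    @classmethod
    def from_dict(cls, d: Mapping[str, float], effective: bool = False) -> "FixedRates":
        unknown = set(d) - set(_RATE_KEYS)
        if unknown:
            raise ValueError(f"unknown rate keys: {sorted(unknown)}")
        missing = set(_RATE_KEYS) - set(d) - {"gamma"}
        if missing:
            raise ValueError(f"missing rate keys: {sorted(missing)}")
        return cls(effective=effective, **{k: float(v) for k, v in d.items()})

    def replaced(self, **kwargs) -> "FixedRates":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class PopulationState:
    """Abundances of the two populations; fraction/total view derived."""

    n_A: float
    n_B: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.n_A) and np.isfinite(self.n_B)):
            raise ValueError("abundances must be finite")
        if self.n_A < 0 or self.n_B < 0:
            raise ValueError("abundances must be non-negative")

    @property
    def N(self) -> float:
        return self.n_A + self.n_B

    @property
    def is_extinct(self) -> bool:
        return self.N == 0.0

    @property
    def p_A(self) -> float:
        if self.is_extinct:
            raise ExtinctStateError("fractions undefined at N = 0")
        return self.n_A / self.N

    @property
    def p_B(self) -> float:
        return 1.0 - self.p_A

    @classmethod
    def from_fractions(cls, p_A: float, N: float) -> "PopulationState":
        if not 0.0 <= p_A <= 1.0:
            raise ValueError("p_A must lie in [0, 1]")
        if N < 0:
            raise ValueError("N must be non-negative")
        return cls(n_A=p_A * N, n_B=(1.0 - p_A) * N)


@dataclass(frozen=True)
class FitnessVector:
    """Density-dependent fitnesses and their population mean.

    ``f_mean = p_A f_A + p_B f_B`` exactly, by construction.
    """

    f_A: float
    f_B: float
    f_mean: float


def _as_counts(state) -> tuple:
    if isinstance(state, PopulationState):
        return state.n_A, state.n_B
    n_A, n_B = state
    return np.asarray(n_A, dtype=float), np.asarray(n_B, dtype=float)


def rhs_counts(state, rates: FixedRates):
    """Right-hand side of the count-space ODEs.

    ``state`` is a :class:`PopulationState` or a pair ``(n_A, n_B)`` of
    scalars/arrays.  The HGT term is antisymmetric: ``+gamma n_A n_B`` to A,
    ``-gamma n_A n_B`` to B, so it vanishes whenever either population is
    absent (no spontaneous generation).
    """
    n_A, n_B = _as_counts(state)
    if not (np.all(np.isfinite(n_A)) and np.all(np.isfinite(n_B))):
        raise ValueError("abundances must be finite")
    if np.any(np.asarray(n_A) < 0) or np.any(np.asarray(n_B) < 0):
        raise ValueError("abundances must be non-negative")
    hgt = rates.gamma * n_A * n_B
    dn_A = n_A * (rates.r_A - rates.a_AA * n_A - rates.a_AB * n_B) + hgt
    dn_B = n_B * (rates.r_B - rates.a_BA * n_A - rates.a_BB * n_B) - hgt
    return dn_A, dn_B


def payoff_matrix(rates: FixedRates, N) -> np.ndarray:
    """Density-dependent 2x2 payoff matrix at total abundance ``N``.

    Entry ``[i, j]`` is the payoff of population ``i`` against ``j``
    (rows/columns ordered A, B)::

        [[r_A - a_AA N,            r_A - (a_AB - gamma) N],
         [r_B - (a_BA + gamma) N,  r_B - a_BB N          ]]

    This is the unique payoff matrix whose p-weighted row expectation
    reproduces the count-space equations: the gene-transfer balance enters
    column-wise through the off-diagonal (between-population) entries.
    """
    N = np.asarray(N, dtype=float)
    if np.any(N < 0):
        raise ValueError("N must be non-negative")
    return np.array(
        [
            [rates.r_A - rates.a_AA * N, rates.r_A - (rates.a_AB - rates.gamma) * N],
            [rates.r_B - (rates.a_BA + rates.gamma) * N, rates.r_B - rates.a_BB * N],
        ]
    )


def fitness(rates: FixedRates, p_A, N) -> FitnessVector:
    """Fitness of each population: expected payoff against the current mix."""
    p_A = np.asarray(p_A, dtype=float)
    if np.any(p_A < 0) or np.any(p_A > 1):
        raise ValueError("p_A must lie in [0, 1]")
    M = payoff_matrix(rates, N)
    p_B = 1.0 - p_A
    f_A = p_A * M[0, 0] + p_B * M[0, 1]
    f_B = p_A * M[1, 0] + p_B * M[1, 1]
    f_mean = p_A * f_A + p_B * f_B
    return FitnessVector(f_A=f_A, f_B=f_B, f_mean=f_mean)


def rhs_replicator(p_A, N, rates: FixedRates):
    """Replicator-with-varying-abundance right-hand side.

    ``dp_A/dt = p_A (f_A - f_mean)``, ``dN/dt = N f_mean``.  Equivalent to
    :func:`rhs_counts` under ``p_A = n_A/N``, ``N = n_A + n_B``.
    """
    f = fitness(rates, p_A, N)
    return np.asarray(p_A) * (f.f_A - f.f_mean), np.asarray(N) * f.f_mean
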