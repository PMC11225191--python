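"""Periodic environments and the emergent-game payoffs (xi, kappa).

The environment oscillates on a fast time scale ``tau = omega * t`` with
``omega > 1``: the reproduction rates and the gene-transfer balance are
``r_i(tau) = r_i + r~_i(tau)`` and ``gamma(tau) = gamma + gamma~(tau)``,
where the tildes are zero-mean, 2*pi-periodic oscillatory parts.

Averaging over the fast oscillations yields an autonomous ("coarse-grained")
system identical in form to the fixed-environment replicator dynamics but
with two additional fitness-surplus terms

    phi_A = N (1 - p_A) xi,     phi_B = -N kappa p_A,

whose payoffs are period-averaged overlaps of the competitor's
reproduction-rate primitive with the gene-transfer oscillation:

    xi    = (1/omega) <r^_B gamma~>,   kappa = (1/omega) <r^_A gamma~>,

``r^_i`` denoting the zero-mean antiderivative of ``r~_i`` and ``< >`` the
average over one period.  Equivalently, the between-population competition
rates are shifted: ``a_AB -> a_AB - xi``, ``a_BA -> a_BA + kappa``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Tuple

import numpy as np

from .model import FixedRates

__all__ = [
    "OscillatorySignal",
    "EnvironmentSpec",
    "EffectivePayoffs",
    "primitive",
    "effective_payoffs",
    "effective_rates",
    "closed_form_payoffs",
]

#: grid size used for tabulated-signal quadrature (one period)
DEFAULT_GRID = 4096


@dataclass(frozen=True)
class OscillatorySignal:
    """Zero-mean 2*pi-periodic signal.

    Either a finite harmonic series ``sum_k alpha_k cos(k tau) + beta_k
    sin(k tau)`` with ``k >= 1`` (``harmonics`` is a tuple of
    ``(k, alpha_k, beta_k)``) or a tabulated periodic function sampled on a
    uniform grid over ``[0, 2*pi)`` (mean-centered at construction).
    """

    harmonics: Tuple[Tuple[int, float, float], ...] = ()
    table: Optional[np.ndarray] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.table is not None and self.harmonics:
            raise ValueError("signal is either harmonic or tabulated, not both")
        for k, a, b in self.harmonics:
            if k < 1:
                raise ValueError("harmonic index k must be >= 1 (no mean term)")
            if not (np.isfinite(a) and np.isfinite(b)):
                raise ValueError("harmonic amplitudes must be finite")
        canon = tuple(sorted((int(k), float(a), float(b)) for k, a, b in self.harmonics))
        object.__setattr__(self, "harmonics", canon)
        if self.table is not None:
            tab = np.asarray(self.table, dtype=float)
            if tab.ndim != 1 or tab.size < 8:
                raise ValueError("tabulated signal must be a 1-d array of >= 8 samples")
            if not np.all(np.isfinite(tab)):
                raise ValueError("tabulated signal must be finite")
            object.__setattr__(self, "table", tab - tab.mean())

    # -- constructors -------------------------------------------------
    @classmethod
    def zero(cls) -> "OscillatorySignal":
        return cls()

    @classmethod
    def cosine(cls, amplitude: float, k: int = 1) -> "OscillatorySignal":
        return cls(harmonics=((k, amplitude, 0.0),))

    @classmethod
    def sine(cls, amplitude: float, k: int = 1) -> "OscillatorySignal":
        return cls(harmonics=((k, 0.0, amplitude),))

    @classmethod
    def from_table(cls, values) -> "OscillatorySignal":
        return cls(table=np.asarray(values, dtype=float))

    # -- basic queries ------------------------------------------------
    @property
    def is_tabulated(self) -> bool:
        return self.table is not None

    @property
    def is_zero(self) -> bool:
        if self.is_tabulated:
            return bool(np.allclose(self.table, 0.0))
        return all(a == 0.0 and b == 0.0 for _, a, b in self.harmonics)

    def __call__(self, tau):
        """Evaluate at fast time(s) ``tau``."""
        tau = np.asarray(tau, dtype=float)
        if self.is_tabulated:
            n = self.table.size
            # trigonometric interpolation not needed for evaluation on the
            # native grid; off-grid queries use linear interpolation
            frac = np.mod(tau, 2.0 * np.pi) / (2.0 * np.pi) * n
            i0 = np.floor(frac).astype(int) % n
            i1 = (i0 + 1) % n
            w = frac - np.floor(frac)
            return (1.0 - w) * self.table[i0] + w * self.table[i1]
        out = np.zeros_like(tau, dtype=float)
        for k, a, b in self.harmonics:
            out = out + a * np.cos(k * tau) + b * np.sin(k * tau)
        return out

    def sample(self, n: int = DEFAULT_GRID) -> np.ndarray:
        """Values on the uniform grid ``tau_j = 2*pi*j/n``."""
        if self.is_tabulated and self.table.size == n:
            return self.table.copy()
        return np.asarray(self(np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)))

    # -- algebra ------------------------------------------------------
    def __mul__(self, scalar: float) -> "OscillatorySignal":
        if self.is_tabulated:
            return OscillatorySignal(table=self.table * scalar)
        return OscillatorySignal(
            harmonics=tuple((k, a * scalar, b * scalar) for k, a, b in self.harmonics)
        )

    __rmul__ = __mul__

    def __add__(self, other: "OscillatorySignal") -> "OscillatorySignal":
        if self.is_tabulated or other.is_tabulated:
            n = max(
                self.table.size if self.is_tabulated else DEFAULT_GRID,
                other.table.size if other.is_tabulated else DEFAULT_GRID,
            )
            return OscillatorySignal(table=self.sample(n) + other.sample(n))
        acc: dict = {}
        for k, a, b in self.harmonics + other.harmonics:
            pa, pb = acc.get(k, (0.0, 0.0))
            acc[k] = (pa + a, pb + b)
        return OscillatorySignal(harmonics=tuple((k, a, b) for k, (a, b) in acc.items()))


def primitive(signal: OscillatorySignal) -> OscillatorySignal:
    """Zero-mean antiderivative of a zero-mean periodic signal.

    Harmonics map as ``cos(k tau) -> sin(k tau)/k`` and ``sin(k tau) ->
    -cos(k tau)/k``.  Tabulated signals are integrated spectrally (FFT
    coefficients divided by ``i k``) and mean-centered; differentiating the
    result recovers the trigonometric interpolant of the input.  The
    additive constant is fixed by mean-centering; it is mathematically
    irrelevant downstream because the averaging partner has zero mean.
    """
    if signal.is_tabulated:
        tab = signal.table
        n = tab.size
        c = np.fft.rfft(tab)
        if abs(c[0]) > 1e-9 * max(1.0, np.abs(c).max()):
            raise ValueError("signal must have zero mean for a periodic primitive")
        k = np.arange(c.size)
        c_int = np.zeros_like(c)
        c_int[1:] = c[1:] / (1j * k[1:])
        c_int[0] = 0.0  # zero mean
        if n % 2 == 0:
            c_int[-1] = 0.0  # unpaired Nyquist mode has no periodic primitive
        return OscillatorySignal(table=np.fft.irfft(c_int, n=n))
    return OscillatorySignal(
        harmonics=tuple((k, -b / k, a / k) for k, a, b in signal.harmonics)
    )


def _period_mean_product(x: OscillatorySignal, y: OscillatorySignal, n_grid: int) -> float:
    """Period average <x y>; exact coefficient algebra for harmonic pairs."""
    if not (x.is_tabulated or y.is_tabulated):
        ya = dict((k, (a, b)) for k, a, b in y.harmonics)
        total = 0.0
        for k, a, b in x.harmonics:
            a2, b2 = ya.get(k, (0.0, 0.0))
            total += 0.5 * (a * a2 + b * b2)
        return total
    n = n_grid
    for s in (x, y):
        if s.is_tabulated:
            n = max(n, s.table.size)
    return float(np.mean(x.sample(n) * y.sample(n)))


@dataclass(frozen=True)
class EnvironmentSpec:
    """Base rates plus periodic oscillations of r_A, r_B and gamma."""

    base: FixedRates
    osc_rA: OscillatorySignal = OscillatorySignal.zero()
    osc_rB: OscillatorySignal = OscillatorySignal.zero()
    osc_gamma: OscillatorySignal = OscillatorySignal.zero()
    omega: float = 5.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.omega) or self.omega <= 1.0:
            raise ValueError("omega must exceed 1 (fast environmental variation)")

    @property
    def period(self) -> float:
        """Environmental period in slow time t."""
        return 2.0 * np.pi / self.omega

    def rates_at(self, t):
        """Instantaneous (r_A, r_B, gamma) at slow time t (tau = omega t)."""
        tau = self.omega * np.asarray(t, dtype=float)
        return (
            self.base.r_A + self.osc_rA(tau),
            self.base.r_B + self.osc_rB(tau),
            self.base.gamma + self.osc_gamma(tau),
        )

    @property
    def is_static(self) -> bool:
        return self.osc_rA.is_zero and self.osc_rB.is_zero and self.osc_gamma.is_zero


@dataclass(frozen=True)
class EffectivePayoffs:
    """Emergent-game payoffs; both scale as 1/omega for fixed shapes."""

    xi: float
    kappa: float

    def phi_A(self, p_A, N):
        """Fitness surplus of A in the averaged dynamics."""
        return np.asarray(N) * (1.0 - np.asarray(p_A)) * self.xi

    def phi_B(self, p_A, N):
        return -np.asarray(N) * self.kappa * np.asarray(p_A)

    @classmethod
    def zero(cls) -> "EffectivePayoffs":
        return cls(xi=0.0, kappa=0.0)


def effective_payoffs(
    env: EnvironmentSpec, n_grid: int = DEFAULT_GRID, force_quadrature: bool = False
) -> EffectivePayoffs:
    """Compute (xi, kappa) by period-averaged quadrature.

    ``xi`` overlaps the primitive of B's reproduction oscillation with the
    gene-transfer oscillation; ``kappa`` uses A's.  Harmonic pairs are
    averaged by exact coefficient algebra unless ``force_quadrature`` is
    set, in which case both factors are sampled on ``n_grid`` points and
    the uniform-grid mean (spectrally accurate for periodic data) is used.
    """
    r_hat_B = primitive(env.osc_rB)
    r_hat_A = primitive(env.osc_rA)
    if force_quadrature:
        g = env.osc_gamma.sample(n_grid)
        xi = float(np.mean(r_hat_B.sample(n_grid) * g)) / env.omega
        kappa = float(np.mean(r_hat_A.sample(n_grid) * g)) / env.omega
    else:
        xi = _period_mean_product(r_hat_B, env.osc_gamma, n_grid) / env.omega
        kappa = _period_mean_product(r_hat_A, env.osc_gamma, n_grid) / env.omega
    return EffectivePayoffs(xi=xi, kappa=kappa)


def effective_rates(base: FixedRates, eff: EffectivePayoffs) -> FixedRates:
    """Fold the emergent game into the competition matrix.

    Returns a copy of ``base`` with ``a_AB - xi`` and ``a_BA + kappa``;
    flagged ``effective`` because the shifted rates may legitimately be
    negative (mutualistic regime) and are exempt from the positivity check.
    """
    return replace(
        base,
        a_AB=base.a_AB - eff.xi,
        a_BA=base.a_BA + eff.kappa,
        effective=True,
    )


def closed_form_payoffs(c_r: float, c_g: float, omega: float) -> float:
    """Analytic payoff for the single-harmonic pair ``r~ = c_r cos(tau)``,
    ``gamma~ = c_g sin(tau)``: the primitive is ``c_r sin(tau)`` and
    ``<sin^2> = 1/2``, so the payoff is ``c_r c_g / (2 omega)``.

    Serves as an independent oracle for :func:`effective_payoffs`.
    """
    if omega <= 1.0:
        raise ValueError("omega must exceed 1")
    return c_r * c_g / (2.0 * omega)
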