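"""Named scenario presets.

The shared base parameterisation (r_A = 1.8, r_B = 1, a_ij = 0.1,
gamma = 0) pits a faster against a slower reproducer with balanced HGT, so
in a fixed environment A excludes B at N_f* = r_A/a = 18.  The three
oscillating scenarios share gamma~ = 0.5 sin(tau) and omega = 5 and differ
only in the reproduction-rate oscillation amplitudes (c1, c2) for
r~_A = c1 cos(tau), r~_B = c2 cos(tau), which place them in phase-map
regions I (coexistence without synergy), II (competitive coexistence with
synergy) and III (mutualistic symbiosis).
"""

from __future__ import annotations

from dataclasses import dataclass

from .environment import EnvironmentSpec, OscillatorySignal
from .model import FixedRates

__all__ = ["ScenarioPreset", "get_preset", "list_presets", "PRESETS"]

BASE_RATES = FixedRates.symmetric(r_A=1.8, r_B=1.0, a=0.1, gamma=0.0)
GAMMA_OSC_AMPLITUDE = 0.5
OMEGA = 5.0


@dataclass(frozen=True)
class ScenarioPreset:
    name: str
    env: EnvironmentSpec
    expected_region: str
    note: str

    @property
    def base(self) -> FixedRates:
        return self.env.base


def _oscillating(name: str, c1: float, c2: float, region: str, note: str) -> ScenarioPreset:
    env = EnvironmentSpec(
        base=BASE_RATES,
        osc_rA=OscillatorySignal.cosine(c1),
        osc_rB=OscillatorySignal.cosine(c2),
        osc_gamma=OscillatorySignal.sine(GAMMA_OSC_AMPLITUDE),
        omega=OMEGA,
    )
    return ScenarioPreset(name=name, env=env, expected_region=region, note=note)


PRESETS = {
    "fixed_exclusion": ScenarioPreset(
        name="fixed_exclusion",
        env=EnvironmentSpec(base=BASE_RATES, omega=OMEGA),
        expected_region="IV",
        note="static environment: A excludes B at N = r_A/a = 18",
    ),
    "region_I": _oscillating(
        "region_I",
        c1=-1.6,
        c2=-0.2,
        region="I",
        note="coexistence without synergy, (xi, kappa) = (-0.01, -0.08)",
    ),
    "region_II": _oscillating(
        "region_II",
        c1=-1.6,
        c2=1.6,
        region="II",
        note="competitive coexistence with synergy, (xi, kappa) = (0.08, -0.08)",
    ),
    "region_III": _oscillating(
        "region_III",
        c1=-2.2,
        c2=2.2,
        region="III",
        note="mutualistic symbiosis, (xi, kappa) = (0.11, -0.11)",
    ),
}


def get_preset(name: str) -> ScenarioPreset:
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {', '.join(sorted(PRESETS))}"
        ) from None


def list_presets() -> list:
    return sorted(PRESETS)
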