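"""Force-dependent kinetics of reversible host-guest crosslinks.

A supramolecular hydrogel crosslink is an inclusion complex between a
cyclodextrin host and a small hydrophobic guest (adamantane or cholic
acid).  Each chemistry is summarised by its association rate constant
``k_on`` (M^-1 s^-1), its zero-force dissociation rate constant
``k_off0`` (s^-1), and a Bell barrier distance ``x_dagger`` (nm) that
sets how strongly a pulling force tilts the unbinding barrier:

    k_off(F) = k_off0 * exp(F * x_dagger / (k_B * T))

The two built-in chemistries share a similar equilibrium constant
(K_eq = k_on / k_off0) but their dissociation rates differ by six
orders of magnitude, which is what makes one network "fast" and the
other "slow" at the timescale of cellular force generation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

__all__ = [
    "BOLTZMANN_PN_NM_PER_K",
    "HostGuestPair",
    "CD_ADA",
    "CD_CA",
    "BUILTIN_PAIRS",
    "bell_rate",
    "mean_lifetime",
    "equilibrium_constant",
    "thermal_energy",
]

#: Boltzmann constant in pN·nm/K (1.380649e-23 J/K expressed in pN·nm).
BOLTZMANN_PN_NM_PER_K = 1.380649e-2

#: Default Bell barrier distance in nm, a package assumption (not an
#: experimentally tabulated value): with the tabulated k_off it keeps the
#: fast-pair lifetime near one millisecond over the 10-102 pN range of
#: filopodial forces.
DEFAULT_X_DAGGER_NM = 0.01


@dataclass(frozen=True)
class HostGuestPair:
    """One host-guest crosslink chemistry.

    Parameters
    ----------
    name : str
        Label, e.g. ``"CD-ADA"``.
    k_on : float
        Association rate constant, M^-1 s^-1.
    k_off0 : float
        Dissociation rate constant at zero force, s^-1.
    x_dagger : float
        Bell barrier distance (distance to the unbinding transition
        state along the pulling coordinate), nm.
    temperature : float
        Absolute temperature, K.  Defaults to 310 K (cell culture).
    """

    name: str
    k_on: float
    k_off0: float
    x_dagger: float = DEFAULT_X_DAGGER_NM
    temperature: float = 310.0

    def __post_init__(self) -> None:
        if not (self.k_on > 0 and math.isfinite(self.k_on)):
            raise ValueError(f"k_on must be positive and finite, got {self.k_on}")
        if not (self.k_off0 > 0 and math.isfinite(self.k_off0)):
            raise ValueError(f"k_off0 must be positive and finite, got {self.k_off0}")
        if not (self.x_dagger >= 0 and math.isfinite(self.x_dagger)):
            raise ValueError(f"x_dagger must be >= 0 and finite, got {self.x_dagger}")
        if not (self.temperature > 0 and math.isfinite(self.temperature)):
            raise ValueError(f"temperature must be positive, got {self.temperature}")

    @property
    def kT(self) -> float:
        """Thermal energy k_B*T in pN·nm (~4.28 at 310 K)."""
        return BOLTZMANN_PN_NM_PER_K * self.temperature

    def with_rates(self, k_off0: float, k_on: float) -> "HostGuestPair":
        """Copy of this pair with replaced kinetic constants."""
        return replace(self, k_off0=k_off0, k_on=k_on)


def thermal_energy(temperature: float = 310.0) -> float:
    """k_B*T in pN·nm at the given temperature in kelvin."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return BOLTZMANN_PN_NM_PER_K * temperature


def bell_rate(pair: HostGuestPair, force: float) -> float:
    """Dissociation rate (s^-1) of a bound pair under a pulling force.

    Bell slip-bond law ``k_off0 * exp(F * x‡ / k_B T)``; non-decreasing
    in force, equal to ``k_off0`` at zero force.

    Parameters
    ----------
    pair : HostGuestPair
    force : float
        Tensile force on the bond, pN.  Must be >= 0.
    """
    if force < 0 or not math.isfinite(force):
        raise ValueError(f"force must be finite and >= 0 pN, got {force}")
    return pair.k_off0 * math.exp(force * pair.x_dagger / pair.kT)


def mean_lifetime(pair: HostGuestPair, force: float) -> float:
    """Mean bound lifetime 1/k_off(F) in seconds; non-increasing in force."""
    return 1.0 / bell_rate(pair, force)


def equilibrium_constant(pair: HostGuestPair) -> float:
    """Equilibrium binding constant K_eq = k_on / k_off0 (M^-1)."""
    return pair.k_on / pair.k_off0


#: Fast crosslink: cyclodextrin-adamantane, tabulated as powers of ten.
CD_ADA = HostGuestPair(name="CD-ADA", k_on=1e8, k_off0=1e3)

#: Slow crosslink: cyclodextrin-cholic acid (steroid-body-side binding).
CD_CA = HostGuestPair(name="CD-CA", k_on=1e1, k_off0=1e-3)

BUILTIN_PAIRS: dict[str, HostGuestPair] = {"CD-ADA": CD_ADA, "CD-CA": CD_CA}


def validate_detailed_balance(
    pair: HostGuestPair, measured_keq: float, tolerance_decades: float = 1.0
) -> bool:
    """Check k_on/k_off0 against an independently measured K_eq.

    User-supplied rate constants are accepted if the implied equilibrium
    constant is within ``tolerance_decades`` orders of magnitude of the
    measured one; a mismatch warns rather than raises, because calorimetric
    K_eq and kinetically derived rates come from different experiments.
    """
    if measured_keq <= 0:
        raise ValueError("measured_keq must be positive")
    mismatch = abs(math.log10(equilibrium_constant(pair) / measured_keq))
    if mismatch > tolerance_decades:
        warnings.warn(
            f"pair {pair.name!r}: implied K_eq {equilibrium_constant(pair):.3g} M^-1 "
            f"deviates from the measured {measured_keq:.3g} M^-1 by "
            f"{mismatch:.2f} decades (> {tolerance_decades})",
            stacklevel=2,
        )
        return False
    return True
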