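"""The crosslink "gate" an elongating actin filament has to open.

In a host-guest hydrogel, the addition of one actin monomer at a
filopodial filament tip requires that the handful of multivalent
crosslinks blocking the tip all dissociate and be displaced — a
gate-opening event.  The gate here is a zero-dimensional ensemble of
bonds: ``n_units`` acrylated host complexes, each carrying ``valency``
host-guest pairs, for ``n_units * valency`` bonds in total (default
4 x 2 = 8).  In a mixed hydrogel each bond is independently fast
(CD-ADA-type) with probability ``p_fast``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GateGeometry",
    "MixtureSpec",
    "GateState",
    "MIXTURE_LABELS",
    "bonds_per_gate",
    "mixture_from_weight_ratio",
    "build_gate",
]

#: Canonical hydrogel mixture labels -> fast-bond molar fraction.
MIXTURE_LABELS = {
    "A100": 1.0,
    "A80C20": 0.8,
    "A50C50": 0.5,
    "A20C80": 0.2,
    "C100": 0.0,
}

# Per-bond states used throughout the KMC engine.
BOUND, UNBOUND, ESCAPED = 0, 1, 2


@dataclass(frozen=True)
class DiffusionModel:
    """Force-dependent diffusion D(F) = D0 * (1 + alpha * F) of an
    unbound guest-decorated chain segment being swept out of the gate.

    ``D0`` in nm^2/s, ``alpha`` in pN^-1.  ``D0 = inf`` means
    displacement is instantaneous (unbound bonds escape immediately).
    """

    D0: float = 1e6
    alpha: float = 0.01

    def __call__(self, force: float) -> float:
        return self.D0 * (1.0 + self.alpha * force)


@dataclass(frozen=True)
class GateGeometry:
    """Geometry and local environment of one gate.

    Parameters
    ----------
    n_units : int
        Crosslinking units (acrylated host complexes) per gate.
    valency : int
        Host-guest pairs per unit; total bonds = n_units * valency.
    capture_distance : float
        Separation (nm) beyond which an unbound pair can no longer
        re-form; sets the escape rate 2*D(F)/delta^2.
    local_host_concentration : float
        Effective molar concentration of free hosts driving rebinding
        (pseudo-first-order rate k_on * c_local).  Zero disables
        rebinding.
    diffusion : DiffusionModel
        Force-dependent diffusion of displaced chain segments.
    correlated_units : bool
        If True, fast/slow identity is drawn once per unit rather than
        i.i.d. per bond (sensitivity-analysis mode).
    """

    n_units: int = 4
    valency: int = 2
    capture_distance: float = 1.0
    local_host_concentration: float = 0.01
    diffusion: DiffusionModel = field(default_factory=DiffusionModel)
    correlated_units: bool = False

    def __post_init__(self) -> None:
        if self.n_units < 0:
            raise ValueError("n_units must be >= 0")
        if self.valency < 1:
            raise ValueError("valency must be >= 1")
        if self.capture_distance <= 0:
            raise ValueError("capture_distance must be positive (nm)")
        if self.local_host_concentration < 0:
            raise ValueError("local_host_concentration must be >= 0 (M)")

    @property
    def n_bonds(self) -> int:
        return self.n_units * self.valency

    def escape_rate(self, force: float) -> float:
        """First-passage rate 2*D(F)/delta^2 (s^-1) for an unbound pair
        to be displaced beyond the capture distance."""
        return 2.0 * self.diffusion(force) / self.capture_distance**2


@dataclass(frozen=True)
class MixtureSpec:
    """Molar fraction of fast bonds in a mixed hydrogel."""

    p_fast: float
    label: str | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_fast <= 1.0):
            raise ValueError(f"p_fast must be in [0, 1], got {self.p_fast}")

    @classmethod
    def from_label(cls, label: str) -> "MixtureSpec":
        try:
            return cls(p_fast=MIXTURE_LABELS[label], label=label)
        except KeyError:
            raise ValueError(
                f"unknown mixture label {label!r}; known: {sorted(MIXTURE_LABELS)}"
            ) from None


@dataclass
class GateState:
    """Discrete state of one gate: per-bond identity and kinetic state.

    ``is_fast`` and ``state`` are equal-length integer arrays; states
    are BOUND (0), UNBOUND (1) or ESCAPED (2).  ESCAPED is absorbing.
    """

    is_fast: np.ndarray
    state: np.ndarray
    elapsed: float = 0.0

    @property
    def n_bonds(self) -> int:
        return self.is_fast.size

    @property
    def all_escaped(self) -> bool:
        return bool(np.all(self.state == ESCAPED))


def bonds_per_gate(geometry: GateGeometry) -> int:
    """Total host-guest bonds obstructing one actin-monomer addition."""
    return geometry.n_bonds


def mixture_from_weight_ratio(w_fast: float, w_slow: float) -> MixtureSpec:
    """Mixture spec from a weight ratio of fast:slow guest polymers.

    Both guest polymers share the same backbone at the same degree of
    guest modification, so the molar fraction of fast bonds equals the
    weight fraction of the fast polymer.
    """
    if w_fast < 0 or w_slow < 0:
        raise ValueError("weight percentages must be non-negative")
    if abs(w_fast + w_slow - 100.0) > 1e-9:
        raise ValueError(f"weights must sum to 100, got {w_fast} + {w_slow}")
    label = f"A{w_fast:g}C{w_slow:g}"
    return MixtureSpec(p_fast=w_fast / 100.0, label=label)


def build_gate(
    mixture: MixtureSpec,
    geometry: GateGeometry = GateGeometry(),
    seed: int | np.random.Generator = 0,
) -> GateState:
    """Random gate realization: bonds i.i.d. fast with probability p_fast
    (or per-unit if the geometry requests correlated units), all BOUND."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if geometry.correlated_units:
        unit_fast = rng.random(geometry.n_units) < mixture.p_fast
        is_fast = np.repeat(unit_fast, geometry.valency)
    else:
        is_fast = rng.random(geometry.n_bonds) < mixture.p_fast
    return GateState(
        is_fast=is_fast.astype(np.int8),
        state=np.zeros(geometry.n_bonds, dtype=np.int8),
    )
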