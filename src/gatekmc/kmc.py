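"""Event-driven (Gillespie) simulation of gate-opening first passage.

Each gate bond is a three-state unit:

    BOUND --k_off(F/N_bound)--> UNBOUND
    UNBOUND --k_on * c_local--> BOUND        (rebinding)
    UNBOUND --2 D(F)/delta^2--> ESCAPED      (irreversible displacement)

The applied filament force is shared equally among the currently bound
bonds; all rates are recomputed after every event and waiting times are
exponential (no time discretization).  The gate is open once every bond
has ESCAPED, i.e. the obstructing chain segments have not only unbound
but been swept beyond the re-capture distance.

Because bonds of the same identity (fast/slow) and kinetic state are
statistically exchangeable, the simulation propagates the six state
counts rather than per-bond labels; this is an exact reformulation of
the per-bond chain, verified against the brute-force master-equation
oracle below.
"""

from __future__ import annotations

import math
import random as _pyrandom
from dataclasses import dataclass
from itertools import product as _iproduct

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from statsmodels.stats.proportion import proportion_confint

from .gate import BOUND, ESCAPED, UNBOUND, GateGeometry, GateState, MixtureSpec
from .kinetics import CD_ADA, CD_CA, HostGuestPair, bell_rate

__all__ = [
    "ConfigurationError",
    "FirstPassage",
    "KMCResult",
    "simulate_gate",
    "simulate_ensemble",
    "opening_probability",
    "sweep_mixtures",
    "sweep_koff_fixed_Keq",
    "master_equation_oracle",
]


class ConfigurationError(ValueError):
    """A kinetic parameter produced a non-finite or negative rate."""


@dataclass(frozen=True)
class FirstPassage:
    """Outcome of one gate simulation: opening time (s) or censoring."""

    time: float
    opened: bool


@dataclass
class KMCResult:
    """Ensemble of gate-opening first-passage times.

    ``times[i]`` is the opening time of replicate ``i`` (equal to
    ``t_max`` where ``opened[i]`` is False).  ``opening_probability`` is
    the fraction of replicates that opened within ``t_window``, with a
    95% Wilson score interval.
    """

    times: np.ndarray
    opened: np.ndarray
    force: float
    t_window: float
    t_max: float
    seed: int
    mixture: MixtureSpec | None = None

    @property
    def n_replicates(self) -> int:
        return self.times.size

    @property
    def n_open_in_window(self) -> int:
        return int(np.sum(self.opened & (self.times <= self.t_window)))

    @property
    def opening_probability(self) -> float:
        return self.n_open_in_window / self.n_replicates

    @property
    def ci95(self) -> tuple[float, float]:
        lo, hi = proportion_confint(
            self.n_open_in_window, self.n_replicates, alpha=0.05, method="wilson"
        )
        return float(lo), float(hi)

    @property
    def censored_fraction(self) -> float:
        return 1.0 - float(np.mean(self.opened))

    def mean_opening_time(self) -> float:
        """Mean first-passage time over uncensored replicates only
        (NaN if every replicate was censored)."""
        if not self.opened.any():
            return math.nan
        return float(self.times[self.opened].mean())

    def summary(self) -> str:
        lo, hi = self.ci95
        label = self.mixture.label if self.mixture and self.mixture.label else "-"
        lines = [
            "Gate-opening KMC ensemble",
            f"  mixture            : {label}"
            + (f" (p_fast={self.mixture.p_fast:g})" if self.mixture else ""),
            f"  force              : {self.force:g} pN",
            f"  replicates         : {self.n_replicates}",
            f"  t_window           : {self.t_window:g} s",
            f"  P(open <= window)  : {self.opening_probability:.4g}"
            f"  [95% CI {lo:.4g}, {hi:.4g}]",
            f"  censored fraction  : {self.censored_fraction:.4g} (t_max={self.t_max:g} s)",
            f"  mean opening time  : {self.mean_opening_time():.4g} s (uncensored)",
        ]
        return "\n".join(lines)


def _checked_rate(value: float, name: str, allow_inf: bool = False) -> float:
    if math.isnan(value) or value < 0 or (math.isinf(value) and not allow_inf):
        raise ConfigurationError(f"parameter {name!r} yields invalid rate {value}")
    return value


def _rate_tables(
    fast_pair: HostGuestPair,
    slow_pair: HostGuestPair,
    geometry: GateGeometry,
    force: float,
    n_bonds: int,
):
    """Precompute all transition rates for a given applied force.

    Returns (fast_bound, slow_bound, rebind_fast, rebind_slow, escape,
    instant_escape) where ``fast_bound[nb]`` is the Bell off-rate of a
    fast bond when ``nb`` bonds share the load.  Escape may be inf,
    meaning displacement is treated as instantaneous.
    """
    if force < 0 or not math.isfinite(force):
        raise ConfigurationError(f"parameter 'force' must be finite and >= 0, got {force}")
    fast_bound = [0.0] * (n_bonds + 1)
    slow_bound = [0.0] * (n_bonds + 1)
    for nb in range(1, n_bonds + 1):
        shared = force / nb
        try:
            fast_bound[nb] = _checked_rate(bell_rate(fast_pair, shared), "fast_pair.k_off0/x_dagger")
            slow_bound[nb] = _checked_rate(bell_rate(slow_pair, shared), "slow_pair.k_off0/x_dagger")
        except OverflowError:
            raise ConfigurationError(
                "parameter 'x_dagger' (with this force) overflows the Bell exponential"
            ) from None
    c = geometry.local_host_concentration
    rebind_fast = _checked_rate(fast_pair.k_on * c, "local_host_concentration*k_on")
    rebind_slow = _checked_rate(slow_pair.k_on * c, "local_host_concentration*k_on")
    escape = _checked_rate(geometry.escape_rate(force), "diffusion/capture_distance", allow_inf=True)
    return fast_bound, slow_bound, rebind_fast, rebind_slow, escape, math.isinf(escape)


def _simulate_counts(
    urand,
    bf: int,
    bs: int,
    fast_bound: list,
    slow_bound: list,
    reb_f: float,
    reb_s: float,
    esc: float,
    t_max: float,
    instant: bool,
) -> tuple[float, bool]:
    """One gate realization on the count state (bf, bs, uf, us).

    ``urand`` is a callable returning U(0,1); the loop uses inversion
    sampling for waiting times and a categorical draw for the event.
    """
    uf = us = 0
    t = 0.0
    log = math.log
    while True:
        if bf == 0 and bs == 0 and uf == 0 and us == 0:
            return t, True
        nb = bf + bs
        r_bf = bf * fast_bound[nb] if bf else 0.0
        r_bs = bs * slow_bound[nb] if bs else 0.0
        if instant:
            r_uf = r_us = 0.0
        else:
            r_uf = uf * (reb_f + esc)
            r_us = us * (reb_s + esc)
        total = r_bf + r_bs + r_uf + r_us
        if total <= 0.0:
            # only reachable if rebinding and escape are both zero
            return t_max, False
        t -= log(1.0 - urand()) / total
        if t >= t_max:
            return t_max, False
        x = urand() * total
        if x < r_bf:
            bf -= 1
            if not instant:
                uf += 1
        elif x < r_bf + r_bs:
            bs -= 1
            if not instant:
                us += 1
        elif x < r_bf + r_bs + r_uf:
            uf -= 1
            if urand() * (reb_f + esc) >= esc:
                bf += 1
        else:
            us -= 1
            if urand() * (reb_s + esc) >= esc:
                bs += 1


def _replicate_stream(seed: int, replicate: int):
    """Deterministic, order-independent substream for one replicate."""
    return _pyrandom.Random(f"gatekmc:{seed}:{replicate}").random


def simulate_gate(
    gate: GateState,
    fast_pair: HostGuestPair = CD_ADA,
    slow_pair: HostGuestPair = CD_CA,
    geometry: GateGeometry = GateGeometry(),
    force: float = 10.0,
    t_max: float = 0.01,
    seed: int = 0,
) -> FirstPassage:
    """First-passage time for one gate realization.

    The gate opens when every bond is ESCAPED; replicates that have not
    opened by ``t_max`` are censored (``opened=False``, ``time=t_max``).
    """
    if t_max <= 0:
        raise ValueError("t_max must be positive")
    n = gate.n_bonds
    if n == 0:
        return FirstPassage(time=0.0, opened=True)
    tables = _rate_tables(fast_pair, slow_pair, geometry, force, n)
    live = gate.state != ESCAPED
    bf = int(np.sum(live & (gate.is_fast == 1) & (gate.state == BOUND)))
    bs = int(np.sum(live & (gate.is_fast == 0) & (gate.state == BOUND)))
    if np.any(gate.state == UNBOUND):
        raise ValueError("simulate_gate expects bonds initialized BOUND or ESCAPED")
    t, opened = _simulate_counts(_replicate_stream(seed, 0), bf, bs, *tables[:5], t_max=t_max, instant=tables[5])
    return FirstPassage(time=t, opened=opened)


def simulate_ensemble(
    is_fast,
    fast_pair: HostGuestPair = CD_ADA,
    slow_pair: HostGuestPair = CD_CA,
    geometry: GateGeometry = GateGeometry(),
    force: float = 10.0,
    t_window: float = 0.01,
    n_replicates: int = 10_000,
    seed: int = 0,
    t_max: float | None = None,
) -> KMCResult:
    """Ensemble of replicates of one *fixed* gate composition.

    Unlike :func:`opening_probability`, the fast/slow identities are the
    same in every replicate; this is the ensemble the master-equation
    oracle describes exactly.
    """
    is_fast = np.asarray(is_fast, dtype=int)
    n = is_fast.size
    t_max = t_window if t_max is None else t_max
    if t_max < t_window:
        raise ValueError("t_max must be >= t_window")
    bf0, bs0 = int(is_fast.sum()), int(n - is_fast.sum())
    tables = _rate_tables(fast_pair, slow_pair, geometry, force, n) if n else None
    times = np.empty(n_replicates)
    opened = np.empty(n_replicates, dtype=bool)
    for r in range(n_replicates):
        if n == 0:
            times[r], opened[r] = 0.0, True
            continue
        urand = _replicate_stream(seed, r)
        times[r], opened[r] = _simulate_counts(
            urand, bf0, bs0, *tables[:5], t_max=t_max, instant=tables[5]
        )
    p_fast = bf0 / n if n else 1.0
    return KMCResult(
        times=times,
        opened=opened,
        force=force,
        t_window=t_window,
        t_max=t_max,
        seed=seed,
        mixture=MixtureSpec(p_fast=p_fast, label="fixed-composition"),
    )


def opening_probability(
    mixture: MixtureSpec,
    force: float = 10.0,
    t_window: float = 0.01,
    n_replicates: int = 100_000,
    seed: int = 0,
    fast_pair: HostGuestPair = CD_ADA,
    slow_pair: HostGuestPair = CD_CA,
    geometry: GateGeometry = GateGeometry(),
    t_max: float | None = None,
) -> KMCResult:
    """Probability that a gate opens within ``t_window`` seconds.

    A fresh random gate composition is drawn per replicate; the default
    ensemble (F = 10 pN, 0.01 s window, 10^5 replicates) corresponds to
    the timescale of adding one actin monomer at a filopodial tip.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if t_window <= 0:
        raise ValueError("t_window must be positive")
    t_max = t_window if t_max is None else t_max
    if t_max < t_window:
        raise ValueError("t_max must be >= t_window")
    n = geometry.n_bonds
    tables = _rate_tables(fast_pair, slow_pair, geometry, force, n) if n else None
    comp_rng = np.random.default_rng(seed)
    if geometry.correlated_units:
        unit_fast = comp_rng.random((n_replicates, geometry.n_units)) < mixture.p_fast
        n_fast = np.repeat(unit_fast, geometry.valency, axis=1).sum(axis=1) if n else np.zeros(n_replicates, int)
    else:
        n_fast = (comp_rng.random((n_replicates, n)) < mixture.p_fast).sum(axis=1) if n else np.zeros(n_replicates, int)
    times = np.empty(n_replicates)
    opened = np.empty(n_replicates, dtype=bool)
    for r in range(n_replicates):
        if n == 0:
            times[r], opened[r] = 0.0, True
            continue
        bf = int(n_fast[r])
        urand = _replicate_stream(seed, r)
        times[r], opened[r] = _simulate_counts(
            urand, bf, n - bf, *tables[:5], t_max=t_max, instant=tables[5]
        )
    return KMCResult(
        times=times,
        opened=opened,
        force=force,
        t_window=t_window,
        t_max=t_max,
        seed=seed,
        mixture=mixture,
    )


def sweep_mixtures(
    mixtures: list[MixtureSpec],
    force: float = 10.0,
    t_window: float = 0.01,
    n_replicates: int = 100_000,
    seed: int = 0,
    **kwargs,
) -> pd.DataFrame:
    """Opening probability across hydrogel compositions (tidy table)."""
    rows = []
    for m in mixtures:
        res = opening_probability(
            m, force=force, t_window=t_window, n_replicates=n_replicates, seed=seed, **kwargs
        )
        lo, hi = res.ci95
        rows.append(
            {
                "label": m.label or f"p_fast={m.p_fast:g}",
                "p_fast": m.p_fast,
                "force_pN": force,
                "t_window_s": t_window,
                "n_replicates": n_replicates,
                "opening_probability": res.opening_probability,
                "ci95_low": lo,
                "ci95_high": hi,
                "mean_open_time_s": res.mean_opening_time(),
                "censored_fraction": res.censored_fraction,
            }
        )
    return pd.DataFrame(rows)


def sweep_koff_fixed_Keq(
    k_off_values,
    K_eq: float = 1e5,
    mixture: MixtureSpec = MixtureSpec(p_fast=1.0, label="single-chemistry"),
    force: float = 10.0,
    t_window: float = 0.01,
    n_replicates: int = 10_000,
    seed: int = 0,
    geometry: GateGeometry = GateGeometry(),
    x_dagger: float | None = None,
    t_max: float | None = None,
) -> pd.DataFrame:
    """Vary the dissociation rate at a fixed equilibrium constant.

    For each ``k_off`` the association rate is set by detailed balance,
    ``k_on = K_eq * k_off``, so the crosslink becomes kinetically faster
    without becoming weaker.  Returns one row per grid point with the
    mean gate-opening time (uncensored replicates), censoring fraction
    and in-window opening probability.
    """
    k_off_values = list(k_off_values)
    if not k_off_values:
        raise ValueError("k_off_values must be a non-empty list")
    if any(k <= 0 for k in k_off_values):
        raise ValueError("all k_off values must be positive")
    rows = []
    for k_off in k_off_values:
        kwargs = {} if x_dagger is None else {"x_dagger": x_dagger}
        pair = HostGuestPair(name=f"koff={k_off:g}", k_on=K_eq * k_off, k_off0=k_off, **kwargs)
        this_t_max = (1e3 / k_off if t_max is None else t_max)
        this_t_max = max(this_t_max, t_window)
        res = opening_probability(
            mixture,
            force=force,
            t_window=t_window,
            n_replicates=n_replicates,
            seed=seed,
            fast_pair=pair,
            slow_pair=pair,
            geometry=geometry,
            t_max=this_t_max,
        )
        lo, hi = res.ci95
        rows.append(
            {
                "k_off_per_s": k_off,
                "k_on_per_M_s": K_eq * k_off,
                "K_eq_per_M": K_eq,
                "force_pN": force,
                "mean_open_time_s": res.mean_opening_time(),
                "censored_fraction": res.censored_fraction,
                "opening_probability": res.opening_probability,
                "ci95_low": lo,
                "ci95_high": hi,
                "n_replicates": n_replicates,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Brute-force verification oracle
# ---------------------------------------------------------------------------

_MAX_ORACLE_BONDS = 4


def master_equation_oracle(
    is_fast,
    fast_pair: HostGuestPair = CD_ADA,
    slow_pair: HostGuestPair = CD_CA,
    geometry: GateGeometry = GateGeometry(),
    force: float = 10.0,
    t_grid=None,
) -> np.ndarray:
    """Exact opening-probability curve P(open by t) for a small gate.

    Numerically integrates the full continuous-time Markov chain over
    every per-bond state combination (3^N states, N <= 4) with exactly
    the same transition rates as the stochastic simulator.  Used as an
    independent check of the SSA; refuses gates it cannot enumerate.

    Parameters
    ----------
    is_fast : sequence of {0, 1}
        Fixed per-bond identities of the gate.
    t_grid : array-like of float
        Times (s) at which to evaluate P.
    """
    is_fast = np.asarray(is_fast, dtype=int)
    n = is_fast.size
    if n > _MAX_ORACLE_BONDS:
        raise ValueError(f"oracle limited to {_MAX_ORACLE_BONDS} bonds (3^N state space); got {n}")
    t_grid = np.asarray([0.01] if t_grid is None else t_grid, dtype=float)
    if np.any(t_grid < 0):
        raise ValueError("t_grid must be non-negative")
    if n == 0:
        return np.ones_like(t_grid)

    fast_bound, slow_bound, reb_f, reb_s, esc, instant = _rate_tables(
        fast_pair, slow_pair, geometry, force, n
    )
    per_bond_states = (BOUND, ESCAPED) if instant else (BOUND, UNBOUND, ESCAPED)
    states = list(_iproduct(per_bond_states, repeat=n))
    index = {s: i for i, s in enumerate(states)}
    m = len(states)
    Q = np.zeros((m, m))
    for s, i in index.items():
        nb = sum(1 for x in s if x == BOUND)
        for b in range(n):
            bound_rate = fast_bound[nb] if is_fast[b] else slow_bound[nb]
            reb = reb_f if is_fast[b] else reb_s
            if s[b] == BOUND:
                target = ESCAPED if instant else UNBOUND
                j = index[s[:b] + (target,) + s[b + 1 :]]
                Q[i, j] += bound_rate
            elif s[b] == UNBOUND:
                j = index[s[:b] + (ESCAPED,) + s[b + 1 :]]
                Q[i, j] += esc
                j = index[s[:b] + (BOUND,) + s[b + 1 :]]
                Q[i, j] += reb
        Q[i, i] = -Q[i].sum() + Q[i, i]

    p0 = np.zeros(m)
    p0[index[tuple([BOUND] * n)]] = 1.0
    open_idx = index[tuple([ESCAPED] * n)]

    t_end = float(t_grid.max())
    if t_end == 0.0:
        return np.zeros_like(t_grid)
    sol = solve_ivp(
        lambda t, p: Q.T @ p,
        (0.0, t_end),
        p0,
        t_eval=np.unique(np.concatenate([[0.0], t_grid])),
        method="Radau",
        rtol=1e-8,
        atol=1e-12,
    )
    if not sol.success:
        raise RuntimeError(f"master-equation integration failed: {sol.message}")
    lookup = dict(zip(sol.t, sol.y[open_idx]))
    return np.array([lookup[t] if t in lookup else np.interp(t, sol.t, sol.y[open_idx]) for t in t_grid])
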