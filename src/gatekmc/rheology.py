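"""Transient-network bridge from crosslink kinetics to bulk viscoelasticity.

Every reversible crosslink species contributes one Maxwell mode whose
relaxation time is the bond lifetime 1/k_off, so a two-chemistry gel
relaxes as

    G(t) = G_p + sum_i G_i exp(-t / tau_i),      tau_i = 1 / k_off,i

with mode weights proportional to the molar fractions of the two
crosslink types and an optional permanent plateau G_p.  This is a
deliberately minimal model: it reproduces the kinetics-driven trends
(mixtures with more fast crosslinks relax faster; a slow-bond gel looks
frequency-independent at 0.1 Hz) and makes no claim to quantitative
agreement with any particular rheometer trace.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .gate import MixtureSpec
from .kinetics import CD_ADA, CD_CA, HostGuestPair

__all__ = [
    "RelaxationSpectrum",
    "SpectrumFit",
    "spectrum_from_mixture",
    "relaxation_modulus",
    "dynamic_moduli",
    "half_relaxation_time",
    "fit_spectrum",
]


@dataclass(frozen=True)
class RelaxationSpectrum:
    """Discrete Maxwell spectrum: (G_i [Pa], tau_i [s]) plus plateau."""

    modes: tuple[tuple[float, float], ...]
    plateau: float = 0.0

    def __post_init__(self) -> None:
        for g, tau in self.modes:
            if g < 0:
                raise ValueError(f"mode weight must be >= 0 Pa, got {g}")
            if tau <= 0:
                raise ValueError(f"relaxation time must be > 0 s, got {tau}")
        if self.plateau < 0:
            raise ValueError("plateau modulus must be >= 0 Pa")

    @property
    def total_modulus(self) -> float:
        """Instantaneous modulus G(0) = sum G_i + plateau."""
        return sum(g for g, _ in self.modes) + self.plateau

    def sorted_modes(self) -> tuple[tuple[float, float], ...]:
        return tuple(sorted(self.modes, key=lambda m: m[1]))


def spectrum_from_mixture(
    mixture: MixtureSpec,
    total_modulus: float = 1000.0,
    fast_pair: HostGuestPair = CD_ADA,
    slow_pair: HostGuestPair = CD_CA,
    plateau: float = 0.0,
) -> RelaxationSpectrum:
    """Two-mode spectrum of a fast/slow crosslink mixture.

    Mode weights split the (non-plateau) modulus by molar fraction;
    mode times are the zero-force bond lifetimes 1/k_off of each pair.
    Zero-weight modes are dropped, so a pure gel has a single mode.
    """
    if total_modulus <= 0:
        raise ValueError("total_modulus must be positive (Pa)")
    g_relax = total_modulus - plateau
    if g_relax < 0:
        raise ValueError("plateau cannot exceed the total modulus")
    modes = []
    if mixture.p_fast > 0:
        modes.append((mixture.p_fast * g_relax, 1.0 / fast_pair.k_off0))
    if mixture.p_fast < 1:
        modes.append(((1.0 - mixture.p_fast) * g_relax, 1.0 / slow_pair.k_off0))
    return RelaxationSpectrum(modes=tuple(modes), plateau=plateau)


def relaxation_modulus(spectrum: RelaxationSpectrum, t) -> np.ndarray | float:
    """Stress-relaxation modulus G(t) in Pa; t in seconds (scalar or array)."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be >= 0 s")
    g = np.full_like(t_arr, spectrum.plateau, dtype=float)
    for gi, tau in spectrum.modes:
        g = g + gi * np.exp(-t_arr / tau)
    return float(g) if np.isscalar(t) or t_arr.ndim == 0 else g


def dynamic_moduli(spectrum: RelaxationSpectrum, omega) -> tuple:
    """Storage and loss moduli (G', G'') at angular frequency omega (rad/s)."""
    w = np.asarray(omega, dtype=float)
    if np.any(w <= 0):
        raise ValueError("omega must be > 0 rad/s")
    gp = np.full_like(w, spectrum.plateau, dtype=float)
    gpp = np.zeros_like(w, dtype=float)
    for gi, tau in spectrum.modes:
        wt2 = (w * tau) ** 2
        gp = gp + gi * wt2 / (1.0 + wt2)
        gpp = gpp + gi * (w * tau) / (1.0 + wt2)
    if np.isscalar(omega) or w.ndim == 0:
        return float(gp), float(gpp)
    return gp, gpp


def half_relaxation_time(
    t, g, monotone_tol: float = 0.1, smooth_window: int = 1
) -> tuple[float, bool]:
    """Time at which a sampled relaxation curve falls to half of G(0).

    Returns ``(t_half, censored)``; ``censored`` is True when the curve
    never reaches G(0)/2 within the sampled range (e.g. a permanent
    plateau above the half level).

    For noisy curves set ``smooth_window`` to an odd number of samples:
    the crossing is then located on a moving-average of the curve, with
    G(0) estimated from the initial plateau (the larger of the window
    and the first tenth of the samples) rather than the single first
    sample.  The (smoothed) curve must be non-increasing up to noise;
    upward excursions larger than ``monotone_tol * G(0)`` raise a
    validation error.  The crossing itself is linearly interpolated
    between the bracketing samples.
    """
    t = np.asarray(t, dtype=float)
    g = np.asarray(g, dtype=float)
    if t.ndim != 1 or t.shape != g.shape or t.size < 2:
        raise ValueError("t and g must be equal-length 1D arrays with >= 2 samples")
    if np.any(np.diff(t) <= 0):
        raise ValueError("time samples must be strictly increasing")
    if smooth_window < 1 or smooth_window % 2 == 0:
        raise ValueError("smooth_window must be a positive odd integer")
    if smooth_window > 1:
        w = smooth_window
        kernel = np.ones(w) / w
        g_s = np.convolve(np.pad(g, w // 2, mode="edge"), kernel, mode="valid")
        g0 = float(g[: max(w, g.size // 10)].mean())
    else:
        g_s = g
        g0 = float(g[0])
    if g0 <= 0:
        raise ValueError("G(0) must be positive")
    rises = np.diff(g_s)
    if np.any(rises > monotone_tol * g0):
        raise ValueError(
            "relaxation curve is not monotone non-increasing within tolerance "
            f"(max rise {rises.max():.3g} Pa vs allowed {monotone_tol * g0:.3g} Pa)"
        )
    half = 0.5 * g0
    below = np.nonzero(g_s <= half)[0]
    if below.size == 0:
        return math.nan, True
    i = below[0]
    if i == 0:
        return float(t[0]), False
    # linear interpolation on the bracketing segment
    t_half = t[i - 1] + (half - g_s[i - 1]) * (t[i] - t[i - 1]) / (g_s[i] - g_s[i - 1])
    return float(t_half), False


@dataclass
class SpectrumFit:
    """Least-squares spectrum recovered from a sampled relaxation curve."""

    spectrum: RelaxationSpectrum
    residual_norm: float
    converged: bool
    message: str = ""

    def summary(self) -> str:
        lines = ["Relaxation-spectrum fit", f"  converged : {self.converged}"]
        for k, (g, tau) in enumerate(self.spectrum.sorted_modes()):
            lines.append(f"  mode {k}    : G = {g:.4g} Pa, tau = {tau:.4g} s")
        lines.append(f"  residual  : {self.residual_norm:.4g} Pa (L2)")
        return "\n".join(lines)


def fit_spectrum(t, g, n_modes: int = 2, plateau: bool = False) -> SpectrumFit:
    """Fit a discrete Maxwell spectrum to a (noisy) sampled G(t).

    Weights and times are optimized in log space to keep them positive
    and to cope with relaxation times spanning many decades; mode times
    are initialized at log-spaced quantiles of the sampled time range.
    Non-convergence is reported on the result, never silently ignored.
    """
    t = np.asarray(t, dtype=float)
    g = np.asarray(g, dtype=float)
    if n_modes < 1:
        raise ValueError("n_modes must be >= 1")
    if t.size < 4 * n_modes:
        raise ValueError(f"need at least {4 * n_modes} samples to fit {n_modes} modes")
    pos = t > 0
    if pos.sum() < 2:
        raise ValueError("need at least two positive time samples")
    log_tmin, log_tmax = np.log(t[pos].min()), np.log(t[pos].max())
    g0 = max(g.max(), 1e-30)
    tau0 = np.exp(np.linspace(log_tmin, log_tmax, n_modes + 2)[1:-1])
    x0 = np.concatenate([np.full(n_modes, np.log(g0 / n_modes)), np.log(tau0)])
    if plateau:
        x0 = np.concatenate([x0, [np.log(g0 * 1e-3)]])

    def unpack(x):
        weights = np.exp(x[:n_modes])
        taus = np.exp(x[n_modes : 2 * n_modes])
        plat = np.exp(x[2 * n_modes]) if plateau else 0.0
        return weights, taus, plat

    def resid(x):
        weights, taus, plat = unpack(x)
        model = plat + (weights[None, :] * np.exp(-t[:, None] / taus[None, :])).sum(axis=1)
        return model - g

    sol = least_squares(resid, x0, method="lm", max_nfev=20000)
    weights, taus, plat = unpack(sol.x)
    spec = RelaxationSpectrum(
        modes=tuple(sorted(zip(weights, taus), key=lambda m: m[1])), plateau=plat
    )
    return SpectrumFit(
        spectrum=spec,
        residual_norm=float(np.linalg.norm(sol.fun)),
        converged=bool(sol.success),
        message=str(sol.message),
    )
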