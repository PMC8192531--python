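"""Synthetic fixtures with known ground truth.

Every generator is a pure function of its spec and seed and returns the
answer key alongside the fixture: rasterized shape phantoms with exact
analytic area/perimeter/circularity, two-channel cell images with a
known nuclear/cytoplasmic intensity ratio, and sampled stress-relaxation
curves with the generating Maxwell spectrum attached.  These phantoms
stand in for confocal segmentations and rheometer traces in tests; they
are deliberately simple (piecewise-constant intensities, additive
truncated-Gaussian noise) and make no attempt at photorealism.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage import draw

from .morphometrics import LabeledMask
from .rheology import RelaxationSpectrum, relaxation_modulus

__all__ = [
    "PhantomSpec",
    "MaskPhantom",
    "TwoChannelPhantom",
    "RelaxationCurve",
    "gen_masks",
    "gen_two_channel_image",
    "gen_relaxation_curve",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic phantom.

    ``shape`` is one of ``disk``, ``ellipse``, ``star`` or ``cluster``
    (a round cell cluster containing ``n_nuclei`` nuclei).  Intensities
    are arbitrary fluorescence units; ``noise_sd`` is the SD of the
    additive Gaussian noise (truncated at zero); ``poisson`` replaces it
    with shot noise.
    """

    shape: str = "disk"
    size: int = 256
    radius: float = 60.0
    aspect: float = 1.0  # ellipse: minor semi-axis = radius / aspect
    n_arms: int = 4
    inner_fraction: float = 0.35  # star: inner vertex radius / outer
    n_nuclei: int = 3
    nucleus_radius: float = 12.0
    nucleus_mean: float = 200.0
    cytoplasm_mean: float = 100.0
    noise_sd: float = 0.0
    poisson: bool = False
    n_cells: int = 1
    pixel_size: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.shape not in ("disk", "ellipse", "star", "cluster"):
            raise ValueError(f"unknown shape family {self.shape!r}")
        if self.radius <= 0 or self.nucleus_radius <= 0:
            raise ValueError("radii must be positive")
        if self.aspect < 1:
            raise ValueError("aspect must be >= 1")
        if self.n_arms < 3:
            raise ValueError("a star needs at least 3 arms")
        if not (0 < self.inner_fraction < 1):
            raise ValueError("inner_fraction must be in (0, 1)")
        if self.nucleus_mean < 0 or self.cytoplasm_mean < 0:
            raise ValueError("intensities must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_cells < 1 or self.n_nuclei < 0:
            raise ValueError("n_cells >= 1 and n_nuclei >= 0 required")


@dataclass
class MaskPhantom:
    mask: LabeledMask
    truth: dict


@dataclass
class TwoChannelPhantom:
    intensity: np.ndarray
    nucleus_mask: LabeledMask
    cell_mask: LabeledMask
    truth: dict


@dataclass
class RelaxationCurve:
    time_s: np.ndarray
    modulus_Pa: np.ndarray
    truth: RelaxationSpectrum


def _star_polygon(cx: float, cy: float, r_out: float, r_in: float, n_arms: int):
    """Vertices of a 2*n_arms star polygon, plus exact area/perimeter."""
    angles = np.arange(2 * n_arms) * math.pi / n_arms
    radii = np.where(np.arange(2 * n_arms) % 2 == 0, r_out, r_in)
    ys = cy + radii * np.sin(angles)
    xs = cx + radii * np.cos(angles)
    # shoelace area and polygon perimeter
    area = 0.5 * abs(np.dot(xs, np.roll(ys, -1)) - np.dot(ys, np.roll(xs, -1)))
    perim = float(np.sum(np.hypot(np.diff(np.append(xs, xs[0])), np.diff(np.append(ys, ys[0])))))
    return ys, xs, area, perim


def _ramanujan_perimeter(a: float, b: float) -> float:
    h = ((a - b) / (a + b)) ** 2
    return math.pi * (a + b) * (1.0 + 3.0 * h / (10.0 + math.sqrt(4.0 - 3.0 * h)))


def gen_masks(spec: PhantomSpec) -> MaskPhantom:
    """Rasterize the phantom and return it with its analytic answer key.

    ``truth`` carries the exact (continuous-geometry) area, perimeter
    and circularity of the generating shape; for clusters it carries the
    nuclei count and the multicellular call instead.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.size
    grid = np.zeros((n, n), dtype=np.int32)
    cy = cx = n / 2.0
    if spec.shape == "disk":
        rr, cc = draw.disk((cy, cx), spec.radius, shape=grid.shape)
        grid[rr, cc] = 1
        area = math.pi * spec.radius**2
        perim = 2 * math.pi * spec.radius
    elif spec.shape == "ellipse":
        a, b = spec.radius, spec.radius / spec.aspect
        rr, cc = draw.ellipse(cy, cx, b, a, shape=grid.shape)
        grid[rr, cc] = 1
        area = math.pi * a * b
        perim = _ramanujan_perimeter(a, b)
    elif spec.shape == "star":
        ys, xs, area, perim = _star_polygon(
            cx, cy, spec.radius, spec.inner_fraction * spec.radius, spec.n_arms
        )
        rr, cc = draw.polygon(ys, xs, shape=grid.shape)
        grid[rr, cc] = 1
    else:  # cluster: one blob, nuclei recorded in the truth
        rr, cc = draw.disk((cy, cx), spec.radius, shape=grid.shape)
        grid[rr, cc] = 1
        centers = _nucleus_centers(rng, cy, cx, spec.radius, spec.nucleus_radius, spec.n_nuclei)
        truth = {
            "n_nuclei": spec.n_nuclei,
            "multicellular": spec.n_nuclei > 2,
            "nucleus_centers": centers,
            "area": math.pi * spec.radius**2 * spec.pixel_size**2,
        }
        return MaskPhantom(mask=LabeledMask(grid, spec.pixel_size), truth=truth)
    circ = 4 * math.pi * area / perim**2
    truth = {
        "area": area * spec.pixel_size**2,
        "perimeter": perim * spec.pixel_size,
        "circularity": circ,
    }
    return MaskPhantom(mask=LabeledMask(grid, spec.pixel_size), truth=truth)


def _nucleus_centers(rng, cy, cx, cell_r, nuc_r, n_nuclei, max_tries=10_000):
    """Non-overlapping nucleus centers strictly inside a disk cell."""
    centers: list[tuple[float, float]] = []
    margin = cell_r - nuc_r - 2.0
    if margin <= 0:
        raise ValueError("nucleus_radius too large for the cell radius")
    tries = 0
    while len(centers) < n_nuclei:
        tries += 1
        if tries > max_tries:
            raise ValueError("could not place non-overlapping nuclei; reduce n_nuclei")
        ang = rng.uniform(0, 2 * math.pi)
        rad = margin * math.sqrt(rng.uniform(0, 1))
        y, x = cy + rad * math.sin(ang), cx + rad * math.cos(ang)
        if all((y - y0) ** 2 + (x - x0) ** 2 > (2 * nuc_r + 1) ** 2 for y0, x0 in centers):
            centers.append((y, x))
    return centers


def gen_two_channel_image(spec: PhantomSpec) -> TwoChannelPhantom:
    """Cells with one nucleus each on a dark background, plus masks.

    Cells are disks tiled on a grid; each nucleus is a concentric disk
    strictly inside its cell.  The intensity channel is piecewise
    constant (nucleus_mean inside nuclei, cytoplasm_mean in the
    cytoplasm, 0 outside) plus noise, so the noise-free nuclear to
    cytoplasmic ratio is exactly ``nucleus_mean / cytoplasm_mean``.
    """
    if spec.nucleus_radius >= spec.radius:
        raise ValueError("nucleus must lie strictly inside the cell")
    if spec.cytoplasm_mean <= 0:
        raise ValueError("cytoplasm_mean must be positive for a defined ratio")
    rng = np.random.default_rng(spec.seed)
    per_side = math.ceil(math.sqrt(spec.n_cells))
    tile = int(2 * spec.radius + 8)
    n = per_side * tile
    cells = np.zeros((n, n), dtype=np.int32)
    nuclei = np.zeros((n, n), dtype=np.int32)
    image = np.zeros((n, n), dtype=float)
    for k in range(spec.n_cells):
        cy = (k // per_side) * tile + tile / 2.0
        cx = (k % per_side) * tile + tile / 2.0
        rr, cc = draw.disk((cy, cx), spec.radius, shape=cells.shape)
        cells[rr, cc] = k + 1
        image[rr, cc] = spec.cytoplasm_mean
        rr, cc = draw.disk((cy, cx), spec.nucleus_radius, shape=cells.shape)
        nuclei[rr, cc] = k + 1
        image[rr, cc] = spec.nucleus_mean
    if spec.poisson:
        image = rng.poisson(image).astype(float)
    elif spec.noise_sd > 0:
        image = np.clip(image + rng.normal(0.0, spec.noise_sd, image.shape), 0.0, None)
    truth = {
        "ratio": spec.nucleus_mean / spec.cytoplasm_mean,
        "n_cells": spec.n_cells,
    }
    return TwoChannelPhantom(
        intensity=image,
        nucleus_mask=LabeledMask(nuclei, spec.pixel_size),
        cell_mask=LabeledMask(cells, spec.pixel_size),
        truth=truth,
    )


def gen_relaxation_curve(
    spectrum: RelaxationSpectrum,
    n_samples: int = 50,
    noise_sd: float = 0.0,
    seed: int = 0,
    t_min: float | None = None,
    t_max: float | None = None,
) -> RelaxationCurve:
    """Log-spaced samples of G(t) with additive Gaussian noise.

    The default window spans two decades below the fastest mode to one
    decade above the slowest, which brackets every relaxation feature.
    """
    if n_samples < 4:
        raise ValueError("n_samples must be >= 4")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    taus = [tau for _, tau in spectrum.modes] or [1.0]
    t_min = min(taus) / 100.0 if t_min is None else t_min
    t_max = max(taus) * 10.0 if t_max is None else t_max
    t = np.logspace(math.log10(t_min), math.log10(t_max), n_samples)
    g = relaxation_modulus(spectrum, t)
    if noise_sd > 0:
        g = g + np.random.default_rng(seed).normal(0.0, noise_sd, g.shape)
    return RelaxationCurve(time_s=t, modulus_Pa=np.asarray(g), truth=spectrum)
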