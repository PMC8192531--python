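"""Image-derived cell statistics on labeled masks.

Covers the three readouts used to score cell behaviour in 3D hydrogels:

* circularity C = 4*pi*A / P^2 of each segmented cell (1 for a disk,
  low for stellate spread cells), with the perimeter measured on a
  sub-pixel marching-squares contour rather than by pixel-edge counting
  (edge counting biases C low by up to ~27% on disks);
* nuclear-to-cytoplasmic mean-intensity ratio (e.g. of YAP staining),
  a mechanosensing readout;
* multicellularity of cell clusters: a cluster is multicellular when it
  contains more than two nuclei (strictly greater).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from skimage import measure

__all__ = [
    "LabeledMask",
    "circularity",
    "nuclear_cyto_ratio",
    "multicellularity",
]


@dataclass(frozen=True)
class LabeledMask:
    """2D labeled object mask: 0 is background, k > 0 is object k.

    ``pixel_size`` is the side of one pixel in micrometres.
    """

    labels: np.ndarray
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.labels)
        if arr.ndim != 2 or arr.size == 0:
            raise ValueError("labels must be a non-empty 2D array")
        if arr.min() < 0:
            raise ValueError("labels must be non-negative integers")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive (um/pixel)")
        object.__setattr__(self, "labels", arr.astype(np.int32))

    @property
    def object_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]


def _contour_perimeter(binary: np.ndarray, sigma: float | None = None) -> float:
    """Total length of the sub-pixel 0.5-level contours of a binary blob.

    The mask is Gaussian-smoothed before marching-squares tracing: on a
    hard 0/1 raster the 0.5-level contour retains a staircase bias of
    several percent on curved boundaries, while the smoothed contour
    recovers disk perimeters to ~1%.  The smoothing length scales with
    the object's equivalent diameter (floor of one pixel) so the
    measurement is stable under resampling.  The mask is padded so
    objects touching the image edge still close their contours; objects
    too small to survive smoothing fall back to the unsmoothed contour.
    """
    if sigma is None:
        eq_diameter = 2.0 * math.sqrt(binary.sum() / math.pi)
        sigma = max(1.0, eq_diameter / 60.0)
    pad = int(4 + 3 * sigma)
    padded = np.pad(binary.astype(float), pad)
    field = gaussian_filter(padded, sigma) if sigma > 0 else padded
    contours = measure.find_contours(field, level=0.5)
    if not contours and sigma > 0:
        contours = measure.find_contours(padded, level=0.5)
    length = 0.0
    for c in contours:
        length += float(np.sum(np.hypot(*(np.diff(c, axis=0).T))))
    return length


def circularity(mask: LabeledMask) -> pd.DataFrame:
    """Per-object area, perimeter and circularity C = 4*pi*A/P^2.

    Area is the pixel-count area; perimeter is traced on the sub-pixel
    boundary, so C is scale-invariant and close to 1 for rasterized
    disks.  Objects touching the grid edge are measured but flagged.
    """
    ids = mask.object_ids
    if ids.size == 0:
        raise ValueError("mask contains no labeled objects")
    px = mask.pixel_size
    h, w = mask.labels.shape
    rows = []
    for k in ids:
        binary = mask.labels == k
        area_px = int(binary.sum())
        perim_px = _contour_perimeter(binary)
        c = 4.0 * math.pi * area_px / perim_px**2 if perim_px > 0 else math.nan
        touches = bool(
            binary[0, :].any() or binary[-1, :].any() or binary[:, 0].any() or binary[:, -1].any()
        )
        rows.append(
            {
                "object_id": int(k),
                "area_um2": area_px * px**2,
                "perimeter_um": perim_px * px,
                "circularity": c,
                "touches_edge": touches,
            }
        )
    return pd.DataFrame(rows)


def _match_nuclei_to_regions(nuclei: LabeledMask, regions: LabeledMask) -> tuple[dict, list]:
    """Assign each nucleus to the region containing its centroid.

    Ties at the centroid (background pixel) fall back to the region of
    largest overlap.  Returns ({nucleus_id: region_id}, [unassigned]).
    """
    assignment: dict[int, int] = {}
    unassigned: list[int] = []
    for prop in measure.regionprops(nuclei.labels):
        r, c = (int(round(x)) for x in prop.centroid)
        r = min(max(r, 0), regions.labels.shape[0] - 1)
        c = min(max(c, 0), regions.labels.shape[1] - 1)
        region = int(regions.labels[r, c])
        if region == 0:
            overlap = regions.labels[nuclei.labels == prop.label]
            overlap = overlap[overlap > 0]
            if overlap.size:
                region = int(np.bincount(overlap).argmax())
        if region == 0:
            unassigned.append(int(prop.label))
        else:
            assignment[int(prop.label)] = region
    return assignment, unassigned


def nuclear_cyto_ratio(
    intensity: np.ndarray,
    nucleus_mask: LabeledMask,
    cell_mask: LabeledMask,
    statistic: str = "mean",
) -> pd.DataFrame:
    """Per-cell nuclear/cytoplasmic intensity ratio.

    The cytoplasm of a cell is its mask minus every nucleus pixel.  The
    default statistic is the mean intensity; ``statistic="sum"`` gives
    integrated intensities instead.  Cells whose cytoplasm is empty or
    has zero intensity get an ``error`` record instead of a ratio; the
    call never fails globally over one bad cell.
    """
    intensity = np.asarray(intensity, dtype=float)
    if intensity.shape != cell_mask.labels.shape or intensity.shape != nucleus_mask.labels.shape:
        raise ValueError("intensity image and masks must share one shape")
    if statistic not in ("mean", "sum"):
        raise ValueError("statistic must be 'mean' or 'sum'")
    agg = np.mean if statistic == "mean" else np.sum
    assignment, unassigned = _match_nuclei_to_regions(nucleus_mask, cell_mask)
    nuclei_of_cell: dict[int, list[int]] = {}
    for nuc, cell in assignment.items():
        nuclei_of_cell.setdefault(cell, []).append(nuc)
    rows = []
    for cell_id in cell_mask.object_ids:
        cell_px = cell_mask.labels == cell_id
        nuc_ids = nuclei_of_cell.get(int(cell_id), [])
        nuc_px = np.isin(nucleus_mask.labels, nuc_ids) & cell_px if nuc_ids else np.zeros_like(cell_px)
        cyto_px = cell_px & ~nuc_px
        row = {"cell_id": int(cell_id), "n_nuclei": len(nuc_ids), "ratio": math.nan, "error": ""}
        if not nuc_ids or not nuc_px.any():
            row["error"] = "no nucleus assigned to this cell"
        elif not cyto_px.any():
            row["error"] = "empty cytoplasm (cell fully covered by nucleus)"
        else:
            nuc_val = float(agg(intensity[nuc_px]))
            cyto_val = float(agg(intensity[cyto_px]))
            if cyto_val == 0:
                row["error"] = "zero cytoplasmic intensity"
            else:
                row["ratio"] = nuc_val / cyto_val
        rows.append(row)
    df = pd.DataFrame(rows)
    df.attrs["unassigned_nuclei"] = unassigned
    return df


def multicellularity(cluster_mask: LabeledMask, nuclei_mask: LabeledMask) -> pd.DataFrame:
    """Per-cluster nuclei count and multicellular flag (> 2 nuclei).

    Nuclei are assigned to the cluster containing their centroid (ties
    broken by largest overlap); nuclei falling in no cluster are counted
    as unassigned and reported via ``df.attrs['unassigned_nuclei']``.
    """
    assignment, unassigned = _match_nuclei_to_regions(nuclei_mask, cluster_mask)
    counts: dict[int, int] = {int(k): 0 for k in cluster_mask.object_ids}
    for _, cluster in assignment.items():
        counts[cluster] = counts.get(cluster, 0) + 1
    df = pd.DataFrame(
        [
            {"cluster_id": k, "n_nuclei": v, "multicellular": v > 2}
            for k, v in sorted(counts.items())
        ]
    )
    df.attrs["unassigned_nuclei"] = unassigned
    return df
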