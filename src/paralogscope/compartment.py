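"""Two-channel per-cell ER vs cytoplasm abundance quantification.

Validation-style analysis for a GFP-tagged protein co-imaged with an ER
reporter: cells near the image edge are removed (margin = the median
major-axis length of the image's cells), images with extreme background are
discarded per replicate (mean +/- sd gates), and within each retained cell
the reporter channel partitions pixels into ER (>= the 0.975 within-cell
intensity quantile) and cytoplasm (< the 0.973 quantile), leaving the thin
band between the two quantiles unassigned. Cells with fewer than 100 ER
pixels are discarded. Compartment abundances are background-normalized
medians of the GFP channel over each pixel class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

ER_QUANTILE = 0.975
CYTO_QUANTILE = 0.973
MIN_ER_PIXELS = 100


@dataclass(frozen=True)
class PixelPartition:
    """Within-cell reporter-channel pixel classes (index arrays into the
    cell's flattened pixel list)."""

    er: np.ndarray
    cytoplasm: np.ndarray
    n_pixels: int
    degenerate: bool = False


@dataclass
class CompartmentProfile:
    """Per-cell background-normalized abundances with QC flags."""

    cell_id: int
    n_er_pixels: int
    abundance_er: float | None
    abundance_cyto: float | None
    abundance_cell: float | None
    qc_flags: set = field(default_factory=set)

    @property
    def retained(self) -> bool:
        return not self.qc_flags


def remove_edge_cells(
    centroids: Sequence[tuple[float, float]],
    major_axis_lengths: Sequence[float],
    image_shape: tuple[int, int],
) -> list[int]:
    """Indices of cells kept after edge removal.

    The margin is the median major-axis length over all cells of the image;
    cells whose centroid lies within the margin of any border are removed.
    """
    if len(centroids) == 0:
        raise ValueError("need at least one cell")
    margin = float(np.median(np.asarray(major_axis_lengths, dtype=float)))
    h, w = image_shape
    kept = []
    for i, (cy, cx) in enumerate(centroids):
        if cy < margin or cx < margin or (h - 1 - cy) < margin or (w - 1 - cx) < margin:
            continue
        kept.append(i)
    return kept


def qc_background_images(
    background_by_image: Mapping[object, float],
    replicate_of: Mapping[object, object] | None = None,
) -> tuple[list, list[str]]:
    """Retain images whose background lies within mean +/- sd of their replicate.

    Bounds are inclusive; the sd is the population standard deviation of the
    per-image backgrounds within the replicate. A replicate with a single
    image is retained with a warning.
    """
    groups: dict[object, list] = {}
    for img_id in background_by_image:
        rep = replicate_of[img_id] if replicate_of else "all"
        groups.setdefault(rep, []).append(img_id)
    retained, warnings_ = [], []
    for rep, ids in groups.items():
        vals = np.array([background_by_image[i] for i in ids], dtype=float)
        if len(ids) < 2:
            warnings_.append(f"replicate {rep!r} has a single image; retained un-QCed")
            retained.extend(ids)
            continue
        lo, hi = vals.mean() - vals.std(ddof=0), vals.mean() + vals.std(ddof=0)
        retained.extend(i for i, v in zip(ids, vals) if lo <= v <= hi)
    return retained, warnings_


def assign_er_cytoplasm(
    reporter_pixels: np.ndarray,
    er_quantile: float = ER_QUANTILE,
    cyto_quantile: float = CYTO_QUANTILE,
) -> PixelPartition:
    """Partition a cell's pixels by reporter intensity quantiles.

    ER pixels are those at or above the ``er_quantile`` within-cell quantile
    (linear-interpolation convention); cytoplasmic pixels lie strictly below
    the ``cyto_quantile`` quantile; the narrow band between the two stays
    unassigned. Constant-intensity cells are flagged degenerate.
    """
    v = np.asarray(reporter_pixels, dtype=float).ravel()
    if v.size < MIN_ER_PIXELS:
        raise ValueError(f"need >= {MIN_ER_PIXELS} pixels in the cell mask")
    if v.max() == v.min():
        empty = np.array([], dtype=int)
        return PixelPartition(er=empty, cytoplasm=empty, n_pixels=v.size, degenerate=True)
    q_er = np.quantile(v, er_quantile)
    q_cyto = np.quantile(v, cyto_quantile)
    return PixelPartition(
        er=np.nonzero(v >= q_er)[0],
        cytoplasm=np.nonzero(v < q_cyto)[0],
        n_pixels=v.size,
    )


def compartment_abundance(
    gfp_pixels: np.ndarray,
    partition: PixelPartition,
    background_intensity: float,
    cell_id: int = 0,
    min_er_pixels: int = MIN_ER_PIXELS,
) -> CompartmentProfile:
    """Background-normalized median abundances per compartment.

    abundance_x = median(GFP over compartment pixels) / background. Cells
    whose ER pixel count falls below ``min_er_pixels`` or whose partition is
    degenerate are flagged and should be discarded by the caller.
    """
    if background_intensity <= 0:
        raise ValueError("background intensity must be positive")
    g = np.asarray(gfp_pixels, dtype=float).ravel()
    if g.size != partition.n_pixels:
        raise ValueError("GFP pixel count does not match the partition")
    flags: set[str] = set()
    if partition.degenerate:
        flags.add("degenerate_reporter")
    n_er = int(partition.er.size)
    if n_er < min_er_pixels:
        flags.add("too_few_er_pixels")
    abundance_er = (
        float(np.median(g[partition.er]) / background_intensity) if n_er else None
    )
    if abundance_er is None:
        flags.add("empty_er")
    abundance_cyto = (
        float(np.median(g[partition.cytoplasm]) / background_intensity)
        if partition.cytoplasm.size
        else None
    )
    if abundance_cyto is None:
        flags.add("empty_cytoplasm")
    return CompartmentProfile(
        cell_id=cell_id,
        n_er_pixels=n_er,
        abundance_er=abundance_er,
        abundance_cyto=abundance_cyto,
        abundance_cell=float(np.median(g) / background_intensity),
        qc_flags=flags,
    )


def estimate_background(image: np.ndarray, labels: np.ndarray) -> float:
    """Image background intensity: median over non-cell pixels."""
    image = np.asarray(image)
    mask = np.asarray(labels) == 0
    if not mask.any():
        raise ValueError("no background pixels in the image")
    return float(np.median(image[mask]))


def quantify_scene(
    gfp: np.ndarray,
    reporter: np.ndarray,
    labels: np.ndarray,
    er_quantile: float = ER_QUANTILE,
    cyto_quantile: float = CYTO_QUANTILE,
    min_er_pixels: int = MIN_ER_PIXELS,
) -> list[CompartmentProfile]:
    """Run the per-cell ER/cytoplasm quantification over one labeled image.

    Applies edge-cell removal, then the quantile partition and normalized
    abundances for every retained cell; cells failing the ER-pixel gate or
    with degenerate reporter signal carry QC flags.
    """
    from scipy import ndimage
    from skimage.measure import regionprops

    labels = np.asarray(labels)
    ids = np.unique(labels[labels > 0])
    if ids.size == 0:
        return []
    props = {p.label: p for p in regionprops(labels)}
    centroids = [props[i].centroid for i in ids]
    axes = [props[i].axis_major_length for i in ids]
    kept_idx = remove_edge_cells(centroids, axes, labels.shape)
    background = estimate_background(gfp, labels)
    profiles = []
    for i in kept_idx:
        cid = int(ids[i])
        mask = labels == cid
        if mask.sum() < min_er_pixels:
            profiles.append(
                CompartmentProfile(
                    cell_id=cid,
                    n_er_pixels=0,
                    abundance_er=None,
                    abundance_cyto=None,
                    abundance_cell=None,
                    qc_flags={"cell_too_small"},
                )
            )
            continue
        part = assign_er_cytoplasm(reporter[mask], er_quantile, cyto_quantile)
        profiles.append(
            compartment_abundance(
                gfp[mask], part, background, cell_id=cid, min_er_pixels=min_er_pixels
            )
        )
    return profiles
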