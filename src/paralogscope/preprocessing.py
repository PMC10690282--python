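"""Background-reference subtraction, log standardization, replicate QC.

The background reference mitigates uneven illumination and read-out noise:
each pixel of the reference is the median of that pixel across all images of
a dataset. Images destined for segmentation are then variance-stabilized with
a natural-log transform and standardized to zero mean, unit standard
deviation per image. Replicate-level filtering removes low-cell-count
replicates and user-listed exclusions, with a full audit trail.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class BackgroundReference:
    """Per-pixel median background over a dataset of same-shape images."""

    reference: np.ndarray
    n_images: int


@dataclass(frozen=True)
class NormalizedImage:
    """Log-transformed, standardized image with its normalization constants.

    ``values`` has mean 0 and population standard deviation 1; ``mu`` and
    ``sigma`` are the mean and population sd of the log-image ln(x + 1).
    """

    values: np.ndarray
    mu: float
    sigma: float


class DegenerateImageError(ValueError):
    """Raised when an image is constant and cannot be standardized."""


def _check_same_shape(images: Sequence[np.ndarray]) -> tuple[int, int]:
    shapes = {img.shape for img in images}
    if len(shapes) != 1:
        raise ValueError(f"images differ in shape: {sorted(shapes)}")
    return next(iter(shapes))


def estimate_background_reference(images: Sequence[np.ndarray]) -> BackgroundReference:
    """Per-pixel median across images of one dataset.

    Even image counts use the arithmetic mean of the two central values.
    """
    images = list(images)
    if not images:
        raise ValueError("need at least one image")
    _check_same_shape(images)
    stack = np.stack(images).astype(np.float64)
    return BackgroundReference(
        reference=np.median(stack, axis=0), n_images=len(images)
    )


def subtract_background(image: np.ndarray, ref: BackgroundReference) -> np.ndarray:
    """Elementwise difference against the reference, clipped at zero.

    Residuals below the median background carry no abundance information, so
    negative differences are set to 0.
    """
    if image.shape != ref.reference.shape:
        raise ValueError(
            f"image shape {image.shape} != reference shape {ref.reference.shape}"
        )
    return np.clip(np.asarray(image, dtype=np.float64) - ref.reference, 0.0, None)


def log_standardize(image: np.ndarray) -> NormalizedImage:
    """x' = ln(x + 1) per pixel, then (x' - mu) / sigma over the whole image.

    ``sigma`` is the population standard deviation. A constant image has
    sigma = 0 and raises :class:`DegenerateImageError`.
    """
    x = np.asarray(image, dtype=np.float64)
    if np.any(x < 0):
        raise ValueError("log_standardize requires nonnegative intensities")
    xp = np.log1p(x)
    mu = float(xp.mean())
    sigma = float(xp.std(ddof=0))
    if sigma == 0.0:
        raise DegenerateImageError("constant image: sigma = 0")
    return NormalizedImage(values=(xp - mu) / sigma, mu=mu, sigma=sigma)


@dataclass
class FilterAudit:
    """Log of replicate/gene removals, one row per action."""

    rows: list[dict] = field(default_factory=list)

    def add(self, identifier: str, action: str, reason: str) -> None:
        self.rows.append({"id": identifier, "action": action, "reason": reason})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=["id", "action", "reason"])


def filter_replicates(
    cell_counts: Mapping[str, Mapping[object, int]],
    min_cells: int = 50,
    exclusions: Iterable[tuple[str, str]] = (),
) -> tuple[dict[str, set], FilterAudit]:
    """Drop low-cell-count replicates and excluded genes/images.

    ``cell_counts`` maps a sample identifier (e.g. gene or strain) to its
    per-replicate cell counts. Replicates with fewer than ``min_cells`` cells
    are removed; any sample on the ``exclusions`` list of ``(id, reason)``
    pairs is dropped entirely. Returns the retained ``{sample: {replicates}}``
    membership and the audit log; the data themselves are never altered.
    """
    audit = FilterAudit()
    excluded = {gid: reason for gid, reason in exclusions}
    retained: dict[str, set] = {}
    for sample, reps in cell_counts.items():
        if sample in excluded:
            audit.add(str(sample), "drop_sample", excluded[sample])
            continue
        kept = set()
        for rep, count in reps.items():
            if count < min_cells:
                audit.add(
                    f"{sample}/{rep}",
                    "drop_replicate",
                    f"low cell count {count} < {min_cells}",
                )
            else:
                kept.add(rep)
        retained[sample] = kept
        if not kept:
            audit.add(str(sample), "flag_empty", "no replicates retained")
    return retained, audit
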