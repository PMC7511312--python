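"""Per-cell astaxanthin quantification from bright-field RGB micrographs.

The scoring procedure follows the channel-arithmetic recipe used for
Haematococcus micrographs: the 8-bit RGB image is inverted (v -> 255 - v)
and split into channels; in the inverted image the green channel tracks the
astaxanthin signal and the red channel the chlorophyll signal, so the
per-pixel difference ``A = G_inv - R_inv`` corrects astaxanthin against
chlorophyll. The integrated density of ``A`` over each segmented cell is
that cell's pigment score (arbitrary units, signed).

Subtraction is signed and unclipped by default, which keeps the score
additive over disjoint regions and invariant to any offset common to both
channels; ``clip_negative=True`` reproduces the 8-bit-clamped dialect of
typical image software.

Segmentation is not part of the published recipe and is an artifact choice:
Otsu threshold on the inverted luminance, hole filling, connected
components, minimum-area filter, border-touching regions discarded — all
configurable.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from skimage import filters, measure
from scipy import ndimage as ndi

from .errors import ValidationError

__all__ = [
    "CellRegion",
    "PigmentScore",
    "PopulationPigmentSummary",
    "as_micrograph",
    "invert_image",
    "astaxanthin_signal",
    "segment_cells",
    "integrated_density",
    "score_micrograph",
    "population_summary",
    "load_micrograph",
]


@dataclass(frozen=True)
class CellRegion:
    """One segmented cell: label, pixel coordinates, area and centroid.

    ``coords`` is an (n, 2) integer array of (row, col) pixel coordinates,
    0-based, row-major.
    """

    label: int
    coords: np.ndarray
    area: int
    centroid: tuple

    def __post_init__(self) -> None:
        if self.area <= 0 or len(self.coords) == 0:
            raise ValidationError("region must contain at least one pixel")


@dataclass(frozen=True)
class PigmentScore:
    """Integrated astaxanthin density of one cell (signed, arbitrary units)."""

    cell_id: int
    integrated_density: float
    area_px: int

    @property
    def mean_density(self) -> float:
        return self.integrated_density / self.area_px


@dataclass(frozen=True)
class PopulationPigmentSummary:
    """Cross-experiment mean +/- s.e. of per-cell pigment scores."""

    n_cells: int
    n_experiments: int
    mean_density: float
    se_density: float
    per_experiment_mean: pd.Series


def as_micrograph(img: np.ndarray) -> np.ndarray:
    """Validate/coerce an array to an 8-bit RGB micrograph (H, W, 3) uint8.

    16-bit input is rescaled to 8 bits (right shift); anything else must
    already be uint8.
    """
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValidationError(f"expected an (H, W, 3) RGB image, got shape {img.shape}")
    if img.dtype == np.uint8:
        return img
    if img.dtype == np.uint16:
        return (img // 257).astype(np.uint8)
    raise ValidationError(f"expected 8-bit (or 16-bit) unsigned image, got dtype {img.dtype}")


def invert_image(img: np.ndarray) -> np.ndarray:
    """Invert an 8-bit RGB image: every channel value v -> 255 - v."""
    return 255 - as_micrograph(img)


def astaxanthin_signal(img_inverted: np.ndarray, *, clip_negative: bool = False) -> np.ndarray:
    """Signed per-pixel astaxanthin map from an already-inverted image.

    ``A = G_inv - R_inv`` as int16 (no clipping by default). In the
    inverted image the green channel carries the astaxanthin signal and the
    red channel the chlorophyll signal, so A is astaxanthin corrected
    against chlorophyll. The blue channel is ignored.
    """
    img_inverted = as_micrograph(img_inverted)
    a = img_inverted[:, :, 1].astype(np.int16) - img_inverted[:, :, 0].astype(np.int16)
    if clip_negative:
        a = np.clip(a, 0, None)
    return a


def segment_cells(
    img: np.ndarray,
    *,
    min_area: int = 50,
    discard_border: bool = True,
    threshold: Optional[float] = None,
) -> List[CellRegion]:
    """Segment roughly circular cells against a bright background.

    Otsu threshold (or a manual one) on the inverted luminance, hole
    filling, connected-component labelling; regions below ``min_area``
    pixels are dropped and border-touching regions discarded by default.
    Returns an empty list for a blank image.
    """
    img = as_micrograph(img)
    lum_inv = 255.0 - img.mean(axis=2)
    if threshold is None:
        if lum_inv.max() - lum_inv.min() < 1.0:  # blank image: Otsu would split noise
            return []
        threshold = filters.threshold_otsu(lum_inv)
    mask = lum_inv > threshold
    mask = ndi.binary_fill_holes(mask)
    labels = measure.label(mask, connectivity=2)
    regions: List[CellRegion] = []
    h, w = labels.shape
    for rp in measure.regionprops(labels):
        if rp.area < min_area:
            continue
        if discard_border:
            rmin, cmin, rmax, cmax = rp.bbox
            if rmin == 0 or cmin == 0 or rmax == h or cmax == w:
                continue
        regions.append(
            CellRegion(
                label=int(rp.label),
                coords=np.asarray(rp.coords),
                area=int(rp.area),
                centroid=tuple(float(c) for c in rp.centroid),
            )
        )
    return regions


def integrated_density(signal: np.ndarray, regions: Sequence[CellRegion]) -> List[PigmentScore]:
    """Sum the signed signal map over each region's pixels."""
    signal = np.asarray(signal)
    if signal.ndim != 2:
        raise ValidationError("signal map must be 2-D")
    h, w = signal.shape
    scores = []
    for region in regions:
        rows, cols = region.coords[:, 0], region.coords[:, 1]
        if rows.min() < 0 or cols.min() < 0 or rows.max() >= h or cols.max() >= w:
            raise ValidationError(f"region {region.label} exceeds image bounds")
        scores.append(
            PigmentScore(
                cell_id=region.label,
                integrated_density=float(signal[rows, cols].sum()),
                area_px=region.area,
            )
        )
    return scores


def score_micrograph(
    img: np.ndarray,
    *,
    clip_negative: bool = False,
    min_area: int = 50,
    discard_border: bool = True,
) -> List[PigmentScore]:
    """Full recipe on one micrograph: invert, subtract, segment, integrate."""
    inverted = invert_image(img)
    signal = astaxanthin_signal(inverted, clip_negative=clip_negative)
    regions = segment_cells(img, min_area=min_area, discard_border=discard_border)
    return integrated_density(signal, regions)


def population_summary(
    scores: pd.DataFrame,
    *,
    value: str = "integrated_density",
    experiment: str = "experiment",
    min_cells: int = 500,
) -> PopulationPigmentSummary:
    """Per-experiment means, then cross-experiment mean +/- s.e.

    ``scores`` is a tidy frame with one row per cell carrying the score
    column named by ``value`` and an experiment id column. Fewer than
    ``min_cells`` cells in any experiment raises a warning (the reporting
    convention targets at least 500 cells per data point). With a single
    experiment the s.e. is reported as 0.
    """
    if scores.empty:
        raise ValidationError("no pigment scores to summarise")
    if value not in scores.columns or experiment not in scores.columns:
        raise ValidationError(f"summary needs columns {value!r} and {experiment!r}")
    counts = scores.groupby(experiment)[value].size()
    if (counts < min_cells).any():
        warnings.warn(
            f"some experiments have fewer than {min_cells} cells per data point",
            stacklevel=2,
        )
    per_exp = scores.groupby(experiment)[value].mean()
    n_exp = len(per_exp)
    se = float(per_exp.std(ddof=1) / math.sqrt(n_exp)) if n_exp > 1 else 0.0
    return PopulationPigmentSummary(
        n_cells=int(len(scores)),
        n_experiments=int(n_exp),
        mean_density=float(per_exp.mean()),
        se_density=se,
        per_experiment_mean=per_exp,
    )


def load_micrograph(path) -> np.ndarray:
    """Read a TIFF/PNG micrograph from disk as an 8-bit RGB array."""
    import imageio.v3 as iio

    return as_micrograph(iio.imread(path))
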