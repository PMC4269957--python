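"""White-matter histomorphometry per region of interest.

Three measurements quantify the histological response in a white-matter
tract: the box-counting fractal dimension of a microglial outline (lower
for activated, amoeboid cells than for ramified resting cells), the
density of Iba-1-positive cells per mm^2, and the percent of the ROI area
positive for a stain (silver burden).

Box counting follows the FracLac convention: the binarized cell is reduced
to its largest connected component, a one-pixel outline (foreground minus
its erosion) is extracted, and for each box size the count of occupied
boxes is minimized over a small set of grid offsets before fitting
``log N`` against ``log box size``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats
from skimage.filters import threshold_otsu

__all__ = [
    "MorphometryResult",
    "boxcount_fd",
    "default_scales",
    "cell_density",
    "percent_positive",
]


@dataclass(frozen=True)
class MorphometryResult:
    """Morphometric summary for one ROI."""

    fractal_dimension: float | None
    cell_density: float | None
    percent_positive: float | None
    roi_area_mm2: float | None = None
    n_cells: int | None = None


def default_scales(image_shape: tuple[int, int]) -> list[int]:
    """Powers of 2 from 2 px up to a quarter of the shorter image side."""
    limit = min(image_shape) // 4
    scales = []
    s = 2
    while s <= limit:
        scales.append(s)
        s *= 2
    return scales


def _binarize(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.dtype == bool:
        return image
    if np.isin(np.unique(image), (0, 1)).all():
        return image.astype(bool)
    return image > threshold_otsu(image)


def _largest_component(mask: np.ndarray) -> np.ndarray:
    labels, n = ndimage.label(mask)
    if n <= 1:
        return mask
    sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
    return labels == (int(np.argmax(sizes)) + 1)


def _outline(mask: np.ndarray) -> np.ndarray:
    """Morphological perimeter: foreground minus its erosion."""
    eroded = ndimage.binary_erosion(mask, structure=np.ones((3, 3)))
    return mask & ~eroded


def _box_count(mask: np.ndarray, scale: int, n_offsets: int) -> int:
    """Occupied-box count at one scale, minimized over grid offsets."""
    offsets = [(0, 0)]
    if n_offsets > 1:
        half = scale // 2
        extra = [(half, 0), (0, half), (half, half)]
        offsets += extra[: n_offsets - 1]
    best = None
    for oy, ox in offsets:
        padded = np.pad(mask, ((oy, 0), (ox, 0)))
        h = -(-padded.shape[0] // scale) * scale
        w = -(-padded.shape[1] // scale) * scale
        padded = np.pad(padded, ((0, h - padded.shape[0]), (0, w - padded.shape[1])))
        blocks = padded.reshape(h // scale, scale, w // scale, scale)
        count = int(blocks.any(axis=(1, 3)).sum())
        best = count if best is None else min(best, count)
    return best


def boxcount_fd(
    image: np.ndarray,
    scales: list[int] | None = None,
    n_offsets: int = 4,
    outline: bool = True,
) -> float:
    """Box-counting fractal dimension of a binarized shape.

    The image is binarized (Otsu for grayscale input), reduced to its
    largest connected component and, when ``outline`` is set, to its
    one-pixel perimeter.  ``N(eps)`` is the minimum over ``n_offsets`` grid
    offsets of the number of ``eps x eps`` boxes containing foreground, and
    the dimension is the negated slope of the least-squares line of
    ``log N(eps)`` on ``log eps``.  Scales default to powers of 2 from 2 px
    to a quarter of the shorter image side and must span at least two
    octaves.
    """
    mask = _binarize(image)
    if not mask.any():
        raise ValueError("image contains no foreground pixels")
    if scales is None:
        rows = np.flatnonzero(mask.any(axis=1))
        cols = np.flatnonzero(mask.any(axis=0))
        extent = max(rows[-1] - rows[0] + 1, cols[-1] - cols[0] + 1)
        scales = default_scales((extent, extent))
        if len(scales) < 4:
            raise ValueError(
                f"foreground extent {extent} px too small for box counting "
                "(need at least 4 dyadic scales); pass scales explicitly"
            )
    scales = sorted(int(s) for s in scales)
    if len(scales) < 4:
        raise ValueError("need at least 4 box scales")
    if scales[0] < 1 or scales[0] == scales[-1]:
        raise ValueError("box scales must be positive and non-degenerate")
    if scales[-1] / scales[0] < 4:
        raise ValueError("box scales must span at least two octaves")

    mask = _largest_component(mask)
    if outline:
        mask = _outline(mask)
        if not mask.any():  # single-pixel-thin shapes erode to nothing
            raise ValueError("outline extraction removed all foreground")

    # anchor the counting grid to the shape: crop to the foreground bounding
    # box so the measured dimension is independent of image translation
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    mask = mask[rows[0] : rows[-1] + 1, cols[0] : cols[-1] + 1]

    counts = np.array([_box_count(mask, s, n_offsets) for s in scales], dtype=float)
    fit = stats.linregress(np.log(scales), np.log(counts))
    return float(-fit.slope)


def cell_density(count: int, roi_mask: np.ndarray, px_per_mm: float) -> float:
    """Cells per mm^2: ``count / (mask pixel area / px_per_mm^2)``.

    ``count`` is the (manually obtained) number of positive cells inside
    the ROI; ``roi_mask`` delimits the ROI and ``px_per_mm`` converts the
    pixel grid to physical units.
    """
    if count < 0:
        raise ValueError("cell count must be non-negative")
    if px_per_mm <= 0:
        raise ValueError("px_per_mm must be positive")
    mask = np.asarray(roi_mask).astype(bool)
    n_px = int(mask.sum())
    if n_px == 0:
        raise ValueError("ROI mask is empty")
    area_mm2 = n_px / px_per_mm**2
    return count / area_mm2


def percent_positive(
    image: np.ndarray, roi_mask: np.ndarray, threshold: float | str = "otsu"
) -> float:
    """Percent of ROI area with signal above threshold.

    ``threshold`` is an absolute intensity, or ``"otsu"`` to derive it from
    the ROI histogram; pixels strictly above the threshold count as
    positive.  Returns ``100 * positive-in-ROI / ROI pixels``.
    """
    image = np.asarray(image)
    mask = np.asarray(roi_mask).astype(bool)
    if mask.shape != image.shape:
        raise ValueError("ROI mask must match the image shape")
    n_roi = int(mask.sum())
    if n_roi == 0:
        raise ValueError("ROI mask is empty")
    roi_values = image[mask]
    if threshold == "otsu":
        threshold = threshold_otsu(roi_values)
    positive = int((roi_values > threshold).sum())
    return 100.0 * positive / n_roi
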