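"""Nuclear morphometry: segmentation, convex-hull solidity, classification.

Solidity — mask area divided by the area of the filled convex hull of the
mask — quantifies how lobed an interphase nucleus is (1 for convex shapes,
lower for multilobed ones).  Nuclei are classified as abnormal when their
solidity falls strictly below the fifth percentile of solidity in the
GFP-only control population.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.ndimage import binary_fill_holes, gaussian_filter
from scipy.spatial import ConvexHull, QhullError
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label
from skimage.segmentation import clear_border

from .errors import SampleSizeError
from .imaging_io import ImageStack

_SEG_SMOOTH_SIGMA_UM = 0.5
MIN_NUCLEUS_AREA_UM2 = 20.0


@dataclass(frozen=True)
class NucleusRecord:
    """Per-nucleus mask statistics."""

    nucleus_id: str
    area_um2: float
    convex_area_um2: float
    solidity: float
    label: str = "unset"        # normal / abnormal / unset


def segment_nuclei(stack: ImageStack, frame: int = 0) -> list[np.ndarray]:
    """Segment well-separated nuclei in a single DNA-channel frame.

    Gaussian smoothing (sigma 0.5 um), global Otsu threshold, hole filling,
    then removal of components smaller than 20 um^2 or touching the image
    border.  Returns one boolean mask (full frame size) per surviving
    connected component; an image with no nuclei yields an empty list.
    """
    px = stack.pixel_size_um
    img = stack.plane("dna", frame).astype(np.float64)
    if img.max() <= img.min():
        return []
    sm = gaussian_filter(img, _SEG_SMOOTH_SIGMA_UM / px, mode="nearest")
    binary = sm > threshold_otsu(sm)
    binary = binary_fill_holes(binary)
    binary = clear_border(binary)
    labels = sk_label(binary)
    min_px = MIN_NUCLEUS_AREA_UM2 / px**2
    masks = []
    for lab in range(1, labels.max() + 1):
        mask = labels == lab
        if mask.sum() >= min_px:
            masks.append(mask)
    return masks


def _convex_area_px(mask: np.ndarray) -> int:
    """Pixel count of the filled convex hull of a boolean mask.

    The hull is taken over pixel centers; a pixel belongs to the filled hull
    when its center satisfies every hull half-plane.  Degenerate masks
    (points, lines) are their own hull.
    """
    pts = np.argwhere(mask)
    if len(pts) < 3:
        return int(mask.sum())
    try:
        hull = ConvexHull(pts.astype(float))
    except QhullError:  # collinear mask
        return int(mask.sum())
    (rmin, cmin), (rmax, cmax) = pts.min(axis=0), pts.max(axis=0)
    rr, cc = np.mgrid[rmin:rmax + 1, cmin:cmax + 1]
    coords = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
    # hull.equations rows are (a, b, offset) with a*x + b*y + offset <= 0 inside
    inside = np.ones(len(coords), dtype=bool)
    for a, b, off in hull.equations:
        inside &= coords[:, 0] * a + coords[:, 1] * b + off <= 1e-9
    return int(inside.sum())


def solidity(mask: np.ndarray) -> float:
    """Solidity of a binary mask: area / filled-convex-hull area, in (0, 1]."""
    mask = np.asarray(mask, dtype=bool)
    area = int(mask.sum())
    if area == 0:
        raise ValueError("mask is empty")
    return area / _convex_area_px(mask)


def measure_nuclei(
    stack: ImageStack, frame: int = 0, id_prefix: str = "n"
) -> list[NucleusRecord]:
    """Segment a field and compute per-nucleus area and solidity records."""
    px2 = stack.pixel_size_um**2
    records = []
    for i, mask in enumerate(segment_nuclei(stack, frame)):
        rows = np.any(mask, axis=1).nonzero()[0]
        cols = np.any(mask, axis=0).nonzero()[0]
        crop = mask[rows[0]:rows[-1] + 1, cols[0]:cols[-1] + 1]
        area = int(crop.sum())
        convex = _convex_area_px(crop)
        records.append(
            NucleusRecord(
                nucleus_id=f"{id_prefix}{i:04d}",
                area_um2=area * px2,
                convex_area_um2=convex * px2,
                solidity=area / convex,
            )
        )
    return records


def control_threshold(control_solidity: Sequence[float]) -> float:
    """Fifth percentile of control-population solidity.

    Uses linear interpolation between closest order statistics; at least 20
    values are required for the percentile to be meaningful.
    """
    values = np.asarray(control_solidity, dtype=float)
    if values.size < 20:
        raise SampleSizeError(
            f"need >= 20 control solidity values, got {values.size}"
        )
    return float(np.percentile(values, 5.0, method="linear"))


def classify_nuclei(
    records: Sequence[NucleusRecord], threshold: float
) -> tuple[list[NucleusRecord], float]:
    """Label records normal/abnormal and return the abnormal fraction.

    A nucleus is abnormal iff its solidity is strictly below the threshold
    (a value exactly at the threshold is normal).
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    if len(records) == 0:
        raise ValueError("no nucleus records to classify")
    labeled = [
        replace(r, label="abnormal" if r.solidity < threshold else "normal")
        for r in records
    ]
    frac = sum(r.label == "abnormal" for r in labeled) / len(labeled)
    return labeled, frac
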