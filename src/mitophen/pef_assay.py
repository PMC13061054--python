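"""Polar-ejection-force assay on monopolar spindles.

Relative polar ejection force is proxied by the distance from the collapsed
spindle-pole pair to the maximum of the DNA channel's radial intensity
profile inside a 14 um circular ROI: stronger ejection pushes the chromosome
rosette further out.  The profile assigns pixels to annular bins by Euclidean
distance from the ROI center and reports per-bin mean intensity, matching
the classic radial-profile measurement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu

from .errors import DetectionError, GeometryError, ProfileError
from .imaging_io import CircularRoi, ImageStack

DEFAULT_ROI_RADIUS_UM = 14.0
DEFAULT_BIN_WIDTH_UM = 0.11     # one pixel at the default calibration
_CENTRIN_SMOOTH_UM = 0.2


@dataclass(frozen=True)
class RadialProfile:
    """Annular-bin radial intensity profile; NaN marks empty bins."""

    radius_um: np.ndarray
    mean_intensity: np.ndarray


@dataclass(frozen=True)
class PefMeasurement:
    cell_id: str
    center_xy: tuple[float, float]
    radii_um: np.ndarray
    mean_intensity: np.ndarray
    pef_distance_um: float


def _weighted_centroid(img: np.ndarray, rc: tuple[int, int],
                       radius: int) -> tuple[float, float]:
    r, c = rc
    h, w = img.shape
    r0, r1 = max(r - radius, 0), min(r + radius + 1, h)
    c0, c1 = max(c - radius, 0), min(c + radius + 1, w)
    win = img[r0:r1, c0:c1] - img[r0:r1, c0:c1].min()
    total = win.sum()
    if total <= 0:
        return float(c), float(r)
    ys, xs = np.mgrid[r0:r1, c0:c1]
    return float((xs * win).sum() / total), float((ys * win).sum() / total)


def locate_monopole_center(stack: ImageStack,
                           frame: int = 0) -> tuple[float, float]:
    """Center of a monopolar spindle as (x, y) pixel coordinates.

    With a centrin channel: the midpoint of the two brightest centrin foci
    (the single focus if only one qualifies; the duplicated poles may blur
    into one peak).  Otherwise: the intensity-weighted centroid of the
    Otsu-thresholded tubulin signal.  Raises :class:`DetectionError` when
    neither yields a position.
    """
    px = stack.pixel_size_um
    if stack.has_channel("centrin"):
        img = stack.plane("centrin", frame).astype(np.float64)
        sm = gaussian_filter(img, _CENTRIN_SMOOTH_UM / px, mode="nearest")
        med = float(np.median(sm))
        mad = float(np.median(np.abs(sm - med)))
        # require foci to stand out from both the noise floor and the
        # global dynamic range; border peaks are smoothing artifacts
        thr = max(med + 8.0 * 1.4826 * mad,
                  med + 0.25 * (float(sm.max()) - med)) + 1e-12
        cand = peak_local_max(sm, min_distance=3, threshold_abs=thr,
                              exclude_border=3)
        if len(cand) >= 2:
            order = np.argsort(sm[cand[:, 0], cand[:, 1]])[::-1]
            cand = cand[order][:2]
            radius = max(2, int(round(2 * _CENTRIN_SMOOTH_UM / px)))
            foci = np.array(
                [_weighted_centroid(sm, tuple(rc), radius) for rc in cand]
            )
            cx, cy = foci.mean(axis=0)
            return float(cx), float(cy)
        if len(cand) == 1:
            # duplicated poles blurred into one spot: use the intensity-
            # weighted centroid of its half-maximum connected region
            from skimage.measure import label as sk_label

            peak = tuple(cand[0])
            half = med + 0.5 * (float(sm[peak]) - med)
            labels = sk_label(sm > half)
            region = labels == labels[peak]
            weights = np.where(region, sm - med, 0.0)
            total = weights.sum()
            ys, xs = np.mgrid[0:sm.shape[0], 0:sm.shape[1]]
            return (float((xs * weights).sum() / total),
                    float((ys * weights).sum() / total))
    if stack.has_channel("tubulin"):
        img = stack.plane("tubulin", frame).astype(np.float64)
        if img.max() > img.min():
            mask = img > threshold_otsu(img)
            if mask.any():
                weights = np.where(mask, img, 0.0)
                total = weights.sum()
                if total > 0:
                    ys, xs = np.mgrid[0:img.shape[0], 0:img.shape[1]]
                    return (float((xs * weights).sum() / total),
                            float((ys * weights).sum() / total))
    raise DetectionError(
        "no centrin foci and no usable tubulin signal; cannot locate the pole"
    )


def radial_profile(
    stack: ImageStack,
    roi: CircularRoi,
    bin_width_um: float = DEFAULT_BIN_WIDTH_UM,
    *,
    frame: int = 0,
    channel: str = "dna",
) -> RadialProfile:
    """Mean DNA intensity in annular bins around the ROI center.

    Bins cover ``(0, roi.radius_um]`` with width ``bin_width_um`` (the last
    bin is clipped to the ROI radius); a pixel at Euclidean distance ``r``
    from the center belongs to the bin whose interval contains it.  Empty
    bins are reported as NaN.
    """
    if not bin_width_um > 0:
        raise ValueError("bin_width_um must be positive")
    roi.validate_inside(stack)
    px = stack.pixel_size_um
    img = stack.plane(channel, frame).astype(np.float64)
    h, w = img.shape
    cx, cy = roi.center_xy

    n_bins = int(np.ceil(roi.radius_um / bin_width_um - 1e-12))
    edges = bin_width_um * np.arange(n_bins + 1, dtype=float)
    edges[-1] = roi.radius_um
    centers = 0.5 * (edges[:-1] + edges[1:])

    ys, xs = np.mgrid[0:h, 0:w]
    r = np.hypot(xs - cx, ys - cy) * px
    inside = (r > 0) & (r <= roi.radius_um)
    if not inside.any():
        raise GeometryError("no pixels fall inside the ROI")
    # bin index for r in (edges[i], edges[i+1]]
    idx = np.searchsorted(edges, r[inside], side="left") - 1
    idx = np.clip(idx, 0, n_bins - 1)
    sums = np.bincount(idx, weights=img[inside], minlength=n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return RadialProfile(radius_um=centers, mean_intensity=means)


def _parabolic_vertex(x: np.ndarray, y: np.ndarray) -> float:
    """Vertex abscissa of the parabola through three (possibly uneven) points."""
    (x0, x1, x2), (y0, y1, y2) = x, y
    d01 = (y1 - y0) / (x1 - x0)
    d12 = (y2 - y1) / (x2 - x1)
    a = (d12 - d01) / (x2 - x0)
    if a >= 0:
        return float(x1)
    v = 0.5 * (x0 + x1 - d01 / a)
    return float(np.clip(v, x0, x2))


def pef_distance(profile: RadialProfile) -> float:
    """Pole-to-rosette distance: radius of the profile's intensity maximum.

    The maximum over non-missing bins is refined by 3-point parabolic
    interpolation over its neighbouring bins; ties break toward the smaller
    radius.  Requires at least 3 non-missing bins.
    """
    keep = ~np.isnan(profile.mean_intensity)
    r = profile.radius_um[keep]
    v = profile.mean_intensity[keep]
    if v.size < 3:
        raise ProfileError("fewer than 3 non-missing radial bins")
    vmax = v.max()
    idx = np.flatnonzero(v == vmax)
    i = int(idx[0])  # ties -> smaller radius
    if idx.size > 1 or i == 0 or i == v.size - 1:
        return float(r[i])  # tied or boundary maxima are not refined
    return _parabolic_vertex(r[i - 1:i + 2], v[i - 1:i + 2])


def measure_pef(
    stack: ImageStack,
    cell_id: str = "cell",
    bin_width_um: float = DEFAULT_BIN_WIDTH_UM,
    roi_radius_um: float = DEFAULT_ROI_RADIUS_UM,
) -> PefMeasurement:
    """Full assay on one monopolar image: locate, profile, peak."""
    center = locate_monopole_center(stack)
    roi = CircularRoi(center_xy=center, radius_um=roi_radius_um)
    prof = radial_profile(stack, roi, bin_width_um)
    return PefMeasurement(
        cell_id=cell_id,
        center_xy=center,
        radii_um=prof.radius_um,
        mean_intensity=prof.mean_intensity,
        pef_distance_um=pef_distance(prof),
    )
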