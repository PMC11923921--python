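"""Aggregate (spheroid) morphometry: segmentation and Feret-diameter stats.

Aggregate size is the process-control variable of suspension expansion:
above ~300 um diameter, diffusion limits make spheroid cores necrotic, so
the summary carries a size-risk flag at that threshold and an
undersampling flag when fewer than 200 objects back the statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_fill_holes
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

__all__ = ["AggregateStats", "segment", "feret", "stats", "analyze_image"]

SIZE_RISK_THRESHOLD_UM = 300.0
MIN_SAMPLE_SIZE = 200


@dataclass
class AggregateStats:
    feret_um: np.ndarray
    count: int
    mean_um: float
    sd_um: float
    size_risk: bool  # mean or any single object above the necrosis threshold
    undersampled: bool  # fewer objects than the required sample size
    threshold_um: float = SIZE_RISK_THRESHOLD_UM
    min_n: int = MIN_SAMPLE_SIZE

    def to_dict(self) -> dict:
        return {
            "count": self.count,
            "mean_um": self.mean_um,
            "sd_um": self.sd_um,
            "size_risk": self.size_risk,
            "undersampled": self.undersampled,
            "threshold_um": self.threshold_um,
            "min_n": self.min_n,
        }


def segment(
    image: np.ndarray,
    pixel_size_um: float,
    min_diameter_um: float = 40.0,
    threshold: float | None = None,
) -> np.ndarray:
    """Label bright aggregates: Otsu threshold, hole filling, size filter.

    Objects with an equivalent-circle diameter below ``min_diameter_um``
    (debris) are removed.  Touching aggregates merge into one label — a
    documented limitation, no watershed splitting is attempted.  A blank
    image yields zero labels; a saturation warning is raised when a large
    fraction of pixels sits at the image maximum.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be positive")
    if np.ptp(image) == 0:
        return np.zeros(image.shape, dtype=int)
    if np.mean(image == image.max()) > 0.25:
        warnings.warn("image looks saturated; segmentation may be unreliable", stacklevel=2)
    thr = threshold_otsu(image) if threshold is None else threshold
    binary = binary_fill_holes(image > thr)
    labels = label(binary)
    min_area_px = np.pi * (min_diameter_um / pixel_size_um / 2.0) ** 2
    out = np.zeros_like(labels)
    next_id = 1
    for region in regionprops(labels):
        if region.area >= min_area_px:
            out[labels == region.label] = next_id
            next_id += 1
    return out


def feret(coords_px: np.ndarray, pixel_size_um: float) -> float:
    """Maximum Feret diameter of one object, micrometres.

    Maximum pairwise distance between the convex-hull vertices of the
    object's pixel-centre coordinates, plus a half-pixel caliper
    correction: centre coordinates systematically under-reach the
    continuous outline (each extreme pixel extends beyond its centre along
    the caliper direction), and half a pixel splits the difference between
    the pixel-centre and pixel-boundary conventions.
    """
    coords = np.asarray(coords_px, dtype=float)
    if coords.shape[0] < 3:
        raise ValueError("object has fewer than 3 pixels; Feret undefined")
    try:
        hull = ConvexHull(coords)
        pts = coords[hull.vertices]
    except QhullError as exc:  # collinear pixels
        raise ValueError(f"degenerate object (collinear pixels): {exc}") from exc
    return float((pdist(pts).max() + 0.5) * pixel_size_um)


def stats(
    ferets_um: np.ndarray | list[float],
    threshold_um: float = SIZE_RISK_THRESHOLD_UM,
    min_n: int = MIN_SAMPLE_SIZE,
) -> AggregateStats:
    """Summary statistics with the size-risk and undersampling flags."""
    f = np.asarray(ferets_um, dtype=float)
    count = int(f.size)
    mean = float(f.mean()) if count else float("nan")
    sd = float(f.std()) if count else float("nan")
    size_risk = bool(count and (mean > threshold_um or np.any(f > threshold_um)))
    return AggregateStats(
        feret_um=f,
        count=count,
        mean_um=mean,
        sd_um=sd,
        size_risk=size_risk,
        undersampled=count < min_n,
        threshold_um=threshold_um,
        min_n=min_n,
    )


def analyze_image(
    image: np.ndarray,
    pixel_size_um: float,
    min_diameter_um: float = 40.0,
    threshold: float | None = None,
    threshold_um: float = SIZE_RISK_THRESHOLD_UM,
    min_n: int = MIN_SAMPLE_SIZE,
) -> AggregateStats:
    """Segment an image and return Feret statistics in one call.

    Degenerate objects (too few or collinear pixels) are excluded with a
    warning rather than aborting the batch.
    """
    labels = segment(image, pixel_size_um, min_diameter_um=min_diameter_um, threshold=threshold)
    ferets = []
    for region in regionprops(labels):
        try:
            ferets.append(feret(region.coords, pixel_size_um))
        except ValueError as exc:
            warnings.warn(f"object {region.label} excluded: {exc}", stacklevel=2)
    return stats(ferets, threshold_um=threshold_um, min_n=min_n)
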