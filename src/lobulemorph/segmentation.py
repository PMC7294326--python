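"""Intensity-based segmentation of lobule sections.

Separates a grayscale section into vessel-lumen, hepatocyte-cytoplasm and
nucleus masks by histogram thresholding, then extracts per-object area and
centroid.  The default "auto" mode fits four intensity bands (nucleus <
hepatocyte < vessel lumen < background slide) with multi-level Otsu
thresholding; explicit bands can be supplied instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure
from skimage.filters import threshold_multiotsu

__all__ = ["ClassMasks", "SegmentedObject", "segment_classes", "extract_objects",
           "iou", "CLASS_ORDER"]

#: dark -> bright intensity ordering of the four bands
CLASS_ORDER = ("nucleus", "hepatocyte", "vessel", "background")


@dataclass
class ClassMasks:
    """Per-class binary masks over one image grid (mutually exclusive)."""

    vessel: np.ndarray
    hepatocyte: np.ndarray
    nucleus: np.ndarray
    scale: float  # µm per pixel

    def __post_init__(self) -> None:
        shapes = {self.vessel.shape, self.hepatocyte.shape, self.nucleus.shape}
        if len(shapes) != 1:
            raise ValueError("all class masks must share one shape")
        if np.any(self.vessel & self.hepatocyte) or np.any(self.vessel & self.nucleus) \
                or np.any(self.hepatocyte & self.nucleus):
            raise ValueError("class masks must be mutually exclusive")
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.vessel.shape

    def as_labels(self) -> np.ndarray:
        """Labelled image: 0 background, 1 vessel, 2 hepatocyte, 3 nucleus."""
        lab = np.zeros(self.shape, dtype=np.uint16)
        lab[self.vessel] = 1
        lab[self.hepatocyte] = 2
        lab[self.nucleus] = 3
        return lab


@dataclass
class SegmentedObject:
    """One connected component: class, area (µm²) and centroid (x, y) in µm."""

    id: int
    class_label: str
    area: float
    centroid: tuple[float, float]


def _bands_from_thresholds(image: np.ndarray, thresholds) -> dict[str, np.ndarray]:
    """Assign pixels to the three tissue classes from explicit bands."""
    items = sorted(thresholds.items(), key=lambda kv: kv[1][0])
    for (_, (lo1, hi1)), (_, (lo2, _)) in zip(items, items[1:]):
        if lo2 < hi1:
            raise ValueError("explicit intensity bands must not overlap")
    out = {}
    for cls, (lo, hi) in thresholds.items():
        if lo >= hi:
            raise ValueError(f"empty intensity band for class {cls!r}")
        out[cls] = (image >= lo) & (image < hi)
    return out


def segment_classes(image: np.ndarray, thresholds="auto",
                    min_area: float = 4.0, scale: float = 1.0) -> ClassMasks:
    """Threshold a grayscale section into vessel/hepatocyte/nucleus masks.

    Parameters
    ----------
    image : 2D float array
        Grayscale section; must be finite-valued.
    thresholds : "auto" or mapping class -> (lo, hi)
        "auto" fits four bands with multi-level Otsu and assigns them
        dark-to-bright as nucleus, hepatocyte, vessel, background.
    min_area : float
        Components smaller than this (µm²) are dropped as noise.
    scale : float
        µm per pixel.

    Holes inside vessel lumens are filled; each pixel belongs to at most one
    class.  A uniform image yields empty masks (not an error).
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("expected a single-channel 2D image")
    if not np.all(np.isfinite(image)):
        raise ValueError("image must be finite-valued")

    empty = np.zeros(image.shape, dtype=bool)
    if thresholds == "auto":
        uniq = np.unique(image)
        if uniq.size < 4:
            # degenerate histogram: nothing to separate
            return ClassMasks(vessel=empty.copy(), hepatocyte=empty.copy(),
                              nucleus=empty.copy(), scale=scale)
        if uniq.size == 4:
            # noise-free four-level image: cut exactly between the levels
            cuts = 0.5 * (uniq[:-1] + uniq[1:])
        else:
            cuts = threshold_multiotsu(image, classes=4)
        band_idx = np.digitize(image, cuts)
        masks = {cls: band_idx == i for i, cls in enumerate(CLASS_ORDER[:3])}
    else:
        masks = _bands_from_thresholds(image, thresholds)
        for cls in CLASS_ORDER[:3]:
            masks.setdefault(cls, empty.copy())

    min_px = int(np.ceil(min_area / scale ** 2))
    if min_px > 1:
        structure = np.ones((3, 3), dtype=int)
        for cls in list(masks):
            lab, n = ndimage.label(masks[cls], structure=structure)
            if n == 0:
                continue
            sizes = np.bincount(lab.ravel())
            keep = sizes >= min_px
            keep[0] = False
            masks[cls] = keep[lab]
    masks["vessel"] = ndimage.binary_fill_holes(masks["vessel"])
    # filling may reclaim pixels from other classes; keep masks exclusive
    masks["hepatocyte"] &= ~masks["vessel"]
    masks["nucleus"] &= ~masks["vessel"]
    return ClassMasks(vessel=masks["vessel"], hepatocyte=masks["hepatocyte"],
                      nucleus=masks["nucleus"], scale=scale)


def extract_objects(masks: ClassMasks) -> list[SegmentedObject]:
    """Connected components (8-connectivity) with area and centroid.

    Areas are pixel counts times scale²; centroids are unweighted pixel
    means in (x=col, y=row) µm, origin at the top-left pixel centre.
    """
    out: list[SegmentedObject] = []
    oid = 0
    for cls in ("vessel", "hepatocyte", "nucleus"):
        lab = measure.label(getattr(masks, cls), connectivity=2)
        for rp in measure.regionprops(lab):
            cy, cx = rp.centroid
            out.append(SegmentedObject(
                id=oid, class_label=cls,
                area=float(rp.area) * masks.scale ** 2,
                centroid=(cx * masks.scale, cy * masks.scale)))
            oid += 1
    return out


def iou(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Intersection-over-union of two binary masks (1.0 if both empty)."""
    union = np.count_nonzero(mask_a | mask_b)
    if union == 0:
        return 1.0
    return np.count_nonzero(mask_a & mask_b) / union
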