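"""Region-specific cell-density quantification for thymus-like sections.

A section is partitioned into four regions from a medullary-marker
channel: the medulla itself, the cortico-medullary junction (a fixed-width
band, default 100 um, surrounding the medulla), the subcapsular zone (the
same width inside the tissue perimeter) and the remaining cortex.  Where
the CMJ and subcapsular bands would overlap in thin tissue, the CMJ takes
precedence; masks are pairwise disjoint and together tile the tissue.
Marker-positive objects are detected by thresholding plus connected
components, assigned to regions by centroid, and reported as counts per
unit area.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import filters

from .core import ImageChannel

__all__ = [
    "RegionPartition",
    "medulla_mask",
    "tissue_mask",
    "partition_regions",
    "cell_density",
]

REGION_NAMES = ("medulla", "cmj", "subcapsular", "cortex")


@dataclass(frozen=True)
class RegionPartition:
    """Disjoint region masks tiling the tissue, with physical areas."""

    medulla: np.ndarray
    cmj: np.ndarray
    subcapsular: np.ndarray
    cortex: np.ndarray
    tissue: np.ndarray
    band_width_um: float
    pixel_size_um: float

    def mask(self, region: str) -> np.ndarray:
        if region not in REGION_NAMES:
            raise KeyError(f"unknown region {region!r}")
        return getattr(self, region)

    def area_um2(self, region: str) -> float:
        return float(self.mask(region).sum()) * self.pixel_size_um**2

    @property
    def areas_um2(self) -> dict[str, float]:
        return {r: self.area_um2(r) for r in REGION_NAMES}


def medulla_mask(
    channel: ImageChannel,
    smoothing_um: float = 20.0,
    threshold_method: str = "otsu",
    min_area_um2: float = 400.0,
) -> np.ndarray:
    """Binary medulla mask from a medullary-marker channel.

    The channel is Gaussian-smoothed (``smoothing_um``), thresholded
    (Otsu by default, invariant to intensity rescaling), and specks
    below ``min_area_um2`` are removed.  An all-background channel gives
    an empty mask with a warning, not an error.
    """
    img = channel.intensities
    px = channel.pixel_size_um
    smoothed = ndimage.gaussian_filter(img, smoothing_um / px)
    if np.ptp(smoothed) == 0:
        warnings.warn("channel has no contrast; returning an empty medulla mask")
        return np.zeros(img.shape, dtype=bool)
    if threshold_method == "otsu":
        thr = filters.threshold_otsu(smoothed)
    elif threshold_method == "mean":
        thr = smoothed.mean()
    else:
        raise ValueError(f"unknown threshold_method {threshold_method!r}")
    mask = smoothed > thr
    min_px = int(np.ceil(min_area_um2 / px**2))
    if min_px > 1 and mask.any():
        labels, n_obj = ndimage.label(mask)
        sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n_obj + 1))
        mask = np.isin(labels, np.flatnonzero(sizes >= min_px) + 1)
    return mask


def tissue_mask(channels: list[ImageChannel]) -> np.ndarray:
    """Whole-tissue mask: Otsu threshold of the summed channels, hole-filled."""
    total = np.sum([c.intensities for c in channels], axis=0)
    if np.ptp(total) == 0:
        warnings.warn("channels have no contrast; returning an empty tissue mask")
        return np.zeros(total.shape, dtype=bool)
    mask = total > filters.threshold_otsu(total)
    return ndimage.binary_fill_holes(mask)


def partition_regions(
    medulla: np.ndarray,
    tissue: np.ndarray,
    pixel_size_um: float,
    band_width_um: float = 100.0,
) -> RegionPartition:
    """Partition tissue into medulla, CMJ, subcapsular band and cortex.

    The CMJ is the band within ``band_width_um`` outside the medulla; the
    subcapsular zone is the band within ``band_width_um`` inside the
    tissue perimeter, minus any CMJ overlap (CMJ precedence); the cortex
    is everything else in the tissue.
    """
    medulla = np.asarray(medulla, dtype=bool)
    tissue = np.asarray(tissue, dtype=bool)
    if medulla.shape != tissue.shape:
        raise ValueError("medulla and tissue masks must share a shape")
    if np.any(medulla & ~tissue):
        raise ValueError("medulla mask must lie inside the tissue mask")
    band_px = band_width_um / pixel_size_um

    if medulla.any():
        dist_to_medulla = ndimage.distance_transform_edt(~medulla)
        cmj = tissue & ~medulla & (dist_to_medulla <= band_px)
    else:
        cmj = np.zeros_like(tissue)
    depth = ndimage.distance_transform_edt(tissue)
    subcap = tissue & (depth <= band_px) & ~medulla & ~cmj
    cortex = tissue & ~medulla & ~cmj & ~subcap
    return RegionPartition(
        medulla=medulla & tissue,
        cmj=cmj,
        subcapsular=subcap,
        cortex=cortex,
        tissue=tissue,
        band_width_um=band_width_um,
        pixel_size_um=pixel_size_um,
    )


def cell_density(
    channel: ImageChannel,
    partition: RegionPartition,
    threshold: float | None = None,
    min_area_um2: float = 10.0,
) -> dict[str, dict[str, float | None]]:
    """Marker-positive object density per region.

    Objects are detected by thresholding (Otsu when ``threshold`` is
    None) and 8-connected components with a minimum area; each object is
    assigned to the region containing its centroid.  Returns, per region,
    ``{"count", "area_um2", "density_per_um2"}``; a zero-area region
    reports a missing (None) density rather than dividing by zero.
    """
    img = channel.intensities
    px = channel.pixel_size_um
    if threshold is None:
        if np.ptp(img) == 0:
            threshold = np.inf
        else:
            threshold = filters.threshold_otsu(img)
    binary = img > threshold
    min_px = max(int(np.ceil(min_area_um2 / px**2)), 1)
    labels, n_obj = ndimage.label(binary, structure=np.ones((3, 3), dtype=int))
    counts = {r: 0 for r in REGION_NAMES}
    if n_obj:
        sizes = ndimage.sum_labels(binary, labels, index=np.arange(1, n_obj + 1))
        keep = np.flatnonzero(sizes >= min_px) + 1
        if keep.size:
            centroids = ndimage.center_of_mass(binary, labels, index=keep)
            for cy, cx in centroids:
                iy, ix = int(round(cy)), int(round(cx))
                for region in REGION_NAMES:
                    if partition.mask(region)[iy, ix]:
                        counts[region] += 1
                        break
    out: dict[str, dict[str, float | None]] = {}
    for region in REGION_NAMES:
        area = partition.area_um2(region)
        out[region] = {
            "count": counts[region],
            "area_um2": area,
            "density_per_um2": counts[region] / area if area > 0 else None,
        }
    return out
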