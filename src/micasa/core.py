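"""Core containers shared across the analysis pipeline.

An analysis operates on *conditions*: sets of two-channel fluorescence
images of tissue sections, one pair of channels per section.  Images within
a condition may differ in pixel dimensions (sections are cut at different
axial levels), but every channel carries the same physical pixel size in
micrometres.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ImageChannel", "ConditionDataset", "AnalysisConfig"]

#: Minimum image side length, in pixels, accepted anywhere in the pipeline.
MIN_IMAGE_DIM = 16


@dataclass(frozen=True)
class ImageChannel:
    """One 2D grayscale intensity grid with a physical pixel size.

    Parameters
    ----------
    intensities
        Real-valued ``(rows, cols)`` array of fluorescence intensities.
    pixel_size_um
        Physical size of one pixel in micrometres.
    """

    intensities: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities, dtype=float)
        if arr.ndim != 2:
            raise ValueError(f"intensities must be 2D, got shape {arr.shape}")
        if arr.shape[0] < MIN_IMAGE_DIM or arr.shape[1] < MIN_IMAGE_DIM:
            raise ValueError(
                f"image must be at least {MIN_IMAGE_DIM}x{MIN_IMAGE_DIM} pixels, "
                f"got {arr.shape}"
            )
        if not np.all(np.isfinite(arr)):
            raise ValueError("intensities must be finite")
        if not (self.pixel_size_um > 0):
            raise ValueError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")
        object.__setattr__(self, "intensities", arr)

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensities.shape

    @property
    def extent_um(self) -> float:
        """Physical length of the longest image side in micrometres."""
        return max(self.shape) * self.pixel_size_um


@dataclass(frozen=True)
class ConditionDataset:
    """N paired-channel images for one biological condition.

    ``pairs[i]`` holds the two marker channels of section ``i``; within a
    pair the channels must share shape and pixel size, but shapes may
    differ between pairs.
    """

    label: str
    pairs: tuple[tuple[ImageChannel, ImageChannel], ...]

    def __post_init__(self) -> None:
        pairs = tuple(tuple(p) for p in self.pairs)
        if len(pairs) == 0:
            raise ValueError("a condition must contain at least one image pair")
        for k, (a, b) in enumerate(pairs):
            if a.shape != b.shape:
                raise ValueError(
                    f"pair {k}: channel shapes differ ({a.shape} vs {b.shape})"
                )
            if a.pixel_size_um != b.pixel_size_um:
                raise ValueError(f"pair {k}: pixel sizes differ")
        object.__setattr__(self, "pairs", pairs)

    @property
    def n_images(self) -> int:
        return len(self.pairs)

    @property
    def pixel_size_um(self) -> float:
        return self.pairs[0][0].pixel_size_um

    @property
    def shapes(self) -> list[tuple[int, int]]:
        return [a.shape for a, _ in self.pairs]


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable parameters of one analysis run.

    Attributes
    ----------
    bandwidth_product
        Per-dimension time-bandwidth parameter ``NW`` of the Slepian taper
        family; the spectral smoothing half-bandwidth is ``NW / n`` cycles
        per pixel for an ``n``-pixel side.
    n_tapers
        Number ``M`` of 2D tapers retained.  With N images this gives
        ``NM`` quasi-independent spectral estimates, hence NM degrees of
        freedom for the jackknife.
    confidence_level
        Two-sided confidence level for all intervals (default 0.99).
    radial_grid_size
        Number of log-spaced radial frequency bins.
    pixel_size_um
        Default pixel calibration, used when images do not carry one.
    jackknife_unit
        Resampling unit for confidence intervals: ``"image"`` deletes one
        image's whole M-taper block at a time (default — robust to the
        across-taper correlation that circular averaging introduces, see
        the jackknife module), ``"estimate"`` deletes single (image,
        taper) estimates, treating all NM as exchangeable.  With a single
        image the estimate unit is the only option and is used
        automatically.
    """

    bandwidth_product: float = 2.0
    n_tapers: int = 7
    confidence_level: float = 0.99
    radial_grid_size: int = 60
    pixel_size_um: float = 2.0
    jackknife_unit: str = "image"

    def __post_init__(self) -> None:
        if self.n_tapers < 2:
            raise ValueError(
                "n_tapers must be >= 2: coherence from a single tapered "
                "estimate is identically 1 and carries no information"
            )
        if not (0.0 < self.confidence_level < 1.0):
            raise ValueError("confidence_level must lie strictly in (0, 1)")
        if self.bandwidth_product < 1.0:
            raise ValueError("bandwidth_product must be >= 1")
        if self.radial_grid_size < 8:
            raise ValueError("radial_grid_size must be >= 8")
        if not (self.pixel_size_um > 0):
            raise ValueError("pixel_size_um must be > 0")
        if self.jackknife_unit not in ("image", "estimate"):
            raise ValueError(
                f"jackknife_unit must be 'image' or 'estimate', "
                f"got {self.jackknife_unit!r}"
            )
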