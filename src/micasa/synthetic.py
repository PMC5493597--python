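"""Seeded generators of two-channel synthetic images with known structure.

Three pattern families stand in for stained tissue sections:

``white_noise``
    Independent Gaussian pixels — flat expected power spectrum; the null
    field for confidence-interval calibration.
``blob_lattice``
    Gaussian-profile blobs on a square lattice of known spacing —
    emulates cells clustered at a characteristic separation, so the
    radial log-spectrum must peak at frequency ``1/spacing``.
``compartments``
    A smoothed Gaussian random field thresholded at a quantile; channel A
    is the intensity inside the resulting mask, channel B outside —
    emulating anticorrelated compartment markers (cortex/medulla-like
    organization) with a controllable compartment scale and
    replicate-to-replicate variability of that scale.

Every generator is a pure function of its spec, including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np
from scipy import ndimage

from .core import ConditionDataset, ImageChannel

__all__ = [
    "GeneratorSpec",
    "make_white_noise",
    "make_blob_lattice",
    "make_compartment_pair",
    "make_channel_pair",
    "make_condition",
]

PATTERNS = ("white_noise", "blob_lattice", "compartments")


@dataclass(frozen=True)
class GeneratorSpec:
    """Full description of one synthetic image draw.

    ``pattern_params`` keys by pattern:

    * white_noise: ``sigma`` (>= 0)
    * blob_lattice: ``spacing_um``, ``blob_radius_um``, ``jitter_um``
    * compartments: ``compartment_scale_um``, ``fill_fraction`` in (0,1),
      ``replicate_variability`` in [0,1]
    """

    pattern: str
    shape: tuple[int, int]
    pixel_size_um: float
    pattern_params: dict[str, Any] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pattern not in PATTERNS:
            raise ValueError(f"unknown pattern {self.pattern!r}; one of {PATTERNS}")
        rows, cols = self.shape
        if rows < 16 or cols < 16:
            raise ValueError(f"shape dims must be >= 16, got {self.shape}")
        if not (self.pixel_size_um > 0):
            raise ValueError("pixel_size_um must be > 0")
        p = self.pattern_params
        for key in ("spacing_um", "blob_radius_um", "compartment_scale_um"):
            if key in p and not (p[key] > 0):
                raise ValueError(f"{key} must be > 0")
        if "fill_fraction" in p and not (0.0 < p["fill_fraction"] < 1.0):
            raise ValueError("fill_fraction must lie in (0, 1)")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def make_white_noise(spec: GeneratorSpec) -> ImageChannel:
    """Independent N(0, sigma^2) pixels; ``sigma=0`` gives the zero image."""
    if spec.pattern != "white_noise":
        raise ValueError(f"spec.pattern must be 'white_noise', got {spec.pattern!r}")
    sigma = float(spec.pattern_params.get("sigma", 1.0))
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    values = spec.rng().normal(0.0, 1.0, spec.shape) * sigma
    return ImageChannel(values, spec.pixel_size_um)


def _lattice_centres(
    n: int, spacing_px: float
) -> np.ndarray:
    """1D lattice coordinates, offset half a period from the image edge."""
    return np.arange(spacing_px / 2.0, n, spacing_px)


def make_blob_lattice(spec: GeneratorSpec) -> ImageChannel:
    """Gaussian blobs on a square lattice of the stated physical spacing.

    Blob profile is a Gaussian of width ``blob_radius_um`` truncated at 3
    radii (smooth spectrum, no ringing); ``jitter_um`` adds independent
    Gaussian displacement to each blob centre.
    """
    if spec.pattern != "blob_lattice":
        raise ValueError(f"spec.pattern must be 'blob_lattice', got {spec.pattern!r}")
    p = spec.pattern_params
    px = spec.pixel_size_um
    spacing_um = float(p["spacing_um"])
    radius_um = float(p["blob_radius_um"])
    jitter_um = float(p.get("jitter_um", 0.0))
    if spacing_um < 2.0 * px:
        raise ValueError(
            f"spacing_um={spacing_um} is below the Nyquist limit of 2 pixels "
            f"({2 * px} um at {px} um/pixel): the lattice cannot be resolved"
        )
    if not (radius_um < spacing_um / 2.0):
        raise ValueError("blob_radius_um must be < spacing_um / 2")

    rows, cols = spec.shape
    spacing_px = spacing_um / px
    radius_px = radius_um / px
    rng = spec.rng()
    ys = _lattice_centres(rows, spacing_px)
    xs = _lattice_centres(cols, spacing_px)
    img = np.zeros(spec.shape, dtype=float)
    half = int(np.ceil(3.0 * radius_px))
    for cy in ys:
        for cx in xs:
            if jitter_um > 0:
                dy, dx = rng.normal(0.0, jitter_um / px, size=2)
            else:
                dy = dx = 0.0
            y0, x0 = cy + dy, cx + dx
            iy0, ix0 = int(round(y0)), int(round(x0))
            ylo, yhi = max(iy0 - half, 0), min(iy0 + half + 1, rows)
            xlo, xhi = max(ix0 - half, 0), min(ix0 + half + 1, cols)
            if ylo >= yhi or xlo >= xhi:
                continue
            yy = np.arange(ylo, yhi)[:, None] - y0
            xx = np.arange(xlo, xhi)[None, :] - x0
            r2 = yy**2 + xx**2
            patch = np.exp(-0.5 * r2 / radius_px**2)
            patch[r2 > (3.0 * radius_px) ** 2] = 0.0
            img[ylo:yhi, xlo:xhi] += patch
    return ImageChannel(img, px)


def compartment_scale_factor(rng: np.random.Generator, replicate_variability: float) -> float:
    """Per-replicate multiplicative rescaling of the compartment scale.

    Log-normal with log-sd equal to ``replicate_variability``; the spread
    grows with the parameter and a value of 0 returns exactly 1 for every
    seed, so all replicates share one scale.
    """
    if not (0.0 <= replicate_variability <= 1.0):
        raise ValueError("replicate_variability must lie in [0, 1]")
    if replicate_variability == 0.0:
        return 1.0
    return float(np.exp(rng.normal(0.0, replicate_variability)))


def make_compartment_pair(spec: GeneratorSpec) -> tuple[ImageChannel, ImageChannel]:
    """Anticorrelated compartment channels from one thresholded random field.

    A Gaussian white-noise field is convolved with a Gaussian kernel of
    width ``compartment_scale_um / 2`` (so compartments have a typical
    diameter near the stated scale) and thresholded at the quantile that
    leaves ``fill_fraction`` of pixels above it.  Channel A is bright
    inside the mask (a stain-like baseline plus the normalized field
    excess), channel B bright outside it; their supports are disjoint,
    emulating markers of two mutually exclusive compartments.  Each
    channel is modulated by its own independent pixel-scale speckle
    (cells of the two marked populations are distinct), so the channels
    share structure only at compartment scales: the coherence peaks near
    ``1 / compartment_scale_um`` and falls off at cellular scales.
    """
    if spec.pattern != "compartments":
        raise ValueError(f"spec.pattern must be 'compartments', got {spec.pattern!r}")
    p = spec.pattern_params
    px = spec.pixel_size_um
    scale_um = float(p["compartment_scale_um"])
    fill = float(p.get("fill_fraction", 0.5))
    rep_var = float(p.get("replicate_variability", 0.0))
    rows, cols = spec.shape
    extent_um = max(rows, cols) * px
    if scale_um >= extent_um:
        raise ValueError(
            f"compartment_scale_um={scale_um} must be smaller than the image "
            f"extent ({extent_um} um)"
        )
    rng = spec.rng()
    # scale factor drawn first so the field noise stream is unaffected by it
    scale_um = scale_um * compartment_scale_factor(rng, rep_var)
    sigma_px = scale_um / (2.0 * px)
    noise = rng.normal(0.0, 1.0, spec.shape)
    fld = ndimage.gaussian_filter(noise, sigma_px, mode="wrap")
    threshold = float(np.quantile(fld, 1.0 - fill))
    inside = fld > threshold
    spread = float(fld.std()) or 1.0
    # gamma speckle: mean 1, cv 0.5, independent between channels
    speckle_a = rng.gamma(4.0, 0.25, spec.shape)
    speckle_b = rng.gamma(4.0, 0.25, spec.shape)
    chan_a = np.where(inside, 1.0 + (fld - threshold) / spread, 0.0) * speckle_a
    chan_b = np.where(~inside, 1.0 + (threshold - fld) / spread, 0.0) * speckle_b
    return ImageChannel(chan_a, px), ImageChannel(chan_b, px)


def make_channel_pair(spec: GeneratorSpec) -> tuple[ImageChannel, ImageChannel]:
    """One two-channel image from a spec, for any pattern.

    ``compartments`` yields the intrinsically paired channels; the
    single-channel patterns yield two independent draws (seed and
    seed-derived companion).
    """
    if spec.pattern == "compartments":
        return make_compartment_pair(spec)
    maker = make_white_noise if spec.pattern == "white_noise" else make_blob_lattice
    child_a, child_b = np.random.SeedSequence(spec.seed).spawn(2)
    a = maker(replace(spec, seed=int(child_a.generate_state(1)[0])))
    b = maker(replace(spec, seed=int(child_b.generate_state(1)[0])))
    return a, b


def make_condition(
    n_images: int, spec: GeneratorSpec, base_seed: int, label: str | None = None
) -> ConditionDataset:
    """N independent image pairs with seeds split deterministically.

    Replicate seeds derive from ``base_seed`` through NumPy seed-sequence
    spawning, so datasets are reproducible element-wise: replicate ``i``
    is identical across calls with the same ``base_seed``.
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    children = np.random.SeedSequence(base_seed).spawn(n_images)
    pairs = []
    for child in children:
        rep_spec = replace(spec, seed=int(child.generate_state(1)[0]))
        pairs.append(make_channel_pair(rep_spec))
    return ConditionDataset(
        label=label if label is not None else f"{spec.pattern}[{base_seed}]",
        pairs=tuple(pairs),
    )
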