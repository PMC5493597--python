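"""Circular averaging of 2D frequency fields onto radial grids.

A 2D frequency-domain field is reduced to a 1D function of radial spatial
frequency ``f = sqrt(fx^2 + fy^2)`` (cycles/um) by averaging over all
angles within log-spaced radial bins.  Each estimate is averaged on its
image's native FFT grid first; curves from images of different sizes are
then linearly interpolated in log-frequency onto a shared grid spanning
the intersection of their ranges.  Large values of a log-spectrum at
frequency ``f`` indicate structure with a characteristic separation of
``1/f`` micrometres.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np

from .spectra import Spectrum2D

__all__ = [
    "RadialGrid",
    "RadialFunction",
    "native_radial_grid",
    "circular_average",
    "interpolate_to_common",
    "length_scale_of",
]


@dataclass(frozen=True)
class RadialGrid:
    """Log-spaced radial spatial-frequency bins in cycles/um.

    ``frequencies`` are the bin representative points (geometric centres);
    ``bin_edges`` has one more element and spans fundamental to Nyquist.
    """

    frequencies: np.ndarray
    bin_edges: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        e = np.asarray(self.bin_edges, dtype=float)
        if f.ndim != 1 or e.ndim != 1 or e.size != f.size + 1:
            raise ValueError("bin_edges must have len(frequencies)+1 entries")
        if not np.all(np.diff(e) > 0) or not np.all(np.diff(f) > 0):
            raise ValueError("grid must be strictly increasing")
        if f[0] <= 0:
            raise ValueError("frequencies must be positive")
        object.__setattr__(self, "frequencies", f)
        object.__setattr__(self, "bin_edges", e)

    @property
    def n_bins(self) -> int:
        return self.frequencies.size

    @property
    def length_scales_um(self) -> np.ndarray:
        return 1.0 / self.frequencies

    def same_as(self, other: "RadialGrid") -> bool:
        return self.n_bins == other.n_bins and np.array_equal(
            self.bin_edges, other.bin_edges
        )


@dataclass(frozen=True)
class RadialFunction:
    """Values on a radial grid with a missing-bin mask (True = missing)."""

    grid: RadialGrid
    values: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        m = np.asarray(self.mask, dtype=bool)
        if v.shape != (self.grid.n_bins,) or m.shape != v.shape:
            raise ValueError("values/mask must match the grid length")
        if not np.all(np.isfinite(v[~m])):
            raise ValueError("unmasked values must be finite")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "mask", m)


def length_scale_of(frequency: float | np.ndarray) -> float | np.ndarray:
    """Characteristic length scale ``1/f`` in um for frequency in cycles/um."""
    f = np.asarray(frequency, dtype=float)
    if np.any(f <= 0):
        raise ValueError("frequency must be positive")
    out = 1.0 / f
    return float(out) if out.ndim == 0 else out


def _grid_from_range(f_min: float, f_max: float, n_bins: int) -> RadialGrid:
    edges = np.geomspace(f_min, f_max, n_bins + 1)
    centres = np.sqrt(edges[:-1] * edges[1:])
    return RadialGrid(frequencies=centres, bin_edges=edges)


def native_radial_grid(
    shape: tuple[int, int], pixel_size_um: float, n_bins: int = 60
) -> RadialGrid:
    """Log-spaced radial grid from an image's fundamental to its Nyquist.

    The fundamental is ``1 / (longest side in um)``; the Nyquist is
    ``1 / (2 * pixel_size_um)``.
    """
    if n_bins < 8:
        raise ValueError("n_bins must be >= 8")
    rows, cols = shape
    f_min = 1.0 / (max(rows, cols) * pixel_size_um)
    f_max = 1.0 / (2.0 * pixel_size_um)
    return _grid_from_range(f_min, f_max, n_bins)


@lru_cache(maxsize=64)
def _binner(
    shape: tuple[int, int],
    pixel_size_um: float,
    edges_key: tuple[float, ...],
    exclude_below: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Flat bin index (-1 = outside) and per-bin counts for one 2D FFT grid.

    ``exclude_below`` drops frequencies with radius <= that value (used to
    remove the DC concentration lobe of the tapers); DC itself is always
    excluded.
    """
    edges = np.asarray(edges_key)
    rows, cols = shape
    fy = np.fft.fftfreq(rows, d=pixel_size_um)
    fx = np.fft.fftfreq(cols, d=pixel_size_um)
    r = np.hypot(fy[:, None], fx[None, :]).ravel()
    idx = np.searchsorted(edges, r, side="right") - 1
    # close the top bin at the Nyquist edge
    idx[r == edges[-1]] = edges.size - 2
    idx[(r < edges[0]) | (r > edges[-1]) | (r <= exclude_below)] = -1
    counts = np.bincount(idx[idx >= 0], minlength=edges.size - 1)
    return idx, counts


def circular_average(
    field: Spectrum2D, grid: RadialGrid, exclude_below: float = 0.0
) -> RadialFunction:
    """Mean of a 2D frequency field over all angles, per radial bin.

    The DC bin never contributes, nor do frequencies with radius at or
    below ``exclude_below`` (cycles/um); radial bins left with no 2D
    frequency are masked.
    """
    values = np.asarray(field.values)
    idx, counts = _binner(
        values.shape, field.pixel_size_um, tuple(grid.bin_edges), exclude_below
    )
    flat = values.ravel()
    keep = idx >= 0
    sums = np.bincount(idx[keep], weights=flat[keep], minlength=grid.n_bins)
    mask = counts == 0
    with np.errstate(invalid="ignore"):
        means = sums / counts
    means[mask] = 0.0
    return RadialFunction(grid=grid, values=means, mask=mask)


def interpolate_to_common(
    fns: Sequence[RadialFunction], n_bins: int | None = None
) -> list[RadialFunction]:
    """Interpolate radial functions onto one shared log-frequency grid.

    The shared grid spans the intersection of the input frequency ranges;
    values are linearly interpolated in log-frequency, and bins outside a
    function's own (unmasked) range are masked, never extrapolated.  When
    every input already lives on one identical grid the functions are
    returned unchanged.
    """
    if len(fns) == 0:
        raise ValueError("need at least one radial function")
    first = fns[0].grid
    if all(f.grid.same_as(first) for f in fns):
        return list(fns)
    f_min = max(f.grid.bin_edges[0] for f in fns)
    f_max = min(f.grid.bin_edges[-1] for f in fns)
    if not (f_min < f_max):
        raise ValueError(
            "radial grids have no overlapping frequency range "
            f"(intersection [{f_min:g}, {f_max:g}] cycles/um is empty)"
        )
    if n_bins is None:
        n_bins = min(f.grid.n_bins for f in fns)
    shared = _grid_from_range(f_min, f_max, n_bins)
    return [interpolate_onto(f, shared) for f in fns]


def interpolate_onto(fn: RadialFunction, target: RadialGrid) -> RadialFunction:
    """Linear interpolation in log-frequency onto ``target``; no extrapolation."""
    if fn.grid.same_as(target):
        return RadialFunction(grid=target, values=fn.values, mask=fn.mask)
    good = ~fn.mask
    if good.sum() < 2:
        raise ValueError("cannot interpolate a function with < 2 known bins")
    src_x = np.log(fn.grid.frequencies[good])
    src_y = fn.values[good]
    tgt_x = np.log(target.frequencies)
    vals = np.interp(tgt_x, src_x, src_y)
    mask = (tgt_x < src_x[0]) | (tgt_x > src_x[-1])
    vals[mask] = 0.0
    return RadialFunction(grid=target, values=vals, mask=mask)
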