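"""Tapered 2D Fourier coefficients, per-estimate log-spectra, pooled coherence.

Each image is mean-subtracted, multiplied by each of the M tapers and
Fourier-transformed (unnormalized forward DFT).  With N images this yields
NM tapered coefficient grids per channel — the quasi-independent spectral
estimates everything downstream is built from:

* the log-spectrum of a channel is ``log |J|^2`` *per estimate* (the NM
  log-spectra are averaged and jackknifed later, after circular
  averaging);
* the coherence pools *all* NM estimates before normalizing,

      C(k) = |sum_i Ja_i(k) conj(Jb_i(k))|
             / sqrt(sum_i |Ja_i|^2 * sum_i |Jb_i|^2),

  which is required algebraically: from a single tapered estimate the
  normalized cross-spectrum is identically 1.  The variance-stabilizing
  arc-hyperbolic-tangent is applied to C, capped just below 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .core import AnalysisConfig, ConditionDataset
from .tapers import cached_taper_set

__all__ = [
    "SpectrumKind",
    "Spectrum2D",
    "TaperedCoefficients",
    "tapered_coefficients",
    "log_spectrum_2d",
    "pooled_coherence",
]

#: additive floor inside the log; only exactly-zero power bins feel it
LOG_FLOOR = float(np.finfo(float).tiny)

#: coherence magnitude cap before atanh (atanh(1) diverges)
COHERENCE_CAP = 1.0 - 1e-6


class SpectrumKind(str, Enum):
    LOG_POWER = "log_power"
    CROSS_COMPLEX = "cross_complex"
    ATANH_COHERENCE = "atanh_coherence"


@dataclass(frozen=True)
class Spectrum2D:
    """A field on the native 2D FFT frequency grid of one image shape."""

    values: np.ndarray
    kind: SpectrumKind
    pixel_size_um: float


@dataclass(frozen=True)
class TaperedCoefficients:
    """Tapered Fourier coefficients of every (image, taper, channel).

    ``coeffs_a[i]`` and ``coeffs_b[i]`` are ``(M, rows_i, cols_i)`` complex
    arrays for image ``i``; shapes may differ between images.
    """

    coeffs_a: tuple[np.ndarray, ...]
    coeffs_b: tuple[np.ndarray, ...]
    pixel_size_um: float
    M: int

    @property
    def N(self) -> int:
        return len(self.coeffs_a)

    @property
    def NM(self) -> int:
        return self.N * self.M

    @property
    def image_shapes(self) -> list[tuple[int, int]]:
        return [c.shape[1:] for c in self.coeffs_a]

    def estimate_index(self, i: int, m: int) -> int:
        """Flat index of taper ``m`` of image ``i`` in estimate order."""
        return i * self.M + m


def tapered_coefficients(
    dataset: ConditionDataset, config: AnalysisConfig
) -> TaperedCoefficients:
    """Mean-subtract, taper and Fourier-transform every channel of a condition."""
    coeffs_a: list[np.ndarray] = []
    coeffs_b: list[np.ndarray] = []
    for chan_a, chan_b in dataset.pairs:
        rows, cols = chan_a.shape
        tset = cached_taper_set(rows, cols, config.bandwidth_product, config.n_tapers)
        for chan, out in ((chan_a, coeffs_a), (chan_b, coeffs_b)):
            img = chan.intensities - chan.intensities.mean()
            out.append(np.fft.fft2(tset.tapers * img[None, :, :], axes=(-2, -1)))
    return TaperedCoefficients(
        coeffs_a=tuple(coeffs_a),
        coeffs_b=tuple(coeffs_b),
        pixel_size_um=dataset.pixel_size_um,
        M=config.n_tapers,
    )


def log_spectrum_2d(
    tc: TaperedCoefficients, channel: str
) -> list[list[Spectrum2D]]:
    """Per-estimate 2D log-spectra ``log(|J|^2 + eps)`` (natural log).

    Returns one list per image, each holding the M per-taper spectra.
    ``channel`` is ``"a"`` or ``"b"``.
    """
    stacks = _channel_stacks(tc, channel)
    out: list[list[Spectrum2D]] = []
    for stack in stacks:
        power = np.abs(stack) ** 2
        logs = np.log(power + LOG_FLOOR)
        out.append(
            [
                Spectrum2D(logs[m], SpectrumKind.LOG_POWER, tc.pixel_size_um)
                for m in range(stack.shape[0])
            ]
        )
    return out


def _channel_stacks(tc: TaperedCoefficients, channel: str) -> tuple[np.ndarray, ...]:
    if channel == "a":
        return tc.coeffs_a
    if channel == "b":
        return tc.coeffs_b
    raise ValueError(f"channel must be 'a' or 'b', got {channel!r}")


def coherence_terms(tc: TaperedCoefficients) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-estimate cross- and auto-power terms on one shared 2D grid.

    Requires every image in ``tc`` to share one shape.  Returns
    ``(cross, power_a, power_b)``, each ``(NM, rows, cols)``, whose sums
    over the first axis form the pooled coherence.
    """
    shapes = set(tc.image_shapes)
    if len(shapes) != 1:
        raise ValueError(
            "coherence pooling on a single 2D grid requires equal image "
            f"shapes; got {sorted(shapes)} — pool per shape group instead"
        )
    ja = np.concatenate(tc.coeffs_a, axis=0)
    jb = np.concatenate(tc.coeffs_b, axis=0)
    return ja * np.conj(jb), np.abs(ja) ** 2, np.abs(jb) ** 2


def coherence_from_sums(
    cross_sum: np.ndarray, pa_sum: np.ndarray, pb_sum: np.ndarray
) -> np.ndarray:
    """atanh coherence magnitude from pooled numerator/denominator sums."""
    denom = np.sqrt(pa_sum * pb_sum)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.abs(cross_sum) / denom
    c = np.nan_to_num(c, nan=0.0)  # 0/0 bins (e.g. DC of mean-subtracted data)
    return np.arctanh(np.minimum(c, COHERENCE_CAP))


def pooled_coherence(
    tc: TaperedCoefficients, leave_out: int | None = None
) -> Spectrum2D:
    """atanh of the magnitude coherence pooled over all NM estimates.

    ``leave_out``, if given, is the flat estimate index (image ``i``, taper
    ``m`` at ``i*M + m``) excluded from the pooled sums — the delete-one
    recomputation the jackknife needs.
    """
    cross, pa, pb = coherence_terms(tc)
    n = cross.shape[0]
    keep = np.ones(n, dtype=bool)
    if leave_out is not None:
        if not (0 <= leave_out < n):
            raise IndexError(f"leave_out must be in [0, {n}), got {leave_out}")
        keep[leave_out] = False
    if keep.sum() < 2:
        raise ValueError(
            "pooled coherence needs at least 2 retained estimates; a single "
            "tapered estimate has coherence identically 1"
        )
    values = coherence_from_sums(
        cross[keep].sum(axis=0), pa[keep].sum(axis=0), pb[keep].sum(axis=0)
    )
    return Spectrum2D(values, SpectrumKind.ATANH_COHERENCE, tc.pixel_size_um)
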