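"""Jackknife confidence intervals, variance curves and condition comparison.

With N images and M tapers the pipeline produces NM quasi-independent
spectral estimates per channel.  Confidence intervals come from a
delete-one jackknife with a t-critical value, variance curves from a
chi-square interval on the across-curve sample variance.

The deletion unit is configurable.  The default deletes one *image* (its
whole M-taper block) at a time: circular averaging mixes frequencies
within the taper bandwidth, which correlates the M per-taper curves of
one image, and treating them as exchangeable units makes the intervals
anticonservative (see docs/methods.md for the measured effect).  The
``"estimate"`` unit — one (image, taper) curve, all NM exchangeable — is
retained as an option, and is the automatic fallback when N = 1, where
the multitaper construction is what makes confidence intervals possible
at all.

Frequencies whose radius lies within the taper concentration bandwidth
of DC are excluded from every curve: below that radius the tapered
transform cannot distinguish structure from the image mean.

Two conditions are compared by confidence-interval overlap: where the
bands at level ``1 - alpha`` are disjoint over a frequency band, the
conditions differ there with at least that confidence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .core import AnalysisConfig, ConditionDataset
from .radial import (
    RadialFunction,
    RadialGrid,
    _grid_from_range,
    circular_average,
    interpolate_onto,
    native_radial_grid,
)
from .spectra import (
    LOG_FLOOR,
    Spectrum2D,
    SpectrumKind,
    TaperedCoefficients,
    coherence_from_sums,
    tapered_coefficients,
)

__all__ = [
    "CIFunction",
    "MiCASAResult",
    "Band",
    "ComparisonReport",
    "jackknife_mean_ci",
    "jackknife_coherence_ci",
    "variance_function",
    "micasa_analyze",
    "compare_conditions",
]

CURVE_NAMES = (
    "log_spectrum_a",
    "log_spectrum_b",
    "atanh_coherence",
    "var_log_spectrum_a",
    "var_log_spectrum_b",
    "var_atanh_coherence",
)


@dataclass(frozen=True)
class CIFunction:
    """Estimate with confidence band on a radial grid.

    ``mask`` marks missing bins (empty radial bins, or bins outside the
    shared band after interpolation); ``dof`` is the number of jackknife
    units behind the interval (the t-interval uses ``dof - 1``).
    """

    grid: RadialGrid
    estimate: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    mask: np.ndarray
    confidence_level: float
    dof: int

    def __post_init__(self) -> None:
        for name in ("estimate", "ci_lower", "ci_upper"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (self.grid.n_bins,):
                raise ValueError(f"{name} must match the grid length")
            object.__setattr__(self, name, arr)
        object.__setattr__(self, "mask", np.asarray(self.mask, dtype=bool))
        good = ~self.mask
        if np.any(self.ci_lower[good] > self.estimate[good] + 1e-12) or np.any(
            self.ci_upper[good] < self.estimate[good] - 1e-12
        ):
            raise ValueError("CI must bracket the estimate on unmasked bins")


@dataclass(frozen=True)
class MiCASAResult:
    """The six output curves of one condition's analysis on one grid."""

    log_spectrum_a: CIFunction
    log_spectrum_b: CIFunction
    atanh_coherence: CIFunction
    var_log_spectrum_a: CIFunction
    var_log_spectrum_b: CIFunction
    var_atanh_coherence: CIFunction
    config: AnalysisConfig
    label: str
    N: int
    M: int

    def __post_init__(self) -> None:
        grids = [getattr(self, name).grid for name in CURVE_NAMES]
        if not all(g.same_as(grids[0]) for g in grids):
            raise ValueError("all six curves must share one radial grid")

    @property
    def NM(self) -> int:
        return self.N * self.M

    @property
    def grid(self) -> RadialGrid:
        return self.log_spectrum_a.grid

    def curve(self, name: str) -> CIFunction:
        if name not in CURVE_NAMES:
            raise KeyError(f"unknown curve {name!r}; one of {CURVE_NAMES}")
        return getattr(self, name)


# ---------------------------------------------------------------------------
# jackknife / interval primitives


def _jackknife_se(values: np.ndarray) -> np.ndarray:
    """Jackknife standard error of the mean along axis 0.

    Computed from the n leave-one-out means; for the plain mean this
    equals s/sqrt(n) algebraically.
    """
    n = values.shape[0]
    total = values.sum(axis=0)
    loo = (total[None] - values) / (n - 1)
    centred = loo - loo.mean(axis=0)
    return np.sqrt((n - 1) / n * np.sum(centred**2, axis=0))


def _se_from_delete_one(delete_one: np.ndarray) -> np.ndarray:
    """Jackknife SE from already-computed delete-one statistics."""
    n = delete_one.shape[0]
    centred = delete_one - delete_one.mean(axis=0)
    return np.sqrt((n - 1) / n * np.sum(centred**2, axis=0))


def _stack(curves: Sequence[RadialFunction]) -> tuple[np.ndarray, np.ndarray, RadialGrid]:
    grid = curves[0].grid
    values = np.stack([c.values for c in curves])
    mask = np.any(np.stack([c.mask for c in curves]), axis=0)
    return values, mask, grid


def jackknife_mean_ci(
    curves: Sequence[RadialFunction], confidence_level: float
) -> CIFunction:
    """Mean of n radial curves with a jackknife t-interval per bin.

    The curves are the jackknife units; the caller decides whether they
    are per-image or per-(image, taper) curves.
    """
    if len(curves) < 2:
        raise ValueError("jackknife needs at least 2 estimates")
    values, mask, grid = _stack(curves)
    n = values.shape[0]
    est = values.mean(axis=0)
    se = _jackknife_se(values)
    tcrit = sps.t.ppf(0.5 * (1.0 + confidence_level), df=n - 1)
    return CIFunction(
        grid=grid,
        estimate=est,
        ci_lower=est - tcrit * se,
        ci_upper=est + tcrit * se,
        mask=mask,
        confidence_level=confidence_level,
        dof=n,
    )


def variance_function(
    curves_or_delete_one: np.ndarray | Sequence[RadialFunction],
    confidence_level: float,
    grid: RadialGrid | None = None,
    mask: np.ndarray | None = None,
    pseudo_from: np.ndarray | None = None,
) -> CIFunction:
    """Sample variance across unit curves with a chi-square interval.

    For the log-spectra, pass the direct unit curves.  For the coherence
    — a pooled statistic with no direct per-unit curve — pass the
    delete-one curves as an array together with ``pseudo_from`` (the
    all-in curve): the jackknife pseudo-values
    ``n*all_in - (n-1)*delete_one_i`` stand in for unit curves, and their
    sample variance is reported.

    The interval is ``[(n-1)s^2/chi2_hi, (n-1)s^2/chi2_lo]`` with n-1
    degrees of freedom.
    """
    if isinstance(curves_or_delete_one, np.ndarray):
        values = curves_or_delete_one
        if grid is None or mask is None:
            raise ValueError("grid and mask are required with array input")
    else:
        values, mask, grid = _stack(curves_or_delete_one)
    n = values.shape[0]
    if n < 2:
        raise ValueError("variance needs at least 2 estimates")
    if pseudo_from is not None:
        values = n * pseudo_from[None, :] - (n - 1) * values
    s2 = values.var(axis=0, ddof=1)
    alpha = 1.0 - confidence_level
    chi_hi = sps.chi2.ppf(1.0 - alpha / 2.0, df=n - 1)
    chi_lo = sps.chi2.ppf(alpha / 2.0, df=n - 1)
    return CIFunction(
        grid=grid,
        estimate=s2,
        ci_lower=(n - 1) * s2 / chi_hi,
        ci_upper=(n - 1) * s2 / chi_lo,
        mask=np.asarray(mask, dtype=bool),
        confidence_level=confidence_level,
        dof=n,
    )


# ---------------------------------------------------------------------------
# deletion blocks and the DC concentration lobe


def _estimate_blocks(tc: TaperedCoefficients, unit: str) -> list[list[int]]:
    """Flat estimate indices grouped into jackknife deletion units."""
    if unit == "image":
        return [
            [tc.estimate_index(i, m) for m in range(tc.M)] for i in range(tc.N)
        ]
    if unit == "estimate":
        return [[j] for j in range(tc.NM)]
    raise ValueError(f"unknown jackknife unit {unit!r}")


def _dc_lobe_radius(
    shape: tuple[int, int], pixel_size_um: float, bandwidth_product: float
) -> float:
    """Radius (cycles/um) of the tapers' DC concentration lobe.

    Per dimension the half-bandwidth is NW/(n*px); the larger of the two
    bounds the region where the tapered transform of a constant is
    concentrated, so frequencies inside it are indistinguishable from
    the image mean.
    """
    return bandwidth_product / (min(shape) * pixel_size_um)


# ---------------------------------------------------------------------------
# coherence curves (pooled statistic, per shape group)


def _coherence_curves(
    tc: TaperedCoefficients,
    native_grids: dict[tuple[int, int], RadialGrid],
    shared: RadialGrid,
    blocks: list[list[int]],
    bandwidth_product: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All-in and delete-one circularly averaged atanh-coherence curves.

    Coherence is pooled over the estimates sharing one 2D frequency grid
    (one shape group); group curves are interpolated onto the shared grid
    and combined as an estimate-count-weighted mean.  For the common case
    of a single shape this is exactly the all-NM pooled coherence.
    Deleting a block that empties a group (a single image deleted from a
    shape of its own) drops that group from the combination.

    Returns ``(all_in, delete_one, mask)`` with ``delete_one`` of shape
    ``(n_blocks, n_bins)`` in block order.
    """
    M = tc.M
    shapes = tc.image_shapes
    groups: dict[tuple[int, int], list[int]] = {}
    for i, shp in enumerate(shapes):
        groups.setdefault(shp, []).append(i)

    group_data = []
    flat_to_group: dict[int, int] = {}
    for gi, (shp, img_idx) in enumerate(groups.items()):
        cross = np.concatenate(
            [tc.coeffs_a[i] * np.conj(tc.coeffs_b[i]) for i in img_idx]
        )
        pa = np.concatenate([np.abs(tc.coeffs_a[i]) ** 2 for i in img_idx])
        pb = np.concatenate([np.abs(tc.coeffs_b[i]) ** 2 for i in img_idx])
        flat_idx = [tc.estimate_index(i, m) for i in img_idx for m in range(M)]
        for local, flat in enumerate(flat_idx):
            flat_to_group[flat] = gi
        group_data.append(
            {
                "grid": native_grids[shp],
                "exclude": _dc_lobe_radius(shp, tc.pixel_size_um, bandwidth_product),
                "cross": cross,
                "pa": pa,
                "pb": pb,
                "sums": (cross.sum(axis=0), pa.sum(axis=0), pb.sum(axis=0)),
                "flat_idx": flat_idx,
            }
        )

    def group_curve(g: dict, drop_locals: list[int]) -> RadialFunction | None:
        cs, ps, qs = g["sums"]
        n_here = g["cross"].shape[0]
        if drop_locals:
            if n_here - len(drop_locals) < 2:
                return None  # group degenerate without these estimates
            cs = cs - g["cross"][drop_locals].sum(axis=0)
            ps = ps - g["pa"][drop_locals].sum(axis=0)
            qs = qs - g["pb"][drop_locals].sum(axis=0)
        atanh_c = coherence_from_sums(cs, ps, qs)
        rf = circular_average(
            Spectrum2D(atanh_c, SpectrumKind.ATANH_COHERENCE, tc.pixel_size_um),
            g["grid"],
            exclude_below=g["exclude"],
        )
        return interpolate_onto(rf, shared)

    def combine(
        curves: list[RadialFunction | None], weights: list[int]
    ) -> tuple[np.ndarray, np.ndarray]:
        live = [(c, w) for c, w in zip(curves, weights) if c is not None and w > 0]
        if not live:
            raise ValueError("no shape group retains >= 2 estimates for coherence")
        if len(live) == 1:
            return live[0][0].values.copy(), live[0][0].mask.copy()
        w = np.asarray([wt for _, wt in live], dtype=float)
        vals = np.stack([c.values for c, _ in live])
        mask = np.any(np.stack([c.mask for c, _ in live]), axis=0)
        combined = np.einsum("g,gb->b", w, vals) / w.sum()
        combined[mask] = 0.0
        return combined, mask

    base_curves = [group_curve(g, []) for g in group_data]
    base_weights = [g["cross"].shape[0] for g in group_data]
    all_in, mask = combine(base_curves, base_weights)

    delete_one = np.empty((len(blocks), shared.n_bins), dtype=float)
    for bi, block in enumerate(blocks):
        touched = {flat_to_group[f] for f in block}
        if len(touched) != 1:
            raise ValueError("a deletion block must lie within one shape group")
        gi = touched.pop()
        g = group_data[gi]
        locs = [g["flat_idx"].index(f) for f in block]
        curves = list(base_curves)
        weights = list(base_weights)
        curves[gi] = group_curve(g, locs)
        weights[gi] -= len(locs)
        vals, m = combine(curves, weights)
        mask = mask | m
        delete_one[bi] = vals
    return all_in, delete_one, mask


def jackknife_coherence_ci(
    tc: TaperedCoefficients,
    grid: RadialGrid,
    confidence_level: float,
    unit: str = "image",
    bandwidth_product: float = 2.0,
) -> CIFunction:
    """t-interval for the circularly averaged pooled atanh-coherence.

    The estimate uses all NM (image, taper) estimates; the standard
    error comes from the delete-one recomputations at the chosen
    jackknife unit; the interval is centred on the all-in estimate.
    """
    if tc.N == 1:
        unit = "estimate"
    blocks = _estimate_blocks(tc, unit)
    if len(blocks) < 3:
        raise ValueError("coherence jackknife needs at least 3 deletion units")
    unique_shapes = set(tc.image_shapes)
    if len(unique_shapes) == 1:
        native = {next(iter(unique_shapes)): grid}
    else:
        native = {
            shp: native_radial_grid(shp, tc.pixel_size_um, grid.n_bins)
            for shp in unique_shapes
        }
    all_in, delete_one, mask = _coherence_curves(
        tc, native, grid, blocks, bandwidth_product
    )
    n = len(blocks)
    se = _se_from_delete_one(delete_one)
    tcrit = sps.t.ppf(0.5 * (1.0 + confidence_level), df=n - 1)
    return CIFunction(
        grid=grid,
        estimate=all_in,
        ci_lower=all_in - tcrit * se,
        ci_upper=all_in + tcrit * se,
        mask=mask,
        confidence_level=confidence_level,
        dof=n,
    )


# ---------------------------------------------------------------------------
# full pipeline


def _shared_grid(
    shapes: Sequence[tuple[int, int]], pixel_size_um: float, n_bins: int
) -> tuple[RadialGrid, dict[tuple[int, int], RadialGrid]]:
    unique = sorted(set(shapes))
    native = {shp: native_radial_grid(shp, pixel_size_um, n_bins) for shp in unique}
    if len(unique) == 1:
        return native[unique[0]], native
    f_min = max(g.bin_edges[0] for g in native.values())
    f_max = min(g.bin_edges[-1] for g in native.values())
    if not (f_min < f_max):
        raise ValueError("image sizes give no overlapping frequency range")
    return _grid_from_range(f_min, f_max, n_bins), native


def _log_spectrum_unit_curves(
    tc: TaperedCoefficients,
    channel: str,
    native: dict[tuple[int, int], RadialGrid],
    shared: RadialGrid,
    bandwidth_product: float,
    unit: str,
) -> tuple[list[RadialFunction], list[RadialFunction]]:
    """Per-estimate and per-unit circularly averaged log-spectrum curves.

    Returns ``(estimate_curves, unit_curves)``: the NM per-(image, taper)
    curves, and the jackknife unit curves (the per-image means of the M
    taper curves for the image unit; the same NM curves for the estimate
    unit).
    """
    stacks = tc.coeffs_a if channel == "a" else tc.coeffs_b
    estimate_curves: list[RadialFunction] = []
    unit_curves: list[RadialFunction] = []
    for stack in stacks:
        shp = stack.shape[1:]
        exclude = _dc_lobe_radius(shp, tc.pixel_size_um, bandwidth_product)
        logs = np.log(np.abs(stack) ** 2 + LOG_FLOOR)
        per_image: list[RadialFunction] = []
        for m in range(stack.shape[0]):
            rf = circular_average(
                Spectrum2D(logs[m], SpectrumKind.LOG_POWER, tc.pixel_size_um),
                native[shp],
                exclude_below=exclude,
            )
            per_image.append(interpolate_onto(rf, shared))
        estimate_curves.extend(per_image)
        if unit == "image":
            vals = np.mean([c.values for c in per_image], axis=0)
            msk = np.any([c.mask for c in per_image], axis=0)
            vals = np.where(msk, 0.0, vals)
            unit_curves.append(RadialFunction(shared, vals, msk))
    if unit == "estimate":
        unit_curves = estimate_curves
    return estimate_curves, unit_curves


def micasa_analyze(
    dataset: ConditionDataset, config: AnalysisConfig | None = None
) -> MiCASAResult:
    """Run the full pipeline on one condition.

    Tapers -> tapered Fourier coefficients -> per-estimate 2D log-spectra
    and pooled atanh-coherence -> circular averaging on each image's
    native grid -> shared log-frequency grid -> jackknife confidence
    intervals and variance curves.
    """
    if config is None:
        config = AnalysisConfig(pixel_size_um=dataset.pixel_size_um)
    tc = tapered_coefficients(dataset, config)
    unit = "estimate" if tc.N == 1 else config.jackknife_unit
    blocks = _estimate_blocks(tc, unit)
    if len(blocks) < 2:
        raise ValueError("need at least 2 jackknife units")
    shared, native = _shared_grid(
        tc.image_shapes, tc.pixel_size_um, config.radial_grid_size
    )
    level = config.confidence_level

    results: dict[str, CIFunction] = {}
    for channel in ("a", "b"):
        _, unit_curves = _log_spectrum_unit_curves(
            tc, channel, native, shared, config.bandwidth_product, unit
        )
        results[f"log_spectrum_{channel}"] = jackknife_mean_ci(unit_curves, level)
        results[f"var_log_spectrum_{channel}"] = variance_function(unit_curves, level)

    if len(blocks) < 3:
        raise ValueError("coherence jackknife needs at least 3 deletion units")
    all_in, delete_one, coh_mask = _coherence_curves(
        tc, native, shared, blocks, config.bandwidth_product
    )
    n = len(blocks)
    se = _se_from_delete_one(delete_one)
    tcrit = sps.t.ppf(0.5 * (1.0 + level), df=n - 1)
    results["atanh_coherence"] = CIFunction(
        grid=shared,
        estimate=all_in,
        ci_lower=all_in - tcrit * se,
        ci_upper=all_in + tcrit * se,
        mask=coh_mask,
        confidence_level=level,
        dof=n,
    )
    results["var_atanh_coherence"] = variance_function(
        delete_one, level, grid=shared, mask=coh_mask, pseudo_from=all_in
    )

    return MiCASAResult(
        config=config,
        label=dataset.label,
        N=tc.N,
        M=tc.M,
        **results,
    )


# ---------------------------------------------------------------------------
# condition comparison


@dataclass(frozen=True)
class Band:
    """A maximal contiguous frequency band of disjoint confidence intervals."""

    curve: str
    direction: str  # label of the condition whose CI lies higher
    bin_start: int
    bin_stop: int  # inclusive
    freq_lo: float
    freq_hi: float

    @property
    def scale_hi_um(self) -> float:
        """Long-length-scale endpoint (from the low-frequency edge)."""
        return 1.0 / self.freq_lo

    @property
    def scale_lo_um(self) -> float:
        return 1.0 / self.freq_hi


@dataclass(frozen=True)
class ComparisonReport:
    """Significant bands per output curve for one A-vs-B comparison."""

    label_a: str
    label_b: str
    confidence_level: float
    bands: dict[str, tuple[Band, ...]]

    @property
    def n_bands(self) -> int:
        return sum(len(b) for b in self.bands.values())

    def to_text(self) -> str:
        lines = [
            f"Comparison: {self.label_a} vs {self.label_b} "
            f"(CI level {self.confidence_level:.2f})"
        ]
        for curve in CURVE_NAMES:
            bands = self.bands.get(curve, ())
            if not bands:
                lines.append(f"  {curve}: no significant bands")
                continue
            lines.append(f"  {curve}:")
            for b in bands:
                lines.append(
                    f"    {b.scale_hi_um:.1f}-{b.scale_lo_um:.1f} um "
                    f"({b.freq_lo:.5g}-{b.freq_hi:.5g} cycles/um): "
                    f"{b.direction} higher"
                )
        return "\n".join(lines)


def _runs(flags: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (start, stop_inclusive)."""
    out = []
    start = None
    for i, f in enumerate(flags):
        if f and start is None:
            start = i
        elif not f and start is not None:
            out.append((start, i - 1))
            start = None
    if start is not None:
        out.append((start, len(flags) - 1))
    return out


def _interp_ci(fn: CIFunction, target: RadialGrid) -> CIFunction:
    if fn.grid.same_as(target):
        return fn
    parts = {}
    mask = None
    for name in ("estimate", "ci_lower", "ci_upper"):
        rf = interpolate_onto(
            RadialFunction(fn.grid, getattr(fn, name), fn.mask), target
        )
        parts[name] = rf.values
        mask = rf.mask
    return CIFunction(
        grid=target,
        mask=mask,
        confidence_level=fn.confidence_level,
        dof=fn.dof,
        **parts,
    )


def compare_conditions(a: MiCASAResult, b: MiCASAResult) -> ComparisonReport:
    """Find frequency bands where two conditions' CIs do not overlap.

    Per curve, reports the maximal contiguous runs of bins with
    ``a.ci_upper < b.ci_lower`` or ``b.ci_upper < a.ci_lower``, with the
    direction (which condition lies higher) and the band endpoints.
    Masked bins never count as significant.
    """
    if a.grid.same_as(b.grid):
        grid = a.grid
        curves_a = {name: a.curve(name) for name in CURVE_NAMES}
        curves_b = {name: b.curve(name) for name in CURVE_NAMES}
    else:
        f_min = max(a.grid.bin_edges[0], b.grid.bin_edges[0])
        f_max = min(a.grid.bin_edges[-1], b.grid.bin_edges[-1])
        if not (f_min < f_max):
            raise ValueError("results have disjoint frequency ranges")
        grid = _grid_from_range(f_min, f_max, min(a.grid.n_bins, b.grid.n_bins))
        curves_a = {n: _interp_ci(a.curve(n), grid) for n in CURVE_NAMES}
        curves_b = {n: _interp_ci(b.curve(n), grid) for n in CURVE_NAMES}

    bands: dict[str, tuple[Band, ...]] = {}
    for name in CURVE_NAMES:
        ca, cb = curves_a[name], curves_b[name]
        good = ~(ca.mask | cb.mask)
        a_higher = good & (ca.ci_lower > cb.ci_upper)
        b_higher = good & (cb.ci_lower > ca.ci_upper)
        found = []
        for flags, direction in ((a_higher, a.label), (b_higher, b.label)):
            for start, stop in _runs(flags):
                found.append(
                    Band(
                        curve=name,
                        direction=direction,
                        bin_start=start,
                        bin_stop=stop,
                        freq_lo=float(grid.bin_edges[start]),
                        freq_hi=float(grid.bin_edges[stop + 1]),
                    )
                )
        found.sort(key=lambda band: band.bin_start)
        bands[name] = tuple(found)
    return ComparisonReport(
        label_a=a.label,
        label_b=b.label,
        confidence_level=min(
            a.log_spectrum_a.confidence_level, b.log_spectrum_a.confidence_level
        ),
        bands=bands,
    )
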