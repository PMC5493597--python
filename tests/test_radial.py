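"""Radial grids, circular averaging, interpolation, length scales."""

import numpy as np
import pytest

from micasa import (
    circular_average,
    interpolate_to_common,
    length_scale_of,
    native_radial_grid,
)
from micasa.radial import RadialFunction, RadialGrid, interpolate_onto
from micasa.spectra import Spectrum2D, SpectrumKind


def spectrum(values, px=2.0):
    return Spectrum2D(np.asarray(values, float), SpectrumKind.LOG_POWER, px)


def brute_force_average(values, px, grid, exclude_below=0.0):
    """Independent oracle: loop over every 2D frequency."""
    rows, cols = values.shape
    fy = np.fft.fftfreq(rows, d=px)
    fx = np.fft.fftfreq(cols, d=px)
    sums = np.zeros(grid.n_bins)
    counts = np.zeros(grid.n_bins)
    for i in range(rows):
        for j in range(cols):
            r = np.hypot(fy[i], fx[j])
            if r <= exclude_below or r < grid.bin_edges[0] or r > grid.bin_edges[-1]:
                continue
            b = min(
                np.searchsorted(grid.bin_edges, r, side="right") - 1,
                grid.n_bins - 1,
            )
            sums[b] += values[i, j]
            counts[b] += 1
    with np.errstate(invalid="ignore"):
        means = sums / counts
    return means, counts


class TestNativeGrid:
    def test_nyquist_edge_from_pixel_size(self):
        grid = native_radial_grid((128, 128), 2.0, 20)
        assert np.isclose(grid.bin_edges[-1], 0.25)

    def test_fundamental_from_image_extent(self):
        # a 1000-pixel section at 2 um/px spans 2000 um
        grid = native_radial_grid((1000, 800), 2.0, 20)
        assert np.isclose(grid.bin_edges[0], 1.0 / 2000.0)

    def test_edges_strictly_increasing(self):
        grid = native_radial_grid((64, 96), 1.5, 33)
        assert np.all(np.diff(grid.bin_edges) > 0)
        assert np.all(np.diff(grid.frequencies) > 0)


class TestCircularAverage:
    def test_constant_field_gives_constant_bins(self):
        grid = native_radial_grid((32, 32), 2.0, 12)
        rf = circular_average(spectrum(np.full((32, 32), 4.2)), grid)
        np.testing.assert_allclose(rf.values[~rf.mask], 4.2)

    def test_linear_in_radius_matches_brute_force_oracle(self):
        rows = cols = 32
        px = 2.0
        fy = np.fft.fftfreq(rows, d=px)
        fx = np.fft.fftfreq(cols, d=px)
        r = np.hypot(fy[:, None], fx[None, :])
        field = 3.0 + 10.0 * r
        grid = native_radial_grid((rows, cols), px, 10)
        rf = circular_average(spectrum(field, px), grid)
        oracle, counts = brute_force_average(field, px, grid)
        good = counts > 0
        np.testing.assert_array_equal(~rf.mask, good)
        np.testing.assert_allclose(rf.values[good], oracle[good], rtol=1e-12)

    def test_single_nonzero_frequency_lands_in_one_bin(self):
        rows = cols = 32
        px = 2.0
        field = np.zeros((rows, cols))
        field[0, 5] = 1.0  # radius = 5 / (32 * 2) cycles/um
        grid = native_radial_grid((rows, cols), px, 10)
        rf = circular_average(spectrum(field, px), grid)
        r = 5 / 64
        target = np.searchsorted(grid.bin_edges, r, side="right") - 1
        hit = np.flatnonzero(rf.values[~rf.mask] != 0)
        unmasked_idx = np.flatnonzero(~rf.mask)
        assert list(unmasked_idx[hit]) == [target]

    def test_linearity(self, rng):
        grid = native_radial_grid((32, 32), 2.0, 10)
        f = rng.normal(size=(32, 32))
        g = rng.normal(size=(32, 32))
        lhs = circular_average(spectrum(f + g), grid).values
        rhs = (
            circular_average(spectrum(f), grid).values
            + circular_average(spectrum(g), grid).values
        )
        np.testing.assert_allclose(lhs, rhs, atol=1e-12)

    def test_total_coverage_partition(self):
        rows, cols, px = 48, 48, 2.0
        grid = native_radial_grid((rows, cols), px, 14)
        _, counts = brute_force_average(np.ones((rows, cols)), px, grid)
        rf = circular_average(spectrum(np.ones((rows, cols)), px), grid)
        fy = np.fft.fftfreq(rows, d=px)
        r = np.hypot(fy[:, None], fy[None, :])
        in_range = (r > 0) & (r >= grid.bin_edges[0]) & (r <= grid.bin_edges[-1])
        from micasa.radial import _binner

        _, pipeline_counts = _binner((rows, cols), px, tuple(grid.bin_edges))
        assert pipeline_counts.sum() == in_range.sum()
        np.testing.assert_array_equal(pipeline_counts, counts.astype(int))

    def test_exclusion_radius_masks_low_frequencies(self):
        grid = native_radial_grid((32, 32), 2.0, 10)
        rf_all = circular_average(spectrum(np.ones((32, 32))), grid)
        rf_excl = circular_average(
            spectrum(np.ones((32, 32))), grid, exclude_below=0.05
        )
        assert rf_excl.mask.sum() > rf_all.mask.sum()
        assert np.all(rf_excl.mask[grid.frequencies < 0.04])


class TestInterpolation:
    def test_identical_grids_pass_through_unchanged(self, rng):
        grid = native_radial_grid((64, 64), 2.0, 15)
        vals = rng.normal(size=15)
        fns = [
            RadialFunction(grid, vals, np.zeros(15, bool)),
            RadialFunction(grid, 2 * vals, np.zeros(15, bool)),
        ]
        out = interpolate_to_common(fns)
        np.testing.assert_array_equal(out[0].values, vals)
        np.testing.assert_array_equal(out[1].values, 2 * vals)

    def test_log_linear_function_interpolated_exactly(self):
        g1 = native_radial_grid((64, 64), 2.0, 20)
        g2 = native_radial_grid((96, 96), 2.0, 20)
        fn = RadialFunction(
            g1, 3.0 + 2.0 * np.log(g1.frequencies), np.zeros(20, bool)
        )
        out = interpolate_onto(fn, g2)
        good = ~out.mask
        np.testing.assert_allclose(
            out.values[good], 3.0 + 2.0 * np.log(g2.frequencies[good]), rtol=1e-12
        )

    def test_differing_sizes_share_only_common_band(self):
        g_small = native_radial_grid((64, 64), 2.0, 20)   # fundamental 1/128
        g_large = native_radial_grid((256, 256), 2.0, 20)  # fundamental 1/512
        fns = [
            RadialFunction(g, np.ones(20), np.zeros(20, bool))
            for g in (g_small, g_large)
        ]
        out = interpolate_to_common(fns)
        shared = out[0].grid
        assert np.isclose(shared.bin_edges[0], g_small.bin_edges[0])
        assert np.isclose(shared.bin_edges[-1], 0.25)
        assert out[0].grid.same_as(out[1].grid)

    def test_disjoint_ranges_rejected(self):
        g1 = RadialGrid(
            frequencies=np.array([0.01, 0.02]),
            bin_edges=np.array([0.005, 0.015, 0.025]),
        )
        g2 = RadialGrid(
            frequencies=np.array([0.1, 0.2]),
            bin_edges=np.array([0.05, 0.15, 0.25]),
        )
        fns = [
            RadialFunction(g1, np.ones(2), np.zeros(2, bool)),
            RadialFunction(g2, np.ones(2), np.zeros(2, bool)),
        ]
        with pytest.raises(ValueError, match="overlap"):
            interpolate_to_common(fns)

    def test_no_extrapolation_outside_source_range(self):
        g_small = native_radial_grid((64, 64), 2.0, 20)
        g_large = native_radial_grid((256, 256), 2.0, 20)
        fn = RadialFunction(g_large, np.ones(20), np.zeros(20, bool))
        out = interpolate_onto(fn, g_small)
        inside = (g_small.frequencies >= g_large.frequencies[0]) & (
            g_small.frequencies <= g_large.frequencies[-1]
        )
        assert not out.mask[inside].any()
        assert out.mask[~inside].all()
        fn2 = RadialFunction(g_small, np.ones(20), np.zeros(20, bool))
        out2 = interpolate_onto(fn2, g_large)
        assert out2.mask[g_large.frequencies < g_small.frequencies[0]].all()


class TestLengthScale:
    @pytest.mark.parametrize(
        "freq,scale", [(1 / 40, 40.0), (0.0025, 400.0), (0.25, 4.0)]
    )
    def test_reciprocal_values(self, freq, scale):
        assert np.isclose(length_scale_of(freq), scale)

    def test_reciprocal_identity(self):
        f = np.geomspace(1e-4, 0.25, 50)
        np.testing.assert_allclose(f * length_scale_of(f), 1.0)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            length_scale_of(0.0)
        with pytest.raises(ValueError):
            length_scale_of(-0.1)


def test_rotation_robustness_of_lattice_spectrum(config):
    """Rotating a blob lattice by 90 deg leaves the circularly averaged
    log-spectrum unchanged to within the tapers' anisotropy (< 5% of the
    curve's dynamic range)."""
    from micasa import GeneratorSpec, make_blob_lattice
    from micasa.spectra import LOG_FLOOR
    from micasa.tapers import taper_set_2d

    spec = GeneratorSpec(
        pattern="blob_lattice",
        shape=(128, 128),
        pixel_size_um=2.0,
        pattern_params={"spacing_um": 40.0, "blob_radius_um": 6.0, "jitter_um": 4.0},
        seed=4,
    )
    img = make_blob_lattice(spec).intensities
    grid = native_radial_grid((128, 128), 2.0, 20)
    tset = taper_set_2d(128, 128, config.bandwidth_product, config.n_tapers)

    def radial_log_spectrum(image):
        centred = image - image.mean()
        coeffs = np.fft.fft2(tset.tapers * centred[None], axes=(-2, -1))
        logs = np.log(np.abs(coeffs) ** 2 + LOG_FLOOR).mean(axis=0)
        return circular_average(spectrum(logs), grid, exclude_below=0.01)

    base = radial_log_spectrum(img)
    rotated = radial_log_spectrum(np.rot90(img))
    good = ~(base.mask | rotated.mask)
    dynamic_range = np.ptp(base.values[good])
    assert np.abs(base.values[good] - rotated.values[good]).max() < 0.05 * dynamic_range
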