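"""Jackknife intervals, variance curves, full pipeline, comparisons."""

import numpy as np
import pytest
from scipy import stats as sps

from micasa import (
    AnalysisConfig,
    ConditionDataset,
    ImageChannel,
    compare_conditions,
    jackknife_mean_ci,
    micasa_analyze,
    variance_function,
)
from micasa.radial import RadialFunction, RadialGrid
from micasa.spectra import COHERENCE_CAP
from micasa.stats import CIFunction, MiCASAResult
from micasa.synthetic import GeneratorSpec, make_condition


def scalar_grid(n_bins=1):
    edges = np.geomspace(0.01, 0.02, n_bins + 1)
    return RadialGrid(
        frequencies=np.sqrt(edges[:-1] * edges[1:]), bin_edges=edges
    )


def curves_from_values(values):
    """One single-bin radial function per scalar value."""
    grid = scalar_grid()
    return [
        RadialFunction(grid, np.array([v], float), np.zeros(1, bool))
        for v in values
    ]


class TestJackknifeMeanCI:
    def test_identical_estimates_give_zero_width_interval(self):
        ci = jackknife_mean_ci(curves_from_values([2.5] * 8), 0.99)
        assert ci.estimate[0] == 2.5
        assert ci.ci_lower[0] == ci.ci_upper[0] == 2.5

    def test_jackknife_se_equals_s_over_sqrt_n_exactly(self, rng):
        """For the plain mean the jackknife SE reduces algebraically to
        s / sqrt(n); check on 10 scalar values against the closed form."""
        values = rng.normal(size=10)
        ci = jackknife_mean_ci(curves_from_values(values), 0.95)
        s = values.std(ddof=1)
        closed_form = s / np.sqrt(10)
        tcrit = sps.t.ppf(0.975, 9)
        np.testing.assert_allclose(
            ci.ci_upper[0] - ci.estimate[0], tcrit * closed_form, rtol=1e-12
        )

    def test_single_estimate_rejected(self):
        with pytest.raises(ValueError):
            jackknife_mean_ci(curves_from_values([1.0]), 0.99)


class TestVarianceFunction:
    def test_identical_curves_give_degenerate_interval(self):
        ci = variance_function(curves_from_values([1.3] * 6), 0.99)
        assert ci.estimate[0] == 0.0
        assert ci.ci_lower[0] == ci.ci_upper[0] == 0.0

    def test_chi_square_interval_covers_true_variance(self):
        """Textbook check: 99% chi-square intervals from n=21 standard
        normals cover sigma^2 = 1 in about 99% of Monte-Carlo replicates.

        Replicates are laid out as independent bins of one call."""
        rng = np.random.default_rng(3)
        n, n_rep = 21, 4000
        values = rng.normal(size=(n, n_rep))
        edges = np.geomspace(0.01, 0.25, n_rep + 1)
        grid = RadialGrid(
            frequencies=np.sqrt(edges[:-1] * edges[1:]), bin_edges=edges
        )
        ci = variance_function(
            values, 0.99, grid=grid, mask=np.zeros(n_rep, bool)
        )
        coverage = np.mean((ci.ci_lower <= 1.0) & (1.0 <= ci.ci_upper))
        se = np.sqrt(0.99 * 0.01 / n_rep)
        assert abs(coverage - 0.99) < 4 * se

    def test_location_invariance(self, rng):
        values = rng.normal(size=12)
        ci_a = variance_function(curves_from_values(values), 0.99)
        ci_b = variance_function(curves_from_values(values + 42.0), 0.99)
        np.testing.assert_allclose(ci_a.estimate, ci_b.estimate, rtol=1e-9)
        np.testing.assert_allclose(ci_a.ci_upper, ci_b.ci_upper, rtol=1e-9)


class TestMicasaAnalyze:
    def test_records_n_m_and_nm(self, noise_dataset, config):
        result = micasa_analyze(noise_dataset, config)
        assert (result.N, result.M, result.NM) == (3, 7, 21)

    def test_no_hidden_randomness(self, noise_dataset, config):
        r1 = micasa_analyze(noise_dataset, config)
        r2 = micasa_analyze(noise_dataset, config)
        for name in ("log_spectrum_a", "atanh_coherence", "var_atanh_coherence"):
            np.testing.assert_array_equal(
                r1.curve(name).estimate, r2.curve(name).estimate
            )
            np.testing.assert_array_equal(
                r1.curve(name).ci_upper, r2.curve(name).ci_upper
            )

    def test_all_curves_share_one_grid_and_bracket_estimates(
        self, noise_dataset, config
    ):
        result = micasa_analyze(noise_dataset, config)
        grid = result.grid
        for name in (
            "log_spectrum_a",
            "log_spectrum_b",
            "atanh_coherence",
            "var_log_spectrum_a",
            "var_log_spectrum_b",
            "var_atanh_coherence",
        ):
            ci = result.curve(name)
            assert ci.grid.same_as(grid)
            good = ~ci.mask
            assert np.all(ci.ci_lower[good] <= ci.estimate[good] + 1e-12)
            assert np.all(ci.ci_upper[good] >= ci.estimate[good] - 1e-12)

    def test_self_coherent_channels_hit_cap_with_zero_spread(self, config):
        rng = np.random.default_rng(0)
        pairs = []
        for _ in range(3):
            img = rng.normal(size=(64, 64))
            pairs.append((ImageChannel(img, 2.0), ImageChannel(img, 2.0)))
        ds = ConditionDataset(label="self", pairs=tuple(pairs))
        result = micasa_analyze(ds, config)
        ci = result.atanh_coherence
        good = ~ci.mask
        np.testing.assert_allclose(
            ci.estimate[good], np.arctanh(COHERENCE_CAP), rtol=1e-9
        )
        np.testing.assert_allclose(ci.ci_upper[good] - ci.ci_lower[good], 0.0,
                                   atol=1e-9)

    def test_mixed_image_sizes_analysed_on_common_band(self, config):
        rng = np.random.default_rng(1)
        pairs = []
        for shape in ((64, 64), (96, 96), (96, 128)):
            pairs.append(
                (
                    ImageChannel(rng.normal(size=shape), 2.0),
                    ImageChannel(rng.normal(size=shape), 2.0),
                )
            )
        ds = ConditionDataset(label="mixed", pairs=tuple(pairs))
        result = micasa_analyze(ds, config)
        # shared band: fundamental of the smallest image up to Nyquist
        assert np.isclose(result.grid.bin_edges[0], 1.0 / 128.0)
        assert np.isclose(result.grid.bin_edges[-1], 0.25)
        assert (~result.log_spectrum_a.mask).sum() > 10

    def test_single_image_falls_back_to_taper_jackknife(self, config):
        rng = np.random.default_rng(2)
        ds = ConditionDataset(
            label="single",
            pairs=(
                (
                    ImageChannel(rng.normal(size=(64, 64)), 2.0),
                    ImageChannel(rng.normal(size=(64, 64)), 2.0),
                ),
            ),
        )
        result = micasa_analyze(ds, config)
        assert result.log_spectrum_a.dof == config.n_tapers

    def test_image_unit_jackknife_dof_is_n(self, noise_dataset, config):
        result = micasa_analyze(noise_dataset, config)
        assert result.log_spectrum_a.dof == 3
        assert result.atanh_coherence.dof == 3

    def test_estimate_unit_option_uses_nm(self, noise_dataset):
        cfg = AnalysisConfig(jackknife_unit="estimate")
        result = micasa_analyze(noise_dataset, cfg)
        assert result.log_spectrum_a.dof == 21

    def test_coherence_ci_op_matches_pipeline_curve(self, noise_dataset, config):
        from micasa import jackknife_coherence_ci, tapered_coefficients
        from micasa.radial import native_radial_grid

        result = micasa_analyze(noise_dataset, config)
        tc = tapered_coefficients(noise_dataset, config)
        grid = native_radial_grid((64, 64), 2.0, config.radial_grid_size)
        ci = jackknife_coherence_ci(
            tc, grid, config.confidence_level,
            unit=config.jackknife_unit,
            bandwidth_product=config.bandwidth_product,
        )
        ref = result.atanh_coherence
        np.testing.assert_allclose(ci.estimate, ref.estimate, atol=1e-12)
        np.testing.assert_allclose(ci.ci_upper, ref.ci_upper, atol=1e-12)
        assert ci.dof == ref.dof

    def test_ci_width_shrinks_with_more_images(self):
        """Median interior CI width at N=6 is below that at N=3 over
        repeated white-noise conditions (same generator)."""
        cfg = AnalysisConfig()
        spec = GeneratorSpec(
            pattern="white_noise",
            shape=(64, 64),
            pixel_size_um=2.0,
            pattern_params={"sigma": 1.0},
        )
        widths = {3: [], 6: []}
        for rep in range(15):
            for n in (3, 6):
                ds = make_condition(n, spec, base_seed=1000 * rep + n)
                ci = micasa_analyze(ds, cfg).log_spectrum_a
                good = ~ci.mask
                widths[n].append(np.median(ci.ci_upper[good] - ci.ci_lower[good]))
        assert np.median(widths[6]) < np.median(widths[3])


def constant_ci(grid, value, half_width, level=0.99, dof=3):
    n = grid.n_bins
    return CIFunction(
        grid=grid,
        estimate=np.full(n, float(value)),
        ci_lower=np.full(n, value - half_width),
        ci_upper=np.full(n, value + half_width),
        mask=np.zeros(n, bool),
        confidence_level=level,
        dof=dof,
    )


def handmade_result(label, grid, offsets=None):
    """A MiCASAResult with constant curves; ``offsets`` maps curve name to
    (bins, delta) pushing the estimate up by delta on those bins."""
    curves = {}
    for name in (
        "log_spectrum_a",
        "log_spectrum_b",
        "atanh_coherence",
        "var_log_spectrum_a",
        "var_log_spectrum_b",
        "var_atanh_coherence",
    ):
        ci = constant_ci(grid, 1.0, 0.1)
        if offsets and name in offsets:
            bins, delta = offsets[name]
            est = ci.estimate.copy()
            lo = ci.ci_lower.copy()
            hi = ci.ci_upper.copy()
            est[bins] += delta
            lo[bins] += delta
            hi[bins] += delta
            ci = CIFunction(
                grid=grid, estimate=est, ci_lower=lo, ci_upper=hi,
                mask=ci.mask, confidence_level=0.99, dof=3,
            )
        curves[name] = ci
    return MiCASAResult(
        config=AnalysisConfig(), label=label, N=3, M=7, **curves
    )


class TestCompareConditions:
    def grid(self):
        edges = np.geomspace(0.005, 0.25, 13)
        return RadialGrid(
            frequencies=np.sqrt(edges[:-1] * edges[1:]), bin_edges=edges
        )

    def test_result_compared_with_itself_has_no_bands(
        self, noise_dataset, config
    ):
        result = micasa_analyze(noise_dataset, config)
        report = compare_conditions(result, result)
        assert report.n_bands == 0

    def test_disjoint_bins_5_to_9_become_one_band(self):
        grid = self.grid()
        a = handmade_result("a", grid)
        b = handmade_result(
            "b", grid, offsets={"log_spectrum_a": (slice(5, 10), 1.0)}
        )
        report = compare_conditions(a, b)
        bands = report.bands["log_spectrum_a"]
        assert len(bands) == 1
        assert (bands[0].bin_start, bands[0].bin_stop) == (5, 9)
        assert bands[0].direction == "b"
        assert report.n_bands == 1

    def test_comparison_is_symmetric_with_flipped_direction(self):
        grid = self.grid()
        a = handmade_result("a", grid)
        b = handmade_result(
            "b", grid, offsets={"atanh_coherence": (slice(2, 5), -1.0)}
        )
        fwd = compare_conditions(a, b).bands["atanh_coherence"]
        rev = compare_conditions(b, a).bands["atanh_coherence"]
        assert len(fwd) == len(rev) == 1
        assert (fwd[0].bin_start, fwd[0].bin_stop) == (
            rev[0].bin_start,
            rev[0].bin_stop,
        )
        assert fwd[0].direction == rev[0].direction == "a"

    def test_band_endpoints_reported_in_length_scale(self):
        grid = self.grid()
        a = handmade_result("a", grid)
        b = handmade_result(
            "b", grid, offsets={"log_spectrum_b": (slice(3, 6), 2.0)}
        )
        band = compare_conditions(a, b).bands["log_spectrum_b"][0]
        assert np.isclose(band.scale_hi_um, 1.0 / grid.bin_edges[3])
        assert np.isclose(band.scale_lo_um, 1.0 / grid.bin_edges[6])
        assert band.scale_hi_um > band.scale_lo_um

    def test_masked_bins_never_significant(self):
        grid = self.grid()
        a = handmade_result("a", grid)
        offsets = {"log_spectrum_a": (slice(5, 10), 1.0)}
        b = handmade_result("b", grid, offsets=offsets)
        masked = np.zeros(grid.n_bins, bool)
        masked[5:10] = True
        ci = b.log_spectrum_a
        b_masked = MiCASAResult(
            config=b.config,
            label="b",
            N=3,
            M=7,
            log_spectrum_a=CIFunction(
                grid=grid, estimate=ci.estimate, ci_lower=ci.ci_lower,
                ci_upper=ci.ci_upper, mask=masked,
                confidence_level=0.99, dof=3,
            ),
            log_spectrum_b=b.log_spectrum_b,
            atanh_coherence=b.atanh_coherence,
            var_log_spectrum_a=b.var_log_spectrum_a,
            var_log_spectrum_b=b.var_log_spectrum_b,
            var_atanh_coherence=b.var_atanh_coherence,
        )
        report = compare_conditions(a, b_masked)
        assert len(report.bands["log_spectrum_a"]) == 0
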