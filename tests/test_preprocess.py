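"""Preprocessing chain: baseline anchors, area normalisation, averaging,
Savitzky-Golay derivatives, dryness QC."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from epispec import (
    GeneratorConfig,
    PreprocessConfig,
    average_spectra,
    baseline_correct,
    generate_ftir,
    generate_replicates,
    is_dry,
    normalize_area,
    oh_stretch_area,
    preprocess_replicates,
    sg_derivative,
)
from epispec.preprocess import DEFAULT_ANCHORS

from conftest import make_spectrum


def gaussian(x, center, amp, fwhm):
    return amp * np.exp(-4 * np.log(2) * ((x - center) / fwhm) ** 2)


class TestBaselineCorrect:
    def test_constant_spectrum_goes_to_zero(self, ftir_grid):
        s = make_spectrum(ftir_grid, np.full(ftir_grid.size, 0.5))
        out = baseline_correct(s)
        assert np.max(np.abs(out.values)) < 1e-12
        assert out.state == "baseline_corrected"

    def test_global_line_goes_to_zero(self, ftir_grid):
        s = make_spectrum(ftir_grid, 0.3 + 1e-4 * ftir_grid)
        out = baseline_correct(s)
        assert np.max(np.abs(out.values)) < 1e-12

    def test_zero_at_every_anchor_grid_point(self, ftir_grid):
        rng = np.random.default_rng(0)
        s = make_spectrum(ftir_grid, rng.normal(size=ftir_grid.size))
        out = baseline_correct(s)
        for a in DEFAULT_ANCHORS:
            assert abs(out.value_at(a)) < 1e-12

    def test_gaussian_on_ramp_recovers_amplitude(self, ftir_grid):
        """A band at 1478 cm^-1 on a linear ramp: the chord through the
        nearby anchors (1510/1438) carries only small Gaussian tails, so
        the corrected apex recovers the amplitude within 1%. The oracle
        re-evaluates chord and subtraction independently on the grid."""
        amp = 0.2
        ramp = 0.1 + 5e-5 * ftir_grid
        vals = gaussian(ftir_grid, 1478.0, amp, 10.0) + ramp
        s = make_spectrum(ftir_grid, vals)
        out = baseline_correct(s)
        assert out.value_at(1478.0) == pytest.approx(amp, rel=0.01)
        # independent piecewise-linear oracle through the snapped anchor samples
        snap_idx = np.array(
            [np.argmin(np.abs(ftir_grid - a)) for a in DEFAULT_ANCHORS]
        )[::-1]
        xs, ys = ftir_grid[snap_idx], vals[snap_idx]
        oracle = vals - np.interp(ftir_grid, xs, ys)
        inside = (ftir_grid >= xs.min()) & (ftir_grid <= xs.max())
        assert np.allclose(out.values[inside], oracle[inside], atol=1e-12)

    def test_idempotent(self, ftir_grid):
        rng = np.random.default_rng(1)
        s = make_spectrum(ftir_grid, rng.normal(size=ftir_grid.size))
        once = baseline_correct(s)
        again = baseline_correct(make_spectrum(ftir_grid, once.values))
        assert np.allclose(again.values, once.values, atol=1e-12)

    def test_rejects_non_raw_input_and_short_axis(self, ftir_grid):
        s = make_spectrum(ftir_grid, np.zeros(ftir_grid.size), state="normalized")
        with pytest.raises(ValueError, match="raw"):
            baseline_correct(s)
        short_axis = np.arange(2000.0, 1000.0, -2.0)
        s2 = make_spectrum(short_axis, np.zeros(short_axis.size))
        with pytest.raises(ValueError, match="anchor"):
            baseline_correct(s2)


class TestNormalizeArea:
    def _corrected(self, ftir_grid, values):
        return make_spectrum(ftir_grid, values, state="baseline_corrected")

    def test_sets_unit_area_and_is_idempotent(self, ftir_grid):
        s = self._corrected(ftir_grid, gaussian(ftir_grid, 1650.0, 1.0, 35.0))
        out = normalize_area(s)
        from epispec.preprocess import region_area
        assert region_area(out, 1513.0, 1750.0) == pytest.approx(1.0, abs=1e-9)
        out2 = normalize_area(self._corrected(ftir_grid, out.values))
        assert np.allclose(out2.values, out.values, atol=1e-12)

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(scale=st.floats(1e-3, 1e3))
    def test_scale_invariant(self, ftir_grid, scale):
        base = gaussian(ftir_grid, 1650.0, 1.0, 35.0)
        a = normalize_area(self._corrected(ftir_grid, base))
        b = normalize_area(self._corrected(ftir_grid, scale * base))
        assert np.allclose(a.values, b.values, rtol=1e-9, atol=1e-12)

    def test_triangle_area_matches_closed_form(self, ftir_grid):
        """Triangle apex 0.5 at 1650, base 1600-1700: area = b*h/2 = 25."""
        tri = np.clip(0.5 * (1 - np.abs(ftir_grid - 1650.0) / 50.0), 0, None)
        s = self._corrected(ftir_grid, tri)
        out = normalize_area(s)
        assert np.allclose(out.values, tri / 25.0, atol=1e-12)

    def test_rejects_empty_base_region(self, ftir_grid):
        s = self._corrected(ftir_grid, np.zeros(ftir_grid.size))
        with pytest.raises(ValueError, match="area"):
            normalize_area(s)


class TestAverageSpectra:
    def test_identity_and_mean(self, ftir_grid):
        a = make_spectrum(ftir_grid, np.full(ftir_grid.size, 1.0))
        b = make_spectrum(ftir_grid, np.full(ftir_grid.size, 3.0))
        assert np.array_equal(average_spectra([a]).values, a.values)
        assert np.allclose(average_spectra([a, b]).values, 2.0)

    def test_averaging_four_scans_halves_noise(self, oligo_catalog):
        """Residual noise SD after a 4-scan average is sigma/2."""
        resid_sd = []
        clean = generate_ftir(
            oligo_catalog, 0.5,
            GeneratorConfig.ftir(noise_sd_rel=0.0, seed=0)
        )
        for seed in range(30):
            cfg = GeneratorConfig.ftir(noise_sd_rel=0.02, seed=0)
            reps = generate_replicates(oligo_catalog, 0.5, cfg, 4, 1000 + 10 * seed)
            avg = average_spectra(reps)
            resid_sd.append(np.std(avg.values - clean.values))
        assert np.mean(resid_sd) == pytest.approx(0.02 / 2.0, rel=0.05)

    def test_rejects_mixed_states_and_empty(self, ftir_grid):
        a = make_spectrum(ftir_grid, np.zeros(ftir_grid.size))
        b = make_spectrum(ftir_grid, np.zeros(ftir_grid.size), state="normalized")
        with pytest.raises(ValueError, match="processing_state"):
            average_spectra([a, b])
        with pytest.raises(ValueError, match="empty"):
            average_spectra([])


class TestSgDerivative:
    def test_exact_on_quadratic(self):
        x = np.arange(2000.0, 1000.0, -2.0)
        a, b, c = 3e-6, -0.01, 5.0
        s = make_spectrum(x, a * x**2 + b * x + c)
        d2 = sg_derivative(s, order=2)
        assert np.allclose(d2.values, 2 * a, atol=1e-12)
        d1 = sg_derivative(s, order=1)
        interior = slice(4, -4)
        assert np.allclose(d1.values[interior], (2 * a * x + b)[interior], atol=1e-9)

    def test_gaussian_second_derivative_minimum_at_center(self, ftir_grid):
        s = make_spectrum(ftir_grid, gaussian(ftir_grid, 2984.0, 0.3, 25.0))
        d2 = sg_derivative(s, order=2)
        assert abs(d2.axis[np.argmin(d2.values)] - 2984.0) <= 2.0

    def test_overlapped_bends_resolve_only_in_second_derivative(
        self, oligo_catalog, noise_free
    ):
        """The CH2 bend (1468) and CH3 bend (1478) merge into one absorbance
        maximum at full methylation but give two distinct 2nd-derivative
        minima."""
        s = generate_ftir(oligo_catalog, 1.0, noise_free)
        avg, d2 = preprocess_replicates([s])
        mask = (avg.axis >= 1445) & (avg.axis <= 1500)
        ax = avg.axis[mask]
        sub_a, sub_d = avg.values[mask], d2.values[mask]
        abs_maxima = [
            i for i in range(1, sub_a.size - 1)
            if sub_a[i] > sub_a[i - 1] and sub_a[i] >= sub_a[i + 1]
        ]
        d2_minima = sorted(
            (i for i in range(1, sub_d.size - 1)
             if sub_d[i] < sub_d[i - 1] and sub_d[i] <= sub_d[i + 1]),
            key=lambda i: sub_d[i],
        )
        assert len(abs_maxima) == 1  # merged absorbance envelope
        assert len(d2_minima) >= 2
        deepest_two = sorted(ax[d2_minima[:2]])
        assert deepest_two[1] == pytest.approx(1478.0, abs=2.0)
        assert deepest_two[0] == pytest.approx(1468.0, abs=4.0)

    def test_rejects_nonuniform_axis_and_short_input(self):
        x = np.array([4000.0, 3998.0, 3995.0, 3990.0, 3980.0, 3960.0,
                      3930.0, 3890.0, 3840.0])
        with pytest.raises(ValueError, match="uniform"):
            sg_derivative(make_spectrum(x, np.zeros(x.size)), order=2)
        x2 = np.arange(4000.0, 3990.0, -2.0)
        with pytest.raises(ValueError, match="shorter"):
            sg_derivative(make_spectrum(x2, np.zeros(x2.size)), order=2)


class TestOhStretchArea:
    def test_zero_and_rectangle(self, ftir_grid):
        zero = make_spectrum(ftir_grid, np.zeros(ftir_grid.size))
        assert oh_stretch_area(zero) == 0.0
        rect = ((ftir_grid >= 3200) & (ftir_grid <= 3600)).astype(float)
        s = make_spectrum(ftir_grid, rect)
        assert oh_stretch_area(s) == pytest.approx(400.0, rel=0.01)

    def test_gaussian_matches_dense_quadrature(self, ftir_grid):
        vals = gaussian(ftir_grid, 3350.0, 0.45, 250.0)
        s = make_spectrum(ftir_grid, vals)
        dense = np.linspace(3000.0, 4000.0, 200001)
        oracle = np.trapezoid(gaussian(dense, 3350.0, 0.45, 250.0), dense)
        assert oh_stretch_area(s) == pytest.approx(oracle, rel=1e-3)

    def test_axis_must_cover_oh_region(self):
        x = np.arange(2000.0, 1000.0, -2.0)
        with pytest.raises(ValueError, match="cover"):
            oh_stretch_area(make_spectrum(x, np.zeros(x.size)))

    def test_dryness_predicate(self):
        assert is_dry([100, 60, 40, 30.0, 29.9, 29.8, 29.9]) is True
        assert is_dry([100, 60, 40, 30]) is False
        assert is_dry([100, 99]) is False


def test_chain_preserves_mixture_rank_order(oligo_catalog, noise_free):
    """Preprocessing keeps the CH3 intensity ordering of a 0-100% series."""
    from epispec import DEFAULT_SYNTHETIC_WINDOWS, band_intensity

    readings = {w.label: [] for w in DEFAULT_SYNTHETIC_WINDOWS}
    for f in (0.0, 0.25, 0.5, 0.75, 1.0):
        s = generate_ftir(oligo_catalog, f, noise_free)
        avg, _ = preprocess_replicates([s])
        for w in DEFAULT_SYNTHETIC_WINDOWS:
            readings[w.label].append(band_intensity(avg, w).intensity)
    for label, vals in readings.items():
        assert np.all(np.diff(vals) > 0), label


def test_states_only_advance_forward(ftir_grid):
    s = make_spectrum(ftir_grid, np.ones(ftir_grid.size))
    with pytest.raises(ValueError, match="baseline_corrected"):
        normalize_area(s)  # raw cannot be normalised directly
    corrected = baseline_correct(
        make_spectrum(ftir_grid, 0.5 + gaussian(ftir_grid, 1650, 1.0, 35.0))
    )
    with pytest.raises(ValueError, match="raw"):
        baseline_correct(corrected)
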