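"""Spectral preprocessing: baseline, normalization, alignment, integration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from ploidyims import synthgen
from ploidyims.imsproc import (
    EXCLUDE_NULL,
    EXCLUDE_SHIFT,
    IMSDataset,
    NullSpectrumError,
    PeakWindow,
    Spectrum,
    baseline_convex_hull,
    build_peak_matrix,
    class_average,
    integrate_endpoint,
    pick_peaks,
    preprocess,
    recalibrate,
    restrict_mass_range,
    tic_normalize,
)


def _gauss(x, c, s, a):
    return a * np.exp(-0.5 * ((x - c) / s) ** 2)


def _scipy_hull_baseline(mz, intensity):
    """Independent lower-hull oracle via scipy's qhull wrapper."""
    from scipy.spatial import ConvexHull

    pts = np.column_stack([mz, intensity])
    hull = ConvexHull(pts)
    verts = hull.vertices
    # lower envelope: walk from leftmost to rightmost vertex the short way
    order = np.argsort(pts[verts, 0])
    vs = verts[order]
    keep = [vs[0]]
    for v in vs[1:]:
        keep.append(v)
    xs, ys = pts[keep, 0], pts[keep, 1]
    # drop upper-envelope vertices: keep only those on or below every chord
    lower_x, lower_y = [xs[0]], [ys[0]]
    for x, y in zip(xs[1:], ys[1:]):
        while len(lower_x) >= 2:
            cross = (lower_x[-1] - lower_x[-2]) * (y - lower_y[-2]) - (
                lower_y[-1] - lower_y[-2]
            ) * (x - lower_x[-2])
            if cross <= 0:
                lower_x.pop(), lower_y.pop()
            else:
                break
        lower_x.append(x), lower_y.append(y)
    return np.interp(mz, lower_x, lower_y)


class TestRestrictMassRange:
    def test_drops_out_of_range_points(self):
        mz = np.linspace(1500, 30000, 500)
        s = restrict_mass_range(Spectrum(mz, np.ones_like(mz)))
        assert s.mz.min() >= 2000 and s.mz.max() <= 25000

    def test_identity_when_within_range(self):
        mz = np.linspace(3000, 20000, 100)
        s = Spectrum(mz, np.ones_like(mz))
        out = restrict_mass_range(s)
        np.testing.assert_array_equal(out.mz, s.mz)

    def test_entirely_below_range_is_null(self):
        mz = np.linspace(100, 1500, 50)
        assert len(restrict_mass_range(Spectrum(mz, np.ones_like(mz)))) == 0


class TestBaselineConvexHull:
    def test_constant_and_linear_signals_vanish(self):
        mz = np.linspace(2000, 3000, 101)
        for y in (np.full_like(mz, 5.0), 0.01 * mz + 3):
            corrected, baseline = baseline_convex_hull(Spectrum(mz, y), flatness=1.0)
            np.testing.assert_allclose(corrected.intensity, 0.0, atol=1e-9)
            np.testing.assert_allclose(baseline, y, rtol=1e-12)

    def test_gaussian_on_ramp_recovers_apex_and_ramp(self):
        mz = np.linspace(2000, 4000, 200)
        ramp = 0.05 * (mz - 2000) + 10
        y = ramp + _gauss(mz, 3000, 40, 100)
        corrected, baseline = baseline_convex_hull(Spectrum(mz, y))
        apex = corrected.intensity.max()
        assert abs(apex - 100) / 100 < 0.01
        away = np.abs(mz - 3000) > 300
        np.testing.assert_allclose(baseline[away], ramp[away], rtol=0.01)

    def test_matches_scipy_hull_oracle(self):
        rng = np.random.default_rng(5)
        mz = np.linspace(2000, 4000, 200)
        y = 20 * np.exp(-(mz - 2000) / 800) + _gauss(mz, 3000, 30, 50) + rng.random(200)
        _, baseline = baseline_convex_hull(Spectrum(mz, y), flatness=1.0)
        np.testing.assert_allclose(baseline, _scipy_hull_baseline(mz, y), atol=1e-9)

    @given(
        y=arrays(
            np.float64,
            st.integers(10, 80),
            elements=st.floats(0, 1000, allow_nan=False, width=32),
        )
    )
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_nonnegative_and_idempotent(self, y):
        mz = np.linspace(2000, 2000 + 10 * len(y), len(y))
        corrected, _ = baseline_convex_hull(Spectrum(mz, y), flatness=1.0)
        assert corrected.intensity.min() >= 0
        twice, baseline2 = baseline_convex_hull(corrected, flatness=1.0)
        scale = max(float(np.abs(y).max()), 1.0)
        np.testing.assert_allclose(
            twice.intensity, corrected.intensity, atol=1e-9 * scale
        )

    def test_idempotent_with_default_flatness_on_smooth_spectrum(self):
        mz = np.linspace(2000, 4000, 400)
        y = 0.05 * (mz - 2000) + 10 + _gauss(mz, 3000, 20, 100)
        corrected, _ = baseline_convex_hull(Spectrum(mz, y))
        twice, _ = baseline_convex_hull(corrected)
        np.testing.assert_allclose(twice.intensity, corrected.intensity, atol=1e-9 * 100)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            baseline_convex_hull(Spectrum([1.0, 2.0], [1.0, 1.0]))


class TestTicNormalize:
    def test_scales_to_unit_sum(self):
        s = tic_normalize(Spectrum([2000.0, 2001.0], [1.0, 3.0]))
        np.testing.assert_allclose(s.intensity, [0.25, 0.75])

    def test_idempotent(self):
        s = tic_normalize(Spectrum([2000.0, 2001.0], [0.25, 0.75]))
        np.testing.assert_allclose(s.intensity, [0.25, 0.75])

    @given(
        y=arrays(
            np.float64,
            st.integers(2, 50),
            elements=st.floats(0, 1e6, allow_nan=False, width=32),
        )
    )
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_unit_sum_invariant(self, y):
        mz = np.linspace(2000, 2000 + len(y), len(y), endpoint=False)
        if y.sum() <= 0:
            with pytest.raises(NullSpectrumError):
                tic_normalize(Spectrum(mz, y))
        else:
            assert tic_normalize(Spectrum(mz, y)).tic == pytest.approx(1.0, abs=1e-12)

    def test_null_spectrum_excluded_not_scaled(self):
        with pytest.raises(NullSpectrumError):
            tic_normalize(Spectrum([2000.0, 2001.0], [0.0, 0.0]))

    def test_negative_intensities_rejected(self):
        with pytest.raises(ValueError):
            tic_normalize(Spectrum([2000.0, 2001.0], [-1.0, 2.0]))


def _peaky_spectrum(factor=1.0):
    mz = np.linspace(2000, 10000, 4001) * factor
    y = np.zeros_like(mz)
    for c in (2500, 4000, 5000, 7000, 9000):
        y += _gauss(mz, c * factor, 8 * factor, 100)
    return Spectrum(mz, y)


class TestRecalibrate:
    def test_identity_gives_zero_shift(self):
        ref = _peaky_spectrum()
        aligned, shifts, excluded = recalibrate([ref.copy()], ref)
        assert not excluded
        assert abs(shifts[0]) < 1e-9
        np.testing.assert_allclose(aligned[0].mz, ref.mz)

    def test_recovers_500_ppm_shift(self):
        ref = _peaky_spectrum()
        shifted = _peaky_spectrum(1 + 500e-6)
        aligned, shifts, excluded = recalibrate([shifted], ref)
        assert not excluded
        assert abs(shifts[0] + 500) < 50  # correction ~ -500 ppm
        # apex alignment at m/z 5,000 within 0.5 Da
        i_ref = ref.mz[np.argmax(ref.intensity * (np.abs(ref.mz - 5000) < 100))]
        al = aligned[0]
        i_al = al.mz[np.argmax(al.intensity * (np.abs(al.mz - 5000) < 100))]
        assert abs(i_al - i_ref) < 0.5

    def test_2000_ppm_shift_excluded(self):
        ref = _peaky_spectrum()
        shifted = _peaky_spectrum(1 + 2000e-6)
        aligned, shifts, excluded = recalibrate([shifted], ref)
        assert excluded == {0: EXCLUDE_SHIFT}
        assert not aligned


class TestClassAverage:
    def test_single_spectrum_is_identity(self):
        s = _peaky_spectrum()
        np.testing.assert_array_equal(class_average([s]).intensity, s.intensity)

    def test_mean_of_scaled_copies(self):
        s = _peaky_spectrum()
        s3 = Spectrum(s.mz, 3 * s.intensity)
        np.testing.assert_allclose(class_average([s, s3]).intensity, 2 * s.intensity)

    def test_monte_carlo_concentration(self):
        rng = np.random.default_rng(8)
        mz = np.linspace(2000, 3000, 200)
        template = _gauss(mz, 2500, 30, 50) + 5
        sd = 2.0
        spectra = [
            Spectrum(mz, template + rng.normal(0, sd, mz.size)) for _ in range(100)
        ]
        avg = class_average(spectra)
        assert np.all(np.abs(avg.intensity - template) < 3 * sd / 10 + 1e-9)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            class_average([])


class TestPickPeaks:
    def test_single_peak_window_contains_center(self):
        mz = np.linspace(4000, 6000, 1001)
        s = Spectrum(mz, _gauss(mz, 4977, 8, 100))
        windows = pick_peaks(s)
        assert len(windows) == 1
        w = windows[0]
        assert w.lo < 4977 < w.hi
        assert abs(w.center_mz - 4977) <= (mz[1] - mz[0])

    def test_flat_spectrum_yields_nothing(self):
        mz = np.linspace(2000, 3000, 100)
        assert pick_peaks(Spectrum(mz, np.full_like(mz, 2.0))) == []

    def test_two_separated_peaks_disjoint_windows(self):
        mz = np.linspace(2000, 8000, 3001)
        s = Spectrum(mz, _gauss(mz, 3000, 10, 80) + _gauss(mz, 6000, 12, 60))
        w1, w2 = pick_peaks(s)
        assert w1.hi <= w2.lo
        assert w1.lo < 3000 < w1.hi
        assert w2.lo < 6000 < w2.hi


class TestIntegrateEndpoint:
    def test_constant_signal_integrates_to_zero(self):
        mz = np.linspace(2000, 2100, 101)
        s = Spectrum(mz, np.full_like(mz, 7.0))
        assert integrate_endpoint(s, PeakWindow(2050, 2020, 2080)) == 0.0

    def test_triangle_closed_form(self):
        # isoceles triangle: apex h = 10, base b = 40 -> area 200
        mz = np.linspace(2000, 2100, 401)
        y = np.clip(10 - np.abs(mz - 2050) * (10 / 20), 0, None)
        s = Spectrum(mz, y)
        area = integrate_endpoint(s, PeakWindow(2050, 2030, 2070))
        assert area == pytest.approx(10 * 40 / 2, rel=1e-9)

    def test_gaussian_on_tilted_chord_matches_fine_grid_oracle(self):
        mz = np.linspace(2000, 2200, 201)
        y = _gauss(mz, 2100, 15, 50) + 0.1 * (mz - 2000) + 4
        s = Spectrum(mz, y)
        w = PeakWindow(2100, 2040, 2160)
        area = integrate_endpoint(s, w)
        # rectangle-sum oracle on a 100x finer grid of the same sampled signal
        fine = np.linspace(w.lo, w.hi, 20001)
        yf = np.interp(fine, mz, y)
        chord = np.interp(fine, [w.lo, w.hi], [np.interp(w.lo, mz, y), np.interp(w.hi, mz, y)])
        oracle = np.sum((yf - chord)) * (fine[1] - fine[0])
        assert area == pytest.approx(oracle, rel=0.005)

    @given(a=st.floats(-5, 5), b=st.floats(0, 100))
    @settings(max_examples=30, derandomize=True, deadline=None)
    def test_affine_offset_invariance(self, a, b):
        mz = np.linspace(2000, 2200, 201)
        y = _gauss(mz, 2100, 15, 50)
        w = PeakWindow(2100, 2040, 2160)
        base = integrate_endpoint(Spectrum(mz, y), w)
        shifted = integrate_endpoint(Spectrum(mz, y + a * (mz - 2000) / 200 + b), w)
        assert shifted == pytest.approx(base, rel=1e-6, abs=1e-6)

    def test_window_outside_spectrum_rejected(self):
        mz = np.linspace(2000, 2100, 11)
        with pytest.raises(ValueError):
            integrate_endpoint(Spectrum(mz, np.ones_like(mz)), PeakWindow(2150, 2120, 2180))


class TestBuildPeakMatrixAndPipeline:
    def test_matrix_shape(self):
        s = _peaky_spectrum()
        windows = [PeakWindow(2500, 2450, 2550), PeakWindow(4000, 3950, 4050)]
        m = build_peak_matrix([s, s.copy()], windows)
        assert m.values.shape == (2, 2)
        assert (m.values.to_numpy() > 0).all()

    def test_exclusions_propagate_and_reasons_recorded(self, noisy_slide):
        ds, _ = noisy_slide
        proc, log = preprocess(ds)
        n_total = len(ds.pixels)
        assert len(proc.pixels) + len(proc.excluded) == n_total
        assert proc.excluded  # the slide plants null pixels
        assert set(proc.excluded.values()) <= {EXCLUDE_NULL, EXCLUDE_SHIFT}
        windows = [PeakWindow(4977, 4900, 5050)]
        m = build_peak_matrix(proc, windows)
        assert set(m.values.index) == set(proc.pixels)
        for xy in proc.excluded:
            assert xy not in m.values.index

    def test_zero_noise_rows_identical_per_class(self, zero_noise_slide):
        ds, masks = zero_noise_slide
        proc, _ = preprocess(ds)
        windows = [PeakWindow(4977, 4950, 5010), PeakWindow(2395, 2370, 2420)]
        m = build_peak_matrix(proc, windows)
        for label, mask in masks.items():
            rows = m.values.loc[
                [xy for xy in m.values.index if mask[xy[0], xy[1]]]
            ].to_numpy()
            assert np.abs(rows - rows[0]).max() <= 1e-9 * np.abs(rows).max()

    def test_processing_log_covers_all_stages(self, processed_noisy):
        _, _, log = processed_noisy
        joined = "\n".join(log)
        for op in ("restrict_mass_range", "null_filter", "recalibrate", "baseline"):
            assert op in joined
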