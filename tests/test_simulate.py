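import numpy as np
import pytest
from scipy.ndimage import label
from scipy.signal import find_peaks

from fibercube import simulate as sim
from fibercube.cube import default_shift_axis, to_raman_shift
from fibercube.geometry import BundleLayout
from fibercube.models import Frame, TraceModel


@pytest.fixture
def axis():
    return default_shift_axis()


class TestSpectralLibrary:
    def test_shipped_peak_centers(self, library):
        assert library.peak_centers("teflon") == [292, 385, 734, 1218, 1302, 1382]
        assert library.peak_centers("pork") == [1064, 1300, 1441, 1656]
        assert library.peak_centers("PS") == [1035]
        assert library.peak_centers("PMMA") == [600]
        assert library.peak_centers("paracetamol") == [800, 860]
        assert library.peak_centers("aspirin") == [752, 1047]
        assert library.peak_centers("caffeine") == [1703]

    def test_unknown_substance(self, library):
        with pytest.raises(KeyError, match="polonium"):
            library["polonium"]

    def test_invalid_peak_rejected(self):
        with pytest.raises(ValueError):
            sim.Peak(center=-100.0)
        with pytest.raises(ValueError):
            sim.Peak(center=100.0, fwhm=0.0)


class TestMakeSpectrum:
    def test_teflon_local_maxima_at_library_positions(self, library, axis):
        spec = sim.make_spectrum(library, {"teflon": 1.0}, axis)
        peaks, _ = find_peaks(spec, height=0.5)
        found = axis[peaks]
        for center in library.peak_centers("teflon"):
            assert np.min(np.abs(found - center)) <= 2.0  # grid resolution

    def test_zero_mixture_is_zero(self, library, axis):
        spec = sim.make_spectrum(library, {"teflon": 0.0, "PS": 0.0}, axis)
        assert np.all(spec == 0.0)

    def test_single_peak_integral_matches_quadrature(self, library):
        # independent oracle: amplitude * sigma * sqrt(2 pi)
        fwhm = 12.0
        axis = np.linspace(900, 1200, 4001)
        spec = sim.make_spectrum(library, {"PS": 1.0}, axis)
        expected = (fwhm / 2.3548200450309493) * np.sqrt(2 * np.pi)
        assert np.trapezoid(spec, axis) == pytest.approx(expected, rel=1e-4)

    def test_baseline_added(self, library, axis):
        spec = sim.make_spectrum(library, {}, axis, baseline_coeffs=[5.0])
        assert np.allclose(spec, 5.0)

    def test_negative_weight_rejected(self, library, axis):
        with pytest.raises(ValueError):
            sim.make_spectrum(library, {"PS": -1.0}, axis)


class TestRenderFrame:
    @pytest.fixture
    def tiny(self):
        det = sim.DetectorConfig(n_rows_px=60, n_cols_px=50, bias_level=100.0)
        tm = TraceModel(coeffs=[[30.2, 0.0]], sigma=1.0,
                        slit_indices=[0], n_slots=1)
        return det, tm

    def test_zero_spectra_gives_bias_everywhere(self, tiny):
        det, tm = tiny
        frame = sim.render_frame(np.zeros((1, 50)), tm, det, noise=False)
        assert np.all(frame.data == det.bias_level)

    def test_flux_conserved_noise_off(self, tiny):
        det, tm = tiny
        frame = sim.render_frame(np.full((1, 50), 1234.5), tm, det, noise=False)
        colsums = (frame.data - det.bias_level).sum(axis=0)
        np.testing.assert_allclose(colsums, 1234.5, rtol=1e-6)

    def test_same_seed_bit_identical(self, tiny):
        det, tm = tiny
        spec = np.full((1, 50), 500.0)
        a = sim.render_frame(spec, tm, det, noise=True,
                             rng=np.random.default_rng(3))
        b = sim.render_frame(spec, tm, det, noise=True,
                             rng=np.random.default_rng(3))
        np.testing.assert_array_equal(a.data, b.data)

    def test_shape_mismatch_rejected(self, tiny):
        det, tm = tiny
        with pytest.raises(ValueError, match="shape"):
            sim.render_frame(np.zeros((2, 50)), tm, det)


class TestCalibrationFrames:
    def test_bias_noise_off_is_constant(self):
        det = sim.DetectorConfig(n_rows_px=40, n_cols_px=30)
        frames = sim.make_bias(det, 2, noise=False)
        assert len(frames) == 2
        for f in frames:
            assert f.exptime == 0.0
            assert np.all(f.data == det.bias_level)

    def test_flat_zero_throughput_trace_absent(self):
        det = sim.DetectorConfig(n_rows_px=80, n_cols_px=40)
        tm = TraceModel(coeffs=[[25.0, 0.0], [50.0, 0.0]], sigma=1.0,
                        slit_indices=[0, 1], n_slots=2)
        frame = sim.make_flat(tm, det, throughput=[1.0, 0.0], noise=False)
        signal = frame.data - det.bias_level
        assert signal[20:30].sum() > 0
        assert signal[45:55].sum() == pytest.approx(0.0, abs=1e-9)

    def test_empty_arc_line_list_rejected(self):
        det = sim.DetectorConfig(n_rows_px=60, n_cols_px=40)
        tm = TraceModel(coeffs=[[30.0, 0.0]], sigma=1.0,
                        slit_indices=[0], n_slots=1)
        disp = sim.DispersionModel(coeffs=[[795.0, 0.25]])
        with pytest.raises(ValueError, match="empty"):
            sim.make_arc([], tm, disp, det)

    def test_arc_line_center_recoverable_by_centroid(self):
        # linear dispersion: invert the polynomial for the truth column
        det = sim.DetectorConfig(n_rows_px=60, n_cols_px=600)
        tm = TraceModel(coeffs=[[30.0, 0.0]], sigma=1.0,
                        slit_indices=[0], n_slots=1)
        disp = sim.DispersionModel(coeffs=[[795.0, 0.25]])
        line = 854.42
        truth_col = (line - 795.0) / 0.25
        frame = sim.make_arc([line], tm, disp, det, noise=False)
        profile = (frame.data - det.bias_level).sum(axis=0)
        sel = np.abs(np.arange(600) - truth_col) <= 5
        cols = np.flatnonzero(sel)
        centroid = (cols * profile[cols]).sum() / profile[cols].sum()
        assert centroid == pytest.approx(truth_col, abs=0.1)


class TestPhantoms:
    def test_half_field_counts(self, layout):
        ph = sim.half_field_phantom(layout)
        assert ph.weights["paracetamol"].sum() == 200
        assert ph.weights["aspirin"].sum() == 200
        assert not (ph.substance_mask("paracetamol")
                    & ph.substance_mask("aspirin")).any()

    def test_empty_bead_spec_is_all_zero(self, layout):
        ph = sim.make_bead_phantom(layout, [])
        assert ph.weights == {}

    def test_fig9_connected_ps_components(self, layout):
        ph = sim.make_bead_phantom(layout, sim.fig9_beads())
        n_ps_beads = sum(1 for b in sim.fig9_beads() if b.substance == "PS")
        _, n_components = label(ph.substance_mask("PS"))
        assert n_components == n_ps_beads

    def test_bead_outside_field_warns_and_clips(self, layout):
        with pytest.warns(UserWarning, match="clipped"):
            ph = sim.make_bead_phantom(layout,
                                       [sim.Bead("PS", 50.0, 50.0, 1.0)])
        assert ph.weights.get("PS", np.zeros(1)).sum() == 0

    def test_illumination_center_corner_ratio(self, layout):
        illum = sim.gaussian_illumination(layout, center_corner_ratio=10.0)
        center = illum[9:11, 9:11].max()
        assert center / illum[0, 0] == pytest.approx(10.0, rel=0.05)
        assert np.all(illum > 0)


class TestInjectCosmics:
    @pytest.fixture
    def quiet_frame(self):
        rng = np.random.default_rng(5)
        return Frame(data=100.0 + rng.normal(0, 3.0, (80, 80)),
                     frametype="science", exptime=1.0)

    def test_zero_hits_unchanged(self, quiet_frame):
        out, hits = sim.inject_cosmics(quiet_frame, 0,
                                       rng=np.random.default_rng(1))
        assert hits == []
        np.testing.assert_array_equal(out.data, quiet_frame.data)

    def test_hit_count(self, quiet_frame):
        _, hits = sim.inject_cosmics(quiet_frame, 5,
                                     rng=np.random.default_rng(1))
        assert len(hits) == 5

    def test_spike_exceeds_local_median_by_10_sigma(self, quiet_frame):
        out, hits = sim.inject_cosmics(quiet_frame, 3,
                                       rng=np.random.default_rng(2))
        for r, c in hits:
            patch = out.data[max(r - 5, 0):r + 6, max(c - 5, 0):c + 6]
            med = np.median(patch)
            sigma = 1.4826 * np.median(np.abs(patch - med))
            assert out.data[r, c] > med + 10 * sigma


class TestAmplitudeForSnr:
    @pytest.mark.parametrize("snr", [5.0, 30.0, 100.0])
    def test_definition_holds(self, snr):
        r = 3.0
        amp = sim.amplitude_for_snr(snr, r)
        assert amp / np.sqrt(amp + r**2) == pytest.approx(snr, rel=1e-9)


class TestDispersionDefaults:
    def test_strictly_increasing_and_stokes_only(self, layout, detector):
        disp = sim.default_dispersion(layout, detector)
        cols = np.arange(detector.n_cols_px, dtype=float)
        for slot in range(0, 400, 37):
            lam = disp.wavelength(slot, cols)
            assert np.all(np.diff(lam) > 0)
            assert lam[0] >= disp.excitation_nm
            shifts = to_raman_shift(lam)
            assert shifts[0] < 200.0 and shifts[-1] > 2000.0
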