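import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from leafwp import (
    RawFrames,
    SpectraSet,
    WavelengthGrid,
    calibrate_reflectance,
    max_abs_normalize,
    read_spectra_csv,
    spectral_angle,
    write_spectra_csv,
)


class TestCalibration:
    def test_sample_equals_white_gives_panel_reflectance(self, rng):
        white = rng.uniform(10, 100, 176)
        dark = rng.uniform(0, 5, 176)
        s = calibrate_reflectance(RawFrames(white, white, dark, panel_reflectance=1.0))
        np.testing.assert_allclose(s.reflectance, 1.0)

    def test_sample_equals_dark_gives_zero(self, rng):
        white = rng.uniform(10, 100, 176)
        dark = rng.uniform(0, 5, 176)
        s = calibrate_reflectance(RawFrames(dark, white, dark))
        np.testing.assert_allclose(s.reflectance, 0.0)

    def test_direct_formula_evaluation(self):
        s = calibrate_reflectance(RawFrames([0.5], [0.9], [0.1], 1.0))
        np.testing.assert_allclose(s.reflectance, [0.5])

    def test_scale_equivariant_in_panel_reflectance(self, rng):
        frames = lambda rw: RawFrames(
            rng.uniform(5, 50, 20), np.full(20, 60.0), np.full(20, 2.0), rw
        )
        o = rng.uniform(5, 50, 20)
        a = calibrate_reflectance(RawFrames(o, np.full(20, 60.0), np.full(20, 2.0), 0.5))
        b = calibrate_reflectance(RawFrames(o, np.full(20, 60.0), np.full(20, 2.0), 1.0))
        np.testing.assert_allclose(2 * a.reflectance, b.reflectance)

    def test_zero_denominator_names_band(self):
        white = np.array([1.0, 5.0, 3.0])
        dark = np.array([1.0, 1.0, 1.0])
        with pytest.raises(ValueError, match="band index 0"):
            calibrate_reflectance(RawFrames(np.zeros(3), white, dark))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="equal shapes"):
            RawFrames(np.zeros(3), np.ones(4), np.zeros(3))

    def test_negative_outputs_clipped(self):
        s = calibrate_reflectance(RawFrames([0.0], [2.0], [1.0]))
        assert s.reflectance[0] == 0.0


class TestMaxAbsNormalize:
    @pytest.mark.parametrize(
        "x, expected",
        [
            ([0.0, 0.0, 2.0], [0.0, 0.0, 1.0]),
            ([-4.0, 2.0], [-1.0, 0.5]),
        ],
    )
    def test_examples(self, x, expected):
        np.testing.assert_allclose(max_abs_normalize(np.array(x)), expected)

    @given(st.lists(st.floats(-100, 100), min_size=2, max_size=40).filter(lambda v: any(x != 0 for x in v)))
    @settings(deadline=None, max_examples=50)
    def test_idempotent_and_unit_max(self, values):
        x = np.array(values)
        y = max_abs_normalize(x)
        assert np.max(np.abs(y)) == pytest.approx(1.0)
        np.testing.assert_allclose(max_abs_normalize(y), y, atol=1e-12)

    def test_rowwise_on_matrix(self):
        m = np.array([[1.0, 2.0], [10.0, -20.0]])
        out = max_abs_normalize(m, axis=-1)
        np.testing.assert_allclose(out, [[0.5, 1.0], [0.5, -1.0]])

    def test_all_zero_errors(self):
        with pytest.raises(ValueError):
            max_abs_normalize(np.zeros(5))


class TestSpectralAngle:
    def test_identical_is_zero(self, rng):
        a = rng.uniform(0.1, 1, 30)
        assert spectral_angle(a, a) == pytest.approx(0.0, abs=1e-7)

    def test_orthogonal_is_right_angle(self):
        assert spectral_angle([1, 0], [0, 1]) == pytest.approx(np.pi / 2)

    def test_hand_computed_quarter_turn(self):
        assert spectral_angle([1, 0], [1, 1]) == pytest.approx(np.pi / 4, abs=1e-12)

    @given(st.integers(1, 10**6), st.integers(1, 10**6))
    @settings(deadline=None, max_examples=30)
    def test_symmetric_and_scale_invariant(self, sa, sb):
        rng = np.random.default_rng(sa * 7 + sb)
        a, b = rng.uniform(0.01, 1, 15), rng.uniform(0.01, 1, 15)
        assert spectral_angle(a, b) == pytest.approx(spectral_angle(b, a))
        assert spectral_angle(a * (sa / 1e3), b) == pytest.approx(spectral_angle(a, b), abs=1e-9)

    def test_zero_vector_errors(self):
        with pytest.raises(ValueError):
            spectral_angle([0, 0], [1, 1])


class TestCsvRoundTrip:
    def test_round_trip_identity(self, tmp_path, default_dataset):
        sub = default_dataset.subset([0, 1, 2])
        path = tmp_path / "three.csv"
        write_spectra_csv(sub, path)
        back = read_spectra_csv(path)
        np.testing.assert_allclose(back.spectra, sub.spectra, rtol=1e-12)
        np.testing.assert_allclose(back.psi, sub.psi, rtol=1e-12)
        assert back.sample_ids == sub.sample_ids
        assert back.provenance == sub.provenance

    def test_bar_unit_written_and_converted_back(self, tmp_path, default_dataset):
        sub = default_dataset.subset([0, 5])
        path = tmp_path / "bar.csv"
        write_spectra_csv(sub, path, unit="bar")
        text = path.read_text()
        assert "psi_bar" in text.splitlines()[0]
        back = read_spectra_csv(path)
        np.testing.assert_allclose(back.psi, sub.psi, rtol=1e-10)

    def test_wrong_band_count_rejected(self, tmp_path, default_dataset):
        path = tmp_path / "bad.csv"
        write_spectra_csv(default_dataset.subset([0]), path)
        expected = WavelengthGrid(np.linspace(400, 900, 175))
        with pytest.raises(ValueError, match="bands"):
            read_spectra_csv(path, grid=expected)

    def test_missing_psi_column_loads_unlabeled(self, tmp_path, default_dataset):
        sub = default_dataset.subset([0, 1])
        unlabeled = SpectraSet(grid=sub.grid, spectra=sub.spectra)
        path = tmp_path / "nolabels.csv"
        write_spectra_csv(unlabeled, path)
        back = read_spectra_csv(path)
        assert not back.is_labeled
        np.testing.assert_allclose(back.spectra, sub.spectra, rtol=1e-12)

    def test_positive_psi_rejected(self, default_dataset):
        with pytest.raises(ValueError, match="<= 0"):
            SpectraSet(
                grid=default_dataset.grid,
                spectra=default_dataset.spectra[:2],
                psi=np.array([0.5, -1.0]),
            )
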