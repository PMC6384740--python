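"""Spectral types, delimited-text I/O, and signal corrections."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from albind.errors import (
    DataError,
    GridMismatchError,
    InvariantError,
    SpectrumParseError,
    WindowRangeError,
)
from albind.spectra import (
    Spectrum,
    SpectrumKind,
    inner_filter_correct,
    integrate_window,
    peak_position,
    read_spectrum,
    spectral_overlap,
    subtract_background,
    write_spectrum,
)
from tests.conftest import gaussian_emission


def make(axis, signal, kind=SpectrumKind.EMISSION, **kw):
    return Spectrum(axis=np.asarray(axis, float), signal=np.asarray(signal, float),
                    kind=kind, **kw)


class TestSpectrumInvariants:
    def test_non_monotonic_axis_rejected(self):
        with pytest.raises(InvariantError):
            make([300, 301, 301], [1, 2, 3])

    def test_length_mismatch_rejected(self):
        with pytest.raises(InvariantError):
            make([300, 301, 302], [1, 2])

    def test_too_short_rejected(self):
        with pytest.raises(InvariantError):
            make([300], [1])

    def test_non_positive_temperature_rejected(self):
        with pytest.raises(InvariantError):
            make([300, 301], [1, 2], temperature=0.0)


class TestIO:
    def test_direct_parse(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("300,0.0\n301,1.5\n302,0.9\n")
        s = read_spectrum(p, SpectrumKind.EMISSION)
        assert len(s) == 3
        np.testing.assert_array_equal(s.axis, [300, 301, 302])
        np.testing.assert_array_equal(s.signal, [0.0, 1.5, 0.9])

    def test_header_and_comments_skipped(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("# a comment\nwavelength,intensity\n300,1\n301,2\n")
        assert len(read_spectrum(p, "emission")) == 2

    def test_duplicated_axis_value_rejected(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("300,1\n301,2\n301,3\n")
        with pytest.raises(InvariantError):
            read_spectrum(p, "emission")

    def test_non_numeric_cell_names_line(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("300,1\n301,2\nthree hundred two,3\n")
        with pytest.raises(SpectrumParseError, match=r":3:"):
            read_spectrum(p, "emission")

    def test_wrong_column_count_names_line(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("300,1\n301\n")
        with pytest.raises(SpectrumParseError, match=r":2:"):
            read_spectrum(p, "emission")

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        values=st.lists(
            st.floats(-1e6, 1e6, allow_nan=False), min_size=2, max_size=40
        )
    )
    def test_round_trip_bit_identical(self, values, tmp_path_factory):
        tmp = tmp_path_factory.mktemp("roundtrip")
        axis = np.arange(len(values), dtype=float) * np.pi  # irrational spacing
        original = make(axis, values, temperature=310.15)
        write_spectrum(original, tmp / "s.csv")
        back = read_spectrum(tmp / "s.csv", SpectrumKind.EMISSION,
                             temperature=310.15)
        np.testing.assert_array_equal(back.axis, original.axis)
        np.testing.assert_array_equal(back.signal, original.signal)


class TestCorrections:
    def test_self_subtraction_is_zero(self):
        s = make([300, 301, 302], [5.0, 3.0, 1.0])
        np.testing.assert_array_equal(subtract_background(s, s).signal, 0.0)

    def test_zero_buffer_is_identity(self):
        s = make([300, 301, 302], [5.0, 3.0, 1.0])
        b = make([300, 301, 302], [0.0, 0.0, 0.0])
        np.testing.assert_array_equal(subtract_background(s, b).signal, s.signal)

    def test_pointwise_difference(self):
        s = make([1, 2, 3], [5.0, 3.0, 1.0])
        b = make([1, 2, 3], [1.0, 1.0, 1.0])
        np.testing.assert_array_equal(subtract_background(s, b).signal, [4, 2, 0])

    def test_subtract_then_add_back_exact(self):
        rng = np.random.default_rng(7)
        axis = np.sort(rng.uniform(300, 400, 50))
        s = make(axis, rng.normal(size=50))
        b = make(axis, rng.normal(size=50))
        diff = subtract_background(s, b)
        np.testing.assert_allclose(diff.signal + b.signal, s.signal, rtol=1e-14)

    def test_grid_mismatch_raises(self):
        s = make([300, 301, 302], [1, 2, 3])
        b = make([300, 301.5, 302], [1, 2, 3])
        with pytest.raises(GridMismatchError):
            subtract_background(s, b)

    def test_metadata_of_sample_retained(self):
        s = make([300, 301], [1, 2], temperature=310.15, label="sample")
        b = make([300, 301], [1, 1], temperature=298.15, label="buffer")
        out = subtract_background(s, b)
        assert out.temperature == 310.15 and out.label == "sample"


class TestInnerFilter:
    def test_zero_absorbance_identity(self):
        assert inner_filter_correct(100.0, 0.0, 0.0) == 100.0

    def test_known_value(self):
        # 100 * 10^((0.1+0.1)/2) = 100 * 10^0.1, frozen from an
        # arbitrary-precision evaluation of 10**(1/10)
        assert inner_filter_correct(100.0, 0.1, 0.1) == pytest.approx(
            125.89254117941673, rel=1e-14
        )

    def test_zero_intensity(self):
        assert inner_filter_correct(0.0, 0.5, 0.5) == 0.0

    def test_negative_absorbance_rejected(self):
        with pytest.raises(DataError):
            inner_filter_correct(1.0, -0.1, 0.0)

    @settings(max_examples=50, derandomize=True)
    @given(
        st.floats(0.0, 1e6),
        st.floats(0.0, 2.0),
        st.floats(0.0, 2.0),
    )
    def test_correction_is_multiplicative(self, f, a1, a2):
        once = inner_filter_correct(f, a1 + a2, 0.0)
        twice = inner_filter_correct(inner_filter_correct(f, a1, 0.0), a2, 0.0)
        assert once == pytest.approx(twice, rel=1e-12, abs=1e-300)


class TestIntegrateWindow:
    def test_flat_unit_signal_counts_inclusive_samples(self):
        s = make(np.arange(300.0, 400.0), np.ones(100))
        assert integrate_window(s, 350.0, 10.0) == 11.0

    def test_zero_width_takes_nearest_sample(self):
        s = make([300, 301, 302], [1.0, 7.0, 3.0])
        assert integrate_window(s, 301.2, 0.0) == 7.0

    def test_window_outside_axis_raises(self):
        s = make([300, 301, 302], [1, 2, 3])
        with pytest.raises(WindowRangeError):
            integrate_window(s, 300.0, 10.0)

    @settings(max_examples=50, derandomize=True)
    @given(st.integers(5, 60), st.floats(1.0, 30.0), st.integers(0, 10_000))
    def test_matches_brute_force_sum(self, n, width, seed):
        rng = np.random.default_rng(seed)
        axis = np.sort(rng.uniform(300, 400, n))
        axis += np.arange(n) * 1e-9  # guard against duplicates
        signal = rng.normal(size=n)
        s = make(axis, signal)
        center = float(rng.uniform(axis[0] + width / 2, axis[-1] - width / 2))
        if center - width / 2 < axis[0] or center + width / 2 > axis[-1]:
            return
        brute = sum(
            y for x, y in zip(axis, signal)
            if center - width / 2 <= x <= center + width / 2
        )
        assert integrate_window(s, center, width) == pytest.approx(
            brute, rel=1e-12, abs=1e-12
        )


class TestPeakPosition:
    def test_symmetric_band(self):
        result = peak_position(gaussian_emission(347.0))
        assert result.position == 347.0 and not result.ambiguous

    def test_tie_breaks_blue_with_flag(self):
        axis = np.arange(400.0, 600.0, 1.0)
        signal = np.zeros_like(axis)
        signal[axis == 450.0] = 1.0
        signal[axis == 525.0] = 1.0
        result = peak_position(make(axis, signal))
        assert result.position == 450.0 and result.ambiguous

    def test_flat_signal_flagged_ambiguous(self):
        result = peak_position(make([300, 301, 302], [1.0, 1.0, 1.0]))
        assert result.ambiguous

    def test_noisy_band_within_one_grid_step(self):
        axis = np.arange(450.0, 600.0, 1.0)
        rng = np.random.default_rng(3)
        signal = np.exp(-((axis - 525.0) ** 2) / (2 * 30.0**2))
        signal *= 1 + 0.002 * rng.standard_normal(axis.size)
        assert abs(peak_position(make(axis, signal)).position - 525.0) <= 1.0

    def test_rejects_non_emission(self):
        s = make([300, 301, 302], [1, 2, 1], kind=SpectrumKind.ABSORBANCE)
        with pytest.raises(InvariantError):
            peak_position(s)


class TestSpectralOverlap:
    def test_identical_rectangles_closed_form(self):
        axis = np.arange(0.0, 10.0 + 0.5, 1.0)
        donor = make(axis, np.full(axis.size, 3.0))
        acceptor = make(axis, np.full(axis.size, 0.7), kind=SpectrumKind.ABSORBANCE)
        result = spectral_overlap(donor, acceptor)
        # unit-area density 1/10 times absorbance 0.7 times width 10
        assert result.score == pytest.approx(0.7, rel=1e-12)
        assert (result.lower, result.upper) == (0.0, 10.0)

    def test_disjoint_ranges_zero_with_warning(self):
        donor = make([300, 310], [1.0, 1.0])
        acceptor = make([400, 410], [1.0, 1.0], kind=SpectrumKind.ABSORBANCE)
        with pytest.warns(UserWarning):
            assert spectral_overlap(donor, acceptor).score == 0.0

    def test_linear_in_acceptor_absorbance(self):
        axis = np.arange(300.0, 400.0, 1.0)
        donor = make(axis, np.exp(-((axis - 347.0) ** 2) / 800.0))
        a1 = make(axis, np.exp(-((axis - 360.0) ** 2) / 500.0),
                  kind=SpectrumKind.ABSORBANCE)
        a2 = a1.with_signal(2.0 * a1.signal)
        s1 = spectral_overlap(donor, a1).score
        s2 = spectral_overlap(donor, a2).score
        assert s2 == pytest.approx(2.0 * s1, rel=1e-12)
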