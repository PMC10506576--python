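"""Harmonic enumeration, band-limiting, pair construction and synthesis."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pitchshift.errors import EmptySpectrumError, InvalidParameterError
from pitchshift.stimulus import (
    ComplexTone,
    band_limited_partials,
    build_experiment1_pairs,
    cents_interval,
    harmonic_partials,
    read_wav,
    pairs_manifest,
    synthesize_tone,
    write_wav,
)


class TestHarmonicPartials:
    @pytest.mark.parametrize(
        "f0,max_freq,expected",
        [
            (230, 1400, [(k, 230 * k) for k in range(1, 7)]),
            (276, 276, [(1, 276)]),
            (100, 350, [(1, 100), (2, 200), (3, 300)]),
        ],
    )
    def test_enumeration(self, f0, max_freq, expected):
        assert harmonic_partials(f0, max_freq) == expected

    def test_no_harmonic_fits(self):
        with pytest.raises(InvalidParameterError):
            harmonic_partials(230, 229)

    def test_nonpositive_f0(self):
        with pytest.raises(InvalidParameterError):
            harmonic_partials(0, 1000)


class TestBandLimitedPartials:
    @pytest.mark.parametrize(
        "f0,low,high,expected",
        [
            # printed X4/Y4 partials: 5th & 6th harmonics of 230; 4th of 276
            (230, 1000, 1600, [(5, 1150.0), (6, 1380.0)]),
            (276, 1000, 1300, [(4, 1104.0)]),
            (230, 250, 1600, [(k, 230.0 * k) for k in range(2, 7)]),
        ],
    )
    def test_examples(self, f0, low, high, expected):
        got = band_limited_partials(f0, low, high)
        assert [(k, pytest.approx(f)) for k, f in got] == expected

    def test_boundary_partial_retained(self):
        # strict "less than"/"greater than" elimination keeps exact-boundary partials
        assert (2, 500.0) in band_limited_partials(250, 500, 1000)
        assert (4, 1000.0) in band_limited_partials(250, 500, 1000)

    def test_empty_spectrum(self):
        with pytest.raises(EmptySpectrumError):
            band_limited_partials(230, 1400, 1450)

    @given(
        f0=st.floats(50, 500),
        low=st.floats(100, 1200),
        width=st.floats(60, 1000),
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_brute_force_filter(self, f0, low, width):
        """Band-limiting equals filtering the full harmonic enumeration.

        The filter applies the same boundary convention as the
        implementation: a partial within 1e-9 relative tolerance of a
        cutoff counts as "exactly at" it and is retained.
        """
        high = low + width
        expected = [
            (k, f)
            for k, f in harmonic_partials(f0, high + f0)
            if low * (1 - 1e-9) <= f <= high * (1 + 1e-9)
        ]
        if not expected:
            with pytest.raises(EmptySpectrumError):
                band_limited_partials(f0, low, high)
        else:
            assert band_limited_partials(f0, low, high) == expected


class TestCentsInterval:
    def test_study_interval_rounds_to_316(self):
        assert round(cents_interval(230, 276)) == 316
        assert cents_interval(230, 276) == pytest.approx(315.641, abs=1e-3)

    def test_identity_and_octave(self):
        assert cents_interval(440, 440) == 0
        assert cents_interval(220, 440) == pytest.approx(1200)
        assert cents_interval(440, 220) == pytest.approx(-1200)

    def test_invalid(self):
        with pytest.raises(InvalidParameterError):
            cents_interval(-1, 440)


class TestExperiment1Pairs:
    def test_eight_pairs_in_order(self, pairs):
        assert [p.name for p in pairs] == ["X1", "X2", "X3", "X4", "Y1", "Y2", "Y3", "Y4"]

    def test_designed_crossover(self, pairs):
        for p in pairs:
            assert p.tone_a.lowest_partial > p.tone_b.lowest_partial

    def test_top_frequencies(self, pairs):
        for p in pairs:
            if p.name.startswith("X"):
                assert p.tone_a.top_frequency == p.tone_b.top_frequency == 1380.0
            else:
                assert p.tone_a.top_frequency == 1150.0
                assert p.tone_b.top_frequency == 1104.0

    def test_only_y4_is_pure(self, pairs):
        pure = [p.name for p in pairs if p.tone_a.is_pure and p.tone_b.is_pure]
        assert pure == ["Y4"]
        y4 = pairs[-1]
        assert list(zip(y4.tone_a.harmonic_ranks, y4.tone_a.partials)) == [(5, 1150.0)]
        assert list(zip(y4.tone_b.harmonic_ranks, y4.tone_b.partials)) == [(4, 1104.0)]

    def test_x1_tone_a_partial_count(self, pairs):
        assert len(pairs[0].tone_a.partials) == 5

    def test_manifest_has_one_row_per_tone(self, pairs):
        m = pairs_manifest(pairs)
        assert len(m) == 16
        assert set(m["condition"]) == {p.name for p in pairs}


class TestComplexToneInvariants:
    def test_rejects_non_harmonic_partial(self):
        with pytest.raises(InvalidParameterError):
            ComplexTone(f0=230, partials=(461.0,), harmonic_ranks=(2,))

    def test_rejects_empty_partials(self):
        with pytest.raises(EmptySpectrumError):
            ComplexTone(f0=230, partials=(), harmonic_ranks=())

    def test_rejects_short_duration(self):
        with pytest.raises(InvalidParameterError):
            ComplexTone(f0=230, partials=(230.0,), harmonic_ranks=(1,), duration=0.015)


class TestSynthesis:
    def test_sample_count(self, pairs):
        wav = synthesize_tone(pairs[0].tone_a)
        assert len(wav) == 22050  # 500 ms at 44.1 kHz

    def test_ramp_boundaries_are_zero(self, pairs):
        wav = synthesize_tone(pairs[0].tone_a)
        assert wav[0] == 0.0
        assert wav[-1] == pytest.approx(0.0, abs=1e-12)

    def test_peak_below_quantization_headroom(self, pairs):
        for p in pairs:
            for tone in (p.tone_a, p.tone_b):
                wav = synthesize_tone(tone)
                assert np.max(np.abs(wav)) <= 1 - 2**-15 + 1e-12

    def test_pure_tone_spectral_peak(self, pairs):
        tone = pairs[-1].tone_a  # Y4 tone A: 1150 Hz pure tone
        wav = synthesize_tone(tone)
        mag = np.abs(np.fft.rfft(wav))
        freqs = np.fft.rfftfreq(len(wav), 1 / tone.sample_rate)
        assert abs(freqs[np.argmax(mag)] - 1150.0) <= freqs[1]

    def test_eliminated_harmonics_are_absent(self, pairs):
        """Partials only at retained frequencies; removed harmonics >= 40 dB down."""
        tone = pairs[3].tone_a  # X4: harmonics 1-4 eliminated
        wav = synthesize_tone(tone)
        mag = np.abs(np.fft.rfft(wav * np.hanning(len(wav))))
        freqs = np.fft.rfftfreq(len(wav), 1 / tone.sample_rate)
        peak = mag.max()
        for k in (1, 2, 3, 4):
            idx = np.argmin(np.abs(freqs - k * tone.f0))
            window = mag[max(0, idx - 2) : idx + 3].max()
            assert 20 * np.log10(window / peak) < -40


class TestWavIO:
    def test_round_trip_quantization_bound(self, tmp_path, pairs):
        wav = synthesize_tone(pairs[0].tone_a)
        path = write_wav(wav, 44100, tmp_path / "t.wav")
        rate, back = read_wav(path)
        assert rate == 44100
        assert len(back) == len(wav)
        assert np.max(np.abs(back - wav)) <= 2 / 2**15

    def test_stereo_duplicates_channels(self, tmp_path, pairs):
        wav = synthesize_tone(pairs[0].tone_a)
        path = write_wav(wav, 44100, tmp_path / "s.wav", stereo=True)
        import wave as wave_mod

        with wave_mod.open(str(path)) as fh:
            assert fh.getnchannels() == 2
            assert fh.getnframes() == len(wav)

    def test_empty_waveform_rejected(self, tmp_path):
        with pytest.raises(InvalidParameterError):
            write_wav(np.array([]), 44100, tmp_path / "e.wav")

    def test_out_of_range_rejected(self, tmp_path):
        with pytest.raises(InvalidParameterError):
            write_wav(np.array([0.0, 1.5]), 44100, tmp_path / "e.wav")
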