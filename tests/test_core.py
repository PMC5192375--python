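"""Unit and property tests for the detection pipeline bricks."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from terma.core import (
    BlockSet,
    SignalRecord,
    SignalTooShortError,
    TermaParams,
    bandpass_filter,
    check_terma_rate,
    compute_offset,
    detect,
    enhance,
    generate_blocks,
    locate_peaks,
    moving_average,
    ms_to_odd_samples,
    reject_blocks,
)


def naive_centered_mean(signal, window):
    """Independent per-index oracle: pad symmetrically, loop and mean."""
    half = (window - 1) // 2
    padded = np.pad(signal, half, mode="symmetric")
    return np.array(
        [padded[i : i + window].mean() for i in range(len(signal))]
    )


class TestMsToOddSamples:
    @pytest.mark.parametrize(
        "ms,fs,expected",
        [
            (97, 360, 35),      # 34.92 -> nearest odd is 35
            (1000, 1, 1),       # already odd, floor of range
            (611, 360, 219),    # 219.96 -> 219 (0.96 < 1.04)
            (611, 1000, 611),   # exact odd integer
            (100, 200, 21),     # 20.0 equidistant between 19 and 21 -> up
            (1, 360, 1),        # sub-sample duration clamps to 1
        ],
    )
    def test_nearest_odd(self, ms, fs, expected):
        assert ms_to_odd_samples(ms, fs) == expected

    @pytest.mark.parametrize("ms,fs", [(0, 360), (-5, 360), (97, 0), (97, -1)])
    def test_rejects_non_positive(self, ms, fs):
        with pytest.raises(ValueError):
            ms_to_odd_samples(ms, fs)

    @given(
        ms=st.floats(min_value=0.1, max_value=5000),
        fs=st.floats(min_value=1, max_value=4000),
    )
    def test_always_positive_odd_and_nearest(self, ms, fs):
        n = ms_to_odd_samples(ms, fs)
        assert n >= 1 and n % 2 == 1
        x = ms * fs / 1000.0
        if x >= 1:  # within the clamp-free region the result is the closest odd
            assert abs(n - x) <= 1.0 + 1e-9


class TestBandpassFilter:
    def test_dc_removed(self):
        rec = SignalRecord(np.full(2000, 3.7), fs=360, label="dc")
        out = bandpass_filter(rec, 8, 20)
        assert np.max(np.abs(out)) < 1e-8

    def test_passband_sinusoid_preserved_zero_phase(self):
        fs = 360
        t = np.arange(fs * 10) / fs
        x = np.sin(2 * np.pi * 14 * t)
        out = bandpass_filter(SignalRecord(x, fs=fs), 8, 20)
        mid = slice(fs, -fs)  # ignore edge transients
        amp = np.max(np.abs(out[mid]))
        assert amp == pytest.approx(1.0, rel=0.05)
        # zero phase: in-band output stays aligned with the input
        corr = np.dot(out[mid], x[mid]) / (
            np.linalg.norm(out[mid]) * np.linalg.norm(x[mid])
        )
        assert corr > 0.999

    def test_stopband_sinusoid_attenuated(self):
        fs = 360
        t = np.arange(fs * 30) / fs
        x = np.sin(2 * np.pi * 0.2 * t)
        out = bandpass_filter(SignalRecord(x, fs=fs), 8, 20)
        assert np.max(np.abs(out)) < 0.01

    def test_zero_low_edge_is_lowpass(self):
        fs = 1000
        t = np.arange(fs * 5) / fs
        x = 1.0 + np.sin(2 * np.pi * 10 * t)
        out = bandpass_filter(SignalRecord(x, fs=fs), 0, 60)
        # a low-pass keeps the DC component a band-pass would kill
        assert np.mean(out) == pytest.approx(1.0, abs=0.01)

    def test_f2_clipped_at_nyquist_with_warning(self, caplog):
        rec = SignalRecord(np.random.default_rng(0).normal(size=1000), fs=100)
        with caplog.at_level("WARNING", logger="terma.core"):
            out = bandpass_filter(rec, 8, 60)  # 60 > Nyquist of 50
        assert out.shape == (1000,)
        assert any("Nyquist" in r.message for r in caplog.records)

    def test_invalid_band_rejected(self):
        rec = SignalRecord(np.zeros(1000), fs=360)
        with pytest.raises(ValueError):
            bandpass_filter(rec, 20, 8)

    def test_too_short_signal_named_error(self):
        rec = SignalRecord(np.zeros(10), fs=360, label="tiny")
        with pytest.raises(SignalTooShortError, match="tiny"):
            bandpass_filter(rec, 8, 20)


class TestEnhance:
    @pytest.mark.parametrize(
        "signal,expected",
        [([1, -2, 3], [1, 4, 9]), ([0, 0], [0, 0]), ([-0.5], [0.25])],
    )
    def test_pointwise_square(self, signal, expected):
        np.testing.assert_allclose(enhance(np.array(signal, float)), expected)

    @given(
        st.lists(st.floats(min_value=-1e6, max_value=1e6), min_size=1, max_size=50)
    )
    def test_non_negative(self, signal):
        assert np.all(enhance(np.array(signal)) >= 0)


class TestMovingAverage:
    def test_constant_fixed_point(self):
        np.testing.assert_allclose(moving_average(np.full(4, 5.0), 3), 5.0)

    def test_symmetric_edge_extension(self):
        out = moving_average(np.array([1.0, 2, 3, 4, 5]), 3)
        np.testing.assert_allclose(out, [4 / 3, 2, 3, 4, 14 / 3])

    @given(
        data=st.data(),
        window=st.integers(min_value=0, max_value=49),
    )
    def test_matches_naive_oracle(self, data, window):
        window = 2 * window + 1
        n = data.draw(st.integers(min_value=window, max_value=500))
        rng = np.random.default_rng(n * 1000 + window)
        signal = rng.normal(size=n)
        np.testing.assert_allclose(
            moving_average(signal, window),
            naive_centered_mean(signal, window),
            atol=1e-9,
        )

    @pytest.mark.parametrize("window", [0, 2, 4, -3])
    def test_even_or_nonpositive_window_rejected(self, window):
        with pytest.raises(ValueError):
            moving_average(np.arange(10.0), window)

    def test_oversized_window_rejected(self):
        with pytest.raises(ValueError):
            moving_average(np.arange(10.0), 11)


class TestComputeOffset:
    def test_fraction_of_mean(self):
        squared = np.full(100, 10.0)
        assert compute_offset(squared, 0.08) == pytest.approx(0.8)
        assert compute_offset(np.array([4.0, 4, 4, 4]), 0.5) == pytest.approx(2.0)

    def test_zero_beta_zero_offset(self):
        assert compute_offset(np.random.default_rng(1).random(50), 0.0) == 0.0

    def test_negative_beta_rejected(self):
        with pytest.raises(ValueError):
            compute_offset(np.ones(5), -0.1)


class TestBlocks:
    def test_strict_threshold_run(self):
        bs = generate_blocks(np.array([0, 1, 3, 3, 1, 0.0]), np.full(6, 2.0))
        assert bs.blocks == ((2, 4),)

    def test_all_below_gives_empty(self):
        bs = generate_blocks(np.zeros(10), np.ones(10))
        assert len(bs) == 0

    def test_boundary_runs_kept(self):
        bs = generate_blocks(np.array([3, 3, 0, 3.0]), np.full(4, 2.0))
        assert bs.blocks == ((0, 2), (3, 4))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            generate_blocks(np.zeros(5), np.zeros(6))

    def test_width_rejection_keeps_equal_width(self):
        bs = BlockSet(blocks=((0, 2), (5, 9)))
        kept = reject_blocks(bs, 3)
        assert kept.blocks == ((5, 9),)
        # a block exactly as wide as the event window is an event
        assert reject_blocks(BlockSet(blocks=((0, 3),)), 3).blocks == ((0, 3),)
        assert len(reject_blocks(BlockSet(blocks=()), 3)) == 0


class TestLocatePeaks:
    def test_max_absolute_value(self):
        peaks = locate_peaks(
            np.array([0, 0, 5, -7, 0.0]), BlockSet(blocks=((2, 4),))
        )
        np.testing.assert_array_equal(peaks, [3])

    def test_width_one_block(self):
        peaks = locate_peaks(np.zeros(5), BlockSet(blocks=((3, 4),)))
        np.testing.assert_array_equal(peaks, [3])

    def test_tie_breaks_earliest(self):
        peaks = locate_peaks(np.array([0, 3, 3, 0.0]), BlockSet(blocks=((1, 3),)))
        np.testing.assert_array_equal(peaks, [1])

    def test_out_of_bounds_block_rejected(self):
        with pytest.raises(ValueError):
            locate_peaks(np.zeros(4), BlockSet(blocks=((2, 6),)))


class TestTermaRate:
    @pytest.mark.parametrize(
        "w1,w2,holds",
        [
            (97, 611, True),    # published QRS optimum, ratio ~6.3
            (100, 200, True),   # inclusive lower bound, ratio exactly 2
            (100, 800, True),   # inclusive upper bound, ratio exactly 8
            (100, 1000, False), # ratio 10: decoupled
            (100, 150, False),  # ratio 1.5: decoupled
        ],
    )
    def test_inclusive_bounds(self, w1, w2, holds):
        report = check_terma_rate(
            TermaParams(F1=8, F2=20, W1_ms=w1, W2_ms=w2, beta=0.08)
        )
        assert report.holds is holds
        assert report.ratio == pytest.approx(w2 / w1)
        assert report.bounds == (2.0, 8.0)


class TestDetect:
    def test_recovers_noise_free_pulse_train(self):
        from terma.synthetic import SyntheticSpec, generate, matched_params

        spec = SyntheticSpec(
            fs=360, duration_s=20, cycle_ms=1000, cycle_jitter_frac=0.0,
            event_width_ms=80, event_shape="biphasic", noise_std=0.0, seed=4,
        )
        rec, ann = generate(spec)
        assert len(ann) == 20
        result = detect(rec, matched_params(spec))
        assert len(result.peaks) == 20
        tol = int(0.075 * spec.fs)
        assert np.all(np.abs(result.peaks - ann.events) <= tol)

    @pytest.mark.parametrize("scale", [0.01, 100.0])
    def test_amplitude_invariance(self, scale, standard_records):
        from terma.synthetic import matched_params

        for spec, rec, _ in standard_records:
            params = matched_params(spec)
            base = detect(rec, params)
            scaled = detect(
                SignalRecord(rec.samples * scale, fs=rec.fs, label=rec.label),
                params,
            )
            np.testing.assert_array_equal(base.peaks, scaled.peaks)
            assert base.blocks.blocks == scaled.blocks.blocks

    def test_all_zero_signal_yields_nothing(self):
        rec = SignalRecord(np.zeros(7200), fs=360)
        result = detect(rec, TermaParams(F1=8, F2=20, W1_ms=97, W2_ms=611, beta=0.08))
        assert len(result.peaks) == 0
        assert len(result.blocks) == 0

    def test_window_longer_than_record_names_window(self):
        rec = SignalRecord(np.random.default_rng(0).normal(size=200), fs=360)
        with pytest.raises(ValueError, match="W2"):
            detect(rec, TermaParams(F1=8, F2=20, W1_ms=97, W2_ms=611, beta=0.08))

    def test_offset_monotone_in_beta(self):
        from terma.synthetic import SyntheticSpec, generate

        spec = SyntheticSpec(noise_std=0.1, cycle_jitter_frac=0.03, seed=3)
        rec, _ = generate(spec)
        counts = []
        for beta in (0.0, 0.02, 0.05, 0.10):
            r = detect(rec, TermaParams(F1=8, F2=20, W1_ms=80, W2_ms=480, beta=beta))
            counts.append(
                int(np.count_nonzero(r.intermediates.ma_event > r.intermediates.thr1))
            )
        assert counts == sorted(counts, reverse=True)

    def test_one_peak_per_retained_block(self, standard_records):
        from terma.synthetic import matched_params

        for spec, rec, _ in standard_records:
            result = detect(rec, matched_params(spec))
            assert len(result.peaks) == len(result.blocks)
            for peak, (onset, offset) in zip(result.peaks, result.blocks.blocks):
                assert onset <= peak < offset

    def test_rate_violation_warns_not_errors(self, caplog):
        rec = SignalRecord(np.random.default_rng(2).normal(size=7200), fs=360)
        params = TermaParams(F1=8, F2=20, W1_ms=50, W2_ms=611, beta=0.08)
        with caplog.at_level("WARNING", logger="terma.core"):
            detect(rec, params)
        assert any("couple" in r.message for r in caplog.records)

    def test_intermediates_consistent(self, standard_records):
        from terma.synthetic import matched_params

        spec, rec, _ = standard_records[0]
        r = detect(rec, matched_params(spec))
        inter = r.intermediates
        n = len(rec)
        for seq in (inter.filtered, inter.squared, inter.ma_event, inter.ma_cycle, inter.thr1):
            assert seq.shape == (n,)
        assert inter.alpha == pytest.approx(r.params.beta * inter.z_bar)
        np.testing.assert_allclose(inter.thr1, inter.ma_cycle + inter.alpha)
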