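import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from deepclick import synthgen
from deepclick.clickdetect import (
    ClickDetection,
    DetectorConfig,
    band_energy_envelope,
    compute_idi,
    confusion_metrics,
    daily_call,
    daily_call_from_times,
    daily_noise_level,
    detect_candidates,
    detect_day_times,
    find_click_sequences,
    round_quarter,
    tune_r,
)

FS = 16000.0


def brute_force_sequences(times, r, lo=0.5, hi=2.0):
    """Independent oracle: enumerate every contiguous window of intervals and
    keep maximal windows whose rounded IDIs are all equal and in range."""
    times = np.asarray(times, dtype=float)
    if times.size < 2:
        return []
    idi = np.diff(times)
    rq = round_quarter(idi)
    n = idi.size
    out = []
    for i in range(n):
        for j in range(i, n):
            win = rq[i : j + 1]
            if (
                j - i + 1 >= r
                and np.all(win == win[0])
                and lo <= win[0] <= hi
                and (i == 0 or rq[i - 1] != rq[i])
                and (j == n - 1 or rq[j + 1] != rq[i])
            ):
                out.append((i, j - i + 1, float(win[0])))
    return out


class TestEnvelope:
    def test_zero_signal_is_finite_constant_floor(self):
        env = band_energy_envelope(np.zeros(int(FS)), FS)
        assert np.all(np.isfinite(env))
        assert np.allclose(env, env[0])

    def test_doubling_tone_amplitude_adds_6dB(self):
        t = np.arange(int(FS)) / FS
        tone = np.sin(2 * np.pi * 2500 * t)
        e1 = band_energy_envelope(tone, FS)
        e2 = band_energy_envelope(2 * tone, FS)
        mid = slice(20, -20)
        assert np.allclose(e2[mid] - e1[mid], 20 * np.log10(2), atol=0.01)

    def test_envelope_length_contract(self):
        cfg = DetectorConfig()
        n = int(3.123 * FS)
        env = band_energy_envelope(np.random.default_rng(0).normal(size=n), FS, cfg)
        assert env.size == int(np.floor((n / FS - cfg.window) / cfg.hop)) + 1

    def test_click_produces_local_maximum_near_onset(self):
        day = synthgen.gen_audio_day(
            [synthgen.ClickTrainSpec(2.0, 2, 5.0, snr_db=25.0)], day_length_s=20.0, rng_seed=4
        )
        cfg = DetectorConfig()
        env = band_energy_envelope(day.waveform, FS, cfg)
        # the train has clicks at 2 s and 7 s; each is a local maximum
        for onset in (2.0, 7.0):
            lo = int((onset - 1.0) / cfg.hop)
            hi = int((onset + 1.0) / cfg.hop)
            t_peak = (lo + np.argmax(env[lo:hi])) * cfg.hop
            assert abs(t_peak - onset) <= cfg.window + cfg.hop

    def test_shorter_than_window_errors(self):
        with pytest.raises(ValueError, match="shorter"):
            band_energy_envelope(np.zeros(10), FS)


class TestDetectCandidates:
    def test_flat_envelope_yields_nothing(self):
        assert detect_candidates(np.zeros(5000)) == []

    def test_single_excursion_yields_one_detection(self):
        cfg = DetectorConfig()
        env = np.zeros(5000)
        env[1000:1002] = 20.0  # 10 ms at 5 ms hop
        dets = detect_candidates(env, cfg)
        assert len(dets) == 1
        assert dets[0].time == pytest.approx(1000 * cfg.hop)
        assert dets[0].peak_excess >= cfg.snr_threshold

    def test_too_long_excursion_rejected(self):
        env = np.zeros(5000)
        env[1000:1030] = 20.0  # 150 ms > max_dur
        assert detect_candidates(env) == []

    def test_impulse_train_recovers_spacing(self):
        spec = synthgen.ClickTrainSpec(5.0, 8, 1.0, snr_db=20.0)
        day = synthgen.gen_audio_day([spec], day_length_s=30.0, rng_seed=7)
        times = detect_day_times(day.waveform, FS)
        assert len(times) == 8
        assert np.allclose(np.diff(times), 1.0, atol=DetectorConfig().hop)


class TestIdi:
    def test_examples(self):
        assert np.allclose(compute_idi([0.0, 1.0, 2.1]), [1.0, 1.1])
        assert compute_idi([3.0]).size == 0
        assert np.allclose(compute_idi([0, 0.5, 1.0, 1.5]), [0.5, 0.5, 0.5])

    def test_unsorted_or_duplicate_errors(self):
        with pytest.raises(ValueError):
            compute_idi([1.0, 0.5])
        with pytest.raises(ValueError):
            compute_idi([1.0, 1.0, 2.0])


class TestRoundQuarter:
    @pytest.mark.parametrize(
        "x,expected",
        [(1.1, 1.0), (0.51, 0.5), (0.625, 0.75), (0.875, 1.0), (2.0, 2.0), (0.3749, 0.25)],
    )
    def test_examples(self, x, expected):
        assert round_quarter(x) == pytest.approx(expected)

    @given(st.floats(min_value=0.01, max_value=100.0))
    @settings(max_examples=200)
    def test_within_eighth_of_input(self, x):
        assert abs(round_quarter(x) - x) <= 0.125 + 1e-12

    def test_nonpositive_errors(self):
        with pytest.raises(ValueError):
            round_quarter(0.0)
        with pytest.raises(ValueError):
            round_quarter(-1.0)


class TestFindClickSequences:
    def test_eight_regular_detections(self):
        seqs = find_click_sequences(np.arange(8.0), r=6)
        assert len(seqs) == 1
        assert seqs[0].n_intervals == 7
        assert seqs[0].rounded_idi == 1.0
        assert seqs[0].mean_ici == pytest.approx(1.0)

    def test_too_few_intervals_is_empty(self):
        assert find_click_sequences(np.arange(6.0), r=6) == []

    def test_out_of_range_idi_is_empty(self):
        assert find_click_sequences(np.arange(10.0) * 2.25, r=6) == []

    def test_boundary_idis_inclusive(self):
        assert len(find_click_sequences(np.arange(8.0) * 0.5, r=6)) == 1
        assert len(find_click_sequences(np.arange(8.0) * 2.0, r=6)) == 1

    def test_accepts_detection_objects(self):
        dets = [ClickDetection(time=float(t), peak_excess=10.0) for t in range(8)]
        assert len(find_click_sequences(dets, r=6)) == 1

    def test_run_terminates_at_rounded_value_change(self):
        times = np.concatenate([np.arange(8.0) * 0.5, 3.5 + np.arange(1, 8) * 1.0])
        seqs = find_click_sequences(times, r=6)
        assert [s.rounded_idi for s in seqs] == [0.5, 1.0]

    @given(
        st.lists(st.floats(min_value=0.05, max_value=3.0), min_size=1, max_size=30),
        st.integers(min_value=1, max_value=8),
    )
    @settings(max_examples=300, deadline=None)
    def test_matches_bruteforce_oracle(self, intervals, r):
        times = np.concatenate([[0.0], np.cumsum(intervals)])
        got = [(s.n_intervals, s.rounded_idi) for s in find_click_sequences(times, r)]
        expected = [(ln, v) for (_, ln, v) in brute_force_sequences(times, r)]
        assert got == expected

    def test_presence_monotone_in_r(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            times = np.cumsum(rng.choice([0.5, 1.0, 1.7, 2.6], size=rng.integers(2, 25)))
            present = [bool(find_click_sequences(times, r)) for r in range(1, 9)]
            # once absent at some r, absent for all larger r
            assert all(a or not b for a, b in zip(present, present[1:]))

    def test_never_constant_rounded_idis_rejected(self):
        # alternating rounded values can never satisfy r >= 2
        times = np.cumsum(np.tile([1.0, 1.5], 20))
        assert find_click_sequences(times, r=2) == []


class TestDailyCall:
    def test_positive_day_detected(self):
        day = synthgen.gen_audio_day(
            [synthgen.ClickTrainSpec(10.0, 8, 1.0, snr_db=20.0)], day_length_s=60.0, rng_seed=1
        )
        assert daily_call(day.waveform, FS, r=6).present

    def test_pure_noise_absent(self):
        day = synthgen.gen_audio_day([], day_length_s=60.0, rng_seed=2)
        call = daily_call(day.waveform, FS, r=6)
        assert not call.present and call.sequences == []

    def test_low_snr_day_absent(self):
        day = synthgen.gen_audio_day(
            [synthgen.ClickTrainSpec(10.0, 8, 1.0, snr_db=-10.0)], day_length_s=60.0, rng_seed=3
        )
        assert not daily_call(day.waveform, FS, r=6).present

    def test_irregular_transients_absent(self):
        rng = np.random.default_rng(8)
        transients = np.sort(rng.uniform(0, 110, 12))
        day = synthgen.gen_audio_day(
            [], day_length_s=120.0, rng_seed=8, transient_times=transients, transient_snr_db=20.0
        )
        call = daily_call(day.waveform, FS, r=6)
        assert call.n_candidates > 0  # the energy detector fires...
        assert not call.present  # ...but the interval filter rejects


class TestTuneR:
    def test_separable_corpus_perfect_at_r6(self):
        # positives: 7 aligned clicks (6 intervals); negatives: 6 (5 intervals)
        corpus = [(np.arange(7.0), True) for _ in range(10)]
        corpus += [(np.arange(6.0), False) for _ in range(10)]
        best_r, reports = tune_r(corpus)
        assert best_r == 6
        assert reports[6].balanced_accuracy == 1.0
        assert reports[5].fpr == 1.0  # negatives pass at looser r
        assert reports[7].recall == 0.0  # positives fail at stricter r

    def test_degenerate_corpus_errors(self):
        with pytest.raises(ValueError):
            tune_r([(np.arange(7.0), True)] * 3)


class TestConfusionMetrics:
    def test_perfect_predictions(self):
        rep = confusion_metrics([True, False] * 5, [True, False] * 5)
        assert rep.precision == rep.recall == rep.balanced_accuracy == 1.0
        assert rep.fpr == 0.0

    def test_printed_arithmetic(self):
        pred = [True] * 24 + [False] * 1 + [False] * 24 + [True] * 1
        truth = [True] * 25 + [False] * 25
        rep = confusion_metrics(pred, truth)
        assert (rep.tp, rep.fn, rep.tn, rep.fp) == (24, 1, 24, 1)
        assert rep.precision == pytest.approx(0.96)
        assert rep.recall == pytest.approx(0.96)
        assert rep.balanced_accuracy == pytest.approx(0.96)
        assert rep.fpr == pytest.approx(0.04)

    def test_all_positive_on_balanced_truth(self):
        rep = confusion_metrics([True] * 10, [True] * 5 + [False] * 5)
        assert rep.recall == 1.0 and rep.fpr == 1.0
        assert rep.balanced_accuracy == 0.5

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            confusion_metrics([True], [True, False])


class TestDailyNoiseLevel:
    def test_doubling_amplitude_adds_6dB(self):
        x = np.random.default_rng(0).normal(size=int(2 * FS))
        assert daily_noise_level(2 * x, FS) - daily_noise_level(x, FS) == pytest.approx(
            20 * np.log10(2), abs=1e-6
        )

    def test_deterministic(self):
        x = np.random.default_rng(1).normal(size=int(2 * FS))
        assert daily_noise_level(x, FS) == daily_noise_level(x.copy(), FS)

    def test_in_band_energy_beats_out_of_band(self):
        from scipy import signal

        rng = np.random.default_rng(2)
        white = rng.normal(size=int(4 * FS))
        sos_in = signal.butter(4, [1400, 4000], btype="bandpass", fs=FS, output="sos")
        sos_out = signal.butter(4, [5000, 7500], btype="bandpass", fs=FS, output="sos")
        inside = signal.sosfilt(sos_in, white)
        outside = signal.sosfilt(sos_out, white)
        inside *= np.std(white) / np.std(inside)
        outside *= np.std(white) / np.std(outside)
        assert daily_noise_level(inside, FS) > daily_noise_level(outside, FS)

    def test_too_short_errors(self):
        with pytest.raises(ValueError):
            daily_noise_level(np.zeros(100), FS)
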