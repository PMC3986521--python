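"""Preprocessing contracts: rejection, trimming, resampling, filtering,
standardization, lag embedding and labeling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from effortdecode import (EEGRecording, bandpass_delta, embed_lags,
                          label_rows, reject_peripheral, resample,
                          standardize, trim_transitions)
from effortdecode.errors import PreprocessingError, UsageError
from effortdecode.montage import MONTAGE_64
from effortdecode.types import EventSchedule, Segment


def eeg_from(data, rate=100.0, labels=None):
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if labels is None:
        labels = [f"ch{i}" for i in range(data.shape[0])]
    return EEGRecording(channel_labels=labels, rate=rate, data=data)


class TestRejectPeripheral:
    def test_default_list_keeps_39_of_64(self):
        eeg = eeg_from(np.zeros((64, 10)), labels=MONTAGE_64)
        out = reject_peripheral(eeg)
        assert out.n_channels == 39

    def test_empty_list_is_identity(self):
        eeg = eeg_from(np.arange(20.0).reshape(4, 5))
        out = reject_peripheral(eeg, reject=[])
        assert out.channel_labels == eeg.channel_labels
        assert np.array_equal(out.data, eeg.data)

    def test_rejecting_all_channels_errors(self):
        eeg = eeg_from(np.zeros((2, 5)), labels=["Cz", "Pz"])
        with pytest.raises(PreprocessingError):
            reject_peripheral(eeg, reject=["Cz", "Pz"])

    def test_unknown_labels_warn_not_fail(self):
        eeg = eeg_from(np.zeros((2, 5)), labels=["Cz", "Pz"])
        with pytest.warns(UserWarning, match="not present"):
            out = reject_peripheral(eeg, reject=["Pz", "XX9"])
        assert out.channel_labels == ["Cz"]

    def test_survivor_order_preserved(self):
        eeg = eeg_from(np.zeros((4, 5)), labels=["Pz", "Cz", "Fz", "Oz"])
        out = reject_peripheral(eeg, reject=["Cz"])
        assert out.channel_labels == ["Pz", "Fz", "Oz"]


class TestTrimTransitions:
    def test_500ms_both_ends(self):
        sched = EventSchedule([Segment(0.0, 10.0, "neutral")])
        out = trim_transitions(sched, 500.0)
        assert out.segments[0].start_s == pytest.approx(0.5)
        assert out.segments[0].end_s == pytest.approx(9.5)

    def test_zero_trim_is_identity(self):
        sched = EventSchedule([Segment(0.0, 10.0, "neutral")])
        out = trim_transitions(sched, 0.0)
        assert out.segments == sched.segments

    def test_short_segment_dropped_with_warning(self):
        sched = EventSchedule([Segment(0.0, 0.8, "neutral"),
                               Segment(1.0, 11.0, "think", "Flow", "free")])
        with pytest.warns(UserWarning, match="dropped"):
            out = trim_transitions(sched, 500.0)
        assert len(out) == 1
        assert out.segments[0].action == "think"


class TestResample:
    def test_length_arithmetic(self):
        eeg = eeg_from(np.random.default_rng(0).normal(size=(2, 10_000)),
                       rate=1000.0)
        out = resample(eeg, 100.0)
        assert out.n_samples == 1000
        assert out.rate == 100.0

    def test_dc_preserved(self):
        eeg = eeg_from(np.full((1, 5000), 3.25), rate=500.0)
        out = resample(eeg, 100.0)
        assert np.allclose(out.data, 3.25, atol=1e-9)

    def test_sinusoid_amplitude_preserved(self):
        # 2 Hz tone downsampled 1000 -> 100 Hz stays a 2 Hz unit tone
        t = np.arange(20_000) / 1000.0
        eeg = eeg_from(np.sin(2 * np.pi * 2.0 * t)[None, :], rate=1000.0)
        out = resample(eeg, 100.0)
        expect = np.sin(2 * np.pi * 2.0 * np.arange(out.n_samples) / 100.0)
        core = slice(50, -50)  # ignore filter edges
        assert np.max(np.abs(out.data[0][core] - expect[core])) < 0.01

    def test_upsampling_rejected(self):
        eeg = eeg_from(np.zeros((1, 100)), rate=100.0)
        with pytest.raises(UsageError):
            resample(eeg, 200.0)


class TestBandpass:
    def test_zero_phase_on_in_band_tone(self):
        t = np.arange(3000) / 100.0
        x = np.sin(2 * np.pi * 1.0 * t)
        out = bandpass_delta(eeg_from(x[None, :], rate=100.0)).data[0]
        xc = np.correlate(x - x.mean(), out - out.mean(), mode="full")
        lag = int(np.argmax(xc)) - (len(x) - 1)
        assert lag == 0

    def test_stopband_attenuation_at_20hz(self):
        # soft-gated tone: an abrupt onset/offset would inject broadband
        # (in-band) energy and mask the steady-state stop-band response,
        # which for the cascaded (forward-backward) filter is |H(20)|^2 ~ 2e-5
        from scipy.signal.windows import tukey
        t = np.arange(6000) / 100.0
        x = np.sin(2 * np.pi * 20.0 * t) * tukey(6000, 0.1)
        out = bandpass_delta(eeg_from(x[None, :], rate=100.0)).data[0]
        rms_in = np.sqrt(np.mean(x ** 2))
        assert np.sqrt(np.mean(out ** 2)) < 0.05 * rms_in

    def test_dc_removed(self):
        x = np.full(3000, 7.0)
        out = bandpass_delta(eeg_from(x[None, :], rate=100.0)).data[0]
        assert abs(out.mean()) < 1e-3 * 7.0

    def test_too_short_signal_errors(self):
        with pytest.raises(PreprocessingError, match="short"):
            bandpass_delta(eeg_from(np.zeros((1, 10)), rate=100.0))


class TestStandardize:
    def test_population_sd_convention(self):
        out = standardize(eeg_from([[1.0, 2.0, 3.0]]))
        expect = np.array([-1.0, 0.0, 1.0]) * np.sqrt(3.0 / 2.0)
        assert np.allclose(out.data[0], expect)

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        once = standardize(eeg_from(rng.normal(2, 5, size=(3, 500))))
        twice = standardize(once)
        assert np.allclose(once.data, twice.data, atol=1e-12)

    def test_constant_channel_errors_naming_channel(self):
        eeg = eeg_from(np.vstack([np.ones(10), np.arange(10.0)]),
                       labels=["Cz", "Pz"])
        with pytest.raises(PreprocessingError, match="Cz"):
            standardize(eeg)


class TestEmbedLags:
    def test_three_lag_example(self):
        fm = embed_lags(eeg_from([[1, 2, 3, 4, 5]]), l=3)
        assert np.array_equal(fm.X, [[1, 2, 3], [2, 3, 4], [3, 4, 5]])

    def test_column_count_is_channels_times_lags(self):
        eeg = eeg_from(np.random.default_rng(0).normal(size=(39, 50)))
        assert embed_lags(eeg, l=10).X.shape[1] == 390

    def test_single_lag_is_transpose(self):
        data = np.random.default_rng(0).normal(size=(3, 20))
        fm = embed_lags(eeg_from(data), l=1)
        assert np.array_equal(fm.X, data.T)

    def test_too_few_samples_errors(self):
        with pytest.raises(PreprocessingError):
            embed_lags(eeg_from([[1.0, 2.0]]), l=3)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(n=st.integers(3, 60), l=st.integers(1, 10), c=st.integers(1, 4))
    def test_row_bookkeeping(self, n, l, c):
        if n < l:
            return
        eeg = eeg_from(np.random.default_rng(0).normal(size=(c, n)))
        fm = embed_lags(eeg, l=l)
        assert fm.X.shape == (n - l + 1, c * l)
        assert fm.row_time[0] == pytest.approx((l - 1) / eeg.rate)


class TestLabelRows:
    def _fm(self, n=200, rate=100.0):
        return embed_lags(
            eeg_from(np.random.default_rng(0).normal(size=(1, n)), rate=rate),
            l=10)

    def test_single_segment_single_label(self):
        sched = EventSchedule([Segment(0.0, 2.0, "think", "Flow", "free")])
        out = label_rows(self._fm(), sched, "effort")
        assert set(out.y) == {"think-free-flow"}

    def test_rows_split_cleanly_across_segments(self):
        sched = EventSchedule([Segment(0.0, 1.0, "neutral"),
                               Segment(1.0, 2.0, "do", "Time", "quick")])
        out = label_rows(self._fm(), sched, "effort")
        assert set(out.y) == {"neutral", "do-quick-time"}
        switch = np.flatnonzero(out.y[:-1] != out.y[1:])
        assert len(switch) == 1

    def test_action_scheme_on_17_class_schedule(self, small_session):
        _, eeg, _, schedule = small_session
        out = label_rows(embed_lags(eeg, l=10), schedule, "action")
        assert sorted(set(out.y)) == ["do", "neutral", "think"]

    def test_no_rows_in_segments_errors(self):
        sched = EventSchedule([Segment(50.0, 51.0, "neutral")])
        with pytest.raises(PreprocessingError):
            label_rows(self._fm(), sched, "effort")
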