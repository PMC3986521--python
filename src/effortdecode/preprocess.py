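"""EEG preprocessing: channel rejection, transition trimming, resampling,
delta-band filtering, standardization, time-lag embedding and row labeling.

The canonical order is fixed::

    reject -> resample -> band-pass -> standardize -> embed -> label

Trimming is applied to the *schedule* (before labeling) rather than by
deleting samples, so the filters always see the full continuous recording.
"""

from __future__ import annotations

import warnings
from fractions import Fraction

import numpy as np
from scipy import signal

from .errors import PreprocessingError, UsageError
from .montage import DEFAULT_REJECT
from .types import (EEGRecording, EventSchedule, FeatureMatrix, Segment,
                    UNLABELED, schedule_to_labels)

__all__ = ["reject_peripheral", "trim_transitions", "resample",
           "bandpass_delta", "standardize", "embed_lags", "label_rows",
           "build_features", "DEFAULT_REJECT"]


def reject_peripheral(eeg: EEGRecording,
                      reject: list[str] | None = None) -> EEGRecording:
    """Drop peripheral channels; survivor order is preserved.

    ``reject`` defaults to the 25 outer-ring labels of the 64-channel
    montage (matched case-insensitively). Unknown labels warn.
    """
    if reject is None:
        reject = DEFAULT_REJECT
    reject_lc = {r.lower() for r in reject}
    have_lc = {c.lower() for c in eeg.channel_labels}
    unknown = sorted(r for r in reject if r.lower() not in have_lc)
    if unknown:
        warnings.warn(f"reject labels not present in recording: {unknown}")
    keep = [i for i, c in enumerate(eeg.channel_labels)
            if c.lower() not in reject_lc]
    if not keep:
        raise PreprocessingError("channel rejection leaves no channels")
    return eeg.copy_with(data=eeg.data[keep],
                         channel_labels=[eeg.channel_labels[i] for i in keep])


def trim_transitions(schedule: EventSchedule,
                     trim_ms: float = 500.0) -> EventSchedule:
    """Shrink every segment by ``trim_ms`` at both ends to drop condition-
    transition samples; segments shorter than ``2 * trim_ms`` are dropped."""
    if trim_ms < 0:
        raise UsageError("trim_ms must be nonnegative")
    trim = trim_ms / 1000.0
    out: list[Segment] = []
    dropped = 0
    for seg in schedule:
        if seg.end_s - seg.start_s <= 2 * trim:
            dropped += 1
            continue
        out.append(Segment(seg.start_s + trim, seg.end_s - trim,
                           seg.action, seg.factor, seg.element))
    if dropped:
        warnings.warn(f"trim_transitions dropped {dropped} segment(s) shorter "
                      f"than {2 * trim:.3f} s")
    return EventSchedule(out)


def resample(eeg: EEGRecording, target_rate: float = 100.0) -> EEGRecording:
    """Anti-aliased polyphase resampling to ``target_rate`` (down only)."""
    if target_rate > eeg.rate:
        raise UsageError(
            f"target rate {target_rate} Hz exceeds recording rate {eeg.rate} Hz")
    if target_rate == eeg.rate:
        return eeg.copy_with()
    frac = Fraction(target_rate / eeg.rate).limit_denominator(10_000)
    data = signal.resample_poly(eeg.data, frac.numerator, frac.denominator,
                                axis=1, padtype="mean")
    n_out = int(round(eeg.n_samples * target_rate / eeg.rate))
    return eeg.copy_with(data=data[:, :n_out], rate=target_rate)


def bandpass_delta(eeg: EEGRecording, low: float = 0.2, high: float = 4.0,
                   order: int = 3) -> EEGRecording:
    """Zero-phase Butterworth band-pass (forward-backward) to the delta band.

    The 0.2 Hz high-pass edge also removes slow drifts and DC offsets.
    """
    nyq = eeg.rate / 2.0
    if not 0 < low < high < nyq:
        raise UsageError(f"band ({low}, {high}) Hz invalid for rate {eeg.rate} Hz")
    sos = signal.butter(order, [low, high], btype="bandpass", fs=eeg.rate,
                        output="sos")
    # startup transients decay on the scale of the low cutoff's period, so
    # pad by a few of those periods (scipy's default pad is far too short)
    padlen = int(min(3.0 * eeg.rate / low, eeg.n_samples - 1))
    min_pad = 3 * (2 * sos.shape[0] + 1)
    if eeg.n_samples <= min_pad:
        raise PreprocessingError(
            f"signal of {eeg.n_samples} samples too short for zero-phase "
            f"filtering (needs > {min_pad})")
    return eeg.copy_with(
        data=signal.sosfiltfilt(sos, eeg.data, axis=1, padlen=padlen))


def standardize(eeg: EEGRecording, ddof: int = 0) -> EEGRecording:
    """Per-channel z-scoring over the whole trial (population SD by default)."""
    mean = eeg.data.mean(axis=1, keepdims=True)
    sd = eeg.data.std(axis=1, ddof=ddof, keepdims=True)
    bad = np.flatnonzero(sd.ravel() == 0)
    if bad.size:
        names = [eeg.channel_labels[i] for i in bad]
        raise PreprocessingError(f"zero-variance channel(s): {names}")
    return eeg.copy_with(data=(eeg.data - mean) / sd)


def embed_lags(eeg: EEGRecording, l: int = 10) -> FeatureMatrix:
    """Time-lag embedding: row for time ``t_n`` concatenates, channel by
    channel, the samples ``t_n-(l-1) ... t_n`` (``N * l`` columns).

    The first row corresponds to the ``l``-th sample of the recording, so no
    row contains out-of-recording data.
    """
    if l < 1:
        raise UsageError("lag count l must be >= 1")
    if eeg.n_samples < l:
        raise PreprocessingError(
            f"{eeg.n_samples} samples cannot support l={l} lags")
    windows = np.lib.stride_tricks.sliding_window_view(eeg.data, l, axis=1)
    # (channels, rows, l) -> (rows, channels * l)
    X = np.ascontiguousarray(windows.transpose(1, 0, 2)).reshape(
        eeg.n_samples - l + 1, eeg.n_channels * l)
    row_time = (np.arange(l - 1, eeg.n_samples)) / eeg.rate
    return FeatureMatrix(X=X, row_time=row_time,
                         channel_labels=list(eeg.channel_labels), l=l,
                         rate=eeg.rate)


def label_rows(fm: FeatureMatrix, schedule: EventSchedule,
               scheme: str = "effort") -> FeatureMatrix:
    """Label every row by the segment containing its timestamp; rows outside
    all segments are dropped."""
    labels = _labels_at(schedule, fm.row_time, scheme)
    keep = labels != UNLABELED
    if not keep.any():
        raise PreprocessingError("no feature rows fall inside labeled segments")
    return FeatureMatrix(X=fm.X[keep], row_time=fm.row_time[keep],
                         channel_labels=fm.channel_labels, l=fm.l,
                         rate=fm.rate, y=labels[keep])


def _labels_at(schedule: EventSchedule, times: np.ndarray,
               scheme: str) -> np.ndarray:
    labels = np.full(times.shape[0], UNLABELED, dtype=object)
    for seg in schedule:
        mask = (times >= seg.start_s - 1e-9) & (times < seg.end_s - 1e-9)
        labels[mask] = seg.label(scheme)
    return labels


def build_features(eeg: EEGRecording, schedule: EventSchedule, *,
                   reject: list[str] | None = None,
                   target_rate: float = 100.0,
                   band: tuple[float, float] = (0.2, 4.0),
                   filter_order: int = 3,
                   l: int = 10,
                   trim_ms: float = 500.0,
                   scheme: str = "effort") -> FeatureMatrix:
    """Full preprocessing chain from raw recording to labeled feature rows."""
    eeg = reject_peripheral(eeg, reject)
    eeg = resample(eeg, target_rate)
    eeg = bandpass_delta(eeg, band[0], band[1], filter_order)
    eeg = standardize(eeg)
    fm = embed_lags(eeg, l)
    trimmed = trim_transitions(schedule, trim_ms)
    return label_rows(fm, trimmed, scheme)
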