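"""Motion-artifact quality control: acceleration PCA, EEG-acceleration
cross-correlation maps, spectrograms, Welch coherence and the
F1-versus-correlation audit.

"Raw EEG" here means resampled (e.g. to 100 Hz) but unfiltered data: the QC
asks how much of the broadband recording the body movement explains, before
the decoding band-pass."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal, stats

from .errors import NumericError, UsageError
from .types import (EEGRecording, EventSchedule, MARGRecording, UNLABELED,
                    schedule_to_labels)

__all__ = ["pca_acceleration", "crosscorr_map", "crosscorr_by_class",
           "spectrogram", "msc_coherence", "f1_vs_correlation",
           "resample_series"]


@dataclass
class AccelerationPCA:
    """PCA of the per-sensor acceleration-magnitude time series."""

    scores: np.ndarray            # samples x components
    variance_fractions: np.ndarray
    components: np.ndarray        # components x sensors
    kurtosis_by_class: pd.Series | None = None  # PC1, plain convention


def pca_acceleration(marg: MARGRecording,
                     schedule: EventSchedule | None = None,
                     scheme: str = "effort") -> AccelerationPCA:
    """Mean-centered PCA over sensors of the acceleration magnitudes.

    Variables are the per-sensor magnitude series (one per sensor), so PC1 is
    the dominant whole-body movement "synergy". Kurtosis of the PC1 scores is
    reported per class in the plain convention (Gaussian = 3) when a schedule
    is supplied.
    """
    mags = marg.magnitudes()          # sensors x samples
    if mags.shape[1] < 2:
        raise UsageError("need at least 2 time samples for PCA")
    centered = mags - mags.mean(axis=1, keepdims=True)
    if np.allclose(centered, 0.0):
        raise NumericError("acceleration magnitudes are constant")
    # SVD on samples x sensors
    U, s, Vt = np.linalg.svd(centered.T, full_matrices=False)
    var = s ** 2
    fractions = var / var.sum()
    scores = U * s
    kurt = None
    if schedule is not None:
        labels = schedule_to_labels(schedule, marg.rate, scheme,
                                    n_samples=mags.shape[1])
        pc1 = scores[:, 0]
        values = {}
        for lab in schedule.labels(scheme):
            x = pc1[labels == lab]
            if x.size > 3:
                values[lab] = float(stats.kurtosis(x, fisher=False))
        kurt = pd.Series(values, name="kurtosis_pc1")
    return AccelerationPCA(scores=scores, variance_fractions=fractions,
                           components=Vt, kurtosis_by_class=kurt)


def resample_series(x: np.ndarray, rate_in: float, rate_out: float,
                    n_out: int) -> np.ndarray:
    """Linear interpolation of a 1-D series onto a new sample grid."""
    t_in = np.arange(len(x)) / rate_in
    t_out = np.arange(n_out) / rate_out
    return np.interp(t_out, t_in, x)


def _pearson_channels(data: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Zero-lag Pearson r of every row of ``data`` with ``ref``."""
    dc = data - data.mean(axis=1, keepdims=True)
    rc = ref - ref.mean()
    denom = np.sqrt((dc ** 2).sum(axis=1) * (rc ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (dc @ rc) / denom
    return np.where(denom > 0, rho, 0.0)


def crosscorr_map(eeg: EEGRecording, reference: np.ndarray,
                  schedule: EventSchedule, class_label: str,
                  scheme: str = "effort") -> pd.DataFrame:
    """Per-channel zero-lag Pearson rho (and rho^2) between the EEG and a
    movement reference over the concatenated samples of one class.

    ``reference`` must already live on the EEG sample grid (same rate and
    length); use :func:`resample_series` to interpolate accelerometer data.
    """
    reference = np.asarray(reference, dtype=float)
    if reference.shape[0] != eeg.n_samples:
        raise UsageError("reference length must match the EEG recording")
    labels = schedule_to_labels(schedule, eeg.rate, scheme,
                                n_samples=eeg.n_samples)
    mask = labels == class_label
    if not mask.any():
        raise UsageError(f"class {class_label!r} has no samples in schedule")
    rho = _pearson_channels(eeg.data[:, mask], reference[mask])
    return pd.DataFrame({"channel": eeg.channel_labels, "rho": rho,
                         "rho2": rho ** 2}).set_index("channel")


def crosscorr_by_class(eeg: EEGRecording, reference: np.ndarray,
                       schedule: EventSchedule,
                       scheme: str = "effort") -> pd.DataFrame:
    """Long-format per-(class, channel) rho and rho^2 table."""
    frames = []
    for lab in schedule.labels(scheme):
        tab = crosscorr_map(eeg, reference, schedule, lab, scheme)
        tab = tab.reset_index()
        tab.insert(0, "class", lab)
        frames.append(tab)
    return pd.concat(frames, ignore_index=True)


def spectrogram(x: np.ndarray, rate: float, window: int = 1024,
                overlap: float = 0.93, band: tuple[float, float] = (0.1, 40.0)):
    """Short-time Fourier power of a 1-D signal.

    Returns ``(freqs, times, power)`` restricted to ``band``; the hop is
    ``window * (1 - overlap)`` rounded to at least one sample.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < window:
        raise UsageError(f"signal of {len(x)} samples shorter than window "
                         f"{window}")
    hop = max(int(round(window * (1.0 - overlap))), 1)
    f, t, S = signal.spectrogram(x, fs=rate, window="hann", nperseg=window,
                                 noverlap=window - hop, mode="psd")
    keep = (f >= band[0]) & (f <= band[1])
    return f[keep], t, S[keep]


def msc_coherence(x: np.ndarray, y: np.ndarray, rate: float,
                  nperseg: int = 1024, overlap: float = 0.5):
    """Magnitude-squared coherence via Welch overlapped-segment averaging.

    Returns ``(freqs, coherence)`` with coherence in [0, 1]. At least two
    averaged segments are required (with one segment the estimate is
    identically 1 and carries no information).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise UsageError("signals must have equal length")
    noverlap = int(round(nperseg * overlap))
    if len(x) < 2 * nperseg - noverlap:
        raise UsageError(f"need >= 2 Welch segments: {len(x)} samples with "
                         f"nperseg={nperseg}, overlap={overlap}")
    f, Cxy = signal.coherence(x, y, fs=rate, window="hann", nperseg=nperseg,
                              noverlap=noverlap)
    return f, np.clip(Cxy, 0.0, 1.0)


def f1_vs_correlation(f1_by_class, median_rho_by_class, *,
                      n_perm: int = 10_000, seed: int = 0):
    """Pair each class's F1 score with its median channel rho and test for a
    positive rank association.

    Returns ``(table, spearman_rho, p_value)`` where ``p_value`` is the
    one-sided (positive association) permutation p-value. A constant input
    yields rank correlation 0 by convention (p = 1).
    """
    f1 = pd.Series(dict(f1_by_class), dtype=float)
    rho = pd.Series(dict(median_rho_by_class), dtype=float)
    if set(f1.index) != set(rho.index):
        raise UsageError("class sets of F1 and correlation tables differ")
    rho = rho.reindex(f1.index)
    table = pd.DataFrame({"median_rho": rho, "f1": f1})
    if f1.nunique() <= 1 or rho.nunique() <= 1:
        return table, 0.0, 1.0
    obs = float(stats.spearmanr(rho.values, f1.values).statistic)
    rng = np.random.default_rng(seed)
    perm = np.empty(n_perm)
    ranks_rho = stats.rankdata(rho.values)
    ranks_f1 = stats.rankdata(f1.values)
    for i in range(n_perm):
        perm[i] = np.corrcoef(ranks_rho, rng.permutation(ranks_f1))[0, 1]
    p = float((1 + np.sum(perm >= obs)) / (1 + n_perm))
    return table, obs, p
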