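"""Synthetic EEG + inertial sessions with the statistical structure the
decoding pipeline assumes.

The generator emulates one recording session of expressive whole-body
movement: trial blocks of a neutral segment followed by think/do segments for
each of the eight Laban effort elements (17 classes in total). EEG channels
carry 1/f-shaped background noise plus class-conditional narrow-band
delta (0.2-4 Hz) components mixed through class-specific spatial patterns;
the inertial array carries class-conditional movement-intensity envelopes;
an optional linear admixture of head-acceleration magnitude into the EEG
emulates mechanical motion artifacts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import signal

from .errors import ConfigurationError
from .montage import SENSOR_ROLES, montage_labels
from .types import (CONDENSING, ELEMENT_FACTOR, EEGRecording, EventSchedule,
                    MARGRecording, Segment, schedule_to_labels)

__all__ = ["SessionConfig", "generate_session", "default_effort_sequence",
            "schedule_to_labels", "head_acceleration_reference"]


def default_effort_sequence() -> list[tuple[str, str]]:
    """Condensing element first within each factor, all 8 elements once."""
    return [
        ("Space", "direct"), ("Space", "indirect"),
        ("Flow", "bound"), ("Flow", "free"),
        ("Weight", "strong"), ("Weight", "light"),
        ("Time", "quick"), ("Time", "sustained"),
    ]


# Relative movement intensity and log-normal envelope spread per condition.
# "Do" segments differentiate strongly by element (light/sustained movements
# are small and steady, free/quick are large and bursty); neutral and think
# segments are ordinary functional movement.
_MOVE_INTENSITY = {
    ("neutral", None): (1.0, 0.30),
    ("think", None): (1.0, 0.30),
    ("do", "direct"): (1.2, 0.35),
    ("do", "indirect"): (1.5, 0.45),
    ("do", "bound"): (0.8, 0.25),
    ("do", "free"): (2.5, 0.80),
    ("do", "strong"): (1.8, 0.50),
    ("do", "light"): (0.3, 0.15),
    ("do", "quick"): (2.2, 0.90),
    ("do", "sustained"): (0.4, 0.15),
}

_ROLE_SCALE = {
    "head": 0.5, "torso": 0.6, "lumbar": 0.6,
    "arm_l": 1.2, "arm_r": 1.2, "thigh_l": 0.8, "thigh_r": 0.8,
    "shank_l": 1.0, "shank_r": 1.0, "foot": 1.3,
}


@dataclass
class SessionConfig:
    """Parameters of one simulated recording session.

    ``class_snr`` and ``artifact_coupling`` may be a single number applied to
    every class or a mapping from class label (effort scheme) to a value;
    ``class_snr`` is the amplitude of the class-specific delta-band component
    relative to the unit-variance EEG background, ``artifact_coupling`` the
    per-class admixture weight kappa in [0, 1] of standardized head
    acceleration into the EEG.
    """

    n_eeg_channels: int = 64
    eeg_rate: float = 1000.0
    n_sensors: int = 10
    marg_rate: float = 128.0
    n_trial_blocks: int = 3
    segment_duration_s: float = 10.0
    effort_sequence: Sequence[tuple[str, str]] = field(
        default_factory=default_effort_sequence)
    class_snr: float | Mapping[str, float] = 1.0
    artifact_coupling: float | Mapping[str, float] = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_eeg_channels < 1:
            raise ConfigurationError("n_eeg_channels must be >= 1")
        if self.eeg_rate <= 0:
            raise ConfigurationError("eeg_rate must be positive")
        if self.n_sensors < 1 or self.n_sensors > len(SENSOR_ROLES):
            raise ConfigurationError(
                f"n_sensors must be in [1, {len(SENSOR_ROLES)}]")
        if self.marg_rate <= 0:
            raise ConfigurationError("marg_rate must be positive")
        if self.n_trial_blocks < 1:
            raise ConfigurationError("n_trial_blocks must be >= 1")
        if self.segment_duration_s <= 0:
            raise ConfigurationError("segment_duration_s must be positive")
        seq = list(self.effort_sequence)
        elements = [e for _, e in seq]
        if sorted(elements) != sorted(ELEMENT_FACTOR):
            raise ConfigurationError(
                "effort_sequence must contain each of the 8 elements exactly once")
        for factor, element in seq:
            if ELEMENT_FACTOR.get(element) != factor:
                raise ConfigurationError(
                    f"effort_sequence pairs element {element!r} with factor "
                    f"{factor!r}")
        # condensing element must precede the indulging one within a factor
        pos = {e: i for i, (_, e) in enumerate(seq)}
        for cond in CONDENSING:
            factor = ELEMENT_FACTOR[cond]
            indulging = next(e for e, f in ELEMENT_FACTOR.items()
                             if f == factor and e != cond)
            if pos[cond] > pos[indulging]:
                raise ConfigurationError(
                    f"effort_sequence: condensing element {cond!r} must precede "
                    f"indulging {indulging!r} within factor {factor!r}")
        for name, value in (("class_snr", self.class_snr),
                            ("artifact_coupling", self.artifact_coupling)):
            values = (value.values() if isinstance(value, Mapping) else [value])
            for v in values:
                if v < 0:
                    raise ConfigurationError(f"{name} must be nonnegative")
                if name == "artifact_coupling" and v > 1:
                    raise ConfigurationError("artifact_coupling must be <= 1")

    def build_schedule(self) -> EventSchedule:
        """Back-to-back segments: per block, neutral then think/do per effort."""
        self.validate()
        dur = self.segment_duration_s
        segments: list[Segment] = []
        t = 0.0
        for _ in range(self.n_trial_blocks):
            segments.append(Segment(t, t + dur, "neutral"))
            t += dur
            for factor, element in self.effort_sequence:
                for action in ("think", "do"):
                    segments.append(Segment(t, t + dur, action, factor, element))
                    t += dur
        return EventSchedule(segments)


def _per_class(value: float | Mapping[str, float], label: str) -> float:
    if isinstance(value, Mapping):
        return float(value.get(label, 0.0))
    return float(value)


def _seg_indices(seg: Segment, rate: float, n: int) -> slice:
    i0 = int(np.ceil(seg.start_s * rate - 1e-9))
    i1 = int(np.ceil(seg.end_s * rate - 1e-9))
    return slice(max(i0, 0), min(i1, n))


def _pink_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    """Unit-variance noise with 1/f power shaping."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1] if n > 1 else 1.0
    spec *= f ** -0.5
    x = np.fft.irfft(spec, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _narrowband(rng: np.random.Generator, n: int, rate: float,
                f_center: float, half_width: float = 0.4) -> np.ndarray:
    """Unit-variance band-limited Gaussian process around ``f_center``."""
    lo = max(f_center - half_width, 0.05)
    hi = min(f_center + half_width, 0.45 * rate)
    sos = signal.butter(2, [lo, hi], btype="bandpass", fs=rate, output="sos")
    x = signal.sosfilt(sos, rng.standard_normal(n + int(2 * rate)))[int(2 * rate):]
    sd = x.std()
    return x / sd if sd > 0 else x


def _smooth_noise(rng: np.random.Generator, n: int, rate: float,
                  cutoff: float = 0.3) -> np.ndarray:
    sos = signal.butter(2, min(cutoff, 0.45 * rate), btype="lowpass",
                        fs=rate, output="sos")
    x = signal.sosfilt(sos, rng.standard_normal(n + int(2 * rate)))[int(2 * rate):]
    sd = x.std()
    return x / sd if sd > 0 else x


def head_acceleration_reference(marg: MARGRecording, eeg_rate: float,
                                n_samples: int) -> np.ndarray:
    """Standardized head-sensor acceleration magnitude on the EEG grid."""
    head = marg.magnitudes()[marg.sensor_roles.index("head")]
    t_marg = np.arange(marg.n_samples) / marg.rate
    t_eeg = np.arange(n_samples) / eeg_rate
    ref = np.interp(t_eeg, t_marg, head)
    sd = ref.std()
    return (ref - ref.mean()) / sd if sd > 0 else ref - ref.mean()


def generate_session(config: SessionConfig
                     ) -> tuple[EEGRecording, MARGRecording, EventSchedule]:
    """Simulate one session; deterministic for a fixed ``config.seed``."""
    config.validate()
    schedule = config.build_schedule()
    rng = np.random.default_rng(config.seed)

    duration = schedule.duration_s
    n_eeg = int(round(duration * config.eeg_rate))
    n_marg = int(round(duration * config.marg_rate))
    n_ch = config.n_eeg_channels

    # -- class-conditional generative parameters (fixed by seed) ------------
    # spatial mixing patterns have unit RMS across channels, so class_snr is
    # the per-channel amplitude of the class component relative to the
    # unit-variance broadband background
    labels17 = schedule.labels("effort")
    patterns = {}
    freqs = {}
    for lab in labels17:
        patterns[lab] = rng.standard_normal(n_ch)
        freqs[lab] = rng.uniform(0.6, 3.8)
    artifact_pattern = rng.standard_normal(n_ch)
    artifact_pattern /= np.linalg.norm(artifact_pattern)
    artifact_pattern *= np.sqrt(n_ch)  # unit RMS across channels

    # -- inertial streams ---------------------------------------------------
    roles = SENSOR_ROLES[:config.n_sensors]
    intensity = np.ones(n_marg)
    spread = np.full(n_marg, 0.3)
    for seg in schedule:
        sl = _seg_indices(seg, config.marg_rate, n_marg)
        base, sigma = _MOVE_INTENSITY[
            (seg.action, seg.element if seg.action == "do" else None)]
        intensity[sl] = base
        spread[sl] = sigma
    accel = np.empty((len(roles), 3, n_marg))
    for s, role in enumerate(roles):
        g = _smooth_noise(rng, n_marg, config.marg_rate)
        envelope = np.exp(spread * g - 0.5 * spread ** 2)
        for axis in range(3):
            base = _smooth_noise(rng, n_marg, config.marg_rate, cutoff=8.0)
            accel[s, axis] = (2.0 * _ROLE_SCALE.get(role, 1.0)
                              * intensity * envelope * base)
    marg = MARGRecording(sensor_roles=list(roles), rate=config.marg_rate,
                         accel=accel)

    # -- EEG ----------------------------------------------------------------
    eeg_data = np.empty((n_ch, n_eeg))
    for c in range(n_ch):
        eeg_data[c] = _pink_noise(rng, n_eeg)

    for seg in schedule:
        sl = _seg_indices(seg, config.eeg_rate, n_eeg)
        n_seg = sl.stop - sl.start
        if n_seg <= 0:
            continue
        lab = seg.label("effort")
        snr = _per_class(config.class_snr, lab)
        if snr > 0:
            course = _narrowband(rng, n_seg, config.eeg_rate, freqs[lab])
            eeg_data[:, sl] += snr * np.outer(patterns[lab], course)

    kappa_any = (any(v > 0 for v in config.artifact_coupling.values())
                 if isinstance(config.artifact_coupling, Mapping)
                 else config.artifact_coupling > 0)
    if kappa_any:
        ref = head_acceleration_reference(marg, config.eeg_rate, n_eeg)
        for seg in schedule:
            sl = _seg_indices(seg, config.eeg_rate, n_eeg)
            kappa = _per_class(config.artifact_coupling, seg.label("effort"))
            if kappa > 0:
                eeg_data[:, sl] += kappa * np.outer(artifact_pattern, ref[sl])

    eeg = EEGRecording(channel_labels=montage_labels(n_ch),
                       rate=config.eeg_rate, data=10.0 * eeg_data)
    return eeg, marg, schedule
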