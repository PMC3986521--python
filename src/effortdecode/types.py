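"""Core in-memory containers: recordings, event schedules, class labels.

Class labels follow one of two schemes:

* ``action`` — three classes: ``neutral``, ``think``, ``do``.
* ``effort`` — seventeen classes: ``neutral`` plus ``{think,do}-{element}-{factor}``
  for the eight Laban effort elements (e.g. ``think-free-flow``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import ScheduleError, UsageError

ACTIONS = ("neutral", "think", "do")
FACTORS = ("Space", "Flow", "Weight", "Time")

#: element -> factor for the four Laban effort factors.
ELEMENT_FACTOR = {
    "indirect": "Space", "direct": "Space",
    "free": "Flow", "bound": "Flow",
    "light": "Weight", "strong": "Weight",
    "sustained": "Time", "quick": "Time",
}

#: "Indulging" elements map to +1 on their factor axis, "condensing" to -1.
ELEMENT_SIGN = {
    "indirect": +1, "direct": -1,
    "free": +1, "bound": -1,
    "light": +1, "strong": -1,
    "sustained": +1, "quick": -1,
}

INDULGING = tuple(e for e, s in ELEMENT_SIGN.items() if s > 0)
CONDENSING = tuple(e for e, s in ELEMENT_SIGN.items() if s < 0)

UNLABELED = "unlabeled"


def class_label(action: str, factor: str | None, element: str | None,
                scheme: str = "effort") -> str:
    """Class label of a (action, factor, element) condition under a scheme."""
    if scheme == "action":
        return action
    if scheme != "effort":
        raise UsageError(f"unknown scheme {scheme!r}; expected 'action' or 'effort'")
    if action == "neutral":
        return "neutral"
    return f"{action}-{element}-{factor.lower()}"


def effort_class_labels() -> list[str]:
    """The 17 labels of the effort scheme, in a fixed order."""
    labels = ["neutral"]
    for action in ("think", "do"):
        for element, factor in ELEMENT_FACTOR.items():
            labels.append(f"{action}-{element}-{factor.lower()}")
    return labels


@dataclass(frozen=True)
class Segment:
    """Half-open labeled interval ``[start_s, end_s)`` in session time."""

    start_s: float
    end_s: float
    action: str
    factor: str | None = None
    element: str | None = None

    def __post_init__(self):
        if not self.end_s > self.start_s:
            raise ScheduleError(
                f"segment end {self.end_s} must exceed start {self.start_s}")
        if self.action not in ACTIONS:
            raise ScheduleError(f"unknown action {self.action!r}")
        factor = self.factor if self.factor not in ("none", "") else None
        element = self.element if self.element not in ("none", "") else None
        object.__setattr__(self, "factor", factor)
        object.__setattr__(self, "element", element)
        if self.action == "neutral":
            if factor is not None or element is not None:
                raise ScheduleError("neutral segments carry no factor/element")
        else:
            if element not in ELEMENT_FACTOR:
                raise ScheduleError(f"unknown effort element {element!r}")
            if factor != ELEMENT_FACTOR[element]:
                raise ScheduleError(
                    f"element {element!r} belongs to factor "
                    f"{ELEMENT_FACTOR[element]!r}, not {factor!r}")

    def label(self, scheme: str = "effort") -> str:
        return class_label(self.action, self.factor, self.element, scheme)


@dataclass
class EventSchedule:
    """Sorted, non-overlapping labeled segments of a session."""

    segments: list[Segment]

    def __post_init__(self):
        segs = list(self.segments)
        for a, b in zip(segs, segs[1:]):
            if b.start_s < a.start_s:
                raise ScheduleError("segments must be sorted by start time")
            if b.start_s < a.end_s:
                raise ScheduleError(
                    f"segments overlap at {b.start_s:.3f} s "
                    f"({a.label()} vs {b.label()})")
        self.segments = segs

    def __len__(self) -> int:
        return len(self.segments)

    def __iter__(self):
        return iter(self.segments)

    @property
    def duration_s(self) -> float:
        return self.segments[-1].end_s if self.segments else 0.0

    def labels(self, scheme: str = "effort") -> list[str]:
        """Distinct class labels present, in first-appearance order."""
        seen: dict[str, None] = {}
        for seg in self.segments:
            seen.setdefault(seg.label(scheme))
        return list(seen)


def schedule_to_labels(schedule: EventSchedule, rate: float, scheme: str = "effort",
                       n_samples: int | None = None) -> np.ndarray:
    """Per-sample class labels for a sample grid ``t_i = i / rate``.

    Samples falling outside every segment are labeled ``"unlabeled"``.
    """
    if rate <= 0:
        raise UsageError("rate must be positive")
    if n_samples is None:
        n_samples = int(round(schedule.duration_s * rate))
    # validate scheme eagerly even for empty schedules
    class_label("neutral", None, None, scheme)
    labels = np.full(n_samples, UNLABELED, dtype=object)
    t = np.arange(n_samples) / rate
    for seg in schedule:
        mask = (t >= seg.start_s) & (t < seg.end_s)
        labels[mask] = seg.label(scheme)
    return labels


@dataclass
class EEGRecording:
    """Multichannel EEG: ``data`` is channels x samples, microvolt scale."""

    channel_labels: list[str]
    rate: float
    data: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise UsageError("EEG data must be 2-D (channels x samples)")
        if len(self.channel_labels) != self.data.shape[0]:
            raise UsageError(
                f"{len(self.channel_labels)} labels for "
                f"{self.data.shape[0]} data rows")
        if self.rate <= 0:
            raise UsageError("sampling rate must be positive")
        if not np.all(np.isfinite(self.data)):
            raise UsageError("EEG data contains non-finite values")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def copy_with(self, *, data=None, rate=None, channel_labels=None) -> "EEGRecording":
        return EEGRecording(
            channel_labels=list(self.channel_labels if channel_labels is None
                                else channel_labels),
            rate=self.rate if rate is None else rate,
            data=self.data.copy() if data is None else data,
        )


@dataclass
class MARGRecording:
    """Inertial array: ``accel`` is sensors x 3 axes x samples (gravity-
    compensated acceleration, m/s^2)."""

    sensor_roles: list[str]
    rate: float
    accel: np.ndarray

    def __post_init__(self):
        self.accel = np.asarray(self.accel, dtype=float)
        if self.accel.ndim != 3 or self.accel.shape[1] != 3:
            raise UsageError("accel must be sensors x 3 x samples")
        if len(self.sensor_roles) != self.accel.shape[0]:
            raise UsageError("sensor role count does not match accel")
        if self.rate <= 0:
            raise UsageError("sampling rate must be positive")
        if not np.all(np.isfinite(self.accel)):
            raise UsageError("acceleration contains non-finite values")

    @property
    def n_sensors(self) -> int:
        return self.accel.shape[0]

    @property
    def n_samples(self) -> int:
        return self.accel.shape[2]

    def magnitudes(self) -> np.ndarray:
        """Per-sensor Euclidean acceleration magnitude (sensors x samples)."""
        return np.linalg.norm(self.accel, axis=1)


@dataclass
class FeatureMatrix:
    """Lag-embedded feature rows with optional per-row labels.

    ``X`` has one column block of ``l`` lags per retained channel, in
    channel order; ``row_time[i]`` is the timestamp of the most recent lag
    in row ``i``.
    """

    X: np.ndarray
    row_time: np.ndarray
    channel_labels: list[str]
    l: int
    rate: float
    y: np.ndarray | None = None

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.row_time = np.asarray(self.row_time, dtype=float)
        if self.X.shape[0] != self.row_time.shape[0]:
            raise UsageError("row_time length must match X rows")
        if self.X.shape[1] != len(self.channel_labels) * self.l:
            raise UsageError("X columns must equal n_channels * l")
        if self.y is not None:
            self.y = np.asarray(self.y, dtype=object)
            if self.y.shape[0] != self.X.shape[0]:
                raise UsageError("y length must match X rows")

    @property
    def n_rows(self) -> int:
        return self.X.shape[0]

    def channel_columns(self, labels: Sequence[str]) -> np.ndarray:
        """Column indices of the lag blocks of the given channels."""
        cols: list[int] = []
        for lab in labels:
            try:
                j = self.channel_labels.index(lab)
            except ValueError:
                raise UsageError(f"channel {lab!r} not in feature matrix")
            cols.extend(range(j * self.l, (j + 1) * self.l))
        return np.asarray(cols, dtype=int)

    def restrict_channels(self, labels: Sequence[str]) -> "FeatureMatrix":
        cols = self.channel_columns(labels)
        return FeatureMatrix(X=self.X[:, cols], row_time=self.row_time,
                             channel_labels=list(labels), l=self.l,
                             rate=self.rate, y=self.y)
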