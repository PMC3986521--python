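"""Readers and writers for the on-disk formats the pipeline touches.

* EEG: plain CSV (one column per channel, rate carried in a ``# rate_hz=``
  sidecar line) or a BrainVision triplet (``.vhdr/.vmrk/.eeg``, read through
  MNE; written as 32-bit float multiplexed binary).
* Kinematics: CSV with one ``<role>_<axis>`` column per sensor axis.
* Event schedules: TSV with ``start_s  end_s  action  factor  element``.
* Run configuration: YAML/JSON; reports: CSV tables, PNG figures and a JSON
  manifest recording the configuration and seed of the run.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import FormatError, ScheduleError, UsageError
from .types import (EEGRecording, EventSchedule, MARGRecording, Segment)

__all__ = ["RunConfig", "read_eeg", "write_eeg", "read_events", "write_events",
           "read_kinematics", "write_kinematics", "write_report"]


@dataclass
class RunConfig:
    """Parameters of one decoding run (preprocessing + model + CV)."""

    channel_reject_list: list[str] | None = None  # None -> default 25 labels
    target_rate: float = 100.0
    band: tuple[float, float] = (0.2, 4.0)
    filter_order: int = 3
    lags: int = 10
    trim_ms: float = 500.0
    scheme: str = "effort"
    r: int = 70
    k_nn: int = 7
    K_max: int = 10
    pct_train: float = 50.0
    n_iter: int = 10
    seed: int = 0

    def __post_init__(self):
        self.band = tuple(self.band)
        low, high = self.band
        if not 0 < low < high < self.target_rate / 2:
            raise UsageError(f"band {self.band} invalid for target rate "
                             f"{self.target_rate}")
        if self.lags < 1:
            raise UsageError("lags must be >= 1")
        if not 0 < self.pct_train < 100:
            raise UsageError("pct_train must lie in (0, 100)")
        if self.scheme not in ("action", "effort"):
            raise UsageError(f"unknown scheme {self.scheme!r}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["band"] = list(self.band)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise UsageError(f"unknown config fields: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# EEG

def _read_rate_line(fh, path) -> float:
    line = fh.readline().strip()
    if not line.startswith("# rate_hz="):
        raise FormatError(f"{path}: missing '# rate_hz=' sidecar line")
    try:
        return float(line.split("=", 1)[1])
    except ValueError:
        raise FormatError(f"{path}: unparseable rate in {line!r}")


def write_eeg(eeg: EEGRecording, path, dialect: str = "csv") -> None:
    """Write a recording as CSV (default) or a BrainVision triplet."""
    path = Path(path)
    if dialect == "csv":
        with open(path, "w") as fh:
            fh.write(f"# rate_hz={eeg.rate!r}\n")
            fh.write(",".join(eeg.channel_labels) + "\n")
            np.savetxt(fh, eeg.data.T, delimiter=",", fmt="%.10g")
    elif dialect == "brainvision":
        _write_brainvision(eeg, path)
    else:
        raise UsageError(f"unknown EEG dialect {dialect!r}")


def read_eeg(path, dialect: str = "csv") -> EEGRecording:
    """Read an EEG recording; channel labels are preserved verbatim."""
    path = Path(path)
    if dialect == "csv":
        with open(path) as fh:
            rate = _read_rate_line(fh, path)
            header = fh.readline().strip()
            labels = [c.strip() for c in header.split(",")]
            if len(set(labels)) != len(labels):
                dupes = sorted({c for c in labels if labels.count(c) > 1})
                raise FormatError(f"{path}: duplicated channel label(s) {dupes}")
            data = np.loadtxt(fh, delimiter=",", ndmin=2)
        if data.shape[1] != len(labels):
            raise FormatError(f"{path}: {data.shape[1]} data columns for "
                              f"{len(labels)} channel labels")
        return EEGRecording(channel_labels=labels, rate=rate, data=data.T)
    if dialect == "brainvision":
        import mne
        raw = mne.io.read_raw_brainvision(path, preload=True, verbose="error")
        labels = list(raw.ch_names)
        if len(set(labels)) != len(labels):
            raise FormatError(f"{path}: duplicated channel labels")
        return EEGRecording(channel_labels=labels, rate=float(raw.info["sfreq"]),
                            data=raw.get_data() * 1e6)  # volts -> microvolts
    raise UsageError(f"unknown EEG dialect {dialect!r}")


def _write_brainvision(eeg: EEGRecording, vhdr_path: Path) -> None:
    """Minimal BrainVision triplet: float32 multiplexed binary, microvolts."""
    if vhdr_path.suffix != ".vhdr":
        raise UsageError("BrainVision path must end in .vhdr")
    stem = vhdr_path.with_suffix("")
    eeg_path = stem.with_suffix(".eeg")
    vmrk_path = stem.with_suffix(".vmrk")
    header = [
        "Brain Vision Data Exchange Header File Version 1.0",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={eeg_path.name}",
        f"MarkerFile={vmrk_path.name}",
        "DataFormat=BINARY",
        "DataOrientation=MULTIPLEXED",
        f"NumberOfChannels={eeg.n_channels}",
        f"SamplingInterval={1e6 / eeg.rate:.6f}",
        "[Binary Infos]",
        "BinaryFormat=IEEE_FLOAT_32",
        "[Channel Infos]",
    ]
    for i, lab in enumerate(eeg.channel_labels, start=1):
        header.append(f"Ch{i}={lab},,1,µV")
    vhdr_path.write_text("\n".join(header) + "\n", encoding="utf-8")
    vmrk_path.write_text(
        "Brain Vision Data Exchange Marker File, Version 1.0\n"
        "[Common Infos]\nCodepage=UTF-8\n"
        f"DataFile={eeg_path.name}\n[Marker Infos]\n"
        "Mk1=New Segment,,1,1,0\n", encoding="utf-8")
    eeg.data.T.astype("<f4").tofile(eeg_path)


# ---------------------------------------------------------------------------
# Kinematics

def write_kinematics(marg: MARGRecording, path) -> None:
    cols = [f"{role}_{ax}" for role in marg.sensor_roles for ax in "xyz"]
    flat = marg.accel.transpose(2, 0, 1).reshape(marg.n_samples, -1)
    with open(path, "w") as fh:
        fh.write(f"# rate_hz={marg.rate!r}\n")
        fh.write(",".join(cols) + "\n")
        np.savetxt(fh, flat, delimiter=",", fmt="%.10g")


def read_kinematics(path) -> MARGRecording:
    path = Path(path)
    with open(path) as fh:
        rate = _read_rate_line(fh, path)
        header = [c.strip() for c in fh.readline().strip().split(",")]
        data = np.loadtxt(fh, delimiter=",", ndmin=2)
    if len(header) % 3 != 0 or data.shape[1] != len(header):
        raise FormatError(f"{path}: expected 3 axis columns per sensor")
    roles = []
    for i in range(0, len(header), 3):
        names = [header[i + j].rsplit("_", 1) for j in range(3)]
        role = names[0][0]
        if any(n[0] != role for n in names) or [n[1] for n in names] != ["x", "y", "z"]:
            raise FormatError(f"{path}: malformed sensor columns near {header[i]!r}")
        roles.append(role)
    accel = data.reshape(data.shape[0], len(roles), 3).transpose(1, 2, 0)
    return MARGRecording(sensor_roles=roles, rate=rate, accel=accel)


# ---------------------------------------------------------------------------
# Event schedules

def write_events(schedule: EventSchedule, path) -> None:
    with open(path, "w") as fh:
        fh.write("start_s\tend_s\taction\tfactor\telement\n")
        for seg in schedule:
            fh.write(f"{seg.start_s!r}\t{seg.end_s!r}\t{seg.action}\t"
                     f"{seg.factor or 'none'}\t{seg.element or 'none'}\n")


def read_events(path) -> EventSchedule:
    path = Path(path)
    segments = []
    with open(path) as fh:
        header = fh.readline().strip().split("\t")
        if header[:5] != ["start_s", "end_s", "action", "factor", "element"]:
            raise FormatError(f"{path}: unexpected schedule header {header}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 5:
                raise FormatError(f"{path}:{lineno}: expected 5 fields")
            try:
                seg = Segment(float(parts[0]), float(parts[1]), parts[2],
                              parts[3], parts[4])
            except ValueError as exc:
                if isinstance(exc, ScheduleError):
                    raise
                raise FormatError(f"{path}:{lineno}: {exc}")
            segments.append(seg)
    return EventSchedule(segments)


# ---------------------------------------------------------------------------
# Reports

def write_report(outdir, *, config: RunConfig | dict, seed: int,
                 cv_result=None, class_metrics=None, qc_table=None,
                 extra: dict | None = None) -> dict:
    """Persist run results: confusion matrices, per-class metrics, QC maps,
    figures and a JSON manifest (always containing the seed used).

    Returns the manifest dictionary.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "seed": int(seed),
        "config": config.to_dict() if isinstance(config, RunConfig) else dict(config),
        "outputs": [],
    }
    if cv_result is not None:
        cv_result.confusion.to_frame().to_csv(outdir / "confusion_counts.csv")
        cv_result.confusion.to_frame(normalized=True).to_csv(
            outdir / "confusion_normalized.csv")
        pd.DataFrame({"iteration": np.arange(len(cv_result.accuracies)),
                      "accuracy": cv_result.accuracies}).to_csv(
            outdir / "cv_accuracies.csv", index=False)
        manifest["outputs"] += ["confusion_counts.csv",
                                "confusion_normalized.csv", "cv_accuracies.csv"]
        manifest["cv"] = {"mean_accuracy": cv_result.mean,
                          "sd": cv_result.sd, "se": cv_result.se,
                          **cv_result.params}
        _plot_confusion(cv_result.confusion, outdir / "confusion.png")
        manifest["outputs"].append("confusion.png")
    if class_metrics is not None:
        class_metrics.frame.to_csv(outdir / "class_metrics.csv")
        manifest["outputs"].append("class_metrics.csv")
    if qc_table is not None:
        qc_table.to_csv(outdir / "qc_crosscorr.csv", index=False)
        manifest["outputs"].append("qc_crosscorr.csv")
    if extra:
        manifest.update(extra)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=float)
    return manifest


def _plot_confusion(cm, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(cm.normalized, cmap="viridis", vmin=0, vmax=100)
    ax.set_xticks(range(len(cm.labels)), cm.labels, rotation=90, fontsize=6)
    ax.set_yticks(range(len(cm.labels)), cm.labels, fontsize=6)
    ax.set_xlabel("predicted")
    ax.set_ylabel("actual")
    fig.colorbar(im, ax=ax, label="% of actual class")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
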