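"""Extended 10-20 montage labels used by the synthetic generator and QC maps.

The 64-channel layout mirrors a standard actiCAP arrangement (FCz reference,
AFz ground, hence neither appears as a data channel). Labels are ordered
central-first so that truncated montages (``n < 64``) consist of channels that
survive the default peripheral rejection.
"""

from __future__ import annotations

# 39 central channels kept by the default peripheral rejection.
CENTRAL_39 = [
    "F3", "Fz", "F4", "FC5", "FC1", "FC2", "FC6",
    "C3", "Cz", "C4", "CP5", "CP1", "CP2", "CP6",
    "P3", "Pz", "P4", "AF3", "AF4", "F5", "F1", "F2", "F6",
    "FC3", "FC4", "C5", "C1", "C2", "C6",
    "CP3", "CPz", "CP4", "P5", "P1", "P2", "P6",
    "PO3", "POz", "PO4",
]

# 25 peripheral channels prone to motion/EMG contamination.
PERIPHERAL_25 = [
    "Fp1", "Fp2", "AF7", "AF8", "F7", "F8",
    "FT9", "FT7", "FT8", "FT10", "T7", "T8",
    "TP9", "TP7", "TP8", "TP10", "P7", "P8",
    "PO9", "PO7", "PO8", "PO10", "O1", "Oz", "O2",
]

MONTAGE_64 = CENTRAL_39 + PERIPHERAL_25

#: Default rejection list: the peripheral ring of the 64-channel montage.
DEFAULT_REJECT = list(PERIPHERAL_25)

#: Sensor placements for the 10-unit inertial array (head, trunk and paired
#: limb sites; one shared foot sensor keeps the count at ten).
SENSOR_ROLES = [
    "head", "torso", "lumbar",
    "arm_l", "arm_r", "thigh_l", "thigh_r",
    "shank_l", "shank_r", "foot",
]


def montage_labels(n_channels: int) -> list[str]:
    """Return ``n_channels`` 10-20 labels (central channels first).

    For ``n_channels > 64`` synthetic labels ``EXT1...`` are appended so that
    oversized simulated caps still have unique names.
    """
    if n_channels <= len(MONTAGE_64):
        return MONTAGE_64[:n_channels]
    extra = [f"EXT{i}" for i in range(1, n_channels - len(MONTAGE_64) + 1)]
    return MONTAGE_64 + extra
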