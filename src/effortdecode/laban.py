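"""Projection of class posteriors into the 4-axis Laban effort space.

Each effort factor (Space, Flow, Weight, Time) is one axis; the indulging
element of a factor (indirect, free, light, sustained) points to +1 and the
condensing element (direct, bound, strong, quick) to -1. A posterior row is
projected by summing signed posterior mass per factor, pooling think and do
posteriors of the same element; the neutral class contributes to no axis, so
a neutral-only posterior sits at the origin. Rows whose largest absolute
coordinate stays below a threshold ``tau`` are flagged non-expressive.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .types import ELEMENT_FACTOR, ELEMENT_SIGN, FACTORS

__all__ = ["default_axis_map", "project_laban"]


def default_axis_map(class_labels) -> dict[str, tuple[str, int]]:
    """Map effort-scheme labels like ``think-free-flow`` to (factor, sign).

    The neutral class is omitted (it carries no expressive direction).
    """
    axis_map: dict[str, tuple[str, int]] = {}
    for lab in class_labels:
        if lab == "neutral":
            continue
        parts = lab.split("-")
        if len(parts) != 3 or parts[1] not in ELEMENT_FACTOR:
            raise ConfigurationError(
                f"cannot derive an axis for class {lab!r}; supply axis_map")
        element = parts[1]
        axis_map[lab] = (ELEMENT_FACTOR[element], ELEMENT_SIGN[element])
    return axis_map


def project_laban(posteriors: pd.DataFrame,
                  axis_map: dict[str, tuple[str, int]] | None = None,
                  tau: float = 0.1) -> pd.DataFrame:
    """Project posterior rows (columns = class labels, rows sum to 1) into
    Laban effort coordinates.

    Returns a frame with columns ``Space, Flow, Weight, Time`` in [-1, 1]
    and a boolean ``expressive`` flag (False when ``max_f |coord_f| < tau``).
    """
    if axis_map is None:
        axis_map = default_axis_map(posteriors.columns)
    unmapped = [c for c in posteriors.columns
                if c != "neutral" and c not in axis_map]
    if unmapped:
        raise ConfigurationError(f"classes without an axis mapping: {unmapped}")
    weights = pd.DataFrame(0.0, index=posteriors.columns, columns=FACTORS)
    for cls, (factor, sign) in axis_map.items():
        if factor not in FACTORS:
            raise ConfigurationError(f"unknown factor {factor!r} for {cls!r}")
        weights.loc[cls, factor] = float(np.sign(sign))
    coords = posteriors.to_numpy(dtype=float) @ weights.to_numpy()
    out = pd.DataFrame(coords, index=posteriors.index, columns=list(FACTORS))
    out["expressive"] = np.abs(coords).max(axis=1) >= tau
    return out
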