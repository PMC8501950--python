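"""Per-nucleus feature extraction: labelled mask x multi-channel field -> table.

Measurements are raw: no background subtraction, no normalisation. The
``total_dapi`` column is the integrated DAPI intensity over the label; each
``mean_<channel>`` column is the arithmetic mean under the label.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .errors import ValidationError
from .images import DAPI, FieldOfView, LabelMask

#: fixed CSV column order (channel means inserted in field order)
FIXED_COLUMNS_HEAD = (
    "field_id",
    "label",
    "area",
    "centroid_row",
    "centroid_col",
    "total_dapi",
)
FIXED_COLUMNS_TAIL = ("border_touching", "condition")


@dataclass
class CellTable:
    """One row per nucleus; the substrate of all downstream gating/plots."""

    df: pd.DataFrame
    channel_names: tuple[str, ...]

    def __post_init__(self) -> None:
        if DAPI not in self.channel_names:
            raise ValidationError("channel_names must include 'DAPI'")
        expected = list(FIXED_COLUMNS_HEAD)
        expected += [f"mean_{ch}" for ch in self.channel_names]
        expected += list(FIXED_COLUMNS_TAIL)
        missing = set(expected) - set(self.df.columns)
        if missing:
            raise ValidationError(f"CellTable missing columns: {sorted(missing)}")
        extra = [c for c in self.df.columns if c not in expected]
        self.df = self.df[expected + extra].reset_index(drop=True)
        keys = self.df[["field_id", "label"]]
        if keys.duplicated().any():
            raise ValidationError("(field_id, label) pairs must be unique")

    def __len__(self) -> int:
        return len(self.df)

    def mean_column(self, channel: str) -> str:
        if channel not in self.channel_names:
            raise ValidationError(
                f"channel {channel!r} not in table (has {self.channel_names})"
            )
        return f"mean_{channel}"

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "CellTable":
        df = pd.read_csv(path, float_precision="round_trip")
        channels = tuple(
            c[len("mean_") :] for c in df.columns if c.startswith("mean_")
        )
        df["condition"] = df["condition"].fillna("")
        return cls(df, channels)


def measure_nuclei(
    mask: LabelMask, field: FieldOfView, condition: str = ""
) -> CellTable:
    """Record area, centroid, integrated DAPI and per-channel means per label.

    Raises :class:`ValidationError` when the mask and field shapes disagree.
    """
    if mask.shape != field.shape:
        raise ValidationError(
            f"mask shape {mask.shape} != field shape {field.shape}"
        )
    n = mask.n_objects
    index = np.arange(1, n + 1)
    labels = mask.labels

    areas = mask.areas()[1:]
    if n:
        centroids = np.array(ndi.center_of_mass(np.ones(mask.shape), labels, index))
    else:
        centroids = np.zeros((0, 2))

    border_labels = set(
        np.unique(
            np.concatenate(
                [labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]]
            )
        )
    ) - {0}

    data: dict[str, object] = {
        "field_id": [field.field_id] * n,
        "label": index,
        "area": areas.astype(np.int64),
        "centroid_row": centroids[:, 0] if n else np.array([]),
        "centroid_col": centroids[:, 1] if n else np.array([]),
    }
    dapi = np.asarray(field.channels[DAPI].pixels, dtype=np.float64)
    data["total_dapi"] = (
        ndi.sum_labels(dapi, labels, index) if n else np.array([])
    )
    for ch in field.channel_names:
        pixels = np.asarray(field.channels[ch].pixels, dtype=np.float64)
        data[f"mean_{ch}"] = ndi.mean(pixels, labels, index) if n else np.array([])
    data["border_touching"] = [int(lbl) in border_labels for lbl in index]
    data["condition"] = [condition] * n

    return CellTable(pd.DataFrame(data), tuple(field.channel_names))


def merge_tables(tables: Sequence[CellTable]) -> CellTable:
    """Concatenate tables (preserving per-row condition labels).

    All inputs must share the same channel set.
    """
    if not tables:
        raise ValidationError("merge_tables requires at least one table")
    channels = tables[0].channel_names
    for t in tables[1:]:
        if tuple(t.channel_names) != tuple(channels):
            raise ValidationError(
                f"channel mismatch: {t.channel_names} vs {channels}"
            )
    df = pd.concat([t.df for t in tables], ignore_index=True)
    if df[["field_id", "label"]].duplicated().any():
        # same field measured under different conditions: disambiguate
        df = df.copy()
        df["field_id"] = df["condition"].astype(str) + ":" + df["field_id"].astype(str)
    return CellTable(df, tuple(channels))
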