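"""QIBC figures: DNA-content scatter plots and jittered dot-bar plots.

Every figure writes a machine-readable CSV sidecar next to the image so
tests assert on plotted data rather than on pixels. Intensity axes default
to log10.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .errors import ValidationError
from .quantification import CellTable


@dataclass(frozen=True)
class ScatterSpec:
    x: str = "total_dapi"
    y: str = "mean_PCNA"
    color: str = "mean_gH2AX"
    color_scale: tuple[float, float] = (0.05, 0.95)
    point_size: float = 4.0
    xscale: str = "log"
    yscale: str = "log"
    cmap: str = "viridis"  # colour map is a documented choice, not a given

    def __post_init__(self) -> None:
        lo, hi = self.color_scale
        if not (0.0 <= lo < hi <= 1.0):
            raise ValidationError(f"invalid color_scale quantiles {self.color_scale}")


@dataclass(frozen=True)
class DotBarSpec:
    value: str = "mean_EdU"
    group: str = "condition"
    jitter_width: float = 0.35
    jitter_seed: int = 0
    bar_color: str = "red"

    def __post_init__(self) -> None:
        if not (0.0 < self.jitter_width <= 0.5):
            raise ValidationError("jitter_width must be in (0, 0.5]")


def _sidecar_path(out_path) -> Path:
    out_path = Path(out_path)
    return out_path.with_name(out_path.stem + ".data.csv")


def _require_columns(table: CellTable, columns) -> None:
    missing = [c for c in columns if c not in table.df.columns]
    if missing:
        raise ValidationError(f"table is missing feature column(s): {missing}")


def qibc_scatter(
    table: CellTable, spec: ScatterSpec | None = None, out_path="qibc_scatter.png"
) -> pd.DataFrame:
    """Scatter of x vs y coloured by a third feature, quantile-clipped.

    Writes the figure (PNG + SVG) and a sidecar CSV of the exact plotted
    values plus the clip bounds; returns the sidecar frame.
    """
    spec = spec or ScatterSpec()
    if len(table) == 0:
        raise ValidationError("cannot plot an empty table")
    _require_columns(table, [spec.x, spec.y, spec.color])

    x = table.df[spec.x].to_numpy(dtype=np.float64)
    y = table.df[spec.y].to_numpy(dtype=np.float64)
    color = table.df[spec.color].to_numpy(dtype=np.float64)
    clip_lo = float(np.quantile(color, spec.color_scale[0]))
    clip_hi = float(np.quantile(color, spec.color_scale[1]))

    sidecar = pd.DataFrame(
        {
            "x": x,
            "y": y,
            "color": color,
            "clip_lo": clip_lo,
            "clip_hi": clip_hi,
        }
    )
    sidecar.to_csv(_sidecar_path(out_path), index=False)

    fig, ax = plt.subplots(figsize=(4.5, 4))
    shown = np.clip(color, clip_lo, clip_hi) if clip_hi > clip_lo else color
    points = ax.scatter(x, y, c=shown, s=spec.point_size, cmap=spec.cmap, linewidths=0)
    ax.set_xscale(spec.xscale)
    ax.set_yscale(spec.yscale)
    ax.set_xlabel(f"{spec.x} (A.U.)")
    ax.set_ylabel(f"{spec.y} (A.U.)")
    fig.colorbar(points, ax=ax, label=f"{spec.color} (A.U.)")
    fig.tight_layout()
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=150)
    fig.savefig(out_path.with_suffix(".svg"))
    plt.close(fig)
    return sidecar


def dot_bar(
    table: CellTable, spec: DotBarSpec | None = None, out_path="qibc_dotbar.png"
) -> pd.DataFrame:
    """Per-group jittered dots with a bar at the group mean.

    Group order follows first appearance. Empty groups are skipped with a
    warning. The sidecar records group, value, jittered x and the group's
    bar (mean) value for every point.
    """
    spec = spec or DotBarSpec()
    if len(table) == 0:
        raise ValidationError("cannot plot an empty table")
    _require_columns(table, [spec.value, spec.group])

    df = table.df
    groups = list(dict.fromkeys(df[spec.group]))
    rng = np.random.default_rng(spec.jitter_seed)

    rows = []
    for slot, group in enumerate(groups):
        values = df.loc[df[spec.group] == group, spec.value].to_numpy(dtype=np.float64)
        if values.size == 0:
            warnings.warn(f"group {group!r} is empty; skipped", stacklevel=2)
            continue
        jitter = rng.uniform(-spec.jitter_width, spec.jitter_width, size=values.size)
        bar = float(values.mean())
        for xj, v in zip(slot + jitter, values):
            rows.append({"group": group, "x": xj, "y": v, "bar": bar})
    sidecar = pd.DataFrame(rows, columns=["group", "x", "y", "bar"])
    sidecar.to_csv(_sidecar_path(out_path), index=False)

    fig, ax = plt.subplots(figsize=(1.0 + 0.9 * len(groups), 4))
    for slot, group in enumerate(groups):
        sub = sidecar[sidecar["group"] == group]
        if sub.empty:
            continue
        ax.scatter(sub["x"], sub["y"], s=5, color="0.4", linewidths=0)
        ax.hlines(sub["bar"].iloc[0], slot - 0.4, slot + 0.4, color=spec.bar_color, lw=2)
    ax.set_xticks(range(len(groups)))
    ax.set_xticklabels([str(g) for g in groups], rotation=45, ha="right")
    ax.set_ylabel(f"{spec.value} (A.U.)")
    if (sidecar["y"] > 0).all():
        ax.set_yscale("log")
    fig.tight_layout()
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=150)
    fig.savefig(out_path.with_suffix(".svg"))
    plt.close(fig)
    return sidecar
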