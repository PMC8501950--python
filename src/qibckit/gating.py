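"""Population filtering for QIBC tables.

Replicates the analysis gates applied before plotting: keep interphase cells
with 2C-4C DNA content (window around the G1 peak of the total-DAPI
distribution), call S-phase from a replication marker, and subsample equal
cell numbers across conditions.

The G1 peak is the leftmost dominant mode of a 100-bin histogram of
log-totals: using the left-of-median restriction protects against
G2-dominant (e.g. arrested) populations. The 2C-4C window defaults to
[0.75, 2.5] x peak — symmetric slack around the theoretical [1, 2] x peak.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import InsufficientDataError, ValidationError
from .quantification import CellTable

MIN_CELLS_FOR_PEAK = 50


@dataclass(frozen=True)
class GatingParams:
    g1_window_lo: float = 0.75
    g1_window_hi: float = 2.5
    histogram_bins: int = 100
    sphase_marker: str = "PCNA"
    sphase_threshold: float | None = None  # fixed threshold; else quantile rule
    sphase_quantile: float = 0.95
    subsample_seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.g1_window_lo < self.g1_window_hi):
            raise ValidationError(
                f"require 0 < g1_window_lo < g1_window_hi, got "
                f"({self.g1_window_lo}, {self.g1_window_hi})"
            )
        if self.histogram_bins < 10:
            raise ValidationError("histogram_bins must be >= 10")
        if not (0 < self.sphase_quantile < 1):
            raise ValidationError("sphase_quantile must be in (0, 1)")


@dataclass(frozen=True)
class GatingResult:
    """Record of one interphase gate: estimated peak, window, kept rows."""

    g1_peak: float
    window: tuple[float, float]
    kept: tuple[int, ...]
    n_before: int
    n_after: int

    def to_json(self, path) -> None:
        payload = {
            "g1_peak": self.g1_peak,
            "window_lo": self.window[0],
            "window_hi": self.window[1],
            "n_before": self.n_before,
            "n_after": self.n_after,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


#: a histogram mode this tall relative to the global mode counts as dominant
_DOMINANT_MODE_FRACTION = 0.25
#: light moving-average smoothing applied to the histogram before peak
#: finding, to keep count noise from splitting one mode into several
_HIST_SMOOTH_WINDOW = 3


def estimate_g1_peak(totals: Sequence[float], params: GatingParams | None = None) -> float:
    """Locate the 2C mode of a total-DAPI distribution.

    Histograms log-totals (``histogram_bins`` bins), lightly smooths the
    counts, finds the local maxima and returns the back-transformed centre
    of the leftmost mode whose height is at least 25% of the tallest — the
    leftmost dominant mode, robust to G2-dominant (arrested) populations.
    """
    params = params or GatingParams()
    totals = np.asarray(totals, dtype=np.float64)
    if totals.size < MIN_CELLS_FOR_PEAK:
        raise InsufficientDataError(
            f"need >= {MIN_CELLS_FOR_PEAK} cells to estimate the G1 peak, "
            f"got {totals.size}"
        )
    if totals.min() <= 0:
        raise ValidationError("total-DAPI values must all be > 0")
    log_totals = np.log10(totals)
    lo = log_totals.min()
    hi = log_totals.max()
    if lo == hi:
        return float(10.0**lo)
    hist, edges = np.histogram(log_totals, bins=params.histogram_bins, range=(lo, hi))
    centers = (edges[:-1] + edges[1:]) / 2.0
    kernel = np.ones(_HIST_SMOOTH_WINDOW) / _HIST_SMOOTH_WINDOW
    smoothed = np.convolve(hist.astype(np.float64), kernel, mode="same")

    from scipy.signal import find_peaks

    padded = np.concatenate([[0.0], smoothed, [0.0]])  # endpoints can be modes
    peaks, _ = find_peaks(padded, height=_DOMINANT_MODE_FRACTION * smoothed.max())
    if peaks.size == 0:  # pathological flat histogram: fall back to argmax
        peak_bin = int(np.argmax(smoothed))
    else:
        peak_bin = int(peaks[0]) - 1
    return float(10.0 ** centers[peak_bin])


def gate_interphase(
    table: CellTable, params: GatingParams | None = None
) -> tuple[CellTable, GatingResult]:
    """Keep rows whose total DAPI lies in [lo, hi] x G1 peak."""
    params = params or GatingParams()
    if len(table) == 0:
        raise ValidationError("cannot gate an empty table")
    totals = table.df["total_dapi"].to_numpy(dtype=np.float64)
    peak = estimate_g1_peak(totals, params)
    window = (params.g1_window_lo * peak, params.g1_window_hi * peak)
    keep = (totals >= window[0]) & (totals <= window[1])
    kept_idx = tuple(int(i) for i in np.flatnonzero(keep))
    gated = CellTable(table.df.loc[keep].reset_index(drop=True), table.channel_names)
    result = GatingResult(
        g1_peak=peak,
        window=window,
        kept=kept_idx,
        n_before=len(table),
        n_after=len(gated),
    )
    return gated, result


def call_sphase(
    table: CellTable,
    params: GatingParams | None = None,
    control: CellTable | None = None,
) -> np.ndarray:
    """Flag S-phase rows: marker mean above a threshold.

    The threshold is either ``params.sphase_threshold`` (fixed) or, when that
    is None, the ``sphase_quantile`` quantile of the marker distribution in a
    ``control`` (marker-negative) table — the quantile rule without a control
    is a :class:`ValidationError`.
    """
    params = params or GatingParams()
    marker_col = table.mean_column(params.sphase_marker)
    if params.sphase_threshold is not None:
        threshold = float(params.sphase_threshold)
    else:
        if control is None:
            raise ValidationError(
                "quantile S-phase thresholding requires a control table"
            )
        control_values = control.df[control.mean_column(params.sphase_marker)]
        threshold = float(np.quantile(control_values.to_numpy(), params.sphase_quantile))
    return table.df[marker_col].to_numpy(dtype=np.float64) > threshold


def subsample_equal(
    tables: Sequence[CellTable], params: GatingParams | None = None
) -> list[CellTable]:
    """Reduce every table to the smallest table's size by seeded sampling
    without replacement (row order preserved). Deterministic given
    ``subsample_seed``."""
    params = params or GatingParams()
    if not tables:
        return []
    for t in tables:
        if len(t) == 0:
            raise ValidationError("subsample_equal requires non-empty tables")
    n = min(len(t) for t in tables)
    rng = np.random.default_rng(params.subsample_seed)
    out = []
    for t in tables:
        idx = np.sort(rng.choice(len(t), size=n, replace=False))
        out.append(CellTable(t.df.iloc[idx].reset_index(drop=True), t.channel_names))
    return out
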