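"""Sensor-series cleaning, imputation, down-sampling, scaling and windowing.

The chain mirrors standard practice for minute-resolution livestock-house
loggers: robust sliding-window outlier masking, linear interpolation of
short gaps (<= 60 min), block-mean down-sampling to a 10-min interval,
training-set min-max normalization with a 1e-7 guard denominator, a
chronological 6:1:3 split, and stride-1 supervised windows that never
cross a segment break left by an un-imputable gap.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic import CHANNELS, RawSeriesTable

ENV_CHANNELS = ["Tin", "RHin", "CO2"]   # forecast targets
AUX_CHANNELS = ["WS", "Tout", "RHout"]  # auxiliary drivers
EPSILON = 1e-7


@dataclass
class CleanSeriesTable:
    """A RawSeriesTable plus the contiguous fully-valid segments.

    Rows outside segments still carry NaN (un-imputable gaps); no row
    inside a segment has any missing channel.
    """

    frame: pd.DataFrame
    step_minutes: int
    segments: list[tuple[int, int]]  # half-open [start, end) row ranges

    def __post_init__(self):
        prev_end = 0
        for s, e in self.segments:
            if not (prev_end <= s < e <= len(self.frame)):
                raise ValueError("segments must be ordered, non-overlapping, in range")
            prev_end = e

    def __len__(self):
        return len(self.frame)

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy()

    def segment_values(self) -> list[np.ndarray]:
        v = self.values
        return [v[s:e] for s, e in self.segments]

    def valid_values(self) -> np.ndarray:
        """Rows inside segments, concatenated."""
        if not self.segments:
            return np.empty((0, len(self.frame.columns)))
        return np.concatenate(self.segment_values(), axis=0)


@dataclass
class NormalizationState:
    """Per-channel min/max for reversible min-max scaling."""

    channels: list[str]
    xmin: np.ndarray
    xmax: np.ndarray
    epsilon: float = EPSILON

    def __post_init__(self):
        self.xmin = np.asarray(self.xmin, dtype=float)
        self.xmax = np.asarray(self.xmax, dtype=float)
        if (self.xmax < self.xmin).any():
            raise ValueError("xmax must be >= xmin for every channel")

    def to_json(self) -> str:
        return json.dumps(
            {
                "channels": self.channels,
                "xmin": self.xmin.tolist(),
                "xmax": self.xmax.tolist(),
                "epsilon": self.epsilon,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "NormalizationState":
        d = json.loads(text)
        return cls(d["channels"], np.array(d["xmin"]), np.array(d["xmax"]), d["epsilon"])


@dataclass
class WindowBatch:
    """Paired (input, target) supervised windows on the normalized scale.

    inputs: (n, N, 6); targets: (n, H, 3) restricted to Tin/RHin/CO2;
    start_rows maps each window back to its source row.
    """

    inputs: np.ndarray
    targets: np.ndarray
    start_rows: np.ndarray
    N: int
    H: int

    def __len__(self):
        return len(self.inputs)

    def subset(self, idx) -> "WindowBatch":
        return WindowBatch(self.inputs[idx], self.targets[idx], self.start_rows[idx],
                           self.N, self.H)


# --------------------------------------------------------------------------
# outlier masking
# --------------------------------------------------------------------------

def detect_outliers(table: RawSeriesTable, window: int = 61,
                    z_threshold: float = 3.0) -> RawSeriesTable:
    """Mask points whose robust z-score in a centred sliding window exceeds
    the threshold.

    The score is |x - median| / (1.4826 * MAD), both statistics taken over
    the window (NaN-aware); flagged points are set to NaN, everything else
    is returned unchanged. Edge points use the nearest full window.
    """
    if window < 5 or window % 2 == 0:
        raise ValueError("window must be odd and >= 5")
    if z_threshold <= 0:
        raise ValueError("z_threshold must be positive")
    if window > len(table):
        raise ValueError("window longer than the series")

    values = table.values
    n = len(values)
    half = window // 2
    frame = table.frame.copy()
    # centred windows; rows within `half` of an edge reuse the nearest full window
    centers = np.clip(np.arange(n), half, n - 1 - half)
    win_idx = centers[:, None] + np.arange(-half, half + 1)[None, :]
    import warnings as _warnings
    for ch in range(values.shape[1]):
        col = values[:, ch]
        wins = col[win_idx]  # (n, window)
        with _warnings.catch_warnings():
            # all-NaN windows (inside long gaps) legitimately yield NaN stats
            _warnings.simplefilter("ignore", RuntimeWarning)
            med = np.nanmedian(wins, axis=1)
            mad = np.nanmedian(np.abs(wins - med[:, None]), axis=1)
        scale = 1.4826 * mad
        scale[scale == 0] = np.inf  # constant window: nothing can deviate robustly
        with np.errstate(invalid="ignore"):
            z = np.abs(col - med) / scale
        frame.iloc[z > z_threshold, ch] = np.nan
    return RawSeriesTable(frame, table.step_minutes)


# --------------------------------------------------------------------------
# gap imputation & segmentation
# --------------------------------------------------------------------------

def _nan_runs(isnan: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, end) runs of True."""
    runs = []
    n = len(isnan)
    i = 0
    while i < n:
        if isnan[i]:
            j = i
            while j < n and isnan[j]:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def fill_gaps(table: RawSeriesTable, max_gap_minutes: int = 60) -> CleanSeriesTable:
    """Linearly interpolate missing runs no longer than ``max_gap_minutes``.

    A run of n missing points between valid neighbours y1 and y2 is filled
    with y_k = y1 + k/(n+1) * (y2 - y1), k = 1..n. Longer runs, and runs
    touching either end of the series, are left missing and become segment
    breaks across which no window may span.
    """
    frame = table.frame.copy()
    step = table.step_minutes
    max_run = max_gap_minutes // step
    values = frame.to_numpy()
    n = len(values)
    for ch in range(values.shape[1]):
        col = values[:, ch]
        for start, end in _nan_runs(np.isnan(col)):
            run = end - start
            if run > max_run or start == 0 or end == n:
                continue
            y1, y2 = col[start - 1], col[end]
            k = np.arange(1, run + 1)
            col[start:end] = y1 + k / (run + 1) * (y2 - y1)
        values[:, ch] = col
    frame.iloc[:, :] = values
    row_valid = ~np.isnan(values).any(axis=1)
    segments = _nan_runs(row_valid)  # maximal runs of fully-valid rows
    return CleanSeriesTable(frame, step, segments)


# --------------------------------------------------------------------------
# down-sampling
# --------------------------------------------------------------------------

def downsample_mean(table: CleanSeriesTable, factor: int = 10) -> CleanSeriesTable:
    """Block-mean down-sampling by ``factor`` within each segment.

    Each output point is the arithmetic mean of `factor` consecutive input
    points; the trailing remainder of a segment is dropped; timestamps are
    the block-start times; segment structure is preserved.
    """
    if factor <= 0:
        raise ValueError("factor must be positive")
    if factor == 1:
        return CleanSeriesTable(table.frame.copy(), table.step_minutes, list(table.segments))
    values = table.values
    index = table.frame.index
    out_blocks, out_times, segments = [], [], []
    pos = 0
    for s, e in table.segments:
        n_blocks = (e - s) // factor
        if n_blocks == 0:
            continue
        block = values[s:s + n_blocks * factor].reshape(n_blocks, factor, -1).mean(axis=1)
        out_blocks.append(block)
        out_times.append(index[s:s + n_blocks * factor:factor])
        segments.append((pos, pos + n_blocks))
        pos += n_blocks
    if not out_blocks:
        frame = table.frame.iloc[:0].copy()
        return CleanSeriesTable(frame, table.step_minutes * factor, [])
    frame = pd.DataFrame(
        np.concatenate(out_blocks, axis=0),
        index=out_times[0].append(out_times[1:]) if len(out_times) > 1 else out_times[0],
        columns=table.frame.columns,
    )
    frame.index.name = "timestamp"
    return CleanSeriesTable(frame, table.step_minutes * factor, segments)


# --------------------------------------------------------------------------
# normalization
# --------------------------------------------------------------------------

def fit_normalizer(train_portion: CleanSeriesTable) -> NormalizationState:
    """Per-channel min/max from the training portion only (no leakage)."""
    valid = train_portion.valid_values()
    if valid.size == 0:
        raise ValueError("cannot fit a normalizer on an empty table")
    return NormalizationState(
        channels=list(train_portion.frame.columns),
        xmin=np.nanmin(valid, axis=0),
        xmax=np.nanmax(valid, axis=0),
    )


def _check_state(channels, state: NormalizationState) -> None:
    if list(channels) != list(state.channels):
        raise ValueError(
            f"channel mismatch: table has {list(channels)}, state has {state.channels}"
        )


def normalize(table: CleanSeriesTable, state: NormalizationState) -> CleanSeriesTable:
    """x_scaled = (x - xmin) / (xmax - xmin + 1e-7), per channel."""
    _check_state(table.frame.columns, state)
    denom = state.xmax - state.xmin + state.epsilon
    frame = (table.frame - state.xmin) / denom
    return CleanSeriesTable(frame, table.step_minutes, list(table.segments))


def denormalize(table: CleanSeriesTable, state: NormalizationState) -> CleanSeriesTable:
    """Exact inverse of :func:`normalize`."""
    _check_state(table.frame.columns, state)
    denom = state.xmax - state.xmin + state.epsilon
    frame = table.frame * denom + state.xmin
    return CleanSeriesTable(frame, table.step_minutes, list(table.segments))


def normalize_array(values: np.ndarray, state: NormalizationState,
                    channels: list[str] | None = None) -> np.ndarray:
    """Array form of :func:`normalize` over the trailing channel axis."""
    ch = channels if channels is not None else state.channels
    sel = [state.channels.index(c) for c in ch]
    return (values - state.xmin[sel]) / (state.xmax[sel] - state.xmin[sel] + state.epsilon)


def denormalize_array(values: np.ndarray, state: NormalizationState,
                      channels: list[str] | None = None) -> np.ndarray:
    ch = channels if channels is not None else state.channels
    sel = [state.channels.index(c) for c in ch]
    return values * (state.xmax[sel] - state.xmin[sel] + state.epsilon) + state.xmin[sel]


# --------------------------------------------------------------------------
# splitting & windowing
# --------------------------------------------------------------------------

def split_sizes(M: int, ratios: tuple[float, float, float] = (6, 1, 3)) -> tuple[int, int, int]:
    """Chronological split sizes with round-half-up on train and val.

    7548 rows at 6:1:3 gives (4529, 755, 2264).
    """
    if any(r <= 0 for r in ratios):
        raise ValueError("ratios must be positive")
    if M < 10:
        raise ValueError("need at least 10 rows to split")
    total = sum(ratios)

    def round_half_up(x: float) -> int:
        return int(np.floor(x + 0.5))

    train = round_half_up(M * ratios[0] / total)
    val = round_half_up(M * ratios[1] / total)
    test = M - train - val
    return train, val, test


def _slice_table(table: CleanSeriesTable, start: int, end: int) -> CleanSeriesTable:
    frame = table.frame.iloc[start:end].copy()
    segments = []
    for s, e in table.segments:
        s2, e2 = max(s, start), min(e, end)
        if s2 < e2:
            segments.append((s2 - start, e2 - start))
    return CleanSeriesTable(frame, table.step_minutes, segments)


def chronological_split(
    table: CleanSeriesTable, ratios: tuple[float, float, float] = (6, 1, 3)
) -> tuple[CleanSeriesTable, CleanSeriesTable, CleanSeriesTable]:
    """Contiguous chronological train/validation/test thirds (default 6:1:3)."""
    M = len(table)
    n_train, n_val, n_test = split_sizes(M, ratios)
    return (
        _slice_table(table, 0, n_train),
        _slice_table(table, n_train, n_train + n_val),
        _slice_table(table, n_train + n_val, M),
    )


def make_windows(table: CleanSeriesTable, N: int, H: int) -> WindowBatch:
    """All stride-1 (input, target) windows fully inside single segments.

    A segment of length S contributes max(0, S - N - H + 1) windows; the
    target window of H steps immediately follows the N input steps and is
    restricted to the three indoor target channels.
    """
    cols = list(table.frame.columns)
    tgt_idx = [cols.index(c) for c in ENV_CHANNELS]
    values = table.values
    inputs, targets, starts = [], [], []
    for s, e in table.segments:
        count = (e - s) - N - H + 1
        for w in range(max(0, count)):
            start = s + w
            inputs.append(values[start:start + N])
            targets.append(values[start + N:start + N + H][:, tgt_idx])
            starts.append(start)
    if not inputs:
        raise ValueError(
            f"no segment is long enough for a window of N + H = {N + H} rows"
        )
    return WindowBatch(
        np.asarray(inputs), np.asarray(targets), np.asarray(starts), N, H
    )
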