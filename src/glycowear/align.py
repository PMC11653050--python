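"""Reduce multi-rate channels to the 5-minute CGM grid and summarize.

Every channel is reduced to the CGM cadence: the value labelled with grid
time ``t`` aggregates raw samples in the half-open window ``[t-300 s, t)``
(the CGM convention that a reading at ``t`` summarizes the preceding
interval). Triaxial acceleration is first collapsed to its Euclidean norm;
the event-based IBI channel is reduced by averaging the interval durations
of events falling in the window. Rolling 3-point (10-minute) mean and
sample-SD summaries are then computed for glucose and each channel.

Missingness is strict: a rolling summary is missing whenever any of its
contributing grid points is missing, which keeps downstream correlation
sample sizes honest.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from glycowear.datatypes import CHANNELS, GRID_SPACING_S, Cohort, GlucoseSeries, SensorStream

log = logging.getLogger(__name__)

#: Variables that get rolling summaries: glucose plus every channel.
GRID_VARIABLES: tuple[str, ...] = ("glucose", *CHANNELS)

_FLOAT_FMT = "%.12g"


def acc_euclidean_norm(triples: np.ndarray) -> np.ndarray:
    """Euclidean norm sqrt(x^2 + y^2 + z^2) of (n, 3) acceleration triples.

    Non-finite components propagate as NaN at that index.
    """
    arr = np.asarray(triples, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ValueError("expected an (n, 3) array of acceleration triples")
    with np.errstate(invalid="ignore"):
        out = np.sqrt(np.sum(arr * arr, axis=1))
    out[~np.isfinite(arr).all(axis=1)] = np.nan
    return out


def _scalar_series(stream: SensorStream) -> tuple[np.ndarray, np.ndarray]:
    """(times, values) with ACC collapsed to its norm and IBI to intervals."""
    if stream.channel == "ACC":
        return stream.times, acc_euclidean_norm(stream.samples)
    if stream.channel == "IBI":
        return stream.times, stream.samples[:, 1]
    return stream.times, stream.samples


def resample_to_grid(
    stream: SensorStream,
    grid_times: np.ndarray,
    aggregator: str = "mean",
    spacing_s: float = GRID_SPACING_S,
) -> np.ndarray:
    """Reduce one stream to per-grid values.

    With ``aggregator="mean"`` each grid value is the mean of raw samples in
    the half-open window ``[t - spacing, t)``; an empty window is NaN. With
    ``"nearest"`` it is the sample closest to ``t`` within ``spacing/2``.
    """
    grid_times = np.asarray(grid_times, dtype=float)
    times, values = _scalar_series(stream)
    finite = np.isfinite(values)
    times, values = times[finite], values[finite]
    out = np.full(grid_times.size, np.nan)
    if times.size == 0 or grid_times.size == 0:
        return out
    if times[-1] < grid_times[0] - spacing_s or times[0] >= grid_times[-1]:
        warnings.warn(
            f"{stream.channel} stream for {stream.participant_id!r} does not "
            "overlap the grid span",
            stacklevel=2,
        )
        return out

    if aggregator == "mean":
        # grid is regular: assign each sample to the window it falls in
        t0 = grid_times[0]
        idx = np.floor((times - t0) / spacing_s).astype(np.int64) + 1
        ok = (idx >= 0) & (idx < grid_times.size)
        sums = np.bincount(idx[ok], weights=values[ok], minlength=grid_times.size)
        counts = np.bincount(idx[ok], minlength=grid_times.size)
        with np.errstate(invalid="ignore"):
            out = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        return out
    if aggregator == "nearest":
        pos = np.searchsorted(times, grid_times)
        for i, t in enumerate(grid_times):
            best, dist = None, spacing_s / 2
            for j in (pos[i] - 1, pos[i]):
                if 0 <= j < times.size and abs(times[j] - t) <= dist:
                    best, dist = values[j], abs(times[j] - t)
            if best is not None:
                out[i] = best
        return out
    raise ValueError(f"unknown aggregator {aggregator!r}")


def rolling_mean_sd(
    values: np.ndarray, window: int = 3, align: str = "trailing"
) -> tuple[np.ndarray, np.ndarray]:
    """Rolling mean and sample SD (denominator n-1) over ``window`` points.

    The default is a trailing window over the current and previous
    ``window - 1`` grid points (10 minutes in total for window 3 at 5-min
    cadence); ``align="centered"`` is available for sensitivity checks.
    A window containing any missing point yields a missing summary.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    if align not in ("trailing", "centered"):
        raise ValueError(f"unknown alignment {align!r}")
    s = pd.Series(np.asarray(values, dtype=float))
    if len(s) < window:
        warnings.warn("series shorter than rolling window; all summaries missing", stacklevel=2)
        return np.full(len(s), np.nan), np.full(len(s), np.nan)
    roll = s.rolling(window=window, min_periods=window, center=(align == "centered"))
    return roll.mean().to_numpy(), roll.std(ddof=1).to_numpy()


def regular_grid(glucose: GlucoseSeries, spacing_s: float = GRID_SPACING_S) -> np.ndarray:
    """Regular grid times spanning a glucose series at the CGM cadence."""
    n = int(round((glucose.times[-1] - glucose.times[0]) / spacing_s)) + 1
    return glucose.times[0] + spacing_s * np.arange(n)


def glucose_on_grid(
    glucose: GlucoseSeries,
    grid_times: np.ndarray,
    spacing_s: float = GRID_SPACING_S,
    tolerance_s: float = 60.0,
) -> np.ndarray:
    """Place glucose readings on the regular grid (NaN in gaps).

    Readings are snapped to the nearest grid point within ``tolerance_s``
    (real CGM timestamps jitter by seconds); collisions keep the first.
    """
    out = np.full(grid_times.size, np.nan)
    idx = np.round((glucose.times - grid_times[0]) / spacing_s).astype(np.int64)
    ok = (idx >= 0) & (idx < grid_times.size)
    ok &= np.abs(glucose.times - (grid_times[0] + idx * spacing_s)) <= tolerance_s
    for i, g in zip(idx[ok][::-1], glucose.glucose[ok][::-1]):
        out[i] = g  # reversed iteration => first occurrence wins
    return out


def build_aligned_grid(
    cohort: Cohort,
    aggregator: str = "mean",
    rolling_window: int = 3,
    rolling_align: str = "trailing",
    spacing_s: float = GRID_SPACING_S,
) -> dict[str, pd.DataFrame]:
    """Build one aligned 5-min grid per participant.

    Returns a dict of DataFrames with columns ``time``, ``glucose``, each
    channel, and ``<var>_mean`` / ``<var>_sd`` rolling summaries for every
    variable. Participants lacking a glucose series are excluded with a
    warning. Channels absent for a participant are all-missing columns.
    """
    grids: dict[str, pd.DataFrame] = {}
    for pid in cohort.participant_ids:
        gs = cohort.glucose.get(pid)
        if gs is None or len(gs) == 0:
            warnings.warn(f"participant {pid!r} has no glucose series; excluded", stacklevel=2)
            continue
        grid_times = regular_grid(gs, spacing_s)
        df = pd.DataFrame({"time": grid_times})
        df["glucose"] = glucose_on_grid(gs, grid_times, spacing_s)
        for ch in CHANNELS:
            stream = cohort.streams.get(pid, {}).get(ch)
            if stream is None:
                df[ch] = np.nan
            else:
                df[ch] = resample_to_grid(stream, grid_times, aggregator, spacing_s)
        for var in GRID_VARIABLES:
            mean, sd = rolling_mean_sd(df[var].to_numpy(), rolling_window, rolling_align)
            df[f"{var}_mean"] = mean
            df[f"{var}_sd"] = sd
        grids[pid] = df
    return grids


def save_grids(grids: Mapping[str, pd.DataFrame], out_dir: str | Path) -> Path:
    """Write per-participant aligned-grid CSVs plus an index file."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for pid in sorted(grids):
        grids[pid].to_csv(out / f"{pid}_grid.csv", index=False, float_format=_FLOAT_FMT)
    (out / "grids.txt").write_text("".join(f"{pid}\n" for pid in sorted(grids)))
    return out


def load_grids(in_dir: str | Path) -> dict[str, pd.DataFrame]:
    root = Path(in_dir)
    pids = [ln.strip() for ln in (root / "grids.txt").read_text().splitlines() if ln.strip()]
    return {pid: pd.read_csv(root / f"{pid}_grid.csv") for pid in pids}
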