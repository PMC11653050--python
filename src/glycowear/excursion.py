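"""Meal-anchored postprandial glucose excursions and the design table.

An excursion is anchored at a food-log entry: the postprandial *peak* is
the maximum grid glucose strictly after the meal and within the horizon
(default 180 min), the *pre-rise trough* is the minimum between the meal
and the peak, and the *post-peak nadir* is the minimum between the peak and
the end of the excursion span. The next meal truncates the span so
excursions never overlap. Ties on extrema are broken to the earliest grid
point. Rise and fall tangent slopes are finite differences in
mg/dL per minute:

    rise = (peak_g − trough_g) / (peak_t − trough_t)
    fall = (nadir_g − peak_g) / (nadir_t − peak_t)

Window features take channel means/SDs over five half-open windows per
channel ``c``: ``c`` = [meal, peak), ``c_af`` = [peak, nadir), and the
pre-meal windows ``c_30`` = [meal−30, meal), ``c_60`` = [meal−60, meal−30),
``c_90`` = [meal−90, meal−60). The ``_af`` (after-peak) features exist only
when a nadir exists and are excluded from rise-slope models downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from glycowear.datatypes import CHANNELS, NUTRIENTS, MealEvent, ParticipantRecord

#: Window tags in reporting order; "" is the meal-to-peak base window.
WINDOW_TAGS: tuple[str, ...] = ("", "_af", "_30", "_60", "_90")


@dataclass
class Excursion:
    """One detected postprandial excursion (times epoch s, glucose mg/dL)."""

    participant_id: str
    meal_time: float
    trough_pre: tuple[float, float]  # (time, glucose)
    peak: tuple[float, float]
    nadir_post: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        if self.trough_pre[0] > self.peak[0]:
            raise ValueError("trough must not come after peak")
        if self.peak[1] < self.trough_pre[1]:
            raise ValueError("peak glucose below trough glucose")


@dataclass
class NutrientTotals:
    """Field-wise nutrient sums over an excursion's contributing meals."""

    calories: float = 0.0
    carbohydrate: float = 0.0
    dietary_fiber: float = 0.0
    sugar: float = 0.0
    protein: float = 0.0
    total_fat: float = 0.0
    complete: bool = True


def detect_excursion(
    grid: pd.DataFrame,
    meal_time: float,
    horizon_minutes: float = 180.0,
    next_meal_time: float | None = None,
    min_amplitude: float = 0.0,
    participant_id: str = "",
) -> tuple[Optional[Excursion], str]:
    """Locate trough/peak/nadir for one meal on the aligned grid.

    Returns ``(excursion, reason)`` where reason is ``"ok"`` on success or a
    code explaining why no excursion was produced (``insufficient_coverage``,
    ``flat``, ``below_min_amplitude``). The search span is
    ``(meal, meal + horizon]`` truncated at the next meal; the earliest grid
    index wins every tie.
    """
    t = grid["time"].to_numpy(dtype=float)
    g = grid["glucose"].to_numpy(dtype=float)
    end = meal_time + horizon_minutes * 60.0
    if next_meal_time is not None:
        end = min(end, next_meal_time)

    post = (t > meal_time) & (t <= end) & np.isfinite(g)
    post_idx = np.flatnonzero(post)
    if post_idx.size == 0:
        return None, "insufficient_coverage"
    peak_i = post_idx[np.argmax(g[post_idx])]  # argmax -> earliest on ties

    pre = (t >= meal_time) & (t <= t[peak_i]) & np.isfinite(g)
    pre_idx = np.flatnonzero(pre)
    if pre_idx.size == 0:
        return None, "insufficient_coverage"
    trough_i = pre_idx[np.argmin(g[pre_idx])]

    amplitude = g[peak_i] - g[trough_i]
    if amplitude == 0.0:
        return None, "flat"
    if amplitude < min_amplitude:
        return None, "below_min_amplitude"

    after = (t >= t[peak_i]) & (t <= end) & np.isfinite(g)
    after_idx = np.flatnonzero(after)
    nadir: Optional[tuple[float, float]] = None
    if after_idx.size:
        nadir_i = after_idx[np.argmin(g[after_idx])]
        if t[nadir_i] > t[peak_i]:  # peak at span end => nadir absent
            nadir = (float(t[nadir_i]), float(g[nadir_i]))

    exc = Excursion(
        participant_id=participant_id,
        meal_time=float(meal_time),
        trough_pre=(float(t[trough_i]), float(g[trough_i])),
        peak=(float(t[peak_i]), float(g[peak_i])),
        nadir_post=nadir,
    )
    return exc, "ok"


def compute_slopes(exc: Excursion) -> tuple[float, Optional[float]]:
    """Rise and fall tangent slopes in mg/dL per minute.

    Fall is ``None`` when no nadir exists. A zero time difference between
    trough and peak is undefined and raises.
    """
    dt_min = (exc.peak[0] - exc.trough_pre[0]) / 60.0
    if dt_min == 0.0:
        raise ValueError("zero time difference between trough and peak")
    rise = (exc.peak[1] - exc.trough_pre[1]) / dt_min
    fall: Optional[float] = None
    if exc.nadir_post is not None:
        dt_fall = (exc.nadir_post[0] - exc.peak[0]) / 60.0
        if dt_fall == 0.0:
            raise ValueError("zero time difference between peak and nadir")
        fall = (exc.nadir_post[1] - exc.peak[1]) / dt_fall
    return rise, fall


def _windows(exc: Excursion) -> dict[str, Optional[tuple[float, float]]]:
    m, p = exc.meal_time, exc.peak[0]
    out: dict[str, Optional[tuple[float, float]]] = {
        "": (m, p),
        "_af": (p, exc.nadir_post[0]) if exc.nadir_post is not None else None,
        "_30": (m - 30 * 60.0, m),
        "_60": (m - 60 * 60.0, m - 30 * 60.0),
        "_90": (m - 90 * 60.0, m - 60 * 60.0),
    }
    return out


def window_features(grid: pd.DataFrame, exc: Excursion) -> dict[str, float]:
    """Per-channel mean and sample SD over the five excursion windows.

    Windows are half-open ``[start, end)`` on the grid. A window with no
    finite points yields both statistics missing; a single point yields a
    mean but no SD. Keys are ``{channel}{tag}_mean`` / ``{channel}{tag}_sd``.
    """
    t = grid["time"].to_numpy(dtype=float)
    feats: dict[str, float] = {}
    for ch in CHANNELS:
        v = grid[ch].to_numpy(dtype=float) if ch in grid.columns else np.full(t.size, np.nan)
        for tag, win in _windows(exc).items():
            mean = sd = np.nan
            if win is not None:
                mask = (t >= win[0]) & (t < win[1]) & np.isfinite(v)
                vals = v[mask]
                if vals.size >= 1:
                    mean = float(np.mean(vals))
                if vals.size >= 2:
                    sd = float(np.std(vals, ddof=1))
            feats[f"{ch}{tag}_mean"] = mean
            feats[f"{ch}{tag}_sd"] = sd
    return feats


def sum_nutrients(meals: Sequence[MealEvent]) -> NutrientTotals:
    """Field-wise nutrient sums; an absent field in any contributing meal
    clears the ``complete`` flag. An empty list gives all-zero totals with
    ``complete=True``."""
    totals = NutrientTotals()
    for m in meals:
        for n in NUTRIENTS:
            v = m.nutrient(n)
            if v is None:
                totals.complete = False
            else:
                setattr(totals, n, getattr(totals, n) + v)
    return totals


def build_design_table(
    grids: Mapping[str, pd.DataFrame],
    meals: Mapping[str, Sequence[MealEvent]],
    participants: Sequence[ParticipantRecord] = (),
    horizon_minutes: float = 180.0,
    min_amplitude: float = 0.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One design row per detected excursion, plus an audit table.

    The design table holds the rise/fall slope responses, all window
    features, summed nutrient totals of meals falling in ``[meal, peak]``
    (with the next meal truncating the span, this is normally the anchor
    meal alone), a ``nutrients_complete`` flag, and the sex covariate. The
    audit table has one row per meal with the detection outcome code.
    """
    sex_by_pid = {p.participant_id: p.sex for p in participants}
    rows: list[dict] = []
    audit: list[dict] = []
    for pid, grid in grids.items():
        plist = sorted(meals.get(pid, []), key=lambda m: m.time)
        for k, meal in enumerate(plist):
            next_time = plist[k + 1].time if k + 1 < len(plist) else None
            exc, reason = detect_excursion(
                grid,
                meal.time,
                horizon_minutes=horizon_minutes,
                next_meal_time=next_time,
                min_amplitude=min_amplitude,
                participant_id=pid,
            )
            audit.append({"participant_id": pid, "meal_time": meal.time, "outcome": reason})
            if exc is None:
                continue
            rise, fall = compute_slopes(exc)
            contributing = [m for m in plist if exc.meal_time <= m.time <= exc.peak[0]]
            totals = sum_nutrients(contributing)
            truncated = next_time is not None and next_time < meal.time + horizon_minutes * 60.0
            row = {
                "participant_id": pid,
                "meal_time": meal.time,
                "rise_slope": rise,
                "fall_slope": np.nan if fall is None else fall,
                "peak_time": exc.peak[0],
                "peak_glucose": exc.peak[1],
                "trough_time": exc.trough_pre[0],
                "trough_glucose": exc.trough_pre[1],
                "truncated_by_next_meal": truncated,
            }
            row.update(window_features(grid, exc))
            for n in NUTRIENTS:
                row[n] = getattr(totals, n)
            row["nutrients_complete"] = totals.complete
            row["sex"] = sex_by_pid.get(pid, "")
            rows.append(row)
    audit_df = pd.DataFrame(audit, columns=["participant_id", "meal_time", "outcome"])
    if not rows:
        raise ValueError(
            "no excursions detected cohort-wide; audit outcomes: "
            + audit_df["outcome"].value_counts().to_dict().__repr__()
        )
    return pd.DataFrame(rows), audit_df


_FLOAT_FMT = "%.12g"


def save_design_table(design: pd.DataFrame, audit: pd.DataFrame, out_path: str | Path) -> None:
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    design.to_csv(out_path, index=False, float_format=_FLOAT_FMT)
    audit.to_csv(out_path.with_name(out_path.stem + "_audit.csv"), index=False, float_format=_FLOAT_FMT)
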