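"""Lagged Spearman correlation profiles between glucose and channel summaries.

Each profile pairs a glucose rolling summary at grid time ``t`` with a
channel rolling summary at ``t + lag`` for lags −120…+120 minutes in 15-min
steps. Negative lag means the physiological signal was measured *before*
the glucose reading; this sign convention is recorded in every output to
prevent drift. Pairs are formed within participant (a shift never spans
participants) and then pooled across the cohort, giving single cohort-level
correlation coefficients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from glycowear.datatypes import CHANNELS, GRID_SPACING_S

#: Statistic pairs reported by the analysis: (glucose statistic, channel
#: statistic) where "mean"/"sd" are the 3-point rolling summaries.
STAT_PAIRS: dict[str, tuple[str, str]] = {
    "mean_vs_mean": ("mean", "mean"),
    "mean_vs_sd": ("mean", "sd"),
    "sd_vs_sd": ("sd", "sd"),
}

#: Default lag offsets in minutes: 0 plus eight 15-min steps on each side.
DEFAULT_LAGS: tuple[int, ...] = tuple(range(-120, 121, 15))

SIGN_CONVENTION = "negative lag = physiological signal measured before glucose"


@dataclass
class LagPairTable:
    """Complete (glucose_stat, channel_stat) pairs at one lag, pooled."""

    lag_minutes: int
    glucose_values: np.ndarray
    channel_values: np.ndarray

    @property
    def n(self) -> int:
        return int(self.glucose_values.size)


@dataclass
class SpearmanResult:
    rho: float
    p_value: float
    n: int
    defined: bool = True


@dataclass
class LagEntry:
    lag_minutes: int
    rho: float
    p_value: float
    n: int
    significant: bool
    defined: bool


@dataclass
class CorrelationProfile:
    """Per-lag Spearman rho/p/n for one channel and statistic pair."""

    channel: str
    stat_pair: str
    entries: list[LagEntry] = field(default_factory=list)
    sign_convention: str = SIGN_CONVENTION

    @property
    def peak_lag(self) -> int | None:
        """Lag of maximal |rho| among defined entries; earliest lag on ties."""
        best: tuple[float, int] | None = None
        for e in self.entries:  # entries are in ascending-lag order
            if e.defined and (best is None or abs(e.rho) > best[0]):
                best = (abs(e.rho), e.lag_minutes)
        return None if best is None else best[1]

    @property
    def peak_rho(self) -> float | None:
        lag = self.peak_lag
        for e in self.entries:
            if e.lag_minutes == lag:
                return e.rho
        return None


def build_lag_pairs(
    grids: Mapping[str, pd.DataFrame],
    channel: str,
    stat_pair: str,
    lag_minutes: int,
    spacing_s: float = GRID_SPACING_S,
) -> LagPairTable:
    """Pool within-participant shifted pairs at one lag.

    The glucose summary at time ``t`` is paired with the channel summary at
    ``t + lag``; rows with either side missing are dropped. The lag must be
    an integer number of grid steps.
    """
    steps_f = lag_minutes * 60.0 / spacing_s
    steps = int(round(steps_f))
    if abs(steps_f - steps) > 1e-9:
        raise ValueError(f"lag {lag_minutes} min is not a whole number of grid steps")
    g_stat, c_stat = STAT_PAIRS[stat_pair]
    gcol, ccol = f"glucose_{g_stat}", f"{channel}_{c_stat}"

    xs: list[np.ndarray] = []
    ys: list[np.ndarray] = []
    any_channel = False
    for df in grids.values():
        if ccol not in df.columns:
            continue
        g = df[gcol].to_numpy(dtype=float)
        c = df[ccol].to_numpy(dtype=float)
        if np.isfinite(c).any():
            any_channel = True
        if abs(steps) >= g.size:
            continue  # shift exceeds this participant's span
        if steps >= 0:
            x, y = (g[: g.size - steps], c[steps:]) if steps else (g, c)
        else:
            x, y = g[-steps:], c[: c.size + steps]
        ok = np.isfinite(x) & np.isfinite(y)
        xs.append(x[ok])
        ys.append(y[ok])
    if not any_channel:
        warnings.warn(f"channel {channel!r} absent for all participants", stacklevel=2)
    gx = np.concatenate(xs) if xs else np.empty(0)
    cy = np.concatenate(ys) if ys else np.empty(0)
    return LagPairTable(lag_minutes=lag_minutes, glucose_values=gx, channel_values=cy)


def spearman(x: np.ndarray, y: np.ndarray) -> SpearmanResult:
    """Spearman rank correlation with mid-ranks and a t-approximation p.

    rho is the Pearson correlation of mid-ranks (average ranks for ties);
    the two-sided p value comes from ``t = rho * sqrt((n-2) / (1-rho^2))``
    on n−2 degrees of freedom; ``|rho| = 1`` reports p = 0. With n < 3 or a
    zero-variance rank vector the result is flagged undefined rather than
    silently reported as 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 3 or np.unique(x).size < 2 or np.unique(y).size < 2:
        return SpearmanResult(rho=np.nan, p_value=np.nan, n=n, defined=False)
    res = stats.spearmanr(x, y)
    rho = float(res.statistic)
    if abs(rho) >= 1.0 - 1e-15:
        return SpearmanResult(rho=float(np.sign(rho)), p_value=0.0, n=n)
    return SpearmanResult(rho=rho, p_value=float(res.pvalue), n=n)


def correlation_profile(
    grids: Mapping[str, pd.DataFrame],
    channel: str,
    stat_pair: str,
    lags: Sequence[int] = DEFAULT_LAGS,
    alpha: float = 0.05,
    spacing_s: float = GRID_SPACING_S,
) -> CorrelationProfile:
    """Spearman profile over all lags for one channel and statistic pair.

    Entries with fewer than 3 complete pairs (or degenerate ranks) are
    marked undefined; the profile is still returned. The significance flag
    mirrors the P < .05 asterisk convention of the profile plots.
    """
    profile = CorrelationProfile(channel=channel, stat_pair=stat_pair)
    for lag in sorted(lags):
        pairs = build_lag_pairs(grids, channel, stat_pair, lag, spacing_s)
        r = spearman(pairs.glucose_values, pairs.channel_values)
        profile.entries.append(
            LagEntry(
                lag_minutes=lag,
                rho=r.rho,
                p_value=r.p_value,
                n=r.n,
                significant=bool(r.defined and r.p_value < alpha),
                defined=r.defined,
            )
        )
    return profile


def profiles_to_frame(profiles: Iterable[CorrelationProfile]) -> pd.DataFrame:
    """Long-format table: channel, stat_pair, lag_minutes, rho, p, n, flag."""
    rows = []
    for prof in profiles:
        for e in prof.entries:
            rows.append(
                {
                    "channel": prof.channel,
                    "stat_pair": prof.stat_pair,
                    "lag_minutes": e.lag_minutes,
                    "rho": e.rho,
                    "p": e.p_value,
                    "n": e.n,
                    "significant": e.significant,
                    "sign_convention": prof.sign_convention,
                }
            )
    return pd.DataFrame(rows)


def all_profiles(
    grids: Mapping[str, pd.DataFrame],
    channels: Sequence[str] = CHANNELS,
    stat_pairs: Sequence[str] = tuple(STAT_PAIRS),
    lags: Sequence[int] = DEFAULT_LAGS,
) -> list[CorrelationProfile]:
    return [
        correlation_profile(grids, ch, sp, lags) for ch in channels for sp in stat_pairs
    ]


def plot_profile(profile: CorrelationProfile, path: str | Path) -> None:
    """Save a rho-vs-lag line plot with P < .05 entries starred."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    lags = [e.lag_minutes for e in profile.entries if e.defined]
    rhos = [e.rho for e in profile.entries if e.defined]
    fig, ax = plt.subplots(figsize=(6, 3.5))
    ax.axhline(0.0, color="0.8", lw=0.8)
    ax.plot(lags, rhos, marker="o", ms=3)
    for e in profile.entries:
        if e.defined and e.significant:
            ax.annotate("*", (e.lag_minutes, e.rho), textcoords="offset points", xytext=(0, 4))
    ax.set_xlabel(f"lag (min); {profile.sign_convention}")
    ax.set_ylabel("Spearman rho")
    ax.set_title(f"{profile.channel} {profile.stat_pair}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
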