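"""Core domain containers shared by every pipeline stage.

Timestamps are epoch seconds (UTC, no DST handling): the source datasets are
date-shifted for de-identification, so absolute dates carry no meaning and
local times are taken at face value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

#: Wearable channels in canonical order. ACC is triaxial acceleration (g),
#: HR heart rate (bpm), TEMP skin temperature (degC), EDA electrodermal
#: activity (uS), BVP blood volume pulse (a.u.), IBI interbeat interval (s).
CHANNELS: tuple[str, ...] = ("ACC", "HR", "TEMP", "EDA", "BVP", "IBI")

#: Channels sampled at a fixed rate (everything but the event-based IBI).
RATED_CHANNELS: tuple[str, ...] = ("ACC", "HR", "TEMP", "EDA", "BVP")

#: Native Empatica E4 sampling rates in Hz (IBI is event based, rate 0).
NATIVE_RATES_HZ: dict[str, float] = {
    "ACC": 32.0,
    "HR": 1.0,
    "TEMP": 4.0,
    "EDA": 4.0,
    "BVP": 64.0,
    "IBI": 0.0,
}

#: Nutrient fields of a food-log entry, canonical order.
NUTRIENTS: tuple[str, ...] = (
    "calories",
    "carbohydrate",
    "dietary_fiber",
    "sugar",
    "protein",
    "total_fat",
)

#: CGM grid spacing in seconds (Dexcom G6 cadence).
GRID_SPACING_S: int = 300


@dataclass(frozen=True)
class ParticipantRecord:
    """One participant: opaque id, sex, and HbA1c in percent."""

    participant_id: str
    sex: str  # "male" | "female"
    hba1c: float

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if not (3.0 < self.hba1c < 20.0):
            raise ValueError(f"implausible HbA1c {self.hba1c}% for {self.participant_id}")


@dataclass
class SensorStream:
    """One raw wearable channel for one participant.

    ``samples`` is a 1-D array for scalar channels, an ``(n, 3)`` array of
    x/y/z triples in g for ACC, and an ``(n, 2)`` array of
    (offset-seconds, interval-seconds) pairs for the event-based IBI channel.
    Sample timestamps for rated channels derive as
    ``start_epoch + i / rate_hz``; IBI event times are
    ``start_epoch + offset``.
    """

    participant_id: str
    channel: str
    rate_hz: float
    start_epoch: float
    samples: np.ndarray

    def __post_init__(self) -> None:
        if self.channel not in CHANNELS:
            raise ValueError(f"unknown channel {self.channel!r}")
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.size == 0:
            raise ValueError(f"{self.channel} stream for {self.participant_id} is empty")
        if self.channel == "IBI":
            if self.samples.ndim != 2 or self.samples.shape[1] != 2:
                raise ValueError("IBI samples must be (offset, interval) pairs")
        elif self.channel == "ACC":
            if self.rate_hz <= 0:
                raise ValueError("ACC stream requires rate_hz > 0")
            if self.samples.ndim != 2 or self.samples.shape[1] != 3:
                raise ValueError("ACC samples must be (x, y, z) triples")
        else:
            if self.rate_hz <= 0:
                raise ValueError(f"{self.channel} stream requires rate_hz > 0")
            if self.samples.ndim != 1:
                raise ValueError(f"{self.channel} samples must be 1-D")

    @property
    def times(self) -> np.ndarray:
        """Epoch-second timestamp of each sample (event time for IBI)."""
        if self.channel == "IBI":
            return self.start_epoch + self.samples[:, 0]
        n = self.samples.shape[0]
        return self.start_epoch + np.arange(n) / self.rate_hz

    @property
    def values(self) -> np.ndarray:
        """Scalar value series (interval seconds for IBI; triples for ACC)."""
        if self.channel == "IBI":
            return self.samples[:, 1]
        return self.samples


@dataclass
class GlucoseSeries:
    """Interstitial glucose (mg/dL) at nominal 5-min cadence, gaps allowed."""

    participant_id: str
    times: np.ndarray
    glucose: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.glucose = np.asarray(self.glucose, dtype=float)
        if self.times.shape != self.glucose.shape or self.times.ndim != 1:
            raise ValueError("times and glucose must be equal-length 1-D arrays")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("glucose timestamps must be strictly increasing")

    def __len__(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class MealEvent:
    """One food-log entry: start time plus nutrient totals.

    A missing nutrient cell is ``None`` (absent), never 0 — absence
    propagates to the ``complete`` flag of summed per-excursion totals.
    """

    participant_id: str
    time: float
    calories: Optional[float] = None
    carbohydrate: Optional[float] = None
    dietary_fiber: Optional[float] = None
    sugar: Optional[float] = None
    protein: Optional[float] = None
    total_fat: Optional[float] = None

    def nutrient(self, name: str) -> Optional[float]:
        if name not in NUTRIENTS:
            raise KeyError(name)
        return getattr(self, name)


@dataclass
class Cohort:
    """In-memory cohort: participants plus per-participant data keyed by id."""

    participants: list[ParticipantRecord] = field(default_factory=list)
    glucose: dict[str, GlucoseSeries] = field(default_factory=dict)
    streams: dict[str, dict[str, SensorStream]] = field(default_factory=dict)
    meals: dict[str, list[MealEvent]] = field(default_factory=dict)

    @property
    def participant_ids(self) -> list[str]:
        return [p.participant_id for p in self.participants]

    def sex_of(self, participant_id: str) -> str:
        for p in self.participants:
            if p.participant_id == participant_id:
                return p.sex
        raise KeyError(participant_id)
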