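"""Seeded synthetic cohort generator with configurable ground-truth couplings.

The generator emulates the statistical structure the analysis assumes in a
16-participant, 8–10-day wearable study: a 5-minute CGM trace built from a
baseline, meal-driven double-exponential excursion kernels, a short-memory
AR(1) physiological fluctuation and white sensor noise; six wearable
channels whose 5-minute summaries carry configurable couplings to the
(lag-shifted) glucose signal; and a food log with correlated nutrient
totals (carbohydrate–calorie r ≈ 0.78, carbohydrate–protein r ≈ 0.49,
matching the cohort the analysis targets).

Couplings act at the 5-minute summary level and are then upsampled with
native-rate noise, because the analyses only ever see 5-minute summaries.
A ``mean`` coupling makes the channel level a standardized linear function
of the shifted glucose; an ``sd`` coupling modulates the channel's local
noise scale multiplicatively, so the 3-point rolling SD tracks the shifted
glucose. Negative lag means the channel leads glucose (the channel value
at time *s* reflects glucose at *s − lag*).

Two output levels are provided: :func:`simulate_grid_cohort` returns
in-memory 5-minute grids (used for statistical calibration at scale), and
:func:`simulate_cohort` additionally writes raw native-rate files in
exactly the dialects the ingest readers consume (ACC 32 Hz triaxial,
EDA/TEMP 4 Hz, HR 1 Hz, BVP 64 Hz, IBI events).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from glycowear import align as _align
from glycowear import excursion as _excursion
from glycowear.datatypes import (
    CHANNELS,
    GRID_SPACING_S,
    NATIVE_RATES_HZ,
    NUTRIENTS,
    Cohort,
    GlucoseSeries,
    MealEvent,
    ParticipantRecord,
    SensorStream,
)

_FLOAT_FMT = "%.12g"

#: Fixed epoch origin for synthetic cohorts (absolute dates carry no meaning).
EPOCH0 = 1_600_000_000.0


@dataclass
class KernelParams:
    """Postprandial glucose response kernel parameters.

    The meal response is a double-exponential bump
    ``A * (exp(-t/tau_fall) - exp(-t/tau_rise)) / peak_norm`` with amplitude
    ``A = carb_gain * carbohydrate * max(0, 1 - fiber_damping * fiber)`` in
    mg/dL, zero at t = 0 and tending to zero as t grows. With the default
    time constants the analytic peak falls ~28 min after the meal.
    """

    baseline: float = 90.0  # mg/dL
    carb_gain: float = 1.0  # mg/dL peak increment per g carbohydrate
    fiber_damping: float = 0.02  # fractional peak reduction per g fiber
    tau_rise: float = 15.0  # min
    tau_fall: float = 60.0  # min

    def __post_init__(self) -> None:
        if self.tau_rise <= 0 or self.tau_fall <= 0 or self.tau_fall == self.tau_rise:
            raise ValueError("time constants must be positive and distinct")

    @property
    def peak_time_minutes(self) -> float:
        """Analytic peak time ln(tau_fall/tau_rise)*tau_rise*tau_fall/(tau_fall-tau_rise)."""
        return (
            np.log(self.tau_fall / self.tau_rise)
            * self.tau_rise
            * self.tau_fall
            / (self.tau_fall - self.tau_rise)
        )


@dataclass
class Coupling:
    """Ground-truth dependence of one channel summary on shifted glucose.

    ``target`` selects which rolling statistic carries the coupling:
    ``"mean"`` shifts the channel level, ``"sd"`` modulates its local noise
    scale. ``strength`` is on the standardized scale in [−1, 1] and its sign
    is the sign of the induced correlation; ``lag_minutes`` < 0 means the
    channel leads glucose.
    """

    channel: str
    target: str  # "mean" | "sd"
    lag_minutes: int
    strength: float

    def __post_init__(self) -> None:
        if self.channel not in CHANNELS:
            raise ValueError(f"unknown channel {self.channel!r}")
        if self.target not in ("mean", "sd"):
            raise ValueError("coupling target must be 'mean' or 'sd'")
        if not -1.0 <= self.strength <= 1.0:
            raise ValueError(f"infeasible coupling strength {self.strength}")


@dataclass
class ChannelLevels:
    """Grid-level baseline, variability and native-rate noise per channel."""

    base: float
    amp: float  # SD of the 5-min level around base
    native_noise: float  # extra white noise SD on raw samples


#: Physiologically plausible default channel levels (ACC norm ~1 g at rest).
DEFAULT_LEVELS: dict[str, ChannelLevels] = {
    "ACC": ChannelLevels(base=0.98, amp=0.20, native_noise=0.05),
    "HR": ChannelLevels(base=72.0, amp=8.0, native_noise=2.0),
    "TEMP": ChannelLevels(base=33.0, amp=0.8, native_noise=0.05),
    "EDA": ChannelLevels(base=2.0, amp=0.5, native_noise=0.05),
    "BVP": ChannelLevels(base=0.0, amp=1.0, native_noise=0.5),
    "IBI": ChannelLevels(base=0.85, amp=0.07, native_noise=0.02),
}

#: Default ground-truth couplings, mirroring the qualitative structure the
#: analysis looks for: EDA/ACC/HR variability leading glucose by 15 min with
#: negative sign, and skin temperature level tracking glucose at lag 0.
DEFAULT_COUPLINGS: tuple[Coupling, ...] = (
    Coupling("EDA", "sd", -15, -0.5),
    Coupling("ACC", "sd", -15, -0.3),
    Coupling("HR", "sd", -15, -0.25),
    Coupling("TEMP", "mean", 0, 0.3),
)


@dataclass
class NutrientParams:
    """Per-meal nutrient distribution with configured correlations."""

    carb_mean: float = 60.0
    carb_sd: float = 25.0
    protein_mean: float = 25.0
    protein_sd: float = 10.0
    calories_mean: float = 650.0
    calories_sd: float = 250.0
    fiber_mean: float = 4.0
    fiber_sd: float = 3.0
    fat_mean: float = 22.0
    fat_sd: float = 10.0
    carb_calorie_corr: float = 0.78
    carb_protein_corr: float = 0.49
    sugar_fraction_range: tuple[float, float] = (0.2, 0.7)


@dataclass
class SimulationConfig:
    """Full description of a synthetic cohort; a fixed seed reproduces it
    bit-identically."""

    n_participants: int = 16
    days_range: tuple[int, int] = (8, 10)
    day_seconds: float = 86400.0
    seed: int = 0
    meals_per_day: int = 3
    meal_hours: tuple[float, ...] = (7.5, 12.5, 18.5)
    meal_jitter_minutes: float = 40.0
    kernel: KernelParams = field(default_factory=KernelParams)
    nutrients: NutrientParams = field(default_factory=NutrientParams)
    couplings: tuple[Coupling, ...] = DEFAULT_COUPLINGS
    levels: dict[str, ChannelLevels] = field(default_factory=lambda: dict(DEFAULT_LEVELS))
    cgm_noise_sd: float = 3.0  # mg/dL white sensor noise
    fluctuation_sd: float = 5.0  # mg/dL AR(1) physiological fluctuation
    fluctuation_phi: float = 0.55  # AR(1) coefficient per 5-min step
    male_fraction: float = 0.44
    hba1c_mean: float = 5.73
    hba1c_sd: float = 0.28
    hba1c_range: tuple[float, float] = (5.2, 6.4)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping) -> "SimulationConfig":
        raw = dict(raw)
        if "kernel" in raw and isinstance(raw["kernel"], Mapping):
            raw["kernel"] = KernelParams(**raw["kernel"])
        if "nutrients" in raw and isinstance(raw["nutrients"], Mapping):
            raw["nutrients"] = NutrientParams(
                **{
                    k: tuple(v) if k == "sugar_fraction_range" else v
                    for k, v in raw["nutrients"].items()
                }
            )
        if "couplings" in raw:
            raw["couplings"] = tuple(
                c if isinstance(c, Coupling) else Coupling(**c) for c in raw["couplings"]
            )
        if "levels" in raw:
            raw["levels"] = {
                k: v if isinstance(v, ChannelLevels) else ChannelLevels(**v)
                for k, v in raw["levels"].items()
            }
        for key in ("days_range", "meal_hours", "hba1c_range"):
            if key in raw and not isinstance(raw[key], tuple):
                raw[key] = tuple(raw[key])
        return cls(**raw)


def glucose_response_kernel(
    carbohydrate: float,
    dietary_fiber: float,
    t_minutes: np.ndarray,
    params: KernelParams,
) -> np.ndarray:
    """Glucose increment (mg/dL) at ``t_minutes`` after a meal.

    Zero at t = 0 and for t < 0; the peak increment equals
    ``carb_gain * carbohydrate * max(0, 1 - fiber_damping * fiber)`` at the
    analytic peak time.
    """
    t = np.asarray(t_minutes, dtype=float)
    amp = params.carb_gain * carbohydrate * max(0.0, 1.0 - params.fiber_damping * dietary_fiber)
    tpos = np.where(t > 0, t, np.inf)  # zero response at and before the meal
    shape = np.exp(-tpos / params.tau_fall) - np.exp(-tpos / params.tau_rise)
    tstar = params.peak_time_minutes
    norm = np.exp(-tstar / params.tau_fall) - np.exp(-tstar / params.tau_rise)
    return amp * shape / norm


def _participant_rng(seed: int, index: int) -> np.random.Generator:
    # splittable per-participant seeding: reproducible under cohort-size changes
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(index)]))


def _draw_meals(cfg: SimulationConfig, rng: np.random.Generator, pid: str, days: int) -> list[MealEvent]:
    nu = cfg.nutrients
    hours = cfg.meal_hours[: cfg.meals_per_day]
    if len(hours) < cfg.meals_per_day:
        hours = tuple(np.linspace(7.0, 19.0, cfg.meals_per_day))
    scale = cfg.day_seconds / 86400.0
    meals: list[MealEvent] = []
    for d in range(days):
        for h in hours:
            t = EPOCH0 + d * cfg.day_seconds + h * 3600.0 * scale
            t += rng.normal(0.0, cfg.meal_jitter_minutes * 60.0 * scale)
            z = rng.standard_normal(4)
            carb = max(5.0, nu.carb_mean + nu.carb_sd * z[0])
            rho_p, rho_c = nu.carb_protein_corr, nu.carb_calorie_corr
            protein = max(
                0.0, nu.protein_mean + nu.protein_sd * (rho_p * z[0] + np.sqrt(1 - rho_p**2) * z[1])
            )
            calories = max(
                50.0,
                nu.calories_mean + nu.calories_sd * (rho_c * z[0] + np.sqrt(1 - rho_c**2) * z[2]),
            )
            fiber = max(0.0, nu.fiber_mean + nu.fiber_sd * z[3])
            sugar = carb * rng.uniform(*nu.sugar_fraction_range)
            fat = max(0.0, nu.fat_mean + nu.fat_sd * rng.standard_normal())
            meals.append(
                MealEvent(
                    participant_id=pid,
                    time=float(t),
                    calories=float(calories),
                    carbohydrate=float(carb),
                    dietary_fiber=float(fiber),
                    sugar=float(sugar),
                    protein=float(protein),
                    total_fat=float(fat),
                )
            )
    meals.sort(key=lambda m: m.time)
    return meals


def _shift(z: np.ndarray, lag_steps: int) -> np.ndarray:
    """Series whose value at index j is ``z[j - lag_steps]`` (0 off the ends)."""
    out = np.zeros_like(z)
    n = z.size
    if lag_steps >= 0:
        if lag_steps < n:
            out[lag_steps:] = z[: n - lag_steps]
    else:
        if -lag_steps < n:
            out[: n + lag_steps] = z[-lag_steps:]
    return out


@dataclass
class ParticipantTruth:
    """Ground truth stored alongside each generated participant."""

    participant_id: str
    days: int
    meal_times: list[float]
    carbohydrate: list[float]
    dietary_fiber: list[float]
    peak_increment: list[float]  # kernel amplitude A per meal (mg/dL)
    true_rise_slope: list[float]  # detection on the noiseless kernel trace
    true_fall_slope: list[Optional[float]]
    couplings: list[dict]


@dataclass
class GridParticipant:
    grid: pd.DataFrame  # time, glucose and the six channel grid values
    meals: list[MealEvent]
    truth: ParticipantTruth
    noiseless_glucose: np.ndarray


def simulate_grid_participant(cfg: SimulationConfig, index: int) -> GridParticipant:
    """One participant at the 5-minute grid level, plus ground truth."""
    rng = _participant_rng(cfg.seed, index)
    pid = f"s{index + 1:02d}"
    days = int(rng.integers(cfg.days_range[0], cfg.days_range[1] + 1))
    n = int(round(days * cfg.day_seconds / GRID_SPACING_S))
    times = EPOCH0 + GRID_SPACING_S * np.arange(n)
    minutes = (times - EPOCH0) / 60.0

    meals = _draw_meals(cfg, rng, pid, days)
    kernel_sum = np.zeros(n)
    amps: list[float] = []
    for m in meals:
        kernel_sum += glucose_response_kernel(
            m.carbohydrate, m.dietary_fiber, minutes - (m.time - EPOCH0) / 60.0, cfg.kernel
        )
        amps.append(
            cfg.kernel.carb_gain
            * m.carbohydrate
            * max(0.0, 1.0 - cfg.kernel.fiber_damping * m.dietary_fiber)
        )
    noiseless = cfg.kernel.baseline + kernel_sum

    # AR(1) physiological fluctuation at the grid cadence
    eps = rng.normal(0.0, cfg.fluctuation_sd * np.sqrt(1 - cfg.fluctuation_phi**2), n)
    fluct = np.empty(n)
    prev = rng.normal(0.0, cfg.fluctuation_sd)
    for i in range(n):
        prev = cfg.fluctuation_phi * prev + eps[i]
        fluct[i] = prev
    g_true = noiseless + fluct
    observed = np.clip(g_true + rng.normal(0.0, cfg.cgm_noise_sd, n), 40.0, 400.0)

    sd = g_true.std()
    z = (g_true - g_true.mean()) / (sd if sd > 0 else 1.0)

    grid = pd.DataFrame({"time": times, "glucose": observed})
    coupling_by_channel = {c.channel: c for c in cfg.couplings}
    for ch in CHANNELS:
        lv = cfg.levels[ch]
        noise = rng.standard_normal(n)
        c = coupling_by_channel.get(ch)
        if c is None:
            vals = lv.base + lv.amp * noise
        else:
            steps = int(round(c.lag_minutes * 60.0 / GRID_SPACING_S))
            zs = _shift(z, steps)
            if c.target == "mean":
                vals = lv.base + lv.amp * (
                    c.strength * zs + np.sqrt(1 - c.strength**2) * noise
                )
            else:  # sd coupling: multiplicative modulation of the noise scale
                vals = lv.base + lv.amp * np.exp(c.strength * np.clip(zs, -3, 3)) * noise
        if ch in ("EDA", "ACC"):
            vals = np.maximum(vals, 0.01)
        elif ch == "HR":
            vals = np.maximum(vals, 30.0)
        elif ch == "IBI":
            vals = np.maximum(vals, 0.3)
        grid[ch] = vals

    # ground-truth slopes: the detection rules applied to the noiseless trace
    truth_grid = pd.DataFrame({"time": times, "glucose": noiseless})
    rises: list[float] = []
    falls: list[Optional[float]] = []
    for k, m in enumerate(meals):
        next_t = meals[k + 1].time if k + 1 < len(meals) else None
        exc, _ = _excursion.detect_excursion(
            truth_grid, m.time, next_meal_time=next_t, participant_id=pid
        )
        if exc is None:
            rises.append(float("nan"))
            falls.append(None)
        else:
            r, f = _excursion.compute_slopes(exc)
            rises.append(r)
            falls.append(f)

    truth = ParticipantTruth(
        participant_id=pid,
        days=days,
        meal_times=[m.time for m in meals],
        carbohydrate=[m.carbohydrate for m in meals],
        dietary_fiber=[m.dietary_fiber for m in meals],
        peak_increment=amps,
        true_rise_slope=rises,
        true_fall_slope=falls,
        couplings=[dataclasses.asdict(c) for c in cfg.couplings],
    )
    return GridParticipant(grid=grid, meals=meals, truth=truth, noiseless_glucose=noiseless)


@dataclass
class GridCohort:
    """In-memory grid-level cohort: the fast path for calibration studies."""

    participants: list[ParticipantRecord]
    grids: dict[str, pd.DataFrame]
    meals: dict[str, list[MealEvent]]
    truth: dict[str, ParticipantTruth]


def _draw_participant_record(cfg: SimulationConfig, rng: np.random.Generator, pid: str) -> ParticipantRecord:
    sex = "male" if rng.random() < cfg.male_fraction else "female"
    hba1c = float(np.clip(rng.normal(cfg.hba1c_mean, cfg.hba1c_sd), *cfg.hba1c_range))
    return ParticipantRecord(participant_id=pid, sex=sex, hba1c=round(hba1c, 1))


def simulate_grid_cohort(cfg: SimulationConfig) -> GridCohort:
    """Generate the whole cohort at the 5-minute grid level."""
    participants: list[ParticipantRecord] = []
    grids: dict[str, pd.DataFrame] = {}
    meals: dict[str, list[MealEvent]] = {}
    truth: dict[str, ParticipantTruth] = {}
    for i in range(cfg.n_participants):
        gp = simulate_grid_participant(cfg, i)
        pid = gp.truth.participant_id
        # demographics drawn from a separate derived stream so grid data do
        # not change if the demographic model changes
        demo_rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), int(i), 7]))
        participants.append(_draw_participant_record(cfg, demo_rng, pid))
        grids[pid] = gp.grid
        meals[pid] = gp.meals
        truth[pid] = gp.truth
    return GridCohort(participants=participants, grids=grids, meals=meals, truth=truth)


def attach_rolling(
    grids: Mapping[str, pd.DataFrame], window: int = 3, align: str = "trailing"
) -> dict[str, pd.DataFrame]:
    """Add the ``_mean``/``_sd`` rolling summary columns to grid-level data."""
    out: dict[str, pd.DataFrame] = {}
    for pid, df in grids.items():
        df = df.copy()
        for var in _align.GRID_VARIABLES:
            mean, sd = _align.rolling_mean_sd(df[var].to_numpy(), window, align)
            df[f"{var}_mean"] = mean
            df[f"{var}_sd"] = sd
        out[pid] = df
    return out


# ---------------------------------------------------------------------------
# Raw native-rate file generation


def _upsample_channel(
    ch: str,
    grid_vals: np.ndarray,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    start_epoch: float,
    pid: str,
) -> SensorStream:
    """Expand 5-min channel levels to native-rate raw samples.

    Raw samples for the window labelled ``t`` fill ``[t - 300, t)``, so the
    mean-resampled grid reproduces the 5-min levels up to native noise.
    """
    lv = cfg.levels[ch]
    rate = NATIVE_RATES_HZ[ch]
    if ch == "IBI":
        # one event per nominal interval; interval value from its 5-min bin
        step = max(lv.base, 0.3)
        total_s = grid_vals.size * GRID_SPACING_S
        offsets = np.arange(0.0, total_s, step)
        bins = np.minimum((offsets // GRID_SPACING_S).astype(int), grid_vals.size - 1)
        intervals = grid_vals[bins] + rng.normal(0.0, lv.native_noise, offsets.size)
        intervals = np.maximum(intervals, 0.1)
        samples = np.column_stack([offsets, intervals])
        return SensorStream(pid, ch, 0.0, start_epoch, samples)
    per_bin = int(round(rate * GRID_SPACING_S))
    raw = np.repeat(grid_vals, per_bin)
    if ch == "ACC":
        comp = raw / np.sqrt(3.0)
        tri = np.column_stack([comp, comp, comp])
        tri += rng.normal(0.0, lv.native_noise, tri.shape)
        return SensorStream(pid, ch, rate, start_epoch, tri)
    raw = raw + rng.normal(0.0, lv.native_noise, raw.size)
    if ch == "EDA":
        raw = np.maximum(raw, 0.0)
    return SensorStream(pid, ch, rate, start_epoch, raw)


def simulate_participant(
    cfg: SimulationConfig, index: int
) -> tuple[ParticipantRecord, GlucoseSeries, dict[str, SensorStream], list[MealEvent], ParticipantTruth]:
    """One participant with raw native-rate streams in memory."""
    gp = simulate_grid_participant(cfg, index)
    pid = gp.truth.participant_id
    raw_rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), int(index), 13]))
    demo_rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), int(index), 7]))
    record = _draw_participant_record(cfg, demo_rng, pid)
    times = gp.grid["time"].to_numpy()
    start_epoch = float(times[0] - GRID_SPACING_S)
    streams = {
        ch: _upsample_channel(ch, gp.grid[ch].to_numpy(), cfg, raw_rng, start_epoch, pid)
        for ch in CHANNELS
    }
    glucose = GlucoseSeries(pid, times, gp.grid["glucose"].to_numpy())
    return record, glucose, streams, gp.meals, gp.truth


def simulate_cohort(cfg: SimulationConfig, out_dir: str | Path, force: bool = False) -> Path:
    """Write a full raw-file cohort plus a ground-truth manifest.

    Layout: ``participants.csv``, ``ground_truth.json``, ``sim_config.yaml``
    and one directory per participant holding ``cgm.csv``, ``food.csv`` and
    the six E4-dialect channel files.
    """
    from glycowear import ingest

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if any(out.iterdir()) and not force:
        raise FileExistsError(f"{out} is not empty (pass force=True to overwrite)")

    records: list[ParticipantRecord] = []
    truths: dict[str, dict] = {}
    for i in range(cfg.n_participants):
        record, glucose, streams, meals, truth = simulate_participant(cfg, i)
        records.append(record)
        pid = record.participant_id
        pdir = out / pid
        pdir.mkdir(exist_ok=True)
        pd.DataFrame({"time": glucose.times, "glucose": glucose.glucose}).to_csv(
            pdir / "cgm.csv", index=False, float_format=_FLOAT_FMT
        )
        rows = [
            {"time": m.time, **{nut: m.nutrient(nut) for nut in NUTRIENTS}} for m in meals
        ]
        pd.DataFrame(rows, columns=["time", *NUTRIENTS]).to_csv(
            pdir / "food.csv", index=False, float_format=_FLOAT_FMT
        )
        for ch, stream in streams.items():
            ingest.write_e4_channel(stream, pdir / f"{ch}.csv")
        truths[pid] = dataclasses.asdict(truth)

    pd.DataFrame(
        [(r.participant_id, r.sex, r.hba1c) for r in records],
        columns=["participant_id", "sex", "hba1c"],
    ).to_csv(out / "participants.csv", index=False, float_format=_FLOAT_FMT)
    manifest = {"config": dataclasses.asdict(cfg), "participants": truths}
    (out / "ground_truth.json").write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    cfg.to_yaml(out / "sim_config.yaml")
    return out


def load_simulated(sim_dir: str | Path) -> Cohort:
    """Read a simulated raw-file cohort back through the ingest readers."""
    from glycowear import ingest

    root = Path(sim_dir)
    pids = pd.read_csv(root / "participants.csv")["participant_id"].astype(str).tolist()
    return ingest.ingest_raw(
        cgm_paths={p: root / p / "cgm.csv" for p in pids},
        e4_dirs={p: root / p for p in pids},
        food_paths={p: root / p / "food.csv" for p in pids},
        participants_path=root / "participants.csv",
    )


def implied_nutrient_effects(
    cohort: "GridCohort", nutrients: Sequence[str] = ("carbohydrate", "dietary_fiber")
) -> pd.Series:
    """Generator-implied regression effects of nutrients on the rise slope.

    Regresses the ground-truth rise slopes (the detection rules applied to
    the noiseless kernel trace) on the chosen per-meal nutrient totals by
    OLS; this is the coefficient vector the generator implies for the
    detected-slope regression under the same model.
    """
    rows = []
    for pid, t in cohort.truth.items():
        meals = cohort.meals[pid]
        for i, slope in enumerate(t.true_rise_slope):
            if np.isfinite(slope):
                rows.append(
                    {"rise": slope, **{n: meals[i].nutrient(n) for n in nutrients}}
                )
    df = pd.DataFrame(rows)
    X = np.column_stack([np.ones(len(df))] + [df[n].to_numpy() for n in nutrients])
    beta, *_ = np.linalg.lstsq(X, df["rise"].to_numpy(), rcond=None)
    return pd.Series(beta[1:], index=list(nutrients))
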