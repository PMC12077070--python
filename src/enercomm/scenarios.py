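"""Drought forcing and the scenario machinery.

A drought is a period during which all habitat resources are reduced to a
fraction of their normal level.  Designed (factorial) events have a
magnitude ``m`` (fraction reduced; default grid {0.98, 0.95, 0.90, 0.80}),
a total length in days (default grid {3, 9, 22, 57}, log-spaced) and
symmetric transition ramps (default 1 day), so a 3-day event is one ramp
day, one plateau day at the full reduction, and one recovery day.

Observed droughts are derived from a soil-moisture-index (SMI) series:
maximal runs of days with index below a percentile threshold become
events, with magnitude equal to one minus the threshold (a 2 % threshold
maps to 98 % resource reduction).  Observed events may be shorter than a
designed ramp-plateau-ramp allows; they then drop the plateau and still
bottom out at ``1 - m``.

A synthetic SMI generator (Gaussian-copula AR(1), uniform marginal) stands
in for monitoring data in tests and fixtures; it is synthetic and is not a
re-distribution of any observational product.
"""

from __future__ import annotations

import zlib
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .allometry import AllometryConfig
from .landscape import SeasonParams

__all__ = [
    "DroughtEvent",
    "ForcingSeries",
    "build_forcing",
    "smi_to_events",
    "synthetic_smi",
    "read_smi_csv",
    "EngineParams",
    "ScenarioConfig",
    "experiment_grid",
    "replicate_seed",
    "MAGNITUDES",
    "LENGTHS",
]

MAGNITUDES = (0.98, 0.95, 0.90, 0.80)
LENGTHS = (3, 9, 22, 57)
THRESHOLD_TO_MAGNITUDE = {0.02: 0.98, 0.05: 0.95, 0.10: 0.90, 0.20: 0.80}


@dataclass(frozen=True)
class DroughtEvent:
    """One drought: ``length_days`` total, resources reduced by ``magnitude``."""

    start_day: int
    length_days: int
    magnitude: float
    transition_days: int = 1

    def __post_init__(self):
        if not 0.0 < self.magnitude < 1.0:
            raise ValueError("magnitude must be in (0, 1)")
        if self.length_days < 1 or self.transition_days < 0:
            raise ValueError("invalid event lengths")

    @property
    def end_day(self) -> int:
        return self.start_day + self.length_days  # exclusive


@dataclass
class ForcingSeries:
    """Day-indexed resource multiplier in (0, 1]; 1 outside droughts."""

    multipliers: np.ndarray

    def __getitem__(self, day: int) -> float:
        if day < len(self.multipliers):
            return float(self.multipliers[day])
        return 1.0

    def __len__(self) -> int:
        return len(self.multipliers)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"day": np.arange(len(self.multipliers)),
                             "multiplier": self.multipliers})


def build_forcing(events: list[DroughtEvent], horizon_days: int,
                  strict: bool = True) -> ForcingSeries:
    """Assemble the daily multiplier series from non-overlapping events.

    Each event ramps linearly from 1 down to ``1 - m`` over its transition
    days, holds the plateau, and ramps back up; a 1-day transition day sits
    at the linear midpoint ``1 - m/2``.  With ``strict=True`` events too
    short for ramp-plateau-ramp raise; with ``strict=False`` (observed
    series) short events drop the plateau but still reach ``1 - m``.
    """
    mult = np.ones(horizon_days)
    prev_end = -1
    for ev in sorted(events, key=lambda e: e.start_day):
        if ev.start_day <= prev_end:
            raise ValueError("overlapping drought events")
        if ev.end_day > horizon_days or ev.start_day < 0:
            raise ValueError("event outside the simulation horizon")
        prev_end = ev.end_day - 1
        t, L, m = ev.transition_days, ev.length_days, ev.magnitude
        if L < 2 * t + 1:
            if strict:
                raise ValueError(
                    f"event of {L} days cannot hold {t}-day transitions plus a plateau")
            shape = _short_event_shape(L, m)
        else:
            down = [1.0 - m * j / (t + 1) for j in range(1, t + 1)]
            plateau = [1.0 - m] * (L - 2 * t)
            shape = down + plateau + down[::-1]
        mult[ev.start_day:ev.end_day] = shape
    return ForcingSeries(mult)


def _short_event_shape(L: int, m: float) -> list[float]:
    # 1-2 day observed events: no room for ramps, drop straight to 1 - m
    return [1.0 - m] * L


def synthetic_smi(n_days: int, autocorr: float = 0.8,
                  seed: int = 0) -> pd.DataFrame:
    """Synthetic soil-moisture-index series with uniform marginal in [0, 1].

    A Gaussian AR(1) process passed through the normal CDF (Gaussian
    copula), so index values are percentile-scaled like a drought-monitor
    SMI, and sub-threshold exceedances cluster into multi-day runs whose
    typical length grows with ``autocorr``.
    """
    if not 0.0 <= autocorr < 1.0:
        raise ValueError("autocorr must be in [0, 1)")
    from scipy.stats import norm

    rng = np.random.default_rng(seed)
    z = np.empty(n_days)
    z[0] = rng.standard_normal()
    innov = rng.standard_normal(n_days) * np.sqrt(1.0 - autocorr ** 2)
    for t in range(1, n_days):
        z[t] = autocorr * z[t - 1] + innov[t]
    dates = pd.date_range("2000-01-01", periods=n_days, freq="D")
    return pd.DataFrame({"date": dates, "smi": norm.cdf(z)})


def read_smi_csv(path: str | Path) -> pd.DataFrame:
    """Read an SMI series CSV with columns date (ISO-8601), smi (0-1)."""
    df = pd.read_csv(path, parse_dates=["date"])
    if df["smi"].isna().any():
        raise ValueError("SMI series has missing values; fill gaps before use")
    return df


def smi_to_events(series, threshold: float,
                  transition_days: int = 1,
                  magnitude: float | None = None) -> list[DroughtEvent]:
    """Threshold an SMI series into drought events.

    Maximal runs of consecutive days with index < ``threshold`` become
    events (run-length encoding of the exceedance mask).  The event
    magnitude defaults to ``1 - threshold``, pairing a 2 % drought
    threshold in the data with a 98 % resource reduction in the model;
    pass ``magnitude`` to override (cross combinations).
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    values = np.asarray(series["smi"] if isinstance(series, pd.DataFrame) else series,
                        dtype=float)
    mag = magnitude if magnitude is not None else round(1.0 - threshold, 10)
    below = values < threshold
    events: list[DroughtEvent] = []
    edges = np.flatnonzero(np.diff(np.concatenate(([False], below, [False]))
                                   .astype(np.int8)))
    for start, end in zip(edges[::2], edges[1::2]):
        events.append(DroughtEvent(int(start), int(end - start), mag,
                                   transition_days))
    return events


@dataclass(frozen=True)
class EngineParams:
    """Scheduler knobs (initial densities, establishment, ordering, burn-in)."""

    n0_per_species: int = 15
    init_storage_frac: float = 0.5
    conception_storage_frac: float = 0.6
    max_trials: int = 10
    dispersal_factor: float = 3.0
    order_alpha: float = 0.5
    order_beta: float = 2.0
    density_radius: float = 5.0
    juvenile_storage_frac: float = 0.25
    condition_jitter: float = 0.6
    max_population: int = 50_000


@dataclass
class ScenarioConfig:
    """Everything one simulation run needs; fully determined by its seed."""

    side_cells: int = 100
    habitat_frac: float = 0.3
    fragmentation: str = "medium"
    n_species: int = 10
    mass_min: float = 10.0
    mass_max: float = 100.0
    single_species: int | None = None    # species_id, or None for the community
    years: int = 10
    events: list[DroughtEvent] = field(default_factory=list)
    behaviour: str = "increase"
    seed: int = 0
    season: SeasonParams = field(default_factory=SeasonParams)
    allometry: AllometryConfig = field(default_factory=AllometryConfig)
    engine: EngineParams = field(default_factory=EngineParams)
    scenario_id: str = ""

    @property
    def horizon_days(self) -> int:
        return self.years * 365

    def forcing(self) -> ForcingSeries:
        return build_forcing(self.events, self.horizon_days, strict=False)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["events"] = [asdict(e) for e in self.events]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        d = dict(d)
        d["events"] = [DroughtEvent(**e) for e in d.get("events", [])]
        d["season"] = SeasonParams(**d["season"]) if isinstance(d.get("season"), dict) else d.get("season", SeasonParams())
        d["allometry"] = AllometryConfig(**d["allometry"]) if isinstance(d.get("allometry"), dict) else d.get("allometry", AllometryConfig())
        d["engine"] = EngineParams(**d["engine"]) if isinstance(d.get("engine"), dict) else d.get("engine", EngineParams())
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScenarioConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def replicate_seed(scenario_id: str, replicate: int) -> int:
    """Stable replicate seed below 2**31 from the scenario id and index."""
    return zlib.crc32(f"{scenario_id}#rep{replicate}".encode()) % (2 ** 31 - 1)


def mid_year_day(drought_year: int) -> int:
    """Simulation day of mid-summer (day 182) of the given 1-based year."""
    return (drought_year - 1) * 365 + 182


def experiment_grid(mode: str, replicates: int = 20,
                    base: ScenarioConfig | None = None,
                    species_ids=None) -> list[ScenarioConfig]:
    """The full factorial experiment of the study protocol.

    Community mode: 10-year runs, one drought starting mid-summer of year
    5.  Single-species mode: 3-year runs, drought in year 2, one species
    per run.  The grid crosses fragmentation {low, medium, high} x
    magnitude {0.98, 0.95, 0.90, 0.80} x length {3, 9, 22, 57} x behaviour
    {increase, maintain, decrease} x replicates, plus one no-drought
    control per fragmentation level and replicate.
    """
    if mode not in ("single_species", "community"):
        raise ValueError("mode must be 'single_species' or 'community'")
    base = base or ScenarioConfig()
    years, drought_year = (3, 2) if mode == "single_species" else (10, 5)
    start = mid_year_day(drought_year)
    species = list(species_ids) if species_ids else (
        list(range(1, base.n_species + 1)) if mode == "single_species" else [None])
    configs: list[ScenarioConfig] = []
    for sp in species:
        sp_tag = f"sp{sp}-" if sp is not None else ""
        for frag in ("low", "medium", "high"):
            for rep in range(1, replicates + 1):
                sid = f"{mode}-{sp_tag}{frag}-control"
                configs.append(replace(
                    base, fragmentation=frag, years=years, events=[],
                    behaviour="increase", single_species=sp,
                    scenario_id=sid, seed=replicate_seed(sid, rep)))
            for mag in MAGNITUDES:
                for length in LENGTHS:
                    for behav in ("increase", "maintain", "decrease"):
                        sid = (f"{mode}-{sp_tag}{frag}-m{mag:g}-L{length}-{behav}")
                        ev = DroughtEvent(start, length, mag)
                        for rep in range(1, replicates + 1):
                            configs.append(replace(
                                base, fragmentation=frag, years=years,
                                events=[ev], behaviour=behav, single_species=sp,
                                scenario_id=sid, seed=replicate_seed(sid, rep)))
    return configs
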