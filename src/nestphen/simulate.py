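"""Synthetic multi-site ground-nest studies with within-season grass growth.

The generator emulates the structure of range-wide sage-grouse nest datasets:
several study areas crossed with years (strata), linear grass growth within
the nesting season with stratum-specific intercepts and slopes, a 27-day
incubation period, periodic nest visits, and replicated grass-height
measurements taken under one of three protocols:

``FATE_DATE``
    vegetation measured on the day the nest's fate is discovered — the biased
    field protocol in which successful nests are measured later in the season;
``HATCH_DATE``
    vegetation measured at the (predicted) hatch date regardless of fate — the
    unbiased protocol;
``SCHEDULED``
    hatch date plus Gaussian timing jitter.

Daily survival of each nest is Bernoulli with
``logit(S) = beta0_logit + beta_grass_surv * (true hatch-date height - mean)``
so that a zero ``beta_grass_surv`` gives the pure measurement-timing bias
scenario and a positive one gives a genuine concealment effect.
"""

from __future__ import annotations

import dataclasses
import enum
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.special import expit, logit


class Protocol(str, enum.Enum):
    FATE_DATE = "FATE_DATE"
    HATCH_DATE = "HATCH_DATE"
    SCHEDULED = "SCHEDULED"


class Fate(str, enum.Enum):
    HATCHED = "HATCHED"
    FAILED = "FAILED"


class VisitState(str, enum.Enum):
    ALIVE = "ALIVE"
    FAILED = "FAILED"


@dataclass(frozen=True)
class SimConfig:
    """Generative parameters for a synthetic multi-site nest study.

    Defaults describe a plausible sage-grouse-like study: four study areas by
    three years, ~15 cm mean grass height at mid-season growing 0.3 cm/day,
    daily nest survival 0.96 (27-day success ~0.33), visits every 4 days, and
    10 replicate height measurements per nest (field studies used 8-20).
    """

    n_sites: int = 4
    n_years: int = 3
    nests_per_stratum: int = 50
    season_start_day: int = 110
    season_end_day: int = 180
    incubation_days: int = 27
    beta0_logit: float = float(logit(0.96))
    beta_grass_surv: float = 0.0
    grass_intercept_mean: float = 15.0
    grass_intercept_sd: float = 3.0
    grass_slope_mean: float = 0.3
    grass_slope_sd: float = 0.1
    nest_height_sd: float = 3.0
    replicate_sd: float = 2.0
    n_replicates: int = 10
    visit_interval_days: int = 4
    protocol: Protocol = Protocol.FATE_DATE
    scheduled_lag_sd: float = 2.0
    discovery_delay: int = 0
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "protocol", Protocol(self.protocol))
        for name in ("n_sites", "n_years", "nests_per_stratum", "incubation_days",
                     "n_replicates", "visit_interval_days"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")
        if self.season_end_day <= self.season_start_day + self.incubation_days:
            raise ValueError(
                "infeasible season window: season_end_day must exceed "
                f"season_start_day + incubation_days "
                f"({self.season_end_day} <= {self.season_start_day} + {self.incubation_days})"
            )
        for name in ("grass_intercept_sd", "grass_slope_sd", "nest_height_sd",
                     "replicate_sd", "scheduled_lag_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.discovery_delay < 0:
            raise ValueError("discovery_delay must be >= 0")

    @property
    def season_mid_day(self) -> float:
        return 0.5 * (self.season_start_day + self.season_end_day)


@dataclass
class NestRecord:
    """One nest: stratum, timing, encounter history and vegetation measurements."""

    nest_id: str
    site_id: str
    year: int
    initiation_day: int
    hatch_day: int
    fate: Fate
    end_day: int
    visits: list  # list of (day, VisitState)
    measurement_day: int
    grass_heights_measured: list
    grass_height_mean: float
    true_height_at_hatch: Optional[float] = None  # simulator-only latent
    covariates: dict = field(default_factory=dict)

    @property
    def stratum(self) -> str:
        return f"{self.site_id}:{self.year}"

    def validate(self) -> None:
        days = [d for d, _ in self.visits]
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValueError(f"nest {self.nest_id}: visit days not strictly increasing")
        states = [VisitState(s) for _, s in self.visits]
        if VisitState.FAILED in states:
            if states.index(VisitState.FAILED) != len(states) - 1:
                raise ValueError(f"nest {self.nest_id}: observation after FAILED")
        if self.end_day > self.hatch_day:
            raise ValueError(f"nest {self.nest_id}: end_day beyond hatch_day")
        if self.measurement_day < days[0]:
            raise ValueError(f"nest {self.nest_id}: measured before first visit")
        if not np.isclose(self.grass_height_mean,
                          float(np.mean(self.grass_heights_measured))):
            raise ValueError(f"nest {self.nest_id}: mean height inconsistent")


@dataclass
class StratumTruth:
    site_id: str
    year: int
    intercept: Optional[float] = None  # cm at season midpoint (simulator-only)
    slope: Optional[float] = None      # cm/day (simulator-only)

    @property
    def key(self) -> str:
        return f"{self.site_id}:{self.year}"


@dataclass
class StudyDataset:
    nests: list
    strata: list
    config_echo: Optional[SimConfig] = None

    def __post_init__(self):
        keys = {s.key for s in self.strata}
        for nest in self.nests:
            if nest.stratum not in keys:
                raise ValueError(f"nest {nest.nest_id}: stratum {nest.stratum} not listed")

    def validate(self) -> None:
        for nest in self.nests:
            nest.validate()

    def __len__(self) -> int:
        return len(self.nests)


def _simulate_nest(cfg: SimConfig, rng: np.random.Generator, nest_id: str,
                   stratum: StratumTruth) -> Optional[NestRecord]:
    last_init = cfg.season_end_day - cfg.incubation_days
    init_day = int(rng.integers(cfg.season_start_day, last_init + 1))
    hatch_day = init_day + cfg.incubation_days

    nest_dev = rng.normal(0.0, cfg.nest_height_sd)

    def line(day: float) -> float:
        return stratum.intercept + stratum.slope * (day - cfg.season_mid_day) + nest_dev

    true_height = line(hatch_day)
    p_daily = expit(cfg.beta0_logit
                    + cfg.beta_grass_surv * (true_height - cfg.grass_intercept_mean))

    # daily Bernoulli survival from the day after initiation through hatch day
    u = rng.random(cfg.incubation_days)
    failed_offsets = np.nonzero(u >= p_daily)[0]
    if failed_offsets.size:
        fate = Fate.FAILED
        fail_day = init_day + int(failed_offsets[0]) + 1
        end_day = fail_day
    else:
        fate = Fate.HATCHED
        fail_day = None
        end_day = hatch_day

    found_day = init_day + cfg.discovery_delay
    if fail_day is not None and fail_day <= found_day:
        return None  # failed before discovery; never enters the study

    visits = []
    day = found_day
    while True:
        if fail_day is not None and day >= fail_day:
            visits.append((day, VisitState.FAILED))
            discovery_day = day
            break
        if day >= hatch_day:
            visits.append((hatch_day, VisitState.ALIVE))
            discovery_day = hatch_day
            break
        visits.append((day, VisitState.ALIVE))
        day += cfg.visit_interval_days
    # terminal hatch check happens on hatch_day itself
    if fate is Fate.HATCHED and visits[-1][0] != hatch_day:
        visits.append((hatch_day, VisitState.ALIVE))
        discovery_day = hatch_day

    if cfg.protocol is Protocol.FATE_DATE:
        if fate is Fate.HATCHED:
            # hatch is confirmed at the first scheduled check on/after hatch
            # day, so successful nests are measured a few days past hatch
            k = cfg.visit_interval_days
            n_steps = -((hatch_day - found_day) // -k)  # ceil division
            measurement_day = found_day + n_steps * k
        else:
            measurement_day = discovery_day
    elif cfg.protocol is Protocol.HATCH_DATE:
        measurement_day = hatch_day
    else:
        jitter = int(round(rng.normal(0.0, cfg.scheduled_lag_sd)))
        measurement_day = max(hatch_day + jitter, found_day)

    reps = line(measurement_day) + rng.normal(0.0, cfg.replicate_sd, cfg.n_replicates)
    reps = [float(r) for r in reps]

    return NestRecord(
        nest_id=nest_id,
        site_id=stratum.site_id,
        year=stratum.year,
        initiation_day=init_day,
        hatch_day=hatch_day,
        fate=fate,
        end_day=end_day,
        visits=visits,
        measurement_day=int(measurement_day),
        grass_heights_measured=reps,
        grass_height_mean=float(np.mean(reps)),
        true_height_at_hatch=float(true_height),
    )


def simulate_study(config: SimConfig) -> StudyDataset:
    """Simulate a multi-stratum nest study under ``config``.

    Per stratum (site x year) the grass phenology line is drawn once; each
    nest gets a persistent height deviation from the line, daily Bernoulli
    survival driven by its true hatch-date height, a periodic visit schedule
    until fate resolution, and replicated height measurements taken on the
    protocol-determined measurement day. Fully deterministic given
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    strata = []
    for i in range(config.n_sites):
        for j in range(config.n_years):
            strata.append(StratumTruth(
                site_id=f"S{i + 1:02d}",
                year=2000 + j,
                intercept=float(rng.normal(config.grass_intercept_mean,
                                           config.grass_intercept_sd)),
                slope=float(rng.normal(config.grass_slope_mean, config.grass_slope_sd)),
            ))

    nests = []
    for stratum in strata:
        made = 0
        while made < config.nests_per_stratum:
            nest_id = f"{stratum.key}:N{made + 1:04d}"
            rec = _simulate_nest(config, rng, nest_id, stratum)
            if rec is None:
                continue  # redraw: study only contains nests found active
            nests.append(rec)
            made += 1

    ds = StudyDataset(nests=nests, strata=strata, config_echo=config)
    ds.validate()
    return ds


def config_to_dict(cfg: SimConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["protocol"] = cfg.protocol.value
    return d


def config_from_dict(d: dict) -> SimConfig:
    if "seed" not in d:
        raise ValueError("simulation config requires an explicit seed")
    return SimConfig(**d)
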