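"""Synthetic flock-foraging worlds with known social structure.

Generates RFID detection streams with the statistical features the
downstream analysis assumes, so the whole pipeline can be exercised and
validated without field data:

* latent social units (fission-fusion flocks) whose members visit a
  feeder together, with correlated arrival times;
* a repeatable individual sociability trait (a logit-scale propensity to
  join unit visits) that is constant across weeks — the between-individual
  variance component the repeatability analysis estimates;
* feeder architectures that shape the read pattern: an open antenna that
  reads continuously while a bird feeds, an entry chamber that logs only
  entry/exit and serializes access, and a bank of adjacent perch antennas;
* non-social solo visits that dilute the social signal.

The generative model is deliberately simple: unit visits are a Poisson
process, members join independently via a logistic sociability model,
arrivals are jittered, stays are exponential. It is the simplest model
exhibiting the three contrasts the analysis probes (gregariousness,
feeder architecture, arrival correlation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .rfid_io import CANONICAL_COLUMNS, DetectionStream
from .networks import SocialNetwork

__all__ = ["WorldConfig", "World", "make_world", "simulate_detections",
           "simulate_weekly_panel", "true_network"]

_DAYS_PER_WEEK = 7
_DAY_START_S = 6 * 3600.0  # recording starts 06:00 each day


@dataclass
class WorldConfig:
    """Study-design and behaviour parameters of a synthetic world.

    Attributes
    ----------
    n_individuals, n_units
        Population size and number of latent social units (flocks).
    p_join
        Baseline probability that a unit member joins one of its unit's
        feeder visits (before the individual sociability offset).
    sigma_social
        Between-individual SD of the logit-scale sociability trait; 0
        switches individual differences off (true repeatability 0).
    flock_rate, solo_rate
        Unit visits per unit per hour; non-social solo visits per
        individual per hour.
    arrival_jitter_sd
        SD (seconds) of the half-normal spread of joiners' arrivals
        around the visit time — the "arriving together" signal.
    stay_mean
        Mean (seconds) of the exponential stay duration.
    read_interval, p_read
        Hardware read period (0.25 s open antenna, 0.5 s chamber/perch)
        and per-read detection probability.
    bout_on_mean, bout_off_mean
        Mean durations (seconds) of the alternating on-antenna feeding
        bouts and off-antenna vigilance bouts within a stay. Birds are
        only read while on the antenna, which is what makes real RFID
        streams bursty per individual; ``bout_off_mean=0`` gives
        continuous presence reads.
    feeder
        "open", "chamber" (entry/exit reads only, one bird at a time) or
        "perches" (n_perches adjacent antennas, one location).
    visit_spacing
        If set, unit visits follow a regular round-robin schedule (one
        visit every `visit_spacing` seconds, units cycling) instead of a
        Poisson process — a well-separated regime useful for validating
        that the association detectors recover the true visit groups.
    capacity
        Maximum simultaneous occupants (chamber always 1; perches default
        to n_perches; open default unlimited).
    n_weeks, hours_per_day
        Recording design: 7 days per week, hours_per_day hours from 06:00.
    """

    n_individuals: int = 30
    n_units: int = 6
    p_join: float = 0.8
    sigma_social: float = 0.6
    flock_rate: float = 1.0
    solo_rate: float = 0.3
    arrival_jitter_sd: float = 10.0
    stay_mean: float = 60.0
    read_interval: float = 0.25
    p_read: float = 0.8
    bout_on_mean: float = 2.0
    bout_off_mean: float = 4.0
    feeder: str = "open"
    n_perches: int = 4
    capacity: int | None = None
    background_assoc: float = 0.01
    n_weeks: int = 8
    hours_per_day: float = 4.0
    visit_spacing: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_join", "p_read"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("flock_rate", "solo_rate", "sigma_social",
                     "arrival_jitter_sd", "stay_mean"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_units > self.n_individuals:
            raise ValueError("n_units cannot exceed n_individuals")
        if self.feeder not in ("open", "chamber", "perches"):
            raise ValueError(f"unknown feeder architecture {self.feeder!r}")

    @classmethod
    def from_yaml(cls, path) -> "WorldConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass
class World:
    config: WorldConfig
    individuals: list[str]
    memberships: np.ndarray          # individual index -> unit index
    sociability: np.ndarray          # logit-scale trait, one per individual
    true_association: np.ndarray     # symmetric, zero diagonal, in [0, 1]

    def join_probabilities(self) -> np.ndarray:
        """Per-individual probability of joining one of its unit's visits."""
        return _join_probs(self.config, self.sociability)


def _join_probs(config: WorldConfig, sociability: np.ndarray) -> np.ndarray:
    # extreme baselines short-circuit the logistic (logit undefined there)
    if config.p_join in (0.0, 1.0):
        return np.full(len(sociability), config.p_join)
    logit = np.log(config.p_join) - np.log1p(-config.p_join)
    return 1.0 / (1.0 + np.exp(-(logit + sociability)))


def make_world(config: WorldConfig) -> World:
    """Draw memberships and sociability; derive the true association matrix.

    True weight of a same-unit pair (i, j) is p_i * p_j — the probability
    both members show up at a given visit of their unit — where p_i is
    the individual's logistic join probability. Cross-unit pairs get a
    small constant background (config.background_assoc), representing
    chance co-occurrence at the shared resource.
    """
    rng = np.random.default_rng(config.seed)
    n, u = config.n_individuals, config.n_units
    individuals = [f"ID{i:03d}" for i in range(n)]
    # balanced assignment, then shuffled so unit sizes differ only by 1
    memberships = rng.permutation(np.arange(n) % u)
    if config.sigma_social == 0.0:
        sociability = np.zeros(n)
    else:
        sociability = rng.normal(0.0, config.sigma_social, size=n)
    p = _join_probs(config, sociability)
    same_unit = memberships[:, None] == memberships[None, :]
    w = np.where(same_unit, p[:, None] * p[None, :], config.background_assoc)
    np.fill_diagonal(w, 0.0)
    w = np.clip((w + w.T) / 2.0, 0.0, 1.0)
    return World(config=config, individuals=individuals,
                 memberships=memberships, sociability=sociability,
                 true_association=w)


def true_network(world: World) -> SocialNetwork:
    """Ground-truth network: edges wherever true association is positive."""
    return SocialNetwork(nodes=list(world.individuals),
                         weights=world.true_association.copy())


def _week_rng(config: WorldConfig, week: int) -> np.random.Generator:
    # independent, reproducible stream per (world seed, week)
    return np.random.default_rng(np.random.SeedSequence([config.seed, week]))


def simulate_detections(world: World, week: int = 0) -> DetectionStream:
    """Simulate one week of RFID reads at a single feeder location.

    Unit visits arrive as a Poisson process within each day's recording
    window; each unit member joins with its logistic probability, arrives
    at the visit time plus a half-normal jitter and stays an exponential
    time. Solo visits are an independent Poisson process per individual.
    The feeder architecture then turns presence intervals into reads.
    """
    cfg = world.config
    if not 0 <= week < cfg.n_weeks:
        raise ValueError(f"week {week} outside 0..{cfg.n_weeks - 1}")
    rng = _week_rng(cfg, week)
    p_join = world.join_probabilities()

    visits: list[tuple[int, float, float]] = []  # (individual, arrival, stay)
    day0 = week * _DAYS_PER_WEEK * 86400.0
    window = cfg.hours_per_day * 3600.0
    for day in range(_DAYS_PER_WEEK):
        t0 = day0 + day * 86400.0 + _DAY_START_S
        # correlated unit visits: Poisson by default, or a regular
        # round-robin schedule when visit_spacing is set
        if cfg.visit_spacing is not None:
            n_sched = int(window // cfg.visit_spacing)
            schedule = [(t0 + (k + 0.5) * cfg.visit_spacing, k % cfg.n_units)
                        for k in range(n_sched)]
        else:
            schedule = []
            for unit in range(cfg.n_units):
                n_visits = rng.poisson(cfg.flock_rate * cfg.hours_per_day)
                schedule.extend(
                    (t, unit)
                    for t in np.sort(rng.uniform(t0, t0 + window, size=n_visits)))
        for t_visit, unit in schedule:
            members = np.flatnonzero(world.memberships == unit)
            joined = members[rng.random(len(members)) < p_join[members]]
            for ind in joined:
                arr = t_visit + abs(rng.normal(0.0, cfg.arrival_jitter_sd))
                visits.append((int(ind), arr, rng.exponential(cfg.stay_mean)))
        # independent solo visits
        n_solo = rng.poisson(cfg.solo_rate * cfg.hours_per_day,
                             size=cfg.n_individuals)
        for ind in np.flatnonzero(n_solo):
            for arr in rng.uniform(t0, t0 + window, size=n_solo[ind]):
                visits.append((int(ind), float(arr), rng.exponential(cfg.stay_mean)))

    visits.sort(key=lambda v: v[1])
    rows = _reads_from_visits(visits, cfg, world.individuals, rng)
    df = pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS))
    if len(df):
        df = df.sort_values("time", kind="stable").reset_index(drop=True)
    return DetectionStream(df=df, metadata={"week": week, "feeder": cfg.feeder,
                                            "read_interval": cfg.read_interval})


def _reads_from_visits(visits, cfg: WorldConfig, ids, rng) -> list[tuple]:
    """Turn (individual, arrival, stay) visits into timestamped reads."""
    loc = "F1"
    rows: list[tuple] = []
    if cfg.feeder == "chamber":
        # one bird inside at a time; later arrivals queue at the entrance;
        # only the entry and exit reads are logged
        free_at = -np.inf
        for ind, arr, stay in visits:
            entry = max(arr, free_at)
            exit_ = entry + stay
            free_at = exit_
            for t in (entry, exit_):
                if rng.random() < cfg.p_read:
                    rows.append((t, ids[ind], "E1", loc))
        return rows

    if cfg.feeder == "perches":
        k = cfg.capacity if cfg.capacity is not None else cfg.n_perches
        free_at = np.full(k, -np.inf)
        for ind, arr, stay in visits:
            perch = int(np.argmin(free_at))
            start = max(arr, free_at[perch])
            free_at[perch] = start + stay
            rows.extend(_presence_reads(start, start + stay, ids[ind],
                                        f"P{perch + 1}", loc, cfg, rng))
        return rows

    # open antenna: unconstrained simultaneous access
    for ind, arr, stay in visits:
        rows.extend(_presence_reads(arr, arr + stay, ids[ind], "A1", loc, cfg, rng))
    return rows


def _presence_reads(start, end, ind, antenna, loc, cfg, rng) -> list[tuple]:
    """Reads during the on-antenna feeding bouts of one stay."""
    kept: list[float] = []
    t = start
    while t < end:
        bout_end = min(end, t + rng.exponential(cfg.bout_on_mean))
        n = max(1, int((bout_end - t) / cfg.read_interval))
        times = t + cfg.read_interval * np.arange(n)
        kept.extend(times[rng.random(n) < cfg.p_read])
        t = bout_end
        if cfg.bout_off_mean > 0:
            t += rng.exponential(cfg.bout_off_mean)
    if not kept:  # a visit always yields at least the arrival read
        kept = [start]
    return [(float(tt), ind, antenna, loc) for tt in kept]


def simulate_weekly_panel(world: World) -> list[DetectionStream]:
    """One independent stream per study week, sharing the sociability traits."""
    return [simulate_detections(world, w) for w in range(world.config.n_weeks)]
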