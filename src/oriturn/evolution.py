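"""Birth-death dynamics of replication origins along a single lineage.

The genome evolves by three elementary stochastic processes, with rates
expressed per unit of evolutionary divergence time *t* (protein-sequence
divergence):

* **birth** -- a new origin appears at the midpoint of an inter-origin
  region; the per-region rate is biased toward regions with a high
  double-stall probability, ``b_i = N * b_bar * (P_i^DS)^gamma * l_i``,
  with the normalization ``N`` fixed so that the total birth rate is
  always ``b_bar * L`` (births per genome per unit time);
* **death** -- an origin disappears; in the *joint* model the per-origin
  rate is biased against inefficient origins,
  ``d_i = N * d_bar * exp(-beta * eff_i)`` with ``sum d_i = n * d_bar``;
  in the *double-stall-aversion* model death is unbiased (``d_i = d_bar``);
* **rate reshuffle** -- an origin's normalized firing rate is resampled
  from a fixed pool with probability ``R`` per unit time.

Because both totals are normalized, the origin count performs a simple
immigration-death random walk whose stationary mean is ``b_bar * L / d_bar``
regardless of the bias strengths; the biases shape *where* events happen,
not how many.

Time is advanced by a tau-leap sweep: all per-region and per-origin event
probabilities are computed from the frozen start-of-step configuration,
every region/origin is sampled independently, and all changes are applied
together at the end of the step.  The step size is capped so that no single
event probability exceeds ``max_event_prob`` (default 0.05), and shrinks
automatically when the rate landscape is rugged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

from .kinetics import (
    CIRCULAR,
    LINEAR,
    GenomeConfiguration,
    KineticParams,
    _double_stall_unchecked,
    double_stall_probability,
    origin_efficiencies,
)

logger = logging.getLogger(__name__)

JOINT = "joint"
DOUBLE_STALL_AVERSION = "double_stall_aversion"

__all__ = [
    "JOINT",
    "DOUBLE_STALL_AVERSION",
    "ModelParams",
    "RateDistribution",
    "EventRecord",
    "EventLog",
    "Snapshot",
    "LineageResult",
    "NormalizationError",
    "StepSizeError",
    "birth_rates",
    "death_rates",
    "step",
    "simulate_lineage",
    "random_configuration",
    "uniform_positions",
]


class NormalizationError(RuntimeError):
    """All bias weights vanished, the birth rates cannot be normalized."""


class StepSizeError(RuntimeError):
    """The requested tau-leap step violates the max-event-probability cap."""


@dataclass(frozen=True)
class ModelParams:
    """All rates and bias strengths of the evolutionary model.

    Rates are per unit of divergence time *t*: ``b_bar`` per Mbp (genome-
    wide birth rate is ``b_bar * L``), ``d_bar`` per origin,
    ``reshuffle_rate`` per origin.  The defaults are the rates estimated
    from origin turnover across the *Lachancea* clade, on the clade's
    average genome length of 10.7 Mbp.  ``variant`` selects the death
    rule: ``"joint"`` (efficiency-biased, strength ``beta``) or
    ``"double_stall_aversion"`` (unbiased death, ``beta`` forced to 0).
    """

    kinetic: KineticParams = field(default_factory=KineticParams)
    b_bar: float = 13.5627       # births / Mbp / t
    d_bar: float = 0.612287      # deaths / origin / t
    reshuffle_rate: float = 0.92  # rate changes / origin / t
    gamma: float = 2.2
    beta: float = 1.9
    variant: str = JOINT
    length_bp: int = 10_700_000
    topology: str = CIRCULAR

    def __post_init__(self) -> None:
        if self.variant not in (JOINT, DOUBLE_STALL_AVERSION):
            raise ValueError(f"unknown variant {self.variant!r}")
        for name in ("b_bar", "d_bar", "reshuffle_rate", "gamma", "beta"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.variant == DOUBLE_STALL_AVERSION and self.beta != 0.0:
            object.__setattr__(self, "beta", 0.0)

    @property
    def total_birth_rate(self) -> float:
        """Genome-wide birth rate ``b_bar * L`` (events per unit time)."""
        return self.b_bar * self.length_bp / 1e6

    @property
    def expected_stationary_count(self) -> float:
        """Balance value ``b_bar * L / d_bar`` of the origin count."""
        return self.total_birth_rate / self.d_bar


@dataclass(frozen=True)
class RateDistribution:
    """Pool of normalized firing rates used for newborns and reshuffling.

    The model resamples rates uniformly from this pool; empirically it
    stands for the distribution of all normalized firing rates across
    species (each species normalized to unit mean).  See
    :func:`oriturn.io.synthetic_rate_distribution` for built-in stand-ins.
    """

    pool: np.ndarray

    def __post_init__(self) -> None:
        pool = np.asarray(self.pool, dtype=np.float64)
        if pool.ndim != 1 or len(pool) == 0:
            raise ValueError("rate pool must be a nonempty 1-d array")
        if np.any(pool < 0):
            raise ValueError("rate pool must be nonnegative")
        object.__setattr__(self, "pool", pool)

    def sample(self, rng: np.random.Generator, size: int | None = None):
        idx = rng.integers(0, len(self.pool), size=size)
        return self.pool[idx]


class EventRecord(NamedTuple):
    time: float
    kind: str            # "birth" | "death" | "rate_change"
    origin_id: int
    position: int
    new_rate: float      # nan for deaths


@dataclass
class EventLog:
    """Timed record of birth, death and rate-change events."""

    records: list[EventRecord] = field(default_factory=list)

    def append(self, rec: EventRecord) -> None:
        self.records.append(rec)

    def extend(self, recs: Iterable[EventRecord]) -> None:
        self.records.extend(recs)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def of_kind(self, kind: str) -> list[EventRecord]:
        return [r for r in self.records if r.kind == kind]

    def count(self, kind: str) -> int:
        return sum(1 for r in self.records if r.kind == kind)

    def ids_of_kind(self, kind: str) -> set[int]:
        return {r.origin_id for r in self.records if r.kind == kind}

    def slice(self, t0: float, t1: float) -> "EventLog":
        """Events with time in the half-open interval ``(t0, t1]``."""
        return EventLog([r for r in self.records if t0 < r.time <= t1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.records,
            columns=["time", "kind", "origin_id", "position_bp", "new_rate"],
        )

    def validate(self) -> None:
        times = [r.time for r in self.records]
        if any(b > a for a, b in zip(times[1:], times)):
            raise ValueError("event times must be nondecreasing")


class Snapshot(NamedTuple):
    time: float
    config: GenomeConfiguration


@dataclass
class LineageResult:
    """Output of a single-lineage simulation."""

    snapshots: list[Snapshot]
    events: EventLog
    final: GenomeConfiguration
    params: ModelParams

    def counts(self) -> np.ndarray:
        return np.array([s.config.n for s in self.snapshots])

    def times(self) -> np.ndarray:
        return np.array([s.time for s in self.snapshots])


def birth_rates(config: GenomeConfiguration, params: ModelParams) -> np.ndarray:
    """Per-region birth rates, normalized so they sum to ``b_bar * L``.

    With ``gamma = 0`` the weights reduce to the region lengths and the
    normalization is the identity: ``b_i = b_bar * l_i``.
    """
    lengths = config.region_lengths().astype(np.float64)
    total = params.b_bar * config.length_bp / 1e6
    if params.gamma == 0:
        weights = lengths
    else:
        p_ds = _double_stall_unchecked(lengths, params.kinetic.pi_stall)
        weights = p_ds**params.gamma * lengths
    s = weights.sum()
    if not s > 0:
        raise NormalizationError("all birth weights are zero; cannot normalize")
    return total * weights / s


def death_rates(
    config: GenomeConfiguration,
    efficiencies: np.ndarray,
    params: ModelParams,
) -> np.ndarray:
    """Per-origin death rates, normalized so their mean is ``d_bar``.

    Joint model: ``d_i = N * d_bar * exp(-beta * eff_i)``; double-stall
    aversion (or ``beta = 0``): every origin dies at the flat rate ``d_bar``.
    """
    n = config.n
    if len(efficiencies) != n:
        raise ValueError("efficiency vector does not match the configuration")
    if params.variant == DOUBLE_STALL_AVERSION or params.beta == 0:
        return np.full(n, params.d_bar)
    w = np.exp(-params.beta * np.asarray(efficiencies, dtype=np.float64))
    return n * params.d_bar * w / w.sum()


def _region_midpoint(config: GenomeConfiguration, region: int) -> int:
    """Midpoint (floored) of inter-origin region ``region``."""
    pos = config.positions
    L = config.length_bp
    if config.topology == LINEAR:
        return int(pos[region] + (pos[region + 1] - pos[region]) // 2)
    if config.n == 1:
        return int((pos[0] + L // 2) % L)
    if region == config.n - 1:  # wrap-around region
        wrap = L - pos[-1] + pos[0]
        return int((pos[-1] + wrap // 2) % L)
    return int(pos[region] + (pos[region + 1] - pos[region]) // 2)


def _apply_step(
    config: GenomeConfiguration,
    params: ModelParams,
    rate_dist: RateDistribution,
    b: np.ndarray,
    d: np.ndarray,
    dt: float,
    rng: np.random.Generator,
    t_end: float,
    record: bool = True,
) -> tuple[GenomeConfiguration, list[EventRecord]]:
    """Sample and apply one tau-leap sweep from precomputed rates."""
    n = config.n
    birth_draw = rng.random(len(b))
    death_hits = rng.random(n) < d * dt
    resh_hits = rng.random(n) < params.reshuffle_rate * dt
    birth_hits = np.flatnonzero(birth_draw < b * dt)

    if len(birth_hits) == 0 and death_hits.all() and n > 0:
        # extinction guard: a genome must retain at least one origin
        spared = int(rng.integers(n)) if n > 1 else 0
        death_hits[spared] = False
        logger.warning(
            "death step would empty the genome at t=%.4f; origin %d spared",
            t_end,
            int(config.ids[spared]),
        )

    events: list[EventRecord] = []
    next_id = config.next_id

    # newborn placement from the frozen configuration
    if len(birth_hits):
        taken = set(int(p) for p in config.positions)
        new_pos: list[int] = []
        new_ids: list[int] = []
        new_rate_list: list[float] = []
        newborn_rates = rate_dist.sample(rng, len(birth_hits))
        for k, region in enumerate(birth_hits):
            cand = _region_midpoint(config, int(region))
            attempts = 0
            while cand in taken:
                cand = (cand + 1) % config.length_bp
                attempts += 1
                if attempts > config.length_bp:  # genome saturated
                    break
            if cand in taken:
                continue
            taken.add(cand)
            new_pos.append(cand)
            new_ids.append(next_id)
            new_rate_list.append(float(newborn_rates[k]))
            if record:
                events.append(
                    EventRecord(t_end, "birth", next_id, cand, float(newborn_rates[k]))
                )
            next_id += 1
    else:
        new_pos, new_ids, new_rate_list = [], [], []

    any_death = death_hits.any()
    survivors = ~death_hits
    if record and any_death:
        for i in np.flatnonzero(death_hits):
            events.append(
                EventRecord(
                    t_end, "death", int(config.ids[i]), int(config.positions[i]),
                    np.nan,
                )
            )

    resh_idx = np.flatnonzero(resh_hits & survivors)
    if len(resh_idx):
        rates = config.rates.copy()
        new_rates = rate_dist.sample(rng, len(resh_idx))
        rates[resh_idx] = new_rates
        if record:
            for i, r in zip(resh_idx, new_rates):
                events.append(
                    EventRecord(
                        t_end, "rate_change", int(config.ids[i]),
                        int(config.positions[i]), float(r),
                    )
                )
    else:
        rates = config.rates

    if new_pos:
        out_pos = np.concatenate(
            [config.positions[survivors], np.array(new_pos, dtype=np.int64)]
        )
        out_rates = np.concatenate(
            [rates[survivors], np.array(new_rate_list, dtype=np.float64)]
        )
        out_ids = np.concatenate(
            [config.ids[survivors], np.array(new_ids, dtype=np.int64)]
        )
    elif any_death:
        out_pos = config.positions[survivors]
        out_rates = rates[survivors]
        out_ids = config.ids[survivors]
    else:
        out_pos = config.positions
        out_rates = rates
        out_ids = config.ids

    new_config = GenomeConfiguration(
        config.length_bp,
        out_pos,
        out_rates,
        ids=out_ids,
        topology=config.topology,
        next_id=next_id,
        validate=False,
    )
    return new_config, events


def _step_rates(config: GenomeConfiguration, params: ModelParams):
    b = birth_rates(config, params)
    if params.variant == JOINT and params.beta > 0:
        eff = origin_efficiencies(config, params.kinetic)
    else:
        eff = np.ones(config.n)
    d = death_rates(config, eff, params)
    return b, d


def step(
    config: GenomeConfiguration,
    params: ModelParams,
    rate_dist: RateDistribution,
    dt: float,
    rng: np.random.Generator,
    t: float = 0.0,
    max_event_prob: float = 0.05,
) -> tuple[GenomeConfiguration, list[EventRecord]]:
    """Advance the configuration by one tau-leap step of size ``dt``.

    All event probabilities are evaluated on the frozen input
    configuration and the changes are applied together; newborn origins
    cannot die or reshuffle within their birth step.  Raises
    :class:`StepSizeError` if any single event probability would exceed
    ``max_event_prob``.
    """
    if dt < 0:
        raise ValueError("dt must be nonnegative")
    if dt == 0:
        return config.copy(), []
    b, d = _step_rates(config, params)
    r_max = max(
        b.max(initial=0.0), d.max(initial=0.0), params.reshuffle_rate
    )
    if r_max * dt > max_event_prob * (1 + 1e-9):
        raise StepSizeError(
            f"dt={dt:g} gives max event probability {r_max * dt:.3g} "
            f"> cap {max_event_prob}"
        )
    return _apply_step(config, params, rate_dist, b, d, dt, rng, t + dt)


def uniform_positions(length_bp: int, n: int, rng: np.random.Generator) -> np.ndarray:
    """``n`` distinct uniform integer coordinates on ``[0, length_bp)``, sorted."""
    if n > length_bp:
        raise ValueError("more origins than basepairs")
    pos = np.unique(rng.integers(0, length_bp, n))
    while len(pos) < n:
        extra = rng.integers(0, length_bp, n - len(pos))
        pos = np.unique(np.concatenate([pos, extra]))
    return pos


def random_configuration(
    params: ModelParams,
    rate_dist: RateDistribution,
    n0: int,
    rng: np.random.Generator,
) -> GenomeConfiguration:
    """Initial genome: ``n0`` origins uniform in position, rates from the pool."""
    if n0 < 1:
        raise ValueError("n0 must be >= 1")
    pos = uniform_positions(params.length_bp, n0, rng)
    rates = rate_dist.sample(rng, n0)
    return GenomeConfiguration(
        params.length_bp, pos, rates, topology=params.topology
    )


def simulate_lineage(
    params: ModelParams,
    rate_dist: RateDistribution,
    t_total: float,
    snapshot_interval: float | None = None,
    n0: int = 50,
    burn_in: float | None = None,
    rng: np.random.Generator | None = None,
    initial_config: GenomeConfiguration | None = None,
    record_events: bool = True,
    max_event_prob: float = 0.05,
    t0: float = 0.0,
) -> LineageResult:
    """Simulate one lineage for ``t_total`` time units.

    Snapshots of the configuration are stored at every multiple of
    ``snapshot_interval`` after ``burn_in`` (and at ``t_total``).
    Defaults: ``burn_in = 20 / d_bar`` (about twenty relaxation times of
    the count process) and ``snapshot_interval = 0.15``, the mean terminal
    branch length of the bundled nine-species tree, so that consecutive
    snapshots are comparable to a terminal branch.  The step size is
    chosen adaptively each sweep as the largest dt honoring the
    ``max_event_prob`` cap.

    When ``initial_config`` is given, ``n0`` is ignored and the run
    continues that genome (used for per-branch simulations on a tree).
    """
    if rng is None:
        rng = np.random.default_rng()
    if burn_in is None:
        burn_in = 20.0 / params.d_bar if params.d_bar > 0 else 0.0
    if t_total < burn_in:
        raise ValueError(f"t_total={t_total} is smaller than burn_in={burn_in}")
    if snapshot_interval is None:
        snapshot_interval = 0.15
    if snapshot_interval <= 0:
        raise ValueError("snapshot_interval must be positive")

    if initial_config is not None:
        config = initial_config.copy()
        if config.length_bp != params.length_bp or config.topology != params.topology:
            raise ValueError("initial_config does not match params genome")
    else:
        config = random_configuration(params, rate_dist, n0, rng)

    events = EventLog()
    snapshots: list[Snapshot] = []
    t = 0.0
    eps = 1e-9
    next_snap = burn_in
    if burn_in <= eps:
        snapshots.append(Snapshot(t0, config))
        next_snap = snapshot_interval
    while t < t_total - eps:
        b, d = _step_rates(config, params)
        r_max = max(b.max(initial=0.0), d.max(initial=0.0), params.reshuffle_rate)
        dt = max_event_prob / r_max if r_max > 0 else t_total - t
        if next_snap <= t_total + eps:
            dt = min(dt, next_snap - t)
        dt = min(dt, t_total - t)
        config, recs = _apply_step(
            config, params, rate_dist, b, d, dt, rng, t0 + t + dt,
            record=record_events,
        )
        if record_events:
            events.extend(recs)
        t += dt
        if next_snap <= t_total + eps and t >= next_snap - eps:
            snapshots.append(Snapshot(t0 + t, config))
            next_snap += snapshot_interval
    if not snapshots or snapshots[-1].time < t0 + t_total - eps:
        snapshots.append(Snapshot(t0 + t_total, config))
    return LineageResult(snapshots, events, config, params)
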