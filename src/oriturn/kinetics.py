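"""Replication kinetics of origins on a one-dimensional genome.

An origin is a locus that can initiate ("fire") replication during S phase.
Firing is stochastic with an origin-intrinsic rate; here rates are always
*normalized* by the species mean, so they are dimensionless and average to 1.
Two quantities derived from a configuration of origins drive everything else
in this package:

* the **double-stall probability** of an inter-origin region -- the chance
  that the two converging forks replicating that region both stall before
  meeting, an event assumed lethal;
* the **efficiency** of an origin -- the probability that it fires actively
  rather than being passively replicated by forks arriving from neighbors.

The closed forms implemented here treat single-fork stalling as a Poisson
process with per-nucleotide rate ``pi_stall`` and origin firing as
exponential with the normalized rate; efficiency considers the two nearest
neighbors only.  Brute-force Monte-Carlo counterparts
(:func:`mc_passive_replication_probability`, :func:`mc_origin_efficiencies`)
are provided as independent checks of the closed forms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

CIRCULAR = "circular"
LINEAR = "linear"

__all__ = [
    "CIRCULAR",
    "LINEAR",
    "KineticParams",
    "Origin",
    "GenomeConfiguration",
    "double_stall_probability",
    "passive_replication_probability",
    "origin_efficiencies",
    "mc_passive_replication_probability",
    "mc_origin_efficiencies",
]


@dataclass(frozen=True)
class KineticParams:
    """Parameters of the replication-kinetics layer.

    Parameters
    ----------
    pi_stall:
        Per-nucleotide fork-stall rate (default ``5e-8``).  The single-fork
        stall law is ``P_S(x) = pi_stall * exp(-pi_stall * x)`` for a fork
        that has replicated ``x`` nucleotides.
    v:
        Replication-fork speed, in bp per unit of normalized-firing-rate
        time, so that only the combination ``rate * distance / v`` enters
        the passive-replication probability.  Default 45,000 bp, of the
        order of the typical inter-origin spacing, so that typical
        exponents are O(1).
    """

    pi_stall: float = 5e-8
    v: float = 45_000.0

    def __post_init__(self) -> None:
        if not self.pi_stall > 0:
            raise ValueError(f"pi_stall must be > 0, got {self.pi_stall}")
        if not self.v > 0:
            raise ValueError(f"v must be > 0, got {self.v}")


@dataclass(frozen=True)
class Origin:
    """A single replication origin: identifier, coordinate, normalized rate."""

    id: int
    position: int
    rate: float


class GenomeConfiguration:
    """An ordered set of origins on a circular or linear genome.

    Internally stored as parallel numpy arrays sorted by position.  The
    ``next_id`` high-water mark guarantees that origin identifiers are
    never reused within a lineage, which is what makes lineage tracking
    across a phylogeny exact.
    """

    __slots__ = ("length_bp", "topology", "ids", "positions", "rates", "next_id")

    def __init__(
        self,
        length_bp: int,
        positions,
        rates,
        ids=None,
        topology: str = CIRCULAR,
        next_id: int | None = None,
        validate: bool = True,
    ) -> None:
        positions = np.asarray(positions, dtype=np.int64)
        order = np.argsort(positions, kind="stable")
        self.length_bp = int(length_bp)
        self.topology = topology
        self.positions = positions[order]
        self.rates = np.asarray(rates, dtype=np.float64)[order]
        if ids is None:
            ids = np.arange(len(positions), dtype=np.int64)
        else:
            ids = np.asarray(ids, dtype=np.int64)
        self.ids = ids[order]
        if next_id is None:
            next_id = int(self.ids.max()) + 1 if len(self.ids) else 0
        self.next_id = int(next_id)
        if validate:
            self.validate()

    def validate(self) -> None:
        if self.topology not in (CIRCULAR, LINEAR):
            raise ValueError(f"unknown topology {self.topology!r}")
        if self.length_bp <= 0:
            raise ValueError("genome length must be positive")
        n = len(self.positions)
        if n < 1:
            raise ValueError("a genome must carry at least one origin")
        if not (len(self.rates) == n == len(self.ids)):
            raise ValueError("ids/positions/rates length mismatch")
        if self.positions[0] < 0 or self.positions[-1] >= self.length_bp:
            raise ValueError("positions must lie in [0, length_bp)")
        if n > 1 and np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if len(np.unique(self.ids)) != n:
            raise ValueError("origin ids must be unique")
        if np.any(self.rates < 0):
            raise ValueError("firing rates must be nonnegative")
        if self.next_id <= int(self.ids.max()):
            raise ValueError("next_id must exceed every existing id")

    @property
    def n(self) -> int:
        return len(self.positions)

    @property
    def origins(self) -> list[Origin]:
        return [
            Origin(int(i), int(p), float(r))
            for i, p, r in zip(self.ids, self.positions, self.rates)
        ]

    def region_lengths(self) -> np.ndarray:
        """Lengths of the inter-origin regions.

        Circular genomes have exactly ``n`` regions, the last one wrapping
        around from the last origin to the first; linear genomes have
        ``n - 1`` interior regions (terminal segments carry no region).
        A circular genome with a single origin has one region of the full
        genome length.
        """
        pos = self.positions
        if self.topology == LINEAR:
            return np.diff(pos)
        if self.n == 1:
            return np.array([self.length_bp], dtype=np.int64)
        gaps = np.diff(pos)
        wrap = self.length_bp - pos[-1] + pos[0]
        return np.concatenate([gaps, [wrap]])

    def copy(self) -> "GenomeConfiguration":
        return GenomeConfiguration(
            self.length_bp,
            self.positions.copy(),
            self.rates.copy(),
            ids=self.ids.copy(),
            topology=self.topology,
            next_id=self.next_id,
            validate=False,
        )

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"GenomeConfiguration(n={self.n}, length_bp={self.length_bp}, "
            f"topology={self.topology!r})"
        )


def double_stall_probability(l, pi_stall: float):
    """Probability that both converging forks stall inside a region.

    For a region of ``l`` nucleotides replicated by two converging forks,
    each stalling as a Poisson process with per-nucleotide rate
    ``pi_stall``, the probability that both stall before meeting is

        ``1 - (1 + pi*l) * exp(-pi*l)``

    Accepts a scalar or array ``l``.  For ``pi*l < 1e-4`` a series
    expansion is used: the naive expression cancels catastrophically when
    the leading term ``(pi*l)^2 / 2`` is tiny.
    """
    l_arr = np.asarray(l, dtype=np.float64)
    if np.any(l_arr < 0):
        raise ValueError("region length must be nonnegative")
    if not pi_stall > 0:
        raise ValueError("pi_stall must be positive")
    out = _double_stall_unchecked(l_arr, pi_stall)
    if np.isscalar(l) or l_arr.ndim == 0:
        return float(out)
    return out


def _double_stall_unchecked(l_arr: np.ndarray, pi_stall: float) -> np.ndarray:
    x = pi_stall * l_arr
    # series: x^2/2 - x^3/3 + x^4/8 - x^5/30 (error O(x^6))
    series = x * x * (0.5 + x * (-1.0 / 3.0 + x * (0.125 - x / 30.0)))
    with np.errstate(over="ignore"):
        closed = 1.0 - (1.0 + x) * np.exp(-x)
    return np.where(x < 1e-4, series, closed)


def passive_replication_probability(
    rate_i: float, rate_j: float, distance: float, v: float
) -> float:
    """Probability that origin *i* is passively replicated by neighbor *j*.

    Origin *i* (normalized rate ``rate_i``) loses the race against a fork
    emitted by neighbor *j* (rate ``rate_j``) at ``distance`` bp, forks
    travelling at speed ``v``:

        ``P_ij = rate_j / (rate_j + rate_i) * exp(-rate_i * distance / v)``

    Both rates zero leaves the race undefined and raises ``ValueError``.
    """
    if rate_i < 0 or rate_j < 0:
        raise ValueError("rates must be nonnegative")
    if distance < 0:
        raise ValueError("distance must be nonnegative")
    if not v > 0:
        raise ValueError("fork speed must be positive")
    total = rate_i + rate_j
    if total == 0:
        raise ValueError(
            "undefined competition: both firing rates are zero"
        )
    return rate_j / total * math.exp(-rate_i * distance / v)


def _wrap_shift(a: np.ndarray, forward: bool) -> np.ndarray:
    """Cyclic shift by one (cheaper than np.roll for the hot loop)."""
    out = np.empty_like(a)
    if forward:
        out[0] = a[-1]
        out[1:] = a[:-1]
    else:
        out[-1] = a[0]
        out[:-1] = a[1:]
    return out


def _neighbor_passive_probs(config: GenomeConfiguration, kp: KineticParams):
    """Vectorized (P_left, P_right) passive-replication probabilities."""
    pos = config.positions.astype(np.float64)
    lam = config.rates
    n = config.n
    if config.topology == CIRCULAR:
        d_left = pos - _wrap_shift(pos, True)
        d_left[0] += config.length_bp
        d_right = _wrap_shift(d_left, False)
        lam_left = _wrap_shift(lam, True)
        lam_right = _wrap_shift(lam, False)
        tot_left = lam + lam_left
        tot_right = lam + lam_right
        if np.any(tot_left == 0) or np.any(tot_right == 0):
            raise ValueError("undefined competition: adjacent origins both have zero rate")
        p_left = lam_left / tot_left * np.exp(-lam * d_left / kp.v)
        p_right = lam_right / tot_right * np.exp(-lam * d_right / kp.v)
    else:
        gaps = np.diff(pos)
        p_left = np.zeros(n)
        p_right = np.zeros(n)
        tot = lam[1:] + lam[:-1]
        if np.any(tot == 0):
            raise ValueError("undefined competition: adjacent origins both have zero rate")
        # fork from the left neighbor replicating origin i (i >= 1)
        p_left[1:] = lam[:-1] / tot * np.exp(-lam[1:] * gaps / kp.v)
        # fork from the right neighbor replicating origin i (i <= n-2)
        p_right[:-1] = lam[1:] / tot * np.exp(-lam[:-1] * gaps / kp.v)
    return p_left, p_right


def origin_efficiencies(
    config: GenomeConfiguration, kp: KineticParams
) -> np.ndarray:
    """Efficiency of every origin: ``eff_i = (1 - P_left)(1 - P_right)``.

    This nearest-neighbor approximation neglects interference from origins
    beyond the two adjacent ones.  A single origin has efficiency 1 (nothing
    competes with it); on a linear genome a missing neighbor contributes a
    factor 1.  On a circular two-origin genome the same neighbor competes
    through both arcs, with the two distinct arc distances.
    """
    if config.n == 1:
        return np.ones(1)
    p_left, p_right = _neighbor_passive_probs(config, kp)
    return (1.0 - p_left) * (1.0 - p_right)


# ---------------------------------------------------------------------------
# Brute-force Monte-Carlo oracles (used by the test suite as independent
# checks; they never call the closed forms above).
# ---------------------------------------------------------------------------

def mc_passive_replication_probability(
    rate_i: float,
    rate_j: float,
    distance: float,
    v: float,
    n_rep: int,
    rng: np.random.Generator,
) -> float:
    """Monte-Carlo estimate of the two-origin passive-replication race.

    Samples exponential firing times for both origins and checks whether
    the fork from *j* reaches *i* before *i* fires.
    """
    t_i = (
        rng.exponential(1.0 / rate_i, n_rep)
        if rate_i > 0
        else np.full(n_rep, np.inf)
    )
    t_j = (
        rng.exponential(1.0 / rate_j, n_rep)
        if rate_j > 0
        else np.full(n_rep, np.inf)
    )
    return float(np.mean(t_j + distance / v < t_i))


def mc_origin_efficiencies(
    config: GenomeConfiguration,
    kp: KineticParams,
    n_rep: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Monte-Carlo S-phase oracle for origin efficiencies.

    Simulates whole S phases: every origin draws an exponential firing
    time, forks spread at speed ``v`` in both directions, and an origin is
    scored as firing actively iff no fork reaches it first.  Unlike the
    closed form this accounts for interference from *all* origins, so it
    doubles as a probe of the nearest-neighbor approximation.
    """
    n = config.n
    pos = config.positions.astype(np.float64)
    lam = config.rates
    delta = np.abs(pos[:, None] - pos[None, :])
    if config.topology == CIRCULAR:
        delta = np.minimum(delta, config.length_bp - delta)
    travel = delta / kp.v  # travel[i, j]: fork time from j to i
    np.fill_diagonal(travel, np.inf)
    with np.errstate(divide="ignore"):
        scale = np.where(lam > 0, 1.0 / np.where(lam > 0, lam, 1.0), np.inf)
    active = np.zeros(n)
    block = max(1, int(2e7) // (n * n))
    done = 0
    while done < n_rep:
        m = min(block, n_rep - done)
        t = rng.exponential(1.0, (m, n)) * scale
        arrival = (t[:, None, :] + travel[None, :, :]).min(axis=2)
        active += (t < arrival).sum(axis=0)
        done += m
    return active / n_rep
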