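"""Readers and writers: origin tables, Newick trees, snapshot and event
TSVs, run configuration, and the synthetic firing-rate stand-in.

The native origin format is a TSV with columns ``species, chromosome,
position, firing_rate`` (0-based bp coordinates); on loading, a
``normalized_rate`` column is added by dividing each rate by its species
mean, so every species averages to exactly 1.  A BED export (0-based,
half-open, rate in the score column) is available for genome browsers.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .evolution import EventLog, EventRecord, LineageResult, RateDistribution
from .kinetics import GenomeConfiguration, KineticParams, origin_efficiencies
from .phylogeny import BranchEventSummary, PhyloTree

ORIGIN_COLUMNS = ["species", "chromosome", "position", "firing_rate"]

__all__ = [
    "OriginTable",
    "RunConfig",
    "read_origin_table",
    "write_origin_table",
    "origin_table_to_bed",
    "synthetic_rate_distribution",
    "empirical_rate_distribution",
    "read_newick",
    "lachancea_tree",
    "write_snapshots",
    "read_snapshots",
    "write_events",
    "read_events",
    "write_branch_summaries",
    "read_branch_summaries",
]


@dataclass
class OriginTable:
    """Empirical origin annotations with per-species normalized rates."""

    frame: pd.DataFrame  # species, chromosome, position, firing_rate, normalized_rate

    def normalized_pool(self) -> np.ndarray:
        return self.frame["normalized_rate"].to_numpy()

    def species(self) -> list[str]:
        return sorted(self.frame["species"].unique())


def read_origin_table(path) -> OriginTable:
    """Read a TSV origin table and compute per-species normalized rates.

    Raises ``ValueError`` naming the offending row for missing columns,
    non-numeric rates, or negative positions.
    """
    frame = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ORIGIN_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"origin table is missing columns: {missing}")
    frame = frame[ORIGIN_COLUMNS].copy()
    for col, kind in (("position", "Int64"), ("firing_rate", "float")):
        parsed = pd.to_numeric(frame[col], errors="coerce")
        bad = parsed.isna() & frame[col].notna() | frame[col].isna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"row {row + 2}: cannot parse {col}={frame[col].iloc[row]!r}"
            )
        frame[col] = parsed
    frame["position"] = frame["position"].astype(np.int64)
    if (frame["position"] < 0).any():
        row = int(np.flatnonzero((frame["position"] < 0).to_numpy())[0])
        raise ValueError(f"row {row + 2}: negative position")
    if (frame["firing_rate"] < 0).any():
        row = int(np.flatnonzero((frame["firing_rate"] < 0).to_numpy())[0])
        raise ValueError(f"row {row + 2}: negative firing rate")
    means = frame.groupby("species")["firing_rate"].transform("mean")
    frame["normalized_rate"] = frame["firing_rate"] / means
    frame = frame.sort_values(["species", "chromosome", "position"]).reset_index(
        drop=True
    )
    return OriginTable(frame)


def write_origin_table(table: OriginTable, path) -> None:
    table.frame[ORIGIN_COLUMNS].to_csv(path, sep="\t", index=False)


def origin_table_to_bed(table: OriginTable, path) -> None:
    """BED export: 0-based half-open single-bp intervals, normalized rate
    in the score-like fifth column."""
    bed = pd.DataFrame(
        {
            "chrom": table.frame["chromosome"],
            "start": table.frame["position"],
            "end": table.frame["position"] + 1,
            "name": table.frame["species"] + ":" + table.frame["position"].astype(str),
            "score": table.frame["normalized_rate"],
        }
    )
    bed.to_csv(path, sep="\t", index=False, header=False)


def synthetic_rate_distribution(
    family: str = "lognormal",
    spread: float = 0.6,
    size: int = 100_000,
    seed: int | np.random.Generator = 0,
) -> RateDistribution:
    """Built-in unit-mean stand-in for the empirical normalized-rate pool.

    Families: ``lognormal`` (log-sd = ``spread``; the default, a broad
    right-skewed pool), ``gamma`` (sd = ``spread``).  ``spread -> 0``
    degenerates to all rates equal to 1.
    """
    if not spread > 0:
        raise ValueError("spread must be positive")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    if family == "lognormal":
        pool = rng.lognormal(mean=-0.5 * spread**2, sigma=spread, size=size)
    elif family == "gamma":
        shape = 1.0 / spread**2
        pool = rng.gamma(shape=shape, scale=spread**2, size=size)
    else:
        raise ValueError(
            f"unknown family {family!r}; choose 'lognormal' or 'gamma'"
        )
    return RateDistribution(pool)


def empirical_rate_distribution(table: OriginTable) -> RateDistribution:
    """Resampling pool built from all normalized rates of an origin table."""
    return RateDistribution(table.normalized_pool())


def read_newick(path) -> PhyloTree:
    """Read a rooted Newick tree with branch lengths in divergence units."""
    text = Path(path).read_text()
    return PhyloTree.from_newick(text)


def lachancea_tree() -> PhyloTree:
    """The bundled nine-leaf tree with the *Lachancea*-clade topology shape.

    Branch lengths are synthetic stand-ins (the empirical lengths are not
    distributed with this package); the three shallow sister pairs of the
    clade are preserved.
    """
    ref = importlib.resources.files("oriturn.data").joinpath(
        "lachancea9_synthetic.nwk"
    )
    return PhyloTree.from_newick(ref.read_text())


# ---------------------------------------------------------------------------
# Snapshot / event-log TSV round-trips
# ---------------------------------------------------------------------------

def write_snapshots(result: LineageResult, path, kp: KineticParams | None = None) -> None:
    """Snapshot TSV: one row per origin per snapshot, with efficiency."""
    if kp is None:
        kp = result.params.kinetic
    rows = []
    for snap in result.snapshots:
        eff = origin_efficiencies(snap.config, kp)
        for oid, pos, rate, e in zip(
            snap.config.ids, snap.config.positions, snap.config.rates, eff
        ):
            rows.append((snap.time, int(oid), int(pos), float(rate), float(e)))
    pd.DataFrame(
        rows, columns=["time", "origin_id", "position_bp", "rate", "efficiency"]
    ).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_snapshots(path, length_bp: int, topology: str = "circular"):
    """Rebuild ``(time, GenomeConfiguration)`` pairs from a snapshot TSV."""
    frame = pd.read_csv(path, sep="\t", float_precision="round_trip")
    out = []
    for t, grp in frame.groupby("time", sort=True):
        out.append(
            (
                float(t),
                GenomeConfiguration(
                    length_bp,
                    grp["position_bp"].to_numpy(),
                    grp["rate"].to_numpy(),
                    ids=grp["origin_id"].to_numpy(),
                    topology=topology,
                ),
            )
        )
    return out


def write_events(log: EventLog, path) -> None:
    log.to_frame().to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_events(path) -> EventLog:
    frame = pd.read_csv(path, sep="\t", float_precision="round_trip")
    records = [
        EventRecord(
            float(r.time),
            str(r.kind),
            int(r.origin_id),
            int(r.position_bp),
            float(r.new_rate) if pd.notna(r.new_rate) else float("nan"),
        )
        for r in frame.itertuples()
    ]
    return EventLog(records)


def write_branch_summaries(summaries, path) -> None:
    pd.DataFrame(
        [
            dict(
                branch_id=s.branch_id,
                n_birth=s.n_birth,
                n_death=s.n_death,
                branch_length=s.branch_length,
                genome_length_bp=s.genome_length_bp,
                n_origins=s.n_origins,
            )
            for s in summaries
        ]
    ).to_csv(path, sep="\t", index=False)


def read_branch_summaries(path) -> list[BranchEventSummary]:
    frame = pd.read_csv(path, sep="\t")
    return [
        BranchEventSummary(
            branch_id=str(r.branch_id),
            n_birth=int(r.n_birth),
            n_death=int(r.n_death),
            branch_length=float(r.branch_length),
            genome_length_bp=int(r.genome_length_bp),
            n_origins=int(r.n_origins),
        )
        for r in frame.itertuples()
    ]


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Everything needed to reproduce a run, YAML round-trippable."""

    # kinetic parameters
    pi_stall: float = 5e-8
    v: float = 45_000.0
    # evolutionary rates and biases
    b_bar: float = 13.5627
    d_bar: float = 0.612287
    reshuffle_rate: float = 0.92
    gamma: float = 2.2
    beta: float = 1.9
    variant: str = "joint"
    length_bp: int = 10_700_000
    topology: str = "circular"
    # simulation policy
    seed: int = 0
    n0: int = 50
    burn_in: float | None = None
    t_total: float = 83.0
    snapshot_interval: float = 0.15
    max_event_prob: float = 0.05
    # rate-pool stand-in
    rate_family: str = "lognormal"
    rate_spread: float = 0.6
    rate_pool_size: int = 100_000
    origin_table: str | None = None
    # tree input
    tree_file: str | None = None
    # fitting grids
    gamma_grid: list = field(default_factory=lambda: [1.8, 2.0, 2.2, 2.4, 2.6])
    beta_grid: list = field(default_factory=lambda: [1.5, 1.7, 1.9, 2.1, 2.3])
    runs_per_point: int = 10
    # histogram bins
    distance_bin_bp: float = 5_000.0
    distance_bin_max_bp: float = 200_000.0
    efficiency_bin: float = 0.05

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def model_params(self):
        from .evolution import ModelParams

        return ModelParams(
            kinetic=KineticParams(pi_stall=self.pi_stall, v=self.v),
            b_bar=self.b_bar,
            d_bar=self.d_bar,
            reshuffle_rate=self.reshuffle_rate,
            gamma=self.gamma,
            beta=self.beta,
            variant=self.variant,
            length_bp=self.length_bp,
            topology=self.topology,
        )

    def rate_distribution(self) -> RateDistribution:
        if self.origin_table:
            return empirical_rate_distribution(read_origin_table(self.origin_table))
        return synthetic_rate_distribution(
            family=self.rate_family,
            spread=self.rate_spread,
            size=self.rate_pool_size,
            seed=np.random.default_rng(self.seed + 988_041),
        )

    def tree(self) -> PhyloTree:
        if self.tree_file:
            return read_newick(self.tree_file)
        return lachancea_tree()
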