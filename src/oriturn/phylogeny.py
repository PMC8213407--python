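"""Origin turnover on a fixed phylogeny: tree simulation, branch
classification, origin families, shared-loss divergence, and the uniform
null model.

The tree topology and branch lengths are inputs; the model does not
describe speciation.  A burned-in single-lineage genome serves as the
root, each branch continues the parent's genome for the branch duration,
and at every internal node the configuration is copied to both children.
Because origin identifiers are globally unique and inherited, orthology
across leaves is known exactly by id (an idealization of the synteny-based
orthology used on real genomes).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .evolution import (
    EventLog,
    EventRecord,
    LineageResult,
    ModelParams,
    RateDistribution,
    random_configuration,
    simulate_lineage,
    uniform_positions,
)
from .kinetics import GenomeConfiguration

__all__ = [
    "PhyloTree",
    "BranchClassification",
    "OriginFamily",
    "BranchEventSummary",
    "TreeSimulation",
    "simulate_tree",
    "classify_branch_events",
    "build_families",
    "pairwise_shared_loss",
    "null_model_simulate",
    "branch_event_summaries",
]


@dataclass
class PhyloTree:
    """Rooted tree stored as parent pointers in preorder.

    Node 0 is the root.  ``lengths[i]`` is the length of the branch above
    node ``i`` (0 for the root), in protein-sequence-divergence units.
    Leaf labels are unique; unlabeled internal nodes get ``node<i>`` names.
    """

    labels: list[str]
    parent: np.ndarray          # parent index per node; -1 for the root
    lengths: np.ndarray         # branch length above each node

    def __post_init__(self) -> None:
        self.parent = np.asarray(self.parent, dtype=np.int64)
        self.lengths = np.asarray(self.lengths, dtype=np.float64)
        if np.any(self.lengths < 0):
            raise ValueError("branch lengths must be nonnegative")
        self._children: list[list[int]] = [[] for _ in self.labels]
        for i, p in enumerate(self.parent):
            if p >= 0:
                self._children[p].append(i)
        leaves = [self.labels[i] for i in self.leaf_indices()]
        if len(set(leaves)) != len(leaves):
            raise ValueError("leaf labels must be unique")

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        import dendropy

        try:
            tree = dendropy.Tree.get(
                data=newick, schema="newick", suppress_internal_node_taxa=False
            )
        except Exception as exc:
            raise ValueError(f"cannot parse Newick tree: {exc}") from exc
        labels: list[str] = []
        parent: list[int] = []
        lengths: list[float] = []
        index: dict[int, int] = {}
        for node in tree.preorder_node_iter():
            i = len(labels)
            index[id(node)] = i
            name = None
            if node.taxon is not None:
                name = node.taxon.label
            elif node.label:
                name = node.label
            labels.append(name if name else f"node{i}")
            if node.parent_node is None:
                parent.append(-1)
                lengths.append(0.0 if node.edge.length is None else float(node.edge.length))
            else:
                parent.append(index[id(node.parent_node)])
                if node.edge.length is None:
                    raise ValueError(
                        f"branch above {labels[-1]!r} has no length"
                    )
                lengths.append(float(node.edge.length))
        return cls(labels, np.array(parent), np.array(lengths))

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    def children(self, i: int) -> list[int]:
        return self._children[i]

    def is_leaf(self, i: int) -> bool:
        return not self._children[i]

    def leaf_indices(self) -> list[int]:
        return [i for i in range(self.n_nodes) if self.is_leaf(i)]

    def leaf_labels(self) -> list[str]:
        return [self.labels[i] for i in self.leaf_indices()]

    def index_of(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"no node labeled {label!r}") from None

    def ancestors(self, i: int) -> list[int]:
        """Node indices from ``i`` up to and including the root."""
        out = [i]
        while self.parent[out[-1]] >= 0:
            out.append(int(self.parent[out[-1]]))
        return out

    def mrca(self, a: str, b: str) -> int:
        anc_a = self.ancestors(self.index_of(a))
        anc_b = set(self.ancestors(self.index_of(b)))
        for node in anc_a:
            if node in anc_b:
                return node
        raise ValueError("nodes share no ancestor (malformed tree)")

    def path_to_ancestor(self, node: int, ancestor: int) -> list[int]:
        """Branches (child-node indices) on the path ``ancestor -> node``."""
        path = []
        while node != ancestor:
            path.append(node)
            node = int(self.parent[node])
            if node < 0:
                raise ValueError("ancestor is not on the path to the root")
        return path

    def mean_terminal_branch_length(self) -> float:
        return float(np.mean([self.lengths[i] for i in self.leaf_indices()]))

    def total_branch_length(self) -> float:
        return float(self.lengths.sum())


@dataclass
class BranchClassification:
    """Origins of one branch labeled conserved / gained / lost.

    Each mapping goes from origin id to ``(position_bp, rate)`` taken at
    the endpoint where the class is observable: branch end for conserved
    and gained origins, branch start (the parent genome) for lost ones.
    Origins both born and lost within the branch appear in no set; they
    would be unobservable when comparing extant genomes.
    """

    conserved: dict[int, tuple[int, float]]
    gained: dict[int, tuple[int, float]]
    lost: dict[int, tuple[int, float]]

    def class_of(self, origin_id: int) -> str | None:
        if origin_id in self.conserved:
            return "conserved"
        if origin_id in self.gained:
            return "gained"
        if origin_id in self.lost:
            return "lost"
        return None


@dataclass
class OriginFamily:
    """Orthologous origins across leaves descending from one founding lineage."""

    founder_id: int
    members: list[tuple[str, int]]  # (leaf label, origin id)

    @property
    def size(self) -> int:
        return len({leaf for leaf, _ in self.members})


@dataclass(frozen=True)
class BranchEventSummary:
    """Per-branch event counts used for rate estimation and the null model."""

    branch_id: str
    n_birth: int
    n_death: int
    branch_length: float
    genome_length_bp: int
    n_origins: int

    def __post_init__(self) -> None:
        if self.n_birth < 0 or self.n_death < 0:
            raise ValueError("event counts must be nonnegative")
        if self.branch_length < 0:
            raise ValueError("branch length must be nonnegative")


@dataclass
class TreeSimulation:
    """Genomes and event logs over a simulated phylogeny.

    ``configs[i]`` is the genome at node ``i``; ``logs[i]`` the events on
    the branch above node ``i`` (the root log is empty).
    """

    tree: PhyloTree
    configs: dict[int, GenomeConfiguration]
    logs: dict[int, EventLog]
    params: ModelParams | None = None

    def leaf_config(self, label: str) -> GenomeConfiguration:
        return self.configs[self.tree.index_of(label)]

    def classify_branch(self, node: int) -> BranchClassification:
        p = int(self.tree.parent[node])
        if p < 0:
            raise ValueError("the root has no branch to classify")
        return classify_branch_events(
            self.configs[p], self.configs[node], self.logs[node]
        )

    def iter_branches(self) -> Iterable[int]:
        for i in range(self.tree.n_nodes):
            if self.tree.parent[i] >= 0:
                yield i


def simulate_tree(
    tree: PhyloTree,
    params: ModelParams,
    rate_dist: RateDistribution,
    rng: np.random.Generator,
    root_config: GenomeConfiguration | None = None,
    root_burn_in: float | None = None,
    n0: int = 50,
) -> TreeSimulation:
    """Simulate the birth-death dynamics along every branch of ``tree``.

    The root genome is the end state of a burned-in single-lineage run
    (freshly generated per call unless ``root_config`` is given).  Each
    internal node's genome is copied into both children's branch
    simulations, so sister branches start from identical configurations
    and diverge only through their independent event draws.
    """
    if tree.n_nodes == 0 or not tree.leaf_indices():
        raise ValueError("tree has no leaves")
    if root_config is None:
        if root_burn_in is None:
            root_burn_in = 20.0 / params.d_bar if params.d_bar > 0 else 1.0
        root = simulate_lineage(
            params,
            rate_dist,
            t_total=root_burn_in,
            burn_in=root_burn_in,
            n0=n0,
            rng=rng,
            record_events=False,
        ).final
    else:
        root = root_config.copy()

    configs: dict[int, GenomeConfiguration] = {0: root}
    logs: dict[int, EventLog] = {0: EventLog()}
    next_id = root.next_id
    for node in range(1, tree.n_nodes):  # preorder: parents precede children
        parent = int(tree.parent[node])
        start = configs[parent].copy()
        start.next_id = max(start.next_id, next_id)  # ids unique across branches
        duration = float(tree.lengths[node])
        if duration == 0.0:
            configs[node] = start
            logs[node] = EventLog()
            continue
        res = simulate_lineage(
            params,
            rate_dist,
            t_total=duration,
            burn_in=0.0,
            snapshot_interval=max(duration, 1.0),
            rng=rng,
            initial_config=start,
            record_events=True,
        )
        configs[node] = res.final
        logs[node] = res.events
        next_id = max(next_id, res.final.next_id)
    return TreeSimulation(tree, configs, logs, params)


def classify_branch_events(
    parent: GenomeConfiguration,
    child: GenomeConfiguration,
    log: EventLog,
) -> BranchClassification:
    """Label every observable origin of a branch conserved, gained or lost.

    Conserved: alive at both endpoints.  Lost: alive at the start, absent
    at the end (position and rate taken from the parent genome).  Gained:
    born within the branch and alive at the end.  Origins born and lost
    inside the branch fall in no class.
    """
    parent_ids = set(int(i) for i in parent.ids)
    child_ids = set(int(i) for i in child.ids)
    born = log.ids_of_kind("birth")
    known = parent_ids | born
    for rec in log:
        if rec.origin_id not in known:
            raise ValueError(
                f"event log references id {rec.origin_id} absent from the "
                "parent genome and never born in-branch"
            )
    parent_row = {
        int(i): (int(p), float(r))
        for i, p, r in zip(parent.ids, parent.positions, parent.rates)
    }
    child_row = {
        int(i): (int(p), float(r))
        for i, p, r in zip(child.ids, child.positions, child.rates)
    }
    conserved = {i: child_row[i] for i in parent_ids & child_ids}
    lost = {i: parent_row[i] for i in parent_ids - child_ids}
    gained = {i: child_row[i] for i in (child_ids - parent_ids)}
    if not (child_ids - parent_ids) <= born:
        raise ValueError("child genome contains ids with no birth record")
    return BranchClassification(conserved=conserved, gained=gained, lost=lost)


def build_families(sim: TreeSimulation) -> list[OriginFamily]:
    """Group extant leaf origins into evolutionary families by founder id.

    One family per root origin or per birth event anywhere in the tree
    that still has at least one extant descendant; because origins never
    move and ids are never reused, the founder id *is* the orthology key.
    """
    members: dict[int, list[tuple[str, int]]] = {}
    for leaf in sim.tree.leaf_indices():
        label = sim.tree.labels[leaf]
        for oid in sim.configs[leaf].ids:
            members.setdefault(int(oid), []).append((label, int(oid)))
    return [
        OriginFamily(founder_id=oid, members=mem)
        for oid, mem in sorted(members.items())
    ]


def pairwise_shared_loss(
    sim: TreeSimulation, leaf_a: str, leaf_b: str
) -> tuple[int, int]:
    """Loss divergence of a species pair below their common ancestor.

    Returns ``(total_losses, ancestor_origins_lost)``: the number of death
    events on the two paths from the MRCA down to each leaf, and the
    number of MRCA origins absent from at least one of the two leaves.
    """
    if leaf_a == leaf_b:
        raise ValueError("the two leaves must differ")
    tree = sim.tree
    mrca = tree.mrca(leaf_a, leaf_b)
    total_losses = 0
    for leaf in (leaf_a, leaf_b):
        for node in tree.path_to_ancestor(tree.index_of(leaf), mrca):
            total_losses += sim.logs[node].count("death")
    anc_ids = set(int(i) for i in sim.configs[mrca].ids)
    ids_a = set(int(i) for i in sim.leaf_config(leaf_a).ids)
    ids_b = set(int(i) for i in sim.leaf_config(leaf_b).ids)
    ancestor_lost = sum(1 for i in anc_ids if i not in ids_a or i not in ids_b)
    return total_losses, ancestor_lost


def branch_event_summaries(sim: TreeSimulation) -> list[BranchEventSummary]:
    """Per-branch birth/death counts from a tree simulation's logs."""
    out = []
    for node in sim.iter_branches():
        out.append(
            BranchEventSummary(
                branch_id=sim.tree.labels[node],
                n_birth=sim.logs[node].count("birth"),
                n_death=sim.logs[node].count("death"),
                branch_length=float(sim.tree.lengths[node]),
                genome_length_bp=sim.configs[node].length_bp,
                n_origins=sim.configs[node].n,
            )
        )
    return out


def null_model_simulate(
    tree: PhyloTree,
    summaries: Mapping[str, BranchEventSummary] | Iterable[BranchEventSummary],
    root_n: int,
    genome_length_bp: int,
    rate_dist: RateDistribution,
    rng: np.random.Generator,
    topology: str = "circular",
) -> TreeSimulation:
    """Uniform birth-death null model with prescribed per-branch counts.

    The root genome carries ``root_n`` origins at uniform positions.  At
    every branching point the genome is copied into the daughters; within
    each branch the prescribed number of death events (uniform over
    origins) is applied first, then the prescribed births at uniform
    positions with fresh ids.  Positions and firing rates play no role in
    event placement, which is what makes this the uncorrelated control.
    """
    if root_n < 1:
        raise ValueError("root_n must be >= 1")
    if not isinstance(summaries, Mapping):
        summaries = {s.branch_id: s for s in summaries}
    pos = uniform_positions(genome_length_bp, root_n, rng)
    root = GenomeConfiguration(
        genome_length_bp,
        pos,
        rate_dist.sample(rng, root_n),
        topology=topology,
    )
    configs: dict[int, GenomeConfiguration] = {0: root}
    logs: dict[int, EventLog] = {0: EventLog()}
    next_id = root.next_id
    for node in range(1, tree.n_nodes):
        label = tree.labels[node]
        if label not in summaries:
            raise KeyError(f"no event summary for branch {label!r}")
        summ = summaries[label]
        cfg = configs[int(tree.parent[node])].copy()
        cfg.next_id = max(cfg.next_id, next_id)
        log = EventLog()
        T = float(tree.lengths[node])
        n_ev = summ.n_death + summ.n_birth
        tick = lambda k: T * (k + 1) / (n_ev + 1) if n_ev else 0.0
        if summ.n_death > cfg.n:
            raise ValueError(
                f"branch {label!r} prescribes {summ.n_death} deaths but only "
                f"{cfg.n} origins are present"
            )
        dead = rng.choice(cfg.n, size=summ.n_death, replace=False)
        keep = np.ones(cfg.n, dtype=bool)
        keep[dead] = False
        for k, i in enumerate(np.sort(dead)):
            log.append(
                EventRecord(
                    tick(k), "death", int(cfg.ids[i]), int(cfg.positions[i]), np.nan
                )
            )
        positions = list(cfg.positions[keep])
        ids = list(cfg.ids[keep])
        rates = list(cfg.rates[keep])
        taken = set(int(p) for p in positions)
        for k in range(summ.n_birth):
            p = int(rng.integers(0, genome_length_bp))
            while p in taken:
                p = int(rng.integers(0, genome_length_bp))
            taken.add(p)
            r = float(rate_dist.sample(rng))
            positions.append(p)
            ids.append(next_id)
            rates.append(r)
            log.append(EventRecord(tick(summ.n_death + k), "birth", next_id, p, r))
            next_id += 1
        configs[node] = GenomeConfiguration(
            genome_length_bp,
            np.array(positions, dtype=np.int64),
            np.array(rates, dtype=np.float64),
            ids=np.array(ids, dtype=np.int64),
            topology=topology,
            next_id=next_id,
        )
        logs[node] = log
    return TreeSimulation(tree, configs, logs, None)
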