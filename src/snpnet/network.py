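"""Super-node genotype network: construction, partition, fractions, Pajek.

The network has one *super-node* per disease group (case, control,
precancer, ...) and one node per observed genotype superset.  A node is
joined to the super-node of every group in which its superset occurs; the
edge weight w is the number of individuals of that group carrying the
superset, so 1 <= w <= P and the weights into a super-node sum to the
group size.  Nodes touching exactly one super-node are *group-specific*;
nodes touching several are *shared* ("common").
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from .geno_core import SupersetFrequencyTable

__all__ = [
    "GenotypeNetwork",
    "NodePartition",
    "build_network",
    "partition_nodes",
    "specific_fraction",
    "write_pajek",
    "read_pajek_edges",
    "write_partition_report",
]


@dataclass(frozen=True)
class GenotypeNetwork:
    """Weighted bipartite graph of superset nodes against group super-nodes."""

    groups: tuple[str, ...]
    counts: pd.DataFrame  # node (superset) x group weight matrix, zeros = no edge

    @property
    def nodes(self) -> tuple[str, ...]:
        return tuple(self.counts.index)

    @property
    def n_nodes(self) -> int:
        return len(self.counts)

    @property
    def total_individuals(self) -> int:
        """P: one individual contributes weight 1 to exactly one edge."""
        return int(self.counts.to_numpy().sum())

    @property
    def edges(self) -> list[tuple[str, str, int]]:
        """(superset, group, weight) for every positive-count pair."""
        out = []
        for sup, row in self.counts.iterrows():
            for g in self.groups:
                w = int(row[g])
                if w > 0:
                    out.append((str(sup), g, w))
        return out

    def membership(self) -> pd.DataFrame:
        """Boolean node x group incidence (which super-nodes a node touches)."""
        return self.counts > 0


def build_network(freq: SupersetFrequencyTable) -> GenotypeNetwork:
    """Build the super-node network from a superset frequency table.

    One node per table row, one edge per positive (row, group) count with
    weight equal to the count.  Node order is the table's lexicographic
    superset order, which makes all downstream output deterministic.
    """
    if freq.counts.to_numpy().sum() == 0:
        raise ValueError("cannot build a network from an all-zero frequency table")
    return GenotypeNetwork(groups=freq.groups, counts=freq.counts.copy())


@dataclass(frozen=True)
class NodePartition:
    """Nodes classed by the exact set of super-nodes they touch.

    `classes` maps every nonempty group subset (a tuple in declared group
    order, 2**k - 1 keys, zero-size classes included) to its node tuple.
    """

    classes: dict[tuple[str, ...], tuple[str, ...]]

    @property
    def class_counts(self) -> dict[tuple[str, ...], int]:
        return {key: len(nodes) for key, nodes in self.classes.items()}

    def specific(self, group: str) -> tuple[str, ...]:
        """Nodes whose membership is exactly {group}."""
        return self.classes[(group,)]


def _subset_keys(groups: tuple[str, ...]) -> list[tuple[str, ...]]:
    keys = []
    for r in range(1, len(groups) + 1):
        keys.extend(combinations(groups, r))
    return keys


def partition_nodes(net: GenotypeNetwork) -> NodePartition:
    """Assign every node to its exact-membership class."""
    member = net.membership()
    classes: dict[tuple[str, ...], list[str]] = {key: [] for key in _subset_keys(net.groups)}
    for sup, row in member.iterrows():
        key = tuple(g for g in net.groups if row[g])
        classes[key].append(str(sup))
    return NodePartition(classes={k: tuple(v) for k, v in classes.items()})


def specific_fraction(net: GenotypeNetwork, group: str, basis: str = "nodes") -> float:
    """Fraction of the network specific to one group.

    basis="nodes": (# nodes touching only `group`) / N.
    basis="individuals": (total weight on those group-specific nodes) / P,
    P being the sum of all edge weights.
    """
    if group not in net.groups:
        raise KeyError(f"unknown group {group!r}; groups are {net.groups}")
    member = net.membership()
    only = member[group] & (member.sum(axis=1) == 1)
    if basis == "nodes":
        return float(only.sum()) / net.n_nodes
    if basis == "individuals":
        return float(net.counts.loc[only, group].sum()) / net.total_individuals
    raise ValueError(f"basis must be 'nodes' or 'individuals', got {basis!r}")


def write_pajek(net: GenotypeNetwork, sink: str | Path | io.TextIOBase | None = None) -> str:
    """Render the network as a Pajek NET document.

    Vertices are 1-based: super-nodes first in declared group order, then
    superset nodes in lexicographic order; all labels double-quoted.
    Edges are undirected ``node supernode weight`` lines with integer
    weights.  Output is byte-stable for a given network.
    """
    if net.n_nodes == 0:
        raise ValueError("cannot export an empty network")
    k = len(net.groups)
    lines = [f"*Vertices {k + net.n_nodes}"]
    for i, g in enumerate(net.groups, start=1):
        lines.append(f'{i} "{g}"')
    node_id = {}
    for j, sup in enumerate(net.nodes, start=k + 1):
        node_id[sup] = j
        lines.append(f'{j} "{sup}"')
    lines.append("*Edges")
    for sup, g, w in net.edges:
        lines.append(f"{node_id[sup]} {net.groups.index(g) + 1} {w}")
    text = "\n".join(lines) + "\n"
    if sink is not None:
        if isinstance(sink, (str, Path)):
            Path(sink).write_text(text, encoding="utf-8")
        else:
            sink.write(text)
    return text


def read_pajek_edges(source: str | Path | io.TextIOBase) -> list[tuple[str, str, int]]:
    """Parse a Pajek NET document back into (label, label, weight) edges."""
    if isinstance(source, (str, Path)):
        text = Path(source).read_text(encoding="utf-8")
    else:
        text = source.read()
    labels: dict[int, str] = {}
    edges: list[tuple[str, str, int]] = []
    section = None
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.lower().startswith("*vertices"):
            section = "vertices"
            continue
        if line.lower().startswith("*edges") or line.lower().startswith("*arcs"):
            section = "edges"
            continue
        if section == "vertices":
            vid, label = line.split(" ", 1)
            labels[int(vid)] = label.strip().strip('"')
        elif section == "edges":
            u, v, w = line.split()
            edges.append((labels[int(u)], labels[int(v)], int(w)))
    return edges


def write_partition_report(net: GenotypeNetwork, sink: str | Path | io.TextIOBase) -> pd.DataFrame:
    """TSV report: superset, membership class and per-group counts."""
    member = net.membership()
    rows = []
    for sup, row in net.counts.iterrows():
        key = "+".join(g for g in net.groups if member.loc[sup, g])
        rows.append({"superset": sup, "membership": key,
                     **{g: int(row[g]) for g in net.groups}})
    report = pd.DataFrame(rows)
    report.to_csv(sink, sep="\t", index=False)
    return report
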