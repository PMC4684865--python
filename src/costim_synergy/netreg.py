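"""Coverage-based classification of regulatory network nodes.

Given a directed regulator -> target edge list over a gene universe (the
costimulation-upregulated set), each node's *coverage* is the fraction of
the rest of the universe it regulates — either directly (its out-neighbours)
or through cascades (its directed reachable set).  Nodes covering more than
30% of the network are *major* regulators, nodes covering 10% to under 30%
are *minor*, everything else is unclassified.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import networkx as nx
import pandas as pd

MAJOR_THRESHOLD = 0.30
MINOR_THRESHOLD = 0.10

MODES = ("direct", "reachable")


@dataclass
class RegNetwork:
    """Directed regulator->target graph restricted to a gene universe."""

    universe: tuple[str, ...]
    graph: nx.DiGraph

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str]],
                   universe: Iterable[str] | None = None) -> "RegNetwork":
        edges = set(tuple(e) for e in edges)
        if universe is None:
            universe = sorted({n for e in edges for n in e})
        universe = tuple(universe)
        members = set(universe)
        for reg, tgt in edges:
            if reg not in members or tgt not in members:
                raise ValueError(
                    f"edge ({reg!r}, {tgt!r}) leaves the gene universe")
        g = nx.DiGraph()
        g.add_nodes_from(universe)
        g.add_edges_from(edges)
        return cls(universe, g)

    @property
    def edges(self) -> set[tuple[str, str]]:
        return set(self.graph.edges())

    def __contains__(self, node: str) -> bool:
        return node in self.graph


def _regulated_set(network: RegNetwork, node: str, mode: str) -> set[str]:
    if node not in network:
        raise KeyError(f"node {node!r} not in network")
    if mode == "direct":
        reached = set(network.graph.successors(node))
    elif mode == "reachable":
        reached = nx.descendants(network.graph, node)
    else:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    reached.discard(node)  # self-regulation never counts toward coverage
    return reached


def node_coverage(network: RegNetwork, node: str, mode: str = "direct") -> float:
    """Fraction of the rest of the universe regulated by ``node``.

    Denominator is |universe| - 1: a node cannot cover itself.
    """
    denom = len(network.universe) - 1
    if denom <= 0:
        return 0.0
    return len(_regulated_set(network, node, mode)) / denom


def classify_nodes(network: RegNetwork, mode: str = "direct",
                   major_threshold: float = MAJOR_THRESHOLD,
                   minor_threshold: float = MINOR_THRESHOLD) -> pd.DataFrame:
    """Coverage and major/minor/none class for every universe node.

    Major requires coverage strictly above ``major_threshold`` (default
    30%); minor spans ``minor_threshold`` (inclusive, default 10%) up to
    and including the major threshold, since exactly 30% is not "more
    than 30%".
    """
    rows = []
    for node in network.universe:
        cov = node_coverage(network, node, mode=mode)
        if cov > major_threshold:
            klass = "major"
        elif cov >= minor_threshold:
            klass = "minor"
        else:
            klass = "none"
        rows.append({"node": node, "coverage": cov, "klass": klass})
    return pd.DataFrame(rows).set_index("node")


def set_coverage(network: RegNetwork, nodes: Iterable[str],
                 mode: str = "direct") -> float:
    """Joint coverage of a node set: fraction of the residual universe
    (universe minus the nodes themselves) reached by the union of their
    regulated sets."""
    nodes = list(dict.fromkeys(nodes))
    if not nodes:
        return 0.0
    node_set = set(nodes)
    covered: set[str] = set()
    for node in nodes:
        covered |= _regulated_set(network, node, mode)
    covered -= node_set
    denom = len(network.universe) - len(node_set & set(network.universe))
    if denom <= 0:
        return 0.0
    return len(covered) / denom


# ---------------------------------------------------------------------------
# file I/O


def read_edge_list(path: str | Path,
                   universe: Iterable[str] | None = None) -> RegNetwork:
    """Read a two-column tab-delimited regulator -> target edge list."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["regulator", "target"]:
        df = pd.read_csv(path, sep="\t", header=None,
                         names=["regulator", "target"], dtype=str)
    edges = list(df.itertuples(index=False, name=None))
    return RegNetwork.from_edges(edges, universe)


def read_universe(path: str | Path) -> list[str]:
    with open(path) as fh:
        genes = [line.strip() for line in fh if line.strip()]
    if genes and genes[0].lower() in ("gene_id", "gene", "node"):
        genes = genes[1:]
    return genes


def write_node_classes(classes: pd.DataFrame, path: str | Path) -> None:
    classes.to_csv(path, sep="\t", float_format="%.6g")
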