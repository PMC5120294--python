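"""Network statistics: ASL curves, APL, clustering, degree distribution.

Graph-theoretic quantities are computed on the undirected view of the live
(non-virtual) memory network via networkx; virtual forgetting placeholders
carry no information and are excluded.  The average search length (ASL) is
the model's own cost measure — nodes visited per retrieval, endpoints
inclusive — and is bounded below by 2 on any intra-modular retrieval.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import networkx as nx

from .intra import ROOT_ID, IntraNetwork
from .inter import InterNetwork, inter_memorize, total_cost
from .intra import memorize_word
from .retrieve import retrieve_word

GraphLike = Union[IntraNetwork, InterNetwork, nx.Graph]


@dataclass
class ASLCurve:
    """Search-length curve over a retrieval schedule."""

    points: list[tuple[int, float]]
    mode: str  # "running_mean" | "instantaneous"

    @property
    def final(self) -> float:
        return self.points[-1][1]

    def at_step(self, step: int) -> float:
        for s, v in self.points:
            if s == step:
                return v
        raise KeyError(f"no point at step {step}")

    def to_csv(self, run_id: str = "run") -> str:
        lines = ["step,asl,mode,run_id"]
        lines += [f"{s},{v:.6f},{self.mode},{run_id}" for s, v in self.points]
        return "\n".join(lines) + "\n"


@dataclass
class NetworkSummary:
    node_count: int
    edge_count: int
    apl: float
    clustering: float
    degree_histogram: dict[int, int] = field(default_factory=dict)


def to_graph(net: GraphLike) -> nx.Graph:
    """Undirected networkx view (live nodes only, for memory networks)."""
    if isinstance(net, nx.Graph):
        return net
    if isinstance(net, InterNetwork):
        return net.graph
    g = nx.Graph()
    for node in net.nodes.values():
        if node.is_virtual:
            continue
        g.add_node(node.id, symbol=node.symbol)
        if node.parent is not None:
            g.add_edge(node.parent, node.id)
    return g


def apl(net: GraphLike, *, from_root: bool = False) -> float:
    """Average path length: mean geodesic over unordered node pairs.

    With ``from_root`` only root-to-node distances are averaged, the
    retrieval-facing variant in which every path starts at the super node.
    """
    g = to_graph(net)
    if not nx.is_connected(g):
        raise ValueError("average path length needs a connected network")
    if from_root:
        dist = nx.single_source_shortest_path_length(g, ROOT_ID)
        others = [d for n, d in dist.items() if n != ROOT_ID]
        if not others:
            raise ValueError("no letter nodes")
        return sum(others) / len(others)
    return nx.average_shortest_path_length(g)


def clustering_coefficient(net: GraphLike) -> float:
    """Mean local clustering coefficient (degree < 2 contributes 0)."""
    g = to_graph(net)
    if g.number_of_nodes() == 0:
        return 0.0
    return nx.average_clustering(g)


def degree_distribution(net: GraphLike) -> dict[int, int]:
    """Histogram degree -> node count on the undirected view."""
    g = to_graph(net)
    return dict(Counter(d for _, d in g.degree()))


def network_summary(net: GraphLike) -> NetworkSummary:
    g = to_graph(net)
    return NetworkSummary(
        node_count=g.number_of_nodes(),
        edge_count=g.number_of_edges(),
        apl=apl(g),
        clustering=clustering_coefficient(g),
        degree_histogram=degree_distribution(g),
    )


def asl_experiment(
    model: Union[IntraNetwork, InterNetwork],
    corpus: Sequence[str],
    passes: int,
    mode: str = "running_mean",
    op_log: Optional[list] = None,
) -> ASLCurve:
    """Memorize a corpus, then retrieve every stored word round-robin.

    All tokens are memorized in order (repeats strengthen), then the
    distinct words, in first-appearance order, are each retrieved once per
    pass.  On a bi-modular model the per-step cost is the total cost —
    inter-modular routing from the entry region plus the in-region search.
    Deterministic for a fixed corpus and schedule.

    ``op_log``, when given, collects one ``(step, op, word, status,
    comparisons, rewired_count)`` tuple per operation.
    """
    if not corpus:
        raise ValueError("corpus must be non-empty")
    if passes < 1:
        raise ValueError("need at least one retrieval pass")
    bimodular = isinstance(model, InterNetwork)
    for word in corpus:
        if bimodular:
            inter_memorize(model, word)
        else:
            memorize_word(model, word)
    schedule = list(dict.fromkeys(corpus))
    points: list[tuple[int, float]] = []
    total = 0
    step = 0
    for _ in range(passes):
        for word in schedule:
            if bimodular:
                cost, result = total_cost(model, word)
            else:
                result = retrieve_word(model, word)
                cost = result.comparisons
            step += 1
            total += cost
            value = total / step if mode == "running_mean" else float(cost)
            points.append((step, value))
            if op_log is not None:
                op_log.append(
                    (step, "retrieve", word, result.status, cost,
                     len(result.rewired))
                )
    return ASLCurve(points, mode)
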