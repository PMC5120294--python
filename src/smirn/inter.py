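"""Bi-modular composition: region super-nodes over intra-modular tries.

Each region (a cortical area in the model's reading; at most 90, the AAL
parcellation count) owns an independent intra-modular network whose root
doubles as the region's super node.  Regions are wired in a ring, a
complete graph — the two extreme connected topologies — or a custom
connected edge list.  Words are routed to regions by an assignment rule,
first-letter binning by default.

The inter-modular search length counts super-nodes visited, source and
destination inclusive.  Ring traversal is unidirectional (ascending region
index), making the worst case R; on the complete graph every distinct pair
costs exactly 2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Iterable, Optional

import networkx as nx

from .intra import IntraNetwork, WordRecord, memorize_word
from .retrieve import RetrievalResult, retrieve_word

MAX_REGIONS = 90

#: First-letter grouping used for the four-region simulations.
FOUR_REGION_BINS = ("a-e", "f-l", "m-q", "r-z")


def first_letter_bins(bins: Iterable[str]) -> Callable[[str], int]:
    """Assignment rule from ranges like ``("a-e", "f-l", "m-q", "r-z")``.

    Every letter must fall in exactly one bin (total function).
    """
    table: dict[str, int] = {}
    for i, spec in enumerate(bins):
        lo, hi = spec.split("-")
        for code in range(ord(lo), ord(hi) + 1):
            sym = chr(code)
            if sym in table:
                raise ValueError(f"letter {sym!r} assigned to two bins")
            table[sym] = i
    missing = set("abcdefghijklmnopqrstuvwxyz") - set(table)
    if missing:
        raise ValueError(f"letters not covered by any bin: {sorted(missing)}")

    def rule(word: str) -> int:
        return table[word[0]]

    return rule


def even_first_letter_bins(r: int) -> Callable[[str], int]:
    """Split a-z into ``r`` contiguous, near-even first-letter groups."""
    letters = "abcdefghijklmnopqrstuvwxyz"
    base, extra = divmod(len(letters), r)
    table: dict[str, int] = {}
    pos = 0
    for i in range(r):
        width = base + (1 if i < extra else 0)
        for sym in letters[pos:pos + width]:
            table[sym] = i
        pos += width
    return lambda word: table[word[0]]


@dataclass
class InterNetwork:
    regions: list[int]
    topology: str  # "ring" | "complete" | "custom"
    graph: nx.Graph
    entry: int
    assignment: Callable[[str], int]
    intra: dict[int, IntraNetwork]

    @property
    def r(self) -> int:
        return len(self.regions)


def build_inter(
    r: int,
    topology: str = "ring",
    assignment: Optional[Callable[[str], int]] = None,
    edges: Optional[Iterable[tuple[int, int]]] = None,
    entry: int = 0,
) -> InterNetwork:
    """Build an inter-modular network of ``r`` empty regions.

    ``r == 1`` degenerates to a single bare intra-modular module.  Values
    above 90 are allowed but warned about, since the model caps the region
    count at the 90 AAL cortical areas.
    """
    if r < 1:
        raise ValueError("need at least one region")
    if r > MAX_REGIONS:
        warnings.warn(
            f"{r} regions exceeds the anatomical bound of {MAX_REGIONS}",
            stacklevel=2,
        )
    regions = list(range(r))
    if topology == "ring":
        graph = nx.cycle_graph(r) if r > 2 else nx.path_graph(r)
    elif topology == "complete":
        graph = nx.complete_graph(r)
    elif topology == "custom":
        graph = nx.Graph()
        graph.add_nodes_from(regions)
        graph.add_edges_from(edges or [])
        if r > 1 and not nx.is_connected(graph):
            raise ValueError("custom inter-modular topology must be connected")
    else:
        raise ValueError(f"unknown topology {topology!r}")
    if assignment is None:
        if r == 1:
            assignment = lambda word: 0  # noqa: E731
        elif r == 4:
            assignment = first_letter_bins(FOUR_REGION_BINS)
        else:
            assignment = even_first_letter_bins(r)
    if entry not in regions:
        raise ValueError(f"entry region {entry} does not exist")
    return InterNetwork(
        regions=regions,
        topology=topology,
        graph=graph,
        entry=entry,
        assignment=assignment,
        intra={i: IntraNetwork() for i in regions},
    )


def inter_search_length(inter: InterNetwork, src: int, dst: int) -> int:
    """Super-nodes visited travelling from ``src`` to ``dst``, inclusive.

    Ring: unidirectional walk in ascending index order, worst case R.
    Complete: 2 for any distinct pair.  Same region: 1.  Custom: nodes on
    a breadth-first shortest path.
    """
    if src not in inter.intra or dst not in inter.intra:
        raise KeyError(f"unknown region in pair ({src}, {dst})")
    if src == dst:
        return 1
    if inter.topology == "ring":
        return (dst - src) % inter.r + 1
    if inter.topology == "complete":
        return 2
    return len(nx.shortest_path(inter.graph, src, dst))


def region_of(inter: InterNetwork, word: str) -> int:
    return inter.assignment(word)


def inter_memorize(inter: InterNetwork, word: str) -> WordRecord:
    """Route a word to its assigned region and memorize it there."""
    return memorize_word(inter.intra[region_of(inter, word)], word)


def total_cost(
    inter: InterNetwork, word: str, entry: Optional[int] = None
) -> tuple[int, RetrievalResult]:
    """Full retrieval cost: inter-modular routing plus intra-modular search.

    cost(sn) is the super-node search length from the entry region to the
    word's region; cost(n) is the in-region word retrieval (which performs
    the usual strengthening).  Returns their sum with the intra result,
    whose status propagates retrieval failure.
    """
    if entry is None:
        entry = inter.entry
    target = region_of(inter, word)
    sn_cost = inter_search_length(inter, entry, target)
    result = retrieve_word(inter.intra[target], word)
    return sn_cost + result.comparisons, result
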