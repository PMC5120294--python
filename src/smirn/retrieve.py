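"""Strengthening retrieval.

A retrieval walks from the root to the target and counts every node visited,
endpoints inclusive, so the search length of a node at depth d is d + 1 and
the fully-strengthened limit is exactly 2 (root plus target).  Successful
retrieval has a side effect: the retrieved nodes and their former proper
ancestors are re-parented directly under the root (path compression), so
repeated retrieval of the same content keeps getting cheaper until the
whole path sits at depth 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

from .intra import ROOT_ID, IntraNetwork, compress_to_root, memorize_word

Status = Literal["success", "partial", "failure"]


@dataclass
class RetrievalResult:
    status: Status
    comparisons: int
    output: list[str] = field(default_factory=list)
    rewired: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.status == "failure" and self.output:
            raise ValueError("a failed retrieval has empty output")


def retrieve_node(net: IntraNetwork, word: str, position: int) -> RetrievalResult:
    """Retrieve a single letter of a registered word.

    Comparisons equal the node's pre-call depth plus one.  The node and its
    former proper ancestors (root excluded, depth-1 nodes already there
    excluded) move under the root; their child links are preserved, so all
    descendants get closer to the root too.  Unknown words or positions
    outside the live path yield a failure and leave the network unchanged.
    """
    rec = net.words.get(word)
    if rec is None or not (0 <= position < len(rec.path)):
        return RetrievalResult("failure", 1)
    net.clock += 1
    target = rec.path[position]
    comparisons = net.depth(target) + 1
    rewired = compress_to_root(net, [target])
    rec.last_access = net.clock
    return RetrievalResult(
        "success", comparisons, [net.nodes[target].symbol], rewired  # type: ignore[list-item]
    )


def retrieve_word(
    net: IntraNetwork, word: str, *, learn_on_fail: bool = False
) -> RetrievalResult:
    """Retrieve a whole word and strengthen its path.

    Comparisons are counted to the word's terminal under pre-call parent
    pointers (depth + 1).  A fully live word succeeds and outputs its
    spelling; a partially forgotten word strengthens and outputs only the
    surviving prefix with status ``partial``.  An absent word fails with
    the nodes visited before the mismatch (plus the failed comparison)
    and, unless ``learn_on_fail`` is set, leaves the network unchanged.
    """
    rec = net.words.get(word)
    if rec is not None:
        net.clock += 1
        comparisons = net.depth(rec.path[-1]) + 1
        rewired = compress_to_root(net, rec.path)
        rec.last_access = net.clock
        symbols = [net.nodes[nid].symbol for nid in rec.path]
        status: Status = "success" if rec.live else "partial"
        return RetrievalResult(status, comparisons, symbols, rewired)  # type: ignore[arg-type]

    cur = ROOT_ID
    matched = 0
    mismatch = False
    for sym in word:
        nxt = net.child_by_symbol(cur, sym)
        if nxt is None:
            mismatch = True
            break
        matched += 1
        cur = nxt
    comparisons = 1 + matched + (1 if mismatch else 0)
    if learn_on_fail:
        memorize_word(net, word)
    return RetrievalResult("failure", comparisons)


def recognize(net: IntraNetwork, word: str) -> tuple[bool, RetrievalResult]:
    """Yes/no recognition: true iff the word is fully present and live.

    Performs the same strengthening side effects as :func:`retrieve_word`;
    a partially forgotten word answers ``False`` with status ``partial``.
    """
    result = retrieve_word(net, word)
    return result.status == "success", result
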