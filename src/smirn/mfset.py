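"""Merge-find set (disjoint-set forest) baseline.

The textbook MFset with union-by-size and path compression, instrumented to
count the nodes visited on each find (leaf to root, endpoints inclusive) so
its average search length can be compared against the strengthening
retrieval algorithm on the same corpus and schedule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Iterable, Sequence

Element = Hashable


@dataclass
class MFset:
    """Disjoint-set forest over arbitrary hashable elements.

    ``parent`` maps each element to its parent (roots map to themselves);
    ``size`` holds tree sizes for roots only.  ``find_log`` accumulates the
    comparison count of every find, in call order.
    """

    parent: dict[Element, Element] = field(default_factory=dict)
    size: dict[Element, int] = field(default_factory=dict)
    find_log: list[int] = field(default_factory=list)

    def add(self, x: Element) -> None:
        """Register a new singleton; a no-op for known elements."""
        if x not in self.parent:
            self.parent[x] = x
            self.size[x] = 1

    def _require(self, x: Element) -> None:
        if x not in self.parent:
            raise KeyError(f"unknown element {x!r}")

    def _root(self, x: Element) -> Element:
        while self.parent[x] != x:
            x = self.parent[x]
        return x

    def merge(self, a: Element, b: Element) -> None:
        """Union by size: the smaller tree's root attaches under the larger.

        Equal sizes attach the second argument's root under the first's.
        Merging elements already in one set is a no-op.
        """
        self._require(a)
        self._require(b)
        ra, rb = self._root(a), self._root(b)
        if ra == rb:
            return
        if self.size[ra] >= self.size[rb]:
            big, small = ra, rb
        else:
            big, small = rb, ra
        self.parent[small] = big
        self.size[big] += self.size.pop(small)

    def find_with_compression(self, x: Element) -> tuple[Element, int]:
        """Find the root of ``x``, counting nodes visited inclusively.

        Every node on the walked path then becomes a direct child of the
        root, so an immediate repeat find costs 2 (or 1 on the root itself).
        """
        self._require(x)
        path = [x]
        while self.parent[path[-1]] != path[-1]:
            path.append(self.parent[path[-1]])
        root = path[-1]
        for node in path[:-1]:
            self.parent[node] = root
        comparisons = len(path)
        self.find_log.append(comparisons)
        return root, comparisons


def initial(n: int) -> MFset:
    """``n`` integer singletons 0..n-1."""
    if n < 1:
        raise ValueError("need at least one element")
    s = MFset()
    for i in range(n):
        s.add(i)
    return s


def build_from_corpus(corpus: Sequence[str]) -> tuple[MFset, dict[str, str]]:
    """Encode a corpus for the baseline comparison.

    Elements are the distinct trie positions (word prefixes) of the corpus;
    for each word its successive positions are merged into one set, built
    once.  Returns the forest and the word -> terminal-element map.
    """
    s = MFset()
    terminal: dict[str, str] = {}
    for word in corpus:
        prev = None
        for i in range(1, len(word) + 1):
            pos = word[:i]
            s.add(pos)
            if prev is not None:
                s.merge(prev, pos)
            prev = pos
        terminal[word] = word
    return s, terminal


def mfset_asl_curve(
    corpus: Sequence[str], passes: int = 1, mode: str = "running_mean"
) -> list[tuple[int, float]]:
    """Average-search-length curve of MFset finds on the shared schedule.

    The schedule mirrors the retrieval experiment: distinct words in first
    appearance order, round-robin for ``passes`` passes, one find on each
    word's terminal element per step.  ``mode`` selects the running mean of
    all finds so far or the instantaneous per-step count.
    """
    if not corpus:
        return []
    s, terminal = build_from_corpus(corpus)
    schedule = list(dict.fromkeys(corpus))
    points: list[tuple[int, float]] = []
    total = 0
    step = 0
    for _ in range(passes):
        for word in schedule:
            _, comps = s.find_with_compression(terminal[word])
            step += 1
            total += comps
            value = total / step if mode == "running_mean" else float(comps)
            points.append((step, value))
    return points
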