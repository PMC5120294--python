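"""Intra-modular memory network.

A memory module is an inverted tree of letter nodes hanging under a
distinguished root (the super node ``sn``, the sole input/output point).
Memorizing a word grows the trie by one node per symbol beyond the longest
matching prefix; re-memorizing strengthens (compresses) the existing path.
Forgetting is threshold-driven decay: a childless *virtual* node replaces a
word's deepest node and climbs toward the root, deleting the nodes it
replaces, until the whole word is gone.

Node identity is positional, not symbolic: the two "e"s of "netbeans" are
two distinct nodes.  The logical clock counts memorize/retrieve/forget
operations; the model has no physical time unit.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

ROOT_ID = 0
DEFAULT_ALPHABET = frozenset("abcdefghijklmnopqrstuvwxyz")

_STRIP_RE = re.compile(r"[^a-z]+")


@dataclass
class LetterNode:
    """One meta-memory unit: a single stored symbol.

    ``parent`` is ``None`` only for the root.  ``children`` keeps insertion
    order; at most one non-virtual child per symbol exists under any node,
    so prefix matching is deterministic.  A virtual node is a childless
    placeholder marking forgetting progress and never takes part in
    matching or comparison counts.
    """

    id: int
    symbol: Optional[str]
    parent: Optional[int]
    children: list[int] = field(default_factory=list)
    is_virtual: bool = False
    last_access: int = 0


@dataclass
class WordRecord:
    """Registry entry for one memorized word.

    ``path`` lists the live node ids in memorization order; while a word is
    partially forgotten ``len(path) == len(word) - forgotten_suffix_len``
    and ``virtual_node`` points at the decay placeholder.
    """

    word: str
    path: list[int]
    last_access: int
    forgotten_suffix_len: int = 0
    virtual_node: Optional[int] = None

    @property
    def terminal(self) -> int:
        """Deepest position of the word: the virtual node once decay began."""
        if self.virtual_node is not None:
            return self.virtual_node
        return self.path[-1]

    @property
    def live(self) -> bool:
        return self.forgotten_suffix_len == 0


@dataclass
class ForgetConfig:
    """Decay threshold: a word untouched for more than ``tau`` ticks loses
    one node per forgetting tick."""

    tau: int = 1000
    enabled: bool = True

    def __post_init__(self) -> None:
        if self.tau < 1:
            raise ValueError(f"tau must be >= 1, got {self.tau}")


class IntraNetwork:
    """Rooted trie of :class:`LetterNode` plus word registry and clock."""

    def __init__(self, alphabet: Iterable[str] | None = None) -> None:
        self.alphabet = frozenset(alphabet) if alphabet is not None else DEFAULT_ALPHABET
        self.nodes: dict[int, LetterNode] = {
            ROOT_ID: LetterNode(ROOT_ID, None, None)
        }
        self.words: dict[str, WordRecord] = {}
        self.clock = 0
        self._next_id = 1

    # -- structure helpers -------------------------------------------------

    @property
    def root(self) -> LetterNode:
        return self.nodes[ROOT_ID]

    def letter_node_count(self) -> int:
        """Live (non-root, non-virtual) nodes."""
        return sum(
            1 for n in self.nodes.values() if n.id != ROOT_ID and not n.is_virtual
        )

    def depth(self, node_id: int) -> int:
        """Edges on the parent-pointer walk from ``node_id`` to the root."""
        d = 0
        nid = node_id
        while nid != ROOT_ID:
            nid = self.nodes[nid].parent  # type: ignore[assignment]
            d += 1
            if d > len(self.nodes):
                raise RuntimeError("parent pointers form a cycle")
        return d

    def ancestors(self, node_id: int) -> list[int]:
        """Proper ancestors of a node, nearest first, root excluded."""
        out = []
        nid = self.nodes[node_id].parent
        while nid is not None and nid != ROOT_ID:
            out.append(nid)
            nid = self.nodes[nid].parent
        return out

    def child_by_symbol(self, node_id: int, symbol: str) -> Optional[int]:
        """First non-virtual child storing ``symbol`` (insertion order)."""
        for cid in self.nodes[node_id].children:
            c = self.nodes[cid]
            if not c.is_virtual and c.symbol == symbol:
                return cid
        return None

    def _new_node(self, symbol: str, parent: int, *, virtual: bool = False) -> LetterNode:
        node = LetterNode(
            self._next_id, symbol, parent, is_virtual=virtual, last_access=self.clock
        )
        self._next_id += 1
        self.nodes[node.id] = node
        self.nodes[parent].children.append(node.id)
        return node

    def _detach(self, node_id: int) -> None:
        parent = self.nodes[node_id].parent
        if parent is not None:
            self.nodes[parent].children.remove(node_id)

    def iter_words(self) -> Iterator[WordRecord]:
        return iter(self.words.values())

    # -- serialization -----------------------------------------------------

    def to_json(self) -> str:
        doc = {
            "nodes": [
                {
                    "id": n.id,
                    "symbol": n.symbol,
                    "parent": n.parent,
                    "virtual": n.is_virtual,
                    "last_access": n.last_access,
                }
                for n in self.nodes.values()
            ],
            "words": [
                {
                    "word": r.word,
                    "path": r.path,
                    "last_access": r.last_access,
                    "forgotten_suffix_len": r.forgotten_suffix_len,
                    "virtual_node": r.virtual_node,
                }
                for r in self.words.values()
            ],
            "clock": self.clock,
            "alphabet": "".join(sorted(self.alphabet)),
        }
        return json.dumps(doc, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "IntraNetwork":
        doc = json.loads(text)
        net = cls(alphabet=doc.get("alphabet") or None)
        net.nodes = {}
        for nd in doc["nodes"]:
            net.nodes[nd["id"]] = LetterNode(
                nd["id"], nd["symbol"], nd["parent"],
                is_virtual=nd["virtual"], last_access=nd["last_access"],
            )
        for nd in doc["nodes"]:
            if nd["parent"] is not None:
                net.nodes[nd["parent"]].children.append(nd["id"])
        for wd in doc["words"]:
            net.words[wd["word"]] = WordRecord(
                wd["word"], list(wd["path"]), wd["last_access"],
                wd["forgotten_suffix_len"], wd["virtual_node"],
            )
        net.clock = doc["clock"]
        net._next_id = max(net.nodes) + 1
        return net

    def edge_list(self) -> list[tuple[int, int]]:
        """(parent, child) pairs over live nodes, for generic graph tools."""
        return [
            (n.parent, n.id)
            for n in self.nodes.values()
            if n.parent is not None and not n.is_virtual
        ]

    def edge_tsv(self) -> str:
        return "".join(f"{p}\t{c}\n" for p, c in self.edge_list())


def tokenize(text: str) -> list[str]:
    """Lowercase, strip non-letter characters, split on whitespace.

    Empty tokens are dropped; order and duplicates are preserved.
    """
    out = []
    for raw in text.lower().split():
        tok = _STRIP_RE.sub("", raw)
        if tok:
            out.append(tok)
    return out


def compress_to_root(net: IntraNetwork, targets: Iterable[int]) -> list[int]:
    """Re-parent the target nodes and every former proper ancestor to the root.

    The ancestor set is snapshotted under pre-call parent pointers, then all
    moves happen in one batch, so the outcome is order independent.  Nodes
    already at depth 1 are untouched; child links of moved nodes are kept,
    so descendants follow their subtree upward.  Returns ids actually moved.
    """
    targets = list(targets)
    moved_set: set[int] = set()
    for t in targets:
        moved_set.add(t)
        moved_set.update(net.ancestors(t))
    moved_set.discard(ROOT_ID)
    rewired = []
    for nid in sorted(moved_set):
        node = net.nodes[nid]
        node.last_access = net.clock
        if node.parent != ROOT_ID:
            net._detach(nid)
            node.parent = ROOT_ID
            net.root.children.append(nid)
            rewired.append(nid)
    for t in targets:
        net.nodes[t].last_access = net.clock
    return rewired


def _validate_word(net: IntraNetwork, word: str) -> None:
    if not word:
        raise ValueError("cannot memorize the empty word")
    for sym in word:
        if sym not in net.alphabet:
            raise ValueError(f"symbol {sym!r} is outside the configured alphabet")


def memorize_word(net: IntraNetwork, word: str) -> WordRecord:
    """Store a word: strengthen old content, append new nodes for the rest.

    Re-input of a registered word is handled by the retrieval algorithm: its
    recorded path is strengthened (path compression to the root) and, if
    partially forgotten, the decayed suffix is rebuilt under the deepest
    surviving node and the virtual node removed.  A first-time word walks
    the trie for its longest matching prefix (following child links at their
    current, possibly retrieval-flattened, positions) and appends the
    remaining symbols as a chain of new nodes at the divergence node, or at
    the root when nothing matches; memorization alone never rewires, so a
    duplicate-free corpus always builds the pristine shared-prefix trie.
    """
    _validate_word(net, word)
    net.clock += 1

    rec = net.words.get(word)
    if rec is not None:
        compress_to_root(net, rec.path)
        if rec.forgotten_suffix_len:
            attach = rec.path[-1]
            for sym in word[len(word) - rec.forgotten_suffix_len:]:
                node = net._new_node(sym, attach)
                rec.path.append(node.id)
                attach = node.id
            if rec.virtual_node is not None:
                net._detach(rec.virtual_node)
                del net.nodes[rec.virtual_node]
                rec.virtual_node = None
            rec.forgotten_suffix_len = 0
        rec.last_access = net.clock
        return rec

    matched: list[int] = []
    cur = ROOT_ID
    for sym in word:
        nxt = net.child_by_symbol(cur, sym)
        if nxt is None:
            break
        matched.append(nxt)
        cur = nxt
    path = list(matched)
    attach = matched[-1] if matched else ROOT_ID
    for sym in word[len(matched):]:
        node = net._new_node(sym, attach)
        path.append(node.id)
        attach = node.id
    rec = WordRecord(word, path, net.clock)
    net.words[word] = rec
    return rec


@dataclass(frozen=True)
class DecayEvent:
    """One forgetting step: a word lost its deepest node.

    ``removed`` is the deleted node id, or ``None`` when the node survived
    because another word's path (or a child) still needs it.  ``remaining``
    is the word's live path length afterwards; 0 means whole forgetting.
    """

    word: str
    removed: Optional[int]
    remaining: int


def forget_tick(net: IntraNetwork, cfg: ForgetConfig) -> list[DecayEvent]:
    """Advance the clock one tick and decay every expired word by one node.

    A word is expired when ``clock - last_access > tau``.  Its deepest
    remaining real node is deleted (unless shared with another registered
    word or still carrying children) and the word's virtual node advances
    one step toward the root; the first expiry creates the virtual node at
    the terminal position.  A word whose last real node goes is unregistered
    and its virtual node disappears with it.
    """
    if not cfg.enabled:
        return []
    net.clock += 1
    events: list[DecayEvent] = []
    for word in list(net.words):
        rec = net.words[word]
        if net.clock - rec.last_access <= cfg.tau:
            continue
        deepest = rec.path[-1]
        node = net.nodes[deepest]
        shared = any(
            deepest in other.path
            for w, other in net.words.items()
            if w != word
        )
        removed: Optional[int] = None
        live_children = [
            c for c in node.children if not net.nodes[c].is_virtual
        ]
        if not shared and not live_children:
            for c in list(node.children):  # re-home a trailing virtual node
                net.nodes[c].parent = node.parent
                net.nodes[node.parent].children.append(c)  # type: ignore[index]
            node.children.clear()
            net._detach(deepest)
            del net.nodes[deepest]
            removed = deepest
        rec.path.pop()
        rec.forgotten_suffix_len += 1
        if rec.path:
            anchor = rec.path[-1]
            if rec.virtual_node is None:
                rec.virtual_node = net._new_node(
                    node.symbol, anchor, virtual=True  # type: ignore[arg-type]
                ).id
            else:
                v = net.nodes[rec.virtual_node]
                net._detach(rec.virtual_node)
                v.parent = anchor
                v.symbol = node.symbol
                net.nodes[anchor].children.append(rec.virtual_node)
            events.append(DecayEvent(word, removed, len(rec.path)))
        else:
            if rec.virtual_node is not None:
                net._detach(rec.virtual_node)
                del net.nodes[rec.virtual_node]
            del net.words[word]
            events.append(DecayEvent(word, removed, 0))
    return events
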