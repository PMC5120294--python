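"""Trie memorization, logical time, and forgetting decay."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from smirn.intra import (
    ROOT_ID,
    ForgetConfig,
    IntraNetwork,
    forget_tick,
    memorize_word,
    tokenize,
)
from smirn.retrieve import retrieve_word

words_strategy = st.lists(
    st.text(alphabet="abcde", min_size=1, max_size=8), min_size=1, max_size=20
)


def distinct_prefixes(words):
    """Brute-force oracle: the set of all non-empty prefixes of all words."""
    return {w[:i] for w in words for i in range(1, len(w) + 1)}


def build(words):
    net = IntraNetwork()
    for w in words:
        memorize_word(net, w)
    return net


@pytest.mark.parametrize(
    "text,expected",
    [
        ("Complex network.", ["complex", "network"]),
        ("", []),
        ("netbeans NETBEANS net-beans", ["netbeans", "netbeans", "netbeans"]),
        ("  one\ttwo\nthree  ", ["one", "two", "three"]),
        ("1984 ... !!", []),
    ],
)
def test_tokenize(text, expected):
    assert tokenize(text) == expected


def test_single_word_grows_a_chain_under_the_root():
    net = IntraNetwork()
    rec = memorize_word(net, "network")
    assert net.letter_node_count() == 7
    assert net.nodes[rec.path[0]].parent == ROOT_ID
    for prev, cur in zip(rec.path, rec.path[1:]):
        assert net.nodes[cur].parent == prev
    assert [net.nodes[n].symbol for n in rec.path] == list("network")


def test_shared_prefix_reuses_trie_positions():
    net = build(["netbeans", "network"])
    # netbeans: 8 nodes; network adds only w,o,r,k under the "t"
    assert net.letter_node_count() == 12
    shared = net.words["netbeans"].path[:3]
    assert net.words["network"].path[:3] == shared


def test_rememorizing_a_present_word_adds_no_nodes():
    net = build(["network"])
    before = net.letter_node_count()
    memorize_word(net, "network")
    assert net.letter_node_count() == before


def test_duplicate_symbols_are_distinct_positional_nodes():
    net = build(["netbeans"])
    symbols = [
        n.symbol for n in net.nodes.values() if n.id != ROOT_ID
    ]
    assert sorted(symbols) == sorted("netbeans")  # both e's, both n's distinct


def test_symbol_outside_alphabet_is_rejected_by_name():
    net = IntraNetwork()
    with pytest.raises(ValueError, match="'7'"):
        memorize_word(net, "net7")
    with pytest.raises(ValueError):
        memorize_word(net, "")


@given(
    st.lists(st.text(alphabet="abcde", min_size=1, max_size=8),
             min_size=1, max_size=20, unique=True)
)
def test_node_count_matches_prefix_set_oracle(words):
    """Before any strengthening (first memorization of each word only),
    live nodes = distinct prefixes of the corpus.  Duplicate tokens would
    strengthen and flatten the trie, after which positions can merge."""
    net = build(words)
    assert net.letter_node_count() == len(distinct_prefixes(words))


@given(words_strategy)
def test_forest_property_after_memorization(words):
    net = build(words)
    for node in net.nodes.values():
        if node.id == ROOT_ID:
            assert node.parent is None
        else:
            assert node.parent in net.nodes
            assert net.depth(node.id) <= len(net.nodes)  # reaches root, acyclic
    for node in net.nodes.values():
        for c in node.children:
            assert net.nodes[c].parent == node.id


@given(words_strategy)
def test_memorization_is_monotone_in_node_count(words):
    net = IntraNetwork()
    last = 0
    for w in words:
        memorize_word(net, w)
        assert net.letter_node_count() >= last
        last = net.letter_node_count()


def test_no_decay_below_threshold():
    net = build(["network"])
    before = {n.id for n in net.nodes.values()}
    events = forget_tick(net, ForgetConfig(tau=10 ** 6))
    assert events == []
    assert {n.id for n in net.nodes.values()} == before


def test_disabled_forgetting_is_inert():
    net = build(["network"])
    assert forget_tick(net, ForgetConfig(tau=1, enabled=False)) == []
    assert net.clock == 1  # disabled ticks do not advance time


def test_single_word_decays_leaf_to_root():
    """Hand-simulated decay: one node per expired tick, deepest first."""
    word = "nets"
    net = build([word])
    cfg = ForgetConfig(tau=1)
    all_events = []
    for _ in range(len(word) + cfg.tau + 2):
        all_events.extend(forget_tick(net, cfg))
    assert [e.remaining for e in all_events] == [3, 2, 1, 0]
    assert all(e.removed is not None for e in all_events)
    assert net.letter_node_count() == 0
    assert word not in net.words
    # virtual node vanished with whole forgetting
    assert all(not n.is_virtual for n in net.nodes.values())


def test_shared_prefix_nodes_survive_partner_decay():
    net = build(["netbeans", "network"])
    cfg = ForgetConfig(tau=3)
    first = None
    while "network" in net.words:
        retrieve_word(net, "netbeans")  # keep netbeans fresh
        events = forget_tick(net, cfg)
        if events and first is None:
            first = events[0]
    assert first.word == "network"
    assert first.removed is not None and first.remaining == 6  # only the "k"
    assert "netbeans" in net.words
    assert net.letter_node_count() == 8  # exactly the netbeans positions remain
    assert retrieve_word(net, "netbeans").status == "success"


def test_virtual_nodes_are_childless_leaves():
    net = build(["nets"])
    cfg = ForgetConfig(tau=1)
    for _ in range(3):
        forget_tick(net, cfg)
    virtuals = [n for n in net.nodes.values() if n.is_virtual]
    assert len(virtuals) == 1
    assert virtuals[0].children == []


def test_partially_forgotten_word_is_rebuilt_on_rememorize():
    net = build(["network"])
    cfg = ForgetConfig(tau=1)
    for _ in range(4):
        forget_tick(net, cfg)
    rec = net.words["network"]
    assert rec.forgotten_suffix_len > 0 and rec.virtual_node is not None
    memorize_word(net, "network")
    rec = net.words["network"]
    assert rec.forgotten_suffix_len == 0 and rec.virtual_node is None
    assert [net.nodes[n].symbol for n in rec.path] == list("network")
    assert all(not n.is_virtual for n in net.nodes.values())


def test_full_forget_then_rememorize_restores_isomorphic_subtree():
    word = "beans"
    reference = build([word])
    ref_shape = [reference.nodes[n].symbol for n in reference.words[word].path]
    net = build([word])
    cfg = ForgetConfig(tau=1)
    while word in net.words:
        forget_tick(net, cfg)
    assert net.letter_node_count() == 0
    memorize_word(net, word)
    rec = net.words[word]
    assert [net.nodes[n].symbol for n in rec.path] == ref_shape
    for prev, cur in zip(rec.path, rec.path[1:]):
        assert net.nodes[cur].parent == prev


def test_json_roundtrip_preserves_structure_and_registry():
    net = build(["netbeans", "network", "bean"])
    retrieve_word(net, "network")
    forget_tick(net, ForgetConfig(tau=1000))
    restored = IntraNetwork.from_json(net.to_json())
    assert restored.clock == net.clock
    assert set(restored.words) == set(net.words)
    for nid, node in net.nodes.items():
        other = restored.nodes[nid]
        assert (other.symbol, other.parent, other.is_virtual) == (
            node.symbol, node.parent, node.is_virtual
        )
    assert sorted(restored.edge_list()) == sorted(net.edge_list())


def test_edge_tsv_lists_parent_child_pairs():
    net = build(["net"])
    lines = net.edge_tsv().strip().splitlines()
    assert len(lines) == 3
    assert lines[0].split("\t") == ["0", "1"]
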