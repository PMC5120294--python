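# Methods

## Model

The simulator implements a functional (not biophysical) memory model in
which a memory module is an inverted rooted tree. Each letter node is a
*meta-memory* unit: it stores one symbol, can compare it with a symbol
handed down from its parent, and forwards or rejects accordingly. The
root (`sn`) is symbol-less and is both the entry and the exit of every
memory operation. The model assumes exact, context-free content: it
covers recognition and verbatim spell-out, not semantic, episodic or
weighted (recall-competition) memory, which would need edge weights.

### Memorization

A word is a path of letter nodes. First-time memorization walks child
links from the root for the longest matching prefix and appends the
remaining symbols as a chain at the divergence node; it never rewires, so
a duplicate-free corpus always produces the pristine shared-prefix trie,
and the live node count equals the number of distinct word prefixes (this
is property-tested against a brute-force prefix-set oracle). Re-input of
an already registered word is old content and is handled by the retrieval
algorithm, i.e. it strengthens. Node identity is positional: the two
"e"s of *netbeans* are distinct nodes. Prefix matching is deterministic
because a node never carries two live children with the same symbol;
after retrieval has flattened part of the trie, matching simply follows
the child links at their current positions and new suffixes attach where
the divergence node now sits.

### Strengthening retrieval

The search length of one retrieval is the number of nodes visited from
the root to the target, endpoints inclusive: `depth + 1`. This is the
only counting convention under which the fully strengthened limit is
exactly 2 while the root-to-node geodesic is 1. After a successful
search, the retrieved nodes and every former proper ancestor (snapshotted
before any move, then re-parented in one batch, so the outcome is order
independent) are connected directly to the root; nodes already at depth 1
stay put, and child links of moved nodes are preserved, so whole subtrees
ride upward. This is the path-compression step of the merge–find set,
walked root-to-leaf instead of leaf-to-root. Consequences, all tested:
depths never increase under retrieval; a second retrieval of the same
word costs exactly 2; a single unbranched word is step-for-step
equivalent to MFset finds on an isomorphic chain.

A failed search (absent word) leaves the network untouched and reports
`1 + matched + 1` comparisons — root, matched prefix nodes, and the
failed child probe (the final `+1` is dropped when the walk exhausts the
word without a symbol mismatch). An optional learn-on-fail flag feeds
the miss back into memorization; it is off by default so that retrieval
of absent words is side-effect free.

### Forgetting

`ForgetConfig(tau)` sets the decay threshold in ticks of the logical
clock; the clock counts memorize/retrieve operations and advances by one
per forgetting tick (so forgetting also progresses during retrieval-only
sessions). Each tick, every word with `clock − last_access > tau` loses
its deepest remaining node; a childless virtual node marks the decay
front and climbs one step toward the root per tick. A node shared with
another registered word, or still carrying children, is removed from the
decaying word's record but not deleted. When the last node goes, the
word is unregistered, the virtual node disappears, and re-learning is a
fresh memorization. Virtual nodes never have children, never match in
prefix walks, never enter comparison counts, and are excluded from graph
metrics and the edge-list serialization. The default `tau = 1000` is an
arbitrary but configurable scale — the model has no physical time unit,
and the threshold's empirical calibration is explicitly open.

### Bi-modular composition

Regions are super-nodes owning independent modules; the region count is
capped (with a warning, not an error) at 90, the AAL cortical
parcellation size. The ring and the complete graph are the two extreme
connected topologies; arbitrary connected edge lists are accepted and
routed by breadth-first shortest path. Ring traversal is unidirectional
in ascending region index — the reading under which the 90-region worst
case is 90 rather than ⌈R/2⌉. Inter-modular search length mirrors the
intra convention (super-nodes visited, endpoints inclusive), so the
complete-graph cost for distinct regions is exactly 2 and the same-region
cost is 1. Total retrieval cost is the sum `cost(sn) + cost(n)`. Words
are routed by first letter; the four-region default uses the groups
a–e, f–l, m–q, r–z, other region counts split the alphabet contiguously
and near-evenly.

## Baseline: merge–find set

The MFset implements union by size (smaller root under larger; on ties
the second argument's root attaches under the first — fixed for
determinism) and find with full path compression, counting nodes visited
leaf-to-root inclusive. For the curve comparison a corpus is encoded
once: elements are the distinct trie positions (word prefixes), and each
word's successive positions are merged in order. The encoding is
plumbing chosen to make the two curves structurally comparable — under
union by size it collapses each first-letter group into a depth-1 star,
so the baseline's search length sits at ≈2 from the first find, below
the strengthening retrieval until compression catches up. Small-instance
correctness is checked exhaustively (≤ 8 elements) against an independent
re-parent simulation, and the pre-compression height bound
⌊log₂ n⌋ + 1 is property-tested. No asymptotic claim about inverse-
Ackermann growth is implemented; only empirical counts are produced.

## Metrics

Average search length (ASL) curves are produced by a fixed schedule:
memorize every token in order (repeats strengthen), then retrieve each
distinct word round-robin, one pass per round. The default curve is the
running mean over completed retrievals; the instantaneous mode reports
the per-step count and is used for exact limit checks. Any intra-modular
point is ≥ 2 and ≤ max word length + 1; the instantaneous curve reaches
exactly 2 no later than the second pass absent forgetting. Average path
length, clustering and degree histograms are computed with networkx on
the undirected live-node graph; APL treats edges as undirected and
averages over all unordered pairs, with a `from_root` variant averaging
root-to-node distances only. The standard local clustering coefficient
is used (0 on any tree); a fully strengthened module is a star, whose
APL `2m/(m+1)` approaches 2 from below.

## Synthetic corpora and determinism

The generator draws `vocab_size` distinct words (uniform lengths within a
configurable range, uniform letters) and `n_tokens` tokens with
rank-frequency `∝ rank^(−s)`; `s = 0` is uniform, `s = 1` the classic
natural-language profile (checked by a chi-square sanity test). It
emulates the repetition and length statistics of text, but not real
orthography: prefix overlap between synthetic words is far rarer than in
English, so synthetic corpora exercise the deep-chain regime while
natural paragraphs exercise prefix sharing — the bundled ~160-token
public-domain paragraph covers the latter. Everything downstream of a
`(config, seed)` pair is deterministic, byte-identical across reruns;
experiments at the default scale (≈160 tokens, 106 distinct words,
20 retrieval passes) complete in well under a second.

## Known limitations

- Edge weights, semantic association, and free/cued recall are out of
  scope; recognition and spell-out are the supported retrieval modes.
- The running-mean ASL converges to 2 only as O(1/passes): pass one pays
  the full trie depths (≈ mean word length + 1 on natural text), so on a
  ~150-word English paragraph the running mean is still ≈ 2.19 after 20
  passes even though the instantaneous value is exactly 2 from pass two
  onward.
- The forgetting threshold is a free parameter with no empirical
  calibration; decay order among simultaneously expired words follows
  registration order.
- Region routing models cost only; regions carry no content semantics
  beyond the first-letter assignment.
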