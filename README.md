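# smirn

A simulator for a simplified memory information retrieval network (SMIRN):
a computational model of word memory built from information-processing
primitives rather than biophysics. Memory content lives in an inverted
tree of *meta-memory* nodes — one symbol per node — hanging under a single
root (the super node `sn`, the sole input/output point of a module).
The package is aimed at people studying memory models from the
complex-networks side: it lets you memorize corpora, replay strengthening
retrieval, decay words by forgetting, compose modules into a bi-modular
region network, and measure the resulting network statistics.

The three memory operations map onto tree operations:

- **Memorization** — a word `w = s1 s2 … sL` is stored as a path of letter
  nodes; the longest existing trie prefix is reused, the remaining suffix
  is appended as new nodes, so `netbeans` and `network` share `n-e-t`.
- **Strengthening** — retrieving a node at depth *d* costs
  `ASL = d + 1` comparisons (nodes visited from the root, endpoints
  inclusive); the retrieved nodes and their former ancestors are then
  re-parented directly under the root, exactly the path-compression step
  of a merge–find set (MFset). Repeated retrieval drives the search
  length to its limit of **2**.
- **Forgetting** — a word untouched longer than a threshold τ loses its
  deepest node per tick to a childless *virtual node* that climbs toward
  the root; shared prefix nodes survive as long as another word needs them.

Modules compose into a bi-modular hierarchy: up to 90 region super-nodes
(the AAL cortical parcellation bound) wired as a ring or a complete graph,
the two extreme connected topologies. The total retrieval cost is
`cost(sn) + cost(n)`: super-nodes visited between entry and target region,
plus the in-region search. On the unidirectional ring of 90 regions the
worst case is 90; on the complete graph every distinct pair costs 2. In a
fully strengthened module every root-to-node geodesic is 1 and every
node-to-node geodesic is 2, so the average path length of an *m*-node
module is `2m/(m+1) < 2` — the small-world regime.

An instrumented MFset (union by size + path compression) serves as the
efficiency baseline: the same corpus is encoded as trie positions merged
per word, and finds are replayed on the identical schedule.

## Worked example

```python
from smirn import IntraNetwork, memorize_word, retrieve_word

net = IntraNetwork()
memorize_word(net, "netbeans")
print(retrieve_word(net, "netbeans").comparisons)   # 9  (depth 8 + 1)
print(retrieve_word(net, "netbeans").comparisons)   # 2  (path compressed)
```

End to end, on the bundled ~160-token public-domain paragraph:

```python
from smirn.experiment import ExperimentConfig, run_experiment
result = run_experiment(ExperimentConfig(passes=20), outdir="smirn-run")
print(result.summary["final_asl"])
```

prints

```
{'smirn1': 2.1929245283018868, 'smirn1b': 3.1929245283018868,
 'smirn4': 4.353301886792453, 'mfset': 1.990566037735849}
```

`smirn1` is the running-mean search length of the single module after 20
round-robin passes over its 106 distinct words: pass one pays the full trie
depths (mean ≈ 5.86), every later pass costs exactly 2, so the running mean
decays toward the limit 2. `smirn1b` adds the one super-node hop of a
single-region bi-modular wrapper (+1); `smirn4` routes words over a
four-region ring binned by first letter (a–e, f–l, m–q, r–z). The `mfset`
baseline sits just below 2 from the start — union by size keeps its trees
at depth 1, which is why the baseline is cheaper than the strengthening
retrieval especially in the beginning, before compression has flattened
the memory network.

The same runs are available from the shell:

```sh
smirn simulate --passes 20 --outdir smirn-run        # curves.csv, network.json, ...
smirn build corpus.txt -o net.json --edges net.tsv
smirn retrieve net.json network
smirn compare-mfset corpus.txt --passes 5 -o curves.csv
smirn generate-corpus --vocab-size 100 --n-tokens 500 --zipf-s 1.0 --seed 7
```

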