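"""End-to-end experiment runner.

One invocation reproduces the full retrieval-efficiency comparison on a
corpus: the single-module run, the same module behind one super node, the
four-region ring, and the merge-find-set baseline, all on an identical
memorize-then-round-robin schedule.  Every artifact is a plain-text file
and every run is fully determined by (config, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

from .corpus import CorpusSpec, default_corpus, generate_corpus
from .inter import build_inter
from .intra import IntraNetwork, memorize_word, tokenize
from .metrics import asl_experiment, network_summary
from .mfset import mfset_asl_curve

#: Fig-6-style run identifiers: module count in parentheses, ``1b`` the
#: single module wrapped in a one-region bi-modular network.
VARIANTS = ("smirn1", "smirn1b", "smirn4")


@dataclass
class ExperimentConfig:
    corpus_path: Optional[Union[str, Path]] = None
    corpus_spec: Optional[CorpusSpec] = None
    variants: tuple[str, ...] = VARIANTS
    passes: int = 20
    mode: str = "running_mean"
    entry: int = 0
    seed: int = 0

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "ExperimentConfig":
        doc = json.loads(Path(path).read_text())
        spec = doc.get("corpus_spec")
        return cls(
            corpus_path=doc.get("corpus_path"),
            corpus_spec=CorpusSpec(**spec) if spec else None,
            variants=tuple(doc.get("variants", VARIANTS)),
            passes=doc.get("passes", 20),
            mode=doc.get("mode", "running_mean"),
            entry=doc.get("entry", 0),
            seed=doc.get("seed", 0),
        )


@dataclass
class ExperimentResult:
    corpus: list[str]
    curves: dict[str, list[tuple[int, float]]]
    summary: dict
    op_log: list = field(default_factory=list)


def _load_corpus(config: ExperimentConfig) -> list[str]:
    if config.corpus_path is not None:
        path = Path(config.corpus_path)
        if not path.exists():
            raise FileNotFoundError(f"corpus file not found: {path}")
        return tokenize(path.read_text())
    if config.corpus_spec is not None:
        spec = config.corpus_spec
        if config.seed and spec.seed == 0:
            spec = CorpusSpec(
                vocab_size=spec.vocab_size, n_tokens=spec.n_tokens,
                word_length=spec.word_length, alphabet=spec.alphabet,
                zipf_s=spec.zipf_s, seed=config.seed,
            )
        return generate_corpus(spec)
    return default_corpus()


def _make_model(variant: str, entry: int):
    if variant == "smirn1":
        return IntraNetwork()
    if variant == "smirn1b":
        return build_inter(1, topology="ring", entry=0)
    if variant == "smirn4":
        return build_inter(4, topology="ring", entry=entry)
    raise ValueError(f"unknown variant {variant!r}")


def run_experiment(
    config: ExperimentConfig, outdir: Optional[Union[str, Path]] = None
) -> ExperimentResult:
    """Run the configured variants plus the MFset baseline on one corpus.

    When ``outdir`` is given, writes ``curves.csv`` (step,asl,mode,run_id),
    ``network.json`` and ``edges.tsv`` for the memorization-only network,
    ``summary.json`` with graph statistics, and ``ops.csv``, the operation
    log of the single-module run.
    """
    corpus = _load_corpus(config)
    if not corpus:
        raise ValueError("corpus is empty after tokenization")

    curves: dict[str, list[tuple[int, float]]] = {}
    op_log: list = []
    for variant in config.variants:
        model = _make_model(variant, config.entry)
        log = op_log if variant == "smirn1" else None
        curve = asl_experiment(
            model, corpus, config.passes, config.mode, op_log=log
        )
        curves[variant] = curve.points
    curves["mfset"] = mfset_asl_curve(corpus, config.passes, config.mode)

    # memorization-only network for the structural artifact
    built = IntraNetwork()
    for word in corpus:
        memorize_word(built, word)
    summary_obj = network_summary(built)
    summary = {
        "tokens": len(corpus),
        "distinct_words": len(set(corpus)),
        "node_count": summary_obj.node_count,
        "edge_count": summary_obj.edge_count,
        "apl": summary_obj.apl,
        "clustering": summary_obj.clustering,
        "degree_histogram": {
            str(k): v for k, v in sorted(summary_obj.degree_histogram.items())
        },
        "final_asl": {name: pts[-1][1] for name, pts in curves.items()},
        "passes": config.passes,
        "mode": config.mode,
        "seed": config.seed,
    }

    result = ExperimentResult(corpus, curves, summary, op_log)
    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        lines = ["step,asl,mode,run_id"]
        for name in sorted(curves):
            lines += [
                f"{s},{v:.6f},{config.mode},{name}" for s, v in curves[name]
            ]
        (out / "curves.csv").write_text("\n".join(lines) + "\n")
        (out / "network.json").write_text(built.to_json())
        (out / "edges.tsv").write_text(built.edge_tsv())
        (out / "summary.json").write_text(json.dumps(summary, indent=2))
        ops = ["step,op,word,status,comparisons,rewired"]
        ops += [",".join(str(x) for x in row) for row in op_log]
        (out / "ops.csv").write_text("\n".join(ops) + "\n")
    return result


def plot_curves(result: ExperimentResult, path: Union[str, Path]) -> None:
    """Optional curve figure (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    for name, pts in sorted(result.curves.items()):
        steps, values = zip(*pts)
        ax.plot(steps, values, label=name)
    ax.axhline(2.0, color="grey", ls=":", lw=0.8)
    ax.set_xlabel("retrieval step")
    ax.set_ylabel("average search length")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
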