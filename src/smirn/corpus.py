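"""Corpora: a bundled default paragraph and a seeded synthetic generator.

The memorization experiments need nothing more than a paragraph of ordinary
English; any text of comparable size reproduces the qualitative curves and
the exact limiting values.  The bundled default is the closing paragraph of
Darwin's *On the Origin of Species* (1859, public domain), about 160 words.

The synthetic generator draws a vocabulary of distinct random words and a
token stream whose rank frequencies follow a Zipf law with configurable
exponent, emulating the repetition structure of natural text.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np

from .intra import tokenize

DEFAULT_PARAGRAPH = (
    "It is interesting to contemplate an entangled bank, clothed with many "
    "plants of many kinds, with birds singing on the bushes, with various "
    "insects flitting about, and with worms crawling through the damp "
    "earth, and to reflect that these elaborately constructed forms, so "
    "different from each other, and dependent on each other in so complex "
    "a manner, have all been produced by laws acting around us. These "
    "laws, taken in the largest sense, being Growth with Reproduction; "
    "Inheritance which is almost implied by reproduction; Variability from "
    "the indirect and direct action of the external conditions of life, "
    "and from use and disuse; a Ratio of Increase so high as to lead to a "
    "Struggle for Life, and as a consequence to Natural Selection, "
    "entailing Divergence of Character and the Extinction of less-improved "
    "forms. Thus, from the war of nature, from famine and death, the most "
    "exalted object which we are capable of conceiving, namely, the "
    "production of the higher animals, directly follows."
)


def default_corpus() -> list[str]:
    """The bundled paragraph as a token list."""
    return tokenize(DEFAULT_PARAGRAPH)


@dataclass
class CorpusSpec:
    """Parameters of a synthetic corpus.

    ``word_length`` is either a fixed length or an inclusive
    ``(min, max)`` range sampled uniformly.  ``zipf_s`` is the Zipf
    exponent of the token-frequency skew: 0 gives uniform sampling, 1 the
    classic harmonic profile of natural language.  Identical (spec, seed)
    pairs generate identical corpora.
    """

    vocab_size: int
    n_tokens: int
    word_length: Union[int, tuple[int, int]] = (2, 9)
    alphabet: str = "abcdefghijklmnopqrstuvwxyz"
    zipf_s: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.vocab_size < 1:
            raise ValueError("vocab_size must be >= 1")
        if self.n_tokens < 0:
            raise ValueError("n_tokens must be >= 0")
        if self.zipf_s < 0:
            raise ValueError("zipf_s must be >= 0")

    @property
    def length_range(self) -> tuple[int, int]:
        if isinstance(self.word_length, int):
            return (self.word_length, self.word_length)
        lo, hi = self.word_length
        if lo < 1 or hi < lo:
            raise ValueError(f"bad word length range {self.word_length}")
        return (lo, hi)


def _possible_words(spec: CorpusSpec) -> int:
    lo, hi = spec.length_range
    a = len(set(spec.alphabet))
    return sum(a ** length for length in range(lo, hi + 1))


def generate_corpus(spec: CorpusSpec) -> list[str]:
    """Draw a vocabulary without replacement, then a Zipf token stream."""
    possible = _possible_words(spec)
    if spec.vocab_size > possible:
        raise ValueError(
            f"vocab_size {spec.vocab_size} exceeds the {possible} distinct "
            f"words available for this alphabet and length range"
        )
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.length_range
    letters = sorted(set(spec.alphabet))
    vocab: list[str] = []
    seen: set[str] = set()
    while len(vocab) < spec.vocab_size:
        length = int(rng.integers(lo, hi + 1))
        word = "".join(rng.choice(letters, size=length))
        if word not in seen:
            seen.add(word)
            vocab.append(word)
    ranks = np.arange(1, spec.vocab_size + 1, dtype=float)
    probs = ranks ** -spec.zipf_s
    probs /= probs.sum()
    idx = rng.choice(spec.vocab_size, size=spec.n_tokens, p=probs)
    return [vocab[i] for i in idx]
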