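"""SMILES tokenization, vocabulary induction and sequence encoding.

Token classes, chosen as the minimal set that preserves round-trip fidelity:
bracket atoms ``[...]`` as one token, two-letter organic-subset halogens
``Cl``/``Br``, ``%NN`` ring closures, and single characters otherwise.
Three special tokens (START, END, PAD) occupy reserved indices 0, 1, 2.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable

START, END, PAD = "<start>", "<end>", "<pad>"
SPECIALS = (START, END, PAD)

_TOKEN_RE = re.compile(r"(\[[^\]]*\]|Cl|Br|%\d\d|.)")


class TokenizationError(ValueError):
    pass


def tokenize(smiles: str) -> list[str]:
    """Split a SMILES string into tokens; concatenation reproduces the input.

    Raises TokenizationError on a dangling ``[`` or ``%`` (no well-formed
    bracket atom / two-digit ring closure to consume).
    """
    tokens = _TOKEN_RE.findall(smiles)
    for t in tokens:
        if t == "[" or t == "%":
            raise TokenizationError(f"dangling {t!r} in {smiles!r}")
    assert "".join(tokens) == smiles
    return tokens


@dataclass(frozen=True)
class Vocabulary:
    """Bijection between token strings and integer indices; specials first."""

    tokens: tuple[str, ...]
    index_of: dict[str, int] = field(default_factory=dict, compare=False)

    def __post_init__(self):
        object.__setattr__(self, "index_of", {t: i for i, t in enumerate(self.tokens)})
        if self.tokens[:3] != SPECIALS:
            raise ValueError("first three tokens must be the specials")
        if len(self.index_of) != len(self.tokens):
            raise ValueError("duplicate tokens in vocabulary")

    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def start_index(self) -> int:
        return 0

    @property
    def end_index(self) -> int:
        return 1

    @property
    def pad_index(self) -> int:
        return 2

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for t in self.tokens:
                fh.write(t + "\n")

    @classmethod
    def load(cls, path) -> "Vocabulary":
        with open(path, encoding="utf-8") as fh:
            tokens = tuple(line.rstrip("\n") for line in fh if line.rstrip("\n"))
        return cls(tokens)


def build_vocabulary(corpus: Iterable[str]) -> Vocabulary:
    """Sorted set of all tokens observed in the corpus, after the specials."""
    seen: set[str] = set()
    n = 0
    for smiles in corpus:
        seen.update(tokenize(smiles))
        n += 1
    if n == 0:
        raise ValueError("empty corpus")
    return Vocabulary(SPECIALS + tuple(sorted(seen)))


class OutOfVocabularyError(KeyError):
    def __init__(self, token: str):
        super().__init__(token)
        self.token = token

    def __str__(self):
        return f"token {self.token!r} not in vocabulary"


def encode(smiles: str, vocab: Vocabulary) -> list[int]:
    """START + token indices + END; names the offending token if unknown."""
    indices = [vocab.start_index]
    for t in tokenize(smiles):
        try:
            indices.append(vocab.index_of[t])
        except KeyError:
            raise OutOfVocabularyError(t) from None
    indices.append(vocab.end_index)
    return indices


def decode(indices: Iterable[int], vocab: Vocabulary) -> str:
    """Inverse of :func:`encode`; specials are dropped."""
    out = []
    for i in indices:
        t = vocab.tokens[i]
        if t not in SPECIALS:
            out.append(t)
    return "".join(out)
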