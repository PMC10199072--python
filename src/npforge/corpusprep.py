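"""Training-corpus preparation: filter, split 72/8/20, augment.

The held-out fraction is 20% and the validation fraction 8% of the filtered
corpus (rounded to the nearest integer); training takes the remainder.  With
406,919 molecules this rule yields 292,981 / 32,554 / 81,384, the partition
used to train the full-scale model.  Augmentation replaces each training and
validation molecule by ``factor`` randomized non-canonical writings of its
graph; the held-out partition is never augmented.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from rdkit import Chem

from .chemio import parse_and_validate, strip_stereochemistry

log = logging.getLogger(__name__)

HELDOUT_FRACTION = 0.20
VALIDATION_FRACTION = 0.08


@dataclass(frozen=True)
class CorpusSplit:
    train: list[str]
    validation: list[str]
    heldout: list[str]
    seed: int

    @property
    def n(self) -> int:
        return len(self.train) + len(self.validation) + len(self.heldout)


def prepare_corpus(raw: list[str]) -> list[str]:
    """Valid, stereo-stripped, canonically deduplicated SMILES.

    First-occurrence order is preserved; removal counts are logged.
    """
    seen: set[str] = set()
    out: list[str] = []
    n_invalid = n_dup = 0
    for s in raw:
        if not parse_and_validate(s).is_valid:
            n_invalid += 1
            continue
        canon = strip_stereochemistry(s)
        if canon in seen:
            n_dup += 1
            continue
        seen.add(canon)
        out.append(canon)
    log.info(
        "prepare_corpus: %d in, %d invalid, %d duplicates, %d out",
        len(raw), n_invalid, n_dup, len(out),
    )
    return out


def partition_sizes(n: int) -> tuple[int, int, int]:
    """(train, validation, heldout) sizes under the rounding rule."""
    n_heldout = round(HELDOUT_FRACTION * n)
    n_validation = round(VALIDATION_FRACTION * n)
    return n - n_heldout - n_validation, n_validation, n_heldout


def split_corpus(corpus: list[str], seed: int) -> CorpusSplit:
    """Seeded uniform shuffle, then partition into train/validation/heldout."""
    if len(corpus) < 3:
        raise ValueError("corpus must contain at least 3 entries")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(corpus))
    shuffled = [corpus[i] for i in order]
    n_train, n_validation, n_heldout = partition_sizes(len(corpus))
    return CorpusSplit(
        train=shuffled[:n_train],
        validation=shuffled[n_train:n_train + n_validation],
        heldout=shuffled[n_train + n_validation:],
        seed=seed,
    )


def enumerate_smiles(smiles: str, k: int, seed: int) -> list[str]:
    """``k`` randomized writings of the molecule (duplicates permitted).

    Each writing is produced by renumbering the atoms with a uniformly random
    permutation and writing non-canonical SMILES from that ordering; every
    output canonicalizes to the canonical form of the input.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    rng = np.random.default_rng(seed)
    n_atoms = mol.GetNumAtoms()
    out = []
    for _ in range(k):
        perm = [int(i) for i in rng.permutation(n_atoms)]
        shuffled = Chem.RenumberAtoms(mol, perm)
        out.append(Chem.MolToSmiles(shuffled, canonical=False))
    return out


def augment_corpus(
    split: CorpusSplit, factor: int, seed: int
) -> tuple[list[str], list[str]]:
    """Replace each train/validation molecule by ``factor`` random writings.

    The held-out partition is untouched; augmentation happens after splitting
    so no molecule's writings leak across partitions.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    rng = np.random.default_rng(seed)

    def _augment(part: list[str]) -> list[str]:
        out: list[str] = []
        for s in part:
            out.extend(enumerate_smiles(s, factor, int(rng.integers(0, 2**31 - 1))))
        return out

    return _augment(split.train), _augment(split.validation)
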