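"""Natural-product-likeness scoring from atom-centred fragments.

A molecule's NP score is the per-heavy-atom mean of fragment contributions,
where each heavy atom contributes the log10 ratio of its circular
environment's prevalence in a natural-product corpus versus a reference
(synthetic/druglike) corpus, with Laplace (+1) smoothing.  Raw scores beyond
±4 are tail-compressed logarithmically so the score lives in roughly [-5, 5].
Circular Morgan environments of radius 2 serve as the atom-centred fragments;
their identifiers are invariant under atom renumbering, so the score does not
depend on how the SMILES was written.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from collections import Counter

from rdkit import Chem
from rdkit.Chem import rdMolDescriptors

DEFAULT_RADIUS = 2


@dataclass(frozen=True)
class FragmentScoreTable:
    contribution: dict[int, float]
    fragment_radius: int
    n_np_molecules: int
    n_ref_molecules: int

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump({
                "fragment_radius": self.fragment_radius,
                "n_np_molecules": self.n_np_molecules,
                "n_ref_molecules": self.n_ref_molecules,
                "contribution": {str(k): v for k, v in self.contribution.items()},
            }, fh)

    @classmethod
    def load(cls, path) -> "FragmentScoreTable":
        with open(path, encoding="utf-8") as fh:
            d = json.load(fh)
        return cls({int(k): v for k, v in d["contribution"].items()},
                   d["fragment_radius"], d["n_np_molecules"], d["n_ref_molecules"])


def _as_mol(molecule):
    if isinstance(molecule, str):
        mol = Chem.MolFromSmiles(molecule)
        if mol is None:
            raise ValueError(f"unparseable SMILES: {molecule!r}")
        return mol
    return molecule


def fragment_molecule(molecule, radius: int = DEFAULT_RADIUS) -> list[int]:
    """One fragment identifier per heavy atom: the atom's circular
    environment out to ``radius`` bonds (smaller when the molecule is).

    The multiset is invariant under atom renumbering.
    """
    mol = _as_mol(molecule)
    bit_info: dict[int, tuple] = {}
    rdMolDescriptors.GetMorganFingerprint(mol, radius, bitInfo=bit_info)
    best: dict[int, tuple[int, int]] = {}  # atom -> (radius, fragment id)
    for frag_id, hits in bit_info.items():
        for atom_idx, r in hits:
            if atom_idx not in best or r > best[atom_idx][0]:
                best[atom_idx] = (r, frag_id)
    return [best[a][1] for a in sorted(best)]


def train_score_table(np_corpus, ref_corpus,
                      radius: int = DEFAULT_RADIUS) -> FragmentScoreTable:
    """Per-fragment log10 prevalence ratios with Laplace smoothing.

    contribution(f) = log10( ((n_f^NP + 1)/(N_NP + 1)) /
                             ((n_f^ref + 1)/(N_ref + 1)) )
    where n_f counts *molecules* containing fragment f.  Swapping the two
    corpora negates every contribution.
    """
    if not np_corpus or not ref_corpus:
        raise ValueError("empty corpus")
    np_counts: Counter = Counter()
    ref_counts: Counter = Counter()
    for mol in np_corpus:
        np_counts.update(set(fragment_molecule(mol, radius)))
    for mol in ref_corpus:
        ref_counts.update(set(fragment_molecule(mol, radius)))
    n_np, n_ref = len(np_corpus), len(ref_corpus)
    contribution = {}
    for f in set(np_counts) | set(ref_counts):
        p_np = (np_counts.get(f, 0) + 1) / (n_np + 1)
        p_ref = (ref_counts.get(f, 0) + 1) / (n_ref + 1)
        contribution[f] = math.log10(p_np / p_ref)
    return FragmentScoreTable(contribution, radius, n_np, n_ref)


def compress_tails(raw: float) -> float:
    """Logarithmic compression of |raw| > 4 into roughly [-5, 5]."""
    if raw > 4:
        return 4 + math.log10(raw - 4 + 1)
    if raw < -4:
        return -(4 + math.log10(-raw - 4 + 1))
    return raw


def score_fragments(fragments, table_contribution: dict, n_heavy_atoms: int) -> float:
    """Raw-sum-over-atoms scoring core (unseen fragments contribute 0)."""
    if n_heavy_atoms == 0:
        raise ValueError("molecule has no heavy atoms")
    raw = sum(table_contribution.get(f, 0.0) for f in fragments) / n_heavy_atoms
    return compress_tails(raw)


def np_score(molecule, table: FragmentScoreTable) -> float:
    """Natural-product-likeness score of a molecule under a trained table."""
    mol = _as_mol(molecule)
    frags = fragment_molecule(mol, table.fragment_radius)
    return score_fragments(frags, table.contribution, mol.GetNumHeavyAtoms())
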