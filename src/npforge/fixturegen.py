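"""Deterministic synthetic SMILES corpora with known ground truth.

Molecules are assembled by bonding 2-4 curated building blocks (a
natural-product-flavoured pool of sugars, phenols, lactones and polyketide
chains, or a druglike pool of aryl amides, sulfonamides and heteroaryls), so
every uncorrupted fixture is chemically valid by construction.  Corruption
operators each target one curation filter — unparseable strings, duplicate
rewrites, salts, isotopes, charges, stereo marks, and severe valence
problems — and the generated manifest records exactly which corruption was
applied where.  The manifest is the oracle for curation tests: the curation
summary's removal counts must equal the planted counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from rdkit import Chem

from .chemio import canonicalize
from .corpusprep import enumerate_smiles

CORRUPTIONS = (
    "syntactic_break", "duplicate_rewrite", "add_salt", "add_isotope",
    "add_charge", "add_stereo", "severe_valence",
)

#: corruptions that leave the molecule's post-curation parent intact
_COSMETIC = {"add_salt", "add_isotope", "add_charge", "add_stereo"}


@dataclass(frozen=True)
class FixtureSpec:
    n_molecules: int
    seed: int
    fragment_pool: str = "np_like"  # or "druglike"
    corruption_plan: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        unknown = set(self.corruption_plan) - set(CORRUPTIONS)
        if unknown:
            raise ValueError(f"unknown corruption(s): {sorted(unknown)}")
        if sum(self.corruption_plan.values()) > self.n_molecules:
            raise ValueError("corruption counts exceed n_molecules")


class CorruptionInapplicable(ValueError):
    """The requested corruption has no applicable site on this molecule."""


def load_pool(name: str) -> list[str]:
    text = resources.files("npforge.data").joinpath(f"pool_{name}.smi").read_text()
    blocks = []
    for line in text.splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            blocks.append(line.split("\t")[0])
    return blocks


def _free_valence_atoms(mol) -> list[int]:
    return [a.GetIdx() for a in mol.GetAtoms() if a.GetTotalNumHs() > 0]


def _join_blocks(mols, rng) -> Chem.Mol | None:
    """Bond the blocks into one molecule with random single bonds."""
    combined = mols[0]
    for block in mols[1:]:
        for _attempt in range(8):
            a_sites = _free_valence_atoms(combined)
            b_sites = _free_valence_atoms(block)
            if not a_sites or not b_sites:
                return None
            a = int(rng.choice(a_sites))
            b = int(rng.choice(b_sites))
            merged = Chem.RWMol(Chem.CombineMols(combined, block))
            merged.AddBond(a, combined.GetNumAtoms() + b, Chem.BondType.SINGLE)
            try:
                candidate = merged.GetMol()
                Chem.SanitizeMol(candidate)
            except Exception:
                continue
            combined = candidate
            break
        else:
            return None
    return combined


def make_molecule(pool_blocks: list[str], rng: np.random.Generator) -> str | None:
    """One assembled molecule (canonical SMILES) or None if assembly failed."""
    n_blocks = int(rng.integers(2, 5))
    picks = [Chem.MolFromSmiles(pool_blocks[int(i)])
             for i in rng.integers(0, len(pool_blocks), n_blocks)]
    mol = _join_blocks(picks, rng)
    if mol is None:
        return None
    Chem.RemoveStereochemistry(mol)
    return Chem.MolToSmiles(mol)


# ---------------------------------------------------------------------------
# corruption operators

def _break_syntax(smiles: str, rng) -> str:
    positions = [i for i, ch in enumerate(smiles) if ch.isdigit() or ch in "()"]
    rng.shuffle(positions)
    for i in positions:
        broken = smiles[:i] + smiles[i + 1:]
        if Chem.MolFromSmiles(broken) is None:
            return broken
    return smiles + "("  # unbalanced parenthesis never parses


def _rewrite(smiles: str, rng) -> str:
    for _ in range(20):
        alt = enumerate_smiles(smiles, 1, int(rng.integers(0, 2**31 - 1)))[0]
        if alt != smiles:
            return alt
    return smiles  # highly symmetric molecule: identical writing is still a duplicate


def _add_salt(smiles: str, rng) -> str:
    return smiles + ("." + str(rng.choice([ "[Na+]", "[Cl-]", "[K+]" ])))


def _add_isotope(smiles: str, rng) -> str:
    mol = Chem.RWMol(Chem.MolFromSmiles(smiles))
    carbons = [a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() == 6]
    if not carbons:
        raise CorruptionInapplicable("no carbon to label")
    mol.GetAtomWithIdx(int(rng.choice(carbons))).SetIsotope(13)
    return Chem.MolToSmiles(mol)


def _add_charge(smiles: str, rng) -> str:
    mol = Chem.RWMol(Chem.MolFromSmiles(smiles))
    hydroxyls = [a.GetIdx() for a in mol.GetAtoms()
                 if a.GetAtomicNum() == 8 and a.GetTotalNumHs() >= 1
                 and a.GetFormalCharge() == 0]
    if hydroxyls:
        atom = mol.GetAtomWithIdx(int(rng.choice(hydroxyls)))
        atom.SetFormalCharge(-1)
        atom.SetNoImplicit(False)
        atom.SetNumExplicitHs(0)
        Chem.SanitizeMol(mol)
        return Chem.MolToSmiles(mol)
    amines = [a.GetIdx() for a in mol.GetAtoms()
              if a.GetAtomicNum() == 7 and not a.GetIsAromatic()
              and a.GetTotalNumHs() >= 1 and a.GetFormalCharge() == 0]
    if amines:
        atom = mol.GetAtomWithIdx(int(rng.choice(amines)))
        atom.SetFormalCharge(1)
        atom.SetNumExplicitHs(atom.GetTotalNumHs() + 1)
        Chem.SanitizeMol(mol)
        return Chem.MolToSmiles(mol)
    raise CorruptionInapplicable("no (de)protonatable site")


def _add_stereo(smiles: str, rng) -> str:
    mol = Chem.MolFromSmiles(smiles)
    centres = [e for e in Chem.FindPotentialStereo(mol)
               if e.type == Chem.StereoType.Atom_Tetrahedral]
    if not centres:
        raise CorruptionInapplicable("no prochiral centre")
    idx = int(centres[int(rng.integers(0, len(centres)))].centeredOn)
    mol.GetAtomWithIdx(idx).SetChiralTag(Chem.ChiralType.CHI_TETRAHEDRAL_CW)
    out = Chem.MolToSmiles(mol)
    if "@" not in out:
        raise CorruptionInapplicable("stereo mark did not survive writing")
    return out


def _severe_valence(smiles: str, rng) -> str:
    mol = Chem.RWMol(Chem.MolFromSmiles(smiles))
    sites = [a.GetIdx() for a in mol.GetAtoms()
             if a.GetAtomicNum() == 6 and not a.GetIsAromatic()
             and a.GetTotalNumHs() >= 1]
    if not sites:
        raise CorruptionInapplicable("no aliphatic C-H to unfill")
    atom = mol.GetAtomWithIdx(int(rng.choice(sites)))
    atom.SetNumExplicitHs(atom.GetTotalNumHs() - 1)
    atom.SetNumRadicalElectrons(1)
    atom.SetNoImplicit(True)
    Chem.SanitizeMol(mol)
    return Chem.MolToSmiles(mol)


_CORRUPT_FN = {
    "syntactic_break": _break_syntax,
    "duplicate_rewrite": _rewrite,
    "add_salt": _add_salt,
    "add_isotope": _add_isotope,
    "add_charge": _add_charge,
    "add_stereo": _add_stereo,
    "severe_valence": _severe_valence,
}


def corrupt(smiles: str, corruption: str, seed: int) -> str:
    """Apply one named corruption; raises CorruptionInapplicable if the
    molecule lacks the required site so a planner can retry elsewhere."""
    if corruption not in _CORRUPT_FN:
        raise ValueError(f"unknown corruption {corruption!r}")
    if Chem.MolFromSmiles(smiles) is None:
        raise ValueError(f"corrupt() requires a valid SMILES, got {smiles!r}")
    return _CORRUPT_FN[corruption](smiles, np.random.default_rng(seed))


# ---------------------------------------------------------------------------
# corpus generation

def generate_corpus(spec: FixtureSpec) -> tuple[list[str], dict]:
    """Seeded fixture corpus plus its ground-truth manifest.

    The returned list has exactly ``spec.n_molecules`` entries.  Duplicate
    rewrites are extra writings of clean molecules already in the corpus;
    all other corruptions modify distinct molecules in place.  The manifest
    maps each index to its corruption (or None) and base canonical SMILES,
    and carries the planted counts a curation run must reproduce.
    """
    rng = np.random.default_rng(spec.seed)
    blocks = load_pool(spec.fragment_pool)
    plan = dict(spec.corruption_plan)
    n_dup = plan.pop("duplicate_rewrite", 0)
    n_base = spec.n_molecules - n_dup

    # unique base molecules
    bases: list[str] = []
    seen: set[str] = set()
    attempts = 0
    while len(bases) < n_base:
        attempts += 1
        if attempts > 50 * n_base:
            raise RuntimeError("fixture assembly failed to converge")
        smi = make_molecule(blocks, rng)
        if smi and smi not in seen:
            seen.add(smi)
            bases.append(smi)

    # assign one corruption per distinct base molecule, retrying when a
    # corruption has no applicable site on the drawn molecule
    roles: dict[int, str] = {}
    unassigned = list(range(n_base))
    rng.shuffle(unassigned)
    entries = [{"smiles": s, "corruption": None, "base_canonical": s} for s in bases]
    for name, count in plan.items():
        placed = 0
        while placed < count:
            if not unassigned:
                raise ValueError(f"infeasible corruption plan at {name!r}")
            i = unassigned.pop()
            try:
                corrupted = _CORRUPT_FN[name](bases[i], rng)
            except CorruptionInapplicable:
                continue
            roles[i] = name
            entries[i] = {"smiles": corrupted, "corruption": name,
                          "base_canonical": bases[i]}
            placed += 1

    # duplicates: rewrites of clean bases, appended then mixed in by shuffle
    clean = [i for i in range(n_base) if i not in roles]
    if n_dup and not clean:
        raise ValueError("infeasible corruption plan: no clean molecule to duplicate")
    for _ in range(n_dup):
        i = int(rng.choice(clean))
        entries.append({"smiles": _rewrite(bases[i], rng),
                        "corruption": "duplicate_rewrite",
                        "base_canonical": bases[i]})
    order = rng.permutation(len(entries))
    entries = [entries[i] for i in order]

    planted = dict(spec.corruption_plan)
    manifest = {
        "seed": spec.seed,
        "fragment_pool": spec.fragment_pool,
        "n_molecules": spec.n_molecules,
        "planted": planted,
        "expected_summary": {
            "n_input": spec.n_molecules,
            "n_syntactic_invalid": planted.get("syntactic_break", 0),
            "n_duplicates": planted.get("duplicate_rewrite", 0),
            "n_checker_removed": planted.get("severe_valence", 0),
            "n_output": spec.n_molecules
            - planted.get("syntactic_break", 0)
            - planted.get("duplicate_rewrite", 0)
            - planted.get("severe_valence", 0),
        },
        "entries": [dict(e, index=i) for i, e in enumerate(entries)],
    }
    return [e["smiles"] for e in entries], manifest


def generate_clean_corpus(n: int, seed: int, pool: str = "np_like") -> list[str]:
    """Convenience: n unique, valid, stereo-free fixture molecules."""
    smiles, _ = generate_corpus(FixtureSpec(n, seed, pool))
    return smiles


# re-exported for callers that only need a rewrite utility
def random_rewrite(smiles: str, seed: int) -> str:
    return _rewrite(smiles, np.random.default_rng(seed))


def verify_pools() -> None:
    """Every packaged building block must parse (used by the test suite)."""
    for pool in ("np_like", "druglike"):
        for smi in load_pool(pool):
            canonicalize(smi)
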