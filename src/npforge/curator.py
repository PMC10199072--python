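"""Post-generation curation: validity, deduplication, quality, parents.

The cascade mirrors a standard compound-registration pipeline: syntactic
filtering, stereo stripping, dual-key deduplication (canonical SMILES OR
InChI), structure standardization, parent extraction (salt/solvent/isotope
removal), and a structure-quality checker that assigns integer penalties.
Records whose maximum penalty exceeds 5 are removed; cosmetic issues
(undefined stereocentres, protonation-state flags, isotopes, counter-ions)
score 2 and are retained with their flags recorded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

from rdkit import Chem
from rdkit.Chem.MolStandardize import rdMolStandardize

from .chemio import MoleculeRecord, parse_and_validate, strip_stereochemistry

log = logging.getLogger(__name__)

REMOVAL_THRESHOLD = 5  # max_error_score strictly above this removes the record


@dataclass(frozen=True)
class CheckerReport:
    fired_rules: tuple[tuple[str, int], ...]
    max_error_score: int

    @property
    def error_types(self) -> list[str]:
        return [name for name, _ in self.fired_rules]


@dataclass
class CurationSummary:
    n_input: int = 0
    n_syntactic_invalid: int = 0
    n_duplicates: int = 0
    n_checker_removed: int = 0
    n_output: int = 0

    def check_conservation(self) -> bool:
        return self.n_output == (
            self.n_input - self.n_syntactic_invalid
            - self.n_duplicates - self.n_checker_removed)


# ---------------------------------------------------------------------------
# checker rules

def _has_undefined_stereo(mol) -> bool:
    si = Chem.FindPotentialStereo(mol)
    return any(e.specified == Chem.StereoSpecified.Unspecified for e in si)


def _needs_neutralization(mol) -> bool:
    if Chem.GetFormalCharge(mol) == 0 and all(
            a.GetFormalCharge() == 0 for a in mol.GetAtoms()):
        return False
    before = Chem.MolToSmiles(mol)
    after = Chem.MolToSmiles(_uncharge(mol))
    return before != after


def _has_isotope(mol) -> bool:
    return any(a.GetIsotope() != 0 for a in mol.GetAtoms())


def _is_multifragment(mol) -> bool:
    return len(Chem.GetMolFrags(mol)) > 1


def _roundtrip_mismatch(mol) -> bool:
    smi = Chem.MolToSmiles(mol)
    re_mol = Chem.MolFromSmiles(smi)
    return re_mol is None or Chem.MolToSmiles(re_mol) != smi


def _valence_error(mol) -> bool:
    # RDKit's parser rejects textbook over-valence at the syntactic stage;
    # the severe class that survives parsing is unfilled valence (radicals).
    return any(a.GetNumRadicalElectrons() > 0 for a in mol.GetAtoms())


def _polymer_or_unsupported(mol) -> bool:
    return any(a.GetAtomicNum() == 0 for a in mol.GetAtoms())


#: (name, penalty, predicate) — penalties grow with severity; > 5 removes.
CHECKER_RULES = (
    ("undefined_stereo", 2, _has_undefined_stereo),
    ("needs_neutralization", 2, _needs_neutralization),
    ("isotope_present", 2, _has_isotope),
    ("salt_or_multifragment", 2, _is_multifragment),
    ("roundtrip_mismatch", 5, _roundtrip_mismatch),
    ("valence_error", 6, _valence_error),
    ("polymer_or_unsupported", 7, _polymer_or_unsupported),
)


def check_structure(mol) -> CheckerReport:
    """Evaluate the fixed rule table on a parsed molecule; deterministic."""
    fired = tuple((name, penalty) for name, penalty, pred in CHECKER_RULES if pred(mol))
    return CheckerReport(fired, max((p for _, p in fired), default=0))


# ---------------------------------------------------------------------------
# standardization and parent extraction

_normalizer = rdMolStandardize.Normalizer()
_uncharger = rdMolStandardize.Uncharger()


def _uncharge(mol):
    return _uncharger.uncharge(mol)


def standardize(mol):
    """Functional-group normalization, then neutralization, then H cleanup.

    Idempotent; sites that cannot be neutralized by (de)protonation (e.g. a
    quaternary nitrogen) are left untouched.
    """
    mol = _normalizer.normalize(mol)
    mol = _uncharger.uncharge(mol)
    mol = Chem.RemoveHs(mol)
    Chem.SanitizeMol(mol)
    return mol


def _load_droplist() -> frozenset[str]:
    text = resources.files("npforge.data").joinpath("salts_solvents.smi").read_text()
    canon = set()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        smi = line.split("\t")[0]
        canon.add(Chem.MolToSmiles(Chem.MolFromSmiles(smi)))
    return frozenset(canon)


SALT_SOLVENT_DROPLIST = _load_droplist()


class NoParentError(ValueError):
    """Every fragment of the molecule is on the salt/solvent drop list."""


def get_parent(mol):
    """Largest non-salt/solvent fragment with all isotope labels cleared.

    Idempotent.  Raises :class:`NoParentError` when nothing remains.
    """
    frags = Chem.GetMolFrags(mol, asMols=True)
    kept = [f for f in frags if Chem.MolToSmiles(f) not in SALT_SOLVENT_DROPLIST]
    if not kept:
        raise NoParentError(Chem.MolToSmiles(mol))
    parent = max(kept, key=lambda f: f.GetNumHeavyAtoms())
    parent = Chem.Mol(parent)
    for atom in parent.GetAtoms():
        if atom.GetIsotope():
            # labelled atoms return to standard valence form: recompute
            # implicit hydrogens instead of keeping the bracket-atom H count
            atom.SetIsotope(0)
            atom.SetNoImplicit(False)
            atom.SetNumExplicitHs(0)
            atom.SetNumRadicalElectrons(0)
    Chem.SanitizeMol(parent)
    return parent


# ---------------------------------------------------------------------------
# deduplication and the full cascade

def deduplicate(records: list[MoleculeRecord]) -> tuple[list[MoleculeRecord], int]:
    """Keep the first record per molecule; canonical SMILES OR InChI matches.

    InChIKey collisions alone do not remove a record but are logged.
    """
    seen_smiles: set[str] = set()
    seen_inchi: set[str] = set()
    seen_inchikey: set[str] = set()
    kept: list[MoleculeRecord] = []
    n_removed = 0
    for r in records:
        if not r.canonical_smiles or not r.inchi:
            raise ValueError(f"record {r.source_id} lacks identifier fields")
        if r.canonical_smiles in seen_smiles or r.inchi in seen_inchi:
            n_removed += 1
            continue
        if r.inchikey and r.inchikey in seen_inchikey:
            log.info("InChIKey collision without SMILES/InChI match: %s", r.source_id)
        seen_smiles.add(r.canonical_smiles)
        seen_inchi.add(r.inchi)
        if r.inchikey:
            seen_inchikey.add(r.inchikey)
        kept.append(r)
    return kept, n_removed


def curate(raw_smiles: list[str],
           source_ids: list[str] | None = None
           ) -> tuple[list[MoleculeRecord], CurationSummary]:
    """Full cascade: validity -> stereo strip -> dedup -> standardize ->
    parent -> check; records with max_error_score > 5 are removed.

    Molecules with no parent (all fragments on the drop list) are counted
    among the checker removals.  The conservation identity
    ``n_output = n_input - invalid - duplicates - checker_removed`` holds on
    every run, and the cascade is idempotent.
    """
    if source_ids is None:
        source_ids = [f"gen{i}" for i in range(len(raw_smiles))]
    summary = CurationSummary(n_input=len(raw_smiles))

    # stage 1+2: syntactic validity, then stereo stripping with fresh identifiers
    records: list[MoleculeRecord] = []
    for sid, smi in zip(source_ids, raw_smiles):
        if not parse_and_validate(smi).is_valid:
            summary.n_syntactic_invalid += 1
            continue
        stripped = strip_stereochemistry(smi)
        pr = parse_and_validate(stripped)
        if not pr.is_valid:
            summary.n_syntactic_invalid += 1
            continue
        records.append(MoleculeRecord(
            source_id=sid, raw_smiles=smi,
            canonical_smiles=pr.canonical_smiles,
            inchi=pr.inchi, inchikey=pr.inchikey))

    # stage 3: dual-key deduplication
    records, summary.n_duplicates = deduplicate(records)

    # stages 4-6: standardize, parent, check
    kept: list[MoleculeRecord] = []
    for r in records:
        mol = Chem.MolFromSmiles(r.canonical_smiles)
        try:
            mol = standardize(mol)
            mol = get_parent(mol)
        except NoParentError:
            summary.n_checker_removed += 1
            continue
        report = check_structure(mol)
        if report.max_error_score > REMOVAL_THRESHOLD:
            summary.n_checker_removed += 1
            continue
        pr = parse_and_validate(Chem.MolToSmiles(mol))
        r.canonical_smiles = pr.canonical_smiles
        r.inchi, r.inchikey = pr.inchi, pr.inchikey
        r.max_error_score = report.max_error_score
        r.error_types = report.error_types
        kept.append(r)

    summary.n_output = len(kept)
    log.info("curate: %s", summary)
    return kept, summary
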