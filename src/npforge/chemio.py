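"""SMILES parsing, canonicalization, identifier generation and record I/O.

A molecule's identity throughout the package is its canonical SMILES (with
stereochemistry removed) together with its InChI/InChIKey.  A SMILES string is
*valid* only if all four toolkit operations succeed: parsing, canonical-SMILES
writing, InChI writing and InChIKey writing; a failure at any stage marks the
string invalid and records the stage that failed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable

from rdkit import Chem, RDLogger
from rdkit.Chem.inchi import MolToInchi, MolToInchiKey

RDLogger.DisableLog("rdApp.*")

log = logging.getLogger(__name__)

#: tokens that mark tetrahedral or double-bond stereochemistry in SMILES
STEREO_MARKS = ("@", "/", "\\")


class FailureStage(str, Enum):
    PARSE = "parse"
    CANONICAL_WRITE = "canonical_write"
    INCHI_WRITE = "inchi_write"
    INCHIKEY_WRITE = "inchikey_write"
    NONE = "none"


@dataclass(frozen=True)
class ParseResult:
    """Outcome of the four-stage validity test on one SMILES string."""

    is_valid: bool
    canonical_smiles: str | None = None
    inchi: str | None = None
    inchikey: str | None = None
    failure_stage: FailureStage = FailureStage.NONE


def parse_and_validate(smiles: str) -> ParseResult:
    """Run the four-stage validity test on ``smiles``.

    Stages: parse -> canonical SMILES write -> InChI write -> InChIKey write.
    Invalidity is a result, not an exception; the first failing stage is
    recorded.  Deterministic.
    """
    if not smiles or not isinstance(smiles, str):
        return ParseResult(False, failure_stage=FailureStage.PARSE)
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return ParseResult(False, failure_stage=FailureStage.PARSE)
    try:
        canonical = Chem.MolToSmiles(mol)
    except Exception:
        canonical = None
    if not canonical:
        return ParseResult(False, failure_stage=FailureStage.CANONICAL_WRITE)
    try:
        inchi = MolToInchi(mol, treatWarningAsError=False)
    except Exception:
        inchi = None
    if not inchi:
        return ParseResult(False, failure_stage=FailureStage.INCHI_WRITE)
    try:
        inchikey = MolToInchiKey(mol)
    except Exception:
        inchikey = None
    if not inchikey:
        return ParseResult(False, failure_stage=FailureStage.INCHIKEY_WRITE)
    return ParseResult(True, canonical, inchi, inchikey, FailureStage.NONE)


def canonicalize(smiles: str) -> str:
    """Canonical SMILES of a valid input; raises ValueError on parse failure."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    return Chem.MolToSmiles(mol)


def strip_stereochemistry(smiles: str) -> str:
    """Remove all tetrahedral and double-bond stereo marks; canonical output.

    Idempotent: stripping a stereo-free SMILES returns its canonical form.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    Chem.RemoveStereochemistry(mol)
    return Chem.MolToSmiles(mol)


def read_smiles_file(path, has_ids: bool = False) -> list[tuple[str, str]]:
    """Read a line-oriented SMILES file into ``(source_id, smiles)`` pairs.

    Lines are ``SMILES`` or ``SMILES<TAB>ID``; blank lines are skipped and
    counted in the log.  Input order is preserved.  A line with more than two
    tab-separated fields raises ValueError.
    """
    records: list[tuple[str, str]] = []
    n_blank = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                n_blank += 1
                continue
            fields = line.split("\t")
            if len(fields) > 2:
                raise ValueError(f"{path}:{lineno}: expected at most 2 fields, got {len(fields)}")
            smiles = fields[0]
            source_id = fields[1] if (has_ids and len(fields) == 2) else f"line{lineno}"
            records.append((source_id, smiles))
    if n_blank:
        log.info("read_smiles_file(%s): skipped %d blank line(s)", path, n_blank)
    return records


def write_smiles_file(smiles: Iterable[str], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in smiles:
            fh.write(s + "\n")


# Fixed column order of the flat record table: identifiers, curation fields,
# score, classification labels; descriptor keys follow in their own map.
RECORD_COLUMNS = (
    "source_id",
    "raw_smiles",
    "canonical_smiles",
    "inchi",
    "inchikey",
    "max_error_score",
    "error_types",
    "np_score",
    "pathway",
    "superclass",
    "class_type",
    "descriptors",
)


@dataclass
class MoleculeRecord:
    """One molecule's identifiers, curation verdicts, score and descriptors."""

    source_id: str
    raw_smiles: str
    canonical_smiles: str
    inchi: str
    inchikey: str
    max_error_score: int = 0
    error_types: list[str] = field(default_factory=list)
    np_score: float | None = None
    pathway: str = "none"
    superclass: str = "none"
    class_type: str = "none"
    descriptors: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {col: getattr(self, col) for col in RECORD_COLUMNS}

    @classmethod
    def from_dict(cls, d: dict) -> "MoleculeRecord":
        return cls(**{col: d[col] for col in RECORD_COLUMNS})


def write_record_table(records: list[MoleculeRecord], path) -> None:
    """Write records as JSON Lines in the fixed column order.

    All records must share the same descriptor keys; round-trips exactly.
    """
    keysets = {tuple(sorted(r.descriptors)) for r in records}
    if len(keysets) > 1:
        raise ValueError("records have heterogeneous descriptor keys")
    with open(path, "w", encoding="utf-8") as fh:
        for r in records:
            fh.write(json.dumps(r.to_dict()) + "\n")


def read_record_table(path) -> list[MoleculeRecord]:
    records = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                records.append(MoleculeRecord.from_dict(json.loads(line)))
    return records
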