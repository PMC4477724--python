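"""Chemical identifier algebra, term typing and 3D structure generation.

Identifier conversions (InChI ↔ SMILES ↔ InChIKey) delegate to RDKit, so
the whole pipeline runs offline.  Name-to-structure resolution is an
interface: a *resolver* is any callable ``name -> InChI | None`` (the
:class:`TableResolver` wraps a local lookup table; networked resolvers can
be plugged in but are never used here).  A term is typed *chemical* only
when independent resolvers agree on the normalized standard InChI —
running two services in parallel and comparing answers is what gives
confidence in bulk assignments.

3D coordinates come from a seeded ETKDG distance-geometry embedding and
are written as Tripos mol2 text keyed by InChIKey in a
:class:`StructureCache`; a key, once written, is never regenerated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Callable, Optional, Sequence

from rdkit import Chem, RDLogger
from rdkit.Chem import rdDistGeom, rdmolops
from rdkit.Chem.inchi import InchiToInchiKey, MolFromInchi, MolToInchi

from .errors import ChemistryError, StructureGenerationError
from .glossary_model import (
    Glossary,
    SemanticIdentifier,
    WordType,
)

RDLogger.DisableLog("rdApp.*")

Resolver = Callable[[str], Optional[str]]


def _mol_from_inchi(inchi: str) -> Chem.Mol:
    if not inchi or not inchi.startswith("InChI="):
        raise ChemistryError(f"not an InChI string: {inchi!r}")
    mol = MolFromInchi(inchi, sanitize=True, treatWarningAsError=False)
    if mol is None:
        raise ChemistryError(f"unparsable InChI: {inchi!r}")
    return mol


def inchi_to_inchikey(inchi: str) -> str:
    """Hash an InChI to its fixed-length 27-character InChIKey."""
    _mol_from_inchi(inchi)  # reject syntactically invalid input
    key = InchiToInchiKey(inchi)
    if not key:
        raise ChemistryError(f"InChIKey computation failed for {inchi!r}")
    return key


def smiles_to_inchi(smiles: str) -> str:
    """Convert a SMILES string to the standard InChI."""
    if not smiles:
        raise ChemistryError("empty SMILES string")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ChemistryError(f"unparsable SMILES: {smiles!r}")
    inchi = MolToInchi(mol)
    if not inchi:
        raise ChemistryError(f"InChI generation failed for SMILES {smiles!r}")
    return inchi


def inchi_to_smiles(inchi: str) -> str:
    """Convert an InChI to a canonical SMILES (round-trips at the InChI level)."""
    return Chem.MolToSmiles(_mol_from_inchi(inchi))


def normalize_inchi(inchi: str) -> Optional[str]:
    """Re-derive the standard InChI so string comparison is canonical.

    Returns None when the input cannot be interpreted as a structure.
    """
    if not inchi or not inchi.startswith("InChI="):
        return None
    mol = MolFromInchi(inchi, sanitize=True, treatWarningAsError=False)
    if mol is None:
        return None
    return MolToInchi(mol) or None


class ResolutionStatus(Enum):
    AGREED = "agreed"
    DISAGREED = "disagreed"
    UNRESOLVED = "unresolved"


@dataclass(frozen=True)
class ResolutionResult:
    """Outcome of querying several name-to-structure resolvers.

    ``agreed``: every resolver that answered returned the same normalized
    InChI, and — unless partial agreement is enabled — every resolver
    answered.  ``disagreed``: at least two distinct answers.
    ``unresolved``: nobody answered, or (default policy) only a subset
    answered; the per-resolver map then shows who said what so the term
    can be routed to manual review.
    """

    name: str
    status: ResolutionStatus
    inchi: Optional[str]
    per_resolver: dict[str, Optional[str]] = field(default_factory=dict)

    @property
    def partially_answered(self) -> bool:
        answers = [v for v in self.per_resolver.values() if v]
        return bool(answers) and len(answers) < len(self.per_resolver)


def resolve_name(
    name: str,
    resolvers: Sequence[Resolver],
    accept_partial: bool = False,
) -> ResolutionResult:
    """Query every resolver for a name and compare normalized InChIs.

    Resolver failures (exceptions) count as empty answers.  The outcome
    is independent of resolver order.  With ``accept_partial`` a single
    answer (others silent) is accepted as agreement; the default routes
    such terms to review via ``unresolved`` status.
    """
    per: dict[str, Optional[str]] = {}
    for i, r in enumerate(resolvers):
        rname = getattr(r, "name", None) or getattr(r, "__name__", None) or f"resolver{i}"
        if rname in per:  # duplicate names must not collapse answers
            rname = f"{rname}#{i}"
        try:
            raw = r(name)
        except Exception:
            raw = None
        per[rname] = normalize_inchi(raw) if raw else None
    answers = [v for v in per.values() if v]
    distinct = set(answers)
    if len(distinct) > 1:
        return ResolutionResult(name, ResolutionStatus.DISAGREED, None, per)
    if not answers:
        return ResolutionResult(name, ResolutionStatus.UNRESOLVED, None, per)
    if len(answers) == len(per) or accept_partial:
        return ResolutionResult(name, ResolutionStatus.AGREED, answers[0], per)
    return ResolutionResult(name, ResolutionStatus.UNRESOLVED, None, per)


class TableResolver:
    """Resolver backed by a local name → InChI table (case-folded lookup)."""

    def __init__(self, table: dict[str, str], name: str = "local"):
        self.table = {k.casefold(): v for k, v in table.items()}
        self.name = name

    def __call__(self, name: str) -> Optional[str]:
        return self.table.get(name.casefold())


def assign_word_types(
    glossary: Glossary,
    resolvers: Sequence[Resolver],
    accept_partial: bool = False,
) -> tuple[Glossary, list[ResolutionResult]]:
    """Type untyped terms as chemicals where resolvers agree on an InChI.

    Terms already typed chemical/protein are never touched.  Disagreed
    terms and partially answered ones are returned on the review list
    with their per-resolver evidence; fully unanswered terms simply stay
    ``no_type`` (most glossary words are not chemicals).
    """
    review: list[ResolutionResult] = []
    for term in glossary.terms.values():
        if term.word_type is not WordType.NO_TYPE:
            continue
        result = resolve_name(term.name, resolvers, accept_partial=accept_partial)
        if result.status is ResolutionStatus.AGREED:
            term.word_type = WordType.CHEMICAL
            term.identifier = SemanticIdentifier.inchi(result.inchi)
        elif result.status is ResolutionStatus.DISAGREED or result.partially_answered:
            review.append(result)
    return glossary, review


class StructureCache:
    """Directory of generated mol2 files keyed by InChIKey.

    ``generation_count`` tracks how many times a structure was actually
    embedded, so tests can assert the once-per-key contract.
    """

    def __init__(self, directory: Path):
        self.directory = Path(directory)
        self.directory.mkdir(parents=True, exist_ok=True)
        self.generation_count = 0

    def path_for(self, inchikey: str) -> Path:
        return self.directory / f"{inchikey}.mol2"

    def __contains__(self, inchikey: str) -> bool:
        return self.path_for(inchikey).exists()


def _mol_to_mol2(mol: Chem.Mol, name: str) -> str:
    """Serialize an embedded molecule as Tripos mol2 text.

    Atom types are plain element symbols; bond types use the Tripos
    single/double/triple/aromatic codes.  Coordinates are written at
    fixed (4-decimal) precision so output is byte-reproducible.
    """
    conf = mol.GetConformer()
    lines = [
        "@<TRIPOS>MOLECULE",
        name,
        f"{mol.GetNumAtoms():>5}{mol.GetNumBonds():>6}",
        "SMALL",
        "NO_CHARGES",
        "",
        "@<TRIPOS>ATOM",
    ]
    for atom in mol.GetAtoms():
        p = conf.GetAtomPosition(atom.GetIdx())
        sym = atom.GetSymbol()
        lines.append(
            f"{atom.GetIdx() + 1:>7} {sym + str(atom.GetIdx() + 1):<8}"
            f"{p.x:>10.4f}{p.y:>10.4f}{p.z:>10.4f} {sym:<5}1  UNL"
        )
    lines.append("@<TRIPOS>BOND")
    bond_code = {
        Chem.BondType.SINGLE: "1",
        Chem.BondType.DOUBLE: "2",
        Chem.BondType.TRIPLE: "3",
        Chem.BondType.AROMATIC: "ar",
    }
    for i, bond in enumerate(mol.GetBonds()):
        code = bond_code.get(bond.GetBondType(), "1")
        lines.append(
            f"{i + 1:>6}{bond.GetBeginAtomIdx() + 1:>6}{bond.GetEndAtomIdx() + 1:>6} {code}"
        )
    lines.append("")
    return "\n".join(lines)


def generate_3d(inchi: str, cache: StructureCache, seed: int = 0) -> Path:
    """Embed a molecule in 3D and write it to the cache as mol2.

    Uses a seeded distance-geometry (ETKDG) embedding, so a fixed seed
    gives byte-identical coordinates.  The file is written once per
    InChIKey; later calls return the cached path without regeneration.
    Disconnected species (salts) are rejected — a single connected
    molecule is required for a meaningful single-structure display.
    """
    inchikey = inchi_to_inchikey(inchi)
    path = cache.path_for(inchikey)
    if path.exists():
        return path
    mol = _mol_from_inchi(inchi)
    if len(rdmolops.GetMolFrags(mol)) > 1:
        raise StructureGenerationError(
            f"disconnected structure, cannot embed: {inchikey}"
        )
    mol = Chem.AddHs(mol)
    params = rdDistGeom.ETKDGv3()
    params.randomSeed = int(seed) & 0x7FFFFFFF
    if rdDistGeom.EmbedMolecule(mol, params) != 0:
        raise StructureGenerationError(f"3D embedding failed for {inchikey}")
    text = _mol_to_mol2(mol, inchikey)
    path.write_text(text, encoding="ascii")
    cache.generation_count += 1
    return path
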