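"""Typed glossary data model.

A :class:`Glossary` is a lexicon of :class:`Term` objects keyed by the
case-folded term name.  Each term carries a :class:`WordType` — plain
(``no_type``), ``chemical`` or ``protein`` — and, for the latter two, a
:class:`SemanticIdentifier` (an InChI string or a 4-character PDB id) that
links the term to structure databases.  Definitions live in up to five
numbered :class:`DefinitionField` slots; a field is either *locked*
(canonical content, e.g. a learned-society definition imported in bulk) or
editable (wiki content), and every successful edit appends a new
:class:`DefinitionVersion` so the full history is retained.

The model is deliberately storage-agnostic: persistence is delegated to
:mod:`whg.glossary_io`, which serializes a glossary to a single XML
document (current content only; edit history is in-memory session state).
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass, field
from datetime import datetime, timezone
from enum import Enum
from typing import Optional, Sequence

from .errors import (
    DuplicateTermError,
    FieldRangeError,
    IdentifierMismatchError,
    LimitViolation,
    LockViolation,
)

MAX_FIELDS = 5

_PDB_ID_RE = re.compile(r"^[A-Za-z0-9]{4}$")


class WordType(Enum):
    """Semantic category of a glossary term.

    The category decides which identifier a term must carry and which
    content tabs its portlet offers: ``chemical`` and ``protein`` terms
    require a :class:`SemanticIdentifier`; ``no_type`` terms forbid one.
    """

    NO_TYPE = "no_type"
    CHEMICAL = "chemical"
    PROTEIN = "protein"

    @property
    def requires_identifier(self) -> bool:
        return self is not WordType.NO_TYPE


class IdentifierKind(Enum):
    INCHI = "inchi"
    PDB_ID = "pdb_id"


@dataclass(frozen=True)
class SemanticIdentifier:
    """A structure-database key attached to a typed term.

    ``inchi`` identifiers must carry the ``InChI=`` prefix; ``pdb_id``
    identifiers are exactly four alphanumeric characters.
    """

    kind: IdentifierKind
    value: str

    def __post_init__(self) -> None:
        if self.kind is IdentifierKind.INCHI:
            if not self.value.startswith("InChI="):
                raise IdentifierMismatchError(
                    f"InChI identifier must start with 'InChI=': {self.value!r}"
                )
        elif self.kind is IdentifierKind.PDB_ID:
            if not _PDB_ID_RE.match(self.value):
                raise IdentifierMismatchError(
                    f"PDB id must be 4 alphanumeric characters: {self.value!r}"
                )

    @classmethod
    def inchi(cls, value: str) -> "SemanticIdentifier":
        return cls(IdentifierKind.INCHI, value)

    @classmethod
    def pdb(cls, value: str) -> "SemanticIdentifier":
        return cls(IdentifierKind.PDB_ID, value)


@dataclass(frozen=True)
class DefinitionVersion:
    """One revision of a definition field; ordinals count from 1."""

    content: str
    author: str
    timestamp: datetime
    ordinal: int


@dataclass
class DefinitionField:
    """A numbered definition slot (index 1..5) with append-only history.

    ``history`` holds every version in ordinal order; the last entry is
    current.  Locked fields reject edits unconditionally.
    """

    index: int
    locked: bool = False
    history: list[DefinitionVersion] = field(default_factory=list)

    @property
    def content(self) -> str:
        return self.history[-1].content if self.history else ""

    @property
    def current_ordinal(self) -> int:
        return self.history[-1].ordinal if self.history else 0


@dataclass
class Term:
    """A glossary entry: display name, lookup key, word type, identifier, fields."""

    name: str
    key: str
    word_type: WordType
    identifier: Optional[SemanticIdentifier]
    fields: list[DefinitionField] = field(default_factory=list)

    def field_at(self, index: int) -> DefinitionField:
        for f in self.fields:
            if f.index == index:
                return f
        raise FieldRangeError(
            f"term {self.name!r} has no definition field {index}"
        )


@dataclass
class Glossary:
    name: str
    field_count: int
    locked_mask: tuple[bool, ...]
    source_citation: Optional[str] = None
    active: bool = True
    terms: dict[str, Term] = field(default_factory=dict)

    def __contains__(self, name: str) -> bool:
        return term_key(name) in self.terms

    def get(self, name: str) -> Term:
        key = term_key(name)
        if key not in self.terms:
            raise KeyError(f"no term {name!r} in glossary {self.name!r}")
        return self.terms[key]


def term_key(name: str) -> str:
    """Canonical lookup key: NFC-normalized, Unicode case-folded, spaces collapsed."""
    collapsed = " ".join(name.split())
    return unicodedata.normalize("NFC", collapsed).casefold()


def _now() -> datetime:
    return datetime.now(timezone.utc)


def _check_identifier(word_type: WordType, identifier: Optional[SemanticIdentifier]) -> None:
    if word_type.requires_identifier and identifier is None:
        raise IdentifierMismatchError(
            f"word type {word_type.value!r} requires a semantic identifier"
        )
    if not word_type.requires_identifier and identifier is not None:
        raise IdentifierMismatchError("no_type terms must not carry an identifier")
    if identifier is not None:
        expected = (
            IdentifierKind.INCHI
            if word_type is WordType.CHEMICAL
            else IdentifierKind.PDB_ID
        )
        if identifier.kind is not expected:
            raise IdentifierMismatchError(
                f"{word_type.value} terms need a {expected.value} identifier, "
                f"got {identifier.kind.value}"
            )


def create_glossary(
    name: str,
    field_count: int,
    locked_mask: Sequence[bool],
    source_citation: Optional[str] = None,
) -> Glossary:
    """Create an empty, active glossary with a fixed field layout.

    ``locked_mask[i]`` states whether field ``i+1`` is canonical (locked)
    for terms subsequently added.  A typical layout is a locked field 1
    bulk-imported from an established glossary with the ``source_citation``
    naming its source, plus one or more unlocked wiki fields.
    """
    if not 1 <= field_count <= MAX_FIELDS:
        raise LimitViolation(
            f"field_count must be in [1, {MAX_FIELDS}], got {field_count}"
        )
    if len(locked_mask) != field_count:
        raise LimitViolation(
            f"locked_mask has {len(locked_mask)} entries for {field_count} fields"
        )
    return Glossary(
        name=name,
        field_count=field_count,
        locked_mask=tuple(bool(b) for b in locked_mask),
        source_citation=source_citation,
    )


def add_term(
    glossary: Glossary,
    name: str,
    word_type: WordType,
    identifier: Optional[SemanticIdentifier] = None,
    definitions: Sequence[str] = (),
    author: str = "import",
) -> Term:
    """Add a term; each definition becomes version 1 of its field.

    Fields inherit their lock state from the glossary's ``locked_mask``.
    """
    key = term_key(name)
    if not key:
        raise DuplicateTermError("term name must not be empty")
    if key in glossary.terms:
        raise DuplicateTermError(
            f"term {name!r} (key {key!r}) already exists in glossary {glossary.name!r}"
        )
    _check_identifier(word_type, identifier)
    if len(definitions) > glossary.field_count:
        raise LimitViolation(
            f"{len(definitions)} definitions exceed glossary field_count "
            f"{glossary.field_count}"
        )
    ts = _now()
    fields = [
        DefinitionField(
            index=i + 1,
            locked=glossary.locked_mask[i],
            history=[DefinitionVersion(content=c, author=author, timestamp=ts, ordinal=1)],
        )
        for i, c in enumerate(definitions)
    ]
    term = Term(name=name, key=key, word_type=word_type, identifier=identifier, fields=fields)
    glossary.terms[key] = term
    return term


def edit_field(term: Term, index: int, new_content: str, author: str) -> DefinitionVersion:
    """Record a new version of an unlocked field; edits are append-only."""
    f = term.field_at(index)
    if f.locked:
        raise LockViolation(
            f"field {index} of term {term.name!r} is locked"
        )
    version = DefinitionVersion(
        content=new_content,
        author=author,
        timestamp=_now(),
        ordinal=f.current_ordinal + 1,
    )
    f.history.append(version)
    return version


def field_history(term: Term, index: int) -> list[DefinitionVersion]:
    """All versions of a field in ordinal order, current last."""
    return list(term.field_at(index).history)


def set_active(glossary: Glossary, active: bool) -> Glossary:
    """Activate or deactivate a glossary; inactive glossaries refuse matching."""
    glossary.active = bool(active)
    return glossary
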