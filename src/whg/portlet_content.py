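"""Per-term content bundles ("portlets").

When a tagged term is activated, the reader is shown an ordered list of
tabs whose composition is fixed by the term's word type:

* ``no_type``  → Definition
* ``chemical`` → Definition, Search, 3D Structure, 2D Structure
* ``protein``  → Definition, 3D Structure

A chemical's 2D-structure tab carries an editable structure payload
(SMILES plus the term's InChI); structures drawn in the editor spawn
additional *editor search* tabs, one per search, which accumulate and
never replace earlier tabs — successively chlorinating methane yields
five search tabs, one per species.

The bundle is a plain data object serialized as JSON; viewer hints name
the client-side component class (3D viewer, 2D editor) a front end would
mount, without bundling one.  Structure search is an interface with an
offline local backend, so "no results" paths are exercisable in tests.
"""

from __future__ import annotations

import base64
import binascii
import hashlib
import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Optional, Protocol

from . import chem_semantics
from .chem_semantics import StructureCache
from .errors import (
    IdentifierMismatchError,
    PayloadError,
    StructureLookupError,
)
from .glossary_model import IdentifierKind, SemanticIdentifier, Term, WordType


class TabKind(Enum):
    DEFINITION = "definition"
    STRUCTURE_SEARCH = "structure_search"
    STRUCTURE_3D = "structure3d"
    STRUCTURE_2D = "structure2d"
    EDITOR_SEARCH = "editor_search"


TAB_TITLES = {
    TabKind.DEFINITION: "Definition",
    TabKind.STRUCTURE_SEARCH: "Search",
    TabKind.STRUCTURE_3D: "3D Structure",
    TabKind.STRUCTURE_2D: "2D Structure",
}

#: Base tab layout per word type (editor-search tabs append after these).
BASE_TABS = {
    WordType.NO_TYPE: (TabKind.DEFINITION,),
    WordType.CHEMICAL: (
        TabKind.DEFINITION,
        TabKind.STRUCTURE_SEARCH,
        TabKind.STRUCTURE_3D,
        TabKind.STRUCTURE_2D,
    ),
    WordType.PROTEIN: (TabKind.DEFINITION, TabKind.STRUCTURE_3D),
}


@dataclass(frozen=True)
class Tab:
    kind: TabKind
    title: str
    payload: dict

    def to_dict(self) -> dict:
        return {"kind": self.kind.value, "title": self.title, "payload": self.payload}

    @classmethod
    def from_dict(cls, d: dict) -> "Tab":
        return cls(TabKind(d["kind"]), d["title"], d["payload"])


@dataclass
class PortletBundle:
    term_key: str
    word_type: WordType
    tabs: list[Tab] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "term_key": self.term_key,
                "word_type": self.word_type.value,
                "tabs": [t.to_dict() for t in self.tabs],
            },
            indent=2,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "PortletBundle":
        d = json.loads(text)
        return cls(
            term_key=d["term_key"],
            word_type=WordType(d["word_type"]),
            tabs=[Tab.from_dict(t) for t in d["tabs"]],
        )


class SearchBackend(Protocol):
    """Structure search: InChIKey → result entries (possibly empty)."""

    def search(self, inchikey: str) -> list[dict]: ...


class LocalSearchBackend:
    """Offline search backend over a fixed InChIKey-keyed result table.

    Each result entry is ``{"id": ..., "thumbnail_b64": ..., "link": ...}``
    mimicking a compound-database simple search plus thumbnail service.
    """

    def __init__(self, table: Optional[dict[str, list[dict]]] = None):
        self.table = table or {}

    def search(self, inchikey: str) -> list[dict]:
        return list(self.table.get(inchikey, []))


@dataclass
class PortletStores:
    """Everything portlet assembly may consult, injected for offline use."""

    curated_store: dict[str, str] = field(default_factory=dict)  # InChIKey → file ref
    pdb_store: dict[str, str] = field(default_factory=dict)  # PDB id → file ref
    cache: Optional[StructureCache] = None
    search_backend: SearchBackend = field(default_factory=LocalSearchBackend)
    seed: int = 0
    curated_lookups: int = 0  # instrumentation


def resolve_structure3d(
    identifier: SemanticIdentifier,
    stores: PortletStores,
) -> tuple[str, str]:
    """Locate a 3D structure file for an identifier.

    Chemicals: the curated store is consulted first by InChIKey and a hit
    short-circuits generation; on a miss a mol2 is generated into the
    cache.  Proteins: the PDB store is consulted by id.  Returns
    ``(file_reference, provenance)`` with provenance one of ``curated``,
    ``generated``, ``pdb``.
    """
    if identifier.kind is IdentifierKind.PDB_ID:
        pdb_id = identifier.value.upper()
        if pdb_id not in stores.pdb_store:
            raise StructureLookupError(f"unknown PDB id {identifier.value!r}")
        return stores.pdb_store[pdb_id], "pdb"

    inchikey = chem_semantics.inchi_to_inchikey(identifier.value)
    stores.curated_lookups += 1
    if inchikey in stores.curated_store:
        return stores.curated_store[inchikey], "curated"
    if stores.cache is None:
        raise StructureLookupError(
            f"no curated structure for {inchikey} and no cache configured"
        )
    path = chem_semantics.generate_3d(identifier.value, stores.cache, stores.seed)
    return str(path), "generated"


def editor_payload(term: Term) -> dict:
    """Editable-structure payload for a chemical term's 2D tab.

    The SMILES is derived from the term's InChI and converts back to it,
    so the editor and the glossary agree on the structure.
    """
    if term.word_type is not WordType.CHEMICAL or term.identifier is None:
        raise IdentifierMismatchError(
            f"term {term.name!r} is not a chemical with an InChI"
        )
    smiles = chem_semantics.inchi_to_smiles(term.identifier.value)
    return {"smiles": smiles, "inchi": term.identifier.value, "viewer": "editor-2d"}


def build_portlet(term: Term, stores: Optional[PortletStores] = None) -> PortletBundle:
    """Assemble the tab bundle for one term.

    The definition tab carries current content of every field in index
    order; structure tabs are added per the word-type layout.
    """
    stores = stores or PortletStores()
    if term.word_type.requires_identifier and term.identifier is None:
        raise IdentifierMismatchError(
            f"{term.word_type.value} term {term.name!r} lacks an identifier"
        )
    bundle = PortletBundle(term_key=term.key, word_type=term.word_type)
    definitions = [
        {"index": f.index, "content": f.content, "locked": f.locked}
        for f in sorted(term.fields, key=lambda f: f.index)
    ]
    for kind in BASE_TABS[term.word_type]:
        if kind is TabKind.DEFINITION:
            payload = {"term": term.name, "fields": definitions}
        elif kind is TabKind.STRUCTURE_SEARCH:
            inchikey = chem_semantics.inchi_to_inchikey(term.identifier.value)
            results = stores.search_backend.search(inchikey)
            payload = {
                "query": inchikey,
                "results": results,
                "no_results": not results,
            }
        elif kind is TabKind.STRUCTURE_3D:
            ref, provenance = resolve_structure3d(term.identifier, stores)
            viewer = "viewer-3d"
            payload = {"file": ref, "provenance": provenance, "viewer": viewer}
        else:  # STRUCTURE_2D
            payload = editor_payload(term)
        bundle.tabs.append(Tab(kind, TAB_TITLES[kind], payload))
    return bundle


def add_editor_search_tab(
    bundle: PortletBundle,
    smiles: str,
    search_backend: SearchBackend,
) -> PortletBundle:
    """Append one editor-search tab for a structure drawn in the editor.

    The SMILES is converted to an InChIKey, the search backend queried,
    and the results (or a no-results marker) recorded in a new tab; tabs
    accumulate, so repeating a search adds another tab.
    """
    if bundle.word_type is not WordType.CHEMICAL:
        raise IdentifierMismatchError("editor search tabs require a chemical portlet")
    inchi = chem_semantics.smiles_to_inchi(smiles)
    inchikey = chem_semantics.inchi_to_inchikey(inchi)
    results = search_backend.search(inchikey)
    bundle.tabs.append(
        Tab(
            TabKind.EDITOR_SEARCH,
            f"Search: {smiles}",
            {
                "smiles": smiles,
                "inchi": inchi,
                "query": inchikey,
                "results": results,
                "no_results": not results,
            },
        )
    )
    return bundle


PNG_SIGNATURE = b"\x89PNG\r\n\x1a\n"


def decode_thumbnail(b64: str, out_store: Path) -> Path:
    """Decode a base64 thumbnail string to a PNG file in a content store.

    Files are keyed by content hash, so repeated decodes of the same
    payload share a single stored file.
    """
    try:
        data = base64.b64decode(b64, validate=True)
    except (binascii.Error, ValueError) as exc:
        raise PayloadError(f"invalid base64 thumbnail payload: {exc}") from exc
    if not data.startswith(PNG_SIGNATURE):
        raise PayloadError("decoded thumbnail is not a PNG (bad signature)")
    out_store = Path(out_store)
    out_store.mkdir(parents=True, exist_ok=True)
    digest = hashlib.sha256(data).hexdigest()[:24]
    path = out_store / f"{digest}.png"
    if not path.exists():
        path.write_bytes(data)
    return path
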