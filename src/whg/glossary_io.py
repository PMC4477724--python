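"""Glossary interchange: XML dialect, CSV dumps, tabular ingestion.

The canonical on-disk form of a glossary is a single UTF-8 XML document
validated against the schema shipped with the package
(``whg/data/glossary.xsd``)::

    <glossary name="..." field_count="2" source_citation="...">
      <term>
        <name>ozone</name>
        <word_type>chemical</word_type>
        <identifier kind="inchi">InChI=1S/O3/c1-3-2</identifier>
        <definition index="1" locked="true"><![CDATA[...]]></definition>
        <definition index="2" locked="false"><![CDATA[...]]></definition>
      </term>
    </glossary>

Definitions are carried as CDATA so embedded HTML survives verbatim.
Only current field content is exported; edit history is session state,
so a write/parse round trip preserves everything except history.

CSV export (RFC 4180) gives one row per term with identifier columns and
one column per definition field.  Tabular ingestion accepts the simple
two-column term/definition dumps produced when preparing an established
glossary for bulk import; the resulting terms are all untyped and are
handed to :func:`whg.chem_semantics.assign_word_types` for typing.
"""

from __future__ import annotations

import csv
import io
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence, Union

from lxml import etree

from .errors import DuplicateTermError, IngestError, SchemaError
from .glossary_model import (
    Glossary,
    IdentifierKind,
    SemanticIdentifier,
    Term,
    WordType,
    add_term,
    create_glossary,
    term_key,
)

_SCHEMA: Optional[etree.XMLSchema] = None


def _schema() -> etree.XMLSchema:
    global _SCHEMA
    if _SCHEMA is None:
        with resources.files("whg.data").joinpath("glossary.xsd").open("rb") as fh:
            _SCHEMA = etree.XMLSchema(etree.parse(fh))
    return _SCHEMA


def parse_glossary_xml(document: Union[str, bytes, Path]) -> Glossary:
    """Parse and validate a glossary XML document.

    Accepts a path or the document itself (string/bytes).  The glossary's
    per-index lock mask is reconstructed from the definitions' ``locked``
    attributes (an index is locked when every term marking it agrees), and
    field 1 is locked whenever a ``source_citation`` is present, matching
    the canonical-plus-wiki import convention.
    """
    try:
        if isinstance(document, Path):
            tree = etree.parse(str(document))
        elif isinstance(document, str) and "<" not in document:
            tree = etree.parse(document)  # treat as a filename
        else:
            data = document.encode("utf-8") if isinstance(document, str) else document
            tree = etree.fromstring(data).getroottree()
    except (etree.XMLSyntaxError, OSError) as exc:
        raise SchemaError(f"not well-formed XML: {exc}") from exc

    schema = _schema()
    if not schema.validate(tree):
        first = schema.error_log[0]
        raise SchemaError(f"schema violation at line {first.line}: {first.message}")

    root = tree.getroot()
    name = root.get("name")
    field_count = int(root.get("field_count"))
    citation = root.get("source_citation")

    # gather per-index lock votes before constructing the glossary
    lock_votes: dict[int, list[bool]] = {}
    parsed_terms = []
    for t in root.findall("term"):
        tname = t.findtext("name") or ""
        wt = WordType(t.findtext("word_type"))
        ident_el = t.find("identifier")
        identifier = None
        if ident_el is not None:
            identifier = SemanticIdentifier(
                IdentifierKind(ident_el.get("kind")), (ident_el.text or "").strip()
            )
        defs: dict[int, tuple[str, bool]] = {}
        for d in t.findall("definition"):
            idx = int(d.get("index"))
            locked = d.get("locked", "false") in ("true", "1")
            if idx > field_count:
                raise SchemaError(
                    f"term {tname!r}: definition index {idx} exceeds "
                    f"field_count {field_count}"
                )
            defs[idx] = (d.text or "", locked)
            lock_votes.setdefault(idx, []).append(locked)
        parsed_terms.append((tname, wt, identifier, defs))

    locked_mask = tuple(
        (citation is not None and i == 1)
        or (bool(lock_votes.get(i)) and all(lock_votes[i]))
        for i in range(1, field_count + 1)
    )
    glossary = create_glossary(name, field_count, locked_mask, citation)
    for tname, wt, identifier, defs in parsed_terms:
        if tname in glossary:
            raise DuplicateTermError(
                f"duplicate term key {term_key(tname)!r} in XML glossary {name!r}"
            )
        contents = [defs.get(i, ("", False))[0] for i in range(1, max(defs, default=0) + 1)]
        term = add_term(glossary, tname, wt, identifier, contents)
        for f in term.fields:  # per-definition lock attribute wins over the mask
            if f.index in defs:
                f.locked = defs[f.index][1] or ((citation is not None) and f.index == 1)
    return glossary


def write_glossary_xml(glossary: Glossary, path: Optional[Path] = None) -> bytes:
    """Serialize a glossary to schema-valid XML (current content only)."""
    root = etree.Element("glossary")
    root.set("name", glossary.name)
    root.set("field_count", str(glossary.field_count))
    if glossary.source_citation is not None:
        root.set("source_citation", glossary.source_citation)
    for key in sorted(glossary.terms):
        t = glossary.terms[key]
        te = etree.SubElement(root, "term")
        etree.SubElement(te, "name").text = t.name
        etree.SubElement(te, "word_type").text = t.word_type.value
        if t.identifier is not None:
            ie = etree.SubElement(te, "identifier")
            ie.set("kind", t.identifier.kind.value)
            ie.text = t.identifier.value
        for f in sorted(t.fields, key=lambda f: f.index):
            de = etree.SubElement(te, "definition")
            de.set("index", str(f.index))
            de.set("locked", "true" if f.locked else "false")
            de.text = etree.CDATA(f.content) if f.content else ""
    data = etree.tostring(
        root, xml_declaration=True, encoding="UTF-8", pretty_print=True
    )
    if path is not None:
        Path(path).write_bytes(data)
    return data


def glossaries_equal(a: Glossary, b: Glossary) -> bool:
    """Structural equality up to edit history (current content only)."""
    if (a.name, a.field_count, a.source_citation) != (
        b.name,
        b.field_count,
        b.source_citation,
    ):
        return False
    if set(a.terms) != set(b.terms):
        return False
    for key, ta in a.terms.items():
        tb = b.terms[key]
        if (ta.name, ta.word_type, ta.identifier) != (tb.name, tb.word_type, tb.identifier):
            return False
        fa = {f.index: (f.content, f.locked) for f in ta.fields}
        fb = {f.index: (f.content, f.locked) for f in tb.fields}
        if fa != fb:
            return False
    return True


def export_csv(glossary: Glossary, path: Optional[Path] = None) -> str:
    """Dump a glossary as RFC 4180 CSV: one row per term, header included."""
    buf = io.StringIO()
    writer = csv.writer(buf, quoting=csv.QUOTE_MINIMAL, lineterminator="\r\n")
    header = ["name", "word_type", "identifier_kind", "identifier_value"] + [
        f"definition_{i}" for i in range(1, glossary.field_count + 1)
    ]
    writer.writerow(header)
    for key in sorted(glossary.terms):
        t = glossary.terms[key]
        by_index = {f.index: f.content for f in t.fields}
        row = [
            t.name,
            t.word_type.value,
            t.identifier.kind.value if t.identifier else "",
            t.identifier.value if t.identifier else "",
        ] + [by_index.get(i, "") for i in range(1, glossary.field_count + 1)]
        writer.writerow(row)
    out = buf.getvalue()
    if path is not None:
        Path(path).write_text(out, encoding="utf-8", newline="")
    return out


RawGlossaryTable = Sequence[tuple[str, str]]


def ingest_table(
    rows: RawGlossaryTable,
    name: str = "ingested",
    field_count: int = 1,
) -> Glossary:
    """Build an untyped glossary from (term, definition) rows.

    Every term is ``no_type`` pending typing by the chemistry pipeline.
    Empty term cells and duplicate keys abort with 1-based row numbers in
    the message.
    """
    glossary = create_glossary(name, field_count, [False] * field_count)
    seen: dict[str, int] = {}
    for rownum, (term, definition) in enumerate(rows, start=1):
        term = term.strip()
        if not term:
            raise IngestError(f"row {rownum}: empty term cell")
        key = term_key(term)
        if key in seen:
            raise IngestError(
                f"duplicate term {term!r} at rows {seen[key]} and {rownum}"
            )
        seen[key] = rownum
        add_term(glossary, term, WordType.NO_TYPE, None, [definition])
    return glossary


def read_table(
    path: Path,
    delimiter: Optional[str] = None,
    term_col: int = 0,
    definition_col: int = 1,
    skip_header: bool = False,
) -> list[tuple[str, str]]:
    """Read a delimited term/definition table (TSV or CSV).

    The delimiter is sniffed from the extension when not given (.tsv/.tab
    → tab, otherwise comma).  ``term_col``/``definition_col`` are 0-based.
    """
    path = Path(path)
    if delimiter is None:
        delimiter = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    rows: list[tuple[str, str]] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter=delimiter)
        for i, row in enumerate(reader):
            if skip_header and i == 0:
                continue
            if not row or all(not c.strip() for c in row):
                continue
            try:
                rows.append((row[term_col], row[definition_col]))
            except IndexError as exc:
                raise IngestError(
                    f"row {i + 1}: expected at least "
                    f"{max(term_col, definition_col) + 1} columns, got {len(row)}"
                ) from exc
    return rows
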