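"""XML dialect round-trips, schema rejection, CSV export, table ingestion."""

import csv
import io
import random

import pytest
from lxml import etree

from whg.errors import IdentifierMismatchError, IngestError, SchemaError
from whg.glossary_io import (
    export_csv,
    glossaries_equal,
    ingest_table,
    parse_glossary_xml,
    read_table,
    write_glossary_xml,
)
from whg.glossary_model import (
    SemanticIdentifier,
    WordType,
    add_term,
    create_glossary,
    edit_field,
)

THREE_TERM_XML = b"""<?xml version="1.0" encoding="UTF-8"?>
<glossary name="mixed" field_count="2" source_citation="Demo source">
  <term>
    <name>entropy</name>
    <word_type>no_type</word_type>
    <definition index="1" locked="true"><![CDATA[Definition 1]]></definition>
    <definition index="2" locked="false"><![CDATA[wiki notes]]></definition>
  </term>
  <term>
    <name>ozone</name>
    <word_type>chemical</word_type>
    <identifier kind="inchi">InChI=1S/O3/c1-3-2</identifier>
    <definition index="1" locked="true"><![CDATA[Definition 2]]></definition>
  </term>
  <term>
    <name>lysozyme</name>
    <word_type>protein</word_type>
    <identifier kind="pdb_id">1LYZ</identifier>
    <definition index="1" locked="true"><![CDATA[Definition 3]]></definition>
  </term>
</glossary>
"""


def random_glossary(rng: random.Random):
    """Random model-level glossary with mixed types and awkward content."""
    field_count = rng.randint(1, 5)
    mask = [rng.random() < 0.4 for _ in range(field_count)]
    citation = "Src, with commas" if rng.random() < 0.5 else None
    if citation:
        mask[0] = True
    g = create_glossary(f"g{rng.randrange(1000)}", field_count, mask, citation)
    nasty = ['a "quoted" bit', "commas, everywhere", "<b>html</b> & more", "plain"]
    for i in range(rng.randint(0, 8)):
        kind = rng.random()
        defs = [rng.choice(nasty) for _ in range(rng.randint(1, field_count))]
        if kind < 0.3:
            add_term(
                g,
                f"chem{i}",
                WordType.CHEMICAL,
                SemanticIdentifier.inchi("InChI=1S/O3/c1-3-2"),
                defs,
            )
        elif kind < 0.5:
            add_term(
                g, f"prot{i}", WordType.PROTEIN, SemanticIdentifier.pdb(f"{i}ABC"[:4]), defs
            )
        else:
            add_term(g, f"word {i}", WordType.NO_TYPE, None, defs)
    return g


class TestParse:
    def test_three_typed_terms(self):
        g = parse_glossary_xml(THREE_TERM_XML)
        assert len(g.terms) == 3
        assert g.get("ozone").word_type is WordType.CHEMICAL
        assert g.get("ozone").identifier.value == "InChI=1S/O3/c1-3-2"
        assert g.get("lysozyme").word_type is WordType.PROTEIN
        assert g.get("entropy").word_type is WordType.NO_TYPE
        # citation present ⇒ field 1 locked
        assert g.get("ozone").fields[0].locked
        assert not g.get("entropy").fields[1].locked

    def test_empty_glossary(self):
        g = parse_glossary_xml(b'<glossary name="g" field_count="1"/>')
        assert g.name == "g" and not g.terms

    def test_chemical_without_identifier_rejected(self):
        bad = (
            b'<glossary name="g" field_count="1"><term>'
            b"<name>ozone</name><word_type>chemical</word_type>"
            b"</term></glossary>"
        )
        with pytest.raises(IdentifierMismatchError):
            parse_glossary_xml(bad)

    @pytest.mark.parametrize(
        "mutate",
        [
            lambda x: x.replace(b'name="mixed" ', b""),  # drop required attribute
            lambda x: x.replace(b"field_count=\"2\"", b"field_count=\"9\""),
            lambda x: x.replace(b"<word_type>no_type</word_type>", b"<word_type>verb</word_type>"),
            lambda x: x.replace(b'kind="inchi"', b'kind="cas"'),
            lambda x: x.replace(b'index="2"', b'index="0"'),
        ],
    )
    def test_schema_rejects_mutated_documents(self, mutate):
        with pytest.raises(SchemaError):
            parse_glossary_xml(mutate(THREE_TERM_XML))

    def test_not_xml(self):
        with pytest.raises(SchemaError):
            parse_glossary_xml(b"just not xml <")

    def test_duplicate_term_keys_rejected(self):
        dup = (
            b'<glossary name="g" field_count="1">'
            b"<term><name>Ozone</name><word_type>no_type</word_type></term>"
            b"<term><name>OZONE</name><word_type>no_type</word_type></term>"
            b"</glossary>"
        )
        with pytest.raises(Exception):
            parse_glossary_xml(dup)


class TestWrite:
    def test_round_trip_three_term_fixture(self):
        g = parse_glossary_xml(THREE_TERM_XML)
        assert glossaries_equal(g, parse_glossary_xml(write_glossary_xml(g)))

    def test_output_is_schema_valid(self, ozone_glossary):
        from whg.glossary_io import _schema

        tree = etree.fromstring(write_glossary_xml(ozone_glossary))
        assert _schema().validate(tree.getroottree())

    def test_citation_once_on_root(self, ozone_glossary):
        root = etree.fromstring(write_glossary_xml(ozone_glossary))
        assert root.get("source_citation") == "Demo source"
        assert not root.xpath("//term[@source_citation]")

    def test_history_truncated_to_current(self, ozone_glossary):
        term = ozone_glossary.get("ozone")
        edit_field(term, 2, "edited twice", "a")
        edit_field(term, 2, "final", "b")
        g2 = parse_glossary_xml(write_glossary_xml(ozone_glossary))
        f = g2.get("ozone").field_at(2)
        assert f.content == "final" and len(f.history) == 1

    def test_random_round_trip_identity(self):
        rng = random.Random(7)
        for _ in range(20):
            g = random_glossary(rng)
            g2 = parse_glossary_xml(write_glossary_xml(g))
            assert glossaries_equal(g, g2)


class TestCSV:
    def test_row_count_and_header(self, ozone_glossary):
        rows = list(csv.reader(io.StringIO(export_csv(ozone_glossary))))
        assert len(rows) == 4
        assert rows[0][:4] == ["name", "word_type", "identifier_kind", "identifier_value"]

    def test_empty_glossary_header_only(self):
        g = create_glossary("g", 1, [False])
        rows = list(csv.reader(io.StringIO(export_csv(g))))
        assert len(rows) == 1

    def test_quoting_survives_round_trip(self):
        g = create_glossary("g", 1, [False])
        nasty = 'contains, commas and "quotes"\nand a newline'
        add_term(g, "entropy", WordType.NO_TYPE, None, [nasty])
        rows = list(csv.reader(io.StringIO(export_csv(g))))
        assert rows[1][4] == nasty

    def test_reingesting_csv_reproduces_key_set(self, ozone_glossary):
        rows = list(csv.reader(io.StringIO(export_csv(ozone_glossary))))[1:]
        g2 = ingest_table([(r[0], r[4]) for r in rows])
        assert set(g2.terms) == set(ozone_glossary.terms)


class TestIngest:
    def test_two_row_table(self):
        g = ingest_table([("ozone", "a gas"), ("entropy", "S")])
        assert len(g.terms) == 2
        assert all(t.word_type is WordType.NO_TYPE for t in g.terms.values())

    def test_duplicates_reported_with_row_numbers(self):
        with pytest.raises(IngestError, match="rows 1 and 3"):
            ingest_table([("ozone", "a"), ("entropy", "b"), ("Ozone", "c")])

    def test_empty_term_cell(self):
        with pytest.raises(IngestError, match="row 2"):
            ingest_table([("ozone", "a"), ("  ", "b")])

    def test_tab_and_comma_dialects_agree(self, tmp_path):
        csv_path = tmp_path / "t.csv"
        tsv_path = tmp_path / "t.tsv"
        csv_path.write_text('ozone,"a, gas"\nentropy,S\n', encoding="utf-8")
        tsv_path.write_text("ozone\ta, gas\nentropy\tS\n", encoding="utf-8")
        g1 = ingest_table(read_table(csv_path))
        g2 = ingest_table(read_table(tsv_path))
        assert glossaries_equal(g1, g2)
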