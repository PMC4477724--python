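"""Portlet assembly: tab arithmetic, 3D source precedence, editor searches."""

import base64

import pytest

from conftest import OZONE_INCHIKEY
from whg.chem_semantics import StructureCache, smiles_to_inchi, inchi_to_inchikey
from whg.errors import IdentifierMismatchError, PayloadError, StructureLookupError
from whg.glossary_model import SemanticIdentifier
from whg.portlet_content import (
    LocalSearchBackend,
    PortletBundle,
    PortletStores,
    TabKind,
    add_editor_search_tab,
    build_portlet,
    decode_thumbnail,
    resolve_structure3d,
)

# 1x1 transparent PNG, the canonical minimal thumbnail payload
PNG_1PX = base64.b64decode(
    "iVBORw0KGgoAAAANSUhEUgAAAAEAAAABCAYAAAAfFcSJAAAADUlEQVR4nGNgYGBgAAAABQAB"
    "h6FO1AAAAABJRU5ErkJggg=="
)


def stores_with_cache(tmp_path, **kw):
    return PortletStores(cache=StructureCache(tmp_path / "cache"), **kw)


class TestTabArithmetic:
    def test_chemical_portlet_has_four_base_tabs(self, ozone_glossary, tmp_path):
        bundle = build_portlet(ozone_glossary.get("ozone"), stores_with_cache(tmp_path))
        assert [t.kind for t in bundle.tabs] == [
            TabKind.DEFINITION,
            TabKind.STRUCTURE_SEARCH,
            TabKind.STRUCTURE_3D,
            TabKind.STRUCTURE_2D,
        ]
        assert [t.title for t in bundle.tabs] == [
            "Definition", "Search", "3D Structure", "2D Structure",
        ]

    def test_plain_term_has_definition_only(self, ozone_glossary):
        bundle = build_portlet(ozone_glossary.get("entropy"))
        assert [t.kind for t in bundle.tabs] == [TabKind.DEFINITION]
        fields = bundle.tabs[0].payload["fields"]
        assert [f["index"] for f in fields] == [1, 2]
        assert fields[0]["content"] == "state function S."

    def test_protein_portlet_has_two_tabs(self, ozone_glossary):
        stores = PortletStores(pdb_store={"1LYZ": "pdb:1LYZ"})
        bundle = build_portlet(ozone_glossary.get("lysozyme"), stores)
        assert [t.kind for t in bundle.tabs] == [TabKind.DEFINITION, TabKind.STRUCTURE_3D]
        assert bundle.tabs[1].payload["provenance"] == "pdb"

    def test_typed_term_without_identifier_rejected(self, ozone_glossary):
        term = ozone_glossary.get("ozone")
        term.identifier = None
        with pytest.raises(IdentifierMismatchError):
            build_portlet(term)


class TestStructure3D:
    def test_curated_hit_short_circuits_generation(self, ozone_glossary, tmp_path):
        stores = stores_with_cache(tmp_path)
        stores.curated_store[OZONE_INCHIKEY] = "curated/ozone.mol"
        ident = ozone_glossary.get("ozone").identifier
        ref, provenance = resolve_structure3d(ident, stores)
        assert (ref, provenance) == ("curated/ozone.mol", "curated")
        assert stores.cache.generation_count == 0

    def test_curated_miss_generates_and_caches(self, ozone_glossary, tmp_path):
        stores = stores_with_cache(tmp_path)
        ident = ozone_glossary.get("ozone").identifier
        ref, provenance = resolve_structure3d(ident, stores)
        assert provenance == "generated"
        assert stores.cache.generation_count == 1
        assert OZONE_INCHIKEY in ref
        resolve_structure3d(ident, stores)
        assert stores.cache.generation_count == 1  # cached on re-entry

    def test_unknown_pdb_id(self):
        with pytest.raises(StructureLookupError):
            resolve_structure3d(SemanticIdentifier.pdb("9ZZZ"), PortletStores())


class TestEditorPayload:
    def test_smiles_round_trips_to_term_inchi(self, ozone_glossary, tmp_path):
        bundle = build_portlet(ozone_glossary.get("ozone"), stores_with_cache(tmp_path))
        payload = bundle.tabs[3].payload
        assert smiles_to_inchi(payload["smiles"]) == payload["inchi"]
        assert payload["inchi"] == ozone_glossary.get("ozone").identifier.value

    def test_non_chemical_term_rejected(self, ozone_glossary):
        from whg.portlet_content import editor_payload

        with pytest.raises(IdentifierMismatchError):
            editor_payload(ozone_glossary.get("entropy"))


class TestEditorSearchTabs:
    CHLORINATION = ["C", "CCl", "ClCCl", "ClC(Cl)Cl", "ClC(Cl)(Cl)Cl"]

    def test_methane_chlorination_accumulates_five_tabs(self, ozone_glossary, tmp_path):
        backend = LocalSearchBackend(
            {
                inchi_to_inchikey(smiles_to_inchi(s)): [
                    {"id": f"CSID{i}", "thumbnail_b64": "", "link": f"#c{i}"}
                ]
                for i, s in enumerate(self.CHLORINATION)
            }
        )
        bundle = build_portlet(
            ozone_glossary.get("ozone"), stores_with_cache(tmp_path)
        )
        for smiles in self.CHLORINATION:
            add_editor_search_tab(bundle, smiles, backend)
        editor_tabs = [t for t in bundle.tabs if t.kind is TabKind.EDITOR_SEARCH]
        assert len(editor_tabs) == 5
        assert len(bundle.tabs) == 9
        assert all(not t.payload["no_results"] for t in editor_tabs)
        assert editor_tabs[0].title == "Search: C"

    def test_append_only_prior_tabs_untouched(self, ozone_glossary, tmp_path):
        bundle = build_portlet(ozone_glossary.get("ozone"), stores_with_cache(tmp_path))
        snapshot = [t.to_dict() for t in bundle.tabs]
        add_editor_search_tab(bundle, "C", LocalSearchBackend())
        assert [t.to_dict() for t in bundle.tabs[:4]] == snapshot

    def test_absent_structure_yields_no_results_marker(self, ozone_glossary, tmp_path):
        bundle = build_portlet(ozone_glossary.get("ozone"), stores_with_cache(tmp_path))
        add_editor_search_tab(bundle, "CCO", LocalSearchBackend())
        assert bundle.tabs[-1].payload["no_results"] is True
        assert bundle.tabs[-1].payload["results"] == []

    def test_same_smiles_twice_gives_two_tabs(self, ozone_glossary, tmp_path):
        bundle = build_portlet(ozone_glossary.get("ozone"), stores_with_cache(tmp_path))
        backend = LocalSearchBackend()
        add_editor_search_tab(bundle, "C", backend)
        add_editor_search_tab(bundle, "C", backend)
        assert len(bundle.tabs) == 6

    def test_non_chemical_bundle_rejected(self, ozone_glossary):
        bundle = build_portlet(ozone_glossary.get("entropy"))
        with pytest.raises(IdentifierMismatchError):
            add_editor_search_tab(bundle, "C", LocalSearchBackend())


class TestSerialization:
    def test_bundle_json_round_trip(self, ozone_glossary, tmp_path):
        bundle = build_portlet(ozone_glossary.get("ozone"), stores_with_cache(tmp_path))
        add_editor_search_tab(bundle, "C", LocalSearchBackend())
        again = PortletBundle.from_json(bundle.to_json())
        assert again.to_json() == bundle.to_json()
        assert [t.kind for t in again.tabs] == [t.kind for t in bundle.tabs]


class TestThumbnails:
    def test_round_trip_bytes(self, tmp_path):
        path = decode_thumbnail(base64.b64encode(PNG_1PX).decode(), tmp_path / "thumbs")
        assert path.read_bytes() == PNG_1PX

    def test_invalid_base64(self, tmp_path):
        with pytest.raises(PayloadError):
            decode_thumbnail("!!!not base64!!!", tmp_path)

    def test_non_png_payload(self, tmp_path):
        with pytest.raises(PayloadError, match="PNG"):
            decode_thumbnail(base64.b64encode(b"GIF89a...").decode(), tmp_path)

    def test_repeated_decode_single_file(self, tmp_path):
        b64 = base64.b64encode(PNG_1PX).decode()
        p1 = decode_thumbnail(b64, tmp_path / "s")
        p2 = decode_thumbnail(b64, tmp_path / "s")
        assert p1 == p2
        assert len(list((tmp_path / "s").iterdir())) == 1
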