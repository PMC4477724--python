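import pytest

from whg.chem_semantics import StructureCache
from whg.glossary_model import (
    SemanticIdentifier,
    WordType,
    add_term,
    create_glossary,
)

OZONE_INCHI = "InChI=1S/O3/c1-3-2"
OZONE_INCHIKEY = "CBENFWSGALASAD-UHFFFAOYSA-N"
METHANE_INCHI = "InChI=1S/CH4/h1H4"
WATER_INCHI = "InChI=1S/H2O/h1H2"
WATER_INCHIKEY = "XLYOFNOQVPJJNP-UHFFFAOYSA-N"


@pytest.fixture
def ozone_glossary():
    """Two-field glossary holding one chemical, one protein, one plain term."""
    g = create_glossary("demo", 2, [True, False], source_citation="Demo source")
    add_term(
        g,
        "ozone",
        WordType.CHEMICAL,
        SemanticIdentifier.inchi(OZONE_INCHI),
        ["O3, a triatomic allotrope of oxygen.", "wiki notes"],
    )
    add_term(
        g,
        "lysozyme",
        WordType.PROTEIN,
        SemanticIdentifier.pdb("1LYZ"),
        ["an antibacterial enzyme.", ""],
    )
    add_term(g, "entropy", WordType.NO_TYPE, None, ["state function S.", ""])
    return g


@pytest.fixture
def cache(tmp_path):
    return StructureCache(tmp_path / "mol2cache")
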