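"""Synthetic glossaries and documents for offline testing and demos.

Everything downstream of glossary construction — matching, tagging,
typing, portlet assembly — is exercised against fixtures built here, so
no network or curated corpus is required.  A :class:`FixtureSpec` fully
determines the output through its seed: glossaries mix untyped vocabulary
words, chemicals drawn from a packaged (name, SMILES) list with InChIs
computed at build time, and protein names with synthetic PDB ids;
documents are small HTML pages with a known manifest of planted term
mentions plus optional negative controls (the same terms inside anchors
and a script block, which must never be tagged).

What these fixtures emulate: mixed-type glossaries, mixed-case mentions,
multi-word chemical names, pre-existing links.  What they do not: the
messiness of real web pages (broken markup at scale, deep nesting,
non-text media), real curated definitions, or names whose chemical
identity is genuinely ambiguous.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Optional

from . import chem_semantics
from .errors import FixtureSpecError
from .glossary_model import (
    Glossary,
    SemanticIdentifier,
    WordType,
    add_term,
    create_glossary,
)

#: Small molecules with trusted SMILES; InChIs are derived at run time.
MOLECULES: list[tuple[str, str]] = [
    ("water", "O"),
    ("methane", "C"),
    ("ethane", "CC"),
    ("propane", "CCC"),
    ("butane", "CCCC"),
    ("pentane", "CCCCC"),
    ("hexane", "CCCCCC"),
    ("ethene", "C=C"),
    ("ethyne", "C#C"),
    ("benzene", "c1ccccc1"),
    ("toluene", "Cc1ccccc1"),
    ("phenol", "Oc1ccccc1"),
    ("aniline", "Nc1ccccc1"),
    ("pyridine", "c1ccncc1"),
    ("furan", "c1ccoc1"),
    ("thiophene", "c1ccsc1"),
    ("pyrrole", "c1cc[nH]c1"),
    ("naphthalene", "c1ccc2ccccc2c1"),
    ("methanol", "CO"),
    ("ethanol", "CCO"),
    ("isopropanol", "CC(C)O"),
    ("glycerol", "OCC(O)CO"),
    ("formaldehyde", "C=O"),
    ("acetaldehyde", "CC=O"),
    ("acetone", "CC(C)=O"),
    ("butanone", "CCC(C)=O"),
    ("propanal", "CCC=O"),
    ("formic acid", "OC=O"),
    ("acetic acid", "CC(O)=O"),
    ("benzoic acid", "OC(=O)c1ccccc1"),
    ("oxalic acid", "OC(=O)C(O)=O"),
    ("ethyl acetate", "CCOC(C)=O"),
    ("methyl formate", "COC=O"),
    ("diethyl ether", "CCOCC"),
    ("tetrahydrofuran", "C1CCOC1"),
    ("dimethyl sulfoxide", "CS(C)=O"),
    ("acetonitrile", "CC#N"),
    ("nitromethane", "C[N+]([O-])=O"),
    ("ammonia", "N"),
    ("hydrogen sulfide", "S"),
    ("carbon dioxide", "O=C=O"),
    ("carbon monoxide", "[C-]#[O+]"),
    ("ozone", "[O-][O+]=O"),
    ("hydrogen peroxide", "OO"),
    ("nitric acid", "O[N+]([O-])=O"),
    ("sulfuric acid", "OS(=O)(=O)O"),
    ("methylamine", "CN"),
    ("dimethylamine", "CNC"),
    ("trimethylamine", "CN(C)C"),
    ("ethylamine", "CCN"),
    ("urea", "NC(N)=O"),
    ("glycine", "NCC(O)=O"),
    ("alanine", "CC(N)C(O)=O"),
    ("glucose", "OCC1OC(O)C(O)C(O)C1O"),
    ("caffeine", "Cn1cnc2c1c(=O)n(C)c(=O)n2C"),
    ("aspirin", "CC(=O)Oc1ccccc1C(O)=O"),
    ("ibuprofen", "CC(C)Cc1ccc(cc1)C(C)C(O)=O"),
    ("paracetamol", "CC(=O)Nc1ccc(O)cc1"),
    ("nicotine", "CN1CCCC1c1cccnc1"),
    ("chloromethane", "CCl"),
    ("dichloromethane", "ClCCl"),
    ("chloroform", "ClC(Cl)Cl"),
    ("carbon tetrachloride", "ClC(Cl)(Cl)Cl"),
    ("ethylene glycol", "OCCO"),
    ("styrene", "C=Cc1ccccc1"),
    ("cyclohexane", "C1CCCCC1"),
    ("cyclohexanol", "OC1CCCCC1"),
]

#: Protein names with synthetic PDB-style ids (4 alphanumerics).
PROTEINS: list[tuple[str, str]] = [
    ("lysozyme", "1LYZ"),
    ("myoglobin", "1MBN"),
    ("hemoglobin", "1HHO"),
    ("insulin", "4INS"),
    ("ubiquitin", "1UBQ"),
    ("trypsin", "1TRN"),
    ("ferritin", "1FHA"),
    ("pepsin", "4PEP"),
    ("catalase", "1DGF"),
    ("albumin", "1AO6"),
]

#: Untyped domain vocabulary (no chemical identity).
VOCABULARY: list[str] = [
    "entropy", "enthalpy", "titration", "catalyst", "isotope", "polymer",
    "oxidation", "reduction", "solvent", "solute", "molarity", "kinetics",
    "equilibrium", "valence", "electronegativity", "stoichiometry",
    "sublimation", "viscosity", "adsorption", "chromatography",
    "distillation", "precipitation", "ligand", "monomer", "electrolysis",
    "anode", "cathode", "allotrope", "azeotrope", "ozone layer",
]

# Filler words are disjoint from every fixture vocabulary above, so a
# planted document matches exactly its manifest.
_FILLER = [
    "the", "report", "describes", "measurements", "taken", "during",
    "routine", "observation", "and", "summarizes", "findings", "for",
    "this", "section", "of", "that", "study", "results", "were",
    "recorded", "in", "series", "then", "reviewed",
]


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a synthetic glossary/document pair.

    Defaults give a small mixed glossary (ten terms: three chemicals, one
    protein, six untyped words) and one document with five planted
    mentions plus link/script negative controls — enough to exercise
    every word type and the unsafe-region rules while staying readable.
    """

    n_terms: int = 10
    fraction_chemical: float = 0.3
    fraction_protein: float = 0.1
    n_documents: int = 1
    mentions_per_document: int = 5
    with_links: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for frac in (self.fraction_chemical, self.fraction_protein):
            if not 0.0 <= frac <= 1.0:
                raise FixtureSpecError(f"fraction {frac} outside [0, 1]")
        if self.fraction_chemical + self.fraction_protein > 1.0 + 1e-12:
            raise FixtureSpecError("word-type fractions sum to more than 1")
        if self.n_terms < 1:
            raise FixtureSpecError("n_terms must be positive")

    @property
    def n_chemical(self) -> int:
        return int(self.fraction_chemical * self.n_terms)

    @property
    def n_protein(self) -> int:
        return int(self.fraction_protein * self.n_terms)


def make_demo_glossary(spec: FixtureSpec, name: str = "demo") -> Glossary:
    """Build a deterministic mixed-type glossary.

    Counts follow ``floor(fraction * n_terms)`` per typed category; the
    remainder is untyped vocabulary.  Field layout is a locked canonical
    field plus one wiki field, with a glossary-wide citation.
    """
    rng = random.Random(spec.seed)
    n_chem, n_prot = spec.n_chemical, spec.n_protein
    n_plain = spec.n_terms - n_chem - n_prot
    if n_chem > len(MOLECULES) or n_prot > len(PROTEINS) or n_plain > len(VOCABULARY):
        raise FixtureSpecError("requested more terms than the packaged vocabularies hold")
    molecules = rng.sample(MOLECULES, n_chem)
    proteins = rng.sample(PROTEINS, n_prot)
    words = rng.sample(VOCABULARY, n_plain)

    glossary = create_glossary(
        name, 2, [True, False], source_citation="Synthetic demo corpus"
    )
    for term_name, smiles in molecules:
        inchi = chem_semantics.smiles_to_inchi(smiles)
        add_term(
            glossary,
            term_name,
            WordType.CHEMICAL,
            SemanticIdentifier.inchi(inchi),
            [f"{term_name}: a small molecule ({smiles}).", ""],
        )
    for term_name, pdb_id in proteins:
        add_term(
            glossary,
            term_name,
            WordType.PROTEIN,
            SemanticIdentifier.pdb(pdb_id),
            [f"{term_name}: a well-characterized protein.", ""],
        )
    for term_name in words:
        add_term(
            glossary,
            term_name,
            WordType.NO_TYPE,
            None,
            [f"{term_name}: a general domain concept.", ""],
        )
    return glossary


def _filler(rng: random.Random, n: int) -> str:
    return " ".join(rng.choice(_FILLER) for _ in range(n))


def _vary_case(rng: random.Random, name: str) -> str:
    style = rng.randrange(3)
    if style == 1:
        return name.capitalize()
    if style == 2:
        return name.upper()
    return name


def make_demo_document(
    glossary: Glossary,
    spec: FixtureSpec,
    rng: Optional[random.Random] = None,
) -> tuple[str, dict]:
    """Generate one HTML document with a known mention manifest.

    The manifest records each planted safe-text mention (canonical key and
    display casing, in order).  With ``with_links`` the page additionally
    plants glossary terms inside an anchor and a script block; those are
    negative controls and appear in the manifest under ``controls``.
    """
    if not glossary.terms:
        raise FixtureSpecError("glossary has no terms to plant")
    rng = rng or random.Random(spec.seed + 1)
    keys = sorted(glossary.terms)
    mentions = []
    sentences = []
    for _ in range(spec.mentions_per_document):
        key = rng.choice(keys)
        display = _vary_case(rng, glossary.terms[key].name)
        mentions.append({"key": key, "display": display})
        sentences.append(
            f"{_filler(rng, rng.randint(3, 6))} {display} {_filler(rng, rng.randint(2, 4))}."
        )
    body = "<p>" + " ".join(sentences) + "</p>"
    controls = []
    if spec.with_links:
        linked = rng.choice(keys)
        scripted = rng.choice(keys)
        controls = [
            {"key": linked, "where": "anchor"},
            {"key": scripted, "where": "script"},
        ]
        body += (
            f'\n<p>See <a href="#ref-{linked.replace(" ", "-")}">'
            f"{glossary.terms[linked].name}</a> for background.</p>"
            f'\n<script>var probe = "{glossary.terms[scripted].name}";</script>'
        )
    html = (
        "<html><head><title>synthetic fixture page</title></head>\n"
        f"<body>\n{body}\n</body></html>\n"
    )
    manifest = {
        "glossary": glossary.name,
        "mentions": mentions,
        "controls": controls,
        "seed": spec.seed,
    }
    return html, manifest


def make_demo_corpus(spec: FixtureSpec) -> tuple[Glossary, list[tuple[str, dict]]]:
    """Glossary plus ``n_documents`` (html, manifest) pairs."""
    glossary = make_demo_glossary(spec)
    rng = random.Random(spec.seed + 1)
    docs = [make_demo_document(glossary, spec, rng) for _ in range(spec.n_documents)]
    return glossary, docs
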