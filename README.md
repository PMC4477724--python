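# whg — an offline hyperglossary toolkit

`whg` automates the hyperlinking of domain terms in documents against typed
glossaries, the way a server-side hyperglossary enhances reading
comprehension: a reader submits a page, the system tags every word or phrase
found in a chosen lexicon, and each tagged term opens a bundle of definition
and structure content. This package is the document-processing and
content-management core of such a system as an offline-first library + CLI:
no web server, no live chemistry services — structure identity is carried by
semantic identifiers (InChI for chemicals, PDB ids for proteins) and all
conversions run locally through RDKit.

It is aimed at chemistry-education and cheminformatics tooling work:
building and curating typed glossaries, bulk-preparing established
glossaries for import, annotating documents reproducibly, and assembling
the per-term "portlet" payloads a front end would render.

## What it does

- **Glossary model** (`whg.glossary_model`) — terms carry a word type
  (`no_type` | `chemical` | `protein`), a semantic identifier where typed,
  and up to 5 numbered definition fields. Fields are *locked* (canonical
  content, e.g. a learned-society definition with a glossary-wide source
  citation) or editable wiki fields with full append-only version history.
- **Document processing** (`whg.document_processor`) — splits HTML into
  *safe* text and *unsafe* regions (markup, pre-existing links, scripts,
  styles, head content, comments, previously inserted tags — all preserved
  byte-for-byte), finds glossary terms in safe text with leftmost-longest,
  case-insensitive whole-word matching, and wraps each hit in an HG tag:

  ```html
  <span class="hg3" context="search" wordterm="ozone">ozone</span>
  ```

  Processing is idempotent, conserves the visible text exactly, and never
  touches existing anchors.
- **Interchange** (`whg.glossary_io`) — a schema-validated XML dialect for
  bulk upload/round-trip, RFC 4180 CSV dumps, and ingestion of two-column
  term/definition tables.
- **Chemical semantics** (`whg.chem_semantics`) — InChI ↔ SMILES ↔ InChIKey
  conversions, dual-resolver name-to-structure agreement (a term is typed
  *chemical* only when independent resolvers return the same normalized
  InChI), and seeded distance-geometry 3D embedding cached as mol2 files
  keyed by InChIKey (each key generated exactly once).
- **Portlets** (`whg.portlet_content`) — the per-term tab bundle: 1 tab for
  plain terms (Definition), 4 for chemicals (Definition, Search,
  3D Structure, 2D Structure), 2 for proteins (Definition, 3D Structure).
  The 2D editor payload spawns accumulating search tabs: successively
  chlorinating methane (CH4 → CH3Cl → CH2Cl2 → CHCl3 → CCl4) yields five
  search tabs, one per species.
- **Fixtures + CLI** (`whg.fixtures`, `whg.cli`) — a seeded synthetic
  generator for mixed-type glossaries and documents with known planted
  mentions, and the `whg` command-line tool.

## Worked example

```sh
$ whg fixtures --out-dir demo --seed 3
{"glossary": "demo/glossary.xml", "document": "demo/document.html",
 "manifest": "demo/manifest.json", "terms": 10, "mentions": 5}

$ whg process --glossary demo/glossary.xml --file demo/document.html \
      --out demo/tagged.html --spans demo/spans.json
```

`demo/spans.json` then lists one entry per planted mention, e.g.

```json
{"wordterm": "dimethylamine", "matched_text": "Dimethylamine",
 "glossary": "demo", "start": 86, "end": 99}
```

— the case-folded glossary key, the display text as it appeared, and the
0-based character offsets into the source document. The tagged HTML wraps
exactly those ranges in HG spans; the terms planted inside the fixture's
anchor and script block are left untouched.

Portlet assembly for a chemical term prints the 4-tab bundle, and editor
searches accumulate:

```sh
$ whg portlet --glossary demo/glossary.xml --term pyrrole \
      --edit-search C --edit-search CCl | python -c \
      "import json,sys; print([t['title'] for t in json.load(sys.stdin)['tabs']])"
['Definition', 'Search', '3D Structure', '2D Structure', 'Search: C', 'Search: CCl']
```

Bulk preparation of a raw glossary table (ingest → map → type → export):

```sh
$ whg prep terms.tsv prepared.xml --resolvers local:svc_a.json,local:svc_b.json
{"glossary": "prepared", "terms": 3, "chemical": 2, "review": 0, "out": "prepared.xml"}
```

Terms both resolver tables agree on become `chemical` with their InChI;
disagreements and partial answers land on a review list instead of being
typed silently.

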