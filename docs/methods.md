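# Methods

This note records the models, conventions and numerical choices behind
`whg`, and what the test fixtures do and do not demonstrate.

## Glossary model

A glossary is a lexicon of terms with a fixed field layout chosen at
creation: `field_count` (1–5) definition slots and a per-index lock mask.
The canonical-plus-wiki architecture — a locked field 1 bulk-imported from
an established glossary, with a glossary-wide `source_citation`, beside up
to four editable wiki fields — is one configuration of this layout, not a
special case in the code. Edits are append-only: each successful edit
appends a `DefinitionVersion` with a strictly increasing ordinal, a
free-text author and a UTC timestamp (UTC so orderings are reproducible
across machines). Locked fields reject edits unconditionally; there is no
authentication layer — access control is out of scope, and the lock flags
are the data-level residue of it.

Term keys are the NFC-normalized, Unicode case-folded, whitespace-collapsed
form of the display name; keys are unique per glossary and the display
casing is preserved. Uniqueness across glossaries is not enforced —
processing runs against one glossary at a time, and multi-glossary
processing is future work.

Persistence is a single XML document per glossary (schema shipped with the
package) rather than a database: glossaries at this scale are small, and a
diffable text store needs no daemon. Deliberate consequence: the store
carries current content only, so version history is session state. A
write/parse round trip preserves everything except history; the CLI
`history` command therefore shows one version, while the in-memory API
keeps the full chain.

## Document processing

Segmentation uses the stdlib tolerant HTML parser with character-reference
conversion disabled, so every safe text token is a literal substring of the
source and all offsets are exact 0-based half-open indices into the raw
document. Unsafe content — preserved byte-for-byte, never tagged — is: all
markup and attributes, comments and declarations, character/entity
references, and the entire content of `a`, `script`, `style`, `head`,
`title`, `textarea`, plus previously inserted HG spans (`span` with class
`hg3`, including nested plain spans within them). The unsafe element set is
a parameter of `segment()`. Treating existing HG spans as unsafe is what
makes processing idempotent. Plain text without markup is a single safe
segment; gaps produced by malformed markup fall to unsafe, so segments
always concatenate to the source.

Matching is case-insensitive with the display text preserved and the
case-folded key recorded in the `wordterm` attribute. Word characters are
Unicode letters, digits and the hyphen: matches must be flanked by
non-word characters, so `ozone` does not match inside `ozonelayer` or
`ozone-depleting` (the hyphen rule reflects hyphenated chemical names; it
is a documented convention, not the only defensible one — underscore is
deliberately a boundary). Phrase-internal single spaces in a key match any
run of whitespace in the document, which is equivalent to normalizing
whitespace before lookup while keeping offsets in the original text.
Overlaps resolve leftmost-longest with no rescanning inside an accepted
span: the scanner finds the earliest position where any key matches, takes
the longest actual match anchored there (candidate keys are tried
explicitly rather than trusting alternation order, since whitespace runs
can make a shorter key yield a longer match), and resumes after it. A
brute-force oracle that enumerates every candidate substring is kept in
the test suite as the reference semantics.

The emitted tag is exactly
`<span class="hg3" context="search" wordterm="KEY">TEXT</span>` with the
attribute value HTML-escaped. The class string `hg3` is reproduced as the
established tag dialect, not interpreted.

## Interchange

The XML dialect (see `src/whg/data/glossary.xsd`) is UTF-8 with
definitions as CDATA so embedded multimedia HTML survives. On parse, a
definition's `locked` attribute wins over the glossary mask, and field 1
is forced locked when a source citation is present — matching the
canonical-import convention. Validation failures report the first
offending element/attribute with its line. CSV export follows RFC 4180
(CRLF, minimal quoting); ingestion starts at the tabular stage (term and
definition columns of a delimited file) — parsing arbitrary source
documents is out of scope, and the delimited form replaces the
spreadsheet-macro step of the historical workflow with the same
information content.

## Chemical semantics

Conversions delegate to RDKit; InChI canonicalization is never
reimplemented. The standard InChIKey is 27 characters including hyphens
(`^[A-Z]{14}-[A-Z]{10}-[A-Z]$`). Name resolution compares answers after
re-deriving the standard InChI from each resolver's string, so trivially
different spellings of the same structure agree, and uses exact string
equality on the result — no layer-dropping. Outcomes: *agreed* (all
resolvers answered identically) types the term; *disagreed* (≥2 distinct
answers) goes to review; a partial answer (some resolvers silent) goes to
review by default, or counts as agreement when `accept_partial=True` —
exposed as configuration because a single affirmative answer is weaker
evidence. Resolver exceptions count as silence, never propagate, and
outcomes are independent of resolver order. Typed terms are never demoted.

3D structures: single conformer from a seeded ETKDGv3 distance-geometry
embedding (no multi-objective conformer ensemble — the contract is
plausible 3D coordinates for display, not a conformational search),
hydrogens added, written as Tripos mol2 with fixed 4-decimal coordinates
so a fixed seed gives byte-identical files. The mol2 serializer is local
to this package (element-symbol atom types, Tripos bond codes);
disconnected species are rejected with the InChIKey named. The cache
directory is keyed by InChIKey and a key, once written, is never
regenerated (`generation_count` instruments this).

## Portlets

Tab layout is a pure function of word type — 1 (Definition) for plain
terms, 4 (Definition, Search, 3D Structure, 2D Structure) for chemicals,
2 (Definition, 3D Structure) for proteins — with editor-search tabs
appended after the base tabs, accumulating and never replacing. 3D source
precedence for chemicals: curated store by InChIKey first, seeded
generation only on a miss; proteins resolve through an injected PDB store
(no live fetch exists anywhere in the package). Payloads are JSON with
viewer hints naming the client component class (3D viewer, 2D editor)
rather than bundling a viewer; the 2D editor payload is SMILES plus the
term's InChI, chosen over a legacy editor-native format because SMILES is
the query currency of the search step and loses nothing at this scale.
Thumbnails arrive as base64, are validated against the PNG signature and
stored once per content hash.

## Synthetic fixtures

The generator emulates the study conditions end to end: mixed-type
glossaries (default 10 terms — floor(0.3·n)=3 chemicals from a packaged
(name, SMILES) list with InChIs derived at run time, floor(0.1·n)=1
protein with a synthetic 4-character PDB-style id, 6 untyped vocabulary
words; two fields, locked canonical + wiki, glossary-wide citation) and
documents with 5 planted mentions in varied casing plus negative controls
(the same terms inside an anchor and a script block). Filler vocabulary is
disjoint from every term list, so the manifest is exact ground truth: n
planted mentions must yield exactly n spans. All outputs are bit-for-bit
reproducible from the spec and seed.

What passing these fixtures does not show: robustness to the messiness of
real web pages at scale (deeply broken markup, frames, huge scripts),
matching of names with genuinely ambiguous chemical identity, term casing
semantics beyond Unicode case-folding (e.g. a text ß matching a key ss is
not supported), or the quality of curated definitions — the fixtures test
the machinery, not a corpus.

## Problem sizes and tolerances

Randomized suites use seeded generators (fixed seeds in tests;
`--seed`-derived streams in `scripts/acceptance.py`): 200 matcher/oracle
instances (documents ≤ 500 characters, ≤ 20 terms), 40 HTML-conservation
documents, 50 XML round-trip glossaries, 50 molecules for the InChIKey
invariant, a 20-document planted-mention corpus. These sizes exercise
every code path many times while keeping the full suite under a few
seconds. All structural quantities (tab counts, field caps, generation
counts) are exact integers with no tolerance; the only floating-point
outputs are percentages of exact-agreement counts.
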