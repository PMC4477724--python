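"""Exception hierarchy.

All domain failures derive from :class:`WHGError` so callers (and the CLI)
can distinguish domain errors (exit code 1) from usage errors (exit code 2).
"""


class WHGError(Exception):
    """Base class for all domain errors raised by this package."""


class LimitViolation(WHGError):
    """A structural cap was exceeded (e.g. more than 5 definition fields)."""


class LockViolation(WHGError):
    """An edit was attempted on a locked definition field."""


class DuplicateTermError(WHGError):
    """A term key (case-folded name) already exists in the glossary."""


class IdentifierMismatchError(WHGError):
    """A term's semantic identifier is inconsistent with its word type."""


class FieldRangeError(WHGError, IndexError):
    """A definition-field index is outside the term's field layout."""


class InactiveGlossaryError(WHGError):
    """An operation requires an active glossary."""


class EmptyGlossaryError(WHGError):
    """An operation requires a glossary with at least one term."""


class SegmentSafetyError(WHGError):
    """A matcher was applied to an unsafe document segment."""


class OverlapError(WHGError):
    """Annotation spans overlap and cannot be rendered."""


class SchemaError(WHGError):
    """An XML glossary document failed schema validation."""


class IngestError(WHGError):
    """A tabular glossary dump could not be ingested."""


class ChemistryError(WHGError):
    """A chemical identifier could not be parsed or converted."""


class StructureGenerationError(ChemistryError):
    """3D coordinate generation failed for a molecule."""


class StructureLookupError(WHGError):
    """No structure could be located for an identifier (curated, generated or PDB)."""


class PayloadError(WHGError):
    """A portlet payload was malformed (bad base64, non-PNG bytes, ...)."""


class FixtureSpecError(WHGError):
    """A synthetic-fixture specification was invalid."""
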