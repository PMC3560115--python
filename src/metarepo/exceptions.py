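"""Exception hierarchy for the repository engine.

Structural problems (a schema that contradicts itself), usage problems (an
instance checked against the wrong schema) and data problems (a value that
fails validation) are kept distinct so callers can react differently.
"""


class RepositoryError(Exception):
    """Base class for every error raised by this package."""


class SchemaStructureError(RepositoryError):
    """A data-type definition violates a structural invariant.

    The message names the offending path (group / loop / attribute).
    """


class SchemaParseError(RepositoryError):
    """An XML document is not a well-formed data-type or instance document."""


class EvolutionError(RepositoryError):
    """A schema change is destructive or would invalidate stored instances."""


class InstanceValidationError(RepositoryError):
    """An instance failed validation against its pinned schema.

    Carries the full violation report in ``report``.
    """

    def __init__(self, message: str, report=None):
        super().__init__(message)
        self.report = list(report or [])


class ValidationUsageError(RepositoryError):
    """validate_instance called with a schema that does not match the
    instance's pinned datatype name/version (distinct from a violation)."""


class AssociationError(RepositoryError):
    """A file was attached to an instance of a non-file-associated datatype."""


class NotFoundError(RepositoryError):
    """A named entity (datatype, subject, instance, sample...) does not exist."""


class ConflictError(RepositoryError):
    """An entity with the same key already exists (schema version, freezer id)."""


class IntegrityError(RepositoryError):
    """A reference does not resolve (dangling subject, data ref...)."""


class TaxonomyError(RepositoryError):
    """A process/event operation violates the taxonomy (unknown type,
    disallowed child type)."""


class CompositionError(RepositoryError):
    """A query condition is invalid against the stored schemas
    (unknown path, operator/kind mismatch)."""


class AccessError(RepositoryError):
    """An ACL operation names an unknown group or resource."""


class OccupancyError(RepositoryError):
    """A freezer coordinate is already occupied or out of bounds."""


class ModalityRejection(RepositoryError):
    """An uploaded file was rejected (not DICOM, or unmapped modality).

    Distinct from OSError: the file was readable, just not acceptable.
    """

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


class ExtractionError(RepositoryError):
    """DICOM metadata extraction failed (missing required tag, bad value)."""
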