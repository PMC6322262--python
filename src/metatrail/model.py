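"""Domain types for the metadata store.

The design is entity–attribute–value (EAV): a tracked entity (project or
sample) carries its metadata as rows of (field, value) pairs rather than as
columns of a wide table, so a study's field set is configuration data, not
schema.  Every change arrives as an *event* — a named group of field values
loaded together — and the per-entity "current state" is merely the fold of
that entity's event history in commit order.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field as dc_field
from typing import Optional

#: the five supported field data types
DATA_TYPES = ("string", "date", "integer", "float", "file")

#: closed set of validation finding codes
ISSUE_CODES = (
    "type_error",
    "required_missing",
    "max_length",
    "option_violation",
    "pattern_mismatch",
    "dictionary_violation",
    "uniqueness_violation",
    "readonly_conflict",
    "unknown_field",
    "unknown_template",
)

#: names of the event templates every store is born with
BUILTIN_TEMPLATES = (
    ("ProjectRegistration", "project"),
    ("ProjectUpdate", "project"),
    ("SampleRegistration", "sample"),
    ("SampleUpdate", "sample"),
)

#: identity columns: they resolve the target entity and are kept in the
#: audit record, but are not materialized as ordinary attributes
PROJECT_NAME_FIELD = "Project Name"
SAMPLE_NAME_FIELD = "Sample Name"
PARENT_SAMPLE_FIELD = "Parent Sample"
IDENTITY_FIELDS = (PROJECT_NAME_FIELD, SAMPLE_NAME_FIELD)

#: an explicit literal NULL cell clears a stored value (an *empty* cell
#: means "no change")
NULL_LITERAL = "NULL"


def canonical_name(name: str) -> str:
    """Canonical form of an event-template name: all whitespace stripped,
    case-insensitive.  ``"Sample Registration"`` and ``"SampleRegistration"``
    are the same template."""
    return re.sub(r"\s+", "", name).lower()


@dataclass(frozen=True)
class InputSpec:
    """Parsed input-type annotation governing allowed values for one field.

    Exactly the attributes relevant to ``kind`` are populated; the rest stay
    at their empty defaults.
    """

    kind: str = "freeform"
    options: tuple[str, ...] = ()          # radio / dropdown / multi_dropdown
    default: str = ""                      # readonly
    pattern: str = ""                      # regex
    validator_key: str = ""                # custom_validator
    dictionary_name: str = ""              # dictionary
    parent_field: Optional[str] = None     # dictionary cascade

    KINDS = (
        "freeform", "radio", "dropdown", "multi_dropdown",
        "readonly", "regex", "custom_validator", "dictionary",
    )

    def __post_init__(self):
        if self.kind not in self.KINDS:
            raise ValueError(f"unknown InputSpec kind {self.kind!r}")
        if self.kind in ("radio", "dropdown", "multi_dropdown") and not self.options:
            raise ValueError(f"{self.kind} spec requires a non-empty option list")
        if self.kind == "dictionary" and not self.dictionary_name:
            raise ValueError("dictionary spec requires a dictionary name")


@dataclass
class FieldDefinition:
    """Metadata about one metadata field: how it is typed, ordered,
    annotated and validated (a *meta-attribute* row)."""

    name: str
    data_type: str = "string"
    required: bool = False
    active: bool = True
    max_length: Optional[int] = None
    description: str = ""
    ontology_class: Optional[str] = None
    position: int = 0
    annotation: InputSpec = dc_field(default_factory=InputSpec)

    def __post_init__(self):
        if self.data_type not in DATA_TYPES:
            raise ValueError(
                f"data_type must be one of {DATA_TYPES}, got {self.data_type!r}")
        if self.max_length is not None and self.max_length <= 0:
            raise ValueError("max_length must be positive")
        if self.required and not self.active:
            raise ValueError("inactive fields cannot be required")


@dataclass
class EventTemplate:
    """A named operation on a project or sample, carrying an ordered set of
    field definitions.  The unit of loading and audit."""

    name: str                  # canonical (whitespace-stripped, lowercase)
    display_name: str
    scope: str                 # "project" | "sample"
    fields: list[FieldDefinition] = dc_field(default_factory=list)

    def __post_init__(self):
        if self.scope not in ("project", "sample"):
            raise ValueError("scope must be 'project' or 'sample'")

    @property
    def is_registration(self) -> bool:
        return self.name.endswith("registration")

    def field_map(self) -> dict[str, FieldDefinition]:
        return {f.name: f for f in self.fields}

    def ordered_fields(self, active_only: bool = False) -> list[FieldDefinition]:
        fs = [f for f in self.fields if f.active or not active_only]
        return sorted(fs, key=lambda f: (f.position, f.name))


@dataclass(frozen=True)
class AttributeValue:
    """One submitted field value inside an event record."""

    field: str           # field name as defined in the template
    raw: str             # text exactly as submitted
    normalized: str      # canonical text (ISO date, canonical decimal, ...)


@dataclass(frozen=True)
class Project:
    id: int
    name: str
    created_by: str
    created_at: str


@dataclass(frozen=True)
class Sample:
    id: int
    project: str         # owning project name
    name: str
    parent_sample: Optional[str] = None


@dataclass(frozen=True)
class UserGrant:
    user: str
    project: str
    role: str            # "view" | "edit"


@dataclass(frozen=True)
class EventRecord:
    """One committed event occurrence — the immutable unit of the audit
    trail.  ``id`` order equals commit order."""

    id: int
    template: str        # canonical template name
    project: str
    sample: Optional[str]
    actor: str
    timestamp: str       # ISO 8601, assigned at commit
    values: tuple[AttributeValue, ...]


@dataclass(frozen=True)
class ValidationIssue:
    """One validation finding, tied to a 1-based row index and a field.
    ``severity`` is "error" (blocks loading) or "warning" (reported only)."""

    row_index: int
    field: str
    code: str
    message: str
    severity: str = "error"

    def __post_init__(self):
        if self.code not in ISSUE_CODES:
            raise ValueError(f"unknown issue code {self.code!r}")


@dataclass
class ValidationReport:
    """Batch validation outcome: all findings plus per-row pass/fail.

    ``normalized_rows`` carries the canonical text of every passing cell so
    a subsequent load does not re-coerce; it is populated by
    :func:`metatrail.validation.validate_batch`.
    """

    issues: list[ValidationIssue]
    row_ok: list[bool]
    normalized_rows: Optional[list[dict[str, str]]] = None

    @property
    def ok(self) -> bool:
        return not any(i.severity == "error" for i in self.issues)

    def errors(self) -> list[ValidationIssue]:
        return [i for i in self.issues if i.severity == "error"]

    def to_csv(self) -> str:
        """Error-report serialization: columns row,field,code,message."""
        import csv as _csv
        import io
        buf = io.StringIO()
        w = _csv.writer(buf, lineterminator="\n")
        w.writerow(["row", "field", "code", "message"])
        for i in self.issues:
            w.writerow([i.row_index, i.field, i.code, i.message])
        return buf.getvalue()


@dataclass
class LoadResult:
    """Outcome of a :meth:`MetadataStore.load_event` call."""

    status: str                      # "committed" | "rejected"
    events_created: int = 0
    samples_created: int = 0
    samples_updated: int = 0
    issues: list[ValidationIssue] = dc_field(default_factory=list)

    def __post_init__(self):
        if self.status == "rejected" and self.events_created:
            raise ValueError("rejected loads cannot create events")
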