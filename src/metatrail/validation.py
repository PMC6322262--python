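"""Row- and batch-level validation.

Validation never mutates the store and never raises on bad *data* — every
finding becomes a :class:`ValidationIssue` with a row index, a field name and
a closed-set code, so an entire CSV batch can be reported in one pass.
Exceptions are reserved for *configuration* problems (an annotation that
names an unregistered custom validator).

The pipeline per row: unknown-column detection, requiredness, annotation
evaluation (options, patterns, dictionary cascades, read-only defaults),
type coercion to canonical text, then custom validators.  Batch-level passes
add cross-row checks, chiefly opt-in field uniqueness
(``{validate:DataValidator.checkFieldUniqueness}``) which is enforced both
within the batch and against values already stored.
"""
from __future__ import annotations

import datetime as _dt
import re
from typing import Callable, Mapping, Optional, Protocol, Sequence

from . import annotations as _ann
from .errors import ConfigurationError
from .model import (
    NULL_LITERAL,
    PARENT_SAMPLE_FIELD,
    SAMPLE_NAME_FIELD,
    EventTemplate,
    ValidationIssue,
    ValidationReport,
)

#: registry key of the built-in cross-row uniqueness validator
UNIQUENESS_KEY = "DataValidator.checkFieldUniqueness"

_VALIDATOR_KEY_RE = re.compile(r"[A-Za-z_]\w*\.[A-Za-z_]\w*")

# accepted date layouts: M/D/YY, M/D/YYYY, ISO
_DATE_MDY = re.compile(r"(\d{1,2})/(\d{1,2})/(\d{2}|\d{4})")
_DATE_ISO = re.compile(r"(\d{4})-(\d{2})-(\d{2})")
_INT_RE = re.compile(r"[+-]?\d+")


def _builtin_uniqueness(field, raw, row, ctx):  # handled by the batch scan
    return []


class ValidatorRegistry:
    """Named custom validation procedures, invoked per row with
    ``(field_name, raw, row, store_context)``.  The built-in uniqueness
    validator is always registered."""

    def __init__(self):
        self._procs: dict[str, Callable] = {UNIQUENESS_KEY: _builtin_uniqueness}

    def register(self, key: str, procedure: Callable) -> None:
        if not _VALIDATOR_KEY_RE.fullmatch(key or ""):
            raise ConfigurationError(
                f"validator key must be dotted Class.method, got {key!r}")
        if key in self._procs:
            raise ConfigurationError(f"validator {key!r} already registered")
        self._procs[key] = procedure

    def __contains__(self, key: str) -> bool:
        return key in self._procs

    def get(self, key: str) -> Callable:
        try:
            return self._procs[key]
        except KeyError:
            raise ConfigurationError(
                f"no custom validator registered under {key!r}") from None


class BatchContext(Protocol):
    """What batch validation needs from the store, scoped to one project."""

    registry: ValidatorRegistry

    def dictionary_values(self, name: str, parent_value: Optional[str] = None) -> list[str]: ...

    def stored_field_values(self, field_name: str, scope: str) -> dict[str, str]:
        """normalized value -> owning entity name, over this project"""
        ...

    def sample_exists(self, name: str) -> bool: ...

    def would_create_cycle(self, child: str, parent: str) -> bool: ...


def coerce_value(
    data_type: str,
    raw: str,
    max_length: Optional[int] = None,
    *,
    row_index: int = 0,
    field: str = "",
) -> tuple[Optional[str], Optional[ValidationIssue]]:
    """Normalize one cell to canonical text.

    Dates become ISO ``YYYY-MM-DD`` (two-digit years pivot 00–69 → 20xx,
    70–99 → 19xx); integers and floats become canonical decimal text;
    string/file values pass through verbatim.  Empty raw yields empty
    normalized — requiredness is checked elsewhere.  Returns
    ``(normalized, None)`` on success or ``(None, issue)`` on failure.
    """

    def fail(code: str, message: str):
        return None, ValidationIssue(row_index=row_index, field=field,
                                     code=code, message=message)

    if raw == "":
        return "", None

    if data_type in ("string", "file"):
        normalized = raw
    elif data_type == "date":
        m = _DATE_MDY.fullmatch(raw)
        if m:
            mo, d, y = int(m.group(1)), int(m.group(2)), m.group(3)
            year = int(y)
            if len(y) == 2:
                year = 2000 + year if year <= 69 else 1900 + year
        else:
            m = _DATE_ISO.fullmatch(raw)
            if not m:
                return fail("type_error",
                            f"{raw!r} is not a valid date (M/D/YY, M/D/YYYY "
                            "or YYYY-MM-DD)")
            year, mo, d = int(m.group(1)), int(m.group(2)), int(m.group(3))
        try:
            normalized = _dt.date(year, mo, d).isoformat()
        except ValueError:
            return fail("type_error", f"{raw!r} is not a calendar date")
    elif data_type == "integer":
        if not _INT_RE.fullmatch(raw.strip()):
            return fail("type_error", f"{raw!r} is not an integer")
        normalized = str(int(raw))
    elif data_type == "float":
        try:
            value = float(raw)
        except ValueError:
            return fail("type_error", f"{raw!r} is not a number")
        if value != value or value in (float("inf"), float("-inf")):
            return fail("type_error", f"{raw!r} is not a finite number")
        normalized = repr(value)
    else:
        raise ValueError(f"unknown data_type {data_type!r}")

    if max_length is not None and len(normalized) > max_length:
        return fail("max_length",
                    f"value of length {len(normalized)} exceeds "
                    f"max_length={max_length}")
    return normalized, None


def validate_row(
    template: EventTemplate,
    row: Mapping[str, str],
    row_index: int,
    store_context: Optional[BatchContext] = None,
) -> tuple[list[ValidationIssue], dict[str, str]]:
    """Validate one row against a template.

    Returns ``(issues, normalized_row)`` where the normalized row carries
    canonical text for every cell that passed (read-only defaults filled,
    dates ISO).  The literal ``NULL`` cell is preserved as-is: it is the
    explicit clear marker, only illegal on required fields.
    """
    issues: list[ValidationIssue] = []
    fmap = template.field_map()
    normalized_row: dict[str, str] = {}

    for col in row:
        fd = fmap.get(col)
        if fd is None:
            issues.append(ValidationIssue(
                row_index=row_index, field=col, code="unknown_field",
                message=f"column {col!r} is not defined for event "
                        f"{template.display_name!r}"))
        elif not fd.active:
            issues.append(ValidationIssue(
                row_index=row_index, field=col, code="unknown_field",
                message=f"field {col!r} is inactive (deprecated)"))

    for fd in template.ordered_fields(active_only=True):
        raw = row.get(fd.name, "")
        if raw == NULL_LITERAL:
            if fd.required:
                issues.append(ValidationIssue(
                    row_index=row_index, field=fd.name, code="required_missing",
                    message=f"required field {fd.name!r} cannot be cleared"))
            else:
                normalized_row[fd.name] = NULL_LITERAL
            continue

        ann_issues, raw = _ann.validate_against_spec(
            fd.annotation, raw, row, store_context,
            row_index=row_index, field=fd.name)
        issues.extend(ann_issues)

        if fd.required and raw == "":
            issues.append(ValidationIssue(
                row_index=row_index, field=fd.name, code="required_missing",
                message=f"required field {fd.name!r} is missing or empty"))
            continue

        normalized, issue = coerce_value(fd.data_type, raw, fd.max_length,
                                         row_index=row_index, field=fd.name)
        if issue is not None:
            issues.append(issue)
            continue
        if ann_issues:
            continue
        if raw and fd.ontology_class and store_context is not None:
            from .ontology import term_issue
            msg = term_issue(getattr(store_context, "ontology_provider", None),
                             fd.ontology_class, raw)
            if msg is not None:
                issues.append(ValidationIssue(
                    row_index=row_index, field=fd.name,
                    code="option_violation", message=msg))
                continue
        normalized_row[fd.name] = normalized

        # custom validators get the whole row for context
        if (fd.annotation.kind == "custom_validator"
                and fd.annotation.validator_key != UNIQUENESS_KEY
                and store_context is not None):
            proc = store_context.registry.get(fd.annotation.validator_key)
            issues.extend(proc(fd.name, raw, row, store_context) or [])

    # sample hierarchy: a non-empty Parent Sample must name a known sample
    if (template.scope == "sample" and PARENT_SAMPLE_FIELD in normalized_row
            and store_context is not None):
        parent = normalized_row[PARENT_SAMPLE_FIELD]
        child = row.get(SAMPLE_NAME_FIELD, "")
        if parent not in ("", NULL_LITERAL):
            if parent == child:
                issues.append(ValidationIssue(
                    row_index=row_index, field=PARENT_SAMPLE_FIELD,
                    code="option_violation",
                    message="a sample cannot be its own parent"))
            elif not store_context.sample_exists(parent):
                issues.append(ValidationIssue(
                    row_index=row_index, field=PARENT_SAMPLE_FIELD,
                    code="option_violation",
                    message=f"parent sample {parent!r} not found in project"))
            elif store_context.would_create_cycle(child, parent):
                issues.append(ValidationIssue(
                    row_index=row_index, field=PARENT_SAMPLE_FIELD,
                    code="option_violation",
                    message=f"parent {parent!r} would create a cycle"))

    return issues, normalized_row


def check_template_validators(template: EventTemplate,
                              registry: ValidatorRegistry) -> None:
    """Configuration-time check: every custom-validator annotation on the
    template must resolve in the registry."""
    for fd in template.fields:
        if fd.annotation.kind == "custom_validator":
            key = fd.annotation.validator_key
            if key not in registry:
                raise ConfigurationError(
                    f"field {fd.name!r} references unregistered validator "
                    f"{key!r}")


def validate_batch(
    template: EventTemplate,
    rows: Sequence[Mapping[str, str]],
    store_context: Optional[BatchContext] = None,
) -> ValidationReport:
    """Validate an ordered batch of rows, including cross-row checks.

    Fields annotated with the built-in uniqueness validator must be unique
    within the batch (later duplicates are errors) and against stored
    values.  A stored collision is an error for registration events; for
    update events it is a warning unless the stored value belongs to the
    row's own target entity (an update legitimately re-sees itself).
    """
    if store_context is not None:
        check_template_validators(template, store_context.registry)

    issues: list[ValidationIssue] = []
    row_ok: list[bool] = []
    normalized_rows: list[dict[str, str]] = []
    for i, row in enumerate(rows, start=1):
        row_issues, normalized = validate_row(template, row, i, store_context)
        issues.extend(row_issues)
        row_ok.append(not any(x.severity == "error" for x in row_issues))
        normalized_rows.append(normalized)

    unique_fields = [fd.name for fd in template.fields
                     if fd.annotation.kind == "custom_validator"
                     and fd.annotation.validator_key == UNIQUENESS_KEY]
    for fname in unique_fields:
        stored: dict[str, str] = {}
        if store_context is not None:
            stored = store_context.stored_field_values(fname, template.scope)
        seen: dict[str, int] = {}
        for i, normalized in enumerate(normalized_rows, start=1):
            value = normalized.get(fname, "")
            if value in ("", NULL_LITERAL):
                continue
            if value in seen:
                issues.append(ValidationIssue(
                    row_index=i, field=fname, code="uniqueness_violation",
                    message=f"value {value!r} duplicates row {seen[value]} "
                            "in this batch"))
                row_ok[i - 1] = False
                continue
            seen[value] = i
            if value in stored:
                owner = stored[value]
                target = rows[i - 1].get(SAMPLE_NAME_FIELD, "")
                if template.is_registration:
                    issues.append(ValidationIssue(
                        row_index=i, field=fname, code="uniqueness_violation",
                        message=f"value {value!r} already stored for "
                                f"{owner!r}"))
                    row_ok[i - 1] = False
                elif owner != target:
                    issues.append(ValidationIssue(
                        row_index=i, field=fname, code="uniqueness_violation",
                        severity="warning",
                        message=f"value {value!r} already stored for "
                                f"{owner!r}"))

    return ValidationReport(issues=issues, row_ok=row_ok,
                            normalized_rows=normalized_rows)
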