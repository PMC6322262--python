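"""CSV dialects: data templates, blank templates, study setup files,
dictionary files.

Three plain-text formats travel between collaborators and the store, all
RFC 4180, UTF-8, LF-normalized on output:

* **data template** — first line ``#DataTemplate: <event name>``, second
  line the field headers, then data rows.  This is the file a lab fills in
  and loads.
* **setup file** — one row per (event, field) defining a study's metadata
  configuration: type, requiredness, activity, max length, description,
  ontology class, display position and the input-type annotation.  A whole
  study is configured from such a file and can be exported back to one, so
  existing studies serve as templates for new ones.
* **dictionary file** — ``dictionary,value,parent_value`` rows holding
  controlled lists; a row with an empty ``value`` declares the dictionary's
  parent (cascade) dictionary.
"""
from __future__ import annotations

import csv
import io
import re
from dataclasses import dataclass
from typing import Optional

from .annotations import parse_annotation, render_annotation
from .errors import FormatError, SetupError
from .model import (
    DATA_TYPES,
    EventTemplate,
    FieldDefinition,
    ValidationIssue,
    canonical_name,
)

_TEMPLATE_LINE_RE = re.compile(r"#DataTemplate:\s*(.+?)\s*$")

SETUP_COLUMNS = (
    "event_name", "field_name", "data_type", "required", "active",
    "max_length", "description", "ontology_class", "position",
    "default_options",
)

DICTIONARY_COLUMNS = ("dictionary", "value", "parent_value")

_TRUE = {"yes", "true", "1", "y"}
_FALSE = {"no", "false", "0", "n", ""}


@dataclass
class ParsedTemplateFile:
    """A parsed data-template CSV: the event name from the
    ``#DataTemplate:`` line, the header, and one mapping per data row."""

    template_name: str
    header: list[str]
    rows: list[dict[str, str]]


def parse_template_csv(text: str) -> ParsedTemplateFile:
    """Parse a data-template CSV (``#DataTemplate:`` dialect).

    Trailing blank lines are ignored; a missing or garbled first line is a
    format error naming line 1, a ragged data row a format error naming its
    row number.
    """
    lines = text.split("\n")
    if not lines:
        raise FormatError("line 1: empty file, expected '#DataTemplate: <name>'")
    m = _TEMPLATE_LINE_RE.match(lines[0].rstrip("\r"))
    if not m:
        raise FormatError(
            f"line 1: expected '#DataTemplate: <name>', got {lines[0]!r}")
    template_name = m.group(1)
    body = "\n".join(lines[1:])
    reader = csv.reader(io.StringIO(body))
    records = [r for r in reader]
    while records and records[-1] in ([], [""]):
        records.pop()
    if not records:
        raise FormatError("line 2: missing field header row")
    header = [h.strip() for h in records[0]]
    rows = []
    for i, rec in enumerate(records[1:], start=1):
        if len(rec) != len(header):
            raise FormatError(
                f"row {i}: expected {len(header)} cells, got {len(rec)}")
        rows.append(dict(zip(header, rec)))
    return ParsedTemplateFile(template_name=template_name, header=header,
                              rows=rows)


def write_template_csv(parsed: ParsedTemplateFile) -> str:
    """Inverse of :func:`parse_template_csv` (minimal RFC 4180 quoting,
    LF line endings)."""
    buf = io.StringIO()
    buf.write(f"#DataTemplate: {parsed.template_name}\n")
    w = csv.writer(buf, lineterminator="\n")
    w.writerow(parsed.header)
    for row in parsed.rows:
        w.writerow([row.get(h, "") for h in parsed.header])
    return buf.getvalue()


def generate_blank_template(template: EventTemplate) -> str:
    """The downloadable blank data template: ``#DataTemplate:`` line plus
    the active field names in position order, no data rows."""
    header = [f.name for f in template.ordered_fields(active_only=True)]
    return write_template_csv(ParsedTemplateFile(
        template_name=template.display_name, header=header, rows=[]))


def _parse_bool(raw: str, row_index: int, column: str,
                issues: list[ValidationIssue]) -> bool:
    v = raw.strip().lower()
    if v in _TRUE:
        return True
    if v in _FALSE:
        return False
    issues.append(ValidationIssue(
        row_index=row_index, field=column, code="type_error",
        message=f"{column} must be yes/no, got {raw!r}"))
    return False


def parse_setup_csv(text: str) -> list[tuple[str, FieldDefinition]]:
    """Parse a study setup CSV into (event name, field definition) pairs.

    All row-level problems (unknown data type, unparseable annotation, bad
    position...) are aggregated with their row numbers and raised together
    as a :class:`SetupError`.
    """
    reader = csv.DictReader(io.StringIO(text))
    if reader.fieldnames is None:
        return []
    missing = [c for c in SETUP_COLUMNS if c not in reader.fieldnames]
    if missing:
        raise FormatError(f"setup file missing columns: {missing}")
    out: list[tuple[str, FieldDefinition]] = []
    issues: list[ValidationIssue] = []
    for i, row in enumerate(reader, start=1):
        event = (row.get("event_name") or "").strip()
        fname = (row.get("field_name") or "").strip()
        if not event or not fname:
            issues.append(ValidationIssue(
                row_index=i, field="event_name", code="required_missing",
                message="event_name and field_name are required"))
            continue
        data_type = (row.get("data_type") or "").strip()
        if data_type not in DATA_TYPES:
            issues.append(ValidationIssue(
                row_index=i, field="data_type", code="type_error",
                message=f"data_type must be one of {DATA_TYPES}, "
                        f"got {data_type!r}"))
            continue
        required = _parse_bool(row.get("required", ""), i, "required", issues)
        active_raw = (row.get("active") or "").strip()
        active = True if active_raw == "" else _parse_bool(
            active_raw, i, "active", issues)
        max_length: Optional[int] = None
        ml = (row.get("max_length") or "").strip()
        if ml:
            try:
                max_length = int(ml)
                if max_length <= 0:
                    raise ValueError
            except ValueError:
                issues.append(ValidationIssue(
                    row_index=i, field="max_length", code="type_error",
                    message=f"max_length must be a positive integer, got {ml!r}"))
                continue
        pos_raw = (row.get("position") or "").strip()
        try:
            position = int(pos_raw) if pos_raw else i
        except ValueError:
            issues.append(ValidationIssue(
                row_index=i, field="position", code="type_error",
                message=f"position must be an integer, got {pos_raw!r}"))
            continue
        try:
            annotation = parse_annotation(row.get("default_options", ""))
        except Exception as exc:
            issues.append(ValidationIssue(
                row_index=i, field="default_options", code="type_error",
                message=str(exc)))
            continue
        if required and not active:
            required = False   # inactive fields are never required
        out.append((event, FieldDefinition(
            name=fname, data_type=data_type, required=required, active=active,
            max_length=max_length,
            description=row.get("description", "") or "",
            ontology_class=(row.get("ontology_class") or "").strip() or None,
            position=position, annotation=annotation)))
    if issues:
        raise SetupError(issues)
    return out


def write_setup_csv(templates: list[EventTemplate]) -> str:
    """Export event templates as a setup CSV;
    :func:`parse_setup_csv` reconstructs equivalent definitions."""
    buf = io.StringIO()
    w = csv.writer(buf, lineterminator="\n")
    w.writerow(SETUP_COLUMNS)
    for t in templates:
        for f in t.ordered_fields():
            w.writerow([
                t.display_name, f.name, f.data_type,
                "yes" if f.required else "no",
                "yes" if f.active else "no",
                "" if f.max_length is None else f.max_length,
                f.description, f.ontology_class or "", f.position,
                render_annotation(f.annotation),
            ])
    return buf.getvalue()


def group_setup_entries(
        entries: list[tuple[str, FieldDefinition]]) -> dict[str, list[FieldDefinition]]:
    """Group setup rows by event display name, preserving first-seen order
    and each event's row order."""
    grouped: dict[str, list[FieldDefinition]] = {}
    for event, fd in entries:
        grouped.setdefault(event, []).append(fd)
    return grouped


def apply_setup(store, text: str, actor: str) -> list[str]:
    """Configure a store from a setup CSV; returns the affected event names.

    Idempotent: templates whose definitions already match are untouched, so
    re-running an identical setup leaves the store dump byte-identical.
    New templates are created; existing ones have their fields upserted
    (new fields added, changed fields updated in place).
    """
    from .errors import ConfigurationError

    entries = parse_setup_csv(text)
    affected = []
    for event, fields in group_setup_entries(entries).items():
        scope = "sample" if "sample" in canonical_name(event) else "project"
        try:
            store.define_event_template(event, scope, fields, actor)
            affected.append(event)
            continue
        except ConfigurationError:
            existing = store.get_template(event)   # already configured: upsert
        emap = existing.field_map()
        for fd in fields:
            changes = dict(
                data_type=fd.data_type, required=fd.required,
                active=fd.active, max_length=fd.max_length,
                description=fd.description,
                ontology_class=fd.ontology_class, position=fd.position,
                annotation=render_annotation(fd.annotation))
            if fd.name in emap:
                cur = emap[fd.name]
                if (cur.data_type, cur.required, cur.active, cur.max_length,
                        cur.description, cur.ontology_class, cur.position,
                        render_annotation(cur.annotation)) == tuple(
                            changes.values()):
                    continue
                store.update_field_definition(event, fd.name, actor, **changes)
            else:
                store.add_field(event, fd, actor)
        affected.append(event)
    return affected


def parse_dictionary_csv(text: str) -> tuple[dict[str, Optional[str]],
                                             list[tuple[str, str, Optional[str]]]]:
    """Parse a dictionary CSV into ``(parents, entries)``.

    ``parents`` maps dictionary name → parent dictionary name (or None); a
    row with an empty ``value`` cell declares the parent.  ``entries`` are
    (dictionary, value, parent_value) in file order.
    """
    reader = csv.DictReader(io.StringIO(text))
    if reader.fieldnames is None:
        return {}, []
    missing = [c for c in DICTIONARY_COLUMNS if c not in reader.fieldnames]
    if missing:
        raise FormatError(f"dictionary file missing columns: {missing}")
    parents: dict[str, Optional[str]] = {}
    entries: list[tuple[str, str, Optional[str]]] = []
    for i, row in enumerate(reader, start=1):
        name = (row.get("dictionary") or "").strip()
        if not name:
            raise FormatError(f"row {i}: empty dictionary name")
        value = row.get("value") or ""
        parent_value = row.get("parent_value") or ""
        if value == "":
            if not parent_value:
                raise FormatError(
                    f"row {i}: parent-declaration row needs a parent name")
            parents[name] = parent_value
        else:
            parents.setdefault(name, None)
            entries.append((name, value, parent_value or None))
    return parents, entries


def write_dictionary_csv(store) -> str:
    """Export every dictionary in the store as a dictionary CSV."""
    buf = io.StringIO()
    w = csv.writer(buf, lineterminator="\n")
    w.writerow(DICTIONARY_COLUMNS)
    for name, parent in store.list_dictionaries():
        if parent is not None:
            w.writerow([name, "", parent])
        for value, parent_value in store.dictionary_entries(name):
            w.writerow([name, value, parent_value or ""])
    return buf.getvalue()


def load_dictionary_csv(store, text: str) -> list[str]:
    """Create dictionaries and entries in a store from a dictionary CSV.
    Dictionaries are created in dependency order so cascades of any depth
    resolve."""
    parents, entries = parse_dictionary_csv(text)
    created: list[str] = []
    pending = dict(parents)
    while pending:
        ready = [n for n, p in pending.items()
                 if p is None or p in created or p not in pending]
        if not ready:
            raise FormatError(
                f"dictionary parent cycle among {sorted(pending)}")
        for name in ready:
            store.create_dictionary(name, pending.pop(name))
            created.append(name)
    for name, value, parent_value in entries:
        store.add_dictionary_entry(name, value, parent_value)
    return created
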