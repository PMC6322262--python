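"""The embedded metadata store: EAV tables, event log, materialized state.

Layout follows the classic entity–attribute–value pattern: ``project`` /
``sample`` rows are the tracked entities, ``*_attribute`` tables hold their
*current* field values one row per field, ``event`` / ``event_attribute``
hold the immutable audit trail, and ``field_def`` rows are the
meta-attributes (metadata about metadata) that define what each event
carries.  Everything lives in a single SQLite file (or in memory), so a
study is a self-contained, copyable artifact.

Two invariants anchor the design:

* every mutation of entity state flows through exactly one committed
  :class:`EventRecord` carrying actor and timestamp — there is no other
  write path; and
* for every entity, the materialized current state equals
  :func:`replay` over that entity's event history (last non-empty write
  per field wins; the literal ``NULL`` clears).
"""
from __future__ import annotations

import datetime as _dt
import sqlite3
from typing import Callable, Iterable, Mapping, Optional, Sequence

from . import annotations as _ann
from .errors import (
    AuthorizationError,
    ConfigurationError,
    NotFoundError,
    UnknownTemplateError,
    UsageError,
)
from .model import (
    BUILTIN_TEMPLATES,
    IDENTITY_FIELDS,
    NULL_LITERAL,
    PARENT_SAMPLE_FIELD,
    PROJECT_NAME_FIELD,
    SAMPLE_NAME_FIELD,
    AttributeValue,
    EventRecord,
    EventTemplate,
    FieldDefinition,
    InputSpec,
    LoadResult,
    Project,
    Sample,
    UserGrant,
    ValidationIssue,
    ValidationReport,
    canonical_name,
)
from .validation import ValidatorRegistry, validate_batch

_SCHEMA = """
CREATE TABLE IF NOT EXISTS app_user (
    name TEXT PRIMARY KEY,
    is_admin INTEGER NOT NULL DEFAULT 0
);
CREATE TABLE IF NOT EXISTS project (
    id INTEGER PRIMARY KEY,
    name TEXT NOT NULL UNIQUE,
    created_by TEXT NOT NULL,
    created_at TEXT NOT NULL
);
CREATE TABLE IF NOT EXISTS sample (
    id INTEGER PRIMARY KEY,
    project_id INTEGER NOT NULL REFERENCES project(id),
    name TEXT NOT NULL,
    parent_sample_id INTEGER REFERENCES sample(id),
    UNIQUE (project_id, name)
);
CREATE TABLE IF NOT EXISTS event_template (
    id INTEGER PRIMARY KEY,
    name TEXT NOT NULL UNIQUE,          -- canonical
    display_name TEXT NOT NULL,
    scope TEXT NOT NULL,
    configured INTEGER NOT NULL DEFAULT 1
);
CREATE TABLE IF NOT EXISTS field_def (
    id INTEGER PRIMARY KEY,
    template_id INTEGER NOT NULL REFERENCES event_template(id),
    name TEXT NOT NULL,
    data_type TEXT NOT NULL,
    required INTEGER NOT NULL,
    active INTEGER NOT NULL,
    max_length INTEGER,
    description TEXT NOT NULL DEFAULT '',
    ontology_class TEXT,
    position INTEGER NOT NULL,
    annotation TEXT NOT NULL DEFAULT '',
    UNIQUE (template_id, name)
);
CREATE TABLE IF NOT EXISTS event (
    id INTEGER PRIMARY KEY AUTOINCREMENT,
    template_id INTEGER NOT NULL REFERENCES event_template(id),
    project_id INTEGER NOT NULL REFERENCES project(id),
    sample_id INTEGER REFERENCES sample(id),
    actor TEXT NOT NULL,
    timestamp TEXT NOT NULL
);
CREATE TABLE IF NOT EXISTS event_attribute (
    event_id INTEGER NOT NULL REFERENCES event(id),
    position INTEGER NOT NULL,
    field_name TEXT NOT NULL,
    raw TEXT NOT NULL,
    normalized TEXT NOT NULL,
    PRIMARY KEY (event_id, position)
);
CREATE TABLE IF NOT EXISTS project_attribute (
    project_id INTEGER NOT NULL REFERENCES project(id),
    field_name TEXT NOT NULL,
    value TEXT NOT NULL,
    PRIMARY KEY (project_id, field_name)
);
CREATE TABLE IF NOT EXISTS sample_attribute (
    sample_id INTEGER NOT NULL REFERENCES sample(id),
    field_name TEXT NOT NULL,
    value TEXT NOT NULL,
    PRIMARY KEY (sample_id, field_name)
);
CREATE TABLE IF NOT EXISTS dictionary (
    id INTEGER PRIMARY KEY,
    name TEXT NOT NULL UNIQUE,
    parent_id INTEGER REFERENCES dictionary(id)
);
CREATE TABLE IF NOT EXISTS dict_entry (
    dict_id INTEGER NOT NULL REFERENCES dictionary(id),
    value TEXT NOT NULL,
    parent_value TEXT,
    UNIQUE (dict_id, value, parent_value)
);
CREATE TABLE IF NOT EXISTS user_grant (
    user TEXT NOT NULL REFERENCES app_user(name),
    project_id INTEGER NOT NULL REFERENCES project(id),
    role TEXT NOT NULL,
    PRIMARY KEY (user, project_id)
);
"""

#: table → (order-by columns) for the canonical dump
_DUMP_TABLES = (
    ("app_user", "name"),
    ("project", "id"),
    ("sample", "id"),
    ("event_template", "id"),
    ("field_def", "id"),
    ("event", "id"),
    ("event_attribute", "event_id, position"),
    ("project_attribute", "project_id, field_name"),
    ("sample_attribute", "sample_id, field_name"),
    ("dictionary", "id"),
    ("dict_entry", "dict_id, value, parent_value"),
    ("user_grant", "user, project_id"),
)


def _default_clock() -> _dt.datetime:
    return _dt.datetime.now(_dt.timezone.utc)


def replay(events: Sequence[EventRecord]) -> dict[str, str]:
    """Fold an entity's event history into its current field→value mapping.

    Pure function and the independent oracle for materialization: the last
    non-empty write per field wins, an empty cell leaves the prior value
    untouched, and the literal ``NULL`` clears a value.  Identity columns
    (Project Name / Sample Name / Parent Sample) are bookkeeping, not
    attributes, and are skipped.
    """
    entities = {(e.project, e.sample) for e in events}
    if len(entities) > 1:
        raise UsageError(f"replay over mixed entities: {sorted(entities)!r}")
    state: dict[str, str] = {}
    for event in events:
        for av in event.values:
            if av.field in IDENTITY_FIELDS or av.field == PARENT_SAMPLE_FIELD:
                continue
            if av.normalized == "":
                continue
            if av.normalized == NULL_LITERAL:
                state.pop(av.field, None)
            else:
                state[av.field] = av.normalized
    return state


class _BatchContext:
    """Project-scoped validation context handed to the validation engine."""

    def __init__(self, store: "MetadataStore", project_name: str,
                 template: EventTemplate):
        self._store = store
        self._project = project_name
        self._template = template
        self.registry = store.registry
        self.ontology_provider = store.ontology_provider

    def dictionary_values(self, name, parent_value=None):
        return self._store.dictionary_values(name, parent_value)

    def stored_field_values(self, field_name, scope):
        return self._store._stored_field_values(self._project, field_name, scope)

    def sample_exists(self, name):
        return self._store._sample_id(self._project, name) is not None

    def would_create_cycle(self, child, parent):
        seen = set()
        current = parent
        while current is not None and current not in seen:
            if current == child:
                return True
            seen.add(current)
            s = self._store.get_sample(self._project, current)
            current = s.parent_sample if s else None
        return False


class MetadataStore:
    """A single study-tracking database.

    Parameters
    ----------
    path:
        SQLite file path, or ``":memory:"`` for an ephemeral store.
    admin_user:
        Bootstrap administrator created on first open.
    clock:
        Zero-argument callable returning the commit timestamp (injectable
        for deterministic audit-trail tests).
    """

    def __init__(self, path: str = ":memory:", admin_user: str = "admin",
                 clock: Optional[Callable[[], _dt.datetime]] = None):
        self.path = path
        # autocommit connection; load_event manages its own BEGIN/COMMIT so
        # the rollback guarantee is explicit
        self._conn = sqlite3.connect(path, isolation_level=None)
        self._conn.row_factory = sqlite3.Row
        self._clock = clock or _default_clock
        self.registry = ValidatorRegistry()
        self.ontology_provider = None   # optional pluggable term lookup
        with self._conn:
            self._conn.executescript(_SCHEMA)
            self._conn.execute(
                "INSERT OR IGNORE INTO app_user (name, is_admin) VALUES (?, 1)",
                (admin_user,))
            for display, scope in BUILTIN_TEMPLATES:
                cur = self._conn.execute(
                    "INSERT OR IGNORE INTO event_template "
                    "(name, display_name, scope, configured) VALUES (?,?,?,0)",
                    (canonical_name(display), display, scope))
                if cur.rowcount:
                    self._seed_identity_fields(canonical_name(display), scope)

    def close(self) -> None:
        self._conn.close()

    # ------------------------------------------------------------------ users

    def create_user(self, name: str, admin: bool = False,
                    actor: Optional[str] = None) -> None:
        if actor is not None:
            self._require_admin(actor)
        if not name:
            raise UsageError("user name must be non-empty")
        with self._conn:
            self._conn.execute(
                "INSERT OR REPLACE INTO app_user (name, is_admin) VALUES (?,?)",
                (name, int(admin)))

    def _user_row(self, name):
        return self._conn.execute(
            "SELECT * FROM app_user WHERE name=?", (name,)).fetchone()

    def is_admin(self, user: str) -> bool:
        row = self._user_row(user)
        return bool(row and row["is_admin"])

    def _require_admin(self, actor: str) -> None:
        if not self.is_admin(actor):
            raise AuthorizationError(f"{actor!r} lacks the admin flag")

    def _require_user(self, actor: str) -> None:
        if self._user_row(actor) is None:
            raise AuthorizationError(f"unknown user {actor!r}")

    def role_on(self, user: str, project_name: str) -> Optional[str]:
        pid = self._project_id(project_name)
        if pid is None:
            return None
        row = self._conn.execute(
            "SELECT role FROM user_grant WHERE user=? AND project_id=?",
            (user, pid)).fetchone()
        return row["role"] if row else None

    def _require_role(self, actor: str, project_name: str, role: str) -> None:
        """``role`` is "view" or "edit"; edit implies view; admins bypass."""
        self._require_user(actor)
        if self.is_admin(actor):
            return
        have = self.role_on(actor, project_name)
        if have == "edit" or have == role:
            return
        raise AuthorizationError(
            f"{actor!r} lacks the {role!r} role on project {project_name!r}")

    def grant_role(self, user: str, project_name: str, role: str,
                   actor: str) -> UserGrant:
        """Grant view/edit on a project, replacing any prior grant."""
        self._require_admin(actor)
        if role not in ("view", "edit"):
            raise UsageError("role must be 'view' or 'edit'")
        pid = self._project_id(project_name)
        if pid is None:
            raise NotFoundError(f"unknown project {project_name!r}")
        if self._user_row(user) is None:
            raise NotFoundError(f"unknown user {user!r}")
        with self._conn:
            self._conn.execute(
                "INSERT OR REPLACE INTO user_grant (user, project_id, role) "
                "VALUES (?,?,?)", (user, pid, role))
        return UserGrant(user=user, project=project_name, role=role)

    # -------------------------------------------------------------- templates

    def _seed_identity_fields(self, canonical: str, scope: str) -> None:
        tid = self._template_id(canonical)
        fields = [FieldDefinition(PROJECT_NAME_FIELD, "string", required=True,
                                  position=1)]
        if scope == "sample":
            fields.append(FieldDefinition(SAMPLE_NAME_FIELD, "string",
                                          required=True, position=2))
        self._insert_fields(tid, fields)

    def _template_id(self, canonical: str):
        row = self._conn.execute(
            "SELECT id FROM event_template WHERE name=?", (canonical,)).fetchone()
        return row["id"] if row else None

    def _insert_fields(self, template_id: int,
                       fields: Iterable[FieldDefinition]) -> None:
        for fd in fields:
            self._conn.execute(
                "INSERT INTO field_def (template_id, name, data_type, required,"
                " active, max_length, description, ontology_class, position,"
                " annotation) VALUES (?,?,?,?,?,?,?,?,?,?)",
                (template_id, fd.name, fd.data_type, int(fd.required),
                 int(fd.active), fd.max_length, fd.description,
                 fd.ontology_class, fd.position,
                 _ann.render_annotation(fd.annotation)))

    def define_event_template(self, name: str, scope: str,
                              fields: Sequence[FieldDefinition],
                              actor: str) -> EventTemplate:
        """Create (or configure a still-blank built-in) event template.

        The four built-in templates exist from store creation holding only
        the identity columns; defining one of them replaces that stub.
        Defining an already-configured template is a configuration error.
        """
        self._require_admin(actor)
        canonical = canonical_name(name)
        if not canonical:
            raise ConfigurationError("template name canonicalizes to empty")
        names = [f.name for f in fields]
        if len(set(names)) != len(names):
            raise ConfigurationError(f"duplicate field names in {name!r}")
        with self._conn:
            row = self._conn.execute(
                "SELECT * FROM event_template WHERE name=?",
                (canonical,)).fetchone()
            if row is not None:
                if row["configured"]:
                    raise ConfigurationError(
                        f"event template {name!r} already defined")
                if row["scope"] != scope:
                    raise ConfigurationError(
                        f"built-in template {row['display_name']!r} has scope "
                        f"{row['scope']!r}, not {scope!r}")
                self._conn.execute(
                    "DELETE FROM field_def WHERE template_id=?", (row["id"],))
                self._conn.execute(
                    "UPDATE event_template SET display_name=?, configured=1 "
                    "WHERE id=?", (name, row["id"]))
                tid = row["id"]
            else:
                cur = self._conn.execute(
                    "INSERT INTO event_template (name, display_name, scope,"
                    " configured) VALUES (?,?,?,1)", (canonical, name, scope))
                tid = cur.lastrowid
            self._insert_fields(tid, fields)
        return self.get_template(name)

    def get_template(self, name: str) -> EventTemplate:
        canonical = canonical_name(name)
        row = self._conn.execute(
            "SELECT * FROM event_template WHERE name=?", (canonical,)).fetchone()
        if row is None:
            raise UnknownTemplateError(f"unknown event template {name!r}")
        fields = []
        for fr in self._conn.execute(
                "SELECT * FROM field_def WHERE template_id=? "
                "ORDER BY position, name", (row["id"],)):
            fields.append(FieldDefinition(
                name=fr["name"], data_type=fr["data_type"],
                required=bool(fr["required"]), active=bool(fr["active"]),
                max_length=fr["max_length"], description=fr["description"],
                ontology_class=fr["ontology_class"], position=fr["position"],
                annotation=_ann.parse_annotation(fr["annotation"])))
        return EventTemplate(name=row["name"], display_name=row["display_name"],
                             scope=row["scope"], fields=fields)

    def list_templates(self) -> list[EventTemplate]:
        rows = self._conn.execute(
            "SELECT display_name FROM event_template ORDER BY id").fetchall()
        return [self.get_template(r["display_name"]) for r in rows]

    def update_field_definition(self, template_name: str, field_name: str,
                                actor: str, **changes) -> FieldDefinition:
        """Partially update one field definition.

        Deactivation never deletes history; deactivating a required field
        also drops the required flag (inactive fields are never required).
        """
        self._require_admin(actor)
        canonical = canonical_name(template_name)
        tid = self._template_id(canonical)
        if tid is None:
            raise UnknownTemplateError(f"unknown event template {template_name!r}")
        row = self._conn.execute(
            "SELECT * FROM field_def WHERE template_id=? AND name=?",
            (tid, field_name)).fetchone()
        if row is None:
            raise NotFoundError(
                f"no field {field_name!r} in template {template_name!r}")
        current = dict(row)
        allowed = {"data_type", "required", "active", "max_length",
                   "description", "ontology_class", "position", "annotation"}
        unknown = set(changes) - allowed
        if unknown:
            raise UsageError(f"unknown field attributes: {sorted(unknown)}")
        if "annotation" in changes:
            ann = changes["annotation"]
            if isinstance(ann, InputSpec):
                ann = _ann.render_annotation(ann)
            _ann.parse_annotation(ann)   # syntax check
            changes = {**changes, "annotation": ann}
        merged = {**current, **{k: v for k, v in changes.items()}}
        if merged["required"] and not merged["active"]:
            if changes.get("required"):
                raise ConfigurationError(
                    "cannot require an inactive field")
            merged["required"] = 0
        with self._conn:
            self._conn.execute(
                "UPDATE field_def SET data_type=?, required=?, active=?,"
                " max_length=?, description=?, ontology_class=?, position=?,"
                " annotation=? WHERE id=?",
                (merged["data_type"], int(merged["required"]),
                 int(merged["active"]), merged["max_length"],
                 merged["description"], merged["ontology_class"],
                 merged["position"], merged["annotation"], row["id"]))
        return self.get_template(template_name).field_map()[field_name]

    def add_field(self, template_name: str, field: FieldDefinition,
                  actor: str) -> None:
        """Append one field definition to an existing template."""
        self._require_admin(actor)
        tid = self._template_id(canonical_name(template_name))
        if tid is None:
            raise UnknownTemplateError(f"unknown event template {template_name!r}")
        exists = self._conn.execute(
            "SELECT 1 FROM field_def WHERE template_id=? AND name=?",
            (tid, field.name)).fetchone()
        if exists:
            raise ConfigurationError(
                f"field {field.name!r} already defined on {template_name!r}")
        self._insert_fields(tid, [field])

    def register_custom_validator(self, key: str, procedure) -> None:
        self.registry.register(key, procedure)

    # ------------------------------------------------------------ dictionaries

    def create_dictionary(self, name: str, parent_name: Optional[str] = None,
                          actor: Optional[str] = None) -> None:
        if actor is not None:
            self._require_admin(actor)
        parent_id = None
        if parent_name is not None:
            parent_id = self._dict_id(parent_name)
            if parent_id is None:
                raise ConfigurationError(
                    f"parent dictionary {parent_name!r} does not exist")
        try:
            with self._conn:
                self._conn.execute(
                    "INSERT INTO dictionary (name, parent_id) VALUES (?,?)",
                    (name, parent_id))
        except sqlite3.IntegrityError:
            raise ConfigurationError(f"dictionary {name!r} already exists")

    def _dict_id(self, name):
        row = self._conn.execute(
            "SELECT id FROM dictionary WHERE name=?", (name,)).fetchone()
        return row["id"] if row else None

    def _dict_row(self, name):
        row = self._conn.execute(
            "SELECT * FROM dictionary WHERE name=?", (name,)).fetchone()
        if row is None:
            raise NotFoundError(f"unknown dictionary {name!r}")
        return row

    def add_dictionary_entry(self, name: str, value: str,
                             parent_value: Optional[str] = None) -> None:
        row = self._dict_row(name)
        if row["parent_id"] is not None:
            if parent_value is None:
                raise ConfigurationError(
                    f"dictionary {name!r} has a parent; parent_value required")
            parent_name = self._conn.execute(
                "SELECT name FROM dictionary WHERE id=?",
                (row["parent_id"],)).fetchone()["name"]
            parent_values = self.dictionary_values(parent_name)
            if parent_value not in parent_values:
                raise ConfigurationError(
                    f"parent value {parent_value!r} not in dictionary "
                    f"{parent_name!r}")
        elif parent_value is not None:
            raise ConfigurationError(
                f"dictionary {name!r} has no parent; parent_value not allowed")
        dup = self._conn.execute(
            "SELECT 1 FROM dict_entry WHERE dict_id=? AND value=? AND "
            "parent_value IS ?", (row["id"], value, parent_value)).fetchone()
        if dup:    # UNIQUE alone misses this: SQL NULLs compare distinct
            raise ConfigurationError(
                f"duplicate entry ({value!r}, {parent_value!r}) in {name!r}")
        with self._conn:
            self._conn.execute(
                "INSERT INTO dict_entry (dict_id, value, parent_value) "
                "VALUES (?,?,?)", (row["id"], value, parent_value))

    def dictionary_values(self, name: str,
                          parent_value: Optional[str] = None) -> list[str]:
        """All values of a dictionary, lexicographically sorted; with
        ``parent_value`` given, only the entries cascading from it."""
        row = self._dict_row(name)
        if parent_value is not None:
            if row["parent_id"] is None:
                raise UsageError(
                    f"dictionary {name!r} has no parent; cannot filter")
            rows = self._conn.execute(
                "SELECT value FROM dict_entry WHERE dict_id=? AND "
                "parent_value=? ORDER BY value", (row["id"], parent_value))
        else:
            rows = self._conn.execute(
                "SELECT DISTINCT value FROM dict_entry WHERE dict_id=? "
                "ORDER BY value", (row["id"],))
        return [r["value"] for r in rows]

    def list_dictionaries(self) -> list[tuple[str, Optional[str]]]:
        """(name, parent_name) pairs in creation order."""
        out = []
        for r in self._conn.execute(
                "SELECT d.name AS name, p.name AS parent FROM dictionary d "
                "LEFT JOIN dictionary p ON d.parent_id = p.id ORDER BY d.id"):
            out.append((r["name"], r["parent"]))
        return out

    def dictionary_entries(self, name: str) -> list[tuple[str, Optional[str]]]:
        row = self._dict_row(name)
        return [(r["value"], r["parent_value"]) for r in self._conn.execute(
            "SELECT value, parent_value FROM dict_entry WHERE dict_id=? "
            "ORDER BY value, parent_value", (row["id"],))]

    # ---------------------------------------------------------------- entities

    def _project_id(self, name):
        row = self._conn.execute(
            "SELECT id FROM project WHERE name=?", (name,)).fetchone()
        return row["id"] if row else None

    def get_project(self, name: str) -> Optional[Project]:
        row = self._conn.execute(
            "SELECT * FROM project WHERE name=?", (name,)).fetchone()
        if row is None:
            return None
        return Project(id=row["id"], name=row["name"],
                       created_by=row["created_by"], created_at=row["created_at"])

    def list_projects(self) -> list[str]:
        return [r["name"] for r in self._conn.execute(
            "SELECT name FROM project ORDER BY name")]

    def _sample_id(self, project_name, sample_name):
        row = self._conn.execute(
            "SELECT s.id FROM sample s JOIN project p ON s.project_id=p.id "
            "WHERE p.name=? AND s.name=?", (project_name, sample_name)).fetchone()
        return row["id"] if row else None

    def get_sample(self, project_name: str, sample_name: str) -> Optional[Sample]:
        row = self._conn.execute(
            "SELECT s.id, s.name, s.parent_sample_id, p.name AS project "
            "FROM sample s JOIN project p ON s.project_id=p.id "
            "WHERE p.name=? AND s.name=?", (project_name, sample_name)).fetchone()
        if row is None:
            return None
        parent = None
        if row["parent_sample_id"] is not None:
            pr = self._conn.execute("SELECT name FROM sample WHERE id=?",
                                    (row["parent_sample_id"],)).fetchone()
            parent = pr["name"] if pr else None
        return Sample(id=row["id"], project=row["project"], name=row["name"],
                      parent_sample=parent)

    def list_samples(self, project_name: str) -> list[str]:
        return [r["name"] for r in self._conn.execute(
            "SELECT s.name FROM sample s JOIN project p ON s.project_id=p.id "
            "WHERE p.name=? ORDER BY s.name", (project_name,))]

    def _stored_field_values(self, project_name, field_name, scope):
        """normalized value -> owning entity name, scoped to one project."""
        if scope == "sample":
            if field_name == SAMPLE_NAME_FIELD:
                return {n: n for n in self.list_samples(project_name)}
            rows = self._conn.execute(
                "SELECT sa.value AS value, s.name AS owner "
                "FROM sample_attribute sa JOIN sample s ON sa.sample_id=s.id "
                "JOIN project p ON s.project_id=p.id WHERE p.name=? AND "
                "sa.field_name=?", (project_name, field_name))
        else:
            if field_name == PROJECT_NAME_FIELD:
                return {n: n for n in self.list_projects()}
            rows = self._conn.execute(
                "SELECT pa.value AS value, p.name AS owner "
                "FROM project_attribute pa JOIN project p ON pa.project_id=p.id "
                "WHERE pa.field_name=?", (field_name,))
        return {r["value"]: r["owner"] for r in rows}

    # ----------------------------------------------------------------- loading

    def validate(self, project_name: str, event_name: str,
                 rows: Sequence[Mapping[str, str]]) -> ValidationReport:
        """Validate a batch without loading it (same checks as load_event)."""
        template = self.get_template(event_name)
        ctx = _BatchContext(self, project_name, template)
        report = validate_batch(template, rows, ctx)
        self._check_identity(template, project_name, rows, report)
        return report

    def _check_identity(self, template, project_name, rows, report):
        """Target-resolution checks layered over the generic engine: the
        Project Name column, when present, must match the target project;
        sample-scope rows must carry a resolvable Sample Name."""
        for i, row in enumerate(rows, start=1):
            pn = row.get(PROJECT_NAME_FIELD, "")
            if pn and pn != project_name:
                report.issues.append(ValidationIssue(
                    row_index=i, field=PROJECT_NAME_FIELD,
                    code="option_violation",
                    message=f"row targets project {pn!r}, but the batch loads "
                            f"into {project_name!r}"))
                report.row_ok[i - 1] = False
            if template.scope == "sample":
                sn = row.get(SAMPLE_NAME_FIELD, "")
                if not sn or sn == NULL_LITERAL:
                    if not any(x.field == SAMPLE_NAME_FIELD
                               and x.row_index == i for x in report.issues):
                        report.issues.append(ValidationIssue(
                            row_index=i, field=SAMPLE_NAME_FIELD,
                            code="required_missing",
                            message="sample events must name their sample"))
                    report.row_ok[i - 1] = False

    def load_event(self, project_name: str, event_name: str,
                   rows: Sequence[Mapping[str, str]], actor: str,
                   mode: str = "atomic") -> LoadResult:
        """Validate and commit a batch of event rows.

        In ``atomic`` mode any failing row rejects the whole batch and the
        store is left untouched; in ``per_row`` mode (bulk semantics) valid
        rows commit and invalid rows are reported.  One immutable
        :class:`EventRecord` is committed per row, carrying actor and
        timestamp; each target entity's materialized attributes are then
        overwritten by the row's non-empty values (empty cells leave prior
        values untouched, the literal ``NULL`` clears).
        """
        if mode not in ("atomic", "per_row"):
            raise UsageError("mode must be 'atomic' or 'per_row'")
        template = self.get_template(event_name)
        self._require_user(actor)

        project = self.get_project(project_name)
        creating_project = template.name == "projectregistration"
        if project is None and not creating_project:
            raise NotFoundError(f"unknown project {project_name!r}")
        if project is not None:
            self._require_role(actor, project_name, "edit")
        if template.scope == "sample" and SAMPLE_NAME_FIELD not in template.field_map():
            raise ConfigurationError(
                f"sample-scope template {template.display_name!r} defines no "
                f"{SAMPLE_NAME_FIELD!r} field")

        report = self.validate(project_name, event_name, rows)
        if mode == "atomic" and not report.ok:
            return LoadResult(status="rejected", issues=report.issues)
        if rows and not any(report.row_ok):
            # per_row batch where every row failed: nothing to commit
            return LoadResult(status="rejected", issues=report.issues)

        events_created = samples_created = samples_updated = 0
        try:
            self._conn.execute("BEGIN")
            pid = self._project_id(project_name)
            if pid is None and any(report.row_ok):
                now = self._clock().isoformat()
                cur = self._conn.execute(
                    "INSERT INTO project (name, created_by, created_at) "
                    "VALUES (?,?,?)", (project_name, actor, now))
                pid = cur.lastrowid
                if not self.is_admin(actor):
                    self._conn.execute(
                        "INSERT OR REPLACE INTO user_grant (user, project_id,"
                        " role) VALUES (?,?, 'edit')", (actor, pid))
            fmap = template.field_map()
            ordered = [f.name for f in template.ordered_fields()]
            for i, row in enumerate(rows, start=1):
                if not report.row_ok[i - 1]:
                    continue
                normalized = report.normalized_rows[i - 1]
                sid = None
                if template.scope == "sample":
                    sname = row[SAMPLE_NAME_FIELD]
                    sid = self._sample_id(project_name, sname)
                    if sid is None:
                        cur = self._conn.execute(
                            "INSERT INTO sample (project_id, name) VALUES (?,?)",
                            (pid, sname))
                        sid = cur.lastrowid
                        samples_created += 1
                    else:
                        samples_updated += 1
                ts = self._clock().isoformat()
                cur = self._conn.execute(
                    "INSERT INTO event (template_id, project_id, sample_id,"
                    " actor, timestamp) VALUES "
                    "((SELECT id FROM event_template WHERE name=?),?,?,?,?)",
                    (template.name, pid, sid, actor, ts))
                eid = cur.lastrowid
                events_created += 1
                pos = 0
                for fname in ordered:
                    raw = row.get(fname, "")
                    norm = normalized.get(fname, "")
                    if raw == "" and norm == "":
                        continue
                    if raw == "" and fmap[fname].annotation.kind == "readonly":
                        raw = norm   # filled default is the effective input
                    pos += 1
                    self._conn.execute(
                        "INSERT INTO event_attribute (event_id, position,"
                        " field_name, raw, normalized) VALUES (?,?,?,?,?)",
                        (eid, pos, fname, raw, norm))
                self._materialize(pid, sid, template.scope, normalized)
                if (template.scope == "sample"
                        and PARENT_SAMPLE_FIELD in normalized):
                    self._set_parent(pid, sid, normalized[PARENT_SAMPLE_FIELD])
            self._conn.execute("COMMIT")
        except BaseException:
            self._conn.execute("ROLLBACK")
            raise
        status = "committed"
        if events_created == 0 and not report.ok:
            status = "rejected"   # per_row batch where every row failed
        return LoadResult(status=status, events_created=events_created,
                          samples_created=samples_created,
                          samples_updated=samples_updated,
                          issues=report.issues)

    def _materialize(self, pid, sid, scope, normalized):
        if scope == "sample":
            table, key, eid = "sample_attribute", "sample_id", sid
        else:
            table, key, eid = "project_attribute", "project_id", pid
        for fname, value in normalized.items():
            if fname in IDENTITY_FIELDS or fname == PARENT_SAMPLE_FIELD:
                continue
            if value == "":
                continue
            if value == NULL_LITERAL:
                self._conn.execute(
                    f"DELETE FROM {table} WHERE {key}=? AND field_name=?",
                    (eid, fname))
            else:
                self._conn.execute(
                    f"INSERT OR REPLACE INTO {table} ({key}, field_name,"
                    " value) VALUES (?,?,?)", (eid, fname, value))

    def _set_parent(self, pid, sid, parent_name):
        if parent_name in ("", None):
            return
        if parent_name == NULL_LITERAL:
            self._conn.execute(
                "UPDATE sample SET parent_sample_id=NULL WHERE id=?", (sid,))
            return
        prow = self._conn.execute(
            "SELECT id FROM sample WHERE project_id=? AND name=?",
            (pid, parent_name)).fetchone()
        if prow is not None:
            self._conn.execute(
                "UPDATE sample SET parent_sample_id=? WHERE id=?",
                (prow["id"], sid))

    def register_project(self, name: str, actor: str,
                         attributes: Optional[Mapping[str, str]] = None) -> LoadResult:
        """Convenience wrapper: load one ProjectRegistration event."""
        row = {PROJECT_NAME_FIELD: name, **(attributes or {})}
        return self.load_event(name, "ProjectRegistration", [row], actor)

    # ------------------------------------------------------------ history/state

    def event_history(self, caller: str, project: Optional[str] = None,
                      sample: Optional[str] = None,
                      template: Optional[str] = None,
                      field: Optional[str] = None) -> list[EventRecord]:
        """The audit trail, in commit order, optionally filtered.

        Requires the view role on the (filtered) project; without a project
        filter, only projects visible to the caller are returned.
        """
        self._require_user(caller)
        if project is not None:
            self._require_role(caller, project, "view")
        sql = ("SELECT e.id, t.name AS template, p.name AS project, "
               "s.name AS sample, e.actor, e.timestamp "
               "FROM event e JOIN event_template t ON e.template_id=t.id "
               "JOIN project p ON e.project_id=p.id "
               "LEFT JOIN sample s ON e.sample_id=s.id WHERE 1=1")
        args: list = []
        if project is not None:
            sql += " AND p.name=?"
            args.append(project)
        if sample is not None:
            sql += " AND s.name=?"
            args.append(sample)
        if template is not None:
            sql += " AND t.name=?"
            args.append(canonical_name(template))
        sql += " ORDER BY e.id"
        records = []
        admin = self.is_admin(caller)
        for row in self._conn.execute(sql, args):
            if not admin and project is None:
                if self.role_on(caller, row["project"]) is None:
                    continue
            values = tuple(
                AttributeValue(field=ar["field_name"], raw=ar["raw"],
                               normalized=ar["normalized"])
                for ar in self._conn.execute(
                    "SELECT field_name, raw, normalized FROM event_attribute "
                    "WHERE event_id=? ORDER BY position", (row["id"],)))
            if field is not None and not any(v.field == field for v in values):
                continue
            records.append(EventRecord(
                id=row["id"], template=row["template"], project=row["project"],
                sample=row["sample"], actor=row["actor"],
                timestamp=row["timestamp"], values=values))
        return records

    def current_state(self, project_name: str,
                      sample_name: Optional[str] = None) -> dict[str, str]:
        """Materialized field→value mapping of one entity.

        Equals :func:`replay` over the entity's event history — the
        event-sourcing invariant the test suite enforces.
        """
        if sample_name is None:
            pid = self._project_id(project_name)
            if pid is None:
                raise NotFoundError(f"unknown project {project_name!r}")
            rows = self._conn.execute(
                "SELECT field_name, value FROM project_attribute "
                "WHERE project_id=?", (pid,))
        else:
            sid = self._sample_id(project_name, sample_name)
            if sid is None:
                raise NotFoundError(
                    f"unknown sample {sample_name!r} in {project_name!r}")
            rows = self._conn.execute(
                "SELECT field_name, value FROM sample_attribute "
                "WHERE sample_id=?", (sid,))
        return {r["field_name"]: r["value"] for r in rows}

    # -------------------------------------------------------------------- dump

    def dump(self) -> str:
        """Canonical, diffable text serialization of every table; two dumps
        are byte-identical iff the stores hold identical data (the rollback
        tests rely on this)."""
        lines = ["# metatrail store dump"]
        for table, order in _DUMP_TABLES:
            lines.append(f"[{table}]")
            cur = self._conn.execute(f"SELECT * FROM {table} ORDER BY {order}")
            cols = [d[0] for d in cur.description]
            for row in cur:
                cells = []
                for c in cols:
                    v = row[c]
                    cells.append("\\N" if v is None else str(v))
                lines.append("|".join(cells))
        return "\n".join(lines) + "\n"
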