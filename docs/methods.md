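# Methods

## Model

`metatrail` treats a study's metadata schema as data and its content as an
event log.

**Entities and meta-attributes.** Tracked entities are projects and
samples; a sample belongs to one project and `(project, sample name)` is
the business key (internal ids are surrogates). Each entity's metadata is
stored entity–attribute–value: one row per (entity, field, value). What
fields exist, and how each behaves, is described by field definitions
("meta-attributes"): name, data type (`string`, `date`, `integer`,
`float`, `file`), required flag, active flag, optional max length,
description, optional ontology class, display position, and at most one
input annotation. Fields are grouped into event templates — named
operations with a `project` or `sample` scope. Four built-in templates
exist in every store (ProjectRegistration, ProjectUpdate,
SampleRegistration, SampleUpdate); they are created holding only the
identity columns and are configured (once) by the first explicit
definition, after which redefinition is a configuration error. Template
names are canonicalized by stripping all whitespace and lowercasing, so
`Sample Registration` and `SampleRegistration` name the same template.

**Events and state.** The only write path for entity data is
`load_event`: each CSV row becomes one immutable event record carrying the
template, target entity, actor, commit timestamp and the submitted values
(raw and normalized). Per-entity current state is materialized
incrementally but is defined by the pure fold `replay(history)`: events in
commit order, last non-empty write per field wins, empty cells leave prior
values untouched, and the literal cell `NULL` clears a value (absence and
deletion are deliberately distinct so the audit trail stays meaningful).
The equivalence `current_state(e) == replay(event_history(e))` is enforced
by the test suite over randomized studies and is the system's central
invariant. Event ids are strictly increasing and records never change
after commit.

**Identity columns.** `Project Name` and `Sample Name` resolve the target
entity. They appear in event records (the audit trail records exactly what
was submitted) but are not materialized as attributes; search and export
expose them as virtual columns backed by the entity names. `Parent Sample`
is treated the same way and sets the sample's parent pointer (same
project; unknown parents, self-parenting and cycles are validation
errors), giving aliquot-style hierarchies without dedicated event
machinery.

**Loading modes.** `atomic` rejects the whole batch if any row has an
error-severity finding and leaves the store byte-identical (verified via a
canonical text dump of every table). `per_row` implements bulk semantics:
valid rows commit, invalid rows are reported in a machine-readable report
(the asynchronous-job/email pattern reduced to its data content). A
sample-scope event row naming an unknown sample creates it — registration
is the conventional first event, not a gatekeeper — because the issue-code
set is closed and a clean validation report must guarantee a clean load.

## Validation

Per row, in order: unknown or inactive columns (`unknown_field`);
annotation evaluation; requiredness of active fields
(`required_missing`, inactive fields are never required); type coercion;
optional ontology-term membership when a provider is configured; custom
validators. All findings carry a 1-based row index, field name and one of
ten closed codes; data problems never raise.

Coercion normalizes to canonical text: dates from `M/D/YY`, `M/D/YYYY` or
`YYYY-MM-DD` to ISO (two-digit years pivot 00–69 → 20xx, 70–99 → 19xx,
chosen to keep 2013–2016-era collection dates in the right century);
integers and floats to canonical decimal text (non-finite floats are
rejected); `string`/`file` pass through verbatim. Max length applies to
the normalized text.

The annotation grammar is `{keyword(...)}` or `{keyword:...}`; option
lists split on `;` preserving order and internal spaces, and matching is
case-sensitive exact (controlled vocabularies are curated verbatim).
Multi-select values split on `;` and every token must be an option.
Regular expressions anchor at both ends (a field validator should accept
the whole value or not at all). Read-only fields fill empty cells with the
default and reject any other submitted value (`readonly_conflict`) rather
than silently overwriting. Dictionary membership is checked against the
named controlled list, filtered by the row's parent-field value when a
cascade is declared; cascade filtering is definitionally the brute-force
filter of the entry set. Keywords are recognized case-insensitively and
re-rendered in canonical spelling; `render(parse(s))` is a fixed point for
every supported form.

Uniqueness is opt-in via
`{validate:DataValidator.checkFieldUniqueness}` — sample names may
legitimately repeat (re-registration appends to the same sample's history)
unless a study configures the validator. Uniqueness is enforced within a
batch (later duplicates are errors) and against stored values, scoped per
project. A stored collision is an error for registration-style events
(canonical name ending in `registration`); for update events it is a
warning, and no finding at all when the stored value belongs to the row's
own target entity, since updates legitimately re-see stored values.
Warnings are reported but do not block loading. Custom validators are
registered under dotted `Class.method` keys and run once per row with the
full row as context; an annotation naming an unregistered key is a
configuration error raised before any row is examined.

## Storage, security, formats

The store is a single SQLite file (or in-memory database) with the EAV
layout spelled out as literal tables: `project`, `sample`,
`event_template`, `field_def`, `event`, `event_attribute`,
`project_attribute`, `sample_attribute`, `dictionary`, `dict_entry`,
`app_user`, `user_grant`. Loading runs in one explicit transaction;
rollback restores the prior state exactly. `dump()` emits a deterministic
text serialization used by the rollback and idempotence tests. Timestamps
come from an injectable clock (UTC wall clock by default) so audit trails
are testable deterministically.

Users carry a store-level admin flag; per project a user holds at most one
of `view` or `edit` (edit implies view; a new grant replaces the old).
Admin-only operations: template and field administration, grants,
dictionary creation via an actor. Reads (history, search, export,
reports) require view; loads require edit; registering a new project
grants its creator edit. A user with no grant sees nothing.

Formats are RFC 4180 CSV, UTF-8, LF-emitted (CRLF accepted): data
templates (`#DataTemplate: <event>` first line, headers second, rows
after), setup files (`event_name, field_name, data_type, required,
active, max_length, description, ontology_class, position,
default_options` — one row per field, annotations verbatim in
`default_options`), dictionary files (`dictionary, value, parent_value`),
and error reports (`row, field, code, message`). Two conventions close
gaps the setup schema itself cannot express: a dictionary row with an
empty `value` declares the dictionary's parent list, and a template's
scope is inferred from its canonical name (containing `sample` → sample
scope). Setup application is an upsert and is idempotent — re-running an
identical setup leaves the dump byte-identical — which is also how an
existing study's exported setup seeds a new study. JSON export emits an
array of flat objects with keys in field-position order for diffability.

Search evaluates query trees (leaves `equal` — exact normalized match,
`like` — case-insensitive substring, `in` — case-sensitive membership;
connectives `AND`/`OR`/`NOT`, a `*` leaf matching any attribute) over
materialized current state only; history questions go to
`event_history`. The contract *is* the naive per-entity scan, and the
tests hold the implementation to a brute-force evaluator over randomized
trees to depth 4, including De Morgan's identity. `like`'s
case-insensitivity and `in`'s case-sensitivity are documented decisions,
not inferences. The CLI accepts a small text grammar (quoted multiword
fields, parentheses, `AND`/`OR`/`NOT`) and a JSON tree form for anything
richer.

## Synthetic studies

The generator emits complete study bundles: a setup CSV (registration
template with required identity fields, a dropdown status vocabulary, a
date, an integer, a float, a two-level State→city dictionary cascade, an
opt-in-unique barcode, a length-capped notes field, plus freeform extras;
update templates touching a subset of fields), a dictionary CSV, data
CSVs mixing the three accepted date spellings, `NULL` clears and empty
no-change cells, and a JSON manifest. Defaults are one project, ten
samples, two event templates and no invalid rows; each study in the
randomized sweeps varies small sample counts (2–8), one to three event
templates and invalid fractions of 0–30%, sizes chosen so hundreds of
independent studies exercise the engine from fresh stores in seconds.
Deliberately invalid rows are produced by a closed set of mutation
operators (bad date, missing required name, off-vocabulary status,
cascade violation, over-length note, duplicate unique barcode) cycled in
order, so every data-level issue code is reachable. The manifest's
expected counts (events, samples, materialized attributes, per-file
invalid row indices) are computed by plain dict bookkeeping inside the
generator, independent of the store, making the manifest an oracle rather
than an echo. Identical configs generate byte-identical bundles; manifest
paths are bundle-relative so bundles are relocatable.

What the generator does not emulate: biologically realistic value
distributions, multi-user interleavings, malformed CSV framing, or
concurrent writers. Passing tests therefore demonstrate the engine's
contracts (validation, atomicity, replay equivalence, query semantics) on
structurally realistic data, not robustness to arbitrarily dirty
real-world exports.

The scale generator streams a wide registration CSV line by line at
constant memory. The performance scenario — 5,000 samples × 30 attributes
(150,000 attribute values) through load, search and export — is a
deliberately scaled-down stand-in for half-million-sample deployments; it
completes in a few seconds in one process, and the acceptance script
reports the measured wall time rather than asserting hardware-dependent
claims.

## Known limitations

* Single-writer embedded store; no server, no concurrent sessions.
* Uniqueness is scoped per project; store-wide uniqueness would need a
  configuration knob that does not exist yet.
* Annotations do not compose (at most one per field); read-only plus
  pattern, for example, cannot be expressed.
* Ontology support is membership-checking against a pluggable provider;
  no live terminology-service client is included.
* `file`-typed fields store the path text verbatim; no content hashing or
  transfer.
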