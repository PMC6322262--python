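"""Validation engine: coercion, row/batch checks, uniqueness, custom
validators, and agreement with an independent brute-force checker."""
import random

import pytest

from metatrail import (
    ConfigurationError,
    EventTemplate,
    FieldDefinition,
    MetadataStore,
    StaticOntologyProvider,
    ValidatorRegistry,
    coerce_value,
    parse_annotation,
    validate_batch,
    validate_row,
)
from metatrail.validation import UNIQUENESS_KEY

from conftest import TABLE1_ROWS, sample_registration_fields


@pytest.mark.parametrize("dtype,raw,expected", [
    ("date", "7/27/16", "2016-07-27"),
    ("date", "10/20/14", "2014-10-20"),
    ("date", "1/5/1999", "1999-01-05"),
    ("date", "2014-10-20", "2014-10-20"),
    ("date", "12/31/69", "2069-12-31"),    # two-digit pivot: 00-69 -> 20xx
    ("date", "1/1/70", "1970-01-01"),      # 70-99 -> 19xx
    ("integer", "42", "42"),
    ("integer", "-007", "-7"),
    ("float", "3.50", "3.5"),
    ("float", "1e3", "1000.0"),
    ("string", "as submitted  ", "as submitted  "),
    ("file", "runs/r1.fastq", "runs/r1.fastq"),
    ("string", "", ""),                    # empty stays empty
])
def test_coercion_normalizes(dtype, raw, expected):
    normalized, issue = coerce_value(dtype, raw)
    assert issue is None
    assert normalized == expected


@pytest.mark.parametrize("dtype,raw,code", [
    ("integer", "3.5", "type_error"),
    ("integer", "abc", "type_error"),
    ("float", "NaN", "type_error"),
    ("date", "13/45/99", "type_error"),
    ("date", "2/30/15", "type_error"),     # not a calendar date
    ("date", "yesterday", "type_error"),
])
def test_coercion_rejects(dtype, raw, code):
    normalized, issue = coerce_value(dtype, raw)
    assert normalized is None
    assert issue.code == code


def test_max_length_applies_to_normalized_text():
    _, issue = coerce_value("string", "x" * 11, max_length=10)
    assert issue.code == "max_length"
    normalized, issue = coerce_value("string", "x" * 10, max_length=10)
    assert issue is None


def _template(fields):
    return EventTemplate(name="sampleregistration",
                         display_name="Sample Registration", scope="sample",
                         fields=fields)


def test_worked_example_rows_validate_clean():
    template = _template(sample_registration_fields())
    for i, row in enumerate(TABLE1_ROWS, start=1):
        issues, normalized = validate_row(template, row, i)
        assert issues == []
        assert normalized["Specimen Collection Date"] in (
            "2016-07-27", "2014-10-20")


def test_missing_required_and_unknown_columns_flagged():
    template = _template(sample_registration_fields())
    row = dict(TABLE1_ROWS[0])
    row["Sample Name"] = ""
    issues, _ = validate_row(template, row, 1)
    assert [i.code for i in issues] == ["required_missing"]
    row = dict(TABLE1_ROWS[0], Color="red")
    issues, _ = validate_row(template, row, 2)
    assert [(i.code, i.field) for i in issues] == [("unknown_field", "Color")]
    assert all(i.row_index == 2 for i in issues)


def test_inactive_fields_are_not_required_but_rejected_as_columns():
    fields = sample_registration_fields()
    fields[-1].required = False
    fields[-1].active = False
    template = _template(fields)
    row = dict(TABLE1_ROWS[0])
    issues, _ = validate_row(template, row, 1)
    assert [i.code for i in issues] == ["unknown_field"]
    row.pop("Specimen Collector Name")
    issues, _ = validate_row(template, row, 1)
    assert issues == []


class _Ctx:
    """Stub batch context with no stored state."""

    def __init__(self, stored=None):
        self.registry = ValidatorRegistry()
        self._stored = stored or {}
        self.ontology_provider = None

    def dictionary_values(self, name, parent_value=None):
        return []

    def stored_field_values(self, field_name, scope):
        return self._stored.get(field_name, {})

    def sample_exists(self, name):
        return False

    def would_create_cycle(self, child, parent):
        return False


def _unique_name_template():
    fields = sample_registration_fields()
    fields[1].annotation = parse_annotation(
        "{validate:DataValidator.checkFieldUniqueness}")
    return _template(fields)


def test_uniqueness_is_opt_in():
    """Duplicate sample names pass when no uniqueness annotation is set."""
    template = _template(sample_registration_fields())
    report = validate_batch(template, TABLE1_ROWS, _Ctx())
    assert report.issues == []
    assert report.row_ok == [True, True]


def test_within_batch_uniqueness_flags_second_row():
    report = validate_batch(_unique_name_template(), TABLE1_ROWS, _Ctx())
    assert [(i.row_index, i.code) for i in report.issues] == [
        (2, "uniqueness_violation")]
    assert report.row_ok == [True, False]


def test_stored_uniqueness_blocks_reregistration():
    ctx = _Ctx(stored={"Sample Name": {"SAM657": "SAM657"}})
    report = validate_batch(_unique_name_template(), TABLE1_ROWS[:1], ctx)
    assert [i.code for i in report.issues] == ["uniqueness_violation"]
    assert [i.severity for i in report.issues] == ["error"]


def test_stored_uniqueness_is_warning_for_updates_of_other_entities():
    fields = [FieldDefinition("Project Name", "string", required=True,
                              position=1),
              FieldDefinition("Sample Name", "string", required=True,
                              position=2),
              FieldDefinition("Barcode", "string", position=3,
                              annotation=parse_annotation(
                                  "{validate:DataValidator.checkFieldUniqueness}"))]
    template = EventTemplate(name="sampleupdate", display_name="SampleUpdate",
                             scope="sample", fields=fields)
    ctx = _Ctx(stored={"Barcode": {"BC1": "OTHER_SAMPLE"}})
    row = {"Project Name": "P", "Sample Name": "SAM657", "Barcode": "BC1"}
    report = validate_batch(template, [row], ctx)
    assert [(i.code, i.severity) for i in report.issues] == [
        ("uniqueness_violation", "warning")]
    assert report.ok and report.row_ok == [True]
    # the entity re-seeing its own stored value is not even a warning
    ctx = _Ctx(stored={"Barcode": {"BC1": "SAM657"}})
    report = validate_batch(template, [row], ctx)
    assert report.issues == []


def test_empty_batch_yields_empty_report():
    report = validate_batch(_template(sample_registration_fields()), [], _Ctx())
    assert report.issues == [] and report.row_ok == []


def test_custom_validator_invoked_once_per_row():
    calls = []

    def check_lat_lon(field, raw, row, ctx):
        calls.append((field, raw))
        return []

    ctx = _Ctx()
    ctx.registry.register("DataValidator.checkLatLon", check_lat_lon)
    fields = sample_registration_fields()
    fields[4].annotation = parse_annotation("{validate:DataValidator.checkLatLon}")
    report = validate_batch(_template(fields), TABLE1_ROWS, ctx)
    assert report.issues == []
    assert len(calls) == len(TABLE1_ROWS)


def test_unregistered_validator_is_a_configuration_error():
    fields = sample_registration_fields()
    fields[4].annotation = parse_annotation("{validate:DataValidator.noSuch}")
    with pytest.raises(ConfigurationError):
        validate_batch(_template(fields), TABLE1_ROWS, _Ctx())


def test_registry_contract():
    registry = ValidatorRegistry()
    assert UNIQUENESS_KEY in registry
    registry.register("DataValidator.checkLatLon", lambda *a: [])
    with pytest.raises(ConfigurationError):
        registry.register("DataValidator.checkLatLon", lambda *a: [])
    with pytest.raises(ConfigurationError):
        registry.register("notdotted", lambda *a: [])
    with pytest.raises(ConfigurationError):
        registry.get("DataValidator.unknown")


def test_validation_idempotent_and_matches_naive_checker():
    """Randomized batches: the engine's issue set equals a naive checker
    that re-implements requiredness, typing and max-length rules."""
    rng = random.Random(17)
    fields = [
        FieldDefinition("Project Name", "string", required=True, position=1),
        FieldDefinition("Sample Name", "string", required=True, position=2),
        FieldDefinition("Age", "integer", position=3),
        FieldDefinition("Note", "string", max_length=5, position=4),
    ]
    template = _template(fields)
    rows = []
    for i in range(60):
        rows.append({
            "Project Name": "P",
            "Sample Name": rng.choice(["", f"S{i}"]),
            "Age": rng.choice(["", "12", "x", "3.5"]),
            "Note": rng.choice(["", "ok", "toolong!"]),
        })

    def naive(row):
        codes = set()
        if not row["Sample Name"]:
            codes.add("required_missing")
        if row["Age"] not in ("",) and not row["Age"].lstrip("+-").isdigit():
            codes.add("type_error")
        if len(row["Note"]) > 5:
            codes.add("max_length")
        return codes

    first = validate_batch(template, rows, _Ctx())
    second = validate_batch(template, rows, _Ctx())
    assert first == second
    for i, row in enumerate(rows, start=1):
        got = {x.code for x in first.issues if x.row_index == i}
        assert got == naive(row), f"row {i}: {row}"


def test_ontology_class_restricts_terms_when_provider_configured():
    store = MetadataStore()
    store.ontology_provider = StaticOntologyProvider(
        {"NCBITaxon": ["E. coli", "S. aureus"]})
    fields = sample_registration_fields()
    fields[4].ontology_class = "NCBITaxon"
    store.define_event_template("Sample Registration", "sample", fields,
                                "admin")
    store.register_project("P", "admin")
    bad = dict(TABLE1_ROWS[0], Organism="Martian virus",
               **{"Project Name": "P"})
    result = store.load_event("P", "SampleRegistration", [bad], "admin")
    assert result.status == "rejected"
    assert [i.code for i in result.issues] == ["option_violation"]
    good = dict(TABLE1_ROWS[0], **{"Project Name": "P"})
    assert store.load_event("P", "SampleRegistration", [good],
                            "admin").status == "committed"
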