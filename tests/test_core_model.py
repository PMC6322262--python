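"""Core domain contracts: template administration, roles, dictionaries
with cascading validation, and referential integrity."""
import pytest

from metatrail import (
    AuthorizationError,
    ConfigurationError,
    FieldDefinition,
    NotFoundError,
    UsageError,
    canonical_name,
    generate_blank_template,
)

from conftest import SAMPLE_REGISTRATION_FIELDS, sample_registration_fields


def test_template_name_canonicalization():
    assert canonical_name("Sample Registration") == "sampleregistration"
    assert canonical_name("  Sample\tRegistration ") == "sampleregistration"
    assert canonical_name("SAMPLEREGISTRATION") == "sampleregistration"


def test_builtin_templates_exist_and_are_configurable_once(store):
    names = {t.name for t in store.list_templates()}
    assert {"projectregistration", "projectupdate", "sampleregistration",
            "sampleupdate"} <= names
    t = store.define_event_template("Sample Registration", "sample",
                                    sample_registration_fields(), "admin")
    assert [f.name for f in t.ordered_fields()] == [
        n for n, _, _ in SAMPLE_REGISTRATION_FIELDS]
    assert len(t.fields) == 7
    with pytest.raises(ConfigurationError):
        store.define_event_template("SampleRegistration", "sample",
                                    sample_registration_fields(), "admin")


def test_empty_template_is_valid_and_duplicate_fields_are_not(store):
    t = store.define_event_template("X", "project", [], "admin")
    assert t.fields == []
    with pytest.raises(ConfigurationError):
        store.define_event_template("Y", "project",
                                    [FieldDefinition("A"),
                                     FieldDefinition("A")], "admin")


def test_non_admin_cannot_define_templates(store):
    store.create_user("u1", admin=False)
    with pytest.raises(AuthorizationError):
        store.define_event_template("Z", "project", [], "u1")


def test_field_update_deactivation_and_reordering(store):
    store.define_event_template("Sample Registration", "sample",
                                sample_registration_fields(), "admin")
    store.update_field_definition("Sample Registration",
                                  "Specimen Collector Name", "admin",
                                  active=False)
    t = store.get_template("Sample Registration")
    blank = generate_blank_template(t)
    assert "Specimen Collector Name" not in blank
    # requiring an inactive field is a configuration error
    with pytest.raises(ConfigurationError):
        store.update_field_definition("Sample Registration",
                                      "Specimen Collector Name", "admin",
                                      required=True)
    with pytest.raises(NotFoundError):
        store.update_field_definition("Sample Registration", "No Such Field",
                                      "admin", active=False)
    # moving the last field to position 1 puts it first in the blank header
    store.update_field_definition("Sample Registration",
                                  "Specimen Collection Date", "admin",
                                  position=0)
    t = store.get_template("Sample Registration")
    header = generate_blank_template(t).splitlines()[1].split(",")
    assert header[0] == "Specimen Collection Date"


def test_role_grants_control_loading(table1_store):
    store = table1_store
    store.create_user("u1")
    with pytest.raises(AuthorizationError):   # no grant at all
        store.load_event("Pilot647", "SampleUpdate", [], "u1")
    store.grant_role("u1", "Pilot647", "view", "admin")
    with pytest.raises(AuthorizationError):   # read-only
        store.load_event("Pilot647", "SampleUpdate", [], "u1")
    assert store.event_history("u1", project="Pilot647")  # view works
    store.grant_role("u1", "Pilot647", "edit", "admin")
    assert store.role_on("u1", "Pilot647") == "edit"      # replaced, not added
    result = store.load_event(
        "Pilot647", "SampleUpdate",
        [{"Project Name": "Pilot647", "Sample Name": "SAM657"}], "u1")
    assert result.status == "committed"


def test_ungranted_user_cannot_read(table1_store):
    table1_store.create_user("stranger")
    with pytest.raises(AuthorizationError):
        table1_store.event_history("stranger", project="Pilot647")
    # and without a project filter they simply see nothing
    assert table1_store.event_history("stranger") == []


def test_grant_requires_known_project_and_admin_actor(store):
    store.create_user("u1")
    with pytest.raises(NotFoundError):
        store.grant_role("u1", "NoProject", "view", "admin")
    store.register_project("P", "admin")
    with pytest.raises(AuthorizationError):
        store.grant_role("u1", "P", "view", "u1")


@pytest.fixture
def cascade(store):
    store.create_dictionary("State")
    store.add_dictionary_entry("State", "MD")
    store.add_dictionary_entry("State", "CA")
    store.create_dictionary("city", parent_name="State")
    store.add_dictionary_entry("city", "Rockville", "MD")
    store.add_dictionary_entry("city", "Baltimore", "MD")
    store.add_dictionary_entry("city", "La Jolla", "CA")
    return store


def test_dictionary_cascade_filtering(cascade):
    assert cascade.dictionary_values("State") == ["CA", "MD"]
    assert cascade.dictionary_values("city", "MD") == ["Baltimore", "Rockville"]
    assert cascade.dictionary_values("city", "CA") == ["La Jolla"]
    assert cascade.dictionary_values("city", "WA") == []   # empty filter


def test_dictionary_values_equal_brute_force_filter(cascade):
    entries = cascade.dictionary_entries("city")
    for parent in ("MD", "CA", "WA"):
        brute = sorted(v for v, p in entries if p == parent)
        assert cascade.dictionary_values("city", parent) == brute
    assert cascade.dictionary_values("city") == sorted(
        {v for v, _ in entries})


def test_dictionary_referential_integrity(cascade):
    with pytest.raises(ConfigurationError):   # WA not in State
        cascade.add_dictionary_entry("city", "Perth", "WA")
    with pytest.raises(ConfigurationError):   # parent required
        cascade.add_dictionary_entry("city", "Perth")
    with pytest.raises(ConfigurationError):   # duplicate entry
        cascade.add_dictionary_entry("State", "MD")
    with pytest.raises(ConfigurationError):   # unknown parent dictionary
        cascade.create_dictionary("species", parent_name="host common name")
    with pytest.raises(UsageError):           # parentless filter
        cascade.dictionary_values("State", "MD")
    with pytest.raises(ConfigurationError):   # duplicate dictionary
        cascade.create_dictionary("State")


def test_species_host_cascade(store):
    """Child values valid only under the selected parent value."""
    store.create_dictionary("host common name")
    for host in ("human", "mouse"):
        store.add_dictionary_entry("host common name", host)
    store.create_dictionary("species", parent_name="host common name")
    store.add_dictionary_entry("species", "Homo sapiens", "human")
    store.add_dictionary_entry("species", "Mus musculus", "mouse")
    assert store.dictionary_values("species", "human") == ["Homo sapiens"]


def test_sample_parent_pointer_and_cycle_rejection(table1_store):
    store = table1_store
    store.add_field("SampleRegistration",
                    FieldDefinition("Parent Sample", "string", position=8),
                    "admin")
    rows = [{"Project Name": "Pilot647", "Sample Name": "SAM658",
             "Parent Sample": "SAM657"}]
    assert store.load_event("Pilot647", "SampleRegistration", rows,
                            "admin").status == "committed"
    assert store.get_sample("Pilot647", "SAM658").parent_sample == "SAM657"
    # unknown parent and self/cycle parents are validation errors
    bad = [{"Project Name": "Pilot647", "Sample Name": "SAM659",
            "Parent Sample": "GHOST"}]
    assert store.load_event("Pilot647", "SampleRegistration", bad,
                            "admin").status == "rejected"
    cyc = [{"Project Name": "Pilot647", "Sample Name": "SAM657",
            "Parent Sample": "SAM658"}]
    result = store.load_event("Pilot647", "SampleRegistration", cyc, "admin")
    assert result.status == "rejected"
    assert [i.code for i in result.issues] == ["option_violation"]
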