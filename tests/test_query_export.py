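"""Search semantics against a brute-force oracle, Boolean identities,
report generation, and export round-trips."""
import csv
import io
import json
import random

import pytest

from metatrail import (
    GLOBAL,
    Leaf,
    MetadataStore,
    Node,
    QueryError,
    evaluate,
    export_csv,
    export_json,
    generate_report,
    parse_query,
    query_from_json,
    search,
)

from conftest import SAM657_FINAL


class TestWorkedExampleQueries:
    def test_equal_matches_normalized_value(self, table1_store):
        hits = search(table1_store, Leaf("Organism", "equal", "E. coli"),
                      "admin", project="Pilot647")
        assert [h[1] for h in hits] == ["SAM657"]

    def test_like_is_case_insensitive_substring(self, table1_store):
        hits = search(table1_store,
                      Leaf("Specimen Collector Name", "like", "michael"),
                      "admin")
        assert [h[1] for h in hits] == ["SAM657"]

    def test_contradiction_on_single_valued_field(self, table1_store):
        q = Node("AND", (Leaf("Sample Type", "equal", "GDNA"),
                         Leaf("Sample Type", "equal", "CDNA")))
        assert search(table1_store, q, "admin") == []

    def test_not_in_returns_complement(self, table1_store):
        q = Node("NOT", (Leaf("Sample Status", "in", ("Deprecated",)),))
        assert [h[1] for h in search(table1_store, q, "admin")] == ["SAM657"]

    def test_global_leaf_matches_any_attribute(self, table1_store):
        hits = search(table1_store, Leaf(GLOBAL, "like", "ted mich"), "admin")
        assert [h[1] for h in hits] == ["SAM657"]

    def test_unknown_field_is_a_query_error(self, table1_store):
        with pytest.raises(QueryError):
            search(table1_store, Leaf("Colour", "equal", "x"), "admin")


@pytest.fixture(scope="module")
def populated():
    """A small project with heterogeneous samples for oracle tests."""
    store = MetadataStore()
    from metatrail import FieldDefinition
    fields = [FieldDefinition("Project Name", "string", required=True,
                              position=1),
              FieldDefinition("Sample Name", "string", required=True,
                              position=2),
              FieldDefinition("Status", "string", position=3),
              FieldDefinition("Organism", "string", position=4),
              FieldDefinition("Site", "string", position=5)]
    store.define_event_template("Sample Registration", "sample", fields,
                                "admin")
    store.register_project("P1", "admin")
    rng = random.Random(23)
    rows = []
    for i in range(40):
        rows.append({
            "Project Name": "P1", "Sample Name": f"S{i:03d}",
            "Status": rng.choice(["Received", "Analysis", "Deprecated", ""]),
            "Organism": rng.choice(["E. coli", "S. aureus", "C. albicans"]),
            "Site": rng.choice(["gut", "oral", ""])})
    store.load_event("P1", "SampleRegistration", rows, "admin")
    return store


def _random_query(rng, fields, values, depth):
    if depth == 0 or rng.random() < 0.4:
        op = rng.choice(["equal", "like", "in"])
        field = rng.choice(fields + [GLOBAL])
        if op == "in":
            k = rng.randint(1, 3)
            return Leaf(field, "in", tuple(rng.sample(values, k)))
        value = rng.choice(values)
        if op == "like":
            value = value[:max(1, len(value) // 2)].swapcase()
        return Leaf(field, op, value)
    conn = rng.choice(["AND", "OR", "NOT"])
    if conn == "NOT":
        return Node("NOT", (_random_query(rng, fields, values, depth - 1),))
    children = tuple(_random_query(rng, fields, values, depth - 1)
                     for _ in range(rng.randint(2, 3)))
    return Node(conn, children)


def test_search_equals_brute_force_oracle(populated):
    """Randomized query trees (depth <= 4) return exactly the entity set a
    naive per-entity evaluator selects."""
    rng = random.Random(99)
    fields = ["Status", "Organism", "Site", "Sample Name"]
    values = ["Received", "Analysis", "Deprecated", "E. coli", "S. aureus",
              "gut", "oral", "S001"]
    samples = populated.list_samples("P1")
    states = {}
    for s in samples:
        attrs = dict(populated.current_state("P1", s))
        attrs["Project Name"] = "P1"
        attrs["Sample Name"] = s
        states[s] = attrs
    for trial in range(150):
        q = _random_query(rng, fields, values, depth=rng.randint(1, 4))
        got = {h[1] for h in search(populated, q, "admin", project="P1")}
        want = {s for s in samples if evaluate(q, states[s])}
        assert got == want, f"trial {trial}: {q}"


def test_de_morgan_identity(populated):
    rng = random.Random(7)
    fields = ["Status", "Organism", "Site"]
    values = ["Received", "E. coli", "gut", "Deprecated"]
    for _ in range(40):
        a = _random_query(rng, fields, values, 1)
        b = _random_query(rng, fields, values, 1)
        lhs = Node("NOT", (Node("AND", (a, b)),))
        rhs = Node("OR", (Node("NOT", (a,)), Node("NOT", (b,))))
        assert {h[1] for h in search(populated, lhs, "admin")} == \
               {h[1] for h in search(populated, rhs, "admin")}


def test_search_requires_view_role(populated):
    populated.create_user("nobody")
    from metatrail import AuthorizationError
    with pytest.raises(AuthorizationError):
        search(populated, Leaf("Status", "equal", "Received"), "nobody",
               project="P1")
    # without a project filter, unseen projects are silently excluded
    assert search(populated, Leaf("Status", "equal", "Received"),
                  "nobody") == []


class TestQueryGrammar:
    @pytest.mark.parametrize("text,expected", [
        ('Organism equal "E. coli"', Leaf("Organism", "equal", "E. coli")),
        ('Organism like coli', Leaf("Organism", "like", "coli")),
        ('"Sample Status" in ("A","B")',
         Leaf("Sample Status", "in", ("A", "B"))),
        ('NOT Site equal gut', Node("NOT", (Leaf("Site", "equal", "gut"),))),
        ('a equal 1 AND b equal 2 OR c equal 3',
         Node("OR", (Node("AND", (Leaf("a", "equal", "1"),
                                  Leaf("b", "equal", "2"))),
                     Leaf("c", "equal", "3")))),
        ('a equal 1 AND (b equal 2 OR c equal 3)',
         Node("AND", (Leaf("a", "equal", "1"),
                      Node("OR", (Leaf("b", "equal", "2"),
                                  Leaf("c", "equal", "3")))))),
    ])
    def test_parse(self, text, expected):
        assert parse_query(text) == expected

    @pytest.mark.parametrize("bad", ["", "Organism", "Organism near x",
                                     "a equal", "a in ()", "a equal 1 extra"])
    def test_reject(self, bad):
        with pytest.raises(QueryError):
            parse_query(bad)

    def test_json_form(self):
        q = query_from_json(json.dumps({
            "connective": "NOT",
            "children": [{"field": "Status", "op": "in",
                          "operand": ["Deprecated"]}]}))
        assert q == Node("NOT", (Leaf("Status", "in", ("Deprecated",)),))


class TestExport:
    def test_csv_export_reflects_last_write_state(self, table1_store):
        text = export_csv(table1_store, "Pilot647", "admin")
        rows = list(csv.DictReader(io.StringIO(text)))
        assert len(rows) == 1
        row = rows[0]
        assert row["Sample Name"] == "SAM657"
        for field, value in SAM657_FINAL.items():
            assert row[field] == value

    def test_json_export_of_empty_project(self, store):
        store.register_project("Empty", "admin")
        assert json.loads(export_json(store, "Empty", "admin")) == []

    def test_json_key_order_follows_field_positions(self, table1_store):
        objs = json.loads(export_json(table1_store, "Pilot647", "admin"))
        assert list(objs[0]) == ["Project Name", "Sample Name",
                                 "Sample Status", "Sample Type", "Organism",
                                 "Specimen Collection Date",
                                 "Specimen Collector Name"]

    def test_unknown_export_field_rejected(self, table1_store):
        with pytest.raises(QueryError):
            export_csv(table1_store, "Pilot647", "admin", ["Colour"])

    def test_export_reimport_export_fixed_point(self, table1_store, clock):
        from conftest import sample_registration_fields
        text = export_csv(table1_store, "Pilot647", "admin")
        fresh = MetadataStore(clock=clock)
        fresh.define_event_template("Sample Registration", "sample",
                                    sample_registration_fields(), "admin")
        fresh.register_project("Pilot647", "admin")
        from metatrail import parse_template_csv
        parsed = parse_template_csv("#DataTemplate: SampleRegistration\n"
                                    + text)
        fresh.load_event("Pilot647", parsed.template_name, parsed.rows,
                         "admin")
        assert export_csv(fresh, "Pilot647", "admin") == text
        assert fresh.current_state("Pilot647", "SAM657") == \
            table1_store.current_state("Pilot647", "SAM657")


class TestReports:
    def test_event_report_one_row_per_record(self, table1_store):
        report = generate_report(table1_store, "Pilot647", "admin",
                                 template="SampleRegistration")
        assert len(report.rows) == 2
        assert report.header[-2:] == ["actor", "timestamp"]
        assert all(r[-2] == "admin" and r[-1] for r in report.rows)

    def test_field_report_equals_export(self, table1_store):
        report = generate_report(table1_store, "Pilot647", "admin",
                                 fields=["Sample Name", "Organism"])
        assert report.rows == [["SAM657", "E. coli"]]

    def test_report_on_eventless_project(self, store):
        store.register_project("Quiet", "admin")
        report = generate_report(store, "Quiet", "admin",
                                 template="SampleRegistration")
        assert report.rows == []
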