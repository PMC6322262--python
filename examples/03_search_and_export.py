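"""Boolean search over materialized state, reports, and CSV/JSON export.

Queries are trees of equal / like / in leaves joined by AND / OR / NOT and
always evaluate exactly like a per-entity scan of current state.
"""
from metatrail import (
    FieldDefinition,
    Leaf,
    MetadataStore,
    Node,
    export_csv,
    export_json,
    generate_report,
    parse_query,
    search,
)

store = MetadataStore()
fields = [FieldDefinition("Project Name", "string", required=True, position=1),
          FieldDefinition("Sample Name", "string", required=True, position=2),
          FieldDefinition("Organism", position=3),
          FieldDefinition("Sample Status", position=4)]
store.define_event_template("Sample Registration", "sample", fields, "admin")
store.register_project("P1", "admin")
store.load_event("P1", "SampleRegistration", [
    {"Project Name": "P1", "Sample Name": "S1", "Organism": "E. coli",
     "Sample Status": "Analysis"},
    {"Project Name": "P1", "Sample Name": "S2", "Organism": "S. aureus",
     "Sample Status": "Deprecated"},
    {"Project Name": "P1", "Sample Name": "S3", "Organism": "E. coli",
     "Sample Status": "Received"},
], "admin")

q = Node("AND", (Leaf("Organism", "equal", "E. coli"),
                 Node("NOT", (Leaf("Sample Status", "in", ("Deprecated",)),))))
hits = search(store, q, "admin", project="P1")
print("matching samples:", [h[1] for h in hits])
# -> ['S1', 'S3']: E. coli samples that are not deprecated

same = parse_query('Organism equal "E. coli" AND NOT '
                   '"Sample Status" in ("Deprecated")')
assert search(store, same, "admin") == hits   # text grammar, same tree

print(export_csv(store, "P1", "admin"), end="")
# -> one CSV row per sample in name order, columns in field position order

print(export_json(store, "P1", "admin", ["Sample Name", "Organism"]))
# -> flat JSON objects keyed by field name, ready for submission pipelines

report = generate_report(store, "P1", "admin", template="SampleRegistration")
print(f"report: {len(report.rows)} event rows, columns {report.header}")
# -> one row per registration event, with actor and timestamp appended
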