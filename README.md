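# metatrail

Event-sourced, data-driven tracking of study metadata for sequencing and
omics projects.

## The problem

Large sequencing efforts — metagenomics cohorts, infectious-disease isolate
collections — track thousands of samples whose metadata requirements differ
per study and evolve mid-study, while data-standard submissions
(MIxS/MIMS-style checklists, BioSample registration) demand validated,
harmonized values and a defensible record of who changed what and when.
Hard-coding each study's fields into a database schema does not survive
this; `metatrail` instead makes the schema itself data.

Three ideas carry the design:

* **Entity–attribute–value storage.** A project or sample carries its
  metadata as rows of (field, value) pairs. Adding or deprecating a field
  is a data edit, not a schema migration. Field definitions —
  *meta-attributes* — carry type (`string`, `date`, `integer`, `float`,
  `file`), requiredness, activity, max length, display position and an
  optional input annotation.
* **Events as the only write path.** Every load is a named event
  (SampleRegistration, SampleUpdate, or any study-defined operation)
  committing one immutable record per CSV row with actor and timestamp.
  Materialized current state is, by construction, the fold of the event
  history: for every entity `current_state(e) == replay(history(e))`,
  where the last non-empty write per field wins and the literal `NULL`
  clears a value. Failed atomic batches roll back to a byte-identical
  store.
* **Validation as configuration.** A curly-brace annotation DSL attaches
  allowed-value rules to fields: `{radio(a;b)}`, `{dropdown(...)}`,
  `{multi-dropdown(...)}`, `{ReadOnly:NA}`, `{RegEx([ACTG]*)}`,
  `{validate:Class.method}` (custom validators, including opt-in field
  uniqueness) and `{Dictionary:city,Parent:State}` (controlled lists with
  cascading parent–child filtering). Batch validation reports every
  finding with row, field and a closed-set code before anything commits.

Studies are configured from plain CSV setup files, loaded from
`#DataTemplate:` data CSVs, queried with boolean trees of
`equal`/`like`/`in` predicates joined by `AND`/`OR`/`NOT`, and exported to
CSV or JSON for submission pipelines. View/edit roles per project gate
every read and write.

## Worked example

```python
from metatrail import FieldDefinition, MetadataStore, parse_template_csv

csv_text = """#DataTemplate: Sample Registration
Project Name,Sample Name,Sample Status,Sample Type,Organism,Specimen Collection Date,Specimen Collector Name
Pilot647,SAM657,Analysis,GDNA,E. coli,7/27/16,John Kim
Pilot647,SAM657,Analysis,CDNA,E. coli,10/20/14,Ted Michael
"""

store = MetadataStore()
store.define_event_template("Sample Registration", "sample", [
    FieldDefinition("Project Name", "string", required=True, position=1),
    FieldDefinition("Sample Name", "string", required=True, position=2),
    FieldDefinition("Sample Status", position=3),
    FieldDefinition("Sample Type", position=4),
    FieldDefinition("Organism", position=5),
    FieldDefinition("Specimen Collection Date", "date", position=6),
    FieldDefinition("Specimen Collector Name", position=7),
], "admin")
store.register_project("Pilot647", "admin")

parsed = parse_template_csv(csv_text)
result = store.load_event("Pilot647", parsed.template_name, parsed.rows, "admin")
print(result.events_created, result.samples_created, result.samples_updated)
print(store.current_state("Pilot647", "SAM657"))
```

prints

```
2 1 1
{'Organism': 'E. coli', 'Sample Status': 'Analysis', 'Sample Type': 'CDNA',
 'Specimen Collection Date': '2014-10-20', 'Specimen Collector Name': 'Ted Michael'}
```

Both rows name the same sample, so the load commits two audited events but
creates one sample and updates it once. The materialized state keeps the
later row's values (`CDNA`, `Ted Michael`) while the earlier ones (`GDNA`,
`John Kim`, `2016-07-27`) stay retrievable from
`store.event_history("admin", sample="SAM657")` with actor and timestamp.
Slash dates are normalized to ISO.

The `examples/` directory has one short script per capability
(configuration and loading, annotations and dictionaries, search and
export, synthetic studies); each prints the numbers it computes and what
they mean. The same workflows are available from the shell:

```sh
metatrail init --store study.db
metatrail setup setup.csv --store study.db
metatrail load-event HMP SampleRegistration samples.csv --store study.db
metatrail search -p HMP -q 'Organism equal "E. coli"' --store study.db
```

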