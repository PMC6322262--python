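"""Field annotations and cascading controlled vocabularies.

A field definition may carry one curly-brace annotation constraining its
values: option lists, regular expressions, read-only defaults, opt-in
uniqueness, or dictionary membership filtered by a parent field.
"""
from metatrail import (
    FieldDefinition,
    MetadataStore,
    parse_annotation,
    render_annotation,
)

spec = parse_annotation("{multi-dropdown(454;Illumina;PacBio;Sanger)}")
print("kind:", spec.kind, "| options:", spec.options)
print("round-trip:", render_annotation(spec))
# -> parse and render are inverses; option order is presentation order

store = MetadataStore()
store.create_dictionary("State")
store.add_dictionary_entry("State", "MD")
store.add_dictionary_entry("State", "CA")
store.create_dictionary("city", parent_name="State")
store.add_dictionary_entry("city", "Rockville", "MD")
store.add_dictionary_entry("city", "La Jolla", "CA")
print("cities under MD:", store.dictionary_values("city", "MD"))
# -> ['Rockville']: the child list is filtered by the selected parent value

fields = [
    FieldDefinition("Project Name", "string", required=True, position=1),
    FieldDefinition("Sample Name", "string", required=True, position=2,
                    annotation=parse_annotation(
                        "{validate:DataValidator.checkFieldUniqueness}")),
    FieldDefinition("State", position=3,
                    annotation=parse_annotation("{Dictionary:State}")),
    FieldDefinition("City", position=4,
                    annotation=parse_annotation(
                        "{Dictionary:city,Parent:State}")),
    FieldDefinition("Read Barcode", position=5,
                    annotation=parse_annotation("{RegEx([ACTG]*)}")),
]
store.define_event_template("Sample Registration", "sample", fields, "admin")
store.register_project("Demo", "admin")

rows = [
    {"Project Name": "Demo", "Sample Name": "S1", "State": "MD",
     "City": "Rockville", "Read Barcode": "ACGT"},
    {"Project Name": "Demo", "Sample Name": "S2", "State": "CA",
     "City": "Rockville", "Read Barcode": "ACGU"},   # two violations
    {"Project Name": "Demo", "Sample Name": "S1", "State": "MD",
     "City": "Rockville", "Read Barcode": ""},       # duplicate unique name
]
report = store.validate("Demo", "SampleRegistration", rows)
for issue in report.issues:
    print(f"row {issue.row_index} [{issue.field}] {issue.code}")
# -> row 2: dictionary_violation (Rockville is not a CA city) and
#    pattern_mismatch (U is not in [ACTG]); row 3: uniqueness_violation
#    because Sample Name opted in to the uniqueness validator
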