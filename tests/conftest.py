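"""Shared fixtures: deterministic clock, a fresh in-memory store, and the
printed sample-registration worked example used across modules."""
import datetime

import pytest

from metatrail import FieldDefinition, MetadataStore


class TickingClock:
    """Deterministic clock: one second per call, fixed epoch."""

    def __init__(self, start="2016-08-01T00:00:00"):
        self.t = datetime.datetime.fromisoformat(start)

    def __call__(self):
        self.t += datetime.timedelta(seconds=1)
        return self.t


@pytest.fixture
def clock():
    return TickingClock()


@pytest.fixture
def store(clock):
    s = MetadataStore(":memory:", admin_user="admin", clock=clock)
    yield s
    s.close()


SAMPLE_REGISTRATION_FIELDS = [
    ("Project Name", "string", True),
    ("Sample Name", "string", True),
    ("Sample Status", "string", False),
    ("Sample Type", "string", False),
    ("Organism", "string", False),
    ("Specimen Collection Date", "date", False),
    ("Specimen Collector Name", "string", False),
]

TABLE1_ROWS = [
    {"Project Name": "Pilot647", "Sample Name": "SAM657",
     "Sample Status": "Analysis", "Sample Type": "GDNA",
     "Organism": "E. coli", "Specimen Collection Date": "7/27/16",
     "Specimen Collector Name": "John Kim"},
    {"Project Name": "Pilot647", "Sample Name": "SAM657",
     "Sample Status": "Analysis", "Sample Type": "CDNA",
     "Organism": "E. coli", "Specimen Collection Date": "10/20/14",
     "Specimen Collector Name": "Ted Michael"},
]

TABLE1_CSV = (
    "#DataTemplate: Sample Registration\n"
    "Project Name,Sample Name,Sample Status,Sample Type,Organism,"
    "Specimen Collection Date,Specimen Collector Name\n"
    "Pilot647,SAM657,Analysis,GDNA,E. coli,7/27/16,John Kim\n"
    "Pilot647,SAM657,Analysis,CDNA,E. coli,10/20/14,Ted Michael\n"
)

#: the materialized state of SAM657 after both rows (last non-empty write
#: wins; dates ISO-normalized)
SAM657_FINAL = {
    "Sample Status": "Analysis",
    "Sample Type": "CDNA",
    "Organism": "E. coli",
    "Specimen Collection Date": "2014-10-20",
    "Specimen Collector Name": "Ted Michael",
}


def sample_registration_fields():
    return [FieldDefinition(name, dtype, required=req, position=i + 1)
            for i, (name, dtype, req) in enumerate(SAMPLE_REGISTRATION_FIELDS)]


@pytest.fixture
def table1_store(store):
    """Store configured with the worked-example template, project
    registered, both data rows loaded."""
    store.define_event_template("Sample Registration", "sample",
                                sample_registration_fields(), "admin")
    store.register_project("Pilot647", "admin")
    result = store.load_event("Pilot647", "SampleRegistration", TABLE1_ROWS,
                              "admin")
    assert result.status == "committed"
    return store
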