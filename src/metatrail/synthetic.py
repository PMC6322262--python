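"""Deterministic synthetic-study generator.

Emits complete, loadable study bundles — setup CSV, dictionary CSV and data
CSVs — plus a JSON manifest of ground-truth expectations (event, sample and
attribute counts; the indices of deliberately invalid rows).  The manifest
is computed by plain dict bookkeeping inside the generator, independent of
the store, so it can serve as the oracle for load/replay/rollback tests.

Structural realism only: field sets, controlled vocabularies, cascading
dictionaries, mixed date spellings and a configurable fraction of broken
rows mirror the *shape* of real study metadata, not its biological content.
Invalid rows are produced by a closed set of mutation operators (bad date,
missing required name, off-vocabulary value, cascade violation, over-length
string, duplicate unique value) so every validation code path is exercised.
"""
from __future__ import annotations

import json
import random
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Iterator, Optional

from .errors import UsageError
from .model import PROJECT_NAME_FIELD, SAMPLE_NAME_FIELD

_STATUS = ("Waiting for sample", "Received", "Sequencing", "Analysis",
           "Submitted", "Completed", "Deprecated")
_STATES = {"MD": ["Rockville", "Baltimore"],
           "CA": ["La Jolla", "San Diego"],
           "WA": ["Perth"]}
_ORGANISMS = ("E. coli", "S. aureus", "P. falciparum", "C. albicans",
              "K. pneumoniae")

#: mutation operators used for deliberately invalid rows, cycled in order
MUTATIONS = ("bad_date", "missing_required", "off_vocabulary",
             "cascade_violation", "over_length", "duplicate_unique")


@dataclass
class FixtureConfig:
    """Shape of one synthetic study; identical configs generate
    byte-identical files."""

    seed: int = 0
    n_projects: int = 1
    n_samples: int = 10
    n_fields_per_event: int = 10
    n_events: int = 2            # templates: 1 registration + updates
    fraction_invalid: float = 0.0
    annotation_mix: dict = dc_field(default_factory=dict)

    def __post_init__(self):
        if min(self.n_projects, self.n_samples, self.n_events) < 0:
            raise UsageError("counts must be non-negative")
        if not 0.0 <= self.fraction_invalid <= 1.0:
            raise UsageError("fraction_invalid must be in [0, 1]")


def _core_fields() -> list[tuple]:
    """(name, data_type, required, max_length, annotation) in position order."""
    return [
        (PROJECT_NAME_FIELD, "string", True, None, ""),
        (SAMPLE_NAME_FIELD, "string", True, None, ""),
        ("Sample Status", "string", False, None,
         "{dropdown(%s)}" % ";".join(_STATUS)),
        ("Organism", "string", False, None, ""),
        ("Collection Date", "date", False, None, ""),
        ("Host Age", "integer", False, None, ""),
        ("Sequencing Depth", "float", False, None, ""),
        ("State", "string", False, None, "{Dictionary:State}"),
        ("City", "string", False, None, "{Dictionary:city,Parent:State}"),
        ("Barcode", "string", False, None,
         "{validate:DataValidator.checkFieldUniqueness}"),
        ("Notes", "string", False, 40, ""),
    ]


_UPDATE_FIELDS = (PROJECT_NAME_FIELD, SAMPLE_NAME_FIELD, "Sample Status",
                  "Collection Date", "Notes")


def _setup_csv(config: FixtureConfig) -> tuple[str, list[str], list[str]]:
    """Returns (setup text, registration header, update template names)."""
    core = _core_fields()
    n_extra = max(0, config.n_fields_per_event - len(core))
    fields = core + [(f"Extra Field {k:02d}", "string", False, None, "")
                     for k in range(1, n_extra + 1)]
    updates = [f"Sample Update {k}" if k > 1 else "SampleUpdate"
               for k in range(1, config.n_events)]
    lines = ["event_name,field_name,data_type,required,active,max_length,"
             "description,ontology_class,position,default_options"]

    def quote(s: str) -> str:
        return '"%s"' % s.replace('"', '""') if ("," in s or '"' in s) else s

    for pos, (name, dtype, req, ml, ann) in enumerate(fields, start=1):
        lines.append(",".join([
            "SampleRegistration", quote(name), dtype,
            "yes" if req else "no", "yes",
            "" if ml is None else str(ml), "", "", str(pos), quote(ann)]))
    for event in updates:
        for pos, name in enumerate(_UPDATE_FIELDS, start=1):
            req = name in (PROJECT_NAME_FIELD, SAMPLE_NAME_FIELD)
            lines.append(",".join([
                quote(event), quote(name), "string" if name != "Collection Date"
                else "date", "yes" if req else "no", "yes", "", "", "",
                str(pos), ""]))
    header = [f[0] for f in fields]
    return "\n".join(lines) + "\n", header, updates


def _dictionary_csv() -> str:
    lines = ["dictionary,value,parent_value", "city,,State"]
    for state in sorted(_STATES):
        lines.append(f"State,{state},")
    for state in sorted(_STATES):
        for city in sorted(_STATES[state]):
            lines.append(f"city,{city},{state}")
    return "\n".join(lines) + "\n"


def _iso_or_slash(rng: random.Random) -> str:
    y = rng.randint(2013, 2019)
    mo = rng.randint(1, 12)
    d = rng.randint(1, 28)
    style = rng.randrange(3)
    if style == 0:
        return f"{mo}/{d}/{y % 100:02d}"
    if style == 1:
        return f"{mo}/{d}/{y}"
    return f"{y:04d}-{mo:02d}-{d:02d}"


def _normalize_date(raw: str) -> str:
    from .validation import coerce_value
    normalized, issue = coerce_value("date", raw)
    assert issue is None
    return normalized


def _invalid_indices(rng: random.Random, n_rows: int,
                     fraction: float) -> list[int]:
    n_bad = int(round(fraction * n_rows))
    return sorted(rng.sample(range(1, n_rows + 1), n_bad)) if n_bad else []


def generate_study(config: FixtureConfig, out_dir) -> dict:
    """Write a study bundle under ``out_dir`` and return its manifest.

    The manifest records every emitted path, the 1-based indices of
    deliberately invalid rows per data file, and the expected post-load
    counts (projects, samples, events, materialized attribute values) under
    per-row loading semantics.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = random.Random(config.seed)
    setup_text, header, update_events = _setup_csv(config)
    (out / "setup.csv").write_text(setup_text, encoding="utf-8")
    dict_text = _dictionary_csv()
    (out / "dictionaries.csv").write_text(dict_text, encoding="utf-8")

    # paths are stored relative to the bundle directory so manifests are
    # relocatable and byte-identical across output locations
    manifest = {
        "seed": config.seed,
        "setup_csv": "setup.csv",
        "dictionary_csv": "dictionaries.csv",
        "projects": [],
        "data_csvs": [],
        "truth": {},
        "expected": {},
    }
    total_events = 0
    total_samples = 0
    total_attributes = 0

    def quote(s: str) -> str:
        return '"%s"' % s.replace('"', '""') if ("," in s or '"' in s) else s

    for p in range(1, config.n_projects + 1):
        project = f"Study{config.seed:03d}_{p:02d}"
        manifest["projects"].append(project)
        # ground-truth materialized state per sample, identity excluded
        truth: dict[str, dict[str, str]] = {}

        reg_rows = []
        barcodes = []
        for i in range(1, config.n_samples + 1):
            name = f"S{p:02d}_{i:04d}"
            state = rng.choice(sorted(_STATES))
            row = {
                PROJECT_NAME_FIELD: project,
                SAMPLE_NAME_FIELD: name,
                "Sample Status": rng.choice(_STATUS[:-1]),
                "Organism": rng.choice(_ORGANISMS),
                "Collection Date": _iso_or_slash(rng),
                "Host Age": str(rng.randint(0, 90)),
                "Sequencing Depth": f"{rng.uniform(1, 100):.1f}",
                "State": state,
                "City": rng.choice(sorted(_STATES[state])),
                "Barcode": f"BC{p:02d}{i:05d}",
                "Notes": f"note {i}",
            }
            for h in header:
                row.setdefault(h, rng.choice(["", f"x{i}", "freeform"]))
            barcodes.append(row["Barcode"])
            reg_rows.append(row)

        bad = _invalid_indices(rng, len(reg_rows), config.fraction_invalid)
        for j, idx in enumerate(bad):
            row = reg_rows[idx - 1]
            op = MUTATIONS[j % len(MUTATIONS)]
            if op == "bad_date":
                row["Collection Date"] = "13/45/99"
            elif op == "missing_required":
                row[SAMPLE_NAME_FIELD] = ""
            elif op == "off_vocabulary":
                row["Sample Status"] = "Lost In Transit"
            elif op == "cascade_violation":
                row["State"], row["City"] = "MD", "Perth"
            elif op == "over_length":
                row["Notes"] = "n" * 41
            elif op == "duplicate_unique":
                # duplicate an *earlier* valid barcode so this row, being
                # the later occurrence, is the one flagged
                donor = next((k for k in range(1, idx) if k not in bad), None)
                if donor is None:
                    row["Collection Date"] = "13/45/99"
                else:
                    row["Barcode"] = reg_rows[donor - 1]["Barcode"]

        path = out / f"{project}_registration.csv"
        lines = ["#DataTemplate: SampleRegistration", ",".join(map(quote, header))]
        for row in reg_rows:
            lines.append(",".join(quote(row.get(h, "")) for h in header))
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")

        for idx, row in enumerate(reg_rows, start=1):
            if idx in bad:
                continue
            entry = truth.setdefault(row[SAMPLE_NAME_FIELD], {})
            for h in header:
                if h in (PROJECT_NAME_FIELD, SAMPLE_NAME_FIELD):
                    continue
                v = row.get(h, "")
                if v == "":
                    continue
                if h == "Collection Date":
                    v = _normalize_date(v)
                entry[h] = v
        n_valid = len(reg_rows) - len(bad)
        manifest["data_csvs"].append({
            "path": path.name, "project": project,
            "event": "SampleRegistration", "n_rows": len(reg_rows),
            "invalid_rows": bad, "expected_events": n_valid})
        total_events += n_valid
        total_samples += len(truth)

        valid_names = sorted(truth)
        uheader = list(_UPDATE_FIELDS)
        for event in update_events:
            if not valid_names:
                break
            n_up = max(1, len(valid_names) // 2)
            chosen = rng.sample(valid_names, n_up)
            up_rows = []
            for name in sorted(chosen):
                row = {PROJECT_NAME_FIELD: project, SAMPLE_NAME_FIELD: name,
                       "Sample Status": rng.choice(_STATUS),
                       "Collection Date":
                           rng.choice(["", _iso_or_slash(rng)]),
                       "Notes": rng.choice(["", "updated", "NULL"])}
                up_rows.append(row)
            ubad = _invalid_indices(rng, len(up_rows), config.fraction_invalid)
            for j, idx in enumerate(ubad):
                row = up_rows[idx - 1]
                op = ("bad_date", "missing_required")[j % 2]
                if op == "bad_date":
                    row["Collection Date"] = "2/30/15"
                else:
                    row[SAMPLE_NAME_FIELD] = ""
            upath = out / f"{project}_{event.replace(' ', '')}.csv"
            lines = [f"#DataTemplate: {event}", ",".join(map(quote, uheader))]
            for row in up_rows:
                lines.append(",".join(quote(row.get(h, "")) for h in uheader))
            upath.write_text("\n".join(lines) + "\n", encoding="utf-8")
            for idx, row in enumerate(up_rows, start=1):
                if idx in ubad:
                    continue
                entry = truth[row[SAMPLE_NAME_FIELD]]
                for h in uheader:
                    if h in (PROJECT_NAME_FIELD, SAMPLE_NAME_FIELD):
                        continue
                    v = row.get(h, "")
                    if v == "":
                        continue
                    if v == "NULL":
                        entry.pop(h, None)
                        continue
                    if h == "Collection Date":
                        v = _normalize_date(v)
                    entry[h] = v
            n_valid_up = len(up_rows) - len(ubad)
            manifest["data_csvs"].append({
                "path": upath.name, "project": project, "event": event,
                "n_rows": len(up_rows), "invalid_rows": ubad,
                "expected_events": n_valid_up})
            total_events += n_valid_up

        total_attributes += sum(len(v) for v in truth.values())
        manifest["truth"][project] = truth

    manifest["expected"] = {
        "projects": config.n_projects,
        "samples": total_samples,
        "data_events": total_events,
        "events": total_events + config.n_projects,  # + project registrations
        "attributes": total_attributes,
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8")
    manifest["base_dir"] = str(out)
    return manifest


def load_study(store, manifest: dict, actor: str, mode: str = "per_row"):
    """Load a generated study bundle into a store: setup, dictionaries,
    project registrations, then every data CSV in manifest order.  Returns
    the list of :class:`LoadResult` for the data files."""
    from .templates import apply_setup, load_dictionary_csv, parse_template_csv

    base = Path(manifest.get("base_dir", "."))
    apply_setup(store, (base / manifest["setup_csv"]).read_text("utf-8"), actor)
    load_dictionary_csv(
        store, (base / manifest["dictionary_csv"]).read_text("utf-8"))
    for project in manifest["projects"]:
        store.register_project(project, actor)
    results = []
    for entry in manifest["data_csvs"]:
        parsed = parse_template_csv(
            (base / entry["path"]).read_text("utf-8"))
        results.append(store.load_event(
            entry["project"], parsed.template_name, parsed.rows, actor,
            mode=mode))
    return results


def generate_scale_fixture(n_samples: int, n_attrs_per_sample: int,
                           seed: int = 0,
                           project: str = "ScaleStudy") -> Iterator[str]:
    """Stream a large registration CSV line by line (constant memory).

    Yields the ``#DataTemplate:`` line, the header, then one row per
    sample with ``n_attrs_per_sample`` attribute columns, every cell
    deterministic in ``seed``.
    """
    if n_samples < 0 or n_attrs_per_sample < 0:
        raise UsageError("counts must be non-negative")
    rng = random.Random(seed)
    attr_names = [f"Attr {k:03d}" for k in range(1, n_attrs_per_sample + 1)]
    yield "#DataTemplate: SampleRegistration\n"
    yield ",".join([PROJECT_NAME_FIELD, SAMPLE_NAME_FIELD] + attr_names) + "\n"
    for i in range(1, n_samples + 1):
        cells = [project, f"SC{i:07d}"]
        cells += [f"v{rng.randrange(10_000)}" for _ in attr_names]
        yield ",".join(cells) + "\n"


def scale_setup_csv(n_attrs_per_sample: int) -> str:
    """Setup CSV matching :func:`generate_scale_fixture`'s header."""
    lines = ["event_name,field_name,data_type,required,active,max_length,"
             "description,ontology_class,position,default_options",
             "SampleRegistration,Project Name,string,yes,yes,,,,1,",
             "SampleRegistration,Sample Name,string,yes,yes,,,,2,"]
    for k in range(1, n_attrs_per_sample + 1):
        lines.append(f"SampleRegistration,Attr {k:03d},string,no,yes,,,,{k + 2},")
    return "\n".join(lines) + "\n"
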