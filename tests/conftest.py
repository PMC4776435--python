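from __future__ import annotations

from pathlib import Path

import pytest

from ecogc.species_io import SpeciesRecord, TraitDataset, Variable


def make_record(
    name="Danio rerio",
    family="Cyprinidae",
    order="Cypriniformes",
    salinity="freshwater",
    migration="",
    value=40.0,
    temperature=None,
):
    return SpeciesRecord(
        species_name=name,
        family=family,
        order=order,
        salinity_raw=salinity,
        migration_raw=migration,
        trait_value=value,
        assay_temperature=temperature,
    )


@pytest.fixture
def record_factory():
    return make_record


def write_table(path: Path, rows, header=("species", "family", "order", "salinity", "migration", "value", "temperature")):
    lines = ["\t".join(header)]
    for row in rows:
        lines.append("\t".join(str(c) for c in row))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


@pytest.fixture
def table_writer(tmp_path):
    def _write(rows, name="table.tsv", header=("species", "family", "order", "salinity", "migration", "value", "temperature")):
        return write_table(tmp_path / name, rows, header)

    return _write


@pytest.fixture
def four_cell_dataset():
    """One species per four-way cell, values 1..4 increasing to SWM."""
    records = [
        make_record("A a", salinity="freshwater", migration="", value=1.0),
        make_record("B b", salinity="freshwater", migration="potamodromous", value=2.0),
        make_record("C c", salinity="marine", migration="", value=3.0),
        make_record("D d", salinity="marine", migration="oceanodromous", value=4.0),
    ]
    return TraitDataset(variable=Variable.GC, records=records)
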