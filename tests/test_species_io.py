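from __future__ import annotations

import pytest
from hypothesis import given, strategies as st

from ecogc.species_io import (
    DEFAULT_EXCLUSIONS,
    Group,
    Migration,
    Salinity,
    SchemaError,
    TraitDataset,
    TraitParseError,
    UnclassifiableSpeciesError,
    Variable,
    apply_exclusions,
    classify_migration,
    classify_salinity,
    collapse_dataset,
    collapse_replicates,
    group_of,
    partition_groups,
    read_trait_table,
    write_trait_table,
)

from .conftest import make_record


class TestReadTraitTable:
    def test_reads_well_formed_table(self, table_writer):
        path = table_writer(
            [
                ("Danio rerio", "Cyprinidae", "Cypriniformes", "freshwater", "", 37.6, ""),
                ("Gadus morhua", "Gadidae", "Gadiformes", "marine", "oceanodromous", 44.8, ""),
                ("Salmo salar", "Salmonidae", "Salmoniformes", "freshwater", "anadromous", 43.5, ""),
            ]
        )
        ds = read_trait_table(path, Variable.GC)
        assert len(ds) == 3
        assert ds.records[0].species_name == "Danio rerio"
        assert ds.records[1].trait_value == pytest.approx(44.8)
        assert ds.records[2].migration_raw == "anadromous"

    def test_missing_order_column_is_schema_error(self, table_writer):
        path = table_writer(
            [("Danio rerio", "Cyprinidae", "freshwater", "", 37.6, "")],
            header=("species", "family", "salinity", "migration", "value", "temperature"),
        )
        with pytest.raises(SchemaError, match="order"):
            read_trait_table(path, Variable.GC)

    def test_non_numeric_value_cites_row(self, table_writer):
        path = table_writer(
            [("Danio rerio", "Cyprinidae", "Cypriniformes", "freshwater", "", "n/a", "")]
        )
        with pytest.raises(TraitParseError, match="row 2"):
            read_trait_table(path, Variable.GC)

    def test_comma_delimited_accepted(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text(
            "species,family,order,salinity,migration,value\n"
            "Danio rerio,Cyprinidae,Cypriniformes,freshwater,,37.6\n"
        )
        assert len(read_trait_table(path, Variable.GC)) == 1

    def test_mr_requires_temperature_column(self, table_writer):
        path = table_writer(
            [("Danio rerio", "Cyprinidae", "Cypriniformes", "freshwater", "", 300.0)],
            header=("species", "family", "order", "salinity", "migration", "value"),
        )
        with pytest.raises(SchemaError, match="temperature"):
            read_trait_table(path, Variable.MR)

    def test_mr_missing_temperature_value(self, table_writer):
        path = table_writer(
            [("Danio rerio", "Cyprinidae", "Cypriniformes", "freshwater", "", 300.0, "")]
        )
        with pytest.raises(TraitParseError, match="temperature"):
            read_trait_table(path, Variable.MR)

    @pytest.mark.parametrize("value", ["0", "-3.5", "101"])
    def test_gc_out_of_range_rejected(self, table_writer, value):
        path = table_writer(
            [("Danio rerio", "Cyprinidae", "Cypriniformes", "freshwater", "", value, "")]
        )
        with pytest.raises(TraitParseError):
            read_trait_table(path, Variable.GC)

    def test_duplicate_species_rejected_unless_replicates_allowed(self, table_writer):
        rows = [
            ("Danio rerio", "Cyprinidae", "Cypriniformes", "freshwater", "", 37.6, ""),
            ("Danio  rerio", "Cyprinidae", "Cypriniformes", "freshwater", "", 38.0, ""),
        ]
        path = table_writer(rows)
        with pytest.raises(TraitParseError, match="duplicate"):
            read_trait_table(path, Variable.GC)
        ds = read_trait_table(path, Variable.GC, allow_replicates=True)
        assert len(ds) == 2

    def test_column_remapping(self, table_writer):
        path = table_writer(
            [("Danio rerio", "Cyprinidae", "Cypriniformes", "freshwater", "", 37.6, "")],
            header=("species", "family", "order", "salinity", "migration", "GC%", "temperature"),
        )
        ds = read_trait_table(path, Variable.GC, columns={"value": "GC%"})
        assert ds.records[0].trait_value == pytest.approx(37.6)

    def test_round_trip_preserves_fields(self, tmp_path, four_cell_dataset):
        out = tmp_path / "out.tsv"
        write_trait_table(four_cell_dataset, out)
        back = read_trait_table(out, Variable.GC)
        for orig, new in zip(four_cell_dataset.records, back.records):
            assert orig.species_name == new.species_name
            assert orig.family == new.family
            assert orig.order == new.order
            assert orig.salinity_raw == new.salinity_raw
            assert orig.migration_raw == new.migration_raw
            assert orig.trait_value == new.trait_value  # bit-identical via repr


class TestClassification:
    def test_freshwater_habitat_is_fw(self):
        rec = make_record(salinity="freshwater", migration="")
        assert classify_salinity(rec) is Salinity.FW

    def test_catadromous_overrides_marine_habitat(self):
        rec = make_record(salinity="marine", migration="catadromous")
        assert classify_salinity(rec) is Salinity.FW

    def test_anadromous_overrides_freshwater_habitat(self):
        rec = make_record(salinity="freshwater", migration="anadromous")
        assert classify_salinity(rec) is Salinity.SW

    @pytest.mark.parametrize(
        "habitat,expected",
        [
            ("freshwater", Salinity.FW),
            ("freshwater-brackish", Salinity.FW),
            ("marine", Salinity.SW),
            ("marine-brackish", Salinity.SW),
        ],
    )
    def test_habitat_vocabulary(self, habitat, expected):
        assert classify_salinity(make_record(salinity=habitat)) is expected

    def test_bare_brackish_unclassifiable_by_default(self):
        rec = make_record(name="Mysterius fishus", salinity="brackish")
        with pytest.raises(UnclassifiableSpeciesError, match="Mysterius fishus"):
            classify_salinity(rec)

    def test_extra_vocabulary_extends_mapping(self):
        rec = make_record(salinity="brackish")
        assert classify_salinity(rec, {"brackish": Salinity.FW}) is Salinity.FW

    @pytest.mark.parametrize(
        "migration",
        ["catadromous", "potamodromous", "amphidromous", "oceanodromous", "anadromous"],
    )
    def test_migratory_classes(self, migration):
        assert classify_migration(make_record(migration=migration)) is Migration.M

    @pytest.mark.parametrize("migration", ["", "non-migratory", "unknown"])
    def test_non_migratory(self, migration):
        assert classify_migration(make_record(migration=migration)) is Migration.NM

    def test_classification_deterministic_and_idempotent(self, four_cell_dataset):
        first = [group_of(r) for r in four_cell_dataset]
        second = [group_of(r) for r in four_cell_dataset]
        assert first == second == [Group.FWNM, Group.FWM, Group.SWNM, Group.SWM]


class TestExclusions:
    def test_printed_species_removed(self):
        ds = TraitDataset(
            Variable.GC,
            [make_record("Perca fluviatilis"), make_record("Danio rerio")],
        )
        out = apply_exclusions(ds)
        assert out.species_names() == ["Danio rerio"]

    def test_empty_exclusion_list_is_identity(self, four_cell_dataset):
        out = apply_exclusions(four_cell_dataset, [])
        assert out.species_names() == four_cell_dataset.species_names()

    def test_absent_name_is_noop(self, four_cell_dataset):
        out = apply_exclusions(four_cell_dataset, ["Nemo clownfishus"])
        assert len(out) == len(four_cell_dataset)

    def test_matching_is_case_and_whitespace_insensitive(self):
        ds = TraitDataset(Variable.GC, [make_record("  PERCA   fluviatilis ")])
        assert len(apply_exclusions(ds)) == 0

    def test_default_list_has_nine_names(self):
        assert len(DEFAULT_EXCLUSIONS) == 9


class TestCollapse:
    @pytest.mark.parametrize(
        "values,expected",
        [([2.0], 2.0), ([1.0, 3.0], 2.0), ([5.0, 1.0, 3.0], 3.0)],
    )
    def test_median_examples(self, values, expected):
        assert collapse_replicates(values) == expected

    def test_empty_list_errors(self):
        with pytest.raises(ValueError):
            collapse_replicates([])

    def test_collapse_dataset_medians_duplicates(self):
        ds = TraitDataset(
            Variable.GILL,
            [
                make_record("Danio rerio", value=1.0),
                make_record("Danio rerio", value=3.0),
                make_record("Gadus morhua", value=5.0),
            ],
        )
        out = collapse_dataset(ds)
        values = dict(zip(out.species_names(), out.values()))
        assert values == {"Danio rerio": 2.0, "Gadus morhua": 5.0}


class TestPartition:
    def test_exhaustive_four_way(self, four_cell_dataset):
        cells = partition_groups(four_cell_dataset, "four_way")
        assert {k: len(v) for k, v in cells.items()} == {
            "FWNM": 1, "FWM": 1, "SWNM": 1, "SWM": 1
        }

    def test_salinity_coarsens_four_way(self, four_cell_dataset):
        four = partition_groups(four_cell_dataset, "four_way")
        two = partition_groups(four_cell_dataset, "salinity")
        assert sorted(two["FW"]) == sorted(four["FWNM"] + four["FWM"])
        assert sorted(two["SW"]) == sorted(four["SWNM"] + four["SWM"])

    def test_unknown_mode_errors(self, four_cell_dataset):
        with pytest.raises(ValueError):
            partition_groups(four_cell_dataset, "by_vibes")

    @given(
        st.lists(
            st.tuples(
                st.sampled_from(["freshwater", "freshwater-brackish", "marine", "marine-brackish"]),
                st.sampled_from(["", "catadromous", "potamodromous", "oceanodromous", "anadromous", "non-migratory"]),
                st.floats(min_value=0.1, max_value=99.0),
            ),
            min_size=1,
            max_size=30,
        )
    )
    def test_partition_completeness(self, rows):
        records = [
            make_record(name=f"Sp {i}", salinity=sal, migration=mig, value=val)
            for i, (sal, mig, val) in enumerate(rows)
        ]
        ds = TraitDataset(Variable.GC, records)
        for mode in ("salinity", "migration", "four_way"):
            cells = partition_groups(ds, mode)
            assert sum(len(v) for v in cells.values()) == len(ds)
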