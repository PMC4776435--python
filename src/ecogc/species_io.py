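"""Reading, validation and ecological classification of species-trait tables.

A trait table holds one row per species (or per measurement, before
replicate collapsing) with taxonomy, habitat-salinity and migration
descriptors, and a single trait value: routine metabolic rate (MR,
mg O2·kg⁻¹·h⁻¹, plus the assay temperature), specific gill area
(Gill, cm²·g⁻¹) or genomic GC content (GC, percent).

Species are classified into a two-by-two design:

* salinity — FW (freshwater, freshwater-brackish habitats, plus
  catadromous migrants) vs SW (marine, marine-brackish, plus anadromous
  migrants); the diadromous migration classes override the habitat
  descriptor.
* migration — M (catadromous, potamodromous, amphidromous, oceanodromous
  or anadromous) vs NM (anything else, including no information).
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Variable",
    "Salinity",
    "Migration",
    "Group",
    "SpeciesRecord",
    "TraitDataset",
    "SchemaError",
    "TraitParseError",
    "UnclassifiableSpeciesError",
    "DEFAULT_EXCLUSIONS",
    "read_trait_table",
    "write_trait_table",
    "classify_salinity",
    "classify_migration",
    "group_of",
    "apply_exclusions",
    "collapse_replicates",
    "collapse_dataset",
    "partition_groups",
]


class Variable(str, Enum):
    """Which trait a dataset measures."""

    MR = "MR"
    GILL = "Gill"
    GC = "GC"


class Salinity(str, Enum):
    FW = "FW"
    SW = "SW"


class Migration(str, Enum):
    NM = "NM"
    M = "M"


class Group(str, Enum):
    """Combined salinity x migration cell; the name concatenates the two."""

    FWNM = "FWNM"
    FWM = "FWM"
    SWNM = "SWNM"
    SWM = "SWM"

    @classmethod
    def from_parts(cls, salinity: Salinity, migration: Migration) -> "Group":
        return cls(salinity.value + migration.value)


#: Habitat descriptors mapped to a salinity class.  Anything else is
#: unclassifiable unless a diadromous migration class decides, or the
#: caller extends the vocabulary.
FW_HABITATS = frozenset({"freshwater", "freshwater-brackish"})
SW_HABITATS = frozenset({"marine", "marine-brackish"})

#: Migration descriptors that make a species migratory.
MIGRATORY_CLASSES = frozenset(
    {"catadromous", "potamodromous", "amphidromous", "oceanodromous", "anadromous"}
)

#: Species discarded for conflicting salinity/migration information.
DEFAULT_EXCLUSIONS = frozenset(
    {
        "aphanius dispar dispar",
        "aphanius fasciatus",
        "ciprinodon variegatus",
        "fundulus heteroclitus",
        "lagodon rhomboides",
        "leptococcus armatus",
        "takifugu rubripes",
        "bathygobius soporator",
        "perca fluviatilis",
    }
)


class SchemaError(ValueError):
    """The input table is missing a required column."""


class TraitParseError(ValueError):
    """A row of the input table failed a type or range check."""


class UnclassifiableSpeciesError(ValueError):
    """A species' habitat descriptor is outside the known vocabulary."""

    def __init__(self, species: Sequence[str]):
        self.species = list(species)
        super().__init__(
            "unclassifiable salinity for species: " + ", ".join(self.species)
        )


def _norm_name(name: str) -> str:
    """Case-insensitive, whitespace-collapsed species-name key."""
    return " ".join(name.split()).lower()


@dataclass(frozen=True)
class SpeciesRecord:
    """One species' taxonomy, ecology descriptors and trait measurement."""

    species_name: str
    family: str
    order: str
    salinity_raw: str
    migration_raw: str
    trait_value: float
    assay_temperature: float | None = None
    extras: Mapping[str, float] = field(default_factory=dict)

    @property
    def name_key(self) -> str:
        return _norm_name(self.species_name)


@dataclass
class TraitDataset:
    """A named, validated collection of :class:`SpeciesRecord`."""

    variable: Variable
    records: list[SpeciesRecord]
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def species_names(self) -> list[str]:
        return [r.species_name for r in self.records]

    def values(self) -> list[float]:
        return [r.trait_value for r in self.records]


DEFAULT_COLUMNS = {
    "species": "species",
    "family": "family",
    "order": "order",
    "salinity": "salinity",
    "migration": "migration",
    "value": "value",
    "temperature": "temperature",
}


def _validate_record(rec: SpeciesRecord, variable: Variable, row: int) -> None:
    if not rec.species_name:
        raise TraitParseError(f"row {row}: empty species name")
    if variable is Variable.GC:
        if not (0.0 < rec.trait_value < 100.0):
            raise TraitParseError(
                f"row {row} ({rec.species_name}): GC% must lie in (0, 100), "
                f"got {rec.trait_value!r}"
            )
    else:
        if not rec.trait_value > 0.0:
            raise TraitParseError(
                f"row {row} ({rec.species_name}): trait value must be positive, "
                f"got {rec.trait_value!r}"
            )
    if variable is Variable.MR and rec.assay_temperature is None:
        raise TraitParseError(
            f"row {row} ({rec.species_name}): MR records require an assay temperature"
        )


def read_trait_table(
    path: str | Path,
    variable: Variable | str,
    *,
    columns: Mapping[str, str] | None = None,
    delimiter: str | None = None,
    allow_replicates: bool = False,
) -> TraitDataset:
    """Read a delimited trait table (TSV by default, comma accepted).

    Parameters
    ----------
    path:
        Input file with a header row naming at least the species, family,
        order, salinity, migration and value columns (plus temperature
        for MR).
    variable:
        Which trait the table holds; drives per-variable range checks.
    columns:
        Optional remapping of logical column names to the file's header
        names, e.g. ``{"value": "GC%"}``.
    delimiter:
        Field separator; autodetected between tab and comma when omitted.
    allow_replicates:
        Permit duplicate species names (to be collapsed later with
        :func:`collapse_dataset`); otherwise duplicates are an error.

    Raises
    ------
    SchemaError
        A required column is absent.
    TraitParseError
        A row fails a type or range check; the message names the row.
    """
    variable = Variable(variable)
    path = Path(path)
    colmap = dict(DEFAULT_COLUMNS)
    if columns:
        colmap.update(columns)

    if delimiter is None:
        with open(path, encoding="utf-8") as fh:
            header = fh.readline()
        delimiter = "," if ("," in header and "\t" not in header) else "\t"
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)

    required = ["species", "family", "order", "salinity", "migration", "value"]
    if variable is Variable.MR:
        required.append("temperature")
    missing = [colmap[c] for c in required if colmap[c] not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing required column(s): {', '.join(missing)}"
        )

    records: list[SpeciesRecord] = []
    seen: dict[str, int] = {}
    for idx, row in enumerate(df.to_dict("records")):
        i = idx + 2  # 1-based file row; row 1 is the header
        get = lambda key: str(row[colmap[key]])
        raw_value = get("value").strip()
        try:
            value = float(raw_value)
        except ValueError:
            raise TraitParseError(
                f"{path}: row {i}: non-numeric trait value {raw_value!r}"
            ) from None
        temp: float | None = None
        if variable is Variable.MR:
            raw_temp = get("temperature").strip()
            if raw_temp:
                try:
                    temp = float(raw_temp)
                except ValueError:
                    raise TraitParseError(
                        f"{path}: row {i}: non-numeric temperature {raw_temp!r}"
                    ) from None
        rec = SpeciesRecord(
            species_name=get("species").strip(),
            family=get("family").strip(),
            order=get("order").strip(),
            salinity_raw=get("salinity").strip().lower(),
            migration_raw=get("migration").strip().lower(),
            trait_value=value,
            assay_temperature=temp,
        )
        _validate_record(rec, variable, i)
        if rec.name_key in seen and not allow_replicates:
            raise TraitParseError(
                f"{path}: row {i}: duplicate species {rec.species_name!r} "
                f"(first seen at row {seen[rec.name_key]}); pass "
                "allow_replicates=True and collapse with collapse_dataset()"
            )
        seen.setdefault(rec.name_key, i)
        records.append(rec)

    logger.info("read %d records from %s (%s)", len(records), path, variable.value)
    return TraitDataset(variable=variable, records=records, provenance=str(path))


def write_trait_table(dataset: TraitDataset, path: str | Path) -> None:
    """Write a normalized trait table as TSV with classification columns."""
    rows = []
    for rec in dataset:
        sal = classify_salinity(rec)
        mig = classify_migration(rec)
        row = {
            "species": rec.species_name,
            "family": rec.family,
            "order": rec.order,
            "salinity": rec.salinity_raw,
            "migration": rec.migration_raw,
            "value": repr(rec.trait_value),
            "temperature": "" if rec.assay_temperature is None
            else repr(rec.assay_temperature),
            "salinity_class": sal.value,
            "migration_class": mig.value,
            "group4": Group.from_parts(sal, mig).value,
        }
        for k, v in rec.extras.items():
            row[k] = repr(v)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def classify_salinity(
    record: SpeciesRecord,
    extra_vocabulary: Mapping[str, Salinity] | None = None,
) -> Salinity:
    """FW/SW assignment from habitat descriptor plus diadromy override.

    Catadromous species are FW and anadromous species are SW regardless
    of the habitat descriptor.  Habitat descriptors outside the known
    vocabulary (e.g. bare "brackish") raise
    :class:`UnclassifiableSpeciesError` rather than guessing; pass
    ``extra_vocabulary`` to extend the mapping.
    """
    mig = record.migration_raw.strip().lower()
    if mig == "catadromous":
        return Salinity.FW
    if mig == "anadromous":
        return Salinity.SW
    sal = record.salinity_raw.strip().lower()
    if sal in FW_HABITATS:
        return Salinity.FW
    if sal in SW_HABITATS:
        return Salinity.SW
    if extra_vocabulary and sal in extra_vocabulary:
        return Salinity(extra_vocabulary[sal])
    raise UnclassifiableSpeciesError([record.species_name])


def classify_migration(record: SpeciesRecord) -> Migration:
    """M iff the descriptor is one of the five migratory classes; species
    with no migration information are non-migratory."""
    if record.migration_raw.strip().lower() in MIGRATORY_CLASSES:
        return Migration.M
    return Migration.NM


def group_of(
    record: SpeciesRecord,
    extra_vocabulary: Mapping[str, Salinity] | None = None,
) -> Group:
    return Group.from_parts(
        classify_salinity(record, extra_vocabulary), classify_migration(record)
    )


def apply_exclusions(
    dataset: TraitDataset,
    exclusions: Iterable[str] = DEFAULT_EXCLUSIONS,
) -> TraitDataset:
    """Drop species on the exclusion list (case-insensitive exact match).

    Defaults to the nine species with conflicting salinity/migration
    information.  Excluded names absent from the dataset are no-ops.
    """
    keys = {_norm_name(n) for n in exclusions}
    kept = [r for r in dataset.records if r.name_key not in keys]
    removed = len(dataset.records) - len(kept)
    missing = keys - {r.name_key for r in dataset.records}
    if missing:
        logger.warning(
            "%d exclusion name(s) not present in dataset: %s",
            len(missing),
            ", ".join(sorted(missing)),
        )
    logger.info(
        "excluded %d of %d records (%s)", removed, len(dataset), dataset.variable.value
    )
    return TraitDataset(
        variable=dataset.variable, records=kept, provenance=dataset.provenance
    )


def collapse_replicates(values: Sequence[float], rule: str = "median") -> float:
    """Collapse replicate measurements for one species; the median is used."""
    if not values:
        raise ValueError("cannot collapse an empty list of replicates")
    if rule != "median":
        raise ValueError(f"unknown collapsing rule {rule!r}")
    return statistics.median(values)


def collapse_dataset(dataset: TraitDataset) -> TraitDataset:
    """Collapse duplicate species to a single record via the median value.

    Non-value fields are taken from the first record of each species.
    """
    by_key: dict[str, list[SpeciesRecord]] = {}
    for rec in dataset:
        by_key.setdefault(rec.name_key, []).append(rec)
    records = []
    for recs in by_key.values():
        if len(recs) == 1:
            records.append(recs[0])
        else:
            med = collapse_replicates([r.trait_value for r in recs])
            records.append(replace(recs[0], trait_value=med))
    return TraitDataset(
        variable=dataset.variable, records=records, provenance=dataset.provenance
    )


def partition_groups(
    dataset: TraitDataset,
    mode: str = "four_way",
    extra_vocabulary: Mapping[str, Salinity] | None = None,
) -> dict[str, list[float]]:
    """Partition trait values into salinity, migration or four-way cells.

    Every record lands in exactly one cell; cell sizes sum to the dataset
    size.  Empty cells in ``four_way`` mode are kept (empty) and a
    warning is logged.
    """
    if mode == "salinity":
        labels = [s.value for s in Salinity]
        keyfn = lambda r: classify_salinity(r, extra_vocabulary).value
    elif mode == "migration":
        labels = [m.value for m in Migration]
        keyfn = lambda r: classify_migration(r).value
    elif mode == "four_way":
        labels = [g.value for g in Group]
        keyfn = lambda r: group_of(r, extra_vocabulary).value
    else:
        raise ValueError(f"unknown partition mode {mode!r}")

    unclassifiable: list[str] = []
    cells: dict[str, list[float]] = {lab: [] for lab in labels}
    for rec in dataset:
        try:
            cells[keyfn(rec)].append(rec.trait_value)
        except UnclassifiableSpeciesError:
            unclassifiable.append(rec.species_name)
    if unclassifiable:
        raise UnclassifiableSpeciesError(unclassifiable)
    for lab, vals in cells.items():
        if not vals:
            logger.warning("empty %s cell %r", mode, lab)
    return cells
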