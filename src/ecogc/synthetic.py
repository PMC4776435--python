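"""Seeded generators for trait tables and CDS/expression sets.

The trait generator emits species rows with order/family labels and the
four-group structure (FWNM/FWM/SWNM/SWM) under configurable location
shifts; noise is right-skewed (shifted lognormal, median zero) by
default so group medians converge to the configured locations, with
normal noise selectable for oracle tests.  The CDS generator builds
valid coding sequences with controlled GC (exact composition sampling)
and GC-correlated expression, plus a requested fraction of sequences
each violating exactly one filter rule, tagged with the intended
violation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cds_expression import CdsRecord, STOP_CODONS
from .species_io import (
    Group,
    SpeciesRecord,
    TraitDataset,
    Variable,
)

__all__ = [
    "SyntheticSpec",
    "SyntheticCdsSpec",
    "generate_trait_dataset",
    "generate_cds_set",
    "generate_parameter_recovery_suite",
    "SuiteBundle",
]

#: Habitat/migration descriptors consistent with each four-way cell.
#: Diadromous classes are restricted to the cells they map to, so the
#: classification override can never move a species out of its cell.
_CELL_DESCRIPTORS = {
    Group.FWNM: (["freshwater", "freshwater-brackish"], ["", "non-migratory"]),
    Group.FWM: (
        ["freshwater", "freshwater-brackish"],
        ["potamodromous", "amphidromous", "catadromous"],
    ),
    Group.SWNM: (["marine", "marine-brackish"], ["", "non-migratory"]),
    Group.SWM: (["marine", "marine-brackish"], ["oceanodromous", "anadromous"]),
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameterization of the trait-table generator."""

    n_per_cell: dict = field(
        default_factory=lambda: {"FWNM": 60, "FWM": 25, "SWNM": 80, "SWM": 30}
    )
    trait_base: float = 42.0
    effect_salinity: float = 0.0
    effect_migration: float = 0.0
    effect_interaction: float = 0.0
    noise: str = "lognormal"  # "lognormal" | "normal"
    noise_scale: float = 1.0
    n_orders: int = 8
    n_families: int = 20
    mr_temperature_range: tuple[float, float] = (5.0, 30.0)
    seed: int = 0

    def __post_init__(self):
        if self.noise not in ("lognormal", "normal"):
            raise ValueError(f"unknown noise kind {self.noise!r}")
        if self.noise_scale <= 0:
            raise ValueError("noise scale must be > 0")
        if any(n < 0 for n in self.n_per_cell.values()):
            raise ValueError("cell counts must be >= 0")

    def cell_location(self, group: Group) -> float:
        """Median trait location of one cell: base + additive effects."""
        loc = self.trait_base
        sw = group in (Group.SWNM, Group.SWM)
        mig = group in (Group.FWM, Group.SWM)
        if sw:
            loc += self.effect_salinity
        if mig:
            loc += self.effect_migration
        if sw and mig:
            loc += self.effect_interaction
        return loc


def _noise(rng: np.random.Generator, kind: str, scale: float, n: int) -> np.ndarray:
    if kind == "normal":
        return rng.normal(0.0, scale, size=n)
    # lognormal(0, sigma) has median 1; shift so the noise median is 0
    return rng.lognormal(mean=0.0, sigma=scale, size=n) - 1.0


def generate_trait_dataset(spec: SyntheticSpec, variable: Variable | str) -> TraitDataset:
    """Generate one seeded trait table with the four-group structure.

    Trait values are ``cell_location + noise`` redrawn until positive
    (GC values are also kept below 100).  MR rows get the generated value
    as the raw rate mr0 plus a uniform assay temperature, so the
    Boltzmann step is exercised end to end.
    """
    variable = Variable(variable)
    total = sum(spec.n_per_cell.values())
    if total == 0:
        raise ValueError("spec generates zero species")
    rng = np.random.default_rng(spec.seed)
    records: list[SpeciesRecord] = []
    idx = 0
    for group in Group:
        n = int(spec.n_per_cell.get(group.value, 0))
        if n == 0:
            continue
        loc = spec.cell_location(group)
        values = loc + _noise(rng, spec.noise, spec.noise_scale, n)
        for _ in range(100):  # redraw out-of-range values
            bad = (values <= 0) | ((variable is Variable.GC) & (values >= 100))
            if not bad.any():
                break
            values[bad] = loc + _noise(rng, spec.noise, spec.noise_scale, int(bad.sum()))
        else:
            raise ValueError("could not generate in-range trait values")
        habitats, migrations = _CELL_DESCRIPTORS[group]
        for v in values:
            temp = None
            if variable is Variable.MR:
                temp = float(rng.uniform(*spec.mr_temperature_range))
            records.append(
                SpeciesRecord(
                    species_name=f"Genus{idx:04d} species{idx:04d}",
                    family=f"Family{idx % spec.n_families:03d}",
                    order=f"Order{idx % spec.n_orders:02d}",
                    salinity_raw=habitats[int(rng.integers(len(habitats)))],
                    migration_raw=migrations[int(rng.integers(len(migrations)))],
                    trait_value=float(v),
                    assay_temperature=temp,
                )
            )
            idx += 1
    return TraitDataset(
        variable=variable,
        records=records,
        provenance=f"synthetic(seed={spec.seed})",
    )


@dataclass(frozen=True)
class SyntheticCdsSpec:
    """Parameterization of the CDS/expression generator."""

    n_cds: int = 200
    gc_range: tuple[float, float] = (0.30, 0.65)
    length_range: tuple[int, int] = (102, 1998)
    expression_slope_on_gc: float = 0.1
    expression_noise_sd: float = 0.5
    fraction_invalid: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.fraction_invalid <= 1.0:
            raise ValueError("fraction_invalid must lie in [0, 1]")
        if not (0.0 <= self.gc_range[0] < self.gc_range[1] <= 1.0):
            raise ValueError("gc_range must be a non-degenerate sub-interval of [0,1]")
        if self.length_range[0] >= self.length_range[1]:
            raise ValueError("length_range must be non-degenerate")
        if self.length_range[0] < 102:
            raise ValueError("minimum CDS length is 102 (start + 32 codons + stop)")


_VIOLATIONS = ("length", "ambiguous", "no_start", "no_stop", "frame")


def _middle(rng: np.random.Generator, n: int, n_gc: int) -> str:
    """Random sequence of length n with exactly n_gc G/C bases."""
    gc = rng.choice(list("GC"), size=n_gc)
    at = rng.choice(list("AT"), size=n - n_gc)
    arr = np.concatenate([gc, at])
    rng.shuffle(arr)
    return "".join(arr)


def _valid_cds(rng: np.random.Generator, length: int, gc_target: float) -> str:
    """ATG + composition-sampled middle + stop, hitting gc_target within 1/length."""
    stop = STOP_CODONS[int(rng.integers(3))]
    fixed_gc = 1 + {"TAA": 0, "TAG": 1, "TGA": 1}[stop]  # ATG has one G
    mid_len = length - 6
    n_gc = int(round(gc_target * length)) - fixed_gc
    n_gc = min(max(n_gc, 0), mid_len)
    return "ATG" + _middle(rng, mid_len, n_gc) + stop


def generate_cds_set(
    spec: SyntheticCdsSpec,
) -> tuple[list[CdsRecord], pd.DataFrame, dict[str, str]]:
    """Generate CDS records, an expression table, and a violation-tag map.

    Returns ``(records, expression, tags)``: expression has columns
    ``cds_id`` and ``expression`` (log scale, slope * GC% + noise), and
    ``tags`` maps each invalid cds_id to the filter rule it violates;
    ids absent from ``tags`` pass every filter rule by construction.
    """
    rng = np.random.default_rng(spec.seed)
    n_invalid = int(round(spec.fraction_invalid * spec.n_cds))
    records: list[CdsRecord] = []
    tags: dict[str, str] = {}
    rows = []
    for i in range(spec.n_cds):
        cds_id = f"cds{i:05d}"
        gc_target = float(rng.uniform(*spec.gc_range))
        length = int(rng.integers(spec.length_range[0] // 3, spec.length_range[1] // 3 + 1)) * 3
        if i < n_invalid:
            rule = _VIOLATIONS[i % len(_VIOLATIONS)]
            tags[cds_id] = rule
            if rule == "length":
                seq = _valid_cds(rng, 99, gc_target)
            elif rule == "ambiguous":
                seq = _valid_cds(rng, length, gc_target)
                j = int(rng.integers(3, length - 3))
                seq = seq[:j] + "N" + seq[j + 1 :]
            elif rule == "no_start":
                seq = "TTG" + _valid_cds(rng, length, gc_target)[3:]
            elif rule == "no_stop":
                seq = _valid_cds(rng, length, gc_target)[:-3] + "GGG"
            else:  # frame: insert one base, keeping start/stop intact
                seq = _valid_cds(rng, length, gc_target)
                seq = seq[:-3] + "A" + seq[-3:]
        else:
            seq = _valid_cds(rng, length, gc_target)
        records.append(CdsRecord(cds_id=cds_id, sequence=seq))
        expr = spec.expression_slope_on_gc * (100.0 * gc_target) + rng.normal(
            0.0, spec.expression_noise_sd
        )
        rows.append(
            {"cds_id": cds_id, "expression": float(expr), "gc_target": gc_target}
        )
    return records, pd.DataFrame(rows), tags


@dataclass
class SuiteBundle:
    """Matched effect/null trait-table bundles with their generating truth."""

    effect: dict  # variable name -> TraitDataset
    null: dict
    truth: dict

    def write_truth(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.truth, indent=2, sort_keys=True))


def generate_parameter_recovery_suite(seed: int = 0) -> SuiteBundle:
    """Emit MR/Gill/GC-like tables with SWM constructed highest everywhere,
    plus a matched no-effect bundle, and record every generating parameter."""
    bases = {"MR": 300.0, "Gill": 3.0, "GC": 42.0}
    scales = {"MR": 0.25, "Gill": 0.2, "GC": 0.02}
    effect, null, truth = {}, {}, {"seed": seed, "variables": {}}
    for offset, (var, base) in enumerate(bases.items()):
        shift = base * 0.25
        eff_spec = SyntheticSpec(
            trait_base=base,
            effect_salinity=shift,
            effect_migration=shift,
            effect_interaction=shift / 2,
            noise="lognormal",
            noise_scale=scales[var],
            mr_temperature_range=(10.0, 20.0),
            seed=seed * 10 + offset,
        )
        null_spec = SyntheticSpec(
            trait_base=base,
            noise="lognormal",
            noise_scale=scales[var],
            mr_temperature_range=(10.0, 20.0),
            seed=seed * 10 + offset + 5,
        )
        effect[var] = generate_trait_dataset(eff_spec, Variable(var))
        null[var] = generate_trait_dataset(null_spec, Variable(var))
        truth["variables"][var] = {
            "base": base,
            "effect_salinity": shift,
            "effect_migration": shift,
            "effect_interaction": shift / 2,
            "noise_scale": scales[var],
            "cell_locations": {
                g.value: eff_spec.cell_location(g) for g in Group
            },
            "expected_top": "SWM",
        }
    return SuiteBundle(effect=effect, null=null, truth=truth)
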