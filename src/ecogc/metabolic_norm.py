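"""Boltzmann temperature correction and ln-normalization of metabolic rates.

A raw mass-specific routine metabolic rate ``mr0`` measured at absolute
temperature ``T`` is corrected as ``mr0 * exp(E / (k*T))`` with activation
energy E (default 0.65 eV) and Boltzmann constant k (8.62e-5 eV/K), and the
corrected rate is ln-transformed.  No reference temperature is subtracted:
the correction is the raw factor, so corrected values carry the ~E/kT
offset (about +25 at typical assay temperatures).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

from .species_io import SpeciesRecord, TraitDataset, Variable

logger = logging.getLogger(__name__)

__all__ = [
    "CELSIUS_OFFSET",
    "BoltzmannParams",
    "CorrectedMR",
    "boltzmann_correct",
    "normalize_dataset",
]

#: Celsius-to-Kelvin offset used throughout.
CELSIUS_OFFSET = 273.15

#: Assay temperatures outside this range trigger a warning, not an error.
PLAUSIBLE_CELSIUS = (-2.0, 45.0)


@dataclass(frozen=True)
class BoltzmannParams:
    """Activation energy E (eV) and Boltzmann constant k (eV/K)."""

    E: float = 0.65
    k: float = 8.62e-5

    def __post_init__(self):
        if self.E < 0:
            raise ValueError("activation energy E must be >= 0")
        if self.k <= 0:
            raise ValueError("Boltzmann constant k must be > 0")


@dataclass(frozen=True)
class CorrectedMR:
    mr0: float
    temperature_kelvin: float
    mr_corrected: float
    ln_mr: float


def boltzmann_correct(
    mr0: float,
    temperature_celsius: float,
    params: BoltzmannParams = BoltzmannParams(),
) -> CorrectedMR:
    """Temperature-correct one rate: ``mr_corrected = mr0 * exp(E/kT)``.

    ``ln_mr`` is computed as ``ln(mr0) + E/(k*T)`` which is exact and
    avoids overflow of the intermediate exponential.
    """
    if mr0 <= 0:
        raise ValueError(f"mr0 must be positive, got {mr0!r}")
    if not PLAUSIBLE_CELSIUS[0] <= temperature_celsius <= PLAUSIBLE_CELSIUS[1]:
        logger.warning(
            "assay temperature %.2f degC outside plausible range %s",
            temperature_celsius,
            PLAUSIBLE_CELSIUS,
        )
    kelvin = temperature_celsius + CELSIUS_OFFSET
    kt = params.k * kelvin
    if kt == 0:
        raise ValueError("k*T is zero; temperature at absolute zero?")
    ln_mr = math.log(mr0) + params.E / kt
    return CorrectedMR(
        mr0=mr0,
        temperature_kelvin=kelvin,
        mr_corrected=mr0 * math.exp(params.E / kt),
        ln_mr=ln_mr,
    )


def normalize_dataset(
    dataset: TraitDataset, params: BoltzmannParams = BoltzmannParams()
) -> TraitDataset:
    """Replace every MR record's value with its temperature-corrected ln rate.

    The raw rate and assay temperature are preserved in the record extras
    (``mr0_raw``, plus the untouched ``assay_temperature`` field).
    """
    if dataset.variable is not Variable.MR:
        raise ValueError("normalize_dataset applies to MR datasets only")
    records: list[SpeciesRecord] = []
    for rec in dataset:
        if rec.assay_temperature is None:
            raise ValueError(
                f"species {rec.species_name!r} has no assay temperature"
            )
        corr = boltzmann_correct(rec.trait_value, rec.assay_temperature, params)
        extras = dict(rec.extras)
        extras["mr0_raw"] = rec.trait_value
        records.append(replace(rec, trait_value=corr.ln_mr, extras=extras))
    return TraitDataset(
        variable=dataset.variable,
        records=records,
        provenance=dataset.provenance + " [boltzmann+ln]",
    )
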