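"""Headspace gas quantification: pressure, ideal-gas moles, CH4/H2 amounts.

End-of-transfer headspace samples are taken into evacuated exetainers and
analysed by GC. Because the vials retain some residual air, measured CH4
and H2 fractions are diluted; the air share is estimated from the measured
O2 fraction divided by the atmospheric O2 proportion (0.2095), and species
fractions are renormalized over the non-air portion. Amounts follow from
the ideal gas law over the 60-mL headspace at the 39 degC incubation
temperature.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

from .constants import (
    ATM_PA,
    HEADSPACE_VOLUME_ML,
    INCUBATION_TEMP_C,
    O2_ATMOSPHERIC,
    R_GAS,
)

logger = logging.getLogger(__name__)


class GasInputError(ValueError):
    """Non-physical gas reading."""


class AirCorrectionError(ValueError):
    """Residual-air correction impossible (sample is entirely air)."""


@dataclass(frozen=True)
class GasReading:
    """One headspace measurement: gauge pressure plus GC molar fractions."""

    gauge_pressure: float
    fractions: dict = field(default_factory=dict)
    headspace_volume: float = HEADSPACE_VOLUME_ML
    temperature: float = INCUBATION_TEMP_C

    def __post_init__(self) -> None:
        if self.gauge_pressure < -ATM_PA:
            raise GasInputError(
                f"gauge pressure {self.gauge_pressure} Pa implies negative absolute pressure"
            )
        if self.headspace_volume < 0:
            raise GasInputError(f"headspace volume {self.headspace_volume} mL < 0")
        if self.temperature <= -273.15:
            raise GasInputError(f"temperature {self.temperature} C below absolute zero")
        for species, frac in self.fractions.items():
            if not 0.0 <= frac <= 1.0:
                raise GasInputError(f"fraction {species}={frac} outside [0, 1]")


@dataclass(frozen=True)
class GasResult:
    total_pressure: float  # Pa
    total_moles: float  # mol
    amounts: dict  # species -> umol, air-corrected
    h2_partial_pressure: float  # atm
    air_fraction: float


def total_pressure(gauge: float) -> float:
    """Absolute headspace pressure (Pa): gauge plus 1 atm (101,325 Pa)."""
    p = gauge + ATM_PA
    if p < 0:
        raise GasInputError(f"absolute pressure {p} Pa < 0")
    return p


def headspace_moles(reading: GasReading) -> float:
    """Total moles of gas in the bottle headspace by the ideal gas law."""
    p = total_pressure(reading.gauge_pressure)
    volume_m3 = reading.headspace_volume * 1e-6
    temp_k = reading.temperature + 273.15
    return p * volume_m3 / (R_GAS * temp_k)


def residual_air_fraction(o2_fraction: float) -> float:
    """Molar fraction of the gas sample that is residual air.

    Air contains no CH4 or H2 at relevant levels, so O2 is its tracer:
    f_air = measured O2 fraction / 0.2095.
    """
    if o2_fraction < 0:
        raise GasInputError(f"O2 fraction {o2_fraction} < 0")
    if o2_fraction > O2_ATMOSPHERIC:
        raise GasInputError(
            f"O2 fraction {o2_fraction} exceeds the atmospheric proportion "
            f"{O2_ATMOSPHERIC}: sample would be more than 100% air"
        )
    return o2_fraction / O2_ATMOSPHERIC

def correct_species_fraction(measured_fraction: float, air_fraction: float) -> float:
    """Undo the dilution of a species fraction by residual air.

    Renormalizes over the non-air portion: corrected = measured / (1 - f_air).
    This exactly inverts mixing the true gas with an air share f_air. A
    corrected value above 1 (inconsistent inputs) is capped with a warning.
    """
    if not 0.0 <= air_fraction < 1.0:
        raise AirCorrectionError(
            f"air fraction {air_fraction} not in [0, 1): correction impossible"
        )
    corrected = measured_fraction / (1.0 - air_fraction)
    if corrected > 1.0:
        warnings.warn(
            f"air-corrected fraction {corrected:.4f} > 1; capping at 1",
            stacklevel=2,
        )
        corrected = 1.0
    return corrected


def species_amounts(reading: GasReading) -> GasResult:
    """Amounts (umol) of CH4 and H2 and the H2 partial pressure (atm).

    Each species amount is its air-corrected molar fraction times the total
    headspace gas amount. The H2 partial pressure is the corrected H2
    fraction times the absolute pressure, expressed in atm.
    """
    p_total = total_pressure(reading.gauge_pressure)
    n_total = headspace_moles(reading)

    if "o2" in reading.fractions:
        f_air = residual_air_fraction(reading.fractions["o2"])
    else:
        logger.warning("no O2 fraction in reading; assuming f_air = 0")
        f_air = 0.0

    amounts: dict[str, float] = {}
    corrected: dict[str, float] = {}
    for species, frac in reading.fractions.items():
        if species == "o2":
            continue
        c = correct_species_fraction(frac, f_air)
        corrected[species] = c
        amounts[species] = c * n_total * 1e6

    ph2_atm = corrected.get("h2", 0.0) * p_total / ATM_PA
    return GasResult(
        total_pressure=p_total,
        total_moles=n_total,
        amounts=amounts,
        h2_partial_pressure=ph2_atm,
        air_fraction=f_air,
    )
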