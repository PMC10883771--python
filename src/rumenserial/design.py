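"""Experimental design model for serially transferred rumen mixed cultures.

The experiment is a 2 x 3 factorial (substrate x average dilution rate) run
as three replicate lineages ("sequences") of eight serial 72-h batch
incubations, repeated in two independent incubation runs. Dilution-rate
treatments are realised by transferring 1, 2, or 4 mL of culture fluid into
fresh medium to a 40-mL working volume, so the average dilution rate is a
property of the bottle volumes and the transfer interval, never an input
read from a file.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .constants import (
    HEADSPACE_VOLUME_ML,
    INCUBATION_TEMP_C,
    TRANSFER_INTERVAL_H,
)

SUBSTRATES = ("high_forage", "high_concentrate")
DILUTION_LEVELS = ("low", "mid", "high")

#: Inoculum volume (mL) realising each average dilution-rate level. The
#: smallest inoculum gives the highest dilution rate.
INOCULUM_ML_BY_LEVEL: Mapping[str, float] = {"low": 4.0, "mid": 2.0, "high": 1.0}

N_SEQUENCES = 3
N_INCUBATIONS = 2
N_TRANSFERS = 8


class DesignError(ValueError):
    """Invalid or inconsistent experimental-design input."""


@dataclass(frozen=True)
class BottleSpec:
    """Physical constants of one incubation bottle.

    Parameters
    ----------
    inoculum_volume : float
        Volume of culture fluid (mL) transferred from the donor bottle.
    medium_volume : float
        Volume of fresh medium (mL) in the receiving bottle.
    substrate_mass : float
        Dry mass of substrate (mg DM) weighed into the bottle.
    headspace_volume : float
        Gas headspace (mL), 60 by default.
    temperature : float
        Incubation temperature (degrees C), 39 by default.
    interval : float
        Batch growth interval between transfers (h), 72 by default.
    """

    inoculum_volume: float
    medium_volume: float
    substrate_mass: float = 401.0
    headspace_volume: float = HEADSPACE_VOLUME_ML
    temperature: float = INCUBATION_TEMP_C
    interval: float = TRANSFER_INTERVAL_H

    def __post_init__(self) -> None:
        if self.inoculum_volume <= 0:
            raise DesignError(f"inoculum_volume must be > 0, got {self.inoculum_volume}")
        if self.medium_volume < 0:
            raise DesignError(f"medium_volume must be >= 0, got {self.medium_volume}")
        if self.substrate_mass <= 0:
            raise DesignError(f"substrate_mass must be > 0, got {self.substrate_mass}")
        if self.headspace_volume <= 0:
            raise DesignError(f"headspace_volume must be > 0, got {self.headspace_volume}")
        if self.interval <= 0:
            raise DesignError(f"interval must be > 0, got {self.interval}")

    @property
    def total_volume(self) -> float:
        """Working liquid volume (mL): inoculum plus fresh medium."""
        return self.inoculum_volume + self.medium_volume


#: Study bottles by dilution level: 4+36, 2+38, 1+39 mL, all 40 mL total.
STUDY_BOTTLES: Mapping[str, BottleSpec] = {
    level: BottleSpec(inoculum_volume=v, medium_volume=40.0 - v)
    for level, v in INOCULUM_ML_BY_LEVEL.items()
}


@dataclass(frozen=True)
class TreatmentFactors:
    """Treatment-cell coordinates of one bottle x transfer observation."""

    substrate: str
    dilution_level: str
    incubation: int
    sequence: int
    transfer: int

    def __post_init__(self) -> None:
        if self.substrate not in SUBSTRATES:
            raise DesignError(f"unknown substrate {self.substrate!r}")
        if self.dilution_level not in DILUTION_LEVELS:
            raise DesignError(f"unknown dilution_level {self.dilution_level!r}")
        if not 1 <= self.transfer <= N_TRANSFERS:
            raise DesignError(
                f"transfer must be in [1, {N_TRANSFERS}], got {self.transfer}"
            )

    @property
    def inoculum_volume(self) -> float:
        return INOCULUM_ML_BY_LEVEL[self.dilution_level]


@dataclass
class TransferObservation:
    """End-of-transfer measurements for one bottle.

    Gas fractions are molar fractions (0-1) of the headspace sample;
    metabolite concentrations are mM in the culture fluid; ``eh_measured``
    is vs the Ag/AgCl reference; ``residue_dry_mass`` (mg) is present only
    for transfers whose whole-bottle contents were lyophilized.
    """

    factors: TreatmentFactors
    gauge_pressure: float = 0.0
    gas_fractions: dict = field(default_factory=dict)
    metabolite_conc: dict = field(default_factory=dict)
    ph: float = 7.0
    eh_measured: float | None = None
    residue_dry_mass: float | None = None

    def __post_init__(self) -> None:
        total = 0.0
        for species, frac in self.gas_fractions.items():
            if not 0.0 <= frac <= 1.0:
                raise DesignError(f"gas fraction {species}={frac} outside [0, 1]")
            total += frac
        if total > 1.0 + 1e-9:
            raise DesignError(f"gas fractions sum to {total} > 1")
        for analyte, conc in self.metabolite_conc.items():
            if conc < 0:
                raise DesignError(f"negative concentration {analyte}={conc}")
        if not 0.0 < self.ph < 14.0:
            raise DesignError(f"pH {self.ph} outside (0, 14)")


def average_dilution_rate(spec: BottleSpec) -> float:
    """Average dilution rate D (h^-1) of a serial transfer scheme.

    D = total incubation volume / (inoculum volume x interval)
      = (inoculum mL + fresh medium mL) / (inoculum mL x 72 h)

    The rate is an average across sequential batch incubations, not a
    chemostat constant: the whole non-transferred fraction is discarded at
    once every ``interval`` hours. Returned at full precision; round only
    for presentation (the study's 1, 2, 4 mL bottles give 0.56, 0.28,
    0.14 h^-1 at two decimals).
    """
    return spec.total_volume / (spec.inoculum_volume * spec.interval)


def present_rate(rate: float, decimals: int = 2) -> float:
    """Presentation rounding (half-to-even) of a rate."""
    return round(rate, decimals)


def study_dilution_rates() -> dict[str, float]:
    """The three treatment dilution rates (h^-1), keyed by level."""
    return {level: average_dilution_rate(spec) for level, spec in STUDY_BOTTLES.items()}


def validate_design(rows: Iterable[TreatmentFactors]) -> dict:
    """Check a set of design rows against the full factorial grid.

    The complete design is 2 substrates x 3 dilution levels x 3 sequences
    x 2 incubations x 8 contiguous transfers = 288 rows. Returns a report
    dict with ``complete`` (bool), ``n_rows``, and ``missing`` (list of
    absent (incubation, substrate, dilution_level, sequence, transfer)
    cells). Duplicated (incubation, substrate, dilution level, sequence,
    transfer) keys raise :class:`DesignError`.
    """
    rows = list(rows)
    seen: set[tuple] = set()
    for r in rows:
        key = (r.incubation, r.substrate, r.dilution_level, r.sequence, r.transfer)
        if key in seen:
            raise DesignError(f"duplicated design key {key}")
        seen.add(key)

    incubations = sorted({r.incubation for r in rows}) or list(range(1, N_INCUBATIONS + 1))
    sequences = sorted({r.sequence for r in rows}) or list(range(1, N_SEQUENCES + 1))
    missing = [
        (i, s, d, q, t)
        for i in incubations
        for s in SUBSTRATES
        for d in DILUTION_LEVELS
        for q in sequences
        for t in range(1, N_TRANSFERS + 1)
        if (i, s, d, q, t) not in seen
    ]
    return {"complete": not missing, "n_rows": len(rows), "missing": missing}


def design_grid() -> pd.DataFrame:
    """The full 288-row factorial design as a tidy frame."""
    records = []
    for inc in range(1, N_INCUBATIONS + 1):
        for sub in SUBSTRATES:
            for level in DILUTION_LEVELS:
                spec = STUDY_BOTTLES[level]
                for seq in range(1, N_SEQUENCES + 1):
                    for t in range(1, N_TRANSFERS + 1):
                        records.append(
                            {
                                "incubation": inc,
                                "sequence": seq,
                                "substrate": sub,
                                "dilution_level": level,
                                "inoculum_volume_ml": spec.inoculum_volume,
                                "medium_volume_ml": spec.medium_volume,
                                "substrate_mass_mg": spec.substrate_mass,
                                "transfer": t,
                            }
                        )
    return pd.DataFrame.from_records(records)


def mean_reads_per_sample(total_reads: int, n_samples: int) -> int:
    """Average sequencing reads per sample, to the nearest integer.

    Simple survey arithmetic used when reporting amplicon library depth
    (e.g. total raw reads over the 56 sequenced samples).
    """
    if n_samples <= 0:
        raise DesignError(f"n_samples must be > 0, got {n_samples}")
    return round(total_reads / n_samples)
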