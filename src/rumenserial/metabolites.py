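"""Carryover-corrected metabolite production, DM disappearance, and redox.

In a serial transfer scheme each bottle receives, dissolved in its
inoculum, metabolites produced by the donor bottle of the previous
transfer. Net production per bottle is therefore the final amount minus the
amount carried in: final mM x total mL minus donor mM x inoculum mL
(mM x mL = umol). For transfer 1 the donor is the rumen inoculum itself.
Net consumption (negative production) is a legitimate outcome, as is
negative apparent dry-matter disappearance when microbial biomass accretion
exceeds substrate disappearance.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import pandas as pd

from .constants import SHE_OFFSET_MV

ANALYTES = (
    "acetate",
    "propionate",
    "butyrate",
    "isobutyrate",
    "methylbutyrate_2_3",
    "valerate",
    "methylvalerate_4",
    "caproate",
    "heptanoate",
    "formate",
    "lactate",
    "succinate",
)

#: Ammonium is reported as concentration only, never as carryover-corrected
#: production.
CONCENTRATION_ONLY = ("nh4",)


class LinkageError(ValueError):
    """Broken donor-recipient chain in a serial-transfer lineage."""


@dataclass(frozen=True)
class ProductionRecord:
    """Net production of one analyte in one bottle x transfer."""

    analyte: str
    transfer: int
    net_production: float  # umol per bottle per transfer; may be negative
    donor_concentration: float  # mM
    final_concentration: float  # mM


@dataclass(frozen=True)
class RedoxPotential:
    """A redox potential (mV) tagged with its reference frame.

    The tag prevents the 197-mV Ag/AgCl -> SHE offset from being applied
    twice: the correction is a pure offset, not idempotent.
    """

    value_mv: float
    reference: str = "AgAgCl"  # or "SHE"

    def __post_init__(self) -> None:
        if self.reference not in ("AgAgCl", "SHE"):
            raise ValueError(f"unknown reference frame {self.reference!r}")


def net_production(
    final_conc: float,
    total_volume: float,
    donor_conc: float,
    inoculum_volume: float,
    medium_conc: float = 0.0,
    medium_volume: float | None = None,
) -> float:
    """Net production (umol per bottle) of one analyte over one transfer.

    final_conc x total_volume - donor_conc x inoculum_volume, optionally
    minus the fresh medium's own contribution (medium_conc x medium_volume)
    when the medium contains measurable analyte. All concentrations in mM,
    volumes in mL, so the product is umol.
    """
    if total_volume <= 0 or inoculum_volume <= 0:
        raise ValueError("volumes must be > 0")
    if final_conc < 0 or donor_conc < 0 or medium_conc < 0:
        raise ValueError("concentrations must be >= 0")
    produced = final_conc * total_volume - donor_conc * inoculum_volume
    if medium_conc > 0:
        if medium_volume is None:
            medium_volume = total_volume - inoculum_volume
        produced -= medium_conc * medium_volume
    return produced


def chain_production(
    lineage: pd.DataFrame,
    analyte: str,
    inoculum_conc: float,
    inoculum_volume: float,
    total_volume: float = 40.0,
    medium_conc: float = 0.0,
) -> list[ProductionRecord]:
    """Per-transfer net production along one serial-transfer lineage.

    ``lineage`` holds one row per transfer for a single sequence, with
    columns ``transfer`` and ``conc_mm`` (final concentration at 72 h).
    Transfer t's donor concentration is the transfer t-1 row's final
    concentration; transfer 1's donor is the measured rumen-inoculum
    concentration ``inoculum_conc``. Transfers must be contiguous from 1.
    """
    df = lineage.sort_values("transfer")
    transfers = df["transfer"].tolist()
    expected = list(range(1, len(transfers) + 1))
    if transfers != expected:
        raise LinkageError(
            f"transfers for analyte {analyte!r} are not contiguous from 1: {transfers}"
        )
    records = []
    donor = inoculum_conc
    for _, row in df.iterrows():
        final = float(row["conc_mm"])
        produced = net_production(
            final, total_volume, donor, inoculum_volume, medium_conc=medium_conc
        )
        records.append(
            ProductionRecord(
                analyte=analyte,
                transfer=int(row["transfer"]),
                net_production=produced,
                donor_concentration=donor,
                final_concentration=final,
            )
        )
        donor = final
    return records


def dm_disappearance(substrate_dm: float, residue_dm: float) -> float:
    """Apparent dry-matter disappearance, percent of substrate DM.

    100 x (substrate - residue) / substrate. Negative values are meaningful:
    the lyophilized residue includes microbial biomass, which can outweigh
    the substrate that disappeared.
    """
    if substrate_dm <= 0:
        raise ValueError(f"substrate_dm must be > 0, got {substrate_dm}")
    if residue_dm < 0:
        raise ValueError(f"residue_dm must be >= 0, got {residue_dm}")
    return 100.0 * (substrate_dm - residue_dm) / substrate_dm


def eh_to_she(eh: float | RedoxPotential) -> RedoxPotential:
    """Re-reference a measured redox potential to the SHE frame (+197 mV).

    A bare float is taken as an Ag/AgCl-referenced reading. Passing a value
    already in the SHE frame raises, guarding against double correction.
    """
    if isinstance(eh, RedoxPotential):
        if eh.reference == "SHE":
            raise ValueError("value is already SHE-referenced; refusing to correct twice")
        value = eh.value_mv
    else:
        value = float(eh)
    return RedoxPotential(value_mv=value + SHE_OFFSET_MV, reference="SHE")


def acetate_propionate_ratio(acetate_umol: float, propionate_umol: float) -> float:
    """Molar acetate:propionate ratio of net production.

    Returns NaN (with a warning) rather than raising when propionate
    production is not positive; the record is flagged missing downstream.
    """
    if propionate_umol <= 0:
        warnings.warn(
            f"propionate production {propionate_umol} <= 0: Ac/Pr undefined",
            stacklevel=2,
        )
        return math.nan
    return acetate_umol / propionate_umol
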