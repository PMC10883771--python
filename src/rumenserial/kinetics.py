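"""Discrete growth-dilution model for replication rates across transfers.

Gene copies per bottle across t serial transfers of interval 72 h are
modelled with a constant average replication rate R (h^-1) against the
treatment dilution rate D (h^-1):

    N_t = N_0 * (1 + R - D)^(t * 72)

so the estimator is R = (N_t / N_0)^(1 / (t * 72)) + D - 1. R below D
means the population is being washed out; R may legitimately be negative.
Doubling time follows the reciprocal definition t_d = 1/R (not ln2/R; the
conventional form is available behind an explicit flag).

N_0 for transfer-1 bottles is assembled from the rumen inoculum's copies
per gram of solids, the inoculum's solids content (g/mL, a required
assumption-carrying parameter), and the inoculated volume (mL).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .constants import TRANSFER_INTERVAL_H

#: Solids content of strained rumen inoculum, g solids per mL. The study
#: reports copies per gram of inoculum solids but not the solids fraction;
#: this default is an explicit, overridable assumption.
DEFAULT_INOCULUM_SOLIDS_G_PER_ML = 0.05

TREND_TOLERANCE = 1e-6  # h^-1


class KineticsError(ValueError):
    """Invalid growth-dilution model input."""


class WashoutLimitError(KineticsError):
    """Final copies are zero: R is undefined (below any finite value)."""


@dataclass(frozen=True)
class KineticsInput:
    """Copies at the start of transfer 1 and the end of transfer t."""

    n_initial: float  # gene copies per bottle at inoculation of transfer 1
    n_final: float  # gene copies per bottle at the end of transfer t
    transfer_index: int  # t, the transfer number of the sampled bottle
    dilution_rate: float  # D, h^-1
    interval: float = TRANSFER_INTERVAL_H

    def __post_init__(self) -> None:
        if self.n_initial <= 0:
            raise KineticsError(f"n_initial must be > 0, got {self.n_initial}")
        if self.n_final < 0:
            raise KineticsError(f"n_final must be >= 0, got {self.n_final}")
        if self.transfer_index < 1:
            raise KineticsError(f"transfer_index must be >= 1, got {self.transfer_index}")
        if not 0.0 < self.dilution_rate < 1.0:
            raise KineticsError(
                f"dilution_rate must be in (0, 1) h^-1, got {self.dilution_rate}"
            )
        if self.interval <= 0:
            raise KineticsError(f"interval must be > 0, got {self.interval}")


@dataclass(frozen=True)
class KineticsResult:
    replication_rate: float  # h^-1; nan when undefined (washout limit)
    doubling_time: float  # h; nan when R <= 0
    net_trend: str  # growing | steady | washing_out


def inoculated_copies(
    copies_per_g_solids: float,
    inoculum_volume_ml: float,
    solids_g_per_ml: float = DEFAULT_INOCULUM_SOLIDS_G_PER_ML,
) -> float:
    """Copies per bottle delivered with the transfer-1 rumen inoculum."""
    if copies_per_g_solids < 0 or inoculum_volume_ml <= 0 or solids_g_per_ml <= 0:
        raise KineticsError("inoculum quantities must be positive")
    return copies_per_g_solids * solids_g_per_ml * inoculum_volume_ml


def forward_copies(
    n_initial: float,
    replication_rate: float,
    dilution_rate: float,
    transfer_index: int,
    interval: float = TRANSFER_INTERVAL_H,
) -> float:
    """Forward model: N_t = N_0 (1 + R - D)^(t * interval)."""
    base = 1.0 + replication_rate - dilution_rate
    if base <= 0:
        raise KineticsError(
            f"1 + R - D = {base} <= 0: outside the model's domain (D - R >= 1)"
        )
    return n_initial * base ** (transfer_index * interval)


def replication_rate(inp: KineticsInput) -> float:
    """Average replication rate R = (N_t/N_0)^(1/(t x interval)) + D - 1."""
    if inp.n_final == 0:
        raise WashoutLimitError(
            "n_final = 0: R is undefined (population fully washed out)"
        )
    exponent = 1.0 / (inp.transfer_index * inp.interval)
    return (inp.n_final / inp.n_initial) ** exponent + inp.dilution_rate - 1.0


def doubling_time(rate: float, conventional: bool = False) -> float:
    """Doubling time in hours from a replication rate.

    The study's definition is the reciprocal, t_d = 1/R. Set
    ``conventional=True`` for the exponential-growth form ln(2)/R. Returns
    NaN for R <= 0 (a non-replicating population has no doubling time).
    """
    if rate <= 0:
        return math.nan
    return (math.log(2.0) if conventional else 1.0) / rate


def classify_trend(rate: float, dilution: float, tol: float = TREND_TOLERANCE) -> str:
    """growing / steady / washing_out by comparing R with D at tolerance."""
    if math.isnan(rate):
        return "washing_out"
    if abs(rate - dilution) <= tol:
        return "steady"
    return "growing" if rate > dilution else "washing_out"


def analyze(inp: KineticsInput, tol: float = TREND_TOLERANCE) -> KineticsResult:
    """Replication rate, doubling time, and trend for one lineage.

    The n_final = 0 washout limit is reported rather than raised: R and the
    doubling time come back NaN with trend ``washing_out``.
    """
    try:
        rate = replication_rate(inp)
    except WashoutLimitError:
        return KineticsResult(math.nan, math.nan, "washing_out")
    return KineticsResult(
        replication_rate=rate,
        doubling_time=doubling_time(rate),
        net_trend=classify_trend(rate, inp.dilution_rate, tol),
    )
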