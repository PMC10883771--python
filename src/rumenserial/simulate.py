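"""Synthetic serial-transfer experiment generator with known ground truth.

The simulator emulates the study's stated world: 2 substrates x 3 dilution
levels (4, 2, 1 mL inocula into 40 mL) x 3 replicate sequences x 2
incubation runs x 8 transfers of 72-h batch growth, 401 mg DM substrate,
60-mL CO2-flushed headspace at 39 degC. Two microbial guilds ("bacteria"
and methanogenic "archaea") grow logistically within each transfer and are
diluted at each inoculation; fermentation products are proportional to the
bacterial biomass increment; H2 is routed to CH4 (4 H2 : 1 CH4,
hydrogenotrophic stoichiometry) in proportion to how close the methanogen
population is to a reference capacity, and unused H2 accumulates. Under
the high-concentrate defaults the methanogens' growth cannot offset the
dilution, reproducing the qualitative washout and H2/formate accumulation
signature; under high forage they keep pace and little H2 is left.

Every observable is generated by the exact inverse of the corresponding
analysis step (ideal-gas pressure from gas amounts, concentrations from
carryover plus production, copies/g from copies per bottle), so with the
noise and air-contamination switches at zero the full pipeline recovers
the ground truth to machine precision. All randomness flows from one seed
via per-lineage labelled streams.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .constants import (
    ATM_PA,
    NATURAL_13C_ABUNDANCE,
    O2_ATMOSPHERIC,
    R_GAS,
)
from .design import (
    DILUTION_LEVELS,
    N_INCUBATIONS,
    N_SEQUENCES,
    N_TRANSFERS,
    SUBSTRATES,
    STUDY_BOTTLES,
    BottleSpec,
    average_dilution_rate,
    design_grid,
)
from .isotopes import VFA_CARBONS
from .kinetics import inoculated_copies
from .metabolites import ANALYTES

#: Transfers whose whole-bottle contents are lyophilized for qPCR/residue
#: analysis, per incubation run.
SAMPLED_TRANSFERS = {1: (8,), 2: (4, 8)}


class SimulationError(ValueError):
    """Invalid simulation parameters."""


@dataclass(frozen=True)
class GuildParams:
    """Logistic growth parameters of one microbial guild."""

    mu_max: float  # h^-1
    carrying_capacity: float  # gene copies per bottle

    def __post_init__(self) -> None:
        if self.mu_max <= 0 or self.carrying_capacity <= 0:
            raise SimulationError("mu_max and carrying_capacity must be > 0")


@dataclass(frozen=True)
class SubstrateScenario:
    """Guild growth, fermentation yields, and chemistry for one substrate.

    Yields are umol per bottle per transfer at full growth (bacterial
    biomass increment equal to the carrying capacity); actual production
    scales with the realised increment.
    """

    bacteria: GuildParams
    archaea: GuildParams
    yields: dict  # analyte -> umol per transfer at full growth
    h2_yield: float  # umol H2 produced per transfer at full growth
    co2_yield: float  # umol CO2 released per transfer at full growth
    undigested_fraction: float  # of substrate DM remaining in the residue
    ph_intercept: float = 7.05
    ph_slope_per_mm: float = 0.0065  # pH drop per mM total VFA
    eh_she_mv: float = -330.0

    def __post_init__(self) -> None:
        if any(y < 0 for y in self.yields.values()):
            raise SimulationError("yields must be >= 0")
        if self.h2_yield < 0 or self.co2_yield < 0:
            raise SimulationError("gas yields must be >= 0")
        if not 0 <= self.undigested_fraction <= 1.2:
            raise SimulationError("undigested_fraction out of range")


@dataclass(frozen=True)
class InoculumParams:
    """Rumen inoculum composition (shared by all transfer-1 bottles)."""

    bact_copies_per_g: float = 10**10.6  # 16S copies per g of inoculum solids
    arch_copies_per_g: float = 10**7.8  # mcrA copies per g of inoculum solids
    solids_g_per_ml: float = 0.05
    conc_mm: dict = field(
        default_factory=lambda: {
            "acetate": 60.0,
            "propionate": 20.0,
            "butyrate": 12.0,
            "isobutyrate": 1.0,
            "methylbutyrate_2_3": 1.2,
            "valerate": 1.5,
            "methylvalerate_4": 0.3,
            "caproate": 0.5,
            "heptanoate": 0.1,
            "formate": 0.2,
            "lactate": 0.8,
            "succinate": 0.6,
        }
    )
    nh4_mm: float = 10.0


def _default_substrates() -> dict:
    # High forage: methanogens keep pace with dilution; little residual H2.
    # High concentrate: methanogen growth cannot offset even the 4-mL
    # dilution (e^(0.03*72) ~ 8.7 < 10), so they wash out and H2/formate
    # accumulate.
    forage = SubstrateScenario(
        bacteria=GuildParams(mu_max=0.35, carrying_capacity=1.0e10),
        archaea=GuildParams(mu_max=0.12, carrying_capacity=1.0e8),
        yields={
            "acetate": 2500.0,
            "propionate": 900.0,
            "butyrate": 350.0,
            "isobutyrate": 40.0,
            "methylbutyrate_2_3": 45.0,
            "valerate": 60.0,
            "methylvalerate_4": 20.0,
            "caproate": 60.0,
            "heptanoate": 10.0,
            "formate": 15.0,
            "lactate": 250.0,
            "succinate": 25.0,
        },
        h2_yield=600.0,
        co2_yield=2800.0,
        undigested_fraction=0.95,
        ph_intercept=7.10,
        eh_she_mv=-350.0,
    )
    concentrate = SubstrateScenario(
        bacteria=GuildParams(mu_max=0.40, carrying_capacity=1.2e10),
        archaea=GuildParams(mu_max=0.03, carrying_capacity=1.0e8),
        yields={
            "acetate": 1300.0,
            "propionate": 750.0,
            "butyrate": 900.0,
            "isobutyrate": 20.0,
            "methylbutyrate_2_3": 25.0,
            "valerate": 70.0,
            "methylvalerate_4": 10.0,
            "caproate": 25.0,
            "heptanoate": 5.0,
            "formate": 500.0,
            "lactate": 320.0,
            "succinate": 15.0,
        },
        h2_yield=900.0,
        co2_yield=3200.0,
        undigested_fraction=0.93,
        ph_intercept=6.95,
        eh_she_mv=-300.0,
    )
    return {"high_forage": forage, "high_concentrate": concentrate}


@dataclass(frozen=True)
class SimulationParams:
    """Everything the generator needs besides the design grid."""

    substrates: dict = field(default_factory=_default_substrates)
    inoculum: InoculumParams = field(default_factory=InoculumParams)
    #: Methanogen abundance at which all produced H2 is used (4:1 to CH4).
    archaea_ref: float = 1.0e8
    #: Gene copies per gram of microbial biomass, converting guild copies
    #: to residue mass contribution.
    copies_per_g_biomass: float = 2.0e12
    sigma_conc: float = 0.05  # lognormal sigma on concentrations/fractions
    sigma_copies: float = 0.2  # lognormal sigma on qPCR copies
    sigma_pressure_pa: float = 500.0  # gaussian sigma on gauge pressure
    air_max: float = 0.1  # exetainer air contamination ~ U[0, air_max]
    label_p: float = NATURAL_13C_ABUNDANCE * 1.05  # 5% above natural
    natural_p: float = NATURAL_13C_ABUNDANCE
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for s in (self.sigma_conc, self.sigma_copies, self.sigma_pressure_pa):
            if s < 0:
                raise SimulationError("noise sigmas must be >= 0")
        if not 0 <= self.air_max < 1:
            raise SimulationError("air_max must be in [0, 1)")
        if not 0 <= self.label_p < 0.5 or not 0 < self.natural_p < 0.5:
            raise SimulationError("13C probabilities out of range")

    def noiseless(self) -> "SimulationParams":
        """A copy with all noise and air contamination switched off."""
        return replace(
            self, sigma_conc=0.0, sigma_copies=0.0, sigma_pressure_pa=0.0, air_max=0.0
        )


def logistic_growth(n0: float, mu: float, capacity: float, hours: float) -> float:
    """Closed-form logistic growth N(t) = K N0 e^(mu t) / (K + N0 (e^(mu t)-1))."""
    if n0 <= 0:
        return 0.0
    growth = math.exp(mu * hours)
    return capacity * n0 * growth / (capacity + n0 * (growth - 1.0))


def binomial_spectrum(n_carbons: int, p: float, scale: float = 1.0e5) -> tuple:
    """Truncated-binomial isotopolog intensities (M+0, M+1, M+2).

    Each of the n carbons is 13C with probability p independently; peaks
    beyond M+2 fall below detection and are omitted, as in the GC-MS data.
    """
    if not 0 <= p < 0.5:
        raise SimulationError(f"p must be in [0, 0.5), got {p}")
    return tuple(
        scale * math.comb(n_carbons, k) * p**k * (1.0 - p) ** (n_carbons - k)
        for k in range(3)
    )


def _lineage_rng(seed: int, incubation: int, substrate: str, level: str, sequence: int):
    key = [seed, incubation, SUBSTRATES.index(substrate), DILUTION_LEVELS.index(level), sequence]
    return np.random.default_rng(key)


@dataclass
class _LineageState:
    bact: float  # copies per bottle at the end of the last transfer
    arch: float
    conc: dict  # analyte -> mM in the bottle fluid at 72 h


def simulate_transfer(
    state: _LineageState,
    spec: BottleSpec,
    scenario: SubstrateScenario,
    params: SimulationParams,
    transfer: int,
    inoculum: InoculumParams,
) -> tuple[_LineageState, dict]:
    """Advance one lineage by one 72-h transfer.

    Returns the new state and a ground-truth record: true copies, true net
    production per metabolite, true gas amounts, and the noise-free gauge
    pressure. Transfer 1 draws its cells and carryover metabolites from the
    rumen inoculum; later transfers draw them from the donor bottle fluid.
    """
    v_in = spec.inoculum_volume
    total = spec.total_volume
    if transfer == 1:
        n_bact_in = inoculated_copies(
            inoculum.bact_copies_per_g, v_in, inoculum.solids_g_per_ml
        )
        n_arch_in = inoculated_copies(
            inoculum.arch_copies_per_g, v_in, inoculum.solids_g_per_ml
        )
        donor_conc = dict(inoculum.conc_mm)
    else:
        n_bact_in = state.bact * v_in / total
        n_arch_in = state.arch * v_in / total
        donor_conc = state.conc

    n_bact = logistic_growth(n_bact_in, scenario.bacteria.mu_max,
                             scenario.bacteria.carrying_capacity, spec.interval)
    n_arch = logistic_growth(n_arch_in, scenario.archaea.mu_max,
                             scenario.archaea.carrying_capacity, spec.interval)
    growth_frac = (n_bact - n_bact_in) / scenario.bacteria.carrying_capacity

    production = {a: scenario.yields.get(a, 0.0) * growth_frac for a in ANALYTES}
    h2_produced = scenario.h2_yield * growth_frac
    co2_produced = scenario.co2_yield * growth_frac
    usable_h2 = h2_produced * min(1.0, n_arch / params.archaea_ref)
    ch4 = usable_h2 / 4.0
    h2_residual = h2_produced - usable_h2

    conc = {
        a: (donor_conc.get(a, 0.0) * v_in + production[a]) / total for a in ANALYTES
    }

    # Headspace: flushed with CO2 to 1 atm at sealing, plus fermentation gas.
    temp_k = spec.temperature + 273.15
    volume_m3 = spec.headspace_volume * 1e-6
    n_init = ATM_PA * volume_m3 / (R_GAS * temp_k)
    n_total = n_init + (ch4 + h2_residual + co2_produced) * 1e-6
    gauge_true = n_total * R_GAS * temp_k / volume_m3 - ATM_PA

    residue_g = (
        spec.substrate_mass / 1000.0 * scenario.undigested_fraction
        + (n_bact + n_arch) / params.copies_per_g_biomass
    )
    total_vfa = sum(conc[a] for a in ("acetate", "propionate", "butyrate"))
    truth = {
        "transfer": transfer,
        "true_bact_copies": n_bact,
        "true_arch_copies": n_arch,
        "true_ch4_umol": ch4,
        "true_h2_umol": h2_residual,
        "true_co2_umol": co2_produced,
        "true_gauge_pa": gauge_true,
        "true_n_total_mol": n_total,
        "true_residue_g": residue_g,
        "true_ph": scenario.ph_intercept - scenario.ph_slope_per_mm * total_vfa,
        "true_eh_she_mv": scenario.eh_she_mv,
        **{f"prod_{a}": production[a] for a in ANALYTES},
        **{f"conc_{a}": conc[a] for a in ANALYTES},
    }
    return _LineageState(bact=n_bact, arch=n_arch, conc=conc), truth


def generate_experiment(params: SimulationParams | None = None, seed: int | None = None) -> dict:
    """Generate the full synthetic experiment as a bundle of tidy frames.

    Returns a dict of DataFrames keyed ``design``, ``gas``, ``metabolites``,
    ``qpcr``, ``inoculum_copies``, ``inoculum_conc``, ``isotopologs``, and
    ``ground_truth``, each in the input schema of the corresponding
    analysis module. Deterministic given (params, seed); ``seed`` overrides
    ``params.rng_seed``.
    """
    params = params or SimulationParams()
    if seed is not None:
        params = replace(params, rng_seed=int(seed))

    key_cols = ("incubation", "sequence", "substrate", "dilution_level")
    gas_rows, met_rows, qpcr_rows, iso_rows, truth_rows = [], [], [], [], []

    for inc in range(1, N_INCUBATIONS + 1):
        for substrate in SUBSTRATES:
            scenario = params.substrates[substrate]
            for level in DILUTION_LEVELS:
                spec = STUDY_BOTTLES[level]
                dilution = average_dilution_rate(spec)
                for seq in range(1, N_SEQUENCES + 1):
                    rng = _lineage_rng(params.rng_seed, inc, substrate, level, seq)
                    state = _LineageState(bact=0.0, arch=0.0, conc={})
                    n0_bact = inoculated_copies(
                        params.inoculum.bact_copies_per_g,
                        spec.inoculum_volume,
                        params.inoculum.solids_g_per_ml,
                    )
                    n0_arch = inoculated_copies(
                        params.inoculum.arch_copies_per_g,
                        spec.inoculum_volume,
                        params.inoculum.solids_g_per_ml,
                    )
                    for t in range(1, N_TRANSFERS + 1):
                        state, truth = simulate_transfer(
                            state, spec, scenario, params, t, params.inoculum
                        )
                        key = dict(zip(key_cols, (inc, seq, substrate, level)))
                        hours = t * spec.interval
                        truth.update(
                            key,
                            r_bact=(state.bact / n0_bact) ** (1.0 / hours) + dilution - 1.0,
                            r_arch=(state.arch / n0_arch) ** (1.0 / hours) + dilution - 1.0,
                        )
                        truth_rows.append(truth)

                        # --- observed gas (exetainer sample, maybe air-diluted)
                        f_air = rng.uniform(0.0, params.air_max) if params.air_max else 0.0
                        n_total = truth["true_n_total_mol"]
                        frac_true = {
                            "ch4": truth["true_ch4_umol"] * 1e-6 / n_total,
                            "h2": truth["true_h2_umol"] * 1e-6 / n_total,
                        }
                        noise = lambda: (
                            rng.lognormal(0.0, params.sigma_conc) if params.sigma_conc else 1.0
                        )
                        gas_rows.append(
                            {
                                **key,
                                "transfer": t,
                                "gauge_pressure_pa": truth["true_gauge_pa"]
                                + (rng.normal(0.0, params.sigma_pressure_pa)
                                   if params.sigma_pressure_pa else 0.0),
                                "frac_ch4": frac_true["ch4"] * (1.0 - f_air) * noise(),
                                "frac_h2": frac_true["h2"] * (1.0 - f_air) * noise(),
                                "frac_o2": O2_ATMOSPHERIC * f_air,
                            }
                        )

                        # --- observed metabolite concentrations
                        met = {**key, "transfer": t}
                        for a in ANALYTES:
                            met[f"{a}_mm"] = truth[f"conc_{a}"] * noise()
                        met["nh4_mm"] = params.inoculum.nh4_mm * noise()
                        met["ph"] = truth["true_ph"] + (
                            rng.normal(0.0, 0.05) if params.sigma_conc else 0.0
                        )
                        met["eh_mv"] = truth["true_eh_she_mv"] - 197.0 + (
                            rng.normal(0.0, 5.0) if params.sigma_conc else 0.0
                        )
                        met_rows.append(met)

                        # --- qPCR on lyophilized residues of sampled transfers
                        if t in SAMPLED_TRANSFERS[inc]:
                            residue = truth["true_residue_g"]
                            for gene, copies in (
                                ("bac_16S", state.bact),
                                ("arc_mcrA", state.arch),
                            ):
                                cpg = copies / residue
                                if params.sigma_copies:
                                    cpg *= rng.lognormal(0.0, params.sigma_copies)
                                qpcr_rows.append(
                                    {
                                        **key,
                                        "transfer": t,
                                        "gene": gene,
                                        "copies_per_g": cpg,
                                        "residue_mass_g": residue,
                                    }
                                )

                    # --- 13C isotopologs: incubation 2, transfer 8 only;
                    # sequences 1-2 labeled, sequence 3 the natural standard.
                    if inc == 2:
                        is_standard = seq == N_SEQUENCES
                        p = params.natural_p if is_standard else params.label_p
                        for analyte, n_c in VFA_CARBONS.items():
                            ai = binomial_spectrum(n_c, p)
                            if params.sigma_conc:
                                ai = tuple(
                                    a * rng.lognormal(0.0, params.sigma_conc) for a in ai
                                )
                            iso_rows.append(
                                {
                                    **key,
                                    "transfer": N_TRANSFERS,
                                    "analyte": analyte,
                                    "ai_m0": ai[0],
                                    "ai_m1": ai[1],
                                    "ai_m2": ai[2],
                                    "is_standard": is_standard,
                                }
                            )

    inoc = params.inoculum
    inoculum_copies_df = pd.DataFrame(
        [
            {"gene": "bac_16S", "copies_per_g_solids": inoc.bact_copies_per_g,
             "solids_g_per_ml": inoc.solids_g_per_ml},
            {"gene": "arc_mcrA", "copies_per_g_solids": inoc.arch_copies_per_g,
             "solids_g_per_ml": inoc.solids_g_per_ml},
        ]
    )
    inoculum_conc_df = pd.DataFrame(
        [{"analyte": a, "conc_mm": c} for a, c in inoc.conc_mm.items()]
        + [{"analyte": "nh4", "conc_mm": inoc.nh4_mm}]
    )
    return {
        "design": design_grid(),
        "gas": pd.DataFrame(gas_rows),
        "metabolites": pd.DataFrame(met_rows),
        "qpcr": pd.DataFrame(qpcr_rows),
        "inoculum_copies": inoculum_copies_df,
        "inoculum_conc": inoculum_conc_df,
        "isotopologs": pd.DataFrame(iso_rows),
        "ground_truth": pd.DataFrame(truth_rows),
    }


def generate_isotopologs(
    enrichment_p: dict,
    params: SimulationParams | None = None,
    scale: float = 1.0e5,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Isotopolog spectra for given per-analyte 13C probabilities.

    ``enrichment_p`` maps analyte -> per-carbon 13C probability. Intensities
    follow the truncated binomial with multiplicative lognormal noise of
    sigma ``params.sigma_conc``.
    """
    params = params or SimulationParams()
    rng = rng or np.random.default_rng(params.rng_seed)
    rows = []
    for analyte, p in enrichment_p.items():
        ai = binomial_spectrum(VFA_CARBONS[analyte], p, scale=scale)
        if params.sigma_conc:
            ai = tuple(a * rng.lognormal(0.0, params.sigma_conc) for a in ai)
        rows.append(
            {"analyte": analyte, "ai_m0": ai[0], "ai_m1": ai[1], "ai_m2": ai[2]}
        )
    return pd.DataFrame(rows)
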