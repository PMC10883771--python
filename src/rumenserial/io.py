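"""CSV schemas, validated I/O, and the staged analysis pipeline.

All interchange is RFC-4180 CSV (UTF-8, '.' decimal, empty field for
missing). Every derived table is written with a single leading ``#``
provenance comment (package version, config hash, input hashes) which
:func:`read_table` skips transparently. The pipeline runs the stages
gas -> production -> kinetics -> qpcr -> isotopes -> stats on a bundle of
input tables, aborting with the stage name on the first failure.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .constants import (
    ATM_PA,
    AVOGADRO,
    DSDNA_BP_G_PER_MOL,
    O2_ATMOSPHERIC,
    R_GAS,
    SHE_OFFSET_MV,
)
from .design import INOCULUM_ML_BY_LEVEL, STUDY_BOTTLES, average_dilution_rate
from .gas import GasReading, species_amounts
from .isotopes import pair_with_standard
from .kinetics import (
    DEFAULT_INOCULUM_SOLIDS_G_PER_ML,
    KineticsInput,
    analyze,
    inoculated_copies,
)
from .metabolites import ANALYTES, chain_production, eh_to_she
from .qpcr import copies_per_bottle, log10_copies
from .stats import (
    OUTLIER_ALPHA,
    MixedModelSpec,
    fit_factorial_mixed_model,
    flag_outliers,
    linear_contrast_coefficients,
    pearson_correlations,
)

logger = logging.getLogger(__name__)

KEY_COLUMNS = ["incubation", "sequence", "substrate", "dilution_level", "transfer"]

#: Required and optional columns per interchange table.
SCHEMAS: dict[str, dict] = {
    "design": {
        "required": [
            "incubation", "sequence", "substrate", "dilution_level",
            "inoculum_volume_ml", "medium_volume_ml", "substrate_mass_mg", "transfer",
        ],
        "optional": [],
    },
    "gas": {
        "required": [*KEY_COLUMNS, "gauge_pressure_pa", "frac_ch4", "frac_h2"],
        "optional": ["frac_o2"],
    },
    "metabolites": {
        "required": [*KEY_COLUMNS, *(f"{a}_mm" for a in ANALYTES)],
        "optional": ["nh4_mm", "ph", "eh_mv"],
    },
    "qpcr": {
        "required": [*KEY_COLUMNS, "gene", "copies_per_g", "residue_mass_g"],
        "optional": [],
    },
    "inoculum_copies": {
        "required": ["gene", "copies_per_g_solids", "solids_g_per_ml"],
        "optional": [],
    },
    "inoculum_conc": {"required": ["analyte", "conc_mm"], "optional": []},
    "isotopologs": {
        "required": [*KEY_COLUMNS, "analyte", "ai_m0", "ai_m1", "ai_m2", "is_standard"],
        "optional": [],
    },
}


class SchemaError(ValueError):
    """Input table does not satisfy its schema."""


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Run configuration: constants block, assumptions, and choices.

    The constants are read-only defaults of the measurement system;
    anything overridden here is logged at run time.
    """

    constants: dict = field(
        default_factory=lambda: {
            "atm_pa": ATM_PA,
            "o2_atmospheric": O2_ATMOSPHERIC,
            "she_offset_mv": SHE_OFFSET_MV,
            "r_gas": R_GAS,
            "dsdna_bp_g_per_mol": DSDNA_BP_G_PER_MOL,
            "avogadro": AVOGADRO,
        }
    )
    inoculum_solids_g_per_ml: float = DEFAULT_INOCULUM_SOLIDS_G_PER_ML
    contrast_scale: str = "volume"  # or "rate"
    outlier_alpha: float = OUTLIER_ALPHA
    seed: int = 0
    #: Response columns the stats stage models (built by earlier stages).
    stat_responses: tuple = ("umol_ch4", "umol_h2", "prod_acetate")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _file_hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:12]


def read_table(path: str | Path, schema: str) -> pd.DataFrame:
    """Read and validate one interchange table.

    Missing required columns raise :class:`SchemaError` naming them; a
    missing optional column (e.g. ``frac_o2``) loads with a warning so the
    no-air-correction path can run. Unit-suffixed columns (_pa, _mm, _ml,
    _mg, _g) must parse as numbers; negative volumes and masses are
    rejected with their row index.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if schema not in SCHEMAS:
        raise SchemaError(f"unknown schema {schema!r}")
    df = pd.read_csv(path, comment="#")
    spec = SCHEMAS[schema]
    missing = [c for c in spec["required"] if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing required columns {missing}")
    for c in spec["optional"]:
        if c not in df.columns:
            warnings.warn(f"{path.name}: optional column {c!r} absent", stacklevel=2)
    unit_suffixes = ("_pa", "_mm", "_ml", "_mg", "_g", "_per_g", "_per_ml")
    for col in df.columns:
        if col.endswith(unit_suffixes):
            try:
                df[col] = pd.to_numeric(df[col])
            except (ValueError, TypeError) as exc:
                raise SchemaError(f"{path.name}: column {col!r} not numeric: {exc}")
            if col.endswith(("_ml", "_mg")) and (df[col] < 0).any():
                row = int(df.index[df[col] < 0][0])
                raise SchemaError(f"{path.name}: negative value in {col!r} at row {row}")
    return df


def write_table(df: pd.DataFrame, path: str | Path, provenance: dict | None = None) -> Path:
    """Write a table with a one-line ``#`` provenance header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    header = {"package": f"rumenserial {__version__}", **(provenance or {})}
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# {json.dumps(header, sort_keys=True)}\n")
        df.to_csv(fh, index=False)
    return path


def write_bundle(bundle: dict, outdir: str | Path, provenance: dict | None = None) -> dict:
    """Write a simulator bundle to ``outdir`` as one CSV per table."""
    outdir = Path(outdir)
    paths = {}
    for name, df in bundle.items():
        paths[name] = write_table(df, outdir / f"{name}.csv", provenance)
    return paths


def read_bundle(indir: str | Path) -> dict:
    """Read every known interchange table present in ``indir``."""
    indir = Path(indir)
    bundle = {}
    for name in SCHEMAS:
        path = indir / f"{name}.csv"
        if path.exists():
            bundle[name] = read_table(path, name)
    if not bundle:
        raise FileNotFoundError(f"no interchange tables found in {indir}")
    return bundle


# ---------------------------------------------------------------------------
# pipeline stages


def gas_stage(gas_df: pd.DataFrame) -> pd.DataFrame:
    """Per-bottle gas results: pressure, moles, CH4/H2 umol, pH2, air."""
    rows = []
    for _, r in gas_df.iterrows():
        fractions = {"ch4": r["frac_ch4"], "h2": r["frac_h2"]}
        if "frac_o2" in gas_df.columns and not pd.isna(r.get("frac_o2")):
            fractions["o2"] = r["frac_o2"]
        result = species_amounts(GasReading(r["gauge_pressure_pa"], fractions))
        rows.append(
            {
                **{k: r[k] for k in KEY_COLUMNS},
                "total_pressure_pa": result.total_pressure,
                "total_mol": result.total_moles,
                "umol_ch4": result.amounts.get("ch4", 0.0),
                "umol_h2": result.amounts.get("h2", 0.0),
                "ph2_atm": result.h2_partial_pressure,
                "air_fraction": result.air_fraction,
            }
        )
    return pd.DataFrame(rows)


def production_stage(
    metabolites_df: pd.DataFrame, inoculum_conc: pd.DataFrame
) -> pd.DataFrame:
    """Carryover-corrected net production per bottle x analyte (umol)."""
    inoc = dict(zip(inoculum_conc["analyte"], inoculum_conc["conc_mm"]))
    rows = []
    lineage_keys = ["incubation", "sequence", "substrate", "dilution_level"]
    for key, grp in metabolites_df.groupby(lineage_keys):
        level = key[lineage_keys.index("dilution_level")]
        spec = STUDY_BOTTLES[level]
        for analyte in ANALYTES:
            lineage = grp[["transfer", f"{analyte}_mm"]].rename(
                columns={f"{analyte}_mm": "conc_mm"}
            )
            try:
                records = chain_production(
                    lineage,
                    analyte,
                    inoculum_conc=inoc.get(analyte, 0.0),
                    inoculum_volume=spec.inoculum_volume,
                    total_volume=spec.total_volume,
                )
            except Exception as exc:
                raise PipelineError(
                    f"production stage failed for lineage {dict(zip(lineage_keys, key))}: {exc}"
                ) from exc
            for rec in records:
                rows.append(
                    {
                        **dict(zip(lineage_keys, key)),
                        "transfer": rec.transfer,
                        "analyte": analyte,
                        "umol_net": rec.net_production,
                    }
                )
    return pd.DataFrame(rows)


def kinetics_stage(
    qpcr_df: pd.DataFrame,
    inoculum_copies_df: pd.DataFrame,
    solids_g_per_ml: float | None = None,
) -> pd.DataFrame:
    """Replication rate, doubling time, and trend per lineage x gene."""
    inoc = inoculum_copies_df.set_index("gene")
    rows = []
    for _, r in qpcr_df.iterrows():
        gene = r["gene"]
        if gene not in inoc.index:
            raise PipelineError(f"kinetics stage: no inoculum copies for gene {gene!r}")
        solids = (
            solids_g_per_ml
            if solids_g_per_ml is not None
            else float(inoc.loc[gene, "solids_g_per_ml"])
        )
        v_in = INOCULUM_ML_BY_LEVEL[r["dilution_level"]]
        n0 = inoculated_copies(float(inoc.loc[gene, "copies_per_g_solids"]), v_in, solids)
        n_final = copies_per_bottle(r["copies_per_g"], r["residue_mass_g"])
        spec = STUDY_BOTTLES[r["dilution_level"]]
        result = analyze(
            KineticsInput(
                n_initial=n0,
                n_final=n_final,
                transfer_index=int(r["transfer"]),
                dilution_rate=average_dilution_rate(spec),
            )
        )
        rows.append(
            {
                **{k: r[k] for k in KEY_COLUMNS},
                "gene": gene,
                "n_initial": n0,
                "n_final": n_final,
                "R_per_h": result.replication_rate,
                "doubling_h": result.doubling_time,
                "trend": result.net_trend,
            }
        )
    return pd.DataFrame(rows)


def qpcr_stage(qpcr_df: pd.DataFrame) -> pd.DataFrame:
    """Copies per bottle and log10 values from per-gram quantities."""
    out = qpcr_df.copy()
    out["copies_per_bottle"] = [
        copies_per_bottle(c, m) for c, m in zip(out["copies_per_g"], out["residue_mass_g"])
    ]
    out["log10_copies_per_g"] = [log10_copies(c) for c in out["copies_per_g"]]
    out["log10_copies_per_bottle"] = [log10_copies(c) for c in out["copies_per_bottle"]]
    return out


def isotopes_stage(isotopologs_df: pd.DataFrame) -> pd.DataFrame:
    return pair_with_standard(isotopologs_df)


def stats_stage(
    gas_results: pd.DataFrame,
    production: pd.DataFrame,
    metabolites_df: pd.DataFrame,
    config: PipelineConfig,
) -> dict:
    """Mixed-model term tables, outlier report, and Pearson correlations."""
    prod_wide = production.pivot_table(
        index=KEY_COLUMNS, columns="analyte", values="umol_net"
    ).add_prefix("prod_").reset_index()
    table = gas_results.merge(prod_wide, on=KEY_COLUMNS)
    if "ph" in metabolites_df.columns:
        table = table.merge(
            metabolites_df[[*KEY_COLUMNS, "ph", "lactate_mm"]], on=KEY_COLUMNS
        )

    term_tables = {}
    outliers = {}
    for response in config.stat_responses:
        if response not in table.columns:
            continue
        fit = fit_factorial_mixed_model(table, MixedModelSpec(response=response))
        term_tables[response] = fit["terms"]
        if fit["result"] is not None:
            resid = np.asarray(fit["result"].resid, dtype=float)
            scale = resid.std(ddof=1)
            student = resid / scale if scale > 0 else resid
            meta = table[["substrate", "dilution_level", "transfer", "sequence", "incubation"]]
            outliers[response] = flag_outliers(
                student, alpha=config.outlier_alpha, metadata=meta
            )

    corr_pairs = [
        (x, "ph2_atm")
        for x in ("umol_ch4", "prod_acetate", "prod_propionate", "prod_butyrate", "lactate_mm")
        if x in table.columns
    ]
    if "ph" in table.columns:
        corr_pairs.append(("umol_h2", "ph"))
    correlations = pearson_correlations(table, corr_pairs)

    if config.contrast_scale == "volume":
        contrast = linear_contrast_coefficients([4, 2, 1])
    else:
        contrast = linear_contrast_coefficients(
            [average_dilution_rate(STUDY_BOTTLES[lv]) for lv in ("low", "mid", "high")]
        )
    return {
        "analysis_table": table,
        "terms": term_tables,
        "outliers": outliers,
        "correlations": correlations,
        "dilution_contrast": contrast,
    }


def run_pipeline(
    indir: str | Path, outdir: str | Path, config: PipelineConfig | None = None
) -> dict:
    """Run all stages on a bundle directory and write the result tables.

    Stage order: gas -> production -> kinetics -> qpcr -> isotopes -> stats.
    Each output CSV carries a provenance header with the config hash and
    the input file hashes; a machine-readable ``run_summary.json`` is
    written alongside. A stage failure raises :class:`PipelineError`
    naming the stage.
    """
    config = config or PipelineConfig()
    indir, outdir = Path(indir), Path(outdir)
    bundle = read_bundle(indir)
    provenance = {
        "config_hash": config.config_hash(),
        "inputs": {p.name: _file_hash(p) for p in sorted(indir.glob("*.csv"))},
    }

    results: dict = {}
    stages = []
    stages.append(("gas", lambda: gas_stage(bundle["gas"])))
    stages.append(
        ("production", lambda: production_stage(bundle["metabolites"], bundle["inoculum_conc"]))
    )
    stages.append(
        (
            "kinetics",
            lambda: kinetics_stage(
                bundle["qpcr"], bundle["inoculum_copies"], config.inoculum_solids_g_per_ml
            ),
        )
    )
    stages.append(("qpcr", lambda: qpcr_stage(bundle["qpcr"])))
    if "isotopologs" in bundle:
        stages.append(("isotopes", lambda: isotopes_stage(bundle["isotopologs"])))

    for name, fn in stages:
        logger.info("pipeline stage: %s", name)
        try:
            results[name] = fn()
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc

    logger.info("pipeline stage: stats")
    try:
        stats_out = stats_stage(
            results["gas"], results["production"], bundle["metabolites"], config
        )
    except Exception as exc:
        raise PipelineError(f"stage 'stats' failed: {exc}") from exc
    results["stats"] = stats_out

    write_table(results["gas"], outdir / "gas_results.csv", provenance)
    write_table(results["production"], outdir / "production.csv", provenance)
    write_table(results["kinetics"], outdir / "kinetics_results.csv", provenance)
    write_table(results["qpcr"], outdir / "qpcr_results.csv", provenance)
    if "isotopes" in results:
        write_table(results["isotopes"], outdir / "enrichment.csv", provenance)
    for response, terms in stats_out["terms"].items():
        write_table(terms, outdir / f"terms_{response}.csv", provenance)
    write_table(stats_out["correlations"], outdir / "correlations.csv", provenance)
    outlier_rows = [
        {"response": resp, "row": int(i), "threshold": rep.threshold,
         "retained": bool(i in rep.retained)}
        for resp, rep in stats_out["outliers"].items()
        for i in rep.flagged
    ]
    write_table(
        pd.DataFrame(outlier_rows, columns=["response", "row", "threshold", "retained"]),
        outdir / "outliers.csv",
        provenance,
    )

    summary = {
        "package": f"rumenserial {__version__}",
        "config": asdict(config),
        "provenance": provenance,
        "stages": sorted(results.keys()),
        "n_rows": {k: (len(v) if isinstance(v, pd.DataFrame) else None) for k, v in results.items()},
        "dilution_contrast": list(stats_out["dilution_contrast"]),
    }
    (outdir / "run_summary.json").write_text(json.dumps(summary, indent=2, default=str))
    return results
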