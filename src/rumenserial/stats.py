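"""Statistical design: mixed model, unequal-spacing contrasts, outliers.

The study's factorial model has fixed effects of substrate (S), dilution
rate (D), transfer number (T) and all their interactions, with random
incubation (I), sequence nested in incubation, and the random I x S x T
and I x D x T interactions. REML estimation is delegated to statsmodels'
MixedLM (never reimplemented here); per-term significance comes from Wald
chi-square tests on the fixed-effect estimates, with significance declared
at p < 0.05 and tendencies at 0.05 <= p < 0.10.

Because the three dilution-rate levels are unequally spaced, the linear
polynomial contrast is built from the centered numeric levels reduced to
the smallest integer vector; on the inoculum-volume scale (4, 2, 1 mL)
this yields the coefficients (5, -1, -4) for low, mid, high.

Outliers are observations outside the central 99.9% of the studentized
residual distribution; outliers that cluster within a treatment cell are
treated as biological results and retained, and the rest are judged by a
leave-one-out refit: an outlier is influential only if removing it changes
which terms are significant.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from math import gcd
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats as sps

logger = logging.getLogger(__name__)

SIGNIFICANCE_P = 0.05
TENDENCY_P = 0.10
OUTLIER_ALPHA = 0.001


class ContrastError(ValueError):
    """Degenerate contrast request."""


class ModelSpecError(ValueError):
    """Model cannot be assembled from the data provided."""


@dataclass(frozen=True)
class MixedModelSpec:
    """Term structure of the factorial mixed model."""

    response: str
    fixed_terms: tuple = (
        "substrate",
        "dilution_level",
        "transfer",
        "substrate:dilution_level",
        "substrate:transfer",
        "dilution_level:transfer",
        "substrate:dilution_level:transfer",
    )
    random_terms: tuple = (
        "incubation",
        "sequence(incubation)",
        "incubation:substrate:transfer",
        "incubation:dilution_level:transfer",
    )


@dataclass
class OutlierReport:
    flagged: list
    threshold: float
    retained: list = field(default_factory=list)
    influential: dict = field(default_factory=dict)


def linear_contrast_coefficients(levels: Sequence[float]) -> tuple[int, ...]:
    """Smallest-integer linear contrast for (possibly unequal) level values.

    Levels are centered at their mean and rescaled by their greatest common
    rational divisor; the coefficients sum to zero by construction and keep
    the sign of the centered levels. The study's inoculum volumes (4, 2, 1)
    mL give (5, -1, -4) for the low, mid, and high dilution rates.
    """
    if len(levels) < 2:
        raise ContrastError("need at least 2 levels")
    fracs = [Fraction(x).limit_denominator(10**9) for x in levels]
    mean = sum(fracs, Fraction(0)) / len(fracs)
    centered = [f - mean for f in fracs]
    if all(c == 0 for c in centered):
        raise ContrastError("all levels equal: contrast is degenerate")
    denom_lcm = 1
    for c in centered:
        denom_lcm = denom_lcm * c.denominator // gcd(denom_lcm, c.denominator)
    ints = [int(c * denom_lcm) for c in centered]
    g = 0
    for v in ints:
        g = gcd(g, abs(v))
    return tuple(v // g for v in ints)


def _fixed_formula(spec: MixedModelSpec) -> str:
    def wrap(term: str) -> str:
        return ":".join(f"C({f})" for f in term.split(":"))

    return f"{spec.response} ~ " + " + ".join(wrap(t) for t in spec.fixed_terms)


def _term_wald_tests(result, design_info) -> pd.DataFrame:
    """Wald chi-square test per fixed-effect term (groups of coefficients)."""
    fe = np.asarray(result.fe_params)
    k_fe = fe.shape[0]
    cov = np.asarray(result.cov_params())[:k_fe, :k_fe]
    rows = []
    for term, sl in design_info.term_name_slices.items():
        if term == "Intercept":
            continue
        idx = np.arange(k_fe)[sl]
        contrast = np.zeros((len(idx), k_fe))
        contrast[np.arange(len(idx)), idx] = 1.0
        cb = contrast @ fe
        vcb = contrast @ cov @ contrast.T
        try:
            stat = float(cb @ np.linalg.solve(vcb, cb))
        except np.linalg.LinAlgError:
            stat = float("nan")
        df = len(idx)
        pvalue = float(sps.chi2.sf(stat, df)) if np.isfinite(stat) else float("nan")
        rows.append(
            {
                "term": term.replace("C(", "").replace(")", ""),
                "df": df,
                "wald_chi2": stat,
                "p_value": pvalue,
                "significant": bool(pvalue < SIGNIFICANCE_P),
                "tendency": bool(SIGNIFICANCE_P <= pvalue < TENDENCY_P),
            }
        )
    return pd.DataFrame(rows)


def fit_factorial_mixed_model(data: pd.DataFrame, spec: MixedModelSpec) -> dict:
    """Fit the factorial mixed model by REML and test each fixed term.

    Random effects are realised as a random incubation intercept (grouping
    variable) with variance components for sequence-in-incubation and the
    I x S x T and I x D x T interactions. Returns a dict with the fitted
    ``result``, a per-term ``terms`` table (Wald chi-square, p, significance
    and tendency flags at 0.05 and 0.10), and ``converged``.

    With a single incubation in the data the incubation random intercept is
    unidentifiable; it is dropped with a warning and sequence becomes the
    grouping factor.
    """
    needed = {spec.response, "substrate", "dilution_level", "transfer", "incubation", "sequence"}
    missing = needed - set(data.columns)
    if missing:
        raise ModelSpecError(f"data missing columns {sorted(missing)}")
    df = data.copy()
    if df[spec.response].std(ddof=0) == 0:
        # Degenerate response: every term is trivially non-significant.
        terms = pd.DataFrame(
            {
                "term": [t for t in spec.fixed_terms],
                "df": np.nan,
                "wald_chi2": np.nan,
                "p_value": 1.0,
                "significant": False,
                "tendency": False,
            }
        )
        return {"result": None, "terms": terms, "converged": True}

    formula = _fixed_formula(spec)
    vc = {"sequence": "0 + C(sequence)"}
    if "incubation:substrate:transfer" in spec.random_terms:
        vc["ixsxt"] = "0 + C(substrate):C(transfer)"
    if "incubation:dilution_level:transfer" in spec.random_terms:
        vc["ixdxt"] = "0 + C(dilution_level):C(transfer)"

    groups = "incubation"
    if df["incubation"].nunique() < 2:
        warnings.warn(
            "only one incubation present: random incubation term dropped",
            stacklevel=2,
        )
        groups = "sequence"
        vc = {k: v for k, v in vc.items() if k != "sequence"}

    model = smf.mixedlm(formula, df, groups=df[groups], vc_formula=vc or None)
    _check_rank(model)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = model.fit(reml=True)
    terms = _term_wald_tests(result, model.data.design_info)
    return {"result": result, "terms": terms, "converged": bool(result.converged)}


def _check_rank(model) -> None:
    exog = np.asarray(model.exog)
    rank = np.linalg.matrix_rank(exog)
    if rank < exog.shape[1]:
        names = model.exog_names
        # crude aliasing diagnosis: columns whose removal restores full rank
        aliased = []
        for j in range(exog.shape[1]):
            sub = np.delete(exog, j, axis=1)
            if np.linalg.matrix_rank(sub) == rank:
                aliased.append(names[j])
        raise ModelSpecError(
            f"fixed-effect design is rank deficient ({rank}/{exog.shape[1]}); "
            f"aliased columns include {aliased[:6]}"
        )


def outlier_threshold(alpha: float = OUTLIER_ALPHA, reference: str = "normal",
                      df: float | None = None) -> float:
    """Two-sided quantile bound of the studentized-residual reference.

    Standard normal by default (z = 3.2905 at alpha = 0.001); pass
    ``reference='t'`` with residual ``df`` for the externally studentized
    variant.
    """
    if reference == "normal":
        return float(sps.norm.ppf(1.0 - alpha / 2.0))
    if reference == "t":
        if df is None or df <= 0:
            raise ValueError("t reference requires positive df")
        return float(sps.t.ppf(1.0 - alpha / 2.0, df))
    raise ValueError(f"unknown reference {reference!r}")


def flag_outliers(
    residuals: Sequence[float],
    alpha: float = OUTLIER_ALPHA,
    reference: str = "normal",
    df: float | None = None,
    metadata: pd.DataFrame | None = None,
) -> OutlierReport:
    """Flag observations outside the central (1 - alpha) residual band.

    ``metadata`` (optional, one row per residual) may carry ``substrate``,
    ``dilution_level``, ``transfer``, and ``sequence`` columns; flagged
    rows that cluster with another flagged row of the same treatment cell
    in the same or a consecutive transfer, or of the same sequence, are
    marked retained as biological results rather than measurement errors.
    """
    res = np.asarray(residuals, dtype=float)
    if not np.all(np.isfinite(res)):
        raise ValueError("residuals must be finite")
    thr = outlier_threshold(alpha=alpha, reference=reference, df=df)
    flagged = list(np.flatnonzero(np.abs(res) > thr))
    retained: list = []
    if metadata is not None and len(flagged) > 1:
        meta = metadata.reset_index(drop=True)
        for i in flagged:
            for j in flagged:
                if i == j:
                    continue
                same_cell = (
                    {"substrate", "dilution_level", "transfer"} <= set(meta.columns)
                    and meta.loc[i, "substrate"] == meta.loc[j, "substrate"]
                    and meta.loc[i, "dilution_level"] == meta.loc[j, "dilution_level"]
                    and abs(int(meta.loc[i, "transfer"]) - int(meta.loc[j, "transfer"])) <= 1
                )
                same_sequence = (
                    {"sequence", "incubation"} <= set(meta.columns)
                    and meta.loc[i, "sequence"] == meta.loc[j, "sequence"]
                    and meta.loc[i, "incubation"] == meta.loc[j, "incubation"]
                )
                if same_cell or same_sequence:
                    retained.append(i)
                    break
    return OutlierReport(flagged=flagged, threshold=thr, retained=sorted(set(retained)))


def leave_one_out_influence(
    data: pd.DataFrame, spec: MixedModelSpec, flagged_rows: Sequence[int]
) -> dict:
    """Refit with each flagged row removed; report which rows are influential.

    A row is influential when its removal changes the set of significant
    (p < 0.05) fixed-effect terms. Rows found non-influential should be
    retained in the final analysis.
    """
    base = fit_factorial_mixed_model(data, spec)
    base_sig = set(base["terms"].loc[base["terms"]["significant"], "term"])
    influential: dict[int, bool] = {}
    for row in flagged_rows:
        reduced = data.drop(index=data.index[row])
        fit = fit_factorial_mixed_model(reduced, spec)
        sig = set(fit["terms"].loc[fit["terms"]["significant"], "term"])
        influential[int(row)] = sig != base_sig
    return influential


def pearson_correlations(data: pd.DataFrame, pairs: Sequence[tuple[str, str]]) -> pd.DataFrame:
    """Pearson r with two-sided p for each (x, y) column pair.

    Rows with missing values are dropped pairwise; pairs with fewer than 3
    complete observations or zero variance are reported with NaN.
    """
    rows = []
    for x, y in pairs:
        sub = data[[x, y]].dropna()
        n = len(sub)
        if n < 3 or sub[x].std(ddof=0) == 0 or sub[y].std(ddof=0) == 0:
            r, p = np.nan, np.nan
        else:
            r, p = sps.pearsonr(sub[x], sub[y])
        rows.append({"x": x, "y": y, "n": n, "r": r, "p_value": p})
    return pd.DataFrame(rows)
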