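"""Contrast construction, mixed-model term tests, outliers, correlations."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rumenserial.stats import (
    ContrastError,
    MixedModelSpec,
    ModelSpecError,
    fit_factorial_mixed_model,
    flag_outliers,
    leave_one_out_influence,
    linear_contrast_coefficients,
    outlier_threshold,
    pearson_correlations,
)


@pytest.mark.parametrize(
    "levels, expected",
    [
        ([4, 2, 1], (5, -1, -4)),  # inoculum volumes, low -> high dilution
        ([1, 2, 3], (-1, 0, 1)),  # equally spaced
        ([5 / 36, 10 / 36, 20 / 36], (-4, -1, 5)),  # the h^-1 rate scale
        ([0.14, 0.28, 0.56], (-4, -1, 5)),
    ],
)
def test_linear_contrast_coefficients(levels, expected):
    assert linear_contrast_coefficients(levels) == expected


def test_contrast_sums_to_zero_and_degenerate_error():
    assert sum(linear_contrast_coefficients([4, 2, 1])) == 0
    with pytest.raises(ContrastError, match="degenerate"):
        linear_contrast_coefficients([2.0, 2.0, 2.0])
    with pytest.raises(ContrastError):
        linear_contrast_coefficients([1.0])


@given(
    a=st.integers(1, 20),
    b=st.integers(-50, 50),
)
@settings(max_examples=50, deadline=None)
def test_contrast_affine_invariance(a, b):
    """Affine rescaling of the levels leaves the integer contrast unchanged."""
    base = linear_contrast_coefficients([4, 2, 1])
    transformed = linear_contrast_coefficients([a * 4 + b, a * 2 + b, a * 1 + b])
    assert transformed == base


def _design_frame(rng, effect=0.0, n_incubations=2, n_transfers=8):
    rows = []
    for inc in range(1, n_incubations + 1):
        for sub in ("high_forage", "high_concentrate"):
            for dil in ("low", "mid", "high"):
                for seq in (1, 2, 3):
                    for t in range(1, n_transfers + 1):
                        y = effect * (sub == "high_forage") + rng.normal(0, 1)
                        rows.append(
                            dict(incubation=inc, substrate=sub, dilution_level=dil,
                                 sequence=seq, transfer=t, y=y)
                        )
    return pd.DataFrame(rows)


def test_mixed_model_detects_injected_substrate_effect():
    """Over 20 seeds, a 3-SD substrate shift is declared significant at
    least 18 times, and the (null) three-way interaction stays quiet."""
    spec = MixedModelSpec(response="y")
    s_hits, sdt_hits = 0, 0
    for seed in range(20):
        df = _design_frame(np.random.default_rng(seed), effect=3.0, n_transfers=4)
        fit = fit_factorial_mixed_model(df, spec)
        terms = fit["terms"].set_index("term")
        s_hits += bool(terms.loc["substrate", "significant"])
        sdt_hits += bool(terms.loc["substrate:dilution_level:transfer", "significant"])
    assert s_hits >= 18
    assert sdt_hits <= 4  # ~5% type-I on the null interaction


def test_mixed_model_constant_response_has_no_significant_terms():
    df = _design_frame(np.random.default_rng(0), n_transfers=2)
    df["y"] = 3.14
    fit = fit_factorial_mixed_model(df, MixedModelSpec(response="y"))
    assert not fit["terms"]["significant"].any()


def test_mixed_model_single_incubation_drops_random_term_with_warning():
    df = _design_frame(np.random.default_rng(1), effect=3.0, n_incubations=1, n_transfers=4)
    with pytest.warns(UserWarning, match="incubation"):
        fit = fit_factorial_mixed_model(df, MixedModelSpec(response="y"))
    assert fit["terms"].set_index("term").loc["substrate", "significant"]


def test_mixed_model_rank_deficiency_is_reported():
    df = _design_frame(np.random.default_rng(2), n_transfers=2)
    # confound dilution level with substrate -> aliased columns
    df["dilution_level"] = np.where(df["substrate"] == "high_forage", "low", "high")
    with pytest.raises(ModelSpecError, match="rank deficient"):
        fit_factorial_mixed_model(df, MixedModelSpec(response="y"))


def test_mixed_model_missing_column():
    with pytest.raises(ModelSpecError, match="missing"):
        fit_factorial_mixed_model(pd.DataFrame({"y": [1.0]}), MixedModelSpec(response="y"))


def test_outlier_threshold_normal_and_t():
    assert outlier_threshold(0.001) == pytest.approx(3.2905, abs=1e-4)
    assert outlier_threshold(0.001, reference="t", df=30) > outlier_threshold(0.001)


def test_flag_outliers_examples():
    assert flag_outliers(np.zeros(100)).flagged == []
    rng = np.random.default_rng(3)
    res = rng.normal(0, 1, 200)
    res = np.clip(res, -3.0, 3.0)  # keep the background under the bound
    res[17] = 3.5
    report = flag_outliers(res)
    assert report.flagged == [17]
    assert flag_outliers(np.array([3.0, 0.0, -3.0])).flagged == []


def test_flag_outliers_clustered_by_treatment_are_retained():
    res = np.zeros(10)
    res[[2, 3]] = 4.0
    meta = pd.DataFrame(
        {
            "substrate": ["high_forage"] * 10,
            "dilution_level": ["low"] * 10,
            "transfer": [1, 2, 3, 4, 5, 6, 7, 8, 1, 2],
            "sequence": [1] * 10,
            "incubation": [1] * 10,
        }
    )
    report = flag_outliers(res, metadata=meta)
    assert report.flagged == [2, 3]
    assert report.retained == [2, 3]  # same cell, consecutive transfers


def test_leave_one_out_refit_on_strong_effect_is_not_influential():
    """With a 3-SD substrate shift and every null term far from the 0.05
    boundary, no single observation flips the significance pattern, so the
    leave-one-out rule retains the flagged rows."""
    df = _design_frame(np.random.default_rng(1), effect=3.0, n_transfers=2)
    influential = leave_one_out_influence(df, MixedModelSpec(response="y"), [0, 7])
    assert set(influential) == {0, 7}
    assert not any(influential.values())


def test_pearson_correlations():
    rng = np.random.default_rng(5)
    x = rng.normal(0, 1, 200)
    df = pd.DataFrame({"x": x, "y": x, "z": -2 * x + rng.normal(0, 1e-6, 200),
                       "c": np.ones(200)})
    out = pearson_correlations(df, [("x", "y"), ("x", "z"), ("x", "c")]).set_index(["x", "y"])
    assert out.loc[("x", "y"), "r"] == pytest.approx(1.0)
    assert out.loc[("x", "z"), "r"] == pytest.approx(-1.0, abs=1e-6)
    assert np.isnan(out.loc[("x", "c"), "r"])  # zero variance -> missing


def test_pearson_independent_samples_are_uncorrelated():
    hits = 0
    for seed in range(40):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame({"a": rng.normal(0, 1, 1000), "b": rng.normal(0, 1, 1000)})
        r = pearson_correlations(df, [("a", "b")])["r"].iloc[0]
        hits += abs(r) < 0.1
    assert hits >= 38  # >= 95% of seeds
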