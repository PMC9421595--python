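"""INT, regression fits, amyloid dichotomization, and the scan."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import ndtri
from scipy.stats import t as t_dist

from tauprs.association import (
    MEDIATOR_COLUMN,
    bonferroni_flag,
    dichotomize_ab,
    inverse_normal_transform,
    linear_assoc,
    logistic_assoc,
    scan,
)
from tauprs.prs import standardize
from tauprs.synthetic import (
    CausalConfig,
    simulate_cohort,
)
from tauprs import score


# ----------------------------------------------------------------------- INT


def test_int_three_values_closed_form():
    out = inverse_normal_transform([10.0, -3.0, 5.0])
    # Blom offsets (r - 3/8)/(n + 1/4): ranks 3, 1, 2 of n=3
    hi = ndtri(2.625 / 3.25)
    assert out[1] == pytest.approx(-hi, abs=1e-12)
    assert out[2] == pytest.approx(0.0, abs=1e-12)
    assert out[0] == pytest.approx(hi, abs=1e-12)


def test_int_preserves_missing_and_ranks():
    x = [3.0, np.nan, 1.0, 2.0]
    out = inverse_normal_transform(x)
    assert np.isnan(out[1])
    assert out[2] < out[3] < out[0]


def test_int_ties_get_average_rank():
    out = inverse_normal_transform([1.0, 1.0, 5.0])
    assert out[0] == out[1] < out[2]


def test_int_identical_values_error():
    with pytest.raises(ValueError, match="distinct"):
        inverse_normal_transform([2.0, 2.0, 2.0])


@settings(derandomize=True, deadline=None, max_examples=40)
@given(
    st.lists(
        st.floats(-1e6, 1e6, allow_nan=False), min_size=3, max_size=60, unique=True
    )
)
def test_int_monotone_and_centered(values):
    x = np.asarray(values)
    out = inverse_normal_transform(x)
    order = np.argsort(x)
    assert np.all(np.diff(out[order]) > 0)
    assert abs(out.mean()) < 1e-10


# ------------------------------------------------------------------- linear


def test_linear_exact_fit():
    x = np.array([-1.5, -0.5, 0.5, 1.5, 0.0, 1.0])
    res = linear_assoc(2.0 * x, x)
    assert res.beta == pytest.approx(2.0, abs=1e-12)
    assert res.se == pytest.approx(0.0, abs=1e-10)


def test_linear_matches_normal_equations_oracle():
    rng = np.random.default_rng(5)
    n = 6
    x = rng.normal(size=n)
    z = rng.normal(size=n)
    y = 0.7 * x - 0.2 * z + rng.normal(size=n)
    res = linear_assoc(y, x, covariates=pd.DataFrame({"z": z}))
    X = np.column_stack([np.ones(n), x, z])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    df = n - 3
    sigma2 = resid @ resid / df
    cov = sigma2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(cov))
    p = 2 * t_dist.sf(abs(beta[1] / se[1]), df)
    assert res.beta == pytest.approx(beta[1], abs=1e-10)
    assert res.se == pytest.approx(se[1], abs=1e-10)
    assert res.p_value == pytest.approx(p, abs=1e-10)


def test_linear_collinear_design_named():
    x = np.arange(8.0)
    cov = pd.DataFrame({"double_x": 2 * x})
    with pytest.raises(ValueError, match="collinear"):
        linear_assoc(x + 1.0, x, covariates=cov)


def test_linear_insufficient_rows():
    with pytest.raises(ValueError, match="complete cases"):
        linear_assoc([1.0, 2.0], [0.1, 0.2])


# ------------------------------------------------------------------ logistic


def test_logistic_matches_log_odds_ratio():
    # 2x2 table: exposure 0: 30/70 events; exposure 1: 60/40
    y = np.r_[np.ones(30), np.zeros(70), np.ones(60), np.zeros(40)]
    x = np.r_[np.zeros(100), np.ones(100)]
    res = logistic_assoc(y, x)
    lor = np.log((60 / 40) / (30 / 70))
    assert res.beta == pytest.approx(lor, abs=1e-6)


def test_logistic_single_class_errors():
    with pytest.raises(ValueError, match="both classes"):
        logistic_assoc(np.ones(20), np.random.default_rng(0).normal(size=20))


def test_logistic_perfect_separation_errors():
    x = np.linspace(-2, 2, 40)
    y = (x > 0).astype(float)
    with pytest.raises(ValueError, match="separation"):
        logistic_assoc(y, x)


def test_logistic_null_consistency():
    rng = np.random.default_rng(11)
    x = rng.normal(size=4000)
    y = rng.integers(0, 2, 4000).astype(float)
    res = logistic_assoc(y, x)
    assert abs(res.beta) < 0.1


def test_logistic_permutation_calibration():
    rng = np.random.default_rng(13)
    y = rng.integers(0, 2, 300).astype(float)
    x = rng.normal(size=300)
    pvals = []
    for _ in range(200):
        pvals.append(logistic_assoc(y, rng.permutation(x)).p_value)
    pvals = np.asarray(pvals)
    assert 0.35 < pvals.mean() < 0.65
    assert 0.005 <= (pvals < 0.05).mean() <= 0.12


# -------------------------------------------------------------- dichotomizer


def test_dichotomize_boundary_and_arithmetic():
    status = dichotomize_ab([91.0, 45.0], [1000.0, 1000.0], cutoff=0.091)
    assert status[0] == 0.0  # exactly at cutoff: non-pathologic
    assert status[1] == 1.0  # 0.045 < 0.091
    flipped = dichotomize_ab(
        [91.0, 45.0], [1000.0, 1000.0], cutoff=0.091, pathologic_low=False
    )
    assert flipped.tolist() == [0.0, 0.0]


def test_dichotomize_all_above_cutoff():
    status = dichotomize_ab([100.0, 120.0], [1000.0, 1000.0])
    assert not status.any()


def test_dichotomize_nonpositive_ab40_errors():
    with pytest.raises(ValueError, match="positive"):
        dichotomize_ab([50.0], [0.0])


# ---------------------------------------------------------------------- scan


def test_bonferroni_definition():
    m = 7
    assert bonferroni_flag(0.05 / 7 - 1e-12, m)
    assert not bonferroni_flag(0.05 / 7 + 1e-12, m)


@pytest.fixture(scope="module")
def planted_cohort():
    # independent-path effects only: the PRS-tau association should be
    # essentially unchanged by mediator adjustment
    from tauprs.prs import threshold_series

    syn = simulate_cohort(
        2000, 50, n_dependent=0, n_independent=15, seed=2024
    )
    models = threshold_series(syn.sumstats, syn.panel)
    usable = [m for m in models if m.n_variants > 0]
    return syn, usable


def test_scan_shape_and_bonferroni(planted_cohort):
    syn, models = planted_cohort
    out = scan(models, syn.cohort)
    ok = out[out["status"] == "ok"]
    assert set(out["model"]) == {m.label for m in models}
    expected = ok["p"] * len(models) < 0.05
    assert (ok["significant"] == expected).all()


def test_scan_independent_effect_survives_adjustment(planted_cohort):
    syn, models = planted_cohort
    unadj = scan(models, syn.cohort, adjust_for_mediator=False)
    adj = scan(models, syn.cohort, adjust_for_mediator=True)
    key = ["model", "biomarker"]
    merged = unadj.merge(adj, on=key, suffixes=("_un", "_ad"))
    row = merged[(merged["model"] == "PRS7") & (merged["biomarker"] == "p_tau181")]
    ratio = float(row["beta_ad"].iloc[0] / row["beta_un"].iloc[0])
    assert row["p_un"].iloc[0] < 1e-6
    assert ratio > 0.8


def test_scan_adjusted_skips_ratio_biomarker(planted_cohort):
    syn, models = planted_cohort
    adj = scan(models, syn.cohort, adjust_for_mediator=True)
    ratio_rows = adj[adj["biomarker"] == "abeta_ratio"]
    assert (ratio_rows["status"] == "skipped: outcome equals mediator").all()


def test_scan_null_biomarker_not_significant(planted_cohort):
    syn, models = planted_cohort
    out = scan(models, syn.cohort)
    nfl = out[(out["biomarker"] == "nfl") & (out["status"] == "ok")]
    assert not nfl["significant"].any()


def test_scan_small_stratum_skipped(planted_cohort):
    syn, models = planted_cohort
    cohort = syn.cohort.copy()
    cohort["stratum"] = "big"
    cohort.loc[:4, "stratum"] = "tiny"
    out = scan(models, cohort, strata="stratum")
    tiny = out[out["stratum"] == "tiny"]
    assert (tiny["status"] == "skipped: insufficient n").all()


def test_scan_stratified_by_diagnosis(planted_cohort):
    syn, models = planted_cohort
    out = scan(
        models[:2], syn.cohort, strata="diagnosis", biomarkers=["p_tau181"]
    )
    assert set(out["stratum"]) == {"CU", "MCI", "AD"}
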