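"""Biomarker transformation and covariate-adjusted association scans.

Continuous CSF biomarkers are rank-based inverse-normal transformed
(Blom offset) and regressed on each standardized PRS with the standard
covariate set (age, sex, education, MMSE, APOE e2/e4 counts — dropped
for APOE-inclusive models — and the top genotype PCs).  The bimodal
Abeta42/40 ratio is dichotomized into amyloid status and modelled by
logistic regression.  Each biomarker's family of PRS models is
Bonferroni-corrected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import ndtri
from scipy.stats import rankdata

CONTINUOUS_BIOMARKERS = ["t_tau", "p_tau181", "abeta38", "abeta40", "abeta42", "nfl"]
RATIO_BIOMARKER = "abeta_ratio"
MEDIATOR_COLUMN = "abeta_status"
BASE_COVARIATES = ["age", "sex", "education", "mmse"]
APOE_COVARIATES = ["apoe_e4", "apoe_e2"]


@dataclass
class AssociationResult:
    """One fitted PRS term: effect size, uncertainty, and multiplicity flag."""

    model_label: str
    biomarker: str
    beta: float
    se: float
    statistic: float
    p_value: float
    n: int
    family: str  # "linear" | "logistic"
    adjusted_for_mediator: bool = False
    bonferroni_m: int = 1
    bonferroni_significant: bool = False
    stratum: str = ""
    status: str = "ok"


def inverse_normal_transform(values, offset: float = 0.375) -> np.ndarray:
    """Rank-based inverse normal transform.

    A non-missing value with (average-tie) rank r among n maps to
    Phi^-1((r - offset) / (n - 2*offset + 1)); the default offset 3/8
    is the Blom convention.  Missing entries stay missing and the map
    is monotone on the rest.
    """
    x = np.asarray(values, dtype=float)
    out = np.full(x.shape, np.nan)
    mask = ~np.isnan(x)
    v = x[mask]
    if np.unique(v).size < 2:
        raise ValueError("need >= 2 distinct non-missing values for INT")
    n = v.size
    ranks = rankdata(v, method="average")
    out[mask] = ndtri((ranks - offset) / (n - 2.0 * offset + 1.0))
    return out


def dichotomize_ab(ab42, ab40, cutoff: float = 0.091, pathologic_low: bool = True):
    """Amyloid status from the Abeta42/40 ratio at a cutoff.

    Default direction: ratio strictly BELOW the cutoff is pathologic
    (the standard CSF convention); ``pathologic_low=False`` flips to a
    strictly-above rule.  A ratio exactly at the cutoff is
    non-pathologic under either direction.
    """
    ab42 = np.asarray(ab42, dtype=float)
    ab40 = np.asarray(ab40, dtype=float)
    if np.any(ab40 <= 0):
        raise ValueError("Abeta1-40 concentrations must be positive")
    ratio = ab42 / ab40
    status = ratio < cutoff if pathologic_low else ratio > cutoff
    return status.astype(float)


def _name_collinear(X: pd.DataFrame) -> list:
    # pivoted QR: columns pivoted past the numerical rank are the offenders
    from scipy.linalg import qr as scipy_qr

    _, r, piv = scipy_qr(X.to_numpy(), mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    return [X.columns[j] for j in piv[rank:]]


def _design(prs, covariates) -> pd.DataFrame:
    X = pd.DataFrame({"prs": np.asarray(prs, dtype=float)})
    if covariates is not None:
        cov = pd.DataFrame(covariates).reset_index(drop=True)
        cov.columns = [str(c) for c in cov.columns]
        X = pd.concat([X, cov.astype(float)], axis=1)
    X.insert(0, "const", 1.0)
    return X


def linear_assoc(
    y, prs, covariates=None, model_label: str = "", biomarker: str = ""
) -> AssociationResult:
    """OLS of a (transformed) biomarker on a standardized PRS.

    Complete cases only; reports the PRS term's beta/SE and two-sided
    t-test p-value.
    """
    y = np.asarray(y, dtype=float)
    X = _design(prs, covariates)
    mask = ~np.isnan(y) & ~X.isna().any(axis=1).to_numpy()
    y, X = y[mask], X.loc[mask]
    if len(y) < X.shape[1] + 2:
        raise ValueError(f"only {len(y)} complete cases for {X.shape[1]} predictors")
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError(f"rank-deficient design; collinear columns: {_name_collinear(X)}")
    fit = sm.OLS(y, X).fit()
    return AssociationResult(
        model_label=model_label,
        biomarker=biomarker,
        beta=float(fit.params["prs"]),
        se=float(fit.bse["prs"]),
        statistic=float(fit.tvalues["prs"]),
        p_value=float(fit.pvalues["prs"]),
        n=int(len(y)),
        family="linear",
    )


def logistic_assoc(
    y, prs, covariates=None, model_label: str = "", biomarker: str = ""
) -> AssociationResult:
    """Maximum-likelihood logistic regression of a binary status on a PRS.

    Newton iterations; perfect separation raises with advice rather
    than returning a diverged fit.
    """
    y = np.asarray(y, dtype=float)
    X = _design(prs, covariates)
    mask = ~np.isnan(y) & ~X.isna().any(axis=1).to_numpy()
    y, X = y[mask], X.loc[mask]
    if len(y) < X.shape[1] + 2:
        raise ValueError(f"only {len(y)} complete cases for {X.shape[1]} predictors")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("binary outcome must contain both classes")
    try:
        fit = sm.Logit(y, X).fit(method="newton", tol=1e-8, maxiter=200, disp=0)
    except Exception as exc:  # statsmodels PerfectSeparation / convergence
        raise ValueError(
            "perfect separation or non-convergence in logistic fit; "
            "penalized regression is out of scope"
        ) from exc
    if np.abs(fit.params).max() > 50:
        raise ValueError(
            "diverging logistic coefficients (perfect separation suspected)"
        )
    return AssociationResult(
        model_label=model_label,
        biomarker=biomarker,
        beta=float(fit.params["prs"]),
        se=float(fit.bse["prs"]),
        statistic=float(fit.tvalues["prs"]),
        p_value=float(fit.pvalues["prs"]),
        n=int(len(y)),
        family="logistic",
    )


def covariate_matrix(
    cohort: pd.DataFrame, include_apoe: bool = True, n_pcs: int = 10
) -> pd.DataFrame:
    """Standard covariate design (no intercept): demographics, optional
    APOE allele counts, and whatever PC1..PCn columns are present."""
    cols = list(BASE_COVARIATES)
    if include_apoe:
        cols += APOE_COVARIATES
    cols += [f"PC{i}" for i in range(1, n_pcs + 1) if f"PC{i}" in cohort.columns]
    missing = [c for c in cols if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort table missing covariate columns: {missing}")
    return cohort[cols].astype(float)


def bonferroni_flag(p: float, m: int, alpha: float = 0.05) -> bool:
    return p * m < alpha


def scan(
    models,
    cohort: pd.DataFrame,
    adjust_for_mediator: bool = False,
    strata: str | None = None,
    biomarkers=None,
    n_pcs: int = 10,
    ab_cutoff: float = 0.091,
    pathologic_low: bool = True,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Association scan: every (PRS model, biomarker[, stratum]) fit.

    Continuous biomarkers are INT-transformed and fitted by OLS; the
    Abeta42/40 ratio is dichotomized and fitted by logistic regression
    (skipped under mediator adjustment, where the dichotomized ratio is
    itself the adjustment variable).  Bonferroni families are the PRS
    models per biomarker (and stratum).
    """
    if biomarkers is None:
        biomarkers = CONTINUOUS_BIOMARKERS + [RATIO_BIOMARKER]
    cohort = cohort.reset_index(drop=True)
    m = len(models)
    groups = [("", cohort)] if strata is None else [
        (str(level), g) for level, g in cohort.groupby(strata, sort=True)
    ]
    rows = []
    for label_stratum, sub in groups:
        sub = sub.reset_index(drop=True)
        rowsel = cohort.index if strata is None else cohort[strata].astype(str).eq(
            label_stratum
        ).to_numpy().nonzero()[0]
        for model in models:
            cov = covariate_matrix(
                sub, include_apoe=not model.includes_apoe, n_pcs=n_pcs
            )
            if adjust_for_mediator:
                cov = cov.assign(**{MEDIATOR_COLUMN: sub[MEDIATOR_COLUMN].to_numpy()})
            prs_scores = np.asarray(model.scores)[rowsel]
            for biomarker in biomarkers:
                record = {
                    "model": model.label,
                    "biomarker": biomarker,
                    "stratum": label_stratum,
                    "adjusted_for_mediator": adjust_for_mediator,
                    "bonferroni_m": m,
                }
                if biomarker == RATIO_BIOMARKER and adjust_for_mediator:
                    record.update(status="skipped: outcome equals mediator")
                    rows.append(record)
                    continue
                try:
                    if biomarker == RATIO_BIOMARKER:
                        yb = dichotomize_ab(
                            sub["abeta42"],
                            sub["abeta40"],
                            cutoff=ab_cutoff,
                            pathologic_low=pathologic_low,
                        )
                        res = logistic_assoc(
                            yb, prs_scores, cov, model.label, biomarker
                        )
                    else:
                        yt = inverse_normal_transform(sub[biomarker])
                        res = linear_assoc(
                            yt, prs_scores, cov, model.label, biomarker
                        )
                except ValueError as exc:
                    msg = str(exc)
                    status = (
                        "skipped: insufficient n"
                        if "complete cases" in msg
                        else f"skipped: {msg}"
                    )
                    record.update(status=status)
                    rows.append(record)
                    continue
                record.update(
                    beta=res.beta,
                    se=res.se,
                    statistic=res.statistic,
                    p=res.p_value,
                    n=res.n,
                    family=res.family,
                    significant=bonferroni_flag(res.p_value, m, alpha),
                    status="ok",
                )
                rows.append(record)
    columns = [
        "model", "biomarker", "stratum", "family", "n", "beta", "se",
        "statistic", "p", "adjusted_for_mediator", "bonferroni_m",
        "significant", "status",
    ]
    return pd.DataFrame(rows).reindex(columns=columns)
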