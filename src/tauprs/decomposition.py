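"""Heuristic decomposition of a PRS into mediator-independent and
exclusive mediator-dependent variant subsets.

Given a full PRS (variant ids + weights), a binary mediator (amyloid
status), and a continuous outcome (INT-transformed tau), the procedure:

1. *Leave-one-out scan* — for every variant, rebuild the PRS from the
   remaining n-1 variants and record the p-value of its association
   with the mediator; variants whose removal strengthens the
   PRS-mediator association contribute little to the mediator path.
2. *Ranking* — order variants by that leave-one-out p-value (ascending
   by default: the variants most dispensable for the mediator path come
   first).
3. *Nested profile* — for k = 1..n, build the top-k PRS and fit the
   outcome association unadjusted and mediator-adjusted, plus a
   bootstrap mediation (reduced resample count for tractability).
4. *Independence screen* — candidate k's show no significant mediation
   yet a significant outcome association both with and without
   mediator adjustment; the optimal mediator-independent subset is the
   candidate whose effect size changes least under adjustment.
5. *Exclusive dependent subset* — the complement of the union of all
   candidate subsets: variants in no mediator-independent PRS.  Its
   PRS is validated against the mediator and the outcome (expected
   pattern: the association collapses under mediator adjustment),
   and both subset PRSs are entered jointly in a two-score model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._stats import design_with_intercept, ols
from .genotypes import GenotypePanel
from .mediation import MediationResult, mediate
from .prs import standardize


@dataclass
class LooRecord:
    """Mediator-association p-value of the PRS with one variant left out."""

    variant_id: str
    p_value: float
    direction: str  # "strengthened" | "weakened" (vs the full PRS)


@dataclass
class NestedProfile:
    """Per-k fits along the ranked variant list (row k = top-k PRS)."""

    frame: pd.DataFrame
    ranked_ids: list

    def top_k(self, k: int) -> list:
        return self.ranked_ids[:k]


@dataclass
class IndependenceSelection:
    candidate_ks: list
    optimal_k: int | None
    optimal_subset: list


@dataclass
class DecompositionResult:
    loo_records: list
    n_strengthened: int
    n_weakened: int
    ranked_ids: list
    profile: NestedProfile
    selection: IndependenceSelection
    exclusive_dependent_subset: list
    independent_validation: dict | None
    dependent_validation: dict | None
    joint: dict | None

    @property
    def optimal_independent_subset(self) -> list:
        return self.selection.optimal_subset


def _cov_array(covariates):
    if covariates is None:
        return None
    return np.asarray(pd.DataFrame(covariates), dtype=float)


def _prs_term_fit(scores, response, cov, extra=None):
    """beta/se/p of the (standardized) score term in an OLS fit."""
    X = design_with_intercept(scores, extra, cov)
    beta, se, _, p, _ = ols(X, np.asarray(response, dtype=float))
    return float(beta[1]), float(se[1]), float(p[1])


def _weighted_matrix(panel: GenotypePanel, variant_ids, weights):
    d = panel.imputed()
    cols = [panel.column_index(v) for v in variant_ids]
    w = np.array([weights[v] for v in variant_ids], dtype=float)
    return d[:, cols] * w


def loo_scan(
    variant_ids, weights, panel: GenotypePanel, mediator, covariates=None
) -> list:
    """Leave-one-out mediator-association scan over the full PRS.

    Returns one :class:`LooRecord` per variant.  A variant with weight
    zero leaves the score unchanged, so its record equals the full-PRS
    p-value exactly (direction "weakened" by the tie rule).
    """
    variant_ids = list(variant_ids)
    if len(variant_ids) < 2:
        raise ValueError("leave-one-out needs a PRS with >= 2 variants")
    mediator = np.asarray(mediator, dtype=float)
    cov = _cov_array(covariates)
    contrib = _weighted_matrix(panel, variant_ids, weights)
    full_raw = contrib.sum(axis=1)
    _, _, p_full = _prs_term_fit(standardize(full_raw), mediator, cov)
    records = []
    for j, vid in enumerate(variant_ids):
        loo_raw = full_raw - contrib[:, j]
        sd = loo_raw.std()
        if sd == 0:
            p_loo = 1.0
        else:
            _, _, p_loo = _prs_term_fit(standardize(loo_raw), mediator, cov)
        direction = "strengthened" if p_loo < p_full else "weakened"
        records.append(LooRecord(variant_id=vid, p_value=float(p_loo), direction=direction))
    return records


def rank_variants(records, order: str = "ascending") -> list:
    """Total order of variants by leave-one-out p-value.

    Ties break by variant id (lexicographic), so the ranking is
    deterministic across runs.  ``descending`` is the mirror path used
    to seek mediator-dependent subsets first.
    """
    if not records:
        raise ValueError("no records to rank")
    if order not in ("ascending", "descending"):
        raise ValueError("order must be 'ascending' or 'descending'")
    reverse = order == "descending"
    keyed = sorted(
        records,
        key=lambda r: ((-r.p_value if reverse else r.p_value), str(r.variant_id)),
    )
    return [r.variant_id for r in keyed]


def nested_profile(
    ranked_ids,
    weights,
    panel: GenotypePanel,
    outcome,
    mediator,
    covariates=None,
    n_boot_screen: int = 200,
    seed: int = 0,
) -> NestedProfile:
    """Fits for every top-k PRS along the ranked list.

    Per k: outcome association unadjusted and mediator-adjusted, and a
    bootstrap mediation with ``n_boot_screen`` resamples.  A k-PRS with
    zero variance (possible at small k) is flagged skipped.
    """
    ranked_ids = list(ranked_ids)
    outcome = np.asarray(outcome, dtype=float)
    mediator = np.asarray(mediator, dtype=float)
    cov = _cov_array(covariates)
    contrib = _weighted_matrix(panel, ranked_ids, weights)
    cumulative = np.cumsum(contrib, axis=1)
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(len(ranked_ids))]
    rows = []
    for k in range(1, len(ranked_ids) + 1):
        raw = cumulative[:, k - 1]
        row = {"k": k, "variant_added": ranked_ids[k - 1], "status": "ok"}
        if raw.std() == 0:
            row.update(status="skipped: zero-variance PRS")
            rows.append(row)
            continue
        scores = standardize(raw)
        b_un, se_un, p_un = _prs_term_fit(scores, outcome, cov)
        b_ad, se_ad, p_ad = _prs_term_fit(scores, outcome, cov, extra=mediator)
        med = mediate(
            scores,
            mediator,
            outcome,
            covariates=cov,
            n_boot=n_boot_screen,
            seed=child_seeds[k - 1],
        )
        row.update(
            beta_unadj=b_un, se_unadj=se_un, p_unadj=p_un,
            beta_adj=b_ad, se_adj=se_ad, p_adj=p_ad,
            indirect=med.indirect, ci_low=med.ci_low, ci_high=med.ci_high,
            mediation_p=med.p_value, proportion_mediated=med.proportion_mediated,
        )
        rows.append(row)
    return NestedProfile(frame=pd.DataFrame(rows), ranked_ids=ranked_ids)


def select_independent(profile: NestedProfile, alpha: float = 0.05) -> IndependenceSelection:
    """Screen the nested profile for mediator-independent candidates.

    A row qualifies when the bootstrap mediation p >= alpha AND the
    outcome association is significant (< alpha) both unadjusted and
    mediator-adjusted.  The optimal subset minimizes |beta_adj -
    beta_unadj|; ties go to the larger k.  An empty candidate list is a
    valid outcome, not an error.
    """
    f = profile.frame
    ok = f[f["status"] == "ok"]
    cand = ok[
        (ok["mediation_p"] >= alpha)
        & (ok["p_unadj"] < alpha)
        & (ok["p_adj"] < alpha)
    ]
    ks = cand["k"].astype(int).tolist()
    if not ks:
        return IndependenceSelection(candidate_ks=[], optimal_k=None, optimal_subset=[])
    delta = (cand["beta_adj"] - cand["beta_unadj"]).abs()
    # ties -> larger k: sort by (delta, -k) and take the head
    best = cand.assign(_d=delta).sort_values(["_d", "k"], ascending=[True, False]).iloc[0]
    k_opt = int(best["k"])
    return IndependenceSelection(
        candidate_ks=ks, optimal_k=k_opt, optimal_subset=profile.top_k(k_opt)
    )


def exclusive_complement(full_variants, candidate_sets) -> list:
    """Variants in no candidate subset (order of the full list kept)."""
    full_variants = list(full_variants)
    union = set()
    for s in candidate_sets:
        s = set(s)
        if not s.issubset(full_variants):
            raise ValueError("candidate set not contained in full variant set")
        union |= s
    return [v for v in full_variants if v not in union]


def validate_subset(
    variant_ids,
    weights,
    panel: GenotypePanel,
    outcome,
    mediator,
    covariates=None,
    n_boot: int = 1000,
    seed: int = 0,
) -> dict:
    """Three reference fits for a subset PRS, plus full bootstrap mediation:
    mediator association, outcome unadjusted, outcome mediator-adjusted."""
    variant_ids = list(variant_ids)
    if not variant_ids:
        raise ValueError("empty variant subset")
    cov = _cov_array(covariates)
    raw = _weighted_matrix(panel, variant_ids, weights).sum(axis=1)
    scores = standardize(raw)
    mediator = np.asarray(mediator, dtype=float)
    outcome = np.asarray(outcome, dtype=float)
    a_b, a_se, a_p = _prs_term_fit(scores, mediator, cov)
    b_un, se_un, p_un = _prs_term_fit(scores, outcome, cov)
    b_ad, se_ad, p_ad = _prs_term_fit(scores, outcome, cov, extra=mediator)
    med = mediate(scores, mediator, outcome, covariates=cov, n_boot=n_boot, seed=seed)
    return {
        "n_variants": len(variant_ids),
        "mediator": {"beta": a_b, "se": a_se, "p": a_p},
        "outcome_unadjusted": {"beta": b_un, "se": se_un, "p": p_un},
        "outcome_adjusted": {"beta": b_ad, "se": se_ad, "p": p_ad},
        "mediation": med.to_dict(),
    }


def joint_model(
    independent_subset,
    dependent_subset,
    weights,
    panel: GenotypePanel,
    outcome,
    mediator,
    covariates=None,
) -> dict:
    """Both subset PRSs entered simultaneously as outcome predictors.

    Reported unadjusted and mediator-adjusted; the expected planted
    pattern is that only the dependent term collapses on adjustment.
    """
    ind = list(independent_subset)
    dep = list(dependent_subset)
    if not ind or not dep:
        raise ValueError("both subsets must be non-empty")
    if set(ind) & set(dep):
        raise ValueError("subsets overlap; they must be disjoint")
    cov = _cov_array(covariates)
    outcome = np.asarray(outcome, dtype=float)
    mediator = np.asarray(mediator, dtype=float)
    s_ind = standardize(_weighted_matrix(panel, ind, weights).sum(axis=1))
    s_dep = standardize(_weighted_matrix(panel, dep, weights).sum(axis=1))

    def fit(extra):
        X = design_with_intercept(s_ind, s_dep, extra, cov)
        beta, se, _, p, _ = ols(X, outcome)
        return {
            "independent": {"beta": float(beta[1]), "se": float(se[1]), "p": float(p[1])},
            "dependent": {"beta": float(beta[2]), "se": float(se[2]), "p": float(p[2])},
        }

    return {"unadjusted": fit(None), "adjusted": fit(mediator)}


def decompose(
    panel: GenotypePanel,
    weights: dict,
    outcome,
    mediator,
    covariates=None,
    alpha: float = 0.05,
    n_boot_screen: int = 200,
    n_boot_final: int = 1000,
    order: str = "ascending",
    seed: int = 0,
) -> DecompositionResult:
    """Run the full decomposition heuristic end-to-end.

    The screening mediation along the nested profile uses
    ``n_boot_screen`` resamples; the selected independent subset and
    the exclusive dependent complement are re-validated at
    ``n_boot_final``.  Pure function of (data, parameters, seed).
    """
    variant_ids = list(weights)
    ss = np.random.SeedSequence(seed)
    s_profile, s_ind, s_dep = (
        int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(3)
    )
    records = loo_scan(variant_ids, weights, panel, mediator, covariates)
    n_str = sum(r.direction == "strengthened" for r in records)
    n_weak = len(records) - n_str
    ranked = rank_variants(records, order=order)
    profile = nested_profile(
        ranked,
        weights,
        panel,
        outcome,
        mediator,
        covariates,
        n_boot_screen=n_boot_screen,
        seed=s_profile,
    )
    selection = select_independent(profile, alpha=alpha)
    candidate_sets = [profile.top_k(k) for k in selection.candidate_ks]
    exclusive = exclusive_complement(variant_ids, candidate_sets)

    ind_val = None
    if selection.optimal_subset:
        ind_val = validate_subset(
            selection.optimal_subset, weights, panel, outcome, mediator,
            covariates, n_boot=n_boot_final, seed=s_ind,
        )
    dep_val = None
    if exclusive:
        dep_val = validate_subset(
            exclusive, weights, panel, outcome, mediator,
            covariates, n_boot=n_boot_final, seed=s_dep,
        )
    joint = None
    if selection.optimal_subset and exclusive:
        joint = joint_model(
            selection.optimal_subset, exclusive, weights, panel,
            outcome, mediator, covariates,
        )
    return DecompositionResult(
        loo_records=records,
        n_strengthened=n_str,
        n_weakened=n_weak,
        ranked_ids=ranked,
        profile=profile,
        selection=selection,
        exclusive_dependent_subset=exclusive,
        independent_validation=ind_val,
        dependent_validation=dep_val,
        joint=joint,
    )
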