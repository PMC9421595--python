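"""Bootstrap mediation of a PRS effect on a continuous outcome through a
binary mediator.

The decomposition is the difference-of-coefficients form with all paths
presented as regression coefficients:

* ``c``  — total effect: OLS of outcome on exposure + covariates;
* ``c'`` — direct effect and ``b`` — mediator path: OLS of outcome on
  exposure + mediator + covariates;
* ``a``  — exposure -> mediator: linear-probability OLS of the binary
  mediator on exposure + covariates;
* indirect effect = ``c - c'``; proportion mediated = ``(c - c') / c``.

The indirect effect's uncertainty comes from a nonparametric percentile
bootstrap over individuals (paired rows, default 1,000 resamples) with
a fraction-based two-sided p-value.  The proportion mediated is
reported as undefined (NaN) when the total effect is too weakly
determined (|c| below a guard multiple of its SE), since a ratio with a
near-zero denominator is not interpretable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._stats import coef_solve, design_with_intercept, ols


@dataclass
class MediationResult:
    a: float
    a_se: float
    a_p: float
    b: float
    b_se: float
    b_p: float
    c: float
    c_se: float
    c_p: float
    c_prime: float
    c_prime_se: float
    c_prime_p: float
    indirect: float
    proportion_mediated: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int
    n_boot: int
    seed: int

    def to_dict(self) -> dict:
        from dataclasses import asdict

        return asdict(self)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.to_dict()])


def mediate(
    exposure,
    mediator,
    outcome,
    covariates=None,
    n_boot: int = 1000,
    seed: int = 0,
    proportion_guard: float = 10.0,
) -> MediationResult:
    """Difference-of-coefficients mediation with a percentile bootstrap.

    Complete cases only.  ``exposure`` is typically a standardized PRS,
    ``mediator`` a binary amyloid status, ``outcome`` an INT-transformed
    biomarker.  Deterministic given ``seed``.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    exposure = np.asarray(exposure, dtype=float)
    mediator = np.asarray(mediator, dtype=float)
    outcome = np.asarray(outcome, dtype=float)
    cov = None
    if covariates is not None:
        cov = np.asarray(pd.DataFrame(covariates), dtype=float)
    mask = ~(np.isnan(exposure) | np.isnan(mediator) | np.isnan(outcome))
    if cov is not None:
        mask &= ~np.isnan(cov).any(axis=1)
    exposure, mediator, outcome = exposure[mask], mediator[mask], outcome[mask]
    if cov is not None:
        cov = cov[mask]
    if np.unique(mediator).size < 2:
        raise ValueError("mediator must contain both classes")
    n = exposure.size

    Xc = design_with_intercept(exposure, cov)
    Xcp = design_with_intercept(exposure, mediator, cov)
    Xa = Xc  # same design, different response

    beta_c, se_c, _, p_c, _ = ols(Xc, outcome)
    beta_cp, se_cp, _, p_cp, _ = ols(Xcp, outcome)
    beta_a, se_a, _, p_a, _ = ols(Xa, mediator)

    c, c_se, c_p = beta_c[1], se_c[1], p_c[1]
    c_prime, cp_se, cp_p = beta_cp[1], se_cp[1], p_cp[1]
    b, b_se, b_p = beta_cp[2], se_cp[2], p_cp[2]
    a, a_se, a_p = beta_a[1], se_a[1], p_a[1]
    indirect = c - c_prime

    rng = np.random.default_rng(seed)
    boot = np.empty(n_boot)
    for i in range(n_boot):
        idx = rng.integers(0, n, n)
        yb = outcome[idx]
        cb = coef_solve(Xc[idx], yb)[1]
        cpb = coef_solve(Xcp[idx], yb)[1]
        boot[i] = cb - cpb
    ci_low, ci_high = np.percentile(boot, [2.5, 97.5])
    frac_le = np.mean(boot <= 0.0)
    frac_ge = np.mean(boot >= 0.0)
    p_boot = min(1.0, max(2.0 * min(frac_le, frac_ge), 1.0 / n_boot))

    if abs(c) >= proportion_guard * c_se and c != 0.0:
        proportion = indirect / c
    else:
        proportion = float("nan")

    return MediationResult(
        a=float(a), a_se=float(a_se), a_p=float(a_p),
        b=float(b), b_se=float(b_se), b_p=float(b_p),
        c=float(c), c_se=float(c_se), c_p=float(c_p),
        c_prime=float(c_prime), c_prime_se=float(cp_se), c_prime_p=float(cp_p),
        indirect=float(indirect),
        proportion_mediated=float(proportion),
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        p_value=float(p_boot),
        n=int(n),
        n_boot=int(n_boot),
        seed=int(seed),
    )
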