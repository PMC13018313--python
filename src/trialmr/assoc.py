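"""Observational association models, BH-FDR control, and the panel screen.

Exposures are assumed standardized to SD 1, so logistic estimates are
log-odds (OR = exp) per SD and linear estimates are SD-per-SD slopes.
Wald confidence intervals are used throughout for comparability with the
MR estimators.  FDR is applied within one family per analysis type.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests


@dataclass
class AssociationResult:
    outcome: str
    estimate: float        # beta per SD, or log-OR per SD
    se: float
    p: float
    n: int
    family: str
    q: float | None = None

    @property
    def ci_low(self) -> float:
        return self.estimate - 1.96 * self.se

    @property
    def ci_high(self) -> float:
        return self.estimate + 1.96 * self.se

    @property
    def odds_ratio(self) -> float | None:
        return float(np.exp(self.estimate)) if self.family == "logistic" else None


def _frame(df: pd.DataFrame, exposure: str, covariates: list[str] | None):
    cols = [exposure] + list(covariates or [])
    X = sm.add_constant(df[cols].astype(float))
    return X


def logistic_assoc(df: pd.DataFrame, outcome: str, exposure: str,
                   covariates: list[str] | None = None) -> AssociationResult:
    """Covariate-adjusted logistic regression; OR per SD of exposure.

    Raises on non-convergence; perfect separation surfaces as a
    statsmodels PerfectSeparationError.
    """
    y = df[outcome].astype(float)
    if set(y.unique()) - {0.0, 1.0}:
        raise ValueError(f"outcome {outcome!r} is not binary 0/1")
    X = _frame(df, exposure, covariates)
    res = sm.Logit(y, X).fit(disp=0)
    if not res.mle_retvals.get("converged", True):
        raise RuntimeError(f"logistic fit for {outcome!r} did not converge: "
                           f"{res.mle_retvals}")
    return AssociationResult(outcome, float(res.params[exposure]),
                             float(res.bse[exposure]), float(res.pvalues[exposure]),
                             int(res.nobs), "logistic")


def linear_assoc(df: pd.DataFrame, outcome: str, exposure: str,
                 covariates: list[str] | None = None,
                 robust: bool = False) -> AssociationResult:
    """Covariate-adjusted OLS; beta per SD of exposure (HC1 SE optional)."""
    X = _frame(df, exposure, covariates)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("rank-deficient design matrix")
    res = sm.OLS(df[outcome].astype(float), X).fit(
        cov_type="HC1" if robust else "nonrobust")
    return AssociationResult(outcome, float(res.params[exposure]),
                             float(res.bse[exposure]), float(res.pvalues[exposure]),
                             int(res.nobs), "linear")


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def panel_screen(trial_effects: pd.Series,
                 obs_results: list[AssociationResult],
                 mr_results: list[AssociationResult],
                 alpha: float = 0.05) -> pd.DataFrame:
    """Multi-source direction-consistency screen over an outcome panel.

    ``trial_effects`` gives the trial effect estimate (its sign is what
    matters) per outcome; BH-FDR is applied separately within the
    observational and MR families.  An outcome is flagged iff both q-values
    are below ``alpha`` and the trial, observational and MR directions all
    agree.
    """
    obs = {r.outcome: r for r in obs_results}
    mr = {r.outcome: r for r in mr_results}
    names = list(trial_effects.index)
    missing = [n for n in names if n not in obs or n not in mr]
    if missing or len(obs) != len(names) or len(mr) != len(names):
        extra = sorted((set(obs) | set(mr)) - set(names))
        raise ValueError(f"outcome name mismatch; missing={missing} extra={extra}")
    q_obs = bh_fdr([obs[n].p for n in names])
    q_mr = bh_fdr([mr[n].p for n in names])
    rows = []
    for i, n in enumerate(names):
        s_trial = np.sign(trial_effects[n])
        s_obs = np.sign(obs[n].estimate)
        s_mr = np.sign(mr[n].estimate)
        flag = bool(q_obs[i] < alpha and q_mr[i] < alpha
                    and s_trial == s_obs == s_mr and s_trial != 0)
        rows.append({
            "outcome": n, "trial_direction": s_trial,
            "obs_estimate": obs[n].estimate, "obs_q": q_obs[i],
            "mr_estimate": mr[n].estimate, "mr_q": q_mr[i],
            "consistent": flag,
        })
    return pd.DataFrame(rows)
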