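"""One- and two-sample Mendelian randomization estimators and diagnostics.

Two-sample estimators operate on harmonized per-variant effect pairs
(gamma_j, se_gamma_j) from the exposure study and (Gamma_j, se_Gamma_j)
from the outcome study, aligned to a common effect allele:

* Wald ratio      theta_j = Gamma_j / gamma_j (delta-method SE)
* IVW             inverse-variance meta-analysis of Wald ratios, equal to a
                  zero-intercept weighted regression of Gamma on gamma;
                  multiplicative random effects by default when J > 3
* weighted median consistent when <50% of the weight is from invalid
                  instruments
* weighted mode   consistent under a plurality of valid instruments
* MR-Egger        weighted regression with a free intercept; a nonzero
                  intercept signals directional pleiotropy
* MR-PRESSO       simulation-based residual-sum-of-squares global test with
                  per-variant outlier flagging and an outlier-corrected IVW

plus a one-sample genetic-score logistic regression and a bi-directional
driver that selects instruments separately in each direction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import check_gwas_frame
from .genetics import DEFAULT_P_GENOME_WIDE, clump

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: harmonized pairs are a plain DataFrame (one row per kept variant); see
#: :func:`harmonize` for the column contract
HarmonizedPairs = pd.DataFrame


# ---------------------------------------------------------------------------
# results containers
# ---------------------------------------------------------------------------

@dataclass
class MREstimate:
    """Method-tagged causal-effect estimate with Wald CI and diagnostics."""

    method: str
    beta: float
    se: float
    p: float
    n_snps: int
    extras: dict = field(default_factory=dict)

    @property
    def ci_low(self) -> float:
        return self.beta - 1.96 * self.se

    @property
    def ci_high(self) -> float:
        return self.beta + 1.96 * self.se

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.beta))

    @property
    def or_ci(self) -> tuple[float, float]:
        return float(np.exp(self.ci_low)), float(np.exp(self.ci_high))


@dataclass
class PressoResult:
    global_rss: float
    global_p: float
    outlier_p: pd.Series          # Bonferroni-corrected, indexed by variant
    outliers: list[str]
    raw: MREstimate
    corrected: MREstimate


# ---------------------------------------------------------------------------
# harmonization
# ---------------------------------------------------------------------------

def _is_palindromic(a1: str, a2: str) -> bool:
    return _COMPLEMENT.get(a1) == a2


def harmonize(exposure: pd.DataFrame, outcome: pd.DataFrame,
              palindrome_eaf_band: tuple[float, float] = (0.42, 0.58)
              ) -> pd.DataFrame:
    """Align exposure and outcome summary statistics to one effect allele.

    Strand flips are resolved via allele complements; when the outcome's
    alleles are swapped relative to the exposure, its beta is negated and
    EAF reflected.  Palindromic (A/T, C/G) variants are dropped when both
    EAFs fall in the ambiguity band, otherwise aligned by allele frequency.
    Irreconcilable alleles drop the variant with a log entry.

    Returns one row per shared variant with columns beta_exp, se_exp,
    beta_out, se_out, eaf_exp, eaf_out, effect_allele, other_allele and an
    ``action`` log entry in {kept, flipped, dropped-palindromic,
    dropped-irreconcilable}.
    """
    check_gwas_frame(exposure, "exposure")
    check_gwas_frame(outcome, "outcome")
    exp = exposure.drop_duplicates("variant_id").set_index("variant_id")
    out = outcome.drop_duplicates("variant_id").set_index("variant_id")
    shared = exp.index.intersection(out.index)
    lo, hi = palindrome_eaf_band

    rows = []
    for vid in shared:
        e, o = exp.loc[vid], out.loc[vid]
        ea, oa = str(e["effect_allele"]).upper(), str(e["other_allele"]).upper()
        b_out, eaf_out = float(o["beta"]), float(o["eaf"])
        oea, ooa = str(o["effect_allele"]).upper(), str(o["other_allele"]).upper()
        action = None
        if _is_palindromic(ea, oa):
            if {oea, ooa} != {ea, oa}:
                action = "dropped-irreconcilable"
            elif (lo < e["eaf"] < hi) and (lo < eaf_out < hi):
                action = "dropped-palindromic"
            else:
                # orient by frequency: the effect allele is the minor (or
                # major) allele in both studies
                if (e["eaf"] < 0.5) != (eaf_out < 0.5):
                    b_out, eaf_out = -b_out, 1 - eaf_out
                action = "kept" if oea == ea else "flipped"
        else:
            cea, coa = _COMPLEMENT.get(oea, "?"), _COMPLEMENT.get(ooa, "?")
            if (oea, ooa) == (ea, oa) or (cea, coa) == (ea, oa):
                action = "kept"
            elif (oea, ooa) == (oa, ea) or (cea, coa) == (oa, ea):
                b_out, eaf_out = -b_out, 1 - eaf_out
                action = "flipped"
            else:
                action = "dropped-irreconcilable"
        rows.append({
            "variant_id": vid, "effect_allele": ea, "other_allele": oa,
            "beta_exp": float(e["beta"]), "se_exp": float(e["se"]),
            "beta_out": b_out, "se_out": float(o["se"]),
            "eaf_exp": float(e["eaf"]), "eaf_out": eaf_out,
            "p_exp": float(e["p"]), "action": action,
        })
    pairs = pd.DataFrame(rows)
    if len(pairs):
        pairs = pairs[~pairs["action"].str.startswith("dropped")].reset_index(drop=True)
    return pairs


def _arrays(pairs: pd.DataFrame):
    return (pairs["beta_exp"].to_numpy(float), pairs["se_exp"].to_numpy(float),
            pairs["beta_out"].to_numpy(float), pairs["se_out"].to_numpy(float))


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

def wald_ratio(gamma: float, se_gamma: float, Gamma: float, se_Gamma: float,
               second_order: bool = False) -> MREstimate:
    """Single-variant causal estimate Gamma/gamma.

    First-order delta SE |se_Gamma/gamma| by default; the second-order
    option adds the exposure-uncertainty term.
    """
    if gamma == 0:
        raise ZeroDivisionError("exposure association gamma must be nonzero")
    theta = Gamma / gamma
    var = se_Gamma**2 / gamma**2
    if second_order:
        var += Gamma**2 * se_gamma**2 / gamma**4
    se = float(np.sqrt(var))
    p = 2 * stats.norm.sf(abs(theta) / se) if se > 0 else 0.0
    return MREstimate("wald_ratio", float(theta), se, float(p), 1)


def _ivw_core(g, sg, G, sG):
    w = g**2 / sG**2
    theta = float((w * (G / g)).sum() / w.sum())
    se_fixed = float(w.sum() ** -0.5)
    q = float((w * (G / g - theta) ** 2).sum())
    return theta, se_fixed, q, w


def ivw(pairs: pd.DataFrame, model: str = "auto") -> MREstimate:
    """Inverse-variance-weighted meta-analysis of per-variant Wald ratios.

    Identical to the zero-intercept weighted least-squares slope of Gamma on
    gamma with weights 1/se_Gamma^2.  ``model``: "fixed", "random"
    (multiplicative, SE inflated by sqrt(Q/(J-1)) when that exceeds 1), or
    "auto" (random when J > 3).
    """
    if len(pairs) < 1:
        raise ValueError("IVW requires at least one harmonized pair")
    g, sg, G, sG = _arrays(pairs)
    theta, se, q, _ = _ivw_core(g, sg, G, sG)
    J = len(g)
    used = model
    if model == "auto":
        used = "random" if J > 3 else "fixed"
    if used == "random" and J > 1:
        se *= max(1.0, np.sqrt(q / (J - 1)))
    elif used not in ("fixed", "random"):
        raise ValueError(f"unknown IVW model: {model!r}")
    p = 2 * stats.norm.sf(abs(theta) / se)
    q_p = stats.chi2.sf(q, J - 1) if J > 1 else np.nan
    return MREstimate(f"ivw_{used}", theta, se, float(p), J,
                      extras={"q_stat": q, "q_p": float(q_p)})


def _weighted_median_point(theta: np.ndarray, w: np.ndarray) -> float:
    order = np.argsort(theta)
    th, wt = theta[order], w[order] / w.sum()
    cum = np.cumsum(wt) - wt / 2  # centred cumulative weight
    if cum[0] >= 0.5:
        return float(th[0])
    if cum[-1] <= 0.5:
        return float(th[-1])
    k = int(np.searchsorted(cum, 0.5))  # first index with cum >= 0.5
    return float(th[k - 1] + (th[k] - th[k - 1]) * (0.5 - cum[k - 1]) / (cum[k] - cum[k - 1]))


def _bootstrap_se(pairs, point_fn, n_boot, seed):
    g, sg, G, sG = _arrays(pairs)
    rng = np.random.default_rng(seed)
    ests = np.empty(n_boot)
    for b in range(n_boot):
        gb = rng.normal(g, sg)
        Gb = rng.normal(G, sG)
        ests[b] = point_fn(Gb / gb, gb**2 / sG**2)
    return float(ests.std(ddof=1))


def weighted_median(pairs: pd.DataFrame, n_boot: int = 1000, seed: int = 0
                    ) -> MREstimate:
    """Weighted median of ratio estimates (inverse-variance weights).

    The estimate interpolates the ordered ratios where the centred
    cumulative normalized weight crosses 0.5; the SE comes from a
    parametric bootstrap resampling (gamma_j, Gamma_j) from normals.
    """
    if len(pairs) < 3:
        raise ValueError("weighted median requires >= 3 pairs")
    g, sg, G, sG = _arrays(pairs)
    theta = _weighted_median_point(G / g, g**2 / sG**2)
    se = _bootstrap_se(pairs, _weighted_median_point, n_boot, seed)
    p = 2 * stats.norm.sf(abs(theta) / se)
    return MREstimate("weighted_median", theta, se, float(p), len(pairs))


def _silverman_bandwidth(theta: np.ndarray, phi: float) -> float:
    s = theta.std(ddof=1)
    mad = stats.median_abs_deviation(theta, scale="normal")
    h = phi * 0.9 * min(s, mad if mad > 0 else s) * len(theta) ** (-0.2)
    return h


def _weighted_mode_point(theta: np.ndarray, w: np.ndarray, phi: float = 1.0,
                         n_grid: int = 4096) -> float:
    h = _silverman_bandwidth(theta, phi)
    if h <= 0 or np.ptp(theta) == 0:
        return float(theta[0])
    grid = np.linspace(theta.min() - 3 * h, theta.max() + 3 * h, n_grid)
    dens = (w[None, :] * np.exp(-0.5 * ((grid[:, None] - theta[None, :]) / h) ** 2)).sum(axis=1)
    return float(grid[np.argmax(dens)])


def weighted_mode(pairs: pd.DataFrame, phi: float = 1.0, n_boot: int = 1000,
                  seed: int = 0) -> MREstimate:
    """Mode of the inverse-variance-weighted kernel density of ratio estimates.

    Bandwidth is ``phi`` times the modified Silverman scale of the ratios;
    weights are the inverse delta-method variances of the ratios.  SE by
    parametric bootstrap.
    """
    if len(pairs) < 3:
        raise ValueError("weighted mode requires >= 3 pairs")
    g, sg, G, sG = _arrays(pairs)
    ratios = G / g
    w = 1.0 / (sG / g) ** 2
    theta = _weighted_mode_point(ratios, w, phi)
    se = _bootstrap_se(pairs, lambda th, wt: _weighted_mode_point(th, wt, phi),
                       n_boot, seed)
    p = 2 * stats.norm.sf(abs(theta) / se)
    return MREstimate("weighted_mode", theta, se, float(p), len(pairs))


def _wls(X: np.ndarray, y: np.ndarray, w: np.ndarray):
    XtW = X.T * w
    cov = np.linalg.inv(XtW @ X)
    coef = cov @ (XtW @ y)
    resid = y - X @ coef
    return coef, cov, float((w * resid**2).sum())


def mr_egger(pairs: pd.DataFrame) -> MREstimate:
    """MR-Egger: weighted regression of Gamma on gamma with a free intercept.

    Pairs are oriented so all exposure betas are positive; weights are
    1/se_Gamma^2.  The slope estimates the causal effect; the intercept and
    its p-value test directional pleiotropy.  SEs use the t reference with
    J-2 df and the residual scale floored at 1.
    """
    if len(pairs) < 3:
        raise ValueError("MR-Egger requires >= 3 pairs")
    g, sg, G, sG = _arrays(pairs)
    flip = np.sign(g)
    flip[flip == 0] = 1.0
    g, G = g * flip, G * flip
    w = 1.0 / sG**2
    X = np.column_stack([np.ones_like(g), g])
    coef, cov, rss = _wls(X, G, w)
    J = len(g)
    scale = max(1.0, np.sqrt(rss / (J - 2)))
    se = np.sqrt(np.diag(cov)) * scale
    tvals = coef / se
    pvals = 2 * stats.t.sf(np.abs(tvals), J - 2)
    return MREstimate("mr_egger", float(coef[1]), float(se[1]), float(pvals[1]), J,
                      extras={"intercept": float(coef[0]),
                              "intercept_se": float(se[0]),
                              "intercept_p": float(pvals[0])})


# ---------------------------------------------------------------------------
# MR-PRESSO
# ---------------------------------------------------------------------------

def _loo_slopes(g, G, w):
    """IVW slope excluding each variant in turn (closed form)."""
    num = (w * g * G).sum() - w * g * G
    den = (w * g * g).sum() - w * g * g
    return num / den


def mr_presso(pairs: pd.DataFrame, n_sim: int = 1000, outlier_alpha: float = 0.05,
              seed: int = 0) -> PressoResult:
    """Pleiotropy residual-sum-of-squares global test with outlier removal.

    The observed RSS uses leave-one-out-predicted weighted residuals
    (weights 1/se_Gamma^2).  Its null distribution comes from ``n_sim``
    parametric simulations under the fitted model; per-variant outlier
    p-values compare each observed squared residual to its simulated
    distribution and are Bonferroni-corrected across variants.  The
    corrected estimate is IVW on the non-flagged subset.
    """
    if len(pairs) < 4:
        raise ValueError("MR-PRESSO requires >= 4 pairs")
    rng = np.random.default_rng(seed)
    g, sg, G, sG = _arrays(pairs)
    J = len(g)
    w = 1.0 / sG**2

    slopes_loo = _loo_slopes(g, G, w)
    obs_sq = w * (G - slopes_loo * g) ** 2
    rss_obs = float(obs_sq.sum())

    # parametric null: gamma* ~ N(gamma, se_gamma), Gamma* ~ N(theta_loo*gamma, se_Gamma)
    g_sim = rng.normal(g, sg, size=(n_sim, J))
    G_sim = rng.normal(slopes_loo * g, sG, size=(n_sim, J))
    num = (w * g_sim * G_sim).sum(axis=1, keepdims=True) - w * g_sim * G_sim
    den = (w * g_sim**2).sum(axis=1, keepdims=True) - w * g_sim**2
    sim_sq = w * (G_sim - (num / den) * g_sim) ** 2
    rss_sim = sim_sq.sum(axis=1)

    global_p = float((rss_sim >= rss_obs).mean())
    p_raw = (sim_sq >= obs_sq[None, :]).mean(axis=0)
    p_bonf = np.minimum(1.0, p_raw * J)
    ids = pairs["variant_id"].to_numpy()
    outliers = [str(v) for v, pb in zip(ids, p_bonf) if pb < outlier_alpha]

    raw = ivw(pairs)
    keep = pairs[~pairs["variant_id"].isin(outliers)]
    corrected = ivw(keep) if len(keep) >= 1 and len(outliers) else raw
    corrected = MREstimate("mr_presso", corrected.beta, corrected.se,
                           corrected.p, corrected.n_snps, corrected.extras)
    return PressoResult(rss_obs, global_p, pd.Series(p_bonf, index=ids),
                        outliers, raw, corrected)


# ---------------------------------------------------------------------------
# one-sample MR and the bidirectional driver
# ---------------------------------------------------------------------------

def one_sample_mr(pheno: pd.DataFrame, genotypes: pd.DataFrame,
                  instruments: list[str], instrument_weights: np.ndarray | None,
                  outcome: str = "outcome", covariates: list[str] | None = None
                  ) -> MREstimate:
    """Genetic-score logistic regression (one-sample MR).

    The per-subject score is the weighted dosage sum over the instruments
    (exposure-GWAS betas by default; ``None`` gives an unweighted allele
    count), standardized to SD 1; the estimate is the log-odds of the binary
    outcome per SD of score, adjusted for the given covariate columns.
    """
    import statsmodels.api as sm

    missing = [v for v in instruments if v not in genotypes.columns]
    if missing:
        raise KeyError(f"instrument dosage columns missing: {missing}")
    if instrument_weights is None:
        wts = np.ones(len(instruments))
    else:
        wts = np.asarray(instrument_weights, dtype=float)
    if np.all(wts == 0):
        raise ValueError("all instrument weights are zero: degenerate score")
    raw = genotypes[instruments].to_numpy(float) @ wts
    if raw.std(ddof=0) == 0:
        raise ValueError("genetic score is constant")
    score_z = (raw - raw.mean()) / raw.std(ddof=0)

    X = pd.DataFrame({"score": score_z}, index=pheno.index)
    if covariates:
        X = X.join(pheno[covariates])
    X = sm.add_constant(X)
    res = sm.Logit(pheno[outcome].astype(float), X.astype(float)).fit(disp=0)
    beta, se = float(res.params["score"]), float(res.bse["score"])
    return MREstimate("one_sample_score", beta, se, float(res.pvalues["score"]),
                      len(instruments))


TWO_SAMPLE_METHODS = ("ivw", "weighted_median", "weighted_mode", "mr_egger", "mr_presso")


def two_sample_suite(pairs: pd.DataFrame, methods=TWO_SAMPLE_METHODS,
                     seed: int = 0, n_boot: int = 1000) -> dict[str, MREstimate]:
    """Run the requested estimators on one set of harmonized pairs."""
    out: dict[str, MREstimate] = {}
    for m in methods:
        try:
            if m == "ivw":
                out[m] = ivw(pairs)
            elif m == "weighted_median":
                out[m] = weighted_median(pairs, n_boot=n_boot, seed=seed)
            elif m == "weighted_mode":
                out[m] = weighted_mode(pairs, n_boot=n_boot, seed=seed + 1)
            elif m == "mr_egger":
                out[m] = mr_egger(pairs)
            elif m == "mr_presso":
                out[m] = mr_presso(pairs, seed=seed + 2).corrected
            else:
                raise ValueError(f"unknown method {m!r}")
        except ValueError as err:
            warnings.warn(f"{m} skipped: {err}")
    return out


def bidirectional(summary_1: pd.DataFrame, summary_2: pd.DataFrame,
                  genotypes_ref: pd.DataFrame,
                  p_threshold: float = DEFAULT_P_GENOME_WIDE,
                  r2_forward: float = 0.01, r2_reverse: float = 0.001,
                  window_bp: int = 1_000_000, methods=TWO_SAMPLE_METHODS,
                  seed: int = 0) -> dict[str, dict[str, MREstimate]]:
    """Forward and reverse two-sample MR between two traits.

    Forward uses trait-1 instruments (clumped at ``r2_forward``) against the
    trait-2 summary; reverse clumps trait-2 at the stricter ``r2_reverse``.
    A direction with no selectable instruments is skipped with a warning.
    """
    panels: dict[str, dict[str, MREstimate]] = {}
    for label, (exp, out, r2) in {
        "forward": (summary_1, summary_2, r2_forward),
        "reverse": (summary_2, summary_1, r2_reverse),
    }.items():
        inst = clump(exp, genotypes_ref, p_threshold, r2, window_bp)
        if len(inst) == 0:
            warnings.warn(f"{label}: empty instrument set; direction skipped")
            continue
        pairs = harmonize(exp[exp["variant_id"].isin(inst.variant_ids)], out)
        if pairs.empty:
            warnings.warn(f"{label}: no harmonized pairs; direction skipped")
            continue
        panels[label] = two_sample_suite(pairs, methods=methods, seed=seed)
    return panels
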