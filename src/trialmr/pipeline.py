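"""End-to-end synthetic study: trial -> signature -> cohort -> GWAS -> MR.

This module wires every stage together on data with known truth: a
randomized trial with sparse planted biomarker responses, an elastic-net
signature fitted to it, two independent genotyped cohorts in which the
planted biomarkers are heritable, a GWAS + clumping instrument selection
for the cohort signature score, one- and two-sample MR of the signature on
a binary outcome, the observational association, and the per-biomarker
mediator screen.

Ground truth: a subset of the trial-responsive biomarkers causally affects
the outcome, each in the direction that makes the signature protective
(biomarkers the treatment raises lower risk and vice versa), so the planted
mediators are exactly the biomarkers the screen should recover and the
signature's causal odds ratio is below 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from ._utils import ConfigError, child_rngs
from .assoc import bh_fdr, logistic_assoc
from .genetics import _linear_scan, _logistic_scan, clump, gwas_scan, inverse_rank_normalize
from .mediators import MediatorCall, MediatorEvidence, select_mediators
from .mr import MREstimate, harmonize, ivw, one_sample_mr, two_sample_suite, wald_ratio
from .signature import SignatureModel, fit_signature, lambda_max, score, standardize
from .simulate import (SimCohortConfig, SimTrialConfig, TrialDataset,
                       simulate_genotypes, simulate_trial, solve_prevalence_intercept)


@dataclass(frozen=True)
class PipelineConfig:
    """Study conditions for the end-to-end synthetic analysis.

    The trial mirrors the default 84-subject, 94-biomarker design with
    ``n_planted`` strong responders (|effect| 1.0 SD, alternating sign), of
    which the first ``n_mediators`` causally affect the outcome with
    ``mediator_logor`` log-odds per biomarker SD, signed so the signature is
    protective.  Each planted biomarker is heritable in the cohorts through
    ``variants_per_biomarker`` dedicated variants (one LD block each,
    ``h2_biomarker`` in total), plus ``n_null_variants`` variants with no
    effect.  Cohorts A (exposure) and B (outcome/observational) are
    independent draws of ``n_cohort`` individuals.
    """

    n_planted: int = 8
    n_mediators: int = 4
    planted_effect: float = 1.0
    mediator_logor: float = 0.30
    n_cohort: int = 20_000
    variants_per_biomarker: int = 4
    n_null_variants: int = 8
    h2_biomarker: float = 0.30
    ld_rho: float = 0.3
    baseline_prev: float = 0.10
    lambda_frac: float | None = 0.10   # None -> LOO-CV lambda selection
    n_biomarkers: int = 94
    seed: int = 0

    def __post_init__(self):
        if self.n_mediators > self.n_planted:
            raise ConfigError("n_mediators must be <= n_planted")
        if self.n_planted > self.n_biomarkers:
            raise ConfigError("n_planted must be <= n_biomarkers")


@dataclass
class PipelineResult:
    signature: SignatureModel
    trial: TrialDataset
    n_gwas_significant: int
    instruments: list[str]
    observational: "object"                  # AssociationResult for the score
    one_sample: MREstimate
    two_sample: dict[str, MREstimate]
    mediator_calls: list[MediatorCall]
    planted_mediators: list[str]
    planted_biomarkers: list[str]

    @property
    def recovered_mediators(self) -> list[str]:
        cand = {c.biomarker for c in self.mediator_calls
                if c.category == "candidate_mediator"}
        return [b for b in self.planted_mediators if b in cand]

    @property
    def recovery_rate(self) -> float:
        return len(self.recovered_mediators) / len(self.planted_mediators)


def _planted_layout(cfg: PipelineConfig):
    names = [f"bm_{k:03d}" for k in range(1, cfg.n_biomarkers + 1)]
    planted = names[: cfg.n_planted]
    effects = np.zeros(cfg.n_biomarkers)
    for i in range(cfg.n_planted):
        effects[i] = cfg.planted_effect * (1 if i % 2 == 0 else -1)
    mediators = planted[: cfg.n_mediators]
    # protective pairing: treatment-raised biomarkers lower risk
    deltas = {b: -cfg.mediator_logor * np.sign(effects[i])
              for i, b in enumerate(names) if b in mediators}
    return names, planted, effects, mediators, deltas


def _simulate_biomarker_cohort(cfg: PipelineConfig, effects, deltas, seed: int):
    """Cohort with heritable planted biomarkers and a mediated binary outcome."""
    n_var = cfg.n_planted * cfg.variants_per_biomarker + cfg.n_null_variants
    gcfg = SimCohortConfig(
        n_individuals=cfg.n_cohort, n_variants=n_var,
        ld_block_size=cfg.variants_per_biomarker, ld_rho=cfg.ld_rho,
        baseline_prev=cfg.baseline_prev, seed=seed)
    rng_g, rng_b, rng_y, rng_c = child_rngs(seed, 4)
    genotypes, variants = simulate_genotypes(gcfg, rng=rng_g)
    n = cfg.n_cohort
    G = genotypes.to_numpy(float)

    names = [f"bm_{k:03d}" for k in range(1, cfg.n_biomarkers + 1)]
    bio = rng_b.standard_normal((n, cfg.n_biomarkers))
    var_effect_map: dict[str, list[str]] = {}
    for i in range(cfg.n_planted):
        cols = slice(i * cfg.variants_per_biomarker, (i + 1) * cfg.variants_per_biomarker)
        sub = G[:, cols]
        gscore = (sub - sub.mean(axis=0)).sum(axis=1)
        gz = gscore / gscore.std(ddof=0)
        bio[:, i] = np.sqrt(cfg.h2_biomarker) * gz + \
            np.sqrt(1 - cfg.h2_biomarker) * bio[:, i]
        var_effect_map[names[i]] = list(variants["variant_id"].iloc[cols])
    biomarkers = pd.DataFrame(bio, columns=names, index=genotypes.index)

    lp = np.zeros(n)
    for b, d in deltas.items():
        col = biomarkers[b].to_numpy()
        lp += d * (col - col.mean()) / col.std(ddof=0)
    alpha = solve_prevalence_intercept(lp, cfg.baseline_prev)
    outcome = (rng_y.uniform(size=n) < expit(alpha + lp)).astype(int)

    pheno = pd.DataFrame({
        "outcome": outcome,
        "age": rng_c.normal(57, 8, n).round(1),
        "cov_1": rng_c.standard_normal(n),
    }, index=genotypes.index)
    return genotypes, variants, biomarkers, pheno, var_effect_map


def run_pipeline(cfg: PipelineConfig = PipelineConfig(),
                 mr_methods=("ivw", "weighted_median", "mr_egger"),
                 n_boot: int = 200) -> PipelineResult:
    """Run the full trial-to-mediators chain on one seeded synthetic study."""
    seeds = np.random.SeedSequence(cfg.seed).generate_state(4) % (2**31)
    names, planted, effects, mediators, deltas = _planted_layout(cfg)

    # --- stage 1: trial and signature -----------------------------------
    trial_cfg = SimTrialConfig(effect_vector=tuple(effects),
                               n_biomarkers=cfg.n_biomarkers, seed=int(seeds[0]))
    trial, _ = simulate_trial(trial_cfg)
    if cfg.lambda_frac is not None:
        from .signature import extract_features
        X_raw, y = extract_features(trial)
        Z, _ = standardize(X_raw)
        lam = cfg.lambda_frac * lambda_max(Z.to_numpy(float), np.asarray(y), 0.5)
        model = fit_signature(X_raw, y, alpha=0.5, lambda_=lam, tol=1e-7)
    else:
        model = fit_signature(trial, alpha=0.5, n_lambda=30)

    # --- stage 2: two independent biomarker cohorts ---------------------
    gen_a, var_a, bio_a, phen_a, vmap = _simulate_biomarker_cohort(
        cfg, effects, deltas, int(seeds[1]))
    gen_b, var_b, bio_b, phen_b, _ = _simulate_biomarker_cohort(
        cfg, effects, deltas, int(seeds[2]))

    za, _ = standardize(bio_a)
    zb, _ = standardize(bio_b)
    score_a = score(model, za)
    score_b = score(model, zb)

    # --- stage 3: signature GWAS in cohort A, instrument selection ------
    covs_a = phen_a[["age", "cov_1"]]
    exp_sum = gwas_scan(inverse_rank_normalize(score_a), gen_a, var_a,
                        covariates=covs_a, family="linear")
    inst = clump(exp_sum, gen_a, r2_threshold=0.01)
    instruments = inst.variant_ids

    # --- stage 4: outcome scan in cohort B, two-sample + one-sample MR --
    out_sum = gwas_scan(phen_b["outcome"], gen_b, var_b, family="logistic")
    pairs = harmonize(exp_sum[exp_sum["variant_id"].isin(instruments)], out_sum)
    two_sample = two_sample_suite(pairs, methods=mr_methods,
                                  seed=int(seeds[3]), n_boot=n_boot)
    wts = exp_sum.set_index("variant_id").loc[instruments, "beta"].to_numpy()
    one_sample = one_sample_mr(phen_b, gen_b, instruments, wts,
                               covariates=["age", "cov_1"])

    # --- stage 5: observational association of the score -----------------
    df_b = phen_b.copy()
    sb = score_b.to_numpy()
    df_b["signature"] = (sb - sb.mean()) / sb.std(ddof=1)
    observational = logistic_assoc(df_b, "outcome", "signature",
                                   covariates=["age", "cov_1"])

    # --- stage 6: per-biomarker evidence and mediator screen -------------
    sel = model.selected
    Gb_cov = np.column_stack([np.ones(len(df_b)), df_b[["age", "cov_1"]]])
    obs_beta, obs_se, obs_p = _logistic_scan(
        df_b["outcome"].to_numpy(float), zb[sel].to_numpy(float), Gb_cov)
    obs_q = bh_fdr(np.clip(obs_p, np.nextafter(0, 1), 1.0))

    exp_idx = exp_sum.set_index("variant_id")
    out_idx = out_sum.set_index("variant_id")
    Xa_cov = np.column_stack([np.ones(len(phen_a)), covs_a])
    Ga = gen_a.to_numpy(float)
    vid_pos = {v: j for j, v in enumerate(var_a["variant_id"])}

    evidence = []
    for k, b in enumerate(sel):
        mr_beta = None
        if b in vmap:  # heritable biomarker: instrument it directly
            cols = [vid_pos[v] for v in vmap[b]]
            bz = za[b].to_numpy(float)
            bbeta, bse, bp = _linear_scan(bz, Ga[:, cols], Xa_cov)
            keep = bp < 5e-8
            if keep.any():
                sub = pd.DataFrame({
                    "variant_id": [vmap[b][i] for i in np.flatnonzero(keep)],
                    "beta_exp": bbeta[keep], "se_exp": bse[keep],
                })
                sub["beta_out"] = out_idx.loc[sub["variant_id"], "beta"].to_numpy()
                sub["se_out"] = out_idx.loc[sub["variant_id"], "se"].to_numpy()
                if len(sub) == 1:
                    r = sub.iloc[0]
                    mr_beta = wald_ratio(r["beta_exp"], r["se_exp"],
                                         r["beta_out"], r["se_out"]).beta
                else:
                    mr_beta = ivw(sub).beta
        evidence.append(MediatorEvidence(
            biomarker=b, weight_sign=int(np.sign(model.weight(b))),
            obs_logor=float(obs_beta[k]), obs_q=float(obs_q[k]),
            mr_beta=mr_beta))
    calls = select_mediators(evidence, outcome="outcome")

    return PipelineResult(
        signature=model, trial=trial,
        n_gwas_significant=int((exp_sum["p"] < 5e-8).sum()),
        instruments=instruments, observational=observational,
        one_sample=one_sample, two_sample=two_sample,
        mediator_calls=calls,
        planted_mediators=mediators, planted_biomarkers=planted)
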