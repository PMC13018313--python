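"""Synthetic trials, genotype cohorts, and paired GWAS summary statistics.

Every generator takes a frozen config dataclass plus a seed and returns both
the dataset and a :class:`TruthRecord` holding the exact effect values used,
so downstream estimators can be scored against known truth without any
external data.

The default trial emulates a 1:1 randomized two-arm study of 84 men with 94
standardized biomarkers measured at baseline and two follow-up visits, with
4 subjects lost to follow-up.  The default clinical-outcome treatment
effects are -0.45 SD (total cholesterol), -0.59 SD (fasting glucose) and
-0.39 SD (LDL-cholesterol).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, ndtri
from scipy.optimize import brentq

from ._utils import ConfigError, GWAS_COLUMNS, child_rngs

VISITS = ("baseline", "wk8", "wk12")

CLINICAL_OUTCOMES = {
    "total_cholesterol": -0.45,
    "fasting_glucose": -0.59,
    "ldl_cholesterol": -0.39,
}


# ---------------------------------------------------------------------------
# configs and truth
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimTrialConfig:
    """Conditions of a simulated randomized two-arm biomarker trial.

    ``effect_vector`` holds per-biomarker treatment effects in SD units
    (sparse; ``None`` means all zero).  ``biomarker_corr`` is the
    exchangeable correlation among biomarkers; ``visit_corr`` the
    within-subject correlation of the same biomarker across visits.
    """

    n_subjects: int = 84
    alloc_ratio: float = 0.5
    n_biomarkers: int = 94
    effect_vector: tuple[float, ...] | None = None
    biomarker_corr: float = 0.1
    visit_corr: float = 0.5
    n_visits: int = 3
    dropout: int = 4
    outcome_effects: tuple[tuple[str, float], ...] = tuple(CLINICAL_OUTCOMES.items())
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 4:
            raise ConfigError("n_subjects must be >= 4")
        if not 0 < self.alloc_ratio < 1:
            raise ConfigError("alloc_ratio must be in (0,1)")
        if not 0 <= self.biomarker_corr < 1:
            raise ConfigError(
                "biomarker_corr must be in [0,1): the exchangeable correlation "
                "matrix is not guaranteed positive semi-definite otherwise"
            )
        if not 0 <= self.visit_corr < 1:
            raise ConfigError("visit_corr must be in [0,1)")
        if not 1 <= self.n_visits <= len(VISITS):
            raise ConfigError(f"n_visits must be in 1..{len(VISITS)}")
        if self.effect_vector is not None:
            object.__setattr__(self, "effect_vector", tuple(float(v) for v in self.effect_vector))
            if len(self.effect_vector) != self.n_biomarkers:
                raise ConfigError("effect_vector length must equal n_biomarkers")
        if self.dropout < 0 or self.dropout >= self.n_subjects:
            raise ConfigError("dropout must be in [0, n_subjects)")

    @property
    def effects(self) -> np.ndarray:
        if self.effect_vector is None:
            return np.zeros(self.n_biomarkers)
        return np.asarray(self.effect_vector, dtype=float)


@dataclass(frozen=True)
class SimCohortConfig:
    """Conditions of a simulated genotyped cohort.

    Genotypes are drawn in LD blocks (latent AR(``ld_rho``) Gaussian per
    haplotype, thresholded at the MAF quantile), so Hardy-Weinberg
    equilibrium holds by construction.  The quantitative "signature"
    phenotype has heritability ``h2`` through ``variant_effects``, shares a
    standard-normal confounder with the outcome (loading
    ``confounder_strength`` on both), and the binary outcome follows a
    logistic model with ``causal_logOR`` per SD of phenotype; the intercept
    is solved so the marginal prevalence matches ``baseline_prev``.
    """

    n_individuals: int = 20_000
    n_variants: int = 60
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_block_size: int = 5
    ld_rho: float = 0.3
    variant_effects: tuple[float, ...] | None = None
    h2: float = 0.2
    causal_logOR: float = 0.0
    baseline_prev: float = 0.10
    n_pleiotropic: int = 0
    pleiotropy_effect: float = 0.0
    pleiotropic_indices: tuple[int, ...] | None = None
    confounder_strength: float = 0.0
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigError("maf_range must lie within (0, 0.5]")
        if not 0 <= self.ld_rho < 1:
            raise ConfigError("ld_rho must be in [0,1)")
        if not 0 < self.h2 < 1:
            raise ConfigError("h2 must be in (0,1)")
        if not 0 < self.baseline_prev < 1:
            raise ConfigError("baseline_prev must be in (0,1)")
        if self.ld_block_size < 1:
            raise ConfigError("ld_block_size must be >= 1")
        if self.variant_effects is not None:
            object.__setattr__(
                self, "variant_effects", tuple(float(v) for v in self.variant_effects)
            )
            if len(self.variant_effects) != self.n_variants:
                raise ConfigError("variant_effects length must equal n_variants")
        if self.n_pleiotropic < 0 or self.n_pleiotropic > self.n_variants:
            raise ConfigError("n_pleiotropic must be a subset of the variant set")
        if self.pleiotropic_indices is not None:
            idx = tuple(int(i) for i in self.pleiotropic_indices)
            if any(i < 0 or i >= self.n_variants for i in idx):
                raise ConfigError("pleiotropic_indices must index the variant set")
            object.__setattr__(self, "pleiotropic_indices", idx)
            object.__setattr__(self, "n_pleiotropic", len(idx))
        if self.h2 + self.confounder_strength**2 >= 1:
            raise ConfigError("h2 + confounder_strength^2 must be < 1")

    @property
    def effects(self) -> np.ndarray:
        if self.variant_effects is None:
            # default: every fourth variant carries a modest effect
            eff = np.zeros(self.n_variants)
            eff[:: max(1, self.n_variants // 15)] = 0.15
            return eff
        return np.asarray(self.variant_effects, dtype=float)


@dataclass
class TruthRecord:
    """Ground-truth effect values used by a generator run."""

    treatment_effects: dict[str, float] = field(default_factory=dict)
    outcome_effects: dict[str, float] = field(default_factory=dict)
    variant_effects: dict[str, float] = field(default_factory=dict)
    causal_logOR: float | None = None
    h2: float | None = None
    baseline_prev: float | None = None
    confounder_strength: float | None = None
    pleiotropic_variants: list[str] = field(default_factory=list)
    pleiotropy_effect: float | None = None
    intercept: float | None = None
    dropped_subjects: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "TruthRecord":
        return cls(**json.loads(text))


# ---------------------------------------------------------------------------
# trial
# ---------------------------------------------------------------------------

@dataclass
class TrialDataset:
    """Long-format randomized-trial data: one row per subject x visit."""

    data: pd.DataFrame
    biomarkers: list[str]
    outcomes: list[str]

    def completers(self) -> "TrialDataset":
        """Subjects observed at every visit (the analysis population)."""
        n_visits = self.data["visit"].nunique()
        counts = self.data.groupby("subject")["visit"].nunique()
        keep = counts[counts == n_visits].index
        return TrialDataset(
            self.data[self.data["subject"].isin(keep)].reset_index(drop=True),
            self.biomarkers,
            self.outcomes,
        )

    def visit_matrix(self, visit: str) -> pd.DataFrame:
        """Biomarker matrix (subjects x biomarkers) at one visit, with arm."""
        sub = self.data[self.data["visit"] == visit].set_index("subject")
        return sub[["arm"] + self.biomarkers]

    def arm_labels(self, visit: str = "wk12") -> pd.Series:
        sub = self.data[self.data["visit"] == visit].set_index("subject")
        return (sub["arm"] == "treated").astype(int)


def _correlated_panel(rng, n, p, rho):
    """n x p standard-normal draws with exchangeable correlation rho."""
    shared = rng.standard_normal((n, 1))
    idio = rng.standard_normal((n, p))
    return np.sqrt(rho) * shared + np.sqrt(1 - rho) * idio


def simulate_trial(cfg: SimTrialConfig) -> tuple[TrialDataset, TruthRecord]:
    """Simulate a 1:1 randomized two-arm trial with repeated biomarker panels.

    Allocation is exactly balanced before dropout (e.g. 42/42 at n=84).
    Treated subjects are shifted by ``cfg.effect_vector`` (biomarkers) and
    ``cfg.outcome_effects`` (clinical outcomes) at post-baseline visits only.
    Dropout removes whole subjects' follow-up visits at random, balanced
    across arms as far as the count allows.
    """
    rng_alloc, rng_bio, rng_out, rng_drop = child_rngs(cfg.seed, 4)
    n, p = cfg.n_subjects, cfg.n_biomarkers
    subjects = [f"S{i:03d}" for i in range(1, n + 1)]
    n_treated = int(round(n * cfg.alloc_ratio))
    arm = np.array(["control"] * n, dtype=object)
    arm[rng_alloc.permutation(n)[:n_treated]] = "treated"

    visits = list(VISITS[: cfg.n_visits])
    bm_names = [f"bm_{k:03d}" for k in range(1, p + 1)]
    effects = cfg.effects
    out_names = [name for name, _ in cfg.outcome_effects]
    out_eff = np.array([e for _, e in cfg.outcome_effects])

    # stable subject-level component gives within-subject visit correlation
    subj_bio = _correlated_panel(rng_bio, n, p, cfg.biomarker_corr)
    subj_out = rng_out.standard_normal((n, len(out_names)))
    treated = (arm == "treated").astype(float)[:, None]

    rows = []
    for v_idx, visit in enumerate(visits):
        noise_bio = _correlated_panel(rng_bio, n, p, cfg.biomarker_corr)
        noise_out = rng_out.standard_normal((n, len(out_names)))
        x = np.sqrt(cfg.visit_corr) * subj_bio + np.sqrt(1 - cfg.visit_corr) * noise_bio
        y = np.sqrt(cfg.visit_corr) * subj_out + np.sqrt(1 - cfg.visit_corr) * noise_out
        if v_idx > 0:  # treatment acts after baseline
            x = x + treated * effects[None, :]
            y = y + treated * out_eff[None, :]
        df = pd.DataFrame(x, columns=bm_names)
        for j, name in enumerate(out_names):
            df[name] = y[:, j]
        df.insert(0, "visit", visit)
        df.insert(0, "arm", arm)
        df.insert(0, "subject", subjects)
        rows.append(df)
    data = pd.concat(rows, ignore_index=True)

    dropped: list[str] = []
    if cfg.dropout and len(visits) > 1:
        per_arm = cfg.dropout // 2
        for a, k in (("treated", per_arm), ("control", cfg.dropout - per_arm)):
            pool = [s for s, ar in zip(subjects, arm) if ar == a]
            dropped += list(rng_drop.choice(pool, size=k, replace=False))
        data = data[
            ~(data["subject"].isin(dropped) & (data["visit"] != "baseline"))
        ].reset_index(drop=True)

    truth = TruthRecord(
        treatment_effects={b: float(e) for b, e in zip(bm_names, effects) if e != 0},
        outcome_effects=dict(cfg.outcome_effects),
        dropped_subjects=sorted(dropped),
    )
    return TrialDataset(data, bm_names, out_names), truth


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def simulate_genotypes(cfg: SimCohortConfig, rng: np.random.Generator | None = None
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw dosages in {0,1,2} with block-AR(rho) LD, HWE-consistent.

    Two independent haplotypes per individual are drawn as latent AR(1)
    Gaussians within each LD block and thresholded at the MAF quantile, so
    genotype frequencies satisfy Hardy-Weinberg by construction while
    adjacent variants within a block are correlated.

    Returns ``(dosages, variants)``: an individuals x variants DataFrame and
    a variant metadata table (id, chrom, pos, alleles, eaf, info, callrate).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n, V = cfg.n_individuals, cfg.n_variants
    lo, hi = cfg.maf_range
    mafs = rng.uniform(lo, hi, size=V)
    thresholds = ndtri(mafs)

    def haplotypes() -> np.ndarray:
        z = np.empty((n, V))
        rho, b = cfg.ld_rho, cfg.ld_block_size
        for start in range(0, V, b):
            stop = min(start + b, V)
            z[:, start] = rng.standard_normal(n)
            for j in range(start + 1, stop):
                z[:, j] = rho * z[:, j - 1] + np.sqrt(1 - rho**2) * rng.standard_normal(n)
        return (z < thresholds[None, :]).astype(np.int8)

    dosage = haplotypes() + haplotypes()
    ids = [f"rs{j:05d}" for j in range(1, V + 1)]
    block = np.arange(V) // cfg.ld_block_size
    variants = pd.DataFrame({
        "variant_id": ids,
        "chrom": "1",
        "pos": 10_000 + np.arange(V) * 10_000,
        "effect_allele": "A",
        "other_allele": "G",
        "eaf": dosage.mean(axis=0) / 2.0,
        "info": 1.0,
        "callrate": 1.0,
        "block": block,
        "maf_true": mafs,
    })
    dosages = pd.DataFrame(
        dosage, columns=ids, index=[f"I{i:06d}" for i in range(1, n + 1)]
    )
    return dosages, variants


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

@dataclass
class CohortDataset:
    """Genotyped cohort: dosages, variant metadata, per-subject phenotypes."""

    genotypes: pd.DataFrame
    variants: pd.DataFrame
    pheno: pd.DataFrame  # signature, outcome, covariates, confounder


def solve_prevalence_intercept(lp: np.ndarray, target: float, tol: float = 1e-4) -> float:
    """Intercept alpha with mean(expit(alpha + lp)) = target, by bisection."""

    def gap(alpha):
        return float(expit(alpha + lp).mean() - target)

    lo, hi = -30.0, 30.0
    if gap(lo) > 0 or gap(hi) < 0:
        raise ArithmeticError(
            f"prevalence {target} unattainable for the given linear predictor"
        )
    alpha = brentq(gap, lo, hi, xtol=1e-10)
    if abs(gap(alpha)) > tol:
        raise ArithmeticError("intercept search did not reach the prevalence tolerance")
    return float(alpha)


def simulate_cohort(cfg: SimCohortConfig) -> tuple[CohortDataset, TruthRecord]:
    """Simulate genotypes, a heritable signature phenotype, and a binary outcome.

    phenotype = sqrt(h2) * z(genetic score) + c * U + sqrt(1 - h2 - c^2) * eps
    outcome   ~ Bernoulli(expit(alpha + causal_logOR * phenotype_z
                                + pleiotropy + c * U))

    where U is the shared standard-normal confounder (loading ``c``) and
    pleiotropic variants add direct, centred dosage effects on the outcome
    log-odds.  alpha is solved so the realized marginal prevalence matches
    ``baseline_prev`` to 1e-4.
    """
    rng_g, rng_p, rng_y, rng_c = child_rngs(cfg.seed, 4)
    genotypes, variants = simulate_genotypes(cfg, rng=rng_g)
    n = cfg.n_individuals
    eff = cfg.effects
    G = genotypes.to_numpy(dtype=float)

    raw_score = G @ eff
    sd = raw_score.std(ddof=0)
    score_z = (raw_score - raw_score.mean()) / sd if sd > 0 else np.zeros(n)
    c = cfg.confounder_strength
    confounder = rng_p.standard_normal(n)
    noise_sd = np.sqrt(1 - cfg.h2 - c**2)
    phenotype = np.sqrt(cfg.h2) * score_z + c * confounder + noise_sd * rng_p.standard_normal(n)
    phen_z = (phenotype - phenotype.mean()) / phenotype.std(ddof=0)

    if cfg.pleiotropic_indices is not None:
        pleio_idx = np.array(cfg.pleiotropic_indices, dtype=int)
    elif cfg.n_pleiotropic:
        nonzero = np.flatnonzero(eff)
        pool = nonzero if nonzero.size >= cfg.n_pleiotropic else np.arange(cfg.n_variants)
        pleio_idx = np.sort(rng_y.choice(pool, size=cfg.n_pleiotropic, replace=False))
    else:
        pleio_idx = np.array([], dtype=int)
    lp = cfg.causal_logOR * phen_z + c * confounder
    for j in pleio_idx:
        lp = lp + cfg.pleiotropy_effect * (G[:, j] - G[:, j].mean())

    alpha = solve_prevalence_intercept(lp, cfg.baseline_prev)
    outcome = (rng_y.uniform(size=n) < expit(alpha + lp)).astype(int)

    # numeric covariate stand-ins (age etc.) with no outcome effect
    covs = pd.DataFrame({
        "age": rng_c.normal(57, 8, n).round(1),
        "cov_1": rng_c.standard_normal(n),
        "cov_2": rng_c.standard_normal(n),
    }, index=genotypes.index)
    pheno = pd.DataFrame({
        "signature": phen_z,
        "genetic_score": score_z,
        "outcome": outcome,
        "confounder": confounder,
    }, index=genotypes.index).join(covs)

    truth = TruthRecord(
        variant_effects={v: float(e) for v, e in zip(variants["variant_id"], eff) if e != 0},
        causal_logOR=cfg.causal_logOR,
        h2=cfg.h2,
        baseline_prev=cfg.baseline_prev,
        confounder_strength=c,
        pleiotropic_variants=[variants["variant_id"].iloc[j] for j in pleio_idx],
        pleiotropy_effect=cfg.pleiotropy_effect if cfg.n_pleiotropic else None,
        intercept=alpha,
    )
    return CohortDataset(genotypes, variants, pheno), truth


# ---------------------------------------------------------------------------
# two-sample summary statistics
# ---------------------------------------------------------------------------

def make_two_sample(cfg: SimCohortConfig) -> tuple[pd.DataFrame, pd.DataFrame, TruthRecord]:
    """Paired non-overlapping exposure/outcome summary statistics.

    Two independent cohorts are simulated under the same variant truth; the
    exposure file is a linear scan of the signature phenotype in cohort A and
    the outcome file a logistic scan of the binary outcome in cohort B, so
    the two samples share no individuals.
    """
    from .genetics import gwas_scan

    seed_a, seed_b = (int(s.generate_state(1)[0] % (2**31))
                      for s in np.random.SeedSequence(cfg.seed).spawn(2))
    cfg_a = dataclasses.replace(cfg, seed=seed_a)
    cfg_b = dataclasses.replace(cfg, seed=seed_b)
    cohort_a, truth = simulate_cohort(cfg_a)
    cohort_b, _ = simulate_cohort(cfg_b)

    exposure = gwas_scan(cohort_a.pheno["signature"], cohort_a.genotypes,
                         cohort_a.variants, family="linear")
    outcome = gwas_scan(cohort_b.pheno["outcome"], cohort_b.genotypes,
                        cohort_b.variants, family="logistic")
    return exposure[GWAS_COLUMNS], outcome[GWAS_COLUMNS], truth


def recovery_study_config(theta: float = -0.16, n: int = 20_000,
                          n_variants: int = 50, seed: int = 0) -> SimCohortConfig:
    """Canonical parameter-recovery design: independent valid instruments.

    A strongly heritable (h2 = 0.6), oligogenic pQTL-like architecture on
    common variants (MAF 0.2-0.5): effect magnitudes alternate between a
    moderate (0.2-0.4) and a strong (0.8-1.0) band with random signs.  The
    two-band spread of instrument strengths keeps every estimator well
    identified -- in particular it holds MR-Egger's between-instrument
    strength variance high relative to the exposure betas' sampling error
    (the NOME/I2_GX condition), so its regression-dilution attenuation is
    negligible at the cohort size -- while the weakest instrument remains
    far from the weak-instrument regime.
    """
    rng = np.random.default_rng(seed)
    mag = np.where(np.arange(n_variants) % 2 == 0,
                   rng.uniform(0.2, 0.4, n_variants),
                   rng.uniform(0.8, 1.0, n_variants))
    eff = mag * rng.choice([-1.0, 1.0], n_variants)
    return SimCohortConfig(
        n_individuals=n, n_variants=n_variants, ld_rho=0.0, ld_block_size=1,
        maf_range=(0.2, 0.5), variant_effects=tuple(eff), h2=0.6,
        causal_logOR=theta, baseline_prev=0.10, seed=seed)


def simulate_summary_pairs(n_variants: int = 20, theta: float = 0.0,
                           n_invalid: int = 0, pleiotropy_mean: float = 0.0,
                           pleiotropy_sd: float = 0.0, se_exp: float = 0.02,
                           se_out: float = 0.04, seed: int = 0) -> tuple[pd.DataFrame, dict]:
    """Harmonized summary-level pairs drawn directly from the MR model.

    gamma_hat_j ~ N(gamma_j, se_exp) with gamma_j uniform(0.1, 0.4);
    Gamma_hat_j ~ N(theta * gamma_j + a_j, se_out), where the first
    ``n_invalid`` variants carry direct (pleiotropic) outcome effects
    a_j ~ N(pleiotropy_mean, pleiotropy_sd) and a_j = 0 otherwise.
    Returns pairs in the harmonized-column layout plus the truth dict.
    """
    rng = np.random.default_rng(seed)
    gamma = rng.uniform(0.1, 0.4, n_variants)
    a = np.zeros(n_variants)
    if n_invalid:
        a[:n_invalid] = rng.normal(pleiotropy_mean, pleiotropy_sd, n_invalid)
    g_hat = rng.normal(gamma, se_exp)
    G_hat = rng.normal(theta * gamma + a, se_out)
    pairs = pd.DataFrame({
        "variant_id": [f"rs{j:05d}" for j in range(1, n_variants + 1)],
        "effect_allele": "A", "other_allele": "G",
        "beta_exp": g_hat, "se_exp": se_exp,
        "beta_out": G_hat, "se_out": se_out,
        "eaf_exp": 0.3, "eaf_out": 0.3, "action": "kept",
    })
    truth = {"theta": theta, "invalid": list(pairs["variant_id"][:n_invalid]),
             "pleiotropy": a[:n_invalid].tolist()}
    return pairs, truth
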