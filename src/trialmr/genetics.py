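"""Variant QC, phenotype transforms, association scans, LD, and clumping.

This is the instrument-selection machinery: quality-control filters on
imputed variants (INFO, missingness, MAF, Hardy-Weinberg), inverse
rank-normal transformation of the phenotype, per-variant covariate-adjusted
regression scans (linear and logistic), pairwise dosage r-squared, greedy
p-value-ordered LD clumping, and cis-region filtering around a gene.

Coordinates are 1-based and all interval bounds inclusive.  Genome-wide
significance defaults to p < 5e-8 and the clumping window to 1 Mb; both are
exposed as arguments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import lgamma

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, ndtri

from ._utils import GWAS_COLUMNS, check_gwas_frame

DEFAULT_P_GENOME_WIDE = 5e-8


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_exact_p(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact conditional Hardy-Weinberg test p-value.

    Sums, over all heterozygote counts compatible with the observed allele
    totals, the conditional probabilities no larger than that of the
    observed table.  Symmetric in the homozygote labels; a monomorphic
    sample has a single possible table and p = 1.
    """
    if min(n_aa, n_ab, n_bb) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_aa + n_ab + n_bb
    if n < 1:
        raise ValueError("at least one genotype required")
    n_a = 2 * n_aa + n_ab  # minor-allele copies (symmetry makes choice moot)
    n_b = 2 * n_bb + n_ab
    rare = min(n_a, n_b)
    if rare == 0:
        return 1.0

    # log P(n_ab | margins) up to a shared constant
    def logprob(het: int) -> float:
        hom_r = (rare - het) // 2
        hom_c = n - het - hom_r
        return (het * np.log(2.0)
                - lgamma(hom_r + 1) - lgamma(het + 1) - lgamma(hom_c + 1))

    hets = np.arange(rare % 2, rare + 1, 2)
    logs = np.array([logprob(int(h)) for h in hets])
    probs = np.exp(logs - logs.max())
    probs /= probs.sum()
    obs = probs[np.where(hets == n_ab)[0][0]]
    return float(min(1.0, probs[probs <= obs * (1 + 1e-12)].sum()))


# ---------------------------------------------------------------------------
# QC filter
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QCThresholds:
    """Inclusion thresholds for imputed-variant QC."""

    min_info: float = 0.7
    max_missing: float = 0.10
    min_maf: float = 0.01
    min_hwe_p: float = 1e-15


def qc_filter(variants: pd.DataFrame,
              genotypes: pd.DataFrame | None = None,
              thresholds: QCThresholds = QCThresholds(),
              ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Keep variants passing INFO, missingness, MAF and HWE rules.

    Missing rate and HWE are computed from ``genotypes`` (NaN = missing)
    when given, else taken from ``callrate`` / ``hwe_p`` columns.  Each
    excluded variant is logged with the *first* failing rule, in the fixed
    order info, missing, maf, hwe; the kept set itself does not depend on
    row order.
    """
    t = thresholds
    df = variants.copy()
    if genotypes is not None:
        g = genotypes[df["variant_id"]].to_numpy(dtype=float)
        miss = np.isnan(g).mean(axis=0)
        df["_missing"] = miss
        hwe = np.empty(g.shape[1])
        for j in range(g.shape[1]):
            col = g[:, j]
            col = col[~np.isnan(col)]
            counts = [(np.rint(col) == k).sum() for k in (0, 1, 2)]
            hwe[j] = hwe_exact_p(counts[2], counts[1], counts[0])
        df["_hwe_p"] = hwe
    else:
        df["_missing"] = 1.0 - df.get("callrate", pd.Series(1.0, index=df.index))
        df["_hwe_p"] = df.get("hwe_p", pd.Series(1.0, index=df.index))
    maf = np.minimum(df["eaf"], 1 - df["eaf"])

    fail_rule = pd.Series("", index=df.index, dtype=object)
    fail_rule[(df["_hwe_p"] < t.min_hwe_p) ] = "hwe"
    fail_rule[maf < t.min_maf] = "maf"
    fail_rule[df["_missing"] > t.max_missing] = "missing"
    fail_rule[df["info"] < t.min_info] = "info"

    kept = df[fail_rule == ""].drop(columns=["_missing", "_hwe_p"]).reset_index(drop=True)
    excluded = pd.DataFrame({
        "variant_id": df.loc[fail_rule != "", "variant_id"].to_numpy(),
        "rule": fail_rule[fail_rule != ""].to_numpy(),
    })
    return kept, excluded


# ---------------------------------------------------------------------------
# inverse rank-normal transform
# ---------------------------------------------------------------------------

def inverse_rank_normalize(x) -> np.ndarray:
    """Blom inverse rank-normal transform: z = ndtri((rank - 3/8)/(n + 1/4)).

    Ties receive average ranks; any strictly monotone pre-transform of the
    input yields identical output.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("need a 1-D array with n >= 2")
    if np.unique(x).size == 1:
        raise ValueError("all values equal: ranks undefined")
    ranks = stats.rankdata(x, method="average")
    return ndtri((ranks - 3.0 / 8.0) / (x.size + 0.25))


# ---------------------------------------------------------------------------
# association scans
# ---------------------------------------------------------------------------

def _design(covariates: pd.DataFrame | np.ndarray | None, n: int) -> np.ndarray:
    if covariates is None:
        return np.ones((n, 1))
    C = np.asarray(covariates, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    X = np.column_stack([np.ones(n), C])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        names = (list(covariates.columns) if isinstance(covariates, pd.DataFrame)
                 else [f"c{j}" for j in range(C.shape[1])])
        raise ValueError(f"collinear covariates (rank {rank} < {X.shape[1]}): {names}")
    return X

def _impute_mean(G: np.ndarray) -> np.ndarray:
    if np.isnan(G).any():
        mu = np.nanmean(G, axis=0)
        idx = np.where(np.isnan(G))
        G = G.copy()
        G[idx] = mu[idx[1]]
    return G


def _linear_scan(y, G, X):
    """Per-variant OLS of y on dosage + covariates, via FWL residualization."""
    n, k = X.shape
    Q, _ = np.linalg.qr(X)
    yr = y - Q @ (Q.T @ y)
    Gr = G - Q @ (Q.T @ G)
    gg = np.einsum("ij,ij->j", Gr, Gr)
    gg = np.where(gg <= 0, np.nan, gg)
    beta = (Gr.T @ yr) / gg
    rss = float(yr @ yr) - beta**2 * gg
    df_resid = n - k - 1
    sigma2 = rss / df_resid
    se = np.sqrt(sigma2 / gg)
    tval = beta / se
    p = 2 * stats.t.sf(np.abs(tval), df_resid)
    return beta, se, p


def _logistic_scan(y, G, X, tol=1e-10, max_iter=40, chunk=512):
    """Per-variant logistic Wald scan, Newton iterations batched over variants.

    Each variant v fits logit(y) ~ X + g_v.  The covariate block is shared,
    so the score and Hessian pieces are assembled with einsums across a
    chunk of variants at a time and the (k+1)-dim Newton systems solved in
    one batched call.
    """
    n, k = X.shape
    V = G.shape[1]
    beta = np.empty(V)
    se = np.empty(V)
    base = np.log(y.mean() / (1 - y.mean() + 1e-12) + 1e-12)
    for start in range(0, V, chunk):
        Gc = G[:, start:start + chunk]
        m = Gc.shape[1]
        B = np.zeros((m, k + 1))
        B[:, 0] = base
        for _ in range(max_iter):
            eta = X @ B[:, :k].T + Gc * B[:, k]          # n x m
            mu = expit(eta)
            W = mu * (1 - mu) + 1e-12
            R = y[:, None] - mu
            grad = np.empty((m, k + 1))
            grad[:, :k] = R.T @ X
            grad[:, k] = np.einsum("nm,nm->m", Gc, R)
            H = np.empty((m, k + 1, k + 1))
            H[:, :k, :k] = np.einsum("ni,nm,nj->mij", X, W, X)
            xg = np.einsum("ni,nm,nm->mi", X, W, Gc)
            H[:, :k, k] = xg
            H[:, k, :k] = xg
            H[:, k, k] = np.einsum("nm,nm,nm->m", Gc, W, Gc)
            H[:, np.arange(k + 1), np.arange(k + 1)] += 1e-10
            step = np.linalg.solve(H, grad[:, :, None])[:, :, 0]
            B += step
            if np.abs(step).max() < tol:
                break
        cov = np.linalg.inv(H)
        beta[start:start + chunk] = B[:, k]
        se[start:start + chunk] = np.sqrt(cov[:, k, k])
    z = beta / se
    p = 2 * stats.norm.sf(np.abs(z))
    return beta, se, p


def gwas_scan(phenotype,
              genotypes: pd.DataFrame,
              variants: pd.DataFrame,
              covariates: pd.DataFrame | None = None,
              family: str = "linear") -> pd.DataFrame:
    """Per-variant association scan of a phenotype on dosages.

    Missing dosages are mean-imputed per variant so n is constant across
    variants.  ``family="linear"`` fits OLS (t reference); ``"logistic"``
    fits a per-variant logistic Wald test.  Returns a GWAS summary table in
    the standard column order joined to the variant metadata.
    """
    y = np.asarray(phenotype, dtype=float)
    ids = list(variants["variant_id"])
    G = _impute_mean(genotypes[ids].to_numpy(dtype=float))
    X = _design(covariates, len(y))
    if family == "linear":
        beta, se, p = _linear_scan(y, G, X)
    elif family == "logistic":
        uniq = np.unique(y)
        if not np.isin(uniq, [0.0, 1.0]).all():
            raise ValueError("logistic family requires a 0/1 phenotype")
        beta, se, p = _logistic_scan(y, G, X)
    else:
        raise ValueError(f"unknown family: {family!r}")
    out = variants.copy()
    out["eaf"] = G.mean(axis=0) / 2.0
    out["beta"] = beta
    out["se"] = se
    out["p"] = np.clip(p, np.nextafter(0, 1), 1.0)
    out["n"] = len(y)
    return out[GWAS_COLUMNS + [c for c in out.columns if c not in GWAS_COLUMNS]]


# ---------------------------------------------------------------------------
# LD and clumping
# ---------------------------------------------------------------------------

def ld_r2(genotypes: pd.DataFrame, i: str, j: str) -> float:
    """Squared Pearson correlation of two dosage columns (pairwise complete).

    Returns NaN (with a warning) when either variant is monomorphic among
    the overlapping individuals.
    """
    a = genotypes[i].to_numpy(dtype=float)
    b = genotypes[j].to_numpy(dtype=float)
    ok = ~(np.isnan(a) | np.isnan(b))
    if ok.sum() < 10:
        raise ValueError("fewer than 10 overlapping non-missing individuals")
    a, b = a[ok], b[ok]
    if a.std() == 0 or b.std() == 0:
        warnings.warn(f"monomorphic variant in pair ({i}, {j}); r2 undefined")
        return float("nan")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


@dataclass
class InstrumentSet:
    """Approximately independent significant variants chosen by clumping."""

    variant_ids: list[str]
    p_threshold: float
    r2_threshold: float
    window_bp: int
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.variant_ids)


def clump(summary: pd.DataFrame,
          genotypes: pd.DataFrame,
          p_threshold: float = DEFAULT_P_GENOME_WIDE,
          r2_threshold: float = 0.01,
          window_bp: int = 1_000_000) -> InstrumentSet:
    """Greedy LD clumping of a GWAS summary table.

    Variants passing ``p_threshold`` are visited in order of ascending p
    (position breaks ties); each accepted index variant discards every
    remaining variant within ``window_bp`` on the same chromosome whose
    dosage r-squared with it exceeds ``r2_threshold``.
    """
    check_gwas_frame(summary)
    sig = summary[summary["p"] < p_threshold].sort_values(
        ["p", "pos"], kind="mergesort").reset_index(drop=True)
    if sig.empty:
        warnings.warn("no variant passes the p threshold; empty instrument set")
        return InstrumentSet([], p_threshold, r2_threshold, window_bp)
    alive = np.ones(len(sig), dtype=bool)
    kept: list[str] = []
    for i in range(len(sig)):
        if not alive[i]:
            continue
        kept.append(sig.at[i, "variant_id"])
        alive[i] = False
        near = alive & (sig["chrom"] == sig.at[i, "chrom"]).to_numpy() & (
            (sig["pos"] - sig.at[i, "pos"]).abs() <= window_bp).to_numpy()
        for j in np.flatnonzero(near):
            if ld_r2(genotypes, sig.at[i, "variant_id"], sig.at[j, "variant_id"]) > r2_threshold:
                alive[j] = False
    return InstrumentSet(kept, p_threshold, r2_threshold, window_bp,
                         provenance={"n_significant": int(len(sig))})


def cis_filter(variants: pd.DataFrame,
               gene_chrom: str,
               gene_start: int,
               gene_end: int,
               flank: int = 100_000) -> pd.DataFrame:
    """Variants within the gene body or ``flank`` bp of it (inclusive bounds)."""
    if gene_start > gene_end:
        raise ValueError("gene_start must be <= gene_end")
    lo, hi = gene_start - flank, gene_end + flank
    keep = (variants["chrom"].astype(str) == str(gene_chrom)) & \
        variants["pos"].between(lo, hi, inclusive="both")
    return variants[keep].reset_index(drop=True)
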