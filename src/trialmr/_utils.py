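"""Shared helpers: error types, RNG derivation, TSV conventions."""

from __future__ import annotations

import numpy as np

#: exact column order of a GWAS summary-statistics table
GWAS_COLUMNS = [
    "variant_id", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "p", "n",
]


class ConfigError(ValueError):
    """Raised when a simulation or analysis configuration is invalid."""


def child_rngs(seed: int, n: int) -> list[np.random.Generator]:
    """Derive ``n`` independent generators from one integer seed."""
    ss = np.random.SeedSequence(seed)
    return [np.random.default_rng(s) for s in ss.spawn(n)]


def check_gwas_frame(df, name: str = "summary") -> None:
    missing = [c for c in GWAS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{name} is missing GWAS columns: {missing}")
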