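"""Tab-delimited readers/writers for the pipeline's tables.

GWAS summary statistics use the fixed column order
variant_id, chrom, pos, effect_allele, other_allele, eaf, beta, se, p, n.
Genotype dosage tables are individuals (rows) x variant ids (columns).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from ._utils import GWAS_COLUMNS, check_gwas_frame
from .signature import SignatureModel


def write_gwas(df: pd.DataFrame, path) -> None:
    check_gwas_frame(df)
    df[GWAS_COLUMNS].to_csv(path, sep="\t", index=False)


def read_gwas(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    check_gwas_frame(df, str(path))
    return df


def write_dosages(genotypes: pd.DataFrame, path) -> None:
    genotypes.to_csv(path, sep="\t", index_label="individual")


def read_dosages(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="individual")


def write_signature(model: SignatureModel, path) -> None:
    Path(path).write_text(json.dumps(model.to_dict(), indent=1))


def read_signature(path) -> SignatureModel:
    d = json.loads(Path(path).read_text())
    return SignatureModel(d["names"], np.asarray(d["weights"]), d["alpha"],
                          d.get("lambda"), cv_auc=d.get("cv_auc"))
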