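"""Immune gene-expression signatures: CytAct and the IFN-gamma score.

CytAct (cytolytic activity) is the per-sample mean of the z-scored log2
expression of granzyme A (GZMA) and perforin 1 (PRF1); it proxies cytotoxic
CD8+ T-cell activity.  The IFN-gamma score averages six interferon-gamma
related genes (IDO1, CXCL9, CXCL10, IFNG, HLA-DRA, STAT1).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

CYTACT_GENES = ("GZMA", "PRF1")
IFNG_GENES = ("IDO1", "CXCL9", "CXCL10", "IFNG", "HLA-DRA", "STAT1")


class ExpressionError(ValueError):
    pass


@dataclass
class ExpressionMatrix:
    """Genes x samples expression table.

    ``values`` has canonical (upper-case) gene symbols as the index and
    sample ids as columns.  ``log2`` marks whether values are already on the
    log2 scale; raw counts are transformed with log2(x + 1) before scoring.
    """

    values: pd.DataFrame
    log2: bool = True

    def __post_init__(self) -> None:
        vals = self.values.copy()
        vals.index = [str(g).upper() for g in vals.index]
        if vals.index.duplicated().any():
            dupes = sorted(set(vals.index[vals.index.duplicated()]))
            raise ExpressionError(f"duplicate gene symbols after canonicalization: {dupes}")
        if vals.columns.duplicated().any():
            raise ExpressionError("duplicate sample ids")
        arr = vals.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ExpressionError("expression values must be finite")
        if not self.log2 and (arr < 0).any():
            raise ExpressionError("raw expression values must be non-negative")
        self.values = vals

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def to_log2(self) -> "ExpressionMatrix":
        if self.log2:
            return self
        return ExpressionMatrix(values=np.log2(self.values + 1.0), log2=True)

    @classmethod
    def read_tsv(cls, path: str | Path, log2: bool = True) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(values=df, log2=log2)

    def write_tsv(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t")


@dataclass
class ImmuneScores:
    cytact: pd.Series
    ifng: pd.Series | None = None

    @property
    def n_samples(self) -> int:
        return len(self.cytact)

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"sample_id": self.cytact.index, "cytact": self.cytact.values})
        if self.ifng is not None:
            out["ifng"] = self.ifng.values
        return out

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def _locate_genes(mat: ExpressionMatrix, genes) -> list[str]:
    wanted = [g.upper() for g in genes]
    missing = [g for g in wanted if g not in mat.values.index]
    if missing:
        raise ExpressionError(f"genes not found in matrix: {missing}")
    return wanted


def zscore_genes(mat: ExpressionMatrix, genes) -> pd.DataFrame:
    """Z-score each requested gene across samples (sample sd, n-1 denominator)."""
    if mat.n_samples < 2:
        raise ExpressionError("need at least 2 samples to z-score")
    rows = mat.values.loc[_locate_genes(mat, genes)]
    mean = rows.mean(axis=1)
    sd = rows.std(axis=1, ddof=1)
    flat = sd[sd <= 0]
    if len(flat):
        raise ExpressionError(f"zero-variance gene(s): {list(flat.index)}")
    return rows.sub(mean, axis=0).div(sd, axis=0)


def cytact(mat: ExpressionMatrix) -> pd.Series:
    """Per-sample CytAct: mean of z-scored log2 GZMA and PRF1 expression."""
    z = zscore_genes(mat.to_log2(), CYTACT_GENES)
    out = z.mean(axis=0)
    out.name = "cytact"
    return out


def ifng_score(mat: ExpressionMatrix, zscore: bool = True) -> pd.Series:
    """Per-sample IFN-gamma score: mean of the six signature genes.

    Each gene is z-scored before averaging by default (comparable scale across
    genes, mirroring CytAct); ``zscore=False`` averages the log2 values
    directly.
    """
    logm = mat.to_log2()
    if zscore:
        rows = zscore_genes(logm, IFNG_GENES)
    else:
        rows = logm.values.loc[_locate_genes(logm, IFNG_GENES)]
    out = rows.mean(axis=0)
    out.name = "ifng"
    return out


def immune_scores(mat: ExpressionMatrix) -> ImmuneScores:
    return ImmuneScores(cytact=cytact(mat), ifng=ifng_score(mat))
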