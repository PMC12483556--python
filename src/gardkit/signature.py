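"""Rank-based gene-expression scoring of the radiosensitivity index (RSI).

RSI is a linear model over the within-sample expression *ranks* of ten
genes (AR, JUN, STAT1, PRKCB, RELA, ABL1, SUMO1, PAK2, HDAC1, IRF1).
Because only ranks enter the score, RSI is invariant to any strictly
increasing per-sample normalization of expression — the property that
makes it portable across array platforms.

Expression matrices are pandas DataFrames with genes as the index and
samples as the columns (the conventional genes-x-samples text layout).
Coefficients ship as a packaged default transcribed from the public
rank-based implementation, and can be overridden from a two-column
``{gene, coefficient}`` delimited file via :func:`load_signature`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

__all__ = [
    "SignatureDefinition",
    "RSI_SIGNATURE",
    "load_signature",
    "load_expression",
    "rank_transform",
    "score_rsi",
]

RankScope = Literal["signature", "all"]

#: Lower clip bound applied when a linear score exits (0, 1].
RSI_FLOOR = 1e-6


@dataclass(frozen=True)
class SignatureDefinition:
    """An ordered gene list with signed per-gene weights applied to ranks."""

    gene_symbols: tuple[str, ...]
    coefficients: tuple[float, ...]
    rank_scope: RankScope = "signature"

    def __post_init__(self) -> None:
        if len(self.gene_symbols) != len(self.coefficients):
            raise ValueError("gene_symbols and coefficients must have equal length")
        if len(set(self.gene_symbols)) != len(self.gene_symbols):
            raise ValueError("duplicate gene symbols in signature")
        if not all(np.isfinite(self.coefficients)):
            raise ValueError("signature coefficients must be finite")


# Ten-gene RSI linear model (ranks within sample; signed weights from the
# published rank-based model, as distributed by its public implementation).
RSI_SIGNATURE = SignatureDefinition(
    gene_symbols=(
        "AR", "JUN", "STAT1", "PRKCB", "RELA",
        "ABL1", "SUMO1", "PAK2", "HDAC1", "IRF1",
    ),
    coefficients=(
        -0.0098009, 0.0128283, 0.0254552, -0.0017589, -0.0038171,
        0.1070213, -0.0002509, -0.0092431, -0.0204469, -0.0441683,
    ),
    rank_scope="signature",
)


def load_signature(path, rank_scope: RankScope = "signature", sep=None) -> SignatureDefinition:
    """Read a ``{gene, coefficient}`` delimited text file into a signature."""
    df = pd.read_csv(path, sep=sep, engine="python")
    df.columns = [c.strip().lower() for c in df.columns]
    if not {"gene", "coefficient"} <= set(df.columns):
        raise ValueError("signature file needs 'gene' and 'coefficient' columns")
    return SignatureDefinition(
        gene_symbols=tuple(df["gene"].astype(str)),
        coefficients=tuple(df["coefficient"].astype(float)),
        rank_scope=rank_scope,
    )


def load_expression(path, sep=None) -> pd.DataFrame:
    """Read a genes-x-samples delimited expression table (gene ids in column 0)."""
    df = pd.read_csv(path, sep=sep, engine="python", index_col=0)
    if df.isna().any().any():
        raise ValueError("expression matrix contains missing values after preprocessing")
    if df.index.has_duplicates:
        raise ValueError("gene identifiers must be unique")
    return df.astype(float)


def _check_genes(matrix: pd.DataFrame, genes) -> None:
    missing = [g for g in genes if g not in matrix.index]
    if missing:
        raise KeyError(f"signature genes absent from expression matrix: {missing}")


def rank_transform(matrix: pd.DataFrame, scope_genes=None) -> pd.DataFrame:
    """Within-sample (column-wise) average ranks, ascending in expression.

    ``scope_genes`` restricts ranking to a gene subset (ranks 1..k within
    the subset); ties receive the average rank.
    """
    if scope_genes is not None:
        _check_genes(matrix, scope_genes)
        matrix = matrix.loc[list(scope_genes)]
    if matrix.shape[0] < 2:
        raise ValueError("need at least 2 genes in rank scope")
    return matrix.rank(axis=0, method="average")


def score_rsi(
    matrix: pd.DataFrame,
    signature: SignatureDefinition = RSI_SIGNATURE,
    clip: bool = True,
) -> pd.Series:
    """Per-sample RSI: the signature-weighted sum of within-sample gene ranks.

    With ``rank_scope="signature"`` the ten genes are ranked among
    themselves; with ``"all"`` each gene's rank is taken within the whole
    matrix. Scores falling outside (0, 1] are clipped to
    ``[RSI_FLOOR, 1]`` with a warning.
    """
    _check_genes(matrix, signature.gene_symbols)
    scope = signature.gene_symbols if signature.rank_scope == "signature" else None
    ranks = rank_transform(matrix, scope_genes=scope)
    coeffs = pd.Series(signature.coefficients, index=list(signature.gene_symbols))
    scores = ranks.loc[coeffs.index].mul(coeffs, axis=0).sum(axis=0)
    if not np.all(np.isfinite(scores)):
        raise ValueError("non-finite RSI score produced")
    if clip:
        out_of_range = (scores <= 0) | (scores > 1)
        if out_of_range.any():
            warnings.warn(
                f"{int(out_of_range.sum())} RSI score(s) outside (0, 1] clipped to "
                f"[{RSI_FLOOR}, 1]",
                RuntimeWarning,
                stacklevel=2,
            )
            scores = scores.clip(lower=RSI_FLOOR, upper=1.0)
    scores.name = "rsi"
    return scores
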