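"""All-pairs Pearson correlation with significance and the Mutual Rank statistic.

Pearson correlations are computed across samples (replicate-level columns by
default, or cell-type means); two-sided p-values come from the t statistic
``t = r * sqrt((n-2) / (1-r^2))`` on n-2 degrees of freedom and are
BH-corrected over the upper triangle. Mutual Rank is the geometric mean of
the position each gene occupies in the other gene's correlation-sorted
partner list: reciprocal best partners have MR = 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import rankdata

from .expression import bh_fdr

__all__ = ["CoexpressionResult", "pearson_matrix", "mutual_rank", "coexpress"]


@dataclass
class CoexpressionResult:
    """Symmetric PCC / p / q / Mutual-Rank matrices over the selected genes."""

    genes: pd.Index
    pcc: pd.DataFrame
    p: pd.DataFrame
    q: pd.DataFrame
    mr: Optional[pd.DataFrame]
    n_samples: int
    masked_genes: list[str]

    def validate(self) -> None:
        r = self.pcc.to_numpy()
        if not np.allclose(r, r.T, equal_nan=True):
            raise ValueError("PCC matrix must be symmetric")
        if np.nanmax(np.abs(r)) > 1 + 1e-9:
            raise ValueError("|PCC| must be <= 1")
        if not np.allclose(np.diag(r), 1.0):
            raise ValueError("PCC diagonal must be 1")
        if self.mr is not None:
            m = self.mr.to_numpy()
            off = ~np.eye(m.shape[0], dtype=bool)
            if not np.allclose(m, m.T, equal_nan=True):
                raise ValueError("MR matrix must be symmetric")
            if m.shape[0] > 1 and np.nanmin(m[off]) < 1 - 1e-9:
                raise ValueError("MR values must be >= 1")

    def pair_table(self) -> pd.DataFrame:
        """Long-format upper triangle: gene_a, gene_b, pcc, p, q, mr."""
        iu = np.triu_indices(len(self.genes), k=1)
        rows = pd.DataFrame(
            {
                "gene_a": self.genes[iu[0]],
                "gene_b": self.genes[iu[1]],
                "pcc": self.pcc.to_numpy()[iu],
                "p": self.p.to_numpy()[iu],
                "q": self.q.to_numpy()[iu],
            }
        )
        if self.mr is not None:
            rows["mr"] = self.mr.to_numpy()[iu]
        return rows


def _celltype_means(tpm: pd.DataFrame, samples: pd.DataFrame) -> pd.DataFrame:
    groups = samples.loc[tpm.columns, "cell_type"]
    order = list(dict.fromkeys(groups))
    return tpm.T.groupby(groups.values).mean().T[order]


def pearson_matrix(
    tpm: pd.DataFrame,
    samples: Optional[pd.DataFrame] = None,
    sample_mode: str = "replicates",
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """PCC, p-value and BH-q matrices over the genes of ``tpm`` (genes x samples).

    Constant (zero-variance) genes are masked: dropped from the result with a
    warning. Requires at least 3 samples.
    """
    if sample_mode not in ("replicates", "celltype_means"):
        raise ValueError("sample_mode must be 'replicates' or 'celltype_means'")
    if sample_mode == "celltype_means":
        if samples is None:
            raise ValueError("celltype_means mode requires sample metadata")
        tpm = _celltype_means(tpm, samples)
    n = tpm.shape[1]
    if n < 3:
        raise ValueError("need >= 3 samples for correlation significance")

    x = tpm.to_numpy(dtype=float)
    variances = x.var(axis=1)
    constant = variances == 0
    masked = list(tpm.index[constant])
    if masked:
        warnings.warn(f"masking {len(masked)} constant gene(s) in correlation")
        tpm = tpm.loc[~constant]
        x = x[~constant]

    r = np.atleast_2d(np.corrcoef(x))
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)

    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r ** 2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    np.fill_diagonal(p, 0.0)

    q = np.zeros_like(p)
    iu = np.triu_indices(len(tpm.index), k=1)
    if iu[0].size:
        q_flat = bh_fdr(p[iu])
        q[iu] = q_flat
        q = q + q.T
    genes = tpm.index
    return (
        pd.DataFrame(r, index=genes, columns=genes),
        pd.DataFrame(p, index=genes, columns=genes),
        pd.DataFrame(q, index=genes, columns=genes),
    )


def mutual_rank(pcc: pd.DataFrame | np.ndarray) -> pd.DataFrame:
    """Mutual Rank: geometric mean of reciprocal correlation ranks.

    For each gene i, partners j != i are ranked by descending PCC (rank 1 =
    most correlated; ties receive the average rank); ``mr[i, j] =
    sqrt(rank_i(j) * rank_j(i))``. The diagonal is NaN.
    """
    df = pd.DataFrame(pcc) if not isinstance(pcc, pd.DataFrame) else pcc
    a = df.to_numpy(dtype=float)
    if a.shape[0] != a.shape[1]:
        raise ValueError("PCC matrix must be square")
    n = a.shape[0]
    ranks = np.full((n, n), np.nan)
    idx = np.arange(n)
    for i in range(n):
        others = idx != i
        ranks[i, others] = rankdata(-a[i, others])
    mr = np.sqrt(ranks * ranks.T)
    return pd.DataFrame(mr, index=df.index, columns=df.columns)


def coexpress(
    tpm: pd.DataFrame,
    samples: Optional[pd.DataFrame] = None,
    sample_mode: str = "replicates",
) -> CoexpressionResult:
    """Full coexpression analysis: PCC + significance + Mutual Rank."""
    n = tpm.shape[1] if sample_mode == "replicates" else \
        len(dict.fromkeys(samples.loc[tpm.columns, "cell_type"]))
    pcc, p, q = pearson_matrix(tpm, samples, sample_mode)
    masked = [g for g in tpm.index if g not in pcc.index]
    mr = mutual_rank(pcc)
    result = CoexpressionResult(pcc.index, pcc, p, q, mr, n, masked)
    result.validate()
    return result
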