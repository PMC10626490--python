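"""Gene-level expression handling: aggregation, TPM, filtering, TMM and
epidermis-vs-rest differential expression.

The analysis follows the cell-type transcriptomics workflow: transcript-level
abundances are summed to gene level; genes are retained when their TPM reaches
a threshold in at least one cell type (a "sample" being the mean of that cell
type's biological replicates); counts are normalized between samples with
trimmed-mean-of-M-values (TMM) scaling factors; and differential expression
contrasts the epidermis against all other cell types pooled, using a
negative-binomial exact test with a method-of-moments common dispersion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ExpressionDataset",
    "aggregate_transcripts_to_genes",
    "tpm_from_counts",
    "expression_filter",
    "tmm_factors",
    "differential_expression",
    "select_de_genes",
    "bh_fdr",
]

TPM_SCALE = 1e6


@dataclass
class ExpressionDataset:
    """Counts + TPM for genes x (cell type, replicate) samples.

    ``counts`` and ``tpm`` are genes x samples DataFrames sharing identical
    indices; ``samples`` maps each sample id to its cell type and replicate.
    """

    counts: pd.DataFrame
    tpm: pd.DataFrame
    samples: pd.DataFrame  # index: sample id; columns: cell_type, replicate
    gene_lengths: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.counts.index.equals(self.tpm.index):
            raise ValueError("counts and tpm must share an identical gene index")
        if not self.counts.columns.equals(self.tpm.columns):
            raise ValueError("counts and tpm must share identical sample columns")
        if not set(self.counts.columns) <= set(self.samples.index):
            missing = set(self.counts.columns) - set(self.samples.index)
            raise ValueError(f"samples missing metadata: {sorted(missing)}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be nonnegative")
        colsums = self.tpm.sum(axis=0).to_numpy(dtype=float)
        nonzero = colsums > 0
        if nonzero.any():
            rel = np.abs(colsums[nonzero] - TPM_SCALE) / TPM_SCALE
            if (rel > 1e-6).any():
                raise ValueError("each nonzero TPM column must sum to 1e6 (rel. 1e-6)")

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def cell_types(self) -> list[str]:
        return list(dict.fromkeys(self.samples["cell_type"]))

    def samples_of(self, cell_type: str) -> list[str]:
        sel = self.samples.index[self.samples["cell_type"] == cell_type]
        return [s for s in self.counts.columns if s in set(sel)]

    def celltype_mean_tpm(self) -> pd.DataFrame:
        """Mean TPM per cell type (one 'sample' = the mean of its replicates)."""
        groups = self.samples.loc[self.counts.columns, "cell_type"]
        out = self.tpm.T.groupby(groups.values).mean().T
        return out[self.cell_types]


def aggregate_transcripts_to_genes(
    transcript_counts: pd.DataFrame,
    transcript_tpm: pd.DataFrame,
    tx2gene: Mapping[str, str] | pd.Series,
    samples: pd.DataFrame,
    gene_lengths: Optional[pd.Series] = None,
) -> ExpressionDataset:
    """Sum transcript-level counts and TPMs to gene level.

    Every transcript must map to exactly one gene; an unmapped transcript id
    raises a ``KeyError`` naming it.
    """
    mapping = pd.Series(dict(tx2gene)) if not isinstance(tx2gene, pd.Series) else tx2gene
    unmapped = transcript_counts.index.difference(mapping.index)
    if len(unmapped):
        raise KeyError(f"unmapped transcript id(s): {list(unmapped[:5])}")
    genes_c = transcript_counts.groupby(mapping.loc[transcript_counts.index].values).sum()
    genes_t = transcript_tpm.groupby(mapping.loc[transcript_tpm.index].values).sum()
    genes_c = genes_c.sort_index()
    genes_t = genes_t.sort_index().loc[genes_c.index]
    return ExpressionDataset(genes_c, genes_t, samples, gene_lengths)


def tpm_from_counts(counts: pd.DataFrame, gene_lengths_bp: pd.Series | np.ndarray) -> pd.DataFrame:
    """Transcripts-per-million from raw counts and gene lengths.

    Per column: ``rate_g = count_g / length_g``; ``tpm_g = 1e6 * rate_g /
    sum(rates)``. Columns with zero total signal come back all-zero with a
    warning rather than NaN.
    """
    lengths = np.asarray(
        gene_lengths_bp.loc[counts.index] if isinstance(gene_lengths_bp, pd.Series) else gene_lengths_bp,
        dtype=float,
    )
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    rates = counts.to_numpy(dtype=float) / lengths[:, None]
    totals = rates.sum(axis=0)
    zero = totals == 0
    if zero.any():
        warnings.warn("all-zero count column(s); emitting all-zero TPM column(s)")
        totals = np.where(zero, 1.0, totals)
    tpm = TPM_SCALE * rates / totals
    return pd.DataFrame(tpm, index=counts.index, columns=counts.columns)


def expression_filter(dataset: ExpressionDataset, threshold_tpm: float = 5.0) -> pd.Index:
    """Genes whose mean TPM reaches ``threshold_tpm`` in at least one cell type.

    The per-cell-type mean over replicates is the unit of comparison; the
    boundary is inclusive (TPM >= threshold).
    """
    groups = dataset.samples.loc[dataset.counts.columns, "cell_type"]
    counts_per_type = groups.value_counts()
    if (counts_per_type < 1).any():
        raise ValueError("every cell type must have at least one replicate")
    means = dataset.celltype_mean_tpm()
    keep = (means >= threshold_tpm).any(axis=1)
    return dataset.genes[keep]


# ---------------------------------------------------------------------------
# TMM normalization
# ---------------------------------------------------------------------------

def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    trim_logratio: float,
    trim_intensity: float,
) -> float:
    """TMM scaling factor of one sample against the reference sample."""
    both = (obs > 0) & (ref > 0)
    if not both.any():
        raise ValueError("sample shares no expressed genes with the reference")
    o = obs[both].astype(float)
    r = ref[both].astype(float)
    m = np.log2((o / lib_obs) / (r / lib_ref))
    a = 0.5 * np.log2((o / lib_obs) * (r / lib_ref))
    # asymptotic (delta-method) inverse variance of M
    w = (lib_obs - o) / (lib_obs * o) + (lib_ref - r) / (lib_ref * r)

    n = m.size
    lo_l = np.floor(n * trim_logratio) + 1
    hi_l = n + 1 - lo_l
    lo_s = np.floor(n * trim_intensity) + 1
    hi_s = n + 1 - lo_s
    rank_m = rankdata(m)
    rank_a = rankdata(a)
    keep = (rank_m >= lo_l) & (rank_m <= hi_l) & (rank_a >= lo_s) & (rank_a <= hi_s)
    if not keep.any() or w[keep].sum() == 0:
        return 1.0
    f = np.sum(w[keep] * m[keep]) / np.sum(w[keep])
    if not np.isfinite(f):
        return 1.0
    return float(2.0 ** f)


def tmm_factors(
    counts: pd.DataFrame,
    trim_logratio: float = 0.3,
    trim_intensity: float = 0.05,
) -> pd.Series:
    """Trimmed-mean-of-M-values scaling factors, one per sample.

    Reference sample: the one whose upper-quartile count proportion is closest
    to the mean upper quartile. Per sample, M (log2 ratio of library-size-
    normalized proportions vs the reference) and A values over genes nonzero
    in both are doubly trimmed (30% of M, 5% of A by default, each side) and
    the factor is 2^(precision-weighted mean of the retained M). Factors are
    rescaled to geometric mean 1.
    """
    x = counts.to_numpy(dtype=float)
    if x.shape[1] < 2:
        raise ValueError("TMM requires at least two samples")
    lib = x.sum(axis=0)
    if (lib == 0).any():
        raise ValueError("zero library size column")
    f75 = np.quantile(x / lib, 0.75, axis=0)
    ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    factors = np.empty(x.shape[1])
    for j in range(x.shape[1]):
        if j == ref_idx:
            factors[j] = _tmm_pair(
                x[:, j], x[:, ref_idx], lib[j], lib[ref_idx], trim_logratio, trim_intensity
            )
        else:
            factors[j] = _tmm_pair(
                x[:, j], x[:, ref_idx], lib[j], lib[ref_idx], trim_logratio, trim_intensity
            )
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


# ---------------------------------------------------------------------------
# Differential expression (NB exact test, common MoM dispersion)
# ---------------------------------------------------------------------------

def _common_dispersion(z: np.ndarray, group_masks: Sequence[np.ndarray]) -> float:
    """Method-of-moments common NB dispersion from within-group variability.

    Per gene, pooled excess variance over squared mean across groups; the
    common value is the across-gene mean of the per-gene estimates (floored
    at 0, i.e. Poisson).
    """
    num = np.zeros(z.shape[0])
    den = np.zeros(z.shape[0])
    for mask in group_masks:
        zk = z[:, mask]
        nk = mask.sum()
        if nk < 2:
            continue
        mk = zk.mean(axis=1)
        vk = zk.var(axis=1, ddof=1)
        num += (nk - 1) * (vk - mk)
        den += (nk - 1) * mk ** 2
    ok = den > 0
    if not ok.any():
        return 0.0
    phi = float(np.mean(num[ok] / den[ok]))
    return max(phi, 0.0)


def _nb_exact_pvalue(s1: float, s2: float, n1: int, n2: int, dispersion: float) -> float:
    """Two-sided exact test of equal means, conditional on the pooled sum.

    Group sums of n iid NB(mu, phi) samples are NB(n*mu, phi/n); conditional
    on S = s1 + s2 the p-value sums the probabilities of all splits at most
    as likely as the observed one. Very large pooled sums (> 2e5) fall back
    to a two-tailed marginal NB approximation.
    """
    s1 = int(round(s1))
    s2 = int(round(s2))
    s = s1 + s2
    if s == 0:
        return 1.0
    frac1 = n1 / (n1 + n2)
    mean1 = s * frac1
    mean2 = s - mean1

    def _logpmf(x: np.ndarray, mean: float, phi_over_n: float) -> np.ndarray:
        if phi_over_n < 1e-12:
            return stats.poisson.logpmf(x, mean)
        r = 1.0 / phi_over_n
        p = r / (r + mean)
        return stats.nbinom.logpmf(x, r, p)

    if s > 200_000:
        lo = stats.nbinom.cdf(s1, n1 / dispersion, (n1 / dispersion) / (n1 / dispersion + mean1)) \
            if dispersion >= 1e-12 else stats.poisson.cdf(s1, mean1)
        hi = stats.nbinom.sf(s1 - 1, n1 / dispersion, (n1 / dispersion) / (n1 / dispersion + mean1)) \
            if dispersion >= 1e-12 else stats.poisson.sf(s1 - 1, mean1)
        return float(min(1.0, 2.0 * min(lo, hi)))

    x = np.arange(s + 1)
    logg = _logpmf(x, mean1, dispersion / n1) + _logpmf(x[::-1], mean2, dispersion / n2)
    logg -= logg.max()
    g = np.exp(logg)
    total = g.sum()
    observed = g[s1]
    p = g[g <= observed * (1 + 1e-12)].sum() / total
    return float(min(1.0, p))


def differential_expression(
    dataset: ExpressionDataset,
    epidermis: str = "epidermis",
    threshold_tpm: float = 5.0,
    pseudocount: float = 0.5,
    min_fold: float = 5.0,
    max_fdr: float = 0.05,
) -> pd.DataFrame:
    """Epidermis-vs-pooled-others differential expression table.

    Counts of expression-filtered genes are TMM-normalized; per gene the fold
    change is the ratio of normalized group means (with a small pseudocount),
    the p-value comes from a conditional negative-binomial exact test with a
    common method-of-moments dispersion, and FDR is Benjamini-Hochberg over
    the tested genes. Genes failing the expression filter carry NaN p/FDR.
    """
    sample_types = dataset.samples.loc[dataset.counts.columns, "cell_type"]
    g1 = (sample_types == epidermis).to_numpy()
    g2 = ~g1
    if g1.sum() < 2 or g2.sum() < 2:
        raise ValueError("each group needs >=2 samples (dispersion inestimable)")

    retained = expression_filter(dataset, threshold_tpm)
    counts = dataset.counts.loc[retained]
    x = counts.to_numpy(dtype=float)
    factors = tmm_factors(counts).to_numpy()
    eff_lib = x.sum(axis=0) * factors
    scale = np.exp(np.mean(np.log(eff_lib))) / eff_lib
    z = x * scale  # counts on a common effective library size

    m1 = z[:, g1].mean(axis=1)
    m2 = z[:, g2].mean(axis=1)
    fc = (m1 + pseudocount) / (m2 + pseudocount)

    phi = _common_dispersion(z, [g1, g2])
    n1, n2 = int(g1.sum()), int(g2.sum())
    s1 = z[:, g1].sum(axis=1)
    s2 = z[:, g2].sum(axis=1)
    pvals = np.array([_nb_exact_pvalue(a, b, n1, n2, phi) for a, b in zip(s1, s2)])
    fdr = bh_fdr(pvals)

    table = pd.DataFrame(index=dataset.genes)
    table["mean_epidermis"] = np.nan
    table["mean_other"] = np.nan
    table["fold_change"] = np.nan
    table["log2_fold_change"] = np.nan
    table["p_value"] = np.nan
    table["fdr"] = np.nan
    table.loc[retained, "mean_epidermis"] = m1
    table.loc[retained, "mean_other"] = m2
    table.loc[retained, "fold_change"] = fc
    table.loc[retained, "log2_fold_change"] = np.log2(fc)
    table.loc[retained, "p_value"] = pvals
    table.loc[retained, "fdr"] = fdr
    table["pass_expression_filter"] = table.index.isin(retained)
    table["direction"] = np.where(table["fold_change"] >= 1, "up", "down")
    up = (table["fold_change"] >= min_fold) & (table["fdr"] < max_fdr)
    down = (table["fold_change"] <= 1.0 / min_fold) & (table["fdr"] < max_fdr)
    table["pass_de_filter"] = table["pass_expression_filter"] & (up | down).fillna(False)
    table.attrs["common_dispersion"] = phi
    table.attrs["tmm_factors"] = dict(zip(counts.columns, factors))
    return table


def select_de_genes(
    table: pd.DataFrame,
    min_fold: float = 5.0,
    max_fdr: float = 0.05,
    direction: str = "up",
) -> pd.Index:
    """Genes meeting the selection rule: fold >= ``min_fold`` (inclusive),
    FDR < ``max_fdr`` (strict), and the expression filter, in the requested
    direction ('up', 'down', or 'both'; down means fold <= 1/min_fold)."""
    if direction not in ("up", "down", "both"):
        raise ValueError("direction must be 'up', 'down' or 'both'")
    fc = table["fold_change"]
    ok_fdr = table["fdr"] < max_fdr
    ok_expr = table["pass_expression_filter"].astype(bool)
    up = fc >= min_fold
    down = fc <= 1.0 / min_fold
    if direction == "up":
        chosen = up
    elif direction == "down":
        chosen = down
    else:
        chosen = up | down
    mask = (chosen & ok_fdr & ok_expr).fillna(False)
    return table.index[mask]


def bh_fdr(p_values: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(list(p_values) if not isinstance(p_values, np.ndarray) else p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
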