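"""Expression summarization and differential-expression statistics.

Implements RPKM, Welch (heteroscedastic) and paired t tests, a one-way F
test, Benjamini-Hochberg adjustment, a volcano-style DE summary, PCA sample
scores on a p-value-prefiltered gene set and row z-scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class ExpressionMatrix:
    """Genes x samples counts with lengths, library sizes and annotations.

    RPKM = counts * 1e9 / (gene_length * library_size); library size defaults
    to the per-sample column sum.
    """

    counts: pd.DataFrame  # genes x samples, non-negative
    gene_lengths: pd.Series  # bp, > 0, indexed like counts
    groups: pd.Series  # per sample
    pairs: pd.Series | None = None  # pairing id per sample, for paired tests
    library_sizes: pd.Series | None = None
    truth: dict = field(default_factory=dict)  # generator ground truth

    def __post_init__(self):
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        self.gene_lengths = self.gene_lengths.reindex(self.counts.index)
        if (self.gene_lengths <= 0).any() or self.gene_lengths.isna().any():
            raise ValueError("gene lengths must be positive for all genes")
        if self.library_sizes is None:
            self.library_sizes = self.counts.sum(axis=0)

    @property
    def rpkm(self) -> pd.DataFrame:
        lib = self.library_sizes.astype(float)
        return (self.counts * 1e9).div(self.gene_lengths, axis=0).div(lib, axis=1)


def rpkm(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Reads per kilobase of transcript per million mapped reads."""
    return matrix.rpkm


def welch_t(matrix: ExpressionMatrix, groups: pd.Series | None = None) -> pd.Series:
    """Two-tailed heteroscedastic t test per gene (Welch-Satterthwaite df).

    Zero-variance genes make the statistic 0/0: identical groups score
    p = 1 (no evidence), differing constant groups p = 0.
    """
    a, b = _two_group_split(matrix, groups)
    with np.errstate(invalid="ignore"):
        p = stats.ttest_ind(a, b, axis=1, equal_var=False).pvalue
    nan = np.isnan(p)
    if nan.any():
        same = np.isclose(a.mean(axis=1), b.mean(axis=1))
        p = np.where(nan & same, 1.0, np.where(nan, 0.0, p))
    return pd.Series(p, index=matrix.counts.index, name="p_welch")


def paired_t(matrix: ExpressionMatrix, pairs: pd.Series | None = None) -> pd.Series:
    """Two-tailed paired t test per gene; samples matched by pairing id."""
    groups = matrix.groups
    pairs = matrix.pairs if pairs is None else pairs
    if pairs is None:
        raise ValueError("paired test requires pairing annotations")
    lv = sorted(groups.unique())
    if len(lv) != 2:
        raise ValueError("paired test requires exactly two groups")
    a_cols = groups[groups == lv[0]].index
    b_by_pair = {pairs[c]: c for c in groups[groups == lv[1]].index}
    try:
        b_cols = [b_by_pair[pairs[c]] for c in a_cols]
    except KeyError as e:
        raise ValueError(f"incomplete pair {e}") from e
    p = stats.ttest_rel(
        matrix.counts[a_cols].values, matrix.counts[b_cols].values, axis=1
    ).pvalue
    return pd.Series(p, index=matrix.counts.index, name="p_paired")


def oneway_f(matrix: ExpressionMatrix, groups: pd.Series | None = None) -> pd.Series:
    """One-way F test per gene across >= 3 groups (2 allowed, = t^2)."""
    groups = matrix.groups if groups is None else groups
    arrays = [
        matrix.counts[groups[groups == g].index].values for g in sorted(groups.unique())
    ]
    if any(a.shape[1] < 2 for a in arrays):
        raise ValueError("each group needs >= 2 samples")
    p = stats.f_oneway(*arrays, axis=1).pvalue
    return pd.Series(p, index=matrix.counts.index, name="p_f")


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up: q_(i) = min_{j>=i} p_(j) * m / j, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-D p-value vector")
    m = p.size
    if m == 0:
        return np.array([])
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


@dataclass
class DEGResult:
    """Per-gene DE summary: log2 fold change, p, BH q, significance flag."""

    table: pd.DataFrame  # columns: log2fc, p, q, significant
    fdr: float
    test: str
    n_dropped_allzero: int
    n_dropped_zerovar: int

    @property
    def significant_genes(self) -> pd.Index:
        return self.table.index[self.table["significant"]]


def differential_expression(
    matrix: ExpressionMatrix,
    groups: pd.Series | None = None,
    paired: bool = False,
    fdr: float = 0.05,
    pseudocount: float = 1.0,
) -> DEGResult:
    """Two-group DE: log2FC on mean RPKM (+pseudocount), Welch or paired t, BH.

    Genes with all-zero counts in both groups are dropped before testing (they
    carry no evidence and would deflate the BH denominator); zero-variance
    non-identical genes are kept, identical-in-both-groups constant genes are
    flagged and excluded from testing.
    """
    groups = matrix.groups if groups is None else groups
    lv = sorted(groups.unique())
    if len(lv) != 2:
        raise ValueError("differential_expression is two-group")
    a_cols = groups[groups == lv[0]].index
    b_cols = groups[groups == lv[1]].index

    counts = matrix.counts
    nonzero = counts[a_cols.union(b_cols)].sum(axis=1) > 0
    n_allzero = int((~nonzero).sum())

    sub = counts.loc[nonzero]
    a, b = sub[a_cols].values, sub[b_cols].values
    zerovar = (a.std(axis=1) == 0) & (b.std(axis=1) == 0) & (a.mean(axis=1) == b.mean(axis=1))
    keep = ~zerovar
    n_zerovar = int(zerovar.sum())

    tested = sub.loc[keep]
    rp = matrix.rpkm.loc[tested.index]
    log2fc = np.log2(rp[a_cols].mean(axis=1) + pseudocount) - np.log2(
        rp[b_cols].mean(axis=1) + pseudocount
    )
    sub_matrix = ExpressionMatrix(
        counts=tested,
        gene_lengths=matrix.gene_lengths.loc[tested.index],
        groups=groups,
        pairs=matrix.pairs,
        library_sizes=matrix.library_sizes,
    )
    p = paired_t(sub_matrix) if paired else welch_t(sub_matrix)
    q = bh_adjust(p.values)
    table = pd.DataFrame(
        {
            "log2fc": log2fc,
            "p": p,
            "q": q,
            "significant": q < fdr,
            "neg_log10_p": -np.log10(np.maximum(p, 1e-300)),
        },
        index=tested.index,
    )
    return DEGResult(
        table=table,
        fdr=fdr,
        test="paired_t" if paired else "welch_t",
        n_dropped_allzero=n_allzero,
        n_dropped_zerovar=n_zerovar,
    )


def zscore_rows(values: pd.DataFrame) -> tuple[pd.DataFrame, pd.Index]:
    """Mean-centre and sigma-normalize each row; constant rows are excluded.

    Returns (z-scored matrix, index of excluded constant rows).
    """
    sd = values.std(axis=1, ddof=0)
    constant = values.index[sd == 0]
    kept = values.loc[sd > 0]
    z = kept.sub(kept.mean(axis=1), axis=0).div(sd[sd > 0], axis=0)
    return z, constant


def pca_scores(
    matrix: ExpressionMatrix,
    prefilter_p: pd.Series | None = None,
    p_cutoff: float = 0.05,
    n_components: int = 2,
) -> pd.DataFrame:
    """Sample scores from SVD of the row-centred (genes x samples) matrix.

    ``prefilter_p`` restricts to genes with p < ``p_cutoff`` (the multigroup
    F test is the conventional source). Sign convention: within each
    component the largest-magnitude gene loading is made positive.
    """
    values = matrix.rpkm
    if prefilter_p is not None:
        values = values.loc[prefilter_p.index[prefilter_p < p_cutoff]]
    if values.shape[0] < 1:
        raise ValueError("no genes left after prefilter")
    centred = values.sub(values.mean(axis=1), axis=0)
    u, s, vt = np.linalg.svd(centred.values, full_matrices=False)
    k = min(n_components, s.size)
    for j in range(k):
        if u[np.abs(u[:, j]).argmax(), j] < 0:
            u[:, j] *= -1
            vt[j, :] *= -1
    scores = vt[:k].T * s[:k]
    return pd.DataFrame(
        scores, index=values.columns, columns=[f"PC{i+1}" for i in range(k)]
    )


def _two_group_split(matrix: ExpressionMatrix, groups: pd.Series | None):
    groups = matrix.groups if groups is None else groups
    lv = sorted(groups.unique())
    if len(lv) != 2:
        raise ValueError("expected exactly two groups")
    a = matrix.counts[groups[groups == lv[0]].index].values
    b = matrix.counts[groups[groups == lv[1]].index].values
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("each group needs >= 2 samples")
    return a, b
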