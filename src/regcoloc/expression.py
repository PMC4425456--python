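"""Expression normalization, fold-change ranking, and GSEA.

RPKM (reads per kilobase of gene model per million library reads)::

    rpkm = count * 1e9 / (gene_length_bp * library_size)

Genes are ranked by log2 fold change of mean RPKM between two sample groups
(with a small pseudo-value to stabilise lowly expressed genes), and a gene
set is tested for enrichment at either end of the ranked list with the GSEA
running-sum statistic.  The enrichment score (ES) is the signed maximum
deviation of the running sum; positive ES = enrichment among upregulated
genes.  Significance comes from a gene-set permutation null.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "GSEAResult",
    "rpkm",
    "rank_by_fold_change",
    "gsea_enrichment_score",
    "gsea_permutation_fdr",
    "gsea",
]

DEFAULT_EPSILON = 0.1  # RPKM pseudo-value in fold changes


@dataclass
class ExpressionMatrix:
    """Gene x sample raw counts with gene lengths and group labels."""

    counts: pd.DataFrame  # genes x samples, non-negative integers
    gene_lengths: pd.Series  # bp, indexed like counts
    groups: dict[str, list[str]]  # group label -> sample names

    def __post_init__(self) -> None:
        self.gene_lengths = self.gene_lengths.reindex(self.counts.index)
        if self.gene_lengths.isna().any():
            raise ValueError("every gene needs a length")
        for label, samples in self.groups.items():
            missing = set(samples) - set(self.counts.columns)
            if missing:
                raise ValueError(f"group {label!r}: unknown samples {sorted(missing)}")

    @property
    def rpkm(self) -> pd.DataFrame:
        return rpkm(self.counts, self.gene_lengths)


def rpkm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """RPKM-normalise a genes x samples count matrix.

    Library size is the column sum of counts.  Raises on zero library sizes
    or non-positive gene lengths.
    """
    lengths = lengths.reindex(counts.index)
    if (lengths <= 0).any() or lengths.isna().any():
        raise ValueError("gene lengths must be positive for all genes")
    libsize = counts.sum(axis=0)
    if (libsize <= 0).any():
        bad = list(libsize.index[libsize <= 0])
        raise ValueError(f"zero library size in samples {bad}")
    return counts * 1e9 / np.outer(lengths.to_numpy(), libsize.to_numpy())


def rank_by_fold_change(
    expr: ExpressionMatrix,
    group_a: str,
    group_b: str,
    epsilon: float = DEFAULT_EPSILON,
) -> pd.Series:
    """Genes ranked by log2 fold change of mean RPKM, group_a over group_b.

    score = log2((mean RPKM_a + eps) / (mean RPKM_b + eps)); descending, so
    the most upregulated gene in group_a comes first.  Ties are broken by
    gene symbol for determinism.
    """
    for g in (group_a, group_b):
        if g not in expr.groups or len(expr.groups[g]) == 0:
            raise ValueError(f"group {g!r} has no samples")
    r = expr.rpkm
    mean_a = r[expr.groups[group_a]].mean(axis=1)
    mean_b = r[expr.groups[group_b]].mean(axis=1)
    score = np.log2((mean_a + epsilon) / (mean_b + epsilon))
    df = pd.DataFrame({"score": score, "gene": score.index})
    df = df.sort_values(["score", "gene"], ascending=[False, True], kind="stable")
    return pd.Series(df["score"].to_numpy(), index=df["gene"].to_numpy(), name="score")


@dataclass
class GSEAResult:
    es: float
    running_sum: np.ndarray
    hit_positions: np.ndarray
    n_permutations: int | None = None
    fdr_p: float | None = None


def _running_sum(scores: np.ndarray, is_hit: np.ndarray, p: float) -> np.ndarray:
    """GSEA running sum over the ranked list.

    Hits add |score|^p normalised by the sum over hits; misses subtract
    1/(N - |S|).  With p = 0 the sum always returns to 0 at the end.
    """
    n = len(scores)
    n_hit = int(is_hit.sum())
    weights = np.abs(scores) ** p
    hit_w = np.where(is_hit, weights, 0.0)
    denom = hit_w.sum()
    if denom == 0:
        # all hit scores are exactly 0 under p>0: fall back to equal weights
        hit_w = is_hit.astype(float)
        denom = hit_w.sum()
    miss_pen = 1.0 / (n - n_hit) if n > n_hit else 0.0
    steps = hit_w / denom - np.where(is_hit, 0.0, miss_pen)
    return np.cumsum(steps)


def gsea_enrichment_score(
    ranked: pd.Series,
    gene_set: Iterable[str],
    weight_exponent: float = 1.0,
) -> GSEAResult:
    """Enrichment score of ``gene_set`` in a ranked (descending) gene list.

    ES is the running-sum value of maximum magnitude; positive when the set
    concentrates at the top (upregulated end).  ``weight_exponent`` 0 gives
    the classic unweighted Kolmogorov–Smirnov-style statistic; 1 weights hits
    by |score|.
    """
    genes = ranked.index.to_numpy()
    gene_set = set(gene_set)
    is_hit = np.isin(genes, list(gene_set))
    if not is_hit.any():
        raise ValueError("gene set does not intersect the ranked list")
    if is_hit.all():
        raise ValueError("gene set covers the whole ranked list")
    rs = _running_sum(ranked.to_numpy(dtype=float), is_hit, weight_exponent)
    hi, lo = float(rs.max()), float(rs.min())
    es = hi if hi >= -lo else lo  # magnitude ties resolve to the positive peak
    return GSEAResult(es=es, running_sum=rs, hit_positions=np.flatnonzero(is_hit))


def _null_es(
    scores: np.ndarray,
    n_hit: int,
    n_perm: int,
    p: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """ES for ``n_perm`` random gene sets of size ``n_hit`` (vectorised).

    For a hit set with sorted positions q_1 < ... < q_k, the running sum
    attains its extrema immediately after a hit or immediately before one, so
    only those 2k values need evaluating per permutation.
    """
    n = len(scores)
    weights = np.abs(scores) ** p
    miss_pen = 1.0 / (n - n_hit)
    # sample hit positions without replacement, per permutation
    pos = np.empty((n_perm, n_hit), dtype=np.int64)
    for i in range(n_perm):
        pos[i] = rng.choice(n, size=n_hit, replace=False)
    pos.sort(axis=1)
    w = weights[pos]
    denom = w.sum(axis=1, keepdims=True)
    # permutations whose sampled hits all have zero weight: equal weights
    zero = denom[:, 0] == 0
    if zero.any():
        w[zero] = 1.0
        denom[zero] = n_hit
    cum_w = np.cumsum(w, axis=1) / denom
    ranks = np.arange(1, n_hit + 1)
    # misses passed just after hit j: pos_j + 1 - j ; just before hit j: pos_j - (j-1)
    after = cum_w - (pos + 1 - ranks) * miss_pen
    before = (cum_w - w / denom) - (pos - (ranks - 1)) * miss_pen
    cand = np.concatenate([after, before], axis=1)
    hi = cand.max(axis=1)
    lo = cand.min(axis=1)
    return np.where(hi >= -lo, hi, lo)  # same tie-break as the scalar path


def gsea_permutation_fdr(
    ranked: pd.Series,
    gene_set: Iterable[str],
    n_permutations: int = 1000,
    weight_exponent: float = 1.0,
    seed: int = 0,
) -> GSEAResult:
    """Gene-set permutation p-value for the enrichment score.

    The null draws random gene sets of the same size from the ranked list;
    the (FDR-style) p-value is ``(1 + #{|ES_null| >= |ES_obs|}) / (1 + m)``
    with ``m = n_permutations``, reproducible from ``seed``.  Gene-set (not
    phenotype) permutation is used: with 3-vs-3 designs phenotype permutation
    is degenerate.
    """
    if n_permutations < 100:
        raise ValueError("need >= 100 permutations")
    res = gsea_enrichment_score(ranked, gene_set, weight_exponent)
    rng = np.random.default_rng(seed)
    null = _null_es(
        ranked.to_numpy(dtype=float),
        n_hit=len(res.hit_positions),
        n_perm=n_permutations,
        p=weight_exponent,
        rng=rng,
    )
    fdr_p = (1 + int(np.sum(np.abs(null) >= abs(res.es)))) / (1 + n_permutations)
    res.n_permutations = n_permutations
    res.fdr_p = float(fdr_p)
    return res


def gsea(
    expr: ExpressionMatrix,
    group_a: str,
    group_b: str,
    gene_set: Iterable[str],
    n_permutations: int = 1000,
    weight_exponent: float = 1.0,
    epsilon: float = DEFAULT_EPSILON,
    seed: int = 0,
) -> GSEAResult:
    """Fold-change ranking + enrichment score + permutation p, in one call."""
    ranked = rank_by_fold_change(expr, group_a, group_b, epsilon=epsilon)
    return gsea_permutation_fdr(ranked, gene_set, n_permutations, weight_exponent, seed)
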