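"""LSC17 stemness scoring, simplified differential expression, and a minimal
preranked enrichment statistic.

The 17-gene stemness score is a fixed linear combination of log2-normalized
expression values. Note the absolute score scale depends on the upstream
normalization, so only relative comparisons within one normalized matrix are
meaningful.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from idhres.methylation import bh_adjust

logger = logging.getLogger(__name__)

#: The published 17-gene stemness signature: (gene, coefficient).
LSC17_SIGNATURE: tuple = (
    ("DNMT3B", 0.0874),
    ("ZBTB46", -0.0347),
    ("NYNRIN", 0.00865),
    ("ARHGAP22", -0.0138),
    ("LAPTM4B", 0.00582),
    ("MMRN1", 0.0258),
    ("DPYSL3", 0.0284),
    ("KIAA0125", 0.0196),
    ("CDK6", -0.0704),
    ("CPXM1", -0.0258),
    ("SOCS2", 0.0271),
    ("SMIM24", -0.0226),
    ("EMP1", 0.0146),
    ("NGFRAP1", 0.0465),
    ("CD34", 0.0338),
    ("AKR1C3", -0.0402),
    ("GPR56", 0.0501),
)

LSC17_GENES: tuple = tuple(g for g, _ in LSC17_SIGNATURE)

#: Current HGNC symbols for legacy signature gene names.
GENE_ALIASES: dict = {
    "KIAA0125": "FAM30A",
    "NGFRAP1": "BEX3",
    "GPR56": "ADGRG1",
}


def _resolve(expr, gene: str, aliases: dict) -> float | None:
    if gene in expr:
        return float(expr[gene])
    alias = aliases.get(gene)
    if alias is not None and alias in expr:
        return float(expr[alias])
    return None


def lsc17_score(
    expression,
    signature=LSC17_SIGNATURE,
    impute_missing: bool = False,
    aliases: dict = GENE_ALIASES,
) -> float:
    """Weighted sum of the 17 signature genes for one sample.

    ``expression`` maps gene symbol -> log2-normalized value (dict or
    Series). Legacy symbols are resolved through ``aliases``. A missing gene
    raises ``KeyError`` naming it unless ``impute_missing`` substitutes 0.
    """
    score = 0.0
    for gene, coef in signature:
        value = _resolve(expression, gene, aliases)
        if value is None:
            if impute_missing:
                value = 0.0
            else:
                raise KeyError(f"signature gene {gene!r} missing from expression data")
        score += coef * value
    return score


def lsc17_scores(matrix: pd.DataFrame, **kwargs) -> pd.Series:
    """LSC17 score per sample column of a genes x samples matrix."""
    return pd.Series(
        {s: lsc17_score(matrix[s], **kwargs) for s in matrix.columns}, name="lsc17"
    )


def differential_expression(
    matrix: pd.DataFrame,
    group_labels: pd.Series,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Welch t-test per gene between two groups on log2 values.

    Log fold-change is mean(group2) - mean(group1) where group2 is the
    higher-sorted label. Returns per-gene lfc, t, p, BH q, significance.
    """
    labels = group_labels.reindex(matrix.columns).dropna()
    levels = sorted(labels.unique())
    if len(levels) != 2:
        raise ValueError(f"need exactly two groups, got {levels}")
    g1 = matrix[labels.index[labels == levels[0]]].to_numpy(dtype=float)
    g2 = matrix[labels.index[labels == levels[1]]].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat, pvals = stats.ttest_ind(g2, g1, axis=1, equal_var=False)
    pvals = np.nan_to_num(pvals, nan=1.0)
    lfc = g2.mean(axis=1) - g1.mean(axis=1)
    q = bh_adjust(pvals)
    return pd.DataFrame(
        {
            "gene": matrix.index,
            "lfc": lfc,
            "t": tstat,
            "p": pvals,
            "q": q,
            "significant": q < fdr,
        }
    ).set_index("gene")


@dataclass
class EnrichmentResult:
    gene_set: str
    es: float  # signed enrichment score in [-1, 1]
    p: float  # permutation p-value in (0, 1]
    direction: str  # "up" (ES > 0) or "down"
    n_permutations: int


def _running_es(stat_sorted: np.ndarray, hit_mask: np.ndarray) -> float:
    """Weighted KS-style running-sum enrichment score (weight exponent 1)."""
    n = len(stat_sorted)
    n_hit = int(hit_mask.sum())
    if n_hit == 0 or n_hit == n:
        return 0.0
    hit_weights = np.abs(stat_sorted) * hit_mask
    total = hit_weights.sum()
    if total == 0:
        hit_weights = hit_mask.astype(float)
        total = hit_weights.sum()
    step = hit_weights / total - (~hit_mask).astype(float) / (n - n_hit)
    running = np.cumsum(step)
    return float(running[np.argmax(np.abs(running))])


def preranked_enrichment(
    ranked: pd.Series,
    gene_set,
    set_id: str = "gene_set",
    n_permutations: int = 1000,
    seed: int = 0,
) -> EnrichmentResult:
    """Preranked gene-set enrichment with gene-label permutation p-value.

    ``ranked`` maps gene -> ranking statistic (e.g. a t statistic); genes are
    sorted by the statistic in decreasing order, and the enrichment score is
    the maximum deviation of the weighted running sum (hits weighted by
    |statistic|). The p-value counts random same-size gene sets whose |ES|
    in the observed direction is at least as extreme, with the +1 correction.
    """
    gene_set = set(gene_set)
    if not gene_set:
        raise ValueError("empty gene set")
    if len(gene_set) < 5:
        raise ValueError("gene set must contain at least 5 genes")
    missing = gene_set - set(ranked.index)
    if missing:
        raise ValueError(f"gene set members missing from ranking: {sorted(missing)[:5]}")
    order = ranked.sort_values(ascending=False, kind="stable")
    stat = order.to_numpy(dtype=float)
    hits = order.index.isin(gene_set)
    es = _running_es(stat, hits)

    rng = np.random.default_rng(seed)
    n = len(order)
    k = len(gene_set)
    es_perms = np.empty(n_permutations)
    for i in range(n_permutations):
        perm_hits = np.zeros(n, dtype=bool)
        perm_hits[rng.choice(n, size=k, replace=False)] = True
        es_perms[i] = _running_es(stat, perm_hits)
    # standard preranked convention: compare against the same-signed side of
    # the permutation null so p is uniform under the null
    if es >= 0:
        side = es_perms[es_perms >= 0]
        extreme = int((side >= es).sum())
    else:
        side = es_perms[es_perms < 0]
        extreme = int((side <= es).sum())
    p = (extreme + 1) / (len(side) + 1)
    return EnrichmentResult(
        gene_set=set_id,
        es=es,
        p=p,
        direction="up" if es >= 0 else "down",
        n_permutations=n_permutations,
    )
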