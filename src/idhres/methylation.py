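"""Promoter methylation analysis: probe filtering, top-variance CpG selection,
consensus k-means clustering, differential methylation, and longitudinal
delta-beta concordance.

Beta matrices are probes x samples with values in [0, 1] and per-probe
metadata (promoter flag, SNP flag, chromosome). The clustering convention
fixes cluster labels by grand-mean beta so that "cluster 2" is always the
relatively hypermethylated group.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

PROBE_META_COLUMNS = ["promoter", "snp_flag", "chrom"]


@dataclass
class BetaMatrix:
    """Methylation beta values (probes x samples) plus probe metadata.

    ``meta`` is indexed by probe id with boolean ``promoter`` / ``snp_flag``
    columns and a ``chrom`` column.
    """

    beta: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self):
        if not self.beta.index.equals(self.meta.index):
            self.meta = self.meta.loc[self.beta.index]
        vals = self.beta.to_numpy(dtype=float)
        if vals.size and (np.isnan(vals).any() or vals.min() < 0 or vals.max() > 1):
            raise ValueError("beta values must be finite and within [0, 1]")

    @property
    def probe_ids(self) -> pd.Index:
        return self.beta.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.beta.columns

    def subset_probes(self, probes) -> "BetaMatrix":
        return BetaMatrix(self.beta.loc[probes], self.meta.loc[probes])

    def subset_samples(self, samples) -> "BetaMatrix":
        return BetaMatrix(self.beta[list(samples)], self.meta)

    def to_tsv(self, beta_path: str | Path, meta_path: str | Path | None = None) -> None:
        self.beta.to_csv(beta_path, sep="\t", index_label="probe_id")
        if meta_path is not None:
            self.meta.to_csv(meta_path, sep="\t", index_label="probe_id")

    @classmethod
    def from_tsv(cls, beta_path: str | Path, meta_path: str | Path) -> "BetaMatrix":
        beta = pd.read_csv(beta_path, sep="\t", index_col="probe_id")
        meta = pd.read_csv(meta_path, sep="\t", index_col="probe_id")
        meta["promoter"] = meta["promoter"].astype(bool)
        meta["snp_flag"] = meta["snp_flag"].astype(bool)
        return cls(beta, meta)


def filter_probes(matrix: BetaMatrix) -> BetaMatrix:
    """Drop SNP-flagged probes and probes on chromosome X or Y."""
    meta = matrix.meta
    bad = meta["snp_flag"] | meta["chrom"].isin(["chrX", "chrY", "X", "Y"])
    kept = matrix.subset_probes(meta.index[~bad])
    logger.info("probe filter: removed %d/%d probes", int(bad.sum()), len(meta))
    if len(kept.probe_ids) == 0:
        warnings.warn("all probes removed by SNP/sex-chromosome filter")
    return kept


def select_top_variable_promoter_cpgs(
    matrix: BetaMatrix, top_fraction: float = 0.01
) -> BetaMatrix:
    """Intersect the top-variance probes with promoter-flagged probes.

    Variance is computed per probe across all samples of the (already
    filtered) matrix; the top ``top_fraction`` of probes by variance is taken
    first and then restricted to promoter probes.
    """
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must be in (0, 1]")
    variances = matrix.beta.var(axis=1, ddof=1)
    n_top = max(1, int(round(top_fraction * len(variances))))
    top = variances.sort_values(ascending=False, kind="stable").index[:n_top]
    promoter = matrix.meta.loc[top, "promoter"]
    selected = top[promoter.to_numpy(dtype=bool)]
    logger.info(
        "top-variance selection: %d/%d probes (%d promoter)",
        n_top,
        len(variances),
        len(selected),
    )
    return matrix.subset_probes(selected)


@dataclass
class ConsensusResult:
    k: int  # chosen cluster count
    assignments: pd.Series  # sample -> cluster label (1-based, 2 = hypermethylated)
    consensus_matrix: pd.DataFrame  # pairwise co-clustering frequencies
    stability: dict  # k -> stability score (1 - PAC)
    per_k_assignments: dict = field(default_factory=dict)


def _consensus_for_k(X, k, n_resamples, subsample_fraction, rng):
    n = X.shape[0]
    hit = np.zeros((n, n))
    both = np.zeros((n, n))
    m = max(k, int(round(subsample_fraction * n)))
    for _ in range(n_resamples):
        idx = rng.choice(n, size=m, replace=False)
        km = KMeans(
            n_clusters=k,
            init="k-means++",
            n_init=10,
            random_state=int(rng.integers(2**31 - 1)),
        ).fit(X[idx])
        labels = km.labels_
        same = labels[:, None] == labels[None, :]
        both[np.ix_(idx, idx)] += 1
        hit[np.ix_(idx, idx)] += same
    with np.errstate(invalid="ignore", divide="ignore"):
        consensus = np.where(both > 0, hit / np.maximum(both, 1), 0.0)
    np.fill_diagonal(consensus, 1.0)
    consensus = (consensus + consensus.T) / 2
    return consensus


def _pac(consensus, lower=0.1, upper=0.9):
    n = consensus.shape[0]
    iu = np.triu_indices(n, k=1)
    vals = consensus[iu]
    return float(np.mean((vals > lower) & (vals < upper)))


def consensus_kmeans_cluster(
    matrix: BetaMatrix,
    k_range=(2,),
    n_resamples: int = 1000,
    subsample_fraction: float = 0.8,
    seed: int = 0,
) -> ConsensusResult:
    """Consensus k-means over sample resamples of a beta matrix.

    For each k, k-means (Euclidean, k-means++, 10 restarts) is run on
    ``n_resamples`` random subsets of ``subsample_fraction`` of the samples;
    co-clustering frequencies over co-sampled pairs form the consensus
    matrix. The final partition comes from k-means on the consensus-matrix
    rows, and cluster labels are renumbered so cluster 2 (and higher) have
    increasing grand-mean beta. Stability per k is 1 - PAC (proportion of
    ambiguous consensus entries in (0.1, 0.9)).

    The k with the highest stability in ``k_range`` is chosen; pass a single
    k (default ``(2,)``) to fix it.
    """
    samples = list(matrix.sample_ids)
    n = len(samples)
    if n < 2:
        raise ValueError("need at least 2 samples")
    X = matrix.beta.to_numpy(dtype=float).T  # samples x probes
    stability = {}
    per_k_assign = {}
    per_k_consensus = {}
    rng = np.random.default_rng(seed)
    for k in k_range:
        if k > n:
            raise ValueError(f"k={k} exceeds number of samples ({n})")
        consensus = _consensus_for_k(X, k, n_resamples, subsample_fraction, rng)
        km = KMeans(n_clusters=k, init="k-means++", n_init=10, random_state=seed).fit(
            consensus
        )
        labels = km.labels_
        # order clusters by grand-mean beta: cluster 2 = hypermethylated
        means = [X[labels == c].mean() if (labels == c).any() else np.inf for c in range(k)]
        order = np.argsort(means)  # ascending: lowest mean -> cluster 1
        relabel = {old: new + 1 for new, old in enumerate(order)}
        labels = np.array([relabel[c] for c in labels])
        stability[k] = 1.0 - _pac(consensus)
        per_k_assign[k] = pd.Series(labels, index=samples, name="cluster")
        per_k_consensus[k] = consensus
        logger.info("consensus k=%d stability=%.3f", k, stability[k])
    best_k = max(stability, key=lambda k: (stability[k], -k))
    consensus_df = pd.DataFrame(per_k_consensus[best_k], index=samples, columns=samples)
    return ConsensusResult(
        k=best_k,
        assignments=per_k_assign[best_k],
        consensus_matrix=consensus_df,
        stability=stability,
        per_k_assignments=per_k_assign,
    )


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone step-up q-values)."""
    p = np.asarray(pvalues, dtype=float)
    return multipletests(p, method="fdr_bh")[1]


def dmp_test(
    matrix: BetaMatrix,
    group_labels: pd.Series,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Per-probe two-sided Welch t-test between two sample groups.

    ``group_labels`` maps sample id -> group (exactly two levels; the
    higher-sorted level is "group 2"). Returns one row per probe with means,
    ``delta_beta`` (group2 - group1), t statistic, p, BH q, significance at
    the given FDR, and direction (hyper/hypo in group 2).
    """
    labels = group_labels.reindex(matrix.sample_ids).dropna()
    levels = sorted(labels.unique())
    if len(levels) != 2:
        raise ValueError(f"need exactly two groups, got {levels}")
    g1 = matrix.beta[labels.index[labels == levels[0]]].to_numpy(dtype=float)
    g2 = matrix.beta[labels.index[labels == levels[1]]].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat, pvals = stats.ttest_ind(g2, g1, axis=1, equal_var=False)
    pvals = np.nan_to_num(pvals, nan=1.0)
    mean1 = g1.mean(axis=1)
    mean2 = g2.mean(axis=1)
    delta = mean2 - mean1
    q = bh_adjust(pvals)
    out = pd.DataFrame(
        {
            "probe_id": matrix.probe_ids,
            "mean_group1": mean1,
            "mean_group2": mean2,
            "delta_beta": delta,
            "t": tstat,
            "p": pvals,
            "q": q,
            "significant": q < fdr,
            "direction": np.where(delta > 0, "hyper", "hypo"),
        }
    ).set_index("probe_id")
    logger.info("dmp_test: %d/%d probes significant at FDR %g", int(out["significant"].sum()), len(out), fdr)
    return out


@dataclass
class LongitudinalDeltaResult:
    per_probe_delta: pd.DataFrame  # probe x group mean paired delta (baseline - post)
    per_sample_trend: pd.DataFrame  # sample, group, baseline/post mean beta
    concordance: float  # Pearson r of per-probe deltas between the two groups


def longitudinal_delta_beta(
    matrix_baseline: BetaMatrix,
    matrix_post: BetaMatrix,
    pairing: dict,
    group_labels: pd.Series | None = None,
) -> LongitudinalDeltaResult:
    """Paired baseline-minus-post methylation deltas and group concordance.

    ``pairing`` maps baseline sample id -> post sample id; only paired
    samples enter. ``group_labels`` (baseline sample -> group) splits samples
    into two groups; concordance is the Pearson correlation of the two
    groups' per-probe mean deltas. With no labels, all samples form one
    group and concordance is NaN.
    """
    base_samples = [s for s in matrix_baseline.sample_ids if s in pairing]
    post_samples = [pairing[s] for s in base_samples]
    missing = [s for s in post_samples if s not in set(matrix_post.sample_ids)]
    if missing:
        raise ValueError(f"post samples missing from post matrix: {missing[:5]}")
    probes = matrix_baseline.probe_ids.intersection(matrix_post.probe_ids)
    B = matrix_baseline.beta.loc[probes, base_samples].to_numpy(dtype=float)
    P = matrix_post.beta.loc[probes, post_samples].to_numpy(dtype=float)
    deltas = B - P  # positive = demethylation after treatment

    if group_labels is None:
        group_labels = pd.Series("all", index=base_samples)
    groups = group_labels.reindex(base_samples)
    levels = sorted(groups.dropna().unique())
    per_group = {}
    trend_rows = []
    for level in levels:
        cols = [i for i, s in enumerate(base_samples) if groups[s] == level]
        per_group[level] = deltas[:, cols].mean(axis=1)
        for i in cols:
            trend_rows.append(
                {
                    "sample_id": base_samples[i],
                    "group": level,
                    "baseline_mean_beta": B[:, i].mean(),
                    "post_mean_beta": P[:, i].mean(),
                }
            )
    per_probe = pd.DataFrame(per_group, index=probes)
    if len(levels) == 2:
        d1 = per_probe[levels[0]].to_numpy()
        d2 = per_probe[levels[1]].to_numpy()
        # a (near-)uniform shift has no per-probe variance; identical shifts
        # in both groups are perfectly concordant by convention
        if d1.std() < 1e-9 or d2.std() < 1e-9:
            concordance = 1.0 if np.allclose(d1, d2, atol=1e-6) else float("nan")
        else:
            concordance = float(np.corrcoef(d1, d2)[0, 1])
    else:
        concordance = float("nan")
    return LongitudinalDeltaResult(
        per_probe_delta=per_probe,
        per_sample_trend=pd.DataFrame(trend_rows),
        concordance=concordance,
    )


def dmp_overlap(probes_a, probes_b) -> dict:
    """Venn counts between two DMP sets (e.g. baseline vs post-treatment)."""
    a, b = set(probes_a), set(probes_b)
    return {"only_a": len(a - b), "both": len(a & b), "only_b": len(b - a)}
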