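"""Response-association statistics: Fisher exact enrichment with odds ratios,
response-rate comparisons, ROC/AUROC, multivariate logistic regression,
methylation x expression starburst integration, and a two-group log-rank
comparison of relapse-free survival.

The two-sided Fisher p-value follows the minimum-likelihood convention: the
sum of hypergeometric probabilities of all tables (with the observed
margins) no more probable than the observed table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sp_stats
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Fisher exact test / odds ratio


def fisher_exact_p(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for table [[a, b], [c, d]].

    Sums hypergeometric probabilities of all tables with the observed margins
    whose probability does not exceed the observed table's (with a small
    relative tolerance against floating-point ties).
    """
    n = a + b + c + d
    r1, c1 = a + b, a + c
    rv = sp_stats.hypergeom(n, c1, r1)
    support = np.arange(max(0, r1 + c1 - n), min(r1, c1) + 1)
    probs = rv.pmf(support)
    p_obs = rv.pmf(a)
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-9)].sum()))


@dataclass
class EnrichmentRow:
    feature: str
    a: int  # feature+ outcome+
    b: int  # feature+ outcome-
    c: int  # feature- outcome+
    d: int  # feature- outcome-
    odds_ratio: float
    ci_low: float
    ci_high: float
    p: float


def fisher_enrichment(feature, outcome, feature_name: str = "feature") -> EnrichmentRow:
    """Fisher exact association between a binary feature and a binary outcome.

    Missing values (NaN/None) are dropped pairwise. The odds ratio is the
    uncorrected cross-product (a*d)/(b*c); the 95% CI is Woolf's logit
    interval on the Haldane-Anscombe +0.5 table when any cell is zero.
    """
    f = pd.Series(feature).astype(float)
    o = pd.Series(outcome).astype(float)
    if len(f) != len(o):
        raise ValueError("feature and outcome must have equal length")
    mask = f.notna() & o.notna()
    f, o = f[mask], o[mask]
    if not set(f.unique()) <= {0.0, 1.0} or not set(o.unique()) <= {0.0, 1.0}:
        raise ValueError("feature and outcome must be binary (0/1)")
    a = int(((f == 1) & (o == 1)).sum())
    b = int(((f == 1) & (o == 0)).sum())
    c = int(((f == 0) & (o == 1)).sum())
    d = int(((f == 0) & (o == 0)).sum())
    if b * c == 0:
        odds = np.inf if a * d > 0 else (0.0 if a * d == 0 and (b or c) else np.nan)
    else:
        odds = (a * d) / (b * c)
    if a * d == 0:
        odds = 0.0 if b * c > 0 else odds
    # Woolf CI on (possibly Haldane-corrected) cells
    if min(a, b, c, d) == 0:
        ah, bh, ch, dh = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    else:
        ah, bh, ch, dh = a, b, c, d
    log_or = np.log((ah * dh) / (bh * ch))
    se = np.sqrt(1 / ah + 1 / bh + 1 / ch + 1 / dh)
    z = sp_stats.norm.ppf(0.975)
    ci_low, ci_high = np.exp(log_or - z * se), np.exp(log_or + z * se)
    p = fisher_exact_p(a, b, c, d)
    return EnrichmentRow(feature_name, a, b, c, d, float(odds), float(ci_low), float(ci_high), p)


def enrichment_table(features: pd.DataFrame, outcome) -> pd.DataFrame:
    """``fisher_enrichment`` for every column of a binary feature frame."""
    rows = [fisher_enrichment(features[c], outcome, feature_name=c) for c in features.columns]
    return pd.DataFrame([r.__dict__ for r in rows]).set_index("feature")


# ---------------------------------------------------------------------------
# Response rates


def response_rates(clinical: pd.DataFrame, grouping: str, outcome: str = "responder") -> dict:
    """Per-group response rates with a between-group Fisher p.

    Patients with a missing outcome ("not assessed") are excluded from each
    denominator. With exactly two groups, a two-sided Fisher p compares them;
    otherwise p is NaN. An empty (all-missing) group gets rate NaN and is
    flagged.
    """
    out = {"groups": {}, "p": float("nan"), "flags": []}
    evaluable = clinical[clinical[outcome].notna()]
    for name, grp in clinical.groupby(grouping):
        ev = grp[grp[outcome].notna()]
        if len(ev) == 0:
            out["groups"][name] = {"n": 0, "responders": 0, "rate": float("nan")}
            out["flags"].append(f"group {name!r} has no evaluable patients")
            continue
        r = int(ev[outcome].astype(float).sum())
        out["groups"][name] = {"n": len(ev), "responders": r, "rate": r / len(ev)}
    names = [g for g in out["groups"] if out["groups"][g]["n"] > 0]
    if len(names) == 2:
        g1, g2 = (out["groups"][n] for n in names)
        out["p"] = fisher_exact_p(
            g1["responders"], g1["n"] - g1["responders"],
            g2["responders"], g2["n"] - g2["responders"],
        )
    return out


# ---------------------------------------------------------------------------
# ROC / AUROC


@dataclass
class RocResult:
    auroc: float
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    oriented_flipped: bool = False


def auroc(scores, outcome, auto_orient: bool = False) -> RocResult:
    """AUROC via the Mann-Whitney U statistic with tie correction.

    Ties between a positive and a negative score count 1/2. ROC points are
    generated at every distinct score threshold (predict positive when
    score >= threshold). With ``auto_orient``, a score direction yielding
    AUROC < 0.5 is flipped and flagged in the result.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcome, dtype=float)
    if s.shape != y.shape:
        raise ValueError("scores and outcome must align")
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("outcome must be binary")
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("need both positive and negative outcomes")
    ranks = sp_stats.rankdata(s)  # midranks handle ties
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2
    auc = float(u / (n1 * n0))
    flipped = False
    if auto_orient and auc < 0.5:
        s = -s
        auc = 1.0 - auc
        flipped = True
    order = np.argsort(-s, kind="stable")
    thresholds = np.concatenate(([np.inf], np.unique(s)[::-1]))
    tpr = [0.0]
    fpr = [0.0]
    tp = fp = 0
    i = 0
    for thr in thresholds[1:]:
        while i < len(order) and s[order[i]] >= thr:
            if y[order[i]] == 1:
                tp += 1
            else:
                fp += 1
            i += 1
        tpr.append(tp / n1)
        fpr.append(fp / n0)
    return RocResult(auc, np.array(fpr), np.array(tpr), thresholds, flipped)


# ---------------------------------------------------------------------------
# Logistic regression (IRLS)


@dataclass
class LogisticFit:
    params: pd.Series
    se: pd.Series
    z: pd.Series
    p: pd.Series
    converged: bool
    separation: bool
    n_iter: int
    n_obs: int


def fit_logistic(
    design: pd.DataFrame,
    outcome,
    add_intercept: bool = True,
    tol: float = 1e-8,
    max_iter: int = 50,
) -> LogisticFit:
    """Maximum-likelihood logistic regression via IRLS with Wald inference.

    Complete cases only. Perfect separation is detected (all fitted
    probabilities pinned to their outcomes) and flagged; in that case
    estimates are returned as NaN.
    """
    X = design.copy()
    y = pd.Series(np.asarray(outcome, dtype=float), index=X.index)
    mask = X.notna().all(axis=1) & y.notna()
    X, y = X[mask], y[mask]
    if not set(y.unique()) <= {0.0, 1.0}:
        raise ValueError("outcome must be binary")
    names = list(X.columns)
    Xm = X.to_numpy(dtype=float)
    if add_intercept:
        Xm = np.column_stack([np.ones(len(Xm)), Xm])
        names = ["intercept"] + names
    yv = y.to_numpy()
    beta = np.zeros(Xm.shape[1])
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = Xm @ beta
        mu = 1 / (1 + np.exp(-np.clip(eta, -30, 30)))
        w = mu * (1 - mu)
        w = np.maximum(w, 1e-10)
        z = eta + (yv - mu) / w
        WX = Xm * w[:, None]
        try:
            beta_new = np.linalg.solve(Xm.T @ WX, Xm.T @ (w * z))
        except np.linalg.LinAlgError:
            break
        if np.max(np.abs(beta_new - beta)) < tol:
            beta = beta_new
            converged = True
            break
        beta = beta_new
    eta = Xm @ beta
    mu = 1 / (1 + np.exp(-np.clip(eta, -30, 30)))
    separation = bool(
        np.all(np.where(yv == 1, mu > 1 - 1e-6, mu < 1e-6)) and len(np.unique(yv)) == 2
    )
    idx = pd.Index(names)
    if separation:
        nan = pd.Series(np.nan, index=idx)
        logger.warning("perfect separation detected; no estimates reported")
        return LogisticFit(nan, nan, nan, nan, False, True, it, len(yv))
    w = np.maximum(mu * (1 - mu), 1e-10)
    cov = np.linalg.inv(Xm.T @ (Xm * w[:, None]))
    se = np.sqrt(np.diag(cov))
    zstat = beta / se
    pvals = 2 * sp_stats.norm.sf(np.abs(zstat))
    return LogisticFit(
        pd.Series(beta, index=idx),
        pd.Series(se, index=idx),
        pd.Series(zstat, index=idx),
        pd.Series(pvals, index=idx),
        converged,
        False,
        it,
        len(yv),
    )


# ---------------------------------------------------------------------------
# Starburst integration


@dataclass
class StarburstResult:
    per_cpg: pd.DataFrame
    quadrant_counts: dict
    n_double_significant: int


def starburst_integration(
    dmp: pd.DataFrame,
    de: pd.DataFrame,
    cpg_to_gene: dict,
    fdr: float = 0.05,
) -> StarburstResult:
    """Joint methylation/expression significance per promoter CpG.

    A CpG is double-significant when its DMP q and its linked gene's DE q are
    both below ``fdr``. Quadrants combine the sign of delta_beta and the
    linked gene's log fold-change: hyper_down, hyper_up, hypo_down, hypo_up.
    CpGs without a linked gene in the DE table are dropped.
    """
    rows = []
    for cpg, gene in cpg_to_gene.items():
        if cpg not in dmp.index or gene not in de.index:
            continue
        dq = float(dmp.loc[cpg, "q"])
        db = float(dmp.loc[cpg, "delta_beta"])
        gq = float(de.loc[gene, "q"])
        lfc = float(de.loc[gene, "lfc"])
        double = (dq < fdr) and (gq < fdr)
        quadrant = ("hyper" if db > 0 else "hypo") + ("_up" if lfc > 0 else "_down")
        rows.append(
            {
                "cpg": cpg,
                "gene": gene,
                "delta_beta": db,
                "meth_q": dq,
                "lfc": lfc,
                "expr_q": gq,
                "double_significant": double,
                "quadrant": quadrant if double else ".",
            }
        )
    per_cpg = pd.DataFrame(
        rows,
        columns=[
            "cpg", "gene", "delta_beta", "meth_q", "lfc", "expr_q",
            "double_significant", "quadrant",
        ],
    ).set_index("cpg") if rows else pd.DataFrame()
    counts = {q: 0 for q in ("hyper_down", "hyper_up", "hypo_down", "hypo_up")}
    if len(per_cpg):
        for q, n in per_cpg.loc[per_cpg["double_significant"], "quadrant"].value_counts().items():
            counts[q] = int(n)
    return StarburstResult(per_cpg, counts, sum(counts.values()))


# ---------------------------------------------------------------------------
# Log-rank relapse-free survival


@dataclass
class LogrankResult:
    statistic: float
    p: float
    medians: dict
    n_events: dict
    flagged: str | None = None


def logrank_rfs(time, event, group) -> LogrankResult:
    """Two-group log-rank test with per-group median survival.

    Right censoring honored (``event`` 0 = censored). With no events in
    either group the result is flagged and p is NaN.
    """
    df = pd.DataFrame({"time": np.asarray(time, dtype=float),
                       "event": np.asarray(event, dtype=int),
                       "group": list(group)})
    levels = sorted(df["group"].unique())
    if len(levels) != 2:
        raise ValueError("exactly two groups required")
    g1 = df[df["group"] == levels[0]]
    g2 = df[df["group"] == levels[1]]
    n_events = {levels[0]: int(g1["event"].sum()), levels[1]: int(g2["event"].sum())}
    medians = {}
    for name, g in ((levels[0], g1), (levels[1], g2)):
        kmf = KaplanMeierFitter()
        kmf.fit(g["time"], g["event"])
        medians[name] = float(kmf.median_survival_time_)
    if sum(n_events.values()) == 0:
        return LogrankResult(0.0, float("nan"), medians, n_events, flagged="no events in either group")
    res = _ll_logrank(g1["time"], g2["time"], event_observed_A=g1["event"], event_observed_B=g2["event"])
    return LogrankResult(float(res.test_statistic), float(res.p_value), medians, n_events)
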