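"""Longitudinal VAF analytics: CCF estimation, relative mutation timing,
IDH-clearance calling, relapse acquisition/selection detection, pathway
summaries, and single-cell clone-independence testing.

CCF model: diploid, copy-neutral, heterozygous — CCF = min(1, 2 x VAF).
The underlying copy-number state is never inferred; this assumption is the
package's stated ground truth and matches the synthetic generator.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from idhres.pathways import PathwayMap
from idhres.stats import fisher_exact_p

logger = logging.getLogger(__name__)

IDH_GENES = ("IDH1", "IDH2")

#: VAF below which a variant is treated as undetectable by the pipeline
DETECTION_FLOOR = 0.05


def compute_ccf(tumor_vaf) -> float | np.ndarray:
    """Cancer cell fraction under the diploid-heterozygous assumption."""
    vaf = np.asarray(tumor_vaf, dtype=float)
    if (vaf < 0).any() or (vaf > 1).any():
        raise ValueError("tumor_vaf outside [0, 1]")
    ccf = np.minimum(1.0, 2.0 * vaf)
    return float(ccf) if ccf.ndim == 0 else ccf


@dataclass
class TimingResult:
    gene: str
    mean_ccf: float
    idh_ccf: float
    ordering: str  # earlier | co-occurring | later


def infer_relative_timing(drivers: pd.DataFrame, tau: float = 0.1) -> list:
    """Order co-occurring genes relative to the IDH mutation by mean CCF.

    ``drivers`` is one patient's baseline driver table. A gene is "later"
    (subclonal) when its mean CCF is below the IDH CCF by more than ``tau``,
    "earlier" when above by more than ``tau``, else "co-occurring".
    """
    ccf = pd.Series(compute_ccf(drivers["tumor_vaf"].to_numpy()), index=drivers.index)
    idh_mask = drivers["gene"].isin(IDH_GENES)
    if not idh_mask.any():
        raise ValueError("no IDH1/2 mutation in driver table (cohort is IDH-mutant by design)")
    idh_ccf = float(ccf[idh_mask].mean())
    results = []
    for gene, grp in drivers.loc[~idh_mask].groupby("gene"):
        mean_ccf = float(ccf[grp.index].mean())
        if mean_ccf < idh_ccf - tau:
            ordering = "later"
        elif mean_ccf > idh_ccf + tau:
            ordering = "earlier"
        else:
            ordering = "co-occurring"
        results.append(TimingResult(gene, mean_ccf, idh_ccf, ordering))
    return results


@dataclass
class ClearanceCall:
    patient_id: str
    baseline_vaf: float
    best_post_vaf: float
    relative_decrease: float
    status: str  # "cleared" | "persistent"

    #: status label for a >= 75% VAF decrease or full clearance
    CLEARED = "cleared"
    PERSISTENT = "persistent"


def classify_idh_clearance(
    patient_id: str,
    baseline_vaf: float,
    post_vafs,
    decrease_threshold: float = 0.75,
) -> ClearanceCall:
    """Call IDH-mutation clearance / substantial reduction on treatment.

    ``post_vafs`` are the on-treatment IDH VAFs in any order; the minimum is
    the best response. The call is "cleared" when the relative decrease from
    baseline reaches ``decrease_threshold`` (boundary inclusive: exactly 75%
    counts as cleared).
    """
    if baseline_vaf is None or not baseline_vaf > 0:
        raise ValueError("baseline IDH VAF must be positive")
    post = [float(v) for v in post_vafs]
    if not post:
        raise ValueError("need at least one on-treatment timepoint")
    best = min(post)
    decrease = (baseline_vaf - best) / baseline_vaf
    status = (
        ClearanceCall.CLEARED
        if best <= (1.0 - decrease_threshold) * baseline_vaf + 1e-12
        else ClearanceCall.PERSISTENT
    )
    return ClearanceCall(patient_id, float(baseline_vaf), best, float(decrease), status)


@dataclass
class RelapseEvent:
    patient_id: str
    gene: str
    event_type: str  # "emergent" | "selected"
    baseline_vaf: float  # 0 for emergent (below detection)
    relapse_vaf: float
    pathway: str


def detect_relapse_events(
    baseline_drivers: pd.DataFrame,
    relapse_drivers: pd.DataFrame,
    fold: float = 2.0,
    detection_floor: float = DETECTION_FLOOR,
    pathway_map: PathwayMap | None = None,
) -> list:
    """Find emergent and selected mutations between baseline and relapse.

    Both tables come from the variant pipeline for a single patient.
    Emergent: present at relapse, absent (i.e. not detectable under the
    pipeline's filters) at baseline. Selected: present at both timepoints
    with relapse VAF at least ``fold`` x baseline VAF.
    """
    pmap = pathway_map or PathwayMap()
    key = ["chrom", "pos", "ref", "alt"]
    base = baseline_drivers.set_index(key) if len(baseline_drivers) else pd.DataFrame()
    events = []
    for _, row in relapse_drivers.iterrows():
        pid = row["patient_id"]
        vkey = tuple(row[k] for k in key)
        base_vaf = 0.0
        present = False
        if len(base) and vkey in base.index:
            base_vaf = float(base.loc[vkey, "tumor_vaf"])
            present = base_vaf >= detection_floor
        relapse_vaf = float(row["tumor_vaf"])
        if not present:
            events.append(
                RelapseEvent(pid, row["gene"], "emergent", 0.0, relapse_vaf, pmap[row["gene"]])
            )
        elif relapse_vaf >= fold * base_vaf:
            events.append(
                RelapseEvent(pid, row["gene"], "selected", base_vaf, relapse_vaf, pmap[row["gene"]])
            )
    return events


def summarize_relapse_pathways(events, n_relapsed_patients: int) -> pd.DataFrame:
    """Fraction of relapsed patients with >= 1 event per pathway.

    Patient-level counting: multiple events in one pathway for the same
    patient count once. The denominator is the number of tested
    baseline/relapse pairs, not the number of patients with events.
    """
    if n_relapsed_patients <= 0:
        raise ValueError("n_relapsed_patients must be positive")
    patients_by_pathway: dict = {}
    for ev in events:
        patients_by_pathway.setdefault(ev.pathway, set()).add(ev.patient_id)
    rows = [
        {
            "pathway": pw,
            "n_patients": len(pats),
            "fraction": len(pats) / n_relapsed_patients,
        }
        for pw, pats in sorted(patients_by_pathway.items())
    ]
    return pd.DataFrame(rows, columns=["pathway", "n_patients", "fraction"])


@dataclass
class CloneIndependence:
    variant_a: str
    variant_b: str
    table: tuple  # ((both, a_only), (b_only, neither))
    n_informative: int
    p: float
    verdict: str  # "mutually_exclusive" | "co-occurring" | "ambiguous"


def test_clone_independence(
    sc_matrix: pd.DataFrame,
    alpha: float = 0.05,
    min_cells: int = 50,
) -> list:
    """Pairwise co-occurrence tests on a cells x variants genotype matrix.

    Genotypes are 0 (wildtype), 1 (mutant), or NA; missing calls are dropped
    pairwise. For each variant pair a 2x2 table of joint genotype counts is
    tested with a two-sided Fisher exact test. The verdict is
    "mutually_exclusive" when the double-mutant count falls below its
    independence expectation with p < alpha, "co-occurring" when above, else
    "ambiguous". Pairs with fewer than ``min_cells`` informative cells are
    ambiguous with a warning.
    """
    results = []
    for va, vb in combinations(sc_matrix.columns, 2):
        sub = sc_matrix[[va, vb]].dropna()
        ga = sub[va].astype(float)
        gb = sub[vb].astype(float)
        both = int(((ga == 1) & (gb == 1)).sum())
        a_only = int(((ga == 1) & (gb == 0)).sum())
        b_only = int(((ga == 0) & (gb == 1)).sum())
        neither = int(((ga == 0) & (gb == 0)).sum())
        n = both + a_only + b_only + neither
        if n < min_cells:
            warnings.warn(
                f"pair ({va}, {vb}): only {n} informative cells; verdict ambiguous"
            )
            results.append(
                CloneIndependence(va, vb, ((both, a_only), (b_only, neither)), n, float("nan"), "ambiguous")
            )
            continue
        p = fisher_exact_p(both, a_only, b_only, neither)
        expected_both = (both + a_only) * (both + b_only) / n
        if p < alpha and both < expected_both:
            verdict = "mutually_exclusive"
        elif p < alpha and both > expected_both:
            verdict = "co-occurring"
        else:
            verdict = "ambiguous"
        results.append(
            CloneIndependence(va, vb, ((both, a_only), (b_only, neither)), n, p, verdict)
        )
    return results
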