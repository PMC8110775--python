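"""Per-patient genetic/epigenetic evolution pattern classification.

Relapsing responders fall into three patterns defined by the joint state of
plasma 2HG and bone-marrow DNA methylation at relapse, together with the
mutations acquired there:

- pattern 1: 2HG and methylation both remain suppressed at relapse
  (relapse typically driven by non-IDH clones, e.g. growing RAS mutations);
- pattern 2: 2HG remains suppressed but methylation rebounds toward the
  baseline level (e.g. emergent TET2 mutations);
- pattern 3: both 2HG and methylation rebound, with an emergent mutation in
  the homologous IDH gene (homolog switching).

Thresholds are explicit, configurable, and reported with every call; a
trajectory matching no rule is returned as ``unclassified`` with evidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

BASELINE = "baseline"
RESPONSE = "response"
RELAPSE = "relapse"

IDH_GENES = ("IDH1", "IDH2")


@dataclass
class TrajectoryPoint:
    """One longitudinal timepoint of a patient's multidimensional profile."""

    label: str  # baseline | response | relapse
    mean_beta: float | None = None  # mean methylation over filtered probes
    hg2: float | None = None  # plasma 2HG level
    idh_vafs: dict = field(default_factory=dict)  # IDH gene -> VAF
    driver_genes: tuple = ()  # driver genes detected at this timepoint
    blast_pct: float | None = None
    response_label: str | None = None


@dataclass
class PatientTrajectory:
    patient_id: str
    timepoints: list  # ordered TrajectoryPoint list

    def __post_init__(self):
        labels = [t.label for t in self.timepoints]
        if len(labels) != len(set(labels)):
            raise ValueError("duplicate timepoint labels")

    def point(self, label: str) -> TrajectoryPoint | None:
        for t in self.timepoints:
            if t.label == label:
                return t
        return None

    @property
    def labels(self) -> list:
        return [t.label for t in self.timepoints]


@dataclass(frozen=True)
class PatternThresholds:
    """Rebound/suppression cutoffs (artifact choices, not literature values)."""

    hg2_suppression: float = 0.5  # suppressed: relapse 2HG <= (1 - r) x baseline
    beta_rebound_delta: float = 0.01  # rebound: relapse beta >= baseline - delta


@dataclass
class EvolutionPattern:
    pattern: int | None  # 1 | 2 | 3 | None (unclassified)
    hg2_state: str | None = None  # suppressed | rebound
    methylation_state: str | None = None  # suppressed | rebound
    homolog_switch: bool = False
    emergent_genes: tuple = ()
    thresholds: PatternThresholds = PatternThresholds()
    reason: str | None = None


def detect_homolog_switch(trajectory: PatientTrajectory) -> str | None:
    """Return the emergent homologous IDH gene at relapse, if any.

    A switch requires one IDH gene mutated at baseline and the *other* IDH
    gene appearing at relapse while absent from baseline.
    """
    base = trajectory.point(BASELINE)
    rel = trajectory.point(RELAPSE)
    if base is None or rel is None:
        return None
    base_idh = {g for g in IDH_GENES if base.idh_vafs.get(g, 0.0) > 0}
    base_idh |= {g for g in base.driver_genes if g in IDH_GENES}
    rel_idh = {g for g in IDH_GENES if rel.idh_vafs.get(g, 0.0) > 0}
    rel_idh |= {g for g in rel.driver_genes if g in IDH_GENES}
    emergent = rel_idh - base_idh
    for gene in emergent:
        homolog = "IDH2" if gene == "IDH1" else "IDH1"
        if homolog in base_idh:
            return gene
    return None


def classify_evolution_pattern(
    trajectory: PatientTrajectory,
    thresholds: PatternThresholds = PatternThresholds(),
) -> EvolutionPattern:
    """Classify a relapsed trajectory into evolution pattern 1, 2, or 3.

    Requires baseline and relapse timepoints carrying both a 2HG level and a
    mean methylation beta. Pattern 3 is never assigned without homolog-switch
    evidence.
    """
    base = trajectory.point(BASELINE)
    rel = trajectory.point(RELAPSE)
    if base is None or rel is None:
        return EvolutionPattern(None, thresholds=thresholds, reason="missing baseline or relapse timepoint")
    if base.hg2 is None or rel.hg2 is None or base.hg2 <= 0:
        return EvolutionPattern(None, thresholds=thresholds, reason="missing 2HG series")
    if base.mean_beta is None or rel.mean_beta is None:
        return EvolutionPattern(None, thresholds=thresholds, reason="missing methylation series")

    hg2_suppressed = rel.hg2 <= (1.0 - thresholds.hg2_suppression) * base.hg2
    beta_rebound = rel.mean_beta >= base.mean_beta - thresholds.beta_rebound_delta
    switch_gene = detect_homolog_switch(trajectory)
    emergent = tuple(sorted(set(rel.driver_genes) - set(base.driver_genes)))

    hg2_state = "suppressed" if hg2_suppressed else "rebound"
    beta_state = "rebound" if beta_rebound else "suppressed"

    if hg2_suppressed and not beta_rebound:
        pattern = 1
    elif hg2_suppressed and beta_rebound:
        pattern = 2
    elif not hg2_suppressed and beta_rebound and switch_gene is not None:
        pattern = 3
    else:
        pattern = None

    return EvolutionPattern(
        pattern,
        hg2_state=hg2_state,
        methylation_state=beta_state,
        homolog_switch=switch_gene is not None,
        emergent_genes=emergent,
        thresholds=thresholds,
        reason=None if pattern else "no rule matched (2HG rebound without homolog switch)",
    )


def summarize_trajectory(
    trajectory: PatientTrajectory,
    beta_distributions: dict | None = None,
) -> pd.DataFrame:
    """Flatten a trajectory into a tidy long table for plotting.

    One row per (timepoint, measure). ``beta_distributions`` optionally maps
    timepoint label -> vector of per-probe betas; when given, five-number
    summaries (min, Q1, median, Q3, max) are appended as ``beta_q*`` rows.
    Missing measures are omitted and recorded in the ``flags`` attribute of
    the returned frame (``df.attrs["flags"]``).
    """
    rows = []
    flags = []
    for pt in trajectory.timepoints:
        measures = {
            "mean_beta": pt.mean_beta,
            "hg2": pt.hg2,
            "blast_pct": pt.blast_pct,
        }
        for gene, vaf in sorted(pt.idh_vafs.items()):
            measures[f"vaf_{gene}"] = vaf
        for name, value in measures.items():
            if value is None:
                flags.append(f"{pt.label}:{name} missing")
                continue
            rows.append(
                {
                    "patient_id": trajectory.patient_id,
                    "timepoint": pt.label,
                    "measure": name,
                    "value": float(value),
                }
            )
        if beta_distributions and pt.label in beta_distributions:
            betas = np.asarray(beta_distributions[pt.label], dtype=float)
            qs = np.quantile(betas, [0.0, 0.25, 0.5, 0.75, 1.0])
            for qname, qval in zip(("beta_min", "beta_q1", "beta_median", "beta_q3", "beta_max"), qs):
                rows.append(
                    {
                        "patient_id": trajectory.patient_id,
                        "timepoint": pt.label,
                        "measure": qname,
                        "value": float(qval),
                    }
                )
    df = pd.DataFrame(rows, columns=["patient_id", "timepoint", "measure", "value"])
    df.attrs["flags"] = flags
    return df
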