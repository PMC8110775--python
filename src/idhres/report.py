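"""End-to-end synthetic analysis: simulate a cohort, run every analysis
stage, and emit report tables plus a machine-readable summary."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from idhres import clonal, methylation, patterns, simulate, stats, stemness
from idhres.pathways import RAS_RTK, HEMATOPOIETIC_TF, PathwayMap
from idhres.patterns import BASELINE, RELAPSE, RESPONSE
from idhres.variants import run_variant_pipeline


def run_end_to_end(
    config: simulate.CohortConfig,
    outdir: Path | None = None,
    n_resamples: int = 200,
) -> dict:
    """Run the full pipeline on one synthetic cohort.

    Returns a dict with intermediate frames and a JSON-serializable
    ``summary``. When ``outdir`` is given, report tables are written there.
    """
    cohort = simulate.generate_cohort(config)
    truth = cohort.truth
    clinical = cohort.clinical.set_index("patient_id")

    # --- variant pipeline ------------------------------------------------
    pipeline = run_variant_pipeline(cohort.variants, cohort.resources)
    drivers = pipeline.drivers
    base_drivers = drivers[drivers["timepoint"] == BASELINE]
    relapse_drivers = drivers[drivers["timepoint"] == RELAPSE]

    # --- IDH clearance ----------------------------------------------------
    clearance_rows = []
    for pid, traj in cohort.trajectories.items():
        base = traj.point(BASELINE)
        idh_gene = truth.idh_gene[pid]
        baseline_vaf = base.idh_vafs.get(idh_gene, 0.0)
        post_vafs = [
            pt.idh_vafs.get(idh_gene, 0.0)
            for pt in traj.timepoints
            if pt.label == RESPONSE
        ]
        if baseline_vaf <= 0 or not post_vafs:
            continue
        call = clonal.classify_idh_clearance(pid, baseline_vaf, post_vafs)
        clearance_rows.append(dataclasses.asdict(call))
    clearance = pd.DataFrame(clearance_rows)

    # --- relapse events and pathway summary ------------------------------
    pmap = PathwayMap()
    events = []
    relapsed_patients = sorted(relapse_drivers["patient_id"].unique())
    for pid in relapsed_patients:
        events.extend(
            clonal.detect_relapse_events(
                base_drivers[base_drivers["patient_id"] == pid],
                relapse_drivers[relapse_drivers["patient_id"] == pid],
                pathway_map=pmap,
            )
        )
    pathway_summary = (
        clonal.summarize_relapse_pathways(events, len(relapsed_patients))
        if relapsed_patients
        else pd.DataFrame(columns=["pathway", "n_patients", "fraction"])
    )

    # --- methylation clustering ------------------------------------------
    filtered = methylation.filter_probes(cohort.beta[BASELINE])
    selected = methylation.select_top_variable_promoter_cpgs(
        filtered, top_fraction=max(0.01, config.discriminating_probe_fraction)
    )
    consensus = methylation.consensus_kmeans_cluster(
        selected, k_range=(2,), n_resamples=n_resamples, seed=config.seed
    )
    clusters = consensus.assignments
    dmp = methylation.dmp_test(filtered, clusters)

    # --- stemness ---------------------------------------------------------
    scores = stemness.lsc17_scores(cohort.expression[BASELINE])
    responder = clinical["responder"].astype(float)
    mean_scores = {
        "responders": float(scores[responder[responder == 1].index].mean()),
        "nonresponders": float(scores[responder[responder == 0].index].mean()),
    }
    roc = stats.auroc(
        scores[responder.index].to_numpy(),
        (1 - responder).to_numpy(),  # larger score predicts nonresponse
        auto_orient=False,
    )
    de = stemness.differential_expression(cohort.expression[BASELINE], clusters)
    ranking = de["t"]
    enrichment = stemness.preranked_enrichment(
        ranking, truth.lsc_genes, set_id="planted_LSC_set",
        n_permutations=500, seed=config.seed,
    )

    # --- cluster-2 vs nonresponse enrichment ------------------------------
    cluster2_flag = (clusters == 2).astype(int).reindex(responder.index)
    nonresponse = (1 - responder).astype(int)
    cluster_assoc = stats.fisher_enrichment(
        cluster2_flag, nonresponse, feature_name="cluster2_vs_nonresponse"
    )

    # --- multivariate logistic model (CR ~ LSC17 + RUNX1 + RAS-RTK) -------
    cr = clinical["best_response"].eq("CR").astype(float)
    runx1 = pd.Series(0.0, index=clinical.index)
    rasrtk = pd.Series(0.0, index=clinical.index)
    for pid, grp in base_drivers.groupby("patient_id"):
        if "RUNX1" in set(grp["gene"]):
            runx1[pid] = 1.0
        if any(pmap[g] == RAS_RTK for g in grp["gene"]):
            rasrtk[pid] = 1.0
    design = pd.DataFrame({"lsc17": scores, "runx1": runx1, "ras_rtk": rasrtk})
    logistic = stats.fit_logistic(design, cr)

    # --- evolution patterns -----------------------------------------------
    pattern_rows = []
    for pid, traj in cohort.trajectories.items():
        if not truth.relapsed[pid]:
            continue
        result = patterns.classify_evolution_pattern(traj)
        pattern_rows.append(
            {
                "patient_id": pid,
                "pattern": result.pattern,
                "true_pattern": truth.pattern.get(pid),
                "hg2_state": result.hg2_state,
                "methylation_state": result.methylation_state,
                "homolog_switch": result.homolog_switch,
            }
        )
    pattern_table = pd.DataFrame(pattern_rows)

    ras_fraction = 0.0
    sel = pathway_summary[pathway_summary["pathway"] == RAS_RTK]
    if len(sel):
        ras_fraction = float(sel["fraction"].iloc[0])

    summary = {
        "n_patients": config.n_patients,
        "n_driver_calls": int(len(drivers)),
        "n_cleared": int((clearance["status"] == "cleared").sum()) if len(clearance) else 0,
        "n_relapsed_pairs": len(relapsed_patients),
        "ras_rtk_relapse_fraction": ras_fraction,
        "lsc17_mean_responders": mean_scores["responders"],
        "lsc17_mean_nonresponders": mean_scores["nonresponders"],
        "auroc_lsc17_nonresponse": roc.auroc,
        "cluster2_nonresponse_or": cluster_assoc.odds_ratio,
        "cluster2_nonresponse_p": cluster_assoc.p,
        "lsc_set_es": enrichment.es,
        "lsc_set_p": enrichment.p,
        "consensus_stability_k2": consensus.stability[2],
        "n_dmps": int(dmp["significant"].sum()),
        "pattern_accuracy": (
            float((pattern_table["pattern"] == pattern_table["true_pattern"]).mean())
            if len(pattern_table)
            else float("nan")
        ),
        "logistic_lsc17_p": float(logistic.p.get("lsc17", float("nan"))),
    }

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        simulate.write_cohort(cohort, outdir / "cohort")
        drivers.to_csv(outdir / "drivers.tsv", sep="\t", index=False)
        (outdir / "audit.log").write_text("\n".join(pipeline.audit) + "\n")
        clearance.to_csv(outdir / "clearance.tsv", sep="\t", index=False)
        pd.DataFrame([dataclasses.asdict(e) for e in events]).to_csv(
            outdir / "relapse_events.tsv", sep="\t", index=False
        )
        pathway_summary.to_csv(outdir / "pathway_summary.tsv", sep="\t", index=False)
        clusters.rename("cluster").to_csv(outdir / "clusters.tsv", sep="\t", index_label="sample_id")
        dmp.to_csv(outdir / "dmp.tsv", sep="\t")
        scores.to_csv(outdir / "lsc17_scores.tsv", sep="\t", index_label="sample_id")
        pattern_table.to_csv(outdir / "patterns.tsv", sep="\t", index=False)
        (outdir / "summary.json").write_text(json.dumps(summary, indent=1))

    return {
        "cohort": cohort,
        "drivers": drivers,
        "clearance": clearance,
        "events": events,
        "pathway_summary": pathway_summary,
        "clusters": clusters,
        "dmp": dmp,
        "scores": scores,
        "roc": roc,
        "enrichment": enrichment,
        "cluster_assoc": cluster_assoc,
        "logistic": logistic,
        "patterns": pattern_table,
        "summary": summary,
    }
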