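"""Seeded synthetic multi-omics cohort generator.

Generates a cohort with the statistical structure the downstream analyses
assume: an IDH1/2-mutant patient set split into responders/nonresponders,
two latent methylation clusters (cluster 1 hypomethylated and enriched for
DNMT3A mutations, cluster 2 hypermethylated with elevated stemness-signature
expression and a nonresponse bias), co-occurring driver mutations with
clonal/subclonal cancer-cell fractions, longitudinal VAF trajectories with
relapse acquisitions, post-treatment demethylation, and plasma 2HG
suppression dynamics. Every planted fact is recorded in a
:class:`SyntheticTruth` sidecar so parameter-recovery tests can check the
pipeline against ground truth.

Ground-truth model: diploid, copy-neutral, heterozygous variants — expected
VAF is CCF/2, observed VAF is binomial at a negative-binomially distributed
depth (around 300x).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from idhres.methylation import BetaMatrix, filter_probes
from idhres.patterns import (
    BASELINE,
    RESPONSE,
    RELAPSE,
    PatientTrajectory,
    TrajectoryPoint,
)
from idhres.stemness import LSC17_GENES
from idhres.variants import AnnotationResource

#: VAF detection floor mirrored from the variant filter cascade
DETECTION_FLOOR = 0.05

# gene -> (chrom, genomic pos, protein pos, protein change, ref, alt,
#          variant class, consequence)
VARIANT_ARCHETYPES: dict = {
    "IDH1": ("2", 209113112, 132, "R132H", "C", "T", "SNV", "missense"),
    "IDH2": ("15", 90631934, 140, "R140Q", "C", "T", "SNV", "missense"),
    "DNMT3A": ("2", 25457242, 882, "R882H", "C", "T", "SNV", "missense"),
    "SRSF2": ("17", 74732959, 95, "P95H", "G", "T", "SNV", "missense"),
    "ASXL1": ("20", 31022441, 642, "G642fs", "AG", "A", "indel", "frameshift"),
    "RUNX1": ("21", 36206711, 201, "R201X", "C", "T", "SNV", "stop_gain"),
    "NRAS": ("1", 115258748, 12, "G12S", "C", "T", "SNV", "missense"),
    "KRAS": ("12", 25380275, 61, "Q61H", "T", "G", "SNV", "missense"),
    "PTPN11": ("12", 112888199, 72, "A72V", "C", "T", "SNV", "missense"),
    "CBL": ("11", 119148988, 420, "C420Y", "G", "A", "SNV", "missense"),
    "NF1": ("17", 29553485, 1423, "R1423fs", "CT", "C", "indel", "frameshift"),
    "TET2": ("4", 106157698, 1843, "R1843X", "C", "T", "SNV", "stop_gain"),
    "BCOR": ("X", 39923211, 1459, "R1459fs", "TC", "T", "indel", "frameshift"),
    "CEBPA": ("19", 33792744, 312, "Q312fs", "GC", "G", "indel", "frameshift"),
    "GATA2": ("3", 128200661, 398, "R398W", "C", "T", "SNV", "missense"),
    "STAG2": ("X", 123191810, 653, "R653X", "C", "T", "SNV", "stop_gain"),
    "U2AF1": ("21", 44524456, 34, "S34F", "G", "A", "SNV", "missense"),
    "TP53": ("17", 7577120, 273, "R273H", "C", "T", "SNV", "missense"),
    "FLT3": ("13", 28592642, 835, "D835Y", "C", "T", "SNV", "missense"),
}

#: the homolog-switch alteration planted for pattern-3 relapses
HOMOLOG_SWITCH_ALLELES = {
    "IDH1": ("2", 209113113, 132, "R132C", "C", "A", "SNV", "missense"),
    "IDH2": ("15", 90631935, 140, "R140W", "C", "T", "SNV", "missense"),
}

TSG_GENES = {
    "RUNX1", "ASXL1", "TET2", "BCOR", "NF1", "TP53", "STAG2", "CEBPA", "GATA2",
}

#: baseline co-mutation rates; the four most frequent genes use reported
#: cohort frequencies, the tail is uniform
CO_MUTATION_RATES: dict = {
    "DNMT3A": 0.44,
    "SRSF2": 0.44,
    "ASXL1": 0.37,
    "RUNX1": 0.31,
    "NRAS": 0.10,
    "PTPN11": 0.10,
    "CBL": 0.08,
    "NF1": 0.08,
    "TET2": 0.10,
    "BCOR": 0.08,
    "CEBPA": 0.08,
    "GATA2": 0.06,
    "STAG2": 0.10,
    "U2AF1": 0.10,
    "TP53": 0.05,
    "FLT3": 0.05,
}

EARLY_GENES = {"DNMT3A", "SRSF2", "ASXL1", "RUNX1", "U2AF1"}
LATE_GENES = {"NRAS", "KRAS", "PTPN11", "CBL", "NF1", "FLT3"}

#: relapse-acquisition gene pool with sampling weights shaped so RAS-RTK,
#: chromatin, hematopoietic-TF and DNA-methylation events all occur
RELAPSE_POOL = {
    "KRAS": 0.13, "NRAS": 0.13, "PTPN11": 0.07, "FLT3": 0.05,
    "BCOR": 0.16, "ASXL1": 0.08,
    "RUNX1": 0.13, "CEBPA": 0.08, "GATA2": 0.04,
    "TET2": 0.13,
}

N_LSC_SET = 40


class ConfigError(ValueError):
    """Invalid cohort configuration."""


@dataclass(frozen=True)
class CohortConfig:
    """Knobs controlling cohort scale, planted effect sizes and noise."""

    n_patients: int = 60
    responder_fraction: float = 0.5
    cluster2_fraction: float = 0.25
    n_probes: int = 5000
    promoter_fraction: float = 0.5
    n_genes: int = 1000
    delta_beta_cluster: float = 0.15
    discriminating_probe_fraction: float = 0.05
    lsc_effect: float = 2.0
    vaf_noise_sd: float = 0.0
    beta_noise_sd: float = 0.03
    seed: int = 0
    # secondary structure knobs
    relapse_fraction: float = 0.65  # of responders
    clearance_fraction: float = 0.29  # of responders
    cluster2_response_weight: float = 0.12  # sampling weight of cluster-2 patients
    depth_mean: float = 300.0
    depth_dispersion: float = 20.0
    demeth_probe_fraction: float = 0.25
    cr_fraction_of_responders: float = 0.4

    def __post_init__(self):
        proportions = {
            "responder_fraction": self.responder_fraction,
            "cluster2_fraction": self.cluster2_fraction,
            "promoter_fraction": self.promoter_fraction,
            "discriminating_probe_fraction": self.discriminating_probe_fraction,
            "relapse_fraction": self.relapse_fraction,
            "clearance_fraction": self.clearance_fraction,
            "demeth_probe_fraction": self.demeth_probe_fraction,
            "cr_fraction_of_responders": self.cr_fraction_of_responders,
        }
        for name, value in proportions.items():
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {value}")
        for name in ("n_patients", "n_probes", "n_genes"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.n_genes < len(LSC17_GENES) + N_LSC_SET:
            raise ConfigError(
                f"n_genes must be >= {len(LSC17_GENES) + N_LSC_SET} to hold the signature genes"
            )
        if self.vaf_noise_sd < 0 or self.beta_noise_sd < 0:
            raise ConfigError("noise standard deviations must be non-negative")


@dataclass
class SyntheticTruth:
    """Every planted fact, recoverable for parameter-recovery tests."""

    cluster: dict = field(default_factory=dict)  # patient -> 1 | 2
    responder: dict = field(default_factory=dict)  # patient -> bool
    best_response: dict = field(default_factory=dict)  # patient -> label
    idh_gene: dict = field(default_factory=dict)
    relapsed: dict = field(default_factory=dict)  # patient -> bool
    cleared: dict = field(default_factory=dict)  # responders: planted clearance
    drivers: dict = field(default_factory=dict)  # patient -> {gene: baseline CCF}
    relapse_acquisitions: dict = field(default_factory=dict)  # patient -> [gene]
    pattern: dict = field(default_factory=dict)  # relapser -> 1 | 2 | 3
    discriminating_probes: list = field(default_factory=list)
    demethylation_probes: list = field(default_factory=list)
    lsc_genes: list = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        return cls(**json.loads(Path(path).read_text()))


@dataclass
class Cohort:
    """Mutually consistent multi-omics bundle for one synthetic cohort."""

    config: CohortConfig
    clinical: pd.DataFrame
    variants: pd.DataFrame  # all timepoints, MAF-like
    beta: dict  # timepoint -> BetaMatrix
    expression: dict  # timepoint -> genes x samples DataFrame
    trajectories: dict  # patient -> PatientTrajectory
    resources: AnnotationResource
    truth: SyntheticTruth


def _build_resource() -> AnnotationResource:
    res = AnnotationResource()
    for gene, (chrom, pos, ppos, pchange, ref, alt, _, _) in VARIANT_ARCHETYPES.items():
        res.cosmic_exact.add((gene, pchange))
        res.cosmic_positions.add((gene, ppos))
        res.damaging.add((chrom, pos, ref, alt))
    for gene, (chrom, pos, ppos, pchange, ref, alt, _, _) in HOMOLOG_SWITCH_ALLELES.items():
        res.cosmic_exact.add((gene, pchange))
        res.cosmic_positions.add((gene, ppos))
        res.damaging.add((chrom, pos, ref, alt))
    res.tsg_genes = set(TSG_GENES)
    return res


def _draw_depth(rng, config: CohortConfig) -> int:
    n = config.depth_dispersion
    p = n / (n + config.depth_mean)
    return max(1, int(rng.negative_binomial(n, p)))


def _observe_vaf(rng, ccf: float, config: CohortConfig) -> tuple[int, float]:
    """Binomial read sampling of a diploid-het variant at a random depth."""
    depth = _draw_depth(rng, config)
    expected = min(1.0, max(0.0, ccf / 2.0))
    alt = rng.binomial(depth, expected)
    vaf = alt / depth
    if config.vaf_noise_sd > 0:
        vaf = float(np.clip(vaf + rng.normal(0.0, config.vaf_noise_sd), 0.0, 1.0))
    return depth, vaf


def _variant_row(patient, timepoint, gene, archetype, depth, vaf):
    chrom, pos, ppos, pchange, ref, alt, vclass, consequence = archetype
    return {
        "patient_id": patient,
        "timepoint": timepoint,
        "gene": gene,
        "chrom": chrom,
        "pos": pos,
        "ref": ref,
        "alt": alt,
        "variant_class": vclass,
        "consequence": consequence,
        "protein_pos": ppos,
        "protein_change": pchange,
        "tumor_depth": depth,
        "tumor_vaf": round(float(vaf), 6),
        "normal_vaf": 0.0,
    }


def _assign_patterns(relapsers: list) -> dict:
    """Deterministic pattern assignment over an (already shuffled) list."""
    n = len(relapsers)
    if n == 0:
        return {}
    if n == 1:
        labels = [1]
    elif n == 2:
        labels = [3, 1]
    else:
        n2 = max(1, n // 6)
        labels = [3] + [2] * n2 + [1] * (n - 1 - n2)
    return dict(zip(relapsers, labels))


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate the full cohort bundle; deterministic under ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    truth = SyntheticTruth()
    patients = [f"P{i:03d}" for i in range(1, config.n_patients + 1)]

    # latent cluster: exactly round(n * cluster2_fraction) patients in cluster 2
    n_cluster2 = int(round(config.cluster2_fraction * config.n_patients))
    cluster2 = set(map(str, rng.choice(patients, size=n_cluster2, replace=False)))
    for p in patients:
        truth.cluster[p] = 2 if p in cluster2 else 1

    # response: exact responder count, biased away from cluster 2
    n_resp = int(round(config.responder_fraction * config.n_patients))
    weights = np.array(
        [config.cluster2_response_weight if p in cluster2 else 1.0 for p in patients]
    )
    responders = set(
        map(str, rng.choice(patients, size=n_resp, replace=False, p=weights / weights.sum()))
    )
    for p in patients:
        truth.responder[p] = p in responders

    # best-response labels; CR only among responders
    resp_list = sorted(responders)
    n_cr = int(round(config.cr_fraction_of_responders * len(resp_list)))
    cr_set = set(map(str, rng.choice(resp_list, size=n_cr, replace=False))) if resp_list else set()
    for p in patients:
        if p in cr_set:
            truth.best_response[p] = "CR"
        elif p in responders:
            truth.best_response[p] = str(rng.choice(["CRp", "MLFS", "PR", "HI"]))
        else:
            truth.best_response[p] = str(rng.choice(["SD", "SD", "SD", "PD"]))

    # IDH genotype and planted baseline drivers
    for p in patients:
        truth.idh_gene[p] = "IDH2" if rng.random() < 0.63 else "IDH1"
        idh_ccf = float(rng.uniform(0.7, 0.95))
        drivers = {truth.idh_gene[p]: idh_ccf}
        for gene, rate in CO_MUTATION_RATES.items():
            r = rate
            if gene == "DNMT3A":  # DNMT3A enriched in the hypomethylated cluster
                r = 0.55 if truth.cluster[p] == 1 else 0.18
            if rng.random() >= r:
                continue
            if gene in EARLY_GENES:
                ccf = float(np.clip(idh_ccf + rng.uniform(0.0, 0.15), 0.0, 1.0))
            elif gene in LATE_GENES:
                ccf = float(rng.uniform(0.2, 0.4))
            else:
                ccf = float(rng.uniform(0.35, idh_ccf))
            drivers[gene] = ccf
        truth.drivers[p] = drivers

    # clearance and relapse structure
    resp_shuffled = list(resp_list)
    rng.shuffle(resp_shuffled)
    n_clear = int(round(config.clearance_fraction * len(resp_shuffled)))
    cleared = set(resp_shuffled[:n_clear])
    for p in resp_list:
        truth.cleared[p] = p in cleared
    n_relapse = int(round(config.relapse_fraction * len(resp_shuffled)))
    relapsers = resp_shuffled[:0] if n_relapse == 0 else list(resp_shuffled)
    rng.shuffle(relapsers)
    relapsers = relapsers[:n_relapse]
    for p in patients:
        truth.relapsed[p] = p in set(relapsers)
    truth.pattern = _assign_patterns(relapsers)

    # relapse acquisitions
    pool_genes = list(RELAPSE_POOL)
    pool_w = np.array([RELAPSE_POOL[g] for g in pool_genes])
    for p in relapsers:
        pat = truth.pattern[p]
        acquired: list = []
        if pat == 3:
            homolog = "IDH1" if truth.idh_gene[p] == "IDH2" else "IDH2"
            acquired.append(homolog)
        elif pat == 2:
            if "TET2" not in truth.drivers[p]:
                acquired.append("TET2")
        elif rng.random() < 0.45:  # pattern 1: RAS-RTK-heavy non-IDH clones
            ras = "KRAS" if rng.random() < 0.5 else "NRAS"
            if ras not in truth.drivers[p]:
                acquired.append(ras)
        available = [g for g in pool_genes if g not in truth.drivers[p] and g not in acquired]
        n_extra = int(rng.poisson(0.8))
        if n_extra and available:
            w = np.array([RELAPSE_POOL[g] for g in available])
            extra = rng.choice(available, size=min(n_extra, len(available)), replace=False, p=w / w.sum())
            acquired.extend(str(g) for g in extra)
        truth.relapse_acquisitions[p] = acquired

    variants = _generate_variant_tables(config, truth, rng, patients, relapsers)
    beta, probe_meta = _generate_methylation(config, truth, rng, patients, relapsers)
    expression = _generate_expression(config, truth, rng, patients, relapsers)
    trajectories, hg2 = _generate_trajectories(
        config, truth, rng, patients, relapsers, variants, beta
    )

    clinical = pd.DataFrame(
        {
            "patient_id": patients,
            "idh_gene": [truth.idh_gene[p] for p in patients],
            "treatment": [
                "enasidenib" if truth.idh_gene[p] == "IDH2" else "ivosidenib"
                for p in patients
            ],
            "responder": [int(truth.responder[p]) for p in patients],
            "best_response": [truth.best_response[p] for p in patients],
            "relapsed": [int(truth.relapsed[p]) for p in patients],
            "rfs_months": [
                round(float(rng.exponential(9.0 if truth.cleared.get(p) else 4.0)), 3)
                if truth.responder[p]
                else np.nan
                for p in patients
            ],
            "rfs_event": [
                int(truth.relapsed[p]) if truth.responder[p] else np.nan
                for p in patients
            ],
        }
    )

    return Cohort(
        config=config,
        clinical=clinical,
        variants=variants,
        beta=beta,
        expression=expression,
        trajectories=trajectories,
        resources=_build_resource(),
        truth=truth,
    )


def _generate_variant_tables(config, truth, rng, patients, relapsers) -> pd.DataFrame:
    """Longitudinal MAF-like calls for all patients and timepoints."""
    rows = []
    suppression: dict = {}
    for p in patients:
        if truth.responder[p]:
            u = rng.uniform(0.0, 0.2) if truth.cleared.get(p) else rng.uniform(0.55, 0.95)
        else:
            u = rng.uniform(0.85, 1.0)
        suppression[p] = float(u)
        for gene, ccf in truth.drivers[p].items():
            arch = VARIANT_ARCHETYPES[gene]
            depth, vaf = _observe_vaf(rng, ccf, config)
            if vaf > 0:
                rows.append(_variant_row(p, BASELINE, gene, arch, depth, vaf))
            depth, vaf = _observe_vaf(rng, ccf * u, config)
            if vaf > 0:
                rows.append(_variant_row(p, RESPONSE, gene, arch, depth, vaf))
        if not truth.relapsed[p]:
            continue
        pattern = truth.pattern[p]
        for gene, ccf in truth.drivers[p].items():
            rel_ccf = ccf * float(rng.uniform(0.9, 1.0))
            if pattern == 3 and gene == truth.idh_gene[p]:
                rel_ccf = ccf * float(rng.uniform(0.0, 0.08))
            depth, vaf = _observe_vaf(rng, rel_ccf, config)
            if vaf > 0:
                rows.append(_variant_row(p, RELAPSE, gene, VARIANT_ARCHETYPES[gene], depth, vaf))
        for gene in truth.relapse_acquisitions[p]:
            if pattern == 3 and gene in ("IDH1", "IDH2"):
                arch = HOMOLOG_SWITCH_ALLELES[gene]
                ccf = float(rng.uniform(0.5, 0.9))
            else:
                arch = VARIANT_ARCHETYPES[gene]
                ccf = float(rng.uniform(0.3, 0.8))
            depth, vaf = _observe_vaf(rng, ccf, config)
            # generator contract: planted acquisitions are detectable at relapse
            if vaf < DETECTION_FLOOR:
                vaf = DETECTION_FLOOR + 0.01
            rows.append(_variant_row(p, RELAPSE, gene, arch, depth, vaf))
    columns = [
        "patient_id", "timepoint", "gene", "chrom", "pos", "ref", "alt",
        "variant_class", "consequence", "protein_pos", "protein_change",
        "tumor_depth", "tumor_vaf", "normal_vaf",
    ]
    return pd.DataFrame(rows, columns=columns)


def _generate_methylation(config, truth, rng, patients, relapsers):
    """Beta matrices per timepoint plus shared probe metadata."""
    n = config.n_probes
    probe_ids = pd.Index([f"cg{i:07d}" for i in range(n)], name="probe_id")
    autosomes = [f"chr{i}" for i in range(1, 23)]
    chrom_draw = rng.random(n)
    chroms = np.where(
        chrom_draw < 0.96,
        rng.choice(autosomes, size=n),
        np.where(chrom_draw < 0.99, "chrX", "chrY"),
    )
    snp_flag = rng.random(n) < 0.05
    promoter = rng.random(n) < config.promoter_fraction
    meta = pd.DataFrame(
        {"promoter": promoter, "snp_flag": snp_flag, "chrom": chroms}, index=probe_ids
    )

    eligible = meta.index[
        meta["promoter"] & ~meta["snp_flag"] & ~meta["chrom"].isin(["chrX", "chrY"])
    ]
    n_disc = min(len(eligible), int(round(config.discriminating_probe_fraction * n)))
    disc = pd.Index(rng.choice(eligible, size=n_disc, replace=False))
    truth.discriminating_probes = sorted(map(str, disc))
    disc_mask = probe_ids.isin(disc)

    n_demeth = int(round(config.demeth_probe_fraction * n))
    demeth = pd.Index(rng.choice(probe_ids, size=n_demeth, replace=False))
    truth.demethylation_probes = sorted(map(str, demeth))
    demeth_amount = np.zeros(n)
    demeth_amount[probe_ids.isin(demeth)] = rng.uniform(0.08, 0.16, size=n_demeth)

    mu = rng.uniform(0.15, 0.85, size=n)
    mu[disc_mask] = rng.uniform(0.2, 0.6, size=int(disc_mask.sum()))
    sd = rng.uniform(0.5, 1.5, size=n) * config.beta_noise_sd

    cluster2 = np.array([truth.cluster[p] == 2 for p in patients])
    shift = np.outer(disc_mask, cluster2) * config.delta_beta_cluster

    def draw(base_offset: np.ndarray, cols) -> pd.DataFrame:
        noise = rng.normal(0.0, 1.0, size=(n, len(cols))) * sd[:, None]
        vals = np.clip(mu[:, None] + base_offset + noise, 0.0, 1.0)
        return pd.DataFrame(vals, index=probe_ids, columns=cols)

    baseline = draw(shift, patients)
    post = draw(shift - demeth_amount[:, None], patients)
    beta = {
        BASELINE: BetaMatrix(baseline, meta),
        RESPONSE: BetaMatrix(post, meta.copy()),
    }
    if relapsers:
        shift_rel = shift[:, [patients.index(p) for p in relapsers]]
        suppressed = np.array([truth.pattern[p] == 1 for p in relapsers])
        offset = shift_rel - demeth_amount[:, None] * suppressed[None, :]
        beta[RELAPSE] = BetaMatrix(draw(offset, relapsers), meta.copy())
    return beta, meta


def _gene_universe(config) -> tuple[list, list]:
    lsc_set = [f"LSCG{i:02d}" for i in range(1, N_LSC_SET + 1)]
    n_background = config.n_genes - len(LSC17_GENES) - len(lsc_set)
    background = [f"GENE{i:05d}" for i in range(1, n_background + 1)]
    return lsc_set, list(LSC17_GENES) + lsc_set + background


def _generate_expression(config, truth, rng, patients, relapsers) -> dict:
    """Log2 expression matrices; stemness genes shifted up in cluster 2."""
    lsc_set, genes = _gene_universe(config)
    truth.lsc_genes = lsc_set
    effect_genes = set(LSC17_GENES) | set(lsc_set)
    effect_mask = np.array([g in effect_genes for g in genes])
    cluster2 = np.array([truth.cluster[p] == 2 for p in patients])
    shift = np.outer(effect_mask, cluster2) * config.lsc_effect

    out = {}
    for timepoint, cols in ((BASELINE, patients), (RESPONSE, patients)):
        vals = rng.normal(5.0, 1.0, size=(len(genes), len(cols))) + shift
        out[timepoint] = pd.DataFrame(vals, index=pd.Index(genes, name="gene"), columns=cols)
    return out


def _generate_trajectories(config, truth, rng, patients, relapsers, variants, beta):
    """PatientTrajectory set with 2HG, blasts, IDH VAFs and mean betas."""
    filtered = {tp: filter_probes(m) for tp, m in beta.items()}
    mean_beta = {tp: m.beta.mean(axis=0) for tp, m in filtered.items()}

    idh_vaf: dict = {}
    genes_at: dict = {}
    for row in variants.itertuples(index=False):
        if row.gene in ("IDH1", "IDH2"):
            idh_vaf.setdefault((row.patient_id, row.timepoint), {})[row.gene] = row.tumor_vaf
        if row.tumor_vaf >= DETECTION_FLOOR:
            genes_at.setdefault((row.patient_id, row.timepoint), set()).add(row.gene)

    trajectories = {}
    hg2_rows = []
    for p in patients:
        hg2_base = float(max(500.0, rng.normal(2000.0, 300.0)))
        hg2_resp = hg2_base * float(rng.uniform(0.02, 0.08))
        blast_base = float(rng.uniform(20, 70))
        blast_resp = float(rng.uniform(0, 5)) if truth.responder[p] else float(
            np.clip(blast_base + rng.uniform(-10, 10), 5, 95)
        )
        points = [
            TrajectoryPoint(
                BASELINE,
                mean_beta=float(mean_beta[BASELINE][p]),
                hg2=hg2_base,
                idh_vafs=idh_vaf.get((p, BASELINE), {}),
                driver_genes=tuple(sorted(genes_at.get((p, BASELINE), set()))),
                blast_pct=blast_base,
                response_label=None,
            ),
            TrajectoryPoint(
                RESPONSE,
                mean_beta=float(mean_beta[RESPONSE][p]),
                hg2=hg2_resp,
                idh_vafs=idh_vaf.get((p, RESPONSE), {}),
                driver_genes=tuple(sorted(genes_at.get((p, RESPONSE), set()))),
                blast_pct=blast_resp,
                response_label=truth.best_response[p],
            ),
        ]
        if truth.relapsed[p]:
            pattern = truth.pattern[p]
            if pattern == 3:
                hg2_rel = hg2_base * float(rng.uniform(0.7, 1.0))
            else:
                hg2_rel = hg2_base * float(rng.uniform(0.02, 0.10))
            points.append(
                TrajectoryPoint(
                    RELAPSE,
                    mean_beta=float(mean_beta[RELAPSE][p]),
                    hg2=hg2_rel,
                    idh_vafs=idh_vaf.get((p, RELAPSE), {}),
                    driver_genes=tuple(sorted(genes_at.get((p, RELAPSE), set()))),
                    blast_pct=float(rng.uniform(30, 80)),
                    response_label="relapse",
                )
            )
        trajectories[p] = PatientTrajectory(p, points)
        for pt in points:
            hg2_rows.append({"patient_id": p, "timepoint": pt.label, "hg2": pt.hg2})
    return trajectories, pd.DataFrame(hg2_rows)


def generate_sc_matrix(
    n_cells: int = 1000,
    clones=None,
    missing_rate: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Cells x variants single-cell genotype matrix with clone structure.

    ``clones`` is a list of ``(fraction, {variant: genotype})`` tuples whose
    fractions sum to 1. The default scenario mirrors relapse driven by
    RAS-mutant clones independent of the IDH2-mutant clone. Genotypes are
    0/1 with NaN at ``missing_rate``.
    """
    if clones is None:
        clones = [
            (0.45, {"IDH2_R140Q": 1, "NRAS_G12S": 0, "KRAS_Q61H": 0}),
            (0.20, {"IDH2_R140Q": 0, "NRAS_G12S": 1, "KRAS_Q61H": 0}),
            (0.15, {"IDH2_R140Q": 0, "NRAS_G12S": 0, "KRAS_Q61H": 1}),
            (0.20, {"IDH2_R140Q": 0, "NRAS_G12S": 0, "KRAS_Q61H": 0}),
        ]
    fractions = np.array([f for f, _ in clones], dtype=float)
    if not np.isclose(fractions.sum(), 1.0):
        raise ConfigError("clone fractions must sum to 1")
    variants = sorted({v for _, g in clones for v in g})
    rng = np.random.default_rng(seed)
    assignments = rng.choice(len(clones), size=n_cells, p=fractions)
    data = np.array(
        [[clones[c][1].get(v, 0) for v in variants] for c in assignments], dtype=float
    )
    if missing_rate > 0:
        data[rng.random(data.shape) < missing_rate] = np.nan
    index = pd.Index([f"cell{i:05d}" for i in range(n_cells)], name="cell_id")
    return pd.DataFrame(data, index=index, columns=variants)


# ---------------------------------------------------------------------------
# on-disk layout (plain TSV + truth JSON sidecar)


def write_cohort(cohort: Cohort, outdir: str | Path) -> None:
    """Write the bundle as the TSV formats the analysis modules read."""
    d = Path(outdir)
    d.mkdir(parents=True, exist_ok=True)
    cohort.clinical.to_csv(d / "clinical.tsv", sep="\t", index=False)
    cohort.variants.to_csv(d / "variants.tsv", sep="\t", index=False)
    for tp, m in cohort.beta.items():
        m.to_tsv(d / f"beta_{tp}.tsv")
    cohort.beta[BASELINE].meta.to_csv(d / "probe_meta.tsv", sep="\t", index_label="probe_id")
    for tp, m in cohort.expression.items():
        m.to_csv(d / f"expression_{tp}.tsv", sep="\t", index_label="gene")
    hg2 = []
    for p, traj in cohort.trajectories.items():
        for pt in traj.timepoints:
            hg2.append(
                {
                    "patient_id": p,
                    "timepoint": pt.label,
                    "hg2": pt.hg2,
                    "mean_beta": pt.mean_beta,
                    "blast_pct": pt.blast_pct,
                }
            )
    pd.DataFrame(hg2).to_csv(d / "trajectories.tsv", sep="\t", index=False)
    cohort.resources.to_dir(d / "resources")
    cohort.truth.to_json(d / "truth.json")
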