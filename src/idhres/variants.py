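"""Somatic variant filtering and hierarchical confidence-tier classification.

The filtering cascade removes low-quality calls (tumor coverage < 15x, tumor
VAF < 5%, normal-allele contamination: >= 1% for SNVs, any for indels),
non-protein-altering consequences, and common polymorphisms (population
frequency >= 0.14%). Surviving variants are assigned a confidence tier by a
strict hierarchy:

1. exact match to a confirmed somatic record (catalog gene + protein change),
2. loss-of-function consequence (splicing, stop-gain, stop-loss, frameshift)
   in a tumor-suppressor gene,
3. same gene and amino-acid position as a confirmed somatic record,
4. within three amino acids of a confirmed somatic record and predicted
   damaging in silico.

Variants matching no rule are left unclassified and excluded from the driver
table. Boundary semantics: the thresholds above are removal triggers, so a
call at exactly 15x coverage or exactly 5% VAF is kept, while a population
frequency of exactly 0.14% is removed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: consequences counted as an "obvious protein-coding change"
PROTEIN_ALTERING = frozenset(
    {
        "missense",
        "nonsense",
        "stop_gain",
        "stop_loss",
        "frameshift",
        "inframe_indel",
        "splicing",
        "splice_site",
    }
)

#: loss-of-function consequences for the TSG rule (tier 2)
LOF_CONSEQUENCES = frozenset(
    {"splicing", "splice_site", "stop_gain", "nonsense", "stop_loss", "frameshift"}
)

VARIANT_KEY = ["patient_id", "timepoint", "chrom", "pos", "ref", "alt"]

REQUIRED_COLUMNS = [
    "patient_id",
    "timepoint",
    "gene",
    "chrom",
    "pos",
    "ref",
    "alt",
    "variant_class",
    "consequence",
    "protein_pos",
    "tumor_depth",
    "tumor_vaf",
    "normal_vaf",
]

UNCLASSIFIED = 0  # sentinel tier for variants matching no hierarchy rule


@dataclass(frozen=True)
class FilterThresholds:
    """Removal triggers for the quality/annotation filter cascade."""

    min_tumor_depth: int = 15
    min_tumor_vaf: float = 0.05
    snv_normal_vaf_removal: float = 0.01  # SNV removed when normal_vaf >= this
    popfreq_removal: float = 0.0014  # removed when popfreq >= this


@dataclass
class AnnotationResource:
    """Mock or real annotation lookups driving the tier classifier.

    Lookups are total over the variant universe: a missing population
    frequency reads as 0 and a missing damaging prediction as False.
    """

    cosmic_exact: set = field(default_factory=set)  # (gene, protein_change)
    cosmic_positions: set = field(default_factory=set)  # (gene, protein_pos)
    tsg_genes: set = field(default_factory=set)
    population_frequency: dict = field(default_factory=dict)  # key -> freq
    damaging: set = field(default_factory=set)  # variant keys predicted damaging

    def popfreq(self, chrom, pos, ref, alt) -> float:
        return self.population_frequency.get((str(chrom), int(pos), ref, alt), 0.0)

    def is_damaging(self, chrom, pos, ref, alt) -> bool:
        return (str(chrom), int(pos), ref, alt) in self.damaging

    def positions_for_gene(self, gene: str) -> list[int]:
        return sorted(p for g, p in self.cosmic_positions if g == gene)

    # -- plain-TSV persistence (cosmic.tsv, tsg.txt, popfreq.tsv, damaging.tsv)

    @classmethod
    def from_dir(cls, resource_dir: str | Path) -> "AnnotationResource":
        d = Path(resource_dir)
        res = cls()
        cosmic = pd.read_csv(d / "cosmic.tsv", sep="\t", dtype={"gene": str})
        for row in cosmic.itertuples(index=False):
            res.cosmic_exact.add((row.gene, row.protein_change))
            res.cosmic_positions.add((row.gene, int(row.protein_pos)))
        res.tsg_genes = set((d / "tsg.txt").read_text().split())
        pf = d / "popfreq.tsv"
        if pf.exists():
            t = pd.read_csv(pf, sep="\t", dtype={"chrom": str})
            for row in t.itertuples(index=False):
                res.population_frequency[
                    (str(row.chrom), int(row.pos), row.ref, row.alt)
                ] = float(row.freq)
        dm = d / "damaging.tsv"
        if dm.exists():
            t = pd.read_csv(dm, sep="\t", dtype={"chrom": str})
            for row in t.itertuples(index=False):
                if bool(row.damaging):
                    res.damaging.add((str(row.chrom), int(row.pos), row.ref, row.alt))
        return res

    def to_dir(self, resource_dir: str | Path) -> None:
        d = Path(resource_dir)
        d.mkdir(parents=True, exist_ok=True)
        pos_by_change = {}
        for gene, change in sorted(self.cosmic_exact):
            digits = "".join(c for c in change if c.isdigit())
            pos_by_change[(gene, change)] = int(digits) if digits else -1
        rows = [
            {"gene": g, "protein_change": c, "protein_pos": pos_by_change[(g, c)]}
            for g, c in sorted(self.cosmic_exact)
        ]
        known = {(r["gene"], r["protein_pos"]) for r in rows}
        for gene, pos in sorted(self.cosmic_positions):
            if (gene, pos) not in known:
                rows.append({"gene": gene, "protein_change": ".", "protein_pos": pos})
        pd.DataFrame(rows, columns=["gene", "protein_change", "protein_pos"]).to_csv(
            d / "cosmic.tsv", sep="\t", index=False
        )
        (d / "tsg.txt").write_text("\n".join(sorted(self.tsg_genes)) + "\n")
        pd.DataFrame(
            [
                {"chrom": k[0], "pos": k[1], "ref": k[2], "alt": k[3], "freq": v}
                for k, v in sorted(self.population_frequency.items())
            ],
            columns=["chrom", "pos", "ref", "alt", "freq"],
        ).to_csv(d / "popfreq.tsv", sep="\t", index=False)
        pd.DataFrame(
            [
                {"chrom": k[0], "pos": k[1], "ref": k[2], "alt": k[3], "damaging": 1}
                for k in sorted(self.damaging)
            ],
            columns=["chrom", "pos", "ref", "alt", "damaging"],
        ).to_csv(d / "damaging.tsv", sep="\t", index=False)


def _validate(calls: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in calls.columns]
    if missing:
        raise ValueError(f"variant table missing columns: {missing}")
    for col in ("tumor_vaf", "normal_vaf"):
        vals = calls[col].astype(float)
        if ((vals < 0) | (vals > 1)).any():
            raise ValueError(f"{col} outside [0, 1]")
    if (calls["tumor_depth"].astype(float) < 0).any():
        raise ValueError("tumor_depth must be non-negative")


def apply_variant_filters(
    calls: pd.DataFrame,
    resource: AnnotationResource,
    thresholds: FilterThresholds = FilterThresholds(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the quality/annotation filter cascade.

    Returns ``(surviving, verdicts)``: the surviving calls and a per-input-row
    verdict table with one boolean column per rule plus a ``failed`` column
    listing every rule the variant tripped (empty string = kept). The rule
    families are independent, so the surviving set does not depend on
    evaluation order.
    """
    _validate(calls)
    t = thresholds
    depth = calls["tumor_depth"].astype(float)
    tvaf = calls["tumor_vaf"].astype(float)
    nvaf = calls["normal_vaf"].astype(float)
    is_indel = calls["variant_class"].str.lower().eq("indel")

    low_coverage = depth < t.min_tumor_depth
    low_vaf = tvaf < t.min_tumor_vaf
    normal_contamination = np.where(
        is_indel, nvaf > 0.0, nvaf >= t.snv_normal_vaf_removal
    )
    non_coding = ~calls["consequence"].isin(PROTEIN_ALTERING)
    popfreqs = np.array(
        [
            resource.popfreq(c, p, r, a)
            for c, p, r, a in zip(calls["chrom"], calls["pos"], calls["ref"], calls["alt"])
        ]
    ) if len(calls) else np.zeros(0)
    common_polymorphism = popfreqs >= t.popfreq_removal

    verdicts = pd.DataFrame(
        {
            "low_coverage": low_coverage.to_numpy(),
            "low_vaf": low_vaf.to_numpy(),
            "normal_contamination": normal_contamination,
            "non_coding": non_coding.to_numpy(),
            "common_polymorphism": common_polymorphism,
        },
        index=calls.index,
    )
    rule_cols = list(verdicts.columns)
    verdicts["failed"] = [
        ",".join(r for r in rule_cols if row[r]) for _, row in verdicts.iterrows()
    ]
    keep = ~verdicts[rule_cols].any(axis=1)
    removed = int((~keep).sum())
    logger.info("variant filters: %d/%d calls removed", removed, len(calls))
    return calls.loc[keep].copy(), verdicts


def classify_confidence(variant, resource: AnnotationResource) -> int:
    """Assign the hierarchical confidence tier to a single surviving variant.

    ``variant`` is a mapping/namedtuple/Series with VariantCall fields, plus
    an optional ``protein_change`` (e.g. ``"R132H"``). Returns 1-4, or
    ``UNCLASSIFIED`` (0) when no rule applies. Position rules (tiers 3 and 4)
    are skipped when ``protein_pos`` is absent.
    """
    get = variant.get if hasattr(variant, "get") else lambda k, d=None: getattr(variant, k, d)
    gene = get("gene")
    consequence = get("consequence")
    protein_change = get("protein_change")
    protein_pos = get("protein_pos")
    has_pos = protein_pos is not None and not (
        isinstance(protein_pos, float) and np.isnan(protein_pos)
    )

    if protein_change and isinstance(protein_change, str) and protein_change != ".":
        if (gene, protein_change) in resource.cosmic_exact:
            return 1
    if consequence in LOF_CONSEQUENCES and gene in resource.tsg_genes:
        return 2
    if has_pos:
        pos = int(protein_pos)
        if (gene, pos) in resource.cosmic_positions:
            return 3
        damaging = resource.is_damaging(get("chrom"), get("pos"), get("ref"), get("alt"))
        if damaging and any(
            abs(pos - cat_pos) <= 3 for cat_pos in resource.positions_for_gene(gene)
        ):
            return 4
    return UNCLASSIFIED


@dataclass
class PipelineResult:
    drivers: pd.DataFrame  # surviving variants with a ``tier`` column in {1..4}
    audit: list  # one line per removed/unclassified variant with its reason
    counts_by_class: dict  # variant_class -> count among drivers


def run_variant_pipeline(
    calls: pd.DataFrame,
    resource: AnnotationResource,
    thresholds: FilterThresholds = FilterThresholds(),
) -> PipelineResult:
    """Dedup -> filter -> classify; returns the high-confidence driver table.

    Duplicated rows (same patient, timepoint, chrom, pos, ref, alt) are
    collapsed to their first occurrence before filtering, making the pipeline
    idempotent on concatenated inputs.
    """
    if calls.empty:
        empty = calls.copy()
        empty["tier"] = pd.Series(dtype=int)
        return PipelineResult(empty, [], {})
    calls = calls.drop_duplicates(subset=VARIANT_KEY, keep="first").reset_index(drop=True)
    surviving, verdicts = apply_variant_filters(calls, resource, thresholds)
    audit = [
        f"{calls.loc[i, 'patient_id']}\t{calls.loc[i, 'timepoint']}\t"
        f"{calls.loc[i, 'gene']}\t{calls.loc[i, 'chrom']}:{calls.loc[i, 'pos']}"
        f"\tremoved\t{verdicts.loc[i, 'failed']}"
        for i in calls.index
        if verdicts.loc[i, "failed"]
    ]
    tiers = [classify_confidence(row, resource) for _, row in surviving.iterrows()]
    surviving = surviving.assign(tier=tiers)
    for _, row in surviving[surviving["tier"] == UNCLASSIFIED].iterrows():
        audit.append(
            f"{row['patient_id']}\t{row['timepoint']}\t{row['gene']}\t"
            f"{row['chrom']}:{row['pos']}\tunclassified\tno_tier_rule"
        )
    drivers = surviving[surviving["tier"] != UNCLASSIFIED].reset_index(drop=True)
    counts = drivers["variant_class"].value_counts().to_dict()
    logger.info(
        "variant pipeline: %d drivers from %d calls (%s)",
        len(drivers),
        len(calls),
        counts,
    )
    return PipelineResult(drivers, audit, counts)
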