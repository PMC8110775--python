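"""Filter-cascade and confidence-tier tests, including an independent
brute-force rule oracle."""

import numpy as np
import pandas as pd
import pytest

from idhres.variants import (
    AnnotationResource,
    FilterThresholds,
    apply_variant_filters,
    classify_confidence,
    run_variant_pipeline,
)


def make_call(**overrides):
    base = dict(
        patient_id="P001",
        timepoint="baseline",
        gene="IDH1",
        chrom="2",
        pos=209113112,
        ref="C",
        alt="T",
        variant_class="SNV",
        consequence="missense",
        protein_pos=132,
        protein_change="R132H",
        tumor_depth=300,
        tumor_vaf=0.4,
        normal_vaf=0.0,
    )
    base.update(overrides)
    return base


@pytest.fixture
def resource():
    res = AnnotationResource()
    res.cosmic_exact = {("IDH1", "R132H"), ("DNMT3A", "R882H"), ("NRAS", "G12D")}
    res.cosmic_positions = {("IDH1", 132), ("DNMT3A", 882), ("NRAS", 12)}
    res.tsg_genes = {"RUNX1", "ASXL1", "TET2"}
    return res


class TestFilters:
    def test_low_coverage_removed(self, resource):
        calls = pd.DataFrame([make_call(tumor_depth=14)])
        kept, verdicts = apply_variant_filters(calls, resource)
        assert kept.empty
        assert verdicts.loc[0, "failed"] == "low_coverage"

    def test_coverage_boundary_kept(self, resource):
        calls = pd.DataFrame([make_call(tumor_depth=15)])
        kept, _ = apply_variant_filters(calls, resource)
        assert len(kept) == 1

    def test_vaf_boundary_exactly_5pct_kept(self, resource):
        calls = pd.DataFrame([make_call(tumor_vaf=0.05)])
        kept, _ = apply_variant_filters(calls, resource)
        assert len(kept) == 1

    def test_vaf_below_5pct_removed(self, resource):
        calls = pd.DataFrame([make_call(tumor_vaf=0.049)])
        kept, verdicts = apply_variant_filters(calls, resource)
        assert kept.empty and verdicts.loc[0, "failed"] == "low_vaf"

    def test_indel_any_normal_contamination_removed(self, resource):
        calls = pd.DataFrame(
            [make_call(variant_class="indel", consequence="frameshift", normal_vaf=0.004)]
        )
        kept, verdicts = apply_variant_filters(calls, resource)
        assert kept.empty
        assert verdicts.loc[0, "failed"] == "normal_contamination"

    def test_snv_normal_below_1pct_kept(self, resource):
        calls = pd.DataFrame([make_call(normal_vaf=0.009)])
        kept, _ = apply_variant_filters(calls, resource)
        assert len(kept) == 1

    def test_snv_normal_at_1pct_removed(self, resource):
        calls = pd.DataFrame([make_call(normal_vaf=0.01)])
        kept, _ = apply_variant_filters(calls, resource)
        assert kept.empty

    def test_synonymous_removed(self, resource):
        calls = pd.DataFrame([make_call(consequence="synonymous")])
        kept, verdicts = apply_variant_filters(calls, resource)
        assert kept.empty and verdicts.loc[0, "failed"] == "non_coding"

    def test_popfreq_at_threshold_removed(self, resource):
        resource.population_frequency[("2", 209113112, "C", "T")] = 0.0014
        calls = pd.DataFrame([make_call()])
        kept, verdicts = apply_variant_filters(calls, resource)
        assert kept.empty and verdicts.loc[0, "failed"] == "common_polymorphism"

    def test_popfreq_below_threshold_kept(self, resource):
        resource.population_frequency[("2", 209113112, "C", "T")] = 0.00139
        kept, _ = apply_variant_filters(pd.DataFrame([make_call()]), resource)
        assert len(kept) == 1

    def test_vaf_out_of_range_rejected(self, resource):
        with pytest.raises(ValueError, match="tumor_vaf"):
            apply_variant_filters(pd.DataFrame([make_call(tumor_vaf=1.2)]), resource)

    def test_multiple_failures_recorded(self, resource):
        calls = pd.DataFrame([make_call(tumor_depth=10, tumor_vaf=0.01)])
        _, verdicts = apply_variant_filters(calls, resource)
        assert set(verdicts.loc[0, "failed"].split(",")) == {"low_coverage", "low_vaf"}


class TestTiers:
    def test_exact_cosmic_match_tier1(self, resource):
        assert classify_confidence(make_call(), resource) == 1

    def test_hierarchy_tier1_beats_tier2(self, resource):
        # exact COSMIC match that is also LoF-in-TSG stays tier 1
        resource.cosmic_exact.add(("RUNX1", "R201X"))
        v = make_call(gene="RUNX1", consequence="stop_gain", protein_change="R201X", protein_pos=201)
        assert classify_confidence(v, resource) == 1

    def test_lof_in_tsg_tier2(self, resource):
        v = make_call(gene="RUNX1", consequence="frameshift", protein_change=".", protein_pos=88)
        assert classify_confidence(v, resource) == 2

    def test_lof_outside_tsg_not_tier2(self, resource):
        v = make_call(gene="GENEX", consequence="frameshift", protein_change=".", protein_pos=88)
        assert classify_confidence(v, resource) == 0

    def test_same_position_tier3(self, resource):
        v = make_call(protein_change="R132L")  # not in exact set, position matches
        assert classify_confidence(v, resource) == 3

    def test_near_position_damaging_tier4(self, resource):
        res = resource
        res.damaging.add(("2", 209113121, "G", "A"))
        v = make_call(pos=209113121, ref="G", alt="A", protein_change="S135F", protein_pos=135)
        assert classify_confidence(v, res) == 4

    def test_four_residues_away_unclassified(self, resource):
        resource.damaging.add(("2", 209113124, "G", "A"))
        v = make_call(pos=209113124, ref="G", alt="A", protein_change="S136F", protein_pos=136)
        assert classify_confidence(v, resource) == 0

    def test_near_position_not_damaging_unclassified(self, resource):
        v = make_call(pos=209113121, ref="G", alt="A", protein_change="S135F", protein_pos=135)
        assert classify_confidence(v, resource) == 0

    def test_missing_protein_pos_skips_position_rules(self, resource):
        v = make_call(protein_change=".", protein_pos=np.nan)
        assert classify_confidence(v, resource) == 0

    def test_adding_exact_match_only_lowers_tier(self, resource):
        v = make_call(gene="RUNX1", consequence="missense", protein_change="R205W", protein_pos=205)
        before = classify_confidence(v, resource)
        resource.cosmic_exact.add(("RUNX1", "R205W"))
        after = classify_confidence(v, resource)
        assert after == 1 and (before == 0 or after <= before)


class TestPipeline:
    def test_empty_input(self, resource):
        cols = list(make_call().keys())
        result = run_variant_pipeline(pd.DataFrame(columns=cols), resource)
        assert result.drivers.empty and result.audit == []

    def test_all_synonymous_empty(self, resource):
        calls = pd.DataFrame([make_call(consequence="synonymous", pos=p) for p in range(5)])
        result = run_variant_pipeline(calls, resource)
        assert result.drivers.empty
        assert len(result.audit) == 5

    def test_duplicates_collapsed(self, resource):
        calls = pd.DataFrame([make_call(), make_call()])
        result = run_variant_pipeline(calls, resource)
        assert len(result.drivers) == 1

    def test_counts_by_class(self, resource):
        calls = pd.DataFrame(
            [
                make_call(),
                make_call(
                    gene="RUNX1", chrom="21", pos=1, ref="AT", alt="A",
                    variant_class="indel", consequence="frameshift",
                    protein_change=".", protein_pos=100,
                ),
            ]
        )
        result = run_variant_pipeline(calls, resource)
        assert result.counts_by_class == {"SNV": 1, "indel": 1}

    def test_audit_logs_every_removal(self, resource):
        calls = pd.DataFrame([make_call(tumor_depth=5, pos=1), make_call(pos=2, protein_change="R132H")])
        result = run_variant_pipeline(calls, resource)
        assert len(result.audit) == 1 and "low_coverage" in result.audit[0]


# ---------------------------------------------------------------------------
# brute-force oracle


CONSEQUENCES = [
    "missense", "nonsense", "stop_gain", "stop_loss", "frameshift",
    "inframe_indel", "splicing", "splice_site", "synonymous", "noncoding",
]
PROTEIN_ALTERING_ORACLE = set(CONSEQUENCES[:8])
LOF_ORACLE = {"splicing", "splice_site", "stop_gain", "nonsense", "stop_loss", "frameshift"}


def oracle_classify(v, res):
    """Naive re-statement of the removal rules and tier hierarchy.

    Returns None when the variant is filtered out, else its tier (0 =
    unclassified). Written independently of the package implementation.
    """
    if v["tumor_depth"] < 15:
        return None
    if v["tumor_vaf"] < 0.05:
        return None
    if v["variant_class"] == "indel":
        if v["normal_vaf"] > 0:
            return None
    else:
        if v["normal_vaf"] >= 0.01:
            return None
    if v["consequence"] not in PROTEIN_ALTERING_ORACLE:
        return None
    key = (v["chrom"], v["pos"], v["ref"], v["alt"])
    if res.population_frequency.get(key, 0.0) >= 0.0014:
        return None
    if (v["gene"], v["protein_change"]) in res.cosmic_exact:
        return 1
    if v["consequence"] in LOF_ORACLE and v["gene"] in res.tsg_genes:
        return 2
    if v["protein_pos"] is not None and not np.isnan(v["protein_pos"]):
        pp = int(v["protein_pos"])
        if (v["gene"], pp) in res.cosmic_positions:
            return 3
        if key in res.damaging:
            for g, cp in res.cosmic_positions:
                if g == v["gene"] and abs(pp - cp) <= 3:
                    return 4
    return 0


def random_variants(n, seed):
    rng = np.random.default_rng(seed)
    genes = ["IDH1", "DNMT3A", "RUNX1", "ASXL1", "NRAS", "GENEX", "TET2"]
    res = AnnotationResource()
    res.tsg_genes = {"RUNX1", "ASXL1", "TET2"}
    for gene in genes:
        for _ in range(3):
            pos = int(rng.integers(1, 300))
            aa = f"{rng.choice(list('ARNDCEQG'))}{pos}{rng.choice(list('ARNDCEQG'))}"
            res.cosmic_exact.add((gene, aa))
            res.cosmic_positions.add((gene, pos))
    rows = []
    for i in range(n):
        vclass = str(rng.choice(["SNV", "indel"]))
        consequence = str(rng.choice(CONSEQUENCES))
        ppos = float(rng.integers(1, 300)) if rng.random() < 0.9 else np.nan
        change = (
            f"{rng.choice(list('ARNDCEQG'))}{int(ppos)}{rng.choice(list('ARNDCEQG'))}"
            if not np.isnan(ppos) and rng.random() < 0.8
            else "."
        )
        row = dict(
            patient_id=f"P{i:04d}",
            timepoint="baseline",
            gene=str(rng.choice(genes)),
            chrom=str(rng.integers(1, 23)),
            pos=int(rng.integers(1, 10**6)),
            ref="C" if vclass == "SNV" else "CA",
            alt="T" if vclass == "SNV" else "C",
            variant_class=vclass,
            consequence=consequence,
            protein_pos=ppos,
            protein_change=change,
            tumor_depth=int(rng.integers(5, 600)),
            tumor_vaf=float(np.round(rng.uniform(0, 0.6), 4)),
            normal_vaf=float(np.round(rng.choice([0.0, 0.0, 0.003, 0.02]), 4)),
        )
        key = (row["chrom"], row["pos"], row["ref"], row["alt"])
        if rng.random() < 0.1:
            res.population_frequency[key] = float(rng.choice([0.0005, 0.0014, 0.01]))
        if rng.random() < 0.5:
            res.damaging.add(key)
        rows.append(row)
    return pd.DataFrame(rows), res


def test_pipeline_matches_bruteforce_oracle_1000():
    calls, res = random_variants(1000, seed=42)
    result = run_variant_pipeline(calls, res)
    expected = {}
    for _, v in calls.iterrows():
        tier = oracle_classify(v.to_dict(), res)
        if tier is not None and tier > 0:
            expected[(v["patient_id"], v["chrom"], v["pos"], v["ref"], v["alt"])] = tier
    got = {
        (r["patient_id"], r["chrom"], r["pos"], r["ref"], r["alt"]): r["tier"]
        for _, r in result.drivers.iterrows()
    }
    assert got == expected


def test_filter_family_order_invariance():
    """Surviving set identical when rule families are applied in any order."""
    calls, res = random_variants(300, seed=11)
    full_kept, verdicts = apply_variant_filters(calls, res)
    families = ["low_coverage", "low_vaf", "normal_contamination", "non_coding", "common_polymorphism"]
    rng = np.random.default_rng(0)
    for _ in range(5):
        order = list(rng.permutation(families))
        surviving = calls.copy()
        for fam in order:
            keep_idx = verdicts.index[~verdicts[fam]]
            surviving = surviving.loc[surviving.index.intersection(keep_idx)]
        assert set(surviving.index) == set(full_kept.index)


def test_tier_is_single_valued(resource):
    calls, res = random_variants(200, seed=3)
    kept, _ = apply_variant_filters(calls, res)
    for _, v in kept.iterrows():
        t1 = classify_confidence(v, res)
        t2 = classify_confidence(v, res)
        assert t1 == t2 and t1 in (0, 1, 2, 3, 4)


def test_resource_tsv_roundtrip(tmp_path):
    _, res = random_variants(50, seed=5)
    res.to_dir(tmp_path)
    back = AnnotationResource.from_dir(tmp_path)
    assert back.tsg_genes == res.tsg_genes
    assert back.cosmic_exact >= {e for e in res.cosmic_exact}
    assert back.cosmic_positions >= res.cosmic_positions
    assert back.damaging == res.damaging
    assert back.population_frequency == res.population_frequency
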