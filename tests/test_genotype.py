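"""Record-level gene-content classification rules."""

from __future__ import annotations

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kirassoc import (
    GenotypeCatalog,
    KirClassMap,
    KirTypingRecord,
    classify_2ds4_variant,
    classify_bx_subset,
    classify_haplotype_group,
    call_linkage_groups,
    content_key,
    count_kir_classes,
    profile_genotype,
)
from kirassoc.genotype import (
    ConfigurationError,
    UntypedMarkerError,
    ValidationError,
)
from kirassoc.loci import (
    A_CONTENT_GENES,
    B_SPECIFIC_GENES,
    C4_GENES,
    FRAMEWORK_GENES,
    KIR_MARKERS,
    T4_GENES,
)
from conftest import make_record


class TestHaplotypeGroup:
    def test_fixed_a_content_is_aa(self, aa_record):
        assert classify_haplotype_group(aa_record) == "AA"

    @pytest.mark.parametrize("b_gene", sorted(B_SPECIFIC_GENES))
    def test_any_b_specific_gene_forces_bx(self, b_gene):
        rec = make_record(A_CONTENT_GENES | {b_gene})
        assert classify_haplotype_group(rec) == "Bx"

    @pytest.mark.parametrize("a_gene", sorted(A_CONTENT_GENES))
    def test_missing_a_content_gene_forces_bx(self, a_gene):
        rec = make_record(A_CONTENT_GENES - {a_gene})
        if a_gene == "2DS4":
            rec.ds4_variant = "negative"
        assert classify_haplotype_group(rec) == "Bx"

    def test_untyped_marker_strict_raises_with_marker_name(self, aa_record):
        aa_record.presence["2DL3"] = None
        with pytest.raises(UntypedMarkerError, match="2DL3"):
            classify_haplotype_group(aa_record)
        assert classify_haplotype_group(aa_record, strict=False) is None

    def test_observed_b_gene_decides_bx_despite_untyped_markers(self):
        rec = make_record(A_CONTENT_GENES | {"2DS2"})
        rec.presence["2DL3"] = None
        assert classify_haplotype_group(rec, strict=False) == "Bx"

    def test_framework_absent_rejected(self, aa_record):
        aa_record.presence["3DL2"] = False
        with pytest.raises(ValidationError, match="3DL2"):
            classify_haplotype_group(aa_record)


class TestLinkageGroups:
    def test_full_c4_cluster_only(self):
        rec = make_record(A_CONTENT_GENES | set(C4_GENES))
        assert call_linkage_groups(rec) == (True, False)

    def test_aa_record_carries_neither_cluster(self, aa_record):
        assert call_linkage_groups(aa_record) == (False, False)

    def test_partial_cluster_is_not_called(self):
        rec = make_record(A_CONTENT_GENES | {"2DS2", "2DL2"})  # no 2DS3/2DL5
        assert call_linkage_groups(rec) == (False, False)

    def test_untyped_required_marker_lenient_gives_unknown(self):
        rec = make_record(A_CONTENT_GENES | set(C4_GENES))
        rec.presence["2DL5"] = None
        with pytest.raises(UntypedMarkerError):
            call_linkage_groups(rec)
        c4, t4 = call_linkage_groups(rec, strict=False)
        assert c4 is None and t4 is False


class TestBxSubset:
    def test_aa_not_applicable(self, aa_record):
        assert classify_bx_subset(aa_record) == "not_applicable"

    @pytest.mark.parametrize(
        "extra, expected",
        [
            (set(C4_GENES), "C4Tx"),
            (set(T4_GENES), "CxT4"),
            (set(C4_GENES) | set(T4_GENES), "C4T4"),
            ({"2DL2"}, "CxTx"),  # rare genotype: 2DL2 without 2DS2
        ],
    )
    def test_subset_truth_table(self, extra, expected):
        rec = make_record(A_CONTENT_GENES | extra)
        assert classify_bx_subset(rec) == expected


class TestKirClassCounts:
    def test_aa_counts_under_default_map(self, aa_record):
        counts = count_kir_classes(aa_record)
        assert (counts.n_inhibitory, counts.n_activating) == (5, 1)
        assert counts.ikir_gt_akir and counts.ikir_gt_4
        assert not counts.akir_gt_ikir and not counts.akir_gt_4

    def test_all_genes_present_counts(self, all_genes_record):
        counts = count_kir_classes(all_genes_record)
        assert (counts.n_inhibitory, counts.n_activating) == (7, 6)
        assert counts.ikir_gt_akir

    def test_tie_sets_neither_directional_flag(self):
        # 4 inhibitory (3DL3, 3DL2 frameworks + 2DL1, 2DL2), 4 activating
        rec = make_record({"2DL1", "2DL2", "2DS1", "2DS2", "2DS3", "2DS4"})
        counts = count_kir_classes(rec)
        assert counts.n_inhibitory == counts.n_activating == 4
        assert not counts.ikir_gt_akir and not counts.akir_gt_ikir

    def test_overlapping_class_map_rejected(self):
        with pytest.raises(ConfigurationError):
            KirClassMap(inhibitory_set=frozenset({"2DL1"}), activating_set=frozenset({"2DL1"}))


class Test2DS4Variant:
    def test_pass_through(self):
        rec = make_record(A_CONTENT_GENES, ds4_variant="fl_del")
        assert classify_2ds4_variant(rec) == "fl_del"

    def test_variant_without_gene_rejected(self):
        with pytest.raises(ValidationError, match="2DS4"):
            rec = make_record(A_CONTENT_GENES - {"2DS4"}, ds4_variant="fl")
            classify_2ds4_variant(rec)

    def test_negative_with_gene_present_rejected(self):
        with pytest.raises(ValidationError):
            rec = make_record(A_CONTENT_GENES, ds4_variant="negative")
            classify_2ds4_variant(rec)


class TestProfileAndCatalog:
    def test_profiling_is_deterministic(self, all_genes_record):
        catalog = GenotypeCatalog()
        p1 = profile_genotype(all_genes_record, catalog)
        p2 = profile_genotype(all_genes_record, catalog)
        assert p1 == p2
        assert p1.content_key == "1" * 16
        assert p1.genotype_id == "G001"

    def test_catalog_gains_one_entry_per_distinct_content(self):
        catalog = GenotypeCatalog()
        recs = [
            make_record(A_CONTENT_GENES),
            make_record(A_CONTENT_GENES),  # duplicate content
            make_record(A_CONTENT_GENES | {"2DS2", "2DL2"}),
            make_record(KIR_MARKERS),
        ]
        for rec in recs:
            profile_genotype(rec, catalog)
        assert len(catalog) == 3

    def test_synthetic_ids_ordered_by_bitmask(self):
        catalog = GenotypeCatalog()
        k_small = content_key(make_record(A_CONTENT_GENES))
        k_big = content_key(make_record(KIR_MARKERS))
        catalog.assign([k_big, k_small])  # order of arrival must not matter
        assert catalog.entries[min(k_small, k_big)] == "G001"

    def test_aa_profile_invariants(self, aa_record):
        p = profile_genotype(aa_record)
        assert p.haplotype_class == "AA"
        assert not p.c4_present and not p.t4_present
        assert p.bx_subset == "not_applicable"


@st.composite
def random_records(draw):
    present = {
        m for m in KIR_MARKERS
        if m in FRAMEWORK_GENES or draw(st.booleans())
    }
    return make_record(present)


@given(random_records())
@settings(max_examples=200, deadline=None)
def test_subset_partition_property(rec):
    """Every record is AA xor Bx; every Bx record falls in exactly one subset,
    and the C4/T4 calls agree with the subset name."""
    group = classify_haplotype_group(rec)
    subset = classify_bx_subset(rec)
    c4, t4 = call_linkage_groups(rec)
    if group == "AA":
        assert subset == "not_applicable" and not c4 and not t4
    else:
        assert subset in {"C4Tx", "CxT4", "C4T4", "CxTx"}
        assert subset == {(True, False): "C4Tx", (False, True): "CxT4",
                          (True, True): "C4T4", (False, False): "CxTx"}[(c4, t4)]
    counts = count_kir_classes(rec)
    assert counts.n_inhibitory + counts.n_activating <= 16
    assert not (counts.ikir_gt_akir and counts.akir_gt_ikir)
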