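"""Variant calling, shifted-reference merging, pseudobulk and modality logic."""

import numpy as np
import pytest

from mitohet.calling import (
    ALLELE_INDEX,
    AlleleCountMatrix,
    VariantCall,
    call_variants,
    merge_shifted_calls,
    modality_compare,
    pileup_reads,
    pseudobulk,
    write_vcf,
)
from mitohet.qc import mask_polyA
from mitohet.reference import CircularReference, rotate_reference
from mitohet.simulate import linearized_views


def matrix(cells, L, entries, ref: CircularReference, base_depth=0):
    """Build a count matrix: entries = {(cell, pos, allele): count}.

    Remaining depth at touched positions is reference-allele filled when
    ``base_depth`` is given.
    """
    counts = np.zeros((len(cells), L, 6), dtype=np.int64)
    if base_depth:
        for i in range(len(cells)):
            for p in range(1, L + 1):
                counts[i, p - 1, ALLELE_INDEX[ref.base(p)]] = base_depth
    for (cell, pos, allele), n in entries.items():
        i = cells.index(cell)
        counts[i, pos - 1, ALLELE_INDEX[allele]] += n
        if base_depth:
            counts[i, pos - 1, ALLELE_INDEX[ref.base(pos)]] -= n
    return AlleleCountMatrix(cells, np.arange(1, L + 1), counts)


@pytest.fixture(scope="module")
def ref8():
    return CircularReference("m", "ACGTACGTACGTACGTACGT")  # L=20


class TestCallVariants:
    def test_af_is_alt_over_depth(self, ref8):
        acm = matrix(["c1"], 20, {("c1", 3, "T"): 60}, ref8, base_depth=100)
        calls = call_variants(acm, ref8, min_depth=50)
        (call,) = calls
        assert call.ref_allele == "G" and call.alt_allele == "T"
        assert call.af["c1"] == pytest.approx(0.6)
        assert call.af["c1"] * call.depth["c1"] == 60  # exact on integers

    def test_min_depth_boundary(self, ref8):
        # RNA rule: depth 49 leaves the AF undefined, depth 50 defines it
        entries = {("c1", 5, "G"): 10, ("c2", 5, "G"): 10}
        counts = matrix(["c1", "c2"], 20, entries, ref8, base_depth=0)
        counts.counts[0, 4, ALLELE_INDEX["A"]] = 39  # depth 49
        counts.counts[1, 4, ALLELE_INDEX["A"]] = 40  # depth 50
        (call,) = call_variants(counts, ref8, min_depth=50)
        assert "c1" not in call.af
        assert call.af["c2"] == pytest.approx(0.2)

    def test_site_without_alt_reads_not_emitted(self, ref8):
        acm = matrix(["c1"], 20, {}, ref8, base_depth=100)
        assert call_variants(acm, ref8, min_depth=50) == []

    def test_emission_floor(self, ref8):
        acm = matrix(["c1"], 20, {("c1", 3, "T"): 2}, ref8, base_depth=1000)
        assert call_variants(acm, ref8, min_depth=50) == []  # AF 0.002 < 0.01
        acm2 = matrix(["c1"], 20, {("c1", 3, "T"): 20}, ref8, base_depth=1000)
        assert len(call_variants(acm2, ref8, min_depth=50)) == 1

    def test_multiallelic_site_yields_one_call_per_alt(self, ref8):
        acm = matrix(
            ["c1"], 20, {("c1", 3, "T"): 30, ("c1", 3, "A"): 30}, ref8, base_depth=100
        )
        calls = call_variants(acm, ref8, min_depth=50)
        assert [(c.pos, c.alt_allele) for c in calls] == [(3, "A"), (3, "T")]

    def test_position_beyond_reference_rejected(self, ref8):
        counts = np.zeros((1, 25, 6), dtype=np.int64)
        acm = AlleleCountMatrix(["c1"], np.arange(1, 26), counts)
        with pytest.raises(ValueError, match="beyond reference"):
            call_variants(acm, ref8)


class TestMergeShiftedCalls:
    def test_empty_shifted_set_is_identity(self, ref8):
        acm = matrix(["c1"], 20, {("c1", 10, "G"): 50}, ref8, base_depth=100)
        calls = call_variants(acm, ref8, min_depth=50)
        merged = merge_shifted_calls(calls, [], s=10, L=20, junction_halfwidth=3)
        assert [(c.key, c.af) for c in merged] == [(c.key, c.af) for c in calls]

    def test_duplicate_collapses_to_merged_source(self, ref8):
        acm = matrix(["c1"], 20, {("c1", 10, "G"): 50}, ref8, base_depth=100)
        (un,) = call_variants(acm, ref8, min_depth=50)
        # the same call observed by the shifted pass: original position 10
        # sits at shifted position 20 under s=10, L=20
        sh = VariantCall(
            pos=20, ref_allele=un.ref_allele, alt_allele="G",
            af=dict(un.af), depth=dict(un.depth), source="shifted",
        )
        merged = merge_shifted_calls([un], [sh], s=10, L=20, junction_halfwidth=3)
        assert len(merged) == 1
        assert merged[0].source == "merged"
        assert merged[0].pos == 10

    def test_conflicting_reference_alleles_rejected(self, ref8):
        un = [VariantCall(pos=10, ref_allele="T", alt_allele="C", af={"c": 0.5}, depth={"c": 100})]
        sh = [VariantCall(pos=20, ref_allele="G", alt_allele="C", af={"c": 0.5}, depth={"c": 100})]
        with pytest.raises(ValueError, match="conflicting reference"):
            merge_shifted_calls(un, sh, s=10, L=20, junction_halfwidth=3)

    def test_origin_variant_recovered_via_shifted_pass(self):
        # a variant 2 bp from the origin, lost by the linear unshifted view
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), size=200))
        ref = CircularReference("m", seq)
        alt = {"A": "G", "G": "A", "C": "T", "T": "C"}[ref.base(2)]
        acm = matrix(["c1", "c2"], 200, {("c1", 2, alt): 40}, ref, base_depth=100)
        s = 100
        un_view, sh_view = linearized_views(acm, ref, s, dropout_halfwidth=20)
        un = call_variants(un_view, ref, min_depth=50)
        sh = call_variants(sh_view, rotate_reference(ref, s), min_depth=50)
        assert all(c.pos != 2 for c in un)  # invisible to the linear pass
        merged = merge_shifted_calls(un, sh, s, 200, junction_halfwidth=50)
        direct = call_variants(acm, ref, min_depth=50)
        assert {c.key for c in merged} == {c.key for c in direct}
        for m, d in zip(merged, direct):
            assert m.af == d.af and m.depth == d.depth

    def test_merge_is_idempotent(self, ref8):
        acm = matrix(["c1"], 20, {("c1", 10, "G"): 50}, ref8, base_depth=100)
        un = call_variants(acm, ref8, min_depth=50)
        merged = merge_shifted_calls(un, [], s=10, L=20, junction_halfwidth=3)
        again = merge_shifted_calls(merged, [], s=10, L=20, junction_halfwidth=3)
        assert [(c.key, c.af) for c in again] == [(c.key, c.af) for c in merged]


class TestPseudobulk:
    def test_pooled_af_is_count_weighted(self, ref8):
        acm = matrix(
            ["c1", "c2"], 20,
            {("c1", 3, "T"): 10, ("c2", 3, "T"): 30},
            ref8, base_depth=100,
        )
        pb = pseudobulk(acm, ref=ref8)
        assert pb[(3, "T")] == pytest.approx(40 / 200)

    def test_single_cell_subset_equals_cell_af(self, ref8):
        acm = matrix(
            ["c1", "c2"], 20, {("c1", 3, "T"): 10, ("c2", 3, "T"): 90}, ref8,
            base_depth=100,
        )
        pb = pseudobulk(acm, cells=["c2"], ref=ref8)
        assert pb[(3, "T")] == pytest.approx(0.9)

    def test_equal_depth_pseudobulk_is_mean_of_cell_afs(self, ref8):
        acm = matrix(
            ["c1", "c2"], 20, {("c1", 3, "T"): 20, ("c2", 3, "T"): 60}, ref8,
            base_depth=100,
        )
        pb = pseudobulk(acm, ref=ref8)
        assert pb[(3, "T")] == pytest.approx((0.2 + 0.6) / 2)

    def test_zero_depth_sites_undefined(self, ref8):
        acm = matrix(["c1"], 20, {("c1", 3, "T"): 10}, ref8, base_depth=0)
        acm.counts[0, 2, ALLELE_INDEX["T"]] = 10
        pb = pseudobulk(acm, ref=ref8)
        assert (5, "A") not in pb  # untouched site has zero pooled depth

    def test_empty_subset_rejected(self, ref8):
        acm = matrix(["c1"], 20, {}, ref8, base_depth=10)
        with pytest.raises(ValueError):
            pseudobulk(acm, cells=[])


class TestModalityCompare:
    def test_classes(self):
        dna = {(10, "T"): 0.10, (20, "G"): 0.10, (30, "C"): 0.02}
        rna = {(20, "G"): 0.10, (30, "C"): 0.30, (40, "A"): 0.01}
        table = modality_compare(dna, rna).set_index(["pos", "alt"])
        assert table.loc[(10, "T"), "class"] == "DNA_specific"
        assert table.loc[(20, "G"), "class"] == "joint"
        assert table.loc[(30, "C"), "class"] == "RNA_specific"
        assert table.loc[(40, "A"), "class"] == "absent"

    def test_untranscribed_site_is_dna_specific(self):
        dna = {(10, "T"): 0.10}
        rna = {(10, "T"): 0.50}  # spurious signal at an untranscribed site
        table = modality_compare(dna, rna, transcribed={20, 21})
        assert table.loc[0, "class"] == "DNA_specific"

    def test_sub_floor_dna_af_not_dna_specific(self):
        # the printed rule: DNA sites with mean RNA AF below 0.04 are
        # DNA-specific; symmetric sub-floor sites on both arms are absent
        table = modality_compare({(5, "T"): 0.03}, {(5, "T"): 0.02})
        assert table.loc[0, "class"] == "absent"


class TestPileupAndVcf:
    def test_pileup_wraps_around_origin(self):
        ref = CircularReference("m", "ACGTACGTAC")  # L=10
        counts = pileup_reads([("c1", 9, "ACAC")], L=10)  # covers 9,10,1,2
        arr = counts["c1"]
        assert arr[8, ALLELE_INDEX["A"]] == 1
        assert arr[9, ALLELE_INDEX["C"]] == 1
        assert arr[0, ALLELE_INDEX["A"]] == 1
        assert arr[1, ALLELE_INDEX["C"]] == 1

    def test_masked_bases_feed_no_counts(self):
        raw = "ACGTAAAAAGCT"
        masked = mask_polyA(raw)
        counts = pileup_reads([("c1", 1, masked)], L=20)["c1"]
        assert counts[4:9].sum() == 0  # the masked run
        assert counts[:4].sum() == 4

    def test_vcf_round_trip_af_dp(self, tmp_path, ref8):
        cyvcf2 = pytest.importorskip("cyvcf2")
        acm = matrix(
            ["c1", "c2"], 20, {("c1", 3, "T"): 60, ("c2", 3, "T"): 10}, ref8,
            base_depth=100,
        )
        calls = call_variants(acm, ref8, min_depth=50)
        path = tmp_path / "calls.vcf"
        write_vcf(calls, ["c1", "c2"], ref8, path)
        (rec,) = list(cyvcf2.VCF(str(path)))
        assert rec.POS == 3 and rec.REF == "G" and rec.ALT == ["T"]
        assert rec.format("AF")[:, 0] == pytest.approx([0.6, 0.1])
        assert list(rec.format("DP")[:, 0]) == [100, 100]
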