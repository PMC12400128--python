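"""Heteroplasmy window, effect annotation and curated mutation lists."""

import numpy as np
import pytest

from mitohet.calling import VariantCall
from mitohet.classify import (
    EffectAnnotation,
    annotate_effect,
    cds_sequence,
    classify_mutations,
    events_per_cell,
    heteroplasmic_cell_fraction,
    is_heteroplasmic,
    joint_impactful,
    most_impactful,
    most_variable,
    translate_cds,
)


def call(pos, afs, ref="A", alt="G", depth=1000):
    return VariantCall(
        pos=pos,
        ref_allele=ref,
        alt_allele=alt,
        af={f"c{i}": af for i, af in enumerate(afs)},
        depth={f"c{i}": depth for i in range(len(afs))},
    )


class TestHeteroplasmyWindow:
    @pytest.mark.parametrize(
        "af,expected",
        [
            (0.5, True),
            (0.04, True),  # floor inclusive
            (0.96, True),  # ceiling inclusive
            (0.039, False),
            (0.97, False),
            (0.0, False),
            (1.0, False),
        ],
    )
    def test_window(self, af, expected):
        assert is_heteroplasmic(af) is expected

    def test_out_of_range_af_rejected(self):
        with pytest.raises(ValueError):
            is_heteroplasmic(1.5)


class TestMostVariable:
    def test_five_percent_bound_is_inclusive(self):
        # heteroplasmic in 5 of 84 cells (5.95%) -> in; 4 of 84 -> out
        in_call = call(10, [0.5] * 5 + [0.0] * 79)
        out_call = call(20, [0.5] * 4 + [0.0] * 80)
        kept = most_variable([in_call, out_call])
        assert [c.pos for c in kept] == [10]

    def test_exactly_at_threshold_included(self):
        c = call(10, [0.5] * 5 + [0.0] * 95)  # exactly 5%
        assert most_variable([c]) == [c]

    def test_all_cells_heteroplasmic_included(self):
        c = call(10, [0.5] * 20)
        assert most_variable([c]) == [c]

    def test_denominator_is_defined_cells_only(self):
        # 3 heteroplasmic of 10 defined (30%), even if many cells exist
        c = call(10, [0.5, 0.5, 0.5] + [0.0] * 7)
        n, frac = heteroplasmic_cell_fraction(c)
        assert (n, frac) == (3, 0.3)

    def test_no_defined_cells_rejected(self):
        with pytest.raises(ValueError):
            most_variable([call(10, [])])


class TestAnnotateEffect:
    def _call(self, ref, pos, alt):
        return VariantCall(pos=pos, ref_allele=ref.base(pos), alt_allele=alt)

    def test_stop_gained(self, toy_ref):
        # plant CAA (Gln) at codon 11 of the forward gene; C>T gives TAA
        seq = list(toy_ref.sequence)
        seq[130:133] = list("CAA")
        ref = toy_ref.__class__("t", "".join(seq), toy_ref.genes)
        eff = annotate_effect(self._call(ref, 131, "T"), ref)
        assert (eff.effect, eff.impact) == ("stop_gained", "HIGH")
        assert eff.codon_change == "CAA>TAA"
        assert eff.aa_change == "Q11*"

    def test_ata_is_methionine_missense(self, toy_ref):
        # ATT (Ile) -> ATA reads Met under the mitochondrial code: missense
        seq = list(toy_ref.sequence)
        seq[130:133] = list("ATT")
        ref = toy_ref.__class__("t", "".join(seq), toy_ref.genes)
        eff = annotate_effect(self._call(ref, 133, "A"), ref)
        assert (eff.effect, eff.impact) == ("missense", "MODERATE")
        assert eff.aa_change == "I11M"

    def test_synonymous(self, toy_ref):
        seq = list(toy_ref.sequence)
        seq[130:133] = list("CTA")  # Leu; CTA>CTG stays Leu
        ref = toy_ref.__class__("t", "".join(seq), toy_ref.genes)
        eff = annotate_effect(self._call(ref, 133, "G"), ref)
        assert (eff.effect, eff.impact) == ("synonymous", "LOW")

    def test_dloop_is_noncoding_modifier(self, toy_ref):
        eff = annotate_effect(self._call(toy_ref, 50, "G" if toy_ref.base(50) != "G" else "C"), toy_ref)
        assert (eff.effect, eff.impact) == ("noncoding", "MODIFIER")
        assert eff.gene == "D-loop"

    def test_trna_is_modifier(self, toy_ref):
        alt = "G" if toy_ref.base(430) != "G" else "C"
        eff = annotate_effect(self._call(toy_ref, 430, alt), toy_ref)
        assert eff.impact == "MODIFIER"
        assert eff.gene == "TOYT"

    def test_intergenic_is_modifier(self, toy_ref):
        alt = "G" if toy_ref.base(780) != "G" else "C"
        eff = annotate_effect(self._call(toy_ref, 780, alt), toy_ref)
        assert (eff.gene, eff.impact) == (None, "MODIFIER")

    def test_coding_deletion_is_frameshift(self, toy_ref):
        vc = VariantCall(pos=200, ref_allele=toy_ref.base(200), alt_allele="DEL")
        eff = annotate_effect(vc, toy_ref)
        assert (eff.effect, eff.impact) == ("frameshift", "HIGH")

    def test_noncoding_deletion_is_modifier(self, toy_ref):
        vc = VariantCall(pos=50, ref_allele=toy_ref.base(50), alt_allele="DEL")
        assert annotate_effect(vc, toy_ref).impact == "MODIFIER"

    def test_mismatched_reference_allele_rejected(self, toy_ref):
        base = toy_ref.base(200)
        wrong = "A" if base != "A" else "C"
        with pytest.raises(ValueError, match="declares ref"):
            annotate_effect(VariantCall(pos=200, ref_allele=wrong, alt_allele="G"), toy_ref)

    @pytest.mark.parametrize("gene,start,end,strand", [("TOYF", 101, 400, "+"), ("TOYR", 451, 750, "-")])
    def test_agrees_with_full_cds_retranslation(self, toy_ref, gene, start, end, strand):
        """Codon-level verdicts equal a whole-CDS mutate-and-retranslate oracle."""
        comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
        cds = cds_sequence(gene, toy_ref)
        protein = translate_cds(cds)
        for pos in range(start, end + 1):
            ref_base = toy_ref.base(pos)
            for alt in "ACGT":
                if alt == ref_base:
                    continue
                # independent oracle arithmetic
                idx = pos - start if strand == "+" else end - pos
                mut_base = alt if strand == "+" else comp[alt]
                mutated = cds[:idx] + mut_base + cds[idx + 1 :]
                mut_protein = translate_cds(mutated)
                diffs = [
                    (a, b) for a, b in zip(protein, mut_protein) if a != b
                ]
                if not diffs:
                    expected = "synonymous"
                elif diffs[0][1] == "*":
                    expected = "stop_gained"
                else:
                    expected = "missense"
                eff = annotate_effect(
                    VariantCall(pos=pos, ref_allele=ref_base, alt_allele=alt), toy_ref
                )
                assert eff.effect == expected, (gene, pos, alt)


class TestMostImpactful:
    def effects(self, mapping):
        table = {
            "missense": "MODERATE",
            "stop_gained": "HIGH",
            "synonymous": "LOW",
            "noncoding": "MODIFIER",
        }
        return {
            key: EffectAnnotation(gene="g", effect=e, impact=table[e])
            for key, e in mapping.items()
        }

    def test_af_and_impact_jointly_required(self):
        calls = [
            call(10, [0.31], ref="A", alt="G"),  # in: above threshold + missense
            call(20, [0.29], ref="A", alt="G"),  # out: below threshold
            call(30, [0.50], ref="A", alt="G"),  # out: synonymous
            call(40, [0.30], ref="A", alt="G"),  # out: threshold is strict
        ]
        effects = self.effects(
            {
                calls[0].key: "missense",
                calls[1].key: "stop_gained",
                calls[2].key: "synonymous",
                calls[3].key: "stop_gained",
            }
        )
        kept = most_impactful(calls, effects)
        assert [c.pos for c in kept] == [10]

    def test_subset_of_high_moderate(self):
        calls = [call(p, [0.9]) for p in (1, 2, 3)]
        effects = self.effects(
            {calls[0].key: "noncoding", calls[1].key: "missense", calls[2].key: "stop_gained"}
        )
        kept = most_impactful(calls, effects)
        assert all(effects[c.key].impact in ("HIGH", "MODERATE") for c in kept)
        assert [c.pos for c in kept] == [2, 3]


class TestJointImpactful:
    def test_requires_rna_heteroplasmy(self):
        dna = [call(10, [0.5]), call(20, [0.5]), call(30, [0.5])]
        rna = [
            call(10, [0.2, 0.2, 0.2]),  # heteroplasmic in RNA -> joint
            call(20, [0.01, 0.02]),  # sub-floor in every RNA cell -> out
            # pos 30 untranscribed: no RNA call at all -> out
        ]
        kept = joint_impactful(dna, rna)
        assert [c.pos for c in kept] == [10]

    def test_joint_is_subset_of_most_impactful(self, default_cohort):
        from mitohet.calling import call_variants

        cohort = default_cohort
        dna_calls = call_variants(cohort.dna_counts, cohort.ref)
        classified = classify_mutations(
            dna_calls,
            cohort.ref,
            rna_calls=call_variants(cohort.rna.counts, cohort.ref, min_depth=50,
                                    emission_floor=0.04),
        )
        mi = {c.call.key for c in classified if c.in_most_impactful}
        ji = {c.call.key for c in classified if c.in_joint_impactful}
        assert ji <= mi
        assert ji  # transcribed impactful variants do appear in RNA


class TestEventsPerCell:
    def test_counts_only_window_afs(self):
        calls = [
            call(10, [0.5]),
            call(20, [0.03]),
            call(30, [0.97]),
        ]
        assert events_per_cell(calls, "c0") == 1

    def test_no_calls_zero_with_known_universe(self):
        assert events_per_cell([], "cellX", known_cells=["cellX"]) == 0

    def test_unknown_cell_rejected(self):
        with pytest.raises(KeyError):
            events_per_cell([call(10, [0.5])], "nope")

    def test_all_sites_heteroplasmic(self):
        calls = [call(p, [0.5]) for p in range(7)]
        assert events_per_cell(calls, "c0") == 7


class TestLinkedVariants:
    def test_linked_trio_afs_track_each_other(self, default_cohort):
        """Variants on one haplotype share per-cell AFs up to sampling noise."""
        from mitohet.calling import call_variants

        cohort = default_cohort
        calls = {c.pos: c for c in call_variants(cohort.dna_counts, cohort.ref)}
        trio = [calls[4542], calls[14262], calls[2000]]
        cells = sorted(set(trio[0].af) & set(trio[1].af) & set(trio[2].af))
        mat = np.array([[c.af[cell] for cell in cells] for c in trio])
        for i in range(3):
            for j in range(i + 1, 3):
                assert np.corrcoef(mat[i], mat[j])[0, 1] > 0.95
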