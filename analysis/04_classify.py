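"""Heteroplasmy classification and effect annotation.

Builds the curated mutation lists from the merged DNA calls: "most
variable" (heteroplasmic in >= 5% of cells), "most impactful" (> 30% AF
in >= 1 cell and HIGH/MODERATE predicted impact under the vertebrate
mitochondrial code) and the DNA-RNA "joint most impactful" intersection.
Writes the classification table under results/classify/.
"""

import importlib
import os
import sys

from mitohet.classify import classify_mutations
from mitohet.report import classification_table
from mitohet.simulate import default_scenario, simulate_cohort

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = "results/classify"


def main() -> None:
    sys.path.insert(0, os.path.dirname(os.path.abspath(__file__)))
    step3 = importlib.import_module("03_call")

    cfg, ref = default_scenario(SEED)
    cohort = simulate_cohort(cfg, ref)
    os.makedirs(OUT, exist_ok=True)

    from mitohet.calling import call_variants, merge_shifted_calls
    from mitohet.reference import rotate_reference
    from mitohet.simulate import linearized_views

    dna = cohort.dna_counts.subset_cells(step3.passing_dna_cells(cohort))
    s = ref.length // 2
    un_view, sh_view = linearized_views(dna, ref, s, dropout_halfwidth=300)
    merged = merge_shifted_calls(
        call_variants(un_view, ref, min_depth=100),
        call_variants(sh_view, rotate_reference(ref, s), min_depth=100),
        s, ref.length,
    )
    rna = cohort.rna.counts.subset_cells(step3.passing_rna_cells(cohort))
    rna_calls = call_variants(rna, ref, min_depth=50, emission_floor=0.04)

    classified = classify_mutations(merged, ref, rna_calls=rna_calls)
    table = classification_table(classified)
    table.to_csv(os.path.join(OUT, "classification.tsv"), sep="\t", index=False)

    mv = table[table.most_variable]
    mi = table[table.most_impactful]
    ji = table[table.joint_impactful]
    print(f"{len(table)} merged DNA mutations classified")
    print(f"most variable ({len(mv)}): "
          + ", ".join(f"{r.pos} {r.ref}>{r.alt}" for r in mv.itertuples()))
    print(f"most impactful ({len(mi)}): "
          + ", ".join(f"{r.pos} {r.ref}>{r.alt} [{r.effect}]" for r in mi.itertuples()))
    print(f"joint most impactful ({len(ji)} of {len(mi)} transcribed & RNA-heteroplasmic)")
    print(f"table -> {OUT}/classification.tsv")


if __name__ == "__main__":
    main()
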