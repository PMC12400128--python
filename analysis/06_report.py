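"""Render the run report: tables, violin/heatmap/scatter figures, manifest.

Collects the outputs of the upstream steps (re-derived from the seed) and
writes the full report under results/report/.
"""

import dataclasses
import importlib
import os
import sys

import pandas as pd

from mitohet.calling import call_variants, merge_shifted_calls, modality_compare, pseudobulk
from mitohet.classify import classify_mutations, events_per_cell
from mitohet.compare import compare_conditions, comparison_table
from mitohet.qc import fragment_depth_qc, qc_table
from mitohet.reference import rotate_reference, transcribed_positions
from mitohet.report import af_matrix, classification_table, render_report
from mitohet.simulate import default_scenario, linearized_views, simulate_cohort

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = "results/report"


def main() -> None:
    sys.path.insert(0, os.path.dirname(os.path.abspath(__file__)))
    step3 = importlib.import_module("03_call")

    cfg, ref = default_scenario(SEED)
    cohort = simulate_cohort(cfg, ref)

    depth = cohort.dna_counts.depth()
    dna_recs = [
        fragment_depth_qc(c, depth[i])
        for i, c in enumerate(cohort.dna_counts.cells)
    ]
    dna = cohort.dna_counts.subset_cells([r.cell_id for r in dna_recs if r.passed])
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

    labels = cohort.conditions("dna")
    variable = [c.call for c in classified if c.in_most_variable]
    impactful = [c.call for c in classified if c.in_most_impactful]
    events = pd.DataFrame(
        {
            "cell_id": dna.cells,
            "condition": [labels[c] for c in dna.cells],
            "events": [events_per_cell(merged, c) for c in dna.cells],
        }
    )
    dna_pb = {k: v for k, v in pseudobulk(dna, ref=ref).items() if v >= 0.01}
    rna_pb = {k: v for k, v in pseudobulk(rna, ref=ref).items() if v >= 0.01}
    modality = modality_compare(dna_pb, rna_pb,
                                transcribed=transcribed_positions(ref.genes))

    written = render_report(
        OUT,
        qc=qc_table(dna_recs),
        classified=classification_table(classified),
        comparisons=comparison_table(compare_conditions(merged, labels)),
        modality=modality,
        variable_af=af_matrix(variable, dna.cells),
        impactful_af=af_matrix(impactful, dna.cells),
        events=events,
        manifest={"seed": SEED, "config": dataclasses.asdict(cfg),
                  "reference": ref.name, "length": ref.length},
    )
    print(f"report written ({len(written)} files):")
    for path in written:
        print("  " + path)


if __name__ == "__main__":
    main()
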