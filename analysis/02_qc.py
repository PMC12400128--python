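"""Cell-level quality control for both arms.

DNA arm: two-fragment depth QC (windows 2000-7000 and 10000-15000, mean
depth >= 1000 in both) with the absolute fragment differential; RNA arm:
mito fraction < 17%, 2100 < features < 4000, mean mito depth >= 50.
Writes per-cell QC tables under results/qc/.
"""

import os
import sys

from mitohet.qc import (
    absolute_fragment_differential,
    fragment_depth_qc,
    qc_table,
    rna_cell_qc,
)
from mitohet.simulate import default_scenario, simulate_cohort

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = "results/qc"


def main() -> None:
    cfg, ref = default_scenario(SEED)
    cohort = simulate_cohort(cfg, ref)
    os.makedirs(OUT, exist_ok=True)

    depth = cohort.dna_counts.depth()
    dna_recs = [
        fragment_depth_qc(c, depth[i])
        for i, c in enumerate(cohort.dna_counts.cells)
    ]
    qc_table(dna_recs).to_csv(os.path.join(OUT, "dna_qc.tsv"), sep="\t", index=False)
    mean_diff, sd_diff = absolute_fragment_differential(dna_recs)
    n_pass = sum(r.passed for r in dna_recs)
    n_warn = sum("fragment_imbalance" in r.warnings for r in dna_recs)
    print(f"DNA arm: {n_pass}/{len(dna_recs)} cells pass fragment QC "
          f"({n_warn} imbalance warnings, kept)")
    print(f"  |fragment depth differential|: mean {mean_diff:.0f}, sd {sd_diff:.0f} reads")

    rdepth = cohort.rna.counts.depth()
    rna_recs = [
        rna_cell_qc(c, cohort.rna.gene_counts.loc[c], rdepth[i])
        for i, c in enumerate(cohort.rna.counts.cells)
    ]
    qc_table(rna_recs).to_csv(os.path.join(OUT, "rna_qc.tsv"), sep="\t", index=False)
    n_pass = sum(r.passed for r in rna_recs)
    reasons = [reason for r in rna_recs for reason in r.fail_reasons]
    print(f"RNA arm: {n_pass}/{len(rna_recs)} cells pass "
          f"(fail reasons: {', '.join(sorted(set(reasons)))})")
    print(f"tables -> {OUT}/")


if __name__ == "__main__":
    main()
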