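"""Generate the synthetic single-cell heteroplasmy cohort.

Simulates the packaged study conditions -- 88 DNA-arm cells (44 induced /
44 noninduced, 4 with degraded fragment-X coverage) and 300 RNA-arm cells
-- by drifting a 12-variant founder panel through 30 Wright-Fisher
divisions of 500 mtDNA copies, then sequencing both arms.  Writes the
ground truth (VCF + manifest) under results/simulation/; the full count
fixture goes to scratch/fixture/ because of its size.
"""

import os
import sys

from mitohet.simulate import default_scenario, simulate_cohort, write_fixture

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = "results/simulation"


def main() -> None:
    cfg, ref = default_scenario(SEED)
    cohort = simulate_cohort(cfg, ref)
    write_fixture(cohort, "scratch/fixture")

    os.makedirs(OUT, exist_ok=True)
    for name in ("truth.vcf", "manifest.json", "reference.fasta", "genes.tsv"):
        src = os.path.join("scratch/fixture", name)
        with open(src) as fh, open(os.path.join(OUT, name), "w") as out:
            out.write(fh.read())

    n_variants = len({p for c in cohort.dna_truth for p in c.true_af})
    print(f"seed {SEED}: reference {ref.name} ({ref.length} bp, {len(ref.genes)} features)")
    print(f"DNA arm: {len(cohort.dna_truth)} cells, {n_variants} true variant sites")
    print(f"  degraded fragment-X cells: {', '.join(cohort.low_depth_cells)}")
    print(f"RNA arm: {len(cohort.rna_truth)} cells, "
          f"{len(cfg.rna.rna_specific_variants)} RNA-specific variants injected")
    print(f"truth + manifest -> {OUT}/; full count fixture -> scratch/fixture/")


if __name__ == "__main__":
    main()
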