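# Methods

## The measurement model

Every quantity in the package reduces to the per-cell allele frequency
AF(cell, site) = alt reads / depth, computed only where depth clears an
arm-specific floor: 100 reads for the deep LRPCR DNA arm (coverage there
is routinely in the thousands), 50 for the shallow RNA arm (sites are
kept only above 49 reads). Below the floor the AF is *undefined*, not
zero — downstream denominators (e.g. the ≥ 5 %-of-cells rule) count only
cells with a defined AF, so a low-depth site is not penalised twice.
Sites are emitted from calling once any cell reaches an emission floor of
0.01, deliberately below the 0.04 heteroplasmy floor so that
sub-threshold AFs remain available for the bulk-vs-single-cell
comparison, where any AF < 0.04 in a cell is counted as 0. On shallow
RNA data an emission floor of 0.01 admits single-error-read sites; the
analysis drivers therefore call the RNA arm with the floor raised to
0.04 (the heteroplasmy floor itself), which at ≥ 50× depth requires ≥ 2–4
concordant reads.

## Circular calling

Linear mappers starve the region around the arbitrary origin (the
D-loop) of coverage. Calling is run twice — against the reference as
published and against a copy rotated by s (default ⌊L/2⌋, the choice
that puts the junction as far as possible from the origin; the rotation
actually used by any particular upstream pipeline is rarely reported, so
it is configurable) — and merged back into original coordinates through
the exact bijection p ↦ ((p−1+s) mod L)+1. Within a junction half-width
(default 1000 bp) of the origin the rotated-derived call wins; elsewhere
the unshifted call wins; sites seen by both collapse to one record.
Conflicting reference alleles at a merged position are treated as a
coordinate bug and raised, never reconciled. The simulator's
`linearized_views` produces the two degraded views a linear mapper would
yield from the same circularly complete counts, which is what makes the
merge testable against direct computation: the merged per-cell AFs must
equal the raw-count arithmetic exactly, in integer arithmetic, with no
tolerance.

## Effect annotation

The annotator classifies SNVs by translating the affected codon before
and after substitution under the vertebrate mitochondrial genetic code
(translation table 2: TGA = Trp, AGA/AGG = stop, ATA = Met), honouring
strand by complementing through the CDS layout; origin-spanning genes are
stored as ordered sub-intervals so the codon arithmetic stays linear.
Single-base DEL/INS alleles in coding sequence are frameshifts. The
verdict taxonomy is deliberately the three printed consequence classes
plus noncoding: stop-gained/frameshift → HIGH, missense → MODERATE,
synonymous → LOW, everything non-protein-coding → MODIFIER. Two
collapses are worth flagging: start/stop-loss sub-cases are folded into
missense/stop-gained, and tRNA/rRNA variants are MODIFIER even though
dedicated annotators would often rank structural-RNA hits higher — a
known divergence risk when comparing against snpEff-style output. The
test oracle mutates and retranslates the whole CDS and diffs the
proteins, sharing no code path with the codon-level annotator.

## The drift simulator

The generator's purpose is a ground truth for intercellular
heteroplasmy, which in a clonal population arises from the mitochondrial
genetic bottleneck: each division transmits a finite sample of mtDNA
copies. The model is Wright–Fisher: a cell carries N copies with
copy-level genotypes (variants sharing a haplotype id co-segregate); a
daughter's N copies are a multinomial resample of the parent's. This
gives the two closed forms the tests pin down — E[AF_t] = p₀ (a
martingale) and one-generation Var(AF) = p₀(1−p₀)/N — and monotone
variance growth over generations. An exact duplicate-to-2N-then-partition
scheme was considered and rejected: its one-generation variance is
p₀(1−p₀)/(2N−1), roughly half binomial, and the binomial form is both
the standard bottleneck formulation and the one the package's
quantitative checks are built on. De novo mutations arise per copy per
generation (rate μ) at uniformly random unused positions; their alt
allele is resolved deterministically as the transition partner of the
reference base, mirroring the strong transition bias of mtDNA mutation
spectra and keeping the DNA and RNA arms consistent without shared
generator state. Only branches ancestral to the n sampled leaves of the
depth-g binary tree are simulated, so g = 30 costs n·g divisions, not
2³⁰.

Copy number and generation count for CHO cells are not measured
quantities; N = 500 and g = 30 are declared defaults, chosen to give
visible but not saturating between-cell variance (drift SD ≈ 0.09 for a
mid-frequency variant), and stated as arbitrary.

## Sequencing arms

Depth is negative-binomial (size parameter `depth_dispersion`, default
10; ∞ means exact depth) around a per-position mean. The DNA arm
multiplies the mean by a per-cell lognormal amplification bias b for
positions in fragment X and 1/b elsewhere (σ = 0.35 on the log scale),
reproducing the occasional cell with > 80 % of reads in one fragment; the
default mean depth of 5000× keeps natural bias excursions comfortably
above the 1000× QC floor, so the exactly-4 engineered low-X cells (bias
additionally ×0.02) are the only QC failures. Read categories at a site
are an exact multinomial (sequential-binomial chain) over the six
alleles: mutant copies report the alt with probability 1−e, wild-type
copies the reference, miscalls scatter e/3 to each other base; indel
alleles are never miscalled. Counts therefore sum to depth identically.

The RNA arm restricts the pileup to transcribed intervals at ~80× mean
depth, injects configured RNA-specific variants at fixed AF (stand-ins
for RNA editing), and builds a cell-by-gene matrix with controlled
feature counts (Normal(3000, 350)) and mitochondrial fractions
(Beta(4, 46), mean ≈ 0.08); QC violators are engineered into the leading
cells deterministically. Raw read records carry polyA contamination
(terminal runs of 5–24 A's at rate 0.15) for the masker to remove;
masking replaces runs with N (coordinate-preserving) rather than
clipping, so masked bases simply feed no pileup. The default RNA cohort
is 300 cells — a down-scaled stand-in for the thousands a droplet/nanowell
run yields, sized so every QC and classification structure is exercised
at interactive runtime.

What the generator does *not* emulate: read-level FASTQ with qualities,
alignment artefacts other than the junction dropout, Numts
contamination, doublets/ambient RNA, UMI structure, or PCR duplicate
families. Passing tests therefore demonstrate the *logic* of the
pipeline (thresholds, coordinate arithmetic, estimators, test
calibration) on data whose noise is idealised binomial/NB; they do not
certify performance against mapper-specific artefacts on real reads.

## Statistical choices

Student's pooled-variance t-test is used for condition comparisons, as
is conventional for this assay's reporting (a Welch switch is exposed);
a mutation is tested only with ≥ 2 defined-AF cells per condition, and no
across-mutation correction is applied there (the non-significance claim
is on nominal p). The quartile differential-expression scan splits cells
at the 25th/75th AF percentiles with boundary ties assigned to the
extreme groups (deterministic, maximises n; identical AFs make the split
degenerate and the scan is skipped with a logged reason), compares each
gene by two-sided Mann–Whitney U, and adjusts by Benjamini–Hochberg
across genes within the mutation. Pearson correlations report n
alongside r so that the above-0.6-AF repeat, which often leaves n < 3,
returns an explicit `low_n` verdict instead of an unstable coefficient.
All printed thresholds are taken literally: < 1000, < 50, < 17 % and the
feature bounds are strict; the 0.04/0.96 window is inclusive; "above
30 %" is strict; "at least 5 %" is inclusive. The bulk time-course
"stable" flag (range ≤ 0.10) is a reporting convenience of this package,
not a community standard.

## Problem sizes and determinism

The packaged study conditions are 88 DNA cells / 300 RNA cells on a
16,283 bp synthetic genome; oracle checks use 20 random genomes of
2–16 kb (6 cells each), 10,000 one-generation drift replicates, 200
cells at 1000× for AF recovery, 1000 null replicates for t-test
calibration and 20 seeds for the DE null. A single integer seed drives
every stage through one `numpy.random.Generator`; the same seed
reproduces fixtures byte-for-byte, and `scripts/acceptance.py` derives
all sub-seeds from its `--seed` argument.

## Known limitations

The annotator's MODIFIER treatment of tRNA/rRNA variants understates
their plausible pathogenicity. Indels are modelled and annotated only as
single-base events at their left-aligned position. The modality
comparison assumes the transcribed-interval annotation is correct;
mis-annotated intervals would misclassify DNA-specific sites. The
condition comparison pools all defined-AF cells per mutation rather than
pairing subsets. Real upstream steps — alignment, duplicate handling,
Numts suppression — are out of scope: the package consumes pileups or
simulates counts directly.
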