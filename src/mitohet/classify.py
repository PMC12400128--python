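"""Heteroplasmy classification and mitochondrial variant-effect annotation.

A variant is *heteroplasmic* in a cell when its allele frequency lies in
the 0.04-0.96 window (inclusive); outside that window it is operationally
homoplasmic (absent or fixed).  Two curated lists drive downstream
comparisons:

* **most variable** -- heteroplasmic in at least 5% of cells with a
  defined AF at the site;
* **most impactful** -- present above 30% AF in at least one cell (strict)
  AND predicted HIGH or MODERATE impact, i.e. stop-gained, frameshift or
  missense under the vertebrate mitochondrial genetic code (translation
  table 2: TGA=Trp, AGA/AGG=stop, ATA=Met).

The *joint* list intersects the DNA most-impactful list with sites that
are heteroplasmic in at least one RNA-arm cell.  Effect annotation is a
built-in reimplementation of the snpEff verdict restricted to the three
printed consequence classes; tRNA/rRNA variants are MODIFIER, since the
HIGH/MODERATE set covers protein-coding consequences only.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Data import CodonTable
from Bio.Seq import Seq

from .calling import VariantCall
from .reference import CircularReference, GeneAnnotation

HET_FLOOR = 0.04
HET_CEILING = 0.96
MIN_CELL_FRACTION = 0.05
IMPACT_AF_THRESHOLD = 0.30

MITO_TABLE = CodonTable.unambiguous_dna_by_id[2]  # vertebrate mitochondrial

_IMPACT_OF_EFFECT = {
    "stop_gained": "HIGH",
    "frameshift": "HIGH",
    "missense": "MODERATE",
    "synonymous": "LOW",
    "noncoding": "MODIFIER",
}

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class EffectAnnotation:
    gene: str | None
    effect: str  # stop_gained / frameshift / missense / synonymous / noncoding
    impact: str  # HIGH / MODERATE / LOW / MODIFIER
    codon_change: str = ""
    aa_change: str = ""

    def __post_init__(self) -> None:
        if _IMPACT_OF_EFFECT[self.effect] != self.impact:
            raise ValueError(f"effect {self.effect} cannot carry impact {self.impact}")


def is_heteroplasmic(
    af: float, floor: float = HET_FLOOR, ceiling: float = HET_CEILING
) -> bool:
    """True iff floor <= af <= ceiling (both inclusive)."""
    if not 0.0 <= af <= 1.0:
        raise ValueError(f"allele frequency {af} outside [0, 1]")
    return floor <= af <= ceiling


def translate_codon(codon: str) -> str:
    """One-letter amino acid under the vertebrate mitochondrial code ('*' = stop)."""
    if codon in MITO_TABLE.stop_codons:
        return "*"
    return MITO_TABLE.forward_table[codon]


def _cds_layout(gene_name: str, genes) -> tuple[list[int], str]:
    """Ordered genomic positions of a protein-coding gene's CDS, plus strand.

    Sub-intervals sharing the gene name are concatenated in listed order
    (transcript order for origin-spanning genes).  The returned positions
    are in *CDS order* for the + strand; for the - strand the CDS reads the
    reverse complement, handled by the caller.
    """
    parts = [g for g in genes if g.gene == gene_name]
    strand = parts[0].strand
    positions: list[int] = []
    for part in parts:
        positions.extend(range(part.start, part.end + 1))
    if len(positions) % 3 != 0:
        raise ValueError(
            f"protein-coding gene {gene_name} has CDS length {len(positions)}, "
            "not a multiple of 3"
        )
    return positions, strand


def cds_sequence(gene_name: str, ref: CircularReference, genes=None) -> str:
    """The coding sequence of a gene, 5'->3' on its coding strand."""
    genes = ref.genes if genes is None else genes
    positions, strand = _cds_layout(gene_name, genes)
    forward = "".join(ref.base(p) for p in positions)
    if strand == "-":
        return "".join(_COMPLEMENT[b] for b in reversed(forward))
    return forward


def annotate_effect(
    call: VariantCall,
    ref: CircularReference,
    genes: tuple[GeneAnnotation, ...] | None = None,
) -> EffectAnnotation:
    """Predict the consequence of a single variant.

    SNVs inside a protein-coding gene are classified by translating the
    affected codon before and after substitution (strand-aware); single
    DEL/INS alleles shift the frame.  Positions in tRNA/rRNA/noncoding
    features, or in no feature at all, are noncoding/MODIFIER.
    """
    genes = ref.genes if genes is None else genes
    if ref.base(call.pos) != call.ref_allele and call.ref_allele in "ACGT":
        raise ValueError(
            f"call at {call.pos} declares ref {call.ref_allele} but reference "
            f"has {ref.base(call.pos)}"
        )
    hits = [g for g in genes if g.contains(call.pos)]
    coding = [g for g in hits if g.feature_type == "protein_coding"]
    if not coding:
        gene_name = hits[0].gene if hits else None
        return EffectAnnotation(gene=gene_name, effect="noncoding", impact="MODIFIER")
    gene = coding[0]

    if call.alt_allele in ("DEL", "INS"):
        # single-base indel in a coding region: frame shift
        return EffectAnnotation(gene=gene.gene, effect="frameshift", impact="HIGH")

    positions, strand = _cds_layout(gene.gene, genes)
    forward_offset = positions.index(call.pos)
    n = len(positions)
    if strand == "-":
        cds_index = n - 1 - forward_offset
        ref_base = _COMPLEMENT[call.ref_allele]
        alt_base = _COMPLEMENT[call.alt_allele]
    else:
        cds_index = forward_offset
        ref_base = call.ref_allele
        alt_base = call.alt_allele

    codon_start = cds_index - cds_index % 3
    codon = "".join(
        _strand_base(ref, positions, strand, n, codon_start + k)
        for k in range(3)
    )
    within = cds_index % 3
    assert codon[within] == ref_base
    mutated = codon[:within] + alt_base + codon[within + 1 :]
    aa_ref = translate_codon(codon)
    aa_alt = translate_codon(mutated)
    aa_pos = codon_start // 3 + 1
    if aa_alt == aa_ref:
        effect = "synonymous"
    elif aa_alt == "*":
        effect = "stop_gained"
    else:
        # includes stop-loss and start-loss, collapsed into missense
        effect = "missense"
    return EffectAnnotation(
        gene=gene.gene,
        effect=effect,
        impact=_IMPACT_OF_EFFECT[effect],
        codon_change=f"{codon}>{mutated}",
        aa_change=f"{aa_ref}{aa_pos}{aa_alt}",
    )


def _strand_base(ref, positions, strand, n, cds_index) -> str:
    if strand == "-":
        return _COMPLEMENT[ref.base(positions[n - 1 - cds_index])]
    return ref.base(positions[cds_index])


def translate_cds(cds: str) -> str:
    """Full-CDS translation under table 2 (used as the annotation oracle)."""
    return str(Seq(cds).translate(table=2))


# ---------------------------------------------------------------------------
# list construction
# ---------------------------------------------------------------------------


def heteroplasmic_cell_fraction(
    call: VariantCall, floor: float = HET_FLOOR, ceiling: float = HET_CEILING
) -> tuple[int, float]:
    """(n cells heteroplasmic, fraction over cells with a defined AF)."""
    defined = call.n_defined()
    if defined == 0:
        return 0, 0.0
    n_het = sum(1 for af in call.af.values() if is_heteroplasmic(af, floor, ceiling))
    return n_het, n_het / defined


def most_variable(
    calls: list[VariantCall],
    min_cell_fraction: float = MIN_CELL_FRACTION,
    floor: float = HET_FLOOR,
    ceiling: float = HET_CEILING,
) -> list[VariantCall]:
    """Calls heteroplasmic in at least ``min_cell_fraction`` of defined cells.

    The denominator is the number of cells with a defined AF at the site,
    so low-depth sites are not penalised twice.
    """
    out = []
    for call in calls:
        if call.n_defined() == 0:
            raise ValueError(f"no cells with defined AF for {call.label}")
        _, frac = heteroplasmic_cell_fraction(call, floor, ceiling)
        if frac >= min_cell_fraction:
            out.append(call)
    return out


def most_impactful(
    calls: list[VariantCall],
    effects: dict[tuple[int, str, str], EffectAnnotation],
    af_threshold: float = IMPACT_AF_THRESHOLD,
) -> list[VariantCall]:
    """Calls above ``af_threshold`` (strict) in >= 1 cell with HIGH/MODERATE impact."""
    out = []
    for call in calls:
        eff = effects[call.key]
        if call.max_af() > af_threshold and eff.impact in ("HIGH", "MODERATE"):
            out.append(call)
    return out


def joint_impactful(
    dna_most_impactful: list[VariantCall],
    rna_calls: list[VariantCall],
    floor: float = HET_FLOOR,
    ceiling: float = HET_CEILING,
) -> list[VariantCall]:
    """DNA most-impactful sites that are heteroplasmic in >= 1 RNA cell."""
    rna_by_key = {c.key: c for c in rna_calls}
    out = []
    for call in dna_most_impactful:
        rna = rna_by_key.get(call.key)
        if rna is None:
            continue  # untranscribed or unobserved in RNA
        if any(is_heteroplasmic(af, floor, ceiling) for af in rna.af.values()):
            out.append(call)
    return out


def events_per_cell(
    calls: list[VariantCall],
    cell_id: str,
    known_cells=None,
    floor: float = HET_FLOOR,
    ceiling: float = HET_CEILING,
) -> int:
    """Number of calls heteroplasmic in the given cell.

    ``known_cells`` (when provided) defines the cell universe; otherwise a
    cell must appear with a defined AF in at least one call, so an unknown
    id raises rather than silently returning 0.
    """
    if known_cells is not None:
        if cell_id not in known_cells:
            raise KeyError(f"unknown cell {cell_id!r}")
    elif calls and all(cell_id not in c.depth for c in calls):
        raise KeyError(f"unknown cell {cell_id!r}")
    return sum(
        1
        for c in calls
        if cell_id in c.af and is_heteroplasmic(c.af[cell_id], floor, ceiling)
    )


@dataclass
class ClassifiedMutation:
    """One mutation with its annotation and list memberships."""

    call: VariantCall
    effect: EffectAnnotation
    n_cells_heteroplasmic: int
    frac_cells_heteroplasmic: float
    max_af: float
    in_most_variable: bool
    in_most_impactful: bool
    in_joint_impactful: bool = False


def classify_mutations(
    calls: list[VariantCall],
    ref: CircularReference,
    rna_calls: list[VariantCall] | None = None,
    min_cell_fraction: float = MIN_CELL_FRACTION,
    af_threshold: float = IMPACT_AF_THRESHOLD,
) -> list[ClassifiedMutation]:
    """Annotate every call and mark list memberships in one pass."""
    effects = {c.key: annotate_effect(c, ref) for c in calls}
    mv = {c.key for c in most_variable(calls, min_cell_fraction)}
    mi_list = most_impactful(calls, effects, af_threshold)
    mi = {c.key for c in mi_list}
    ji = (
        {c.key for c in joint_impactful(mi_list, rna_calls)}
        if rna_calls is not None
        else set()
    )
    out = []
    for call in calls:
        n_het, frac = heteroplasmic_cell_fraction(call)
        out.append(
            ClassifiedMutation(
                call=call,
                effect=effects[call.key],
                n_cells_heteroplasmic=n_het,
                frac_cells_heteroplasmic=frac,
                max_af=call.max_af(),
                in_most_variable=call.key in mv,
                in_most_impactful=call.key in mi,
                in_joint_impactful=call.key in ji,
            )
        )
    return out
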