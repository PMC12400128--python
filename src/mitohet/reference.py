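"""Circular mitochondrial reference genome and coordinate arithmetic.

The mitochondrial genome is a circle, but read mappers and pileup engines
assume a linear sequence, which starves the region around the arbitrary
origin (the D-loop in vertebrate mtDNA) of coverage.  The standard remedy
is to call variants twice -- once against the reference as published and
once against a rotated ("shifted") copy whose junction falls mid-molecule
-- and merge the two call sets back into original coordinates.  This
module holds the reference representation and the exact coordinate maps
that merging relies on.

All coordinates are 1-based and inclusive, matching the ``6790 G>A`` style
of mutation notation used throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO

VALID_BASES = frozenset("ACGTN")
FEATURE_TYPES = frozenset({"protein_coding", "tRNA", "rRNA", "noncoding"})
STRANDS = frozenset({"+", "-"})


@dataclass(frozen=True)
class GeneAnnotation:
    """One annotated interval of the mitochondrial genome.

    Genes that span the circular origin are represented as two (or more)
    sub-intervals sharing the same ``gene`` name, listed in transcript
    order, so that downstream interval logic stays linear.
    """

    gene: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    strand: str  # '+' or '-'
    feature_type: str  # protein_coding / tRNA / rRNA / noncoding

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValueError(f"unknown strand {self.strand!r} for gene {self.gene}")
        if self.feature_type not in FEATURE_TYPES:
            raise ValueError(
                f"unknown feature_type {self.feature_type!r} for gene {self.gene}"
            )
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"bad interval [{self.start}, {self.end}] for gene {self.gene}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end


@dataclass(frozen=True)
class CircularReference:
    """A single circular nucleotide sequence with origin fixed at position 1."""

    name: str
    sequence: str
    genes: tuple[GeneAnnotation, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        bad = set(seq) - VALID_BASES
        if bad:
            raise ValueError(f"reference contains non-ACGTN characters: {sorted(bad)}")
        object.__setattr__(self, "sequence", seq)
        for g in self.genes:
            if g.end > self.length:
                raise ValueError(
                    f"gene {g.gene} ends at {g.end} beyond reference length {self.length}"
                )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def base(self, pos: int) -> str:
        """Reference base at a 1-based position."""
        if not 1 <= pos <= self.length:
            raise ValueError(f"position {pos} outside [1, {self.length}]")
        return self.sequence[pos - 1]


def rotate_reference(ref: CircularReference, s: int) -> CircularReference:
    """Rotate the circle so original position ``s + 1`` becomes position 1.

    The rotated copy is what a "shifted" calling pass maps against; its name
    records the shift so merged calls can be traced.  Gene annotations are
    deliberately dropped from the rotated copy -- annotation always happens
    in original coordinates after merging.
    """
    L = ref.length
    if not 0 <= s < L:
        raise ValueError(f"shift {s} outside [0, {L})")
    rotated = ref.sequence[s:] + ref.sequence[:s]
    return CircularReference(name=f"{ref.name}|shift={s}", sequence=rotated)


def shifted_to_original(pos_shifted: int, s: int, L: int) -> int:
    """Map a 1-based position on the shifted reference back to the original."""
    if not 1 <= pos_shifted <= L:
        raise ValueError(f"shifted position {pos_shifted} outside [1, {L}]")
    return (pos_shifted - 1 + s) % L + 1


def original_to_shifted(pos: int, s: int, L: int) -> int:
    """Inverse of :func:`shifted_to_original`."""
    if not 1 <= pos <= L:
        raise ValueError(f"position {pos} outside [1, {L}]")
    return (pos - 1 - s) % L + 1


def default_shift(L: int) -> int:
    """Default rotation: put the origin junction mid-molecule."""
    return L // 2


def load_reference(fasta_path, annotation_path=None) -> CircularReference:
    """Load a single-record FASTA plus an optional gene-annotation table.

    The annotation table is a tab-separated file with columns
    ``gene  start  end  strand  feature_type`` (1-based inclusive
    coordinates).  An absent or empty table yields a reference with no
    genes; every position is then classed noncoding downstream.
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if len(records) != 1:
        raise ValueError(
            f"expected exactly one FASTA record in {fasta_path}, found {len(records)}"
        )
    rec = records[0]
    genes: tuple[GeneAnnotation, ...] = ()
    if annotation_path is not None:
        table = pd.read_csv(annotation_path, sep="\t", comment="#")
        required = {"gene", "start", "end", "strand", "feature_type"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"annotation table missing columns: {sorted(missing)}")
        genes = tuple(
            GeneAnnotation(
                gene=str(row.gene),
                start=int(row.start),
                end=int(row.end),
                strand=str(row.strand),
                feature_type=str(row.feature_type),
            )
            for row in table.itertuples()
        )
    return CircularReference(name=rec.id, sequence=str(rec.seq), genes=genes)


def transcribed_positions(genes) -> set[int]:
    """All 1-based positions inside a transcribed (non-``noncoding``) feature.

    The RNA arm can only observe these; variants elsewhere are structurally
    invisible to scRNA-seq and hence DNA-specific.
    """
    out: set[int] = set()
    for g in genes:
        if g.feature_type != "noncoding":
            out.update(range(g.start, g.end + 1))
    return out


def write_annotation_table(genes, path) -> None:
    """Write gene annotations in the 5-column TSV read by load_reference."""
    pd.DataFrame(
        [
            {
                "gene": g.gene,
                "start": g.start,
                "end": g.end,
                "strand": g.strand,
                "feature_type": g.feature_type,
            }
            for g in genes
        ],
        columns=["gene", "start", "end", "strand", "feature_type"],
    ).to_csv(path, sep="\t", index=False)
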