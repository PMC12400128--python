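"""Per-cell variant calling from allele-count pileups on a circular genome.

The substrate of every heteroplasmy quantity in the package is the
cell x position x allele count tensor: the per-cell allele frequency (AF)
of a mutation is simply alt reads / depth at its site, computed only where
depth clears a floor.  Calling is run twice -- against the reference as-is
and against a rotated copy -- and the two call sets are merged with the
rotated-derived call winning near the origin junction, which restores full
circular coverage.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .reference import CircularReference, shifted_to_original

ALLELES: tuple[str, ...] = ("A", "C", "G", "T", "DEL", "INS")
ALLELE_INDEX: dict[str, int] = {a: i for i, a in enumerate(ALLELES)}

#: DNA arm: long-range PCR coverage is deep (>1000x typical), so demand a
#: solid floor before an AF is considered defined.
DNA_MIN_DEPTH = 100
#: RNA arm: sites kept only above 49 reads, i.e. depth >= 50.
RNA_MIN_DEPTH = 50
#: Sites are emitted once any cell reaches this AF -- deliberately below
#: the 0.04 heteroplasmy floor so sub-threshold AFs stay available for the
#: "counted as 0" bulk comparison.
EMISSION_FLOOR = 0.01
#: Half-width of the origin window in which rotated-reference calls win.
JUNCTION_HALFWIDTH = 1000


class AlleleCountMatrix:
    """Dense cell x position x allele read counts.

    ``positions`` are 1-based reference coordinates (not necessarily the
    full genome: the RNA arm is restricted to transcribed intervals).
    ``counts`` has shape ``(n_cells, n_positions, 6)`` over the allele
    alphabet A/C/G/T/DEL/INS; depth at (cell, position) is the sum over
    alleles by construction.
    """

    def __init__(self, cells, positions, counts):
        self.cells: list[str] = list(cells)
        self.positions: np.ndarray = np.asarray(positions, dtype=np.int64)
        self.counts: np.ndarray = np.asarray(counts)
        if self.counts.shape != (len(self.cells), len(self.positions), len(ALLELES)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.cells)} cells x {len(self.positions)} positions x {len(ALLELES)} alleles"
            )
        if np.any(self.counts < 0):
            raise ValueError("negative allele counts")
        if len(self.positions) and np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")

    # -- basic accessors -------------------------------------------------

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def depth(self) -> np.ndarray:
        """(n_cells, n_positions) total read depth."""
        return self.counts.sum(axis=2)

    def position_index(self) -> dict[int, int]:
        return {int(p): i for i, p in enumerate(self.positions)}

    def subset_cells(self, keep) -> "AlleleCountMatrix":
        keep = list(keep)
        idx = [self.cells.index(c) for c in keep]
        return AlleleCountMatrix(keep, self.positions, self.counts[idx])

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, AlleleCountMatrix)
            and self.cells == other.cells
            and np.array_equal(self.positions, other.positions)
            and np.array_equal(self.counts, other.counts)
        )

    # -- sparse TSV round trip -------------------------------------------

    def to_tsv(self, path) -> None:
        """Write non-zero counts as cell/pos/allele/count triplets.

        Header comment lines record the full cell list and position range so
        all-zero cells and positions survive a round trip.
        """
        ci, pi, ai = np.nonzero(self.counts)
        table = pd.DataFrame(
            {
                "cell": np.asarray(self.cells, dtype=object)[ci],
                "pos": self.positions[pi],
                "allele": np.asarray(ALLELES, dtype=object)[ai],
                "count": self.counts[ci, pi, ai],
            }
        )
        with open(path, "w") as fh:
            fh.write("#cells\t" + ",".join(self.cells) + "\n")
            fh.write("#positions\t" + _compress_ranges(self.positions) + "\n")
            table.to_csv(fh, sep="\t", index=False, lineterminator="\n")

    @classmethod
    def from_tsv(cls, path) -> "AlleleCountMatrix":
        with open(path) as fh:
            header_cells = fh.readline().rstrip("\n").split("\t")
            header_pos = fh.readline().rstrip("\n").split("\t")
            if header_cells[0] != "#cells" or header_pos[0] != "#positions":
                raise ValueError(f"{path} is not an allele-count TSV")
            cells = header_cells[1].split(",") if len(header_cells) > 1 else []
            positions = _expand_ranges(header_pos[1] if len(header_pos) > 1 else "")
            table = pd.read_csv(fh, sep="\t")
        counts = np.zeros((len(cells), len(positions), len(ALLELES)), dtype=np.int64)
        if len(table):
            cell_idx = {c: i for i, c in enumerate(cells)}
            pos_idx = {int(p): i for i, p in enumerate(positions)}
            ci = table["cell"].map(cell_idx).to_numpy()
            pi = table["pos"].map(pos_idx).to_numpy()
            ai = table["allele"].map(ALLELE_INDEX).to_numpy()
            counts[ci, pi, ai] = table["count"].to_numpy()
        return cls(cells, positions, counts)


def _compress_ranges(positions: np.ndarray) -> str:
    """1,2,3,7,8 -> '1-3,7-8'."""
    if len(positions) == 0:
        return ""
    parts = []
    start = prev = int(positions[0])
    for p in positions[1:]:
        p = int(p)
        if p == prev + 1:
            prev = p
            continue
        parts.append(f"{start}-{prev}")
        start = prev = p
    parts.append(f"{start}-{prev}")
    return ",".join(parts)


def _expand_ranges(spec: str) -> np.ndarray:
    out: list[int] = []
    if spec:
        for part in spec.split(","):
            lo, hi = part.split("-")
            out.extend(range(int(lo), int(hi) + 1))
    return np.asarray(out, dtype=np.int64)


@dataclass
class VariantCall:
    """A site-level mutation with per-cell allele frequencies.

    ``af`` and ``depth`` are keyed by cell id and carry entries only for
    cells whose depth at the site reached the calling floor; the AF is
    undefined (absent) elsewhere.
    """

    pos: int
    ref_allele: str
    alt_allele: str
    af: dict[str, float] = field(default_factory=dict)
    depth: dict[str, int] = field(default_factory=dict)
    source: str = "unshifted"  # unshifted / shifted / merged

    @property
    def key(self) -> tuple[int, str, str]:
        return (self.pos, self.ref_allele, self.alt_allele)

    @property
    def label(self) -> str:
        return f"{self.pos} {self.ref_allele}>{self.alt_allele}"

    def max_af(self) -> float:
        return max(self.af.values()) if self.af else 0.0

    def n_defined(self) -> int:
        return len(self.af)


def call_variants(
    counts: AlleleCountMatrix,
    ref: CircularReference,
    min_depth: int = DNA_MIN_DEPTH,
    emission_floor: float = EMISSION_FLOOR,
    source: str = "unshifted",
) -> list[VariantCall]:
    """Emit per-cell AFs for every non-reference allele seen at any site.

    A site/allele pair becomes a call when at least one cell with defined
    depth reaches ``emission_floor``; AF(cell) = alt count / depth wherever
    depth >= ``min_depth`` and is undefined elsewhere.
    """
    L = ref.length
    if len(counts.positions) and int(counts.positions[-1]) > L:
        raise ValueError(
            f"count matrix position {counts.positions[-1]} beyond reference length {L}"
        )
    depth = counts.depth()
    defined = depth >= min_depth
    ref_idx = np.array([ALLELE_INDEX[ref.base(int(p))] for p in counts.positions])
    calls: list[VariantCall] = []
    with np.errstate(divide="ignore", invalid="ignore"):
        for a, allele in enumerate(ALLELES):
            alt_counts = counts.counts[:, :, a]
            candidate = (ref_idx != a) & (alt_counts.sum(axis=0) > 0)
            if not candidate.any():
                continue
            af = np.where(defined, alt_counts / np.maximum(depth, 1), np.nan)
            best = np.where(np.isnan(af), -1.0, af).max(axis=0)
            emit = candidate & (best >= emission_floor)
            for j in np.nonzero(emit)[0]:
                cells_def = np.nonzero(defined[:, j])[0]
                calls.append(
                    VariantCall(
                        pos=int(counts.positions[j]),
                        ref_allele=ALLELES[ref_idx[j]],
                        alt_allele=allele,
                        af={counts.cells[i]: float(af[i, j]) for i in cells_def},
                        depth={counts.cells[i]: int(depth[i, j]) for i in cells_def},
                        source=source,
                    )
                )
    calls.sort(key=lambda c: c.key)
    return calls


def merge_shifted_calls(
    calls_unshifted: list[VariantCall],
    calls_shifted: list[VariantCall],
    s: int,
    L: int,
    junction_halfwidth: int = JUNCTION_HALFWIDTH,
) -> list[VariantCall]:
    """Concatenate unshifted and shifted call sets into original coordinates.

    Shifted calls are mapped back through the rotation; within
    ``junction_halfwidth`` of the origin (where the linear unshifted pass
    loses reads) the shifted-derived call wins, elsewhere the unshifted one
    does.  A site present in both passes collapses to a single record with
    ``source='merged'``.
    """

    def near_origin(pos: int) -> bool:
        return pos <= junction_halfwidth or pos > L - junction_halfwidth

    mapped: dict[tuple[int, str, str], VariantCall] = {}
    for call in calls_shifted:
        pos = shifted_to_original(call.pos, s, L)
        mapped[(pos, call.ref_allele, call.alt_allele)] = VariantCall(
            pos=pos,
            ref_allele=call.ref_allele,
            alt_allele=call.alt_allele,
            af=dict(call.af),
            depth=dict(call.depth),
            source="shifted",
        )
    unshifted = {c.key: c for c in calls_unshifted}

    for (pos, ref_a, _alt), _call in list(mapped.items()):
        for (pos_u, ref_u, _alt_u) in unshifted:
            if pos_u == pos and ref_u != ref_a:
                raise ValueError(
                    f"conflicting reference alleles at position {pos}: "
                    f"{ref_u} (unshifted) vs {ref_a} (shifted) -- coordinate bug"
                )

    merged: dict[tuple[int, str, str], VariantCall] = {}
    for key in set(unshifted) | set(mapped):
        u, sh = unshifted.get(key), mapped.get(key)
        if u is not None and sh is not None:
            winner = sh if near_origin(key[0]) else u
            merged[key] = VariantCall(
                pos=winner.pos,
                ref_allele=winner.ref_allele,
                alt_allele=winner.alt_allele,
                af=dict(winner.af),
                depth=dict(winner.depth),
                source="merged",
            )
        else:
            only = u if u is not None else sh
            merged[key] = only
    return sorted(merged.values(), key=lambda c: c.key)


def pseudobulk(
    counts: AlleleCountMatrix,
    cells=None,
    ref: CircularReference | None = None,
) -> dict[tuple[int, str], float]:
    """Pool single cells into one bulk-like sample.

    Returns AF = (sum of allele counts over cells) / (sum of depths) per
    (position, allele) with a non-zero pooled count; sites with zero pooled
    depth are undefined and omitted.  When a reference is given, reference
    alleles are excluded so the map contains mutations only.
    """
    subset = counts if cells is None else counts.subset_cells(cells)
    if subset.n_cells == 0:
        raise ValueError("pseudobulk requires a non-empty cell subset")
    pooled = subset.counts.sum(axis=0)  # (n_pos, 6)
    total = pooled.sum(axis=1)
    out: dict[tuple[int, str], float] = {}
    for j, pos in enumerate(subset.positions):
        if total[j] == 0:
            continue
        ref_base = ref.base(int(pos)) if ref is not None else None
        for a, allele in enumerate(ALLELES):
            if pooled[j, a] == 0 or allele == ref_base:
                continue
            out[(int(pos), allele)] = float(pooled[j, a] / total[j])
    return out


def modality_compare(
    dna_af: dict[tuple[int, str], float],
    rna_af: dict[tuple[int, str], float],
    het_floor: float = 0.04,
    transcribed=None,
) -> pd.DataFrame:
    """Classify sites as joint, DNA-specific, RNA-specific or absent.

    Both maps are (position, alt allele) -> AF in original coordinates.
    A site missing from a map counts as AF 0 there; a DNA site outside the
    transcribed intervals (when given) is DNA-specific regardless of the
    RNA value, since the RNA arm cannot see it.
    """
    rows = []
    for pos, alt in sorted(set(dna_af) | set(rna_af)):
        d = dna_af.get((pos, alt), 0.0)
        r = rna_af.get((pos, alt), 0.0)
        untranscribed = transcribed is not None and pos not in transcribed
        if d >= het_floor and (r < het_floor or untranscribed):
            cls = "DNA_specific"
        elif r >= het_floor and d < het_floor:
            cls = "RNA_specific"
        elif d >= het_floor and r >= het_floor:
            cls = "joint"
        else:
            cls = "absent"
        rows.append(
            {"pos": pos, "alt": alt, "dna_af": d, "rna_af": r, "class": cls}
        )
    return pd.DataFrame(rows, columns=["pos", "alt", "dna_af", "rna_af", "class"])


def pileup_reads(records, L: int) -> dict[str, np.ndarray]:
    """Tally raw read records into per-cell A/C/G/T counts on the circle.

    ``records`` are (cell_id, 1-based start, sequence) triples; reads wrap
    around the origin.  Masked (``N``) bases contribute to no allele count,
    which is how polyA masking keeps contaminated stretches out of the AF
    arithmetic.
    """
    out: dict[str, np.ndarray] = {}
    for cell_id, start, seq in records:
        arr = out.setdefault(cell_id, np.zeros((L, 4), dtype=np.int64))
        for i, base in enumerate(seq):
            if base == "N":
                continue
            if base not in "ACGT":
                raise ValueError(f"unexpected base {base!r} in read for {cell_id}")
            pos0 = (start - 1 + i) % L
            arr[pos0, ALLELE_INDEX[base]] += 1
    return out


def write_vcf(
    calls: list[VariantCall],
    cells: list[str],
    ref: CircularReference,
    path,
) -> None:
    """Write calls as VCF 4.2 with per-sample AF and DP FORMAT fields.

    Coordinates are 1-based inclusive (native VCF); DEL/INS alleles are
    encoded symbolically as ``<DEL>`` / ``<INS>`` at their (left-aligned)
    reference position.
    """
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={ref.name},length={ref.length}>",
        '##FORMAT=<ID=AF,Number=1,Type=Float,Description="Cell allele frequency">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Cell read depth">',
        '##INFO=<ID=SRC,Number=1,Type=String,Description="Calling pass (unshifted/shifted/merged)">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(cells),
    ]
    for call in sorted(calls, key=lambda c: c.key):
        alt = call.alt_allele if call.alt_allele in "ACGT" else f"<{call.alt_allele}>"
        samples = []
        for cell in cells:
            if cell in call.af:
                samples.append(f"{call.af[cell]:.6g}:{call.depth[cell]}")
            else:
                samples.append(".:.")
        lines.append(
            f"{ref.name}\t{call.pos}\t.\t{call.ref_allele}\t{alt}\t.\tPASS\t"
            f"SRC={call.source}\tAF:DP\t" + "\t".join(samples)
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
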