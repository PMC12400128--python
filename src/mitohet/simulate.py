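"""Ground-truthed synthetic data: heteroplasmy segregation and sequencing.

Why simulate.  Heteroplasmic allele frequencies in a clonal cell population
are shaped by a genetic bottleneck: at each division only a finite number
of mtDNA copies is transmitted, so an initially uniform founder frequency
drifts apart between lineages.  The generator models that drift explicitly
(a Wright-Fisher resampling of N mtDNA copies per division), then overlays
the two measurement processes of the real experiment: a deep two-fragment
long-range-PCR DNA arm with per-cell amplification bias between fragments,
and a shallow RNA arm restricted to transcribed intervals, with
polyA-contaminated reads, RNA-only variants, and a cell-by-gene expression
matrix carrying mitochondrial-fraction and feature-count structure.

Every stochastic step draws from a single :class:`numpy.random.Generator`
seeded from ``SimulationConfig.seed``, so a cohort is reproducible
byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calling import ALLELE_INDEX, ALLELES, AlleleCountMatrix
from .reference import (
    CircularReference,
    GeneAnnotation,
    transcribed_positions,
    write_annotation_table,
)

#: mtDNA substitutions are strongly transition-biased; when a variant's alt
#: allele is unspecified it is resolved as the transition partner of the
#: reference base, deterministically, so the DNA and RNA arms agree.
TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Stop codons of the vertebrate mitochondrial genetic code.
MITO_STOPS = ("TAA", "TAG", "AGA", "AGG")


# ---------------------------------------------------------------------------
# configuration and ground truth
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FounderVariant:
    """A heteroplasmic variant present in the founder cell.

    ``ref``/``alt`` may be left ``None`` and are then resolved against the
    reference (alt = transition of ref).  Variants sharing a ``haplotype``
    id are placed on the same mtDNA copies and therefore co-segregate.
    """

    pos: int
    af: float
    ref: str | None = None
    alt: str | None = None
    haplotype: int | None = None


@dataclass
class RNAConfig:
    """Parameters of the RNA arm (expression matrix + mito pileup + reads)."""

    n_cells: int = 300
    n_genes: int = 6000  # nuclear genes in the expression matrix
    mean_depth: float = 80.0  # mito per-base depth over transcribed intervals
    polyA_rate: float = 0.15  # fraction of raw reads carrying an A-run >= 5
    reads_per_cell: int = 30
    read_length: int = 90
    rna_specific_variants: tuple[FounderVariant, ...] = ()
    mito_fraction_beta: tuple[float, float] = (4.0, 46.0)  # mean ~0.08
    feature_mean: float = 3000.0
    feature_sd: float = 350.0
    nuclear_gene_mean: float = 15.0
    # engineered QC violators (leading cells, in id order)
    n_high_mito: int = 5
    high_mito_value: float = 0.30
    n_low_features: int = 4
    low_features_value: int = 1500
    n_high_features: int = 3
    high_features_value: int = 4500
    n_low_depth: int = 4
    low_depth_mean: float = 25.0


@dataclass
class SimulationConfig:
    """Study-level parameters of the synthetic cohort.

    The DNA-arm defaults mirror the experiment the package targets: 88
    single cells split evenly between induced and noninduced conditions, of
    which 4 (2 per condition) are constructed with sub-threshold coverage in
    one LRPCR fragment, so fragment QC passes exactly 84.  Copy number
    (N=500) and generation count (g=30) are not measured quantities for CHO
    cells; they are declared defaults of the drift model.
    """

    seed: int = 0
    n_cells: int = 88
    generations: int = 30
    mtdna_copies: int = 500
    founder_variants: tuple[FounderVariant, ...] = ()
    mutation_rate: float = 2e-5  # de novo mutations per copy per generation
    genome_length: int = 16283
    mean_depth: float = 5000.0
    depth_dispersion: float = 10.0  # NB size parameter; inf = exact depth
    error_rate: float = 0.001  # per-base miscall probability
    fragment_bias_sd: float = 0.35  # sd of per-cell log amplification bias
    fragment_x: tuple[int, int] = (1500, 8000)  # fragment X interval; Y = rest
    n_low_depth_cells: int = 4
    low_depth_factor: float = 0.02  # applied to fragment X of degraded cells
    induced_fraction: float = 0.5
    rna: RNAConfig = field(default_factory=RNAConfig)

    def validate(self) -> None:
        if self.mtdna_copies < 1:
            raise ValueError("mtdna_copies must be >= 1")
        if self.generations < 0 or self.n_cells < 1:
            raise ValueError("generations >= 0 and n_cells >= 1 required")
        if self.n_cells > 2 ** self.generations:
            raise ValueError(
                f"n_cells={self.n_cells} exceeds 2^g={2 ** self.generations} leaves"
            )
        for p in (self.mutation_rate, self.error_rate, self.induced_fraction,
                  self.rna.polyA_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        for fv in self.founder_variants:
            if not 0.0 <= fv.af <= 1.0:
                raise ValueError(f"founder AF {fv.af} outside [0, 1]")
            if not 1 <= fv.pos <= self.genome_length:
                raise ValueError(f"founder variant position {fv.pos} outside genome")
        if self.mean_depth < 0 or self.rna.mean_depth < 0:
            raise ValueError("depths must be >= 0")


@dataclass
class CellTruth:
    """Simulator ground truth for one cell."""

    cell_id: str
    parent_id: str
    condition: str  # induced / noninduced
    true_af: dict[int, float]  # position -> AF; every founder variant present


# ---------------------------------------------------------------------------
# lineage drift
# ---------------------------------------------------------------------------


def simulate_lineage(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> list[CellTruth]:
    """Drift heteroplasmy through a clonal lineage and sample n_cells leaves.

    Model: the founder cell carries N mtDNA copies with each founder
    variant placed on ``round(af * N)`` copies (co-placed within a haplotype
    group).  At each division a daughter's N copies are a Wright-Fisher
    (multinomial) resample of the parent's N, giving the one-generation
    allele-frequency variance p(1-p)/N and the martingale property
    E[AF_t] = p0.  De novo mutations arise per copy per generation at rate
    ``mutation_rate`` at uniformly random previously unused positions.  Only
    the branches ancestral to the sampled leaves of the depth-g binary tree
    are simulated.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    N = config.mtdna_copies
    g = config.generations
    L = config.genome_length

    # founder copy-level genotypes
    copy_sets: list[set[int]] = [set() for _ in range(N)]
    used_positions = {fv.pos for fv in config.founder_variants}
    groups: dict[object, list[FounderVariant]] = {}
    for i, fv in enumerate(config.founder_variants):
        key = ("hap", fv.haplotype) if fv.haplotype is not None else ("solo", i)
        groups.setdefault(key, []).append(fv)
    for key, members in groups.items():
        afs = {fv.af for fv in members}
        if len(afs) > 1:
            raise ValueError(f"haplotype group {key} has unequal founder AFs")
        k = int(round(members[0].af * N))
        if k > 0:
            chosen = rng.choice(N, size=k, replace=False)
            for c in chosen:
                copy_sets[c].update(fv.pos for fv in members)

    hap_index: dict[frozenset, int] = {}
    hap_of_copy = []
    for s in copy_sets:
        key = frozenset(s)
        hap_of_copy.append(hap_index.setdefault(key, len(hap_index)))
    haps: list[frozenset] = list(hap_index)
    counts = np.bincount(hap_of_copy, minlength=len(haps)).astype(np.int64)

    def divide(haps, counts):
        child = rng.multinomial(N, counts / N)
        keep = child > 0
        return [haps[i] for i in np.nonzero(keep)[0]], child[keep]

    def mutate(haps, counts):
        n_new = rng.binomial(N, config.mutation_rate)
        haps, counts = list(haps), counts.copy()
        for _ in range(n_new):
            pos = int(rng.integers(1, L + 1))
            while pos in used_positions:
                pos = int(rng.integers(1, L + 1))
            used_positions.add(pos)
            r = int(rng.integers(N))
            cum = np.cumsum(counts)
            h = int(np.searchsorted(cum, r, side="right"))
            counts[h] -= 1
            haps.append(haps[h] | {pos})
            counts = np.append(counts, 1)
            if counts[h] == 0:
                del haps[h]
                counts = np.delete(counts, h)
        return haps, counts

    # sample distinct leaves of the depth-g binary tree
    total = 1 << g
    n = config.n_cells
    if total <= 4096:
        leaves = np.sort(rng.choice(total, size=n, replace=False))
    else:
        seen: set[int] = set()
        while len(seen) < n:
            seen.add(int(rng.integers(total)))
        leaves = np.array(sorted(seen), dtype=np.int64)

    founder_positions = [fv.pos for fv in config.founder_variants]
    cells: list[CellTruth] = []

    def emit(leaf: int, haps, counts) -> None:
        af: dict[int, float] = {}
        for pos in founder_positions:
            af[pos] = float(sum(int(c) for h, c in zip(haps, counts) if pos in h)) / N
        for h, c in zip(haps, counts):
            for pos in h:
                if pos not in af:
                    af[pos] = 0.0
                    af[pos] = float(
                        sum(int(cc) for hh, cc in zip(haps, counts) if pos in hh)
                    ) / N
        parent = "founder" if g == 0 else f"node{leaf >> 1}.g{g - 1}"
        cells.append(
            CellTruth(
                cell_id=f"cell{len(cells):03d}",
                parent_id=parent,
                condition="",
                true_af=af,
            )
        )

    def rec(haps, counts, depth: int, subset: np.ndarray) -> None:
        if depth == g:
            emit(int(subset[0]), haps, counts)
            return
        bit = g - depth - 1
        mask = (subset >> bit) & 1 == 0
        for side in (subset[mask], subset[~mask]):
            if len(side):
                h2, c2 = divide(haps, counts)
                h2, c2 = mutate(h2, c2)
                rec(h2, c2, depth + 1, side)

    if g == 0:
        emit(0, haps, counts)
    else:
        rec(haps, counts, 0, leaves)

    n_induced = int(round(config.induced_fraction * n))
    order = rng.permutation(n)
    for rank, idx in enumerate(order):
        cells[idx].condition = "induced" if rank < n_induced else "noninduced"
    return cells


# ---------------------------------------------------------------------------
# sequencing arms
# ---------------------------------------------------------------------------


def resolve_alt(ref_base: str, fv: FounderVariant | None) -> str:
    """Alt allele for a variant position: configured, else the transition."""
    if fv is not None and fv.alt is not None:
        return fv.alt
    return TRANSITION[ref_base]


def _multinomial_chain(n: np.ndarray, probs: np.ndarray, rng) -> np.ndarray:
    """Exact multinomial draws via sequential binomials, vectorised.

    ``n`` broadcasts against ``probs[..., k]``; categories are drawn in
    order with renormalised remainders, so per-sample totals equal ``n``.
    """
    n = np.asarray(n, dtype=np.int64)
    out = np.empty(probs.shape, dtype=np.int64)
    remaining = np.broadcast_to(n, probs.shape[:-1]).copy()
    remaining_p = np.ones(probs.shape[:-1])
    for i in range(probs.shape[-1] - 1):
        with np.errstate(divide="ignore", invalid="ignore"):
            frac = np.where(
                remaining_p > 1e-12, probs[..., i] / np.maximum(remaining_p, 1e-12), 0.0
            )
        draw = rng.binomial(remaining, np.clip(frac, 0.0, 1.0))
        out[..., i] = draw
        remaining = remaining - draw
        remaining_p = remaining_p - probs[..., i]
    out[..., -1] = remaining
    return out

def _draw_depth(mean: np.ndarray, dispersion: float, rng) -> np.ndarray:
    mean = np.asarray(mean, dtype=float)
    if not np.isfinite(dispersion):
        return np.rint(mean).astype(np.int64)
    p = dispersion / (dispersion + np.maximum(mean, 1e-12))
    return rng.negative_binomial(dispersion, p).astype(np.int64)


def _allele_probs(af: np.ndarray, ref_idx: int, alt_idx: int, e: float) -> np.ndarray:
    """(n_cells, 6) read-category probabilities for one variant site.

    Reads from mutant copies report the alt with probability 1-e (indel
    alleles are never miscalled); reads from wild-type copies report the
    reference with probability 1-e; miscalls scatter evenly over the other
    three bases.
    """
    C = len(af)
    probs = np.zeros((C, len(ALLELES)))
    if alt_idx >= 4:  # DEL / INS
        probs[:, alt_idx] = af
        for b in range(4):
            if b == ref_idx:
                probs[:, b] = (1 - af) * (1 - e)
            else:
                probs[:, b] += (1 - af) * e / 3
    else:
        for b in range(4):
            if b == alt_idx:
                probs[:, b] = af * (1 - e) + (1 - af) * e / 3
            elif b == ref_idx:
                probs[:, b] = (1 - af) * (1 - e) + af * e / 3
            else:
                probs[:, b] = e / 3
    return probs


def _simulate_counts(
    cells: list[str],
    positions: np.ndarray,
    ref: CircularReference,
    af_by_pos: dict[int, np.ndarray],  # pos -> per-cell true AF
    alt_by_pos: dict[int, str],
    depth_mean: np.ndarray,  # (n_cells, n_positions)
    dispersion: float,
    error_rate: float,
    rng: np.random.Generator,
) -> AlleleCountMatrix:
    """Shared read-count engine for both arms.

    Background (non-variant) sites receive pure sequencing error; variant
    sites are drawn from the per-cell mixture of mutant and wild-type
    copies.  Counts sum to depth at every (cell, position) by construction.
    """
    C, P = len(cells), len(positions)
    depth = _draw_depth(depth_mean, dispersion, rng)
    ref_idx = np.array([ALLELE_INDEX[ref.base(int(p))] for p in positions])
    e = error_rate

    # background: three error bases then the reference remainder
    bg_probs = np.empty((P, 4))
    others = np.empty((P, 3), dtype=np.int64)
    for j in range(P):
        others[j] = [b for b in range(4) if b != ref_idx[j]]
    bg_probs[:, :3] = e / 3
    bg_probs[:, 3] = 1 - e
    bg = _multinomial_chain(depth, np.broadcast_to(bg_probs, (C, P, 4)), rng)

    counts = np.zeros((C, P, len(ALLELES)), dtype=np.int64)
    rows = np.arange(C)[:, None]
    cols = np.arange(P)[None, :]
    for k in range(3):
        counts[rows, cols, others[None, :, k]] = bg[:, :, k]
    counts[rows, cols, ref_idx[None, :]] = bg[:, :, 3]

    pos_index = {int(p): j for j, p in enumerate(positions)}
    for pos, af in sorted(af_by_pos.items()):
        if pos not in pos_index:
            continue  # e.g. untranscribed site in the RNA arm
        j = pos_index[pos]
        alt_idx = ALLELE_INDEX[alt_by_pos[pos]]
        if alt_idx == ref_idx[j]:
            raise ValueError(f"alt allele equals reference at position {pos}")
        probs = _allele_probs(np.asarray(af, dtype=float), int(ref_idx[j]), alt_idx, e)
        counts[:, j, :] = _multinomial_chain(depth[:, j], probs, rng)
    return AlleleCountMatrix(cells, positions, counts)


def _variant_tables(
    truth: list[CellTruth],
    ref: CircularReference,
    founders: tuple[FounderVariant, ...],
    extra: tuple[FounderVariant, ...] = (),
) -> tuple[dict[int, np.ndarray], dict[int, str]]:
    """Per-cell AF vectors and alt alleles for every variant position."""
    by_pos = {fv.pos: fv for fv in founders}
    by_pos.update({fv.pos: fv for fv in extra})
    positions = sorted({p for cell in truth for p in cell.true_af} | set(by_pos))
    af_by_pos: dict[int, np.ndarray] = {}
    alt_by_pos: dict[int, str] = {}
    for pos in positions:
        fv = by_pos.get(pos)
        ref_base = ref.base(pos)
        if fv is not None and fv.ref is not None and fv.ref != ref_base:
            raise ValueError(
                f"founder variant at {pos} declares ref {fv.ref} but reference has {ref_base}"
            )
        alt_by_pos[pos] = resolve_alt(ref_base, fv)
        if fv is not None and fv.pos not in {c_pos for cell in truth for c_pos in cell.true_af}:
            # RNA-specific variant: constant AF across cells
            af_by_pos[pos] = np.full(len(truth), fv.af)
        else:
            af_by_pos[pos] = np.array([cell.true_af.get(pos, 0.0) for cell in truth])
    return af_by_pos, alt_by_pos


def simulate_dna_counts(
    truth: list[CellTruth],
    ref: CircularReference,
    config: SimulationConfig,
    rng: np.random.Generator,
    low_depth_cells: list[str] | None = None,
) -> AlleleCountMatrix:
    """Deep LRPCR-style allele counts over the full circle.

    Each cell draws a lognormal amplification bias b: positions inside the
    X fragment interval get mean depth scaled by b, all other positions
    (fragment Y, which spans the origin) by 1/b -- reproducing the
    per-cell fragment imbalance seen in two-fragment amplification.
    Cells named in ``low_depth_cells`` additionally have their X-fragment
    depth multiplied by ``low_depth_factor`` so they fail fragment QC.
    """
    L = ref.length
    cells = [c.cell_id for c in truth]
    positions = np.arange(1, L + 1, dtype=np.int64)
    bias = np.exp(rng.normal(0.0, config.fragment_bias_sd, size=len(cells)))
    x_lo, x_hi = config.fragment_x
    in_x = (positions >= x_lo) & (positions <= x_hi)
    factor = np.where(in_x[None, :], bias[:, None], 1.0 / bias[:, None])
    if low_depth_cells:
        degraded = np.isin(np.array(cells), np.array(list(low_depth_cells)))
        factor[np.ix_(degraded, in_x)] *= config.low_depth_factor
    depth_mean = config.mean_depth * factor

    af_by_pos, alt_by_pos = _variant_tables(truth, ref, config.founder_variants)
    return _simulate_counts(
        cells, positions, ref, af_by_pos, alt_by_pos, depth_mean,
        config.depth_dispersion, config.error_rate, rng,
    )


def linearized_views(
    counts: AlleleCountMatrix,
    ref: CircularReference,
    s: int,
    dropout_halfwidth: int,
) -> tuple[AlleleCountMatrix, AlleleCountMatrix]:
    """Emulate linear-reference mapping loss around each junction.

    Returns the (unshifted, shifted) count matrices a linear mapper would
    produce from the same circularly complete reads: the unshifted view
    loses all counts within ``dropout_halfwidth`` of the origin, and the
    shifted view (expressed in shifted coordinates) loses counts within the
    same distance of its own junction, which sits at original position s.
    Merging calls from the two views should recover the complete matrix.
    """
    L = ref.length
    if len(counts.positions) != L or counts.positions[0] != 1:
        raise ValueError("linearized_views requires a full-genome count matrix")
    pos = counts.positions
    near = (pos <= dropout_halfwidth) | (pos > L - dropout_halfwidth)
    un = counts.counts.copy()
    un[:, near, :] = 0

    perm = (np.arange(L) + s) % L  # shifted index q-1 -> original index
    sh = counts.counts[:, perm, :].copy()
    sh[:, near, :] = 0  # same predicate in shifted coordinates
    return (
        AlleleCountMatrix(counts.cells, pos, un),
        AlleleCountMatrix(counts.cells, pos.copy(), sh),
    )


@dataclass
class RNAArm:
    """Outputs of the RNA-arm simulation."""

    gene_counts: pd.DataFrame  # cells x genes (mito genes prefixed MT-)
    counts: AlleleCountMatrix  # mito allele counts, transcribed positions only
    reads: list[tuple[str, int, str]]  # (cell_id, 1-based start, sequence)


def simulate_rna_arm(
    truth: list[CellTruth],
    ref: CircularReference,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> RNAArm:
    """Shallow transcribed-region pileup, expression matrix and raw reads.

    QC violators are engineered deterministically into the leading cells in
    id order: first ``n_high_mito`` cells get the forced high mitochondrial
    fraction, the next ``n_low_features`` / ``n_high_features`` cells get
    out-of-bounds feature counts, and the next ``n_low_depth`` cells get a
    sub-threshold mitochondrial pileup depth.
    """
    rc = config.rna
    cells = [c.cell_id for c in truth]
    C = len(cells)

    # --- expression matrix -------------------------------------------------
    mito_genes = [g for g in ref.genes if g.feature_type in ("protein_coding", "rRNA")]
    mito_names = sorted({g.gene for g in mito_genes})
    mito_len = {
        name: sum(g.length for g in mito_genes if g.gene == name) for name in mito_names
    }
    mito_w = np.array([mito_len[n] for n in mito_names], dtype=float)
    mito_w /= mito_w.sum()
    nuclear_names = [f"G{i:04d}" for i in range(rc.n_genes)]
    all_names = mito_names + nuclear_names

    i0 = 0
    forced_mito = dict.fromkeys(range(i0, i0 + rc.n_high_mito), rc.high_mito_value)
    i0 += rc.n_high_mito
    forced_feat = dict.fromkeys(range(i0, i0 + rc.n_low_features), rc.low_features_value)
    i0 += rc.n_low_features
    forced_feat.update(
        dict.fromkeys(range(i0, i0 + rc.n_high_features), rc.high_features_value)
    )
    i0 += rc.n_high_features
    low_depth_idx = set(range(i0, i0 + rc.n_low_depth))

    expr = np.zeros((C, len(all_names)), dtype=np.int64)
    a, b = rc.mito_fraction_beta
    for i in range(C):
        target_features = forced_feat.get(
            i, int(round(rng.normal(rc.feature_mean, rc.feature_sd)))
        )
        n_nuc = int(np.clip(target_features - len(mito_names), 1, rc.n_genes))
        chosen = rng.choice(rc.n_genes, size=n_nuc, replace=False)
        nuc_counts = 1 + rng.negative_binomial(
            2.0, 2.0 / (2.0 + rc.nuclear_gene_mean), size=n_nuc
        )
        expr[i, len(mito_names) + chosen] = nuc_counts
        t_nuc = int(nuc_counts.sum())
        m = forced_mito.get(i, float(rng.beta(a, b)))
        t_mito = max(int(round(m / (1.0 - m) * t_nuc)), len(mito_names))
        mito_counts = rng.multinomial(t_mito - len(mito_names), mito_w) + 1
        expr[i, : len(mito_names)] = mito_counts
    gene_counts = pd.DataFrame(expr, index=cells, columns=all_names)
    gene_counts.columns.name = "gene"
    gene_counts.index.name = "cell"

    # --- mito allele counts over transcribed intervals ---------------------
    tpos = np.array(sorted(transcribed_positions(ref.genes)), dtype=np.int64)
    depth_mean = np.full((C, len(tpos)), rc.mean_depth)
    for i in low_depth_idx:
        depth_mean[i, :] = rc.low_depth_mean
    af_by_pos, alt_by_pos = _variant_tables(
        truth, ref, config.founder_variants, extra=rc.rna_specific_variants
    )
    acm = _simulate_counts(
        cells, tpos, ref, af_by_pos, alt_by_pos, depth_mean,
        config.depth_dispersion, config.error_rate, rng,
    )

    # --- raw read records with polyA contamination -------------------------
    reads: list[tuple[str, int, str]] = []
    doubled = ref.sequence * 2
    for cell_id in cells:
        for _ in range(rc.reads_per_cell):
            start = int(rng.integers(1, ref.length + 1))
            seq = doubled[start - 1 : start - 1 + rc.read_length]
            if rng.random() < rc.polyA_rate:
                run = int(rng.integers(5, 25))
                seq = seq[: rc.read_length - run] + "A" * run
            reads.append((cell_id, start, seq))
    return RNAArm(gene_counts=gene_counts, counts=acm, reads=reads)


# ---------------------------------------------------------------------------
# default scenario: reference, annotation and founder variants
# ---------------------------------------------------------------------------

# (name, start, end, strand, feature_type); protein-coding lengths are
# multiples of 3.  The D-loop spans the origin as two sub-intervals.
_GENE_LAYOUT = [
    ("D-loop", 15741, 16283, "+", "noncoding"),
    ("D-loop", 1, 430, "+", "noncoding"),
    ("MT-TF", 440, 508, "+", "tRNA"),
    ("MT-RNR1", 520, 1470, "+", "rRNA"),
    ("MT-TV", 1480, 1545, "+", "tRNA"),
    ("MT-RNR2", 1555, 3110, "+", "rRNA"),
    ("MT-TL1", 3120, 3190, "+", "tRNA"),
    ("MT-ND1", 3200, 4156, "+", "protein_coding"),
    ("MT-ND2", 4300, 5340, "+", "protein_coding"),
    ("MT-CO1", 5900, 7441, "+", "protein_coding"),
    ("MT-CO2", 7600, 8283, "+", "protein_coding"),
    ("MT-ATP6", 8400, 9080, "+", "protein_coding"),
    ("MT-CO3", 9200, 9982, "+", "protein_coding"),
    ("MT-ND4", 10100, 11476, "+", "protein_coding"),
    ("MT-ND5", 11700, 13199, "+", "protein_coding"),
    ("MT-ND6", 13300, 13824, "-", "protein_coding"),
    ("MT-CYB", 13900, 15039, "+", "protein_coding"),
]


def _random_cds(n_codons: int, rng) -> str:
    """Random coding sequence with no internal stop, terminated by TAA."""
    bases = "ACGT"
    codons = []
    while len(codons) < n_codons - 1:
        c = "".join(rng.choice(list(bases), size=3))
        if c not in MITO_STOPS:
            codons.append(c)
    codons.append("TAA")
    return "".join(codons)


def _break_a_runs(seq: list[str]) -> None:
    """Replace the 5th consecutive A with C, in place.

    C never occurs in a mitochondrial stop codon, so this cannot introduce
    a premature stop into any coding frame; it guarantees the reference
    itself contains no polyA run that the read masker would hit.
    """
    run = 0
    for i, b in enumerate(seq):
        run = run + 1 if b == "A" else 0
        if run >= 5:
            seq[i] = "C"
            run = 0


def make_default_reference(rng: np.random.Generator) -> CircularReference:
    """Random CHO-like mitochondrial genome under the layout above."""
    L = 16283
    seq = list(rng.choice(list("ACGT"), size=L))
    genes = tuple(GeneAnnotation(*row) for row in _GENE_LAYOUT)
    for g in genes:
        if g.feature_type != "protein_coding":
            continue
        cds = _random_cds(g.length // 3, rng)
        if g.strand == "+":
            seq[g.start - 1 : g.end] = list(cds)
        else:
            rc = "".join(COMPLEMENT[b] for b in reversed(cds))
            seq[g.start - 1 : g.end] = list(rc)
    _break_a_runs(seq)
    return CircularReference(name="synthMT", sequence="".join(seq), genes=genes)


def _plant_codon(seq: list[str], pos0: int, codon: str) -> None:
    """Place a codon at 0-based ``pos0`` with C flanks (A-run safe, stop safe)."""
    seq[pos0 : pos0 + 3] = list(codon)
    if pos0 - 1 >= 0:
        seq[pos0 - 1] = "C"
    if pos0 + 3 < len(seq):
        seq[pos0 + 3] = "C"


def default_scenario(seed: int = 0) -> tuple[SimulationConfig, CircularReference]:
    """The packaged study conditions: reference + founder variant panel.

    The founder panel echoes the structure of the experiment's findings:
    a common stop-gain in MT-CO1 (cf. a 6790 G>A analogue), a high-frequency
    missense in MT-ND5 (a 4958 G>A analogue at AF 0.60), a perfectly linked
    three-variant haplotype, a minus-strand missense, a frameshifting
    single-base deletion, a variant 8 bp from the circular origin, two
    untranscribed (hence DNA-specific) variants, and low-frequency variants
    hovering at the 0.04 heteroplasmy floor.
    """
    rng = np.random.default_rng(seed)
    ref = make_default_reference(rng)
    seq = list(ref.sequence)

    # planted marker codons (genomic 0-based starts; all + strand except ND6)
    _plant_codon(seq, 5900 - 1 + 300, "CAA")  # MT-CO1 codon 101: C>T -> TAA stop
    _plant_codon(seq, 11700 - 1 + 450, "GCT")  # MT-ND5 codon 151: C>T -> GTT missense
    _plant_codon(seq, 4300 - 1 + 240, "ATT")  # MT-ND2 codon 81: T>A -> ATA missense
    _plant_codon(seq, 13900 - 1 + 360, "CTA")  # MT-CYB codon 121: A>G -> CTG synonymous
    # MT-ND6 (- strand): CDS codon 51 = TTC (Phe); genomic carries the
    # reverse complement, so genomic positions 13672..13674 hold G,A,A.
    nd6_end = 13824
    for off, base in zip((150, 151, 152), "TTC"):
        seq[nd6_end - 1 - off] = COMPLEMENT[base]
    seq[nd6_end - 1 - 153] = "C"  # flank guards against A-runs
    seq[nd6_end - 1 - 149] = "C"

    ref = CircularReference(name=ref.name, sequence="".join(seq), genes=ref.genes)

    founders = (
        FounderVariant(pos=8, af=0.25),  # D-loop, 8 bp from the origin
        FounderVariant(pos=6200, af=0.30, ref="C", alt="T"),  # CO1 stop-gain
        FounderVariant(pos=12151, af=0.60, ref="C", alt="T"),  # ND5 missense, high AF
        FounderVariant(pos=4542, af=0.18, ref="T", alt="A", haplotype=1),  # linked trio
        FounderVariant(pos=14262, af=0.18, ref="A", alt="G", haplotype=1),
        FounderVariant(pos=2000, af=0.18, haplotype=1),  # rRNA member of the trio
        FounderVariant(pos=13672, af=0.22, ref="G", alt="T"),  # ND6 (-) missense
        FounderVariant(pos=8600, af=0.12, alt="DEL"),  # ATP6 frameshift deletion
        FounderVariant(pos=15100, af=0.10),  # untranscribed -> DNA-specific
        FounderVariant(pos=15600, af=0.07),  # untranscribed -> DNA-specific
        FounderVariant(pos=900, af=0.05),  # rRNA, low AF
        FounderVariant(pos=10700, af=0.03),  # mostly below the 0.04 floor
    )
    rna_specific = (
        FounderVariant(pos=720, af=0.35),
        FounderVariant(pos=2155, af=0.20),
        FounderVariant(pos=6800, af=0.15),
        FounderVariant(pos=9500, af=0.10),
        FounderVariant(pos=10900, af=0.08),
        FounderVariant(pos=14500, af=0.05),
    )
    config = SimulationConfig(
        seed=seed,
        founder_variants=founders,
        rna=RNAConfig(rna_specific_variants=rna_specific),
    )
    return config, ref


# ---------------------------------------------------------------------------
# cohort orchestration and fixture output
# ---------------------------------------------------------------------------


@dataclass
class SyntheticCohort:
    """Everything one simulated study produces."""

    config: SimulationConfig
    ref: CircularReference
    dna_truth: list[CellTruth]
    dna_counts: AlleleCountMatrix
    low_depth_cells: list[str]
    rna_truth: list[CellTruth]
    rna: RNAArm

    def conditions(self, arm: str = "dna") -> dict[str, str]:
        truth = self.dna_truth if arm == "dna" else self.rna_truth
        return {c.cell_id: c.condition for c in truth}


def simulate_cohort(
    config: SimulationConfig, ref: CircularReference
) -> SyntheticCohort:
    """Run lineage drift and both sequencing arms from one seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    dna_truth = simulate_lineage(config, rng)

    # pick fragment-QC casualties, balanced across conditions as in the study
    by_cond: dict[str, list[str]] = {"induced": [], "noninduced": []}
    for c in dna_truth:
        by_cond[c.condition].append(c.cell_id)
    n_low = config.n_low_depth_cells
    low: list[str] = []
    for cond, want in (("induced", n_low // 2), ("noninduced", n_low - n_low // 2)):
        pool = by_cond[cond]
        if pool:
            low.extend(
                str(c) for c in rng.choice(pool, size=min(want, len(pool)), replace=False)
            )
    dna_counts = simulate_dna_counts(dna_truth, ref, config, rng, low_depth_cells=low)

    rna_cfg = dataclasses.replace(config, n_cells=config.rna.n_cells)
    rna_truth = simulate_lineage(rna_cfg, rng)
    for c in rna_truth:
        c.cell_id = "r" + c.cell_id
    rna = simulate_rna_arm(rna_truth, ref, config, rng)
    return SyntheticCohort(
        config=config,
        ref=ref,
        dna_truth=dna_truth,
        dna_counts=dna_counts,
        low_depth_cells=sorted(low),
        rna_truth=rna_truth,
        rna=rna,
    )


def write_fixture(cohort: SyntheticCohort, out_dir) -> None:
    """Write the cohort as plain-text files: FASTA, TSVs, VCF, MTX, manifest.

    Output is a pure function of the configuration seed: the same seed
    produces byte-identical files.
    """
    import os

    from scipy.io import mmwrite
    from scipy.sparse import csr_matrix

    os.makedirs(out_dir, exist_ok=True)
    ref = cohort.ref
    with open(os.path.join(out_dir, "reference.fasta"), "w") as fh:
        fh.write(f">{ref.name}\n")
        for i in range(0, ref.length, 70):
            fh.write(ref.sequence[i : i + 70] + "\n")
    write_annotation_table(ref.genes, os.path.join(out_dir, "genes.tsv"))

    # ground-truth VCF with per-cell true AF sample fields
    by_pos = {fv.pos: fv for fv in cohort.config.founder_variants}
    positions = sorted({p for c in cohort.dna_truth for p in c.true_af})
    cells = [c.cell_id for c in cohort.dna_truth]
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={ref.name},length={ref.length}>",
        '##FORMAT=<ID=AF,Number=1,Type=Float,Description="True cell allele frequency">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(cells),
    ]
    for pos in positions:
        ref_base = ref.base(pos)
        alt = resolve_alt(ref_base, by_pos.get(pos))
        alt_field = alt if alt in "ACGT" else f"<{alt}>"
        sample = "\t".join(f"{c.true_af.get(pos, 0.0):.6g}" for c in cohort.dna_truth)
        lines.append(
            f"{ref.name}\t{pos}\t.\t{ref_base}\t{alt_field}\t.\tPASS\t.\tAF\t{sample}"
        )
    with open(os.path.join(out_dir, "truth.vcf"), "w") as fh:
        fh.write("\n".join(lines) + "\n")

    cohort.dna_counts.to_tsv(os.path.join(out_dir, "dna_counts.tsv"))
    cohort.rna.counts.to_tsv(os.path.join(out_dir, "rna_counts.tsv"))

    gc = cohort.rna.gene_counts
    mmwrite(
        os.path.join(out_dir, "gene_counts.mtx"),
        csr_matrix(gc.to_numpy()),
    )
    with open(os.path.join(out_dir, "gene_counts_genes.txt"), "w") as fh:
        fh.write("\n".join(gc.columns) + "\n")
    with open(os.path.join(out_dir, "gene_counts_cells.txt"), "w") as fh:
        fh.write("\n".join(gc.index) + "\n")

    manifest = dataclasses.asdict(cohort.config)
    manifest["low_depth_cells"] = cohort.low_depth_cells
    manifest["reference_name"] = ref.name
    manifest["reference_length"] = ref.length
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=list)
        fh.write("\n")
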