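"""Read- and cell-level quality control.

Three filters gate the analysis, mirroring how the two assays fail in
practice.  The DNA arm amplifies the mitochondrial circle as two long-range
PCR fragments, and per-cell amplification bias between them can leave one
fragment too shallow to call: cells with a mean per-base depth below 1000
in either fragment window are removed (strict), and cells with more than
80% of depth in one fragment are flagged but kept.  The RNA arm suffers
polyA contamination (runs of >= 5 A's are masked to N so they feed no
pileup) and its cells must look alive: mitochondrial read fraction < 17%,
2100 < expressed features < 4000 (both bounds strict, as printed), and a
mean mitochondrial per-base depth of at least 50.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: QC thresholds, overridable per call.
FRAGMENT_WINDOW_X = (2000, 7000)
FRAGMENT_WINDOW_Y = (10000, 15000)
MIN_FRAGMENT_MEAN_DEPTH = 1000.0
IMBALANCE_PROPORTION = 0.8
MAX_MITO_FRACTION = 0.17
FEATURE_BOUNDS = (2100, 4000)
MIN_MEAN_MITO_DEPTH = 50.0
POLYA_MIN_RUN = 5


@dataclass
class CellQCRecord:
    """Per-cell QC metrics and verdict; ``passed`` iff no fail reasons."""

    cell_id: str
    mean_depth_x: float | None = None
    mean_depth_y: float | None = None
    fragment_proportion_y: float | None = None
    mito_fraction: float | None = None
    n_features: int | None = None
    mean_mito_depth: float | None = None
    fail_reasons: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not self.fail_reasons


def mask_polyA(read_sequence: str, k: int = POLYA_MIN_RUN) -> str:
    """Mask every maximal run of >= k consecutive A's to N's.

    Masking (rather than clipping) preserves read coordinates, so pileup
    arithmetic needs no realignment; N bases contribute to no allele count.
    Idempotent, length-preserving, and untouched below the run threshold.
    """
    bad = set(read_sequence) - set("ACGTN")
    if bad:
        raise ValueError(f"read contains non-ACGTN characters: {sorted(bad)}")
    return re.sub(
        "A{%d,}" % k, lambda m: "N" * (m.end() - m.start()), read_sequence
    )


def fragment_depth_qc(
    cell_id: str,
    depth_profile: np.ndarray,
    window_x: tuple[int, int] = FRAGMENT_WINDOW_X,
    window_y: tuple[int, int] = FRAGMENT_WINDOW_Y,
    min_mean_depth: float = MIN_FRAGMENT_MEAN_DEPTH,
    imbalance: float = IMBALANCE_PROPORTION,
) -> CellQCRecord:
    """Two-fragment depth QC for one cell of the DNA arm.

    ``depth_profile`` is per-position depth with index 0 = position 1.
    Window bounds are 1-based inclusive; the mean is over every position in
    the window.  Failure (``low_fragment_depth``) is strict: a mean exactly
    at ``min_mean_depth`` passes.  Fragment imbalance beyond ``imbalance``
    in either direction earns a non-fatal ``fragment_imbalance`` warning --
    such cells were retained in the source protocol.
    """
    profile = np.asarray(depth_profile, dtype=float)
    for lo, hi in (window_x, window_y):
        if lo < 1 or hi > len(profile):
            raise ValueError(
                f"window [{lo}, {hi}] outside depth profile of length {len(profile)}"
            )
    mean_x = float(profile[window_x[0] - 1 : window_x[1]].mean())
    mean_y = float(profile[window_y[0] - 1 : window_y[1]].mean())
    rec = CellQCRecord(cell_id=cell_id, mean_depth_x=mean_x, mean_depth_y=mean_y)
    if mean_x + mean_y > 0:
        rec.fragment_proportion_y = mean_y / (mean_x + mean_y)
    if mean_x < min_mean_depth or mean_y < min_mean_depth:
        rec.fail_reasons.append("low_fragment_depth")
    if rec.fragment_proportion_y is not None and (
        rec.fragment_proportion_y > imbalance
        or 1.0 - rec.fragment_proportion_y > imbalance
    ):
        rec.warnings.append("fragment_imbalance")
    return rec


def absolute_fragment_differential(
    records: list[CellQCRecord],
) -> tuple[float, float]:
    """Mean and sample SD of |mean_depth_X - mean_depth_Y| over passing cells."""
    diffs = [
        abs(r.mean_depth_x - r.mean_depth_y)
        for r in records
        if r.passed and r.mean_depth_x is not None and r.mean_depth_y is not None
    ]
    if len(diffs) < 2:
        raise ValueError(
            f"need >= 2 passing cells with fragment depths, have {len(diffs)}"
        )
    arr = np.asarray(diffs)
    return float(arr.mean()), float(arr.std(ddof=1))


def rna_cell_qc(
    cell_id: str,
    gene_counts: pd.Series,
    mito_depth_profile: np.ndarray,
    max_mito_fraction: float = MAX_MITO_FRACTION,
    feature_bounds: tuple[int, int] = FEATURE_BOUNDS,
    min_mean_mito_depth: float = MIN_MEAN_MITO_DEPTH,
    mito_prefix: str = "MT-",
) -> CellQCRecord:
    """Live/high-quality cell filter for the RNA arm.

    ``gene_counts`` is the cell's expression vector (mitochondrial genes
    identified by ``mito_prefix``); ``mito_depth_profile`` is its per-base
    mitochondrial pileup depth over the transcribed intervals.  A cell
    passes iff mito fraction < ``max_mito_fraction`` AND
    ``feature_bounds[0] < n_features < feature_bounds[1]`` (all strict) AND
    mean mito depth >= ``min_mean_mito_depth``.  All violated rules are
    listed, not just the first.
    """
    if (gene_counts < 0).any():
        raise ValueError("gene counts must be non-negative")
    is_mito = gene_counts.index.str.startswith(mito_prefix)
    total = float(gene_counts.sum())
    mito_fraction = float(gene_counts[is_mito].sum()) / total if total > 0 else 0.0
    n_features = int((gene_counts > 0).sum())
    mean_depth = float(np.asarray(mito_depth_profile, dtype=float).mean())
    rec = CellQCRecord(
        cell_id=cell_id,
        mito_fraction=mito_fraction,
        n_features=n_features,
        mean_mito_depth=mean_depth,
    )
    if not mito_fraction < max_mito_fraction:
        rec.fail_reasons.append("high_mito_fraction")
    if not feature_bounds[0] < n_features < feature_bounds[1]:
        rec.fail_reasons.append("n_features_out_of_bounds")
    if mean_depth < min_mean_mito_depth:
        rec.fail_reasons.append("low_mito_depth")
    return rec


def qc_table(records: list[CellQCRecord]) -> pd.DataFrame:
    """One row per cell; list fields joined with ';' for TSV output."""
    rows = []
    for r in records:
        rows.append(
            {
                "cell_id": r.cell_id,
                "mean_depth_x": r.mean_depth_x,
                "mean_depth_y": r.mean_depth_y,
                "fragment_proportion_y": r.fragment_proportion_y,
                "mito_fraction": r.mito_fraction,
                "n_features": r.n_features,
                "mean_mito_depth": r.mean_mito_depth,
                "passed": r.passed,
                "fail_reasons": ";".join(r.fail_reasons),
                "warnings": ";".join(r.warnings),
            }
        )
    return pd.DataFrame(rows)
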