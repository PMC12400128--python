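"""Report rendering: TSV tables, figures and a run manifest.

Tables are written deterministically (same inputs -> byte-identical
files); figures are violin / heatmap / scatter analogues of the standard
heteroplasmy views.  Nothing here computes -- it serialises what upstream
stages produced.
"""

from __future__ import annotations

import json
import os

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .calling import VariantCall


def af_matrix(calls: list[VariantCall], cells: list[str]) -> pd.DataFrame:
    """Mutations x cells AF table (NaN where undefined)."""
    data = {
        call.label: [call.af.get(c, np.nan) for c in cells] for call in calls
    }
    return pd.DataFrame(data, index=cells).T


def classification_table(classified) -> pd.DataFrame:
    """One row per mutation: position, alleles, effect and list membership."""
    rows = []
    for cm in classified:
        rows.append(
            {
                "pos": cm.call.pos,
                "ref": cm.call.ref_allele,
                "alt": cm.call.alt_allele,
                "gene": cm.effect.gene or "",
                "effect": cm.effect.effect,
                "impact": cm.effect.impact,
                "aa_change": cm.effect.aa_change,
                "n_het_cells": cm.n_cells_heteroplasmic,
                "frac_het_cells": cm.frac_cells_heteroplasmic,
                "max_af": cm.max_af,
                "most_variable": cm.in_most_variable,
                "most_impactful": cm.in_most_impactful,
                "joint_impactful": cm.in_joint_impactful,
            }
        )
    columns = [
        "pos", "ref", "alt", "gene", "effect", "impact", "aa_change",
        "n_het_cells", "frac_het_cells", "max_af",
        "most_variable", "most_impactful", "joint_impactful",
    ]
    if not rows:
        return pd.DataFrame(columns=columns)
    return pd.DataFrame(rows, columns=columns).sort_values(["pos", "alt"]).reset_index(drop=True)


def _violin(ax, data: pd.DataFrame, title: str) -> None:
    cols = [c for c in data.index if data.loc[c].notna().any()]
    if cols:
        ax.violinplot(
            [data.loc[c].dropna().to_numpy() for c in cols], showmedians=True
        )
        ax.set_xticks(range(1, len(cols) + 1), cols, rotation=90, fontsize=6)
    ax.set_ylabel("allele frequency")
    ax.set_title(title)


def render_report(
    out_dir,
    *,
    qc: pd.DataFrame | None = None,
    classified: pd.DataFrame | None = None,
    comparisons: pd.DataFrame | None = None,
    modality: pd.DataFrame | None = None,
    variable_af: pd.DataFrame | None = None,
    impactful_af: pd.DataFrame | None = None,
    events: pd.DataFrame | None = None,
    manifest: dict | None = None,
) -> list[str]:
    """Write every provided table/figure; returns the paths written.

    Empty inputs produce zero-row tables rather than errors, so a run with
    no calls still renders a complete (if vacuous) report.
    """
    os.makedirs(out_dir, exist_ok=True)
    written: list[str] = []

    tables = {
        "qc.tsv": qc,
        "classification.tsv": classified,
        "comparisons.tsv": comparisons,
        "modality.tsv": modality,
    }
    for name, table in tables.items():
        if table is None:
            continue
        path = os.path.join(out_dir, name)
        table.to_csv(path, sep="\t", index=False)
        written.append(path)

    if variable_af is not None:
        fig, ax = plt.subplots(figsize=(8, 4))
        _violin(ax, variable_af, "most variable mutations")
        path = os.path.join(out_dir, "most_variable_violin.png")
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)

    if impactful_af is not None:
        fig, ax = plt.subplots(figsize=(8, 4))
        arr = impactful_af.to_numpy(dtype=float)
        im = ax.imshow(arr, aspect="auto", cmap="viridis", vmin=0, vmax=1)
        ax.set_yticks(range(len(impactful_af.index)), impactful_af.index, fontsize=6)
        ax.set_xlabel("cell")
        ax.set_title("most impactful mutations: per-cell AF")
        fig.colorbar(im, ax=ax, label="AF")
        path = os.path.join(out_dir, "most_impactful_heatmap.png")
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)

    if events is not None and len(events):
        fig, ax = plt.subplots(figsize=(4, 4))
        groups = sorted(events["condition"].unique())
        ax.violinplot(
            [events.loc[events["condition"] == g, "events"].to_numpy() for g in groups],
            showmedians=True,
        )
        ax.set_xticks(range(1, len(groups) + 1), groups)
        ax.set_ylabel("heteroplasmic events per cell")
        path = os.path.join(out_dir, "events_per_cell_violin.png")
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)

    if modality is not None and len(modality):
        fig, ax = plt.subplots(figsize=(4.5, 4.5))
        eps = 1e-4
        ax.scatter(modality["dna_af"] + eps, modality["rna_af"] + eps, s=12)
        lim = (eps, 1.5)
        ax.plot(lim, lim, "k--", lw=0.8)
        ax.set_xscale("log")
        ax.set_yscale("log")
        ax.set_xlabel("DNA pseudobulk AF")
        ax.set_ylabel("RNA pseudobulk AF")
        path = os.path.join(out_dir, "modality_scatter.png")
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)

    if manifest is not None:
        path = os.path.join(out_dir, "manifest.json")
        with open(path, "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
            fh.write("\n")
        written.append(path)
    return written
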