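"""Condition and modality comparisons, and summary statistics.

Covers the statistical surface of the analysis: bulk-versus-single-cell
mean allele frequencies (sub-0.04 AFs counted as 0 in the single-cell
mean, which is why single-cell averages sit slightly below the pooled
bulk), Student's pooled-variance t-tests of induced versus noninduced AF
distributions and of heteroplasmic events per cell, Pearson correlation of
AF against transcript abundance (optionally restricted to cells above an
AF threshold, with n reported so low-n r values can be discounted), a
quartile-split rank-sum differential-expression scan with
Benjamini-Hochberg correction, and a bulk time-course range summary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .calling import VariantCall
from .classify import HET_CEILING, HET_FLOOR, events_per_cell

logger = logging.getLogger(__name__)

ZERO_BELOW = 0.04
MIN_GROUP_SIZE = 2


@dataclass
class GroupComparisonResult:
    mutation: str
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    statistic: float
    p_value: float
    adjusted_p: float | None = None


def single_cell_mean_af(call: VariantCall, zero_below: float = ZERO_BELOW) -> float:
    """Mean AF over defined cells with sub-threshold AFs counted as 0.

    Mirrors how a bulk comparison is made against single-cell data: any AF
    below the heteroplasmy floor in an individual cell is not a call there
    and contributes 0, which biases the single-cell mean below the pooled
    (pseudobulk) AF whenever such cells exist.
    """
    if call.n_defined() == 0:
        raise ValueError(f"no cells with defined AF for {call.label}")
    vals = [af if af >= zero_below else 0.0 for af in call.af.values()]
    return float(np.mean(vals))


def compare_conditions(
    calls: list[VariantCall],
    labels: dict[str, str],
    group_a: str = "induced",
    group_b: str = "noninduced",
    min_group: int = MIN_GROUP_SIZE,
    equal_var: bool = True,
) -> list[GroupComparisonResult]:
    """Two-sided two-sample t-test of AF per mutation between conditions.

    Student's pooled-variance test by default (``equal_var=False`` switches
    to Welch).  A mutation is tested only when both groups have at least
    ``min_group`` cells with a defined AF; otherwise it is skipped and
    logged.  One additional test compares heteroplasmic events per cell
    between the conditions (reported as mutation
    ``heteroplasmic_events_per_cell``).  No across-mutation multiple-testing
    correction is applied here.
    """
    results: list[GroupComparisonResult] = []
    for call in calls:
        a = [af for cell, af in call.af.items() if labels.get(cell) == group_a]
        b = [af for cell, af in call.af.items() if labels.get(cell) == group_b]
        if len(a) < min_group or len(b) < min_group:
            logger.info(
                "skipping %s: group sizes %d vs %d below %d",
                call.label, len(a), len(b), min_group,
            )
            continue
        t, p = stats.ttest_ind(a, b, equal_var=equal_var)
        results.append(
            GroupComparisonResult(
                mutation=call.label,
                group_a=group_a,
                group_b=group_b,
                n_a=len(a),
                n_b=len(b),
                mean_a=float(np.mean(a)),
                mean_b=float(np.mean(b)),
                statistic=float(t),
                p_value=float(p),
            )
        )

    cells = sorted({c for call in calls for c in call.depth})
    ev_a = [
        events_per_cell(calls, c, known_cells=cells)
        for c in cells
        if labels.get(c) == group_a
    ]
    ev_b = [
        events_per_cell(calls, c, known_cells=cells)
        for c in cells
        if labels.get(c) == group_b
    ]
    if len(ev_a) >= min_group and len(ev_b) >= min_group:
        t, p = stats.ttest_ind(ev_a, ev_b, equal_var=equal_var)
        results.append(
            GroupComparisonResult(
                mutation="heteroplasmic_events_per_cell",
                group_a=group_a,
                group_b=group_b,
                n_a=len(ev_a),
                n_b=len(ev_b),
                mean_a=float(np.mean(ev_a)),
                mean_b=float(np.mean(ev_b)),
                statistic=float(t),
                p_value=float(p),
            )
        )
    return results


@dataclass
class CorrelationResult:
    r: float | None
    p_value: float | None
    n: int
    reason: str | None = None  # set when undefined (e.g. low_n)


def af_expression_correlation(
    af: dict[str, float],
    transcript: dict[str, float],
    min_af: float | None = None,
) -> CorrelationResult:
    """Pearson r between AF and transcript abundance over qualifying cells.

    ``min_af`` restricts to cells strictly above the threshold (the
    above-phenotypic-threshold repeat of the analysis).  With fewer than 3
    pairs the correlation is undefined and a reason is returned instead of
    an unstable r; ``n`` is always reported so small-n correlations can be
    flagged.
    """
    cells = sorted(set(af) & set(transcript))
    if min_af is not None:
        cells = [c for c in cells if af[c] > min_af]
    if len(cells) < 3:
        return CorrelationResult(r=None, p_value=None, n=len(cells), reason="low_n")
    x = np.array([af[c] for c in cells])
    y = np.array([transcript[c] for c in cells])
    if np.all(x == x[0]) or np.all(y == y[0]):
        return CorrelationResult(
            r=None, p_value=None, n=len(cells), reason="constant_input"
        )
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(r=float(r), p_value=float(p), n=len(cells))


def quartile_expression_test(
    expression: pd.DataFrame,
    af: pd.Series,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Rank-sum differential expression between AF quartiles.

    Cells are split at the 25th/75th AF percentiles (boundary ties assigned
    to the extreme groups, which maximises n and is deterministic); each
    gene is compared top-vs-bottom with a two-sided Mann-Whitney U test and
    p values are BH-adjusted across genes.  Returns one row per gene with
    ``significant`` marking adjusted p < alpha.  Degenerate quartiles (all
    AFs identical, or fewer than 4 cells) yield an empty frame and a log
    entry rather than an error.
    """
    common = expression.index.intersection(af.index)
    expression = expression.loc[common]
    af = af.loc[common]
    empty = pd.DataFrame(
        columns=["gene", "statistic", "p_value", "adjusted_p", "significant"]
    )
    if len(af) < 4:
        logger.info("quartile test skipped: only %d cells with AF", len(af))
        return empty
    q1, q3 = np.quantile(af.to_numpy(), [0.25, 0.75])
    if q1 == q3:
        logger.info("quartile test skipped: degenerate quartiles (q1 == q3 == %g)", q1)
        return empty
    bottom = expression.loc[af <= q1]
    top = expression.loc[af >= q3]
    stat, p = stats.mannwhitneyu(
        top.to_numpy(), bottom.to_numpy(), alternative="two-sided", axis=0
    )
    _, p_adj, _, _ = multipletests(p, method="fdr_bh")
    return pd.DataFrame(
        {
            "gene": expression.columns,
            "statistic": stat,
            "p_value": p,
            "adjusted_p": p_adj,
            "significant": p_adj < alpha,
        }
    )


def bulk_timecourse_summary(
    bulk_afs: dict[object, dict[str, float]],
    stable_range: float = 0.10,
) -> pd.DataFrame:
    """Per-site min/max/range over bulk time points, flagging stable sites.

    ``bulk_afs`` maps time point -> {site label -> AF}; sites absent at a
    time point count as AF 0 there.  ``stable`` means range <= the
    configurable threshold (a reporting convenience, default 0.10).
    """
    times = sorted(bulk_afs)
    if len(times) < 2:
        raise ValueError("need >= 2 time points")
    sites = sorted({s for t in times for s in bulk_afs[t]})
    rows = []
    for site in sites:
        series = {t: bulk_afs[t].get(site, 0.0) for t in times}
        vals = np.array(list(series.values()))
        row = {"site": site}
        row.update({f"af_t{t}": v for t, v in series.items()})
        row["min_af"] = float(vals.min())
        row["max_af"] = float(vals.max())
        row["range"] = float(vals.max() - vals.min())
        row["stable"] = bool(row["range"] <= stable_range)
        rows.append(row)
    return pd.DataFrame(rows)


def comparison_table(results: list[GroupComparisonResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "mutation": r.mutation,
                "group_a": r.group_a,
                "group_b": r.group_b,
                "n_a": r.n_a,
                "n_b": r.n_b,
                "mean_a": r.mean_a,
                "mean_b": r.mean_b,
                "statistic": r.statistic,
                "p_value": r.p_value,
                "adjusted_p": r.adjusted_p,
            }
            for r in results
        ]
    )


__all__ = [
    "GroupComparisonResult",
    "CorrelationResult",
    "single_cell_mean_af",
    "compare_conditions",
    "af_expression_correlation",
    "quartile_expression_test",
    "bulk_timecourse_summary",
    "comparison_table",
    "HET_FLOOR",
    "HET_CEILING",
]
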