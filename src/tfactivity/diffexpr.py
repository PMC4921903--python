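"""Fold-change classification and genome-fraction-changed summaries.

A gene is called responsive at a sampling point when its transcript level
is at least ``up_threshold``-fold above, or at most ``down_threshold`` of,
the pre-treatment level (defaults 2.0 and 0.5, both boundaries inclusive).
Expression values are log2 ratios to the minute-0 baseline, so the linear
ratio is ``2**value``.  Missing measurements propagate as ``missing`` calls
and are excluded from denominators; they are never treated as unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CategoryMap, ExpressionTimeCourse, TableFormatError

UP, DOWN, UNCHANGED, MISSING = "up", "down", "unchanged", "missing"


@dataclass(frozen=True)
class RegulationCalls:
    """Per-gene, per-timepoint regulation calls over the non-baseline grid."""

    gene_ids: tuple[str, ...]
    timepoints_min: tuple[float, ...]  # non-baseline sampling points, ascending
    calls: np.ndarray  # (n_genes, n_timepoints) of {up,down,unchanged,missing}
    ratios: np.ndarray  # linear fold ratios, NaN where missing
    up_threshold: float
    down_threshold: float

    def timepoint_index(self, timepoint: float) -> int:
        try:
            return self.timepoints_min.index(float(timepoint))
        except ValueError:
            raise KeyError(
                f"timepoint {timepoint} min not among {list(self.timepoints_min)}"
            ) from None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, g in enumerate(self.gene_ids):
            for j, t in enumerate(self.timepoints_min):
                rows.append(
                    {"gene": g, "minute": t, "call": self.calls[i, j], "ratio": self.ratios[i, j]}
                )
        return pd.DataFrame(rows)


def classify_regulation(
    expr: ExpressionTimeCourse,
    up_threshold: float = 2.0,
    down_threshold: float = 0.5,
) -> RegulationCalls:
    """Call each gene up/down/unchanged at every non-baseline timepoint.

    Thresholds are linear ratios with ``down_threshold <= 1 <= up_threshold``;
    ratios exactly on a threshold count as changed (inclusive boundaries).
    """
    if not (down_threshold <= 1.0 <= up_threshold):
        raise ValueError(
            f"thresholds must satisfy down <= 1 <= up, got ({down_threshold}, {up_threshold})"
        )
    mask = np.array([t > 0 for t in expr.timepoints_min])
    if not mask.any():
        raise TableFormatError("expression matrix has no non-baseline timepoints")
    values = expr.values[:, mask]
    ratios = np.exp2(values)
    calls = np.full(ratios.shape, UNCHANGED, dtype=object)
    with np.errstate(invalid="ignore"):
        calls[ratios >= up_threshold] = UP
        calls[ratios <= down_threshold] = DOWN
    calls[np.isnan(ratios)] = MISSING
    return RegulationCalls(
        gene_ids=expr.gene_ids,
        timepoints_min=tuple(t for t in expr.timepoints_min if t > 0),
        calls=calls,
        ratios=ratios,
        up_threshold=up_threshold,
        down_threshold=down_threshold,
    )


def fraction_changed(calls: RegulationCalls, timepoint: float) -> float:
    """Fraction of non-missing genes called up or down at one timepoint.

    The denominator is genes measured (non-missing) at that timepoint — the
    genome fraction is relative to what the array reports, not to an external
    genome annotation.
    """
    j = calls.timepoint_index(timepoint)
    col = calls.calls[:, j]
    n_obs = int(np.sum(col != MISSING))
    if n_obs == 0:
        raise TableFormatError(f"all genes missing at {timepoint} min")
    n_changed = int(np.sum((col == UP) | (col == DOWN)))
    return n_changed / n_obs


@dataclass(frozen=True)
class CategorySummary:
    category: str
    n_genes: int
    n_up: int
    n_down: int
    percent_up: float
    percent_down: float


def category_summary(
    calls: RegulationCalls, categories: CategoryMap, timepoint: float
) -> list[CategorySummary]:
    """Per-category percentages of up- and down-regulated genes at one timepoint.

    Percentages are relative to the genes of that category present in the
    expression matrix; up and down are reported separately and need not sum
    to 100.  Categories with no genes in the matrix get zero counts and
    ``n_genes = 0``.
    """
    j = calls.timepoint_index(timepoint)
    tallies: dict[str, list[int]] = {c: [0, 0, 0] for c in categories.categories}
    for i, gene in enumerate(calls.gene_ids):
        cat = categories.category(gene)
        tallies.setdefault(cat, [0, 0, 0])
        tallies[cat][0] += 1
        if calls.calls[i, j] == UP:
            tallies[cat][1] += 1
        elif calls.calls[i, j] == DOWN:
            tallies[cat][2] += 1
    out = []
    for cat in sorted(tallies):
        n, n_up, n_down = tallies[cat]
        out.append(
            CategorySummary(
                category=cat,
                n_genes=n,
                n_up=n_up,
                n_down=n_down,
                percent_up=100.0 * n_up / n if n else 0.0,
                percent_down=100.0 * n_down / n if n else 0.0,
            )
        )
    return out


def time_strip(
    expr: ExpressionTimeCourse, gene_list: list[str]
) -> tuple[pd.DataFrame, list[str]]:
    """Ordered per-gene log2 profiles over the non-baseline sampling points.

    Returns a genes x minutes frame (heat-strip export) plus the list of
    requested genes absent from the matrix; absent genes are reported, never
    silently dropped.
    """
    mask = [t > 0 for t in expr.timepoints_min]
    minutes = [t for t in expr.timepoints_min if t > 0]
    found = [g for g in gene_list if g in expr.gene_ids]
    not_found = [g for g in gene_list if g not in expr.gene_ids]
    idx = [expr.gene_index(g) for g in found]
    frame = pd.DataFrame(expr.values[np.ix_(idx, np.where(mask)[0])], index=found, columns=minutes)
    return frame, not_found
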