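"""Ranked-expression check that immune signal comes from infiltrate.

Within each sample every gene is ranked by expression (1 = lowest, ties
averaged). If the immune marker genes rank high in tumours but near the
middle or bottom in cancer cell lines — which contain no infiltrating immune
cells — the marker signal in bulk tumours must originate from the tumour
microenvironment rather than from cancer cells themselves.

Ranks are invariant to any strictly increasing transform, so the check is
insensitive to whether the matrix is TPM or log TPM. Percentile ranks
(rank / number of genes) make matrices with different gene counts
comparable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from scipy.stats import mannwhitneyu, rankdata

from .cohort_io import ExpressionMatrix, MarkerPanel

log = logging.getLogger(__name__)


@dataclass
class RankProfile:
    """Per-sample within-sample gene ranks (1 = lowest; ties averaged)."""

    ranks: pd.DataFrame  # genes x samples
    n_genes: int

    @property
    def percentiles(self) -> pd.DataFrame:
        return self.ranks / self.n_genes


def rank_genes(expr: ExpressionMatrix) -> RankProfile:
    """Rank genes within each sample, averaging tied values."""
    if expr.data.shape[0] < 2:
        raise ValueError("ranking needs at least 2 genes")
    ranks = pd.DataFrame(
        rankdata(expr.data.to_numpy(), axis=0),
        index=expr.data.index,
        columns=expr.data.columns,
    )
    return RankProfile(ranks=ranks, n_genes=expr.data.shape[0])


def mean_immune_rank(
    profile: RankProfile,
    panel: MarkerPanel,
    groups: pd.Series | None = None,
) -> pd.DataFrame:
    """Mean rank (and percentile) of each marker gene within each group.

    `groups` maps sample id -> group label (e.g. cancer type); omitted means
    one pooled group. Returns long-form rows (group, gene, mean_rank,
    mean_percentile, n_samples).
    """
    samples = profile.ranks.columns
    if groups is None:
        groups = pd.Series("all", index=samples)
    groups = groups.reindex(samples)
    marker_rows = profile.ranks.loc[[g for g in panel.genes if g in profile.ranks.index]]
    if marker_rows.empty:
        raise ValueError("no marker genes present in the matrix")
    rows = []
    for key, cols in marker_rows.T.groupby(groups, sort=False).groups.items():
        if len(cols) == 0:
            raise ValueError(f"empty sample group {key!r}")
        block = marker_rows[list(cols)]
        mr = block.mean(axis=1)
        for gene, val in mr.items():
            rows.append({
                "group": key, "gene": gene,
                "mean_rank": float(val),
                "mean_percentile": float(val) / profile.n_genes,
                "n_samples": len(cols),
            })
    return pd.DataFrame(rows)


def sample_mean_marker_percentile(
    profile: RankProfile, panel: MarkerPanel
) -> pd.Series:
    """Per-sample mean percentile rank over the panel's marker genes."""
    present = [g for g in panel.genes if g in profile.ranks.index]
    if not present:
        raise ValueError("no marker genes present in the matrix")
    s = profile.percentiles.loc[present].mean(axis=0)
    s.name = "mean_marker_percentile"
    return s


def compare_tumour_vs_cellline(
    tumour: pd.Series,
    cellline: pd.Series,
) -> dict:
    """One-sided rank-sum test that tumour marker percentiles exceed cell lines.

    Inputs are per-sample mean marker percentiles (from
    :func:`sample_mean_marker_percentile`) for the two arms of one matched
    tissue. Returns the group means, their difference, and the one-sided
    Wilcoxon rank-sum p-value (tumour greater).
    """
    if len(tumour) == 0 or len(cellline) == 0:
        raise ValueError("both groups must be non-empty")
    if len(tumour) < 2 or len(cellline) < 2:
        log.warning("tumour-vs-cell-line test with a singleton group is degenerate")
    stat, p = mannwhitneyu(tumour, cellline, alternative="greater")
    return {
        "n_tumour": int(len(tumour)),
        "n_cellline": int(len(cellline)),
        "mean_tumour": float(tumour.mean()),
        "mean_cellline": float(cellline.mean()),
        "effect": float(tumour.mean() - cellline.mean()),
        "statistic": float(stat),
        "p_value": float(p),
    }
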