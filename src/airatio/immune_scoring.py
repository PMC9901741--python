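"""Marker-gene immune cell-type scores and the total TIL score.

Each cell type's score for a sample is the unweighted mean of the
log2(TPM+1) expression of its marker genes (Danaher-style). No per-gene
standardisation is applied before averaging. The total tumour-infiltrating
leukocyte (TIL) score is the mean over all panel cell types, including any
cell types excluded from the adaptive/innate compartment ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .cohort_io import Cohort, CohortError


@dataclass
class CellTypeScores:
    """Per-sample cell-type scores (log2 scale) plus the TIL score."""

    scores: pd.DataFrame  # samples x cell types, log2(TPM+1) scale
    til: pd.Series  # per-sample TIL score

    @property
    def samples(self) -> list[str]:
        return self.scores.index.tolist()

    @property
    def cell_types(self) -> list[str]:
        return self.scores.columns.tolist()

    def write_tsv(self, path) -> None:
        out = self.scores.copy()
        out["TIL_score"] = self.til
        out.index.name = "sample_id"
        out.to_csv(path, sep="\t")


def score_cell_types(cohort: Cohort) -> CellTypeScores:
    """Score every panel cell type in every sample.

    Expression supplied on the linear TPM scale is converted to log2(TPM+1)
    first, so scores are always on the log2 scale. Marker genes absent from
    the matrix are skipped (coverage was validated at join time); a cell type
    with no present markers at all is a hard error.
    """
    logexpr = cohort.expr.to_log2p1().data
    cols = {}
    for ct in cohort.panel.cell_types:
        present = cohort.present_markers(ct)
        if not present:
            raise CohortError(f"cell type {ct!r} has no marker genes in the matrix")
        cols[ct] = logexpr.loc[present].mean(axis=0)
    scores = pd.DataFrame(cols)
    scores = scores[cohort.panel.cell_types]
    return CellTypeScores(scores=scores, til=til_score(scores))


def til_score(scores: pd.DataFrame) -> pd.Series:
    """Total TIL score: unweighted mean over all cell-type scores per sample."""
    s = scores.mean(axis=1)
    s.name = "TIL_score"
    return s
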