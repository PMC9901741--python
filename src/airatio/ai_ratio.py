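"""The adaptive-to-innate (A/I) ratio and its stratum labels.

The compartment statistic is cohort-relative: per cell type, scores are
reverse log-transformed back to the linear scale and min-max scaled to [0, 1]
across the scaling scope (the whole cohort by default, optionally per cancer
type):

    scaled = (x - min) / (max - min)

The adaptive score A is the mean of the scaled adaptive cell types
(CD8 T-cells, B-cells, CD45, Cytotoxic cells, T-cells, Th1 cells, Treg), the
innate score I the mean of the scaled innate cell types (Dendritic cells,
Macrophages, Mast cells, Neutrophils, NK cells, NK CD56dim cells), and the
A/I ratio is A / I. Because the scaling extremes are cohort-wide, adding or
removing samples can change every sample's profile — the ratio is comparable
within one analysis cohort, not across cohorts.

Degenerate choices are deterministic: a cell type constant across the scope
scales to 0 everywhere; I = 0 yields a *missing* ratio rather than an
epsilon-inflated infinity; median-split ties go to "low" (high means strictly
above the median).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort_io import MarkerPanel
from .immune_scoring import CellTypeScores

log = logging.getLogger(__name__)


@dataclass
class StratumLabels:
    """Per-sample high/low strata with the medians that defined them."""

    labels: pd.DataFrame  # columns: ai_group, til_group, quadrant (subset ok)
    medians: dict = field(default_factory=dict)  # scope key -> median value


def reverse_log(scores: pd.DataFrame, transform: str = "log2p1") -> pd.DataFrame:
    """Map log2(x+1)-scale values back to the linear scale: x -> 2**x - 1.

    If the values are declared already linear the map is the identity.
    """
    if transform == "linear_tpm":
        return scores.copy()
    return np.exp2(scores) - 1.0


def minmax_scale(
    linear: pd.DataFrame,
    scope: pd.Series | None = None,
) -> pd.DataFrame:
    """Min-max scale each column to [0, 1] within each scope group.

    `linear` is samples x cell types on the linear scale; `scope` is an
    optional per-sample grouping (e.g. cancer type). A column constant within
    a group carries no discriminative signal and maps to 0 with a warning.
    """
    if scope is None:
        scope = pd.Series("__all__", index=linear.index)
    scope = scope.reindex(linear.index)
    sizes = scope.value_counts()
    small = sizes[sizes < 2]
    if not small.empty:
        raise ValueError(f"scaling scope group(s) with < 2 samples: "
                         f"{small.index.tolist()}")
    out = pd.DataFrame(index=linear.index, columns=linear.columns, dtype=float)
    for _, idx in linear.groupby(scope, sort=False).groups.items():
        block = linear.loc[idx]
        lo = block.min(axis=0)
        hi = block.max(axis=0)
        span = hi - lo
        degenerate = span <= 0
        if degenerate.any():
            log.warning("degenerate cell type(s) scaled to 0: %s",
                        span.index[degenerate].tolist())
        span = span.where(~degenerate, 1.0)
        scaled = (block - lo) / span
        scaled.loc[:, degenerate] = 0.0
        out.loc[idx] = scaled
    return out


def compartment_scores(
    scaled: pd.DataFrame, panel: MarkerPanel
) -> tuple[pd.Series, pd.Series]:
    """Mean scaled value over the adaptive and the innate cell types.

    Cell types with compartment ``excluded`` contribute to neither score.
    """
    adaptive = [c for c in panel.by_compartment("adaptive") if c in scaled.columns]
    innate = [c for c in panel.by_compartment("innate") if c in scaled.columns]
    if not adaptive or not innate:
        raise ValueError("both compartments need at least one scaled cell type")
    A = scaled[adaptive].mean(axis=1)
    I = scaled[innate].mean(axis=1)
    A.name, I.name = "A", "I"
    return A, I


def ai_ratio(A: pd.Series, I: pd.Series, *, epsilon: float = 0.0) -> pd.Series:
    """A/I ratio per sample; missing (NaN) where I = 0.

    An optional `epsilon` is added to both numerator and denominator for
    users who need a complete ratio; the default never fabricates values.
    """
    if epsilon > 0:
        ratio = (A + epsilon) / (I + epsilon)
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = A / I
        ratio = ratio.where(I > 0, np.nan)
        n_missing = int((I == 0).sum())
        if n_missing:
            log.info("ai_ratio: %d sample(s) with I = 0 -> missing ratio", n_missing)
    ratio.name = "ai_ratio"
    return ratio


def compute_profiles(
    scores: CellTypeScores,
    panel: MarkerPanel,
    *,
    scope: pd.Series | None = None,
    transform: str = "log2p1",
    epsilon: float = 0.0,
) -> pd.DataFrame:
    """Full per-sample immune profile: scaled cell types, A, I, A/I, TIL.

    Returns a DataFrame indexed by sample with one ``scaled_<cell type>``
    column per cell type plus A, I, ai_ratio and til_score.
    """
    linear = reverse_log(scores.scores, transform)
    scaled = minmax_scale(linear, scope)
    A, I = compartment_scores(scaled, panel)
    ratio = ai_ratio(A, I, epsilon=epsilon)
    prof = scaled.rename(columns=lambda c: f"scaled_{c}")
    prof["A"] = A
    prof["I"] = I
    prof["ai_ratio"] = ratio
    prof["til_score"] = scores.til
    return prof


def median_split(
    values: pd.Series,
    scope: pd.Series | None = None,
    *,
    name: str = "group",
) -> StratumLabels:
    """Label samples high/low against the median of their scope group.

    "High" means strictly greater than the group median; ties are low.
    Missing values are excluded from the median and labelled missing (NaN).
    """
    if scope is None:
        scope = pd.Series("__all__", index=values.index)
    scope = scope.reindex(values.index)
    labels = pd.Series(np.nan, index=values.index, dtype=object)
    medians: dict = {}
    for key, idx in values.groupby(scope, sort=False).groups.items():
        vals = values.loc[idx].dropna()
        if vals.empty:
            continue
        med = float(vals.median())
        medians[key] = med
        labels.loc[vals.index] = np.where(vals > med, "high", "low")
    return StratumLabels(labels=labels.to_frame(name), medians=medians)


def female_median_reference(
    values: pd.Series,
    gender: pd.Series,
    scope: pd.Series | None = None,
    *,
    name: str = "group",
) -> StratumLabels:
    """Label both genders against the *female* median of their scope group.

    Used to test whether male survival improves once males are held to the
    female A/I threshold: males are high iff their value strictly exceeds the
    female median of the same stratum (females are thereby labelled by their
    own median, as usual). A stratum without female samples leaves its males
    unlabelled with a warning.
    """
    if scope is None:
        scope = pd.Series("__all__", index=values.index)
    scope = scope.reindex(values.index)
    gender = gender.reindex(values.index)
    labels = pd.Series(np.nan, index=values.index, dtype=object)
    medians: dict = {}
    for key, idx in values.groupby(scope, sort=False).groups.items():
        fem = values.loc[idx][gender.loc[idx] == "female"].dropna()
        if fem.empty:
            log.warning("no female samples in stratum %r; males left unlabelled", key)
            continue
        med = float(fem.median())
        medians[key] = med
        vals = values.loc[idx].dropna()
        labels.loc[vals.index] = np.where(vals > med, "high", "low")
    return StratumLabels(labels=labels.to_frame(name), medians=medians)


def quadrant_labels(
    ai_values: pd.Series,
    til_values: pd.Series,
    scope: pd.Series | None = None,
) -> StratumLabels:
    """Joint A/I x TIL median-split quadrants (``high/high`` ... ``low/low``)."""
    ai = median_split(ai_values, scope, name="ai_group")
    til = median_split(til_values, scope, name="til_group")
    labels = ai.labels.join(til.labels)
    both = labels["ai_group"].notna() & labels["til_group"].notna()
    labels["quadrant"] = pd.Series(np.nan, index=labels.index, dtype=object)
    labels.loc[both, "quadrant"] = (
        labels.loc[both, "ai_group"] + "/" + labels.loc[both, "til_group"]
    )
    medians = {"ai": ai.medians, "til": til.medians}
    return StratumLabels(labels=labels, medians=medians)
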