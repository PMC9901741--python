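"""Survival and response statistics downstream of the immune profiles.

Covers the association analyses the pipeline runs on a scored cohort:

* Cox proportional-hazards fits (multivariable and univariate; Efron ties)
  via lifelines, with complete-case handling and flagged non-convergence.
* Kaplan-Meier curves and log-rank tests on median-split strata, truncated
  at an analysis horizon.
* Fixed-effect inverse-variance meta-analysis of per-stratum hazard ratios
  (random-effects DerSimonian-Laird available for sensitivity analysis).
* Nested-model likelihood-ratio tests.
* Two-sided Wilcoxon rank-sum comparisons between response groups (exact
  enumeration for small tie-free groups).
* Fisher's exact test on the high-A/I x high-TIL quadrant vs response.
* The below-diagonal fraction: how many patients of a response group have a
  higher innate than adaptive compartment score (I > A strictly).

All p-values are two-sided unless an operation's contract says otherwise.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

log = logging.getLogger(__name__)


@dataclass
class CoxResult:
    """Hazard ratios with 95% CIs and p-values from one Cox PH fit."""

    summary: pd.DataFrame  # per covariate: coef, se, hr, ci_lower, ci_upper, p
    log_likelihood: float
    n: int
    n_events: int
    covariates: tuple[str, ...]
    converged: bool = True
    message: str = ""

    def hr(self, covariate: str) -> float:
        return float(self.summary.loc[covariate, "hr"])

    def p(self, covariate: str) -> float:
        return float(self.summary.loc[covariate, "p"])


@dataclass
class MetaResult:
    """Inverse-variance combined hazard ratio across strata."""

    per_stratum: pd.DataFrame  # stratum, log_hr, se, weight
    hr: float
    ci_lower: float
    ci_upper: float
    p: float
    method: str = "fixed-effect inverse-variance"


@dataclass
class GroupTestResult:
    """A two-group (or 2x2) comparison: statistic, p, sizes, direction."""

    groups: tuple
    sizes: tuple
    statistic: float
    p: float
    effect_direction: str = ""
    extra: dict = field(default_factory=dict)


def _prepare_survival_frame(
    df: pd.DataFrame, endpoint: str, covariates: list[str]
) -> pd.DataFrame:
    time_col, event_col = f"{endpoint}_time", f"{endpoint}_event"
    cols = [time_col, event_col] + list(covariates)
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"missing column(s) for Cox fit: {missing}")
    data = df[cols].apply(pd.to_numeric, errors="raise")
    data = data.dropna()
    return data.rename(columns={time_col: "_time", event_col: "_event"})


def fit_cox(
    df: pd.DataFrame,
    endpoint: str,
    covariates: list[str],
) -> CoxResult:
    """Cox proportional-hazards fit on `<endpoint>_time` / `<endpoint>_event`.

    Covariate columns must already be numeric (gender/stage encoded upstream;
    see :func:`encode_covariates`). Rows with any missing value are dropped
    (complete case). Ties are handled by the Efron approximation. A fit that
    fails to converge (e.g. perfect separation) is returned flagged, not
    raised.
    """
    data = _prepare_survival_frame(df, endpoint, covariates)
    if int(data["_event"].sum()) < 2:
        raise ValueError("Cox fit needs at least 2 events")
    for cov in covariates:
        if data[cov].nunique() < 2:
            raise ValueError(f"covariate {cov!r} is constant across samples")
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(data, duration_col="_time", event_col="_event")
    except ConvergenceError as err:  # separation etc: flag, don't crash
        empty = pd.DataFrame(
            np.nan, index=covariates,
            columns=["coef", "se", "hr", "ci_lower", "ci_upper", "p"],
        )
        return CoxResult(
            summary=empty, log_likelihood=np.nan, n=len(data),
            n_events=int(data["_event"].sum()), covariates=tuple(covariates),
            converged=False, message=str(err),
        )
    s = cph.summary
    summary = pd.DataFrame({
        "coef": s["coef"],
        "se": s["se(coef)"],
        "hr": s["exp(coef)"],
        "ci_lower": np.exp(s["coef"] - 1.959963984540054 * s["se(coef)"]),
        "ci_upper": np.exp(s["coef"] + 1.959963984540054 * s["se(coef)"]),
        "p": s["p"],
    })
    return CoxResult(
        summary=summary,
        log_likelihood=float(cph.log_likelihood_),
        n=len(data),
        n_events=int(data["_event"].sum()),
        covariates=tuple(covariates),
    )


def encode_covariates(clinical: pd.DataFrame) -> pd.DataFrame:
    """Numeric covariate encodings for regression.

    gender -> is_male (1 male, 0 female, NaN unknown); stage -> ordinal 1-4
    (unknown -> NaN, dropped by complete-case); age passed through numeric.
    """
    from .cohort_io import stage_ordinal

    out = pd.DataFrame(index=clinical.index)
    if "gender" in clinical:
        out["is_male"] = clinical["gender"].map(
            {"male": 1.0, "female": 0.0}).astype(float)
    if "stage" in clinical:
        out["stage_ordinal"] = clinical["stage"].map(stage_ordinal)
    if "age" in clinical:
        out["age"] = pd.to_numeric(clinical["age"], errors="coerce")
    return out


def km_logrank(
    df: pd.DataFrame,
    strata: pd.Series,
    endpoint: str,
    horizon_years: float | None = None,
) -> tuple[pd.DataFrame, GroupTestResult]:
    """Kaplan-Meier curves per stratum plus a log-rank test.

    Times are in days; `horizon_years` administratively censors everything
    beyond the horizon (e.g. 15-year overall survival). Returns the stacked
    survival-curve points and the (k-group) log-rank result.
    """
    time_col, event_col = f"{endpoint}_time", f"{endpoint}_event"
    strata = strata.reindex(df.index)
    keep = strata.notna() & df[time_col].notna() & df[event_col].notna()
    data = df.loc[keep, [time_col, event_col]].copy()
    labels = strata.loc[keep]
    if labels.nunique() < 2:
        raise ValueError("log-rank needs at least 2 non-empty strata")
    t = data[time_col].astype(float)
    e = data[event_col].astype(float)
    if horizon_years is not None:
        h = horizon_years * 365.25
        e = e.where(t <= h, 0.0)
        t = t.clip(upper=h)
    counts = labels.value_counts()
    events_per = e.groupby(labels).sum()
    if (events_per < 1).any():
        raise ValueError(
            f"stratum/strata without events: "
            f"{events_per[events_per < 1].index.tolist()}"
        )
    curves = []
    for key in sorted(labels.unique()):
        mask = labels == key
        kmf = KaplanMeierFitter()
        kmf.fit(t[mask], e[mask], label=str(key))
        sf = kmf.survival_function_.reset_index()
        sf.columns = ["time", "survival"]
        sf.insert(0, "stratum", key)
        curves.append(sf)
    res = multivariate_logrank_test(t, labels, e)
    test = GroupTestResult(
        groups=tuple(sorted(labels.unique())),
        sizes=tuple(int(counts[k]) for k in sorted(labels.unique())),
        statistic=float(res.test_statistic),
        p=float(res.p_value),
    )
    return pd.concat(curves, ignore_index=True), test


def meta_fixed_effect(
    per_stratum: dict[str, CoxResult] | pd.DataFrame,
    covariate: str | None = None,
    *,
    random_effects: bool = False,
) -> MetaResult:
    """Combine per-stratum hazard ratios by inverse-variance weighting.

    Accepts either ``{stratum: CoxResult}`` (then `covariate` selects the
    term) or a DataFrame with columns ``stratum, log_hr, se``. Strata with
    non-finite estimates or SE = 0 are excluded with a warning. Fixed-effect
    by default; `random_effects` applies a DerSimonian-Laird between-stratum
    variance for sensitivity analysis.
    """
    if isinstance(per_stratum, dict):
        rows = []
        for key, res in per_stratum.items():
            if covariate is None:
                raise ValueError("covariate is required with CoxResult input")
            if not res.converged:
                log.warning("meta: stratum %r excluded (non-converged fit)", key)
                continue
            rows.append({
                "stratum": key,
                "log_hr": float(res.summary.loc[covariate, "coef"]),
                "se": float(res.summary.loc[covariate, "se"]),
            })
        table = pd.DataFrame(rows)
    else:
        table = per_stratum.copy()
    ok = np.isfinite(table["log_hr"]) & np.isfinite(table["se"]) & (table["se"] > 0)
    if (~ok).any():
        log.warning("meta: excluding stratum/strata with bad estimates: %s",
                    table.loc[~ok, "stratum"].tolist())
        table = table.loc[ok]
    if len(table) < 2:
        raise ValueError("meta-analysis needs >= 2 usable strata")
    w = 1.0 / table["se"] ** 2
    method = "fixed-effect inverse-variance"
    if random_effects:
        # DerSimonian-Laird: inflate within-stratum variances by tau^2
        fixed = float(np.sum(w * table["log_hr"]) / np.sum(w))
        q = float(np.sum(w * (table["log_hr"] - fixed) ** 2))
        dfree = len(table) - 1
        c = float(np.sum(w) - np.sum(w**2) / np.sum(w))
        tau2 = max(0.0, (q - dfree) / c) if c > 0 else 0.0
        w = 1.0 / (table["se"] ** 2 + tau2)
        method = "random-effects DerSimonian-Laird"
    table = table.assign(weight=w / w.sum())
    combined = float(np.sum(w * table["log_hr"]) / np.sum(w))
    se = float(np.sqrt(1.0 / np.sum(w)))
    z = combined / se
    p = 2.0 * stats.norm.sf(abs(z))
    return MetaResult(
        per_stratum=table.reset_index(drop=True),
        hr=float(np.exp(combined)),
        ci_lower=float(np.exp(combined - 1.959963984540054 * se)),
        ci_upper=float(np.exp(combined + 1.959963984540054 * se)),
        p=float(p),
        method=method,
    )


def nested_lrt(model_small: CoxResult, model_large: CoxResult) -> GroupTestResult:
    """Likelihood-ratio test of a nested pair of Cox models.

    The small model's covariates must be a strict subset of the large
    model's, fitted on the same samples and endpoint. The statistic is
    2 * (llf_large - llf_small) on a chi-square with df = extra covariates.
    """
    small, large = set(model_small.covariates), set(model_large.covariates)
    if not small <= large:
        raise ValueError("models are not nested")
    if model_small.n != model_large.n or model_small.n_events != model_large.n_events:
        raise ValueError("nested models must be fitted on the same samples")
    df_diff = len(large) - len(small)
    statistic = 2.0 * (model_large.log_likelihood - model_small.log_likelihood)
    statistic = max(statistic, 0.0)
    if df_diff == 0 or statistic == 0.0:
        p = 1.0
    else:
        p = float(stats.chi2.sf(statistic, df_diff))
    return GroupTestResult(
        groups=("small", "large"),
        sizes=(len(small), len(large)),
        statistic=float(statistic),
        p=p,
        extra={"df": df_diff},
    )


def group_wilcoxon(
    values: pd.Series,
    groups: pd.Series,
    group_a: str,
    group_b: str,
) -> GroupTestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) comparison of two groups.

    Exact enumeration when both groups have <= 8 observations and no ties;
    otherwise the tie-corrected normal approximation. Missing values are
    dropped per group.
    """
    groups = groups.reindex(values.index)
    a = values[groups == group_a].dropna()
    b = values[groups == group_b].dropna()
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must have at least one observation")
    pooled = np.concatenate([a, b])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(a) <= 8 and len(b) <= 8 and no_ties) else "asymptotic"
    stat, p = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    direction = f"{group_a} > {group_b}" if a.mean() > b.mean() else f"{group_b} > {group_a}"
    return GroupTestResult(
        groups=(group_a, group_b),
        sizes=(len(a), len(b)),
        statistic=float(stat),
        p=float(p),
        effect_direction=direction,
        extra={"method": method,
               "median_a": float(a.median()), "median_b": float(b.median())},
    )


def fisher_quadrant(
    in_quadrant: pd.Series,
    responder: pd.Series,
) -> GroupTestResult:
    """Fisher's exact test: is response enriched in the high/high quadrant?

    Builds the 2x2 table (responder x in high-A/I-and-high-TIL quadrant) and
    returns the two-sided point-probability p with the sample odds ratio.
    """
    responder = responder.reindex(in_quadrant.index)
    keep = in_quadrant.notna() & responder.notna()
    q = in_quadrant[keep].astype(bool)
    r = responder[keep].astype(bool)
    if len(q) == 0:
        raise ValueError("empty 2x2 table")
    table = np.array([
        [int((r & q).sum()), int((r & ~q).sum())],
        [int((~r & q).sum()), int((~r & ~q).sum())],
    ])
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return GroupTestResult(
        groups=("responder", "non-responder"),
        sizes=(int(r.sum()), int((~r).sum())),
        statistic=float(odds) if np.isfinite(odds) else np.inf,
        p=float(p),
        extra={"table": table.tolist(),
               "responders_in_quadrant": int((r & q).sum()),
               "n_responders": int(r.sum())},
    )


def below_diagonal_fraction(
    profiles: pd.DataFrame,
    mask: pd.Series | None = None,
) -> dict:
    """Fraction of (selected) samples with innate score strictly above adaptive.

    Equivalent to A/I ratio < 1 where defined. Samples with a missing ratio
    (I = 0) are excluded and counted. Returns NaN fraction (with a warning)
    if nothing remains.
    """
    sel = profiles if mask is None else profiles.loc[mask.reindex(profiles.index).fillna(False).astype(bool)]
    usable = sel.loc[sel["ai_ratio"].notna()]
    n_missing = len(sel) - len(usable)
    if usable.empty:
        log.warning("below_diagonal_fraction: no usable samples")
        return {"fraction": np.nan, "n": 0, "n_below": 0, "n_missing": n_missing}
    below = usable["I"] > usable["A"]
    return {
        "fraction": float(below.mean()),
        "n": int(len(usable)),
        "n_below": int(below.sum()),
        "n_missing": int(n_missing),
    }
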