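"""End-to-end pipeline: cohort assembly -> scoring -> ratio -> statistics.

Outputs are plain TSV/JSON tables written under an output directory, with a
manifest recording input checksums, package version and the resolved config,
so a rerun on identical inputs is verifiable byte-for-byte (the manifest's
timestamp is the only non-reproducible field).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .ai_ratio import (compute_profiles, female_median_reference, median_split,
                       quadrant_labels)
from .cohort_io import (filter_response_evaluable, join_cohort, load_clinical,
                        load_expression, load_marker_panel)
from .immune_scoring import score_cell_types
from .outcome_stats import (below_diagonal_fraction, encode_covariates,
                            fisher_quadrant, fit_cox, group_wilcoxon,
                            km_logrank, meta_fixed_effect, nested_lrt)
from .rank_validation import mean_immune_rank, rank_genes

log = logging.getLogger(__name__)

KNOWN_ANALYSES = ("cox_forest", "km", "meta", "lrt_gender", "response",
                  "quadrant", "diagonal", "rank_check")


@dataclass
class RunConfig:
    """Resolved configuration for one pipeline run."""

    expr: str
    clin: str
    out_dir: str
    transform: str = "log2p1"
    panel: str | None = None
    scale_scope: str = "cohort"  # cohort | cancer_type
    split_scope: str = "gender"  # cohort | gender | cancer_type | both
    endpoint: str = "os"
    horizon_years: float | None = 15.0
    covariates: tuple[str, ...] = ("age", "is_male", "stage_ordinal")
    analyses: tuple[str, ...] = KNOWN_ANALYSES
    min_coverage: float = 0.5

    def __post_init__(self) -> None:
        unknown = set(self.analyses) - set(KNOWN_ANALYSES)
        if unknown:
            raise ValueError(f"unknown analysis toggle(s): {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key in ("covariates", "analyses"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class RunReport:
    """What a pipeline run produced: section name -> output paths/values."""

    sections: dict = field(default_factory=dict)
    out_dir: Path | None = None


def _scope_series(clinical: pd.DataFrame, scope: str) -> pd.Series | None:
    if scope == "cohort":
        return None
    if scope == "gender":
        return clinical["gender"]
    if scope == "cancer_type":
        return clinical["cancer_type"]
    if scope == "both":
        return clinical["gender"] + "|" + clinical["cancer_type"]
    raise ValueError(f"unknown scope {scope!r}")


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_json(path: Path, obj) -> None:
    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(type(o))

    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=default)
                    + "\n")


def run_pipeline(cfg: RunConfig) -> RunReport:
    """Execute the configured analysis stages and write their tables."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(out_dir=out)

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as err:
            raise RuntimeError(f"[{name}] {err}") from err

    expr = stage("cohort_io", load_expression, cfg.expr, cfg.transform)
    clinical = stage("cohort_io", load_clinical, cfg.clin)
    panel = stage("cohort_io", load_marker_panel, cfg.panel)
    cohort = stage("cohort_io", join_cohort, expr, clinical, panel,
                   min_coverage=cfg.min_coverage)
    clin = cohort.clinical

    scores = stage("immune_scoring", score_cell_types, cohort)
    scores.write_tsv(out / "celltype_scores.tsv")

    scale_scope = _scope_series(clin, cfg.scale_scope)
    profiles = stage("ai_ratio", compute_profiles, scores, panel,
                     scope=scale_scope)
    split_scope = _scope_series(clin, cfg.split_scope)
    quad = stage("ai_ratio", quadrant_labels, profiles["ai_ratio"],
                 profiles["til_score"], split_scope)
    prof_out = profiles.copy()
    prof_out[["ai_group", "til_group", "quadrant"]] = quad.labels
    prof_out.index.name = "sample_id"
    prof_out.to_csv(out / "immune_profiles.tsv", sep="\t")
    _write_json(out / "split_medians.json", quad.medians)
    report.sections["profiles"] = str(out / "immune_profiles.tsv")

    covs = encode_covariates(clin)
    surv = clin[[c for c in clin.columns
                 if c.endswith("_time") or c.endswith("_event")]].join(covs)

    if "cox_forest" in cfg.analyses:
        frame = surv.join(profiles[["ai_ratio", "til_score"]])
        usable = [c for c in ("ai_ratio", "til_score") + tuple(cfg.covariates)
                  if c in frame.columns and frame[c].nunique() > 1]
        res = stage("outcome_stats", fit_cox, frame, cfg.endpoint, usable)
        tab = res.summary.copy()
        tab.index.name = "covariate"
        tab.to_csv(out / "cox_forest.tsv", sep="\t")
        report.sections["cox_forest"] = {
            "path": str(out / "cox_forest.tsv"), "n": res.n,
            "events": res.n_events, "converged": res.converged,
        }

    if "km" in cfg.analyses:
        strata = clin["gender"] + "/" + quad.labels["ai_group"].astype(str)
        curves, test = stage("outcome_stats", km_logrank, surv, strata,
                             cfg.endpoint, cfg.horizon_years)
        curves.to_csv(out / "km_curves.tsv", sep="\t", index=False)
        _write_json(out / "km_test.json", {
            "groups": list(test.groups), "sizes": list(test.sizes),
            "statistic": test.statistic, "p": test.p,
        })
        report.sections["km"] = {"p": test.p}

    if "meta" in cfg.analyses:
        meta_out = {}
        for g in ("female", "male"):
            per = {}
            for ct, idx in clin.groupby("cancer_type").groups.items():
                sub = clin.loc[idx]
                sel = sub.index[sub["gender"] == g]
                if len(sel) < 10:
                    continue
                split = median_split(profiles.loc[sel, "ai_ratio"])
                frame = surv.loc[sel].copy()
                frame["ai_high"] = (split.labels["group"] == "high").astype(float)
                try:
                    per[ct] = fit_cox(frame, cfg.endpoint, ["ai_high"])
                except ValueError as err:
                    log.warning("meta: skipping %s/%s (%s)", ct, g, err)
            if len(per) >= 2:
                m = stage("outcome_stats", meta_fixed_effect, per, "ai_high")
                meta_out[g] = {"hr": m.hr, "ci": [m.ci_lower, m.ci_upper],
                               "p": m.p, "n_strata": len(m.per_stratum)}
            else:
                meta_out[g] = {"hr": None,
                               "note": "fewer than 2 usable strata"}
        _write_json(out / "meta_analysis.json", meta_out)
        report.sections["meta"] = meta_out

    if "lrt_gender" in cfg.analyses:
        frame = surv.join(profiles[["ai_ratio"]])
        base = [c for c in ("age", "stage_ordinal") if frame[c].nunique() > 1]
        small = stage("outcome_stats", fit_cox, frame.dropna(
            subset=["ai_ratio", "is_male"] + base),
            cfg.endpoint, base + ["is_male"])
        large = stage("outcome_stats", fit_cox, frame.dropna(
            subset=["ai_ratio", "is_male"] + base),
            cfg.endpoint, base + ["is_male", "ai_ratio"])
        lrt = stage("outcome_stats", nested_lrt, small, large)
        _write_json(out / "lrt_gender.json",
                    {"statistic": lrt.statistic, "p": lrt.p,
                     "df": lrt.extra["df"]})
        report.sections["lrt_gender"] = {"p": lrt.p}

    evaluable = filter_response_evaluable(clin)
    if "response" in cfg.analyses and not evaluable.empty:
        tests = {}
        vals = profiles.loc[evaluable.index, "ai_ratio"]
        resp = evaluable["response"]
        for a, b in (("CR", "PD"), ("PR", "PD"), ("CR", "PR")):
            if (resp == a).sum() and (resp == b).sum():
                t = stage("outcome_stats", group_wilcoxon, vals, resp, a, b)
                tests[f"{a}_vs_{b}"] = {"p": t.p, "sizes": list(t.sizes),
                                        "direction": t.effect_direction}
        _write_json(out / "response_tests.json", tests)
        report.sections["response"] = tests

    if "quadrant" in cfg.analyses and not evaluable.empty:
        in_hh = quad.labels.loc[evaluable.index, "quadrant"] == "high/high"
        responder = evaluable["response"].isin(["CR", "PR"])
        t = stage("outcome_stats", fisher_quadrant, in_hh, responder)
        _write_json(out / "quadrant_fisher.json", {
            "p": t.p, "odds_ratio": t.statistic, "table": t.extra["table"],
            "responders_in_quadrant": t.extra["responders_in_quadrant"],
            "n_responders": t.extra["n_responders"],
        })
        report.sections["quadrant"] = {"p": t.p}

    if "diagonal" in cfg.analyses and not evaluable.empty:
        diag = {}
        for label in ("PD", "PR", "CR"):
            mask = pd.Series(False, index=profiles.index)
            mask.loc[evaluable.index[evaluable["response"] == label]] = True
            if mask.any():
                diag[label] = stage("outcome_stats",
                                    below_diagonal_fraction, profiles, mask)
        _write_json(out / "diagonal_fractions.json", diag)
        report.sections["diagonal"] = diag

    if "rank_check" in cfg.analyses:
        prof = stage("rank_validation", rank_genes, cohort.expr)
        ranks = stage("rank_validation", mean_immune_rank, prof, panel,
                      clin["cancer_type"])
        ranks.to_csv(out / "immune_gene_ranks.tsv", sep="\t", index=False)
        report.sections["rank_check"] = str(out / "immune_gene_ranks.tsv")

    manifest = {
        "package_version": __version__,
        "timestamp_utc": datetime.now(timezone.utc).isoformat(),
        "inputs": {
            "expr": {"path": str(cfg.expr), "sha256": _sha256(cfg.expr)},
            "clin": {"path": str(cfg.clin), "sha256": _sha256(cfg.clin)},
        },
        "config": dataclasses.asdict(cfg),
        "outputs": {p.name: _sha256(p) for p in sorted(out.iterdir())
                    if p.name != "manifest.json"},
    }
    _write_json(out / "manifest.json", manifest)
    report.sections["manifest"] = str(out / "manifest.json")
    return report
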