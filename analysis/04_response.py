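#!/usr/bin/env python
"""Immunotherapy-response analyses on the simulated study: A/I ratio by
response group (Wilcoxon), enrichment of responders in the high-A/I /
high-TIL quadrant (Fisher), and the below-diagonal (I > A) fraction among
progressors.
"""

import json
from pathlib import Path

import pandas as pd

from airatio.ai_ratio import quadrant_labels
from airatio.cohort_io import filter_response_evaluable, load_clinical
from airatio.outcome_stats import (below_diagonal_fraction, fisher_quadrant,
                                   group_wilcoxon)

RESULTS = Path("results/response")


def main() -> None:
    RESULTS.mkdir(parents=True, exist_ok=True)
    clin = load_clinical("scratch/cohort/clinical.tsv")
    profiles = pd.read_csv("scratch/profiles/immune_profiles.tsv", sep="\t",
                           index_col="sample_id").loc[clin.index]
    evaluable = filter_response_evaluable(clin)
    print(f"{len(evaluable)}/{len(clin)} samples response-evaluable "
          f"(CR/PR/PD; SD and unlabelled excluded)")

    vals = profiles.loc[evaluable.index, "ai_ratio"]
    resp = evaluable["response"]
    tests = {}
    for a, b in (("CR", "PD"), ("PR", "PD"), ("CR", "PR")):
        t = group_wilcoxon(vals, resp, a, b)
        tests[f"{a}_vs_{b}"] = {"p": t.p, "sizes": list(t.sizes),
                                "direction": t.effect_direction}
        print(f"A/I ratio {a} vs {b}: p = {t.p:.2e} ({t.effect_direction})")
    (RESULTS / "wilcoxon_tests.json").write_text(
        json.dumps(tests, indent=2) + "\n")

    quad = quadrant_labels(vals, profiles.loc[evaluable.index, "til_score"])
    in_hh = quad.labels["quadrant"] == "high/high"
    responder = resp.isin(["CR", "PR"])
    fq = fisher_quadrant(in_hh, responder)
    frac = fq.extra["responders_in_quadrant"] / fq.extra["n_responders"]
    (RESULTS / "quadrant_fisher.json").write_text(json.dumps(
        {"p": fq.p, "odds_ratio": fq.statistic, "table": fq.extra["table"],
         "responder_fraction_in_high_high": frac}, indent=2) + "\n")
    print(f"responders with high A/I and high TIL: "
          f"{fq.extra['responders_in_quadrant']}/{fq.extra['n_responders']} "
          f"({100 * frac:.0f}%), Fisher p = {fq.p:.2e}")

    diag = {}
    for label in ("PD", "PR", "CR"):
        mask = pd.Series(False, index=profiles.index)
        mask.loc[evaluable.index[resp == label]] = True
        diag[label] = below_diagonal_fraction(profiles, mask)
        print(f"fraction with I > A in {label}: "
              f"{100 * diag[label]['fraction']:.0f}% (n={diag[label]['n']})")
    (RESULTS / "diagonal_fractions.json").write_text(
        json.dumps(diag, indent=2) + "\n")


if __name__ == "__main__":
    main()
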