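"""Synthetic tumour-cohort generator with recorded ground truth.

Emulates the statistical structure the A/I-ratio analysis assumes so every
pipeline stage is testable without external cohorts:

* a per-sample latent adaptive skew ``s`` (gender-shifted normal) that tilts
  infiltration towards adaptive (s > 0) or innate (s < 0) cell types;
* per-cell-type infiltration levels that multiply a marker-gene signal on
  top of a log-normal background transcriptome (TPM scale);
* exponential proportional-hazards survival with log-hazard ``beta_ai * s``,
  independent exponential censoring, and a progression-free endpoint that
  shares the same truth but runs on an accelerated clock;
* an ordinal (cumulative-logit) therapy response PD < SD < PR < CR driven by
  the same latent skew, with SD generated explicitly so response filtering
  is exercised.

One root seed is expanded into independent per-stage substreams, so e.g.
changing the response model never perturbs the expression draws, and a fixed
seed reproduces every output byte-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cohort_io import Cohort, ExpressionMatrix, MarkerPanel, load_marker_panel

_STAGES = ("I", "II", "III", "IV")
# substream ids (SeedSequence spawn keys) per generation stage
_STREAMS = {"cohort": 0, "genes": 1, "expression": 2, "outcomes": 3, "response": 4}


@dataclass
class SimConfig:
    """Study conditions for one synthetic cohort.

    Defaults are the reference conditions used throughout the test-bed:
    1,000 patients, half female, a +0.5 shift of the female latent adaptive
    skew, and a protective log-hazard of -0.7 per unit latent skew.
    """

    n_samples: int = 1000
    n_background_genes: int = 2000
    panel: MarkerPanel | None = None  # packaged Danaher-style panel if None
    gender_mix: float = 0.5  # fraction female
    adaptive_skew_effect: float = 0.5  # female minus male mean latent skew
    infiltration_scale: float = 0.2  # mean total infiltration multiplier
    beta_ai: float = -0.7  # log-hazard per unit latent skew (centred)
    baseline_hazard: float = 1.0 / 1000.0  # events per day
    censor_rate: float = 1.0 / 3000.0  # independent censoring per day
    pfi_accel: float = 1.6  # PFI hazard runs this much faster than OS
    response_slope: float = 1.0  # ordinal-logit slope on latent skew
    response_cutpoints: tuple[float, float, float] = (-0.4, 0.7, 2.2)
    noise_sd: float = 0.5  # log-normal multiplicative expression noise
    background_meanlog: float = 1.0  # baseline TPM ~ LogNormal(1.0, 1.5)
    background_sdlog: float = 1.5
    signal_tpm: float = 100.0  # marker-gene signal at unit infiltration
    infiltration_disp: float = 0.5  # sdlog of per-sample total infiltration
    celltype_noise_sd: float = 0.3  # per-sample per-cell-type jitter (log)
    cancer_type: str = "SYNTH"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.gender_mix <= 1.0:
            raise ValueError("gender_mix must be in [0, 1]")
        for name in ("baseline_hazard", "censor_rate", "pfi_accel"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.infiltration_scale < 0:
            raise ValueError("infiltration_scale must be >= 0")

    def resolved_panel(self) -> MarkerPanel:
        return self.panel if self.panel is not None else load_marker_panel()

    def with_(self, **kwargs) -> "SimConfig":
        return replace(self, **kwargs)


@dataclass
class SyntheticTruth:
    """Ground truth recorded per sample for recovery tests."""

    table: pd.DataFrame  # sample_id-indexed: gender, skew, infiltration ...
    infiltration: pd.DataFrame  # samples x cell types, true levels
    config: SimConfig = field(repr=False, default=None)


def _streams(cfg: SimConfig) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(cfg.seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(children[i])
            for name, i in _STREAMS.items()}


def _compartment_direction(panel: MarkerPanel) -> pd.Series:
    d = {}
    for ct in panel.cell_types:
        comp = panel.compartment(ct)
        d[ct] = {"adaptive": 1.0, "innate": -1.0}.get(comp, 0.0)
    return pd.Series(d)


def simulate_expression(cfg: SimConfig) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Draw a gene x sample TPM matrix plus its ground truth.

    Marker-gene TPM = log-normal background + infiltration * gene amplitude;
    non-marker genes carry background only. With ``infiltration_scale = 0``
    ("cell-line mode") marker genes are draws from the same background family
    as every other gene.
    """
    panel = cfg.resolved_panel()
    if not panel.cell_types:
        raise ValueError("marker panel is empty")
    rng_cohort = _streams(cfg)["cohort"]
    rng_genes = _streams(cfg)["genes"]
    rng_expr = _streams(cfg)["expression"]

    n = cfg.n_samples
    sample_ids = [f"S{i:05d}" for i in range(n)]
    female = rng_cohort.random(n) < cfg.gender_mix
    gender = np.where(female, "female", "male")
    skew = rng_cohort.normal(0.0, 1.0, n) + np.where(
        female, cfg.adaptive_skew_effect, 0.0)
    total_inf = cfg.infiltration_scale * np.exp(
        rng_cohort.normal(0.0, cfg.infiltration_disp, n))
    age = np.round(rng_cohort.normal(62.0, 10.0, n)).clip(25, 90)
    stage = rng_cohort.choice(_STAGES, size=n, p=[0.25, 0.3, 0.3, 0.15])

    direction = _compartment_direction(panel)
    cell_types = direction.index.tolist()
    # infiltration level per cell type: tilted by the latent skew, jittered
    tilt = np.exp(0.5 * np.outer(skew, direction.to_numpy()))
    jitter = np.exp(rng_expr.normal(0.0, cfg.celltype_noise_sd,
                                    (n, len(cell_types))))
    infiltration = pd.DataFrame(
        total_inf[:, None] * tilt * jitter, index=sample_ids, columns=cell_types)

    marker_genes = panel.genes
    background_genes = [f"BG{i:05d}" for i in range(cfg.n_background_genes)]
    genes = marker_genes + background_genes
    baseline = np.exp(rng_genes.normal(cfg.background_meanlog,
                                       cfg.background_sdlog, len(genes)))
    amplitude = cfg.signal_tpm * rng_genes.uniform(0.5, 1.5, len(marker_genes))

    tpm = baseline[:, None] * np.exp(
        rng_expr.normal(0.0, cfg.noise_sd, (len(genes), n)))
    gene_celltype = (panel.entries.drop_duplicates("gene")
                     .set_index("gene")["cell_type"])
    for j, g in enumerate(marker_genes):
        f = infiltration[gene_celltype[g]].to_numpy()
        tpm[j, :] += amplitude[j] * f

    expr = ExpressionMatrix(
        pd.DataFrame(tpm, index=genes, columns=sample_ids), "linear_tpm")
    truth_table = pd.DataFrame({
        "sample_id": sample_ids,
        "gender": gender,
        "age": age,
        "stage": stage,
        "skew": skew,
        "total_infiltration": total_inf,
    }).set_index("sample_id", drop=False)
    return expr, SyntheticTruth(table=truth_table, infiltration=infiltration,
                                config=cfg)


def simulate_outcomes(truth: SyntheticTruth, cfg: SimConfig) -> pd.DataFrame:
    """Exponential PH survival + censoring for OS and an accelerated PFI.

    Hazard per sample: ``baseline_hazard * exp(beta_ai * (s - mean(s)))``.
    Censoring is an independent exponential clock shared between endpoints'
    rates. Appends os/pfi time & event plus the true log-hazard to the truth
    table and returns the clinical columns.
    """
    rng = _streams(cfg)["outcomes"]
    s = truth.table["skew"].to_numpy()
    log_hr = cfg.beta_ai * (s - s.mean())
    hazard = cfg.baseline_hazard * np.exp(log_hr)
    n = len(s)

    os_event_t = rng.exponential(1.0 / hazard)
    os_censor_t = rng.exponential(1.0 / cfg.censor_rate, n)
    os_time = np.minimum(os_event_t, os_censor_t)
    os_event = (os_event_t <= os_censor_t).astype(int)

    pfi_event_t = rng.exponential(1.0 / (hazard * cfg.pfi_accel))
    pfi_censor_t = rng.exponential(1.0 / cfg.censor_rate, n)
    pfi_time = np.minimum(pfi_event_t, pfi_censor_t)
    pfi_event = (pfi_event_t <= pfi_censor_t).astype(int)

    truth.table["true_log_hazard"] = log_hr
    out = pd.DataFrame({
        "os_time": np.round(os_time, 1),
        "os_event": os_event,
        "pfi_time": np.round(pfi_time, 1),
        "pfi_event": pfi_event,
    }, index=truth.table.index)
    return out


def simulate_response(truth: SyntheticTruth, cfg: SimConfig) -> pd.Series:
    """Ordinal therapy response PD < SD < PR < CR from the latent skew.

    Cumulative-logit: latent ``u = slope * s + logistic noise`` cut at the
    configured cutpoints. True class probabilities are recorded in the truth
    table. Cutpoints at +/-inf collapse classes (boundary behaviour).
    """
    rng = _streams(cfg)["response"]
    s = truth.table["skew"].to_numpy()
    eta = cfg.response_slope * s
    u = eta + rng.logistic(0.0, 1.0, len(s))
    c1, c2, c3 = cfg.response_cutpoints
    labels = np.select(
        [u < c1, u < c2, u < c3], ["PD", "SD", "PR"], default="CR")

    def expit(x):
        return 1.0 / (1.0 + np.exp(-x))

    truth.table["p_PD"] = expit(c1 - eta)
    truth.table["p_SD"] = expit(c2 - eta) - expit(c1 - eta)
    truth.table["p_PR"] = expit(c3 - eta) - expit(c2 - eta)
    truth.table["p_CR"] = 1.0 - expit(c3 - eta)
    return pd.Series(labels, index=truth.table.index, name="response")


def simulate_cohort(cfg: SimConfig) -> tuple[ExpressionMatrix, pd.DataFrame,
                                             SyntheticTruth]:
    """Full synthetic cohort: expression, clinical table, ground truth.

    The clinical table matches the cohort_io vocabulary, including a crude
    immunohistochemistry-style phenotype (infiltration tertiles ->
    desert / excluded / inflamed).
    """
    expr, truth = simulate_expression(cfg)
    outcomes = simulate_outcomes(truth, cfg)
    response = simulate_response(truth, cfg)
    tert = truth.table["total_infiltration"].rank(pct=True)
    phenotype = pd.cut(tert, [0, 1 / 3, 2 / 3, 1.0],
                       labels=["desert", "excluded", "inflamed"],
                       include_lowest=True).astype(str)
    clinical = pd.DataFrame({
        "sample_id": truth.table["sample_id"],
        "gender": truth.table["gender"],
        "age": truth.table["age"],
        "stage": truth.table["stage"],
        "cancer_type": cfg.cancer_type,
        "response": response,
        "phenotype": phenotype,
    }, index=truth.table.index).join(outcomes)
    return expr, clinical, truth


def simulated_cohort_object(cfg: SimConfig) -> tuple[Cohort, SyntheticTruth]:
    """Convenience: simulate and join into a ready-to-score Cohort."""
    from .cohort_io import join_cohort

    expr, clinical, truth = simulate_cohort(cfg)
    cohort = join_cohort(expr, clinical, cfg.resolved_panel())
    return cohort, truth
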