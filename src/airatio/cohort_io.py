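"""Readers, validators and the joined-cohort container.

Bulk expression matrices arrive either as TSV (genes in rows, header row of
sample ids) or as MatrixMarket triplets with separate row/column name files.
The expression transform (linear TPM vs log2(TPM+1)) is *declared* by the
caller, never sniffed from the data: downstream min-max scaling reverses the
log transform, and a silently misdetected transform would corrupt it.

Clinical tables are TSV with a documented column vocabulary; missing optional
columns are filled with ``unknown``/``none`` sentinels so a minimal table
(sample_id, gender, cancer_type) is already valid.
"""

from __future__ import annotations

import gzip
import io
import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

log = logging.getLogger(__name__)

TRANSFORMS = ("linear_tpm", "log2p1")
COMPARTMENTS = ("adaptive", "innate", "excluded")
GENDERS = ("male", "female", "unknown")
RESPONSES = ("CR", "PR", "SD", "PD", "none")
PHENOTYPES = ("inflamed", "excluded", "desert", "none")

#: clinical columns beyond the required three, with their fill sentinel
_OPTIONAL_CLINICAL = {
    "age": np.nan,
    "stage": "unknown",
    "os_time": np.nan,
    "os_event": np.nan,
    "pfi_time": np.nan,
    "pfi_event": np.nan,
    "response": "none",
    "phenotype": "none",
}
_REQUIRED_CLINICAL = ["sample_id", "gender", "cancer_type"]

_ROMAN = {"I": 1, "II": 2, "III": 3, "IV": 4}


class CohortError(ValueError):
    """Raised on any hard validation failure while assembling a cohort."""


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix with a declared transform state."""

    data: pd.DataFrame  # index = gene symbols, columns = sample ids
    transform: str

    def __post_init__(self) -> None:
        if self.transform not in TRANSFORMS:
            raise CohortError(
                f"transform must be one of {TRANSFORMS}, got {self.transform!r}"
            )
        if self.data.index.duplicated().any():
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise CohortError(f"duplicate gene symbols: {dupes}")
        if self.data.columns.duplicated().any():
            dupes = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise CohortError(f"duplicate sample ids: {dupes}")
        vals = self.data.to_numpy()
        if vals.size and np.nanmin(vals) < 0:
            g, s = np.argwhere(np.asarray(self.data < 0))[0]
            raise CohortError(
                f"negative expression value for gene {self.data.index[g]!r} "
                f"in sample {self.data.columns[s]!r}"
            )

    @property
    def genes(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def samples(self) -> list[str]:
        return self.data.columns.tolist()

    def to_log2p1(self) -> "ExpressionMatrix":
        """Return the matrix on the log2(TPM+1) scale (no-op if already there)."""
        if self.transform == "log2p1":
            return self
        return ExpressionMatrix(np.log2(self.data + 1.0), "log2p1")

    def write_tsv(self, path: str | Path) -> None:
        df = self.data.copy()
        df.index.name = "gene"
        df.to_csv(path, sep="\t")


@dataclass
class MarkerPanel:
    """Cell type -> marker genes, with adaptive/innate/excluded compartments."""

    entries: pd.DataFrame  # columns: cell_type, gene, compartment

    def __post_init__(self) -> None:
        need = {"cell_type", "gene", "compartment"}
        if not need.issubset(self.entries.columns):
            raise CohortError(f"marker panel needs columns {sorted(need)}")
        bad = set(self.entries["compartment"]) - set(COMPARTMENTS)
        if bad:
            raise CohortError(f"unknown compartments: {sorted(bad)}")
        ncomp = self.entries.groupby("cell_type")["compartment"].nunique()
        mixed = ncomp[ncomp > 1].index.tolist()
        if mixed:
            raise CohortError(f"compartment not constant within cell type(s): {mixed}")
        if (self.entries.groupby("cell_type")["gene"].count() < 1).any():
            raise CohortError("every cell type needs at least one marker gene")

    @property
    def cell_types(self) -> list[str]:
        return sorted(self.entries["cell_type"].unique())

    def markers(self, cell_type: str) -> list[str]:
        sel = self.entries.loc[self.entries["cell_type"] == cell_type, "gene"]
        return sorted(sel.unique())

    def compartment(self, cell_type: str) -> str:
        sel = self.entries.loc[self.entries["cell_type"] == cell_type, "compartment"]
        return sel.iloc[0]

    def by_compartment(self, compartment: str) -> list[str]:
        sel = self.entries.loc[self.entries["compartment"] == compartment, "cell_type"]
        return sorted(sel.unique())

    @property
    def genes(self) -> list[str]:
        return sorted(self.entries["gene"].unique())


@dataclass
class Cohort:
    """Expression, clinical table and panel restricted to shared samples."""

    expr: ExpressionMatrix
    clinical: pd.DataFrame  # indexed by sample_id
    panel: MarkerPanel
    coverage: pd.DataFrame = field(default_factory=pd.DataFrame)
    missing_genes: list[str] = field(default_factory=list)

    @property
    def samples(self) -> list[str]:
        return self.expr.samples

    def present_markers(self, cell_type: str) -> list[str]:
        have = set(self.expr.data.index)
        return [g for g in self.panel.markers(cell_type) if g in have]


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path)


def load_expression(
    path: str | Path,
    transform: str,
    *,
    rows: str | Path | None = None,
    cols: str | Path | None = None,
) -> ExpressionMatrix:
    """Load an expression matrix from TSV or MatrixMarket.

    Parameters
    ----------
    path
        TSV with gene symbols in the first column and one column per sample,
        or a ``.mtx``/``.mtx.gz`` file (then `rows` and `cols` are required
        gene / sample name files, one name per line).
    transform
        Declared scale of the stored values: ``linear_tpm`` or ``log2p1``.
        There is deliberately no auto-detection.
    """
    path = Path(path)
    if not path.exists():
        raise CohortError(f"expression file not found: {path}")
    if transform not in TRANSFORMS:
        raise CohortError(f"transform must be one of {TRANSFORMS}, got {transform!r}")

    if ".mtx" in path.suffixes or path.suffix == ".mtx":
        if rows is None or cols is None:
            raise CohortError("MatrixMarket input needs rows= and cols= name files")
        with (gzip.open(path, "rb") if path.suffix == ".gz" else open(path, "rb")) as fh:
            mat = scipy.io.mmread(fh)
        with _open_text(rows) as fh:
            genes = [ln.strip() for ln in fh if ln.strip()]
        with _open_text(cols) as fh:
            samples = [ln.strip() for ln in fh if ln.strip()]
        dense = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat)
        if dense.shape != (len(genes), len(samples)):
            raise CohortError(
                f"matrix shape {dense.shape} does not match "
                f"{len(genes)} genes x {len(samples)} samples"
            )
        df = pd.DataFrame(dense, index=genes, columns=samples)
    else:
        with _open_text(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")[1:]
        stripped = [h.strip() for h in header]
        if len(set(stripped)) != len(stripped):
            dupes = sorted({h for h in stripped if stripped.count(h) > 1})
            raise CohortError(f"duplicate sample ids in {path}: {dupes}")
        df = pd.read_csv(path, sep="\t", index_col=0,
                         float_precision="round_trip")
        if df.isna().any().any():
            raise CohortError(f"ragged or missing entries in {path}")
    df.index = df.index.astype(str).str.strip()
    df.columns = df.columns.astype(str).str.strip()

    if df.columns.duplicated().any():
        dupes = df.columns[df.columns.duplicated()].unique().tolist()
        raise CohortError(f"duplicate sample ids in {path}: {dupes}")
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()
        log.warning("collapsing %d duplicated gene symbol(s) by mean: %s",
                    len(dupes), dupes)
        df = df.groupby(level=0, sort=False).mean()
    return ExpressionMatrix(df.astype(float), transform)


def _parse_stage(raw: object) -> str:
    """Collapse substages ('IIIb', 'Stage IIA') to the major stage I..IV."""
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return "unknown"
    s = str(raw).strip().upper()
    s = re.sub(r"^STAGE\s*", "", s)
    m = re.match(r"(IV|III|II|I)", s)
    return m.group(1) if m else "unknown"


def stage_ordinal(stage: str) -> float:
    """Ordinal 1-4 encoding for regression; unknown -> NaN.

    Accepts raw substage strings ('IIIb', 'Stage IIA') as well as already
    collapsed major stages.
    """
    return float(_ROMAN.get(_parse_stage(stage), np.nan))


def load_clinical(path: str | Path) -> pd.DataFrame:
    """Load and normalise a clinical TSV.

    Required columns: sample_id, gender, cancer_type. Optional columns are
    filled with their sentinel; stage substrings collapse to the major stage.
    """
    path = Path(path)
    if not path.exists():
        raise CohortError(f"clinical file not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    missing = [c for c in _REQUIRED_CLINICAL if c not in df.columns]
    if missing:
        raise CohortError(f"clinical table missing required column(s): {missing}")
    for col, sentinel in _OPTIONAL_CLINICAL.items():
        if col not in df.columns:
            df[col] = sentinel
        else:
            if isinstance(sentinel, str):
                df[col] = df[col].fillna(sentinel)
    df["sample_id"] = df["sample_id"].str.strip()
    if df["sample_id"].duplicated().any():
        dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise CohortError(f"duplicate sample ids in clinical table: {dupes}")
    df["gender"] = df["gender"].astype(str).str.strip().str.lower()
    df.loc[~df["gender"].isin(GENDERS), "gender"] = "unknown"
    df["stage"] = df["stage"].map(_parse_stage)
    bad = set(df["response"].dropna()) - set(RESPONSES)
    if bad:
        raise CohortError(f"unknown response label(s): {sorted(bad)}")
    bad = set(df["phenotype"].dropna()) - set(PHENOTYPES)
    if bad:
        raise CohortError(f"unknown phenotype label(s): {sorted(bad)}")
    for tcol in ("os_time", "pfi_time"):
        t = pd.to_numeric(df[tcol], errors="coerce")
        if (t < 0).any():
            bad_ids = df.loc[t < 0, "sample_id"].tolist()
            raise CohortError(f"negative {tcol} for sample(s) {bad_ids}")
        df[tcol] = t
    for ecol in ("os_event", "pfi_event"):
        e = pd.to_numeric(df[ecol], errors="coerce")
        if (~e.dropna().isin([0, 1])).any():
            raise CohortError(f"{ecol} must be 0 or 1")
        df[ecol] = e
    return df.set_index("sample_id", drop=False)


def filter_response_evaluable(clinical: pd.DataFrame) -> pd.DataFrame:
    """Keep only response-evaluable patients (CR, PR, PD).

    Stable disease is deliberately dropped: SD is ambiguous between contained
    growth under effective therapy and stagnant growth under ineffective
    therapy. Idempotent; logs how many rows were removed.
    """
    keep = clinical["response"].isin(["CR", "PR", "PD"])
    removed = int((~keep).sum())
    if removed:
        log.info("filter_response_evaluable: removed %d sample(s) (SD or no response)",
                 removed)
    out = clinical.loc[keep]
    if out.empty:
        log.warning("filter_response_evaluable: no evaluable samples remain")
    return out


def load_marker_panel(path: str | Path | None = None) -> MarkerPanel:
    """Load a three-column marker panel TSV, or the packaged default.

    The default follows the Danaher et al. immune cell-type marker table:
    14 cell types, 7 adaptive + 6 innate used for the compartment ratio, with
    Exhausted CD8 marked ``excluded`` (counted in the TIL mean only).
    """
    if path is None:
        ref = resources.files("airatio.data").joinpath("danaher_panel.tsv")
        with resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        with _open_text(path) as fh:
            df = pd.read_csv(fh, sep="\t")
    for col in ("cell_type", "gene", "compartment"):
        df[col] = df[col].astype(str).str.strip()
    return MarkerPanel(df)


def join_cohort(
    expr: ExpressionMatrix,
    clinical: pd.DataFrame,
    panel: MarkerPanel,
    *,
    min_coverage: float = 0.5,
) -> Cohort:
    """Restrict to shared samples and validate marker coverage.

    Every panel cell type must keep at least ``min_coverage`` of its markers
    in the expression matrix (hard error below the threshold, warning between
    the threshold and full coverage). Sample-id matching is exact string
    match after whitespace strip; no cohort-specific barcode munging.
    """
    shared = sorted(set(expr.samples) & set(clinical.index))
    if not shared:
        raise CohortError("no shared sample ids between expression and clinical table")
    have = set(expr.data.index)
    missing = sorted(set(panel.genes) - have)
    rows = []
    for ct in panel.cell_types:
        markers = panel.markers(ct)
        present = [g for g in markers if g in have]
        frac = len(present) / len(markers)
        rows.append({"cell_type": ct, "n_markers": len(markers),
                     "n_present": len(present), "coverage": frac})
        if frac < min_coverage:
            raise CohortError(
                f"cell type {ct!r} has marker coverage {frac:.2f} "
                f"({len(present)}/{len(markers)}), below threshold {min_coverage}"
            )
        if frac < 1.0:
            log.warning("cell type %r: only %d/%d marker genes present",
                        ct, len(present), len(markers))
    coverage = pd.DataFrame(rows)
    restricted = ExpressionMatrix(expr.data.loc[:, shared], expr.transform)
    return Cohort(
        expr=restricted,
        clinical=clinical.loc[shared],
        panel=panel,
        coverage=coverage,
        missing_genes=missing,
    )
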