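"""Validated readers and writers for the pipeline's tab-separated artifacts.

All tables are UTF-8 TSV with a ``#`` schema-version comment line, '.' decimal
and deterministic column order; sparse counts may alternatively be supplied as
a matrix-market triplet file with ``.rows``/``.cols`` label sidecars.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

SCHEMA_VERSION = "rootzone/1"

REQUIRED_DESIGN_COLUMNS = ("tissue", "treatment", "replicate", "lane")
VALID_TISSUES = {"Mz", "Ez", "Co", "St"}
VALID_TREATMENTS = {"control", "deficit"}


class FormatError(ValueError):
    """Raised when an input file violates the documented schema."""


def write_table(frame: pd.DataFrame, path: str | Path, kind: str) -> None:
    """Write a TSV with a schema-version header comment."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# schema={SCHEMA_VERSION} kind={kind}\n")
        frame.to_csv(fh, sep="\t")


def _read_tsv(path: str | Path, index_col: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: file not found")
    frame = pd.read_csv(path, sep="\t", comment="#", dtype={index_col: str})
    if index_col not in frame.columns:
        raise FormatError(f"{path}: missing required column '{index_col}'")
    dup = frame[index_col][frame[index_col].duplicated()]
    if len(dup):
        raise FormatError(f"{path}: duplicate {index_col} '{dup.iloc[0]}'")
    return frame.set_index(index_col)


def read_counts(path: str | Path) -> pd.DataFrame:
    """Read a gene x sample count matrix (TSV, or matrix-market + sidecars)."""
    path = Path(path)
    if path.suffix == ".mtx":
        mat = scipy.io.mmread(path)
        genes = Path(str(path) + ".rows").read_text().split()
        samples = Path(str(path) + ".cols").read_text().split()
        counts = pd.DataFrame(
            np.asarray(scipy.sparse.coo_matrix(mat).todense()),
            index=genes,
            columns=samples,
        )
    else:
        counts = _read_tsv(path, "gene_id")
    for col in counts.columns:
        values = pd.to_numeric(counts[col], errors="coerce")
        bad = values.isna() | (values != np.floor(values))
        if bad.any():
            gene = counts.index[bad.to_numpy().nonzero()[0][0]]
            raise FormatError(
                f"{path}: non-integer count for gene '{gene}', sample '{col}'"
            )
        neg = values < 0
        if neg.any():
            gene = counts.index[neg.to_numpy().nonzero()[0][0]]
            raise FormatError(
                f"{path}: negative count for gene '{gene}', sample '{col}'"
            )
    return counts.astype(np.int64)


def write_counts_mtx(counts: pd.DataFrame, path: str | Path) -> None:
    """Write counts as a sparse matrix-market file with label sidecars."""
    path = Path(path)
    scipy.io.mmwrite(path, scipy.sparse.coo_matrix(counts.to_numpy()))
    Path(str(path) + ".rows").write_text("\n".join(counts.index) + "\n")
    Path(str(path) + ".cols").write_text("\n".join(counts.columns) + "\n")


def read_design(path: str | Path) -> pd.DataFrame:
    """Read and validate the sample design table (complete factorial)."""
    design = _read_tsv(path, "sample_id").reset_index()
    for col in REQUIRED_DESIGN_COLUMNS:
        if col not in design.columns:
            raise FormatError(f"{path}: missing required column '{col}'")
    bad_tissue = set(design["tissue"]) - VALID_TISSUES
    if bad_tissue:
        raise FormatError(f"{path}: unknown tissue label(s) {sorted(bad_tissue)}")
    bad_trt = set(design["treatment"]) - VALID_TREATMENTS
    if bad_trt:
        raise FormatError(f"{path}: unknown treatment label(s) {sorted(bad_trt)}")
    design["replicate"] = design["replicate"].astype(int)
    reps = sorted(design["replicate"].unique())
    missing = []
    for tissue in sorted(VALID_TISSUES):
        for trt in sorted(VALID_TREATMENTS):
            for rep in reps:
                hit = (
                    (design["tissue"] == tissue)
                    & (design["treatment"] == trt)
                    & (design["replicate"] == rep)
                )
                if hit.sum() != 1:
                    missing.append(f"{tissue} x {trt} x replicate {rep}")
    if missing:
        raise FormatError(
            f"{path}: design is not a complete tissue x treatment x replicate "
            f"crossing; problem cells: {', '.join(missing)}"
        )
    return design[["sample_id"] + list(REQUIRED_DESIGN_COLUMNS)]


def read_covariates(path: str | Path) -> pd.DataFrame:
    """Read per-gene covariates (length_bp, gc_fraction)."""
    cov = _read_tsv(path, "gene_id")
    for col in ("length_bp", "gc_fraction"):
        if col not in cov.columns:
            raise FormatError(f"{path}: missing required column '{col}'")
    if (cov["length_bp"] <= 0).any():
        raise FormatError(f"{path}: length_bp must be positive")
    if ((cov["gc_fraction"] < 0) | (cov["gc_fraction"] > 1)).any():
        raise FormatError(f"{path}: gc_fraction must lie in [0, 1]")
    return cov[["length_bp", "gc_fraction"]]


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Read a gene -> category annotation table (gene_id, category[, system])."""
    frame = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    for col in ("gene_id", "category"):
        if col not in frame.columns:
            raise FormatError(f"{path}: missing required column '{col}'")
    if "system" not in frame.columns:
        frame["system"] = "default"
    return frame[["gene_id", "category", "system"]]


def read_table(path: str | Path, index_col: str = "gene_id") -> pd.DataFrame:
    """Generic reader for pipeline artifact tables."""
    return _read_tsv(path, index_col)
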