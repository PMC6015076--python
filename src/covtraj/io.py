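"""Readers and writers for delimited expression/covariate matrices.

Expression input is delimited text (TSV or CSV, optionally gzipped) with
row and column labels, or MatrixMarket coordinate format with plain-text
label sidecars.  Whatever the declared on-disk layout, matrices come back
oriented samples x genes.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import CovariateMatrix, ExpressionMatrix
from .exceptions import ConfigError, ValidationError
from .model import encode_covariate_frame

logger = logging.getLogger(__name__)

__all__ = [
    "read_expression",
    "read_expression_mtx",
    "read_covariates",
    "write_expression",
    "write_matrix_with_truth",
]

LAYOUTS = ("samples_by_genes", "genes_by_samples")


def _sep_for(path: Path) -> str:
    name = path.name[:-3] if path.name.endswith(".gz") else path.name
    return "," if name.endswith(".csv") else "\t"


def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        frame = pd.read_csv(path, sep=_sep_for(path), index_col=0, float_precision="round_trip")
    except (pd.errors.ParserError, UnicodeDecodeError, ValueError) as exc:
        raise ValidationError(f"cannot parse {path}: {exc}") from exc
    if frame.index.has_duplicates:
        dup = frame.index[frame.index.duplicated()][:5].tolist()
        raise ValidationError(f"duplicate row labels in {path}: {dup}")
    if frame.columns.has_duplicates:
        dup = frame.columns[frame.columns.duplicated()][:5].tolist()
        raise ValidationError(f"duplicate column labels in {path}: {dup}")
    return frame


def read_expression(path, layout: str = "samples_by_genes") -> ExpressionMatrix:
    """Read a labelled delimited matrix, reorienting to samples x genes."""
    if layout not in LAYOUTS:
        raise ConfigError(f"layout must be one of {LAYOUTS}, got {layout!r}")
    frame = _read_table(path)
    try:
        values = frame.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        bad = [c for c in frame.columns if not pd.api.types.is_numeric_dtype(frame[c])]
        raise ValidationError(
            f"non-numeric cells in {path} (columns {bad[:5]}): {exc}"
        ) from exc
    if layout == "genes_by_samples":
        values = values.T
        sample_ids, gene_ids = tuple(frame.columns), tuple(frame.index)
    else:
        sample_ids, gene_ids = tuple(frame.index), tuple(frame.columns)
    return ExpressionMatrix(values, sample_ids=map(str, sample_ids), gene_ids=map(str, gene_ids))


def read_expression_mtx(
    mtx_path, row_labels_path, col_labels_path, layout: str = "samples_by_genes"
) -> ExpressionMatrix:
    """Read MatrixMarket coordinate triplets with one-label-per-line sidecars."""
    from scipy.io import mmread

    if layout not in LAYOUTS:
        raise ConfigError(f"layout must be one of {LAYOUTS}, got {layout!r}")
    mat = mmread(str(mtx_path))
    values = np.asarray(mat.todense() if hasattr(mat, "todense") else mat, dtype=float)
    rows = Path(row_labels_path).read_text().split()
    cols = Path(col_labels_path).read_text().split()
    if len(rows) != values.shape[0] or len(cols) != values.shape[1]:
        raise ValidationError(
            f"label sidecars ({len(rows)} x {len(cols)}) do not match matrix {values.shape}"
        )
    if layout == "genes_by_samples":
        values, rows, cols = values.T, cols, rows
    return ExpressionMatrix(values, sample_ids=rows, gene_ids=cols)


def read_covariates(path, standardize: bool = True) -> tuple[CovariateMatrix, dict]:
    """Read a covariate table, auto-coding two-level string columns to {-1, +1}.

    Returns the numeric matrix plus the coding record (level maps /
    standardisation constants) for provenance.
    """
    frame = _read_table(path)
    cov, coding = encode_covariate_frame(frame, standardize=standardize)
    for name, record in coding.items():
        if record["kind"] == "binary":
            logger.info("covariate %r coded %s", name, record["levels"])
    return cov, coding


def write_expression(expr: ExpressionMatrix, path) -> None:
    """Write samples x genes values as (optionally gzipped) delimited text."""
    path = Path(path)
    frame = pd.DataFrame(expr.values, index=list(expr.sample_ids), columns=list(expr.gene_ids))
    # %.17g round-trips IEEE binary64 exactly
    frame.to_csv(path, sep=_sep_for(path), float_format="%.17g")


def write_matrix_with_truth(expr, cov, truth, prefix) -> dict:
    """Write a simulated dataset: gzipped TSVs plus a JSON truth sidecar.

    Returns the paths written, keyed by role.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": prefix.with_suffix(".expression.tsv.gz"),
        "covariates": prefix.with_suffix(".covariates.tsv.gz"),
        "truth": prefix.with_suffix(".truth.json"),
    }
    write_expression(expr, paths["expression"])
    pd.DataFrame(
        cov.values, index=list(expr.sample_ids), columns=list(cov.covariate_ids)
    ).to_csv(paths["covariates"], sep="\t")
    with open(paths["truth"], "w") as fh:
        json.dump(truth.to_json_dict(), fh, indent=1)
    return {k: str(v) for k, v in paths.items()}
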