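"""File-format helpers shared by the CLI: count matrices, sheets, schemas.

Count matrices are accepted either as CSV (genes in rows, first column =
gene name) or MatrixMarket ``.mtx`` with two plain-text sidecars holding the
row (gene) and column (sample) names, one per line, at ``<stem>.rows.txt``
and ``<stem>.cols.txt``.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
import scipy.io
import scipy.sparse


class SchemaError(ValueError):
    """An input file violates its declared schema (exit code 3 in the CLI)."""


def sha256_of(path) -> str:
    """Hex digest of a file, for run logs and determinism checks."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def require_columns(df: pd.DataFrame, cols, what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing columns {missing}")


def read_counts(path) -> pd.DataFrame:
    """Read a gene-by-sample integer count matrix (CSV or MTX + sidecars)."""
    path = Path(path)
    if path.suffix == ".mtx":
        mat = scipy.io.mmread(path)
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        stem = path.with_suffix("")
        rows_file = Path(f"{stem}.rows.txt")
        cols_file = Path(f"{stem}.cols.txt")
        if not rows_file.exists() or not cols_file.exists():
            raise SchemaError(
                f"MTX sidecars not found: {rows_file}, {cols_file}")
        genes = rows_file.read_text().split()
        samples = cols_file.read_text().split()
        if mat.shape != (len(genes), len(samples)):
            raise SchemaError("MTX shape does not match sidecar name counts")
        df = pd.DataFrame(mat, index=pd.Index(genes, name="gene"),
                          columns=samples)
    else:
        df = pd.read_csv(path, index_col=0)
        df.index.name = "gene"
    if (df.to_numpy() < 0).any():
        raise SchemaError(f"{path}: negative counts")
    return df.astype(int)


def write_counts_mtx(counts: pd.DataFrame, path) -> None:
    """Write counts as MatrixMarket plus the two name sidecars."""
    path = Path(path)
    scipy.io.mmwrite(path, scipy.sparse.csr_matrix(counts.to_numpy()))
    stem = path.with_suffix("")
    Path(f"{stem}.rows.txt").write_text("\n".join(counts.index) + "\n")
    Path(f"{stem}.cols.txt").write_text("\n".join(counts.columns) + "\n")


def read_gene_lengths(path) -> pd.Series:
    """CSV with columns (gene, length_kb) -> Series indexed by gene."""
    df = pd.read_csv(path)
    require_columns(df, ["gene", "length_kb"], "gene lengths")
    s = df.set_index("gene")["length_kb"].astype(float)
    if (s <= 0).any():
        raise SchemaError("gene lengths must be positive")
    return s


def read_sample_sheet(path) -> pd.DataFrame:
    """Expression sample sheet: sample_id, timepoint[, tumor_fraction, ...]."""
    df = pd.read_csv(path)
    require_columns(df, ["sample_id", "timepoint"], "sample sheet")
    if df["sample_id"].duplicated().any():
        raise SchemaError("duplicate sample_id in sample sheet")
    return df


def read_patients(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    require_columns(df, ["patient_id", "best_response"], "patient table")
    return df


def read_ae(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    require_columns(df, ["patient_id", "ae_name", "grade"], "AE table")
    return df


def dump_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True,
                                     default=_json_default) + "\n")


def _json_default(o):
    import numpy as np

    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
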