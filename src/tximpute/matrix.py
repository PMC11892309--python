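"""Expression-matrix container and tab-delimited I/O.

The exchange format is plain tab-delimited text: one header row of sample
IDs, a first column of gene IDs, numeric body. Matrices are always held in
genes x samples orientation with a unit tag recording what the numbers are
(raw counts, CPM, log2 CPM, normalized values, or imputed expression).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VALID_UNITS = ("counts", "cpm", "log2cpm", "normalized", "imputed")


class MatrixValidationError(ValueError):
    """An expression matrix violates a structural invariant."""


class MatrixParseError(ValueError):
    """A file could not be parsed as an expression matrix."""


@dataclass
class ExpressionMatrix:
    """Gene x sample numeric expression matrix.

    Parameters
    ----------
    data
        DataFrame with gene IDs as the index and sample IDs as columns.
    unit
        One of ``counts``, ``cpm``, ``log2cpm``, ``normalized``, ``imputed``.
    """

    data: pd.DataFrame
    unit: str = "counts"

    def __post_init__(self) -> None:
        if self.unit not in VALID_UNITS:
            raise MatrixValidationError(
                f"unknown unit {self.unit!r}; expected one of {VALID_UNITS}"
            )
        if not self.data.index.is_unique:
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise MatrixValidationError(f"duplicate gene IDs: {dupes[:5]}")
        if not self.data.columns.is_unique:
            dupes = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise MatrixValidationError(f"duplicate sample IDs: {dupes[:5]}")
        values = self.data.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.number):
            raise MatrixValidationError("matrix body must be numeric")
        if values.size and not np.isfinite(values).all():
            bad = np.argwhere(~np.isfinite(values))[0]
            raise MatrixValidationError(
                "non-finite value at gene "
                f"{self.data.index[bad[0]]!r}, sample {self.data.columns[bad[1]]!r}"
            )
        if self.unit == "counts" and values.size and (values < 0).any():
            bad = np.argwhere(values < 0)[0]
            raise MatrixValidationError(
                "negative count at gene "
                f"{self.data.index[bad[0]]!r}, sample {self.data.columns[bad[1]]!r}"
            )

    # -- convenience accessors -------------------------------------------------

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def select_genes(self, gene_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[list(gene_ids)], self.unit)

    def select_samples(self, sample_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data[list(sample_ids)], self.unit)

    def with_values(self, values: np.ndarray, unit: str | None = None) -> "ExpressionMatrix":
        """Return a copy holding *values* (same shape/labels), optionally re-tagged."""
        df = pd.DataFrame(values, index=self.data.index, columns=self.data.columns)
        return ExpressionMatrix(df, self.unit if unit is None else unit)


def strip_gene_versions(ids) -> list[str]:
    """Remove a trailing ``.<integer>`` version suffix from each gene ID.

    IDs without a version suffix pass through untouched; order is preserved.
    """
    out = []
    for gid in ids:
        gid = str(gid)
        stem, dot, tail = gid.rpartition(".")
        out.append(stem if dot and tail.isdigit() else gid)
    return out


def collapse_duplicate_genes(df: pd.DataFrame) -> pd.DataFrame:
    """Resolve duplicate gene IDs by keeping, per ID, the row with the highest mean.

    Emits a warning listing the collapsed IDs. Used after version stripping,
    where distinct versioned IDs can collide.
    """
    if df.index.is_unique:
        return df
    dup_ids = df.index[df.index.duplicated()].unique().tolist()
    warnings.warn(
        f"{len(dup_ids)} duplicate gene ID(s) after version stripping; "
        f"keeping the highest-mean row for each (e.g. {dup_ids[:3]})",
        stacklevel=2,
    )
    means = df.mean(axis=1).to_numpy()
    order = np.argsort(-means, kind="stable")
    keep_mask = ~df.index[order].duplicated()
    kept_positions = np.sort(order[keep_mask])
    return df.iloc[kept_positions]


def read_expression_matrix(
    path, orientation: str = "genes_in_rows", unit: str = "counts"
) -> ExpressionMatrix:
    """Read a tab-delimited expression table into genes x samples orientation.

    ``orientation`` says how the *file* is laid out; the result is always
    genes x samples. Gene version suffixes are stripped; duplicates arising
    from stripping are collapsed to the highest-mean row with a warning.
    """
    if orientation not in ("genes_in_rows", "samples_in_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    with open(path, "rt", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    col_ids = header[1:]
    if len(set(col_ids)) != len(col_ids):
        dupes = sorted({c for c in col_ids if col_ids.count(c) > 1})
        raise MatrixValidationError(f"duplicate column IDs in header: {dupes[:5]}")
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    body = raw.apply(pd.to_numeric, errors="coerce")
    bad = body.isna() & raw.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise MatrixParseError(
            f"non-numeric cell {raw.iat[r, c]!r} at row {raw.index[r]!r}, "
            f"column {raw.columns[c]!r} in {path}"
        )
    if body.isna().to_numpy().any():
        r, c = np.argwhere(body.isna().to_numpy())[0]
        raise MatrixValidationError(
            f"missing value at row {raw.index[r]!r}, column {raw.columns[c]!r}"
        )
    if orientation == "samples_in_rows":
        body = body.T
    body.index = strip_gene_versions(body.index)
    body = collapse_duplicate_genes(body)
    body.index.name = "gene_id"
    return ExpressionMatrix(body.astype(float), unit)


def write_expression_matrix(m: ExpressionMatrix, path) -> None:
    """Write genes x samples tab-delimited text at full float precision."""
    m.data.to_csv(path, sep="\t", float_format="%.17g", index_label="gene_id")


def harmonize_genes(
    a: ExpressionMatrix, b: ExpressionMatrix
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Restrict two matrices to their shared genes, in a common order.

    Needed whenever a model trained on one dataset is applied to another
    (different annotation releases rarely share the full gene universe).
    """
    b_set = set(b.gene_ids)
    shared = [g for g in a.gene_ids if g in b_set]
    if not shared:
        raise ValueError("no shared genes between the two matrices")
    return a.select_genes(shared), b.select_genes(shared)


METADATA_REQUIRED = ("sample_id", "subject_id", "age", "sex")
LEUKOCYTE_COLUMNS = ("pct_neut", "pct_lymph", "pct_mono", "pct_eos")


def read_sample_metadata(path) -> pd.DataFrame:
    """Read a per-sample metadata table (tab-delimited).

    Required columns: sample_id, subject_id, age, sex. Optional: batch,
    disease_status, fev1_fvc, and the four leukocyte percentages
    (pct_neut, pct_lymph, pct_mono, pct_eos), which must be present or
    absent together within each row.
    """
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "subject_id": str})
    return validate_sample_metadata(meta)


def validate_sample_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in METADATA_REQUIRED if c not in meta.columns]
    if missing:
        raise MatrixValidationError(f"metadata missing required columns: {missing}")
    if meta["sample_id"].duplicated().any():
        dupes = meta.loc[meta["sample_id"].duplicated(), "sample_id"].tolist()
        raise MatrixValidationError(f"duplicate sample IDs in metadata: {dupes[:5]}")
    bad_sex = set(meta["sex"].dropna()) - {"male", "female"}
    if bad_sex:
        raise MatrixValidationError(f"sex must be male/female; got {sorted(bad_sex)}")
    present = [c for c in LEUKOCYTE_COLUMNS if c in meta.columns]
    if present and len(present) != len(LEUKOCYTE_COLUMNS):
        raise MatrixValidationError(
            "leukocyte percentages must be provided together; "
            f"found only {present}"
        )
    if present:
        partial = meta[list(LEUKOCYTE_COLUMNS)].isna().any(axis=1) & meta[
            list(LEUKOCYTE_COLUMNS)
        ].notna().any(axis=1)
        if partial.any():
            rows = meta.loc[partial, "sample_id"].tolist()
            raise MatrixValidationError(
                f"rows with partial leukocyte percentages: {rows[:5]}"
            )
        vals = meta[list(LEUKOCYTE_COLUMNS)].to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            out_of_range = (vals < 0) | (vals > 100)
        if np.nansum(out_of_range):
            raise MatrixValidationError("leukocyte percentages must lie in [0, 100]")
    return meta.set_index("sample_id", drop=False)
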