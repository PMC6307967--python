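"""Expression-matrix, metadata, and qPCR I/O plus scale transforms.

All tabular interchange is tab-delimited UTF-8 text with the identifier in
the first column and sample ids in the header row.  Matrices are stored
genes x samples and carry an explicit scale tag (``counts``, ``log2`` or
``centered_log2``); scale changes happen only through the declared
transform operations below.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

SCALES = ("counts", "log2", "centered_log2")

__all__ = [
    "ExpressionMatrix",
    "CtTable",
    "read_expression_table",
    "write_expression_table",
    "read_metadata",
    "write_metadata",
    "read_ct_table",
    "log2_transform",
    "zero_center_genes",
    "normalize_qpcr",
    "filter_expressed",
]


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values on a declared scale.

    Parameters
    ----------
    values : pandas.DataFrame
        Rows are gene symbols, columns are sample ids.
    scale : str
        One of ``counts``, ``log2``, ``centered_log2``.
    """

    values: pd.DataFrame
    scale: str

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise ValueError(f"unknown scale {self.scale!r}; expected one of {SCALES}")
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dupes}")
        if self.values.columns.duplicated().any():
            dupes = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dupes}")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValueError("expression values must be numeric")
        if not np.isfinite(arr).all():
            bad = np.argwhere(~np.isfinite(arr))[0]
            raise ValueError(
                f"non-finite value at gene {self.values.index[bad[0]]!r}, "
                f"sample {self.values.columns[bad[1]]!r}"
            )
        if self.scale == "counts" and (arr < 0).any():
            raise ValueError("counts must be nonnegative")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_genes(self, genes: list[str]) -> "ExpressionMatrix":
        missing = [g for g in genes if g not in self.values.index]
        if missing:
            raise KeyError(f"genes not in matrix: {missing}")
        return ExpressionMatrix(self.values.loc[genes].copy(), self.scale)

    def subset_samples(self, samples: list[str]) -> "ExpressionMatrix":
        missing = [s for s in samples if s not in self.values.columns]
        if missing:
            raise KeyError(f"samples not in matrix: {missing}")
        return ExpressionMatrix(self.values[samples].copy(), self.scale)


@dataclass
class CtTable:
    """qPCR cycle-threshold values with designated reference genes."""

    values: pd.DataFrame  # genes x samples, Ct cycles
    reference_genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValueError("duplicate gene ids in Ct table")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate sample ids in Ct table")
        missing = [g for g in self.reference_genes if g not in self.values.index]
        if missing:
            raise ValueError(f"reference genes absent from Ct table: {missing}")
        if not self.reference_genes:
            raise ValueError("at least one reference gene is required")
        arr = self.values.to_numpy(dtype=float)
        finite = arr[np.isfinite(arr)]
        if (finite <= 0).any():
            raise ValueError("Ct values must be positive")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


def read_expression_table(path: str | Path, scale: str) -> ExpressionMatrix:
    """Read a genes x samples TSV (first column gene ids, header sample ids)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path.name}: duplicated gene row(s): {dupes}")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            gene = df.index[bad.to_numpy().argmax()]
            raise ValueError(
                f"{path.name}: non-numeric cell at gene {gene!r}, sample {col!r}"
            )
        if coerced.isna().any():
            gene = df.index[coerced.isna().to_numpy().argmax()]
            raise ValueError(f"{path.name}: missing value at gene {gene!r}, sample {col!r}")
        df[col] = coerced
    return ExpressionMatrix(df.astype(float), scale)


def write_expression_table(m: ExpressionMatrix, path: str | Path) -> None:
    # %.17g guarantees binary round-trip of float64 values through text
    m.values.to_csv(path, sep="\t", index_label="gene_id", float_format="%.17g")


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read a sample-metadata TSV indexed by sample_id."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        raise ValueError("duplicate sample ids in metadata")
    # lung-area percentages are fractions of a whole; FEV1 %-predicted is
    # relative to a reference and may legitimately exceed 100
    for col in df.columns:
        if col.startswith("prm_") and col.endswith("_pct"):
            vals = df[col].dropna()
            if ((vals < 0) | (vals > 100)).any():
                raise ValueError(f"metadata column {col!r} outside [0, 100]")
    return df


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index_label="sample_id")


def read_ct_table(path: str | Path, reference_genes: list[str]) -> CtTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return CtTable(df.astype(float), list(reference_genes))


def log2_transform(m: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """log2(count + pseudocount) for a counts matrix."""
    if m.scale != "counts":
        raise ValueError(f"log2_transform expects counts, got {m.scale!r}")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    if pseudocount == 0 and (m.values.to_numpy() == 0).any():
        raise ValueError("pseudocount 0 with zero counts would produce -inf")
    return ExpressionMatrix(np.log2(m.values + pseudocount), "log2")


def zero_center_genes(
    m: ExpressionMatrix, reference_samples: list[str] | None = None
) -> ExpressionMatrix:
    """Subtract each gene's mean over the reference samples from its row.

    The reference defaults to all samples of the matrix, matching the
    within-dataset centering used for signature scoring.
    """
    if m.scale not in ("log2", "centered_log2"):
        raise ValueError(f"zero_center_genes expects log2-scale values, got {m.scale!r}")
    if reference_samples is None:
        ref = m.values
    else:
        if len(reference_samples) == 0:
            raise ValueError("reference sample set is empty")
        missing = [s for s in reference_samples if s not in m.values.columns]
        if missing:
            raise KeyError(f"reference samples not in matrix: {missing}")
        ref = m.values[list(reference_samples)]
    centered = m.values.sub(ref.mean(axis=1), axis=0)
    return ExpressionMatrix(centered, "centered_log2")


def normalize_qpcr(ct: CtTable) -> ExpressionMatrix:
    """Reference-gene delta-Ct normalization.

    Per sample, expression(g) = mean(Ct of reference genes) - Ct(g), in
    log2 units (one PCR cycle = one doubling).  Reference-gene rows are
    retained with their own normalized values.
    """
    ref = ct.values.loc[ct.reference_genes]
    if ref.isna().any().any():
        sample = ref.columns[ref.isna().any(axis=0).to_numpy().argmax()]
        raise ValueError(f"missing reference-gene Ct in sample {sample!r}")
    ref_mean = ref.mean(axis=0)
    expr = (-ct.values).add(ref_mean, axis=1)
    return ExpressionMatrix(expr, "log2")


def filter_expressed(
    m: ExpressionMatrix, background_threshold: float, min_fraction: float = 0.1
) -> tuple[ExpressionMatrix, list[str]]:
    """Drop genes not expressed above background often enough.

    A gene is kept when its expression exceeds ``background_threshold`` in at
    least ``min_fraction`` of samples; removed genes are returned for
    reporting (e.g. signature adaptation records them as background
    exclusions).
    """
    if not 0 <= min_fraction <= 1:
        raise ValueError("min_fraction must lie in [0, 1]")
    if m.scale not in ("log2", "centered_log2"):
        raise ValueError("filter_expressed expects a log2-scale matrix")
    frac = (m.values > background_threshold).mean(axis=1)
    keep = frac >= min_fraction
    excluded = list(m.values.index[~keep])
    if not keep.any():
        warnings.warn("all genes fall below the background rule", stacklevel=2)
    return ExpressionMatrix(m.values.loc[keep].copy(), m.scale), excluded
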