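"""Paired stimulated-vs-control differential expression and candidate selection.

Stage 1 of the signature pipeline: rank genes by their response to cytokine
stimulation in paired air-liquid-interface cultures.  Normalization uses
median-of-ratios size factors; inference is a paired t-test on per-donor
log2 ratios — a deliberately transparent simplification of negative-binomial
GLM testing that is adequate for ranking candidates by log2 fold change.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .expr_io import ExpressionMatrix

__all__ = [
    "PairedDesign",
    "CandidateSet",
    "size_factors",
    "paired_de",
    "bh_fdr",
    "select_candidates",
]


@dataclass
class PairedDesign:
    """Matched (stimulated, control) sample pairs from the same donor."""

    pairs: list[tuple[str, str]]

    def __post_init__(self) -> None:
        flat = [s for pair in self.pairs for s in pair]
        if len(set(flat)) != len(flat):
            raise ValueError("each sample may appear in exactly one pair")
        if not self.pairs:
            raise ValueError("at least one pair is required")

    def validate_against(self, m: ExpressionMatrix) -> None:
        missing = [s for pair in self.pairs for s in pair if s not in m.values.columns]
        if missing:
            raise KeyError(f"design samples absent from matrix: {missing}")

    @classmethod
    def from_table(cls, path) -> "PairedDesign":
        df = pd.read_csv(path, sep="\t")
        if not {"stimulated_id", "control_id"} <= set(df.columns):
            raise ValueError("pairs table needs columns stimulated_id, control_id")
        return cls(list(zip(df["stimulated_id"].astype(str), df["control_id"].astype(str))))


@dataclass
class CandidateSet:
    """Top-k upregulated genes, ordered by descending log2 fold change."""

    genes: list[str]
    k: int
    fdr_cutoff: float | None = None

    def __post_init__(self) -> None:
        if len(self.genes) != len(set(self.genes)):
            raise ValueError("duplicate genes in candidate set")
        if len(self.genes) > self.k:
            raise ValueError("candidate set larger than k")


def size_factors(counts: ExpressionMatrix) -> pd.Series:
    """Median-of-ratios normalization factors, rescaled to geometric mean 1.

    Only genes with strictly positive counts in every sample contribute to
    the reference, so appending all-zero or partially zero genes leaves the
    factors unchanged.
    """
    if counts.scale != "counts":
        raise ValueError("size_factors expects a counts matrix")
    arr = counts.values.to_numpy(dtype=float)
    if arr.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    pos = (arr > 0).all(axis=1)
    if not pos.any():
        raise ValueError("no gene has positive counts in all samples")
    logs = np.log(arr[pos])
    log_ratios = logs - logs.mean(axis=1, keepdims=True)
    log_sf = np.median(log_ratios, axis=0)
    log_sf = log_sf - log_sf.mean()  # geometric mean of factors = 1
    return pd.Series(np.exp(log_sf), index=counts.values.columns, name="size_factor")


def paired_de(
    counts: ExpressionMatrix,
    design: PairedDesign,
    factors: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-gene paired differential expression.

    Returns a DataFrame indexed by gene with columns ``log2fc`` (mean over
    pairs of log2((stim/sf + 1)/(ctrl/sf + 1))), ``p_value`` (two-sided
    paired t-test on the per-pair log2 differences) and ``q_value``
    (Benjamini-Hochberg).  Zero-variance differences get p = 1 by
    convention.  With a single pair only the fold change is computable and
    p/q are NaN.
    """
    if counts.scale != "counts":
        raise ValueError("paired_de expects a counts matrix")
    design.validate_against(counts)
    if factors is None:
        factors = size_factors(counts)
    norm = counts.values.div(factors, axis=1)
    diffs = np.column_stack(
        [
            np.log2(norm[stim].to_numpy() + 1.0) - np.log2(norm[ctrl].to_numpy() + 1.0)
            for stim, ctrl in design.pairs
        ]
    )
    log2fc = diffs.mean(axis=1)
    n_pairs = diffs.shape[1]
    if n_pairs >= 2:
        sd = diffs.std(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = log2fc / (sd / np.sqrt(n_pairs))
        p = 2.0 * stats.t.sf(np.abs(t), df=n_pairs - 1)
        p = np.where(sd == 0, 1.0, p)
        p = np.clip(p, np.finfo(float).tiny, 1.0)
        q = bh_fdr(p)
    else:
        p = np.full(len(log2fc), np.nan)
        q = np.full(len(log2fc), np.nan)
    return pd.DataFrame(
        {"log2fc": log2fc, "p_value": p, "q_value": q}, index=counts.values.index
    )


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved.

    q_(i) = min_{j >= i} min(1, p_(j) * m / j) over the sorted p-values.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a nonempty 1-D array")
    if np.isnan(p).any() or (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


def select_candidates(
    results: pd.DataFrame, k: int = 100, fdr_max: float | None = 0.05
) -> CandidateSet:
    """Top-k genes by descending log2fc among significantly upregulated genes.

    ``fdr_max=None`` disables the significance filter (ranking over all
    upregulated genes).  Ties are broken by ascending q-value then gene id.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    df = results.copy()
    eligible = df["log2fc"] > 0
    if fdr_max is not None:
        eligible &= df["q_value"] <= fdr_max
    df = df[eligible].copy()
    df["_gene"] = df.index.astype(str)
    df = df.sort_values(
        by=["log2fc", "q_value", "_gene"],
        ascending=[False, True, True],
        kind="stable",
    )
    genes = list(df.index[:k])
    if len(genes) < k:
        warnings.warn(
            f"only {len(genes)} eligible genes for a requested top-{k} set",
            stacklevel=2,
        )
    return CandidateSet(genes=genes, k=k, fdr_cutoff=fdr_max)
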