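"""Per-sample signature scores.

The primary metric is the mean of the zero-centered log2 expression of the
signature genes (equal weights, centering over a reference sample set that
defaults to the cohort being scored).  A standardized-mean mode (per-gene
z-score, then mean) is provided for generic gene-set covariate scores such
as the three-gene type-2 score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expr_io import ExpressionMatrix
from .signature_refine import Signature

MODES = ("zero_centered_mean", "standardized_mean")

__all__ = ["ScoreVector", "score_samples", "score_gene_set"]


@dataclass
class ScoreVector:
    """Per-sample signature scores in centered-log2 (or z-score) units."""

    scores: pd.Series
    signature_id: str
    mode: str
    reference_samples: list[str] = field(default_factory=list)
    genes_used: list[str] = field(default_factory=list)
    genes_skipped: list[str] = field(default_factory=list)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.scores.index)

    def to_frame(self) -> pd.DataFrame:
        return self.scores.rename("score").rename_axis("sample_id").reset_index()


def _score(
    m: ExpressionMatrix,
    genes: list[str],
    mode: str,
    reference_samples: list[str] | None,
    signature_id: str,
    skipped: list[str],
) -> ScoreVector:
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    if m.scale not in ("log2", "centered_log2"):
        raise ValueError("scoring expects a log2-scale matrix")
    if not genes:
        raise ValueError("no signature genes present in the matrix")
    sub = m.values.loc[genes]
    ref_ids = list(reference_samples) if reference_samples else list(m.values.columns)
    missing_ref = [s for s in ref_ids if s not in m.values.columns]
    if missing_ref:
        raise KeyError(f"reference samples not in matrix: {missing_ref}")
    ref = sub[ref_ids]
    centered = sub.sub(ref.mean(axis=1), axis=0)
    if mode == "standardized_mean":
        sd = ref.std(axis=1, ddof=1)
        zero_var = sd[sd == 0]
        if len(zero_var):
            raise ValueError(
                f"zero-variance gene(s) under standardized_mean: {list(zero_var.index)}"
            )
        centered = centered.div(sd, axis=0)
    scores = centered.mean(axis=0)
    scores.name = "score"
    return ScoreVector(
        scores=scores,
        signature_id=signature_id,
        mode=mode,
        reference_samples=ref_ids,
        genes_used=genes,
        genes_skipped=skipped,
    )


def score_samples(
    m: ExpressionMatrix,
    sig: Signature,
    mode: str = "zero_centered_mean",
    reference_samples: list[str] | None = None,
) -> ScoreVector:
    """Score every sample of ``m`` against a signature.

    Signature genes absent from the matrix are skipped only when the
    signature records them as excluded (platform adaptation); otherwise the
    absence is an error, since silently dropping genes would change the
    metric.
    """
    present = [g for g in sig.genes if g in m.values.index]
    missing = [g for g in sig.genes if g not in m.values.index]
    unexplained = [g for g in missing if g not in sig.excluded_genes]
    if unexplained:
        raise KeyError(
            f"signature genes absent from matrix without recorded exclusion: {unexplained}"
        )
    return _score(m, present, mode, reference_samples, sig.anchor, missing)


def score_gene_set(
    m: ExpressionMatrix,
    genes: list[str],
    mode: str = "standardized_mean",
    reference_samples: list[str] | None = None,
) -> ScoreVector:
    """Score an ad-hoc gene list (e.g. the POSTN/SERPINB2/CLCA1 type-2 set)."""
    if len(genes) != len(set(genes)):
        raise ValueError("duplicate genes in gene set")
    missing = [g for g in genes if g not in m.values.index]
    if missing:
        raise KeyError(f"gene-set members absent from matrix: {missing}")
    return _score(m, list(genes), mode, reference_samples, "+".join(genes), [])
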