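"""Covariate-adjusted association, interaction, and biomarker models.

Cross-sectional associations between the signature score and clinical
variables use ordinary least squares (or logistic regression for binary
outcomes), before and after adjustment for age and smoking status.  The
randomized-trial analysis relates change in lung function to the
treatment x baseline-score interaction.  Repeated-biopsy designs use a
random-intercept linear mixed model for the treatment x time interaction.
Biomarker performance is summarized by Mann-Whitney AUC and 2x2
sensitivity/specificity for the dichotomized signature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .signature_score import ScoreVector
from .stim_de import bh_fdr

__all__ = [
    "AssociationResult",
    "InteractionResult",
    "BiomarkerPerformance",
    "linear_assoc",
    "spearman",
    "interaction_trial",
    "mixed_effects_longitudinal",
    "roc_auc",
    "dichotomized_performance",
    "adjust_family",
]


@dataclass
class AssociationResult:
    params: pd.Series
    bse: pd.Series
    p_values: pd.Series
    model: str
    n: int
    q_values: pd.Series | None = None

    def term(self, name: str) -> tuple[float, float, float]:
        return (
            float(self.params[name]),
            float(self.bse[name]),
            float(self.p_values[name]),
        )


@dataclass
class InteractionResult:
    coefficient: float  # treatment x baseline score -> delta outcome
    se: float
    p_value: float
    conf_int: tuple[float, float]
    r_squared_treated: float  # score-only model within the treated arm
    n: int
    params: pd.Series | None = None
    p_values: pd.Series | None = None


@dataclass
class BiomarkerPerformance:
    auc: float | None = None
    sensitivity: float | None = None
    specificity: float | None = None
    cutoff: float | str | None = None
    table: dict | None = None


def _as_series(x, name: str) -> pd.Series:
    if isinstance(x, ScoreVector):
        return x.scores.rename(name)
    if isinstance(x, pd.Series):
        return x.rename(name)
    return pd.Series(np.asarray(x, dtype=float), name=name)


def _check_rank(design: pd.DataFrame) -> None:
    arr = design.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        # identify a minimal offending column by greedy removal
        cols = list(design.columns)
        for c in cols:
            reduced = design.drop(columns=c).to_numpy(dtype=float)
            if np.linalg.matrix_rank(reduced) == rank:
                raise ValueError(f"collinear design: column {c!r} is redundant")
        raise ValueError(f"collinear design among columns {cols}")


def linear_assoc(
    outcome,
    score,
    covariates: pd.DataFrame | None = None,
    logistic: bool = False,
) -> AssociationResult:
    """Outcome ~ score (+ covariates); Wald p for the score term.

    Complete cases only; binary outcomes use logistic maximum likelihood.
    """
    y = _as_series(outcome, "outcome")
    s = _as_series(score, "score")
    frames = [y, s]
    if covariates is not None:
        frames.append(covariates)
    df = pd.concat(frames, axis=1, join="inner").dropna()
    n_cov = 0 if covariates is None else covariates.shape[1]
    if len(df) < n_cov + 2:
        raise ValueError("too few complete cases for the requested model")
    design = sm.add_constant(df.drop(columns="outcome").astype(float))
    _check_rank(design)
    if logistic:
        model = sm.Logit(df["outcome"].astype(float), design)
        fit = model.fit(disp=0)
        desc = "logistic"
    else:
        fit = sm.OLS(df["outcome"].astype(float), design).fit()
        desc = "ols"
    return AssociationResult(
        params=fit.params,
        bse=fit.bse,
        p_values=fit.pvalues,
        model=desc,
        n=len(df),
    )


def adjust_family(results: list[AssociationResult], term: str = "score") -> list[AssociationResult]:
    """BH-adjust the score-term p-values across a declared family of outcomes."""
    ps = np.array([r.p_values[term] for r in results])
    qs = bh_fdr(np.clip(ps, np.finfo(float).tiny, 1.0))
    for r, q in zip(results, qs):
        r.q_values = pd.Series({term: q})
    return results


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with t-approximation p-value."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1 or len(xa) < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    if np.all(xa == xa[0]) or np.all(ya == ya[0]):
        raise ValueError("Spearman correlation undefined for a constant vector")
    rho, p = stats.spearmanr(xa, ya)
    return float(rho), float(p)


def interaction_trial(
    delta_outcome,
    treatment,
    baseline_score,
    covariates: pd.DataFrame | None = None,
) -> InteractionResult:
    """Treatment x baseline-score interaction on change in outcome.

    Fits delta = b0 + b1*treatment + b2*score + b3*(treatment x score)
    (+ covariates) by OLS and reports b3 with its Wald p and 95% CI, plus
    the r-squared of the score-only model within the treated arm.
    Secondary adjustment variants (eosinophils, type-2 score, neutrophils,
    macrophages) are passed through ``covariates``.
    """
    delta = _as_series(delta_outcome, "delta")
    trt = _as_series(treatment, "treatment").astype(float)
    score = _as_series(baseline_score, "score")
    frames = [delta, trt, score]
    if covariates is not None:
        frames.append(covariates)
    df = pd.concat(frames, axis=1, join="inner").dropna()
    arms = df["treatment"].unique()
    if len(arms) < 2:
        raise ValueError("both treatment arms must be represented")
    df["treatment_x_score"] = df["treatment"] * df["score"]
    design = sm.add_constant(df.drop(columns="delta").astype(float))
    _check_rank(design)
    fit = sm.OLS(df["delta"], design).fit()
    ci = fit.conf_int().loc["treatment_x_score"]
    treated = df[df["treatment"] == df["treatment"].max()]
    fit_treated = sm.OLS(
        treated["delta"], sm.add_constant(treated[["score"]])
    ).fit()
    return InteractionResult(
        coefficient=float(fit.params["treatment_x_score"]),
        se=float(fit.bse["treatment_x_score"]),
        p_value=float(fit.pvalues["treatment_x_score"]),
        conf_int=(float(ci[0]), float(ci[1])),
        r_squared_treated=float(fit_treated.rsquared),
        n=len(df),
        params=fit.params,
        p_values=fit.pvalues,
    )


def mixed_effects_longitudinal(
    score,
    treatment,
    time,
    subject,
) -> AssociationResult:
    """Random-intercept mixed model: score ~ treatment * time, subject random.

    REML fit; the treatment x time Wald statistic is referred to a t
    distribution with between-within denominator degrees of freedom
    df = (N - n_subjects) - 2 (the within-subject fixed terms), which for
    the balanced two-timepoint design reduces to the exact two-sample t
    test on subject-level changes.
    """
    s = _as_series(score, "score")
    df = pd.DataFrame(
        {
            "score": s.to_numpy(dtype=float),
            "treatment": np.asarray(treatment, dtype=float),
            "time": np.asarray(time, dtype=float),
            "subject": np.asarray(subject).astype(str),
        }
    )
    if df["time"].nunique() < 2:
        raise ValueError("need at least 2 timepoints")
    df["treatment_x_time"] = df["treatment"] * df["time"]
    exog = sm.add_constant(df[["treatment", "time", "treatment_x_time"]])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(df["score"], exog, groups=df["subject"])
        fit = model.fit(reml=True)
    params = fit.fe_params
    bse = fit.bse_fe
    n_subjects = df["subject"].nunique()
    ddf = (len(df) - n_subjects) - 2
    if ddf < 1:
        raise ValueError("not enough observations for the interaction test")
    tvals = params / bse
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df=ddf)
    return AssociationResult(
        params=params,
        bse=bse,
        p_values=pd.Series(pvals, index=params.index),
        model=f"mixedlm-reml (between-within df={ddf})",
        n=len(df),
    )


def roc_auc(scores, binary_labels, cutoff: float | None = None) -> BiomarkerPerformance:
    """Mann-Whitney AUC with optional sensitivity/specificity at a cutoff.

    AUC = P(score_pos > score_neg) + 0.5 * P(tie), computed via midranks
    (exactly the all-pairs count).  A sample is called test-positive when
    its score >= cutoff.
    """
    s = np.asarray(
        scores.scores if isinstance(scores, ScoreVector) else scores, dtype=float
    )
    labels = np.asarray(binary_labels, dtype=bool)
    if s.shape != labels.shape:
        raise ValueError("scores/labels length mismatch")
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(s)
    auc = (ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    sens = spec = None
    if cutoff is not None:
        called = s >= cutoff
        sens = float((called & labels).sum() / n_pos)
        spec = float((~called & ~labels).sum() / n_neg)
    return BiomarkerPerformance(
        auc=float(auc), sensitivity=sens, specificity=spec, cutoff=cutoff
    )


def dichotomized_performance(labels, responder) -> BiomarkerPerformance:
    """Sensitivity/specificity of the high/low call for non-response.

    ``high`` is the test-positive call for the event "no improvement"
    (steroid unresponsiveness); specificity = TN / (TN + FP) among
    responders, sensitivity = TP / (TP + FN) among non-responders.
    Trimmed samples should be excluded before calling this.
    """
    lab = pd.Series(labels).astype(str)
    resp = np.asarray(responder, dtype=bool)
    if set(lab.unique()) - {"high", "low"}:
        raise ValueError("labels must be 'high'/'low' only (drop trimmed samples)")
    if lab.nunique() < 2 or len(np.unique(resp)) < 2:
        raise ValueError("need both label values and both responder values")
    positive = (lab == "high").to_numpy()
    event = ~resp  # non-response is the event being detected
    tp = int((positive & event).sum())
    fn = int((~positive & event).sum())
    fp = int((positive & ~event).sum())
    tn = int((~positive & ~event).sum())
    sens = tp / (tp + fn) if (tp + fn) else None
    spec = tn / (tn + fp) if (tn + fp) else None
    return BiomarkerPerformance(
        sensitivity=sens,
        specificity=spec,
        cutoff="high/low label",
        table={"tp": tp, "fn": fn, "fp": fp, "tn": tn},
    )
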