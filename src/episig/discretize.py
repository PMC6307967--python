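"""Dichotomization of participants into signature-high/low.

Samples are clustered on their (centered) signature-gene expression with
Euclidean average linkage; the number of clusters is chosen by a majority
vote over a declared panel of internal cluster-validity indices; clusters
with mean score above the majority (low) cluster are merged into the
"high" group.  Cohorts are first stratified by smoking status because of
its large effect on airway gene expression, and a configurable fraction of
samples with scores nearest the high/low boundary is trimmed before
downstream dichotomized analyses.  A top-quartile rule is provided as the
simpler alternative cutoff.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .expr_io import ExpressionMatrix
from .signature_score import ScoreVector

__all__ = [
    "Dendrogram",
    "DiscretizationResult",
    "average_linkage_dendrogram",
    "cut_k",
    "validity_indices",
    "consensus_k",
    "assign_high_low",
    "stratified_discretize",
    "quartile_rule",
]

#: index name -> optimization direction ("max" better or "min" better).
#: "wss" carries no direction: it votes through an elbow rule in consensus_k.
INDEX_PANEL = {
    "calinski_harabasz": "max",
    "silhouette": "max",
    "davies_bouldin": "min",
    "dunn": "max",
    "c_index": "min",
    "mcclain_rao": "min",
    "point_biserial": "max",
    "wss": "elbow",
}


@dataclass
class Dendrogram:
    """Average-linkage merge tree.

    ``merges`` rows are (cluster_a, cluster_b, height, size) in scipy
    linkage convention: leaves are 0..n-1, the i-th merge creates cluster
    n+i.  Ties in merge height are broken toward the pair whose minimal
    member sample-ids sort first.
    """

    sample_ids: list[str]
    merges: np.ndarray  # (n-1, 4)

    @property
    def n(self) -> int:
        return len(self.sample_ids)


def _as_points(points) -> tuple[np.ndarray, list[str]]:
    if isinstance(points, pd.DataFrame):
        return points.to_numpy(dtype=float), [str(i) for i in points.index]
    arr = np.asarray(points, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return arr, [str(i) for i in range(arr.shape[0])]


def average_linkage_dendrogram(points, sample_ids: list[str] | None = None) -> Dendrogram:
    """Agglomerative UPGMA on Euclidean distances.

    At each step the pair of clusters with the smallest average pairwise
    point distance is merged (Lance-Williams average update, which is exact
    for UPGMA).  Equal distances are resolved deterministically by the
    lexicographically smallest pair of minimal member ids.
    """
    X, ids = _as_points(points)
    if sample_ids is not None:
        if len(sample_ids) != X.shape[0]:
            raise ValueError("sample_ids length mismatch")
        ids = [str(s) for s in sample_ids]
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples to cluster")
    if not np.isfinite(X).all():
        raise ValueError("non-finite feature values")

    D = squareform(pdist(X))
    active: dict[int, dict] = {
        i: {"size": 1, "min_id": ids[i]} for i in range(n)
    }
    dist: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = D[i, j]

    merges = np.zeros((n - 1, 4))
    next_id = n
    for step in range(n - 1):
        best_key = None
        best_pair = None
        for (ci, cj), d in dist.items():
            a, b = sorted((active[ci]["min_id"], active[cj]["min_id"]))
            key = (d, a, b)
            if best_key is None or key < best_key:
                best_key, best_pair = key, (ci, cj)
        ci, cj = best_pair
        d = dist.pop((ci, cj))
        ni, nj = active[ci]["size"], active[cj]["size"]
        new = {
            "size": ni + nj,
            "min_id": min(active[ci]["min_id"], active[cj]["min_id"]),
        }
        merges[step] = (min(ci, cj), max(ci, cj), d, ni + nj)
        for ck in list(active):
            if ck in (ci, cj):
                continue
            d_ki = dist.pop((min(ck, ci), max(ck, ci)))
            d_kj = dist.pop((min(ck, cj), max(ck, cj)))
            dist[(ck, next_id)] = (ni * d_ki + nj * d_kj) / (ni + nj)
        del active[ci], active[cj]
        active[next_id] = new
        next_id += 1
    return Dendrogram(sample_ids=ids, merges=merges)


def cut_k(tree: Dendrogram, k: int) -> pd.Series:
    """Cut the dendrogram into k clusters.

    Returns integer labels (0..k-1, numbered by each cluster's minimal
    member position) indexed by sample id.
    """
    n = tree.n
    if not 1 <= k <= n:
        raise ValueError(f"k must lie in [1, {n}]")
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    for step in range(n - k):
        a, b, _, _ = tree.merges[step]
        new = n + step
        members[new] = members.pop(int(a)) + members.pop(int(b))
    clusters = sorted(members.values(), key=min)
    labels = np.empty(n, dtype=int)
    for lab, idxs in enumerate(clusters):
        labels[idxs] = lab
    return pd.Series(labels, index=tree.sample_ids, name="cluster")


def _pairwise_masks(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    same = labels[:, None] == labels[None, :]
    iu = np.triu_indices(len(labels), k=1)
    return same[iu], iu


def validity_indices(points, labels) -> dict[str, float]:
    """Internal cluster-validity indices from their literature formulas.

    Returns ``{name: value}`` for the panel in :data:`INDEX_PANEL`;
    indices that are undefined for the given partition (e.g. silhouette
    with only singleton clusters) are returned as NaN and excluded from
    consensus voting.
    """
    X, _ = _as_points(points)
    lab = np.asarray(labels if not isinstance(labels, pd.Series) else labels.to_numpy())
    if X.shape[0] != lab.shape[0]:
        raise ValueError("points/labels length mismatch")
    uniq = np.unique(lab)
    k, n = len(uniq), X.shape[0]
    if k < 2:
        raise ValueError("need at least 2 clusters")

    out: dict[str, float] = {}
    D = squareform(pdist(X))
    centroids = np.vstack([X[lab == c].mean(axis=0) for c in uniq])
    sizes = np.array([(lab == c).sum() for c in uniq])
    overall = X.mean(axis=0)

    # within/between sums of squares (Calinski-Harabasz, WSS)
    wss_per = np.array(
        [np.sum((X[lab == c] - centroids[i]) ** 2) for i, c in enumerate(uniq)]
    )
    wss = wss_per.sum()
    bss = float(np.sum(sizes * np.sum((centroids - overall) ** 2, axis=1)))
    out["wss"] = float(wss)
    out["calinski_harabasz"] = (
        (bss / (k - 1)) / (wss / (n - k)) if wss > 0 else np.nan
    )

    # silhouette (singleton samples contribute 0, as is conventional)
    if np.all(sizes == 1):
        out["silhouette"] = np.nan
    else:
        s = np.zeros(n)
        for i in range(n):
            own = lab == lab[i]
            if own.sum() == 1:
                s[i] = 0.0
                continue
            a = D[i, own & (np.arange(n) != i)].mean()
            b = min(D[i, lab == c].mean() for c in uniq if c != lab[i])
            s[i] = (b - a) / max(a, b) if max(a, b) > 0 else 0.0
        out["silhouette"] = float(s.mean())

    # Davies-Bouldin
    scatter = np.array(
        [
            np.mean(np.linalg.norm(X[lab == c] - centroids[i], axis=1))
            for i, c in enumerate(uniq)
        ]
    )
    db_terms = []
    for i in range(k):
        ratios = [
            (scatter[i] + scatter[j]) / np.linalg.norm(centroids[i] - centroids[j])
            for j in range(k)
            if j != i and np.linalg.norm(centroids[i] - centroids[j]) > 0
        ]
        if ratios:
            db_terms.append(max(ratios))
    out["davies_bouldin"] = float(np.mean(db_terms)) if db_terms else np.nan

    # Dunn: min between-cluster distance / max cluster diameter
    same, iu = _pairwise_masks(lab)
    dvec = D[iu]
    within = dvec[same]
    between = dvec[~same]
    max_diam = within.max() if within.size else 0.0
    if within.size == 0 or max_diam == 0:
        out["dunn"] = np.nan
    else:
        out["dunn"] = float(between.min() / max_diam)

    # C-index
    nw = within.size
    if nw == 0 or between.size == 0:
        out["c_index"] = np.nan
        out["mcclain_rao"] = np.nan
        out["point_biserial"] = np.nan
        return out
    s_w = within.sum()
    d_sorted = np.sort(dvec)
    s_min = d_sorted[:nw].sum()
    s_max = d_sorted[-nw:].sum()
    out["c_index"] = (
        float((s_w - s_min) / (s_max - s_min)) if s_max > s_min else np.nan
    )

    # McClain-Rao: mean within / mean between distance
    mean_b = between.mean()
    out["mcclain_rao"] = float(within.mean() / mean_b) if mean_b > 0 else np.nan

    # point-biserial correlation of distances with the between-pair indicator
    nt = dvec.size
    sd_all = dvec.std()
    if sd_all == 0:
        out["point_biserial"] = np.nan
    else:
        out["point_biserial"] = float(
            (mean_b - within.mean()) * np.sqrt(nw * between.size / nt**2) / sd_all
        )
    return out


def consensus_k(
    points,
    k_range=range(2, 7),
    sample_ids: list[str] | None = None,
    tree: Dendrogram | None = None,
) -> tuple[int, pd.DataFrame]:
    """Choose the number of clusters by a majority vote of validity indices.

    For each k in ``k_range`` the dendrogram is cut and the index panel is
    computed; each defined index votes for its optimal k (the WSS index
    votes through the largest second difference, i.e. the elbow); the
    consensus is the modal vote, ties broken toward smaller k.

    Returns ``(best_k, table)`` where ``table`` has one row per index with
    its per-k values and its vote.
    """
    ks = sorted(set(int(k) for k in k_range))
    X, ids = _as_points(points)
    if sample_ids is not None:
        ids = [str(s) for s in sample_ids]
    if not ks:
        raise ValueError("empty k_range")
    if ks[0] < 2 or ks[-1] > X.shape[0] - 1:
        raise ValueError("k_range must lie within [2, n-1]")
    if tree is None:
        tree = average_linkage_dendrogram(X, ids)
    values = {k: validity_indices(X, cut_k(tree, k).to_numpy()) for k in ks}

    table = pd.DataFrame({k: pd.Series(values[k]) for k in ks})
    votes: dict[str, float] = {}
    for name, direction in INDEX_PANEL.items():
        row = table.loc[name]
        defined = row.dropna()
        if direction == "elbow":
            wss = row.to_numpy(dtype=float)
            if len(ks) < 3 or np.isnan(wss).any():
                votes[name] = np.nan
                continue
            second_diff = wss[:-2] - 2 * wss[1:-1] + wss[2:]
            votes[name] = ks[1 + int(np.argmax(second_diff))]
        elif defined.empty:
            votes[name] = np.nan
        elif direction == "max":
            votes[name] = int(defined.idxmax())  # first (smallest k) on ties
        else:
            votes[name] = int(defined.idxmin())
    table["vote"] = pd.Series(votes)

    cast = [int(v) for v in votes.values() if not np.isnan(v)]
    if not cast:
        raise ValueError("no validity index produced a defined vote")
    counts = pd.Series(cast).value_counts()
    top = counts[counts == counts.max()].index
    best_k = int(min(top))
    return best_k, table


def assign_high_low(labels, scores: ScoreVector | pd.Series) -> pd.Series:
    """Label clusters high/low relative to the majority cluster.

    The largest cluster (ties: the one with the lower mean score) anchors
    the "low" group; every cluster with mean score above it is merged into
    "high"; clusters at or below the majority mean — including low-scoring
    outlier singletons — stay "low".
    """
    s = scores.scores if isinstance(scores, ScoreVector) else scores
    lab = labels if isinstance(labels, pd.Series) else pd.Series(np.asarray(labels))
    if not lab.index.equals(s.index):
        s = s.loc[lab.index]
    stats = pd.DataFrame({"cluster": lab, "score": s}).groupby("cluster")["score"].agg(
        ["size", "mean"]
    )
    if len(stats) == 1:
        warnings.warn("single cluster: all samples labeled low", stacklevel=2)
        return pd.Series("low", index=lab.index, name="label")
    majority = stats.sort_values(["size", "mean"], ascending=[False, True]).index[0]
    majority_mean = stats.loc[majority, "mean"]
    high_clusters = stats.index[stats["mean"] > majority_mean]
    out = lab.isin(high_clusters).map({True: "high", False: "low"})
    out.name = "label"
    return out


@dataclass
class DiscretizationResult:
    """High/low/trimmed labels with the per-stratum clustering audit trail."""

    labels: pd.Series  # values in {high, low, trimmed}
    method: str
    chosen_k: dict[str, int] = field(default_factory=dict)
    index_votes: dict[str, pd.DataFrame] = field(default_factory=dict)
    boundaries: dict[str, float] = field(default_factory=dict)
    trimmed: dict[str, int] = field(default_factory=dict)
    skipped_strata: list[str] = field(default_factory=list)

    @property
    def high_fraction(self) -> float:
        """Fraction of untrimmed samples labeled high."""
        kept = self.labels[self.labels != "trimmed"]
        if kept.empty:
            return float("nan")
        return float((kept == "high").mean())


def stratified_discretize(
    matrix: ExpressionMatrix,
    scores: ScoreVector,
    metadata: pd.DataFrame,
    trim_fraction: float = 0.10,
    k_range=range(2, 7),
    stratify_by: str = "smoking_status",
) -> DiscretizationResult:
    """Consensus-cluster dichotomization within smoking strata.

    Within each stratum: cluster the samples on the centered signature-gene
    matrix, choose k by index vote, label clusters high/low, then place the
    partition boundary at the midpoint between the lowest high score and
    the highest low score and relabel the round(trim_fraction * n) samples
    nearest that boundary as ``trimmed``.  Strata with fewer than 4 samples
    are skipped (their samples are reported as trimmed).
    """
    if not 0 <= trim_fraction < 0.5:
        raise ValueError("trim_fraction must lie in [0, 0.5)")
    if stratify_by not in metadata.columns:
        raise KeyError(f"metadata lacks column {stratify_by!r}")
    sample_ids = list(matrix.sample_ids)
    missing = [s for s in sample_ids if s not in metadata.index]
    if missing:
        raise KeyError(f"samples missing from metadata: {missing}")
    strata = metadata.loc[sample_ids, stratify_by]
    if strata.isna().any():
        raise ValueError("every sample needs a smoking status")

    labels = pd.Series(index=pd.Index(sample_ids), dtype=object, name="label")
    result = DiscretizationResult(labels=labels, method="consensus_cluster")
    for stratum, members in strata.groupby(strata).groups.items():
        members = list(members)
        if len(members) < 4:
            warnings.warn(
                f"stratum {stratum!r} has {len(members)} samples (<4); skipped",
                stacklevel=2,
            )
            labels.loc[members] = "trimmed"
            result.skipped_strata.append(str(stratum))
            continue
        sub = matrix.subset_samples(members)
        centered = sub.values.sub(sub.values.mean(axis=1), axis=0)
        points = centered.T  # samples x genes
        s_scores = scores.scores.loc[members]
        ks = [k for k in k_range if k <= len(members) - 1]
        best_k, table = consensus_k(points.to_numpy(), ks, sample_ids=members)
        tree = average_linkage_dendrogram(points.to_numpy(), members)
        cluster_labels = cut_k(tree, best_k)
        hl = assign_high_low(cluster_labels, s_scores)
        n_trim = int(np.floor(trim_fraction * len(members) + 0.5))
        if (hl == "high").any() and (hl == "low").any():
            boundary = 0.5 * (
                s_scores[hl == "high"].min() + s_scores[hl == "low"].max()
            )
            result.boundaries[str(stratum)] = float(boundary)
            if n_trim > 0:
                nearest = (s_scores - boundary).abs().sort_values(kind="stable").index[
                    :n_trim
                ]
                hl.loc[nearest] = "trimmed"
                result.trimmed[str(stratum)] = int(n_trim)
            # make labels consistent with the score boundary so the high/low
            # partition is monotone on the score axis
            keep = hl.index[hl != "trimmed"]
            hl.loc[keep] = np.where(s_scores.loc[keep] > boundary, "high", "low")
        else:
            result.trimmed[str(stratum)] = 0
        labels.loc[members] = hl
        result.chosen_k[str(stratum)] = best_k
        result.index_votes[str(stratum)] = table

    # within a stratum every untrimmed high score exceeds every low score
    for stratum, members in strata.groupby(strata).groups.items():
        sub = labels.loc[list(members)]
        hi = scores.scores.loc[sub.index[sub == "high"]]
        lo = scores.scores.loc[sub.index[sub == "low"]]
        if len(hi) and len(lo):
            assert hi.min() > lo.max(), "high/low not separated on the score axis"
    return result


def quartile_rule(scores: ScoreVector | pd.Series) -> pd.Series:
    """Top-quartile alternative: high iff score >= 75th percentile."""
    s = scores.scores if isinstance(scores, ScoreVector) else scores
    if len(s) < 4:
        raise ValueError("need at least 4 samples")
    threshold = np.percentile(s.to_numpy(dtype=float), 75)
    if s.nunique() == 1:
        warnings.warn("all scores equal: every sample labeled high", stacklevel=2)
    out = pd.Series(np.where(s >= threshold, "high", "low"), index=s.index, name="label")
    return out
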