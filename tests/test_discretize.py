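import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import cdist
from sklearn import metrics as skmetrics

from episig.discretize import (
    assign_high_low,
    average_linkage_dendrogram,
    consensus_k,
    cut_k,
    quartile_rule,
    stratified_discretize,
    validity_indices,
)
from episig.expr_io import ExpressionMatrix
from episig.signature_refine import Signature
from episig.signature_score import score_samples
from episig.synthetic_data import SIGNATURE_BLOCK, gen_cohort


def brute_force_upgma(X, ids):
    """Independent UPGMA: recompute average inter-cluster distances from the
    raw points at every step (no Lance-Williams update)."""
    D = cdist(X, X)
    clusters = {i: [i] for i in range(len(ids))}
    min_id = {i: ids[i] for i in range(len(ids))}
    merges = []
    nxt = len(ids)
    while len(clusters) > 1:
        best = None
        for ci in clusters:
            for cj in clusters:
                if cj <= ci:
                    continue
                d = np.mean(
                    [D[a, b] for a in clusters[ci] for b in clusters[cj]]
                )
                a, b = sorted((min_id[ci], min_id[cj]))
                key = (d, a, b)
                if best is None or key < best[0]:
                    best = (key, ci, cj)
        (d, _, _), ci, cj = best
        merges.append((min(ci, cj), max(ci, cj), d, len(clusters[ci]) + len(clusters[cj])))
        clusters[nxt] = clusters.pop(ci) + clusters.pop(cj)
        min_id[nxt] = min(min_id[ci], min_id[cj])
        nxt += 1
    return np.array(merges)


class TestAverageLinkage:
    def test_two_samples_single_merge_at_their_distance(self):
        pts = np.array([[0.0, 0.0], [3.0, 4.0]])
        tree = average_linkage_dendrogram(pts)
        assert tree.merges.shape == (1, 4)
        assert tree.merges[0, 2] == pytest.approx(5.0)

    def test_hand_upgma_on_one_dimensional_points(self):
        tree = average_linkage_dendrogram(np.array([[0.0], [1.0], [10.0]]))
        assert tree.merges[0, 2] == pytest.approx(1.0)  # {0,1} first
        assert tree.merges[1, 2] == pytest.approx(9.5)  # mean(10, 9)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(12, 3))
        ids = [f"s{i:02d}" for i in range(12)]
        tree = average_linkage_dendrogram(X, ids)
        oracle = brute_force_upgma(X, ids)
        np.testing.assert_allclose(tree.merges, oracle)

    def test_tie_break_on_duplicate_points_is_deterministic(self):
        # three identical points: first merge must pick lexicographically
        # smallest member-id pair (a, b)
        X = np.zeros((3, 2))
        tree = average_linkage_dendrogram(X, ["a", "b", "c"])
        assert tuple(tree.merges[0, :2]) == (0.0, 1.0)
        oracle = brute_force_upgma(X, ["a", "b", "c"])
        np.testing.assert_allclose(tree.merges, oracle)

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            average_linkage_dendrogram(np.array([[1.0]]))


class TestCutK:
    def test_extreme_cuts(self):
        X = np.random.default_rng(0).normal(size=(6, 2))
        tree = average_linkage_dendrogram(X)
        assert cut_k(tree, 6).nunique() == 6
        assert cut_k(tree, 1).nunique() == 1

    def test_two_blobs_recovered_at_k_two(self):
        rng = np.random.default_rng(1)
        X = np.vstack([rng.normal(0, 0.5, (10, 2)), rng.normal(10, 0.5, (8, 2))])
        tree = average_linkage_dendrogram(X)
        labels = cut_k(tree, 2)
        assert labels.iloc[:10].nunique() == 1
        assert labels.iloc[10:].nunique() == 1
        assert labels.iloc[0] != labels.iloc[-1]

    def test_out_of_range_k(self):
        tree = average_linkage_dendrogram(np.random.default_rng(0).normal(size=(4, 2)))
        with pytest.raises(ValueError):
            cut_k(tree, 5)


class TestValidityIndices:
    def test_separated_blobs_have_high_silhouette(self):
        rng = np.random.default_rng(2)
        X = np.vstack([rng.normal(0, 0.3, (12, 2)), rng.normal(10, 0.3, (12, 2))])
        labels = np.array([0] * 12 + [1] * 12)
        idx = validity_indices(X, labels)
        assert idx["silhouette"] > 0.8

    def test_silhouette_ch_db_match_sklearn(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(15, 3))
        labels = rng.integers(0, 3, size=15)
        while len(np.unique(labels)) < 3:
            labels = rng.integers(0, 3, size=15)
        idx = validity_indices(X, labels)
        assert idx["silhouette"] == pytest.approx(
            skmetrics.silhouette_score(X, labels), abs=1e-10
        )
        assert idx["calinski_harabasz"] == pytest.approx(
            skmetrics.calinski_harabasz_score(X, labels), abs=1e-8
        )
        assert idx["davies_bouldin"] == pytest.approx(
            skmetrics.davies_bouldin_score(X, labels), abs=1e-10
        )

    def test_calinski_harabasz_hand_example(self):
        # 6 one-dimensional points in two tight groups
        X = np.array([[0.0], [1.0], [2.0], [10.0], [11.0], [12.0]])
        labels = np.array([0, 0, 0, 1, 1, 1])
        # centroids 1 and 11, overall 6; B = 3*25+3*25 = 150, W = 2+2 = 4
        expected = (150 / 1) / (4 / 4)
        assert validity_indices(X, labels)["calinski_harabasz"] == pytest.approx(expected)

    def test_pairwise_indices_match_brute_force(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(9, 2))
        labels = np.array([0, 0, 0, 1, 1, 1, 2, 2, 2])
        idx = validity_indices(X, labels)
        D = cdist(X, X)
        within, between = [], []
        for i in range(9):
            for j in range(i + 1, 9):
                (within if labels[i] == labels[j] else between).append(D[i, j])
        within, between = np.array(within), np.array(between)
        assert idx["dunn"] == pytest.approx(between.min() / within.max())
        assert idx["mcclain_rao"] == pytest.approx(within.mean() / between.mean())
        nw = len(within)
        all_d = np.sort(np.concatenate([within, between]))
        c_expected = (within.sum() - all_d[:nw].sum()) / (
            all_d[-nw:].sum() - all_d[:nw].sum()
        )
        assert idx["c_index"] == pytest.approx(c_expected)
        nt = nw + len(between)
        pb_expected = (
            (between.mean() - within.mean())
            * np.sqrt(nw * len(between) / nt**2)
            / np.concatenate([within, between]).std()
        )
        assert idx["point_biserial"] == pytest.approx(pb_expected)

    def test_all_singletons_silhouette_undefined(self):
        X = np.array([[0.0], [1.0], [5.0]])
        idx = validity_indices(X, np.array([0, 1, 2]))
        assert np.isnan(idx["silhouette"])


class TestConsensusK:
    def test_single_candidate_k(self):
        X = np.random.default_rng(0).normal(size=(10, 2))
        best, table = consensus_k(X, [2])
        assert best == 2

    def test_votes_accounted_for(self):
        rng = np.random.default_rng(5)
        X = np.vstack([rng.normal(0, 1, (10, 2)), rng.normal(6, 1, (10, 2))])
        best, table = consensus_k(X, range(2, 6))
        cast = table["vote"].dropna()
        defined = table.drop(columns="vote").notna().all(axis=1)
        # every index with defined values across k casts exactly one vote
        assert set(cast.index) <= set(table.index)
        assert len(cast) >= defined.sum() - 1  # elbow may abstain on short ranges

    def test_two_blobs_majority_votes_k_two(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = np.vstack([rng.normal(0, 1, (15, 2)), rng.normal(8, 1, (18, 2))])
            best, _ = consensus_k(X, range(2, 7))
            hits += best == 2
        assert hits >= 19

    def test_empty_range_rejected(self):
        with pytest.raises(ValueError):
            consensus_k(np.random.default_rng(0).normal(size=(8, 2)), [])


class TestAssignHighLow:
    def test_higher_mean_minority_is_high(self):
        labels = pd.Series([0] * 8 + [1] * 2, index=[f"s{i}" for i in range(10)])
        scores = pd.Series([0.0] * 8 + [2.0] * 2, index=labels.index)
        out = assign_high_low(labels, scores)
        assert (out.iloc[8:] == "high").all()
        assert (out.iloc[:8] == "low").all()

    def test_multiple_high_clusters_merged(self):
        labels = pd.Series([0] * 6 + [1] * 2 + [2] * 2, index=[f"s{i}" for i in range(10)])
        scores = pd.Series([0.0] * 6 + [2.0] * 2 + [4.0] * 2, index=labels.index)
        out = assign_high_low(labels, scores)
        assert (out.iloc[6:] == "high").all()

    def test_low_scoring_singleton_stays_low(self):
        labels = pd.Series([0] * 7 + [1] * 2 + [2], index=[f"s{i}" for i in range(10)])
        scores = pd.Series([0.0] * 7 + [2.0] * 2 + [-3.0], index=labels.index)
        out = assign_high_low(labels, scores)
        assert out.iloc[-1] == "low"
        assert (out.iloc[7:9] == "high").all()

    def test_invariant_to_cluster_label_permutation(self):
        idx = [f"s{i}" for i in range(10)]
        labels = pd.Series([0] * 6 + [1] * 2 + [2] * 2, index=idx)
        permuted = labels.map({0: 7, 1: 3, 2: 5})
        scores = pd.Series(np.r_[np.zeros(6), 2 * np.ones(2), 4 * np.ones(2)], index=idx)
        pd.testing.assert_series_equal(
            assign_high_low(labels, scores), assign_high_low(permuted, scores)
        )

    def test_single_cluster_warns_all_low(self):
        labels = pd.Series([0] * 5, index=[f"s{i}" for i in range(5)])
        scores = pd.Series(np.arange(5.0), index=labels.index)
        with pytest.warns(UserWarning):
            out = assign_high_low(labels, scores)
        assert (out == "low").all()


def _discretize_cohort(seed, delta=2.0, trim=0.10):
    cohort, meta, truth = gen_cohort(seed=seed, delta=delta)
    sig = Signature(anchor="CCL20", genes=list(SIGNATURE_BLOCK))
    sv = score_samples(cohort, sig)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stratified_discretize(
            cohort.subset_genes(list(SIGNATURE_BLOCK)), sv, meta, trim_fraction=trim
        )
    return res, sv, meta, truth


class TestStratifiedDiscretize:
    def test_trim_counts_exact_per_stratum(self):
        res, sv, meta, _ = _discretize_cohort(seed=0)
        for stratum, n_trim in res.trimmed.items():
            n = (meta["smoking_status"] == stratum).sum()
            assert n_trim == int(np.floor(0.10 * n + 0.5))
            members = meta.index[meta["smoking_status"] == stratum]
            assert (res.labels.loc[members] == "trimmed").sum() == n_trim

    def test_zero_trim_keeps_every_label(self):
        res, _, _, _ = _discretize_cohort(seed=1, trim=0.0)
        assert (res.labels != "trimmed").all()

    def test_high_and_low_separated_on_score_axis(self):
        res, sv, meta, _ = _discretize_cohort(seed=2)
        for stratum in res.boundaries:
            members = meta.index[meta["smoking_status"] == stratum]
            lab = res.labels.loc[members]
            hi = sv.scores.loc[lab.index[lab == "high"]]
            lo = sv.scores.loc[lab.index[lab == "low"]]
            if len(hi) and len(lo):
                assert hi.min() > lo.max()

    def test_tiny_stratum_skipped_with_warning(self, rng):
        genes = ["A", "B"]
        df = pd.DataFrame(rng.normal(size=(2, 6)), index=genes,
                          columns=[f"s{i}" for i in range(6)])
        m = ExpressionMatrix(df, "log2")
        sig = Signature(anchor="A", genes=genes)
        sv = score_samples(m, sig)
        meta = pd.DataFrame(
            {"smoking_status": ["former"] * 4 + ["current"] * 2},
            index=df.columns,
        )
        with pytest.warns(UserWarning, match="current"):
            res = stratified_discretize(m, sv, meta, trim_fraction=0.0, k_range=[2])
        assert "current" in res.skipped_strata

    def test_invalid_trim_fraction(self):
        res, sv, meta, _ = _discretize_cohort(seed=0)
        cohort, meta, _ = gen_cohort(seed=0)
        sig = Signature(anchor="CCL20", genes=list(SIGNATURE_BLOCK))
        sv = score_samples(cohort, sig)
        with pytest.raises(ValueError):
            stratified_discretize(
                cohort.subset_genes(list(SIGNATURE_BLOCK)), sv, meta, trim_fraction=0.6
            )


class TestQuartileRule:
    def test_eighty_samples_give_twenty_high(self, rng):
        scores = pd.Series(rng.normal(size=80), index=[f"s{i}" for i in range(80)])
        out = quartile_rule(scores)
        assert (out == "high").sum() == 20

    def test_all_equal_scores_all_high_with_warning(self):
        scores = pd.Series([1.0] * 6, index=[f"s{i}" for i in range(6)])
        with pytest.warns(UserWarning):
            out = quartile_rule(scores)
        assert (out == "high").all()

    def test_matches_sort_based_oracle(self, rng):
        scores = pd.Series(rng.normal(size=37), index=[f"s{i}" for i in range(37)])
        out = quartile_rule(scores)
        thr = np.percentile(scores.to_numpy(), 75)
        for sid in scores.index:
            assert out[sid] == ("high" if scores[sid] >= thr else "low")

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            quartile_rule(pd.Series([1.0, 2.0, 3.0]))
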