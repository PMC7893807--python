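import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import cdist
from sklearn.metrics import adjusted_rand_score

from gutsig.io_core import AbundanceTable, ValidationError
from gutsig.subtyping import (
    KnnModel,
    cluster_subtypes,
    fit_knn,
    loocv_accuracy,
    predict,
)


def brute_force_average_linkage(d):
    """Oracle: naive UPGMA agglomeration, returning the sets merged in order."""
    clusters = [frozenset([i]) for i in range(d.shape[0])]
    merges = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            dist = np.mean([d[i, j] for i in clusters[a] for j in clusters[b]])
            if best is None or dist < best[0] - 1e-12:
                best = (dist, a, b)
        dist, a, b = best
        merged = clusters[a] | clusters[b]
        merges.append((frozenset(clusters[a]), frozenset(clusters[b]), dist))
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)] + [merged]
    return merges


def brute_force_knn(train, labels, query, k):
    """Oracle: exhaustive nearest-neighbor vote with stable distance ordering."""
    d = cdist([query], train, metric="braycurtis")[0]
    order = np.argsort(d, kind="stable")[:k]
    votes = labels[order]
    classes, counts = np.unique(votes, return_counts=True)
    winners = classes[counts == counts.max()]
    return winners[0] if winners.size == 1 else votes[0]


def _blocks_table(n_per=10, seed=0):
    """Two well-separated abundance blocks with matching CARS totals."""
    rng = np.random.default_rng(seed)
    block1 = np.column_stack(
        [rng.uniform(80, 100, n_per), rng.uniform(1, 5, n_per), rng.uniform(5, 10, n_per)]
    )
    block2 = np.column_stack(
        [rng.uniform(1, 5, n_per), rng.uniform(80, 100, n_per), rng.uniform(5, 10, n_per)]
    )
    values = np.vstack([block1, block2])
    ids = [f"s{i}" for i in range(2 * n_per)]
    table = AbundanceTable(
        pd.DataFrame(values, index=ids, columns=["gA", "gB", "gC"]), mode="counts"
    )
    cars = pd.Series([20.0] * n_per + [45.0] * n_per, index=ids)
    truth = np.array([0] * n_per + [1] * n_per)
    return table, cars, truth


class TestClusterSubtypes:
    def test_separable_blocks_fully_recovered(self):
        table, cars, truth = _blocks_table()
        asg = cluster_subtypes(table, ["gA", "gB", "gC"], cars)
        assert adjusted_rand_score(truth, (asg.labels == "mp2").to_numpy()) == 1.0

    def test_mp1_is_the_milder_cluster(self):
        table, cars, _ = _blocks_table()
        asg = cluster_subtypes(table, ["gA", "gB", "gC"], cars)
        assert cars[asg.labels == "mp1"].mean() < cars[asg.labels == "mp2"].mean()

    @pytest.mark.parametrize("n,seed", [(4, 0), (5, 1), (6, 2)])
    def test_merge_order_matches_brute_force_oracle(self, n, seed):
        rng = np.random.default_rng(seed)
        values = rng.uniform(1, 50, size=(n, 4))
        ids = [f"s{i}" for i in range(n)]
        table = AbundanceTable(
            pd.DataFrame(values, index=ids, columns=list("wxyz")), mode="counts"
        )
        cars = pd.Series(rng.uniform(20, 50, n), index=ids)
        asg = cluster_subtypes(table, list("wxyz"), cars)
        rel = table.to_relative().subset_genera(list("wxyz"), renormalize=True)
        from gutsig.diversity import bray_curtis

        d = bray_curtis(rel).data
        oracle = brute_force_average_linkage(d)
        z = asg.linkage_matrix
        # compare merge heights (scipy records them in the same greedy order)
        np.testing.assert_allclose(
            sorted(z[:, 2]), sorted(m[2] for m in oracle), atol=1e-10
        )
        # and merge heights are monotone non-decreasing (UPGMA cannot invert)
        assert (np.diff(z[:, 2]) >= -1e-12).all()

    def test_sample_and_genus_order_invariance(self, discovery, discovery_scores):
        sig = list(discovery.truth.planted_signature)
        asg = cluster_subtypes(discovery.abundance, sig, discovery_scores["cars_total"])
        rng = np.random.default_rng(3)
        perm = rng.permutation(discovery.abundance.shape[0])
        shuffled = AbundanceTable(
            discovery.abundance.data.iloc[perm, ::-1], mode="counts"
        )
        asg2 = cluster_subtypes(shuffled, sig[::-1], discovery_scores["cars_total"])
        assert (asg2.labels.reindex(asg.labels.index) == asg.labels).all()

    def test_degenerate_distances_rejected(self):
        ids = list("abcd")
        table = AbundanceTable(
            pd.DataFrame(np.ones((4, 2)), index=ids, columns=["g1", "g2"]), mode="counts"
        )
        with pytest.raises(ValidationError, match="degenerate"):
            cluster_subtypes(table, ["g1", "g2"], pd.Series([20, 30, 40, 50.0], index=ids))


class TestKnn:
    def test_training_row_identity_k1(self):
        table, cars, truth = _blocks_table()
        labels = pd.Series(np.where(truth == 0, "mp1", "mp2"), index=table.sample_ids)
        model = fit_knn(table, ["gA", "gB", "gC"], labels, k=1)
        pred = predict(model, table)
        assert (pred == labels).all()

    def test_even_k_rejected(self):
        table, cars, truth = _blocks_table()
        labels = pd.Series(np.where(truth == 0, "mp1", "mp2"), index=table.sample_ids)
        with pytest.raises(ValidationError, match="odd"):
            fit_knn(table, ["gA", "gB", "gC"], labels, k=2)

    def test_separated_blobs_perfectly_classified(self):
        table, cars, truth = _blocks_table(n_per=15, seed=4)
        labels = pd.Series(np.where(truth == 0, "mp1", "mp2"), index=table.sample_ids)
        model = fit_knn(table, ["gA", "gB", "gC"], labels, k=3)
        held, _, held_truth = _blocks_table(n_per=8, seed=9)
        pred = predict(model, held)
        assert (pred.to_numpy() == np.where(held_truth == 0, "mp1", "mp2")).all()

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(12)
        for trial in range(50):
            train = rng.uniform(0.1, 1, size=(10, 4))
            train /= train.sum(axis=1, keepdims=True)
            labels = rng.choice(["mp1", "mp2"], size=10)
            query = rng.uniform(0.1, 1, size=4)
            query /= query.sum()
            k = int(rng.choice([1, 3, 5]))
            ids = [f"t{i}" for i in range(10)]
            model = KnnModel(
                training=pd.DataFrame(train, index=ids, columns=list("abcd")),
                labels=pd.Series(labels, index=ids),
                k=k,
                signature=tuple("abcd"),
            )
            table = AbundanceTable(
                pd.DataFrame([query], index=["q"], columns=list("abcd")), mode="relative"
            )
            assert predict(model, table).iloc[0] == brute_force_knn(train, labels, query, k)

    def test_missing_signature_genus_imputed_with_warning(self):
        table, cars, truth = _blocks_table()
        labels = pd.Series(np.where(truth == 0, "mp1", "mp2"), index=table.sample_ids)
        model = fit_knn(table, ["gA", "gB", "gC"], labels, k=1)
        partial = AbundanceTable(
            pd.DataFrame([[10.0, 90.0]], index=["q"], columns=["gA", "gB"]), mode="counts"
        )
        with pytest.warns(UserWarning, match="gC"):
            pred = predict(model, partial)
        assert pred.iloc[0] in ("mp1", "mp2")


class TestLoocv:
    def test_duplicated_points_perfect_at_k1(self):
        values = np.array([[10, 1, 1], [10, 1, 1], [1, 10, 1], [1, 10, 1]], float)
        ids = list("abcd")
        table = AbundanceTable(pd.DataFrame(values, index=ids, columns=["g1", "g2", "g3"]))
        labels = pd.Series(["mp1", "mp1", "mp2", "mp2"], index=ids)
        assert loocv_accuracy(table, ["g1", "g2", "g3"], labels, k=1) == 1.0

    def test_perfect_blocks_score_one(self):
        table, cars, truth = _blocks_table()
        labels = pd.Series(np.where(truth == 0, "mp1", "mp2"), index=table.sample_ids)
        assert loocv_accuracy(table, ["gA", "gB", "gC"], labels, k=3) == 1.0

    def test_k_exceeding_folds_rejected(self):
        table, cars, truth = _blocks_table(n_per=2)
        labels = pd.Series(np.where(truth == 0, "mp1", "mp2"), index=table.sample_ids)
        with pytest.raises(ValidationError):
            loocv_accuracy(table, ["gA", "gB", "gC"], labels, k=5)
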