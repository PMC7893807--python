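"""Two-cluster subtyping on signature genera and a kNN subtype classifier.

Clustering: Bray-Curtis dissimilarity over the signature genera
(relative abundances renormalized to the subset), average-linkage (UPGMA)
agglomeration, cut at two clusters. The cluster with the lower mean CARS
total is labelled ``mp1`` — by construction ``mp2`` is the more severe
subpopulation.

Classification: a k-nearest-neighbors vote under the same Bray-Curtis
metric (Euclidean optional), with deterministic tie-breaking, evaluated by
leave-one-out cross-validation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist, squareform

from .diversity import bray_curtis
from .io_core import AbundanceTable, CohortMetadata, ValidationError, metadata_to_frame

__all__ = ["SubtypeAssignment", "KnnModel", "cluster_subtypes", "fit_knn", "predict", "loocv_accuracy"]

MP1, MP2 = "mp1", "mp2"


@dataclass(frozen=True)
class SubtypeAssignment:
    """Per-sample subtype labels plus the linkage that produced them."""

    labels: pd.Series  # sample_id -> mp1/mp2
    linkage_matrix: np.ndarray
    labelling_rule: str

    @property
    def cluster_sizes(self) -> dict[str, int]:
        return self.labels.value_counts().to_dict()


def _cars_totals(metadata) -> pd.Series:
    if isinstance(metadata, pd.Series):
        return metadata
    if isinstance(metadata, pd.DataFrame):
        return metadata["cars_total"]
    return metadata_to_frame(metadata)["cars_total"]


def cluster_subtypes(
    table: AbundanceTable,
    signature: list[str],
    metadata,
) -> SubtypeAssignment:
    """UPGMA two-cluster subtyping on the signature genera.

    Parameters
    ----------
    table : AbundanceTable
        Full cohort table (counts or relative).
    signature : list of genus ids
        Genera defining the subtype space.
    metadata : CohortMetadata list, DataFrame, or Series
        Source of per-sample CARS totals for the mp1/mp2 labelling rule.
    """
    if not signature:
        raise ValidationError("signature must be non-empty")
    if table.shape[0] < 4:
        raise ValidationError("need at least 4 samples to subtype")
    rel = table if table.mode == "relative" else table.to_relative()
    sub = rel.subset_genera(signature, renormalize=True)
    dm = bray_curtis(sub)
    condensed = squareform(dm.data, checks=False)
    if np.all(condensed == 0):
        raise ValidationError("degenerate abundance data: all pairwise distances are 0")
    z = linkage(condensed, method="average")
    assignment = fcluster(z, t=2, criterion="maxclust")
    totals = _cars_totals(metadata).reindex(sub.data.index)
    if totals.isna().any():
        raise ValidationError("metadata does not cover every sample in the table")
    means = {c: totals[assignment == c].mean() for c in (1, 2)}
    sizes = {c: int((assignment == c).sum()) for c in (1, 2)}
    if means[1] != means[2]:
        mp1_cluster = min(means, key=lambda c: means[c])
        rule = "lower_mean_cars_total"
    else:
        mp1_cluster = max(sizes, key=lambda c: sizes[c])
        rule = "tie_on_mean:larger_cluster"
    labels = pd.Series(
        np.where(assignment == mp1_cluster, MP1, MP2),
        index=sub.data.index,
        name="subtype",
    )
    return SubtypeAssignment(labels=labels, linkage_matrix=z, labelling_rule=rule)


@dataclass(frozen=True)
class KnnModel:
    """kNN classifier state over subset-renormalized signature abundances."""

    training: pd.DataFrame  # samples x signature genera, relative, renormalized
    labels: pd.Series
    k: int
    distance: str = "bray_curtis"
    signature: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.k < 1 or self.k % 2 == 0:
            raise ValidationError(f"k must be an odd positive integer, got {self.k}")
        if self.k > len(self.training):
            raise ValidationError(f"k={self.k} exceeds n_training={len(self.training)}")
        if self.distance not in ("bray_curtis", "euclidean"):
            raise ValidationError(f"unknown distance {self.distance!r}")


def fit_knn(
    table: AbundanceTable,
    signature: list[str],
    labels: pd.Series,
    k: int = 3,
    distance: str = "bray_curtis",
) -> KnnModel:
    """Fit (store) a kNN model on the signature-genus profile of the cohort."""
    rel = table if table.mode == "relative" else table.to_relative()
    sub = rel.subset_genera(signature, renormalize=True)
    lab = pd.Series(labels).reindex(sub.data.index)
    if lab.isna().any():
        raise ValidationError("labels do not cover every training sample")
    return KnnModel(sub.data, lab, k=k, distance=distance, signature=tuple(signature))


def _pairwise(query: np.ndarray, train: np.ndarray, metric: str) -> np.ndarray:
    return cdist(query, train, metric="braycurtis" if metric == "bray_curtis" else "euclidean")


def _vote(dist_row: np.ndarray, train_labels: np.ndarray, k: int) -> str:
    # stable sort: distance ties resolved by training-row order
    order = np.argsort(dist_row, kind="stable")[:k]
    votes = train_labels[order]
    classes, counts = np.unique(votes, return_counts=True)
    winners = classes[counts == counts.max()]
    if winners.size == 1:
        return str(winners[0])
    return str(votes[0])  # vote tie: defer to the single nearest neighbor


def predict(model: KnnModel, new_samples: AbundanceTable) -> pd.Series:
    """Classify new samples by majority vote among the k nearest training rows.

    Signature genera missing from the new table are treated as zero with a
    warning.
    """
    rel = new_samples if new_samples.mode == "relative" else new_samples.to_relative()
    missing = [g for g in model.signature if g not in rel.data.columns]
    if missing:
        warnings.warn(f"signature genera missing from input, imputing 0: {missing}", stacklevel=2)
    sub = rel.data.reindex(columns=list(model.signature), fill_value=0.0)
    sums = sub.to_numpy(float).sum(axis=1)
    if (sums == 0).any():
        bad = sub.index[np.where(sums == 0)[0][0]]
        raise ValidationError(f"sample {bad!r} has zero total over the signature genera")
    q = sub.to_numpy(float) / sums[:, None]
    d = _pairwise(q, model.training.to_numpy(float), model.distance)
    train_labels = model.labels.to_numpy()
    out = [_vote(d[i], train_labels, model.k) for i in range(d.shape[0])]
    return pd.Series(out, index=sub.index, name="subtype")


def loocv_accuracy(
    table: AbundanceTable,
    signature: list[str],
    labels: pd.Series,
    k: int = 3,
    distance: str = "bray_curtis",
) -> float:
    """Leave-one-out cross-validated accuracy of the kNN subtype classifier.

    Labels are held fixed (they come from clustering the full cohort); each
    sample is predicted from the remaining n-1.
    """
    model = fit_knn(table, signature, labels, k=k, distance=distance)
    if k > len(model.training) - 1:
        raise ValidationError(f"k={k} requires at least {k + 1} samples")
    x = model.training.to_numpy(float)
    lab = model.labels.to_numpy()
    d = _pairwise(x, x, model.distance)
    correct = 0
    n = x.shape[0]
    for i in range(n):
        keep = np.arange(n) != i
        if _vote(d[i, keep], lab[keep], k) == lab[i]:
            correct += 1
    return correct / n
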