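"""Alpha diversity, Bray-Curtis dissimilarity, and principal coordinates.

Shannon entropy is computed in natural-log units by default (Pielou's
evenness is base-invariant); Faith's phylogenetic diversity follows the
rooted convention (total branch length on the union of root-to-leaf paths
of the observed taxa), delegating to scikit-bio.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import skbio
from scipy.spatial.distance import pdist, squareform
from skbio.stats.distance import DistanceMatrix

from .io_core import AbundanceTable, ValidationError, validate_tree

__all__ = [
    "PcoaResult",
    "bray_curtis",
    "alpha_diversity",
    "pcoa",
    "rarefy",
]


def bray_curtis(table: AbundanceTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity d(u,v) = sum|u-v| / sum(u+v) between samples.

    Raises
    ------
    ValidationError
        If any sample is all-zero over the table's genera.
    """
    values = table.values
    totals = values.sum(axis=1)
    zero = np.where(totals == 0)[0]
    if zero.size:
        raise ValidationError(
            f"sample {table.sample_ids[zero[0]]!r} has zero total over the selected genera"
        )
    condensed = pdist(values, metric="braycurtis")
    return DistanceMatrix(squareform(condensed, checks=False), ids=table.sample_ids)


def _faith_pd(tree: skbio.TreeNode, observed: set[str]) -> float:
    """Total branch length on the union of root-to-leaf paths of observed taxa.

    Rooted convention; accepts multifurcations (a star tree with m observed
    unit branches scores m).
    """
    total = 0.0
    below: dict[int, bool] = {}
    for node in tree.postorder(include_self=False):
        if node.is_tip():
            hit = node.name in observed
        else:
            hit = any(below[id(c)] for c in node.children)
        below[id(node)] = hit
        if hit:
            total += node.length or 0.0
    return total


def alpha_diversity(
    table: AbundanceTable,
    tree: skbio.TreeNode | None = None,
    shannon_base: float = np.e,
) -> pd.DataFrame:
    """Per-sample alpha diversity: observed features, Shannon, Pielou, Faith PD.

    Returns a DataFrame indexed by sample id. ``pielou`` is NaN (undefined)
    for samples with fewer than two observed genera rather than 0, so group
    means are not silently deflated. ``faith_pd`` is included only when a
    tree is supplied; every genus observed in any sample must then be a leaf.
    """
    values = table.values
    genus_ids = np.asarray(table.genus_ids)
    rows = []
    if tree is not None:
        tree = validate_tree(tree)
        leaves = {t.name for t in tree.tips()}
    for i, sid in enumerate(table.sample_ids):
        v = values[i]
        total = v.sum()
        if total == 0:
            raise ValidationError(f"sample {sid!r} has zero total abundance")
        p = v[v > 0] / total
        observed = int((v > 0).sum())
        shannon = float(-(p * (np.log(p) / np.log(shannon_base))).sum())
        pielou = (
            shannon / (np.log(observed) / np.log(shannon_base))
            if observed >= 2
            else np.nan
        )
        row = {
            "observed_features": observed,
            "shannon": shannon,
            "pielou": pielou,
        }
        if tree is not None:
            present = genus_ids[v > 0]
            missing = [g for g in present if g not in leaves]
            if missing:
                raise ValidationError(
                    f"sample {sid!r}: genera absent from the tree: {missing}"
                )
            row["faith_pd"] = _faith_pd(tree, set(present))
        rows.append((sid, row))
    return pd.DataFrame({sid: row for sid, row in rows}).T.rename_axis("sample_id")


@dataclass(frozen=True)
class PcoaResult:
    """Classical-scaling embedding of a dissimilarity matrix."""

    coordinates: pd.DataFrame  # samples x axes
    eigenvalues: np.ndarray  # positive eigenvalues, descending
    proportion_explained: np.ndarray
    negative_eigenvalues: np.ndarray  # recorded, their axes dropped


def pcoa(dm: DistanceMatrix, n_axes: int = 2) -> PcoaResult:
    """Principal coordinates analysis (Gower's classical scaling).

    Double-centers -D^2/2, eigendecomposes, and scales eigenvectors by the
    square roots of positive eigenvalues. Negative eigenvalues (from
    non-Euclidean dissimilarities) are recorded and their axes dropped;
    proportions explained are taken over the positive part only. Asking for
    more axes than there are positive eigenvalues truncates with a warning.
    """
    d = np.asarray(dm.data, dtype=float)
    n = d.shape[0]
    if n_axes > n - 1:
        raise ValidationError(f"n_axes={n_axes} exceeds n_samples-1={n - 1}")
    b = -0.5 * d**2
    centerer = np.eye(n) - np.ones((n, n)) / n
    b = centerer @ b @ centerer
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = max(1e-12, 1e-10 * abs(eigvals[0]) if n else 0.0)
    positive = eigvals > tol
    pos_vals = eigvals[positive]
    neg_vals = eigvals[eigvals < -tol]
    k = min(n_axes, pos_vals.size)
    if k < n_axes:
        warnings.warn(
            f"only {pos_vals.size} positive eigenvalues; returning {k} axes", stacklevel=2
        )
    coords = eigvecs[:, positive][:, :k] * np.sqrt(pos_vals[:k])
    frame = pd.DataFrame(
        coords, index=dm.ids, columns=[f"PC{i + 1}" for i in range(k)]
    ).rename_axis("sample_id")
    return PcoaResult(
        coordinates=frame,
        eigenvalues=pos_vals,
        proportion_explained=pos_vals[:k] / pos_vals.sum() if pos_vals.size else pos_vals,
        negative_eigenvalues=neg_vals,
    )


def rarefy(table: AbundanceTable, depth: int | None = None, seed: int = 0) -> AbundanceTable:
    """Seeded rarefaction of a count table to a common depth.

    ``depth`` defaults to the minimum sample total; samples below the
    requested depth are dropped with a warning.
    """
    if table.mode != "counts":
        raise ValidationError("rarefaction requires a count table")
    values = table.values.astype(int)
    totals = values.sum(axis=1)
    if depth is None:
        depth = int(totals.min())
    keep = totals >= depth
    if not keep.all():
        dropped = [s for s, k in zip(table.sample_ids, keep) if not k]
        warnings.warn(f"dropping samples below depth {depth}: {dropped}", stacklevel=2)
    rng = np.random.default_rng(seed)
    out = np.zeros((int(keep.sum()), values.shape[1]), dtype=int)
    for row, i in enumerate(np.where(keep)[0]):
        pool = np.repeat(np.arange(values.shape[1]), values[i])
        picked = rng.choice(pool, size=depth, replace=False)
        out[row] = np.bincount(picked, minlength=values.shape[1])
    frame = pd.DataFrame(
        out,
        index=[s for s, k in zip(table.sample_ids, keep) if k],
        columns=table.genus_ids,
    )
    return AbundanceTable(frame, mode="counts")
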