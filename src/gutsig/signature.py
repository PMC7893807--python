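"""Greedy discovery of a compact genus signature tied to behavioral severity.

The procedure has two stages:

1. *Spearman screen* — every genus is correlated (Spearman, average ranks)
   against each behavioral variable (CARS total by default, optionally ADOS
   total and the three CARS domain scores). The top ``pool`` genera by best
   absolute rho form the candidate pool; p-values are Benjamini-Hochberg
   adjusted across genera within each variable.

2. *Greedy forward selection* — starting from the screen's top genus, each
   step tentatively adds every remaining candidate, re-derives the
   two-cluster Bray-Curtis/UPGMA subtyping on the enlarged subset, and
   scores the candidate by the Kruskal-Wallis H of the CARS total across
   the two clusters. The best candidate is kept while the objective does
   not decrease; ties are broken by larger marginal |rho|, then genus id.
   Degenerate clusterings (a singleton cluster, or all-zero distances)
   score 0 so the search avoids pathological splits.

The H statistic (not its p-value) is the objective, keeping the inner loop
permutation-free; significance of the final signature is assessed once at
the end with a label-permutation test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as sps

from . import stats as gstats
from .io_core import AbundanceTable, ValidationError
from .subtyping import SubtypeAssignment, cluster_subtypes

__all__ = ["SignatureResult", "marginal_association", "greedy_search"]

DEFAULT_POOL_SIZE = 30
DEFAULT_TARGET_SIZE = 12


@dataclass(frozen=True)
class SignatureResult:
    """Outcome of the greedy signature search."""

    selected_genera: tuple[str, ...]
    objective_trace: tuple[float, ...]  # KW H after each addition
    per_genus_marginal: pd.DataFrame  # rho / variable / p_bh / degenerate per genus
    assignment: SubtypeAssignment | None
    final_test: dict | None = None  # permutation test of the final objective
    truncated: bool = False  # pool exhausted before target size

    def to_frame(self) -> pd.DataFrame:
        """Flat per-rank table of the selected signature."""
        marg = self.per_genus_marginal
        rows = []
        for rank, g in enumerate(self.selected_genera, 1):
            rows.append(
                {
                    "rank": rank,
                    "genus": g,
                    "marginal_rho": marg.loc[g, "rho"],
                    "variable": marg.loc[g, "variable"],
                    "p_bh": marg.loc[g, "p_bh"],
                    "objective": self.objective_trace[rank - 1],
                }
            )
        return pd.DataFrame(rows)


def marginal_association(table: AbundanceTable, behaviors: pd.DataFrame) -> pd.DataFrame:
    """Spearman screen of every genus against each behavioral variable.

    Returns a DataFrame indexed by genus with columns ``rho`` (best absolute
    Spearman correlation, signed), ``variable`` (which behavioral variable
    achieved it), ``p_bh`` (its BH-adjusted p across genera for that
    variable), and ``degenerate`` (constant genus column).
    """
    if table.shape[0] < 8:
        raise ValidationError("need at least 8 samples for the Spearman screen")
    rel = table if table.mode == "relative" else table.to_relative()
    behaviors = behaviors.reindex(rel.data.index)
    if behaviors.isna().all(axis=None):
        raise ValidationError("behavioral table does not cover the cohort samples")
    genera = rel.genus_ids
    per_var: dict[str, pd.DataFrame] = {}
    for var in behaviors.columns:
        y = behaviors[var]
        keep = y.notna()
        rhos, pvals, degen = [], [], []
        for g in genera:
            x = rel.data.loc[keep, g].to_numpy(float)
            if np.unique(x).size < 2 or y[keep].nunique() < 2:
                rhos.append(0.0)
                pvals.append(1.0)
                degen.append(True)
            else:
                r = sps.spearmanr(x, y[keep].to_numpy(float))
                rhos.append(float(r.statistic))
                pvals.append(float(min(max(r.pvalue, np.finfo(float).tiny), 1.0)))
                degen.append(False)
        per_var[var] = pd.DataFrame(
            {"rho": rhos, "p_bh": gstats.bh_adjust(pvals), "degenerate": degen},
            index=genera,
        )
    rows = {}
    for g in genera:
        best_var = max(per_var, key=lambda v: abs(per_var[v].loc[g, "rho"]))
        row = per_var[best_var].loc[g]
        rows[g] = {
            "rho": float(row["rho"]),
            "variable": best_var,
            "p_bh": float(row["p_bh"]),
            "degenerate": bool(row["degenerate"]),
        }
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("genus")


def _objective(table: AbundanceTable, subset: list[str], cars_total: pd.Series):
    """Severity separation (KW H of cars_total) of the 2-cluster subtyping."""
    try:
        assignment = cluster_subtypes(table, subset, cars_total)
    except ValidationError:
        return 0.0, None
    labels = assignment.labels
    sizes = labels.value_counts()
    if len(sizes) < 2 or sizes.min() < 2:
        return 0.0, assignment  # singleton cluster: pathological split
    groups = [cars_total[labels == c].to_numpy(float) for c in sizes.index]
    if np.unique(cars_total.to_numpy(float)).size < 2:
        return 0.0, assignment
    h = sps.kruskal(*groups).statistic
    return float(h), assignment


def greedy_search(
    table: AbundanceTable,
    behaviors: pd.DataFrame,
    candidate_pool_size: int = DEFAULT_POOL_SIZE,
    target_size: int = DEFAULT_TARGET_SIZE,
    seed: int = 0,
    n_permutations: int = 0,
) -> SignatureResult:
    """Forward-select a genus signature maximizing cluster-severity separation.

    Parameters
    ----------
    table : AbundanceTable
        Cohort abundances (counts or relative).
    behaviors : DataFrame
        Per-sample behavioral variables; must contain ``cars_total``.
    candidate_pool_size : int
        Number of top-screened genera eligible for selection.
    target_size : int
        Signature size to aim for; the search stops early if every remaining
        candidate strictly decreases the objective.
    seed : int
        Seed for the final permutation test (the search itself is
        deterministic).
    n_permutations : int
        If > 0, the final objective's significance is assessed by that many
        shuffles of ``cars_total`` across the final two clusters.
    """
    if "cars_total" not in behaviors.columns:
        raise ValidationError("behaviors must include cars_total")
    marginal = marginal_association(table, behaviors)
    cars_total = behaviors["cars_total"].reindex(table.data.index)
    # screen: rank by |rho| descending, genus id as deterministic tie-break
    ranked = (
        marginal.assign(abs_rho=marginal["rho"].abs())
        .sort_index()
        .sort_values("abs_rho", ascending=False, kind="mergesort")
    )
    pool = list(ranked.index[:candidate_pool_size])
    truncated = len(pool) < target_size
    selected: list[str] = []
    trace: list[float] = []
    current = 0.0
    assignment = None
    remaining = list(pool)
    while remaining and len(selected) < target_size:
        best = None
        for g in sorted(remaining):
            obj, asg = _objective(table, selected + [g], cars_total)
            key = (obj, abs(marginal.loc[g, "rho"]), _NegStr(g))
            if best is None or key > best[0]:
                best = (key, g, obj, asg)
        _, g_best, obj_best, asg_best = best
        if selected and obj_best < current:
            break  # every candidate worsens the separation
        selected.append(g_best)
        remaining.remove(g_best)
        current = obj_best
        assignment = asg_best
        trace.append(current)
    final_test = None
    if n_permutations > 0 and assignment is not None:
        labels = assignment.labels
        if labels.nunique() == 2:
            res = gstats.kruskal_wallis_perm(
                cars_total.reindex(labels.index).to_numpy(float),
                labels.to_numpy(),
                n_permutations=n_permutations,
                seed=seed,
            )
            final_test = res.to_dict()
    return SignatureResult(
        selected_genera=tuple(selected),
        objective_trace=tuple(trace),
        per_genus_marginal=marginal,
        assignment=assignment,
        final_test=final_test,
        truncated=truncated,
    )


class _NegStr(str):
    """String whose ordering is reversed, so max() prefers the lexicographically
    smaller genus id on full ties."""

    def __lt__(self, other):  # noqa: D105
        return str.__gt__(self, other)

    def __gt__(self, other):  # noqa: D105
        return str.__lt__(self, other)
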