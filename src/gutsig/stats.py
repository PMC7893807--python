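"""Permutation-based group comparisons, contingency statistics, and FDR control.

Permutation p-values use the add-one estimator ``(1 + #extreme) / (1 + B)``
so they are never zero and honor the resolution floor of B shuffles.
B defaults to 5000. All resampling is driven by an explicit seed and
reproduces exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats as sps
from statsmodels.stats.multitest import multipletests

from .io_core import AbundanceTable, ContingencyTable2x2, ValidationError

__all__ = [
    "TestResult",
    "OddsRatioResult",
    "kruskal_wallis_perm",
    "spearman_perm",
    "odds_ratio",
    "chi_square",
    "opposite_pattern_test",
    "bh_adjust",
    "group_profile",
]

DEFAULT_PERMUTATIONS = 5000

_EPS = 1e-12  # guards >= comparisons of permuted statistics against roundoff


@dataclass(frozen=True)
class TestResult:
    """Outcome of a single hypothesis test.

    ``p_perm`` is the permutation p-value (None for purely asymptotic tests
    such as the chi-square); ``p_asymptotic`` the large-sample reference
    p-value when available.
    """

    statistic_name: str
    statistic: float
    p_perm: float | None
    p_asymptotic: float | None = None
    n_permutations: int = 0
    seed: int | None = None
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.p_perm is not None:
            floor = 1.0 / (self.n_permutations + 1)
            if not (floor - _EPS <= self.p_perm <= 1.0 + _EPS):
                raise ValidationError(
                    f"permutation p {self.p_perm} outside [{floor}, 1]"
                )

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic_name,
            "value": self.statistic,
            "p_perm": self.p_perm,
            "p_asymptotic": self.p_asymptotic,
            "n_permutations": self.n_permutations,
            "seed": self.seed,
            "degenerate": self.degenerate,
        }


def _rank_h_statistic(ranks: np.ndarray, sizes: np.ndarray, tie_correction: float) -> np.ndarray:
    """Kruskal-Wallis H from (possibly batched) rank rows, given group sizes.

    ``ranks`` has groups laid out contiguously along the last axis in the
    order of ``sizes``.
    """
    n = ranks.shape[-1]
    bounds = np.concatenate(([0], np.cumsum(sizes)))
    h = np.zeros(ranks.shape[:-1])
    for j in range(sizes.size):
        rj = ranks[..., bounds[j] : bounds[j + 1]].sum(axis=-1)
        h = h + rj**2 / sizes[j]
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    return h / tie_correction


def kruskal_wallis_perm(
    values: Sequence[float],
    group_labels: Sequence,
    n_permutations: int = DEFAULT_PERMUTATIONS,
    seed: int = 0,
) -> TestResult:
    """Kruskal-Wallis H test with a label-permutation p-value.

    H uses average ranks with the standard tie correction. The permutation
    null shuffles group labels; the asymptotic chi-square p-value is also
    reported.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(group_labels)
    uniq, counts = np.unique(labels, return_counts=True)
    if uniq.size < 2:
        raise ValidationError("need at least 2 non-empty groups")
    ranks = sps.rankdata(values)
    n = values.size
    _, tie_counts = np.unique(values, return_counts=True)
    tie_correction = 1.0 - ((tie_counts**3 - tie_counts).sum()) / (n**3 - n)
    if tie_correction == 0:  # all values identical
        return TestResult(
            "kruskal_wallis_H", 0.0, 1.0, 1.0, n_permutations, seed, degenerate=True
        )
    # lay groups out contiguously so permuting rank positions == permuting labels
    order = np.argsort(labels, kind="stable")
    ranks_by_group = ranks[order]
    h_obs = float(_rank_h_statistic(ranks_by_group, counts, tie_correction))
    rng = np.random.default_rng(seed)
    perm = rng.permuted(
        np.broadcast_to(ranks_by_group, (n_permutations, n)).copy(), axis=1
    )
    h_null = _rank_h_statistic(perm, counts, tie_correction)
    p_perm = (1 + int((h_null >= h_obs - _EPS).sum())) / (1 + n_permutations)
    p_asym = float(sps.chi2.sf(h_obs, uniq.size - 1))
    return TestResult("kruskal_wallis_H", h_obs, p_perm, p_asym, n_permutations, seed)


def spearman_perm(
    x: Sequence[float],
    y: Sequence[float],
    n_permutations: int = DEFAULT_PERMUTATIONS,
    seed: int = 0,
) -> TestResult:
    """Spearman rank correlation with a two-sided permutation p-value.

    Shuffles ``y`` against ``x``. A constant vector yields rho = 0 with the
    degenerate flag set.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 5:
        raise ValidationError("need paired vectors with n >= 5")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        return TestResult(
            "spearman_rho", 0.0, 1.0, None, n_permutations, seed, degenerate=True
        )
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rx_c = rx - rx.mean()
    ry_c = ry - ry.mean()
    denom = np.sqrt((rx_c**2).sum() * (ry_c**2).sum())
    rho_obs = float((rx_c * ry_c).sum() / denom)
    rng = np.random.default_rng(seed)
    perm = rng.permuted(np.broadcast_to(ry_c, (n_permutations, y.size)).copy(), axis=1)
    rho_null = perm @ rx_c / denom
    p_perm = (1 + int((np.abs(rho_null) >= abs(rho_obs) - _EPS).sum())) / (
        1 + n_permutations
    )
    p_asym = float(sps.spearmanr(x, y).pvalue)
    return TestResult("spearman_rho", rho_obs, p_perm, p_asym, n_permutations, seed)


@dataclass(frozen=True)
class OddsRatioResult:
    odds_ratio: float
    p_value: float  # Fisher exact, two-sided
    haldane_corrected: bool = False


def odds_ratio(t: ContingencyTable2x2) -> OddsRatioResult:
    """Odds ratio (a*d)/(b*c) with Fisher's exact two-sided p-value.

    A zero cell triggers the Haldane-Anscombe +0.5 correction (flagged);
    the Fisher p is always computed on the uncorrected counts.
    """
    arr = t.to_array()
    corrected = bool((arr == 0).any())
    work = arr + 0.5 if corrected else arr
    or_value = float(work[0, 0] * work[1, 1] / (work[0, 1] * work[1, 0]))
    p = float(sps.fisher_exact(arr.astype(int), alternative="two-sided").pvalue)
    return OddsRatioResult(or_value, p, corrected)


def chi_square(t: ContingencyTable2x2, yates: bool = False) -> TestResult:
    """Pearson chi-square on a 2x2 table (df = 1), optional Yates correction."""
    arr = t.to_array()
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValidationError("chi-square undefined: empty margin")
    res = sps.chi2_contingency(arr, correction=yates)
    return TestResult("chi_square", float(res.statistic), None, float(res.pvalue))


def opposite_pattern_test(
    table: AbundanceTable,
    genus_a: str,
    genus_b: str,
    labels: pd.Series | dict,
) -> tuple[ContingencyTable2x2, TestResult]:
    """Test whether per-sample dominance of one genus over another tracks subtype.

    Each sample is classified by whether (a + eps)/(b + eps) exceeds 1, with
    eps set to half the smallest nonzero relative abundance in the table, and
    the dominance flag is cross-tabulated against the subtype labels.
    """
    for g in (genus_a, genus_b):
        if g not in table.data.columns:
            raise ValidationError(f"genus {g!r} absent from the table")
    rel = table if table.mode == "relative" else table.to_relative()
    values = rel.values
    nonzero = values[values > 0]
    eps = 0.5 * nonzero.min() if nonzero.size else 0.5
    a = rel.data[genus_a].to_numpy(dtype=float)
    b = rel.data[genus_b].to_numpy(dtype=float)
    dominant = (a + eps) / (b + eps) > 1
    lab = pd.Series(labels).reindex(rel.data.index)
    if lab.isna().any():
        raise ValidationError("labels do not cover every sample in the table")
    groups = sorted(lab.unique())
    if len(groups) != 2:
        raise ValidationError("opposite-pattern test needs exactly 2 subtypes")
    g1 = lab.to_numpy() == groups[0]
    ct = ContingencyTable2x2(
        int((g1 & dominant).sum()),
        int((g1 & ~dominant).sum()),
        int((~g1 & dominant).sum()),
        int((~g1 & ~dominant).sum()),
    )
    return ct, chi_square(ct)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p <= 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValidationError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def group_profile(
    scores: pd.DataFrame,
    labels: pd.Series | dict,
    ados_total: pd.Series | None = None,
    brain: pd.DataFrame | None = None,
    n_permutations: int = DEFAULT_PERMUTATIONS,
    seed: int = 0,
    alpha: float = 0.05,
) -> dict:
    """Compare clinical scores, severity, and brain volumes across two subtypes.

    Parameters
    ----------
    scores : DataFrame
        Per-sample domain scores from :func:`gutsig.cars_scoring.score_cohort`
        (must include cars_total, items_ge3, the three domains, severity).
    labels : Series or dict
        Subtype label (mp1/mp2) per sample.
    ados_total : Series, optional
        ADOS totals; samples with missing values are dropped for that test.
    brain : DataFrame, optional
        Samples x regions volumes; per-region Kruskal-Wallis permutation
        p-values are BH-adjusted as a family, and regions significant after
        adjustment are correlated (Spearman, permutation p) with the
        distorted-sensory-response score within each subtype.

    Returns a nested dict report; every test row records its statistic, p,
    permutation count, and seed, so the report reruns bit-identically.
    """
    lab = pd.Series(labels).reindex(scores.index)
    if lab.isna().any():
        raise ValidationError("labels do not cover every scored sample")
    ss = np.random.SeedSequence(seed)
    seeds = iter(int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(4096))
    report: dict = {"n_by_subtype": lab.value_counts().to_dict(), "clinical": {}}
    clinical_vars = [
        "cars_total",
        "items_ge3",
        "social_impairment",
        "negative_emotionality",
        "distorted_sensory_response",
    ]
    for var in clinical_vars:
        report["clinical"][var] = kruskal_wallis_perm(
            scores[var].to_numpy(float), lab.to_numpy(), n_permutations, next(seeds)
        ).to_dict()
    if ados_total is not None:
        ados = pd.Series(ados_total).reindex(scores.index)
        keep = ados.notna()
        if keep.sum() >= 4 and lab[keep].nunique() == 2:
            res = kruskal_wallis_perm(
                ados[keep].to_numpy(float), lab[keep].to_numpy(), n_permutations, next(seeds)
            )
            report["clinical"]["ados_total"] = {**res.to_dict(), "n": int(keep.sum())}
    # severity x subtype contingency
    groups = sorted(lab.unique())
    sev = scores["severity"] == "severe"
    g1 = lab == groups[0]
    ct = ContingencyTable2x2(
        int((g1 & sev).sum()),
        int((g1 & ~sev).sum()),
        int((~g1 & sev).sum()),
        int((~g1 & ~sev).sum()),
    )
    orr = odds_ratio(ct)
    report["severity_by_subtype"] = {
        "table": [[ct.a, ct.b], [ct.c, ct.d]],
        "severe_fraction": {
            str(groups[0]): ct.a / max(ct.a + ct.b, 1),
            str(groups[1]): ct.c / max(ct.c + ct.d, 1),
        },
        "odds_ratio": orr.odds_ratio,
        "fisher_p": orr.p_value,
        "haldane_corrected": orr.haldane_corrected,
    }
    if brain is not None:
        brain = brain.reindex(scores.index)
        region_tests = {}
        for region in brain.columns:
            vol = brain[region]
            keep = vol.notna()
            if keep.sum() < 4 or lab[keep].nunique() < 2:
                continue
            res = kruskal_wallis_perm(
                vol[keep].to_numpy(float), lab[keep].to_numpy(), n_permutations, next(seeds)
            )
            region_tests[region] = {**res.to_dict(), "n": int(keep.sum())}
        raw = [region_tests[r]["p_perm"] for r in region_tests]
        adj = bh_adjust(raw) if raw else []
        for r, q in zip(region_tests, adj):
            region_tests[r]["p_bh"] = float(q)
        report["brain_regions"] = region_tests
        flagged = [r for r in region_tests if region_tests[r]["p_bh"] <= alpha]
        corr: dict = {}
        for region in flagged:
            corr[region] = {}
            for grp in groups:
                mask = (lab == grp) & brain[region].notna()
                if mask.sum() < 5:
                    continue
                res = spearman_perm(
                    brain.loc[mask, region].to_numpy(float),
                    scores.loc[mask, "distorted_sensory_response"].to_numpy(float),
                    n_permutations,
                    next(seeds),
                )
                corr[region][str(grp)] = {**res.to_dict(), "n": int(mask.sum())}
        report["brain_sensory_correlation"] = corr
    return report
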