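import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from gutsig.io_core import AbundanceTable, ContingencyTable2x2, ValidationError
from gutsig.stats import (
    bh_adjust,
    chi_square,
    group_profile,
    kruskal_wallis_perm,
    odds_ratio,
    opposite_pattern_test,
    spearman_perm,
)


def fisher_exact_enumeration(a, b, c, d):
    """Independent oracle: two-sided Fisher p by hypergeometric enumeration."""
    row1, col1, n = a + b, a + c, a + b + c + d
    lo, hi = max(0, row1 + col1 - n), min(row1, col1)
    probs = {x: hypergeom.pmf(x, n, row1, col1) for x in range(lo, hi + 1)}
    p_obs = probs[a]
    return sum(p for p in probs.values() if p <= p_obs * (1 + 1e-9))


class TestKruskalWallis:
    def test_hand_computed_h(self):
        res = kruskal_wallis_perm([1, 2, 3, 4, 5, 6], ["a", "a", "a", "b", "b", "b"], 999, 0)
        assert res.statistic == pytest.approx(3.857, abs=1e-3)
        assert res.p_asymptotic == pytest.approx(0.0495, abs=1e-3)

    def test_all_equal_degenerate(self):
        res = kruskal_wallis_perm([2, 2, 2, 2], ["a", "a", "b", "b"], 99, 0)
        assert res.statistic == 0.0
        assert res.p_perm == 1.0
        assert res.degenerate

    def test_seed_reproduces_p_exactly(self):
        rng = np.random.default_rng(4)
        x, g = rng.normal(size=30), rng.integers(0, 2, size=30)
        p1 = kruskal_wallis_perm(x, g, 500, seed=11).p_perm
        p2 = kruskal_wallis_perm(x, g, 500, seed=11).p_perm
        assert p1 == p2

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            kruskal_wallis_perm([1, 2, 3], ["a", "a", "a"], 99, 0)


class TestSpearman:
    def test_perfect_correlation_hits_floor(self):
        x = np.arange(10.0)
        res = spearman_perm(x, x, n_permutations=199, seed=0)
        assert res.statistic == pytest.approx(1.0)
        assert res.p_perm == pytest.approx(1 / 200)

    def test_rank_formula_hand_value(self):
        # d^2 = (4,1,1,1,1), rho = 1 - 6*8/(5*24) = 0.6
        res = spearman_perm([1, 2, 3, 4, 5], [3, 1, 2, 5, 4], 99, 0)
        assert res.statistic == pytest.approx(0.6)

    def test_constant_vector_degenerate(self):
        res = spearman_perm([1, 1, 1, 1, 1], [1, 2, 3, 4, 5], 99, 0)
        assert res.statistic == 0.0
        assert res.degenerate


class TestContingency:
    def test_printed_count_reconstruction_rounds_to_0_2(self):
        res = odds_ratio(ContingencyTable2x2(13, 19, 14, 4))
        assert res.odds_ratio == pytest.approx(0.195, abs=5e-4)
        assert round(res.odds_ratio, 1) == 0.2
        assert not res.haldane_corrected

    def test_no_association(self):
        assert odds_ratio(ContingencyTable2x2(5, 5, 5, 5)).odds_ratio == 1.0

    def test_haldane_correction_on_zero_cell(self):
        res = odds_ratio(ContingencyTable2x2(10, 0, 0, 10))
        assert res.haldane_corrected
        assert res.odds_ratio == pytest.approx(441.0)

    def test_fisher_matches_enumeration_small_tables(self):
        for n in range(2, 13):
            for a, b, c in itertools.product(range(n + 1), repeat=3):
                d = n - a - b - c
                if d < 0 or (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
                    continue
                ours = odds_ratio(ContingencyTable2x2(a, b, c, d)).p_value
                oracle = fisher_exact_enumeration(a, b, c, d)
                assert ours == pytest.approx(oracle, abs=1e-9), (a, b, c, d)

    def test_chi_square_closed_form(self):
        res = chi_square(ContingencyTable2x2(13, 19, 14, 4))
        a, b, c, d = 13, 19, 14, 4
        n = a + b + c + d
        expected = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        assert res.statistic == pytest.approx(expected)
        assert res.statistic == pytest.approx(6.40, abs=5e-3)

    def test_yates_never_exceeds_uncorrected(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a, b, c, d = rng.integers(1, 20, size=4)
            t = ContingencyTable2x2(int(a), int(b), int(c), int(d))
            assert chi_square(t, yates=True).statistic <= chi_square(t).statistic + 1e-12

    def test_zero_table_chi_square(self):
        assert chi_square(ContingencyTable2x2(5, 5, 5, 5)).statistic == 0.0


class TestBhAdjust:
    def test_equal_ps_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.01] * 10), [0.01] * 10)

    def test_hand_step_up(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_single_p_identity_and_bounds(self):
        assert bh_adjust([0.5])[0] == 0.5
        p = np.sort(np.random.default_rng(1).uniform(0.001, 1, 20))
        adj = bh_adjust(p)
        assert (adj >= p - 1e-12).all()
        assert (np.diff(adj) >= -1e-12).all()

    def test_rejects_out_of_range(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.0, 0.5])


class TestOppositePattern:
    def test_planted_pair_detected(self, discovery):
        lab = discovery.truth.latent_labels.map({1: "mp1", 2: "mp2"})
        ga, gb = discovery.truth.opposite_pair
        table, res = opposite_pattern_test(discovery.abundance, ga, gb, lab)
        assert res.p_asymptotic < 0.01

    def test_same_genus_degenerate(self, discovery):
        lab = discovery.truth.latent_labels.map({1: "mp1", 2: "mp2"})
        g = discovery.abundance.genus_ids[0]
        with pytest.raises(ValidationError, match="margin"):
            opposite_pattern_test(discovery.abundance, g, g, lab)

    def test_missing_genus_errors(self, discovery):
        lab = discovery.truth.latent_labels.map({1: "mp1", 2: "mp2"})
        with pytest.raises(ValidationError, match="nope"):
            opposite_pattern_test(discovery.abundance, "nope", "Genus001", lab)


class TestGroupProfile:
    def test_report_is_deterministic_and_complete(self, discovery, discovery_scores):
        lab = discovery.truth.latent_labels.map({1: "mp1", 2: "mp2"})
        kwargs = dict(
            labels=lab,
            brain=discovery.brain.data,
            n_permutations=199,
            seed=5,
        )
        r1 = group_profile(discovery_scores, **kwargs)
        r2 = group_profile(discovery_scores, **kwargs)
        assert r1 == r2
        assert set(r1["clinical"]) >= {
            "cars_total",
            "items_ge3",
            "social_impairment",
            "negative_emotionality",
            "distorted_sensory_response",
        }
        assert r1["clinical"]["cars_total"]["p_perm"] <= 0.05
        assert "odds_ratio" in r1["severity_by_subtype"]
        assert len(r1["brain_regions"]) == 10
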