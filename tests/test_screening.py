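"""Correlation screening: Spearman, two-stage FDR, Rueger areas, bin screens."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from statsmodels.stats.multitest import multipletests

from napqeeg.screening import (
    ALPHA,
    RUGER_HALF,
    RUGER_THIRD,
    binwise_screen,
    bky_adjust,
    extract_areas,
    ruger_decide,
    spearman,
    spearman_matrix,
)


def spearman_rank_oracle(x, y):
    """Brute-force Spearman: average ranks computed by explicit enumeration,
    then the Pearson product-moment formula on the ranks."""
    def avg_ranks(v):
        v = np.asarray(v, dtype=float)
        r = np.empty(len(v))
        for i, vi in enumerate(v):
            less = np.sum(v < vi)
            ties = np.sum(v == vi)
            r[i] = less + (ties + 1) / 2.0
        return r

    rx, ry = avg_ranks(x), avg_ranks(y)
    rx -= rx.mean()
    ry -= ry.mean()
    return float((rx @ ry) / math.sqrt((rx @ rx) * (ry @ ry)))


class TestSpearman:
    def test_perfect_monotone(self):
        res = spearman([1, 2, 3, 4], [10, 20, 30, 40])
        assert res.rho == 1.0
        assert res.p_raw == pytest.approx(2.0 / math.factorial(4))

    def test_perfect_antitone(self):
        assert spearman([1, 2, 3, 4], [4, 3, 2, 1]).rho == -1.0

    def test_ties_match_rank_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 15))
            x = rng.integers(0, 5, n).astype(float)
            y = rng.integers(0, 5, n).astype(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            assert spearman(x, y).rho == pytest.approx(
                spearman_rank_oracle(x, y), abs=1e-12
            )

    def test_example_tied_data(self):
        res = spearman([1, 1, 2, 3], [2, 1, 1, 3])
        assert res.rho == pytest.approx(
            spearman_rank_oracle([1, 1, 2, 3], [2, 1, 1, 3]), abs=1e-12
        )

    def test_p_matches_t_approximation(self, rng):
        x = rng.standard_normal(20)
        y = rng.standard_normal(20)
        res = spearman(x, y)
        ref = stats.spearmanr(x, y)
        assert res.rho == pytest.approx(ref.statistic, abs=1e-12)
        assert res.p_raw == pytest.approx(ref.pvalue, abs=1e-10)

    def test_pairwise_deletion_and_min_pairs(self):
        x = [1, 2, 3, np.nan, 5]
        y = [2, 4, np.nan, 8, 10]
        assert spearman(x, y).n_pairs == 3
        assert not spearman(x, y).computable

    def test_zero_variance_flagged(self):
        res = spearman([1, 1, 1, 1], [1, 2, 3, 4])
        assert not res.computable and "variance" in res.reason

    def test_matrix_agrees_with_scalar(self, rng):
        mat = rng.standard_normal((12, 5))
        mat[2, 1] = np.nan
        cov = rng.standard_normal(12)
        rho, p, n = spearman_matrix(mat, cov)
        for j in range(5):
            ref = spearman(cov, mat[:, j])
            assert rho[j] == pytest.approx(ref.rho, abs=1e-12)
            assert p[j] == pytest.approx(ref.p_raw, abs=1e-10)
            assert n[j] == ref.n_pairs


def bky_oracle_reject(p, level=0.05):
    """Hand-stepped two-stage procedure, straight from its definition."""
    p = np.asarray(p, dtype=float)
    m = len(p)

    def bh(level_):
        order = np.argsort(p)
        passed = [i for i in range(m)
                  if p[order[i]] <= (i + 1) / m * level_]
        k = (passed[-1] + 1) if passed else 0
        rej = np.zeros(m, dtype=bool)
        rej[order[:k]] = True
        return rej

    lvl1 = level / (1 + level)
    r1 = int(bh(lvl1).sum())
    if r1 == 0:
        return np.zeros(m, dtype=bool)
    if r1 == m:
        return np.ones(m, dtype=bool)
    return bh(lvl1 * m / (m - r1))


class TestBKY:
    def test_all_large_none_rejected(self):
        assert bky_adjust(np.full(10, 0.9)).reject.sum() == 0

    def test_all_tiny_all_rejected(self):
        assert bky_adjust(np.full(10, 0.001)).reject.all()

    def test_mixed_family_matches_hand_stepped_oracle(self):
        p = np.array([0.001, 0.01, 0.02, 0.2, 0.8])
        res = bky_adjust(p)
        assert np.array_equal(res.reject, bky_oracle_reject(p))
        assert np.array_equal(res.reject, [True, True, True, False, False])

    def test_random_families_match_oracle_and_statsmodels(self, rng):
        for _ in range(100):
            m = int(rng.integers(2, 50))
            p = np.clip(rng.beta(0.4, 3.0, m), 1e-12, 1.0)
            res = bky_adjust(p)
            assert np.array_equal(res.reject, bky_oracle_reject(p))
            sm = multipletests(p, alpha=0.05, method="fdr_tsbky")[0]
            assert np.array_equal(res.reject, sm)

    def test_q_values_are_smallest_rejecting_level(self, rng):
        p = np.clip(rng.beta(0.5, 2.0, 12), 1e-9, 1.0)
        res = bky_adjust(p)
        for i in range(len(p)):
            q = res.q[i]
            if q < 1.0:
                rej_at_q = bky_oracle_reject(p, level=min(1.0, q * 1.01))
                assert rej_at_q[i]
            if q > 1e-6:
                assert not bky_oracle_reject(p, level=q * 0.9)[i]

    def test_q_monotone_in_p(self, rng):
        p = np.sort(np.clip(rng.beta(0.5, 2.0, 20), 1e-9, 1.0))
        q = bky_adjust(p).q
        assert (np.diff(q) >= -1e-12).all()

    def test_adaptivity_superset_of_bh_when_signal_dense(self, rng):
        """BKY rejects everything BH rejects whenever stage 1 rejects at
        least a (1 - lvl1/level) share of the family, which makes the
        stage-2 level exceed the nominal one; checked on dense-signal
        families where that condition holds."""
        checked = 0
        while checked < 50:
            m = int(rng.integers(5, 40))
            p = np.clip(np.concatenate([
                rng.beta(0.1, 8.0, m // 2), rng.random(m - m // 2)
            ]), 1e-12, 1.0)
            lvl1 = 0.05 / 1.05
            r1 = int(multipletests(p, alpha=lvl1, method="fdr_bh")[0].sum())
            if not 0 < r1 < m or r1 < (1 - lvl1 / 0.05) * m:
                continue
            bh = multipletests(p, alpha=0.05, method="fdr_bh")[0]
            bky = bky_adjust(p).reject
            assert (bky | ~bh).all()  # BH set is a subset of the BKY set
            checked += 1

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bky_adjust(np.array([0.1, 1.2]))
        with pytest.raises(ValueError):
            bky_adjust(np.array([]))


class TestRugerDecide:
    def test_sub_thresholds_derive_from_alpha(self):
        assert RUGER_HALF == ALPHA / 2 == 0.025
        assert RUGER_THIRD == ALPHA / 3
        assert round(RUGER_THIRD, 4) == 0.0167

    @pytest.mark.parametrize("ps,expected", [
        ([0.04, 0.04, 0.04, 0.04], False),  # none below 0.025
        ([0.01, 0.01, 0.03], True),  # 2/3 below both sub-thresholds
        ([0.02, 0.02, 0.02, 0.02], False),  # all below 0.025, none below 1/3
        ([0.01], True),  # lone bin below 0.05/3 passes both fractions
        ([0.02], False),
    ])
    def test_printed_rule_arithmetic(self, ps, expected):
        assert ruger_decide(np.array(ps)).significant is expected

    def test_malformed_cluster_rejected(self):
        with pytest.raises(ValueError, match="malformed"):
            ruger_decide(np.array([0.01, 0.06]))

    def test_permutation_invariance(self, rng):
        ps = rng.random(8) * 0.049
        base = ruger_decide(ps).significant
        for _ in range(10):
            assert ruger_decide(rng.permutation(ps)).significant == base

    @given(st.lists(st.floats(1e-6, 0.0499), min_size=1, max_size=12),
           st.integers(0, 11))
    @settings(max_examples=200, deadline=None)
    def test_lowering_a_p_never_loses_significance(self, ps, idx):
        ps = np.array(ps)
        before = ruger_decide(ps).significant
        lowered = ps.copy()
        lowered[idx % len(ps)] *= 0.1
        after = ruger_decide(lowered).significant
        assert after or not before


class TestExtractAreas:
    def test_runs_are_maximal_and_disjoint(self):
        bins = 0.5 + 0.25 * np.arange(12)
        p = np.array([0.2, 0.01, 0.02, 0.3, 0.04, 0.5,
                      0.001, 0.001, 0.001, 0.9, 0.04, 0.03])
        areas = extract_areas(bins, p)
        spans = [(a.f_lo, a.f_hi) for a in areas]
        assert spans == [(bins[1], bins[2]), (bins[4], bins[4]),
                         (bins[6], bins[8]), (bins[10], bins[11])]
        assert [a.significant for a in areas] == [True, False, True, False]

    def test_nan_breaks_runs(self):
        bins = np.arange(5, dtype=float)
        p = np.array([0.01, np.nan, 0.01, 0.01, 0.8])
        areas = extract_areas(bins, p)
        assert [(a.f_lo, a.f_hi) for a in areas] == [(0.0, 0.0), (2.0, 3.0)]


class TestBinwiseScreen:
    def test_constant_covariate_not_computable(self, rng):
        bins = 0.5 + 0.25 * np.arange(20)
        res = binwise_screen(rng.standard_normal((10, 20)), np.ones(10), bins)
        assert not res.computable and res.areas == []

    def test_subjects_missing_state_dropped_whole(self, rng):
        bins = 0.5 + 0.25 * np.arange(10)
        mat = rng.standard_normal((8, 10))
        mat[3, :] = np.nan
        res = binwise_screen(mat, rng.standard_normal(8), bins)
        assert (res.n_pairs == 7).all()

    def test_too_few_subjects_skipped_with_reason(self, rng):
        bins = 0.5 + 0.25 * np.arange(10)
        mat = rng.standard_normal((3, 10))
        res = binwise_screen(mat, rng.standard_normal(3), bins)
        assert not res.computable and "3 subjects" in res.reason

    def test_injected_effect_bins_recovered(self, rng):
        bins = 0.5 + 0.25 * np.arange(40)
        n = 28
        cov = rng.standard_normal(n)
        mat = rng.standard_normal((n, 40))
        mat[:, 10:14] = 0.9 * cov[:, None] + 0.3 * rng.standard_normal((n, 4))
        res = binwise_screen(mat, cov, bins)
        sig = res.significant_areas
        assert sig, "expected a significant area over the injected bins"
        assert any(a.f_lo >= bins[9] and a.f_hi <= bins[14] for a in sig)
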