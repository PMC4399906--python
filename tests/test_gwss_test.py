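"""Tests of the GWSS statistic, the VT sweep and the permutation engine.

The key oracles are written independently of the engine: a pure-Python
transcription of the whole pipeline (`naive_statistic`), an exhaustive
enumeration of label arrangements on a 6-subject instance, and a directly
coded Madsen-Browning weighted rank-sum statistic.
"""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gwss.gwss_test import (
    METHODS,
    GenotypeMatrix,
    GwssMethod,
    GwssTest,
    aggregate,
    gwss_statistic,
    permutation_pvalue,
    permutation_test,
    ranksum_summary,
    resolve_method,
    threshold_set,
    tsum_summary,
)


# ---------------------------------------------------------------------------
# Independent oracle: plain-Python transcription of the algorithm
# ---------------------------------------------------------------------------

def naive_statistic(G, y, weight, summary, variable_threshold, theta=None):
    """Loop-based GWSS statistic, coded without the vectorised engine."""
    G = [[int(g) for g in row] for row in np.asarray(G)]
    y = [int(v) for v in y]
    n = len(y)
    k = len(G[0])
    n1 = sum(y)
    n0 = n - n1
    m = [sum(G[i][j] for i in range(n) if y[i] == 0) for j in range(k)]
    a = [sum(G[i][j] for i in range(n) if y[i] == 1) for j in range(k)]
    q = [(m[j] + 1) / (2 * n0 + 2) for j in range(k)]
    orj = [((a[j] + 0.5) * (2 * n0 - m[j] + 0.5))
           / ((2 * n1 - a[j] + 0.5) * (m[j] + 0.5)) for j in range(k)]

    def wj(j):
        maf = 1.0 / math.sqrt(n0 * q[j] * (1 - q[j]))
        if weight == "MAF":
            return maf
        if weight == "OR":
            return math.log(orj[j])
        d = (1 if orj[j] > 1 else 0) - (1 if orj[j] < 1 else 0)
        if weight == "D":
            return d
        return d * maf

    def stat_at(th):
        scores = [sum(wj(j) * G[i][j] for j in range(k) if th is None or q[j] <= th)
                  for i in range(n)]
        if summary == "t-sum":
            s1 = [scores[i] for i in range(n) if y[i] == 1]
            s0 = [scores[i] for i in range(n) if y[i] == 0]
            m1 = sum(s1) / len(s1)
            m0 = sum(s0) / len(s0)
            v1 = sum((x - m1) ** 2 for x in s1) / (len(s1) - 1)
            v0 = sum((x - m0) ** 2 for x in s0) / (len(s0) - 1)
            den = math.sqrt(v1 / len(s1) + v0 / len(s0))
            if den == 0:
                return 0.0 if abs(m1 - m0) < 1e-12 else math.inf
            return abs(m1 - m0) / den
        # rank-sum with midranks
        order = sorted(range(n), key=lambda i: scores[i])
        ranks = [0.0] * n
        i = 0
        while i < n:
            j = i
            while j + 1 < n and scores[order[j + 1]] == scores[order[i]]:
                j += 1
            mid = (i + j) / 2 + 1
            for t in range(i, j + 1):
                ranks[order[t]] = mid
            i = j + 1
        return sum(ranks[i] for i in range(n) if y[i] == 1)

    if not variable_threshold:
        return stat_at(theta)
    return max(stat_at(th) for th in sorted(set(q)))


def random_instance(rng, n=12, k=4):
    G = rng.binomial(2, rng.uniform(0.05, 0.4, size=k), size=(n, k))
    y = np.zeros(n, dtype=np.int8)
    y[rng.choice(n, n // 2, replace=False)] = 1
    return G.astype(np.int8), y


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------

class TestAggregate:
    def test_empty_filter_gives_zero(self):
        G = np.array([[1, 2], [0, 1]])
        s = aggregate(G, w=[1.0, 1.0], q=[0.3, 0.4], theta=0.1)
        np.testing.assert_array_equal(s, 0.0)

    def test_single_variant_passthrough(self):
        G = np.array([[0], [1], [2]])
        s = aggregate(G, w=[1.0], q=[0.05], theta=0.1)
        np.testing.assert_array_equal(s, [0, 1, 2])

    def test_opposite_directions_cancel(self):
        s = aggregate(np.array([[2, 2]]), w=[1.0, -1.0], q=[0.1, 0.1], theta=None)
        assert s[0] == 0.0

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            aggregate(np.eye(2), w=[1.0], q=[0.1, 0.2])


class TestSummaries:
    def test_ranksum_extreme_ordering(self):
        scores = np.array([0.1, 0.2, 0.8, 0.9])
        y = np.array([0, 0, 1, 1])
        assert ranksum_summary(scores, y) == 7.0

    def test_ranksum_complete_ties_gives_midranks(self):
        scores = np.zeros(6)
        y = np.array([1, 1, 0, 0, 1, 0])
        assert ranksum_summary(scores, y) == 3 * (6 + 1) / 2

    def test_ranksum_hand_example(self):
        scores = np.array([0.3, 0.1, 0.2, 0.0])
        y = np.array([1, 1, 0, 0])
        assert ranksum_summary(scores, y) == 6.0

    def test_tsum_equal_means_is_zero(self):
        scores = np.array([1.0, 2.0, 1.0, 2.0])
        y = np.array([1, 1, 0, 0])
        assert tsum_summary(scores, y) == 0.0

    def test_tsum_welch_hand_example(self):
        scores = np.array([1.0, 1.0, 1.0, 3.0, 0.0, 0.0, 0.0, 0.0])
        y = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        assert tsum_summary(scores, y) == pytest.approx(3.0)

    def test_tsum_label_swap_invariant(self, rng):
        scores = rng.normal(size=10)
        y = np.array([1] * 5 + [0] * 5)
        assert tsum_summary(scores, y) == pytest.approx(tsum_summary(scores, 1 - y))

    def test_tsum_degenerate_unequal_means(self):
        scores = np.array([1.0, 1.0, 0.0, 0.0])
        y = np.array([1, 1, 0, 0])
        with pytest.warns(UserWarning, match="degenerate"):
            assert tsum_summary(scores, y) == np.inf


class TestThresholdSet:
    def test_unique_sort(self):
        np.testing.assert_array_equal(threshold_set([0.001, 0.001, 0.03]),
                                      [0.001, 0.03])

    def test_fixed_policy(self):
        np.testing.assert_array_equal(
            threshold_set([0.1, 0.2], policy="fixed", theta=0.01), [0.01])

    def test_distinct_values_full_size(self, rng):
        q = rng.uniform(0.001, 0.4, size=9)
        assert threshold_set(q).size == 9

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            threshold_set([0.1], policy="grid", grid=[])


# ---------------------------------------------------------------------------
# The statistic: engine vs naive transcription
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("name", sorted(METHODS))
def test_engine_matches_naive_transcription(name, rng):
    """Every registered method agrees with the loop-based oracle."""
    m = METHODS[name]
    for _ in range(5):
        G, y = random_instance(rng)
        S, theta_sel, _ = gwss_statistic(G, y, name)
        expected = naive_statistic(G, y, m.weight, m.summary,
                                   m.variable_threshold, m.theta)
        assert S == pytest.approx(expected, rel=1e-10)


def test_fixed_theta_matches_naive(rng):
    G, y = random_instance(rng)
    S, theta_sel, _ = gwss_statistic(G, y, "WSS-t", theta=0.2)
    assert theta_sel == 0.2
    assert S == pytest.approx(naive_statistic(G, y, "MAF", "t-sum", False, 0.2))


def test_sup_dominates_every_fixed_threshold(rng):
    """VT statistic >= the fixed-threshold statistic at every candidate."""
    for _ in range(5):
        G, y = random_instance(rng, n=16, k=5)
        S_sup, theta_sel, profile = gwss_statistic(G, y, "VDWSS-t")
        thetas, stats = profile
        assert S_sup == pytest.approx(max(stats))
        for th, s in zip(thetas, stats):
            S_fixed, _, _ = gwss_statistic(G, y, "DWSS-t", theta=th)
            assert S_fixed == pytest.approx(s)
            assert S_sup >= S_fixed - 1e-12
        # smallest maximising threshold reported on ties
        assert theta_sel == thetas[np.argmax(np.isclose(stats, S_sup))]


def test_single_shared_maf_collapses_vt_to_fixed():
    """With one distinct adjusted MAF, sup and no-filter modes coincide."""
    rng = np.random.default_rng(3)
    G = rng.binomial(2, 0.2, size=(20, 3)).astype(np.int8)
    y = np.array([1] * 10 + [0] * 10)
    # force identical control counts across variants
    G[y == 0] = G[y == 0][:, [0, 0, 0]]
    S_v, _, _ = gwss_statistic(G, y, "VWSS-t")
    S_f, _, _ = gwss_statistic(G, y, "WSS-t")
    assert S_v == pytest.approx(S_f)


def test_madsen_browning_special_case(rng):
    """Method WSS reproduces a directly coded Madsen-Browning weighted
    rank-sum statistic (control-adjusted MAF weights, pooled case ranks)."""
    for _ in range(5):
        G, y = random_instance(rng, n=14, k=4)
        S, _, _ = gwss_statistic(G, y, "WSS")
        n0 = int((y == 0).sum())
        q = [(sum(G[i, j] for i in range(len(y)) if y[i] == 0) + 1)
             / (2 * n0 + 2) for j in range(G.shape[1])]
        w = [1 / math.sqrt(n0 * qj * (1 - qj)) for qj in q]
        burden = [sum(w[j] * G[i, j] for j in range(G.shape[1]))
                  for i in range(len(y))]
        expected = ranksum_summary(np.array(burden), y)
        assert S == pytest.approx(expected)


def test_orwss_special_case(rng):
    """Method ORWSS matches a direct transcription of the log-OR weighted
    rank-sum with 0.5-corrected allele tables."""
    G, y = random_instance(rng, n=14, k=4)
    S, _, _ = gwss_statistic(G, y, "ORWSS")
    assert S == pytest.approx(naive_statistic(G, y, "OR", "rank-sum", False))


# ---------------------------------------------------------------------------
# Permutation engine
# ---------------------------------------------------------------------------

def test_pvalue_add_one_extreme_case():
    """Observed S above every permuted S gives p = 1/(B+1)."""
    rng = np.random.default_rng(0)
    G = np.zeros((12, 2), dtype=np.int8)
    G[:6, 0] = 2  # perfect separation: cases carry everything
    y = np.array([1] * 6 + [0] * 6)
    res = permutation_pvalue(G, y, "DWSS-t", n_permutations=50, seed=1,
                             keep_null=True)
    assert res.p_value >= 1 / 51
    assert res.p_value == (1 + (res.null_statistics >= res.statistic - 1e-12).sum()) / 51


def test_exhaustive_enumeration_oracle():
    """On n=6 (3 cases), the engine's permutation distribution over all 20
    label arrangements equals the brute-force enumeration exactly."""
    rng = np.random.default_rng(5)
    G = rng.binomial(2, [0.3, 0.15, 0.4], size=(6, 3)).astype(np.int8)
    G[0, 1] = 2  # break symmetry
    y = np.array([1, 1, 1, 0, 0, 0])
    arrangements = [np.array(p, dtype=np.int8)
                    for p in sorted(set(itertools.permutations(y)))]
    assert len(arrangements) == 20
    perms = np.vstack(arrangements)
    for name in ("VDWSS-t", "WSS", "ORWSS-t"):
        m = METHODS[name]
        res = permutation_pvalue(G, y, name, permutations=perms, keep_null=True)
        oracle = np.array([
            naive_statistic(G, lab, m.weight, m.summary, m.variable_threshold)
            for lab in arrangements
        ])
        np.testing.assert_allclose(np.sort(res.null_statistics), np.sort(oracle),
                                   rtol=1e-10)
        n_ge = int((oracle >= res.statistic - 1e-12).sum())
        assert res.p_value == pytest.approx((1 + n_ge) / 21)


def test_full_recomputation_under_permutation():
    """Permuted statistics must differ from simply re-scoring fixed weights:
    a labeling with reversed case burden changes q, OR and hence weights."""
    rng = np.random.default_rng(8)
    G, y = random_instance(rng, n=20, k=3)
    flipped = 1 - y
    S_obs, _, _ = gwss_statistic(G, y, "ORWSS-t")
    S_flip, _, _ = gwss_statistic(G, flipped, "ORWSS-t")
    res = permutation_pvalue(G, y, "ORWSS-t", permutations=flipped[None, :])
    # the engine's single "permutation" row equals the recomputed statistic
    assert res.p_value == pytest.approx((1 + (S_flip >= S_obs - 1e-12)) / 2)


def test_tsum_label_swap_invariance_balanced(rng):
    """With n1 = n0 and no MAF filter, OR- and D-weighted t-sum statistics
    are invariant to exchanging case/control roles: the swap inverts every
    odds ratio exactly, so the weights (and scores) only change sign and
    the absolute Welch t is unchanged.  MAF-based weights are recomputed
    from the *new* control group, so no such exact symmetry holds there."""
    G, y = random_instance(rng, n=16, k=4)
    for name in ("ORWSS-t", "DSS-t"):
        S1, _, _ = gwss_statistic(G, y, name)
        S2, _, _ = gwss_statistic(G, 1 - y, name)
        assert S1 == pytest.approx(S2)


def test_bit_reproducibility(small_dataset):
    G, y = small_dataset
    r1 = permutation_test(G, y, list(METHODS), n_permutations=40, seed=123)
    r2 = permutation_test(G, y, list(METHODS), n_permutations=40, seed=123)
    for name in METHODS:
        assert r1[name].statistic == r2[name].statistic
        assert r1[name].p_value == r2[name].p_value
        assert r1[name].selected_threshold == r2[name].selected_threshold


def test_null_calibration_small():
    """With phenotype independent of genotype, p-values are approximately
    uniform: rejection at alpha=0.05 stays within Monte-Carlo error."""
    rng = np.random.default_rng(42)
    n, k, reps, B = 40, 4, 200, 99
    y = np.array([1] * 20 + [0] * 20, dtype=np.int8)
    rejections = 0
    pvals = []
    for _ in range(reps):
        G = rng.binomial(2, [0.05, 0.1, 0.2, 0.3], size=(n, k)).astype(np.int8)
        res = permutation_pvalue(G, y, "VDWSS-t", n_permutations=B, rng=rng)
        pvals.append(res.p_value)
        rejections += res.p_value <= 0.05
    rate = rejections / reps
    se = np.sqrt(0.05 * 0.95 / reps)
    assert rate <= 0.05 + 3 * se
    # p-values should not pile up near 0 or 1
    assert 0.3 <= np.mean(pvals) <= 0.7


class TestEstimatorApi:
    def test_fit_exposes_sklearn_attributes(self, small_dataset):
        G, y = small_dataset
        est = GwssTest(method="VDWSS-t", n_permutations=60, random_state=0)
        assert est.get_params()["n_permutations"] == 60
        est.fit(G, y)
        assert 0 < est.p_value_ <= 1
        assert est.n_features_in_ == G.shape[1]
        assert est.per_threshold_stats_ is not None
        assert est.statistic_ == pytest.approx(est.per_threshold_stats_["statistic"].max())

    def test_estimator_clone_and_reseed(self, small_dataset):
        from sklearn.base import clone
        G, y = small_dataset
        est = GwssTest(n_permutations=40, random_state=7)
        p1 = clone(est).fit(G, y).p_value_
        p2 = clone(est).fit(G, y).p_value_
        assert p1 == p2

    def test_unknown_method_rejected(self, small_dataset):
        G, y = small_dataset
        with pytest.raises(ValueError, match="unknown method"):
            GwssTest(method="SKAT").fit(G, y)

    def test_genotype_matrix_container(self, small_dataset):
        G, y = small_dataset
        gm = GenotypeMatrix(G, variant_ids=[f"rs{j}" for j in range(G.shape[1])])
        res = permutation_pvalue(gm, y, "DSS-t", n_permutations=30, seed=0)
        assert 0 < res.p_value <= 1

    def test_vt_method_refuses_fixed_theta(self):
        with pytest.raises(ValueError, match="variable threshold"):
            resolve_method("VDWSS-t", theta=0.01)

    def test_zero_permutations_rejected(self, small_dataset):
        G, y = small_dataset
        with pytest.raises(ValueError):
            permutation_pvalue(G, y, "WSS", n_permutations=0)


@given(st.integers(0, 2**31 - 1))
@settings(deadline=None, max_examples=15)
def test_property_engine_agrees_with_naive_on_random_instances(seed):
    """Derandomised property check of engine-vs-oracle agreement."""
    rng = np.random.default_rng(seed)
    G, y = random_instance(rng, n=10, k=3)
    for name in ("VDWSS-t", "DSS-t", "WSS"):
        m = METHODS[name]
        S, _, _ = gwss_statistic(G, y, name)
        assert S == pytest.approx(
            naive_statistic(G, y, m.weight, m.summary, m.variable_threshold),
            rel=1e-9)
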