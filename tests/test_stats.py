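"""Richness extrapolation, BCa intervals, phylogenetic signal D and the G-test."""
import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from conftest import random_trait_tree
from ervi import stats
from ervi.stats import (
    RichnessInput,
    TraitPhylogeny,
    bca_interval,
    d_statistic,
    estimate_total_votus,
    g_test,
    prevalence_summary,
)


def bca_oracle(boots, observed, jack, alpha=0.05):
    """Independently coded BCa endpoints (own quantile interpolation)."""
    boots = sorted(float(b) for b in boots)
    B = len(boots)
    less = sum(1 for b in boots if b < observed) + 0.5 * sum(1 for b in boots if b == observed)
    z0 = sps.norm.ppf(less / B)
    jbar = sum(jack) / len(jack)
    num = sum((jbar - j) ** 3 for j in jack)
    den = 6.0 * (sum((jbar - j) ** 2 for j in jack)) ** 1.5
    a = 0.0 if den == 0 else num / den

    def quantile(q):
        pos = q * (B - 1)
        lo = math.floor(pos)
        hi = math.ceil(pos)
        frac = pos - lo
        return boots[lo] * (1 - frac) + boots[hi] * frac

    out = []
    for z_alpha in (sps.norm.ppf(alpha / 2), sps.norm.ppf(1 - alpha / 2)):
        adj = z0 + (z0 + z_alpha) / (1 - a * (z0 + z_alpha))
        out.append(quantile(float(sps.norm.cdf(adj))))
    return out[0], out[1]


class TestBcaInterval:
    def test_exhaustive_enumeration_oracle(self):
        # all 5^5 resamples of an n=5 sample, statistic = mean
        data = [2.0, 3.5, 5.0, 9.0, 1.0]
        boots = [
            float(np.mean(r)) for r in itertools.product(data, repeat=5)
        ]
        observed = float(np.mean(data))
        jack = [float(np.mean(np.delete(data, i))) for i in range(5)]
        low, high, z0, a = bca_interval(boots, observed, jack)
        olow, ohigh = bca_oracle(boots, observed, jack)
        assert low == pytest.approx(olow, abs=1e-12)
        assert high == pytest.approx(ohigh, abs=1e-12)

    def test_collapses_to_percentile_when_symmetric(self):
        # symmetric bootstrap distribution with observed at its median and
        # symmetric jackknife: z0 = 0, a = 0 -> percentile interval
        boots = np.concatenate([np.linspace(-1, -0.01, 500), np.linspace(0.01, 1, 500)])
        jack = [-1.0, 0.0, 1.0]
        low, high, z0, a = bca_interval(boots, 0.0, jack)
        assert z0 == pytest.approx(0.0)
        assert a == pytest.approx(0.0)
        assert low == pytest.approx(float(np.quantile(boots, 0.025)))
        assert high == pytest.approx(float(np.quantile(boots, 0.975)))

    def test_constant_data_zero_width(self):
        low, high, z0, a = bca_interval([5.0] * 200, 5.0, [5.0, 5.0, 5.0])
        assert low == high == 5.0

    def test_observed_outside_range_raises(self):
        boots = list(np.linspace(0, 1, 200))
        with pytest.raises(ValueError):
            bca_interval(boots, 2.0, [0.1, 0.2, 0.3])

    def test_minimum_sizes_enforced(self):
        with pytest.raises(ValueError):
            bca_interval([1.0] * 50, 1.0, [1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            bca_interval(list(np.linspace(0, 1, 200)), 0.5, [0.5, 0.6])


class TestEstimateTotalVotus:
    def test_closed_form_rate_scaling(self):
        counts = {f"s{i}": c for i, c in enumerate([1] * 73 + [3] * 44 + [2] * 6 + [0] * 1881)}
        est = estimate_total_votus(RichnessInput(counts, seed=5))
        assert est.point == pytest.approx(217 / 2004 * 74140)

    def test_order_invariance_of_point(self):
        rng = np.random.default_rng(0)
        counts = {f"s{i}": int(c) for i, c in enumerate(rng.poisson(0.5, 100))}
        a = estimate_total_votus(RichnessInput(counts, reps=200, seed=1))
        shuffled = dict(sorted(counts.items(), key=lambda kv: kv[1]))
        b = estimate_total_votus(RichnessInput(shuffled, reps=200, seed=1))
        assert a.point == b.point

    def test_all_zero_counts(self):
        est = estimate_total_votus(RichnessInput({f"s{i}": 0 for i in range(10)}))
        assert est.point == 0.0 and est.ci_low == est.ci_high == 0.0 and est.flagged

    def test_constant_counts_zero_width(self):
        est = estimate_total_votus(RichnessInput({f"s{i}": 1 for i in range(10)}, n_total_species=100))
        assert est.point == est.ci_low == est.ci_high == 100.0

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(2)
        counts = {f"s{i}": int(c) for i, c in enumerate(rng.poisson(1.0, 50))}
        a = estimate_total_votus(RichnessInput(counts, reps=500, seed=9))
        b = estimate_total_votus(RichnessInput(counts, reps=500, seed=9))
        assert (a.ci_low, a.ci_high, a.z0, a.a) == (b.ci_low, b.ci_high, b.z0, b.a)


class TestDStatistic:
    def _states(self, tree, x):
        labels = [l.taxon.label for l in tree.leaf_node_iter()]
        return TraitPhylogeny(tree, dict(zip(labels, [int(v) for v in x])))

    def test_random_states_near_one(self):
        rng = np.random.default_rng(0)
        ds = []
        for rep in range(10):
            tree = random_trait_tree(100, rep)
            x = np.zeros(100, int)
            x[:30] = 1
            rng.shuffle(x)
            ds.append(d_statistic(self._states(tree, x), 200, 200, seed=rep).D)
        assert abs(float(np.mean(ds)) - 1.0) < 0.25

    def test_brownian_states_near_zero(self):
        ds = []
        for rep in range(10):
            tree = random_trait_tree(100, 100 + rep)
            labels = [l.taxon.label for l in tree.leaf_node_iter()]
            states = stats.brownian_threshold_states(tree, 30, seed=rep)
            x = np.array([states[t] for t in labels])
            ds.append(d_statistic(self._states(tree, x), 200, 200, seed=rep).D)
        assert abs(float(np.mean(ds))) < 0.25

    def test_monomorphic_raises(self):
        tree = random_trait_tree(60, 1)
        with pytest.raises(ValueError):
            d_statistic(self._states(tree, np.ones(60, int)), 50, 50, seed=0)

    def test_zero_branch_length_raises(self):
        tree = random_trait_tree(60, 2)
        next(tree.postorder_internal_node_iter()).edge.length = 0.0
        # re-inject a zero-length internal edge
        for nd in tree.postorder_node_iter():
            if nd.parent_node is not None and not nd.is_leaf():
                nd.edge.length = 0.0
                break
        x = np.zeros(60, int)
        x[:20] = 1
        with pytest.raises(ValueError):
            d_statistic(self._states(tree, x), 50, 50, seed=0)

    def test_seed_reproducibility(self):
        tree = random_trait_tree(80, 3)
        x = np.zeros(80, int)
        x[:25] = 1
        np.random.default_rng(0).shuffle(x)
        a = d_statistic(self._states(tree, x), 100, 100, seed=7)
        b = d_statistic(self._states(tree, x), 100, 100, seed=7)
        assert a.D == b.D and a.p_gt0 == b.p_gt0 and a.p_lt1 == b.p_lt1

    def test_permutation_p_value_validity(self):
        # under permuted (random) traits, p_lt1 should not be concentrated
        # near 0: spot-check super-uniformity at coarse resolution
        rng = np.random.default_rng(1)
        ps = []
        for rep in range(20):
            tree = random_trait_tree(60, 200 + rep)
            x = np.zeros(60, int)
            x[:20] = 1
            rng.shuffle(x)
            ps.append(d_statistic(self._states(tree, x), 100, 100, seed=rep).p_lt1)
        assert float(np.mean([p <= 0.1 for p in ps])) <= 0.3


class TestGTest:
    def test_identical_proportions_zero(self):
        g, df, p = g_test([[10, 10], [20, 20]])
        assert g == pytest.approx(0.0) and p == pytest.approx(1.0) and df == 1

    def test_matches_direct_formula(self):
        obs = np.array([[10, 20], [30, 40]], float)
        expected = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
        direct = 2 * float(np.sum(obs * np.log(obs / expected)))
        g, df, p = g_test(obs)
        assert g == pytest.approx(direct, abs=1e-10)
        assert p == pytest.approx(float(sps.chi2.sf(direct, 1)), abs=1e-12)

    def test_one_dimensional_table_raises(self):
        with pytest.raises(ValueError):
            g_test([[1, 2, 3]])

    def test_zero_margin_raises(self):
        with pytest.raises(ValueError):
            g_test([[0, 0], [3, 4]])

    def test_williams_correction_shrinks_g(self):
        g_plain, *_ = g_test([[10, 20], [30, 40]])
        g_corr, *_ = g_test([[10, 20], [30, 40]], williams=True)
        assert g_corr < g_plain


class TestPrevalence:
    @pytest.mark.parametrize(
        "hit,total,expected",
        [(123, 2004, 6.14), (50, 123, 40.65), (0, 10, 0.0)],
    )
    def test_published_proportions(self, hit, total, expected):
        res = prevalence_summary(hit, total)
        assert res.percent == pytest.approx(expected)
        assert res.fraction == pytest.approx(hit / total)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            prevalence_summary(1, 0)
        with pytest.raises(ValueError):
            prevalence_summary(5, 4)
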