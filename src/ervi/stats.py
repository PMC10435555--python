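"""Downstream statistics for ERVi survey data.

* richness extrapolation: the per-species vOTU rate in the surveyed species
  scaled to the number of described vertebrate species, with a 95%
  bias-corrected and accelerated (BCa) bootstrap interval;
* the Fritz & Purvis D statistic of phylogenetic signal for a binary trait,
  with permutation and Brownian-threshold nulls;
* the G-test of independence;
* prevalence summaries (percent of species invaded).

All resampling is driven by a numpy Generator and fully reproducible from a
seed.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import dendropy
import numpy as np
from scipy import stats as sps


# ---------------------------------------------------------------------------
# richness extrapolation
# ---------------------------------------------------------------------------

@dataclass
class RichnessInput:
    """Per-species vOTU counts for surveyed species (zeros included)."""

    per_species_votus: Mapping[str, int]
    n_total_species: int = 74140
    reps: int = 10000
    seed: int = 0

    @property
    def n_surveyed(self) -> int:
        return len(self.per_species_votus)


@dataclass
class BootstrapEstimate:
    point: float
    ci_low: float
    ci_high: float
    z0: float
    a: float
    reps: int
    seed: int
    flagged: bool = False


def estimate_total_votus(inp: RichnessInput) -> BootstrapEstimate:
    """Bootstrap the rate-scaled total vOTU richness.

    The statistic is ``mean(per-species counts) * n_total_species``; species
    are resampled with replacement and the 95% interval is BCa.
    """
    counts = np.asarray([inp.per_species_votus[k] for k in sorted(inp.per_species_votus)], float)
    n = counts.size
    if n < 2:
        raise ValueError("need at least two surveyed species")
    point = counts.mean() * inp.n_total_species
    if np.all(counts == counts[0]):
        # no resampling variance (includes the all-zero case)
        return BootstrapEstimate(point, point, point, 0.0, 0.0, inp.reps, inp.seed,
                                 flagged=bool(np.all(counts == 0)))
    rng = np.random.default_rng(inp.seed)
    idx = rng.integers(0, n, size=(inp.reps, n))
    boots = counts[idx].mean(axis=1) * inp.n_total_species
    jack = (counts.sum() - counts) / (n - 1) * inp.n_total_species
    low, high, z0, a = bca_interval(boots, point, jack)
    return BootstrapEstimate(point, low, high, z0, a, inp.reps, inp.seed,
                             flagged=not (low <= point <= high))


def bca_interval(
    bootstrap_stats: Sequence[float],
    observed: float,
    jackknife_stats: Sequence[float],
    alpha: float = 0.05,
) -> tuple[float, float, float, float]:
    """Bias-corrected and accelerated bootstrap percentile interval.

    ``z0 = Phi^-1(#{theta* < theta_hat} / B)`` with ties counted half;
    the acceleration ``a`` comes from the jackknife skewness; endpoints are
    empirical quantiles (linear interpolation) at the adjusted levels.
    """
    boots = np.asarray(bootstrap_stats, float)
    jack = np.asarray(jackknife_stats, float)
    if boots.size < 100:
        raise ValueError("need at least 100 bootstrap statistics")
    if jack.size < 3:
        raise ValueError("need at least 3 jackknife statistics")
    if np.all(boots == boots[0]):
        return float(boots[0]), float(boots[0]), 0.0, 0.0
    prop = (np.sum(boots < observed) + 0.5 * np.sum(boots == observed)) / boots.size
    if prop <= 0.0 or prop >= 1.0:
        raise ValueError("observed statistic outside the bootstrap distribution; z0 infinite")
    z0 = float(sps.norm.ppf(prop))
    centered = jack.mean() - jack
    denom = 6.0 * (np.sum(centered**2) ** 1.5)
    if denom == 0:
        warnings.warn("zero jackknife variance; acceleration set to 0")
        a = 0.0
    else:
        a = float(np.sum(centered**3) / denom)
    out = []
    for z_alpha in (sps.norm.ppf(alpha / 2), sps.norm.ppf(1 - alpha / 2)):
        adj = z0 + (z0 + z_alpha) / (1.0 - a * (z0 + z_alpha))
        level = sps.norm.cdf(adj)
        out.append(float(np.quantile(boots, level, method="linear")))
    return out[0], out[1], z0, a


# ---------------------------------------------------------------------------
# phylogenetic signal D
# ---------------------------------------------------------------------------

@dataclass
class TraitPhylogeny:
    """A rooted phylogeny with positive branch lengths and binary tip states."""

    tree: dendropy.Tree
    states: Mapping[str, int]


@dataclass
class DResult:
    D: float
    d_obs: float
    p_gt0: float  # fraction of Brownian-null d >= d_obs; small => departs from Brownian
    p_lt1: float  # fraction of permutation-null d <= d_obs; small => departs from random
    n_perm: int
    n_brownian: int
    seed: int
    mean_d_random: float = 0.0
    mean_d_brownian: float = 0.0


class _TreeArrays:
    """Array form of a tree: a linear operator from tip states to the sum of
    absolute nodal changes along edges, with nodal values reconstructed by
    the contrasts-style weighted-average pruning pass."""

    def __init__(self, tree: dendropy.Tree, tip_labels: list[str]):
        nodes = list(tree.postorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        n_nodes = len(nodes)
        tip_index = {label: i for i, label in enumerate(tip_labels)}
        n_tips = len(tip_labels)
        W = np.zeros((n_nodes, n_tips))
        adj_bl = np.zeros(n_nodes)  # pruning-adjusted branch length to parent
        self.edge_len = np.zeros(n_nodes)
        for nd in nodes:
            i = index[id(nd)]
            bl = nd.edge.length
            if nd.parent_node is not None:
                if bl is None or bl <= 0:
                    raise ValueError(
                        "zero or absent branch length; resolve the tree before computing D"
                    )
                self.edge_len[i] = bl
            if nd.is_leaf():
                label = nd.taxon.label
                W[i, tip_index[label]] = 1.0
                adj_bl[i] = self.edge_len[i]
            else:
                kids = nd.child_nodes()
                inv = np.array([1.0 / adj_bl[index[id(c)]] for c in kids])
                rows = np.stack([W[index[id(c)]] for c in kids])
                W[i] = (inv[:, None] * rows).sum(axis=0) / inv.sum()
                adj_bl[i] = self.edge_len[i] + 1.0 / inv.sum()
        # edge difference operator: rows = W[parent] - W[child]
        diffs = []
        for nd in nodes:
            if nd.parent_node is None:
                continue
            diffs.append(W[index[id(nd.parent_node)]] - W[index[id(nd)]])
        self.A = np.stack(diffs)
        self.nodes = nodes
        self.index = index
        self.n_tips = n_tips
        # node-array rows of the leaves, ordered to match tip_labels
        by_label = {nd.taxon.label: index[id(nd)] for nd in nodes if nd.is_leaf()}
        self.leaf_rows_in_label_order = np.array([by_label[t] for t in tip_labels])

    def d_sum(self, x: np.ndarray) -> np.ndarray:
        """Sum of |parent - child| nodal values; x is (n_tips,) or (n_tips, B)."""
        return np.abs(self.A @ x).sum(axis=0)


def _prepare(data: TraitPhylogeny) -> tuple[_TreeArrays, np.ndarray, list[str]]:
    tree = data.tree
    tip_labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    missing = [t for t in tip_labels if t not in data.states]
    if missing:
        raise ValueError(f"tips without states: {missing[:5]}")
    x = np.array([float(data.states[t]) for t in tip_labels])
    if set(np.unique(x)) - {0.0, 1.0}:
        raise ValueError("states must be binary 0/1")
    if x.min() == x.max():
        raise ValueError("monomorphic states: D is undefined")
    if x.size < 50:
        warnings.warn("fewer than 50 tips: D depends on prevalence and tree shape")
    arrays = _TreeArrays(tree, tip_labels)
    return arrays, x, tip_labels


def d_statistic(
    data: TraitPhylogeny, n_perm: int = 1000, n_brownian: int = 1000, seed: int = 0
) -> DResult:
    """Phylogenetic signal D for a binary trait.

    ``d_obs`` is the sum over edges of absolute changes in nodal values
    (weighted-average reconstruction, states treated as continuous);
    the permutation null shuffles tip states preserving prevalence and the
    Brownian null thresholds unit-rate Brownian tip values to the observed
    prevalence.  D scales d_obs so that 1 corresponds to the random
    expectation and 0 to the Brownian expectation.
    """
    arrays, x, tip_labels = _prepare(data)
    rng = np.random.default_rng(seed)
    d_obs = float(arrays.d_sum(x))
    # permutation null
    perm = np.tile(x, (n_perm, 1))
    perm = rng.permuted(perm, axis=1).T  # (n_tips, n_perm)
    d_rand = arrays.d_sum(perm)
    # Brownian-threshold null
    k = int(x.sum())
    tips = _brownian_tip_matrix(arrays, rng, n_brownian)
    order = np.argsort(-tips, axis=0)
    bro = np.zeros_like(tips)
    cols = np.arange(n_brownian)
    for r in range(k):
        bro[order[r], cols] = 1.0
    d_bro = arrays.d_sum(bro)
    mean_r, mean_b = float(d_rand.mean()), float(d_bro.mean())
    if mean_r == mean_b:
        raise ValueError("degenerate nulls: cannot scale D")
    D = (d_obs - mean_b) / (mean_r - mean_b)
    return DResult(
        D=float(D),
        d_obs=d_obs,
        p_gt0=float(np.mean(d_bro >= d_obs)),
        p_lt1=float(np.mean(d_rand <= d_obs)),
        n_perm=n_perm,
        n_brownian=n_brownian,
        seed=seed,
        mean_d_random=mean_r,
        mean_d_brownian=mean_b,
    )


def brownian_threshold_states(
    tree: dendropy.Tree, n_ones: int, seed: int = 0
) -> dict[str, int]:
    """Binary tip states from thresholded unit-rate Brownian motion.

    The ``n_ones`` tips with the largest simulated Brownian values get state
    1 — the D statistic's clumped (phylogenetically conserved) null model.
    """
    tip_labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    arrays = _TreeArrays(tree, tip_labels)
    tips = _brownian_tip_matrix(arrays, np.random.default_rng(seed), 1)[:, 0]
    threshold = np.sort(tips)[::-1][n_ones - 1]
    return {label: int(v >= threshold) for label, v in zip(tip_labels, tips)}


def _brownian_tip_matrix(arrays: _TreeArrays, rng: np.random.Generator, n_sims: int) -> np.ndarray:
    """Unit-rate Brownian tip values, (n_tips, n_sims), tips in label order."""
    n_nodes = len(arrays.nodes)
    z = rng.standard_normal((n_nodes, n_sims))
    vals = np.zeros((n_nodes, n_sims))
    for nd in reversed(arrays.nodes):  # root-to-tip
        i = arrays.index[id(nd)]
        if nd.parent_node is None:
            continue
        p = arrays.index[id(nd.parent_node)]
        vals[i] = vals[p] + np.sqrt(arrays.edge_len[i]) * z[i]
    return vals[arrays.leaf_rows_in_label_order]


# ---------------------------------------------------------------------------
# G-test and prevalence
# ---------------------------------------------------------------------------

def g_test(table, williams: bool = False) -> tuple[float, int, float]:
    """Log-likelihood-ratio (G) test of independence on an r x c table.

    ``G = 2 * sum O * ln(O/E)`` over nonzero cells; df = (r-1)(c-1);
    p from the upper chi-square tail.  The optional Williams correction
    divides G by the standard q factor.
    """
    obs = np.asarray(table, float)
    if obs.ndim != 2 or min(obs.shape) < 2:
        raise ValueError("G-test of independence needs an r x c table with r, c >= 2")
    if np.any(obs < 0):
        raise ValueError("counts must be non-negative")
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    if np.any(rows == 0) or np.any(cols == 0):
        raise ValueError("zero row or column margin")
    total = obs.sum()
    expected = np.outer(rows, cols) / total
    mask = obs > 0
    g = 2.0 * float(np.sum(obs[mask] * np.log(obs[mask] / expected[mask])))
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    if williams:
        q = 1.0 + (total * np.sum(1.0 / rows) - 1.0) * (total * np.sum(1.0 / cols) - 1.0) / (
            6.0 * total * df
        )
        g = g / q
    p = float(sps.chi2.sf(g, df))
    return g, df, p


@dataclass(frozen=True)
class Prevalence:
    n_hit: int
    n_total: int
    percent: float  # rounded to two decimals
    fraction: float


def prevalence_summary(n_hit: int, n_total: int) -> Prevalence:
    """Percent of surveyed species with the feature, to two decimals."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not (0 <= n_hit <= n_total):
        raise ValueError("n_hit must lie in [0, n_total]")
    frac = n_hit / n_total
    return Prevalence(n_hit=n_hit, n_total=n_total, percent=round(100.0 * frac, 2), fraction=frac)


__all__ = [
    "RichnessInput",
    "BootstrapEstimate",
    "estimate_total_votus",
    "bca_interval",
    "TraitPhylogeny",
    "DResult",
    "d_statistic",
    "g_test",
    "Prevalence",
    "prevalence_summary",
]
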