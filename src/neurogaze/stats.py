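"""Permutation inference for two-group scalp studies.

Implements the study's inferential toolkit: bin-/band-wise permutation ANOVA
with Benjamini–Hochberg FDR across the band family, two-sample and
Spearman-correlation cluster-based permutation tests on scalp maps with
max-cluster-size correction, permutation t-tests, and Spearman follow-up
correlations with Fisher confidence intervals.

All permutation p-values use the add-one estimator
``p = (1 + #{T_perm >= T_obs}) / (n_perm + 1)`` and are deterministic for a
fixed seed.  Face channels are excluded from scalp-level tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats
from statsmodels.stats.multitest import multipletests

from .montage import Montage

__all__ = [
    "PermTestResult", "ClusterResult", "CorrelationResult",
    "perm_anova_global", "perm_ttest", "fdr_bh", "spearman",
    "cluster_perm_ttest", "cluster_perm_correlation",
]


@dataclass(frozen=True)
class PermTestResult:
    statistic: float
    p_perm: float
    n_perm: int
    p_fdr: float = None


@dataclass(frozen=True)
class ClusterResult:
    """Suprathreshold channel clusters with max-cluster-size permutation p's."""
    clusters: tuple            # tuples of channel labels
    cluster_sizes: tuple
    signs: tuple               # '+' or '-'
    cluster_p: tuple
    cluster_alpha: float
    alpha: float

    @property
    def significant(self) -> tuple:
        return tuple(i for i, p in enumerate(self.cluster_p) if p < self.alpha)


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    ci95: tuple
    n: int


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _check_groups(groups) -> np.ndarray:
    groups = np.asarray(groups)
    labels, counts = np.unique(groups, return_counts=True)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    if counts.min() < 2:
        raise ValueError("every group needs n >= 2")
    return groups


def _f_oneway(values: np.ndarray, group_codes: np.ndarray, n_groups: int) -> float:
    n = len(values)
    grand = values.mean()
    ss_b = 0.0
    ss_w = 0.0
    for g in range(n_groups):
        v = values[group_codes == g]
        ss_b += len(v) * (v.mean() - grand) ** 2
        ss_w += ((v - v.mean()) ** 2).sum()
    df_b, df_w = n_groups - 1, n - n_groups
    return (ss_b / df_b) / (ss_w / df_w)


def perm_anova_global(values, groups, n_perm: int = 1000, seed=0) -> PermTestResult:
    """One-way ANOVA F with a label-permutation null distribution."""
    values = np.asarray(values, dtype=float)
    groups = _check_groups(groups)
    _, codes = np.unique(groups, return_inverse=True)
    k = codes.max() + 1
    f_obs = _f_oneway(values, codes, k)
    rng = _rng(seed)
    count = 0
    for _ in range(n_perm):
        count += _f_oneway(values, rng.permutation(codes), k) >= f_obs
    p = (1 + count) / (n_perm + 1)
    return PermTestResult(statistic=float(f_obs), p_perm=float(p), n_perm=n_perm)


def _pooled_t(x: np.ndarray, y: np.ndarray) -> float:
    nx, ny = len(x), len(y)
    sp2 = (((x - x.mean()) ** 2).sum() + ((y - y.mean()) ** 2).sum()) / (nx + ny - 2)
    return (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / nx + 1 / ny))


def perm_ttest(values, groups, n_perm: int = 1000, seed=0) -> PermTestResult:
    """Two-sample pooled-variance t with a two-tailed permutation p-value."""
    values = np.asarray(values, dtype=float)
    groups = _check_groups(groups)
    labels = np.unique(groups)
    if len(labels) != 2:
        raise ValueError("perm_ttest needs exactly two groups")
    mask = groups == labels[0]
    t_obs = _pooled_t(values[mask], values[~mask])
    rng = _rng(seed)
    count = 0
    for _ in range(n_perm):
        pm = rng.permutation(mask)
        count += abs(_pooled_t(values[pm], values[~pm])) >= abs(t_obs)
    p = (1 + count) / (n_perm + 1)
    return PermTestResult(statistic=float(t_obs), p_perm=float(p), n_perm=n_perm)


def fdr_bh(pvals, q: float = 0.05):
    """Benjamini–Hochberg step-up adjustment.

    Returns ``(adjusted_pvals, reject_mask)`` at level ``q``.
    """
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        raise ValueError("empty p-value family")
    reject, p_adj, *_ = multipletests(pvals, alpha=q, method="fdr_bh")
    return p_adj, reject


def spearman(x, y) -> CorrelationResult:
    """Spearman rank correlation with t-approximation p and Fisher 95% CI."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 4:
        raise ValueError("spearman needs n >= 4")
    r, p = sstats.spearmanr(x, y)
    z = np.arctanh(np.clip(r, -0.999999, 0.999999))
    se = 1.0 / np.sqrt(n - 3)
    ci = (float(np.tanh(z - 1.959964 * se)), float(np.tanh(z + 1.959964 * se)))
    return CorrelationResult(r=float(r), p=float(p), ci95=ci, n=n)


# ---------------------------------------------------------------------------
# cluster-based permutation machinery


def _components(mask: np.ndarray, neighbor_lists) -> list:
    """Connected components (index lists) of the suprathreshold channel set."""
    active = set(np.flatnonzero(mask))
    comps = []
    while active:
        seed_node = active.pop()
        comp = [seed_node]
        frontier = [seed_node]
        while frontier:
            node = frontier.pop()
            for nb in neighbor_lists[node]:
                if nb in active:
                    active.discard(nb)
                    comp.append(nb)
                    frontier.append(nb)
        comps.append(sorted(comp))
    return comps


def _max_comp_size(mask: np.ndarray, neighbor_lists) -> int:
    k = int(mask.sum())
    if k <= 1:
        return k
    return max(len(c) for c in _components(mask, neighbor_lists))


def _scalp_subgraph(montage: Montage):
    """Indices of non-face channels and neighbour lists re-indexed to them."""
    keep = np.flatnonzero(montage.scalp_mask)
    pos_of = {int(ch): i for i, ch in enumerate(keep)}
    nl = []
    for ch in keep:
        nl.append([pos_of[int(nb)] for nb in np.flatnonzero(montage.adjacency[ch])
                   if int(nb) in pos_of])
    return keep, nl


def _batch_pooled_t(x: np.ndarray, member: np.ndarray) -> np.ndarray:
    """Pooled-variance t per (permutation, channel).

    x: subjects × channels; member: permutations × subjects (bool, group 1).
    """
    n = x.shape[0]
    n1 = member.sum(axis=1, keepdims=True).astype(float)
    n2 = n - n1
    s = x.sum(axis=0)
    ss = (x ** 2).sum(axis=0)
    s1 = member @ x                       # perms × channels
    ss1 = member @ (x ** 2)
    m1 = s1 / n1
    m2 = (s - s1) / n2
    var1 = ss1 - n1 * m1 ** 2
    var2 = (ss - ss1) - n2 * m2 ** 2
    sp2 = (var1 + var2) / (n - 2)
    denom = np.sqrt(sp2 * (1 / n1 + 1 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / denom
    return np.nan_to_num(t)


def _cluster_test(stat_obs: np.ndarray, stat_perm: np.ndarray, thresh: float,
                  neighbor_lists, labels, cluster_alpha: float, alpha: float,
                  n_perm: int) -> ClusterResult:
    """Shared clustering + max-size null evaluation.

    ``stat_obs``: per-channel statistic; ``stat_perm``: permutations × channels.
    """
    null_max = np.zeros(stat_perm.shape[0], dtype=int)
    pos = stat_perm > thresh
    neg = stat_perm < -thresh
    any_hit = pos.any(axis=1) | neg.any(axis=1)
    for pi in np.flatnonzero(any_hit):
        null_max[pi] = max(_max_comp_size(pos[pi], neighbor_lists),
                           _max_comp_size(neg[pi], neighbor_lists))

    clusters, sizes, signs, pvals = [], [], [], []
    for sign, mask in (("+", stat_obs > thresh), ("-", stat_obs < -thresh)):
        for comp in _components(mask, neighbor_lists):
            size = len(comp)
            p = (1 + int((null_max >= size).sum())) / (n_perm + 1)
            clusters.append(tuple(labels[c] for c in comp))
            sizes.append(size)
            signs.append(sign)
            pvals.append(float(p))
    return ClusterResult(clusters=tuple(clusters), cluster_sizes=tuple(sizes),
                         signs=tuple(signs), cluster_p=tuple(pvals),
                         cluster_alpha=cluster_alpha, alpha=alpha)


def cluster_perm_ttest(maps, groups, montage: Montage, cluster_alpha: float = 0.01,
                       alpha: float = 0.05, n_perm: int = 1000, seed=0) -> ClusterResult:
    """Two-group cluster-based permutation test on scalp maps.

    Per-channel two-sample t-values are thresholded at the two-tailed
    ``cluster_alpha`` critical value; suprathreshold channels form clusters
    through the montage neighbour graph (face channels excluded), split by
    sign.  Each observed cluster's size is compared against the permutation
    null of the maximum cluster size over the map.
    """
    maps = np.asarray(maps, dtype=float)
    groups = _check_groups(groups)
    if maps.shape[0] != len(groups):
        raise ValueError("maps and groups disagree on subject count")
    if maps.shape[1] != montage.n_channels:
        raise ValueError("maps and montage disagree on channel count")
    labels = np.unique(groups)
    if len(labels) != 2:
        raise ValueError("cluster_perm_ttest needs exactly two groups")

    keep, nl = _scalp_subgraph(montage)
    x = maps[:, keep]
    kept_labels = [montage.labels[i] for i in keep]
    n = x.shape[0]
    n1 = int((groups == labels[0]).sum())
    df = n - 2
    thresh = sstats.t.ppf(1 - cluster_alpha / 2, df)

    g1 = groups == labels[0]
    t_obs = _batch_pooled_t(x, g1[None, :])[0]

    rng = _rng(seed)
    member = np.zeros((n_perm, n), dtype=bool)
    for pi in range(n_perm):
        member[pi, rng.choice(n, size=n1, replace=False)] = True
    t_perm = _batch_pooled_t(x, member)
    return _cluster_test(t_obs, t_perm, thresh, nl, kept_labels,
                         cluster_alpha, alpha, n_perm)


def _rank(a: np.ndarray, axis: int = -1) -> np.ndarray:
    return sstats.rankdata(a, axis=axis)


def cluster_perm_correlation(maps, covariate, montage: Montage,
                             cluster_alpha: float = 0.01, alpha: float = 0.05,
                             n_perm: int = 1000, seed=0) -> ClusterResult:
    """Correlation variant: per-channel Spearman r against a subject covariate.

    The forming threshold converts ``cluster_alpha`` to a critical |r| via
    the t approximation for the given n; the null permutes the covariate
    across subjects and records the maximum cluster size.
    """
    maps = np.asarray(maps, dtype=float)
    cov = np.asarray(covariate, dtype=float)
    if np.ptp(cov) == 0:
        raise ValueError("covariate is constant")
    if maps.shape[0] != len(cov):
        raise ValueError("maps and covariate disagree on subject count")
    n = maps.shape[0]

    keep, nl = _scalp_subgraph(montage)
    x = maps[:, keep]
    kept_labels = [montage.labels[i] for i in keep]

    t_crit = sstats.t.ppf(1 - cluster_alpha / 2, n - 2)
    r_crit = t_crit / np.sqrt(n - 2 + t_crit ** 2)

    rx = _rank(x, axis=0)
    rx = (rx - rx.mean(axis=0)) / rx.std(axis=0)
    rc = _rank(cov)
    rc = (rc - rc.mean()) / rc.std()
    r_obs = rc @ rx / n

    rng = _rng(seed)
    perm = np.stack([rng.permutation(rc) for _ in range(n_perm)])
    r_perm = perm @ rx / n
    return _cluster_test(r_obs, r_perm, r_crit, nl, kept_labels,
                         cluster_alpha, alpha, n_perm)
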