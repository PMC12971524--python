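"""Set-to-set network distances, degree-controlled proximity tests, and the
per-gene proximity features.

The central feature is the *proximity fraction*: for a gene g and a gene set
S, the share of S's network-resident members (excluding g itself) that lie
within hop distance d of g. With the nine-set collection this yields nine
features per gene in [0, 1]; d defaults to 2, the median pairwise distance
between random genes in a STRING-scale network.

Whether a gene set X sits closer to a set Y than chance allows is tested
against a degree-matched background: a control set X' with (near-)identical
degrees is drawn, the two cross-set distance distributions are compared with
a one-sided Wilcoxon rank-sum test (X stochastically closer), and the effect
is summarized as log2(mean dist(X,Y) / mean dist(X',Y)) — negative when X is
more proximal.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .netgraph import DEFAULT_DISTANCE_THRESHOLD, sample_degree_matched, \
    shortest_distances

logger = logging.getLogger(__name__)


class ProximityTestError(RuntimeError):
    """Raised when a proximity test cannot be carried out."""


@dataclass
class FeatureConfig:
    """Distance threshold for the proximity features (inclusive, hops)."""

    distance_threshold: int = DEFAULT_DISTANCE_THRESHOLD

    def __post_init__(self):
        if self.distance_threshold < 1:
            raise ValueError("distance_threshold must be >= 1")


@dataclass
class ProximityRecord:
    set_x: str
    set_y: str
    n_pairs_actual: int
    n_pairs_background: int
    rank_sum_p: float
    log_fc_means: float
    n_infinite_dropped: int


def _resident(genes, graph, label: str) -> set:
    present = set(genes) & set(graph.nodes)
    dropped = len(set(genes)) - len(present)
    if dropped:
        logger.info("%s: %d member(s) not in network dropped", label, dropped)
    return present


def cross_set_distances(graph, x, y, with_counts: bool = False):
    """Finite hop distances for all ordered pairs (a in x, b in y, a != b).

    Pairs with no path are counted (returned with ``with_counts=True``) but
    not included in the distance list.
    """
    xg = _resident(x, graph, "cross_set_distances/x")
    yg = _resident(y, graph, "cross_set_distances/y")
    if not xg or not yg:
        raise ValueError("a gene set is empty after intersecting with the network")
    distances = []
    n_infinite = 0
    for a in sorted(xg):
        dist = shortest_distances(graph, a)
        for b in sorted(yg):
            if b == a:
                continue
            if b in dist:
                distances.append(dist[b])
            else:
                n_infinite += 1
    if with_counts:
        return distances, n_infinite
    return distances


def rank_sum_less(a, b) -> float:
    """One-sided Wilcoxon rank-sum p for "a stochastically smaller than b".

    For small samples (both <= 8) the p-value is computed by exact
    enumeration of all rank assignments of the pooled multiset, with the
    mid-p convention for ties (P[W < w] + 0.5 P[W = w]); this makes a fully
    tied comparison come out at 0.5 rather than 1. Larger samples use the
    tie-corrected normal approximation without continuity correction, which
    shares that convention at the null center.
    """
    a = list(a)
    b = list(b)
    if len(a) < 2 or len(b) < 2:
        raise ProximityTestError("need at least 2 finite distances per side")
    pooled = a + b
    if len(set(pooled)) == 1:
        return 0.5
    if len(a) <= 8 and len(b) <= 8:
        ranks = stats.rankdata(pooled)
        n = len(a)
        observed = ranks[:n].sum()
        below = equal = total = 0
        for idx in combinations(range(len(pooled)), n):
            w = ranks[list(idx)].sum()
            if w < observed - 1e-9:
                below += 1
            elif abs(w - observed) <= 1e-9:
                equal += 1
            total += 1
        return (below + 0.5 * equal) / total
    res = stats.mannwhitneyu(a, b, alternative="less", method="asymptotic",
                             use_continuity=False)
    return float(res.pvalue)


def proximity_test(graph, x, y, set_x: str = "X", set_y: str = "Y",
                   max_tolerance: int | None = 1, seed: int = 0,
                   n_repeats: int = 1) -> ProximityRecord:
    """Test whether set x is closer to set y than a degree-matched background.

    A background set x' is drawn degree-matched to x (excluding x itself),
    the distance distributions dist(x, y) and dist(x', y) are compared with
    the one-sided rank-sum test, and the effect size is
    log2(mean dist(x,y) / mean dist(x',y)). With ``n_repeats`` > 1 the
    background is redrawn and p and the log fold-change are averaged over
    draws.
    """
    xg = _resident(x, graph, "proximity_test/x")
    actual, n_inf_actual = cross_set_distances(graph, xg, y, with_counts=True)
    if len(actual) < 2:
        raise ProximityTestError("fewer than 2 finite actual distances")
    ps, lfcs, n_bg, n_inf_bg = [], [], 0, 0
    for r in range(n_repeats):
        background = sample_degree_matched(
            graph, sorted(xg), exclude=xg, max_tolerance=max_tolerance,
            seed=seed + r)
        bg_dist, n_inf = cross_set_distances(graph, background, y, with_counts=True)
        if len(bg_dist) < 2:
            raise ProximityTestError("fewer than 2 finite background distances")
        ps.append(rank_sum_less(actual, bg_dist))
        lfcs.append(math.log2(np.mean(actual) / np.mean(bg_dist)))
        n_bg += len(bg_dist)
        n_inf_bg += n_inf
    return ProximityRecord(
        set_x=set_x, set_y=set_y, n_pairs_actual=len(actual),
        n_pairs_background=n_bg, rank_sum_p=float(np.mean(ps)),
        log_fc_means=float(np.mean(lfcs)),
        n_infinite_dropped=n_inf_actual + n_inf_bg)


def proximity_fraction(graph, gene, members, config: FeatureConfig | None = None) -> float:
    """Fraction of a set's network-resident members within d hops of ``gene``.

    The gene itself is excluded from the set (its own membership would leak
    a zero distance into its feature). Unreachable members count only in the
    denominator. Returns NaN (logged) when the set has no network-resident
    member besides the gene.
    """
    config = config or FeatureConfig()
    if gene not in graph:
        raise KeyError(f"gene {gene!r} not in graph")
    resident = (set(members) & set(graph.nodes)) - {gene}
    if not resident:
        logger.warning("proximity_fraction: no network-resident members for %r", gene)
        return math.nan
    dist = shortest_distances(graph, gene, cutoff=config.distance_threshold)
    within = sum(1 for m in resident if m in dist)
    return within / len(resident)


def build_feature_matrix(graph, collection, genes,
                         config: FeatureConfig | None = None) -> pd.DataFrame:
    """Genes x gene-sets matrix of proximity fractions.

    Rows follow the input gene order and columns the collection order. One
    depth-truncated breadth-first traversal per gene is shared across all
    columns. Entries without a network-resident denominator are NaN (count
    logged); downstream model code imputes them to zero.
    """
    config = config or FeatureConfig()
    genes = list(genes)
    node_set = set(graph.nodes)
    missing = [g for g in genes if g not in node_set]
    if missing:
        raise KeyError(f"gene(s) not in graph: {missing[:5]}")
    resident_members = [set(s.members) & node_set for s in collection]
    matrix = np.empty((len(genes), len(resident_members)))
    n_missing = 0
    for i, gene in enumerate(genes):
        reached = shortest_distances(graph, gene,
                                     cutoff=config.distance_threshold)
        reached_set = set(reached)
        for j, members in enumerate(resident_members):
            denom_set = members - {gene}
            if not denom_set:
                matrix[i, j] = math.nan
                n_missing += 1
                continue
            matrix[i, j] = len(denom_set & reached_set) / len(denom_set)
    if n_missing:
        logger.warning("build_feature_matrix: %d entries without resident members (NaN)",
                       n_missing)
    return pd.DataFrame(matrix, index=pd.Index(genes, name="gene"),
                        columns=list(collection.names))


def write_feature_matrix(features: pd.DataFrame, path, header_comment=None) -> None:
    with open(path, "w") as handle:
        if header_comment:
            handle.write(f"# {header_comment}\n")
        features.to_csv(handle, sep="\t")


def read_feature_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col="gene")
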