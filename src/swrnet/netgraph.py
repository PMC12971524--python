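"""Interaction-network I/O and graph primitives.

The pipeline operates on an undirected simple graph of gene symbols whose
edges carry an integer confidence score in [0, 1000] (the STRING
``combined_score`` convention; "medium confidence" is conventionally >= 400).
Shortest paths are computed on unit-length edges, so hop distances are
integers and breadth-first search is exact.

This module also provides the degree-matched sampling primitive used to draw
null gene sets: for each target gene a control gene of (near-)identical
degree is drawn without replacement, widening the allowed degree window by
one unit at a time only when the current pool is exhausted.
"""

from __future__ import annotations

import gzip
import logging
import random
from dataclasses import dataclass, field

import networkx as nx

logger = logging.getLogger(__name__)

#: Conventional STRING "medium confidence" cutoff on the combined score.
DEFAULT_MIN_CONFIDENCE = 400

#: Default hop-distance threshold for proximity features: the median
#: pairwise shortest-path distance between two random genes in a
#: STRING-scale network (see :func:`estimate_median_pair_distance`).
DEFAULT_DISTANCE_THRESHOLD = 2


class NetworkParseError(ValueError):
    """Raised when an edge-list line cannot be parsed."""


class DegreeMatchError(RuntimeError):
    """Raised when no degree-matched control exists within tolerance."""


class MedianEstimationError(RuntimeError):
    """Raised when no connected node pair is found within the retry bound."""


def _open_text(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def _looks_like_header(fields) -> bool:
    try:
        int(float(fields[2]))
    except (ValueError, IndexError):
        return True
    return False


def read_network(path, min_confidence: int = DEFAULT_MIN_CONFIDENCE,
                 universe=None) -> nx.Graph:
    """Read a whitespace/tab-delimited edge list into a gene graph.

    Parameters
    ----------
    path
        TSV with >= 3 columns: node, node, integer confidence in [0, 1000].
        A header line is auto-detected (non-numeric third field). Gzip input
        is handled transparently.
    min_confidence
        Edges with confidence below this are dropped (default 400, the
        conventional "medium confidence" cutoff).
    universe
        Optional node universe: a path to a one-gene-per-line file or an
        iterable of gene identifiers. When given, universe genes are kept in
        the graph even if all their edges were filtered; without it, isolated
        nodes are dropped.

    Notes
    -----
    Self-loop lines are dropped (count logged). Duplicate or reversed edge
    lines collapse to a single edge keeping the maximum confidence.
    """
    graph = nx.Graph()
    n_self_loops = 0
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            fields = line.split()
            if not fields:
                continue
            if lineno == 1 and _looks_like_header(fields):
                continue
            if len(fields) < 3:
                raise NetworkParseError(
                    f"{path}: line {lineno}: expected >= 3 columns, got {len(fields)}")
            a, b = fields[0], fields[1]
            try:
                conf = int(fields[2])
            except ValueError as exc:
                raise NetworkParseError(
                    f"{path}: line {lineno}: non-integer confidence "
                    f"{fields[2]!r}") from exc
            if a == b:
                n_self_loops += 1
                continue
            if conf < min_confidence:
                continue
            if graph.has_edge(a, b):
                if conf > graph[a][b]["confidence"]:
                    graph[a][b]["confidence"] = conf
            else:
                graph.add_edge(a, b, confidence=conf)
    if n_self_loops:
        logger.warning("read_network: dropped %d self-loop line(s)", n_self_loops)
    if universe is not None:
        if isinstance(universe, (str, bytes)) or hasattr(universe, "__fspath__"):
            with _open_text(universe) as handle:
                genes = [ln.strip() for ln in handle if ln.strip()]
        else:
            genes = list(universe)
        graph.add_nodes_from(genes)
    return graph


def write_network(graph: nx.Graph, path) -> None:
    """Write a graph back to edge-list TSV (deterministic edge order)."""
    with open(path, "w") as handle:
        handle.write("protein1\tprotein2\tcombined_score\n")
        for a, b in sorted(tuple(sorted(e)) for e in graph.edges):
            handle.write(f"{a}\t{b}\t{graph[a][b]['confidence']}\n")


def shortest_distances(graph: nx.Graph, source, cutoff=None) -> dict:
    """Hop distances from ``source`` to every reachable node.

    Edges count as unit length regardless of confidence, so this is
    breadth-first search (identical to unit-weight Dijkstra). Unreachable
    nodes are absent from the mapping; with ``cutoff`` the mapping is
    restricted to distances <= cutoff.
    """
    if source not in graph:
        raise KeyError(f"source gene {source!r} not in graph")
    return dict(nx.single_source_shortest_path_length(graph, source, cutoff=cutoff))


def _lower_median(values) -> int:
    values = sorted(values)
    return values[(len(values) - 1) // 2]


def estimate_median_pair_distance(graph: nx.Graph, n_pairs: int = 10_000,
                                  seed: int = 0) -> int:
    """Median shortest-path distance over random connected node pairs.

    If the graph has at most ``n_pairs`` distinct pairs the median is exact
    over all connected pairs (seed-independent); otherwise ``n_pairs``
    distinct pairs are sampled uniformly, disconnected pairs being discarded
    and resampled up to a retry bound. The median of an even-length sample is
    the lower middle value, so the result is always an integer hop count.
    """
    nodes = sorted(graph.nodes)
    n = len(nodes)
    if n < 2:
        raise ValueError("graph must have at least 2 nodes")
    total_pairs = n * (n - 1) // 2
    if total_pairs <= n_pairs:
        distances = []
        for i, a in enumerate(nodes):
            dist = shortest_distances(graph, a)
            for b in nodes[i + 1:]:
                if b in dist:
                    distances.append(dist[b])
        if not distances:
            raise MedianEstimationError("graph has no connected node pair")
        return _lower_median(distances)
    rng = random.Random(seed)
    distances = []
    attempts = 0
    max_attempts = 20 * n_pairs
    while len(distances) < n_pairs:
        if attempts >= max_attempts:
            if not distances:
                raise MedianEstimationError(
                    f"no connected pair found in {max_attempts} attempts")
            break
        attempts += 1
        a, b = rng.sample(nodes, 2)
        try:
            distances.append(nx.shortest_path_length(graph, a, b))
        except nx.NetworkXNoPath:
            continue
    return _lower_median(distances)


@dataclass
class DegreeIndex:
    """Degree lookup plus a degree -> genes bucket index.

    Bucket member lists are sorted so that seeded sampling is reproducible
    regardless of graph construction order.
    """

    degree: dict = field(default_factory=dict)
    buckets: dict = field(default_factory=dict)

    @classmethod
    def from_graph(cls, graph: nx.Graph) -> "DegreeIndex":
        degree = dict(graph.degree())
        buckets: dict = {}
        for gene in sorted(degree):
            buckets.setdefault(degree[gene], []).append(gene)
        return cls(degree=degree, buckets=buckets)

    def pool(self, target_degree: int, tolerance: int, used) -> list:
        """Genes with degree within ``tolerance`` of ``target_degree``, not in ``used``."""
        out = []
        for d in range(max(0, target_degree - tolerance), target_degree + tolerance + 1):
            for gene in self.buckets.get(d, ()):
                if gene not in used:
                    out.append(gene)
        return out


def sample_degree_matched(graph, targets, exclude=(), max_tolerance=1,
                          seed: int = 0, index: DegreeIndex | None = None) -> list:
    """Draw one degree-matched control gene per target, without replacement.

    For each target the pool is first restricted to genes of exactly equal
    degree; the degree window widens by +-1 per step, but only when the
    current pool is empty, up to ``max_tolerance`` (``None`` means unbounded
    widening). Controls are never drawn from ``targets``, ``exclude`` or
    earlier draws. The returned list parallels the target order.

    Raises
    ------
    DegreeMatchError
        If some target has no admissible control within ``max_tolerance``;
        the message names the gene and its degree.
    """
    if index is None:
        index = DegreeIndex.from_graph(graph)
    targets = list(targets)
    for t in targets:
        if t not in index.degree:
            raise KeyError(f"target gene {t!r} not in graph")
    rng = random.Random(seed)
    used = set(exclude) | set(targets)
    if max_tolerance is None:
        max_tolerance = max(index.buckets) if index.buckets else 0
    matched = []
    for target in targets:
        deg = index.degree[target]
        choice = None
        for tol in range(max_tolerance + 1):
            pool = index.pool(deg, tol, used)
            if pool:
                choice = rng.choice(pool)
                break
        if choice is None:
            raise DegreeMatchError(
                f"no degree-matched control for {target!r} (degree {deg}) "
                f"within tolerance {max_tolerance}")
        used.add(choice)
        matched.append(choice)
    return matched
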