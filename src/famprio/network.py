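"""Offline protein-interaction network stage.

Reproduces, without any web service, the analysis a STRING user performs on
a prioritized protein list: combine per-channel interaction evidence
(experiments, databases, co-expression) into one confidence score by the
prior-corrected noisy-OR rule, keep edges at combined score >= 0.400, test
the query set for protein-protein interaction (PPI) enrichment against a
null of random node sets, partition the induced subgraph with Markov
clustering (MCL), and annotate clusters by hypergeometric gene-set
enrichment with Benjamini-Hochberg FDR control.

The PPI enrichment null is deliberately NOT a re-implementation of
STRING's proprietary calibration: two documented nulls are shipped — a
seeded permutation test (default) and a degree-based Poisson approximation
— so that p-values are reproducible and testable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

STRING_PRIOR = 0.041  # STRING's prior probability of a random pair interacting


# ---------------------------------------------------------------------------
# score combination and the network container
# ---------------------------------------------------------------------------

def combine_channel_scores(channels: Iterable[float], prior: float = 0.0) -> float:
    """Combine per-channel confidences by prior-corrected noisy-OR.

    Each channel score s is first corrected for the prior p:
    s' = max(0, (s - p) / (1 - p)); the corrected scores are combined as
    1 - prod(1 - s'), and the result is re-benchmarked against the prior
    (combined * (1 - p) + p) whenever any evidence survives correction.
    With prior 0 this reduces to the plain noisy-OR.
    """
    scores = [float(s) for s in channels]
    if not scores:
        raise ValueError("at least one channel score is required")
    if not 0.0 <= prior < 1.0:
        raise ValueError(f"prior must be in [0, 1), got {prior}")
    for s in scores:
        if not 0.0 <= s <= 1.0:
            raise ValueError(f"channel score {s} outside [0, 1]")
    corrected = [max(0.0, (s - prior) / (1.0 - prior)) for s in scores]
    combined = 1.0 - float(np.prod([1.0 - c for c in corrected]))
    if combined > 0.0:
        combined = combined * (1.0 - prior) + prior
    return combined


@dataclass
class Network:
    """Undirected weighted protein graph (no self-edges, no duplicates)."""

    graph: nx.Graph

    @classmethod
    def from_edge_table(
        cls,
        edges: pd.DataFrame,
        prior: float = STRING_PRIOR,
        channel_columns: Optional[Sequence[str]] = None,
    ) -> "Network":
        """Build a network from a merged edge table (see read_edge_list).

        A ``combined_score`` column is used verbatim when present;
        otherwise the combined score is computed from the channel columns.
        """
        g = nx.Graph()
        channels = channel_columns or [
            c for c in edges.columns if c not in ("protein_a", "protein_b", "combined_score")
        ]
        for row in edges.itertuples(index=False):
            d = row._asdict()
            a, b = d["protein_a"], d["protein_b"]
            if a == b:
                continue
            chan = {c: float(d[c]) for c in channels if not pd.isna(d[c])}
            if "combined_score" in d and not pd.isna(d.get("combined_score")):
                combined = float(d["combined_score"])
            else:
                combined = combine_channel_scores(chan.values(), prior=prior)
            g.add_edge(a, b, combined_score=combined, **chan)
        return cls(graph=g)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def m(self) -> int:
        return self.graph.number_of_edges()

    def degree(self, node: str) -> int:
        return self.graph.degree[node]

    def induced_edge_count(self, nodes: Iterable[str]) -> int:
        return self.graph.subgraph(set(nodes)).number_of_edges()


def filter_edges(network: Network, min_score: float = 0.400) -> Network:
    """Keep edges with combined score >= min_score; nodes are retained
    even if they become isolated ("minimum required" reads inclusive)."""
    g = nx.Graph()
    g.add_nodes_from(network.graph.nodes(data=True))
    for a, b, data in network.graph.edges(data=True):
        if data.get("combined_score", 0.0) >= min_score:
            g.add_edge(a, b, **data)
    return Network(graph=g)


# ---------------------------------------------------------------------------
# PPI enrichment
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentResult:
    observed_edges: int
    expected_edges: float
    p_value: float
    method: str
    n_query: int = 0
    terms: Optional[pd.DataFrame] = None


def ppi_enrichment(
    network: Network,
    query: Iterable[str],
    method: str = "permutation",
    reps: int = 1000,
    seed: int = 0,
) -> EnrichmentResult:
    """Is the query set more internally connected than a random set?

    permutation (default): draw ``reps`` uniform node sets of the query's
    size and report p = (1 + #{draws with >= observed edges}) / (reps + 1);
    exact exchangeability makes this valid without any degree model.

    degree_poisson: expected edges lambda = sum over query pairs of
    min(k_i * k_j / (2m), 1) (Chung-Lu pair probabilities) and an
    upper-tail Poisson p-value at the observed count; cheap, degree-aware,
    approximate.
    """
    query = sorted(set(query))
    missing = [q for q in query if q not in network.graph]
    if missing:
        raise KeyError(f"query proteins not in network: {missing}")
    if len(query) < 2:
        raise ValueError("query needs at least 2 proteins")
    if reps < 100:
        log.warning("reps=%d is low; permutation p-values will be coarse", reps)

    nodes = sorted(network.graph.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    adj = np.zeros((n, n), dtype=bool)
    for a, b in network.graph.edges:
        adj[index[a], index[b]] = adj[index[b], index[a]] = True
    q_idx = np.array([index[q] for q in query])
    observed = int(adj[np.ix_(q_idx, q_idx)].sum() // 2)

    deg = adj.sum(axis=1).astype(float)
    m = network.m
    if m > 0:
        ki = deg[q_idx]
        pair = np.minimum(np.outer(ki, ki) / (2.0 * m), 1.0)
        lam = float(np.triu(pair, k=1).sum())
    else:
        lam = 0.0

    if method == "permutation":
        rng = np.random.default_rng(seed)
        k = len(q_idx)
        ge = 0
        exp_sum = 0.0
        for _ in range(reps):
            draw = rng.choice(n, size=k, replace=False)
            cnt = int(adj[np.ix_(draw, draw)].sum() // 2)
            exp_sum += cnt
            if cnt >= observed:
                ge += 1
        p = (1 + ge) / (reps + 1)
        expected = exp_sum / reps
    elif method == "degree_poisson":
        expected = lam
        p = float(stats.poisson.sf(observed - 1, lam)) if lam > 0 else (1.0 if observed == 0 else 0.0)
        p = min(max(p, np.nextafter(0, 1)), 1.0)
    else:
        raise ValueError(f"unknown enrichment method {method!r}")
    return EnrichmentResult(
        observed_edges=observed,
        expected_edges=expected,
        p_value=p,
        method=method,
        n_query=len(query),
    )


# ---------------------------------------------------------------------------
# Markov clustering
# ---------------------------------------------------------------------------

@dataclass
class MCLParams:
    """Markov clustering parameters.

    inflation controls granularity (STRING's web default of 3.0 is kept);
    self-loops are added at the node's maximum incident edge weight so that
    dense neighbourhoods keep their random walk local (isolated nodes get
    weight 1 and become singletons).
    """

    inflation: float = 3.0
    expansion: int = 2
    prune_threshold: float = 1e-5
    max_iter: int = 100
    convergence_tol: float = 1e-6

    def __post_init__(self) -> None:
        if self.inflation <= 1:
            raise ValueError("inflation must be > 1")
        if self.expansion < 2:
            raise ValueError("expansion must be >= 2")
        if not (self.prune_threshold > 0 and self.convergence_tol > 0 and self.max_iter > 0):
            raise ValueError("prune_threshold, convergence_tol and max_iter must be positive")


@dataclass
class ClusterSet:
    clusters: list[set[str]]
    params: MCLParams
    converged: bool = True
    include_singletons: bool = True

    def labels(self) -> dict[str, int]:
        return {n: i for i, c in enumerate(self.clusters) for n in c}

    def __len__(self) -> int:
        return len(self.clusters)


def _normalize_columns(m: np.ndarray) -> np.ndarray:
    sums = m.sum(axis=0)
    sums[sums == 0.0] = 1.0
    return m / sums


def mcl_cluster(
    network: Network,
    params: Optional[MCLParams] = None,
    nodes: Optional[Iterable[str]] = None,
) -> ClusterSet:
    """Markov clustering of (an induced subgraph of) the network.

    The column-stochastic transition matrix (with self-loops) is evolved by
    alternating expansion (matrix power) and inflation (entrywise power
    followed by column renormalization), pruning entries below
    ``prune_threshold``.  At the attractor state, clusters are the
    connected components of the attractor structure: attractor rows with
    overlapping support merge, and each node joins the attractor holding
    its largest transition mass (ties broken lexicographically).  Nodes in
    different graph components can never merge.
    """
    params = params or MCLParams()
    g = network.graph if nodes is None else network.graph.subgraph(set(nodes))
    node_list = sorted(g.nodes)
    n = len(node_list)
    if n == 0:
        raise ValueError("network is empty")
    index = {v: i for i, v in enumerate(node_list)}
    a = np.zeros((n, n))
    for u, v, data in g.edges(data=True):
        w = float(data.get("combined_score", 1.0))
        a[index[u], index[v]] = a[index[v], index[u]] = w
    # self-loop rule: max incident weight (1.0 for isolated nodes)
    diag = a.max(axis=0)
    diag[diag == 0.0] = 1.0
    np.fill_diagonal(a, diag)

    m = _normalize_columns(a)
    converged = False
    for _ in range(params.max_iter):
        expanded = np.linalg.matrix_power(m, params.expansion)
        inflated = _normalize_columns(expanded ** params.inflation)
        # prune tiny entries but never a column's maximum
        keep = inflated >= params.prune_threshold
        keep[inflated.argmax(axis=0), np.arange(n)] = True
        inflated = _normalize_columns(np.where(keep, inflated, 0.0))
        if np.max(np.abs(inflated - m)) < params.convergence_tol:
            m = inflated
            converged = True
            break
        m = inflated
    if not converged:
        log.warning("MCL did not converge in %d iterations", params.max_iter)

    clusters = _extract_clusters(m, node_list, params.prune_threshold)
    return ClusterSet(clusters=clusters, params=params, converged=converged)


def _extract_clusters(m: np.ndarray, node_list: list[str], thr: float) -> list[set[str]]:
    n = len(node_list)
    attractors = [i for i in range(n) if m[i, i] > thr]
    if not attractors:  # degenerate; fall back to per-node assignment
        attractors = list(range(n))
    # union-find over attractors sharing support
    parent = {a: a for a in attractors}

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: int, y: int) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[ry] = rx

    support = {a: set(np.nonzero(m[a] > thr)[0]) | {a} for a in attractors}
    for j in range(n):
        covering = [a for a in attractors if j in support[a]]
        for a in covering[1:]:
            union(covering[0], a)

    att_rows = np.array(attractors)
    groups: dict[int, set[str]] = {}
    for j in range(n):
        masses = m[att_rows, j]
        best = float(masses.max())
        if best <= 0.0:
            groups.setdefault(-j - 1, set()).add(node_list[j])  # uncovered: singleton
            continue
        # tie-break: largest attractor value, then lexicographic node order
        tied = [int(att_rows[i]) for i in range(len(att_rows)) if masses[i] == best]
        choice = min(tied, key=lambda a: node_list[a])
        groups.setdefault(find(choice), set()).add(node_list[j])
    return sorted(groups.values(), key=lambda c: (-len(c), min(c)))


# ---------------------------------------------------------------------------
# gene-set enrichment
# ---------------------------------------------------------------------------

def benjamini_hochberg(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    q_(i) = min over j >= i of p_(j) * m / j, clipped to 1; ties receive
    equal q's and q >= p elementwise.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def gene_set_enrichment(
    query: Iterable[str],
    gene_sets: Mapping[str, set[str]],
    universe: Iterable[str],
) -> EnrichmentResult:
    """Hypergeometric over-representation test per term with BH-FDR.

    Each term is intersected with the universe before testing; the p-value
    is the upper tail P(X >= k) for overlap k, term size K, query size n,
    universe size N.  Terms are returned sorted by q then p.
    """
    universe_set = {g.upper() for g in universe}
    if not universe_set:
        raise ValueError("universe is empty")
    query_set = {g.upper() for g in query}
    if not query_set <= universe_set:
        raise ValueError(f"query genes outside universe: {sorted(query_set - universe_set)[:5]}")
    rows = []
    big_n = len(universe_set)
    n = len(query_set)
    for term, genes in gene_sets.items():
        term_genes = {g.upper() for g in genes} & universe_set
        big_k = len(term_genes)
        if big_k == 0:
            continue
        k = len(term_genes & query_set)
        p = 1.0 if k == 0 else float(stats.hypergeom.sf(k - 1, big_n, big_k, n))
        rows.append({"term": term, "overlap": k, "term_size": big_k, "query_size": n,
                     "universe_size": big_n, "p": min(p, 1.0)})
    df = pd.DataFrame(rows, columns=["term", "overlap", "term_size", "query_size",
                                     "universe_size", "p"])
    if len(df):
        df["q"] = benjamini_hochberg(df["p"].to_numpy())
        df = df.sort_values(["q", "p", "term"], kind="stable").reset_index(drop=True)
    else:
        df["q"] = pd.Series(dtype=float)
    top_p = float(df["p"].iloc[0]) if len(df) else 1.0
    return EnrichmentResult(
        observed_edges=0, expected_edges=0.0, p_value=top_p,
        method="hypergeometric_bh", n_query=n, terms=df,
    )
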