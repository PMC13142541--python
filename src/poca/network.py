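"""Interaction enrichment against a degree-preserving randomization null.

Given a bait–prey interactome and a query protein set (e.g. the hits of a
differential-enrichment analysis), the test counts interactions among the
query proteins and compares the count with its distribution over
randomized networks that preserve, exactly: the vertex set, the edge
count, every node's degree, and each edge's bait→prey role structure.
Randomization uses role-respecting double-edge swaps (pick edges b1–p1,
b2–p2; rewire to b1–p2, b2–p1 when the result is simple), the standard
sampler for graphs with a fixed bipartite degree sequence.  The z-score
of the observed count against the null mean/sd yields a two-sided
normal-approximation p-value; an empirical permutation p-value is
reported alongside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy import stats

__all__ = [
    "InteractionNetwork", "NullDistribution",
    "merge_networks", "count_internal_edges",
    "randomize_preserving", "null_test", "null_counts_for_queries",
]


def _pair_key(a: str, b: str) -> tuple:
    return (a, b) if a <= b else (b, a)


@dataclass
class InteractionNetwork:
    """A role-labeled protein graph with bait→prey oriented edges.

    ``edges`` are deduplicated at the unordered-pair level and contain no
    self-loops; ``roles`` maps each node to ``bait``, ``prey``, or
    ``both``.
    """

    edges: list
    roles: dict

    @classmethod
    def from_edges(cls, edges, roles: dict | None = None) -> "InteractionNetwork":
        seen: set = set()
        clean: list = []
        inferred: dict = {}
        for b, p in edges:
            b, p = str(b), str(p)
            if b == p:
                raise ValueError(f"self-loop edge {b!r}-{p!r} not allowed")
            key = _pair_key(b, p)
            if key in seen:
                continue
            seen.add(key)
            clean.append((b, p))
            for node, side in ((b, "bait"), (p, "prey")):
                prev = inferred.get(node)
                inferred[node] = side if prev in (None, side) else "both"
        if roles is None:
            roles = inferred
        else:
            roles = dict(roles)
            for n, r in inferred.items():
                roles.setdefault(n, r)
        missing = [n for e in clean for n in e if n not in roles]
        if missing:
            raise ValueError(f"edges reference nodes without roles: {missing[:5]}")
        return cls(edges=clean, roles=roles)

    @property
    def nodes(self) -> set:
        return set(self.roles)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degree(self) -> dict:
        d: dict = {n: 0 for n in self.roles}
        for b, p in self.edges:
            d[b] += 1
            d[p] += 1
        return d


@dataclass
class NullDistribution:
    """Observed interaction count vs a randomization null."""

    observed_count: int
    null_counts: np.ndarray
    null_mean: float
    null_sd: float
    z_score: float
    p_value: float
    empirical_p: float
    n_random: int
    n_query_mapped: int
    n_query_dropped: int
    degenerate: bool = False


def merge_networks(nets: list[InteractionNetwork]) -> InteractionNetwork:
    """Union of networks: pair-level edge dedup, role union (bait+prey=both)."""
    if not nets:
        raise ValueError("no networks to merge")
    roles: dict = {}
    for net in nets:
        for n, r in net.roles.items():
            prev = roles.get(n)
            if prev is None:
                roles[n] = r
            elif prev != r:
                roles[n] = "both"
    all_edges = [e for net in nets for e in net.edges]
    return InteractionNetwork.from_edges(all_edges, roles=roles)


def count_internal_edges(query: set, net: InteractionNetwork) -> tuple[int, int, int]:
    """Edges with both endpoints in ``query``.

    Returns ``(count, n_mapped, n_dropped)`` where ``n_mapped`` is the
    number of query proteins present in the network and ``n_dropped``
    those absent (interactome coverage is partial by nature).
    """
    query = set(query)
    mapped = query & net.nodes
    count = sum(1 for b, p in net.edges if b in mapped and p in mapped)
    return count, len(mapped), len(query) - len(mapped)


# ---------------------------------------------------------------------------
# randomization


@njit(cache=False)
def _swap_chain(b, p, adj, bait_as_prey, prey_as_bait, n_attempts, seed):  # pragma: no cover
    np.random.seed(seed)
    n_edges = b.shape[0]
    accepted = 0
    for _ in range(n_attempts):
        i = np.random.randint(0, n_edges)
        j = np.random.randint(0, n_edges)
        b1, p1 = b[i], p[i]
        b2, p2 = b[j], p[j]
        if b1 == b2 or p1 == p2:
            continue
        # self-loops: new edge's bait is the same protein as its prey
        if bait_as_prey[b1] == p2 or bait_as_prey[b2] == p1:
            continue
        if adj[b1, p2] or adj[b2, p1]:
            continue
        # duplicate unordered pair stored with opposite orientation
        pb = prey_as_bait[p2]
        bp = bait_as_prey[b1]
        if pb >= 0 and bp >= 0 and adj[pb, bp]:
            continue
        pb = prey_as_bait[p1]
        bp = bait_as_prey[b2]
        if pb >= 0 and bp >= 0 and adj[pb, bp]:
            continue
        adj[b1, p1] = False
        adj[b2, p2] = False
        adj[b1, p2] = True
        adj[b2, p1] = True
        p[i] = p2
        p[j] = p1
        accepted += 1
    return accepted


class _EncodedNetwork:
    """Integer encoding of a network for fast repeated randomization."""

    def __init__(self, net: InteractionNetwork):
        self.net = net
        bait_nodes = sorted({b for b, _ in net.edges})
        prey_nodes = sorted({p for _, p in net.edges})
        self.bait_nodes = bait_nodes
        self.prey_nodes = prey_nodes
        b_index = {n: i for i, n in enumerate(bait_nodes)}
        p_index = {n: i for i, n in enumerate(prey_nodes)}
        self.b = np.array([b_index[b] for b, _ in net.edges], dtype=np.int64)
        self.p = np.array([p_index[p] for _, p in net.edges], dtype=np.int64)
        self.adj = np.zeros((len(bait_nodes), len(prey_nodes)), dtype=np.bool_)
        self.adj[self.b, self.p] = True
        self.bait_as_prey = np.array(
            [p_index.get(n, -1) for n in bait_nodes], dtype=np.int64)
        self.prey_as_bait = np.array(
            [b_index.get(n, -1) for n in prey_nodes], dtype=np.int64)

    def randomized_edges(self, seed: int, swap_factor: int) -> tuple:
        """One fresh swap chain from the observed graph; returns (b, p, accepted)."""
        b = self.b.copy()
        p = self.p.copy()
        adj = self.adj.copy()
        n_attempts = int(swap_factor) * len(b)
        accepted = _swap_chain(b, p, adj, self.bait_as_prey,
                               self.prey_as_bait, n_attempts, seed)
        return b, p, accepted

    def query_masks(self, query: set) -> tuple:
        qb = np.array([n in query for n in self.bait_nodes], dtype=bool)
        qp = np.array([n in query for n in self.prey_nodes], dtype=bool)
        return qb, qp

    def decode(self, b: np.ndarray, p: np.ndarray) -> InteractionNetwork:
        edges = [(self.bait_nodes[i], self.prey_nodes[j]) for i, j in zip(b, p)]
        return InteractionNetwork(edges=edges, roles=dict(self.net.roles))


def _child_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(0, 2 ** 31 - 1, size=n)


def randomize_preserving(net: InteractionNetwork, seed: int = 0,
                         swap_factor: int = 10) -> InteractionNetwork:
    """A degree-, role-, and size-preserving randomization of the network.

    Performs ``swap_factor * |E|`` attempted double-edge swaps on the
    bait→prey edge set, rejecting any swap that would create a self-loop
    or duplicate pair.  If no swap is ever accepted the input is returned
    unchanged with a warning (the degree sequence admits only one graph,
    or the chain is stuck).
    """
    if net.n_edges < 2:
        warnings.warn("network has fewer than 2 edges; nothing to randomize")
        return InteractionNetwork(edges=list(net.edges), roles=dict(net.roles))
    enc = _EncodedNetwork(net)
    b, p, accepted = enc.randomized_edges(int(seed), swap_factor)
    if accepted == 0:
        warnings.warn("no valid double-edge swap was accepted; "
                      "returning the input network unchanged")
    return enc.decode(b, p)


def null_counts_for_queries(queries: list[set], net: InteractionNetwork,
                            n_random: int = 200, seed: int = 0,
                            swap_factor: int = 10) -> tuple[np.ndarray, np.ndarray]:
    """Observed and null internal-edge counts for many query sets at once.

    The ``n_random`` randomized networks are query-independent, so they
    are generated once (each an independent fresh swap chain from the
    observed graph) and scored against every query.  Returns
    ``(observed, null_counts)`` with shapes ``(n_queries,)`` and
    ``(n_queries, n_random)``.
    """
    enc = _EncodedNetwork(net)
    masks = [enc.query_masks(set(q)) for q in queries]
    qb = np.stack([m[0] for m in masks])  # (n_queries, n_bait_side)
    qp = np.stack([m[1] for m in masks])
    observed = (qb[:, enc.b] & qp[:, enc.p]).sum(axis=1)
    nulls = np.empty((len(queries), n_random), dtype=np.int64)
    for r, s in enumerate(_child_seeds(seed, n_random)):
        b, p, _ = enc.randomized_edges(int(s), swap_factor)
        nulls[:, r] = (qb[:, b] & qp[:, p]).sum(axis=1)
    return observed, nulls


def null_test(query: set, net: InteractionNetwork, n_random: int = 200,
              seed: int = 0, swap_factor: int = 10) -> NullDistribution:
    """Interaction enrichment of ``query`` vs the randomization null.

    ``z = (observed - null_mean) / null_sd`` (sd with ddof=1 over the
    ``n_random`` null counts) and ``p = 2 * (1 - Phi(|z|))``.  If the null
    counts are constant the result is flagged degenerate and z/p are NaN.
    """
    query = set(query)
    mapped = query & net.nodes
    if len(mapped) < 2:
        raise ValueError(
            f"query maps to {len(mapped)} network node(s); need at least 2")
    observed, nulls = null_counts_for_queries(
        [query], net, n_random=n_random, seed=seed, swap_factor=swap_factor)
    obs = int(observed[0])
    counts = nulls[0]
    mean = float(counts.mean())
    sd = float(counts.std(ddof=1))
    emp = float((1 + np.sum(np.abs(counts - mean) >= abs(obs - mean)))
                / (n_random + 1))
    if sd == 0.0:
        return NullDistribution(
            observed_count=obs, null_counts=counts, null_mean=mean,
            null_sd=0.0, z_score=float("nan"), p_value=float("nan"),
            empirical_p=emp, n_random=n_random, n_query_mapped=len(mapped),
            n_query_dropped=len(query) - len(mapped), degenerate=True)
    z = (obs - mean) / sd
    p = float(2.0 * stats.norm.sf(abs(z)))
    return NullDistribution(
        observed_count=obs, null_counts=counts, null_mean=mean, null_sd=sd,
        z_score=float(z), p_value=p, empirical_p=emp, n_random=n_random,
        n_query_mapped=len(mapped), n_query_dropped=len(query) - len(mapped))
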