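"""Independent brute-force oracles used by the test suite.

These deliberately re-derive quantities by exhaustive enumeration or the
textbook definition, independent of the library's implementation paths.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def bh_stepup(p):
    """Literal Benjamini-Hochberg step-up: find largest i with
    p(i) <= i*q/m by scanning, expressed as adjusted values."""
    p = list(p)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adjusted = [None] * m
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        value = min(prev, p[i] * m / rank)
        adjusted[i] = value
        prev = value
    return adjusted


def shortest_path_counts(nodes, edges):
    """Floyd-Warshall distances, then geodesic counts by dynamic
    programming in order of increasing distance from each source."""
    n = len(nodes)
    index = {v: i for i, v in enumerate(nodes)}
    dist = np.full((n, n), np.inf)
    for v in nodes:
        dist[index[v], index[v]] = 0
    for u, v in edges:
        i, j = index[u], index[v]
        dist[i, j] = dist[j, i] = 1
    for k in range(n):
        for i in range(n):
            for j in range(n):
                via = dist[i, k] + dist[k, j]
                if via < dist[i, j]:
                    dist[i, j] = via
    count = np.zeros((n, n))
    for i in range(n):
        count[i, i] = 1
    adjacency = {v: set() for v in nodes}
    for u, v in edges:
        adjacency[u].add(v)
        adjacency[v].add(u)
    for s in nodes:
        si = index[s]
        reachable = sorted(
            (v for v in nodes if np.isfinite(dist[si, index[v]])),
            key=lambda v: dist[si, index[v]],
        )
        for v in reachable:
            vi = index[v]
            if v == s:
                continue
            count[si, vi] = sum(
                count[si, index[u]]
                for u in adjacency[v]
                if dist[si, index[u]] == dist[si, vi] - 1
            )
    return dist, count, index


def betweenness_exhaustive(nodes, edges):
    """Unnormalised betweenness: for each unordered reachable pair (s, t),
    the fraction of geodesics through v, summed."""
    dist, count, index = shortest_path_counts(nodes, edges)
    result = {v: 0.0 for v in nodes}
    for s, t in itertools.combinations(nodes, 2):
        si, ti = index[s], index[t]
        if not np.isfinite(dist[si, ti]) or count[si, ti] == 0:
            continue
        for v in nodes:
            if v in (s, t):
                continue
            vi = index[v]
            if dist[si, vi] + dist[vi, ti] == dist[si, ti]:
                result[v] += count[si, vi] * count[vi, ti] / count[si, ti]
    return result


def closeness_reciprocal(nodes, edges):
    """1 / sum of finite shortest-path distances (0 for isolated nodes)."""
    dist, _, index = shortest_path_counts(nodes, edges)
    result = {}
    for v in nodes:
        total = sum(
            dist[index[v], index[u]]
            for u in nodes
            if u != v and np.isfinite(dist[index[v], index[u]])
        )
        result[v] = 1.0 / total if total > 0 else 0.0
    return result


def hypergeom_upper_tail(k, n, m, N):
    """Exact upper tail from factorials."""
    total = 0
    for x in range(k, min(n, m) + 1):
        total += math.comb(m, x) * math.comb(N - m, n - x)
    return total / math.comb(N, n)
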