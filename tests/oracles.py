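"""Independent brute-force oracles for graph metrics.

Everything here is deliberately naive (Floyd-Warshall, explicit pair
enumeration, shortest-path counting from the distance matrix) and shares no
code with the package implementation, so agreement is meaningful.
"""

import numpy as np


def floyd_warshall(a: np.ndarray) -> np.ndarray:
    """All-pairs shortest paths, O(n^3) triple loop. ``a`` holds edge lengths
    (0 = no edge) for weighted graphs, or 0/1 adjacency for hop counts."""
    n = a.shape[0]
    d = np.full((n, n), np.inf)
    for i in range(n):
        d[i, i] = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and a[i, j] > 0:
                d[i, j] = a[i, j]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def count_shortest_paths(adj: np.ndarray, d: np.ndarray) -> np.ndarray:
    """sigma[s, t] = number of shortest s-t paths, by dynamic programming on
    the (independently computed) distance matrix."""
    n = adj.shape[0]
    sigma = np.zeros((n, n))
    for s in range(n):
        sigma[s, s] = 1.0
        order = np.argsort(d[s])
        for t in order:
            if t == s or not np.isfinite(d[s, t]):
                continue
            total = 0.0
            for u in range(n):
                if adj[u, t] > 0 and d[s, u] == d[s, t] - 1:
                    total += sigma[s, u]
            sigma[s, t] = total
    return sigma


def betweenness_oracle(adj: np.ndarray) -> np.ndarray:
    """Unnormalized betweenness over unordered source-target pairs via the
    pair-dependency formula sigma(s,i)*sigma(i,t)/sigma(s,t)."""
    n = adj.shape[0]
    d = floyd_warshall(adj)
    sigma = count_shortest_paths(adj, d)
    b = np.zeros(n)
    for i in range(n):
        for s in range(n):
            for t in range(s + 1, n):
                if i in (s, t) or not np.isfinite(d[s, t]) or sigma[s, t] == 0:
                    continue
                if d[s, i] + d[i, t] == d[s, t]:
                    b[i] += sigma[s, i] * sigma[i, t] / sigma[s, t]
    return b


def clustering_oracle(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    c = np.zeros(n)
    for i in range(n):
        nbr = [j for j in range(n) if adj[i, j]]
        k = len(nbr)
        if k < 2:
            continue
        links = sum(
            1 for x in range(k) for y in range(x + 1, k) if adj[nbr[x], nbr[y]]
        )
        c[i] = 2.0 * links / (k * (k - 1))
    return c


def nodal_efficiency_oracle(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    d = floyd_warshall(adj)
    e = np.zeros(n)
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(d[i, j]):
                e[i] += 1.0 / d[i, j]
        e[i] /= n - 1
    return e


def local_efficiency_oracle(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    e = np.zeros(n)
    for i in range(n):
        nbr = [j for j in range(n) if adj[i, j]]
        if len(nbr) < 2:
            continue
        sub = adj[np.ix_(nbr, nbr)]
        e[i] = global_efficiency_oracle(sub)
    return e


def nodal_shortest_path_oracle(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    d = floyd_warshall(adj)
    out = np.full(n, np.nan)
    for i in range(n):
        finite = [d[i, j] for j in range(n) if j != i and np.isfinite(d[i, j])]
        if finite:
            out[i] = float(np.mean(finite))
    return out


def global_efficiency_oracle(adj: np.ndarray) -> float:
    n = adj.shape[0]
    if n < 2:
        return 0.0
    d = floyd_warshall(adj)
    total = sum(
        1.0 / d[i, j]
        for i in range(n)
        for j in range(n)
        if i != j and np.isfinite(d[i, j])
    )
    return total / (n * (n - 1))


def char_path_length_oracle(adj: np.ndarray) -> float:
    n = adj.shape[0]
    d = floyd_warshall(adj)
    finite = [
        d[i, j] for i in range(n) for j in range(n) if i != j and np.isfinite(d[i, j])
    ]
    return float(np.mean(finite))


def random_graph(rng: np.random.Generator, n_max: int = 12):
    """A random simple undirected graph (possibly disconnected)."""
    n = int(rng.integers(2, n_max + 1))
    p = rng.uniform(0.1, 0.8)
    a = (rng.random((n, n)) < p).astype(int)
    a = np.triu(a, 1)
    return a + a.T
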