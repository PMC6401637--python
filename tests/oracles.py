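"""Independent reference computations used to check the implementation.

Everything here is deliberately naive: exhaustive enumeration and direct
resampling, never sharing code with the package under test.
"""

from __future__ import annotations

import itertools

import numpy as np


def set_partitions(items: list):
    """All partitions of a list (restricted-growth-string enumeration)."""
    items = list(items)
    n = len(items)
    if n == 0:
        yield []
        return
    rgs = [0] * n

    def rec(i: int, maxval: int):
        if i == n:
            blocks: dict[int, list] = {}
            for item, b in zip(items, rgs):
                blocks.setdefault(b, []).append(item)
            yield [blocks[b] for b in sorted(blocks)]
            return
        for b in range(maxval + 2):
            rgs[i] = b
            yield from rec(i + 1, max(maxval, b))

    yield from rec(1, 0)


def modularity_direct(graph, assignment: dict) -> float:
    """Q from its definition, summing over all ordered node pairs."""
    nodes = list(graph.nodes)
    m = graph.number_of_edges()
    if m == 0:
        return 0.0
    a = {n: graph.degree(n) for n in nodes}
    q = 0.0
    for u in nodes:
        for v in nodes:
            if assignment[u] != assignment[v]:
                continue
            a_uv = 1.0 if graph.has_edge(u, v) and u != v else 0.0
            q += a_uv - a[u] * a[v] / (2.0 * m)
    return q / (2.0 * m)


def max_modularity_brute_force(graph) -> tuple[float, list]:
    """Maximum Q over every partition of the nodes (viable to ~9 nodes)."""
    best_q, best_part = -np.inf, None
    for blocks in set_partitions(list(graph.nodes)):
        assignment = {v: i for i, block in enumerate(blocks) for v in block}
        q = modularity_direct(graph, assignment)
        if q > best_q:
            best_q, best_part = q, blocks
    return best_q, best_part


def permutation_p_value(
    x: np.ndarray, y: np.ndarray, n_perm: int = 10_000, seed: int = 0
) -> float:
    """Two-sided permutation p-value for the Pearson correlation of x, y."""
    rng = np.random.default_rng(seed)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    r_obs = np.corrcoef(x, y)[0, 1]
    count = 0
    for _ in range(n_perm):
        r = np.corrcoef(x, rng.permutation(y))[0, 1]
        if abs(r) >= abs(r_obs) - 1e-12:
            count += 1
    return (count + 1) / (n_perm + 1)
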