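"""Shared test oracles: random pathway graphs and the RWR closed form."""

from __future__ import annotations

import numpy as np

from survwalk import PathwayGraph


def random_graph(rng: np.random.Generator, n_nodes: int,
                 pid: str = "p") -> PathwayGraph:
    """Connected random pathway graph with ~80% gene nodes."""
    nodes = {f"n{i:02d}": ("gene" if rng.random() < 0.8 else "other")
             for i in range(n_nodes)}
    ids = sorted(nodes)
    edges = set()
    for k in range(1, n_nodes):  # random tree keeps it connected
        edges.add((ids[int(rng.integers(0, k))], ids[k]))
    for _ in range(n_nodes):
        i, j = rng.integers(0, n_nodes, 2)
        if i != j:
            edges.add((ids[int(i)], ids[int(j)]))
    return PathwayGraph(pid, pid, nodes, edges)


def linear_solve_steady_state(W: np.ndarray, p0: np.ndarray,
                              r: float) -> np.ndarray:
    """Oracle: closed-form RWR fixed point p* = r (I - (1-r) W)^-1 p0."""
    n = W.shape[0]
    return r * np.linalg.solve(np.eye(n) - (1 - r) * W, p0)
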