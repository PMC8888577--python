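"""Graph ensembles the simulations run on.

Random regular graphs (every node has degree exactly k), Erdős–Rényi
G(N, p) graphs with p chosen to give a target average degree, and complete
graphs. Generation is delegated to networkx; the :class:`Network` container
stores the edge set plus a CSR adjacency used by the simulation kernels.
Node ids are 0-based integers everywhere, including edge-list files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Union

import networkx as nx
import numpy as np

__all__ = [
    "Network",
    "random_regular_graph",
    "erdos_renyi_graph",
    "complete_graph",
    "read_edge_list",
    "write_edge_list",
    "make_network",
]


@dataclass
class Network:
    """Undirected simple graph over nodes 0..N-1.

    ``indptr``/``indices`` form the CSR adjacency (each undirected edge
    appears twice); ``edges`` is the canonical sorted (i<j) edge array.
    """

    N: int
    edges: np.ndarray  # shape (E, 2), each row i < j, lexicographically sorted
    indptr: np.ndarray = field(repr=False)
    indices: np.ndarray = field(repr=False)
    meta: dict = field(default_factory=dict)

    @classmethod
    def from_edges(cls, N: int, edges: Iterable[tuple[int, int]], meta: dict | None = None) -> "Network":
        canon = set()
        for u, v in edges:
            u, v = int(u), int(v)
            if u == v:
                raise ValueError(f"self-loop at node {u}")
            if not (0 <= u < N and 0 <= v < N):
                raise ValueError(f"edge ({u},{v}) out of range for N={N}")
            e = (u, v) if u < v else (v, u)
            if e in canon:
                raise ValueError(f"duplicate edge {e}")
            canon.add(e)
        if canon:
            arr = np.array(sorted(canon), dtype=np.int64)
        else:
            arr = np.empty((0, 2), dtype=np.int64)
        deg = np.zeros(N, dtype=np.int64)
        for u, v in arr:
            deg[u] += 1
            deg[v] += 1
        indptr = np.zeros(N + 1, dtype=np.int64)
        indptr[1:] = np.cumsum(deg)
        indices = np.empty(indptr[-1], dtype=np.int64)
        cursor = indptr[:-1].copy()
        for u, v in arr:
            indices[cursor[u]] = v
            cursor[u] += 1
            indices[cursor[v]] = u
            cursor[v] += 1
        return cls(N=N, edges=arr, indptr=indptr, indices=indices, meta=meta or {})

    @classmethod
    def from_networkx(cls, g: nx.Graph, N: int | None = None, meta: dict | None = None) -> "Network":
        n = N if N is not None else g.number_of_nodes()
        return cls.from_edges(n, g.edges(), meta=meta)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degree(self, i: int) -> int:
        return int(self.indptr[i + 1] - self.indptr[i])

    @property
    def degrees(self) -> np.ndarray:
        return np.diff(self.indptr)

    def neighbors(self, i: int) -> np.ndarray:
        return self.indices[self.indptr[i] : self.indptr[i + 1]]

    @property
    def max_degree(self) -> int:
        return int(self.degrees.max()) if self.N else 0


def random_regular_graph(N: int, k: int, seed: int) -> Network:
    """Uniform-ish random simple graph with every degree exactly k.

    Pairing (configuration-model) construction with rejection of
    self-loops and multi-edges; requires N*k even and 0 <= k < N.
    Bit-reproducible for a given seed.
    """
    if not (0 <= k < N):
        raise ValueError(f"need 0 <= k < N, got k={k}, N={N}")
    if (N * k) % 2 != 0:
        raise ValueError(f"N*k must be even, got N={N}, k={k}")
    if k == 0:
        g = nx.empty_graph(N)
    else:
        g = nx.random_regular_graph(k, N, seed=seed)
    return Network.from_networkx(
        g, N=N, meta={"family": "random_regular", "N": N, "k": k, "seed": seed}
    )


def erdos_renyi_graph(N: int, k_avg: float, seed: int) -> Network:
    """G(N, p) with p = k_avg/(N-1), matching a target average degree.

    Isolated nodes are kept (they occur naturally at low k_avg); the
    dialect is Bernoulli edges, not a fixed edge count.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    if not (0 <= k_avg <= N - 1):
        raise ValueError(f"need 0 <= k_avg <= N-1, got k_avg={k_avg}, N={N}")
    p = k_avg / (N - 1) if N > 1 else 0.0
    g = nx.fast_gnp_random_graph(N, p, seed=seed)
    return Network.from_networkx(
        g, N=N, meta={"family": "erdos_renyi", "N": N, "k_avg": k_avg, "seed": seed}
    )


def complete_graph(N: int) -> Network:
    if N < 2:
        raise ValueError(f"complete graph needs N >= 2, got N={N}")
    g = nx.complete_graph(N)
    return Network.from_networkx(g, N=N, meta={"family": "complete", "N": N})


PathLike = Union[str, Path]


def write_edge_list(net: Network, path: PathLike) -> None:
    """Write one "u v" pair per line, 0-based ids, canonical order."""
    with open(path, "w") as fh:
        for u, v in net.edges:
            fh.write(f"{u} {v}\n")


def read_edge_list(path: PathLike, N: int | None = None) -> Network:
    """Read a whitespace-separated edge list; validates simple-graph rules.

    N defaults to 1 + the largest node id seen.
    """
    edges = []
    max_id = -1
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected two integers, got {line!r}")
            u, v = int(parts[0]), int(parts[1])
            if u < 0 or v < 0:
                raise ValueError(f"{path}:{lineno}: negative node id")
            edges.append((u, v))
            max_id = max(max_id, u, v)
    n = N if N is not None else max_id + 1
    return Network.from_edges(n, edges, meta={"family": "file", "path": str(path)})


def make_network(family: str, N: int, k: float | None = None, seed: int = 0) -> Network:
    """Dispatch on family name: random_regular | erdos_renyi | complete."""
    if family == "random_regular":
        return random_regular_graph(N, int(k), seed)
    if family == "erdos_renyi":
        return erdos_renyi_graph(N, float(k), seed)
    if family == "complete":
        return complete_graph(N)
    raise ValueError(f"unknown network family {family!r}")
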