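"""Graph representation, named generators, connected Erdős-Rényi sampling,
and node-temperature computation.

Graphs are undirected, unweighted, simple (no self-loops) and stored as a
dense 0/1 adjacency matrix; all supported exact computations operate on
small graphs (the full-configuration fixation solver caps ``N`` at
:data:`FULL_SOLVER_MAX_N`), while reduced-chain star computations accept
much larger ``N`` and never instantiate the adjacency.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .errors import SamplingError, ValidationError

#: Hard cap on N for the 2^N full-configuration fixation solver.
FULL_SOLVER_MAX_N = 24

#: Default rejection budget for connected Erdős-Rényi sampling.
ER_MAX_TRIES = 10**5

NAMED_KINDS = ("star", "cycle", "complete", "grid2d")


class Graph:
    """An undirected, unweighted graph over nodes ``0..N-1``.

    Parameters
    ----------
    adjacency:
        Square 0/1 array-like; must be symmetric with a zero diagonal.

    Node indexing is 0-based everywhere; for star graphs node 0 is the
    centre by convention.
    """

    __slots__ = ("adjacency", "_neighbors")

    def __init__(self, adjacency) -> None:
        a = np.asarray(adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValidationError(f"adjacency must be square, got shape {a.shape}")
        if a.shape[0] < 2:
            raise ValidationError("graph must have at least 2 nodes")
        vals = np.unique(a)
        if not np.isin(vals, (0, 1)).all():
            raise ValidationError("adjacency entries must be 0 or 1")
        a = a.astype(np.int8)
        if (a != a.T).any():
            raise ValidationError("adjacency must be symmetric (undirected graph)")
        if np.diagonal(a).any():
            raise ValidationError("self-loops are not allowed (nonzero diagonal)")
        a.setflags(write=False)
        self.adjacency = a
        self._neighbors: list[tuple[int, ...]] | None = None

    # -- basic structure ---------------------------------------------------

    @property
    def N(self) -> int:
        """Number of nodes."""
        return self.adjacency.shape[0]

    @property
    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1).astype(np.int64)

    @property
    def neighbors(self) -> list[tuple[int, ...]]:
        """Per-node tuples of neighbour indices (cached)."""
        if self._neighbors is None:
            a = self.adjacency
            self._neighbors = [tuple(np.flatnonzero(a[i]).tolist()) for i in range(self.N)]
        return self._neighbors

    def edges(self) -> list[tuple[int, int]]:
        """Sorted list of edges (i < j)."""
        i, j = np.nonzero(np.triu(self.adjacency, k=1))
        return list(zip(i.tolist(), j.tolist()))

    def is_connected(self) -> bool:
        return nx.is_connected(self.to_networkx())

    def is_regular(self) -> bool:
        d = self.degrees
        return bool((d == d[0]).all())

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.N))
        g.add_edges_from(self.edges())
        return g

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[int, int]], n: int | None = None) -> "Graph":
        edges = list(edges)
        if n is None:
            n = 1 + max(max(e) for e in edges)
        a = np.zeros((n, n), dtype=np.int8)
        for u, v in edges:
            if not (0 <= u < n and 0 <= v < n):
                raise ValidationError(f"edge ({u}, {v}) out of range for N={n}")
            if u == v:
                raise ValidationError(f"self-loop on node {u} is not allowed")
            a[u, v] = a[v, u] = 1
        return cls(a)

    def __eq__(self, other) -> bool:
        return isinstance(other, Graph) and np.array_equal(self.adjacency, other.adjacency)

    def __hash__(self) -> int:
        return hash((self.N, self.adjacency.tobytes()))

    def __repr__(self) -> str:
        return f"Graph(N={self.N}, edges={len(self.edges())})"


class TemperatureVector:
    """Per-node temperatures (sum of normalised incident weights).

    For a graph with no isolated nodes the in-temperatures sum to ``N``
    (column sums of a row-stochastic matrix); for undirected graphs the
    in- and out-directions coincide.
    """

    __slots__ = ("values", "direction")

    def __init__(self, values: np.ndarray, direction: str) -> None:
        if direction not in ("in", "out"):
            raise ValidationError(f"direction must be 'in' or 'out', got {direction!r}")
        self.values = np.asarray(values, dtype=float)
        self.direction = direction

    def __repr__(self) -> str:
        return f"TemperatureVector({self.values!r}, direction={self.direction!r})"


def temperature(g: Graph, direction: str = "in") -> TemperatureVector:
    """Node temperatures of ``g``.

    The in-temperature of node *i* is ``sum_j a_ji / sum_k a_jk`` and the
    out-temperature is ``sum_j a_ij / sum_k a_kj``; for the undirected
    graphs handled here the two are identical.
    """
    a = g.adjacency.astype(float)
    deg = a.sum(axis=1)
    if (deg == 0).any():
        bad = int(np.flatnonzero(deg == 0)[0])
        raise ValidationError(f"temperature undefined: node {bad} is isolated")
    if direction == "in":
        vals = (a / deg[:, None]).sum(axis=0)
    elif direction == "out":
        vals = (a / a.sum(axis=0)[None, :]).sum(axis=1)
    else:
        raise ValidationError(f"direction must be 'in' or 'out', got {direction!r}")
    return TemperatureVector(vals, direction)


# -- generators ------------------------------------------------------------


def make_named_graph(
    kind: str,
    n: int | None = None,
    *,
    rows: int | None = None,
    cols: int | None = None,
    periodic: bool = False,
) -> Graph:
    """Build one of the canonical graphs: star, cycle, complete, grid2d.

    ``star``/``cycle``/``complete`` take ``n``; ``grid2d`` takes
    ``rows``/``cols`` (and a ``periodic`` flag). Node 0 is the star centre.
    """
    if kind == "star":
        if n is None or n < 3:
            raise ValidationError("star requires N >= 3")
        return Graph(nx.to_numpy_array(nx.star_graph(n - 1), nodelist=range(n)))
    if kind == "cycle":
        if n is None or n < 3:
            raise ValidationError("cycle requires N >= 3")
        return Graph(nx.to_numpy_array(nx.cycle_graph(n), nodelist=range(n)))
    if kind == "complete":
        if n is None or n < 2:
            raise ValidationError("complete requires N >= 2")
        return Graph(nx.to_numpy_array(nx.complete_graph(n), nodelist=range(n)))
    if kind == "grid2d":
        if rows is None or cols is None:
            raise ValidationError("grid2d requires rows and cols")
        lo = 3 if periodic else 2
        if rows < lo or cols < lo:
            raise ValidationError(
                f"grid2d requires rows, cols >= {lo}" + (" when periodic" if periodic else "")
            )
        gg = nx.grid_2d_graph(rows, cols, periodic=periodic)
        order = [(r, c) for r in range(rows) for c in range(cols)]
        return Graph(nx.to_numpy_array(gg, nodelist=order))
    raise ValidationError(f"unknown graph kind {kind!r}; expected one of {NAMED_KINDS}")


def sample_er_connected(
    n: int, p: float, seed: int, max_tries: int = ER_MAX_TRIES
) -> Graph:
    """Sample a connected G(N, p) graph by rejection.

    Rejection (rather than e.g. spanning-tree augmentation) preserves the
    conditional G(N,p)-given-connected distribution. Deterministic for a
    given ``(n, p, seed)``.
    """
    if n < 2:
        raise ValidationError("need at least 2 nodes")
    if not 0.0 < p <= 1.0:
        raise ValidationError(f"edge probability must be in (0, 1], got {p}")
    rng = np.random.default_rng(seed)
    m = n * (n - 1) // 2
    iu = np.triu_indices(n, k=1)
    for _ in range(max_tries):
        a = np.zeros((n, n), dtype=np.int8)
        a[iu] = rng.random(m) < p
        a |= a.T
        g = Graph(a)
        if g.is_connected():
            return g
    raise SamplingError(
        f"no connected G({n}, {p}) sample in {max_tries} draws; p is likely too small"
    )


def sample_er_connected_many(
    n: int, p: float, n_samples: int, seed: int, max_tries: int = ER_MAX_TRIES
) -> list[Graph]:
    """Draw ``n_samples`` connected ER graphs from one seeded stream.

    Isomorphic duplicates are kept: censuses are over sampled graphs.
    """
    rng = np.random.default_rng(seed)
    m = n * (n - 1) // 2
    iu = np.triu_indices(n, k=1)
    out: list[Graph] = []
    tries = 0
    while len(out) < n_samples:
        if tries >= max_tries:
            raise SamplingError(
                f"only {len(out)}/{n_samples} connected G({n}, {p}) samples in {max_tries} draws"
            )
        tries += 1
        a = np.zeros((n, n), dtype=np.int8)
        a[iu] = rng.random(m) < p
        a |= a.T
        g = Graph(a)
        if g.is_connected():
            out.append(g)
    return out
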