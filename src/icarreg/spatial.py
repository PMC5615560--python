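"""County adjacency graphs and the intrinsic CAR (ICAR) distribution.

The adjacency graph encodes which counties share a border.  The ICAR prior
on county effects ``s`` places each ``s_i`` conditionally normal around the
average of its neighbours' effects with variance ``sigma2_s / L_i``, where
``L_i`` is the neighbour count.  The joint (improper) density is the
pairwise-difference kernel ``exp(-(1/(2 sigma2_s)) * sum_{i~j} (s_i-s_j)^2)``,
identified by a sum-to-zero constraint because the model carries a separate
intercept.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

logger = logging.getLogger(__name__)

__all__ = [
    "AdjacencyGraph",
    "build_grid_adjacency",
    "read_adjacency",
    "write_adjacency",
    "icar_conditional_params",
    "icar_log_density",
    "gibbs_sample_icar",
    "morans_i",
]


@dataclass(frozen=True)
class AdjacencyGraph:
    """Symmetric neighbour structure over counties.

    Parameters
    ----------
    node_ids
        Ordered county identifiers (opaque strings).
    neighbours
        Map from node id to the set of adjacent node ids.  Must be
        symmetric and free of self-loops; validated on construction.
    """

    node_ids: tuple[str, ...]
    neighbours: Mapping[str, frozenset[str]]
    _index: Mapping[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        ids = set(self.node_ids)
        if len(ids) != len(self.node_ids):
            raise ValueError("duplicate node identifiers")
        for i, nbrs in self.neighbours.items():
            if i not in ids:
                raise ValueError(f"neighbour map references unknown node {i!r}")
            if i in nbrs:
                raise ValueError(f"self-loop on node {i!r}")
            for j in nbrs:
                if j not in ids:
                    raise ValueError(f"unknown node {j!r} adjacent to {i!r}")
                if i not in self.neighbours.get(j, frozenset()):
                    raise ValueError(f"asymmetric adjacency: {i!r} -> {j!r}")
        object.__setattr__(
            self, "_index", {nid: k for k, nid in enumerate(self.node_ids)}
        )

    @classmethod
    def from_neighbours(
        cls, neighbours: Mapping[str, Iterable[str]], node_ids: Sequence[str] | None = None
    ) -> "AdjacencyGraph":
        if node_ids is None:
            node_ids = sorted(neighbours)
        frozen = {i: frozenset(neighbours.get(i, ())) for i in node_ids}
        return cls(tuple(node_ids), frozen)

    # -- basic queries -------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.node_ids)

    def index_of(self, node: str) -> int:
        return self._index[node]

    @property
    def L(self) -> dict[str, int]:
        """Neighbour count per node."""
        return {i: len(self.neighbours[i]) for i in self.node_ids}

    def degrees(self) -> np.ndarray:
        """Neighbour counts in node order."""
        return np.array([len(self.neighbours[i]) for i in self.node_ids])

    def n_edges(self) -> int:
        return sum(len(v) for v in self.neighbours.values()) // 2

    def adjacency_matrix(self) -> sp.csr_matrix:
        """0/1 sparse adjacency in node order."""
        rows, cols = [], []
        for i in self.node_ids:
            ii = self._index[i]
            for j in self.neighbours[i]:
                rows.append(ii)
                cols.append(self._index[j])
        data = np.ones(len(rows))
        return sp.csr_matrix((data, (rows, cols)), shape=(self.n, self.n))

    def laplacian(self) -> sp.csr_matrix:
        A = self.adjacency_matrix()
        return sp.diags(self.degrees().astype(float)) - A

    def is_connected(self) -> bool:
        if self.n <= 1:
            return True
        ncomp, _ = connected_components(self.adjacency_matrix(), directed=False)
        return ncomp == 1

    def islands(self) -> list[str]:
        """Nodes with no neighbours (e.g. offshore counties)."""
        return [i for i in self.node_ids if not self.neighbours[i]]

    def colouring(self) -> list[np.ndarray]:
        """Greedy proper colouring, as index arrays per colour class.

        Nodes in one class share no edge, so their ICAR conditionals may be
        updated simultaneously in a Gibbs sweep.
        """
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(range(self.n))
        for i in self.node_ids:
            ii = self._index[i]
            for j in self.neighbours[i]:
                g.add_edge(ii, self._index[j])
        colours = nx.greedy_color(g, strategy="largest_first")
        ncol = max(colours.values(), default=0) + 1
        return [
            np.array(sorted(k for k, c in colours.items() if c == cc), dtype=int)
            for cc in range(ncol)
        ]


def build_grid_adjacency(rows: int, cols: int, scheme: str = "rook") -> AdjacencyGraph:
    """Regular lattice contiguity, a synthetic stand-in for county borders.

    ``rook`` joins cells sharing an edge; ``queen`` also joins diagonal
    neighbours.  Node ids are ``"r{r}c{c}"`` in row-major order.
    """
    if rows < 1 or cols < 1:
        raise ValueError(f"lattice dimensions must be positive, got {rows}x{cols}")
    if rows * cols < 2:
        raise ValueError("lattice must have at least 2 cells")
    if scheme not in {"rook", "queen"}:
        raise ValueError(f"unknown contiguity scheme {scheme!r}")

    if scheme == "rook":
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        steps = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]

    def nid(r: int, c: int) -> str:
        return f"r{r}c{c}"

    neighbours: dict[str, set[str]] = {}
    for r in range(rows):
        for c in range(cols):
            nbrs = set()
            for dr, dc in steps:
                rr, cc = r + dr, c + dc
                if 0 <= rr < rows and 0 <= cc < cols:
                    nbrs.add(nid(rr, cc))
            neighbours[nid(r, c)] = nbrs
    ids = [nid(r, c) for r in range(rows) for c in range(cols)]
    return AdjacencyGraph.from_neighbours(neighbours, ids)


# ---------------------------------------------------------------------------
# File formats: GAL spatial weights and plain edge lists
# ---------------------------------------------------------------------------

def read_adjacency(path: str | Path, dialect: str = "gal") -> AdjacencyGraph:
    """Read an adjacency structure from a GAL or whitespace edge-list file.

    Asymmetric input (a listed in b's record but not vice versa) is
    symmetrised with a logged warning.  Self-loops are rejected.
    """
    path = Path(path)
    text = path.read_text()
    lines = [ln.strip() for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise ValueError(f"empty adjacency file: {path}")

    neighbours: dict[str, set[str]] = {}
    if dialect == "gal":
        # header: either "n" or the 4-token "0 n shapefile key" variant
        header = lines[0].split()
        try:
            n_declared = int(header[1] if len(header) >= 2 else header[0])
        except ValueError as exc:
            raise ValueError(f"unparseable GAL header: {lines[0]!r}") from exc
        k = 1
        while k < len(lines):
            rec = lines[k].split()
            if len(rec) != 2:
                raise ValueError(f"malformed GAL record line: {lines[k]!r}")
            node, cnt = rec[0], int(rec[1])
            neighbours.setdefault(node, set())
            if cnt > 0:
                if k + 1 >= len(lines):
                    raise ValueError(f"GAL record for {node!r} truncated")
                nbrs = lines[k + 1].split()
                if len(nbrs) != cnt:
                    raise ValueError(
                        f"GAL record for {node!r} declares {cnt} neighbours, "
                        f"found {len(nbrs)}"
                    )
                neighbours[node].update(nbrs)
                k += 2
            else:
                k += 1
        if len(neighbours) != n_declared:
            logger.warning(
                "GAL header declares %d nodes, file contains %d",
                n_declared,
                len(neighbours),
            )
    elif dialect == "edge_list":
        for ln in lines:
            parts = ln.split()
            if len(parts) != 2:
                raise ValueError(f"malformed edge-list line: {ln!r}")
            a, b = parts
            neighbours.setdefault(a, set()).add(b)
            neighbours.setdefault(b, set()).add(a)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    for i, nbrs in neighbours.items():
        if i in nbrs:
            raise ValueError(f"self-loop on node {i!r} in {path}")
        for j in nbrs:
            if j not in neighbours:
                raise ValueError(f"edge references unknown node {j!r} (from {i!r})")

    # symmetrise
    asym = [
        (i, j)
        for i, nbrs in neighbours.items()
        for j in nbrs
        if i not in neighbours[j]
    ]
    if asym:
        warnings.warn(
            f"symmetrising {len(asym)} one-directional adjacencies "
            f"(e.g. {asym[0][0]!r} -> {asym[0][1]!r})",
            stacklevel=2,
        )
        for i, j in asym:
            neighbours[j] = set(neighbours[j]) | {i}

    return AdjacencyGraph.from_neighbours(neighbours, sorted(neighbours))


def write_adjacency(graph: AdjacencyGraph, path: str | Path, dialect: str = "gal") -> None:
    """Write the graph as a GAL file (1-based record counts) or edge list."""
    path = Path(path)
    if dialect == "gal":
        out = [str(graph.n)]
        for i in graph.node_ids:
            nbrs = sorted(graph.neighbours[i])
            out.append(f"{i} {len(nbrs)}")
            if nbrs:
                out.append(" ".join(nbrs))
        path.write_text("\n".join(out) + "\n")
    elif dialect == "edge_list":
        seen = set()
        out = []
        for i in graph.node_ids:
            for j in sorted(graph.neighbours[i]):
                if (j, i) not in seen:
                    seen.add((i, j))
                    out.append(f"{i} {j}")
        path.write_text("\n".join(out) + "\n")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# ICAR distributional machinery
# ---------------------------------------------------------------------------

def icar_conditional_params(
    i: str, s: np.ndarray, graph: AdjacencyGraph, sigma2_s: float
) -> tuple[float, float]:
    """Conditional mean and variance of ``s_i`` given its neighbours.

    The ICAR prior sets ``s_i | s_{-i} ~ N(mean of neighbours, sigma2_s/L_i)``.
    """
    if sigma2_s <= 0:
        raise ValueError("sigma2_s must be positive")
    nbrs = graph.neighbours[i]
    if not nbrs:
        raise ValueError(
            f"node {i!r} has no neighbours; island nodes have their effect "
            "pinned to 0 rather than an ICAR conditional (island policy)"
        )
    idx = [graph.index_of(j) for j in nbrs]
    return float(np.mean(s[idx])), float(sigma2_s / len(nbrs))


def icar_log_density(s: np.ndarray, graph: AdjacencyGraph, sigma2_s: float) -> float:
    """Log pairwise-difference kernel, up to an additive constant.

    ``-(1/(2 sigma2_s)) * sum_{i~j} (s_i - s_j)^2``.  Requires a connected
    graph (otherwise the kernel is rank-deficient beyond the single
    sum-to-zero constraint) and a sum-to-zero ``s``.
    """
    if sigma2_s <= 0:
        raise ValueError("sigma2_s must be positive")
    s = np.asarray(s, dtype=float)
    if s.shape != (graph.n,):
        raise ValueError(f"s has shape {s.shape}, expected ({graph.n},)")
    if not graph.is_connected():
        raise ValueError(
            "graph is disconnected: the pairwise-difference kernel is rank "
            "deficient beyond the single sum-to-zero constraint"
        )
    if abs(s.sum()) > 1e-6 * max(1.0, np.abs(s).max()):
        raise ValueError("s must sum to zero (apply the identification constraint)")
    q = float(s @ (graph.laplacian() @ s))
    return -q / (2.0 * sigma2_s)


def gibbs_sample_icar(
    graph: AdjacencyGraph,
    sigma2_s: float,
    n_chains: int,
    n_sweeps: int,
    burn_in: int,
    rng: np.random.Generator,
    keep_every_sweep: bool = True,
) -> np.ndarray:
    """Sample the sum-to-zero ICAR distribution by single-site Gibbs.

    Runs ``n_chains`` independent chains vectorised across chains; each
    sweep updates every node from its ICAR conditional and then recentres
    each chain to mean zero (the identification constraint).  Returns draws
    with shape ``(n_chains * (n_sweeps - burn_in), n)`` if
    ``keep_every_sweep`` else the final state per chain.
    """
    if not graph.is_connected():
        raise ValueError("gibbs_sample_icar requires a connected graph")
    n = graph.n
    deg = graph.degrees().astype(float)
    nbr_idx = [
        np.array([graph.index_of(j) for j in graph.neighbours[i]], dtype=int)
        for i in graph.node_ids
    ]
    s = rng.standard_normal((n_chains, n)) * np.sqrt(sigma2_s)
    s -= s.mean(axis=1, keepdims=True)
    kept = []
    for sweep in range(n_sweeps):
        for k in range(n):
            m = s[:, nbr_idx[k]].mean(axis=1)
            sd = np.sqrt(sigma2_s / deg[k])
            s[:, k] = m + sd * rng.standard_normal(n_chains)
        s -= s.mean(axis=1, keepdims=True)
        if keep_every_sweep and sweep >= burn_in:
            kept.append(s.copy())
    if keep_every_sweep:
        return np.concatenate(kept, axis=0)
    return s.copy()


def morans_i(x: np.ndarray, graph: AdjacencyGraph) -> float:
    """Moran's I spatial autocorrelation with binary contiguity weights."""
    x = np.asarray(x, dtype=float)
    if x.shape != (graph.n,):
        raise ValueError("x must align with the graph's nodes")
    z = x - x.mean()
    denom = float(z @ z)
    if denom == 0:
        raise ValueError("x is constant; Moran's I undefined")
    A = graph.adjacency_matrix()
    w_sum = A.sum()
    return float(graph.n / w_sum * (z @ (A @ z)) / denom)
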