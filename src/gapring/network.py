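"""Connectivity construction: ring, chain, all-to-all; contiguous partitions.

The network is a virtual ring of N cells in which every cell couples to its
``n_cc`` closest neighbours (``n_cc/2`` on each side, modular index
arithmetic).  ``n_cc = N-1`` adds the antipodal connection so the graph is
complete; a chain uses the same windows without wrap-around.  Per-synapse
conductance is ``g_el / n_cc`` so the per-cell total stays ``g_el`` (on a
chain the edge cells keep the per-synapse value and therefore a weaker total,
unless ``chain_renormalize`` is set).

Cells are indexed 0-based internally; reports and plots use 1-based numbers.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

TOPOLOGIES = ("ring", "chain", "complete")


@dataclass(frozen=True)
class NetworkSpec:
    N: int
    topology: str
    n_cc: int
    g_el: float
    adjacency: np.ndarray = field(repr=False, compare=False)
    chain_renormalize: bool = False

    @property
    def per_synapse_conductance(self) -> float:
        return self.g_el / self.n_cc

    def synapse_divisor(self) -> np.ndarray:
        """Per-cell divisor of g_el: ``n_cc`` by default, or the cell's own
        degree when a chain's edge cells renormalize to a full g_el total."""
        if self.chain_renormalize:
            return np.maximum(self.degree(), 1).astype(float)
        return np.full(self.N, float(self.n_cc))

    def with_gel(self, g_el: float) -> "NetworkSpec":
        return NetworkSpec(self.N, self.topology, self.n_cc, g_el,
                           self.adjacency, self.chain_renormalize)

    def degree(self) -> np.ndarray:
        return self.adjacency.sum(axis=1).astype(int)

    def to_edgelist(self, path) -> None:
        """Write the (1-based) undirected edge list as text."""
        with open(path, "w") as fh:
            fh.write("# source target conductance\n")
            for i in range(self.N):
                for j in range(i + 1, self.N):
                    if self.adjacency[i, j]:
                        fh.write(f"{i + 1} {j + 1} "
                                 f"{self.per_synapse_conductance:.6g}\n")

    def to_graphml(self, path) -> None:
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(range(1, self.N + 1))
        for i in range(self.N):
            for j in range(i + 1, self.N):
                if self.adjacency[i, j]:
                    g.add_edge(i + 1, j + 1,
                               conductance=self.per_synapse_conductance)
        nx.write_graphml(g, path)


@dataclass(frozen=True)
class GroupPartition:
    """Contiguous arcs of cells, group 0 starting at cell 0."""

    labels: np.ndarray = field(repr=False)
    sizes: tuple
    contiguous: bool = True

    @property
    def n_groups(self) -> int:
        return len(self.sizes)

    def members(self, g: int) -> np.ndarray:
        return np.flatnonzero(self.labels == g)


def build_adjacency(N: int, topology: str, n_cc: int, g_el: float = 0.0,
                    chain_renormalize: bool = False) -> NetworkSpec:
    """Build a NetworkSpec for the given topology and connectivity.

    Ring / complete: every cell couples to the ``n_cc/2`` nearest cells on
    each side (wrap-around); ``n_cc = N-1`` additionally couples antipodes so
    the graph is complete.  Chain: same windows without wrap-around.  Odd
    ``n_cc`` other than ``N-1`` is rejected rather than approximated.
    """
    if N < 2 or N % 2:
        raise ValueError("N must be an even integer >= 2")
    if topology not in TOPOLOGIES:
        raise ValueError(f"unknown topology {topology!r}; use one of {TOPOLOGIES}")
    if n_cc == N - 1:
        if topology == "chain":
            raise ValueError("all-to-all (n_cc = N-1) is not a chain")
        topology = "complete"
    else:
        if topology == "complete":
            raise ValueError("complete topology requires n_cc = N-1")
        if n_cc < 2 or n_cc > N - 2 or n_cc % 2:
            raise ValueError(
                f"n_cc must be even with 2 <= n_cc <= N-2, or n_cc = N-1 "
                f"(got n_cc={n_cc}, N={N})")

    A = np.zeros((N, N), dtype=np.int8)
    half = (N - 2) // 2 if n_cc == N - 1 else n_cc // 2
    for i in range(N):
        for j in range(1, half + 1):
            for k in (i + j, i - j):
                if topology == "chain":
                    if 0 <= k < N:
                        A[i, k % N] = 1
                else:
                    A[i, k % N] = 1
    if n_cc == N - 1:
        # ls rule: one extra (antipodal) connection completes the graph
        for i in range(N):
            A[i, (i + N // 2) % N] = 1
    np.fill_diagonal(A, 0)
    return NetworkSpec(N=N, topology=topology, n_cc=n_cc, g_el=g_el,
                       adjacency=A,
                       chain_renormalize=chain_renormalize and
                       topology == "chain")


def partition(N: int, sizes) -> GroupPartition:
    """Partition the ring into contiguous arcs with the given sizes.

    Deterministic: group 0 starts at cell 0 (cell 1 in 1-based reports) and
    groups follow in index order.
    """
    sizes = tuple(int(s) for s in sizes)
    if any(s <= 0 for s in sizes):
        raise ValueError("group sizes must be positive")
    if sum(sizes) != N:
        raise ValueError(f"group sizes {sizes} do not sum to N={N}")
    labels = np.repeat(np.arange(len(sizes)), sizes)
    return GroupPartition(labels=labels, sizes=sizes, contiguous=True)
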