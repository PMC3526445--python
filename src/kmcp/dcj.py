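"""Breakpoint graphs, the DCJ distance, and a BFS sorting-distance oracle.

For genomes ``G1, G2`` on the same ``n`` genes the breakpoint graph
``B(G1, G2)`` is the multigraph on all 2n extremities whose edges are the
adjacencies of both genomes, colored by genome of origin.  Since each genome
is a matching, every component of a two-genome breakpoint graph is a simple
path (possibly a single vertex) or a cycle.  The double-cut-and-join
distance is

    d_DCJ(G1, G2) = n - c - p/2

where ``c`` is the number of cycle components and ``p`` the number of path
components with an *odd number of vertices* (isolated extremities count as
1-vertex paths).  When at least one genome is circular, p = 0 and the
distance reduces to n - c.
"""

from __future__ import annotations

import itertools
from collections import deque
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx

from .genomes import Adjacency, Genome, GenomeError

CYCLE = "cycle"
PATH = "path"


@dataclass(frozen=True)
class Component:
    """One connected component of a breakpoint graph."""

    vertices: frozenset
    n_edges: int
    kind: str  # 'cycle' or 'path'

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def odd(self) -> bool:
        return self.kind == PATH and self.n_vertices % 2 == 1


@dataclass(frozen=True)
class BreakpointGraph:
    """Edge-colored multigraph over extremities plus its component decomposition."""

    graph: nx.MultiGraph
    components: tuple[Component, ...]
    n_genes: int

    @property
    def n_cycles(self) -> int:
        return sum(1 for c in self.components if c.kind == CYCLE)

    @property
    def n_odd_paths(self) -> int:
        return sum(1 for c in self.components if c.odd)

    def component_of(self, x) -> Component:
        for c in self.components:
            if x in c.vertices:
                return c
        raise GenomeError(f"{x} is not a vertex of this breakpoint graph")


def breakpoint_graph(genomes: Sequence[Genome]) -> BreakpointGraph:
    """Breakpoint graph of two or more genomes on the same genes.

    Components are classified as cycles (as many edges as vertices) or paths
    and returned in deterministic order (smallest extremity first).
    """
    if len(genomes) < 2:
        raise GenomeError("a breakpoint graph needs at least two genomes")
    n = genomes[0].n_genes
    if any(g.n_genes != n for g in genomes):
        raise GenomeError("all genomes must be on the same number of genes")
    g = nx.MultiGraph()
    g.add_nodes_from(genomes[0].extremities())
    for label, genome in enumerate(genomes):
        for a in genome.adjacencies:
            g.add_edge(a.first, a.second, genome=label, adjacency=a)
    comps = []
    for nodes in sorted(nx.connected_components(g), key=lambda c: min(c)._key()):
        n_edges = g.subgraph(nodes).number_of_edges()
        kind = CYCLE if n_edges == len(nodes) else PATH
        comps.append(Component(frozenset(nodes), n_edges, kind))
    return BreakpointGraph(g, tuple(comps), n)


def dcj_distance(G1: Genome, G2: Genome) -> int:
    """DCJ distance ``n - c - p/2`` from the two-genome breakpoint graph."""
    b = breakpoint_graph([G1, G2])
    p = b.n_odd_paths
    assert p % 2 == 0, "odd-vertex paths pair up in a two-genome breakpoint graph"
    return b.n_genes - b.n_cycles - p // 2


def dcj_neighbors(G: Genome) -> list[Genome]:
    """All genomes one DCJ move away from ``G`` (deduplicated, sorted).

    Moves: cut two adjacencies and rejoin either way; cut one adjacency and
    rejoin one side to a telomere; split an adjacency into two telomeres; and
    join two telomeres into an adjacency.
    """
    results: set[frozenset[Adjacency]] = set()
    adjacencies = sorted(G.adjacencies)
    telomeres = sorted(G.telomeres)

    def add(removed: Iterable[Adjacency], added: Iterable[Adjacency]) -> None:
        results.add(G.adjacencies - set(removed) | set(added))

    for a1, a2 in itertools.combinations(adjacencies, 2):
        p, q = a1.first, a1.second
        r, s = a2.first, a2.second
        add([a1, a2], [Adjacency(p, r), Adjacency(q, s)])
        add([a1, a2], [Adjacency(p, s), Adjacency(q, r)])
    for a in adjacencies:
        for t in telomeres:
            add([a], [Adjacency(a.first, t)])
            add([a], [Adjacency(a.second, t)])
        add([a], [])  # split into two telomeres
    for t1, t2 in itertools.combinations(telomeres, 2):
        add([], [Adjacency(t1, t2)])
    results.discard(G.adjacencies)
    return [Genome(G.n_genes, s) for s in sorted(results, key=lambda s: sorted(s))]


def dcj_bfs_distance(G1: Genome, G2: Genome, max_genes: int = 4) -> int:
    """Shortest DCJ move count by breadth-first search (independent oracle).

    Guarded to tiny instances: the state space is every matching on 2n
    extremities.
    """
    if G1.n_genes != G2.n_genes:
        raise GenomeError("genomes must be on the same number of genes")
    if G1.n_genes > max_genes:
        raise GenomeError(f"BFS oracle restricted to n <= {max_genes} genes")
    start, goal = G1.adjacencies, G2.adjacencies
    if start == goal:
        return 0
    seen = {start}
    queue = deque([(start, 0)])
    while queue:
        state, d = queue.popleft()
        for nb in dcj_neighbors(Genome(G1.n_genes, state)):
            s = nb.adjacencies
            if s == goal:
                return d + 1
            if s not in seen:
                seen.add(s)
                queue.append((s, d + 1))
    raise AssertionError("DCJ move graph is connected; unreachable")
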