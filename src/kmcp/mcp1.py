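"""Exact single-genome completion (1-MCP) under the DCJ distance.

Given a partial genome ``G`` (a matching missing some adjacencies) and a
reference genome ``A`` on the same genes, the minimum completion problem asks
for a completion of ``G`` — a genome containing it and satisfying a chromosomal
condition set — at minimum DCJ distance from ``A``.  Three condition sets have
exact solvers, each linear-time in the number of genes:

* unrestricted (:func:`complete_unrestricted`) — close every breakpoint-graph
  path whose two terminal edges are reference adjacencies;
* circular uni-chromosomal (:func:`complete_circular`) — a greedy pass over
  the *free-extremities graph*;
* linear uni-chromosomal (:func:`complete_linear`) — reduce to the circular
  case by closing the reference into a circle, then reopen the result, using
  the correction term :func:`theta`.

The free-extremities graph ``R(G, A)`` is a bicolored multigraph on the free
extremities of ``G``: a *blue* (desired) edge joins the endpoints of each path
of the breakpoint graph B(G, A) — adding that pair as an adjacency closes a
breakpoint cycle — and a *red* (excluded) edge joins the endpoints of each
path of the augmented genome graph of ``G`` — adding that pair closes a
chromosome.  For a circular reference both edge sets are perfect matchings on
the free extremities, so every component of ``R`` is an even cycle alternating
blue and red (parallel blue/red edges form 2-cycles).  With ``N_b`` blue edges
and ``c`` cycles, the maximum number of cycle-closing (blue-edge) updates is
``N_b - c + 1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .dcj import CYCLE, PATH, BreakpointGraph, breakpoint_graph
from .genomes import (
    CIRCULAR_UNI,
    LINEAR_UNI,
    Adjacency,
    Extremity,
    Genome,
    GenomeError,
    augmented_graph,
    is_completable,
    satisfies,
)


class CompletionError(GenomeError):
    """Raised when no completion satisfying the requested conditions exists."""


class IllegalUpdateError(GenomeError):
    """Raised by an update that would close a premature circular chromosome."""


# ---------------------------------------------------------------------------
# Free-extremities graph
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FreeExtremitiesGraph:
    """Bicolored graph on the free extremities of a partial genome.

    ``blue`` and ``red`` are partner maps (each a perfect matching stored in
    both directions).  ``cycle_gain`` counts breakpoint cycles closed by the
    blue-edge updates performed so far.
    """

    vertices: frozenset[Extremity]
    blue: dict[Extremity, Extremity] = field(compare=False)
    red: dict[Extremity, Extremity] = field(compare=False)
    cycle_gain: int = 0

    def __post_init__(self) -> None:
        for name, matching in (("blue", self.blue), ("red", self.red)):
            if set(matching) != set(self.vertices):
                raise GenomeError(f"{name} edges must form a perfect matching on the vertices")
            for u, v in matching.items():
                if matching[v] != u or u == v:
                    raise GenomeError(f"{name} edges must form a perfect matching on the vertices")

    # -- structure ---------------------------------------------------------
    @property
    def n_blue(self) -> int:
        return len(self.vertices) // 2

    def blue_edges(self) -> list[Adjacency]:
        return sorted({Adjacency(u, v) for u, v in self.blue.items()})

    def red_edges(self) -> list[Adjacency]:
        return sorted({Adjacency(u, v) for u, v in self.red.items()})

    def cycles(self) -> list[list[Extremity]]:
        """Alternating blue/red cycles, each starting at its smallest vertex."""
        seen: set[Extremity] = set()
        out = []
        for start in sorted(self.vertices):
            if start in seen:
                continue
            cycle = [start]
            seen.add(start)
            v, use_blue = start, True
            while True:
                v = self.blue[v] if use_blue else self.red[v]
                use_blue = not use_blue
                if v == start:
                    break
                cycle.append(v)
                seen.add(v)
            out.append(cycle)
        return out

    @property
    def n_cycles(self) -> int:
        return len(self.cycles())

    def cycle_index(self) -> dict[Extremity, int]:
        return {v: i for i, cyc in enumerate(self.cycles()) for v in cyc}

    # -- the update transformation ------------------------------------------
    def update(self, u: Extremity, v: Extremity) -> "FreeExtremitiesGraph":
        """Record the effect of adding adjacency {u, v} to the partial genome.

        ``u`` and ``v`` leave the vertex set; their incident blue edges merge
        into one blue edge — or, if they are the same edge, a breakpoint cycle
        is closed and ``cycle_gain`` increments — and their incident red edges
        merge likewise.  Merging a red edge with itself closes a chromosome,
        which is only legal when ``u`` and ``v`` are the last two vertices.
        """
        if u == v or u not in self.vertices or v not in self.vertices:
            raise GenomeError("update needs two distinct vertices of the graph")
        gain = self.cycle_gain
        blue = dict(self.blue)
        red = dict(self.red)
        bu, bv = blue.pop(u), blue.pop(v)
        if bu == v:  # same blue edge: the breakpoint paths close into a cycle
            gain += 1
        else:
            blue[bu], blue[bv] = bv, bu
        ru, rv = red.pop(u), red.pop(v)
        if ru == v:  # same red edge: the chromosome paths close into a cycle
            if self.vertices - {u, v}:
                raise IllegalUpdateError(
                    f"adding {{{u},{v}}} closes a circular chromosome while free "
                    "extremities remain; the completion could not be uni-chromosomal"
                )
        else:
            red[ru], red[rv] = rv, ru
        return FreeExtremitiesGraph(self.vertices - {u, v}, blue, red, gain)


def free_extremities_graph(G: Genome, A: Genome) -> FreeExtremitiesGraph:
    """Build R(G, A) for a partial genome ``G`` and *circular* reference ``A``."""
    if G.n_genes != A.n_genes:
        raise GenomeError("partial genome and reference must share the same genes")
    if not A.is_circular():
        raise GenomeError("the reference must be circular: its adjacencies must form "
                          "a perfect matching on the extremities")
    free = G.telomeres
    if not free:
        raise GenomeError("the partial genome has no free extremities")

    def endpoint_matching(graph) -> dict[Extremity, Extremity]:
        matching: dict[Extremity, Extremity] = {}
        for nodes in nx.connected_components(graph):
            sub = graph.subgraph(nodes)
            ends = sorted(x for x in nodes if sub.degree(x) <= 1)
            if not ends:
                continue  # cycle component: no free endpoints
            assert len(ends) == 2 and all(e in free for e in ends)
            matching[ends[0]] = ends[1]
            matching[ends[1]] = ends[0]
        return matching

    blue = endpoint_matching(breakpoint_graph([G, A]).graph)
    red = endpoint_matching(augmented_graph(G))
    return FreeExtremitiesGraph(frozenset(free), blue, red)


def max_blue_updates(R: FreeExtremitiesGraph) -> int:
    """Maximum number of blue-edge (cycle-closing) updates: ``N_b - c + 1``."""
    return R.n_blue - R.n_cycles + 1


# ---------------------------------------------------------------------------
# Solvers
# ---------------------------------------------------------------------------

def complete_unrestricted(G: Genome, A: Genome) -> Genome:
    """Optimal unrestricted completion of ``G`` against reference ``A``.

    Adds one closing adjacency per breakpoint-graph path whose first and last
    edges are both reference adjacencies; all other free extremities stay
    telomeres.  The result minimizes the DCJ distance to ``A`` over every
    matching extension of ``G``.
    """
    if G.n_genes != A.n_genes:
        raise GenomeError("partial genome and reference must share the same genes")
    b = breakpoint_graph([G, A])
    g = b.graph
    added: list[Adjacency] = []
    for comp in b.components:
        if comp.kind != PATH or comp.n_edges == 0:
            continue
        sub = g.subgraph(comp.vertices)
        x, y = sorted(v for v in comp.vertices if sub.degree(v) == 1)
        # terminal edges of the path: both must be reference adjacencies
        if all(label == 1 for end in (x, y)
               for _, _, label in sub.edges(end, data="genome")):
            added.append(Adjacency(x, y))
    return G.with_adjacencies(added)


def complete_circular(G: Genome, A: Genome) -> Genome:
    """Optimal circular uni-chromosomal completion (greedy over R(G, A)).

    Repeatedly adds adjacencies: first pairs of vertices from different cycles
    of ``R`` (merging them), then blue edges (each closing a breakpoint
    cycle), and finally the single remaining excluded edge, which closes the
    one circular chromosome.  Ties are broken by the lexicographically
    smallest eligible pair, so the output is deterministic.  The result
    maximizes the breakpoint-cycle count c(., A) — equivalently minimizes the
    DCJ distance to ``A`` — over all circular uni-chromosomal completions.
    """
    if G.n_genes != A.n_genes:
        raise GenomeError("partial genome and reference must share the same genes")
    if not A.is_circular():
        raise GenomeError("the reference must be circular")
    if satisfies(G, CIRCULAR_UNI):
        return G
    if not is_completable(G, CIRCULAR_UNI):
        raise CompletionError("partial genome has a circular chromosome that is not "
                              "the whole genome; no circular uni-chromosomal completion")
    R = free_extremities_graph(G, A)
    added: list[Adjacency] = []
    while R.n_cycles > 1:
        index = R.cycle_index()
        u = min(R.vertices)
        v = min(x for x in R.vertices if index[x] != index[u])
        added.append(Adjacency(u, v))
        R = R.update(u, v)
    while R.n_blue > 1:
        u = min(R.vertices)
        v = R.blue[u]
        added.append(Adjacency(u, v))
        R = R.update(u, v)
    # the last two free extremities carry the final excluded (and blue) edge
    u = min(R.vertices)
    added.append(Adjacency(u, R.red[u]))
    Gc = G.with_adjacencies(added)
    assert satisfies(Gc, CIRCULAR_UNI)
    return Gc


def theta(G: Genome, A_c: Genome, e: Adjacency) -> int:
    """Correction term relating circular and linear completions.

    ``theta(e)`` is 2 if the reference adjacency ``e`` lies on a cycle
    component of the breakpoint graph B(G, A_c), and 1 otherwise.  It equals
    the gap between the best circular and best linear uni-chromosomal
    breakpoint-cycle counts when ``e`` is the adjacency removed from ``A_c``.
    """
    if e not in A_c.adjacencies:
        raise GenomeError(f"{e} is not an adjacency of the circular reference")
    b = breakpoint_graph([G, A_c])
    return 2 if b.component_of(e.first).kind == CYCLE else 1


def _cycle_of_edge(b: BreakpointGraph, e: Adjacency) -> frozenset[Extremity]:
    comp = b.component_of(e.first)
    return comp.vertices


def complete_linear(G: Genome, A_l: Genome) -> Genome:
    """Optimal linear uni-chromosomal completion via the circular solver.

    The linear reference's two telomeres define its excluded edge ``e``;
    adding ``e`` yields a circular reference ``A_c``.  The circular optimum is
    then reopened: when ``theta(e) = 1`` remove an *added* adjacency sharing
    e's breakpoint cycle in B(Gc, A_c); when ``theta(e) = 2`` remove the
    smallest added adjacency.  The result attains the optimal cycle count
    ``c_circ - theta(e)`` against ``A_l``.
    """
    if G.n_genes != A_l.n_genes:
        raise GenomeError("partial genome and reference must share the same genes")
    if not satisfies(A_l, LINEAR_UNI):
        raise GenomeError("the reference must be a linear uni-chromosomal genome")
    if satisfies(G, LINEAR_UNI):
        return G
    if not is_completable(G, LINEAR_UNI):
        raise CompletionError("partial genome has a circular chromosome; "
                              "no linear uni-chromosomal completion exists")
    t1, t2 = sorted(A_l.telomeres)
    e = Adjacency(t1, t2)
    A_c = A_l.with_adjacencies([e])
    Gc = complete_circular(G, A_c)
    added = sorted(Gc.adjacencies - G.adjacencies)
    assert added, "an incomplete partial genome always gains adjacencies"
    if theta(G, A_c, e) == 1:
        cycle = _cycle_of_edge(breakpoint_graph([Gc, A_c]), e)
        f = next(a for a in added if a.first in cycle)
    else:
        f = added[0]
    Gl = Gc.without_adjacency(f)
    assert satisfies(Gl, LINEAR_UNI)
    return Gl
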