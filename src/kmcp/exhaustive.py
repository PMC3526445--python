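"""Exhaustive enumeration oracles for tiny instances.

These brute-force routines exist to certify the linear-time solvers and the
edge-coloring machinery on small inputs; they enumerate complete solution
spaces and are guarded against anything but tiny problem sizes.
"""

from __future__ import annotations

from typing import Iterable, Iterator, Sequence

from .dcj import breakpoint_graph
from .genomes import Adjacency, Extremity, Genome, GenomeError, satisfies
from .mcp1 import FreeExtremitiesGraph, IllegalUpdateError


def all_matchings(vertices: Sequence[Extremity]) -> Iterator[frozenset[Adjacency]]:
    """Every matching (including partial and empty) on the given vertices."""
    vertices = sorted(vertices)

    def rec(rest: tuple[Extremity, ...]) -> Iterator[frozenset[Adjacency]]:
        if not rest:
            yield frozenset()
            return
        v, others = rest[0], rest[1:]
        for sub in rec(others):  # v left unmatched
            yield sub
        for i, u in enumerate(others):
            pair = Adjacency(v, u)
            for sub in rec(others[:i] + others[i + 1:]):
                yield sub | {pair}

    return rec(tuple(vertices))


def all_perfect_matchings(vertices: Sequence[Extremity]) -> Iterator[frozenset[Adjacency]]:
    vertices = sorted(vertices)
    if len(vertices) % 2:
        return iter(())

    def rec(rest: tuple[Extremity, ...]) -> Iterator[frozenset[Adjacency]]:
        if not rest:
            yield frozenset()
            return
        v, others = rest[0], rest[1:]
        for i, u in enumerate(others):
            pair = Adjacency(v, u)
            for sub in rec(others[:i] + others[i + 1:]):
                yield sub | {pair}

    return rec(tuple(vertices))


def enumerate_completions(G: Genome, conditions: Iterable[str],
                          max_free: int = 10) -> Iterator[Genome]:
    """All completions of ``G`` satisfying the chromosomal conditions.

    Enumerates every matching over the free extremities and filters by
    :func:`~kmcp.genomes.satisfies`.  Guarded by ``max_free``.
    """
    free = sorted(G.telomeres)
    if len(free) > max_free:
        raise GenomeError(f"completion enumeration restricted to <= {max_free} free extremities")
    flags = frozenset(conditions)
    for extra in all_matchings(free):
        cand = G.with_adjacencies(extra)
        if satisfies(cand, flags):
            yield cand


def best_completion_cycles(G: Genome, A: Genome, conditions: Iterable[str]) -> int:
    """Maximum breakpoint-cycle count c(., A) over all enumerated completions."""
    best = None
    for cand in enumerate_completions(G, conditions):
        c = breakpoint_graph([cand, A]).n_cycles
        best = c if best is None else max(best, c)
    if best is None:
        raise GenomeError("no completion satisfies the requested conditions")
    return best


def max_blue_updates_exhaustive(R: FreeExtremitiesGraph) -> int:
    """Maximum blue-edge updates over every legal complete update sequence.

    Independent check of the closed form N_b - c + 1: tries every order of
    vertex pairs, counting updates whose pair is a blue edge, and takes the
    maximum over sequences that empty the graph.
    """
    if not R.vertices:
        return R.cycle_gain

    best = -1
    verts = sorted(R.vertices)
    for i, u in enumerate(verts):
        for v in verts[i + 1:]:
            try:
                nxt = R.update(u, v)
            except IllegalUpdateError:
                continue
            best = max(best, max_blue_updates_exhaustive(nxt))
    if best < 0:
        raise GenomeError("no legal update sequence empties the graph")
    return best
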