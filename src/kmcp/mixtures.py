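"""Genome mixtures: k-completions, edge coloring, mixture trees, exact k-MCP.

A partial multi-genome ``M`` (a multiset of adjacencies with unknown genome of
origin) has an unrestricted k-completion exactly when its genome graph admits
a proper edge coloring with k colors — each color class is a matching, hence a
partial genome, and any completion of the classes covers ``M``.  Deciding
chromatic index is NP-complete for maximum degree >= 3, so the k-MCP is
solved here only exhaustively on tiny instances: minimize, over every proper
k-edge-coloring, every condition-satisfying completion of each class, and
every labeled mixture tree rooted at the reference, the sum of pairwise
distances along the tree edges.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Callable, Iterable, Iterator, Optional, Sequence

import networkx as nx

from .dcj import dcj_distance
from .exhaustive import enumerate_completions
from .genomes import (
    UNRESTRICTED,
    Adjacency,
    Genome,
    GenomeError,
    PartialMultiGenome,
    validate_conditions,
)

#: Result statuses for the k-completion existence test.
YES = "yes"
NO = "no"
UNDECIDED = "undecided"


class NoValidSolutionError(GenomeError):
    """Raised when a mixture admits no k-completion under the given conditions."""


def genome_graph(M: PartialMultiGenome) -> nx.MultiGraph:
    """Multigraph on all extremities with one edge per adjacency occurrence."""
    g = nx.MultiGraph()
    g.add_nodes_from(Genome(M.n_genes).extremities())
    for a, mult in M.counts:
        for _ in range(mult):
            g.add_edge(a.first, a.second, adjacency=a)
    return g


# ---------------------------------------------------------------------------
# Edge coloring
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EdgeColoringResult:
    """Outcome of the chromatic-index test.

    ``status`` is ``'yes'``, ``'no'`` or ``'undecided'`` (search guard
    exceeded and the degree bound did not decide).  On ``'yes'``,
    ``classes`` holds one adjacency list per color (each a matching).
    """

    status: str
    classes: Optional[tuple[tuple[Adjacency, ...], ...]] = None

    def __bool__(self) -> bool:
        return self.status == YES


def _edges_by_degree(g: nx.MultiGraph) -> list[tuple]:
    deg = dict(g.degree())
    edges = list(g.edges(data="adjacency"))
    edges.sort(key=lambda e: (-(deg[e[0]] + deg[e[1]]), e[2]))
    return edges


def chromatic_index_at_most(g: nx.MultiGraph, k: int, max_edges: int = 32) -> EdgeColoringResult:
    """Exact decision: can the edges of ``g`` be properly colored with k colors?

    A proper edge coloring gives no vertex two incident edges of one color.
    Since the chromatic index is at least the maximum degree, ``Delta > k``
    decides negatively at any size; otherwise a backtracking search over edges
    (largest-degree-first, with color-symmetry breaking) answers exactly up to
    ``max_edges`` edges, and the result is ``'undecided'`` beyond the guard —
    never a guess.
    """
    if k < 1:
        raise GenomeError("k must be a positive integer")
    if g.number_of_edges() == 0:
        return EdgeColoringResult(YES, tuple(() for _ in range(k)))
    if max(dict(g.degree()).values()) > k:
        return EdgeColoringResult(NO)
    if g.number_of_edges() > max_edges:
        return EdgeColoringResult(UNDECIDED)

    edges = _edges_by_degree(g)
    vertex_colors: dict = {v: set() for v in g.nodes}
    assignment: list[int] = []

    def backtrack(i: int, used: int) -> bool:
        if i == len(edges):
            return True
        u, v, _ = edges[i]
        for color in range(min(used + 1, k)):
            if color in vertex_colors[u] or color in vertex_colors[v]:
                continue
            vertex_colors[u].add(color)
            vertex_colors[v].add(color)
            assignment.append(color)
            if backtrack(i + 1, max(used, color + 1)):
                return True
            assignment.pop()
            vertex_colors[u].remove(color)
            vertex_colors[v].remove(color)
        return False

    if not backtrack(0, 0):
        return EdgeColoringResult(NO)
    classes: list[list[Adjacency]] = [[] for _ in range(k)]
    for (u, v, a), color in zip(edges, assignment):
        classes[color].append(a)
    return EdgeColoringResult(YES, tuple(tuple(sorted(c)) for c in classes))


def enumerate_colorings(g: nx.MultiGraph, k: int) -> Iterator[tuple[frozenset[Adjacency], ...]]:
    """All distinct partitions of the edges into at most k matchings.

    Color classes are unordered: partitions differing only by a permutation of
    colors are yielded once.  Intended for tiny instances (exhaustive search).
    """
    edges = _edges_by_degree(g)
    if not edges:
        yield tuple(frozenset() for _ in range(k))
        return
    if max(dict(g.degree()).values()) > k:
        return
    vertex_colors: dict = {v: set() for v in g.nodes}
    assignment: list[int] = []
    seen: set = set()

    def rec(i: int, used: int) -> Iterator[tuple[frozenset[Adjacency], ...]]:
        if i == len(edges):
            classes = [set() for _ in range(k)]
            for (u, v, a), color in zip(edges, assignment):
                classes[color].add(a)
            part = tuple(sorted((frozenset(c) for c in classes), key=lambda s: sorted(s)))
            if part not in seen:
                seen.add(part)
                yield part
            return
        u, v, _ = edges[i]
        for color in range(min(used + 1, k)):
            if color in vertex_colors[u] or color in vertex_colors[v]:
                continue
            vertex_colors[u].add(color)
            vertex_colors[v].add(color)
            assignment.append(color)
            yield from rec(i + 1, max(used, color + 1))
            assignment.pop()
            vertex_colors[u].remove(color)
            vertex_colors[v].remove(color)

    yield from rec(0, 0)


def k_completion(M: PartialMultiGenome, k: int) -> list[Genome]:
    """An unrestricted k-completion of the mixture, if one exists.

    The witness color classes of the chromatic-index test are promoted to
    genomes (a matching is already an unrestricted genome); their multiset
    union contains ``M``.
    """
    result = chromatic_index_at_most(genome_graph(M), k)
    if result.status == NO:
        raise NoValidSolutionError(f"mixture has no {k}-completion: chromatic index exceeds {k}")
    if result.status == UNDECIDED:
        raise GenomeError("instance too large for the exact edge-coloring search")
    return [Genome(M.n_genes, frozenset(c)) for c in result.classes]


# ---------------------------------------------------------------------------
# Mixture trees
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MixtureTree:
    """Rooted tree on the reference (vertex 0) and genomes 1..k.

    ``parents[i-1]`` is the parent of genome ``i``; parent 0 is the reference.
    """

    parents: tuple[int, ...]

    def __post_init__(self) -> None:
        k = len(self.parents)
        g = nx.Graph(self.edges())
        if g.number_of_nodes() != k + 1 or not nx.is_tree(g):
            raise GenomeError(f"parent list {self.parents} does not describe a tree on 0..{k}")

    @property
    def k(self) -> int:
        return len(self.parents)

    def edges(self) -> list[tuple[int, int]]:
        return [(p, i + 1) for i, p in enumerate(self.parents)]

    def is_path_tree(self) -> bool:
        """True iff the reference has a single child (the tree is a path below A)."""
        degree = [0] * (self.k + 1)
        for u, v in self.edges():
            degree[u] += 1
            degree[v] += 1
        return degree[0] == 1 and all(d <= 2 for d in degree)


def phi_value(tree: MixtureTree, genomes: Sequence[Genome],
              phi: Callable[[Genome, Genome], float] = dcj_distance) -> float:
    """Sum of pairwise distances over the tree edges.

    ``genomes[0]`` is the reference at the root; ``genomes[i]`` sits at
    vertex ``i``.
    """
    if len(genomes) != tree.k + 1:
        raise GenomeError("need one genome per tree vertex (reference first)")
    return sum(phi(genomes[u], genomes[v]) for u, v in tree.edges())


def enumerate_mixture_trees(k: int, max_k: int = 4) -> list[MixtureTree]:
    """All labeled trees on {reference, G_1..G_k}, via Pruefer sequences.

    There are (k+1)^(k-1) of them; for k = 2 the three trees cover the branch
    topology and the two orientations of the path topology.
    """
    if not 1 <= k <= max_k:
        raise GenomeError(f"tree enumeration restricted to 1 <= k <= {max_k}")
    if k == 1:
        return [MixtureTree((0,))]
    trees = []
    for seq in itertools.product(range(k + 1), repeat=k - 1):
        t = nx.from_prufer_sequence(list(seq))
        parents = [0] * k
        for child, parent in nx.bfs_predecessors(t, 0):
            parents[child - 1] = parent
        trees.append(MixtureTree(tuple(parents)))
    return trees


# ---------------------------------------------------------------------------
# Exact k-MCP on tiny instances
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KMCPSolution:
    genomes: tuple[Genome, ...]  # the k completed genomes, G_1..G_k
    tree: MixtureTree
    value: float


def brute_force_kmcp(M: PartialMultiGenome, A: Genome, k: int,
                     conditions: Iterable[str] = UNRESTRICTED,
                     phi: Callable[[Genome, Genome], float] | None = None,
                     max_genes: int = 3, max_k: int = 3) -> KMCPSolution:
    """Exhaustive minimum over colorings x completions x mixture trees.

    Enumerates every partition of the mixture's edges into at most k
    matchings, every completion of each class satisfying ``conditions``, and
    every labeled mixture tree, returning a solution of minimum phi-value
    (DCJ distance by default).  Guarded to tiny instances via ``max_genes`` /
    ``max_k``; callers may widen the guard knowingly, e.g. for mixture graphs
    made of disjoint even cycles whose color classes are already complete.

    Raises :class:`NoValidSolutionError` when no k-completion exists.
    """
    validate_conditions(conditions)
    if M.n_genes != A.n_genes:
        raise GenomeError("mixture and reference must share the same genes")
    if M.n_genes > max_genes:
        raise GenomeError(f"brute force restricted to n <= {max_genes} genes")
    if k > max_k:
        raise GenomeError(f"brute force restricted to k <= {max_k}")

    if phi is None:
        phi = dcj_distance
    cache: dict[tuple[frozenset, frozenset], float] = {}

    def dist(g1: Genome, g2: Genome) -> float:
        key = (g1.adjacencies, g2.adjacencies)
        rkey = (key[1], key[0])
        if key not in cache:
            cache[key] = cache[rkey] = phi(g1, g2)
        return cache[key]

    trees = enumerate_mixture_trees(k, max_k=max(k, 4))
    best: Optional[KMCPSolution] = None
    found_completion = False
    for classes in enumerate_colorings(genome_graph(M), k):
        partials = [Genome(M.n_genes, c) for c in classes]
        options = [list(enumerate_completions(p, conditions, max_free=2 * M.n_genes))
                   for p in partials]
        if any(not opts for opts in options):
            continue
        found_completion = True
        for combo in itertools.product(*options):
            genomes = (A,) + combo
            for tree in trees:
                value = sum(dist(genomes[u], genomes[v]) for u, v in tree.edges())
                if best is None or value < best.value:
                    best = KMCPSolution(combo, tree, value)
    if best is None:
        reason = ("no proper edge coloring with k colors"
                  if not found_completion else "no completion satisfies the conditions")
        raise NoValidSolutionError(f"mixture has no valid {k}-completion: {reason}")
    return best
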