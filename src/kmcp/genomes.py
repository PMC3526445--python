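"""Core data model: genes, extremities, adjacencies, genomes and chromosomes.

A gene is an oriented segment with two extremities, a *tail* ``g_t`` and a
*head* ``g_h``.  An adjacency is an unordered pair of distinct extremities; a
genome on ``n`` genes is a set of adjacencies in which every extremity occurs
at most once (a matching on the 2n extremities).  Extremities matched by no
adjacency are telomeres.  The *augmented genome graph* adds one edge per gene
joining its two extremities; its connected components are the chromosomes
(cycle components are circular chromosomes, path components linear ones).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from functools import total_ordering
from typing import Iterable, Iterator

import networkx as nx

TAIL = "t"
HEAD = "h"

#: Chromosomal condition flags.
CIRCULAR = "circular"
LINEAR = "linear"
UNICHROMOSOMAL = "uni-chromosomal"

#: The three condition sets with dedicated completion machinery.
UNRESTRICTED: frozenset[str] = frozenset()
CIRCULAR_UNI: frozenset[str] = frozenset({CIRCULAR, UNICHROMOSOMAL})
LINEAR_UNI: frozenset[str] = frozenset({LINEAR, UNICHROMOSOMAL})

_VALID_FLAGS = {CIRCULAR, LINEAR, UNICHROMOSOMAL}


class GenomeError(ValueError):
    """Raised for malformed genomes, adjacencies or condition sets."""


@total_ordering
@dataclass(frozen=True)
class Extremity:
    """One end of an oriented gene: ``Extremity(3, 'h')`` is the head of gene 3."""

    gene: int
    end: str

    def __post_init__(self) -> None:
        if self.gene < 1:
            raise GenomeError(f"gene identifiers are positive integers, got {self.gene}")
        if self.end not in (TAIL, HEAD):
            raise GenomeError(f"extremity end must be '{TAIL}' or '{HEAD}', got {self.end!r}")

    # tail sorts before head so iteration order matches gene orientation
    def _key(self) -> tuple[int, int]:
        return (self.gene, 0 if self.end == TAIL else 1)

    def __lt__(self, other: "Extremity") -> bool:
        return self._key() < other._key()

    @property
    def mate(self) -> "Extremity":
        """The other extremity of the same gene."""
        return Extremity(self.gene, HEAD if self.end == TAIL else TAIL)

    @property
    def token(self) -> str:
        return f"{self.gene}{self.end}"

    @classmethod
    def from_token(cls, token: str) -> "Extremity":
        token = token.strip()
        if len(token) < 2 or token[-1] not in (TAIL, HEAD) or not token[:-1].isdigit():
            raise GenomeError(f"malformed extremity token {token!r}")
        return cls(int(token[:-1]), token[-1])

    def __repr__(self) -> str:
        return self.token


def ext(token: str) -> Extremity:
    """Shorthand constructor: ``ext('1h')``."""
    return Extremity.from_token(token)


@total_ordering
@dataclass(frozen=True)
class Adjacency:
    """An unordered pair of distinct extremities, stored smaller-first."""

    first: Extremity
    second: Extremity

    def __post_init__(self) -> None:
        if self.first == self.second:
            raise GenomeError(f"adjacency cannot pair an extremity with itself: {self.first}")
        if self.second < self.first:
            a, b = self.second, self.first
            object.__setattr__(self, "first", a)
            object.__setattr__(self, "second", b)

    def __iter__(self) -> Iterator[Extremity]:
        yield self.first
        yield self.second

    def __contains__(self, item: object) -> bool:
        return item == self.first or item == self.second

    def other(self, x: Extremity) -> Extremity:
        if x == self.first:
            return self.second
        if x == self.second:
            return self.first
        raise GenomeError(f"{x} is not an endpoint of {self}")

    def _key(self) -> tuple:
        return (self.first._key(), self.second._key())

    def __lt__(self, other: "Adjacency") -> bool:
        return self._key() < other._key()

    def __repr__(self) -> str:
        return f"{{{self.first},{self.second}}}"


def adj(a: str, b: str) -> Adjacency:
    """Shorthand constructor: ``adj('1h', '3h')``."""
    return Adjacency(ext(a), ext(b))


def validate_conditions(conditions: Iterable[str]) -> frozenset[str]:
    flags = frozenset(conditions)
    unknown = flags - _VALID_FLAGS
    if unknown:
        raise GenomeError(f"unknown chromosomal condition(s): {sorted(unknown)}")
    if CIRCULAR in flags and LINEAR in flags:
        raise GenomeError("'circular' and 'linear' are mutually exclusive conditions")
    return flags


@dataclass(frozen=True)
class Chromosome:
    """One connected component of the augmented genome graph."""

    extremities: frozenset[Extremity]
    kind: str  # 'linear' or 'circular'

    @property
    def genes(self) -> frozenset[int]:
        return frozenset(x.gene for x in self.extremities)


@dataclass(frozen=True)
class Genome:
    """A genome (or, viewed as such, a partial genome): a matching on extremities.

    ``adjacencies`` must never place an extremity in two pairs, and every
    referenced gene must lie in ``1..n_genes``.
    """

    n_genes: int
    adjacencies: frozenset[Adjacency] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise GenomeError("a genome needs at least one gene")
        object.__setattr__(self, "adjacencies", frozenset(self.adjacencies))
        seen: set[Extremity] = set()
        for a in self.adjacencies:
            for x in a:
                if x.gene > self.n_genes:
                    raise GenomeError(f"extremity {x} out of range for {self.n_genes} genes")
                if x in seen:
                    raise GenomeError(f"extremity {x} occurs in more than one adjacency")
                seen.add(x)

    # -- basic structure ---------------------------------------------------
    def extremities(self) -> list[Extremity]:
        """All 2n extremities in canonical order."""
        return [Extremity(g, e) for g in range(1, self.n_genes + 1) for e in (TAIL, HEAD)]

    @property
    def telomeres(self) -> frozenset[Extremity]:
        matched = {x for a in self.adjacencies for x in a}
        return frozenset(x for x in self.extremities() if x not in matched)

    #: Free extremities of a partial genome coincide with its telomeres.
    free_extremities = telomeres

    def sorted_adjacencies(self) -> list[Adjacency]:
        return sorted(self.adjacencies)

    def is_circular(self) -> bool:
        """True iff every chromosome is circular, i.e. the matching is perfect."""
        return len(self.adjacencies) == self.n_genes

    def with_adjacencies(self, extra: Iterable[Adjacency]) -> "Genome":
        return Genome(self.n_genes, self.adjacencies | set(extra))

    def without_adjacency(self, a: Adjacency) -> "Genome":
        if a not in self.adjacencies:
            raise GenomeError(f"{a} is not an adjacency of this genome")
        return Genome(self.n_genes, self.adjacencies - {a})


@dataclass(frozen=True)
class PartialGenome(Genome):
    """A genome together with the condition set it is partial with respect to."""

    conditions: frozenset[str] = UNRESTRICTED

    def __post_init__(self) -> None:
        super().__post_init__()
        object.__setattr__(self, "conditions", validate_conditions(self.conditions))

    def is_completable(self) -> bool:
        return is_completable(self, self.conditions)


@dataclass(frozen=True)
class PartialMultiGenome:
    """A mixture: a multiset of adjacencies with unknown genome of origin.

    Unlike a genome, the multiset is unconstrained — the same extremity may
    occur in several adjacencies and the same adjacency several times, because
    the adjacencies come from different (unattributed) genomes.
    """

    n_genes: int
    counts: tuple[tuple[Adjacency, int], ...]

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise GenomeError("a multi-genome needs at least one gene")
        c = Counter()
        for a, m in self.counts:
            if m < 1:
                raise GenomeError("adjacency multiplicities must be positive")
            for x in a:
                if x.gene > self.n_genes:
                    raise GenomeError(f"extremity {x} out of range for {self.n_genes} genes")
            c[a] += m
        object.__setattr__(self, "counts", tuple(sorted(c.items())))

    @classmethod
    def from_adjacencies(cls, n_genes: int, adjacencies: Iterable[Adjacency]) -> "PartialMultiGenome":
        return cls(n_genes, tuple(Counter(adjacencies).items()))

    @classmethod
    def from_genomes(cls, genomes: Iterable[Genome]) -> "PartialMultiGenome":
        genomes = list(genomes)
        if not genomes:
            raise GenomeError("need at least one genome")
        n = genomes[0].n_genes
        if any(g.n_genes != n for g in genomes):
            raise GenomeError("all genomes in a mixture must share the same genes")
        return cls.from_adjacencies(n, (a for g in genomes for a in g.adjacencies))

    def multiset(self) -> Counter:
        return Counter(dict(self.counts))

    def adjacency_list(self) -> list[Adjacency]:
        """Adjacencies with multiplicity, in canonical order."""
        return [a for a, m in self.counts for _ in range(m)]

    @property
    def n_edges(self) -> int:
        return sum(m for _, m in self.counts)


# ---------------------------------------------------------------------------
# Construction and structural queries
# ---------------------------------------------------------------------------

def make_genome(n_genes: int, adjacencies: Iterable[Adjacency]) -> Genome:
    """Validated genome constructor (matching property, gene range)."""
    return Genome(n_genes, frozenset(adjacencies))


def augmented_graph(G: Genome) -> nx.MultiGraph:
    """Genome graph plus one edge per gene joining its two extremities."""
    g = nx.MultiGraph()
    g.add_nodes_from(G.extremities())
    for gene in range(1, G.n_genes + 1):
        g.add_edge(Extremity(gene, TAIL), Extremity(gene, HEAD), kind="gene")
    for a in G.adjacencies:
        g.add_edge(a.first, a.second, kind="adjacency")
    return g


def _component_kind(g: nx.MultiGraph, nodes: set) -> str:
    n_edges = g.subgraph(nodes).number_of_edges()
    return CIRCULAR if n_edges == len(nodes) else LINEAR


def chromosomes(G: Genome) -> list[Chromosome]:
    """Chromosomes of ``G`` in deterministic order (smallest extremity first).

    A component of the augmented genome graph is a cycle (circular chromosome)
    exactly when it has as many edges as vertices; otherwise it is a path.
    """
    g = augmented_graph(G)
    comps = sorted(nx.connected_components(g), key=lambda c: min(c)._key())
    return [Chromosome(frozenset(c), _component_kind(g, c)) for c in comps]


def satisfies(G: Genome, conditions: Iterable[str]) -> bool:
    """Does ``G`` meet every chromosomal condition in the set?"""
    flags = validate_conditions(conditions)
    if not flags:
        return True
    chroms = chromosomes(G)
    if UNICHROMOSOMAL in flags and len(chroms) != 1:
        return False
    if CIRCULAR in flags and any(c.kind != CIRCULAR for c in chroms):
        return False
    if LINEAR in flags and any(c.kind != LINEAR for c in chroms):
        return False
    return True


def is_completable(G: Genome, conditions: Iterable[str]) -> bool:
    """Can ``G`` be extended to a genome satisfying ``conditions``?

    Structural rules (each certified by a witness construction):

    * unrestricted — always (a partial genome is itself a genome);
    * ``{circular}`` — always (every path component of the augmented graph can
      be closed into its own circular chromosome);
    * ``{linear}`` / ``{linear, uni-chromosomal}`` — iff the augmented graph
      has no cycle component (a circular chromosome can never be re-opened by
      adding adjacencies; conversely all paths can be chained into one);
    * ``{circular, uni-chromosomal}`` — iff there is no cycle component, or
      ``G`` is already a single circular chromosome covering all genes.

    Other condition sets are rejected: completability is only defined here for
    the sets the completion machinery supports.
    """
    flags = validate_conditions(conditions)
    supported = {UNRESTRICTED, frozenset({CIRCULAR}), frozenset({LINEAR}),
                 CIRCULAR_UNI, LINEAR_UNI}
    if flags not in supported:
        raise GenomeError(f"completability undefined for condition set {sorted(flags)}")
    if not flags or flags == frozenset({CIRCULAR}):
        return True
    chroms = chromosomes(G)
    has_cycle = any(c.kind == CIRCULAR for c in chroms)
    if LINEAR in flags:
        return not has_cycle
    # {circular, uni-chromosomal}
    if not has_cycle:
        return True
    return satisfies(G, CIRCULAR_UNI)
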