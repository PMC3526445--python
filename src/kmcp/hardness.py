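"""Constructive hardness reductions: MAX 3-SAT -> MAX 3-AND -> 2-MCP.

MAX 3-AND asks for a truth assignment maximizing the number of fully
satisfied 3-literal conjunctions.  Each 3-clause expands into the seven
sign-pattern conjunctions that exclude the all-negated pattern
(:func:`expand_clause`); for any assignment at most one of the seven holds,
and one holds exactly when the clause does, so clause optima transfer.

A MAX 3-AND instance becomes a 2-MCP instance (:func:`build_gadget`): every
variable is an even cycle whose two perfect matchings encode true/false;
every 3-literal conjunction picks one host edge per literal (from the true
matching for a positive literal, the false matching for a negated one) and
closes them with three new *conjunction edges* into a 6-cycle that survives
exactly under satisfying assignments.  The variable-cycle edges form the
mixture (partial multi-genome), the conjunction edges the reference genome.
Padding with 3m+1 single-variable conjunctions — hence 3m+1 variable-cycles
untouched by conjunction edges — is the device used to force the optimal
mixture tree to be a path-tree.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .genomes import (
    HEAD,
    TAIL,
    Adjacency,
    Extremity,
    Genome,
    GenomeError,
    PartialMultiGenome,
)

PADDING_PREFIX = "_pad"


@dataclass(frozen=True)
class Literal:
    var: str
    positive: bool = True

    def holds(self, assignment: Mapping[str, bool]) -> bool:
        if self.var not in assignment:
            raise GenomeError(f"assignment is missing variable {self.var!r}")
        return assignment[self.var] == self.positive

    @property
    def negated(self) -> "Literal":
        return Literal(self.var, not self.positive)

    def __repr__(self) -> str:
        return self.var if self.positive else f"~{self.var}"


@dataclass(frozen=True)
class Conjunction:
    """A conjunction of three literals, or a single-literal padding conjunction."""

    literals: tuple[Literal, ...]

    def __post_init__(self) -> None:
        if len(self.literals) not in (1, 3):
            raise GenomeError("conjunctions have exactly three literals "
                              "(or one, for padding)")

    @property
    def variables(self) -> tuple[str, ...]:
        return tuple(l.var for l in self.literals)

    def satisfied_by(self, assignment: Mapping[str, bool]) -> bool:
        return all(l.holds(assignment) for l in self.literals)

    def __repr__(self) -> str:
        return " & ".join(map(repr, self.literals))


def expand_clause(clause: Sequence[Literal]) -> list[Conjunction]:
    """The seven conjunctions equivalent (as a disjunction) to a 3-clause.

    All eight sign patterns over the clause's literals except the one negating
    every literal.  For any assignment at most one of the seven is satisfied,
    and exactly one is satisfied iff the clause is.
    """
    if len(clause) != 3:
        raise GenomeError("a clause has exactly three literals")
    if len({l.var for l in clause}) != 3:
        raise GenomeError("clause literals must be over distinct variables")
    out = []
    for pattern in itertools.product((True, False), repeat=3):
        if pattern == (False, False, False):
            continue  # the all-negated pattern is excluded
        out.append(Conjunction(tuple(l if keep else l.negated
                                     for l, keep in zip(clause, pattern))))
    return out


def expand_instance(clauses: Iterable[Sequence[Literal]]) -> list[Conjunction]:
    """Expand a MAX 3-SAT instance clause by clause into MAX 3-AND form."""
    return [c for clause in clauses for c in expand_clause(clause)]


def max_assignment_score(conjunctions: Sequence[Conjunction],
                         max_vars: int = 16) -> tuple[int, dict[str, bool]]:
    """Exhaustive MAX 3-AND optimum over all assignments (tiny instances)."""
    variables = sorted({v for c in conjunctions for v in c.variables})
    if len(variables) > max_vars:
        raise GenomeError(f"exhaustive search restricted to <= {max_vars} variables")
    best, best_assign = -1, {}
    for values in itertools.product((False, True), repeat=len(variables)):
        assignment = dict(zip(variables, values))
        score = sum(c.satisfied_by(assignment) for c in conjunctions)
        if score > best:
            best, best_assign = score, assignment
    return best, best_assign


# ---------------------------------------------------------------------------
# The graphical representation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VariableCycle:
    """An even cycle encoding one variable; its two perfect matchings are the
    true and false assignments."""

    variable: str
    vertices: tuple[Extremity, ...]  # in cycle order
    true_matching: frozenset[Adjacency]
    false_matching: frozenset[Adjacency]

    @property
    def length(self) -> int:
        return len(self.vertices)

    @property
    def edges(self) -> frozenset[Adjacency]:
        return self.true_matching | self.false_matching


@dataclass(frozen=True)
class GadgetInstance:
    """A 2-MCP instance graphically representing a MAX 3-AND instance."""

    mixture: PartialMultiGenome          # all variable-cycle edges
    reference: Genome                    # all conjunction edges
    conjunctions: tuple[Conjunction, ...]  # input conjunctions then padding
    n_input: int                         # how many are input (the rest are padding)
    variable_cycles: Mapping[str, VariableCycle]
    conjunction_cycles: Mapping[int, frozenset[Adjacency]]  # index -> 6 edges

    @property
    def n_genes(self) -> int:
        return self.mixture.n_genes

    @property
    def padding_variables(self) -> tuple[str, ...]:
        return tuple(c.literals[0].var for c in self.conjunctions[self.n_input:])

    @property
    def variables(self) -> tuple[str, ...]:
        return tuple(self.variable_cycles)


def build_gadget(conjunctions: Sequence[Conjunction]) -> GadgetInstance:
    """Graphical representation of a MAX 3-AND instance, padded for 2-MCP.

    Adds 3m+1 fresh single-variable padding conjunctions (m = number of input
    conjunctions).  Each variable gets a cycle of length max(4t, 4), where t
    counts its literal occurrences in 3-literal conjunctions; the i-th
    occurrence is hosted in its own block of four consecutive cycle vertices,
    so no variable-cycle edge touches conjunction edges of two different
    conjunction-cycles.  Vertices are fresh extremities, two per new gene.
    """
    conjunctions = list(conjunctions)
    m = len(conjunctions)
    padding = [Conjunction((Literal(f"{PADDING_PREFIX}{i}"),))
               for i in range(3 * m + 1)]
    for c in conjunctions:
        for l in c.literals:
            if l.var.startswith(PADDING_PREFIX):
                raise GenomeError(f"variable names may not start with {PADDING_PREFIX!r}")
    all_conjunctions = conjunctions + padding

    # occurrences needing host edges: literals of 3-literal conjunctions
    t_count: dict[str, int] = {}
    order: list[str] = []
    for c in all_conjunctions:
        for l in c.literals:
            if l.var not in t_count:
                t_count[l.var] = 0
                order.append(l.var)
            if len(c.literals) == 3:
                t_count[l.var] += 1

    # build the variable cycles on fresh extremities (two per fresh gene)
    cycles: dict[str, VariableCycle] = {}
    next_vertex = 0

    def vertex(j: int) -> Extremity:
        return Extremity(j // 2 + 1, TAIL if j % 2 == 0 else HEAD)

    for var in order:
        length = max(4 * t_count[var], 4)
        verts = tuple(vertex(next_vertex + i) for i in range(length))
        next_vertex += length
        true_m = frozenset(Adjacency(verts[i], verts[i + 1]) for i in range(0, length, 2))
        false_m = frozenset(Adjacency(verts[i], verts[(i + 1) % length])
                            for i in range(1, length, 2))
        cycles[var] = VariableCycle(var, verts, true_m, false_m)

    # host edges and conjunction edges, one 4-vertex block per occurrence
    block_counter = {var: 0 for var in order}
    conj_cycles: dict[int, frozenset[Adjacency]] = {}
    reference_edges: list[Adjacency] = []
    for idx, c in enumerate(all_conjunctions):
        if len(c.literals) != 3:
            continue
        hosts: list[tuple[Extremity, Extremity]] = []
        for l in c.literals:
            b = block_counter[l.var]
            block_counter[l.var] += 1
            verts = cycles[l.var].vertices
            if l.positive:
                host = (verts[4 * b], verts[4 * b + 1])       # true-matching edge
            else:
                host = (verts[4 * b + 1], verts[4 * b + 2])   # false-matching edge
            hosts.append(host)
        conj_edges = [Adjacency(hosts[i][1], hosts[(i + 1) % 3][0]) for i in range(3)]
        reference_edges.extend(conj_edges)
        conj_cycles[idx] = frozenset(
            [Adjacency(*h) for h in hosts] + conj_edges)

    n_genes = next_vertex // 2
    mixture = PartialMultiGenome.from_adjacencies(
        n_genes, (e for var in order for e in cycles[var].edges))
    reference = Genome(n_genes, frozenset(reference_edges))
    return GadgetInstance(mixture, reference, tuple(all_conjunctions), m,
                          cycles, conj_cycles)


def matching_of(instance: GadgetInstance,
                assignment: Mapping[str, bool]) -> Genome:
    """The genome induced by an assignment: per cycle, its chosen matching."""
    edges: set[Adjacency] = set()
    for var, cyc in instance.variable_cycles.items():
        if var not in assignment:
            raise GenomeError(f"assignment is missing variable {var!r}")
        edges |= cyc.true_matching if assignment[var] else cyc.false_matching
    return Genome(instance.n_genes, frozenset(edges))


def assignment_score(instance: GadgetInstance,
                     assignment: Mapping[str, bool]) -> int:
    """Number of satisfied conjunctions (input and padding alike).

    For 3-literal conjunctions this equals the number of conjunction-cycles
    fully preserved by the induced matchings.
    """
    return sum(c.satisfied_by(assignment) for c in instance.conjunctions)


def preserved_conjunction_cycles(instance: GadgetInstance, genome: Genome) -> int:
    """Conjunction-cycles whose three host edges all survive in ``genome``."""
    count = 0
    for idx, cycle_edges in instance.conjunction_cycles.items():
        hosts = cycle_edges - instance.reference.adjacencies
        if hosts <= genome.adjacencies:
            count += 1
    return count


def recover_assignment(instance: GadgetInstance, genome: Genome) -> dict[str, bool]:
    """Back-map a completed mixture genome to a truth assignment.

    Reads each input variable from which of its cycle's matchings the genome
    contains.  Padding variables are unconstrained by the geometry (their
    cycles carry no conjunction edges), so they are fixed to true, their
    trivially optimal value.
    """
    padding = set(instance.padding_variables)
    assignment: dict[str, bool] = {}
    for var, cyc in instance.variable_cycles.items():
        if var in padding:
            assignment[var] = True
        elif cyc.true_matching <= genome.adjacencies:
            assignment[var] = True
        elif cyc.false_matching <= genome.adjacencies:
            assignment[var] = False
        else:
            raise GenomeError(f"genome does not choose a matching of cycle {var!r}")
    return assignment
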