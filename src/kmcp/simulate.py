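"""Seeded synthetic instances: reference genomes, DCJ-scrambled descendants
along a mixture tree, adjacency masking, and mixing.

The generator emulates the data model of tumor sequencing that motivates the
completion problems: k genomes each derived from a shared reference by an
unknown sequence of DCJ rearrangements, observed only as an unattributed,
incomplete multiset of adjacencies.  Masking is per-adjacency independent
Bernoulli dropout; no false-positive adjacencies or copy-number events are
simulated.  All randomness flows from the single configuration seed.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Sequence

from .dcj import dcj_neighbors
from .genomes import (
    HEAD,
    TAIL,
    Adjacency,
    Extremity,
    Genome,
    GenomeError,
    PartialMultiGenome,
)
from .mixtures import MixtureTree


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic mixture.

    Defaults describe a modest tumor-like scenario: a 30-gene reference with
    two linear chromosomes, two derived genomes on a path below the reference,
    five rearrangements per tree edge, and 20% of adjacencies unobserved.
    """

    n_genes: int = 30
    n_linear: int = 2
    n_circular: int = 0
    tree: MixtureTree = field(default_factory=lambda: MixtureTree((0, 1)))
    moves_per_edge: int = 5
    mask_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.mask_fraction <= 1.0:
            raise GenomeError("mask fraction must lie in [0, 1]")
        if self.moves_per_edge < 0:
            raise GenomeError("moves per edge must be non-negative")

    @property
    def k(self) -> int:
        return self.tree.k


@dataclass(frozen=True)
class SimulationResult:
    reference: Genome
    genomes: tuple[Genome, ...]            # ground-truth genomes G_1..G_k
    tree: MixtureTree
    partial_genomes: tuple[Genome, ...]    # after masking, per genome
    mixture: PartialMultiGenome            # unattributed union of the partials
    move_logs: tuple[tuple, ...]           # per tree edge, the moves applied


def random_genome(n_genes: int, n_linear: int = 1, n_circular: int = 0,
                  seed: int | random.Random = 0) -> Genome:
    """A uniformly shuffled genome with the requested chromosome counts.

    Genes are randomly ordered and oriented, then cut into the requested
    number of chromosomes; every linear chromosome needs at least one gene and
    every circular chromosome at least one gene.
    """
    rng = seed if isinstance(seed, random.Random) else random.Random(seed)
    n_chrom = n_linear + n_circular
    if n_chrom < 1 or n_chrom > n_genes:
        raise GenomeError(f"cannot arrange {n_genes} genes into {n_chrom} chromosomes")
    genes = list(range(1, n_genes + 1))
    rng.shuffle(genes)
    signs = [rng.choice((1, -1)) for _ in genes]
    # choose chromosome sizes: composition of n_genes into n_chrom positive parts
    cuts = sorted(rng.sample(range(1, n_genes), n_chrom - 1)) if n_chrom > 1 else []
    bounds = [0, *cuts, n_genes]
    kinds = [True] * n_circular + [False] * n_linear  # True = circular
    rng.shuffle(kinds)
    adjacencies: list[Adjacency] = []

    def right(g: int, s: int) -> Extremity:
        return Extremity(g, HEAD if s > 0 else TAIL)

    def left(g: int, s: int) -> Extremity:
        return Extremity(g, TAIL if s > 0 else HEAD)

    for (lo, hi), circular in zip(zip(bounds, bounds[1:]), kinds):
        chrom = [(genes[i], signs[i]) for i in range(lo, hi)]
        for (g1, s1), (g2, s2) in zip(chrom, chrom[1:]):
            adjacencies.append(Adjacency(right(g1, s1), left(g2, s2)))
        if circular:
            adjacencies.append(Adjacency(right(*chrom[-1]), left(*chrom[0])))
    return Genome(n_genes, frozenset(adjacencies))


def scramble(G: Genome, moves: int, seed: int | random.Random = 0
             ) -> tuple[Genome, tuple[tuple, ...]]:
    """Apply ``moves`` uniformly chosen DCJ moves; returns result and log.

    Each step picks uniformly among the distinct one-move neighbors.  The log
    records, per move, the adjacencies removed and added.
    """
    rng = seed if isinstance(seed, random.Random) else random.Random(seed)
    log = []
    current = G
    for _ in range(moves):
        nxt = rng.choice(dcj_neighbors(current))
        removed = tuple(sorted(current.adjacencies - nxt.adjacencies))
        added = tuple(sorted(nxt.adjacencies - current.adjacencies))
        log.append((removed, added))
        current = nxt
    return current, tuple(log)


def mask(G: Genome, fraction: float, seed: int | random.Random = 0) -> Genome:
    """Drop each adjacency independently with the given probability."""
    rng = seed if isinstance(seed, random.Random) else random.Random(seed)
    kept = frozenset(a for a in G.sorted_adjacencies() if rng.random() >= fraction)
    return Genome(G.n_genes, kept)


def simulate_mixture(config: SimulationConfig) -> SimulationResult:
    """Generate a full synthetic instance with ground truth.

    The reference is drawn first; each genome is obtained by scrambling its
    tree parent with ``moves_per_edge`` DCJ moves (intermediate genomes are
    not constrained to the root's chromosome structure); each genome is then
    masked independently and the retained adjacencies are pooled, losing the
    attribution — which is returned separately as ground truth.
    """
    rng = random.Random(config.seed)
    reference = random_genome(config.n_genes, config.n_linear, config.n_circular, rng)
    children: dict[int, list[int]] = {}
    for i, p in enumerate(config.tree.parents, start=1):
        children.setdefault(p, []).append(i)
    by_vertex: dict[int, Genome] = {0: reference}
    log_by_vertex: dict[int, tuple] = {}
    frontier = [0]
    while frontier:
        v = frontier.pop(0)
        for child in sorted(children.get(v, ())):
            g, log = scramble(by_vertex[v], config.moves_per_edge, rng)
            by_vertex[child] = g
            log_by_vertex[child] = log
            frontier.append(child)
    genomes = [by_vertex[i] for i in range(1, config.k + 1)]
    logs = [log_by_vertex[i] for i in range(1, config.k + 1)]
    partials = tuple(mask(g, config.mask_fraction, rng) for g in genomes)
    mixture = PartialMultiGenome.from_adjacencies(
        config.n_genes, (a for p in partials for a in p.sorted_adjacencies()))
    return SimulationResult(reference, tuple(genomes), config.tree,
                            partials, mixture, tuple(logs))
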