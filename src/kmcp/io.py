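"""Plain-text I/O for genomes and mixtures.

Two formats are supported:

* the *adjacency format*: a header line ``genes <n>`` followed by one
  adjacency per line as two whitespace-separated extremity tokens
  (``1h 3h``); ``#`` starts a comment.  In a multi-genome file a repeated
  line denotes multiplicity; in a single-genome file it is an error.
* a GRIMM-style signed-permutation format for complete genomes: an optional
  ``>name`` header, then chromosomes as lines of signed gene identifiers
  terminated by ``$`` (linear) or ``@`` (circular).
"""

from __future__ import annotations

import os
from typing import Iterable, Union

from .genomes import (
    HEAD,
    TAIL,
    Adjacency,
    Extremity,
    Genome,
    GenomeError,
    PartialMultiGenome,
)

PathLike = Union[str, "os.PathLike[str]"]


def _adjacency_lines(text: str) -> tuple[int, list[Adjacency]]:
    n_genes = None
    adjacencies: list[Adjacency] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        fields = line.split()
        if n_genes is None:
            if len(fields) != 2 or fields[0] != "genes" or not fields[1].isdigit():
                raise GenomeError(f"line {lineno}: expected header 'genes <n>', got {raw!r}")
            n_genes = int(fields[1])
            continue
        if len(fields) != 2:
            raise GenomeError(f"line {lineno}: expected two extremity tokens, got {raw!r}")
        a, b = (Extremity.from_token(t) for t in fields)
        if a == b:
            raise GenomeError(f"line {lineno}: adjacency pairs an extremity with itself")
        if max(a.gene, b.gene) > n_genes:
            raise GenomeError(f"line {lineno}: gene index out of range (n={n_genes})")
        adjacencies.append(Adjacency(a, b))
    if n_genes is None:
        raise GenomeError("missing 'genes <n>' header")
    return n_genes, adjacencies


def parse_genome(text: str) -> Genome:
    """Parse a single (partial) genome; duplicate adjacencies are an error."""
    n, adjacencies = _adjacency_lines(text)
    if len(set(adjacencies)) != len(adjacencies):
        raise GenomeError("duplicate adjacency in a single-genome file")
    return Genome(n, frozenset(adjacencies))


def parse_mixture(text: str) -> PartialMultiGenome:
    """Parse a partial multi-genome; repeated lines accumulate multiplicity."""
    n, adjacencies = _adjacency_lines(text)
    return PartialMultiGenome.from_adjacencies(n, adjacencies)


def format_genome(G: Genome) -> str:
    lines = [f"genes {G.n_genes}"]
    lines += [f"{a.first.token} {a.second.token}" for a in G.sorted_adjacencies()]
    return "\n".join(lines) + "\n"


def format_mixture(M: PartialMultiGenome) -> str:
    lines = [f"genes {M.n_genes}"]
    lines += [f"{a.first.token} {a.second.token}" for a in M.adjacency_list()]
    return "\n".join(lines) + "\n"


def read_genome(path: PathLike) -> Genome:
    with open(path) as fh:
        return parse_genome(fh.read())


def read_mixture(path: PathLike) -> PartialMultiGenome:
    with open(path) as fh:
        return parse_mixture(fh.read())


def write_genome(path: PathLike, G: Genome) -> None:
    with open(path, "w") as fh:
        fh.write(format_genome(G))


def write_mixture(path: PathLike, M: PartialMultiGenome) -> None:
    with open(path, "w") as fh:
        fh.write(format_mixture(M))


# ---------------------------------------------------------------------------
# GRIMM-style signed permutations
# ---------------------------------------------------------------------------

def _right(gene: int) -> Extremity:
    # right end of an oriented gene occurrence: head if forward, tail if reversed
    return Extremity(abs(gene), HEAD if gene > 0 else TAIL)


def _left(gene: int) -> Extremity:
    return Extremity(abs(gene), TAIL if gene > 0 else HEAD)


def from_signed_permutations(chromosome_lines: Iterable[str], n_genes: int | None = None) -> Genome:
    """Build a genome from GRIMM-style chromosome strings.

    Each line is a sequence of signed gene identifiers ended by ``$`` (linear)
    or ``@`` (circular); ``>name`` headers and blank lines are skipped.  The
    adjacency between consecutive genes joins the right extremity of the first
    to the left extremity of the second; a circular terminator additionally
    joins the last gene's right extremity to the first gene's left extremity.
    """
    adjacencies: list[Adjacency] = []
    seen_genes: set[int] = set()
    for raw in chromosome_lines:
        line = raw.split("#", 1)[0].strip()
        if not line or line.startswith(">"):
            continue
        tokens = line.split()
        if tokens[-1] not in ("$", "@"):
            raise GenomeError(f"chromosome line missing '$' or '@' terminator: {raw!r}")
        terminator = tokens[-1]
        genes: list[int] = []
        for t in tokens[:-1]:
            try:
                g = int(t)
            except ValueError:
                raise GenomeError(f"malformed gene token {t!r}") from None
            if g == 0:
                raise GenomeError("gene identifier 0 is not allowed")
            if abs(g) in seen_genes:
                raise GenomeError(f"repeated gene identifier {abs(g)}")
            seen_genes.add(abs(g))
            genes.append(g)
        if not genes:
            raise GenomeError("empty chromosome")
        for a, b in zip(genes, genes[1:]):
            adjacencies.append(Adjacency(_right(a), _left(b)))
        if terminator == "@":
            adjacencies.append(Adjacency(_right(genes[-1]), _left(genes[0])))
    if not seen_genes:
        raise GenomeError("no chromosomes found")
    n = n_genes if n_genes is not None else max(seen_genes)
    return Genome(n, frozenset(adjacencies))
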