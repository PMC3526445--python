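import functools
import random

import pytest

from kmcp import Genome, adj, make_genome
from kmcp.exhaustive import all_matchings


@pytest.fixture
def fig_genome() -> Genome:
    """5-gene worked example: one circular chromosome (genes 2,4,5) and one
    linear chromosome (genes 1,3); telomeres 1t and 3t."""
    return make_genome(5, [adj("1h", "3h"), adj("5t", "2t"),
                           adj("2h", "4t"), adj("4h", "5h")])


@functools.lru_cache(maxsize=None)
def matchings_on(n_genes: int) -> tuple:
    """All matchings on the 2n extremities of n genes (i.e. all genomes)."""
    return tuple(all_matchings(Genome(n_genes).extremities()))


def random_genome_on(n_genes: int, rng: random.Random) -> Genome:
    """A genome drawn uniformly from all matchings on n genes (tiny n only)."""
    return Genome(n_genes, rng.choice(matchings_on(n_genes)))
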