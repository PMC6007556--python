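"""Shared fixtures: synthetic genomes, contigs and indexes, built once."""

import numpy as np
import pytest

from scafflink import IndexSpec, build_index
from scafflink.simdata import fragment_genome, simulate_genome


@pytest.fixture(scope="session")
def small_genome():
    """50 kb repeat-free genome."""
    genome, _ = simulate_genome(50_000, seed=101)
    return genome


@pytest.fixture(scope="session")
def small_index(small_genome):
    return build_index([("g", small_genome)], IndexSpec(k=21))


@pytest.fixture(scope="session")
def repeat_genome():
    """120 kb genome with one 3 kb exact repeat planted three times."""
    genome, repeats = simulate_genome(120_000, repeat_spec=[(3000, 3)], seed=102)
    return genome, repeats


@pytest.fixture(scope="session")
def fragmented():
    """300 kb genome with a planted repeat, tiled into 10 contigs.

    Returns (genome, repeat_intervals, contigs, layout, index).
    """
    genome, repeats = simulate_genome(300_000, repeat_spec=[(2000, 2)], seed=103)
    contigs, layout = fragment_genome(genome, n_contigs=10)
    index = build_index(contigs, IndexSpec(k=21))
    return genome, repeats, contigs, layout, index


def in_intervals(start, end, intervals):
    """True when [start, end) intersects any (s, e) interval."""
    return any(start < e and end > s for s, e in intervals)


def genome_pos_to_contig(pos, layout):
    """Map a genome coordinate to (contig_index, offset) in a tiled layout."""
    for i, (_, _, s, e, _) in enumerate(layout):
        if s <= pos < e:
            return i, pos - s
    raise ValueError(f"position {pos} outside the layout")


def crosses_boundary(start, end, layout):
    ci, _ = genome_pos_to_contig(start, layout)
    cj, _ = genome_pos_to_contig(end - 1, layout)
    return ci != cj


@pytest.fixture
def rng():
    return np.random.default_rng(7)
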