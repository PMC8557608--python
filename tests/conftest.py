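"""Shared fixtures: one simulated study reused across the heavy tests.

The expensive simulations (1-Mbp genome, 20x long reads, full scaffolding
and correction runs) are session-scoped so the recovery, symmetry and
conservation tests all score the same runs instead of re-simulating.
"""

from __future__ import annotations

import pytest

from minscaff.correction import correct_assembly
from minscaff.pipeline import scaffold_assembly
from minscaff.synthetic import (
    fragment_genome,
    induce_chimeras,
    simulate_genome,
    simulate_reads,
)

GENOME_LEN = 1_000_000
COVERAGE = 20
MEAN_READ_LEN = 15_000


@pytest.fixture(scope="session")
def genome():
    return simulate_genome(GENOME_LEN, gc=0.5, seed=1)


@pytest.fixture(scope="session")
def fragmented(genome):
    """25 contigs, 50-500 bp gaps, random orientations and shuffle."""
    return fragment_genome(genome, 25, (50, 500), seed=2)


@pytest.fixture(scope="session")
def errorfree_reads(genome):
    return simulate_reads(genome, COVERAGE, MEAN_READ_LEN, 0.0, seed=3)


@pytest.fixture(scope="session")
def noisy_reads(genome):
    return simulate_reads(genome, COVERAGE, MEAN_READ_LEN, 0.05, seed=4)


@pytest.fixture(scope="session")
def errorfree_scaffold(fragmented, errorfree_reads):
    contigs, _ = fragmented
    reads, _ = errorfree_reads
    return scaffold_assembly(contigs, reads, GENOME_LEN, k=24, w=100)


@pytest.fixture(scope="session")
def noisy_scaffold(fragmented, noisy_reads):
    contigs, _ = fragmented
    reads, _ = noisy_reads
    return scaffold_assembly(contigs, reads, GENOME_LEN, k=24, w=100)


@pytest.fixture(scope="session")
def chimeric_draft(genome):
    """Draft with 10 planted chimeric junctions (contigs big enough that
    every junction sits outside the terminal-exempt zone)."""
    contigs, truth = fragment_genome(genome, 25, (50, 500), seed=2, min_len=34_000)
    chimeric, chim_truth = induce_chimeras(contigs, 10, seed=5, truth=truth)
    return contigs, chimeric, truth, chim_truth


@pytest.fixture(scope="session")
def chimera_correction(chimeric_draft, errorfree_reads):
    _, chimeric, _, _ = chimeric_draft
    reads, _ = errorfree_reads
    return correct_assembly(chimeric, reads, GENOME_LEN)


@pytest.fixture(scope="session")
def clean_correction(chimeric_draft, errorfree_reads):
    contigs, _, _, _ = chimeric_draft
    reads, _ = errorfree_reads
    return correct_assembly(contigs, reads, GENOME_LEN)
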