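"""Shared fixtures: simulated datasets reused across test modules."""

import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from grapesdr.ld import aggregate_ld_bins, filter_variants, pairwise_r2
from grapesdr.simulate import (
    GenomeSimConfig,
    PopSimConfig,
    simulate_genome_set,
    simulate_population,
)
from grapesdr.synteny import detect_collinear_blocks
from grapesdr.windows import assign_orthologous, make_windows, summarize_windows


@pytest.fixture(scope="session")
def genome_set():
    """Planted-window genome simulation: 20 haplotypes, 2400 genes."""
    return simulate_genome_set(GenomeSimConfig(seed=7))


@pytest.fixture(scope="session")
def genome_summary(genome_set):
    """Orthologous-window summary table for the planted-window set."""
    gs = genome_set
    wins = make_windows(gs.ref, 12)
    assignments = {}
    for hap, ann in gs.annotations.items():
        blocks = detect_collinear_blocks(gs.ref, ann, gs.hit_tables[hap])
        assignments[hap] = assign_orthologous(
            wins, blocks, gs.hit_tables[hap].self_scores, hap
        )
    clade_of = gs.truth.params["clade_of"]
    return wins, summarize_windows(wins, assignments, clade_of)


@pytest.fixture(scope="session")
def population():
    """Diploid population with a 150-kbp non-recombining SDR."""
    return simulate_population(PopSimConfig(seed=3))


@pytest.fixture(scope="session")
def population_ld(population):
    """Filtered matrix, pairwise r2 and the 1-kbp LD landscape."""
    m = population.genotype_matrix()
    filtered, _ = filter_variants(m)
    pairs = pairwise_r2(filtered)
    landscape = aggregate_ld_bins(
        pairs,
        (0, population.config.chrom_length_bp),
        1000,
        min_snps=5,
        positions=filtered.positions,
    )
    return filtered, pairs, landscape
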