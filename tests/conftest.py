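import numpy as np
import pytest

from sibtrace import popsim, snp_select

CHROMS = [f"chr{i}" for i in range(1, 13)]


@pytest.fixture(scope="session")
def small_genome():
    return popsim.simulate_genome(CHROMS, 3000, seed=101)


@pytest.fixture(scope="session")
def planted_population(small_genome):
    """Founder pool with 10 one-per-chromosome private het sites planted in
    one focal father, chr1/chr7 excluded; the selection matrix carries the
    focal father as two replicates."""
    founders, freqs = popsim.simulate_founders(
        12, CHROMS, 3, allele_freq_range=(0.2, 0.8), seed=7, genome=small_genome
    )
    founders, truth = popsim.plant_specific_sites(
        founders, "father_005", 10,
        excluded_chroms=["chr1", "chr7"], seed=8, genome=small_genome,
    )
    selection = founders.with_replicates("father_005", ["father_005A", "father_005B"])
    return founders, selection, truth


@pytest.fixture(scope="session")
def planted_panel(planted_population):
    _, _, truth = planted_population
    return snp_select.build_panel(
        truth.planted_specific_sites, 10,
        excluded_chroms=("chr1", "chr7"), target_label="father_005",
    )


def hwe_genotypes(p: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Diploid genotypes (alt-allele counts) under HWE at frequencies p."""
    return ((rng.random(p.shape) < p).astype(np.int8)
            + (rng.random(p.shape) < p).astype(np.int8))


def mendelian_child(g1: np.ndarray, g2: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One allele from each parent, independently per site."""
    a = (rng.random(g1.shape) < g1 / 2.0).astype(np.int8)
    b = (rng.random(g2.shape) < g2 / 2.0).astype(np.int8)
    return a + b
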