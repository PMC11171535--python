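"""Shared fixtures: hand-built toy panels and small simulated panels."""

from __future__ import annotations

import numpy as np
import pytest

from introscan import (
    GenotypePanel,
    PopulationMap,
    QuartetSpec,
    SimulationConfig,
    allele_freqs,
    simulate_panel,
)


def build_panel(
    haplotypes: np.ndarray,
    pos: np.ndarray | list[int],
    chrom: str = "1",
    phased: bool = True,
    sample_prefix: str = "s",
) -> GenotypePanel:
    """Panel from a (2N, S) haplotype matrix; haplotypes 2j, 2j+1 -> sample j.

    Entries may be -1 for missing (both alleles of the genotype are then
    missing).
    """
    haps = np.asarray(haplotypes, dtype=np.int8)
    n_hap, S = haps.shape
    assert n_hap % 2 == 0
    N = n_hap // 2
    geno = haps.reshape(N, 2, S).transpose(2, 0, 1)
    miss = (geno == -1).any(axis=2)
    geno = geno.copy()
    geno[miss] = -1
    return GenotypePanel(
        chrom=np.full(S, chrom, dtype=object),
        pos=np.asarray(pos, dtype=np.int64),
        ref=np.full(S, "A", dtype=object),
        alt=np.full(S, "G", dtype=object),
        genotypes=geno,
        phased=np.full((S, N), phased, dtype=bool),
        samples=[f"{sample_prefix}{j}" for j in range(N)],
    )


def popmap_for(panel: GenotypePanel, pops: list[str]) -> PopulationMap:
    """Assign panel samples to populations in the given per-sample order."""
    assert len(pops) == panel.n_samples
    return PopulationMap({s: p for s, p in zip(panel.samples, pops)})


@pytest.fixture(scope="session")
def quartet() -> QuartetSpec:
    return QuartetSpec("P1", "P2", "P3", "O")


@pytest.fixture(scope="session")
def sim_small():
    """10k-site planted-tract panel shared by read-only tests."""
    cfg = SimulationConfig(n_sites=10_000, seed=7)
    panel, popmap, truth = simulate_panel(cfg)
    return panel, popmap, truth, cfg


@pytest.fixture(scope="session")
def sim_power():
    """Genome-scale panel: 400 Mb, 20% tract at f=0.3, 80 jackknife blocks."""
    cfg = SimulationConfig(
        n_sites=50_000, chrom_length_bp=400_000_000,
        tract_start=160_000_001, tract_end=240_000_000,
        introgression_fraction=0.3, seed=13,
    )
    panel, popmap, truth = simulate_panel(cfg)
    return allele_freqs(panel, popmap), truth


@pytest.fixture(scope="session")
def sim_small_freqs(sim_small):
    panel, popmap, _, _ = sim_small
    return allele_freqs(panel, popmap)
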