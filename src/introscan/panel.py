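"""Core in-memory containers: genotype panels, population maps, filters.

A :class:`GenotypePanel` holds biallelic SNP genotypes as a dense
``(n_sites, n_samples, 2)`` array of allele codes (0 = REF, 1 = ALT,
-1 = missing), with per-site chromosome/position and per-genotype phase
flags. Positions are 1-based and strictly increasing within each
chromosome, matching VCF coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

MISSING = -1

#: autosome labels of the domestic pig reference assembly
PIG_AUTOSOMES = frozenset(str(c) for c in range(1, 19))


@dataclass
class GenotypePanel:
    """Biallelic diploid SNP genotypes for an ordered set of samples."""

    chrom: np.ndarray        # (S,) str labels
    pos: np.ndarray          # (S,) int64, 1-based bp
    ref: np.ndarray          # (S,) single-base str
    alt: np.ndarray          # (S,) single-base str
    genotypes: np.ndarray    # (S, N, 2) int8; 0/1 alleles, -1 missing
    phased: np.ndarray       # (S, N) bool
    samples: list[str]

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.phased = np.asarray(self.phased, dtype=bool)

    # -- basic shape ---------------------------------------------------
    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def validate(self) -> None:
        """Raise ``ValueError`` on any violated panel invariant."""
        S, N = self.n_sites, self.n_samples
        if self.genotypes.shape != (S, N, 2):
            raise ValueError(
                f"genotype array shape {self.genotypes.shape} != {(S, N, 2)}"
            )
        if len(set(self.samples)) != N:
            raise ValueError("duplicate sample ids")
        g = self.genotypes
        if not np.isin(g, (MISSING, 0, 1)).all():
            raise ValueError("allele codes must be 0, 1 or missing (-1)")
        for c in self.chromosomes():
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on {c}")

    def chromosomes(self) -> list[str]:
        """Chromosome labels in order of first appearance."""
        seen: dict[str, None] = {}
        for c in self.chrom:
            seen.setdefault(c, None)
        return list(seen)

    # -- subsetting ----------------------------------------------------
    def take_sites(self, index: np.ndarray) -> "GenotypePanel":
        """New panel restricted to a boolean mask or index array of sites."""
        return GenotypePanel(
            chrom=self.chrom[index],
            pos=self.pos[index],
            ref=np.asarray(self.ref, dtype=object)[index],
            alt=np.asarray(self.alt, dtype=object)[index],
            genotypes=self.genotypes[index],
            phased=self.phased[index],
            samples=list(self.samples),
        )

    def take_samples(self, names: list[str]) -> "GenotypePanel":
        missing = [n for n in names if n not in self.samples]
        if missing:
            raise KeyError(f"samples not in panel: {missing}")
        idx = [self.samples.index(n) for n in names]
        return GenotypePanel(
            chrom=self.chrom,
            pos=self.pos,
            ref=self.ref,
            alt=self.alt,
            genotypes=self.genotypes[:, idx, :],
            phased=self.phased[:, idx],
            samples=list(names),
        )

    def region(self, chrom: str, start: int, end: int) -> "GenotypePanel":
        """Sites on ``chrom`` with ``start <= pos <= end`` (1-based inclusive)."""
        mask = (self.chrom == chrom) & (self.pos >= start) & (self.pos <= end)
        return self.take_sites(mask)

    # -- derived quantities --------------------------------------------
    def call_rate(self) -> np.ndarray:
        """Per-site fraction of samples with a fully called genotype."""
        called = (self.genotypes != MISSING).all(axis=2)
        return called.mean(axis=1)

    def pooled_maf(self) -> np.ndarray:
        """Minor-allele frequency per site over all called alleles, pooled.

        Sites with zero called alleles get MAF 0.
        """
        called = self.genotypes != MISSING
        n = called.sum(axis=(1, 2))
        alt = (self.genotypes == 1).sum(axis=(1, 2))
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n > 0, alt / np.maximum(n, 1), 0.0)
        return np.minimum(p, 1.0 - p)


@dataclass
class PopulationMap:
    """Assignment of sample ids to population labels.

    ``populations`` preserves first-appearance order from the source map.
    """

    assignments: dict[str, str]
    populations: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.populations:
            seen: dict[str, None] = {}
            for p in self.assignments.values():
                seen.setdefault(p, None)
            self.populations = list(seen)
        for p in self.populations:
            if not any(v == p for v in self.assignments.values()):
                raise ValueError(f"population {p!r} has no samples")

    @property
    def samples(self) -> list[str]:
        return list(self.assignments)

    def samples_for(self, population: str) -> list[str]:
        out = [s for s, p in self.assignments.items() if p == population]
        if not out:
            raise KeyError(f"unknown population {population!r}")
        return out

    def sample_indices(self, panel: GenotypePanel, population: str) -> list[int]:
        """Column indices in ``panel`` of the samples of one population."""
        idx = []
        for s in self.samples_for(population):
            if s not in panel.samples:
                raise KeyError(f"popmap sample {s!r} absent from panel")
            idx.append(panel.samples.index(s))
        return idx


@dataclass
class FilterConfig:
    """Variant-level QC thresholds.

    Defaults mirror cohort-level WGS filtering: drop SNPs with pooled
    MAF < 0.01 or call rate < 0.9, and keep pig autosomes 1-18 only.
    Both thresholds keep the boundary value (``>=`` is inclusive).
    """

    min_maf: float = 0.01
    min_call_rate: float = 0.9
    allowed_chroms: frozenset[str] = PIG_AUTOSOMES

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_maf <= 0.5:
            raise ValueError("min_maf must lie in [0, 0.5]")
        if not 0.0 <= self.min_call_rate <= 1.0:
            raise ValueError("min_call_rate must lie in [0, 1]")
        self.allowed_chroms = frozenset(str(c) for c in self.allowed_chroms)


def filter_variants(
    panel: GenotypePanel, cfg: FilterConfig | None = None
) -> tuple[GenotypePanel, dict[str, int]]:
    """Apply chromosome / call-rate / MAF filters to a panel.

    Returns the retained panel and per-rule removal counts under keys
    ``chromosome``, ``call_rate``, ``maf``. A site failing several rules
    is attributed to the first failing rule in that precedence order, so
    the counts plus the retained site count equal the input site count.
    """
    cfg = cfg or FilterConfig()
    chrom_ok = np.isin(panel.chrom.astype(str), list(cfg.allowed_chroms))
    cr_ok = panel.call_rate() >= cfg.min_call_rate
    maf_ok = panel.pooled_maf() >= cfg.min_maf

    removed_chrom = ~chrom_ok
    removed_cr = chrom_ok & ~cr_ok
    removed_maf = chrom_ok & cr_ok & ~maf_ok
    keep = chrom_ok & cr_ok & maf_ok

    counts = {
        "chromosome": int(removed_chrom.sum()),
        "call_rate": int(removed_cr.sum()),
        "maf": int(removed_maf.sum()),
    }
    if not keep.any():
        warnings.warn("all sites removed by variant filters", stacklevel=2)
    return panel.take_sites(keep), counts
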