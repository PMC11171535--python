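"""Population differentiation and diversity statistics.

Two FST estimators are exported and are *not* interchangeable:

* :func:`fst_hudson_pair` — Hudson's ratio-of-sums estimator, used for
  the genome-wide population matrix (the convention of PCA-based tools).
* :func:`fst_wc_window` — the Weir & Cockerham (1984) weighted theta,
  computed per window from genotype counts including observed
  heterozygosity (the convention of per-window VCF tools).

Window statistics (π, dxy, Tajima's D, WC FST) operate on fixed,
non-overlapping tiles anchored at position 1; the final partial window
of each chromosome is retained. π and dxy are normalised by the full
window length in bp by default (monomorphic-site aware); per-site
normalisation is available via ``denominator="sites"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import MISSING, GenotypePanel, PopulationMap

__all__ = [
    "AlleleFrequencyTable",
    "FstMatrix",
    "allele_freqs",
    "fst_hudson_pair",
    "nm_from_fst",
    "fst_matrix",
    "make_windows",
    "fst_wc_window",
    "pi_window",
    "dxy_window",
    "tajimas_d_window",
    "tajima_constants",
]


# ---------------------------------------------------------------------------
# allele frequencies
# ---------------------------------------------------------------------------

@dataclass
class AlleleFrequencyTable:
    """Per-site, per-population ALT allele counts and frequencies.

    ``freq`` is NaN where a population has zero called alleles at a site.
    Site coordinates are carried along so downstream window/block
    statistics need only this table.
    """

    chrom: np.ndarray                 # (S,)
    pos: np.ndarray                   # (S,)
    populations: list[str]
    alt_count: np.ndarray             # (S, P) int64
    called_count: np.ndarray          # (S, P) int64
    freq: np.ndarray = field(init=False)  # (S, P) float64, NaN if uncalled

    def __post_init__(self) -> None:
        if np.any(self.alt_count > self.called_count) or np.any(self.alt_count < 0):
            raise ValueError("require 0 <= alt_count <= called_count")
        with np.errstate(invalid="ignore", divide="ignore"):
            self.freq = np.where(
                self.called_count > 0,
                self.alt_count / np.maximum(self.called_count, 1),
                np.nan,
            )

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    def column(self, population: str) -> int:
        try:
            return self.populations.index(population)
        except ValueError:
            raise KeyError(f"unknown population {population!r}") from None


def allele_freqs(panel: GenotypePanel, popmap: PopulationMap) -> AlleleFrequencyTable:
    """Count ALT alleles per site within each population of ``popmap``.

    Missing genotype alleles are excluded from the denominators; a
    population with no called alleles at a site gets frequency NaN.
    """
    pops = popmap.populations
    S = panel.n_sites
    alt = np.zeros((S, len(pops)), dtype=np.int64)
    called = np.zeros((S, len(pops)), dtype=np.int64)
    for k, pop in enumerate(pops):
        idx = popmap.sample_indices(panel, pop)
        g = panel.genotypes[:, idx, :]
        alt[:, k] = (g == 1).sum(axis=(1, 2))
        called[:, k] = (g != MISSING).sum(axis=(1, 2))
    return AlleleFrequencyTable(
        chrom=panel.chrom, pos=panel.pos, populations=list(pops),
        alt_count=alt, called_count=called,
    )


# ---------------------------------------------------------------------------
# FST and gene flow
# ---------------------------------------------------------------------------

def fst_hudson_pair(freqs: AlleleFrequencyTable, pop_a: str, pop_b: str) -> float:
    """Hudson's FST between two populations as a ratio of sums.

    Per site, with sample frequencies pA, pB and called allele counts
    nA, nB::

        num = (pA - pB)^2 - pA(1-pA)/(nA-1) - pB(1-pB)/(nB-1)
        den = pA(1-pB) + pB(1-pA)

    and FST = sum(num)/sum(den) over sites where both populations have
    at least two called alleles. Small negative values are reported raw.
    """
    a, b = freqs.column(pop_a), freqs.column(pop_b)
    na = freqs.called_count[:, a].astype(float)
    nb = freqs.called_count[:, b].astype(float)
    pa = freqs.freq[:, a]
    pb = freqs.freq[:, b]
    ok = (na >= 2) & (nb >= 2) & ~np.isnan(pa) & ~np.isnan(pb)
    if not ok.any():
        raise ValueError(f"no jointly called sites for {pop_a!r} vs {pop_b!r}")
    pa, pb, na, nb = pa[ok], pb[ok], na[ok], nb[ok]
    num = (pa - pb) ** 2 - pa * (1 - pa) / (na - 1) - pb * (1 - pb) / (nb - 1)
    den = pa * (1 - pb) + pb * (1 - pa)
    total = den.sum()
    if total == 0:
        return 0.0
    return float(num.sum() / total)


def nm_from_fst(fst: float) -> float:
    """Island-model gene-flow level Nm = (1 - FST) / (4 FST).

    FST <= 0 implies effectively unbounded exchange; returns ``+inf``
    with a warning rather than raising.
    """
    fst = float(fst)
    if fst <= 0.0:
        warnings.warn("FST <= 0: Nm undefined, reporting +inf", stacklevel=2)
        return float("inf")
    return (1.0 - fst) / (4.0 * fst)


@dataclass
class FstMatrix:
    """Pairwise Hudson FST and implied Nm among populations."""

    populations: list[str]
    fst: np.ndarray   # (P, P) symmetric, zero diagonal
    nm: np.ndarray    # (P, P); +inf where FST <= 0, NaN on diagonal

    def to_frame(self, which: str = "fst") -> pd.DataFrame:
        m = self.fst if which == "fst" else self.nm
        return pd.DataFrame(m, index=self.populations, columns=self.populations)


def fst_matrix(freqs: AlleleFrequencyTable, popmap: PopulationMap) -> FstMatrix:
    """All pairwise Hudson FST values plus Nm. Pair failures become NaN cells."""
    pops = popmap.populations
    P = len(pops)
    fst = np.zeros((P, P))
    nm = np.full((P, P), np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(P):
            for j in range(i + 1, P):
                try:
                    f = fst_hudson_pair(freqs, pops[i], pops[j])
                except ValueError:
                    warnings.warn(
                        f"no data for pair {pops[i]}/{pops[j]}; cell set to NaN",
                        stacklevel=2,
                    )
                    f = np.nan
                fst[i, j] = fst[j, i] = f
                nm[i, j] = nm[j, i] = nm_from_fst(f) if f == f else np.nan
    return FstMatrix(populations=list(pops), fst=fst, nm=nm)


# ---------------------------------------------------------------------------
# windows
# ---------------------------------------------------------------------------

def make_windows(
    chrom: np.ndarray, pos: np.ndarray, window_size: int = 100_000
) -> pd.DataFrame:
    """Tile each chromosome with fixed windows anchored at position 1.

    Returns a frame with 1-based inclusive ``start``/``end`` columns
    covering every chromosome up to its last observed site; the final
    window may be partial and carries ``partial=True``.
    """
    rows = []
    chrom = np.asarray(chrom, dtype=object)
    pos = np.asarray(pos)
    seen: dict[str, None] = {}
    for c in chrom:
        seen.setdefault(c, None)
    for c in seen:
        last = int(pos[chrom == c].max())
        start = 1
        while start <= last:
            end = start + window_size - 1
            rows.append((c, start, min(end, last), end > last))
            start = end + 1
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "partial"])


def _window_index(
    chrom: np.ndarray, pos: np.ndarray, windows: pd.DataFrame
) -> list[np.ndarray]:
    """Site index arrays, one per window row."""
    out = []
    for c, s, e in zip(windows["chrom"], windows["start"], windows["end"]):
        out.append(np.flatnonzero((chrom == c) & (pos >= s) & (pos <= e)))
    return out


def _pop_site_stats(panel: GenotypePanel, popmap: PopulationMap, pop: str):
    """Per-site (freq, called alleles, het count, called diploids) for one pop."""
    idx = popmap.sample_indices(panel, pop)
    g = panel.genotypes[:, idx, :]
    called_dip = (g != MISSING).all(axis=2)
    n_dip = called_dip.sum(axis=1).astype(float)
    alt = np.where(called_dip, (g == 1).sum(axis=2), 0).sum(axis=1).astype(float)
    het = (called_dip & (g[:, :, 0] != g[:, :, 1])).sum(axis=1).astype(float)
    n_alleles = 2.0 * n_dip
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_alleles > 0, alt / np.maximum(n_alleles, 1), np.nan)
    return p, n_alleles, het, n_dip


def fst_wc_window(
    panel: GenotypePanel,
    popmap: PopulationMap,
    pop_a: str,
    pop_b: str,
    windows: pd.DataFrame,
) -> pd.DataFrame:
    """Per-window Weir & Cockerham (1984) weighted FST between two populations.

    Theta is the ratio of the summed among-population variance component
    ``a`` to the summed total ``a + b + c`` over sites in the window,
    using observed heterozygote counts. Windows without usable sites get
    NaN.
    """
    pa, na_dip_alleles, ha, na_dip = _pop_site_stats(panel, popmap, pop_a)
    pb, nb_dip_alleles, hb, nb_dip = _pop_site_stats(panel, popmap, pop_b)
    del na_dip_alleles, nb_dip_alleles

    r = 2.0
    ok = (na_dip >= 1) & (nb_dip >= 1) & ~np.isnan(pa) & ~np.isnan(pb)
    n1, n2 = na_dip, nb_dip
    nbar = (n1 + n2) / r
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
        pbar = (n1 * pa + n2 * pb) / (r * nbar)
        s2 = (n1 * (pa - pbar) ** 2 + n2 * (pb - pbar) ** 2) / ((r - 1.0) * nbar)
        h1 = np.where(n1 > 0, ha / np.maximum(n1, 1), 0.0)
        h2 = np.where(n2 > 0, hb / np.maximum(n2, 1), 0.0)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2
            - (1.0 / (nbar - 1.0))
            * (pbar * (1.0 - pbar) - s2 * (r - 1.0) / r - hbar / 4.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1.0 - pbar)
            - s2 * (r - 1.0) / r
            - hbar * (2.0 * nbar - 1.0) / (4.0 * nbar)
        )
        c = hbar / 2.0
    # sites with a single diploid per pop make nbar-1 or nc degenerate
    ok &= (nbar > 1.0) & (nc > 0)
    a = np.where(ok, a, 0.0)
    b = np.where(ok, b, 0.0)
    c = np.where(ok, c, 0.0)

    out = windows.copy()
    n_sites, theta = [], []
    for sites in _window_index(panel.chrom, panel.pos, windows):
        use = sites[ok[sites]]
        n_sites.append(len(use))
        denom = (a[use] + b[use] + c[use]).sum()
        theta.append(a[use].sum() / denom if len(use) and denom != 0 else np.nan)
    out["n_sites"] = n_sites
    out["fst_wc"] = theta
    return out


# ---------------------------------------------------------------------------
# diversity windows
# ---------------------------------------------------------------------------

def _window_lengths(windows: pd.DataFrame) -> np.ndarray:
    return (windows["end"] - windows["start"] + 1).to_numpy(dtype=float)


def pi_window(
    panel: GenotypePanel,
    popmap: PopulationMap,
    pop: str,
    windows: pd.DataFrame,
    denominator: str = "bp",
) -> pd.DataFrame:
    """Per-window nucleotide diversity π within one population.

    Per site the unbiased pairwise heterozygosity is ``2 p (1-p) n/(n-1)``
    with ``n`` the called allele count; the window sum is divided by the
    window length in bp (default) or by the number of usable sites
    (``denominator="sites"``).
    """
    freqs = allele_freqs(panel, popmap)
    return _diversity_window(
        freqs, windows, denominator, stat="pi", pop=pop
    )


def dxy_window(
    panel: GenotypePanel,
    popmap: PopulationMap,
    pop_a: str,
    pop_b: str,
    windows: pd.DataFrame,
    denominator: str = "bp",
) -> pd.DataFrame:
    """Per-window between-population divergence dxy.

    Per site ``pA(1-pB) + pB(1-pA)``, summed and normalised like π.
    """
    freqs = allele_freqs(panel, popmap)
    return _diversity_window(
        freqs, windows, denominator, stat="dxy", pop=pop_a, pop_b=pop_b
    )


def _diversity_window(
    freqs: AlleleFrequencyTable,
    windows: pd.DataFrame,
    denominator: str,
    stat: str,
    pop: str,
    pop_b: str | None = None,
) -> pd.DataFrame:
    if denominator not in ("bp", "sites"):
        raise ValueError("denominator must be 'bp' or 'sites'")
    k = freqs.column(pop)
    p = freqs.freq[:, k]
    n = freqs.called_count[:, k].astype(float)
    if stat == "pi":
        ok = (n >= 2) & ~np.isnan(p)
        per_site = np.where(ok, 2.0 * p * (1.0 - p) * n / np.maximum(n - 1.0, 1), 0.0)
    else:
        kb = freqs.column(pop_b)  # type: ignore[arg-type]
        q = freqs.freq[:, kb]
        ok = ~np.isnan(p) & ~np.isnan(q)
        per_site = np.where(ok, p * (1.0 - q) + q * (1.0 - p), 0.0)

    out = windows.copy()
    lengths = _window_lengths(windows)
    sums, counts = [], []
    for sites in _window_index(freqs.chrom, freqs.pos, windows):
        use = sites[ok[sites]]
        counts.append(len(use))
        sums.append(per_site[use].sum())
    sums = np.asarray(sums)
    counts_arr = np.asarray(counts, dtype=float)
    denom = lengths if denominator == "bp" else counts_arr
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = np.where(denom > 0, sums / np.maximum(denom, 1), np.nan)
    out["n_sites"] = counts
    out[stat] = vals
    return out


# ---------------------------------------------------------------------------
# Tajima's D
# ---------------------------------------------------------------------------

def tajima_constants(n: int) -> dict[str, float]:
    """Tajima (1989) normalising constants for ``n`` sequences."""
    if n < 2:
        raise ValueError("need n >= 2 sequences")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n**2 + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2,
            "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def tajimas_d_window(
    panel: GenotypePanel,
    popmap: PopulationMap,
    pop: str,
    windows: pd.DataFrame,
) -> pd.DataFrame:
    """Per-window Tajima's D within one population.

    ``D = (pi_sum - S/a1) / sqrt(e1 S + e2 S (S-1))`` with ``pi_sum`` the
    unnormalised pairwise-heterozygosity sum and ``S`` the segregating
    site count. Under missingness the constants use the window-minimum
    called allele count, which reduces to the exact complete-data formula
    when ``n`` is constant. Windows with ``S = 0`` or fewer than 4
    alleles get NaN.
    """
    freqs = allele_freqs(panel, popmap)
    k = freqs.column(pop)
    p = freqs.freq[:, k]
    n = freqs.called_count[:, k].astype(float)
    usable = (n >= 2) & ~np.isnan(p)
    pi_site = np.where(usable, 2.0 * p * (1.0 - p) * n / np.maximum(n - 1.0, 1), 0.0)
    seg = usable & (p > 0) & (p < 1)

    out = windows.copy()
    vals, n_sites = [], []
    for sites in _window_index(freqs.chrom, freqs.pos, windows):
        use = sites[usable[sites]]
        n_sites.append(len(use))
        S = int(seg[use].sum())
        if len(use) == 0 or S == 0:
            vals.append(np.nan)
            continue
        n_min = int(n[use].min())
        if n_min < 4:
            vals.append(np.nan)
            continue
        const = tajima_constants(n_min)
        pi_sum = pi_site[use].sum()
        var = const["e1"] * S + const["e2"] * S * (S - 1.0)
        vals.append((pi_sum - S / const["a1"]) / np.sqrt(var) if var > 0 else np.nan)
    out["n_sites"] = n_sites
    out["tajimas_d"] = vals
    return out
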