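"""Haplotype-level evidence around candidate introgression regions.

Operations work on a :class:`HaplotypePanel`: 2N phased haplotype rows
over the fully called, fully phased sites of a query region. Unphased
input is refused rather than pseudo-phased, since fabricated phase
corrupts haplotype-length statistics such as EHH.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import MISSING, GenotypePanel, PopulationMap

__all__ = [
    "HaplotypePanel",
    "BifurcationTree",
    "BifurcationNode",
    "major_allele_matrix",
    "ehh",
    "ehh_from_tree",
    "bifurcation",
    "ld_r2",
]

log = logging.getLogger(__name__)


@dataclass
class HaplotypePanel:
    """Phased binary haplotypes (rows) over region sites (columns)."""

    haplotypes: np.ndarray      # (2N, S) int8 in {0,1}
    pos: np.ndarray             # (S,) 1-based bp
    chrom: str
    sample_of_hap: list[str]    # length 2N
    pop_of_hap: list[str]       # length 2N
    n_dropped_sites: int = 0

    @classmethod
    def from_panel(
        cls,
        panel: GenotypePanel,
        popmap: PopulationMap,
        chrom: str,
        start: int,
        end: int,
    ) -> "HaplotypePanel":
        """Build haplotypes from the phased, fully called sites of a region.

        Sites with any missing or unphased genotype among the popmap
        samples are dropped and counted in ``n_dropped_sites``.
        """
        samples = [s for p in popmap.populations for s in popmap.samples_for(p)]
        sub = panel.take_samples(samples).region(chrom, start, end)
        if sub.n_sites == 0:
            raise ValueError(f"no sites in region {chrom}:{start}-{end}")
        called = (sub.genotypes != MISSING).all(axis=2).all(axis=1)
        phased_ok = sub.phased.all(axis=1)
        keep = called & phased_ok
        dropped = int((~keep).sum())
        if dropped:
            log.info("HaplotypePanel: dropped %d unphased/missing sites", dropped)
        sub = sub.take_sites(keep)
        if sub.n_sites == 0:
            raise ValueError("no fully phased, fully called sites in region")
        # (S, N, 2) -> (2N, S): sample j contributes rows 2j and 2j+1
        haps = sub.genotypes.transpose(1, 2, 0).reshape(2 * sub.n_samples, sub.n_sites)
        sample_of_hap = [s for s in sub.samples for _ in (0, 1)]
        pop_of_hap = [popmap.assignments[s] for s in sample_of_hap]
        return cls(
            haplotypes=haps.astype(np.int8),
            pos=sub.pos.copy(),
            chrom=chrom,
            sample_of_hap=sample_of_hap,
            pop_of_hap=pop_of_hap,
            n_dropped_sites=dropped,
        )

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.haplotypes.shape[1]

    def site_index(self, pos: int) -> int:
        idx = np.flatnonzero(self.pos == pos)
        if len(idx) == 0:
            raise KeyError(f"no site at {self.chrom}:{pos}")
        return int(idx[0])


# ---------------------------------------------------------------------------
# haplotype sharing
# ---------------------------------------------------------------------------

def major_allele_matrix(hap_panel: HaplotypePanel):
    """Major-allele indicator matrix for a phased region.

    The major allele per site is taken over all haplotypes pooled across
    populations; an exact 50/50 tie designates the ALT allele (code 1)
    major, deterministically. Returns ``(matrix, major)`` where
    ``matrix`` is a DataFrame (rows = haplotypes grouped by population,
    index ``pop/sample/hap``) with entry 1 iff the haplotype carries the
    major allele, and ``major`` is the per-site major-allele code.
    """
    H = hap_panel.haplotypes
    n = H.shape[0]
    ones = H.sum(axis=0)
    major = np.where(ones * 2 >= n, 1, 0).astype(np.int8)
    ties = int((ones * 2 == n).sum())
    if ties:
        log.info("major_allele_matrix: %d tied sites, ALT designated major", ties)
    carries = (H == major[None, :]).astype(np.int8)

    order = np.argsort(
        pd.Categorical(
            hap_panel.pop_of_hap,
            categories=list(dict.fromkeys(hap_panel.pop_of_hap)),
            ordered=True,
        ).codes,
        kind="stable",
    )
    index = [
        f"{hap_panel.pop_of_hap[i]}/{hap_panel.sample_of_hap[i]}/{i % 2}"
        for i in order
    ]
    matrix = pd.DataFrame(carries[order], index=index, columns=hap_panel.pos)
    return matrix, major


# ---------------------------------------------------------------------------
# EHH and bifurcation
# ---------------------------------------------------------------------------

def _carrier_rows(hap_panel: HaplotypePanel, core_site: int, core_allele: int):
    core_idx = hap_panel.site_index(core_site)
    carriers = np.flatnonzero(hap_panel.haplotypes[:, core_idx] == core_allele)
    if len(carriers) < 2:
        raise ValueError(
            f"need >= 2 carriers of allele {core_allele} at "
            f"{hap_panel.chrom}:{core_site}, got {len(carriers)}"
        )
    return core_idx, carriers


def ehh(
    hap_panel: HaplotypePanel,
    core_site: int,
    core_allele: int,
    truncate: float = 0.05,
) -> pd.DataFrame:
    """Extended haplotype homozygosity around a core allele.

    ``EHH(x)`` is the probability that two random carrier haplotypes are
    identical over every site from the core out to ``x``:
    ``sum_g C(k_g, 2) / C(n, 2)`` over distinct extended haplotypes g.
    EHH at the core itself is 1; each direction is reported outward
    until EHH drops below ``truncate`` (the first sub-threshold site is
    included) or the region ends.

    Returns a frame with columns ``pos, direction, ehh``.
    """
    core_idx, carriers = _carrier_rows(hap_panel, core_site, core_allele)
    H = hap_panel.haplotypes[carriers]
    n = len(carriers)
    denom = n * (n - 1) / 2

    rows = [(int(core_site), "core", 1.0)]
    for direction, sites in (
        ("left", range(core_idx - 1, -1, -1)),
        ("right", range(core_idx + 1, hap_panel.n_sites)),
    ):
        groups = np.zeros(n, dtype=np.int64)
        for s in sites:
            # refine partition by the allele at the next site outward
            groups = groups * 2 + H[:, s]
            _, counts = np.unique(groups, return_counts=True)
            groups = np.unique(groups, return_inverse=True)[1]  # re-compact ids
            val = float((counts * (counts - 1) / 2).sum() / denom)
            rows.append((int(hap_panel.pos[s]), direction, val))
            if val < truncate:
                break
    out = pd.DataFrame(rows, columns=["pos", "direction", "ehh"])
    return out.sort_values("pos").reset_index(drop=True)


@dataclass
class BifurcationNode:
    """One branch of the bifurcation diagram."""

    site_pos: int          # position of the site whose allele splits here
    allele: int            # allele carried on this branch (core node: core allele)
    count: int             # carrier haplotypes passing through
    children: list["BifurcationNode"]

    def to_dict(self) -> dict:
        return {
            "site": self.site_pos,
            "allele": self.allele,
            "count": self.count,
            "children": [c.to_dict() for c in self.children],
        }

    def leaf_counts(self) -> list[int]:
        if not self.children:
            return [self.count]
        return [c for child in self.children for c in child.leaf_counts()]


@dataclass
class BifurcationTree:
    """Prefix-partition tree of carrier haplotypes away from a core site."""

    core_site: int
    core_allele: int
    direction: str
    root: BifurcationNode

    def to_dict(self) -> dict:
        return {
            "core_site": self.core_site,
            "core_allele": self.core_allele,
            "direction": self.direction,
            "tree": self.root.to_dict(),
        }


def bifurcation(
    hap_panel: HaplotypePanel,
    core_site: int,
    core_allele: int,
    direction: str = "right",
    max_steps: int | None = None,
) -> BifurcationTree:
    """Bifurcation diagram of carrier haplotypes extending from the core.

    Starting from all carriers of ``core_allele`` at ``core_site``, the
    carrier set is split site by site outward by the allele observed at
    each next site; branch counts at every depth sum to the carrier
    count.
    """
    if direction not in ("left", "right"):
        raise ValueError("direction must be 'left' or 'right'")
    core_idx, carriers = _carrier_rows(hap_panel, core_site, core_allele)
    H = hap_panel.haplotypes
    if direction == "right":
        sites = list(range(core_idx + 1, hap_panel.n_sites))
    else:
        sites = list(range(core_idx - 1, -1, -1))
    if max_steps is not None:
        sites = sites[:max_steps]

    root = BifurcationNode(
        site_pos=int(core_site), allele=core_allele,
        count=len(carriers), children=[],
    )

    def grow(node: BifurcationNode, rows: np.ndarray, remaining: list[int]) -> None:
        if not remaining:
            return
        s, rest = remaining[0], remaining[1:]
        for allele in (0, 1):
            sub = rows[H[rows, s] == allele]
            if len(sub) == 0:
                continue
            child = BifurcationNode(
                site_pos=int(hap_panel.pos[s]), allele=allele,
                count=len(sub), children=[],
            )
            node.children.append(child)
            grow(child, sub, rest)

    grow(root, carriers, sites)
    return BifurcationTree(
        core_site=int(core_site), core_allele=core_allele,
        direction=direction, root=root,
    )


def ehh_from_tree(tree: BifurcationTree) -> list[float]:
    """EHH at each extension step computed from a bifurcation tree.

    Independent route to the same quantity as :func:`ehh`: at depth d
    the tree's branch counts are the haplotype-prefix group sizes.
    """
    n = tree.root.count
    denom = n * (n - 1) / 2
    out = [1.0]
    level = [tree.root]
    while True:
        level = [c for node in level for c in node.children]
        if not level:
            break
        out.append(sum(c.count * (c.count - 1) / 2 for c in level) / denom)
    return out


# ---------------------------------------------------------------------------
# linkage disequilibrium
# ---------------------------------------------------------------------------

def ld_r2(hap_panel: HaplotypePanel) -> pd.DataFrame:
    """Pairwise r² between all sites of the region, from phased haplotypes.

    ``r² = (p_AB - p_A p_B)² / (p_A(1-p_A) p_B(1-p_B))``; rows/columns of
    monomorphic sites are NaN. Returned as a symmetric DataFrame indexed
    by position.
    """
    H = hap_panel.haplotypes.astype(float)
    n = H.shape[0]
    p = H.mean(axis=0)
    pab = (H.T @ H) / n
    cov = pab - np.outer(p, p)
    var = p * (1.0 - p)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = cov**2 / np.outer(var, var)
    mono = var == 0
    r2[mono, :] = np.nan
    r2[:, mono] = np.nan
    return pd.DataFrame(r2, index=hap_panel.pos, columns=hap_panel.pos)
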