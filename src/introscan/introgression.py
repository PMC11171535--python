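"""Four-taxon introgression statistics: Patterson's D and the windowed fd scan.

The quartet is ordered (H1, H2, H3, H4) on the tree (((H1, H2), H3), H4)
with H4 the outgroup. Sites are polarized so that the outgroup carries
the ancestral allele: where the outgroup's ALT frequency exceeds 0.5 all
frequencies are flipped, and sites where the outgroup remains polymorphic
above ``max_outgroup_minor`` (default 0.1) are dropped, since the
ancestral state is then ambiguous.

Genome-wide significance uses a weighted delete-one block jackknife over
contiguous coordinate blocks (default 5 Mbp), with blocks weighted by
their informative-site counts (Busing, Meijer & van der Leeden 1999).
|Z| > 3 is the conventional significance rule.

The windowed fd statistic estimates the local admixture fraction: the
ABBA-BABA numerator of a window divided by the value it would take under
complete sharing, obtained by substituting for both H2 and H3 the
"donor proxy" frequency — whichever of the two is larger at each site.
fd is only meaningful where the window's own D is non-negative; windows
with negative D or too few informative sites report missing fd.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .popgen import AlleleFrequencyTable, make_windows

__all__ = [
    "QuartetSpec",
    "DStatResult",
    "IntrogressionSignal",
    "site_abba_baba",
    "polarize",
    "d_statistic",
    "d_matrix",
    "fd_scan",
    "detect_outliers",
]

DEFAULT_BLOCK_SIZE = 5_000_000
DEFAULT_WINDOW_SIZE = 100_000
DEFAULT_MERGE_DISTANCE = 1_000_000
DEFAULT_QUANTILE = 0.001
DEFAULT_MIN_SITES = 10


@dataclass(frozen=True)
class QuartetSpec:
    """Ordered population quartet; ``h4`` is the outgroup."""

    h1: str
    h2: str
    h3: str
    h4: str

    def __post_init__(self) -> None:
        labels = (self.h1, self.h2, self.h3, self.h4)
        if len(set(labels)) != 4:
            raise ValueError(f"quartet labels must be distinct: {labels}")

    @property
    def labels(self) -> tuple[str, str, str, str]:
        return (self.h1, self.h2, self.h3, self.h4)


@dataclass
class DStatResult:
    """Genome-wide Patterson's D with block-jackknife uncertainty."""

    d: float
    abba_sum: float
    baba_sum: float
    se: float
    z: float
    n_blocks: int
    block_size: int
    n_informative: int
    quartet: QuartetSpec

    @property
    def significant(self) -> bool:
        return abs(self.z) > 3.0


@dataclass
class IntrogressionSignal:
    """A run of merged outlier windows on one chromosome."""

    chrom: str
    start: int
    end: int
    member_windows: pd.DataFrame
    peak_fd: float = field(init=False)
    peak_window: tuple[int, int] = field(init=False)

    def __post_init__(self) -> None:
        if len(self.member_windows) == 0:
            raise ValueError("signal must contain at least one window")
        peak = self.member_windows.loc[self.member_windows["fd"].idxmax()]
        self.peak_fd = float(peak["fd"])
        self.peak_window = (int(peak["start"]), int(peak["end"]))

    @property
    def n_windows(self) -> int:
        return len(self.member_windows)


# ---------------------------------------------------------------------------
# site patterns
# ---------------------------------------------------------------------------

def site_abba_baba(p1, p2, p3, p4):
    """Frequency-weighted ABBA and BABA site patterns.

    ``abba = (1-p1) p2 p3 (1-p4)`` and ``baba = p1 (1-p2) p3 (1-p4)``
    for derived-allele frequencies p1..p4 (p4 = outgroup). Accepts
    scalars or arrays.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    abba = (1.0 - p1) * p2 * p3 * (1.0 - p4)
    baba = p1 * (1.0 - p2) * p3 * (1.0 - p4)
    return abba, baba


def polarize(
    freqs: AlleleFrequencyTable,
    quartet: QuartetSpec,
    max_outgroup_minor: float = 0.1,
):
    """Derived-allele frequencies for a quartet, ancestral = outgroup major.

    Returns ``(chrom, pos, p1, p2, p3, p4)`` restricted to sites where
    all four populations are called and the outgroup minor-allele
    frequency is at most ``max_outgroup_minor``.
    """
    cols = [freqs.column(lbl) for lbl in quartet.labels]
    p = freqs.freq[:, cols]  # (S, 4)
    ok = ~np.isnan(p).any(axis=1)
    p4 = p[:, 3]
    flip = p4 > 0.5
    p = np.where(flip[:, None], 1.0 - p, p)
    ok &= p[:, 3] <= max_outgroup_minor
    p = p[ok]
    return freqs.chrom[ok], freqs.pos[ok], p[:, 0], p[:, 1], p[:, 2], p[:, 3]


# ---------------------------------------------------------------------------
# genome-wide D with weighted block jackknife
# ---------------------------------------------------------------------------

def _block_ids(chrom: np.ndarray, pos: np.ndarray, block_size: int) -> np.ndarray:
    """Integer block id per site: contiguous coordinate blocks per chromosome."""
    codes = pd.factorize(chrom)[0].astype(np.int64)
    return codes * 10_000_000 + (pos - 1) // block_size


def weighted_jackknife(theta_hat: float, theta_del: np.ndarray, m: np.ndarray):
    """Delete-one-block jackknife SE with unequal block weights.

    ``theta_del[j]`` is the estimate with block j removed and ``m[j]``
    its weight (informative-site count). With equal weights this reduces
    to the classic delete-one formula. Returns ``(se, theta_jack)``.
    """
    m = np.asarray(m, dtype=float)
    g = len(m)
    n = m.sum()
    h = n / m
    theta_jack = g * theta_hat - np.sum((1.0 - m / n) * theta_del)
    tau = h * theta_hat - (h - 1.0) * theta_del
    var = np.sum((tau - theta_jack) ** 2 / (h - 1.0)) / g
    return float(np.sqrt(var)), float(theta_jack)


def d_statistic(
    freqs: AlleleFrequencyTable,
    quartet: QuartetSpec,
    block_size: int = DEFAULT_BLOCK_SIZE,
    max_outgroup_minor: float = 0.1,
) -> DStatResult:
    """Genome-wide D = (ABBA - BABA) / (ABBA + BABA) with jackknife Z.

    Positive D indicates excess derived-allele sharing between H2 and
    H3. Blocks with zero informative sites are dropped; at least two
    non-empty blocks are required. If every delete-one estimate is
    identical the SE is zero and Z is reported as signed infinity.
    """
    chrom, pos, p1, p2, p3, p4 = polarize(freqs, quartet, max_outgroup_minor)
    abba, baba = site_abba_baba(p1, p2, p3, p4)
    num = abba - baba
    den = abba + baba
    total_den = den.sum()
    if total_den == 0:
        raise ValueError("no informative sites for D statistic")
    d_hat = float(num.sum() / total_den)

    informative = den > 0
    blocks = _block_ids(chrom, pos, block_size)
    frame = pd.DataFrame({
        "block": blocks, "num": num, "den": den, "inf": informative.astype(int)
    })
    agg = frame.groupby("block", sort=True).sum()
    agg = agg[agg["inf"] > 0]
    g = len(agg)
    if g < 2:
        raise ValueError(f"need >= 2 non-empty jackknife blocks, got {g}")

    num_tot, den_tot = num.sum(), den.sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        d_del = (num_tot - agg["num"].to_numpy()) / (den_tot - agg["den"].to_numpy())
    se, _ = weighted_jackknife(d_hat, d_del, agg["inf"].to_numpy())
    if se <= 1e-12 * max(1.0, abs(d_hat)):  # identical blocks: zero variance
        se = 0.0
        z = float(np.sign(d_hat) * np.inf) if d_hat != 0 else 0.0
    else:
        z = d_hat / se
    return DStatResult(
        d=d_hat, abba_sum=float(abba.sum()), baba_sum=float(baba.sum()),
        se=se, z=float(z), n_blocks=g, block_size=block_size,
        n_informative=int(informative.sum()), quartet=quartet,
    )


def d_matrix(
    freqs: AlleleFrequencyTable,
    h3_candidates: list[str],
    h1: str,
    h2: str,
    h4: str,
    block_size: int = DEFAULT_BLOCK_SIZE,
) -> pd.DataFrame:
    """D statistics over a panel of candidate H3 donors.

    Sign convention: positive D means H3 shares more derived alleles
    with H1 than with H2 (the quartet is evaluated with H1 and H2
    exchanged relative to :func:`d_statistic`, whose positive pole is
    H2-H3 sharing). Swapping ``h1`` and ``h2`` flips every sign.
    """
    rows = []
    for h3 in h3_candidates:
        res = d_statistic(freqs, QuartetSpec(h2, h1, h3, h4), block_size=block_size)
        rows.append({
            "H1": h1, "H2": h2, "H3": h3, "H4": h4,
            "D": res.d, "SE": res.se, "Z": res.z,
            "n_blocks": res.n_blocks, "ABBA": res.abba_sum, "BABA": res.baba_sum,
            "significant": res.significant,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# windowed fd scan
# ---------------------------------------------------------------------------

def fd_scan(
    freqs: AlleleFrequencyTable,
    quartet: QuartetSpec,
    window_size: int = DEFAULT_WINDOW_SIZE,
    min_sites: int = DEFAULT_MIN_SITES,
    max_outgroup_minor: float = 0.1,
) -> pd.DataFrame:
    """Windowed fd estimate of the local admixture fraction.

    H2 is the putative recipient and H3 the donor. Per window the
    ABBA-BABA numerator is divided by the same sum with both H2 and H3
    replaced by the site-wise donor proxy (the larger of the two
    frequencies). ``fd`` is NaN where the window D is negative, the
    denominator vanishes, or fewer than ``min_sites`` informative sites
    remain; values can exceed 1 in noisy windows and are reported raw.

    Returns a frame with columns ``chrom, start, end, n_informative,
    d_num, d_den, window_D, fd``.
    """
    chrom, pos, p1, p2, p3, p4 = polarize(freqs, quartet, max_outgroup_minor)
    abba, baba = site_abba_baba(p1, p2, p3, p4)
    pd_proxy = np.maximum(p2, p3)
    abba_d, baba_d = site_abba_baba(p1, pd_proxy, pd_proxy, p4)
    num = abba - baba
    den_d = abba + baba
    fd_den = abba_d - baba_d
    informative = den_d > 0

    windows = make_windows(chrom, pos, window_size)
    out = windows[["chrom", "start", "end"]].copy()
    n_inf, d_nums, d_dens, fd_nums, fd_dens = [], [], [], [], []
    for c, s, e in zip(out["chrom"], out["start"], out["end"]):
        sel = (chrom == c) & (pos >= s) & (pos <= e)
        n_inf.append(int(informative[sel].sum()))
        d_nums.append(num[sel].sum())
        d_dens.append(den_d[sel].sum())
        fd_nums.append(num[sel].sum())
        fd_dens.append(fd_den[sel].sum())
    out["n_informative"] = n_inf
    d_nums = np.asarray(d_nums)
    d_dens = np.asarray(d_dens)
    fd_dens = np.asarray(fd_dens)
    with np.errstate(invalid="ignore", divide="ignore"):
        window_d = np.where(d_dens > 0, d_nums / np.maximum(d_dens, 1e-300), np.nan)
        fd = np.where(fd_dens != 0, d_nums / np.where(fd_dens == 0, 1, fd_dens), np.nan)
    bad = (
        np.isnan(window_d)
        | (window_d < 0)
        | (np.asarray(n_inf) < min_sites)
        | (fd_dens == 0)
    )
    fd = np.where(bad, np.nan, fd)
    out["d_num"] = d_nums
    out["d_den"] = d_dens
    out["window_D"] = window_d
    out["fd"] = fd
    return out


def detect_outliers(
    fd_windows: pd.DataFrame,
    quantile: float = DEFAULT_QUANTILE,
    merge_distance: int = DEFAULT_MERGE_DISTANCE,
) -> list[IntrogressionSignal]:
    """Select top-quantile fd windows and merge nearby ones into signals.

    The threshold is the empirical (1 - ``quantile``) quantile of the
    non-missing fd values, taken as the k-th largest value with
    ``k = max(1, round(quantile * N))`` so that exactly k windows are
    selected when values are distinct. Outlier windows on the same
    chromosome whose gap is at most ``merge_distance`` bp are chained
    into a single :class:`IntrogressionSignal`.
    """
    valid = fd_windows.dropna(subset=["fd"])
    n = len(valid)
    if n == 0:
        return []
    k = max(1, int(round(quantile * n)))
    if n < 1.0 / quantile:
        warnings.warn(
            f"only {n} windows for quantile {quantile}; taking top {k}",
            stacklevel=2,
        )
    threshold = np.partition(valid["fd"].to_numpy(), n - k)[n - k]
    outliers = valid[valid["fd"] >= threshold].sort_values(["chrom", "start"])

    signals: list[IntrogressionSignal] = []
    current: list[int] = []
    prev_chrom, prev_end = None, None
    for idx, row in outliers.iterrows():
        if (
            current
            and row["chrom"] == prev_chrom
            and row["start"] - prev_end <= merge_distance
        ):
            current.append(idx)
        else:
            if current:
                signals.append(_make_signal(outliers.loc[current]))
            current = [idx]
        prev_chrom, prev_end = row["chrom"], row["end"]
    if current:
        signals.append(_make_signal(outliers.loc[current]))
    return signals


def _make_signal(members: pd.DataFrame) -> IntrogressionSignal:
    return IntrogressionSignal(
        chrom=str(members.iloc[0]["chrom"]),
        start=int(members["start"].min()),
        end=int(members["end"].max()),
        member_windows=members.reset_index(drop=True),
    )
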