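# Methods

## Data model and filtering

Genotypes are held as a dense site × sample × 2 array of allele codes
(0 = REF, 1 = ALT, −1 = missing) with 1-based positions, read from VCF 4.x
via cyvcf2. Only biallelic SNPs are kept; multiallelic and non-SNP records
are skipped with a logged count, and half-called genotypes (`0/.`) are
demoted to fully missing — the simplest defensible treatment, since a half
call carries no reliable diplotype information.

Variant filtering mirrors cohort-level WGS practice: pooled minor-allele
frequency (over all samples' called alleles) ≥ 0.01, genotype call rate
≥ 0.9, and an allowed-chromosome set (default: pig autosomes 1–18). Both
thresholds keep the boundary value. A site failing several rules is counted
once under the precedence chromosome > call rate > MAF, so per-rule removal
counts plus the retained count always equal the input count. Filtering is
idempotent.

## Differentiation and diversity

Two FST estimators are exported deliberately, because the field's common
tools disagree and the two are not interchangeable:

- **Hudson ratio-of-sums** (population matrix). Per site,
  `num = (pA−pB)² − pA(1−pA)/(nA−1) − pB(1−pB)/(nB−1)`,
  `den = pA(1−pB) + pB(1−pA)`; FST = Σnum/Σden. Unbiased under unequal
  sample sizes; small negatives are reported raw (two identical samples of n
  alleles give exactly −1/(n−1)).
- **Weir–Cockerham weighted θ** (windows). The a/b/c variance components per
  site, including observed heterozygosity, summed over the window;
  θ = Σa/Σ(a+b+c). This matches per-window VCF tooling conventions.

Gene flow is summarised as the island-model equivalent migrant number
Nm = (1 − FST)/(4·FST), +∞ for FST ≤ 0 (with a warning), strictly
decreasing in FST, Nm(1) = 0.

Windows are fixed non-overlapping tiles anchored at position 1 (default
100 kb); the final partial window is kept and flagged. π uses the unbiased
per-site pairwise heterozygosity `2p(1−p)·n/(n−1)`; d<sub>xy</sub> uses
`pA(1−pB) + pB(1−pA)`; both are normalised by window length in bp by default
(monomorphic-aware), with a per-site alternative. Both equal all-pairs
Hamming enumeration exactly on complete data — the test suite asserts this
to 1e−9. Tajima's D uses the 1989 constants; under missingness the constants
take the window-minimum called allele count (the estimator then reduces to
the exact complete-data formula when n is constant), with windows below
4 alleles or without segregating sites reported missing.

## D statistic, block jackknife, fd

Sites are polarized by the outgroup: where the outgroup ALT frequency
exceeds 0.5 all frequencies are flipped, and sites whose outgroup
minor-allele frequency still exceeds 0.1 are dropped as ancestrally
ambiguous. Patterson's D uses frequency-weighted patterns
`abba = (1−p1)p2p3(1−p4)`, `baba = p1(1−p2)p3(1−p4)`,
D = Σ(abba−baba)/Σ(abba+baba); positive D means excess H2–H3 sharing.
The candidate-donor table (`d_matrix`) follows the opposite display
convention common in donor screens — positive values mean H3 shares with
H1 — by evaluating the quartet with H1/H2 exchanged; swapping H1 and H2
flips every sign.

Significance uses a delete-one block jackknife over contiguous 5-Mbp
coordinate blocks. Because SNP density varies between blocks, blocks are
weighted by their informative-site counts using the weighted-jackknife
variance (Busing–Meijer–van der Leeden); with equal weights this reduces
exactly to the classic delete-one formula, which the tests assert. Identical
blocks give SE = 0 and a flagged infinite Z. A caveat the package surfaces
rather than hides: with very few blocks (e.g. one short chromosome) the Z is
essentially a 1-df t statistic and should not be read against the |Z| > 3
rule; and when gene flow is confined to a minority of blocks, block-to-block
heterogeneity legitimately inflates the SE, so a localized tract yields a
much smaller Z than genome-wide admixture of the same strength.

The windowed f<sub>d</sub> statistic estimates the local admixture fraction:
the window's Σ(abba−baba) divided by the same sum with both H2 and H3
replaced at each site by the donor proxy PD = max(p2, p3) (the value under
complete sharing). f<sub>d</sub> is reported missing where the window's own
D is negative, the denominator vanishes, or fewer than `min_sites` (default
10) informative sites remain; values above 1 can occur in noise and are
reported raw. Outlier windows are the top quantile (default 0.001, i.e. the
empirical 99.9% threshold implemented as the k-th largest value with
k = max(1, round(q·N)), making the selected count exact for distinct
values); same-chromosome outliers whose gap is ≤ 1 Mbp are chained into one
signal carrying its span, members and peak window.

Signal validation operationalizes "low divergence relative to the genomic
average" as: member-window mean FST and d<sub>xy</sub> (recipient vs donor)
both below the genome-wide medians — the median is used as the comparator
for robustness to the outlier windows themselves — and the sign of the
recipient's Tajima's D over the signal is recorded alongside.

## Haplotype evidence

Haplotype operations require fully phased, fully called sites within the
query region; violating sites are dropped and counted, and an unphased
region is refused outright rather than pseudo-phased, because fabricated
phase silently corrupts haplotype-length statistics. The sharing matrix
marks carriage of the pooled major allele (exact ties deterministically
resolve to ALT). EHH(x) is the probability that two random carriers of the
core allele are identical from the core to x, Σ C(k_g,2)/C(n,2) over
distinct prefixes, reported outward per direction until it falls below 0.05
(a conventional truncation; the tooling the threshold imitates leaves it
unstated). The bifurcation tree is the same prefix partition represented
explicitly; EHH recomputed from the tree equals the direct computation, a
two-route identity the tests enforce. LD is the haplotype-count
r² = (p_AB − p_A p_B)²/(p_A q_A p_B q_B) with monomorphic sites masked.

## Simulator design

The generator draws an ancestral frequency per site from Beta(0.8, 0.8) and
drifts it along each branch of (((P1,P2),P3),O) with the Balding–Nichols
kernel Beta(p(1−F)/F, (1−p)(1−F)/F). Defaults (chosen once, as the study
conditions of the standard fixture): 50,000 SNPs on a 10-Mb chromosome, 20
diploids per population, branch drift F = 0.01 (P1, P2), 0.02 (ancestor of
the sister pair), 0.30 (P3), 0.10 (internal ancestor), 0.50 (outgroup), and
an introgression episode P3→P2 at fraction f = 0.5 confined to the
5.0–5.8 Mb tract. These drift values emulate the intended study system — a
weakly differentiated sister pair (realised Hudson FST ≈ 0.01), a strongly
diverged donor (≈ 0.16 against the sister pair) and a deep outgroup
(≈ 0.3–0.45) — and were fixed by the requirement that f<sub>d</sub> behave
as an approximately unbiased estimator of f: when sister-pair drift is large
relative to donor divergence, drift noise enters the max(p2, p3) denominator
and attenuates f<sub>d</sub> well below f, which is a property of the
statistic, not a bug.

Introgression is planted as contiguous replacement: round(f · 2n) recipient
haplotypes have their tract alleles resampled from the donor's frequencies,
preserving phase, so haplotype-sharing and EHH stages see tract-scale
signal. With f = 0 the output is bit-identical to the no-flow model at the
same seed, and with f > 0 the panel outside the tract is bit-identical to
the null panel.

Problem sizes used in the validation experiments (package defaults, stated
as the package's own study conditions): tract recovery uses 20 replicates of
the standard fixture; null calibration of the |Z| > 3 rule uses 20
replicates at f = 0 on a 100-Mb chromosome, i.e. 20 jackknife blocks — the
desk-scale stand-in for genome-wide D over hundreds of blocks, since with
only two blocks the jackknife Z has 1-df-t tails and the rule is
uninterpretable; the localized-flow power check uses a 400-Mb chromosome
(80 blocks) with f = 0.3 over a 20% tract.

## Known limitations

- **No background linkage.** Sites are independent outside the planted
  tract; LD- and EHH-based checks therefore only carry signal inside the
  tract, and genome-wide LD decay is not emulated.
- **Non-neutral site-frequency spectrum.** The Balding–Nichols/Beta model
  has no genealogy, so its SFS lacks the singleton-heavy shape of the
  neutral coalescent: window Tajima's D averages clearly positive (≈ +0.7 to
  +1.6 depending on the ancestral Beta shape) even without selection or
  admixture. Tajima's D is validated against enumeration oracles and
  directional toys (all-singleton panels give D < 0), not against a neutral
  zero expectation; on real data its genome-wide distribution should be
  interpreted relative to its own empirical background, which is also how
  the window-validation stage uses every statistic.
- **Frequency-level drift.** Balding–Nichols drift reproduces the first two
  moments that D, f<sub>d</sub> and FST consume, but not deeper coalescent
  features (shared internal branches, ILS tract lengths). A coalescent
  backend is out of scope.
- **Phasing is trusted.** Haplotype statistics take the phase flags in the
  input at face value; statistically phased data will dilute EHH contrast
  near switch errors.
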