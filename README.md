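# introscan

Detection of adaptive introgression between populations from diploid SNP
panels. `introscan` is aimed at population geneticists who have a filtered,
optionally phased multi-population VCF (for example from a livestock or wild
resequencing cohort) and want to answer three questions:

1. **Is there gene flow?** Genome-wide Patterson's *D* on a four-taxon quartet
   (((H1, H2), H3), Outgroup), with a weighted 5-Mbp block jackknife giving a
   *Z*-score; |Z| > 3 is called significant.
2. **Where is it?** A windowed *f<sub>d</sub>* scan (default 100-kb windows)
   estimating the local admixture fraction, with top-quantile outlier windows
   (default top 0.1%) merged into signals when within 1 Mbp of each other.
3. **Is a signal credible?** Window-level validation — Weir–Cockerham FST,
   d<sub>xy</sub>, nucleotide diversity π and Tajima's D around each signal —
   plus haplotype-level evidence from phased data: a major-allele sharing
   matrix, extended haplotype homozygosity (EHH), haplotype bifurcation trees
   and pairwise LD r².

Population differentiation is summarised with Hudson's FST
(ratio-of-sums) and converted to island-model gene-flow levels via
Nm = (1 − FST)/(4·FST).

A built-in simulator (`introscan.simulate`) draws four populations under
Balding–Nichols drift on the fixed topology and plants a contiguous
donor→recipient introgression tract at a known admixture fraction *f*, so the
whole pipeline can be validated against ground truth without any external
data.

## Worked example

```python
import introscan as I

# a 10-Mb chromosome, 50k SNPs, 20 diploids in each of P1, P2, P3, O;
# half the P2 haplotypes carry donor (P3) alleles in a 0.8-Mb tract
panel, popmap, truth = I.simulate_panel(I.SimulationConfig(seed=42))
freqs = I.allele_freqs(panel, popmap)
quartet = I.QuartetSpec("P1", "P2", "P3", "O")

res = I.d_statistic(freqs, quartet)
print(f"D = {res.d:.4f}  SE = {res.se:.4f}  Z = {res.z:.2f}")

fd = I.fd_scan(freqs, quartet)
for s in I.detect_outliers(fd):
    print(f"signal {s.chrom}:{s.start}-{s.end}  peak fd = {s.peak_fd:.3f}")
```

prints

```
D = 0.0124  SE = 0.0122  Z = 1.02
signal 1:5000001-5100000  peak fd = 0.502
```

The top outlier window falls inside the planted 5.0–5.8 Mb tract and its
*f<sub>d</sub>* (0.502) estimates the planted admixture fraction (0.5). The
mean *f<sub>d</sub>* over all tract windows in this replicate is 0.429 — the
mild downward bias expected of *f<sub>d</sub>* under drift and finite
sampling. Genome-wide *D* is positive but non-significant here because a
single 10-Mb chromosome yields only two jackknife blocks; use many blocks (a
real genome, or the larger simulated genomes in the test suite) for a
calibrated *Z*.

The same analysis is available from the shell:

```sh
introscan simulate --seed 42 --out fix/
introscan run --vcf fix/panel.vcf --popmap fix/popmap.tsv \
    --h1 P1 --h2 P2 --h3 P3 --h4 O --out scan/
```

which writes `dstat.tsv`, `fd_scan.tsv`, `signals.tsv`/`signals.bed`,
`window_stats.tsv` (FST, d<sub>xy</sub>, π, Tajima's D per window),
`signal_validation.json`, haplotype evidence for the peak window, and a
`MANIFEST.json` + `run.log` that make the bundle exactly reproducible from
its config and seed.

Gene-flow levels from pairwise FST:

```python
>>> I.nm_from_fst(0.004)
62.25
```

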