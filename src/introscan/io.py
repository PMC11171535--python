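"""VCF and population-map input/output.

Reading goes through :mod:`cyvcf2`; only biallelic SNP records with a GT
field are kept (multiallelic, indel and symbolic records are skipped and
counted). Writing emits minimal GT-only VCF 4.2 text whose body
round-trips through :func:`read_vcf`.
"""

from __future__ import annotations

import logging
import os
from pathlib import Path

import numpy as np
from cyvcf2 import VCF

from .panel import MISSING, FilterConfig, GenotypePanel, PopulationMap, filter_variants

__all__ = [
    "read_vcf",
    "write_vcf",
    "read_popmap",
    "write_popmap",
    "filter_variants",
    "FilterConfig",
    "write_filter_report",
]

log = logging.getLogger(__name__)

_BASES = frozenset("ACGT")


def read_vcf(path: str | os.PathLike, samples: list[str] | None = None) -> GenotypePanel:
    """Read a VCF 4.x file into a :class:`GenotypePanel`.

    Parameters
    ----------
    path
        Plain or bgzipped VCF with GT genotypes.
    samples
        Optional sample subset (order preserved); absent names raise
        ``KeyError``.

    Non-SNP or multiallelic records are skipped; the skipped count is
    logged, not raised. Half-called genotypes (e.g. ``0/.``) are set to
    fully missing.
    """
    vcf = VCF(str(path), gts012=False)
    if samples is not None:
        absent = [s for s in samples if s not in vcf.samples]
        if absent:
            raise KeyError(f"requested samples absent from VCF: {absent}")
        vcf.set_samples(samples)
        sample_ids = list(vcf.samples)
    else:
        sample_ids = list(vcf.samples)

    chroms: list[str] = []
    poss: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    gts: list[np.ndarray] = []
    phased: list[np.ndarray] = []
    skipped = 0
    for var in vcf:
        if len(var.ALT) != 1 or var.REF not in _BASES or var.ALT[0] not in _BASES:
            skipped += 1
            continue
        # rows: [allele0, allele1, phased]; cyvcf2 codes missing as -1
        raw = np.asarray(var.genotypes, dtype=np.int64)
        g = raw[:, :2].astype(np.int8)
        half = (g == MISSING).any(axis=1)
        g[half] = MISSING  # half-calls -> fully missing
        chroms.append(var.CHROM)
        poss.append(var.POS)
        refs.append(var.REF)
        alts.append(var.ALT[0])
        gts.append(g)
        phased.append(raw[:, 2].astype(bool))
    vcf.close()
    if skipped:
        log.info("read_vcf: skipped %d non-biallelic-SNP records", skipped)

    n = len(poss)
    panel = GenotypePanel(
        chrom=np.asarray(chroms, dtype=object),
        pos=np.asarray(poss, dtype=np.int64),
        ref=np.asarray(refs, dtype=object),
        alt=np.asarray(alts, dtype=object),
        genotypes=(
            np.stack(gts) if n else np.empty((0, len(sample_ids), 2), dtype=np.int8)
        ),
        phased=(
            np.stack(phased) if n else np.empty((0, len(sample_ids)), dtype=bool)
        ),
        samples=sample_ids,
    )
    panel.validate()
    return panel


def write_vcf(
    panel: GenotypePanel,
    path: str | os.PathLike,
    extra_header: dict[str, str] | None = None,
) -> None:
    """Write a panel as GT-only VCF 4.2 text.

    ``extra_header`` entries become ``##key=value`` lines (used by the
    simulator to record its seed and configuration).
    """
    lines = ["##fileformat=VCFv4.2", "##source=introscan"]
    for key, value in (extra_header or {}).items():
        lines.append(f"##{key}={value}")
    for c in panel.chromosomes():
        length = int(panel.pos[panel.chrom == c].max()) if panel.n_sites else 0
        lines.append(f"##contig=<ID={c},length={max(length, 1)}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(panel.samples)
    )
    g = panel.genotypes
    ph = panel.phased
    for i in range(panel.n_sites):
        fields = [
            str(panel.chrom[i]),
            str(int(panel.pos[i])),
            ".",
            str(panel.ref[i]),
            str(panel.alt[i]),
            ".",
            "PASS",
            ".",
            "GT",
        ]
        row = []
        for j in range(panel.n_samples):
            a, b = g[i, j]
            sep = "|" if ph[i, j] else "/"
            row.append(
                "./." if a == MISSING else f"{a}{sep}{b}"
            )
        fields.extend(row)
        lines.append("\t".join(fields))
    Path(path).write_text("\n".join(lines) + "\n")


def read_popmap(path: str | os.PathLike) -> PopulationMap:
    """Read a headerless two-column TSV of ``sample<TAB>population``."""
    assignments: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated columns")
            sample, pop = parts
            if sample in assignments:
                raise ValueError(f"{path}:{lineno}: duplicate sample id {sample!r}")
            assignments[sample] = pop
    if not assignments:
        raise ValueError(f"{path}: empty population map")
    return PopulationMap(assignments=assignments)


def write_popmap(popmap: PopulationMap, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for sample, pop in popmap.assignments.items():
            fh.write(f"{sample}\t{pop}\n")


def write_filter_report(counts: dict[str, int], path: str | os.PathLike) -> None:
    """Emit per-rule removal counts as a two-column TSV ``rule\\tcount``."""
    with open(path, "w") as fh:
        for rule, count in counts.items():
            fh.write(f"{rule}\t{count}\n")
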