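"""Central genotype container and VCF input/output.

The pipeline operates on a :class:`VariantTable`: per-site metadata
(chromosome, position, alleles, site quality) together with a
samples x sites alt-allele dosage matrix and a matching read-depth
matrix.  Dosage is 0/1/2 with ``NaN`` marking a genotype the caller
reported as missing (``./.``).  Because the joint caller emits a
homozygous-reference call at zero-coverage positions, a dosage of 0
with depth 0 is *not* missing — that distinction is the heart of the
reference-bias diagnostics downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

SITE_COLUMNS = ["chrom", "pos", "ref", "alt", "qual"]


@dataclass
class VariantTable:
    """Biallelic SNP matrix for a multi-sample cohort.

    Parameters
    ----------
    sites
        DataFrame with columns ``chrom, pos, ref, alt, qual``; one row
        per site, unique by (chrom, pos), sorted by (chrom, pos) with
        chromosomes in file order.
    samples
        Sample identifiers, one per dosage row.
    dosage
        ``(n_samples, n_sites)`` float array of alt-allele counts in
        {0, 1, 2}; ``NaN`` where the genotype is missing.
    depth
        ``(n_samples, n_sites)`` integer array of per-sample read depth
        (DP); absent DP fields are recorded as 0.
    """

    sites: pd.DataFrame
    samples: list[str]
    dosage: np.ndarray
    depth: np.ndarray

    def __post_init__(self) -> None:
        self.sites = self.sites.reset_index(drop=True)
        self.dosage = np.asarray(self.dosage, dtype=float)
        self.depth = np.asarray(self.depth, dtype=int)
        n, j = len(self.samples), len(self.sites)
        if self.dosage.shape != (n, j) or self.depth.shape != (n, j):
            raise ValueError(
                f"matrix shapes {self.dosage.shape}/{self.depth.shape} do not "
                f"match {n} samples x {j} sites"
            )
        keys = list(zip(self.sites["chrom"], self.sites["pos"]))
        if len(set(keys)) != len(keys):
            raise ValueError("sites are not unique by (chrom, pos)")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def sample_index(self, sample_id: str) -> int:
        return self.samples.index(sample_id)

    def take_sites(self, idx) -> "VariantTable":
        """Subset to the given site indices (order preserved)."""
        idx = np.asarray(idx)
        return VariantTable(
            sites=self.sites.iloc[idx],
            samples=list(self.samples),
            dosage=self.dosage[:, idx],
            depth=self.depth[:, idx],
        )

    def take_samples(self, ids) -> "VariantTable":
        rows = [self.sample_index(s) for s in ids]
        return VariantTable(
            sites=self.sites,
            samples=list(ids),
            dosage=self.dosage[rows],
            depth=self.depth[rows],
        )


def read_vcf(path) -> VariantTable:
    """Read a multi-sample VCF into a :class:`VariantTable`.

    Only biallelic SNP records are kept; multi-allelic records and
    indels are dropped (a count is logged).  ``./.`` genotypes become
    ``NaN`` dosage; a missing DP field becomes depth 0.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    n = len(samples)

    rows, dosage_cols, depth_cols = [], [], []
    n_dropped = 0
    for variant in vcf:
        if len(variant.ALT) != 1 or not variant.is_snp:
            n_dropped += 1
            continue
        rows.append(
            (variant.CHROM, variant.POS, variant.REF, variant.ALT[0],
             float(variant.QUAL) if variant.QUAL is not None else 0.0)
        )
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = variant.gt_types.astype(float)
        dos = np.where(gt == 3, 2.0, gt)
        dos[gt == 2] = np.nan
        dosage_cols.append(dos)
        try:
            dp = variant.format("DP")
            dp = np.where(dp < 0, 0, dp).reshape(n)
        except (KeyError, TypeError):
            dp = np.zeros(n, dtype=int)
        depth_cols.append(dp)
    if n_dropped:
        log.info("read_vcf: dropped %d non-biallelic-SNP records", n_dropped)

    sites = pd.DataFrame(rows, columns=SITE_COLUMNS)
    if rows:
        dosage = np.column_stack(dosage_cols)
        depth = np.column_stack(depth_cols)
    else:
        dosage = np.empty((n, 0))
        depth = np.empty((n, 0), dtype=int)
    return VariantTable(sites=sites, samples=samples, dosage=dosage, depth=depth)


_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1"}


def write_vcf(table: VariantTable, path) -> None:
    """Write a VariantTable as VCF v4.2 with FORMAT GT:DP."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        for chrom in dict.fromkeys(table.sites["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(table.samples) + "\n")
        for j, site in enumerate(table.sites.itertuples(index=False)):
            calls = []
            for i in range(table.n_samples):
                d = table.dosage[i, j]
                gt = "./." if np.isnan(d) else _GT_STRINGS[int(d)]
                calls.append(f"{gt}:{table.depth[i, j]}")
            fh.write(
                f"{site.chrom}\t{site.pos}\t.\t{site.ref}\t{site.alt}\t"
                f"{site.qual:.2f}\t.\t.\tGT:DP\t" + "\t".join(calls) + "\n"
            )


@dataclass
class SampleSheet:
    """Sample metadata: id, putative species label, and (for synthetic
    data) the true simulation class."""

    frame: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["sample_id", "species_label", "truth_class"]))

    def write(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path) -> "SampleSheet":
        return cls(pd.read_csv(path, sep="\t", dtype=str))

    def labels_for(self, samples: list[str]) -> list[str | None]:
        """Putative species label per sample ('armigera'/'zea'/None)."""
        lookup = dict(zip(self.frame["sample_id"], self.frame["species_label"]))
        out = []
        for s in samples:
            lab = lookup.get(s)
            out.append(lab if lab in ("armigera", "zea") else None)
        return out
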