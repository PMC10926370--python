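"""Two-species genotype simulation with hybrids and caller artifacts.

The generator emulates the post-calling genotype matrix of a joint
variant-calling run over *Helicoverpa armigera* and *H. zea* genomes
mapped to an armigera-derived reference:

* population allele frequencies follow a Balding–Nichols divergence
  model parameterised by F_ST, with a configurable fraction of sites
  forced to fixed differences (the AIM-like sites);
* individuals are pure, F1, backcross, or arbitrarily admixed; the two
  allele copies of an admixed individual are drawn independently from
  the two populations' frequencies (unlinked-loci approximation);
* read depth is Poisson per sample per site, each read carries one of
  the individual's two allele copies uniformly at random, and —
  crucially — a zero-coverage position is emitted as homozygous
  *reference* (armigera-like) genotype, never as missing.  This is the
  reference bias the downstream diagnostics quantify.

The alt allele is defined relative to the armigera-like reference, so
at diagnostic sites the alt allele segregates in *H. zea*.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .variants import VariantTable, SampleSheet, write_vcf

PURE_ARMIGERA = "pure_armigera"
PURE_ZEA = "pure_zea"
F1 = "F1"
BC_TOWARD_A = "BC_toward_A"
BC_TOWARD_Z = "BC_toward_Z"
ADMIXED = "admixed"

_BC_Q = {BC_TOWARD_A: 0.75, BC_TOWARD_Z: 0.25}


@dataclass
class HybridSpec:
    """One block of hybrid individuals.

    kind is one of ``F1``, ``BC_toward_A``, ``BC_toward_Z`` or
    ``admixed``; ``q_armigera`` is required only for ``admixed`` and
    gives the armigera ancestry fraction.
    """

    kind: str
    count: int
    q_armigera: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in (F1, BC_TOWARD_A, BC_TOWARD_Z, ADMIXED):
            raise ValueError(f"unknown hybrid class {self.kind!r}")
        if self.count < 0:
            raise ValueError("count must be >= 0")
        if self.kind == ADMIXED:
            if self.q_armigera is None or not 0.0 <= self.q_armigera <= 1.0:
                raise ValueError("admixed class needs q_armigera in [0,1]")


@dataclass
class SimConfig:
    """Study conditions for one synthetic cohort.

    Defaults mirror the scale of the real study: a few-dozen-sample
    cohort at ~30x mean depth with moderate between-species divergence
    and 31 chromosomes of which chromosome 1 is the (excludable) sex
    chromosome.
    """

    n_sites: int = 5000
    n_chromosomes: int = 31
    fst: float = 0.3
    n_pure_armigera: int = 20
    n_pure_zea: int = 20
    hybrid_spec: list[HybridSpec] = field(default_factory=list)
    mean_depth: float = 30.0
    fixed_diff_fraction: float = 0.02
    low_qual_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        self.hybrid_spec = [
            h if isinstance(h, HybridSpec) else HybridSpec(**h)
            for h in self.hybrid_spec
        ]
        if not 0.0 < self.fst < 1.0:
            raise ValueError("fst must lie in (0, 1)")
        if min(self.n_sites, self.n_chromosomes,
               self.n_pure_armigera, self.n_pure_zea) < 0:
            raise ValueError("counts must be >= 0")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be > 0")
        if not 0.0 <= self.fixed_diff_fraction <= 1.0:
            raise ValueError("fixed_diff_fraction must lie in [0, 1]")

    def panel(self) -> pd.DataFrame:
        """Sample manifest: id, truth class, true armigera fraction."""
        rows = []
        for i in range(self.n_pure_armigera):
            rows.append((f"armA{i+1:03d}", PURE_ARMIGERA, "armigera", 1.0))
        for i in range(self.n_pure_zea):
            rows.append((f"zeaZ{i+1:03d}", PURE_ZEA, "zea", 0.0))
        counter = 0
        for h in self.hybrid_spec:
            q = {F1: 0.5, ADMIXED: h.q_armigera}.get(h.kind, _BC_Q.get(h.kind))
            for _ in range(h.count):
                counter += 1
                rows.append((f"hyb{counter:03d}", h.kind, "unknown", float(q)))
        return pd.DataFrame(
            rows, columns=["sample_id", "truth_class", "species_label", "q_armigera"]
        )

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class TruthSet:
    """Simulator ground truth, kept for parameter-recovery checks."""

    q_true: pd.DataFrame            # sample_id, q_armigera, q_zea
    freq_armigera: np.ndarray       # per-site alt-allele frequency
    freq_zea: np.ndarray
    genotype_true: np.ndarray       # (n_samples, n_sites) dosage before caller
    fixed_diff_sites: np.ndarray    # indices where |freq difference| == 1

    def __post_init__(self) -> None:
        qs = self.q_true[["q_armigera", "q_zea"]].to_numpy()
        if not np.allclose(qs.sum(axis=1), 1.0):
            raise ValueError("q_true rows must sum to 1")
        n, j = self.genotype_true.shape
        if len(self.q_true) != n or len(self.freq_armigera) != j:
            raise ValueError("TruthSet dimensions are inconsistent")


def draw_population_frequencies(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-site alt-allele frequencies for the two populations.

    Balding–Nichols model: an ancestral frequency p0 ~ Uniform(0.05,
    0.95) per site, each population's frequency drawn
    Beta(p0(1-F)/F, (1-p0)(1-F)/F) with F the configured F_ST.  A
    fraction of sites is then forced to fixed differences (armigera 0,
    zea 1, i.e. the alt allele is zea-diagnostic).

    Returns (freq_armigera, freq_zea, fixed_diff_sites).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    j = config.n_sites
    p0 = rng.uniform(0.05, 0.95, size=j)
    ratio = (1.0 - config.fst) / config.fst
    freq_a = rng.beta(p0 * ratio, (1.0 - p0) * ratio, size=j)
    freq_z = rng.beta(p0 * ratio, (1.0 - p0) * ratio, size=j)
    n_fixed = int(round(config.fixed_diff_fraction * j))
    fixed = rng.choice(j, size=n_fixed, replace=False) if n_fixed else np.array([], dtype=int)
    freq_a[fixed] = 0.0
    freq_z[fixed] = 1.0
    return freq_a, freq_z, np.sort(fixed)


def simulate_genotypes(
    freq_armigera: np.ndarray,
    freq_zea: np.ndarray,
    panel: pd.DataFrame,
    rng: np.random.Generator,
) -> np.ndarray:
    """True dosage matrix for the panel, prior to caller emulation.

    Pure individuals draw Binomial(2, freq); an F1 carries exactly one
    allele per parental population; an admixed(q) individual draws each
    of its two allele copies from the armigera frequency with
    probability q_armigera, else from the zea frequency.  Backcrosses
    are admixed with q = 0.75 / 0.25.
    """
    fa = np.asarray(freq_armigera, dtype=float)
    fz = np.asarray(freq_zea, dtype=float)
    if fa.shape != fz.shape or ((fa < 0) | (fa > 1) | (fz < 0) | (fz > 1)).any():
        raise ValueError("frequencies must be equal-length vectors in [0, 1]")
    j = fa.size
    geno = np.empty((len(panel), j), dtype=np.int8)
    for i, row in enumerate(panel.itertuples(index=False)):
        if row.truth_class == PURE_ARMIGERA:
            geno[i] = rng.binomial(2, fa)
        elif row.truth_class == PURE_ZEA:
            geno[i] = rng.binomial(2, fz)
        elif row.truth_class == F1:
            geno[i] = rng.binomial(1, fa) + rng.binomial(1, fz)
        else:  # admixed / backcross: two independent allele copies
            q = float(row.q_armigera)
            src = rng.random((2, j)) < q
            probs = np.where(src, fa, fz)
            geno[i] = (rng.random((2, j)) < probs).sum(axis=0)
    return geno


def emulate_caller(
    genotype_true: np.ndarray,
    mean_depth: float,
    rng: np.random.Generator,
    low_qual_fraction: float = 0.05,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Turn true genotypes into called dosage, DP and site QUAL.

    DP ~ Poisson(mean_depth) independently per sample and site; each
    read carries one of the individual's two allele copies uniformly at
    random; the call is homozygous if only one allele was observed,
    heterozygous if both.  DP = 0 yields dosage 0 — the homozygous-
    reference call of the joint caller, not a missing genotype.

    QUAL is a depth-linked stand-in: min(99, 3 x mean DP at the site),
    with ``low_qual_fraction`` of sites forced below 20 to exercise the
    quality filter.
    """
    if mean_depth <= 0:
        raise ValueError("mean_depth must be > 0")
    g = np.asarray(genotype_true)
    if not np.isin(g, (0, 1, 2)).all():
        raise ValueError("true dosages must be in {0, 1, 2}")
    dp = rng.poisson(mean_depth, size=g.shape)
    alt_reads = rng.binomial(dp, g / 2.0)
    called = np.ones_like(g, dtype=float)
    called[alt_reads == 0] = 0.0
    called[alt_reads == dp] = 2.0
    called[dp == 0] = 0.0  # zero coverage -> reference call

    qual = np.minimum(99.0, 3.0 * dp.mean(axis=0))
    n_low = int(round(low_qual_fraction * g.shape[1]))
    if n_low:
        low = rng.choice(g.shape[1], size=n_low, replace=False)
        qual[low] = rng.uniform(2.0, 19.5, size=n_low)
    return called, dp, qual


def _site_frame(config: SimConfig, qual: np.ndarray, rng: np.random.Generator) -> pd.DataFrame:
    """Assign sites to chromosomes round-robin; 1-based positions,
    sorted by (chrom, pos) with chromosomes in numeric order."""
    j = config.n_sites
    chrom_idx = np.arange(j) % max(config.n_chromosomes, 1)
    pos_within = np.arange(j) // max(config.n_chromosomes, 1)
    bases = np.array(list("ACGT"))
    ref = rng.integers(0, 4, size=j)
    alt = (ref + rng.integers(1, 4, size=j)) % 4
    frame = pd.DataFrame({
        "chrom": [f"chr{c + 1}" for c in chrom_idx],
        "pos": (pos_within + 1) * 100,
        "ref": bases[ref],
        "alt": bases[alt],
        "qual": qual,
        "_order": chrom_idx * 10**9 + pos_within,
    })
    frame = frame.sort_values("_order", kind="stable").drop(columns="_order")
    return frame.reset_index(drop=True)


@dataclass
class SimulatedDataset:
    table: VariantTable
    truth: TruthSet
    sheet: SampleSheet
    config: SimConfig


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Run the full generator in memory: frequencies, genotypes, caller."""
    rng = np.random.default_rng(config.seed)
    freq_a, freq_z, fixed = draw_population_frequencies(config, rng)
    panel = config.panel()
    geno = simulate_genotypes(freq_a, freq_z, panel, rng)
    called, dp, qual = emulate_caller(
        geno, config.mean_depth, rng, config.low_qual_fraction
    )
    sites = _site_frame(config, qual, rng)
    # _site_frame sorts rows by (chrom, pos); apply the same permutation
    # to the matrices and remap the fixed-difference indices
    perm = _raw_order(config)
    called = called[:, perm]
    dp = dp[:, perm]
    geno = geno[:, perm]
    freq_a, freq_z = freq_a[perm], freq_z[perm]
    fixed = np.sort(np.argsort(perm)[fixed]) if fixed.size else fixed

    table = VariantTable(
        sites=sites,
        samples=list(panel["sample_id"]),
        dosage=called,
        depth=dp,
    )
    truth = TruthSet(
        q_true=pd.DataFrame({
            "sample_id": panel["sample_id"],
            "q_armigera": panel["q_armigera"],
            "q_zea": 1.0 - panel["q_armigera"],
        }),
        freq_armigera=freq_a,
        freq_zea=freq_z,
        genotype_true=geno,
        fixed_diff_sites=fixed,
    )
    sheet = SampleSheet(panel[["sample_id", "species_label", "truth_class"]].copy())
    return SimulatedDataset(table=table, truth=truth, sheet=sheet, config=config)


def _raw_order(config: SimConfig) -> np.ndarray:
    """Permutation from raw site index to (chrom, pos)-sorted order."""
    j = config.n_sites
    nc = max(config.n_chromosomes, 1)
    chrom_idx = np.arange(j) % nc
    pos_within = np.arange(j) // nc
    return np.lexsort((pos_within, chrom_idx))


def generate_dataset(config: SimConfig, out_dir) -> dict[str, Path]:
    """Write a synthetic cohort to disk: VCF, sample sheet, truth manifest.

    Returns a dict of output paths plus the in-memory dataset under
    key ``"dataset"``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ds = simulate_dataset(config)

    vcf_path = out / "cohort.vcf"
    write_vcf(ds.table, vcf_path)
    sheet_path = out / "samples.tsv"
    ds.sheet.write(sheet_path)

    truth = ds.truth
    manifest = {
        "config": config.to_dict(),
        "q_true": truth.q_true.to_dict(orient="list"),
        "freq_armigera": truth.freq_armigera.round(8).tolist(),
        "freq_zea": truth.freq_zea.round(8).tolist(),
        "fixed_diff_sites": truth.fixed_diff_sites.tolist(),
        "genotype_true_sha256": hashlib.sha256(
            truth.genotype_true.tobytes()
        ).hexdigest(),
    }
    manifest_path = out / "truth.json"
    manifest_path.write_text(json.dumps(manifest, indent=1))
    geno_path = out / "genotype_true.tsv"
    pd.DataFrame(
        truth.genotype_true.T, columns=list(ds.table.samples)
    ).to_csv(geno_path, sep="\t", index=False)
    return {
        "vcf": vcf_path,
        "sample_sheet": sheet_path,
        "manifest": manifest_path,
        "genotype_true": geno_path,
        "dataset": ds,
    }


def hudson_fst(freq_a: np.ndarray, freq_z: np.ndarray,
               n_a: int, n_z: int) -> float:
    """Hudson-type F_ST estimator from sample allele frequencies.

    Per-site numerator (p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1),
    denominator p1(1-p2) + p2(1-p1); ratio of averages across sites.
    ``n_a``/``n_z`` are allele counts (2x individuals).
    """
    p1, p2 = np.asarray(freq_a, float), np.asarray(freq_z, float)
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n_a - 1) - p2 * (1 - p2) / (n_z - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    keep = den > 0
    return float(num[keep].sum() / den[keep].sum())
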