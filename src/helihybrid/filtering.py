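"""Site-level filters applied to the joint-call variant matrix.

A site is retained iff it passes *all* of: mean read depth across all
samples >= min_mean_dp, site quality >= min_qual, minor allele
frequency >= min_maf, and not on an excluded chromosome (the sex
chromosome, chr1, by default).  Thresholds are inclusive on the keep
side — the removal conditions are strict "<".  Mean depth includes
samples at DP=0, consistent with the caller emitting reference calls
there; MAF is computed jointly across all samples, mirroring the joint
SNP-calling run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .variants import VariantTable


def compute_maf(dosages: np.ndarray) -> float:
    """Minor-allele frequency of one site from per-sample dosages.

    Missing (NaN) genotypes are excluded from both numerator and
    denominator.  All-missing sites return NaN (treated downstream as
    failing the MAF filter).
    """
    d = np.asarray(dosages, dtype=float)
    called = ~np.isnan(d)
    n = called.sum()
    if n == 0:
        return float("nan")
    alt = np.nansum(d) / (2.0 * n)
    return float(min(alt, 1.0 - alt))


def site_mafs(table: VariantTable) -> np.ndarray:
    """Vectorised per-site MAF over all samples."""
    called = ~np.isnan(table.dosage)
    n = called.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        alt = np.nansum(table.dosage, axis=0) / (2.0 * n)
    alt[n == 0] = np.nan
    return np.minimum(alt, 1.0 - alt)


@dataclass
class FilterReport:
    """Per-criterion removal counts; criteria are evaluated on the
    unfiltered table, so a site failing two criteria is counted once
    per criterion and once in the union."""

    n_input: int
    n_retained: int
    n_fail_depth: int
    n_fail_qual: int
    n_fail_maf: int
    n_fail_chrom: int

    @property
    def n_removed(self) -> int:
        return self.n_input - self.n_retained

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "criterion": ["mean_depth", "qual", "maf", "chromosome", "union"],
                "n_removed": [
                    self.n_fail_depth, self.n_fail_qual, self.n_fail_maf,
                    self.n_fail_chrom, self.n_removed,
                ],
            }
        )


class SiteFilter(BaseEstimator):
    """Sklearn-style transformer applying the site-level filters.

    Parameters
    ----------
    min_mean_dp : float, default 5
        Keep sites whose mean DP over all samples is >= this value.
    min_qual : float, default 20
        Keep sites with QUAL >= this value.
    min_maf : float, default 0.05
        Keep sites with joint minor-allele frequency >= this value.
    exclude_chroms : tuple of str, default ("chr1",)
        Chromosomes dropped entirely (the lepidopteran Z chromosome).

    Attributes (after :meth:`fit`)
    ------------------------------
    keep_mask_ : boolean array over input sites
    report_ : :class:`FilterReport`
    """

    def __init__(self, min_mean_dp: float = 5.0, min_qual: float = 20.0,
                 min_maf: float = 0.05, exclude_chroms: tuple = ("chr1",)):
        self.min_mean_dp = min_mean_dp
        self.min_qual = min_qual
        self.min_maf = min_maf
        self.exclude_chroms = exclude_chroms

    def fit(self, table: VariantTable, y=None) -> "SiteFilter":
        if self.min_mean_dp < 0 or self.min_qual < 0:
            raise ValueError("thresholds must be >= 0")
        if not 0.0 <= self.min_maf <= 0.5:
            raise ValueError("min_maf must lie in [0, 0.5]")
        mean_dp = (table.depth.mean(axis=0) if table.n_samples
                   else np.zeros(table.n_sites))
        maf = site_mafs(table)
        pass_depth = mean_dp >= self.min_mean_dp
        pass_qual = table.sites["qual"].to_numpy() >= self.min_qual
        with np.errstate(invalid="ignore"):
            pass_maf = maf >= self.min_maf  # NaN MAF fails
        pass_chrom = ~table.sites["chrom"].isin(self.exclude_chroms).to_numpy()
        self.keep_mask_ = pass_depth & pass_qual & pass_maf & pass_chrom
        self.report_ = FilterReport(
            n_input=table.n_sites,
            n_retained=int(self.keep_mask_.sum()),
            n_fail_depth=int((~pass_depth).sum()),
            n_fail_qual=int((~pass_qual).sum()),
            n_fail_maf=int((~pass_maf).sum()),
            n_fail_chrom=int((~pass_chrom).sum()),
        )
        return self

    def transform(self, table: VariantTable) -> VariantTable:
        return table.take_sites(np.flatnonzero(self.keep_mask_))

    def fit_transform(self, table: VariantTable, y=None) -> VariantTable:
        return self.fit(table).transform(table)


def apply_site_filters(table: VariantTable, spec: SiteFilter | None = None,
                       **params) -> tuple[VariantTable, FilterReport]:
    """Functional wrapper: filter a table, return (filtered, report)."""
    flt = spec if spec is not None else SiteFilter(**params)
    out = flt.fit_transform(table)
    return out, flt.report_
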