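"""Linkage-disequilibrium pruning on genotype dosages.

The ancestry model assumes unlinked loci; highly correlated SNP pairs
are thinned with a plink-style sliding window.  r² is the squared
Pearson correlation of unphased allele dosages over jointly called
samples (genotypes are unphased, so haplotype LD is out of reach).
Within each window of ``window_size`` consecutive SNPs, while any
retained pair exceeds ``r2_max``, the member of the worst (highest-r²)
pair with the lower MAF is removed (ties: the later position goes);
the window then advances by ``window_step`` SNPs.  Windows never span
chromosomes.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .filtering import site_mafs
from .variants import VariantTable


def genotype_r2(dosages_a, dosages_b) -> float:
    """Squared Pearson correlation of two dosage vectors.

    Pairs with a missing value on either side are dropped; a constant
    vector (zero variance) or fewer than 2 jointly called samples gives
    0 by convention.
    """
    a = np.asarray(dosages_a, dtype=float)
    b = np.asarray(dosages_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("dosage vectors must have equal length")
    ok = ~(np.isnan(a) | np.isnan(b))
    a, b = a[ok], b[ok]
    if a.size < 2:
        return 0.0
    va, vb = a.var(), b.var()
    if va == 0.0 or vb == 0.0:
        return 0.0
    cov = ((a - a.mean()) * (b - b.mean())).mean()
    return float(cov * cov / (va * vb))


def _pairwise_r2(dosage: np.ndarray) -> np.ndarray:
    """Pairwise-complete r² matrix for a (samples x sites) block."""
    m = ~np.isnan(dosage)
    x = np.where(m, dosage, 0.0)
    mf = m.astype(float)
    n = mf.T @ mf                      # jointly called counts
    sx = x.T @ mf                      # sum of site-j dosage over joint calls
    sxx = (x * x).T @ mf
    sxy = x.T @ x
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = n * sxy - sx * sx.T
        var_j = n * sxx - sx * sx
        denom = var_j * var_j.T
        r2 = np.where(denom > 0, cov * cov / denom, 0.0)
    r2[n < 2] = 0.0
    # guard float overshoot
    return np.clip(r2, 0.0, 1.0)


class LDPruner(BaseEstimator):
    """Sliding-window pairwise LD pruner (sklearn-style transformer).

    Parameters
    ----------
    r2_max : float, default 0.95
        Dosage-r² ceiling for retained pairs.
    window_size : int, default 50
        Window width in SNPs.
    window_step : int, default 5
        Window advance in SNPs (must be <= window_size).

    Attributes (after :meth:`fit`)
    ------------------------------
    retained_idx_ : integer indices of retained sites, order-preserving
    n_removed_ : int
    """

    def __init__(self, r2_max: float = 0.95, window_size: int = 50,
                 window_step: int = 5):
        self.r2_max = r2_max
        self.window_size = window_size
        self.window_step = window_step

    def fit(self, table: VariantTable, y=None) -> "LDPruner":
        if not 0.0 < self.r2_max <= 1.0:
            raise ValueError("r2_max must lie in (0, 1]")
        if self.window_step > self.window_size or self.window_step < 1:
            raise ValueError("require 1 <= window_step <= window_size")
        maf = site_mafs(table)
        keep = np.ones(table.n_sites, dtype=bool)
        chroms = table.sites["chrom"].to_numpy()
        for chrom in dict.fromkeys(chroms):
            idx = np.flatnonzero(chroms == chrom)
            self._prune_chrom(table, idx, maf, keep)
        self.retained_idx_ = np.flatnonzero(keep)
        self.n_removed_ = int(table.n_sites - self.retained_idx_.size)
        return self

    def _prune_chrom(self, table: VariantTable, idx: np.ndarray,
                     maf: np.ndarray, keep: np.ndarray) -> None:
        n = idx.size
        for start in range(0, max(n - 1, 1), self.window_step):
            win = idx[start:start + self.window_size]
            win = win[keep[win]]
            if win.size < 2:
                continue
            r2 = _pairwise_r2(table.dosage[:, win])
            np.fill_diagonal(r2, 0.0)
            alive = np.ones(win.size, dtype=bool)
            while True:
                sub = np.where(np.outer(alive, alive), r2, 0.0)
                worst = sub.max()
                if worst <= self.r2_max:
                    break
                a, b = np.unravel_index(np.argmax(sub), sub.shape)
                # remove the lower-MAF member; tie -> larger position index
                sa, sb = win[a], win[b]
                if maf[sa] < maf[sb]:
                    drop = a
                elif maf[sb] < maf[sa]:
                    drop = b
                else:
                    drop = max(a, b)
                alive[drop] = False
                keep[win[drop]] = False

    def transform(self, table: VariantTable) -> VariantTable:
        return table.take_sites(self.retained_idx_)

    def fit_transform(self, table: VariantTable, y=None) -> VariantTable:
        return self.fit(table).transform(table)


def prune(table: VariantTable, spec: LDPruner | None = None,
          **params) -> np.ndarray:
    """Functional wrapper: return retained site indices."""
    pruner = spec if spec is not None else LDPruner(**params)
    pruner.fit(table)
    return pruner.retained_idx_
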