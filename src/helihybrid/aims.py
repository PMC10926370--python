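"""Ancestry-informative markers (AIMs) and reference-bias diagnostics.

Discovery rule (zea-diagnostic, alt allele relative to the
armigera-like reference): a site is an AIM iff

* every genome of the unhybridized *H. zea* reference panel carries at
  least one alt allele (no 0/0 and no missing call), and
* at most one genome of the unhybridized *H. armigera* reference panel
  carries the alt allele.

Scoring: the per-sample zea-AIM proportion, either dosage-coded
(alt-allele count over 2x scored AIMs — the coding whose analytic F1
expectation is exactly 50%) or presence-coded (fraction of AIMs with
any alt allele).  Because zero-coverage positions are called as the
armigera reference, low depth deflates the zea proportion of a zea
genome; the DP-threshold mask quantifies and removes that bias.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .variants import VariantTable

DOSAGE = "dosage"
PRESENCE = "presence"


@dataclass
class AIMSet:
    """Diagnostic sites with per-site provenance counts."""

    frame: pd.DataFrame  # chrom, pos, site_idx, n_zea_carriers, n_armigera_carriers

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def site_idx(self) -> np.ndarray:
        return self.frame["site_idx"].to_numpy()

    def to_bed_frame(self, table: VariantTable) -> pd.DataFrame:
        """BED-like export: chrom, 0-based start, 1-based end,
        diagnostic (alt) allele, carrier counts."""
        alt = table.sites["alt"].to_numpy()[self.site_idx]
        return pd.DataFrame({
            "chrom": self.frame["chrom"],
            "start": self.frame["pos"] - 1,
            "end": self.frame["pos"],
            "diagnostic_allele": alt,
            "n_zea_carriers": self.frame["n_zea_carriers"],
            "n_armigera_carriers": self.frame["n_armigera_carriers"],
        })


class AIMFinder(BaseEstimator):
    """Sklearn-style discovery of zea-diagnostic markers.

    Parameters
    ----------
    max_armigera_carriers : int, default 1
        Maximum number of armigera reference genomes allowed to carry
        the diagnostic allele (0 = strictly private to zea).

    Attributes (after :meth:`fit`)
    ------------------------------
    aims_ : :class:`AIMSet`
    """

    def __init__(self, max_armigera_carriers: int = 1):
        self.max_armigera_carriers = max_armigera_carriers

    def fit(self, table: VariantTable, zea_ids: list[str],
            armigera_ids: list[str]) -> "AIMFinder":
        if not zea_ids:
            raise ValueError("empty zea reference panel: AIM criterion undefined")
        zi = [table.sample_index(s) for s in zea_ids]
        ai = [table.sample_index(s) for s in armigera_ids]
        dz = table.dosage[zi]
        da = table.dosage[ai]
        # every zea genome carries the alt allele; a missing call cannot
        # certify presence, so it disqualifies the site
        all_zea = (~np.isnan(dz) & (dz >= 1)).all(axis=0)
        n_arm = (np.nan_to_num(da, nan=0.0) >= 1).sum(axis=0) if ai else \
            np.zeros(table.n_sites, dtype=int)
        is_aim = all_zea & (n_arm <= self.max_armigera_carriers)
        idx = np.flatnonzero(is_aim)
        self.aims_ = AIMSet(pd.DataFrame({
            "chrom": table.sites["chrom"].to_numpy()[idx],
            "pos": table.sites["pos"].to_numpy()[idx],
            "site_idx": idx,
            "n_zea_carriers": len(zi),
            "n_armigera_carriers": np.asarray(n_arm)[idx].astype(int),
        }))
        return self


def discover_aims(table: VariantTable, zea_ids: list[str],
                  armigera_ids: list[str],
                  max_armigera_carriers: int = 1) -> AIMSet:
    """Functional wrapper over :class:`AIMFinder`."""
    finder = AIMFinder(max_armigera_carriers=max_armigera_carriers)
    return finder.fit(table, zea_ids, armigera_ids).aims_


def aim_ancestry_proportion(dosage: np.ndarray, aims: AIMSet,
                            coding: str = DOSAGE,
                            depth: np.ndarray | None = None,
                            mask_below_dp: int | None = None
                            ) -> tuple[float, int]:
    """Percentage of zea-specific AIM alleles carried by one sample.

    ``dosage``/``depth`` are the sample's full site vectors; AIM sites
    are selected internally.  With ``mask_below_dp`` set, AIMs whose DP
    is below the threshold are excluded from numerator and denominator
    (the low-coverage reference-bias mask).  Returns (percentage,
    n_scored); all AIMs masked gives (NaN, 0) with a warning.
    """
    if len(aims) == 0:
        raise ValueError("AIM set is empty")
    if coding not in (DOSAGE, PRESENCE):
        raise ValueError(f"unknown coding {coding!r}")
    d = np.asarray(dosage, float)[aims.site_idx]
    keep = ~np.isnan(d)
    if mask_below_dp is not None:
        if depth is None:
            raise ValueError("mask_below_dp requires the sample's DP vector")
        keep &= np.asarray(depth)[aims.site_idx] >= mask_below_dp
    n_scored = int(keep.sum())
    if n_scored == 0:
        warnings.warn("all AIMs masked; proportion undefined", stacklevel=2)
        return float("nan"), 0
    d = d[keep]
    if coding == DOSAGE:
        return float(100.0 * d.sum() / (2.0 * n_scored)), n_scored
    return float(100.0 * (d >= 1).sum() / n_scored), n_scored


def depth_diagnostics(depth: np.ndarray, aims: AIMSet,
                      dp_threshold: int = 5
                      ) -> tuple[int, int, np.ndarray]:
    """Low-coverage accounting over AIM positions for one sample.

    Returns (#AIMs with DP=0, #AIMs with DP<threshold, flagged site
    indices for masking).
    """
    dp = np.asarray(depth)[aims.site_idx]
    below = dp < dp_threshold
    return int((dp == 0).sum()), int(below.sum()), aims.site_idx[below]


def aim_report(table: VariantTable, aims: AIMSet, dp_threshold: int = 5
               ) -> pd.DataFrame:
    """Per-sample AIM summary: both codings, depth diagnostics, and the
    masked (DP >= threshold) dosage-coded proportion."""
    rows = []
    for i, sample in enumerate(table.samples):
        d, dp = table.dosage[i], table.depth[i]
        prop_dos, _ = aim_ancestry_proportion(d, aims, DOSAGE)
        prop_pres, _ = aim_ancestry_proportion(d, aims, PRESENCE)
        n0, nlow, _ = depth_diagnostics(dp, aims, dp_threshold)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            prop_masked, n_scored = aim_ancestry_proportion(
                d, aims, DOSAGE, depth=dp, mask_below_dp=dp_threshold)
        rows.append((sample, prop_dos, prop_pres, n0, nlow,
                     prop_masked, n_scored))
    return pd.DataFrame(rows, columns=[
        "sample_id", "prop_zea_dosage", "prop_zea_presence",
        "n_aims_dp0", "n_aims_dp_below_thresh", "prop_zea_masked",
        "n_aims_scored",
    ])
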