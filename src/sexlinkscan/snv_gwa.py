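"""SNV-based genome-wide association scan with site filtering.

Sites are filtered (biallelic only; genotypes at depth < 20 set missing;
minor allele frequency > 0.05 required; sites with more than half the
genotypes missing dropped), then each surviving site is tested for
sex association with the shared 2x3 contingency chi-square, Bonferroni-
corrected over the number of sites tested.

Run against an unmasked reference that still contains a recently
duplicated paralog of a male-specific region, this scan reproduces the
classic cross-mapping artifact: male-only reads pile onto the paralog and
fake perfectly sex-associated heterozygous sites.  After hard-masking the
duplicated regions the artifact disappears.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Tuple

import numpy as np
import pandas as pd

from . import stats
from .cnv_gwa import PLOT_P_FLOOR, qq_export  # shared export conventions
from .genotypes import SnvGenotypeTable

__all__ = ["SiteFilterConfig", "filter_sites", "snv_gwa_scan", "qq_export"]


@dataclass(frozen=True)
class SiteFilterConfig:
    min_depth: int = 20
    require_biallelic: bool = True
    maf_min: float = 0.05
    max_missing_frac: float = 0.5
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not (0 <= self.maf_min < 0.5):
            raise ValueError("maf_min must be in [0, 0.5)")
        if self.min_depth < 0:
            raise ValueError("min_depth must be >= 0")


def _maf(gt_row: np.ndarray) -> float:
    """Minor allele frequency from called genotypes (2n allele counting,
    missing excluded)."""
    called = gt_row[gt_row >= 0]
    if called.size == 0:
        return 0.0
    alt = int(called.sum())  # codes 0/1/2 = alt allele dosage
    total = 2 * called.size
    return min(alt, total - alt) / total


def filter_sites(
    table: SnvGenotypeTable,
    cfg: SiteFilterConfig = SiteFilterConfig(),
) -> Tuple[SnvGenotypeTable, Dict[str, int]]:
    """Apply the site filters; returns the filtered table and per-filter
    removal counts.

    Order of application: non-biallelic removal, then depth-based genotype
    masking, then missingness, then MAF.  The filters commute on the final
    site set (each is a per-site predicate on the depth-masked genotypes).
    """
    removed = {"non_biallelic": 0, "high_missing": 0, "low_maf": 0}
    n = table.n_sites
    gt = table.gt.copy()
    gt[table.dp < cfg.min_depth] = -1

    keep = np.ones(n, dtype=bool)
    if cfg.require_biallelic and n:
        # a site written with a degenerate alt (or flagged multi-allelic
        # upstream) is non-biallelic; in-table convention: alt == ref or
        # alt not a single base marks such sites
        bad = (table.sites["alt"].str.len() != 1) | \
              (table.sites["ref"].str.len() != 1) | \
              (table.sites["alt"] == table.sites["ref"])
        removed["non_biallelic"] = int(bad.sum())
        keep &= ~bad.to_numpy()

    if n:
        missing_frac = (gt == -1).mean(axis=1)
        bad = keep & (missing_frac > cfg.max_missing_frac)
        removed["high_missing"] = int(bad.sum())
        keep &= ~bad

        mafs = np.array([_maf(gt[i]) for i in range(n)])
        bad = keep & (mafs <= cfg.maf_min)
        removed["low_maf"] = int(bad.sum())
        keep &= ~bad

    out = SnvGenotypeTable(
        sites=table.sites.loc[keep].reset_index(drop=True),
        gt=gt[keep], dp=table.dp[keep], samples=table.samples)
    return out, removed


def snv_gwa_scan(
    table: SnvGenotypeTable,
    sexes: Mapping[str, str],
    cfg: SiteFilterConfig = SiteFilterConfig(),
) -> pd.DataFrame:
    """Per-site contingency GWA after filtering.

    Returns a DataFrame with scaffold, pos, ref, alt, chi2, dof, p,
    neglog10_p (floored at 1e-15 for plotting; raw p retained) and the
    Bonferroni ``significant`` flag at alpha / (sites tested).
    """
    sex_vec = np.array([sexes[s] for s in table.samples])
    if (sex_vec == "M").sum() < 2 or (sex_vec == "F").sum() < 2:
        raise ValueError("need at least two samples per sex")
    filtered, _ = filter_sites(table, cfg)
    rows = []
    for i in range(filtered.n_sites):
        chi2, dof, p = stats.gwa_contingency(filtered.gt[i], sex_vec)
        rows.append({
            "scaffold": filtered.sites.at[i, "scaffold"],
            "pos": filtered.sites.at[i, "pos"],
            "ref": filtered.sites.at[i, "ref"],
            "alt": filtered.sites.at[i, "alt"],
            "chi2": chi2, "dof": dof, "p": p,
        })
    df = pd.DataFrame(rows, columns=["scaffold", "pos", "ref", "alt",
                                     "chi2", "dof", "p"])
    thr = stats.bonferroni_threshold(cfg.alpha, len(df))
    if len(df):
        df["neglog10_p"] = -np.log10(np.maximum(df["p"], PLOT_P_FLOOR))
        df["significant"] = df["p"] < thr
    else:
        df["neglog10_p"] = pd.Series(dtype=float)
        df["significant"] = pd.Series(dtype=bool)
    return df
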