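"""Multi-sample SNV genotype table (VCF-like TSV).

Genotypes are coded 0 (0/0), 1 (0/1), 2 (1/1), -1 (./., missing); each
genotype travels with its per-sample read depth.  The on-disk form is a
tab-separated table with columns scaffold, pos (1-based), ref, alt and one
``GT:DP`` column per sample.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, Tuple

import numpy as np
import pandas as pd

GT_LABELS = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
GT_CODES = {v: k for k, v in GT_LABELS.items()}


@dataclass
class SnvGenotypeTable:
    #: columns scaffold, pos (1-based), ref, alt; one row per site
    sites: pd.DataFrame
    #: sites x samples genotype codes (int8)
    gt: np.ndarray
    #: sites x samples read depth (int32)
    dp: np.ndarray
    samples: Tuple[str, ...]

    def __post_init__(self) -> None:
        n = len(self.sites)
        if self.gt.shape != (n, len(self.samples)) or \
                self.dp.shape != (n, len(self.samples)):
            raise ValueError("gt/dp shape does not match sites x samples")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def subset(self, mask: np.ndarray) -> "SnvGenotypeTable":
        return SnvGenotypeTable(
            sites=self.sites.loc[mask].reset_index(drop=True),
            gt=self.gt[mask], dp=self.dp[mask], samples=self.samples)

    def to_tsv(self, path: str | Path) -> None:
        df = self.sites.copy()
        for j, s in enumerate(self.samples):
            df[s] = [f"{GT_LABELS[int(g)]}:{int(d)}"
                     for g, d in zip(self.gt[:, j], self.dp[:, j])]
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SnvGenotypeTable":
        df = pd.read_csv(path, sep="\t", dtype={"scaffold": str})
        fixed = ["scaffold", "pos", "ref", "alt"]
        samples = tuple(c for c in df.columns if c not in fixed)
        n = len(df)
        gt = np.empty((n, len(samples)), dtype=np.int8)
        dp = np.empty((n, len(samples)), dtype=np.int32)
        for j, s in enumerate(samples):
            parts = df[s].str.split(":", expand=True)
            gt[:, j] = parts[0].map(GT_CODES).to_numpy(dtype=np.int8)
            dp[:, j] = parts[1].astype(np.int32)
        return cls(sites=df[fixed].copy(), gt=gt, dp=dp, samples=samples)

    @classmethod
    def build(cls, rows: Sequence[dict], samples: Sequence[str]
              ) -> "SnvGenotypeTable":
        """Assemble from dicts with keys scaffold/pos/ref/alt/gt/dp where gt
        and dp are per-sample sequences in ``samples`` order."""
        samples = tuple(samples)
        sites = pd.DataFrame([{k: r[k] for k in
                               ("scaffold", "pos", "ref", "alt")}
                              for r in rows])
        gt = np.array([r["gt"] for r in rows], dtype=np.int8).reshape(
            len(rows), len(samples))
        dp = np.array([r["dp"] for r in rows], dtype=np.int32).reshape(
            len(rows), len(samples))
        return cls(sites=sites, gt=gt, dp=dp, samples=samples)
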