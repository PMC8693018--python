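"""Relative read-depth analysis.

Shotgun read depth is proportional to copy number: a locus present on both
chromosome sets of a diploid sample sits at the scaffold-typical depth, a
hemizygous (single-copy) locus at about half of it, and an absent locus at
zero.  Normalizing per-site depth by the per-scaffold median depth therefore
turns raw coverage into an estimate of relative copy number (diploid = 1),
which is the core signal used to recognise a male-specific, paternally
inherited insertion: relative depth ~0.5 in every male and ~0 in every
female.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

#: canonical relative-copy-number grid (diploid = 1)
CN_GRID = (0.0, 0.5, 1.0, 1.5, 2.0)

PLOIDY_LABELS = {0.0: "absent", 0.5: "haploid", 1.0: "diploid",
                 1.5: "higher", 2.0: "higher"}


class NormalizationError(ValueError):
    """Raised when the per-scaffold median depth is zero."""


@dataclass
class DepthTable:
    """Dense per-site read depth for one sample.

    ``depths`` maps scaffold name to a vector whose index i holds the depth
    at 1-based position i+1.  Vectors are treated as immutable once the
    table is built; per-scaffold medians are cached on first use.
    """

    sample: str
    depths: Dict[str, np.ndarray]
    _medians: Dict[str, float] = field(default_factory=dict, repr=False)

    def median(self, scaffold: str) -> float:
        if scaffold not in self._medians:
            self._medians[scaffold] = float(np.median(self.depths[scaffold]))
        return self._medians[scaffold]

    def scaffold_length(self, scaffold: str) -> int:
        return int(self.depths[scaffold].size)

    def to_tsv(self, path: str | Path) -> None:
        """Write the 3-column (scaffold, 1-based position, depth) layout."""
        with open(path, "w") as fh:
            for name, vec in self.depths.items():
                df = pd.DataFrame(
                    {"scaffold": name,
                     "pos": np.arange(1, vec.size + 1),
                     "depth": vec}
                )
                df.to_csv(fh, sep="\t", header=False, index=False)

    @classmethod
    def from_tsv(
        cls,
        path: str | Path,
        sample: str | None = None,
        scaffold_lengths: Mapping[str, int] | None = None,
    ) -> "DepthTable":
        """Read a samtools-depth-style TSV.  Positions absent from the file
        get depth 0; vector lengths come from ``scaffold_lengths`` when given,
        otherwise from the maximum position seen per scaffold."""
        df = pd.read_csv(path, sep="\t", header=None,
                         names=["scaffold", "pos", "depth"])
        depths: Dict[str, np.ndarray] = {}
        for name, grp in df.groupby("scaffold", sort=False):
            length = (scaffold_lengths[name] if scaffold_lengths
                      else int(grp["pos"].max()))
            vec = np.zeros(length, dtype=np.int32)
            vec[grp["pos"].to_numpy() - 1] = grp["depth"].to_numpy()
            depths[str(name)] = vec
        return cls(sample=sample or Path(path).stem, depths=depths)


@dataclass(frozen=True)
class RelativeDepthReport:
    sample: str
    scaffold: str
    start: int  # 0-based half-open
    end: int
    mean_rel_depth: float
    ploidy_class: str


def relative_depth(table: DepthTable, scaffold: str, start: int, end: int) -> float:
    """Mean over [start, end) of per-site depth divided by the scaffold median.

    Zero-depth sites count in both the median and the mean: excluding them
    would bias absent regions upward.
    """
    vec = table.depths[scaffold]
    if not (0 <= start < end <= vec.size):
        raise ValueError(f"region [{start},{end}) outside {scaffold} "
                         f"(length {vec.size})")
    med = table.median(scaffold)
    if med <= 0:
        raise NormalizationError(
            f"median depth of {scaffold} in sample {table.sample} is 0")
    return float(vec[start:end].mean() / med)


def classify_ploidy(rel: float, tol: float = 0.15,
                    grid: Sequence[float] = CN_GRID) -> str:
    """Snap a mean relative depth to the nearest copy-number grid point.

    Returns 'absent' (0), 'haploid' (0.5), 'diploid' (1), 'higher' (>=1.5)
    or 'unresolved' when no grid point lies within ``tol``.
    """
    if rel < 0:
        raise ValueError("relative depth must be non-negative")
    grid = np.asarray(grid, dtype=float)
    idx = int(np.argmin(np.abs(grid - rel)))
    if abs(grid[idx] - rel) > tol:
        return "unresolved"
    return PLOIDY_LABELS[float(grid[idx])]


def region_report(table: DepthTable, scaffold: str, start: int, end: int,
                  tol: float = 0.15) -> RelativeDepthReport:
    rel = relative_depth(table, scaffold, start, end)
    return RelativeDepthReport(table.sample, scaffold, start, end,
                               rel, classify_ploidy(rel, tol=tol))


def sexed_region_profile(
    reports: Iterable[RelativeDepthReport],
    sexes: Mapping[str, str],
) -> str:
    """Joint per-sex consensus over one region.

    'male-hemizygous' iff every male is haploid (0.5) and every female absent
    (0); 'shared-diploid' iff every sample is diploid (1); otherwise 'other'.
    """
    reports = list(reports)
    classes: Dict[str, list] = {"M": [], "F": []}
    for rep in reports:
        if rep.sample not in sexes:
            raise KeyError(f"no sex label for sample {rep.sample}")
        classes[sexes[rep.sample]].append(rep.ploidy_class)
    if not classes["M"] or not classes["F"]:
        raise ValueError("need at least one sample of each sex")
    if (all(c == "haploid" for c in classes["M"])
            and all(c == "absent" for c in classes["F"])):
        return "male-hemizygous"
    if all(c == "diploid" for c in classes["M"] + classes["F"]):
        return "shared-diploid"
    return "other"


def profile_table(
    tables: Mapping[str, DepthTable],
    regions: Sequence[Tuple[str, int, int]],
    sexes: Mapping[str, str],
    tol: float = 0.15,
) -> pd.DataFrame:
    """Per-sample relative-depth report over each region, plus the per-region
    joint sex profile, as one tidy DataFrame."""
    rows = []
    for scaffold, start, end in regions:
        reps = [region_report(t, scaffold, start, end, tol=tol)
                for t in tables.values()]
        label = sexed_region_profile(reps, sexes)
        for rep in reps:
            rows.append({
                "scaffold": scaffold, "start": start, "end": end,
                "sample": rep.sample, "sex": sexes[rep.sample],
                "mean_rel_depth": rep.mean_rel_depth,
                "ploidy_class": rep.ploidy_class,
                "region_profile": label,
            })
    return pd.DataFrame(rows)
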