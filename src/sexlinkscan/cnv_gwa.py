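"""Copy-number-variation genome-wide association scan.

The scan converts per-sample depth into windowed, median-normalized copy
numbers (500 bp windows by default), snaps them to the half-integer grid
{0, 0.5, 1, 1.5, 2}, merges runs of windows whose across-sample copy-number
vectors agree into regions, and then tests each region for a sex difference
two ways:

* a two-sided Mann-Whitney U test on the regional copy numbers, and
* a 2x3 contingency ("quasigenotype") association test, after restricting
  to regions whose copy numbers all lie in {0, 0.5, 1} and recoding
  0 -> 0/0, 0.5 -> 0/1, 1 -> 1/1.

Both scans are Bonferroni-corrected over the regions they test.  A
male-hemizygous insertion shows up as the unique region with copy number
0.5 in every male and 0 in every female.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from . import stats
from .depthscan import CN_GRID, DepthTable

#: p-values below this are floored in plotting exports only
PLOT_P_FLOOR = 1e-15

QUASI_CODES = {0.0: 0, 0.5: 1, 1.0: 2}
QUASI_LABELS = {0: "0/0", 1: "0/1", 2: "1/1"}


def window_copy_number(
    table: DepthTable,
    window: int = 500,
    tol: float = 0.15,
    grid: Sequence[float] = CN_GRID,
) -> Dict[str, np.ndarray]:
    """Per-window copy number for one sample.

    CN_raw = mean window depth / per-scaffold median depth, snapped to the
    nearest grid point within ``tol``; NaN marks unresolved windows.
    Trailing partial windows are dropped.  Scaffolds with median depth 0 are
    skipped (no normalization is possible there).
    """
    if window < 50:
        raise ValueError("window must be >= 50 bp")
    grid_arr = np.asarray(grid, dtype=float)
    out: Dict[str, np.ndarray] = {}
    for name, vec in table.depths.items():
        med = table.median(name)
        nw = vec.size // window
        if med <= 0 or nw == 0:
            continue
        means = vec[: nw * window].reshape(nw, window).mean(axis=1)
        raw = means / med
        idx = np.abs(raw[:, None] - grid_arr[None, :]).argmin(axis=1)
        snapped = grid_arr[idx]
        snapped = np.where(np.abs(snapped - raw) <= tol, snapped, np.nan)
        out[name] = snapped
    return out


@dataclass(frozen=True)
class Region:
    scaffold: str
    start: int  # 0-based half-open, bp
    end: int
    cn: Tuple[float, ...]  # per-sample copy number, fixed sample order

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class CopyNumberMatrix:
    samples: Tuple[str, ...]
    regions: List[Region]
    window: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.regions:
            row = {"scaffold": r.scaffold, "start": r.start, "end": r.end}
            row.update(dict(zip(self.samples, r.cn)))
            rows.append(row)
        return pd.DataFrame(rows)


def merge_windows(
    window_cn: Mapping[str, Mapping[str, np.ndarray]],
    samples: Sequence[str],
    window: int = 500,
    max_gap: int = 2,
    min_region_windows: int = 3,
) -> CopyNumberMatrix:
    """Merge consecutive windows with identical across-sample CN vectors.

    ``window_cn`` maps sample -> scaffold -> snapped CN vector (NaN =
    unresolved).  A window is resolved when every sample's value is
    defined; up to ``max_gap`` consecutive unresolved windows may sit
    inside a run without breaking it.  Runs spanning fewer than
    ``min_region_windows`` resolved windows are dropped.
    """
    samples = tuple(samples)
    scaffolds: List[str] = []
    for s in samples:
        for name in window_cn[s]:
            if name not in scaffolds:
                scaffolds.append(name)
    regions: List[Region] = []
    for name in scaffolds:
        mats = [window_cn[s][name] for s in samples if name in window_cn[s]]
        if len(mats) != len(samples):
            continue
        mat = np.vstack(mats)  # samples x windows
        nw = mat.shape[1]
        resolved = ~np.isnan(mat).any(axis=0)
        run_vec: np.ndarray | None = None
        run_start = run_last = -1
        run_count = 0
        gap = 0

        def close() -> None:
            nonlocal run_vec, run_count
            if run_vec is not None and run_count >= min_region_windows:
                regions.append(Region(
                    scaffold=name,
                    start=run_start * window,
                    end=(run_last + 1) * window,
                    cn=tuple(float(v) for v in run_vec),
                ))
            run_vec = None
            run_count = 0

        for w in range(nw):
            if not resolved[w]:
                gap += 1
                if run_vec is not None and gap > max_gap:
                    close()
                continue
            vec = mat[:, w]
            if run_vec is None:
                run_vec = vec
                run_start = run_last = w
                run_count = 1
            elif np.array_equal(vec, run_vec) and gap <= max_gap:
                run_last = w
                run_count += 1
            else:
                close()
                run_vec = vec
                run_start = run_last = w
                run_count = 1
            gap = 0
        close()
    return CopyNumberMatrix(samples=samples, regions=regions, window=window)


def select_trihaploid_regions(cnm: CopyNumberMatrix) -> CopyNumberMatrix:
    """Keep regions where every sample's copy number is 0, 0.5 or 1."""
    keep = [r for r in cnm.regions
            if all(v in (0.0, 0.5, 1.0) for v in r.cn)]
    return CopyNumberMatrix(samples=cnm.samples, regions=keep,
                            window=cnm.window)


def cn_to_quasigenotype(cn: float) -> int:
    """Copy number -> genotype code: 0 -> 0/0 (0), 0.5 -> 0/1 (1), 1 -> 1/1 (2)."""
    if cn not in QUASI_CODES:
        raise ValueError(f"copy number {cn!r} is not in {{0, 0.5, 1}}")
    return QUASI_CODES[cn]


@dataclass
class RegionTestResult:
    region: Region
    u: float
    p_mwu: float
    direction: str
    p_gwa: float | None  # None when the region was not quasigenotype-testable
    sig_mwu: bool = False
    sig_gwa: bool = False


def cnv_gwa_scan(
    depths: Mapping[str, DepthTable],
    sexes: Mapping[str, str],
    window: int = 500,
    tol: float = 0.15,
    alpha: float = 0.05,
    max_gap: int = 2,
    min_region_windows: int = 3,
) -> Tuple[List[RegionTestResult], CopyNumberMatrix]:
    """Full windowed CNV association scan.

    Bonferroni thresholds are alpha / (#regions tested), computed separately
    for the Mann-Whitney scan (all merged regions) and the quasigenotype
    contingency scan ({0, 0.5, 1} regions only).
    """
    samples = tuple(depths)
    if sum(sexes[s] == "M" for s in samples) < 2 or \
            sum(sexes[s] == "F" for s in samples) < 2:
        raise ValueError("need at least two samples per sex")
    wcn = {s: window_copy_number(depths[s], window=window, tol=tol)
           for s in samples}
    cnm = merge_windows(wcn, samples, window=window, max_gap=max_gap,
                        min_region_windows=min_region_windows)
    sex_vec = np.array([sexes[s] for s in samples])
    tri = {id(r) for r in select_trihaploid_regions(cnm).regions}

    results: List[RegionTestResult] = []
    for r in cnm.regions:
        cn = np.asarray(r.cn)
        u, p_mwu, direction = stats.mwu_sex_test(cn[sex_vec == "M"],
                                                 cn[sex_vec == "F"])
        p_gwa = None
        if id(r) in tri:
            codes = [cn_to_quasigenotype(v) for v in r.cn]
            _, _, p_gwa = stats.gwa_contingency(codes, sex_vec)
        results.append(RegionTestResult(r, u, p_mwu, direction, p_gwa))

    thr_mwu = stats.bonferroni_threshold(alpha, len(results))
    n_gwa = sum(res.p_gwa is not None for res in results)
    thr_gwa = stats.bonferroni_threshold(alpha, n_gwa)
    for res in results:
        res.sig_mwu = res.p_mwu < thr_mwu
        res.sig_gwa = res.p_gwa is not None and res.p_gwa < thr_gwa
    return results, cnm


def results_frame(results: Sequence[RegionTestResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "scaffold": r.region.scaffold, "start": r.region.start,
        "end": r.region.end, "U": r.u, "p_mwu": r.p_mwu,
        "direction": r.direction, "p_gwa": r.p_gwa,
        "sig_mwu": r.sig_mwu, "sig_gwa": r.sig_gwa,
    } for r in results])


def manhattan_export(results: Sequence[RegionTestResult]) -> pd.DataFrame:
    """Plotting table: -log10(p) with the 1e-15 floor, signed by direction
    for the Mann-Whitney scan (positive = copy number larger in males).
    Raw p-values stay untouched in the results table."""
    rows = []
    for r in results:
        p_m = max(r.p_mwu, PLOT_P_FLOOR)
        sign = 1.0 if r.direction == "male>female" else \
            -1.0 if r.direction == "female>male" else 0.0
        row = {
            "scaffold": r.region.scaffold,
            "pos": (r.region.start + r.region.end) // 2,
            "signed_neglog10_p_mwu": sign * -np.log10(p_m),
        }
        if r.p_gwa is not None:
            row["neglog10_p_gwa"] = -np.log10(max(r.p_gwa, PLOT_P_FLOOR))
        rows.append(row)
    return pd.DataFrame(rows)


def qq_export(pvalues: Sequence[float]) -> pd.DataFrame:
    """Observed vs expected -log10 p for a Q-Q plot (expected quantiles
    -log10((i - 0.5) / m), observed floored at 1e-15)."""
    p = np.sort(np.asarray([v for v in pvalues if v is not None], dtype=float))
    m = p.size
    expected = -np.log10((np.arange(1, m + 1) - 0.5) / m)
    observed = -np.log10(np.maximum(p, PLOT_P_FLOOR))
    return pd.DataFrame({"expected": expected, "observed": observed})
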