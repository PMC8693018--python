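"""Windowed copy-number scan: snapping, merging, region tests."""

import numpy as np
import pytest

from sexlinkscan import cnv_gwa
from sexlinkscan.cnv_gwa import (cn_to_quasigenotype, cnv_gwa_scan,
                                 manhattan_export, merge_windows,
                                 results_frame, select_trihaploid_regions,
                                 window_copy_number)
from sexlinkscan.depthscan import DepthTable


def _table(sample, vec):
    return DepthTable(sample=sample,
                      depths={"s": np.asarray(vec, dtype=np.int32)})


class TestWindowCopyNumber:
    def test_half_and_zero_windows(self):
        vec = np.full(10_000, 30)
        vec[0:500] = 15
        vec[500:1000] = 0
        wcn = window_copy_number(_table("a", vec), window=500)["s"]
        assert wcn[0] == 0.5
        assert wcn[1] == 0.0
        assert (wcn[2:] == 1.0).all()

    def test_off_grid_window_unresolved(self):
        vec = np.full(5_000, 30)
        vec[0:500] = 22  # 0.733 of the median: no grid point within 0.15
        wcn = window_copy_number(_table("a", vec), window=500)["s"]
        assert np.isnan(wcn[0])

    def test_window_minimum_enforced(self):
        with pytest.raises(ValueError):
            window_copy_number(_table("a", np.full(1000, 30)), window=10)

    def test_simulated_male_msr_windows_snap_to_half(self, desk_panel):
        cfg, truth, depths = desk_panel
        sc, a, b = truth.msr_interval
        wcn = window_copy_number(depths["M03"], window=500)[sc]
        inside = wcn[a // 500: b // 500]
        frac = np.mean([v == 0.5 for v in inside if not np.isnan(v)])
        assert frac >= 0.95


class TestMergeWindows:
    def _wcn(self, per_sample):
        return {s: {"s": np.asarray(v, dtype=float)}
                for s, v in per_sample.items()}

    def test_uniform_run_merges_to_one_region(self):
        # 120 consecutive windows of (male 0.5, female 0) -> one 60 kb region
        wcn = self._wcn({"M": [0.5] * 120, "F": [0.0] * 120})
        cnm = merge_windows(wcn, ["M", "F"], window=500)
        assert len(cnm.regions) == 1
        r = cnm.regions[0]
        assert (r.start, r.end) == (0, 60_000)
        assert r.cn == (0.5, 0.0)

    def test_alternating_vectors_no_merge(self):
        vals = [1.0 if i % 2 == 0 else 0.5 for i in range(10)]
        wcn = self._wcn({"M": vals, "F": [1.0] * 10})
        cnm = merge_windows(wcn, ["M", "F"], window=500, max_gap=0,
                            min_region_windows=3)
        assert cnm.regions == []

    def test_unresolved_gap_tolerated(self):
        vals = [1.0] * 10
        vals[5] = np.nan
        wcn = self._wcn({"M": vals, "F": [1.0] * 10})
        cnm = merge_windows(wcn, ["M", "F"], window=500, max_gap=1)
        assert len(cnm.regions) == 1
        assert (cnm.regions[0].start, cnm.regions[0].end) == (0, 5_000)

    def test_gap_beyond_limit_splits(self):
        vals = [1.0] * 10
        vals[4] = vals[5] = np.nan
        wcn = self._wcn({"M": vals, "F": [1.0] * 10})
        cnm = merge_windows(wcn, ["M", "F"], window=500, max_gap=1)
        assert len(cnm.regions) == 2

    def test_short_regions_dropped(self):
        wcn = self._wcn({"M": [0.5, 0.5], "F": [0.0, 0.0]})
        cnm = merge_windows(wcn, ["M", "F"], window=500,
                            min_region_windows=3)
        assert cnm.regions == []


class TestSelectionAndQuasigenotypes:
    def test_selection_keeps_only_trihaploid(self):
        regions = [
            cnv_gwa.Region("s", 0, 1500, (0.5, 0.0, 1.0)),
            cnv_gwa.Region("s", 2000, 3500, (1.5, 1.0, 1.0)),
            cnv_gwa.Region("s", 4000, 5500, (1.0, 1.0, 1.0)),
        ]
        cnm = cnv_gwa.CopyNumberMatrix(("a", "b", "c"), regions, 500)
        kept = select_trihaploid_regions(cnm).regions
        assert [r.start for r in kept] == [0, 4000]

    @pytest.mark.parametrize("cn,code", [(0.0, 0), (0.5, 1), (1.0, 2)])
    def test_quasigenotype_codes(self, cn, code):
        assert cn_to_quasigenotype(cn) == code

    def test_quasigenotype_domain_error(self):
        with pytest.raises(ValueError):
            cn_to_quasigenotype(1.5)


def _panel(n_m=4, n_f=4, length=5_000, seed=0, hemizygous=True):
    """Tiny synthetic depth panel with one 1.5 kb sex-linked segment."""
    rng = np.random.default_rng(seed)
    tables, sexes = {}, {}
    for i in range(n_m + n_f):
        sex = "M" if i < n_m else "F"
        name = f"{sex}{i:02d}"
        vec = rng.poisson(30, size=length)
        if hemizygous:
            if sex == "M":
                vec[1000:2500] = rng.poisson(15, size=1500)
            else:
                vec[1000:2500] = 0
        tables[name] = _table(name, vec)
        sexes[name] = sex
    return tables, sexes


class TestScan:
    def test_detects_sex_linked_region(self):
        tables, sexes = _panel(n_m=6, n_f=6)
        results, _ = cnv_gwa_scan(tables, sexes, window=500)
        sig = [r for r in results if r.sig_mwu and r.sig_gwa]
        assert len(sig) == 1
        r = sig[0].region
        assert r.start == 1000 and r.end == 2500
        assert sig[0].direction == "male>female"

    def test_no_signal_without_sex_linkage(self):
        tables, sexes = _panel(n_m=6, n_f=6, hemizygous=False)
        results, _ = cnv_gwa_scan(tables, sexes, window=500)
        assert not any(r.sig_mwu or r.sig_gwa for r in results)

    def test_label_swap_symmetry(self):
        tables, sexes = _panel(n_m=5, n_f=5)
        swapped = {s: ("M" if v == "F" else "F") for s, v in sexes.items()}
        res_a, _ = cnv_gwa_scan(tables, sexes, window=500)
        res_b, _ = cnv_gwa_scan(tables, swapped, window=500)
        for a, b in zip(res_a, res_b):
            assert a.p_mwu == pytest.approx(b.p_mwu, rel=1e-9)
            if a.p_gwa is not None:
                assert a.p_gwa == pytest.approx(b.p_gwa, rel=1e-9)
            if a.direction == "male>female":
                assert b.direction == "female>male"

    def test_plot_floor_applied_only_to_export(self):
        tables, sexes = _panel(n_m=6, n_f=6)
        results, _ = cnv_gwa_scan(tables, sexes, window=500)
        df = results_frame(results)
        man = manhattan_export(results)
        sig = df[df.sig_gwa]
        assert (man["signed_neglog10_p_mwu"].abs() <= 15 + 1e-9).all()
        # raw p kept un-floored (may be arbitrarily small in principle)
        assert (sig["p_mwu"] > 0).all()

    def test_requires_two_samples_per_sex(self):
        tables, sexes = _panel(n_m=1, n_f=5)
        with pytest.raises(ValueError):
            cnv_gwa_scan(tables, sexes)


class TestManhattanFloor:
    def test_p_below_floor_clamped(self):
        r = cnv_gwa.RegionTestResult(
            region=cnv_gwa.Region("s", 0, 1000, (0.5, 0.0)),
            u=1.0, p_mwu=1e-20, direction="male>female", p_gwa=1e-20)
        man = manhattan_export([r])
        assert man["signed_neglog10_p_mwu"].iloc[0] == pytest.approx(15.0)
        assert man["neglog10_p_gwa"].iloc[0] == pytest.approx(15.0)
        assert r.p_mwu == 1e-20  # table value untouched


class TestQQExport:
    def test_expected_quantiles(self):
        df = cnv_gwa.qq_export([0.5, 0.1, 0.9, 0.3])
        m = 4
        expected = -np.log10((np.arange(1, m + 1) - 0.5) / m)
        assert np.allclose(df["expected"], expected)
        assert np.allclose(df["observed"],
                           -np.log10([0.1, 0.3, 0.5, 0.9]))
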