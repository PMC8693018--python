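"""End-to-end pipeline: simulate -> CNV scan -> depth profile -> mask ->
map/call -> SNV scans (masked and unmasked) -> cross-mapping audit ->
PCR assay -> expression test.

Stage order mirrors the discovery logic: the windowed copy-number GWA finds
the male-hemizygous candidate region from depth alone; the SNV branch is
run against the female-style reference both unmasked (reproducing the
cross-mapping artifact) and after duplication masking (removing it); the
audit explains the artifact read-by-read; and the PCR and expression assays
validate the candidate.

A run manifest (seed, parameters, per-output SHA-256) makes reruns
checkable: the same config and seed reproduce identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Dict, List, Mapping

import numpy as np
import pandas as pd
import yaml

from . import _seq, cnv_gwa, crossmap, depthscan, maskdup, mapper
from . import sexassay, simgen, snv_gwa

log = logging.getLogger("sexlinkscan")

ALL_STAGES = ("simulate", "cnv", "depth_profile", "mask", "snv",
              "crossmap", "pcr", "express")

#: small end-to-end demonstration panel (full 15M + 16F study design,
#: genome scaled to tens of kb so the in-repo mapper runs in seconds)
DEMO_CONFIG: Dict = {
    "sim": {
        "n_males": 15, "n_females": 16,
        "scaffold_lengths": [16_000, 8_000],
        "msr_scaffold": "scaffold_1", "msr_start": 4_000,
        "msr_length": 4_000,
        "paralog_scaffold": "scaffold_2",
        "paralog_length": 3_000, "paralog_identity": 0.92,
        "cassette_deletion": 7,
        "coverage": 30.0, "read_length": 100, "error_rate": 0.001,
        "seed": 7,
    },
    "stages": list(ALL_STAGES),
    "params": {
        "window": 500, "alpha": 0.05, "cn_tol": 0.15,
        "mapper_k": 15, "max_mismatch": 12,
        "mask_k": 13, "mask_min_len": 500, "mask_min_ident": 0.85,
        "n_testis": 10, "n_ovary": 10,
    },
}


def load_config(path: str | Path) -> Dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    unknown = set(cfg.get("stages", [])) - set(ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown stage(s): {sorted(unknown)}")
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_df(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def run_pipeline(config: Mapping, out_dir: str | Path) -> Dict:
    """Execute the enabled stages in dependency order; returns the manifest.

    Stage failures raise with a message naming the stage.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = list(config.get("stages", ALL_STAGES))
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown stage(s): {sorted(unknown)}")
    params = {**DEMO_CONFIG["params"], **dict(config.get("params", {}))}
    sim_kwargs = {**DEMO_CONFIG["sim"], **dict(config.get("sim", {}))}
    sim_kwargs["scaffold_lengths"] = tuple(sim_kwargs["scaffold_lengths"])
    cfg = simgen.SimConfig(**sim_kwargs)
    manifest: Dict = {"seed": cfg.seed,
                      "config": {"sim": sim_kwargs, "params": params,
                                 "stages": stages},
                      "stages": {}, "outputs": {}}
    state: Dict = {}

    def finish(stage: str, paths: List[Path]) -> None:
        manifest["stages"][stage] = "ok"
        for p in paths:
            manifest["outputs"][str(p.relative_to(out))] = _sha256(p)
        log.info("stage %s done (%d outputs)", stage, len(paths))

    def run_stage(stage: str) -> None:
        try:
            _STAGE_FUNCS[stage](cfg, params, out, state)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        finish(stage, state.pop("_new_outputs", []))

    for stage in ALL_STAGES:  # dependency order is the canonical order
        if stage in stages:
            run_stage(stage)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _stage_simulate(cfg, params, out: Path, state: Dict) -> None:
    female, male, truth = simgen.make_genomes(cfg)
    _seq.write_fasta(female, out / "female.fasta")
    _seq.write_fasta(male, out / "male.fasta")
    truth.write(out)
    depths = simgen.simulate_depth(cfg, truth)
    depth_dir = out / "depth"
    depth_dir.mkdir(exist_ok=True)
    for s, dt in depths.items():
        dt.to_tsv(depth_dir / f"{s}.depth.tsv")
    reads = simgen.simulate_reads(cfg, truth, female, male,
                                  out_dir=out / "reads")
    state.update(female=female, male=male, truth=truth, depths=depths,
                 read_paths=reads)
    state["_new_outputs"] = [out / "female.fasta", out / "male.fasta",
                             out / "truth_regions.bed",
                             out / "sample_sheet.tsv"]


def _stage_cnv(cfg, params, out: Path, state: Dict) -> None:
    truth = state["truth"]
    results, cnm = cnv_gwa.cnv_gwa_scan(
        state["depths"], truth.sample_sheet,
        window=params["window"], tol=params["cn_tol"],
        alpha=params["alpha"])
    _write_df(cnv_gwa.results_frame(results), out / "cnv_regions.tsv")
    _write_df(cnv_gwa.manhattan_export(results), out / "cnv_manhattan.tsv")
    _write_df(cnv_gwa.qq_export([r.p_gwa for r in results
                                 if r.p_gwa is not None]),
              out / "cnv_qq.tsv")
    sig = [r for r in results if r.sig_mwu and r.sig_gwa]
    maskdup.write_bed([(r.region.scaffold, r.region.start, r.region.end)
                       for r in sig], out / "cnv_significant.bed")
    state["cnv_results"] = results
    state["cnv_significant"] = sig
    state["_new_outputs"] = [out / "cnv_regions.tsv",
                             out / "cnv_manhattan.tsv",
                             out / "cnv_qq.tsv", out / "cnv_significant.bed"]


def _stage_depth_profile(cfg, params, out: Path, state: Dict) -> None:
    truth = state["truth"]
    regions = [(r.region.scaffold, r.region.start, r.region.end)
               for r in state.get("cnv_significant", [])]
    if not regions:  # fall back to the truth interval
        regions = [truth.msr_interval]
    # add a diploid control region on the other scaffold
    ctrl_sc = cfg.paralog_scaffold
    ctrl_len = min(5 * params["window"],
                   state["female"][ctrl_sc].size // 2)
    regions.append((ctrl_sc, 0, ctrl_len))
    df = depthscan.profile_table(state["depths"], regions,
                                 truth.sample_sheet, tol=params["cn_tol"])
    _write_df(df, out / "depth_profile.tsv")
    state["_new_outputs"] = [out / "depth_profile.tsv"]


def _stage_mask(cfg, params, out: Path, state: Dict) -> None:
    # duplications are visible only where both copies are assembled: the
    # male genome carries cassette + paralog
    calls = maskdup.find_self_duplications(
        state["male"], k=params["mask_k"],
        min_len=params["mask_min_len"],
        min_ident=params["mask_min_ident"])
    # carry the masking to the mapping reference by sequence, not by
    # coordinate: locate each duplicated sequence in the female assembly
    queries = [state["male"][name][a:b]
               for c in calls for name, a, b in c.intervals()]
    intervals = maskdup.locate_sequences(
        state["female"], queries, k=params["mask_k"],
        min_len=params["mask_min_len"],
        min_ident=params["mask_min_ident"])
    masked, intervals = maskdup.mask_genome(state["female"], intervals)
    _seq.write_fasta(masked, out / "female.masked.fasta")
    maskdup.write_bed(intervals, out / "masked_regions.bed")
    state["female_masked"] = masked
    state["dup_calls"] = calls
    state["_new_outputs"] = [out / "female.masked.fasta",
                             out / "masked_regions.bed"]


def _map_panel(cfg, params, state, reference) -> Dict[str, list]:
    idx = mapper.ReferenceIndex(reference, k=params["mapper_k"])
    truth = state["truth"]
    by_sample = {}
    for s in truth.sample_sheet:
        reads = simgen.sample_reads(cfg, truth, state["female"],
                                    state["male"], s)
        by_sample[s] = mapper.map_reads(
            reads, idx, max_mismatch=params["max_mismatch"])
    return by_sample

def _stage_snv(cfg, params, out: Path, state: Dict) -> None:
    truth = state["truth"]
    scans = {}
    for tag, ref in (("unmasked", state["female"]),
                     ("masked", state.get("female_masked",
                                          state["female"]))):
        aln = _map_panel(cfg, params, state, ref)
        table = mapper.pileup_and_call(aln, ref)
        scan = snv_gwa.snv_gwa_scan(table, truth.sample_sheet,
                                    snv_gwa.SiteFilterConfig(
                                        alpha=params["alpha"]))
        _write_df(scan, out / f"snv_gwa.{tag}.tsv")
        _write_df(snv_gwa.qq_export(scan["p"]), out / f"snv_qq.{tag}.tsv")
        scans[tag] = scan
        if tag == "unmasked":
            state["alignments_unmasked"] = aln
    state["snv_scans"] = scans
    state["_new_outputs"] = [out / f"snv_gwa.{t}.tsv" for t in scans] + \
        [out / f"snv_qq.{t}.tsv" for t in scans]


def _stage_crossmap(cfg, params, out: Path, state: Dict) -> None:
    truth = state["truth"]
    psc, pa, pb = truth.paralog_interval
    csc, ca, cb = truth.cassette_interval
    candidates = {
        "paralog": state["female"][psc][pa:pb],
        "msr_cassette": state["male"][csc][ca:cb],
    }
    aln = state.get("alignments_unmasked")
    if aln is None:
        aln = _map_panel(cfg, params, state, state["female"])
    rows = []
    for s in truth.sample_sheet:
        reads = {rid: codes for rid, codes in
                 simgen.sample_reads(cfg, truth, state["female"],
                                     state["male"], s)}
        cls = crossmap.classify_mapped_reads(
            aln[s], (psc, pa, pb), candidates, reads, "paralog")
        if not cls:
            continue
        frac, counts = crossmap.crossmap_fraction(cls)
        rows.append({"sample": s, "sex": truth.sample_sheet[s],
                     "n_mapped": len(cls), "fraction_foreign": frac,
                     **{f"n_{k}": v for k, v in counts.items()}})
    _write_df(pd.DataFrame(rows), out / "crossmap_summary.tsv")
    state["_new_outputs"] = [out / "crossmap_summary.tsv"]


def _stage_pcr(cfg, params, out: Path, state: Dict) -> None:
    truth = state["truth"]
    primers = simgen.design_sex_primers(cfg, truth, state["female"],
                                        state["male"])
    rows = []
    for genome_name, genome in (("male", state["male"]),
                                ("female", state["female"])):
        products = {}
        for set_name, (fwd, rev) in primers.items():
            pair = sexassay.PrimerPair(name=set_name, forward=fwd,
                                       reverse=rev)
            preds = sexassay.predict_amplicons(genome, pair)
            products[set_name] = [p.size for p in preds]
        call = sexassay.sex_call_from_patterns(products)
        rows.append({"genome": genome_name,
                     **{f"sizes_{k}": ",".join(map(str, v)) or "-"
                        for k, v in products.items()},
                     "sex_call": call})
    pd.DataFrame(
        [{"set": k, "forward": f, "reverse": r}
         for k, (f, r) in primers.items()]
    ).to_csv(out / "primers.tsv", sep="\t", index=False)
    _write_df(pd.DataFrame(rows), out / "pcr_sex_calls.tsv")
    state["_new_outputs"] = [out / "primers.tsv", out / "pcr_sex_calls.tsv"]


def _stage_express(cfg, params, out: Path, state: Dict) -> None:
    counts, lengths, groups = simgen.simulate_expression(
        n_testis=params["n_testis"], n_ovary=params["n_ovary"],
        seed=cfg.seed)
    counts.to_csv(out / "expression_counts.tsv", sep="\t")
    fp = sexassay.fpkm(counts, lengths)
    fp.round(4).to_csv(out / "expression_fpkm.tsv", sep="\t")
    res = sexassay.expression_sex_test(counts, lengths, groups, "sult_y")
    pct = sexassay.percent_of_control(fp, "beta_actin")
    pct.round(4).to_csv(out / "expression_pct_of_control.tsv", sep="\t")
    with open(out / "expression_test.json", "w") as fh:
        json.dump({"gene": res["gene"], "p": res["p"],
                   "table": np.asarray(res["table"]).tolist(),
                   "n_expressed_testis": res["n_expressed_testis"],
                   "n_expressed_ovary": res["n_expressed_ovary"]},
                  fh, indent=2)
    state["expression_test"] = res
    state["_new_outputs"] = [out / "expression_counts.tsv",
                             out / "expression_fpkm.tsv",
                             out / "expression_pct_of_control.tsv",
                             out / "expression_test.json"]


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "cnv": _stage_cnv,
    "depth_profile": _stage_depth_profile,
    "mask": _stage_mask,
    "snv": _stage_snv,
    "crossmap": _stage_crossmap,
    "pcr": _stage_pcr,
    "express": _stage_express,
}
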