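"""Synthetic data generator.

Emulates the data structure the sex-linked-region analysis assumes for an
XY (male-heterogametic) species:

* a **female** diploid reference made of random scaffolds, one of which
  carries an autosomal "paralog" gene cassette present in both sexes;
* a **male** genome equal to the female genome plus a single hemizygous
  insertion (the male-specific region, MSR) whose gene cassette is a
  diverged copy of the autosomal paralog (default nucleotide identity 0.92,
  plus a small deletion so PCR products from the two copies differ in size);
* per-sample **depth tables** under a Poisson shotgun model, with the MSR at
  half molarity in males and zero in females;
* per-sample **reads** whose names encode their true origin, enabling the
  cross-mapping audit;
* gonad **expression count matrices** in which the male-specific gene has
  positive counts in every testis sample and zero in every ovary sample.

Default panel: 15 males + 16 females at 30x; the MSR is 60,750 bp.
All generators are byte-deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterator, List, Mapping, Tuple

import numpy as np
import pandas as pd

from . import _seq
from .depthscan import DepthTable

# independent RNG streams fanned out from the config seed
_STREAM_GENOME = 0
_STREAM_DEPTH = 1
_STREAM_READS = 2
_STREAM_EXPR = 3


class ConfigurationError(ValueError):
    pass


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


@dataclass
class SimConfig:
    """Study-design parameters for one synthetic panel."""

    n_males: int = 15
    n_females: int = 16
    #: male-genome scaffold lengths, bp (the analysis reference)
    scaffold_lengths: Tuple[int, ...] = (250_000, 750_000)
    msr_scaffold: str = "scaffold_1"
    msr_start: int = 18_000  # 0-based; mirrors an insertion at 18,001 (1-based)
    msr_length: int = 60_750
    paralog_scaffold: str = "scaffold_2"
    paralog_start: int | None = None  # None -> centered in its scaffold
    paralog_length: int = 8_000
    paralog_identity: float = 0.92
    #: bp deleted from the MSR cassette relative to the paralog (size marker)
    cassette_deletion: int = 7
    coverage: float = 30.0  # mean depth at a diploid site
    read_length: int = 100
    error_rate: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.paralog_identity <= 1):
            raise ConfigurationError("paralog_identity must be in (0, 1]")
        if self.coverage <= 0:
            raise ConfigurationError("coverage must be > 0")
        if any(l < 1 for l in self.scaffold_lengths):
            raise ConfigurationError("scaffold lengths must be >= 1")
        if self.msr_length < 1 or self.paralog_length < 1:
            raise ConfigurationError("region lengths must be >= 1")
        if self.cassette_length < 1:
            raise ConfigurationError("cassette_deletion >= paralog_length")
        names = self.scaffold_names
        if self.msr_scaffold not in names or self.paralog_scaffold not in names:
            raise ConfigurationError("msr/paralog scaffold not in scaffold list")
        msr_len_of = dict(zip(names, self.scaffold_lengths))
        if self.msr_start + self.msr_length > msr_len_of[self.msr_scaffold]:
            raise ConfigurationError("MSR interval overflows its scaffold")
        if self.cassette_length > self.msr_length:
            raise ConfigurationError("gene cassette longer than the MSR")
        p0 = self.paralog_start_resolved
        if p0 < 0 or p0 + self.paralog_length > msr_len_of[self.paralog_scaffold]:
            raise ConfigurationError("paralog interval overflows its scaffold")
        if (self.paralog_scaffold == self.msr_scaffold
                and not (p0 + self.paralog_length <= self.msr_start
                         or p0 >= self.msr_start + self.msr_length)):
            raise ConfigurationError("paralog overlaps the MSR interval")

    @property
    def scaffold_names(self) -> Tuple[str, ...]:
        return tuple(f"scaffold_{i + 1}" for i in range(len(self.scaffold_lengths)))

    @property
    def cassette_length(self) -> int:
        return self.paralog_length - self.cassette_deletion

    @property
    def paralog_start_resolved(self) -> int:
        if self.paralog_start is not None:
            return self.paralog_start
        idx = self.scaffold_names.index(self.paralog_scaffold)
        return (self.scaffold_lengths[idx] - self.paralog_length) // 2

    @property
    def samples(self) -> Dict[str, str]:
        sheet = {f"M{i + 1:02d}": "M" for i in range(self.n_males)}
        sheet.update({f"F{i + 1:02d}": "F" for i in range(self.n_females)})
        return sheet


@dataclass
class SimTruth:
    """Machine-readable ground truth emitted with every simulation."""

    #: (scaffold, start, end), 0-based half-open, male-genome coordinates
    msr_interval: Tuple[str, int, int]
    #: MSR gene cassette interval, male-genome coordinates
    cassette_interval: Tuple[str, int, int]
    #: autosomal paralog interval (same coords in both genomes)
    paralog_interval: Tuple[str, int, int]
    paralog_identity: float
    sample_sheet: Dict[str, str]  # sample -> 'M' / 'F'
    #: expected relative copy number over the MSR per sample (M 0.5, F 0)
    expected_cn: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.expected_cn:
            self.expected_cn = {
                s: (0.5 if sex == "M" else 0.0)
                for s, sex in self.sample_sheet.items()
            }

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        with open(out / "truth_regions.bed", "w") as fh:
            for tag, (sc, a, b) in (
                ("msr", self.msr_interval),
                ("msr_cassette", self.cassette_interval),
                ("paralog", self.paralog_interval),
            ):
                fh.write(f"{sc}\t{a}\t{b}\t{tag}\n")
        pd.DataFrame(
            {"sample": list(self.sample_sheet),
             "sex": list(self.sample_sheet.values()),
             "expected_cn_msr": [self.expected_cn[s] for s in self.sample_sheet]}
        ).to_csv(out / "sample_sheet.tsv", sep="\t", index=False)


def make_genomes(
    config: SimConfig,
) -> Tuple[Dict[str, np.ndarray], Dict[str, np.ndarray], SimTruth]:
    """Build the female and male genomes plus the truth record.

    The male genome is the female genome with one hemizygous insertion of
    ``msr_length`` bp in ``msr_scaffold``; the insertion carries a gene
    cassette diverged from the autosomal paralog at per-site substitution
    rate ``1 - paralog_identity`` (and shortened by ``cassette_deletion`` bp
    at its centre).
    """
    rng = _rng(config.seed, _STREAM_GENOME)
    names = config.scaffold_names
    male_lengths = dict(zip(names, config.scaffold_lengths))

    # female genome: male lengths, minus the insertion in the MSR scaffold
    female: Dict[str, np.ndarray] = {}
    for name in names:
        length = male_lengths[name]
        if name == config.msr_scaffold:
            length -= config.msr_length
        female[name] = _seq.random_codes(rng, length)

    p0 = config.paralog_start_resolved
    paralog = female[config.paralog_scaffold][p0:p0 + config.paralog_length]

    # diverged cassette: substitutions, then a centred deletion
    cassette, _ = _seq.mutate(paralog, rng, 1.0 - config.paralog_identity)
    if config.cassette_deletion:
        mid = cassette.size // 2
        cassette = np.concatenate(
            [cassette[:mid], cassette[mid + config.cassette_deletion:]])

    # MSR insert = left flank + cassette + right flank
    flank_total = config.msr_length - cassette.size
    left = flank_total // 2
    insert = np.concatenate([
        _seq.random_codes(rng, left),
        cassette,
        _seq.random_codes(rng, flank_total - left),
    ])

    male: Dict[str, np.ndarray] = dict(female)
    s = config.msr_start
    fem_scaf = female[config.msr_scaffold]
    male[config.msr_scaffold] = np.concatenate(
        [fem_scaf[:s], insert, fem_scaf[s:]])

    cass_start = s + left
    truth = SimTruth(
        msr_interval=(config.msr_scaffold, s, s + config.msr_length),
        cassette_interval=(config.msr_scaffold, cass_start,
                           cass_start + cassette.size),
        paralog_interval=(config.paralog_scaffold, p0,
                          p0 + config.paralog_length),
        paralog_identity=config.paralog_identity,
        sample_sheet=config.samples,
    )
    return female, male, truth


def simulate_depth(config: SimConfig, truth: SimTruth) -> Dict[str, DepthTable]:
    """Per-sample Poisson depth over the male-genome coordinates.

    Site depth ~ Poisson(coverage * CN / 2) where CN is 2 everywhere except
    over the MSR: 1 in males, 0 in females.
    """
    names = config.scaffold_names
    lengths = dict(zip(names, config.scaffold_lengths))
    msr_sc, msr_a, msr_b = truth.msr_interval
    tables: Dict[str, DepthTable] = {}
    for i, (sample, sex) in enumerate(truth.sample_sheet.items()):
        rng = _rng(config.seed, _STREAM_DEPTH, i)
        depths: Dict[str, np.ndarray] = {}
        for name in names:
            vec = rng.poisson(config.coverage, size=lengths[name]).astype(np.int32)
            if name == msr_sc:
                span = msr_b - msr_a
                if sex == "M":
                    vec[msr_a:msr_b] = rng.poisson(config.coverage / 2.0, size=span)
                else:
                    vec[msr_a:msr_b] = 0
            depths[name] = vec
        tables[sample] = DepthTable(sample=sample, depths=depths)
    return tables


def _haplotypes(
    sample_sex: str,
    female: Mapping[str, np.ndarray],
    male: Mapping[str, np.ndarray],
) -> List[Tuple[str, Mapping[str, np.ndarray]]]:
    """A sample's two genome copies: females carry two female haplotypes,
    males one female (maternal) plus one male (paternal, with the MSR)."""
    if sample_sex == "M":
        return [("mat", female), ("pat", male)]
    return [("mat", female), ("pat", female)]


def sample_reads(
    config: SimConfig,
    truth: SimTruth,
    female: Mapping[str, np.ndarray],
    male: Mapping[str, np.ndarray],
    sample: str,
) -> Iterator[Tuple[str, np.ndarray]]:
    """Single-end reads for one sample, uniform over its two genome copies.

    Read names are colon-delimited ``sample:hap:scaffold:pos:index`` (pos
    0-based), carrying the true origin for the cross-mapping audit.
    Expected read count = coverage * haploid-equivalent genome size / read
    length (each haplotype is sampled at coverage/2).
    """
    idx = list(truth.sample_sheet).index(sample)
    rng = _rng(config.seed, _STREAM_READS, idx)
    rl = config.read_length
    haps = _haplotypes(truth.sample_sheet[sample], female, male)
    # sampling weights: (hap, scaffold) proportional to scaffold length
    units = [(hap, name, seqs[name].size)
             for hap, seqs in haps for name in seqs]
    lens = np.array([u[2] for u in units], dtype=float)
    if rl > min(int(l) for l in lens):
        raise ConfigurationError("read_length exceeds a scaffold length")
    mean_reads = config.coverage / 2.0 * lens.sum() / rl
    n_reads = int(rng.poisson(mean_reads))
    choices = rng.choice(len(units), size=n_reads, p=lens / lens.sum())
    hap_map = dict(haps)
    for i in range(n_reads):
        hap, name, length = units[choices[i]]
        pos = int(rng.integers(0, length - rl + 1))
        codes = hap_map[hap][name][pos:pos + rl]
        if config.error_rate > 0:
            codes, _ = _seq.mutate(codes, rng, config.error_rate)
        yield f"{sample}:{hap}:{name}:{pos}:{i}", codes


def simulate_reads(
    config: SimConfig,
    truth: SimTruth,
    female: Mapping[str, np.ndarray],
    male: Mapping[str, np.ndarray],
    out_dir: str | Path | None = None,
) -> Dict[str, List[Tuple[str, np.ndarray]]] | Dict[str, Path]:
    """All samples' reads; written as FASTQ when ``out_dir`` is given."""
    if out_dir is None:
        return {s: list(sample_reads(config, truth, female, male, s))
                for s in truth.sample_sheet}
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, Path] = {}
    for s in truth.sample_sheet:
        p = out / f"{s}.fastq"
        _seq.write_fastq(sample_reads(config, truth, female, male, s), p)
        paths[s] = p
    return paths


DEFAULT_GENES = ("beta_actin", "sult_y", "sult_a")


def default_gene_table(n_background: int = 20,
                       seed: int = 0) -> pd.DataFrame:
    """Gene specification for the gonad expression simulation.

    ``sult_y`` is the male-specific gene (testis-only), ``sult_a`` its
    autosomal paralog (low in both sexes), ``beta_actin`` the highly
    expressed control; background genes span a realistic mean range.
    """
    rng = _rng(seed, _STREAM_EXPR, 0)
    rows = [
        {"gene": "beta_actin", "length": 1_800,
         "mean_testis": 20_000.0, "mean_ovary": 20_000.0, "dispersion": 0.05},
        {"gene": "sult_y", "length": 1_200,
         "mean_testis": 60.0, "mean_ovary": 0.0, "dispersion": 0.2},
        {"gene": "sult_a", "length": 1_200,
         "mean_testis": 40.0, "mean_ovary": 10.0, "dispersion": 0.2},
    ]
    means = 10 ** rng.uniform(1.5, 3.5, size=n_background)
    lengths = rng.integers(500, 5_000, size=n_background)
    for i in range(n_background):
        rows.append({"gene": f"bg{i + 1:03d}", "length": int(lengths[i]),
                     "mean_testis": float(means[i]),
                     "mean_ovary": float(means[i]), "dispersion": 0.1})
    return pd.DataFrame(rows).set_index("gene")


def _nb_draw(rng: np.random.Generator, mean: float, dispersion: float,
             size: int) -> np.ndarray:
    """Negative-binomial counts with var = mean + dispersion * mean^2."""
    if mean <= 0:
        return np.zeros(size, dtype=np.int64)
    if dispersion <= 0:
        return rng.poisson(mean, size=size).astype(np.int64)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size=size).astype(np.int64)


def simulate_expression(
    n_testis: int = 10,
    n_ovary: int = 10,
    genes: pd.DataFrame | None = None,
    seed: int = 0,
    male_specific_gene: str = "sult_y",
) -> Tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Gonad RNA-seq count matrix (genes x samples), gene lengths, groups.

    The male-specific gene gets a count > 0 in every testis sample (zero
    draws are replaced by redrawing from the same stream) and exactly 0 in
    every ovary sample.
    """
    if n_testis < 1 or n_ovary < 1:
        raise ConfigurationError("need at least one sample per group")
    if genes is None:
        genes = default_gene_table(seed=seed)
    rng = _rng(seed, _STREAM_EXPR, 1)
    samples = ([f"testis{i + 1:02d}" for i in range(n_testis)]
               + [f"ovary{i + 1:02d}" for i in range(n_ovary)])
    groups = pd.Series(["testis"] * n_testis + ["ovary"] * n_ovary,
                       index=samples, name="group")
    counts = pd.DataFrame(0, index=genes.index, columns=samples, dtype=np.int64)
    for gene, row in genes.iterrows():
        t = _nb_draw(rng, row["mean_testis"], row["dispersion"], n_testis)
        o = _nb_draw(rng, row["mean_ovary"], row["dispersion"], n_ovary)
        if gene == male_specific_gene:
            while (t == 0).any():  # expressed in every testis sample
                zeros = t == 0
                t[zeros] = _nb_draw(rng, row["mean_testis"],
                                    row["dispersion"], int(zeros.sum()))
            o[:] = 0  # absent from every ovary sample
        counts.loc[gene] = np.concatenate([t, o])
    lengths = genes["length"].astype(int)
    return counts, lengths, groups


def design_sex_primers(
    config: SimConfig,
    truth: SimTruth,
    female: Mapping[str, np.ndarray],
    male: Mapping[str, np.ndarray],
    primer_len: int = 20,
) -> Dict[str, Tuple[str, str]]:
    """Pick three primer pairs from the simulated genomes mirroring the
    classic amplification-pattern assay: two pairs specific to the
    male-specific cassette (no female product) and one "common" pair sitting
    in stretches conserved between cassette and paralog that bracket the
    cassette's deletion, so males show two product sizes and females one.

    Returns ``{"male_a": (fwd, rev), "male_b": (...), "common": (...)}``
    with primer sequences as strings (5'->3').
    """
    sc, ca, cb = truth.cassette_interval
    psc, pa, pb = truth.paralog_interval
    cass = male[sc][ca:cb]
    par = female[psc][pa:pb]
    dele = config.cassette_deletion
    mid = par.size // 2  # deletion was centred in the paralog copy

    def _counterpart(off: int) -> np.ndarray:
        """Paralog window aligned (approximately) with a cassette window."""
        par_off = off if off + primer_len <= mid else off + dele
        return par[par_off:par_off + primer_len]

    def diverged_offsets(min_mm: int) -> List[int]:
        return [off for off in range(cass.size - primer_len)
                if (cass[off:off + primer_len] != _counterpart(off)).sum()
                >= min_mm]

    # male-specific pairs: forward and reverse both diverged from the
    # paralog so neither template amplifies in females; relax the
    # divergence requirement until two disjoint pairs fit
    pairs: List[Tuple[int, int]] = []
    for min_mm in (3, 2, 1):
        pairs = []
        d = diverged_offsets(min_mm)
        i = 0
        while len(pairs) < 2 and i < len(d):
            f = d[i]
            rs = [o for o in d if f + 2 * primer_len <= o <= f + 300]
            if rs:
                r = rs[0]
                pairs.append((f, r))
                i = next((j for j, o in enumerate(d)
                          if o > r + primer_len), len(d))
            else:
                i += 1
        if len(pairs) >= 2:
            break
    if len(pairs) < 2:
        raise RuntimeError("no male-specific primer sites found; "
                           "decrease paralog_identity")

    def conserved_kmer(positions: range) -> np.ndarray:
        for off in positions:
            w_c = cass[off:off + primer_len]
            if (w_c == _counterpart(off)).all():
                return w_c
        raise RuntimeError("no conserved primer site found; "
                           "increase paralog_identity or length")

    # common pair: conserved sites bracketing the deletion point, so the
    # cassette product runs `dele` bp shorter than the paralog product
    cass_mid = mid - dele // 2  # deletion midpoint in cassette coordinates
    c_f = conserved_kmer(range(cass_mid - 40, 0, -1))
    c_r = _seq.revcomp(conserved_kmer(
        range(cass_mid + 40, cass.size - primer_len)))

    def pair_seqs(f: int, r: int) -> Tuple[str, str]:
        return (_seq.decode(cass[f:f + primer_len]),
                _seq.decode(_seq.revcomp(cass[r:r + primer_len])))

    return {
        "male_a": pair_seqs(*pairs[0]),
        "male_b": pair_seqs(*pairs[1]),
        "common": (_seq.decode(c_f), _seq.decode(c_r)),
    }
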