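"""Minimal deterministic read mapper and pileup genotyper.

Ungapped, exact-k-mer-seeded alignment: candidate loci are found by shared
k-mers (both strands), each candidate is scored by full-length mismatch
count, and the best (fewest-mismatch) locus is reported.  Ties are broken
by (scaffold name, leftmost coordinate, forward strand first) and flagged
``is_ambiguous`` -- tied reads are still assigned and counted in depth,
which is deliberately the behaviour that creates cross-mapping artifacts at
unmasked paralogs.

N bases (including hard-masked reference stretches) never match anything,
so masked regions attract no reads.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from . import _seq
from .genotypes import SnvGenotypeTable


@dataclass
class Alignment:
    read_id: str
    scaffold: str
    start: int  # 0-based
    strand: str  # '+' or '-'
    mismatches: int  # over the full read length
    score: int  # read_length - mismatches
    is_ambiguous: bool
    #: read codes in reference orientation (reverse-complemented for '-')
    read_codes: np.ndarray
    #: soft-clip span [clip_lo, clip_hi) within the read: the maximal
    #: locally-scoring subsegment; bases outside it (e.g. overhang past a
    #: structural-variant junction) are excluded from pileup
    clip_lo: int = 0
    clip_hi: int = -1

    def __post_init__(self) -> None:
        if self.clip_hi < 0:
            self.clip_hi = self.read_codes.size

    @property
    def end(self) -> int:
        return self.start + self.read_codes.size


class ReferenceIndex:
    """Exact k-mer index over a set of scaffolds."""

    def __init__(self, reference: Mapping[str, np.ndarray], k: int = 15,
                 max_kmer_occ: int = 1000):
        if not reference:
            raise ValueError("empty reference")
        self.k = k
        self.names: List[str] = list(reference)
        self.name_to_id = {n: i for i, n in enumerate(self.names)}
        self.seqs: List[np.ndarray] = [np.ascontiguousarray(reference[n])
                                       for n in self.names]
        self.index: Dict[int, List[Tuple[int, int]]] = {}
        for ref_id, codes in enumerate(self.seqs):
            kmers = _seq.kmer_codes(codes, k)
            order = np.argsort(kmers, kind="stable")
            svals = kmers[order]
            bounds = np.flatnonzero(np.diff(svals)) + 1
            starts = np.concatenate([[0], bounds])
            ends = np.concatenate([bounds, [svals.size]])
            for a, b in zip(starts, ends):
                key = int(svals[a])
                if key < 0 or b - a > max_kmer_occ:
                    continue
                bucket = self.index.setdefault(key, [])
                bucket.extend((ref_id, int(p)) for p in order[a:b])


_OFFSET_CACHE: dict = {}


def _seed_offsets(read_len: int, k: int, n_seeds: int = 8) -> tuple:
    key = (read_len, k, n_seeds)
    if key not in _OFFSET_CACHE:
        if read_len < k:
            raise ValueError("k exceeds read length")
        _OFFSET_CACHE[key] = tuple(
            np.unique(np.linspace(0, read_len - k, n_seeds).astype(int)))
    return _OFFSET_CACHE[key]


def _best_alignment(
    read_id: str,
    codes: np.ndarray,
    idx: ReferenceIndex,
    max_mismatch: int,
) -> Alignment | None:
    k = idx.k
    offsets = _seed_offsets(codes.size, k)
    candidates = set()
    for strand, rc in (("+", codes), ("-", _seq.revcomp(codes))):
        kmers = _seq.kmer_codes(rc, k)
        for off in offsets:
            key = int(kmers[off])
            if key < 0:
                continue
            for ref_id, pos in idx.index.get(key, ()):
                start = pos - int(off)
                if 0 <= start and start + rc.size <= idx.seqs[ref_id].size:
                    candidates.add((strand, ref_id, start))
    best: Tuple[int, str, int, str] | None = None  # (mism, name, start, strand)
    best_count = 0
    rc_cache = {"+": codes, "-": _seq.revcomp(codes)}
    for strand, ref_id, start in candidates:
        rc = rc_cache[strand]
        mism = int(np.count_nonzero(
            idx.seqs[ref_id][start:start + rc.size] != rc))
        if mism > max_mismatch:
            continue
        key = (mism, idx.names[ref_id], start, strand)
        if best is None or key[0] < best[0]:
            best, best_count = key, 1
        elif key[0] == best[0]:
            best_count += 1
            if key < best:
                best = key
    if best is None:
        return None
    mism, name, start, strand = best
    rc = rc_cache[strand]
    ref_seg = idx.seqs[idx.name_to_id[name]][start:start + rc.size]
    lo, hi = _soft_clip(ref_seg, rc)
    return Alignment(read_id=read_id, scaffold=name, start=start,
                     strand=strand, mismatches=mism,
                     score=codes.size - mism,
                     is_ambiguous=best_count > 1,
                     read_codes=rc, clip_lo=lo, clip_hi=hi)


def _soft_clip(ref_seg: np.ndarray, read: np.ndarray,
               mismatch_penalty: float = 2.0) -> Tuple[int, int]:
    """Maximal-scoring subsegment (match +1, mismatch -penalty) of the
    read against its placement -- the ungapped analogue of soft-clipping.
    Reads overhanging a junction into unrelated sequence get their
    mismatch-dense tail clipped; uniformly diverged reads are barely
    affected."""
    eq = ref_seg == read
    score = np.where(eq, 1.0, -mismatch_penalty)
    prefix = np.concatenate([[0.0], np.cumsum(score)])
    min_before = np.minimum.accumulate(prefix)[:-1]
    gains = prefix[1:] - min_before
    hi = int(np.argmax(gains)) + 1
    if gains[hi - 1] <= 0:  # no positively scoring stretch at all
        return 0, read.size
    lo = int(np.argmin(prefix[:hi]))
    return lo, hi


def map_reads(
    reads: Iterable[Tuple[str, np.ndarray]] | str | Path,
    reference: Mapping[str, np.ndarray] | ReferenceIndex | str | Path,
    k: int = 15,
    max_mismatch: int = 12,
) -> List[Alignment]:
    """Map reads to a reference; unmapped reads are omitted from the output.

    ``reads`` may be an iterable of (id, code-array) pairs or a FASTQ path;
    ``reference`` a dict of code arrays, a prebuilt ReferenceIndex, or a
    FASTA path.  The result is independent of read order (each read is
    aligned independently; output order follows input order).
    """
    if isinstance(reference, ReferenceIndex):
        idx = reference
    else:
        if isinstance(reference, (str, Path)):
            reference = _seq.read_fasta(reference)
        idx = ReferenceIndex(reference, k=k)
    if isinstance(reads, (str, Path)):
        reads = _seq.read_fastq(reads)
    out: List[Alignment] = []
    for read_id, codes in reads:
        aln = _best_alignment(read_id, codes, idx, max_mismatch)
        if aln is not None:
            out.append(aln)
    return out


def alignments_to_tsv(alignments: Sequence[Alignment],
                      path: str | Path) -> None:
    """SAM-compatible minimal TSV: QNAME, FLAG (strand), RNAME, POS
    (1-based), NM, plus the aligned sequence for pileup replay."""
    pd.DataFrame([{
        "QNAME": a.read_id, "FLAG": 0 if a.strand == "+" else 16,
        "RNAME": a.scaffold, "POS": a.start + 1, "NM": a.mismatches,
        "AMBIG": int(a.is_ambiguous), "CLIP_LO": a.clip_lo,
        "CLIP_HI": a.clip_hi, "SEQ": _seq.decode(a.read_codes),
    } for a in alignments]).to_csv(path, sep="\t", index=False)


def alignments_from_tsv(path: str | Path) -> List[Alignment]:
    df = pd.read_csv(path, sep="\t", dtype={"RNAME": str})
    out = []
    for row in df.itertuples(index=False):
        codes = _seq.encode(row.SEQ)
        out.append(Alignment(
            read_id=row.QNAME, scaffold=row.RNAME, start=int(row.POS) - 1,
            strand="+" if row.FLAG == 0 else "-",
            mismatches=int(row.NM), score=codes.size - int(row.NM),
            is_ambiguous=bool(row.AMBIG), read_codes=codes,
            clip_lo=int(row.CLIP_LO), clip_hi=int(row.CLIP_HI)))
    return out


def pileup_and_call(
    alignments_by_sample: Mapping[str, Sequence[Alignment]],
    reference: Mapping[str, np.ndarray],
    min_depth: int = 20,
    het_band: Tuple[float, float] = (0.2, 0.8),
) -> SnvGenotypeTable:
    """Pileup the alignments and call biallelic SNV genotypes per sample.

    Per site: depth = reads covering it; candidate SNVs are sites where
    exactly two alleles are observed across the pooled samples.  Genotype
    per sample from the alt-allele fraction f: f < lo -> 0/0, lo <= f <= hi
    -> 0/1, f > hi -> 1/1; sites with depth < ``min_depth`` in a sample are
    ./., matching the depth<20 site filter convention.
    """
    lo, hi = het_band
    samples = tuple(alignments_by_sample)
    # per sample, per scaffold: 5 x L base counts (A,C,G,T,N)
    counts: Dict[str, Dict[str, np.ndarray]] = {
        s: {name: np.zeros((5, codes.size), dtype=np.int32)
            for name, codes in reference.items()}
        for s in samples
    }
    for s in samples:
        for aln in alignments_by_sample[s]:
            bc = counts[s][aln.scaffold]
            clo, chi = aln.clip_lo, aln.clip_hi
            span = np.arange(aln.start + clo, aln.start + chi)
            np.add.at(bc, (aln.read_codes[clo:chi], span), 1)

    rows = []
    for name, ref_codes in reference.items():
        pooled = sum(counts[s][name] for s in samples)
        base_pool = pooled[:4]
        observed = (base_pool > 0).sum(axis=0)
        ref_ok = ref_codes < 4
        cand = np.flatnonzero((observed == 2) & ref_ok)
        for pos in cand:
            col = base_pool[:, pos]
            ref_b = int(ref_codes[pos])
            if col[ref_b] == 0:
                continue  # two non-ref alleles: not a ref/alt biallelic site
            alt_b = int(np.argmax(np.where(np.arange(4) == ref_b, -1, col)))
            gt = np.empty(len(samples), dtype=np.int8)
            dp = np.empty(len(samples), dtype=np.int32)
            for j, s in enumerate(samples):
                c = counts[s][name][:, pos]
                depth = int(c[:4].sum())
                dp[j] = depth
                if depth < min_depth:
                    gt[j] = -1
                    continue
                frac = c[alt_b] / depth
                gt[j] = 0 if frac < lo else (1 if frac <= hi else 2)
            rows.append({
                "scaffold": name, "pos": int(pos) + 1,
                "ref": _seq.BASES[ref_b], "alt": _seq.BASES[alt_b],
                "gt": gt, "dp": dp,
            })
    if not rows:
        return SnvGenotypeTable(
            sites=pd.DataFrame(columns=["scaffold", "pos", "ref", "alt"]),
            gt=np.empty((0, len(samples)), dtype=np.int8),
            dp=np.empty((0, len(samples)), dtype=np.int32),
            samples=samples)
    return SnvGenotypeTable.build(rows, samples)
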