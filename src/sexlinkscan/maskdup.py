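"""Intra-genome duplication detection and hard-masking.

Recently duplicated regions (paralogs) attract each other's reads during
short-read mapping, which manufactures fake heterozygous SNV calls and
spurious association peaks.  The remedy is to find duplicated stretches by
seeded self-comparison of the assembly and hard-mask them (replace with N)
before mapping, so neither copy can capture the other's reads.

Detection: shared k-mer seeds (the trivial self-diagonal excluded) are
chained along co-diagonals and extended ungapped in both directions while
the running identity stays above the threshold -- equivalent to finding the
maximum-scoring segment through the seed with match = +1 and mismatch =
-(min_ident / (1 - min_ident)).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np

from . import _seq


@dataclass(frozen=True)
class DuplicationCall:
    scaffold_a: str
    start_a: int  # 0-based half-open
    end_a: int
    scaffold_b: str
    start_b: int
    end_b: int
    identity: float
    length: int

    def intervals(self) -> List[Tuple[str, int, int]]:
        return [(self.scaffold_a, self.start_a, self.end_a),
                (self.scaffold_b, self.start_b, self.end_b)]


def _extend_pair(
    a: np.ndarray, b: np.ndarray,
    sa: int, sb: int, seed_len: int,
    min_ident: float,
    max_extend: int = 50_000,
) -> Tuple[int, int, int, float] | None:
    """Maximum-scoring ungapped segment through the seed at (sa, sb).

    Extension is capped at ``max_extend`` bp per side (duplications longer
    than that are still recovered piecewise from their other seeds).
    Returns (offset_a_start, offset_b_start, length, identity) or None.
    """
    # co-linear range around the seed, limited by both sequences and the cap
    left = min(sa, sb, max_extend)
    right = min(a.size - sa, b.size - sb, max_extend + seed_len)
    wa = a[sa - left: sa + right]
    wb = b[sb - left: sb + right]
    eq = wa == wb
    penalty = min_ident / (1.0 - min_ident) if min_ident < 1 else np.inf
    score = np.where(eq, 1.0, -penalty)
    prefix = np.concatenate([[0.0], np.cumsum(score)])
    # best segment [i, j) containing the seed [left, left + seed_len)
    i = int(np.argmin(prefix[: left + 1]))
    j = int(np.argmax(prefix[left + seed_len:])) + left + seed_len
    # trim ends to matches
    while i < j and not eq[i]:
        i += 1
    while j > i and not eq[j - 1]:
        j -= 1
    length = j - i
    if length <= 0:
        return None
    ident = float(eq[i:j].mean())
    if ident < min_ident:
        return None
    return sa - left + i, sb - left + i, length, ident


def find_self_duplications(
    genome: Mapping[str, np.ndarray] | str,
    k: int = 15,
    min_len: int = 500,
    min_ident: float = 0.9,
    max_kmer_occ: int = 100,
    chain_gap: int = 200,
) -> List[DuplicationCall]:
    """Detect duplicated region pairs within a genome.

    Seeds are k-mers occurring more than once; seed pairs on the same
    diagonal within ``chain_gap`` bp are chained and each chain is extended
    ungapped.  Each duplication pair is reported once (A before B in
    concatenated coordinate order).  Deterministic.
    """
    if k < 11:
        raise ValueError("k must be >= 11")
    if min_ident < 0.8:
        raise ValueError("min_ident must be >= 0.8")
    if isinstance(genome, str):
        genome = _seq.read_fasta(genome)
    names = list(genome)
    seqs = [genome[n] for n in names]
    offsets = np.cumsum([0] + [s.size for s in seqs])
    concat = np.concatenate(seqs) if seqs else np.empty(0, dtype=np.uint8)

    def locate(gpos: int) -> Tuple[int, int]:
        ref = int(np.searchsorted(offsets, gpos, side="right")) - 1
        return ref, gpos - int(offsets[ref])

    kmers = _seq.kmer_codes(concat, k)
    # mask k-mers spanning scaffold boundaries
    for b in offsets[1:-1]:
        kmers[max(0, b - k + 1): b] = -1
    order = np.argsort(kmers, kind="stable")
    svals = kmers[order]
    bounds = np.flatnonzero(np.diff(svals)) + 1
    starts = np.concatenate([[0], bounds])
    ends = np.concatenate([bounds, [svals.size]])

    # collect seed pairs (p < q) keyed by diagonal q - p
    pairs_by_diag: Dict[int, List[int]] = {}
    for a, b in zip(starts, ends):
        if svals[a] < 0 or not (2 <= b - a <= max_kmer_occ):
            continue
        pos = np.sort(order[a:b])
        for i in range(pos.size):
            for j in range(i + 1, pos.size):
                p, q = int(pos[i]), int(pos[j])
                pairs_by_diag.setdefault(q - p, []).append(p)

    calls: List[DuplicationCall] = []
    seen: set = set()
    for diag, plist in sorted(pairs_by_diag.items()):
        plist.sort()
        # chain seeds on this diagonal within chain_gap
        chains: List[List[int]] = [[plist[0]]]
        for p in plist[1:]:
            if p - chains[-1][-1] <= chain_gap:
                chains[-1].append(p)
            else:
                chains.append([p])
        for chain in chains:
            p0 = chain[len(chain) // 2]  # extend from a central seed
            q0 = p0 + diag
            ra, pa = locate(p0)
            rb, pb = locate(q0)
            ext = _extend_pair(seqs[ra], seqs[rb], pa, pb, k, min_ident)
            if ext is None:
                continue
            ia, ib, length, ident = ext
            if length < min_len:
                continue
            call = DuplicationCall(
                scaffold_a=names[ra], start_a=ia, end_a=ia + length,
                scaffold_b=names[rb], start_b=ib, end_b=ib + length,
                identity=ident, length=length)
            key = (call.scaffold_a, call.start_a, call.end_a,
                   call.scaffold_b, call.start_b, call.end_b)
            if key not in seen and (call.scaffold_a, call.start_a) != (
                    call.scaffold_b, call.start_b):
                seen.add(key)
                calls.append(call)
    return calls


def locate_sequences(
    genome: Mapping[str, np.ndarray],
    queries: Sequence[np.ndarray],
    k: int = 15,
    min_len: int = 500,
    min_ident: float = 0.9,
    max_kmer_occ: int = 100,
    chain_gap: int = 200,
) -> List[Tuple[str, int, int]]:
    """Find (near-)matching occurrences of query sequences in a genome.

    Used to carry duplication masking across assemblies: duplications are
    detected where both copies are assembled, and the detected *sequences*
    are then located -- at ``min_ident`` or better -- in the mapping
    reference, whose matching intervals are returned for masking.
    """
    combined: Dict[str, np.ndarray] = dict(genome)
    for i, q in enumerate(queries):
        combined[f"__query_{i}"] = q
    calls = find_self_duplications(
        combined, k=k, min_len=min_len, min_ident=min_ident,
        max_kmer_occ=max_kmer_occ, chain_gap=chain_gap)
    out: List[Tuple[str, int, int]] = []
    for c in calls:
        a_is_q = c.scaffold_a.startswith("__query_")
        b_is_q = c.scaffold_b.startswith("__query_")
        if a_is_q == b_is_q:  # genome-internal or query-query pair
            continue
        name, s, e = ((c.scaffold_b, c.start_b, c.end_b) if a_is_q
                      else (c.scaffold_a, c.start_a, c.end_a))
        out.append((name, s, e))
    return _union_intervals(out)


def _union_intervals(
    intervals: Sequence[Tuple[str, int, int]]
) -> List[Tuple[str, int, int]]:
    by_scaffold: Dict[str, List[Tuple[int, int]]] = {}
    for name, a, b in intervals:
        by_scaffold.setdefault(name, []).append((a, b))
    out: List[Tuple[str, int, int]] = []
    for name in by_scaffold:
        merged: List[List[int]] = []
        for a, b in sorted(by_scaffold[name]):
            if merged and a <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], b)
            else:
                merged.append([a, b])
        out.extend((name, a, b) for a, b in merged)
    return out


def mask_genome(
    genome: Mapping[str, np.ndarray],
    calls: Sequence[DuplicationCall] | Sequence[Tuple[str, int, int]],
) -> Tuple[Dict[str, np.ndarray], List[Tuple[str, int, int]]]:
    """Hard-mask every base inside any call interval with N.

    Accepts DuplicationCalls or plain (scaffold, start, end) intervals;
    intervals on scaffolds absent from ``genome`` are ignored (duplications
    may have been detected on a different assembly).  Returns the masked
    genome (sequence lengths unchanged, unmasked bases untouched) and the
    merged BED-style interval list actually masked.  Idempotent.
    """
    intervals: List[Tuple[str, int, int]] = []
    for c in calls:
        ivs = c.intervals() if isinstance(c, DuplicationCall) else [tuple(c)]
        for name, a, b in ivs:
            if name not in genome:
                continue
            if not (0 <= a <= b <= genome[name].size):
                raise ValueError(
                    f"interval [{a},{b}) out of bounds on {name}")
            intervals.append((name, a, b))
    merged = _union_intervals(intervals)
    masked = {name: codes.copy() for name, codes in genome.items()}
    for name, a, b in merged:
        masked[name][a:b] = _seq.N_CODE
    return masked, merged


def write_bed(intervals: Sequence[Tuple[str, int, int]], path) -> None:
    with open(path, "w") as fh:
        for name, a, b in intervals:
            fh.write(f"{name}\t{a}\t{b}\n")
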