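"""Low-level nucleotide sequence utilities.

Sequences are held internally as ``uint8`` code arrays (A,C,G,T -> 0..3,
anything else -> 4).  Code 4 never equals any base code, so an N in either
sequence counts as a mismatch in every comparison -- which is exactly the
behaviour the hard-masking step relies on.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Iterable, Mapping, Tuple

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

BASES = "ACGT"
N_CODE = 4

_ENCODE = np.full(256, N_CODE, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)

# complement: A<->T, C<->G, N->N
_COMPLEMENT = np.array([3, 2, 1, 0, 4], dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string to a uint8 code array."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode("ascii")


def revcomp(codes: np.ndarray) -> np.ndarray:
    return _COMPLEMENT[codes[::-1]]


def random_codes(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 4, size=length, dtype=np.uint8)


def mutate(
    codes: np.ndarray, rng: np.random.Generator, rate: float
) -> Tuple[np.ndarray, int]:
    """Substitute bases independently at ``rate``; always to a different base.

    Returns the mutated copy and the number of substitutions applied.
    """
    out = codes.copy()
    if rate <= 0:
        return out, 0
    hits = np.flatnonzero(rng.random(codes.size) < rate)
    if hits.size:
        # shift by 1..3 mod 4 guarantees a different base
        out[hits] = (out[hits] + rng.integers(1, 4, size=hits.size)) % 4
    return out, int(hits.size)


_POWER_CACHE: dict = {}


def _powers(k: int) -> np.ndarray:
    if k not in _POWER_CACHE:
        _POWER_CACHE[k] = (4 ** np.arange(k - 1, -1, -1)).astype(np.int64)
    return _POWER_CACHE[k]


def kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Integer value of every k-mer (2 bits/base); -1 where the window has an N."""
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    codes = np.ascontiguousarray(codes)
    windows = np.lib.stride_tricks.as_strided(
        codes, shape=(n, k), strides=(codes.strides[0], codes.strides[0]))
    vals = windows @ _powers(k)
    if (codes >= N_CODE).any():
        vals[windows.max(axis=1) >= N_CODE] = -1
    return vals


def match_positions(
    template: np.ndarray, query: np.ndarray, max_mismatch: int = 0
) -> np.ndarray:
    """All start positions where ``query`` matches ``template`` with at most
    ``max_mismatch`` substitutions (ungapped).  N in either counts as mismatch."""
    m = query.size
    if template.size < m:
        return np.empty(0, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(template, m)
    mism = (windows != query).sum(axis=1)
    return np.flatnonzero(mism <= max_mismatch).astype(np.int64)


def read_fasta(path: str | Path) -> Dict[str, np.ndarray]:
    """Read a FASTA file into a dict of code arrays (order preserved)."""
    out: Dict[str, np.ndarray] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        out[rec.id] = encode(str(rec.seq))
    return out


def write_fasta(seqs: Mapping[str, np.ndarray], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(decode(codes)), id=name, description="")
        for name, codes in seqs.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fastq(path: str | Path) -> Iterable[Tuple[str, np.ndarray]]:
    for rec in SeqIO.parse(str(path), "fastq"):
        yield rec.id, encode(str(rec.seq))


def write_fastq(reads: Iterable[Tuple[str, np.ndarray]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, codes in reads:
            seq = decode(codes)
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")
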