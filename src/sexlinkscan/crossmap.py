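"""Cross-mapping audit.

When a read's true source locus is missing from (or diverged in) the
mapping reference, the read lands on the closest paralog instead.  This
module quantifies that effect for a focal region: every read mapped there
is re-scored (full-length ungapped mismatch count) against a set of
candidate locus sequences -- which must include the focal region itself --
and classified:

* ``concordant``   best-scoring locus is the mapped one, strictly;
* ``cross-mapped`` a foreign locus scores strictly better (margin >= 1);
* ``ambiguous``    the best score is tied across distinct loci.

The summary fraction counts cross-mapped reads plus ambiguous reads whose
tie involves a foreign locus, over all reads mapped to the focal region.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np

from . import _seq
from .mapper import Alignment


@dataclass(frozen=True)
class OriginClassification:
    read_id: str
    mapped_locus: str
    best_locus: str
    best_mismatches: int
    margin: int  # mismatch difference to the second-best locus
    classification: str  # concordant / cross-mapped / ambiguous
    foreign_in_tie: bool


class _LocusIndex:
    """Sorted k-mer positions of one candidate locus, built once."""

    def __init__(self, locus: np.ndarray, k: int):
        self.locus = locus
        self.k = k
        kmers = _seq.kmer_codes(locus, k)
        self.order = np.argsort(kmers, kind="stable")
        self.svals = kmers[self.order]


def _best_mismatch_on_locus(codes: np.ndarray, idx: _LocusIndex) -> int | None:
    """Fewest mismatches of the read anywhere on the locus (both strands),
    found by dense k-mer seeding plus full-length rescoring."""
    best: int | None = None
    locus, k = idx.locus, idx.k
    order, svals = idx.order, idx.svals
    for rc in (codes, _seq.revcomp(codes)):
        if rc.size > locus.size:
            continue
        read_kmers = _seq.kmer_codes(rc, k)
        lo = np.searchsorted(svals, read_kmers, side="left")
        hi = np.searchsorted(svals, read_kmers, side="right")
        starts = set()
        for off in np.flatnonzero((hi > lo) & (read_kmers >= 0)):
            for pos in order[lo[off]:hi[off]]:
                s = int(pos) - int(off)
                if 0 <= s <= locus.size - rc.size:
                    starts.add(s)
        for s in starts:
            mism = int(np.count_nonzero(locus[s:s + rc.size] != rc))
            if best is None or mism < best:
                best = mism
    return best


def classify_mapped_reads(
    alignments: Sequence[Alignment],
    focal: Tuple[str, int, int],
    candidates: Mapping[str, np.ndarray],
    reads: Mapping[str, np.ndarray],
    focal_name: str,
    k: int = 13,
) -> List[OriginClassification]:
    """Classify reads mapped inside the focal region by most plausible origin.

    ``alignments`` is any alignment set over the mapping reference;
    ``focal`` = (scaffold, start, end) selects the reads to audit;
    ``candidates`` maps locus name -> sequence and must contain
    ``focal_name`` (the focal region's own sequence).  ``reads`` maps read
    id -> original read codes.  Reads absent from ``reads`` are skipped.
    """
    if focal_name not in candidates:
        raise ValueError("candidate set must include the focal region")
    scaffold, start, end = focal
    indices = {name: _LocusIndex(locus, k)
               for name, locus in candidates.items()}
    out: List[OriginClassification] = []
    for aln in alignments:
        if aln.scaffold != scaffold or aln.end <= start or aln.start >= end:
            continue
        codes = reads.get(aln.read_id)
        if codes is None:
            continue
        scores: Dict[str, int] = {}
        for name, locus_idx in indices.items():
            mism = _best_mismatch_on_locus(codes, locus_idx)
            if mism is not None:
                scores[name] = mism
        if not scores:
            continue
        best_val = min(scores.values())
        best_loci = sorted(n for n, v in scores.items() if v == best_val)
        others = [v for n, v in scores.items() if n not in best_loci]
        margin = (min(others) - best_val) if others else 0
        if len(best_loci) > 1:
            cls = "ambiguous"
            margin = 0
        elif best_loci[0] == focal_name:
            cls = "concordant"
        else:
            cls = "cross-mapped"
        out.append(OriginClassification(
            read_id=aln.read_id,
            mapped_locus=focal_name,
            best_locus=best_loci[0],
            best_mismatches=best_val,
            margin=margin,
            classification=cls,
            foreign_in_tie=any(n != focal_name for n in best_loci),
        ))
    return out


def crossmap_fraction(
    classifications: Sequence[OriginClassification],
) -> Tuple[float, Dict[str, int]]:
    """Fraction of audited reads whose best origin is (or ties with) a
    foreign locus, plus per-class counts."""
    if not classifications:
        raise ValueError("no classified reads")
    counts = {"concordant": 0, "cross-mapped": 0, "ambiguous": 0}
    foreign = 0
    for c in classifications:
        counts[c.classification] += 1
        if c.classification == "cross-mapped" or (
                c.classification == "ambiguous" and c.foreign_in_tie):
            foreign += 1
    return foreign / len(classifications), counts
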