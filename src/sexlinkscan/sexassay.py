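"""In-silico PCR sex genotyping and the gonad expression test.

PCR assay: three primer pairs are evaluated against a genome; two are
male-specific (they amplify only off the male-specific region) and one is
"common" (conserved sites present in both the male-specific cassette and
its autosomal paralog, with a small length difference between the two
templates).  The amplification pattern then reads out sex: males show both
male-specific products and two size classes for the common pair; females
show no male-specific product and a single common product.

Expression test: FPKM = counts * 1e9 / (gene length * library size); a gene
is "expressed" in a sample iff FPKM > 0, and the testis/ovary expressed
pattern of a candidate male-specific gene is tested with a two-sided
Fisher's exact test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from . import _seq
from .stats import fisher_exact_2x2


@dataclass(frozen=True)
class PrimerPair:
    name: str
    forward: str  # 5'->3'
    reverse: str  # 5'->3'
    max_product_size: int = 2000
    max_mismatches: int = 0

    def __post_init__(self) -> None:
        for seq in (self.forward, self.reverse):
            if len(seq) < 15:
                raise ValueError("primers must be >= 15 bp")
            if set(seq) - set(_seq.BASES):
                raise ValueError("primers must be over {A,C,G,T}")


@dataclass(frozen=True)
class AmpliconPrediction:
    primer_name: str
    scaffold: str
    start: int  # 0-based half-open; 5' end of the forward site
    end: int  # one past the 5' end of the reverse site
    size: int


def predict_amplicons(
    template: Mapping[str, np.ndarray],
    pair: PrimerPair,
) -> List[AmpliconPrediction]:
    """All products the primer pair would amplify off the template.

    A product requires a forward-primer site on the plus strand upstream of
    a reverse-complemented reverse-primer site, within ``max_product_size``;
    the size runs from the forward site's 5' end to the reverse site's 5'
    end inclusive.  An empty list is a valid "not amplified" result.
    """
    fwd = _seq.encode(pair.forward)
    rev_rc = _seq.revcomp(_seq.encode(pair.reverse))
    out: List[AmpliconPrediction] = []
    for name, codes in template.items():
        f_sites = _seq.match_positions(codes, fwd, pair.max_mismatches)
        r_sites = _seq.match_positions(codes, rev_rc, pair.max_mismatches)
        for f in f_sites:
            for r in r_sites:
                end = int(r) + rev_rc.size  # 5' end of the reverse primer
                size = end - int(f)
                if f + fwd.size <= r and size <= pair.max_product_size:
                    out.append(AmpliconPrediction(
                        primer_name=pair.name, scaffold=name,
                        start=int(f), end=end, size=size))
    return sorted(out, key=lambda a: (a.scaffold, a.start, a.size))


def sex_call_from_patterns(
    products: Mapping[str, Sequence[int]],
    male_sets: Tuple[str, str] = ("male_a", "male_b"),
    common_set: str = "common",
) -> str:
    """Sex call from the amplification pattern of the three primer sets.

    male   iff both male-specific sets amplify and the common set yields
           two distinct size classes;
    female iff neither male-specific set amplifies and the common set
           yields a single size class;
    otherwise inconclusive.
    """
    for key in (*male_sets, common_set):
        if key not in products:
            raise KeyError(f"missing primer set {key!r}")
    male_amp = [len(products[k]) > 0 for k in male_sets]
    common_sizes = sorted(set(products[common_set]))
    if all(male_amp) and len(common_sizes) == 2:
        return "male"
    if not any(male_amp) and len(common_sizes) == 1:
        return "female"
    return "inconclusive"


def fpkm(
    counts: pd.DataFrame,
    lengths: pd.Series | Mapping[str, int],
    totals: pd.Series | Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """FPKM[g, s] = counts[g, s] * 1e9 / (length[g] * total[s]).

    ``totals`` defaults to the per-sample column sums of ``counts``.
    """
    lengths = pd.Series(lengths).reindex(counts.index)
    if lengths.isna().any() or (lengths < 1).any():
        raise ValueError("every gene needs a length >= 1")
    if totals is None:
        totals = counts.sum(axis=0)
    totals = pd.Series(totals).reindex(counts.columns)
    if (totals <= 0).any():
        raise ValueError("library sizes must be > 0")
    return counts.mul(1e9).div(lengths, axis=0).div(totals, axis=1)


def percent_of_control(fpkm_matrix: pd.DataFrame,
                       control_gene: str) -> pd.DataFrame:
    """Each gene's FPKM as a percentage of the control gene's FPKM, per
    sample; NaN where the control is unexpressed in that sample."""
    control = fpkm_matrix.loc[control_gene]
    denom = control.where(control > 0)
    return fpkm_matrix.div(denom, axis=1) * 100.0


def expressed_flag(value: float | np.ndarray | pd.DataFrame):
    """'Expressed' iff FPKM > 0 (a detectable transcript at any level)."""
    if np.any(np.asarray(value) < 0):
        raise ValueError("FPKM must be non-negative")
    return value > 0


def expression_sex_test(
    counts: pd.DataFrame,
    lengths: pd.Series | Mapping[str, int],
    groups: pd.Series | Mapping[str, str],
    gene: str,
    totals: pd.Series | Mapping[str, int] | None = None,
) -> Dict[str, object]:
    """Expressed/not-expressed Fisher test of one gene between gonad groups.

    Builds the 2x2 table (testis/ovary x expressed/not) from FPKM > 0 and
    returns the table, per-group expressed counts and the two-sided p.
    """
    groups = pd.Series(groups)
    fp = fpkm(counts, lengths, totals)
    flags = expressed_flag(fp.loc[gene])
    table = np.zeros((2, 2), dtype=int)
    for i, grp in enumerate(("testis", "ovary")):
        in_grp = groups == grp
        table[i, 0] = int((flags & in_grp).sum())
        table[i, 1] = int((~flags & in_grp).sum())
    return {
        "gene": gene,
        "table": table,
        "n_expressed_testis": int(table[0, 0]),
        "n_expressed_ovary": int(table[1, 0]),
        "p": fisher_exact_2x2(table),
    }


def read_primers_tsv(path) -> List[PrimerPair]:
    """Primer table: columns name, forward, reverse[, max_product_size,
    max_mismatches]."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for row in df.itertuples(index=False):
        kwargs = {}
        if hasattr(row, "max_product_size"):
            kwargs["max_product_size"] = int(row.max_product_size)
        if hasattr(row, "max_mismatches"):
            kwargs["max_mismatches"] = int(row.max_mismatches)
        out.append(PrimerPair(name=row.name, forward=row.forward,
                              reverse=row.reverse, **kwargs))
    return out
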