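"""Peptide format classification by cysteine scaffold.

Bicyclic-peptide libraries display peptides of the form
``X_l C X_m C X_n C X_o`` whose three cysteines are chemically cross-linked
into two rings; the loop lengths (m, n) define the format, e.g. "3x4" means
three residues between Cys1 and Cys2 and four between Cys2 and Cys3.
Peptides with fewer or more cysteines (library-construction errors or
disulfide formats) are classified by their cysteine count alone.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from bicypep.preprocess import AbundanceTable

__all__ = ["FormatClass", "classify_format", "format_statistics", "CYS_BUCKETS"]

CYS_BUCKETS = ("<3C", "3C", "4C", ">4C")


@dataclass(frozen=True)
class FormatClass:
    """Cysteine census of one peptide: count, loop lengths and flanks."""

    n_cys: int
    loops: tuple[int, ...]
    flank_l: int
    flank_r: int

    @property
    def loop_label(self) -> str:
        """Library-style loop label, e.g. '4x4' (first two loops)."""
        if self.n_cys < 2:
            return ""
        return "x".join(str(n) for n in self.loops[:2])

    @property
    def cys_bucket(self) -> str:
        if self.n_cys < 3:
            return "<3C"
        if self.n_cys == 3:
            return "3C"
        if self.n_cys == 4:
            return "4C"
        return ">4C"


def classify_format(aa_seq: str) -> FormatClass:
    """Census the cysteines of a peptide and the residue runs between them."""
    if not aa_seq:
        raise ValueError("empty peptide sequence")
    positions = [i for i, aa in enumerate(aa_seq) if aa == "C"]
    if not positions:
        return FormatClass(0, (), 0, 0)
    loops = tuple(
        positions[i + 1] - positions[i] - 1 for i in range(len(positions) - 1)
    )
    return FormatClass(
        n_cys=len(positions),
        loops=loops,
        flank_l=positions[0],
        flank_r=len(aa_seq) - positions[-1] - 1,
    )


def format_statistics(table: AbundanceTable, weighted: bool = False) -> dict[str, float]:
    """Fraction of peptides per cysteine bucket, sub-bucketed by loop format.

    Returns a flat map with the four cysteine buckets '<3C', '3C', '4C',
    '>4C' (these sum to 1) plus one entry per 3-cysteine loop format, keyed
    '3C mxn', giving its share of the whole table (the '3C mxn' entries sum
    to the '3C' entry).  ``weighted=True`` weights by read abundance,
    otherwise each distinct peptide counts once.
    """
    if not len(table):
        raise ValueError("empty abundance table")
    bucket_w: Counter[str] = Counter()
    loop_w: Counter[str] = Counter()
    total = 0.0
    for rec in table:
        fc = classify_format(rec.aa_seq)
        w = rec.count if weighted else 1
        bucket_w[fc.cys_bucket] += w
        if fc.n_cys == 3:
            loop_w[f"3C {fc.loop_label}"] += w
        total += w
    stats = {b: bucket_w.get(b, 0) / total for b in CYS_BUCKETS}
    for key in sorted(loop_w):
        stats[key] = loop_w[key] / total
    return stats


def format_statistics_to_tsv(table: AbundanceTable, path: str) -> None:
    """Write per-bucket distinct counts, read counts and both fractions."""
    distinct = format_statistics(table, weighted=False)
    weighted = format_statistics(table, weighted=True)
    n_distinct: Counter[str] = Counter()
    n_reads: Counter[str] = Counter()
    for rec in table:
        fc = classify_format(rec.aa_seq)
        keys = [fc.cys_bucket]
        if fc.n_cys == 3:
            keys.append(f"3C {fc.loop_label}")
        for key in keys:
            n_distinct[key] += 1
            n_reads[key] += rec.count
    with open(path, "w") as handle:
        handle.write(
            "bucket\tdistinct_peptides\ttotal_reads\t"
            "fraction_distinct\tfraction_weighted\n"
        )
        for key in distinct:
            handle.write(
                f"{key}\t{n_distinct[key]}\t{n_reads[key]}\t"
                f"{distinct[key]:.6f}\t{weighted[key]:.6f}\n"
            )
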