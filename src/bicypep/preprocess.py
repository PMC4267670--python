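"""Quality filtering, translation, abundance ranking and error correction.

After demultiplexing, each read consists of a constant 5' flank, the random
peptide-coding region, and a constant 3' flank.  This module filters reads on
per-base Phred quality, extracts the variable region between the flanks,
translates it with NNK/amber awareness (the amber stop TAG encodes glutamine
in supE hosts such as TG1), aggregates translated peptides into an
abundance-ranked table that preserves the underlying nucleotide variants, and
corrects sequencing errors by merging rare sequences into near-identical
abundant clones.

Error correction rationale: random peptide libraries sample only a tiny
fraction of sequence space, so two independently selected clones almost never
differ by just one or two bases.  A low-copy sequence within edit distance
two of a clone that is at least ``min_ratio`` times more abundant is
therefore attributed to a sequencing error and its reads are reassigned to
that clone.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Optional

import edlib
import numpy as np
from Bio.Data.CodonTable import standard_dna_table

__all__ = [
    "FilterPolicy",
    "ExtractionWindow",
    "PeptideRecord",
    "AbundanceTable",
    "quality_filter",
    "extract_region",
    "translate_region",
    "build_abundance_table",
    "correct_errors",
    "denoise_counts",
]

# standard genetic code; amber (TAG) handled separately at translate time
_CODON_TABLE = dict(standard_dna_table.forward_table)
_STOP_CODONS = frozenset(standard_dna_table.stop_codons)  # TAA, TAG, TGA


@dataclass(frozen=True)
class FilterPolicy:
    """Whole-read quality filter: tolerate at most ``max_below`` bases under
    ``q_threshold``.

    The permissive default (Q18, 3) keeps homopolymer-rich reads that a
    stricter filter would discard, avoiding a sequence-composition bias;
    a restrictive alternative is (Q20, 1).
    """

    q_threshold: int = 18
    max_below: int = 3

    def __post_init__(self) -> None:
        if self.q_threshold < 0 or self.max_below < 0:
            raise ValueError("q_threshold and max_below must be >= 0")


@dataclass(frozen=True)
class ExtractionWindow:
    """Constant flanks delimiting the random region, with length bounds."""

    left_flank: str
    right_flank: str
    min_len: int = 9
    max_len: int = 45

    def __post_init__(self) -> None:
        if not self.left_flank or not self.right_flank:
            raise ValueError("flanks must be non-empty")
        if self.min_len > self.max_len:
            raise ValueError("min_len > max_len")


@dataclass
class PeptideRecord:
    """One distinct peptide with its total count and nucleotide variants."""

    aa_seq: str
    nt_variants: dict[str, int]

    @property
    def count(self) -> int:
        return sum(self.nt_variants.values())

    @property
    def top_nt_seq(self) -> str:
        return min(self.nt_variants, key=lambda nt: (-self.nt_variants[nt], nt))


@dataclass
class AbundanceTable:
    """Peptides ranked by descending count (ties broken lexicographically)."""

    records: list[PeptideRecord] = field(default_factory=list)

    @property
    def total_reads(self) -> int:
        return sum(r.count for r in self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def counts(self) -> dict[str, int]:
        """Peptide -> count mapping (order follows the ranking)."""
        return {r.aa_seq: r.count for r in self.records}

    def nt_counts(self) -> dict[str, int]:
        """Pooled nucleotide-level counts across all records."""
        pooled: Counter[str] = Counter()
        for rec in self.records:
            pooled.update(rec.nt_variants)
        return dict(pooled)

    def head(self, n: int) -> list[PeptideRecord]:
        return self.records[:n]

    @classmethod
    def from_counts(
        cls, aa_nt_counts: dict[str, dict[str, int]]
    ) -> "AbundanceTable":
        records = [
            PeptideRecord(aa, dict(nts)) for aa, nts in aa_nt_counts.items()
        ]
        records.sort(key=lambda r: (-r.count, r.aa_seq))
        return cls(records)

    @classmethod
    def from_variants_tsv(cls, path: str) -> "AbundanceTable":
        """Load a table from the nt-variant TSV written by variants_to_tsv."""
        table: dict[str, dict[str, int]] = defaultdict(dict)
        with open(path) as handle:
            header = handle.readline().rstrip("\n").split("\t")
            if header != ["aa_seq", "nt_seq", "count"]:
                raise ValueError(f"{path}: not an nt-variant TSV")
            for line in handle:
                aa, nt, count = line.rstrip("\n").split("\t")
                table[aa][nt] = table[aa].get(nt, 0) + int(count)
        return cls.from_counts(table)

    def to_tsv(self, path: str) -> None:
        """Serialize rank, peptide, count, fraction, variant summary as TSV."""
        total = self.total_reads
        with open(path, "w") as handle:
            handle.write(
                "rank\taa_seq\tcount\tfraction\tn_nt_variants\ttop_nt_seq\n"
            )
            for rank, rec in enumerate(self.records, start=1):
                frac = rec.count / total if total else 0.0
                handle.write(
                    f"{rank}\t{rec.aa_seq}\t{rec.count}\t{frac:.6f}\t"
                    f"{len(rec.nt_variants)}\t{rec.top_nt_seq}\n"
                )

    def variants_to_tsv(self, path: str) -> None:
        with open(path, "w") as handle:
            handle.write("aa_seq\tnt_seq\tcount\n")
            for rec in self.records:
                for nt, c in sorted(
                    rec.nt_variants.items(), key=lambda kv: (-kv[1], kv[0])
                ):
                    handle.write(f"{rec.aa_seq}\t{nt}\t{c}\n")


def quality_filter(read, policy: FilterPolicy) -> bool:
    """True when at most ``policy.max_below`` bases fall under the threshold."""
    quals = read.quals
    n_below = 0
    for q in quals:
        if q < policy.q_threshold:
            n_below += 1
            if n_below > policy.max_below:
                return False
    return True


def extract_region(read, window: ExtractionWindow) -> Optional[str]:
    """Extract the variable region strictly between the first left flank and
    the first subsequent right flank; ``None`` if absent or out of bounds."""
    bases = read.bases if hasattr(read, "bases") else read
    i = bases.find(window.left_flank)
    if i < 0:
        return None
    start = i + len(window.left_flank)
    j = bases.find(window.right_flank, start)
    if j < 0:
        return None
    region = bases[start:j]
    if not (window.min_len <= len(region) <= window.max_len):
        return None
    return region


def translate_region(nt: str, amber_as_gln: bool = True) -> Optional[str]:
    """Translate a coding region under the standard genetic code.

    Returns ``None`` for sequences whose length is not a multiple of three,
    that contain bases outside ACGT, or that hit a true stop codon (TAA/TGA —
    a phage cannot display a prematurely terminated peptide).  The amber stop
    TAG is read as glutamine when ``amber_as_gln`` (NNK libraries are
    propagated in supE suppressor strains), otherwise it too aborts.
    """
    if not nt or len(nt) % 3 != 0:
        return None
    aa = []
    for i in range(0, len(nt), 3):
        codon = nt[i : i + 3]
        if codon in _STOP_CODONS:
            if codon == "TAG" and amber_as_gln:
                aa.append("Q")
                continue
            return None
        try:
            aa.append(_CODON_TABLE[codon])
        except KeyError:
            return None  # N or other non-ACGT base
    return "".join(aa)


class InconsistentPairError(ValueError):
    """A (peptide, nucleotide) pair whose translation does not match."""


def build_abundance_table(
    aa_nt_pairs: Iterable[tuple[str, str]],
    validate: bool = True,
    amber_as_gln: bool = True,
) -> AbundanceTable:
    """Aggregate per-read (peptide, nucleotide) pairs into a ranked table."""
    table: dict[str, Counter[str]] = defaultdict(Counter)
    for aa, nt in aa_nt_pairs:
        if validate and translate_region(nt, amber_as_gln) != aa:
            raise InconsistentPairError(
                f"nucleotide sequence {nt!r} does not translate to {aa!r}"
            )
        table[aa][nt] += 1
    return AbundanceTable.from_counts(table)


_BASE_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i
_BASE_CODE[ord("N")] = 4


def _encode(seq: str) -> np.ndarray:
    return _BASE_CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


class _ParentPool:
    """Retained (parent) sequences grouped by length for fast distance queries."""

    def __init__(self) -> None:
        self.by_len: dict[int, list[int]] = defaultdict(list)  # parent indices
        self.mats: dict[int, np.ndarray] = {}
        self.used: dict[int, int] = defaultdict(int)
        self.seqs: list[str] = []
        self.counts: list[int] = []  # running (accumulated) counts

    def add(self, seq: str, count: int) -> int:
        idx = len(self.seqs)
        self.seqs.append(seq)
        self.counts.append(count)
        L = len(seq)
        n = self.used[L]
        mat = self.mats.get(L)
        if mat is None or n == mat.shape[0]:
            cap = 16 if mat is None else mat.shape[0] * 2
            new = np.empty((cap, L), dtype=np.uint8)
            if mat is not None:
                new[:n] = mat[:n]
            self.mats[L] = new
            mat = new
        mat[n] = _encode(seq)
        self.by_len[L].append(idx)
        self.used[L] = n + 1
        return idx

    def find_parent(
        self, seq: str, count: int, max_mismatch: int, min_ratio: float
    ) -> Optional[int]:
        """Earliest-retained parent within distance and abundance bounds.

        Parents were added in descending-abundance order, so the smallest
        eligible index is the most abundant eligible parent.
        """
        L = len(seq)
        need = min_ratio * count
        best: Optional[int] = None
        # equal length: Hamming distance, vectorized
        if L in self.mats and self.used[L]:
            n = self.used[L]
            dists = (self.mats[L][:n] != _encode(seq)).sum(axis=1)
            idxs = np.asarray(self.by_len[L][:n])
            ok = dists <= max_mismatch
            for idx in idxs[ok]:
                if self.counts[idx] >= need:
                    best = int(idx)
                    break
        # nearby lengths: Levenshtein distance via edlib
        for dL in range(1, max_mismatch + 1):
            for L2 in (L - dL, L + dL):
                for idx in self.by_len.get(L2, ()):
                    if best is not None and idx >= best:
                        break
                    if self.counts[idx] < need:
                        continue
                    res = edlib.align(
                        seq, self.seqs[idx], task="distance", k=max_mismatch
                    )
                    if 0 <= res["editDistance"] <= max_mismatch:
                        best = idx if best is None else min(best, idx)
                        break
        return best


def _denoise_pass(
    counts: dict[str, int], max_mismatch: int, min_ratio: float
) -> tuple[dict[str, int], dict[str, str], bool]:
    pool = _ParentPool()
    parent_of: dict[str, str] = {}
    changed = False
    for seq, count in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])):
        pidx = pool.find_parent(seq, count, max_mismatch, min_ratio)
        if pidx is None:
            pool.add(seq, count)
            parent_of[seq] = seq
        else:
            pool.counts[pidx] += count
            parent_of[seq] = pool.seqs[pidx]
            changed = True
    merged = {s: c for s, c in zip(pool.seqs, pool.counts)}
    return merged, parent_of, changed


def denoise_counts(
    counts: dict[str, int], max_mismatch: int = 2, min_ratio: float = 10.0
) -> tuple[dict[str, int], dict[str, str]]:
    """Merge rare near-identical sequences into abundant parents.

    Sequences are visited in descending-count order; a sequence joins the
    most abundant already-retained parent within ``max_mismatch`` edits
    (Hamming for equal lengths, Levenshtein otherwise) whose accumulated
    count is at least ``min_ratio`` times its own.  Passes repeat until no
    merge occurs, so the result is a fixed point and the operation is
    idempotent.  Total counts are conserved.

    Returns the merged counts and a map from every input sequence to its
    final representative.
    """
    final_map = {s: s for s in counts}
    current = dict(counts)
    while True:
        current, parent_of, changed = _denoise_pass(current, max_mismatch, min_ratio)
        final_map = {s: parent_of[p] for s, p in final_map.items()}
        if not changed:
            return current, final_map


def correct_errors(
    table: AbundanceTable,
    max_mismatch: int = 2,
    min_ratio: float = 10.0,
    amber_as_gln: bool = True,
) -> AbundanceTable:
    """Correct sequencing errors by abundance at the nucleotide level.

    Operates on the pooled nucleotide variants of the table (so silent
    variants of the same peptide are also corrected), merges each rare
    sequence into a near-identical clone at least ``min_ratio`` times more
    abundant, then re-translates and re-ranks.  Never increases the number
    of distinct sequences, conserves total reads, and is idempotent.
    """
    merged, _ = denoise_counts(table.nt_counts(), max_mismatch, min_ratio)
    out: dict[str, dict[str, int]] = defaultdict(dict)
    for nt, count in merged.items():
        aa = translate_region(nt, amber_as_gln)
        if aa is None:
            raise ValueError(f"retained sequence {nt!r} is untranslatable")
        out[aa][nt] = count
    return AbundanceTable.from_counts(out)
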