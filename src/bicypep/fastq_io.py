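"""FASTQ input/output and barcode demultiplexing.

Amplicon reads from multiplexed phage selections carry a short sample barcode
at the read start (the sequencing adaptor is already removed by the
basecaller).  This module parses 4-line FASTQ with Phred+33 qualities into
:class:`QualityRead` objects, writes them back losslessly, and assigns reads
to selections by exact barcode match, with an optional single-edit rescue for
barcodes hit by one substitution, insertion or deletion.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

import edlib
from Bio.SeqIO.QualityIO import FastqGeneralIterator

__all__ = [
    "QualityRead",
    "BarcodeSpec",
    "DemuxResult",
    "RescueHit",
    "FastqParseError",
    "read_fastq",
    "write_fastq",
    "demultiplex",
    "rescue_barcode",
    "write_demux_fastq",
]

_NUCLEOTIDES = frozenset("ACGTN")


class FastqParseError(ValueError):
    """Raised for malformed FASTQ records; the message names the record."""


@dataclass(frozen=True)
class QualityRead:
    """One sequencing read: identifier, bases and per-base Phred scores."""

    read_id: str
    bases: str
    quals: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "quals", tuple(self.quals))
        if len(self.bases) != len(self.quals):
            raise ValueError(
                f"read {self.read_id!r}: {len(self.bases)} bases but "
                f"{len(self.quals)} quality scores"
            )
        if any(q < 0 for q in self.quals):
            raise ValueError(f"read {self.read_id!r}: negative Phred score")

    def __len__(self) -> int:
        return len(self.bases)

    def trimmed(self, start: int) -> "QualityRead":
        """Return a copy with everything before ``start`` removed."""
        return QualityRead(self.read_id, self.bases[start:], self.quals[start:])


@dataclass(frozen=True)
class BarcodeSpec:
    """A sample barcode: label, sequence and expected start offset."""

    label: str
    barcode: str
    expected_offset: int = 0

    def __post_init__(self) -> None:
        if not self.barcode:
            raise ValueError(f"barcode for {self.label!r} is empty")
        bad = set(self.barcode) - set("ACGT")
        if bad:
            raise ValueError(f"barcode for {self.label!r} has non-ACGT bases: {bad}")
        if self.expected_offset < 0:
            raise ValueError("expected_offset must be >= 0")


@dataclass
class DemuxResult:
    """Partition of input reads into per-label bins plus the unassigned rest."""

    assigned: dict[str, list[QualityRead]] = field(default_factory=dict)
    unassigned: list[QualityRead] = field(default_factory=list)

    @property
    def counts(self) -> dict[str, int]:
        return {label: len(reads) for label, reads in self.assigned.items()}

    @property
    def n_total(self) -> int:
        return sum(self.counts.values()) + len(self.unassigned)


@dataclass(frozen=True)
class RescueHit:
    """A successful single-edit barcode rescue: label and new trim point."""

    label: str
    trim_end: int


def read_fastq(path: str | os.PathLike) -> Iterator[QualityRead]:
    """Yield :class:`QualityRead` records from a 4-line Phred+33 FASTQ file.

    Parsing is strict: a record whose quality string length differs from its
    sequence length, or whose header lines are malformed, raises
    :class:`FastqParseError` naming the 1-based record number.
    """
    with open(path) as handle:
        record_no = 0
        iterator = FastqGeneralIterator(handle)
        while True:
            record_no += 1
            try:
                title, seq, qual = next(iterator)
            except StopIteration:
                return
            except ValueError as exc:
                raise FastqParseError(f"record {record_no}: {exc}") from exc
            if len(seq) != len(qual):
                raise FastqParseError(
                    f"record {record_no}: sequence length {len(seq)} != "
                    f"quality length {len(qual)}"
                )
            yield QualityRead(title, seq.upper(), tuple(ord(c) - 33 for c in qual))


def write_fastq(reads: Iterable[QualityRead], path: str | os.PathLike) -> None:
    """Write reads as 4-line FASTQ with Phred+33 qualities (round-trip safe)."""
    with open(path, "w") as handle:
        for read in reads:
            qual = "".join(chr(q + 33) for q in read.quals)
            handle.write(f"@{read.read_id}\n{read.bases}\n+\n{qual}\n")


def _check_specs(specs: Sequence[BarcodeSpec]) -> None:
    if not specs:
        raise ValueError("no barcode specs given")
    labels = [s.label for s in specs]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate barcode labels")
    barcodes = [(s.barcode, s.expected_offset) for s in specs]
    if len(set(barcodes)) != len(barcodes):
        raise ValueError("two barcode specs share the same barcode sequence")


def rescue_barcode(prefix: str, specs: Sequence[BarcodeSpec]) -> Optional[RescueHit]:
    """Assign a read prefix to a barcode within edit distance 1, if unambiguous.

    For each spec the prefix window at the expected offset is tested against
    the barcode allowing one substitution, one insertion or one deletion.  A
    hit is returned only when exactly one spec matches; equidistant barcodes
    yield ``None`` (ambiguity must never cross-contaminate selections).  For
    indel matches the trim point shifts by +/-1.  'N' bases never match.
    """
    hits: list[RescueHit] = []
    for spec in specs:
        b, off = spec.barcode, spec.expected_offset
        best: Optional[int] = None  # trim_end of the best edit for this spec
        # window length len(b): one substitution; len(b)-1: read lost a base;
        # len(b)+1: read gained a base.
        for delta in (0, -1, 1):
            window = prefix[off : off + len(b) + delta]
            if len(window) != len(b) + delta:
                continue
            res = edlib.align(b, window, task="distance", k=1)
            if res["editDistance"] == 1 or (delta == 0 and res["editDistance"] == 0):
                best = off + len(b) + delta
                break
        if best is not None:
            hits.append(RescueHit(spec.label, best))
    if len(hits) == 1:
        return hits[0]
    return None


def demultiplex(
    reads: Iterable[QualityRead],
    specs: Sequence[BarcodeSpec],
    rescue: bool = False,
) -> DemuxResult:
    """Partition reads by barcode; trim the barcode from assigned reads.

    A read is assigned to a label when its bases at the expected offset match
    that barcode exactly.  With ``rescue`` enabled, reads that match no
    barcode exactly are re-tested with :func:`rescue_barcode` (off by
    default: single-edit rescue recovers few reads and risks
    misassignment).  The barcode and everything before its end is trimmed
    from assigned reads; unassigned reads are kept untouched.
    """
    _check_specs(specs)
    result = DemuxResult(assigned={s.label: [] for s in specs})
    exact = {(s.barcode, s.expected_offset): s for s in specs}
    max_end = max(s.expected_offset + len(s.barcode) for s in specs)
    for read in reads:
        hit: Optional[RescueHit] = None
        for (barcode, off), spec in exact.items():
            if read.bases[off : off + len(barcode)] == barcode:
                hit = RescueHit(spec.label, off + len(barcode))
                break
        if hit is None and rescue:
            hit = rescue_barcode(read.bases[: max_end + 1], specs)
        if hit is None:
            result.unassigned.append(read)
        else:
            result.assigned[hit.label].append(read.trimmed(hit.trim_end))
    return result


def write_demux_fastq(result: DemuxResult, outdir: str | os.PathLike) -> str:
    """Write one FASTQ per label plus unassigned.fastq and a TSV report.

    Returns the path of the report file.
    """
    os.makedirs(outdir, exist_ok=True)
    for label, reads in result.assigned.items():
        write_fastq(reads, os.path.join(outdir, f"{label}.fastq"))
    write_fastq(result.unassigned, os.path.join(outdir, "unassigned.fastq"))
    total = result.n_total
    report_path = os.path.join(outdir, "demux_report.tsv")
    with open(report_path, "w") as handle:
        handle.write("label\tcount\tfraction\n")
        for label, count in result.counts.items():
            frac = count / total if total else 0.0
            handle.write(f"{label}\t{count}\t{frac:.6f}\n")
        frac = len(result.unassigned) / total if total else 0.0
        handle.write(f"unassigned\t{len(result.unassigned)}\t{frac:.6f}\n")
    return report_path
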