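"""Synthetic phage-selection datasets with known ground truth.

Every pipeline stage can be validated against data whose true composition is
known by construction.  This module generates:

* NNK-encoded peptide libraries of the bicyclic format
  ``X_l C X_m C X_n C X_o`` with optional constant flanking residues
  (randomized codons are NNK: any base at positions 1-2, G or T at
  position 3, so the only reachable stop is amber TAG, read as Gln in supE
  hosts);
* selection outputs with skewed clone-abundance distributions (uniform,
  geometric or Zipf) and optionally planted motif families — groups of
  clones sharing a conserved amino-acid core at a fixed loop position,
  emulating independently selected target binders;
* error-bearing reads: per-base substitutions and homopolymer-biased
  insertions/deletions, with Phred quality strings in which erroneous bases
  score low and even correct homopolymer bases are down-shifted, as flow
  sequencers assign them less confidence.

All operations are deterministic under their seed, and every simulation
returns its ground truth alongside the data.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from bicypep.fastq_io import QualityRead
from bicypep.preprocess import AbundanceTable, translate_region

__all__ = [
    "PeptideFormat",
    "LibrarySpec",
    "PlantedFamily",
    "SelectionSpec",
    "ErrorModel",
    "ReadTruth",
    "SimulatedSelection",
    "generate_library",
    "simulate_selection",
    "simulate_reads",
    "corrupt_regions",
    "sub_rate_for_read_error_rate",
    "NNK_CODONS_BY_AA",
]


def _nnk_codons_by_aa() -> dict[str, list[str]]:
    table: dict[str, list[str]] = defaultdict(list)
    for b1 in "ACGT":
        for b2 in "ACGT":
            for b3 in "GT":
                codon = b1 + b2 + b3
                aa = translate_region(codon, amber_as_gln=True)
                if aa is not None:
                    table[aa].append(codon)
    return dict(table)


NNK_CODONS_BY_AA = _nnk_codons_by_aa()
_ALL_NNK = sorted(c for codons in NNK_CODONS_BY_AA.values() for c in codons)


@dataclass(frozen=True)
class PeptideFormat:
    """Loop layout (l, m, n, o) with optional constant flanking residues.

    The displayed peptide is ``left_const + X^l C X^m C X^n C X^o +
    right_const``; e.g. ``PeptideFormat(0, 3, 3, 0, "A", "G")`` gives the
    A-C-loop-C-loop-C-G scaffold, and ``PeptideFormat(1, 3, 3, 1)`` the
    "3x3" X-C-XXX-C-XXX-C-X layout.
    """

    l: int
    m: int
    n: int
    o: int
    left_const: str = ""
    right_const: str = ""

    def __post_init__(self) -> None:
        if min(self.l, self.m, self.n, self.o) < 0:
            raise ValueError("loop lengths must be >= 0")
        for res in self.left_const + self.right_const:
            if res not in NNK_CODONS_BY_AA:
                raise ValueError(f"constant residue {res!r} is not an amino acid")

    @property
    def aa_template(self) -> str:
        """Template with 'X' at randomized positions."""
        return (
            self.left_const
            + "X" * self.l
            + "C"
            + "X" * self.m
            + "C"
            + "X" * self.n
            + "C"
            + "X" * self.o
            + self.right_const
        )

    @property
    def length(self) -> int:
        return len(self.aa_template)

    def loop_start(self, loop_index: int) -> int:
        """Peptide position where loop 0 (l), 1 (m), 2 (n) or 3 (o) begins."""
        starts = [
            len(self.left_const),
            len(self.left_const) + self.l + 1,
            len(self.left_const) + self.l + 1 + self.m + 1,
            len(self.left_const) + self.l + 1 + self.m + 1 + self.n + 1,
        ]
        return starts[loop_index]


@dataclass
class LibrarySpec:
    """A synthetic NNK library: formats, clone count and seed."""

    formats: list[PeptideFormat]
    n_clones: int
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.formats:
            raise ValueError("at least one format required")
        if self.n_clones < 1:
            raise ValueError("n_clones must be >= 1")


def _draw_clone(fmt: PeptideFormat, rng: np.random.Generator) -> tuple[str, str]:
    codons = []
    for res in fmt.aa_template:
        if res == "X":
            codons.append(_ALL_NNK[rng.integers(len(_ALL_NNK))])
        else:
            options = NNK_CODONS_BY_AA[res]
            codons.append(options[rng.integers(len(options))])
    nt = "".join(codons)
    aa = translate_region(nt, amber_as_gln=True)
    assert aa is not None
    return nt, aa


def _matches_template(aa: str, template: str) -> bool:
    if len(aa) != len(template):
        return False
    for got, want in zip(aa, template):
        if want == "X":
            if got == "C":  # an extra cysteine would change the scaffold
                return False
        elif got != want:
            return False
    return True


def generate_library(spec: LibrarySpec) -> list[tuple[str, str]]:
    """Draw ``n_clones`` distinct (nt_seq, aa_seq) clones from NNK space.

    Formats are sampled uniformly.  Clones whose randomized positions happen
    to encode an extra cysteine (NNK reaches TGT) are redrawn so that every
    clone classifies as its declared scaffold; distinctness is enforced at
    the nucleotide level.
    """
    rng = np.random.default_rng(spec.seed)
    clones: list[tuple[str, str]] = []
    seen: set[str] = set()
    while len(clones) < spec.n_clones:
        fmt = spec.formats[rng.integers(len(spec.formats))]
        nt, aa = _draw_clone(fmt, rng)
        if nt in seen or not _matches_template(aa, fmt.aa_template):
            continue
        seen.add(nt)
        clones.append((nt, aa))
    return clones


@dataclass(frozen=True)
class PlantedFamily:
    """A consensus family: clones sharing a conserved core at a fixed loop.

    Members descend from one ancestor clone: the core is implanted at the
    start of the chosen loop, and each member varies ``n_vary`` randomized
    (non-scaffold, non-core) positions.  This mirrors real consensus
    groups, whose members are highly similar across the peptide rather
    than sharing only the short motif.
    """

    core: str
    n_members: int
    copy_range: tuple[int, int]
    loop_index: int = 1  # plant in the first inter-cysteine loop by default
    n_vary: int = 2

    def __post_init__(self) -> None:
        if not self.core or self.n_members < 1:
            raise ValueError("core must be non-empty and n_members >= 1")
        lo, hi = self.copy_range
        if not 1 <= lo <= hi:
            raise ValueError("copy_range must satisfy 1 <= lo <= hi")
        if self.n_vary < 0:
            raise ValueError("n_vary must be >= 0")


@dataclass
class SelectionSpec:
    """Abundance law and planted families for a simulated selection round."""

    abundance_law: tuple = ("geometric", 0.01)
    planted_families: list[PlantedFamily] = field(default_factory=list)
    background_fraction: Optional[float] = None

    def __post_init__(self) -> None:
        law = self.abundance_law[0]
        if law not in ("uniform", "geometric", "zipf"):
            raise ValueError(f"unknown abundance law {law!r}")
        if self.background_fraction is not None and not (
            0.0 <= self.background_fraction <= 1.0
        ):
            raise ValueError("background_fraction must be in [0, 1]")


@dataclass
class SimulatedSelection:
    """Ordered per-read true sequences plus the ground-truth census."""

    reads: list[str]  # true nucleotide sequence of each read, in read order
    truth_nt_counts: dict[str, int]
    truth_table: AbundanceTable
    planted_members: list[list[str]]  # nt sequences per planted family


def _abundance_weights(law: tuple, n: int) -> np.ndarray:
    kind = law[0]
    ranks = np.arange(1, n + 1, dtype=float)
    if kind == "uniform":
        w = np.ones(n)
    elif kind == "geometric":
        p = float(law[1])
        w = (1.0 - p) ** (ranks - 1)
    else:  # zipf
        s = float(law[1])
        w = ranks ** (-s)
    return w / w.sum()


def _plant_family(
    family: PlantedFamily,
    library: Sequence[tuple[str, str]],
    fmt_of: dict[str, PeptideFormat],
    rng: np.random.Generator,
) -> list[str]:
    """Build member nt sequences around one ancestor carrying the core."""
    eligible = []
    for nt, aa in library:
        fmt = fmt_of[nt]
        loop_len = (fmt.l, fmt.m, fmt.n, fmt.o)[family.loop_index]
        if loop_len >= len(family.core):
            eligible.append((nt, aa, fmt))
    if not eligible:
        raise ValueError(
            f"no library clone has a loop {family.loop_index} that fits "
            f"core {family.core!r}"
        )
    nt, aa, fmt = eligible[rng.integers(len(eligible))]
    start = fmt.loop_start(family.loop_index)
    ancestor = [nt[i : i + 3] for i in range(0, len(nt), 3)]
    for offset, res in enumerate(family.core):
        options = NNK_CODONS_BY_AA[res]
        ancestor[start + offset] = options[rng.integers(len(options))]
    core_positions = set(range(start, start + len(family.core)))
    variable = [
        i
        for i, res in enumerate(fmt.aa_template)
        if res == "X" and i not in core_positions
    ]
    members: list[str] = []
    seen: set[str] = set()
    while len(members) < family.n_members:
        codons = list(ancestor)
        n_vary = min(family.n_vary, len(variable))
        for pos in rng.choice(variable, size=n_vary, replace=False):
            while True:
                codon = _ALL_NNK[rng.integers(len(_ALL_NNK))]
                if translate_region(codon) != "C":  # preserve the scaffold
                    break
            codons[pos] = codon
        new_nt = "".join(codons)
        if new_nt in seen:
            continue
        seen.add(new_nt)
        members.append(new_nt)
    return members


def simulate_selection(
    library: Sequence[tuple[str, str]],
    spec: SelectionSpec,
    n_reads: int,
    seed: int = 0,
    fmt_of: Optional[dict[str, PeptideFormat]] = None,
    library_formats: Optional[Sequence[PeptideFormat]] = None,
) -> SimulatedSelection:
    """Sample a selection output: per-read true sequences plus ground truth.

    Background reads are drawn multinomially from the library clones under
    the abundance law; planted family members receive explicit copy numbers
    drawn uniformly from their ``copy_range``.  When
    ``spec.background_fraction`` is set, planted copies are rescaled so the
    background holds that share of the reads.  Read order is shuffled.
    """
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    rng = np.random.default_rng(seed)
    library = list(library)
    if fmt_of is None:
        fmt_of = {}
        if spec.planted_families:
            if library_formats is None:
                raise ValueError(
                    "planting families requires fmt_of or library_formats"
                )
            for nt, aa in library:
                for fmt in library_formats:
                    if _matches_template(aa, fmt.aa_template):
                        fmt_of[nt] = fmt
                        break
            library = [(nt, aa) for nt, aa in library if nt in fmt_of]

    planted_members = [
        _plant_family(fam, library, fmt_of, rng) for fam in spec.planted_families
    ]
    planted_counts: Counter[str] = Counter()
    for fam, members in zip(spec.planted_families, planted_members):
        lo, hi = fam.copy_range
        for nt in members:
            planted_counts[nt] += int(rng.integers(lo, hi + 1))
    n_planted = sum(planted_counts.values())
    if spec.background_fraction is not None and n_planted:
        target = int(round((1.0 - spec.background_fraction) * n_reads))
        scale = target / n_planted
        planted_counts = Counter(
            {nt: max(1, int(round(c * scale))) for nt, c in planted_counts.items()}
        )
        n_planted = sum(planted_counts.values())
    if n_planted > n_reads:
        raise ValueError("planted copies exceed n_reads")

    n_background = n_reads - n_planted
    counts: Counter[str] = Counter(planted_counts)
    if n_background:
        weights = _abundance_weights(spec.abundance_law, len(library))
        draw = rng.multinomial(n_background, weights)
        for (nt, _), c in zip(library, draw):
            if c:
                counts[nt] += int(c)

    reads = np.repeat(
        np.array(sorted(counts), dtype=object),
        [counts[nt] for nt in sorted(counts)],
    )
    rng.shuffle(reads)
    truth_aa: dict[str, dict[str, int]] = defaultdict(dict)
    for nt, c in counts.items():
        aa = translate_region(nt, amber_as_gln=True)
        truth_aa[aa][nt] = c
    return SimulatedSelection(
        reads=list(reads),
        truth_nt_counts=dict(counts),
        truth_table=AbundanceTable.from_counts(truth_aa),
        planted_members=planted_members,
    )


@dataclass
class ErrorModel:
    """Per-base sequencing-error model with quality emission.

    Substitutions occur at ``sub_rate`` per base; insertions/deletions at
    ``indel_rate`` per base, multiplied by ``homopolymer_multiplier`` inside
    runs of at least ``homopolymer_min_run`` identical bases (flow-call
    over/under-calls concentrate there; an insertion duplicates the base, so
    indels lengthen or shorten runs).  Quality scores are drawn from normal
    laws discretized to Phred integers: correct bases around
    ``q_correct_mode``, erroneous bases around ``q_error_mode``, and correct
    bases inside homopolymer runs down-shifted by ``q_homopolymer_shift``.
    """

    sub_rate: float = 0.003
    indel_rate: float = 0.0005
    homopolymer_multiplier: float = 5.0
    homopolymer_min_run: int = 3
    q_correct_mode: float = 30.0
    q_error_mode: float = 12.0
    q_homopolymer_shift: float = 6.0
    q_sd: float = 4.0

    def __post_init__(self) -> None:
        for rate in (self.sub_rate, self.indel_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must be in [0, 1]")
        if self.q_error_mode >= self.q_correct_mode:
            raise ValueError("erroneous bases must score lower than correct ones")

    @classmethod
    def zero(cls) -> "ErrorModel":
        """An idealized error-free instrument: no errors and no confidence
        degradation in homopolymer runs (that degradation models flow-call
        uncertainty, which an error-free instrument does not have)."""
        return cls(sub_rate=0.0, indel_rate=0.0, q_homopolymer_shift=0.0)


def sub_rate_for_read_error_rate(per_read_rate: float, read_len: int) -> float:
    """Per-base substitution rate giving the target per-read error rate."""
    if not 0.0 <= per_read_rate < 1.0:
        raise ValueError("per_read_rate must be in [0, 1)")
    return 1.0 - (1.0 - per_read_rate) ** (1.0 / read_len)


@dataclass(frozen=True)
class ReadTruth:
    """Ground truth for one simulated read."""

    true_seq: str
    observed_seq: str
    n_errors: int
    has_indel: bool

    @property
    def is_erroneous(self) -> bool:
        return self.observed_seq != self.true_seq


_DECODE = np.frombuffer(b"ACGT", dtype=np.uint8)
_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i


def _run_lengths(seq: str) -> np.ndarray:
    """Length of the homopolymer run containing each position."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    runs = np.empty(len(arr), dtype=np.int64)
    start = 0
    for i in range(1, len(arr) + 1):
        if i == len(arr) or arr[i] != arr[start]:
            runs[start:i] = i - start
            start = i
    return runs


def _quals(model: ErrorModel, mode: float, size, rng) -> np.ndarray:
    q = np.rint(rng.normal(mode, model.q_sd, size=size))
    return np.clip(q, 2, 40).astype(np.int64)


def _corrupt_batch(
    seq: str, n: int, model: ErrorModel, rng: np.random.Generator
) -> list[tuple[str, np.ndarray, int, bool]]:
    """Corrupt ``n`` copies of ``seq``; returns (seq', quals, n_errors, indel)."""
    L = len(seq)
    arr = _ENCODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    runs = _run_lengths(seq)
    hp = runs >= model.homopolymer_min_run
    indel_vec = np.where(
        hp, model.indel_rate * model.homopolymer_multiplier, model.indel_rate
    )
    sub_mask = rng.random((n, L)) < model.sub_rate
    ind_mask = rng.random((n, L)) < indel_vec[None, :]

    bases = np.broadcast_to(arr, (n, L)).copy()
    n_subs = int(sub_mask.sum())
    if n_subs:
        shifts = rng.integers(1, 4, size=n_subs).astype(np.uint8)
        bases[sub_mask] = (bases[sub_mask] + shifts) % 4

    quals = _quals(model, model.q_correct_mode, (n, L), rng)
    if hp.any():
        quals[:, hp] = np.maximum(quals[:, hp] - int(model.q_homopolymer_shift), 2)
    if n_subs:
        quals[sub_mask] = _quals(model, model.q_error_mode, n_subs, rng)

    out: list[tuple[str, np.ndarray, int, bool]] = []
    indel_rows = ind_mask.any(axis=1)
    for row in range(n):
        row_bases = bases[row]
        row_quals = quals[row]
        n_err = int(sub_mask[row].sum())
        has_indel = bool(indel_rows[row])
        if has_indel:
            blist = list(row_bases)
            qlist = list(row_quals)
            for pos in np.nonzero(ind_mask[row])[0][::-1]:
                n_err += 1
                if rng.random() < 0.5:  # deletion
                    del blist[pos]
                    del qlist[pos]
                else:  # insertion: duplicate the base (flow over-call)
                    blist.insert(pos, blist[pos])
                    qlist.insert(pos, int(_quals(model, model.q_error_mode, 1, rng)[0]))
            row_bases = np.array(blist, dtype=np.uint8)
            row_quals = np.array(qlist, dtype=np.int64)
        observed = _DECODE[row_bases].tobytes().decode()
        out.append((observed, row_quals, n_err, has_indel))
    return out


def _corrupt_stream(
    true_seqs: Sequence[str], model: ErrorModel, rng: np.random.Generator
) -> tuple[list[ReadTruth], list[np.ndarray]]:
    """Corrupt each read in stream order; returns truths and region quals.

    Reads of each distinct true sequence are corrupted in one vectorized
    batch (identical sequences are interchangeable), then dealt back out in
    stream order.
    """
    queues: dict[str, list] = {}
    for seq, n in sorted(Counter(true_seqs).items()):
        queues[seq] = _corrupt_batch(seq, n, model, rng)
    truths: list[ReadTruth] = []
    quals: list[np.ndarray] = []
    for seq in true_seqs:
        obs, q, n_err, has_indel = queues[seq].pop()
        truths.append(ReadTruth(seq, obs, n_err, has_indel))
        quals.append(q)
    return truths, quals


def corrupt_regions(
    true_seqs: Sequence[str], model: ErrorModel, seed: int = 0
) -> tuple[list[str], list[ReadTruth]]:
    """Apply the error model to a stream of true sequences (no FASTQ plumbing).

    Returns the observed sequences in the same read order plus per-read
    truth records.  Used for diversity studies where barcodes, flanks and
    quality strings are irrelevant.
    """
    rng = np.random.default_rng(seed)
    truths, _ = _corrupt_stream(true_seqs, model, rng)
    return [t.observed_seq for t in truths], truths


def simulate_reads(
    true_seqs: Sequence[str],
    error_model: ErrorModel,
    barcode: str,
    flanks: tuple[str, str],
    seed: int = 0,
) -> tuple[list[QualityRead], list[ReadTruth]]:
    """Emit full amplicon reads: barcode + flank + corrupted region + flank.

    Corruption (substitutions and homopolymer-weighted indels) applies to
    the coding region; barcode and flanks are emitted error-free with
    correct-base qualities.  Per-read ground truth records the observed
    region and its error status.
    """
    left, right = flanks
    rng = np.random.default_rng(seed)
    truths, region_quals = _corrupt_stream(true_seqs, error_model, rng)
    prefix, suffix = barcode + left, right
    n = len(truths)
    const_left = _quals(error_model, error_model.q_correct_mode, (n, len(prefix)), rng)
    const_right = _quals(error_model, error_model.q_correct_mode, (n, len(suffix)), rng)
    reads: list[QualityRead] = []
    for i, truth in enumerate(truths):
        bases = prefix + truth.observed_seq + suffix
        quals = (
            tuple(const_left[i]) + tuple(region_quals[i]) + tuple(const_right[i])
        )
        reads.append(QualityRead(f"sim_{i}", bases, quals))
    return reads, truths
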