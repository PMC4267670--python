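"""Consensus-group clustering and degenerate motif search.

Peptides independently selected against the same target often share a short
conserved motif (e.g. LPP, HPQ, [ST]AR) embedded in otherwise random
sequence.  This module finds such motifs by clustering the most abundant
peptides: pairwise distances are derived from global (Needleman-Wunsch)
BLOSUM62 alignment scores, an average-linkage (UPGMA) guide tree is built,
and cutting the tree at a height threshold yields consensus groups whose
members are summarized as position-frequency matrices.  A separate search
operation then scans the whole peptide pool for a degenerate motif pattern
written in a small mini-language (fixed residues, bracketed residue sets
such as ``[ST]``, and the wildcard ``X`` or ``.``).

The score-to-distance transform is d = 1 - S(p,q) / min(S(p,p), S(q,q)),
clipped to [0, 1]: identical peptides are at distance 0 and unrelated ones
near or at 1.  Such distances need not satisfy the triangle inequality,
which UPGMA does not require.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy.spatial.distance import squareform

from bicypep.preprocess import AbundanceTable

__all__ = [
    "AMINO_ACIDS",
    "DistanceMatrix",
    "ConsensusGroup",
    "PositionFrequencyMatrix",
    "MotifPattern",
    "MotifSearchResult",
    "MotifParseError",
    "pairwise_distance",
    "distance_matrix",
    "cluster_top",
    "build_pfm",
    "find_motif",
    "parse_motif",
    "render_motif",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)
GAP = "-"


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -1.0
    return aligner


_ALIGNER = _make_aligner()


def _self_score(seq: str) -> float:
    matrix = _ALIGNER.substitution_matrix
    return float(sum(matrix[aa, aa] for aa in seq))


def pairwise_distance(p1: str, p2: str) -> float:
    """BLOSUM62 global-alignment distance in [0, 1] between two peptides."""
    if not p1 or not p2:
        raise ValueError("peptides must be non-empty")
    if p1 == p2:
        return 0.0
    score = float(_ALIGNER.score(p1, p2))
    norm = min(_self_score(p1), _self_score(p2))
    return float(np.clip(1.0 - score / norm, 0.0, 1.0))


@dataclass
class DistanceMatrix:
    """Symmetric pairwise peptide distances with their sequence labels."""

    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")


def distance_matrix(seqs: Sequence[str]) -> DistanceMatrix:
    """All pairwise distances among ``seqs`` (O(n^2) alignments)."""
    seqs = list(seqs)
    n = len(seqs)
    self_scores = np.array([_self_score(s) for s in seqs])
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if seqs[i] == seqs[j]:
                continue
            score = float(_ALIGNER.score(seqs[i], seqs[j]))
            norm = min(self_scores[i], self_scores[j])
            d[i, j] = d[j, i] = float(np.clip(1.0 - score / norm, 0.0, 1.0))
    return DistanceMatrix(seqs, d)


@dataclass
class PositionFrequencyMatrix:
    """Per-position residue counts over the aligned members of a group."""

    alphabet: str  # 20 amino acids + gap
    counts: np.ndarray  # shape (length, len(alphabet))

    @property
    def length(self) -> int:
        return self.counts.shape[0]

    @property
    def n_sequences(self) -> int:
        return int(self.counts[0].sum()) if self.length else 0

    def consensus(self) -> str:
        """Most frequent residue per column (gap rendered as lowercase x)."""
        out = []
        for col in self.counts:
            best = int(np.argmax(col))
            ch = self.alphabet[best]
            out.append("x" if ch == GAP else ch)
        return "".join(out)

    def to_tsv_rows(self) -> Iterable[str]:
        yield "pos\t" + "\t".join(self.alphabet)
        for pos, col in enumerate(self.counts):
            yield f"{pos}\t" + "\t".join(str(int(c)) for c in col)


@dataclass
class ConsensusGroup:
    """A cluster of similar peptides with abundances and a PFM."""

    members: list[tuple[str, int]]  # (aa_seq, count), descending abundance
    pfm: PositionFrequencyMatrix
    mean_intra_distance: float


def _merge_gap_columns(aligned: list[str], gap_cols: list[int]) -> list[str]:
    out = []
    for seq in aligned:
        chars = list(seq)
        for col in gap_cols:
            chars.insert(col, GAP)
        out.append("".join(chars))
    return out


def progressive_align(seqs: Sequence[str]) -> list[str]:
    """Progressively align sequences (in the given order) into one profile.

    Each new sequence is globally aligned against the running profile's
    majority consensus; gap columns opened by the alignment are propagated
    into all previously aligned members.  Equal-length inputs come back
    unchanged (stacked positionally).
    """
    seqs = list(seqs)
    if len({len(s) for s in seqs}) == 1:
        return seqs
    aligned = [seqs[0]]
    for seq in seqs[1:]:
        profile = _consensus_of(aligned)
        aln = _ALIGNER.align(profile, seq)[0]
        row_profile, row_seq = str(aln[0]), str(aln[1])
        gap_cols = [i for i, ch in enumerate(row_profile) if ch == GAP]
        aligned = _merge_gap_columns(aligned, gap_cols)
        aligned.append(row_seq)
    return aligned


def _consensus_of(aligned: list[str]) -> str:
    cols = zip(*aligned)
    out = []
    for col in cols:
        residues = [c for c in col if c != GAP]
        if not residues:
            out.append("X")
            continue
        counts: dict[str, int] = {}
        for c in residues:
            counts[c] = counts.get(c, 0) + 1
        out.append(min(counts, key=lambda c: (-counts[c], c)))
    return "".join(out)


def build_pfm(members: Sequence[str] | Sequence[tuple[str, int]]) -> PositionFrequencyMatrix:
    """Position-frequency matrix over group members (aligned if needed)."""
    seqs = [m[0] if isinstance(m, tuple) else m for m in members]
    if len(seqs) < 2:
        raise ValueError("a PFM needs at least 2 member sequences")
    aligned = progressive_align(seqs)
    alphabet = AMINO_ACIDS + GAP
    index = {c: i for i, c in enumerate(alphabet)}
    counts = np.zeros((len(aligned[0]), len(alphabet)), dtype=np.int64)
    for seq in aligned:
        for pos, ch in enumerate(seq):
            counts[pos, index[ch]] += 1
    return PositionFrequencyMatrix(alphabet, counts)


def cluster_top(
    table: AbundanceTable,
    top_n: int = 200,
    cut_height: float = 0.55,
    min_size: int = 3,
) -> tuple[list[ConsensusGroup], list[tuple[str, int]]]:
    """Cluster the ``top_n`` most abundant peptides into consensus groups.

    Builds the pairwise distance matrix, an average-linkage (UPGMA) tree,
    and cuts it at ``cut_height``; clusters with at least ``min_size``
    members become :class:`ConsensusGroup` objects (members ordered by
    abundance, PFM built in guide-tree leaf order), the rest are returned
    as singletons.  ``cut_height`` and ``min_size`` are the two tuning
    knobs: lower heights split groups, higher ones merge them.

    Returns ``(groups, leftovers)`` with groups ordered by total abundance.
    """
    if top_n < min_size:
        raise ValueError("top_n must be >= min_size")
    if len(table) < min_size:
        raise ValueError(f"table has fewer than min_size={min_size} records")
    top = table.head(top_n)
    seqs = [rec.aa_seq for rec in top]
    counts = {rec.aa_seq: rec.count for rec in top}
    dm = distance_matrix(seqs)
    if len(seqs) == 1:
        return [], [(seqs[0], counts[seqs[0]])]
    condensed = squareform(dm.d, checks=False)
    tree = linkage(condensed, method="average")
    assignments = fcluster(tree, t=cut_height, criterion="distance")
    leaf_rank = {idx: rank for rank, idx in enumerate(leaves_list(tree))}
    clusters: dict[int, list[int]] = {}
    for idx, cl in enumerate(assignments):
        clusters.setdefault(int(cl), []).append(idx)
    groups: list[ConsensusGroup] = []
    leftovers: list[tuple[str, int]] = []
    for idxs in clusters.values():
        member_seqs = [seqs[i] for i in idxs]
        if len(idxs) < min_size:
            leftovers.extend((s, counts[s]) for s in member_seqs)
            continue
        tree_order = sorted(idxs, key=lambda i: leaf_rank[i])
        pfm = build_pfm([seqs[i] for i in tree_order])
        sub = dm.d[np.ix_(idxs, idxs)]
        n = len(idxs)
        mean_d = float(sub[np.triu_indices(n, k=1)].mean())
        members = sorted(
            ((s, counts[s]) for s in member_seqs), key=lambda m: (-m[1], m[0])
        )
        groups.append(ConsensusGroup(members, pfm, mean_d))
    groups.sort(key=lambda g: (-sum(c for _, c in g.members), g.members[0][0]))
    leftovers.sort(key=lambda m: (-m[1], m[0]))
    return groups, leftovers


class MotifParseError(ValueError):
    """Malformed motif pattern; the message points at the offending position."""


@dataclass(frozen=True)
class MotifPattern:
    """A degenerate peptide motif: fixed residues, residue sets, wildcards."""

    elements: tuple[frozenset, ...]

    def __post_init__(self) -> None:
        if not self.elements:
            raise MotifParseError("empty motif pattern")
        for el in self.elements:
            if not el or not el <= _AA_SET:
                raise MotifParseError(f"invalid residue set {set(el)!r}")

    def __len__(self) -> int:
        return len(self.elements)

    def matches_at(self, seq: str, start: int) -> bool:
        for offset, allowed in enumerate(self.elements):
            if seq[start + offset] not in allowed:
                return False
        return True

    def search(self, seq: str) -> bool:
        k = len(self.elements)
        return any(self.matches_at(seq, i) for i in range(len(seq) - k + 1))


_WILDCARD = frozenset(AMINO_ACIDS)


def parse_motif(text: str) -> MotifPattern:
    """Parse the motif mini-language.

    One element per residue position: an amino-acid letter matches itself,
    ``X`` or ``.`` matches any residue, and a bracketed set such as
    ``[ST]`` matches any of its letters.  Example: ``"[ST]AR"``.
    """
    elements: list[frozenset] = []
    i = 0
    while i < len(text):
        ch = text[i]
        if ch == "[":
            end = text.find("]", i)
            if end < 0:
                raise MotifParseError(f"position {i}: unclosed '['")
            letters = text[i + 1 : end]
            if not letters:
                raise MotifParseError(f"position {i}: empty residue set")
            bad = set(letters) - _AA_SET
            if bad:
                raise MotifParseError(
                    f"position {i}: unknown residues {sorted(bad)} in set"
                )
            elements.append(frozenset(letters))
            i = end + 1
        elif ch in ("X", "."):
            elements.append(_WILDCARD)
            i += 1
        elif ch in _AA_SET:
            elements.append(frozenset(ch))
            i += 1
        else:
            raise MotifParseError(f"position {i}: unknown character {ch!r}")
    return MotifPattern(tuple(elements))


def render_motif(pattern: MotifPattern) -> str:
    """Canonical text form of a pattern (round-trips through parse_motif)."""
    out = []
    for el in pattern.elements:
        if el == _WILDCARD:
            out.append("X")
        elif len(el) == 1:
            out.append(next(iter(el)))
        else:
            out.append("[" + "".join(sorted(el)) + "]")
    return "".join(out)


@dataclass
class MotifSearchResult:
    """Peptides matching a motif, with pool-level summary statistics."""

    pattern: MotifPattern
    hits: list[tuple[str, int]]  # (aa_seq, count), descending abundance
    n_peptides: int  # distinct matching peptides
    total_count: int  # summed abundance of matches
    fraction: float  # total_count / table total reads

    def __iter__(self):
        return iter(self.hits)

    def __len__(self) -> int:
        return len(self.hits)


def find_motif(
    table: AbundanceTable, pattern: MotifPattern | str
) -> MotifSearchResult:
    """All peptides in the table containing a contiguous match of the motif.

    Matching is positional: a fixed residue must match exactly, a residue
    set by membership, a wildcard matches anything.  Hits come back in
    abundance order together with the distinct-peptide count and the share
    of the read population they represent.
    """
    if isinstance(pattern, str):
        pattern = parse_motif(pattern)
    hits = [
        (rec.aa_seq, rec.count) for rec in table if pattern.search(rec.aa_seq)
    ]
    total_count = sum(c for _, c in hits)
    total_reads = table.total_reads
    return MotifSearchResult(
        pattern=pattern,
        hits=hits,
        n_peptides=len(hits),
        total_count=total_count,
        fraction=total_count / total_reads if total_reads else 0.0,
    )


def clusters_to_text(
    groups: Sequence[ConsensusGroup], leftovers: Sequence[tuple[str, int]]
) -> str:
    """Plain-text cluster report: one block per group, then singletons."""
    lines: list[str] = []
    for i, group in enumerate(groups, start=1):
        lines.append(
            f"# group {i}  members={len(group.members)}  "
            f"mean_intra_distance={group.mean_intra_distance:.4f}  "
            f"consensus={group.pfm.consensus()}"
        )
        for seq, count in group.members:
            lines.append(f"{seq}\t{count}")
        lines.extend(group.pfm.to_tsv_rows())
        lines.append("")
    lines.append(f"# singletons  n={len(leftovers)}")
    for seq, count in leftovers:
        lines.append(f"{seq}\t{count}")
    return "\n".join(lines) + "\n"
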