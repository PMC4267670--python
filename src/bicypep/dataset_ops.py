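"""Inter-dataset comparison and round-to-round population dynamics.

Comparing parallel selections against the same target separates
target-specific peptides (found independently in both pools) from the
nonspecific background; comparing consecutive selection rounds quantifies
how much diversity is lost and how much of the later population is new.
Comparisons are keyed on amino-acid sequence by default, with an option to
compare at the nucleotide level.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

from bicypep.preprocess import AbundanceTable

__all__ = ["ComparisonResult", "compare_datasets", "round_dynamics"]


@dataclass
class ComparisonResult:
    """Stratification of 2-3 peptide datasets into common/exclusive sets.

    ``common`` holds peptides present in all datasets with one count per
    dataset.  For three datasets, ``pairwise_common`` holds, per unordered
    dataset pair, the peptides present in exactly those two.  ``exclusive``
    lists, per dataset, the peptides found nowhere else.  Together the
    strata partition the union of all input peptides.
    """

    n_datasets: int
    common: list[tuple[str, tuple[int, ...]]]
    exclusive: list[list[tuple[str, int]]]
    pairwise_common: dict[tuple[int, int], list[tuple[str, tuple[int, int]]]] = field(
        default_factory=dict
    )

    def write_tsv(self, outdir: str) -> None:
        os.makedirs(outdir, exist_ok=True)
        header = "\t".join(f"count_{i + 1}" for i in range(self.n_datasets))
        with open(os.path.join(outdir, "common.tsv"), "w") as handle:
            handle.write(f"aa_seq\t{header}\n")
            for seq, counts in self.common:
                handle.write(seq + "\t" + "\t".join(map(str, counts)) + "\n")
        for (i, j), rows in self.pairwise_common.items():
            path = os.path.join(outdir, f"common_{i + 1}_{j + 1}.tsv")
            with open(path, "w") as handle:
                handle.write(f"aa_seq\tcount_{i + 1}\tcount_{j + 1}\n")
                for seq, counts in rows:
                    handle.write(f"{seq}\t{counts[0]}\t{counts[1]}\n")
        for i, rows in enumerate(self.exclusive):
            path = os.path.join(outdir, f"exclusive_{i + 1}.tsv")
            with open(path, "w") as handle:
                handle.write(f"aa_seq\tcount_{i + 1}\n")
                for seq, count in rows:
                    handle.write(f"{seq}\t{count}\n")


def _key_counts(table: AbundanceTable, nt_level: bool) -> dict[str, int]:
    return table.nt_counts() if nt_level else table.counts()


def compare_datasets(
    tables: Sequence[AbundanceTable], nt_level: bool = False
) -> ComparisonResult:
    """Set algebra over 2-3 abundance tables.

    Common peptides carry each dataset's abundance and are sorted by the
    first dataset's counts; exclusives keep their own dataset's ranking.
    """
    if not 2 <= len(tables) <= 3:
        raise ValueError("compare_datasets takes 2 or 3 tables")
    counts = [_key_counts(t, nt_level) for t in tables]
    keysets = [set(c) for c in counts]
    n = len(tables)

    in_all = set.intersection(*keysets)
    common = sorted(
        ((seq, tuple(c[seq] for c in counts)) for seq in in_all),
        key=lambda row: (-row[1][0], row[0]),
    )
    pairwise: dict[tuple[int, int], list[tuple[str, tuple[int, int]]]] = {}
    if n == 3:
        for i, j in combinations(range(3), 2):
            k = 3 - i - j
            pair = (keysets[i] & keysets[j]) - keysets[k]
            pairwise[(i, j)] = sorted(
                ((seq, (counts[i][seq], counts[j][seq])) for seq in pair),
                key=lambda row: (-row[1][0], row[0]),
            )
    exclusive = []
    for i in range(n):
        others = set.union(*(keysets[j] for j in range(n) if j != i))
        only = keysets[i] - others
        exclusive.append(
            sorted(
                ((seq, counts[i][seq]) for seq in only),
                key=lambda row: (-row[1], row[0]),
            )
        )
    return ComparisonResult(n, common, exclusive, pairwise)


def round_dynamics(round1: AbundanceTable, round2: AbundanceTable) -> dict:
    """Population change between two consecutive selection rounds.

    Reports the distinct-sequence counts of both rounds, the fraction of
    round-1 peptides lost in round 2, the fraction of round-2 reads whose
    peptide was already present in round 1, and the complementary fraction
    of the round-2 population that is new.
    """
    if not len(round1) or not len(round2):
        raise ValueError("both rounds must be non-empty")
    c1, c2 = round1.counts(), round2.counts()
    total2 = sum(c2.values())
    retained_reads = sum(count for seq, count in c2.items() if seq in c1)
    lost = sum(1 for seq in c1 if seq not in c2)
    return {
        "distinct_round1": len(c1),
        "distinct_round2": len(c2),
        "lost_peptide_fraction": lost / len(c1),
        "retained_read_fraction": retained_reads / total2,
        "new_population_fraction": 1.0 - retained_reads / total2,
    }


def dynamics_to_json(report: dict, path: str) -> None:
    with open(path, "w") as handle:
        json.dump(report, handle, indent=2)
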