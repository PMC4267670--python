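"""Quality filtering, translation, abundance tables and error correction."""

import numpy as np
import pytest

from bicypep.fastq_io import QualityRead
from bicypep.preprocess import (
    AbundanceTable,
    ExtractionWindow,
    FilterPolicy,
    InconsistentPairError,
    build_abundance_table,
    correct_errors,
    denoise_counts,
    extract_region,
    quality_filter,
    translate_region,
)
from tests.conftest import table_from_nt_counts


def _read(quals):
    return QualityRead("r", "A" * len(quals), tuple(quals))


class TestQualityFilter:
    def test_all_high_passes(self):
        assert quality_filter(_read([40] * 30), FilterPolicy(18, 3))

    def test_boundary_at_three_low_bases(self):
        ok = [17, 17, 17] + [30] * 27
        assert quality_filter(_read(ok), FilterPolicy(18, 3))
        assert not quality_filter(_read(ok + [17]), FilterPolicy(18, 3))

    def test_restrictive_policy(self):
        # two bases at Q19 exceed the (Q20, 1) budget
        assert not quality_filter(_read([19, 19] + [30] * 10), FilterPolicy(20, 1))

    @pytest.mark.parametrize("policy", [FilterPolicy(18, 3), FilterPolicy(20, 1)])
    def test_matches_brute_force_recount(self, policy, rng):
        for _ in range(200):
            quals = rng.integers(0, 41, size=rng.integers(5, 60))
            expected = sum(1 for q in quals if q < policy.q_threshold)
            assert quality_filter(_read(quals), policy) == (
                expected <= policy.max_below
            )

    def test_monotone_in_stringency(self, rng):
        reads = [
            _read(rng.integers(0, 41, size=30)) for _ in range(300)
        ]
        def n_pass(q, m):
            return sum(quality_filter(r, FilterPolicy(q, m)) for r in reads)
        assert n_pass(18, 4) >= n_pass(18, 3) >= n_pass(18, 2)
        assert n_pass(16, 3) >= n_pass(18, 3) >= n_pass(20, 3)


WINDOW = ExtractionWindow("GGTGCT", "GGCTCG", min_len=9, max_len=39)


class TestExtractRegion:
    def test_between_flanks(self):
        assert extract_region("GGTGCTTGTAAATTTGGCTCG", WINDOW) == "TGTAAATTT"

    def test_left_flank_absent(self):
        assert extract_region("AAATGTAAATTTGGCTCG", WINDOW) is None

    def test_right_flank_absent(self):
        assert extract_region("GGTGCTTGTAAATTT", WINDOW) is None

    def test_length_bounds(self):
        assert extract_region("GGTGCTACGTACGGCTCG", WINDOW) is None  # 6 < 9
        # length 10 within [9, 39] is retained even though not codon-sized
        assert extract_region("GGTGCTACGTACGTACGGCTCG", WINDOW) == "ACGTACGTAC"


class TestTranslateRegion:
    @pytest.mark.parametrize(
        "nt,aa",
        [
            ("TGTTTTTCT", "CFS"),
            ("TGTTTT", "CF"),
            ("TAGGCT", "QA"),  # amber read through as Gln
        ],
    )
    def test_known_translations(self, nt, aa):
        assert translate_region(nt) == aa

    def test_amber_flag_off(self):
        assert translate_region("TAGGCT", amber_as_gln=False) is None

    @pytest.mark.parametrize("nt", ["TAAGCT", "TGAGCT"])
    def test_true_stops_reject(self, nt):
        assert translate_region(nt) is None

    @pytest.mark.parametrize("nt", ["TGTTT", "ANTGTT", ""])
    def test_unparseable(self, nt):
        assert translate_region(nt) is None

    def test_matches_reference_genetic_code(self):
        from Bio.Seq import Seq

        rng = np.random.default_rng(7)
        for _ in range(100):
            nt = "".join(rng.choice(list("ACGT"), size=12))
            mine = translate_region(nt, amber_as_gln=False)
            ref = str(Seq(nt).translate())
            if "*" in ref:
                assert mine is None
            else:
                assert mine == ref


class TestAbundanceTable:
    def test_aggregation_and_variants(self):
        pairs = [("CF", "TGTTTT"), ("CF", "TGCTTT"), ("CS", "TGTTCT")]
        table = build_abundance_table(pairs)
        assert [r.aa_seq for r in table] == ["CF", "CS"]
        assert table.records[0].nt_variants == {"TGTTTT": 1, "TGCTTT": 1}
        assert table.total_reads == 3

    def test_lexicographic_tie_break(self):
        table = build_abundance_table([("CS", "TGTTCT"), ("CF", "TGTTTT")])
        assert [r.aa_seq for r in table] == ["CF", "CS"]

    def test_empty_stream(self):
        table = build_abundance_table([])
        assert len(table) == 0 and table.total_reads == 0

    def test_inconsistent_pair_rejected(self):
        with pytest.raises(InconsistentPairError):
            build_abundance_table([("CF", "TGTTCT")])

    def test_variants_tsv_round_trip(self, tmp_path):
        table = build_abundance_table(
            [("CF", "TGTTTT"), ("CF", "TGCTTT"), ("CS", "TGTTCT")]
        )
        path = tmp_path / "variants.tsv"
        table.variants_to_tsv(path)
        loaded = AbundanceTable.from_variants_tsv(path)
        assert loaded.counts() == table.counts()
        assert loaded.nt_counts() == table.nt_counts()


class TestCorrectErrors:
    def test_merge_arithmetic(self):
        table = table_from_nt_counts({"TGTTTTTCT": 100, "TGTTTTTCG": 2})
        corrected = correct_errors(table)
        assert corrected.nt_counts() == {"TGTTTTTCT": 102}

    def test_ratio_guard_blocks_merge(self):
        table = table_from_nt_counts({"TGTTTTTCT": 50, "TGTTTTTCG": 40})
        corrected = correct_errors(table, min_ratio=10)
        assert len(corrected.nt_counts()) == 2

    def test_abundant_clone_absorbs_distance1_variants(self):
        counts = {"TGTTTTTCTGCT": 4592}
        parent = "TGTTTTTCTGCT"
        variants = []
        for i, base in [(0, "C"), (3, "A"), (5, "G"), (8, "A"), (11, "G")]:
            v = parent[:i] + base + parent[i + 1 :]
            counts[v] = 8 + 3 * i
            variants.append(v)
        merged, parent_map = denoise_counts(counts)
        assert merged == {parent: 4592 + sum(8 + 3 * i for i in (0, 3, 5, 8, 11))}
        assert all(parent_map[v] == parent for v in variants)

    def test_distance_two_merges_but_three_does_not(self):
        table = table_from_nt_counts(
            {"TGTTTTTCT": 100, "TGGTTTTCG": 2, "AGGTTTTCG": 1}
        )
        # second seq at Hamming 2, third at Hamming 3 from the parent
        corrected = correct_errors(table, max_mismatch=2)
        counts = corrected.nt_counts()
        assert counts["TGTTTTTCT"] == 102
        assert counts["AGGTTTTCG"] == 1

    def test_conserves_reads_and_never_increases_distinct(self, rng):
        nts = list({
            "".join(rng.choice(list("ACGT"), size=9)) for _ in range(200)
        })
        nts = [nt for nt in nts if translate_region(nt) is not None]
        counts = {nt: int(rng.integers(1, 1000)) for nt in nts}
        table = table_from_nt_counts(counts)
        corrected = correct_errors(table)
        assert corrected.total_reads == table.total_reads
        assert len(corrected.nt_counts()) <= len(table.nt_counts())

    def test_idempotent(self, rng):
        nts = list({
            "".join(rng.choice(list("ACGT"), size=9)) for _ in range(150)
        })
        nts = [nt for nt in nts if translate_region(nt) is not None]
        counts = {nt: int(rng.integers(1, 500)) for nt in nts}
        once = correct_errors(table_from_nt_counts(counts))
        twice = correct_errors(once)
        assert twice.nt_counts() == once.nt_counts()

    def test_levenshtein_merge_across_lengths(self):
        # a single-base deletion variant (length differs by 1) is absorbed
        merged, _ = denoise_counts({"TGTTTTTCT": 100, "TGTTTTCT": 3})
        assert merged == {"TGTTTTTCT": 103}

    def test_silent_variants_corrected_within_record(self):
        # TGTTTT and TGCTTT both encode CF; the rare silent variant merges
        table = build_abundance_table([("CF", "TGTTTT")] * 80 + [("CF", "TGCTTT")] * 2)
        corrected = correct_errors(table)
        assert corrected.records[0].nt_variants == {"TGTTTT": 82}
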