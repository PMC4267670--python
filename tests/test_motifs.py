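"""Peptide distances, consensus clustering, PFMs and motif search."""

import re

import numpy as np
import pytest

from bicypep.motif_analysis import (
    AMINO_ACIDS,
    MotifParseError,
    build_pfm,
    cluster_top,
    find_motif,
    pairwise_distance,
    parse_motif,
    render_motif,
)
from bicypep.preprocess import translate_region
from bicypep.synthetic import (
    LibrarySpec,
    PeptideFormat,
    PlantedFamily,
    SelectionSpec,
    generate_library,
    simulate_selection,
)
from tests.conftest import table_from_aa_counts


def _blosum62_nw_oracle(s1, s2, gap_open=10, gap_extend=1):
    """Independent affine-gap global alignment DP (Gotoh), BLOSUM62."""
    from Bio.Align import substitution_matrices

    mat = substitution_matrices.load("BLOSUM62")
    n, m = len(s1), len(s2)
    neg = float("-inf")
    M = np.full((n + 1, m + 1), neg)
    X = np.full((n + 1, m + 1), neg)  # gap in s2
    Y = np.full((n + 1, m + 1), neg)  # gap in s1
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -gap_open - (i - 1) * gap_extend
    for j in range(1, m + 1):
        Y[0, j] = -gap_open - (j - 1) * gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = mat[s1[i - 1], s2[j - 1]]
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] - gap_open, X[i - 1, j] - gap_extend)
            Y[i, j] = max(M[i, j - 1] - gap_open, Y[i, j - 1] - gap_extend)
    return max(M[n, m], X[n, m], Y[n, m])


def _oracle_distance(p1, p2):
    self1 = _blosum62_nw_oracle(p1, p1)
    self2 = _blosum62_nw_oracle(p2, p2)
    d = 1.0 - _blosum62_nw_oracle(p1, p2) / min(self1, self2)
    return min(max(d, 0.0), 1.0)


class TestPairwiseDistance:
    def test_identity(self):
        assert pairwise_distance("ACDEF", "ACDEF") == 0.0

    def test_hand_computed_substitution(self):
        # ACDEF vs ACDEW: matched pairs score 4+9+6+5, F:W scores 1 -> S=25;
        # self-scores 30 and 35 -> d = 1 - 25/30
        assert pairwise_distance("ACDEF", "ACDEW") == pytest.approx(1 - 25 / 30)

    def test_matches_dp_oracle_on_random_pairs(self, rng):
        aas = np.array(list(AMINO_ACIDS))
        for _ in range(25):
            p1 = "".join(rng.choice(aas, size=rng.integers(5, 14)))
            p2 = "".join(rng.choice(aas, size=rng.integers(5, 14)))
            assert pairwise_distance(p1, p2) == pytest.approx(
                _oracle_distance(p1, p2), abs=1e-9
            )

    def test_symmetry_and_range(self, rng):
        aas = np.array(list(AMINO_ACIDS))
        for _ in range(50):
            p1 = "".join(rng.choice(aas, size=10))
            p2 = "".join(rng.choice(aas, size=12))
            d12 = pairwise_distance(p1, p2)
            assert d12 == pairwise_distance(p2, p1)
            assert 0.0 <= d12 <= 1.0


class TestClusterTop:
    def test_all_identical_single_group(self):
        table = table_from_aa_counts({"ACDEFGH": 5})
        # duplicate records are impossible in a table; use multiple distinct
        # records at distance 0 is impossible too, so check via planted data
        groups, singles = cluster_top(
            table_from_aa_counts({"ACDEFGH": 5, "ACDEFGY": 4, "ACDEFGW": 3}),
            top_n=3,
            cut_height=0.55,
            min_size=3,
        )
        assert len(groups) == 1 and len(singles) == 0
        assert len(groups[0].members) == 3

    def test_cut_height_zero_yields_no_groups(self, random_peptides):
        counts = {p: i + 1 for i, p in enumerate(random_peptides[:30])}
        groups, singles = cluster_top(
            table_from_aa_counts(counts), top_n=30, cut_height=0.0, min_size=2
        )
        assert groups == []
        assert len(singles) == 30

    def test_deterministic(self, random_peptides):
        counts = {p: i + 1 for i, p in enumerate(random_peptides[:60])}
        table = table_from_aa_counts(counts)
        g1, s1 = cluster_top(table, top_n=60, cut_height=0.6)
        g2, s2 = cluster_top(table, top_n=60, cut_height=0.6)
        assert [g.members for g in g1] == [g.members for g in g2]
        assert s1 == s2

    def test_config_errors(self):
        table = table_from_aa_counts({"ACDEF": 1, "ACDEW": 1, "ACDEY": 1})
        with pytest.raises(ValueError):
            cluster_top(table, top_n=2, min_size=3)

    def test_planted_family_recovered(self):
        fmt = PeptideFormat(1, 4, 4, 1)
        lib = generate_library(LibrarySpec([fmt], 100, seed=3))
        spec = SelectionSpec(
            ("uniform",),
            planted_families=[PlantedFamily("WLPP", 20, (100, 150))],
        )
        sel = simulate_selection(lib, spec, 6000, seed=4, library_formats=[fmt])
        planted_aa = {translate_region(nt) for nt in sel.planted_members[0]}
        groups, _ = cluster_top(sel.truth_table, top_n=60)
        best = max(
            groups, key=lambda g: sum(1 for s, _ in g.members if s in planted_aa)
        )
        hits = sum(1 for s, _ in best.members if s in planted_aa)
        assert hits >= 0.9 * len(planted_aa)


class TestBuildPfm:
    def test_equal_length_stacking(self):
        pfm = build_pfm(["ACD", "ACD"])
        assert pfm.n_sequences == 2
        a, c, d = (pfm.alphabet.index(x) for x in "ACD")
        assert pfm.counts[0, a] == 2
        assert pfm.counts[1, c] == 2
        assert pfm.counts[2, d] == 2

    def test_split_column(self):
        pfm = build_pfm(["ACD", "AFD"])
        c, f = pfm.alphabet.index("C"), pfm.alphabet.index("F")
        assert pfm.counts[1, c] == 1 and pfm.counts[1, f] == 1

    def test_column_sums_equal_membership(self, rng):
        aas = np.array(list(AMINO_ACIDS))
        members = ["".join(rng.choice(aas, size=rng.integers(8, 11)))
                   for _ in range(6)]
        pfm = build_pfm(members)
        assert np.all(pfm.counts.sum(axis=1) == len(members))

    def test_shared_core_shows_in_consensus(self, rng):
        aas = np.array(list(AMINO_ACIDS))
        members = [
            "".join(rng.choice(aas, size=3)) + "HPQ" + "".join(rng.choice(aas, size=3))
            for _ in range(10)
        ]
        pfm = build_pfm(members)
        assert "HPQ" in pfm.consensus()


PATTERN_CHARS = list(AMINO_ACIDS)


def _random_pattern(rng):
    parts, regex = [], []
    for _ in range(rng.integers(2, 6)):
        kind = rng.integers(3)
        if kind == 0:
            aa = rng.choice(PATTERN_CHARS)
            parts.append(aa)
            regex.append(aa)
        elif kind == 1:
            parts.append("X")
            regex.append(".")
        else:
            k = rng.integers(2, 5)
            chosen = sorted(set(rng.choice(PATTERN_CHARS, size=k)))
            parts.append("[" + "".join(chosen) + "]")
            regex.append("[" + "".join(chosen) + "]")
    return "".join(parts), "".join(regex)


class TestMotifSearch:
    def test_known_binders(self):
        table = table_from_aa_counts(
            {"ACDARPCPQTYCL": 307, "QCVPLKCLWDRCE": 40}
        )
        assert [s for s, _ in find_motif(table, "RPCP")] == ["ACDARPCPQTYCL"]
        assert [s for s, _ in find_motif(table, "VXXKCL")] == ["QCVPLKCLWDRCE"]

    def test_set_semantics(self):
        table = table_from_aa_counts({"QSTARGG": 2, "QQARGG": 1})
        hits = find_motif(table, "[ST]AR")
        assert [s for s, _ in hits] == ["QSTARGG"]

    def test_summary_statistics(self):
        table = table_from_aa_counts({"AHPQA": 3, "GGGGG": 1})
        result = find_motif(table, "HPQ")
        assert result.n_peptides == 1
        assert result.total_count == 3
        assert result.fraction == pytest.approx(0.75)

    def test_matches_regex_oracle(self, rng, random_peptides):
        table = table_from_aa_counts(
            {p: i + 1 for i, p in enumerate(random_peptides)}
        )
        for _ in range(10):
            text, regex = _random_pattern(rng)
            mine = {s for s, _ in find_motif(table, text)}
            oracle = {
                r.aa_seq for r in table if re.search(regex, r.aa_seq)
            }
            assert mine == oracle, text


class TestParseMotif:
    @pytest.mark.parametrize(
        "text,canonical",
        [
            ("[ST]AR", "[ST]AR"),
            ("[TS]AR", "[ST]AR"),
            ("VXXKCL", "VXXKCL"),
            ("V..KCL", "VXXKCL"),
        ],
    )
    def test_round_trip(self, text, canonical):
        assert render_motif(parse_motif(text)) == canonical

    @pytest.mark.parametrize("bad", ["[]AR", "A[ST", "A1C", "", "[ZB]A"])
    def test_parse_errors(self, bad):
        with pytest.raises(MotifParseError):
            parse_motif(bad)
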