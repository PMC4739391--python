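import itertools

import numpy as np
import pytest

from barcode_gauge import align as al
from conftest import make_dataset

PARAMS = dict(match=1, mismatch=-1, gap_open=-5, gap_extend=-1)


def brute_force_global_score(a, b, match=1, mismatch=-1, gap_open=-5,
                             gap_extend=-1):
    """Exhaustive optimal affine global score: recursion over all alignment
    paths with the previous operation as state (feasible for len <= 6)."""

    def rec(i, j, last):
        if i == len(a) and j == len(b):
            return 0
        best = -1e18
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else mismatch
            best = max(best, s + rec(i + 1, j + 1, "D"))
        if i < len(a):
            cost = gap_extend if last == "B" else gap_open
            best = max(best, cost + rec(i + 1, j, "B"))
        if j < len(b):
            cost = gap_extend if last == "A" else gap_open
            best = max(best, cost + rec(i, j + 1, "A"))
        return best

    return rec(0, 0, None)


class TestGlobalAlign:
    def test_identical(self):
        pa = al.global_align("ACGT", "ACGT")
        assert pa.score == 4 and pa.identity == 1.0

    def test_single_gap(self):
        pa = al.global_align("ACGT", "ACT")
        # unique optimum: one gap column, all aligned columns identical
        assert len(pa.gapped_a) == 4
        assert pa.gapped_b.count("-") == 1
        assert pa.identity == 1.0

    def test_all_mismatch(self):
        assert al.global_align("AAAA", "TTTT").identity == 0.0

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            al.global_align("", "ACGT")

    def test_matches_exhaustive_oracle(self, rng):
        bases = "ACGT"
        for _ in range(40):
            a = "".join(rng.choice(list(bases), size=rng.integers(1, 7)))
            b = "".join(rng.choice(list(bases), size=rng.integers(1, 7)))
            assert al.global_align(a, b, **PARAMS).score == pytest.approx(
                brute_force_global_score(a, b, **PARAMS)), (a, b)


class TestLocalAlign:
    def test_shared_block(self):
        pa, a_span, b_span = al.local_align("GGACGTGG", "TTACGTTT")
        assert pa.score == 4
        assert "GGACGTGG"[a_span[0]:a_span[1]] == "ACGT"
        assert "TTACGTTT"[b_span[0]:b_span[1]] == "ACGT"

    def test_identical_inputs_full_block(self):
        pa, a_span, _ = al.local_align("ACGTACGT", "ACGTACGT")
        assert a_span == (0, 8)
        assert pa.score == al.global_align("ACGTACGT", "ACGTACGT").score

    def test_no_similarity_empty(self):
        pa, a_span, b_span = al.local_align("AAAA", "TTTT")
        assert pa.is_empty and pa.score == 0
        assert a_span == (0, 0)

    def test_score_never_negative(self, rng):
        for _ in range(20):
            a = "".join(rng.choice(list("ACGT"), size=10))
            b = "".join(rng.choice(list("ACGT"), size=10))
            assert al.local_align(a, b)[0].score >= 0


class TestProgressiveMSA:
    def test_identical_sequences_gap_free(self):
        ds = make_dataset([(f"A{i}", "Uncaria alpha", "ACGTACGT")
                           for i in range(3)])
        msa = al.progressive_msa(ds)
        assert all("-" not in row for row in msa.rows)
        assert msa.n_columns == 8

    def test_single_deletion_row(self):
        ds = make_dataset([("A", "Uncaria alpha", "ACGT"),
                           ("B", "Uncaria alpha", "AGT"),
                           ("C", "Uncaria alpha", "ACGT")])
        msa = al.progressive_msa(ds)
        assert msa.n_columns == 4
        assert msa.rows[0] == "ACGT"
        assert msa.rows[2] == "ACGT"
        assert msa.rows[1].count("-") == 1
        assert msa.rows[1].replace("-", "") == "AGT"

    def test_requires_two_records(self):
        ds = make_dataset([("A", "Uncaria alpha", "ACGT")])
        with pytest.raises(ValueError):
            al.progressive_msa(ds)

    def test_row_order_is_input_order(self, sim_small, sim_small_msa):
        assert sim_small_msa.row_ids == sim_small.dataset.ids

    def test_within_species_identity_exceeds_between(self, sim_small,
                                                     sim_small_msa):
        rows = sim_small_msa.matrix()
        species = np.array(sim_small.dataset.species)
        n = len(species)
        within, between = [], []
        for i in range(n):
            for j in range(i + 1, n):
                both = (rows[i] < 4) & (rows[j] < 4)
                ident = (rows[i][both] == rows[j][both]).mean()
                (within if species[i] == species[j] else between).append(ident)
        assert np.mean(within) > np.mean(between)
        assert np.mean(within) > 0.98

    def test_order_invariance_up_to_row_permutation(self, rng):
        entries = [("A", "Uncaria alpha", "ACGTACGTAAGGCCTT"),
                   ("B", "Uncaria alpha", "ACGTACGTAAGGCC"),
                   ("C", "Uncaria beta", "ACGTTCGTAAGGCCTT"),
                   ("D", "Uncaria beta", "AGGTTCGTAAGGCCTT")]
        ref = al.progressive_msa(make_dataset(entries))
        ref_map = dict(zip(ref.row_ids, ref.rows))
        for perm in ([1, 0, 3, 2], [3, 2, 1, 0], [2, 0, 3, 1]):
            msa = al.progressive_msa(make_dataset([entries[i] for i in perm]))
            assert dict(zip(msa.row_ids, msa.rows)) == ref_map

    def test_profile_pair_matches_pairwise_engine(self, rng):
        # merging two single-sequence profiles is plain pairwise alignment
        for _ in range(15):
            a = "".join(rng.choice(list("ACGT"), size=rng.integers(4, 12)))
            b = "".join(rng.choice(list("ACGT"), size=rng.integers(4, 12)))
            rows = al._align_profiles([a], [b], **PARAMS)
            pa = al.PairwiseAlignment(rows[0], rows[1], 0.0)
            ref = al.global_align(a, b, **PARAMS)
            score = _score_alignment(rows[0], rows[1])
            assert score == pytest.approx(ref.score), (a, b)


def _score_alignment(ga, gb, match=1, mismatch=-1, gap_open=-5, gap_extend=-1):
    score = 0.0
    last = None
    for x, y in zip(ga, gb):
        if x == "-" or y == "-":
            op = "A" if x == "-" else "B"
            score += gap_extend if last == op else gap_open
            last = op
        else:
            score += match if x == y else mismatch
            last = "D"
    return score


class TestColumnStatistics:
    def test_identical_rows_no_variation(self):
        msa = al.MultipleAlignment(rows=["ACGT"] * 3, row_ids=list("abc"))
        assert al.count_variable_sites(msa) == 0

    def test_single_variable_column(self):
        msa = al.MultipleAlignment(rows=["ACGT", "ACGA"], row_ids=["a", "b"])
        assert al.count_variable_sites(msa) == 1

    def test_gap_column_not_variable(self):
        msa = al.MultipleAlignment(rows=["A-GT", "ACGA"], row_ids=["a", "b"])
        assert al.count_variable_sites(msa) == 1

    def test_ambiguity_not_a_state(self):
        msa = al.MultipleAlignment(rows=["ANGT", "AAGT"], row_ids=["a", "b"])
        assert al.count_variable_sites(msa) == 0

    def test_gap_free_msa_no_indels(self):
        msa = al.MultipleAlignment(rows=["ACGT"] * 2, row_ids=["a", "b"])
        assert al.count_indel_sites(msa) == 0

    def test_single_gap_run_is_one_event(self):
        msa = al.MultipleAlignment(rows=["AC--GT", "ACTTGT"],
                                   row_ids=["a", "b"])
        assert al.count_indel_sites(msa) == 1

    def test_shared_run_counted_once(self):
        msa = al.MultipleAlignment(rows=["AC--GT", "ACTTGT", "AC--GT"],
                                   row_ids=list("abc"))
        assert al.count_indel_sites(msa) == 1

    def test_distinct_intervals_counted_separately(self):
        msa = al.MultipleAlignment(rows=["AC--GT", "A--TGT", "ACTTGT"],
                                   row_ids=list("abc"))
        assert al.count_indel_sites(msa) == 2

    def test_gap_column_count(self):
        msa = al.MultipleAlignment(rows=["AC--GT", "ACTTGT"],
                                   row_ids=["a", "b"])
        assert al.count_gap_columns(msa) == 2


class TestAlignedFastaIO:
    def test_round_trip(self, tmp_path, sim_small_msa):
        p = tmp_path / "msa.fasta"
        al.write_aligned_fasta(sim_small_msa, p)
        back = al.read_aligned_fasta(p)
        assert back.rows == sim_small_msa.rows
        assert back.row_ids == sim_small_msa.row_ids
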