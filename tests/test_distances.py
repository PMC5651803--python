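"""Alignment plumbing, complete deletion, bootstrap p-distance, windows."""

import numpy as np
import pytest

from mitocomp.distances import (
    AlignmentBlock,
    align_score,
    complete_deletion,
    concat_genes,
    global_align,
    p_distance,
    sliding_window_distance,
)
from mitocomp.errors import InputError


def nw_score_oracle(a, b, match=1.0, mismatch=-1.0, gap=-2.0):
    """Plain DP-table Needleman-Wunsch score, written independently."""
    n, m = len(a), len(b)
    dp = [[0.0] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        dp[i][0] = i * gap
    for j in range(1, m + 1):
        dp[0][j] = j * gap
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            sub = match if a[i - 1] == b[j - 1] else mismatch
            dp[i][j] = max(dp[i - 1][j - 1] + sub,
                           dp[i - 1][j] + gap, dp[i][j - 1] + gap)
    return dp[n][m]


class TestGlobalAlign:
    def test_identical_sequences_gapless(self):
        blk = global_align("ACGTACGT", "ACGTACGT")
        assert blk.rows == ("ACGTACGT", "ACGTACGT")
        assert align_score("ACGTACGT", "ACGTACGT") == 8.0

    def test_one_gap_case_matches_dp_oracle(self):
        assert align_score("ACGT", "ACT") == 1.0 == nw_score_oracle("ACGT", "ACT")
        blk = global_align("ACGT", "ACT")
        assert sum(r.count("-") for r in blk.rows) == 1

    @pytest.mark.parametrize("seed", range(5))
    def test_random_scores_match_dp_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = "".join(rng.choice(list("ACGT"), rng.integers(3, 25)))
        b = "".join(rng.choice(list("ACGT"), rng.integers(3, 25)))
        assert align_score(a, b) == nw_score_oracle(a, b)
        assert align_score(a, b) == align_score(b, a)

    def test_empty_rejected(self):
        with pytest.raises(InputError):
            global_align("", "ACGT")


class TestCompleteDeletion:
    def test_gapless_unchanged(self):
        blk = AlignmentBlock(("x", "y"), ("ACGT", "ACGA"))
        assert complete_deletion(blk).rows == blk.rows

    def test_gap_column_dropped_for_all_rows(self):
        blk = AlignmentBlock(("x", "y", "z"), ("ACGT", "AC-T", "ACGT"))
        out = complete_deletion(blk)
        assert out.rows == ("ACT", "ACT", "ACT")

    def test_question_mark_treated_as_missing(self):
        blk = AlignmentBlock(("x", "y"), ("A?GT", "ACGT"))
        assert complete_deletion(blk).rows == ("AGT", "AGT")

    @pytest.mark.parametrize("seed", range(5))
    def test_random_blocks_match_column_scan_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        rows = [
            "".join(rng.choice(list("ACGT-?"), 60, p=[0.2] * 4 + [0.1, 0.1]))
            for _ in range(3)
        ]
        kept_oracle = [
            j for j in range(60)
            if all(r[j] not in "-?" for r in rows)
        ]
        blk = AlignmentBlock(("a", "b", "c"), tuple(rows))
        if not kept_oracle:
            with pytest.raises(InputError):
                complete_deletion(blk)
        else:
            out = complete_deletion(blk)
            assert out.n_cols == len(kept_oracle)
            assert out.rows[0] == "".join(rows[0][j] for j in kept_oracle)

    def test_all_columns_removed_is_error(self):
        blk = AlignmentBlock(("x", "y"), ("A-", "-A"))
        with pytest.raises(InputError):
            complete_deletion(blk)


class TestPDistance:
    def test_identical_rows(self):
        blk = AlignmentBlock(("x", "y"), ("ACGTACGT", "ACGTACGT"))
        est = p_distance(blk, "x", "y", replicates=100, seed=0)
        assert est.p == 0.0 and est.se == 0.0

    def test_direct_count(self):
        blk = AlignmentBlock(("x", "y"), ("AAAA", "AAAT"))
        est = p_distance(blk, "x", "y", replicates=0, seed=0)
        assert est.p == 0.25
        assert est.n_sites == 4

    def test_bootstrap_se_near_binomial_closed_form(self):
        n, p = 1000, 0.2
        a = "A" * n
        b = "C" * int(n * p) + "A" * (n - int(n * p))
        blk = AlignmentBlock(("x", "y"), (a, b))
        est = p_distance(blk, "x", "y", replicates=1000, seed=42)
        analytic = np.sqrt(p * (1 - p) / n)
        assert abs(est.se - analytic) / analytic < 0.15

    def test_reproducible_bit_for_bit(self):
        rng = np.random.default_rng(3)
        a = "".join(rng.choice(list("ACGT"), 500))
        b = "".join(rng.choice(list("ACGT"), 500))
        blk = AlignmentBlock(("x", "y"), (a, b))
        e1 = p_distance(blk, "x", "y", replicates=200, seed=9)
        e2 = p_distance(blk, "x", "y", replicates=200, seed=9)
        assert (e1.p, e1.se) == (e2.p, e2.se)

    def test_symmetry(self):
        blk = AlignmentBlock(("x", "y"), ("ACGTAC", "ATGTAA"))
        assert (p_distance(blk, "x", "y", replicates=0).p
                == p_distance(blk, "y", "x", replicates=0).p)

    def test_gaps_rejected(self):
        blk = AlignmentBlock(("x", "y"), ("AC-T", "ACGT"))
        with pytest.raises(InputError):
            p_distance(blk, "x", "y")


class TestConcat:
    def test_self_concat_doubles_sites_preserves_p(self):
        blk = AlignmentBlock(("x", "y"), ("AAAA", "AAAT"))
        cat = concat_genes([blk, blk])
        est = p_distance(cat, "x", "y", replicates=0)
        assert est.n_sites == 8 and est.p == 0.25

    def test_order_permutation_leaves_p_unchanged(self):
        b1 = AlignmentBlock(("x", "y"), ("AAAA", "AAAT"))
        b2 = AlignmentBlock(("x", "y"), ("CCCC", "CGCC"))
        p12 = p_distance(concat_genes([b1, b2]), "x", "y", replicates=0).p
        p21 = p_distance(concat_genes([b2, b1]), "x", "y", replicates=0).p
        assert p12 == p21

    def test_empty_list_rejected(self):
        with pytest.raises(InputError):
            concat_genes([])

    def test_label_mismatch_rejected(self):
        b1 = AlignmentBlock(("x", "y"), ("AA", "AT"))
        b2 = AlignmentBlock(("x", "z"), ("AA", "AT"))
        with pytest.raises(InputError):
            concat_genes([b1, b2])


class TestSlidingWindowDistance:
    def test_identical_rows_all_zero(self):
        blk = AlignmentBlock(("x", "y"), ("ACGT" * 200, "ACGT" * 200))
        prof = sliding_window_distance(blk, width=300, step=10)
        assert np.all(prof["p"] == 0.0)

    def test_planted_divergent_segment_localized(self):
        rng = np.random.default_rng(17)
        L, seg_start, seg_len = 3000, 1500, 600
        a = list(rng.choice(list("ACGT"), L))
        b = list(a)
        for i in range(seg_start, seg_start + seg_len):
            if rng.random() < 0.3:
                choices = [c for c in "ACGT" if c != b[i]]
                b[i] = choices[rng.integers(0, 3)]
        blk = AlignmentBlock(("x", "y"), ("".join(a), "".join(b)))
        prof = sliding_window_distance(blk, width=300, step=10)
        peak = prof["centers"][np.nanargmax(prof["p"])]
        seg_mid = seg_start + seg_len / 2
        assert abs(peak - seg_mid) <= seg_len / 2 + 150

    def test_partition_identity_step_equals_width(self):
        rng = np.random.default_rng(23)
        a = "".join(rng.choice(list("ACGT"), 1200))
        b = "".join(rng.choice(list("ACGT"), 1200))
        blk = AlignmentBlock(("x", "y"), (a, b))
        prof = sliding_window_distance(blk, width=300, step=300)
        global_p = p_distance(blk, "x", "y", replicates=0).p
        assert np.average(prof["p"], weights=prof["n_sites"]) == pytest.approx(global_p)

    def test_window_longer_than_alignment_rejected(self):
        blk = AlignmentBlock(("x", "y"), ("ACGT", "ACGT"))
        with pytest.raises(InputError):
            sliding_window_distance(blk, width=300)
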