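"""Quality-based filtering/trimming: LQR, Mott window, TERA, end trims."""

import itertools

import pytest

from seqscrub import (
    EndTrimParams,
    LqrParams,
    MinLengthPolicy,
    MottParams,
    TeraParams,
    extract_mott_window,
    filter_lqr,
    trim_ends,
    trim_tera,
)

from conftest import mk, oracle_lqr_removes, oracle_mott, random_read

M0 = MinLengthPolicy(0)


class TestLqr:
    @pytest.mark.parametrize(
        "qual,lqs,p,status",
        [
            ([5, 5, 5, 40], 10, 50, "removed"),  # 75% > 50
            ([5, 5, 40, 40], 10, 50, "kept"),  # exactly 50%, not over
            ([40, 40, 40, 40], 40, 50, "kept"),  # no base strictly under lqs
            ([10, 10, 10, 10], 10, 99, "kept"),  # Phred == lqs is not "under"
        ],
    )
    def test_strict_boundaries(self, qual, lqs, p, status):
        assert filter_lqr(mk("A" * len(qual), qual), LqrParams(lqs, p)).status == status

    def test_exhaustive_agreement_with_counting_oracle(self):
        """All reads of length <= 6 over Phred {0, 20, 40}, several cutoffs."""
        for L in range(1, 7):
            for quals in itertools.product((0, 20, 40), repeat=L):
                read = mk("A" * L, list(quals))
                for lqs, p in ((10, 50.0), (20, 50.0), (21, 33.0), (41, 100.0)):
                    got = filter_lqr(read, LqrParams(lqs, p)).status == "removed"
                    assert got == oracle_lqr_removes(list(quals), lqs, p)


class TestMott:
    def test_documented_window(self):
        out = extract_mott_window(mk("ACGT", [2, 30, 30, 30]), MottParams(0.05), M0)
        assert out.status == "trimmed"
        assert out.reads[0].seq == "CGT"  # bases 2-4
        assert out.bases_removed == 1

    def test_all_good_read_kept(self):
        assert extract_mott_window(mk("ACGT", [30] * 4), MottParams(0.05), M0).status == "kept"

    def test_all_bad_read_removed(self):
        assert extract_mott_window(mk("ACGT", [2] * 4), MottParams(0.05), M0).status == "removed"

    def test_min_rl_restores_3prime_side_first(self):
        # 13 good bases + one bad 3' base: window is bases 1-2 (1-based);
        # the floor restores bases on the 3' side of the window
        read = mk("A" * 14, [30] * 13 + [2])
        out = extract_mott_window(read, MottParams(0.05), MinLengthPolicy(0))
        assert out.reads[0].qual == [30, 30]
        out5 = extract_mott_window(read, MottParams(0.05), MinLengthPolicy(5))
        assert out5.reads[0].qual == [30] * 5  # bases 1-5

    def test_min_rl_restores_5prime_side_when_3prime_exhausted(self):
        # window is the last two bases; restoration must come from the 5' side
        read = mk("A" * 14, [2] * 12 + [30, 30])
        out = extract_mott_window(read, MottParams(0.05), MinLengthPolicy(5))
        assert out.reads[0].qual == [2, 2, 2, 30, 30]  # bases 10-14

    def test_agreement_with_direct_summation_oracle(self, rng):
        for _ in range(400):
            read = random_read(rng, int(rng.integers(1, 13)), qmin=2, qmax=40)
            ml = float(rng.choice([0.01, 0.05, 0.2]))
            got = extract_mott_window(read, MottParams(ml), M0)
            want = oracle_mott(read.qual, ml)
            if want is None:
                assert got.status == "removed"
            else:
                s, e = want
                assert got.reads[0].qual == read.qual[s : e + 1]


class TestTera:
    def test_documented_example(self):
        out = trim_tera(mk("ACGT", [40, 40, 40, 2]), TeraParams(20), M0)
        assert out.status == "trimmed"
        assert out.reads[0].qual == [40, 40, 40]

    def test_good_3prime_end_untouched(self):
        assert trim_tera(mk("ACGT", [40] * 4), TeraParams(20), M0).status == "kept"

    def test_never_exceeds_with_floor_retains_floor(self):
        out = trim_tera(mk("ACGT", [2] * 4), TeraParams(20), MinLengthPolicy(2))
        assert out.reads[0].qual == [2, 2]

    def test_never_exceeds_without_floor_removes(self):
        assert trim_tera(mk("ACGT", [2] * 4), TeraParams(20), M0).status == "removed"

    def test_trimmed_suffixes_all_have_low_running_average(self, rng):
        """Every base TERA discards closes a suffix whose mean Phred <= avg."""
        for _ in range(300):
            read = random_read(rng, 30, qmin=2, qmax=40)
            avg = float(rng.choice([10.0, 20.0, 30.0]))
            out = trim_tera(read, TeraParams(avg), M0)
            survivors = out.reads[0].qual if out.reads else []
            trimmed = len(read) - len(survivors)
            for k in range(1, trimmed + 1):
                suffix = read.qual[len(read) - k :]
                assert sum(suffix) / k <= avg


class TestTrimEnds:
    def test_fixed_counts(self):
        out = trim_ends(mk("A" * 100), EndTrimParams(x=10, y=0), M0)
        assert len(out.reads[0]) == 90

    def test_floor_caps_trimming(self):
        out = trim_ends(mk("A" * 12), EndTrimParams(x=10), MinLengthPolicy(5))
        assert len(out.reads[0]) == 5
        assert out.bases_removed == 7

    def test_identity(self):
        read = mk("ACGT")
        out = trim_ends(read, EndTrimParams(0, 0), M0)
        assert out.status == "kept" and out.reads == (read,)

    def test_three_prime_trimmed_before_five_prime(self):
        read = mk("ACGTACGT")
        out = trim_ends(read, EndTrimParams(x=3, y=2), M0)
        assert out.reads[0].seq == "GTA"  # last 3 then first 2 removed
        capped = trim_ends(read, EndTrimParams(x=4, y=4), MinLengthPolicy(6))
        assert capped.reads[0].seq == "ACGTAC"  # 3' trim consumes the budget

    def test_whole_read_consumed_removes(self):
        assert trim_ends(mk("ACGT"), EndTrimParams(x=3, y=2), M0).status == "removed"


def test_min_rl_guarantee_across_methods(rng):
    """No survivor of Mott/TERA/3end/5end is shorter than min(min_rl, L)."""
    policy = MinLengthPolicy(36)
    ops = [
        lambda r: extract_mott_window(r, MottParams(0.05), policy),
        lambda r: trim_tera(r, TeraParams(20), policy),
        lambda r: trim_ends(r, EndTrimParams(x=80), policy),
        lambda r: trim_ends(r, EndTrimParams(y=80), policy),
    ]
    for _ in range(300):
        read = random_read(rng, 100, qmin=2, qmax=40)
        for op in ops:
            for r in op(read).reads:
                assert len(r) >= 36
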