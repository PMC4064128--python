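"""Artifact (adapter) detection/removal and homopolymer removal."""

import numpy as np
import pytest

from seqscrub import (
    ArtifactLibrary,
    HomopolymerSpec,
    MatchSpec,
    apply_5adpt,
    find_artifact,
    remove_homopolymer,
)

from conftest import levenshtein, mk, oracle_find_artifact, random_read

LIB1 = ArtifactLibrary.from_sequences(["ACGTACGT"])


class TestFindArtifact:
    def test_exact_match(self):
        hit = find_artifact(mk("TTTTACGTACGTTTTT"), LIB1, MatchSpec(mp=100, search_depth=16))
        assert (hit.start, hit.end, hit.distance) == (4, 12, 0)

    def test_one_substitution_within_budget(self):
        read = mk("AAAAACGTACCTAAAA")  # ACGTACCT = 1 sub from ACGTACGT
        hit = find_artifact(read, LIB1, MatchSpec(mp=87.5, search_depth=16))
        assert hit.distance == 1
        assert find_artifact(read, LIB1, MatchSpec(mp=100, search_depth=16)) is None

    def test_no_shared_bases(self):
        lib = ArtifactLibrary.from_sequences(["GGGG"])
        assert find_artifact(mk("AAAAAAAA"), lib, MatchSpec(mp=100, search_depth=8)) is None

    def test_search_depth_constrains_start_not_end(self):
        read = mk("TTTTACGTACGT")
        assert find_artifact(read, LIB1, MatchSpec(mp=100, search_depth=4)) is None
        hit = find_artifact(read, LIB1, MatchSpec(mp=100, search_depth=5))
        assert (hit.start, hit.end) == (4, 12)

    def test_n_mismatches_every_artifact_base(self):
        hit = find_artifact(mk("ACGTNCGT"), LIB1, MatchSpec(mp=87.5, search_depth=8))
        assert hit.distance == 1

    def test_case_insensitive(self):
        hit = find_artifact(mk("ttttacgtacgt".upper()), LIB1, MatchSpec(mp=100, search_depth=12))
        assert hit is not None

    def test_tiebreak_smallest_start(self):
        lib = ArtifactLibrary.from_sequences(["ACAC"])
        hit = find_artifact(mk("TTACACTTACACTT"), lib, MatchSpec(mp=100, search_depth=14))
        assert hit.start == 2

    def test_tiebreak_longer_artifact_then_order(self):
        lib = ArtifactLibrary.from_sequences(["ACGT", "ACGTAC"])
        hit = find_artifact(mk("TTACGTACTT"), lib, MatchSpec(mp=100, search_depth=10))
        assert hit.artifact_name == "artifact_2"  # longer wins at equal distance/start
        lib2 = ArtifactLibrary.from_sequences(["ACGT", "TACG"])
        hit2 = find_artifact(mk("TTTACGTTTT"), lib2, MatchSpec(mp=100, search_depth=10))
        assert hit2.artifact_name == "artifact_2"  # same length: smaller start wins
        assert hit2.start == 2

    def test_agrees_with_exhaustive_oracle_randomised(self, rng):
        """Randomised cross-check against the all-substring edlib oracle."""
        for _ in range(400):
            read = random_read(rng, int(rng.integers(1, 31)))
            arts = [
                "".join(rng.choice(list("ACGT"), size=int(rng.integers(1, 11))))
                for _ in range(int(rng.integers(1, 4)))
            ]
            lib = ArtifactLibrary.from_sequences(arts)
            mp = float(rng.choice([70.0, 80.0, 90.0, 100.0]))
            depth = int(rng.integers(1, 32))
            got = find_artifact(read, lib, MatchSpec(mp=mp, search_depth=depth))
            want = oracle_find_artifact(read.seq, lib.entries, mp, depth)
            if want is None:
                assert got is None
            else:
                assert (got.artifact_name, got.start, got.end, got.distance) == want


class TestCappedMatching:
    def test_caps_override_mp_budget(self):
        read = mk("AAAAACGTACCTAAAA")  # 1 substitution from ACGTACGT
        spec = MatchSpec(mp=50, max_sub=0, search_depth=16)
        assert find_artifact(read, LIB1, spec) is None
        spec = MatchSpec(mp=100, max_sub=1, search_depth=16)
        assert find_artifact(read, LIB1, spec).distance == 1

    def test_edit_types_are_distinguished(self):
        lib = ArtifactLibrary.from_sequences(["ACGTACGT"])
        deleted = mk("TTTACGTCGTTTT")  # one artifact base missing
        assert find_artifact(deleted, lib, MatchSpec(max_del=1, search_depth=13)) is not None
        assert find_artifact(deleted, lib, MatchSpec(max_ins=1, search_depth=13)) is None
        inserted = mk("TTTACGTAACGTTTT")  # one extra read base inside
        assert find_artifact(inserted, lib, MatchSpec(max_ins=1, search_depth=15)) is not None
        assert find_artifact(inserted, lib, MatchSpec(max_del=1, search_depth=15)) is None

    def test_generous_caps_reduce_to_plain_levenshtein(self, rng):
        """With per-type caps >= the artifact length the capped matcher must
        find the same best (distance, start) as unconstrained all-substring
        Levenshtein enumeration."""
        for _ in range(60):
            read = random_read(rng, int(rng.integers(4, 16)))
            m = int(rng.integers(2, 7))
            art = "".join(rng.choice(list("ACGT"), size=m))
            lib = ArtifactLibrary.from_sequences([art])
            got = find_artifact(
                read, lib, MatchSpec(max_ins=m, max_sub=m, max_del=m, search_depth=16)
            )
            want = min(
                (levenshtein(art, read.seq[s:e]), s, e)
                for s in range(len(read))
                for e in range(s + 1, len(read) + 1)
                if abs((e - s) - m) <= m
            )
            assert got is not None
            assert (got.distance, got.start, got.end) == want


class TestApply5adpt:
    def test_kill_after_keeps_5prime_prefix(self):
        out = apply_5adpt(mk("TTTTACGTACGTTTTT"), LIB1, MatchSpec(mp=100, search_depth=16))
        assert out.status == "trimmed"
        assert out.reads[0].seq == "TTTT"
        assert out.bases_removed == 12

    def test_match_at_start_promotes_to_removed(self):
        out = apply_5adpt(mk("ACGTACGTTTTT"), LIB1, MatchSpec(mp=100, search_depth=12))
        assert out.status == "removed" and out.reads == ()

    def test_kill_read(self):
        out = apply_5adpt(
            mk("TTTTACGTACGTTTTT"), LIB1, MatchSpec(mp=100, search_depth=16, action="kr")
        )
        assert out.status == "removed"

    def test_no_match_keeps_read(self):
        read = mk("TTTTTTTT")
        out = apply_5adpt(read, LIB1, MatchSpec(mp=100, search_depth=8))
        assert out.status == "kept" and out.reads == (read,)

    def test_survivor_is_strict_prefix(self, rng):
        for _ in range(100):
            read = random_read(rng, 30)
            out = apply_5adpt(read, LIB1, MatchSpec(mp=75, search_depth=30))
            for r in out.reads:
                assert len(r) <= len(read)
                assert read.seq.startswith(r.seq)


class TestRemoveHomopolymer:
    def test_run_and_3prime_tail_removed(self):
        out = remove_homopolymer(mk("ACG" + "A" * 12 + "CGT"), HomopolymerSpec(h=10, b=frozenset("A")))
        assert out.status == "trimmed"
        assert out.reads[0].seq == "ACG"
        assert out.bases_removed == 15

    def test_run_below_threshold_kept(self):
        read = mk("ACG" + "A" * 9 + "CGT")
        out = remove_homopolymer(read, HomopolymerSpec(h=10, b=frozenset("A")))
        assert out.status == "kept"

    def test_run_at_start_removes_read(self):
        out = remove_homopolymer(mk("TTTTTACGT"), HomopolymerSpec(h=5, b=frozenset("T")))
        assert out.status == "removed"

    def test_only_first_qualifying_run_matters(self):
        out = remove_homopolymer(mk("AACCCCGGGG"), HomopolymerSpec(h=4, b=frozenset("CG")))
        assert out.reads[0].seq == "AA"

    def test_retained_prefix_has_no_qualifying_run(self, rng):
        spec = HomopolymerSpec(h=3, b=frozenset("ACGT"))
        for _ in range(200):
            read = random_read(rng, 20, alphabet="ACG")
            out = remove_homopolymer(read, spec)
            for r in out.reads:
                assert not any(b * spec.h in r.seq for b in spec.b)
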