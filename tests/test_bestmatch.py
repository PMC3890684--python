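from __future__ import annotations

import random
from fractions import Fraction

import pytest

from barcodeid.bestmatch import (
    MatchCandidate,
    SearchConfig,
    Status,
    classify,
    find_candidates,
    identify_all,
)
from barcodeid.errors import ConfigurationError
from barcodeid.refdata import BarcodeRecord

CFG = SearchConfig(threshold_pct=Fraction(99), min_overlap=1)


def rec(seq, rid, species=None, **kw):
    return BarcodeRecord(rid, species, seq, **kw)


def cand(ref, species, sim, overlap=100):
    return MatchCandidate(ref, species, Fraction(sim), overlap)


class TestFindCandidates:
    def test_single_identical_reference(self):
        q = rec("A" * 100, "q")
        lib = [
            rec("A" * 100, "ref1", species="Aus xus"),
            rec("T" * 20 + "A" * 80, "ref2", species="Bus yus"),
        ]
        ml = find_candidates(q, lib, CFG)
        assert [c.reference_id for c in ml.candidates] == ["ref1"]
        assert ml.candidates[0].similarity_pct == 100

    def test_exactly_99_percent_is_excluded(self):
        # 1 mismatch in 100 sites: similarity exactly 99.0, not > 99
        q = rec("A" * 100, "q")
        lib = [rec("T" + "A" * 99, "ref", species="Aus xus")]
        ml = find_candidates(q, lib, CFG)
        assert ml.candidates == ()

    def test_hit_cap_truncates_deterministically(self):
        q = rec("A" * 100, "q")
        lib = [rec("A" * 100, f"ref{i:03d}", species="Aus xus") for i in range(150)]
        cfg = SearchConfig(threshold_pct=Fraction(99), min_overlap=1, max_hits=99)
        ml = find_candidates(q, lib, cfg)
        assert len(ml.candidates) == 99
        assert ml.truncated
        # deterministic tie-break: reference_id ascending
        assert [c.reference_id for c in ml.candidates] == sorted(
            f"ref{i:03d}" for i in range(99)
        )

    def test_provisional_references_excluded(self):
        q = rec("A" * 100, "q")
        lib = [rec("A" * 100, "ref", species="Fannia sp1")]
        with pytest.raises(ConfigurationError):
            find_candidates(q, lib, CFG)

    def test_insufficient_overlap_skipped_and_counted(self):
        q = rec("A" * 10 + "N" * 90, "q")
        lib = [
            rec("A" * 100, "near", species="Aus xus"),
            rec("N" * 95 + "A" * 5, "short", species="Aus xus"),
        ]
        cfg = SearchConfig(threshold_pct=Fraction(99), min_overlap=10)
        ml = find_candidates(q, lib, cfg)
        assert [c.reference_id for c in ml.candidates] == ["near"]
        assert ml.n_skipped_overlap == 1


class TestClassify:
    def test_all_correct_is_unambiguous(self):
        r = classify("q", [cand("r1", "Aus xus", 100), cand("r2", "Aus xus", "99.5")],
                     query_label="Aus xus")
        assert r.status is Status.UNAMBIGUOUS
        assert r.correctness.value == "correct"
        assert not r.tie

    def test_equal_best_correct_and_incorrect_is_tie(self):
        r = classify("q", [cand("r1", "Aus xus", 100), cand("r2", "Aus yus", 100)],
                     query_label="Aus xus")
        assert r.status is Status.AMBIGUOUS
        assert r.correctness.value == "mixed"
        assert r.tie and r.correct_closer is False

    def test_correct_closer_without_tie(self):
        r = classify(
            "q",
            [cand("r1", "Aus xus", Fraction("99.85")),
             cand("r2", "Aus yus", Fraction("99.54"))],
            query_label="Aus xus",
        )
        assert r.status is Status.AMBIGUOUS
        assert not r.tie
        assert r.correct_closer is True

    def test_no_candidates_is_no_match(self):
        r = classify("q", [], query_label="Aus xus")
        assert r.status is Status.NO_MATCH
        assert r.assigned_species == frozenset()
        assert r.best_similarity_pct is None

    def test_single_wrong_species_is_unambiguous_incorrect(self):
        r = classify("q", [cand("r1", "Aus yus", 100)], query_label="Aus xus")
        assert r.status is Status.UNAMBIGUOUS
        assert r.correctness.value == "incorrect"

    def test_genus_level_agreement_is_separate_flag(self):
        r = classify("q", [cand("r1", "Fannia lustrator", 100)],
                     query_label="Fannia sp1", query_genus="Fannia")
        assert r.correctness.value == "incorrect"
        assert r.genus_correct is True

    def test_tie_flag_is_exact_in_rational_arithmetic(self):
        # similarities built from different denominators but equal value
        r = classify(
            "q",
            [MatchCandidate("r1", "Aus xus", Fraction(199, 2), 100),
             MatchCandidate("r2", "Aus yus", Fraction(995, 10), 100)],
            query_label="Aus xus",
        )
        assert r.tie

    def test_perturbing_one_mismatch_breaks_tie(self):
        q = rec("A" * 200, "q")
        correct = rec("A" * 200, "good", species="Aus xus")
        tied = rec("A" * 200, "bad", species="Aus yus")
        off = rec("T" + "A" * 199, "bad2", species="Aus yus")
        cfg = SearchConfig(threshold_pct=Fraction(99), min_overlap=1)
        tie_res = classify("q", find_candidates(q, [correct, tied], cfg), "Aus xus")
        no_tie = classify("q", find_candidates(q, [correct, off], cfg), "Aus xus")
        assert tie_res.tie
        assert not no_tie.tie and no_tie.correct_closer


class TestIdentifyAll:
    def test_empty_query_list(self):
        lib = [rec("A" * 100, "ref", species="Aus xus")]
        assert identify_all([], lib, CFG) == []

    def test_order_preserving(self):
        lib = [rec("A" * 100, "ref", species="Aus xus")]
        queries = [rec("A" * 100, f"q{i}", species="Aus xus") for i in range(5)]
        results = identify_all(queries, lib, CFG)
        assert [r.query_id for r in results] == [q.record_id for q in queries]

    def test_identical_reference_never_no_match_at_default_threshold(self):
        rng = random.Random(3)
        for trial in range(5):
            seq = "".join(rng.choice("ACGT") for _ in range(120))
            q = rec(seq, "q")
            lib = [rec(seq, "same", species="Aus xus"),
                   rec("".join(rng.choice("ACGT") for _ in range(120)),
                       "far", species="Bus yus")]
            res = identify_all([q], lib, CFG)[0]
            assert res.status is not Status.NO_MATCH

    def test_raising_threshold_shrinks_candidates(self):
        rng = random.Random(9)
        base = "".join(rng.choice("ACGT") for _ in range(200))
        q = rec(base, "q")
        lib = []
        for i in range(20):
            seq = list(base)
            for pos in rng.sample(range(200), rng.randint(0, 3)):
                seq[pos] = rng.choice([c for c in "ACGT" if c != seq[pos]])
            lib.append(rec("".join(seq), f"ref{i}", species="Aus xus"))
        prev = None
        for t in (Fraction(98), Fraction(99), Fraction("99.5"), Fraction("99.9")):
            cfg = SearchConfig(threshold_pct=t, min_overlap=1)
            ids = {c.reference_id for c in find_candidates(q, lib, cfg).candidates}
            if prev is not None:
                assert ids <= prev
            prev = ids

    def test_threshold_validation(self):
        with pytest.raises(ConfigurationError):
            SearchConfig(threshold_pct=Fraction(101))
        with pytest.raises(ConfigurationError):
            SearchConfig(max_hits=0)
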