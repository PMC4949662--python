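from __future__ import annotations

import numpy as np
import pytest

from mirhunt.annotate import (
    ArmCandidate,
    LedgerError,
    compute_ledger,
    match_known,
    match_known_by_sequence,
    pair_arms,
)


def cand(cid: str, span: tuple[int, int], arm: str, count: int = 10,
         scaffold: str = "s1", strand: str = "+") -> ArmCandidate:
    return ArmCandidate(candidate_id=cid, scaffold=scaffold, strand=strand,
                        span=span, arm=arm, total_count=count)


class TestPairArms:
    def test_identical_spans_opposite_arms_pair(self):
        pairings = pair_arms([cand("a", (0, 80), "5p"), cand("b", (0, 80), "3p")])
        assert len(pairings) == 1 and pairings[0].is_pair

    def test_same_arm_never_pairs(self):
        pairings = pair_arms([cand("a", (0, 80), "5p"), cand("b", (0, 80), "5p")])
        assert len(pairings) == 2
        assert all(not p.is_pair for p in pairings)

    def test_reciprocal_overlap_threshold(self):
        # 30/80 reciprocal overlap: below 50%, no pairing
        pairings = pair_arms([cand("a", (0, 80), "5p"), cand("b", (50, 130), "3p")])
        assert all(not p.is_pair for p in pairings)

    def test_different_scaffold_or_strand_never_pairs(self):
        assert not any(
            p.is_pair
            for p in pair_arms(
                [cand("a", (0, 80), "5p"), cand("b", (0, 80), "3p", scaffold="s2")]
            )
        )
        assert not any(
            p.is_pair
            for p in pair_arms(
                [cand("a", (0, 80), "5p"), cand("b", (0, 80), "3p", strand="-")]
            )
        )

    def test_crowded_span_keeps_best_expressed_pair(self):
        pairings = pair_arms(
            [
                cand("lo5", (0, 80), "5p", count=5),
                cand("hi5", (0, 80), "5p", count=50),
                cand("x3", (0, 80), "3p", count=20),
            ]
        )
        pairs = [p for p in pairings if p.is_pair]
        assert len(pairs) == 1
        assert pairs[0].five_p.candidate_id == "hi5"
        singles = [p for p in pairings if not p.is_pair]
        assert [p.members[0].candidate_id for p in singles] == ["lo5"]

    def test_pairs_plus_singletons_account_for_all_locations(self):
        cs = (
            [cand(f"p5_{i}", (i * 200, i * 200 + 80), "5p") for i in range(6)]
            + [cand(f"p3_{i}", (i * 200, i * 200 + 80), "3p") for i in range(6)]
            + [cand(f"s_{i}", (5000 + i * 200, 5080 + i * 200), "5p") for i in range(63)]
        )
        pairings = pair_arms(cs)
        n_pairs = sum(1 for p in pairings if p.is_pair)
        assert n_pairs == 6
        assert len(pairings) == 69  # 75 locations -> 69 distinct precursors
        assert sum(len(p.members) for p in pairings) == len(cs)


class TestMatchKnown:
    KNOWN = [("pre1", "s1", "+", 100, 160), ("pre2", "s1", "+", 300, 360)]

    def test_containment(self):
        m = match_known("c", "s1", "+", (110, 132), self.KNOWN)
        assert m.relation == "contained" and m.known_precursor_id == "pre1"

    def test_overlap(self):
        m = match_known("c", "s1", "+", (90, 112), self.KNOWN)
        assert m.relation == "overlapping"

    def test_disjoint_is_none(self):
        assert match_known("c", "s1", "+", (200, 222), self.KNOWN) is None
        assert match_known("c", "s2", "+", (110, 132), self.KNOWN) is None
        assert match_known("c", "s1", "-", (110, 132), self.KNOWN) is None

    def test_matches_brute_force_on_random_intervals(self):
        rng = np.random.default_rng(41)
        known = [
            (f"pre{i}", "s1", "+", int(s), int(s) + int(rng.integers(50, 90)))
            for i, s in enumerate(rng.integers(0, 5000, size=40))
        ]
        for _ in range(200):
            s = int(rng.integers(0, 5000))
            iv = (s, s + 22)
            got = match_known("c", "s1", "+", iv, known)
            contained = [k for k in known if k[3] <= iv[0] and iv[1] <= k[4]]
            overlapping = [
                k for k in known if min(iv[1], k[4]) - max(iv[0], k[3]) >= 1
            ]
            if contained:
                assert got.relation == "contained"
            elif overlapping:
                assert got.relation == "overlapping"
            else:
                assert got is None

    def test_sequence_fallback_complementary_arm(self):
        precursor = "G" * 10 + "ACGTACGTACGTACGTAC" + "C" * 10
        known = [("cgr-miR-9-5p", "5p", "ACGTACGTACGTACGTAC")]
        assert match_known_by_sequence("c", precursor, "3p", known) is not None
        assert match_known_by_sequence("c", precursor, "5p", known) is None


class TestComputeLedger:
    def test_candidate_subtraction(self):
        ledger = compute_ledger(
            n_unique_aligned=1720, n_annotated_excluded=307, n_hairpin_pass=454,
            n_expressed=71, n_dual_locus=4, n_arm_pairs=6, n_on_known_hairpin=13,
            prior_mature=307, prior_precursors=200, n_locus_clusters=546,
        )
        assert ledger.n_candidates == 1413

    def test_full_discovery_arithmetic(self):
        ledger = compute_ledger(
            n_unique_aligned=1720, n_annotated_excluded=307, n_hairpin_pass=454,
            n_expressed=71, n_dual_locus=4, n_arm_pairs=6, n_on_known_hairpin=13,
            prior_mature=307, prior_precursors=200, n_locus_clusters=546,
        )
        assert ledger.n_not_expressed == 383
        assert ledger.n_locations == 75
        assert ledger.n_distinct_precursors == 69
        assert ledger.n_novel_precursors == 56
        assert ledger.total_mature == 378
        assert ledger.pct_mature_increase == 23.1
        assert ledger.total_precursors == 256
        assert ledger.pct_precursor_increase == 28.0

    def test_zero_novel_inputs(self):
        ledger = compute_ledger(
            n_unique_aligned=0, n_annotated_excluded=0, n_hairpin_pass=0,
            n_expressed=0, n_dual_locus=0, n_arm_pairs=0, n_on_known_hairpin=0,
            prior_mature=307, prior_precursors=200,
        )
        assert ledger.total_mature == 307
        assert ledger.total_precursors == 200
        assert ledger.pct_mature_increase == 0.0
        assert ledger.pct_precursor_increase == 0.0

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(n_unique_aligned=5, n_annotated_excluded=7),  # negative candidates
            dict(n_expressed=10, n_hairpin_pass=5),  # expressed > hairpin pass
            dict(n_expressed=2, n_hairpin_pass=5, n_arm_pairs=4),  # pairs > locations
            dict(n_unique_aligned=-1),
        ],
    )
    def test_inconsistent_inputs_rejected(self, kwargs):
        base = dict(
            n_unique_aligned=100, n_annotated_excluded=10, n_hairpin_pass=50,
            n_expressed=20, n_dual_locus=0, n_arm_pairs=0, n_on_known_hairpin=0,
            prior_mature=10, prior_precursors=10,
        )
        base.update(kwargs)
        with pytest.raises(LedgerError):
            compute_ledger(**base)

    def test_rounding_half_up(self):
        ledger = compute_ledger(
            n_unique_aligned=10, n_annotated_excluded=0, n_hairpin_pass=10,
            n_expressed=5, n_dual_locus=0, n_arm_pairs=0, n_on_known_hairpin=0,
            prior_mature=2000, prior_precursors=2000,
        )
        assert ledger.pct_mature_increase == 0.3  # 0.25 rounds half-up, not half-even
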