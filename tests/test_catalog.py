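from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirhunt.catalog import (
    collapse_unique,
    exclude_species,
    hairpin_context,
    prepare_queries,
)
from mirhunt.io import SequenceRecord

SEQ_A = "ACGTACGTACGTACGTAC"


def rec(ident: str, seq: str) -> SequenceRecord:
    return SequenceRecord(id=ident, sequence=seq)


class TestCollapseUnique:
    def test_exact_duplicates_collapse(self):
        uniques = collapse_unique([rec("hsa-miR-x", SEQ_A), rec("mmu-miR-x", SEQ_A)])
        assert len(uniques) == 1
        assert [m.full for m in uniques[0].members] == ["hsa-miR-x", "mmu-miR-x"]
        assert uniques[0].display_name == "hsa-miR-x"

    def test_distinct_sequences_stay_distinct(self):
        recs = [rec(f"hsa-miR-{i}", SEQ_A[:-1] + b) for i, b in enumerate("ACG")]
        assert len(collapse_unique(recs)) == 3

    def test_entry_count_equals_distinct_sequences(self):
        rng = np.random.default_rng(7)
        seqs = ["".join(rng.choice(list("ACGT"), 18)) for _ in range(12)]
        pool = [seqs[i % len(seqs)] for i in range(40)]
        recs = [rec(f"sp{i % 5}-miR-{i}", s) for i, s in enumerate(pool)]
        assert len(collapse_unique(recs)) == len(set(pool))

    def test_idempotent(self):
        recs = [rec("hsa-miR-x", SEQ_A), rec("mmu-miR-x", SEQ_A), rec("hsa-miR-y", SEQ_A[::-1])]
        once = collapse_unique(recs)
        again = collapse_unique(
            [rec(m.full, u.sequence) for u in once for m in u.members]
        )
        assert [(u.sequence, u.members) for u in once] == [
            (u.sequence, u.members) for u in again
        ]

    def test_member_counts_conserved(self):
        recs = [rec(f"sp{i}-miR-1", SEQ_A) for i in range(4)] + [rec("hsa-miR-2", SEQ_A[::-1])]
        uniques = collapse_unique(recs)
        assert sum(len(u.members) for u in uniques) == len(recs)


class TestExcludeSpecies:
    def test_any_member_rule(self):
        uniques = collapse_unique(
            [rec("cgr-miR-21-5p", SEQ_A), rec("hsa-miR-21-5p", SEQ_A)]
        )
        kept, excluded = exclude_species(uniques, "cgr")
        assert kept == [] and len(excluded) == 1

    def test_foreign_only_kept(self):
        uniques = collapse_unique([rec("hsa-miR-1", SEQ_A)])
        kept, excluded = exclude_species(uniques, "cgr")
        assert len(kept) == 1 and excluded == []

    def test_partition_is_exact(self):
        rng = np.random.default_rng(3)
        recs = []
        for i in range(10):
            seq = "".join(rng.choice(list("ACGT"), 20))
            prefix = "cgr" if i < 4 else "hsa"
            recs.append(rec(f"{prefix}-miR-{i}", seq))
        uniques = collapse_unique(recs)
        kept, excluded = exclude_species(uniques, "cgr")
        assert len(kept) == 6 and len(excluded) == 4
        assert sorted(u.sequence for u in kept + excluded) == sorted(
            u.sequence for u in uniques
        )
        assert not any(u.has_species("cgr") for u in kept)


class TestHairpinContext:
    def test_flank_arithmetic(self):
        mature = "ACGTACGTACGTACGTACGTAC"  # 22 nt
        hairpin = "G" * 5 + mature + "C" * 33
        ctx = hairpin_context(
            rec("xxx-miR-9-5p", mature), [rec("xxx-mir-9", hairpin)]
        )
        assert (ctx.upstream_len, ctx.downstream_len) == (5, 33)
        assert hairpin[ctx.upstream_len : ctx.upstream_len + len(mature)] == mature

    def test_absent_mature_gives_none(self):
        assert (
            hairpin_context(rec("xxx-miR-9-5p", "A" * 20), [rec("xxx-mir-9", "C" * 60)])
            is None
        )

    def test_first_occurrence_wins(self):
        mature = "ACGTACGTACGTACG"
        hairpin = "TT" + mature + "AA" + mature + "GG"
        ctx = hairpin_context(rec("xxx-miR-9-5p", mature), [rec("xxx-mir-9", hairpin)])
        # exhaustive scan oracle for first occurrence
        first = min(i for i in range(len(hairpin)) if hairpin.startswith(mature, i))
        assert ctx.mature_offset == first == 2

    def test_multicopy_precursor_prefix_match(self):
        mature = "ACGTACGTACGTACGTAC"
        hairpins = [
            rec("xxx-mir-9-2", "T" * 10 + mature + "G" * 10),
            rec("xxx-mir-9-1", "A" * 4 + mature + "G" * 12),
        ]
        ctx = hairpin_context(rec("xxx-miR-9-5p", mature), hairpins)
        assert ctx.hairpin_id == "xxx-mir-9-1"  # lexicographically first wins
        assert ctx.upstream_len == 4


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_context_offsets_reconstruct_mature(seed):
    """hairpin[upstream : upstream+len] == mature for random geometries."""
    rng = np.random.default_rng(seed)
    mature = "".join(rng.choice(list("ACGT"), int(rng.integers(16, 25))))
    up, down = int(rng.integers(0, 40)), int(rng.integers(0, 40))
    hairpin = (
        "".join(rng.choice(list("ACGT"), up)) + mature + "".join(rng.choice(list("ACGT"), down))
    )
    ctx = hairpin_context(rec("aaa-miR-5-5p", mature), [rec("aaa-mir-5", hairpin)])
    assert ctx is not None
    assert (
        hairpin[ctx.upstream_len : ctx.upstream_len + len(mature)] == mature
    )
    assert ctx.upstream_len + len(mature) + ctx.downstream_len == len(hairpin)


class TestPrepareQueries:
    def test_drops_ambiguous_and_offsize_with_context_fallback(self, caplog):
        matures = [
            rec("hsa-miR-1", "ACGTACGTACGTACGTACGT"),
            rec("hsa-miR-2", "ACGNACGTACGTACGTACGT"),  # N: dropped
            rec("hsa-miR-3", "ACGT"),  # too short: dropped
            rec("cgr-miR-4", "TTTTACGTACGTACGTACGT"),
        ]
        kept, excluded, contexts = prepare_queries(matures, [rec("zzz-mir-0", "A" * 30)], "cgr")
        assert [u.display_name for u in kept] == ["hsa-miR-1"]
        assert [u.display_name for u in excluded] == ["cgr-miR-4"]
        ctx = contexts[kept[0].sequence]
        assert (ctx.upstream_len, ctx.downstream_len) == (25, 25)  # fallback flanks

    def test_longest_precursor_context_wins(self):
        mature = "ACGTACGTACGTACGTACGT"
        matures = [rec("aaa-miR-7-5p", mature), rec("bbb-miR-7-5p", mature)]
        hairpins = [
            rec("aaa-mir-7", "G" * 5 + mature + "C" * 5),
            rec("bbb-mir-7", "G" * 20 + mature + "C" * 30),
        ]
        _kept, _exc, contexts = prepare_queries(matures, hairpins, "cgr")
        ctx = contexts[mature]
        assert ctx.hairpin_id == "bbb-mir-7"
        assert (ctx.upstream_len, ctx.downstream_len) == (20, 30)
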