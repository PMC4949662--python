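from __future__ import annotations

import numpy as np
import pytest

from mirhunt.folding import evaluate_hairpin, fold
from mirhunt.io import reverse_complement
from mirhunt.match import find_exact_hits
from mirhunt.synthetic import (
    build_hairpin,
    make_genome,
    make_scenario,
    plant_hairpin,
    simulate_counts,
    TruthRecord,
)


class TestMakeGenome:
    def test_seeded_reproducibility(self):
        a = make_genome(3, 2000, 0.5, 7)
        b = make_genome(3, 2000, 0.5, 7)
        assert a == b
        assert len(a) == 3

    def test_gc_within_binomial_bound(self):
        (rec,) = make_genome(1, 100_000, 0.5, 3)
        gc = sum(c in "GC" for c in rec.sequence)
        sd = (100_000 * 0.25) ** 0.5
        assert abs(gc - 50_000) < 3 * sd

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            make_genome(1, 500, 0.5, 0)
        with pytest.raises(ValueError):
            make_genome(1, 2000, 1.5, 0)


class TestPlantHairpin:
    def test_zero_mismatch_hairpin_folds_clean(self):
        """Perfect planted stems give one terminal loop, mature fully paired."""
        rng = np.random.default_rng(1)
        for _ in range(10):
            mature = "".join(rng.choice(list("ACGT"), 22))
            hairpin, offset, _star = build_hairpin(
                mature, loop_len=6, flank_len=15, stem_mismatches=0, rng=rng
            )
            fr = fold(hairpin)
            ev = evaluate_hairpin(fr, (offset, offset + 22))
            assert ev.n_terminal_loops == 1
            assert ev.mature_paired_fraction == 1.0

    def test_minus_strand_planting_yields_minus_hit(self):
        rng = np.random.default_rng(2)
        genome = make_genome(1, 5000, 0.5, rng)
        mature = "".join(rng.choice(list("ACGT"), 22))
        genome2, truth = plant_hairpin(
            genome, mature, strand="-", seed=rng, stem_mismatches=2
        )
        locus = truth.loci[0]
        from mirhunt.catalog import UniqueMature
        from mirhunt.io import parse_mirna_id

        pattern = UniqueMature(sequence=mature, members=(parse_mirna_id("xaa-miR-1"),))
        hits = find_exact_hits([pattern], genome2, "genome")
        assert any(
            h.strand == "-" and h.start == locus["start"] and h.end == locus["end"]
            for h in hits
        )

    def test_insertion_preserves_background(self):
        genome = make_genome(1, 3000, 0.5, 5)
        mature = "ACGTACGTACGTACGTACGTAC"
        genome2, truth = plant_hairpin(genome, mature, seed=5, stem_mismatches=1)
        hp = truth.hairpin_sequence
        locus = truth.loci[0]
        s = genome2[0].sequence
        assert s[locus["hairpin_start"] : locus["hairpin_end"]] == hp
        # removing the insert restores the background exactly
        assert (
            s[: locus["hairpin_start"]] + s[locus["hairpin_end"] :]
            == genome[0].sequence
        )

    def test_dual_planting_creates_two_loci(self):
        from mirhunt.catalog import UniqueMature
        from mirhunt.cluster import cluster_hits
        from mirhunt.io import parse_mirna_id
        from mirhunt.synthetic import plant_hairpins

        rng = np.random.default_rng(9)
        genome = make_genome(2, 5000, 0.5, rng)
        mature = "".join(rng.choice(list("ACGT"), 22))
        hairpin, offset, _ = build_hairpin(mature, stem_mismatches=2, rng=rng)
        truth = TruthRecord(
            name="xaa-miR-1-5p", mature_sequence=mature, arm="5p",
            hairpin_id="mir-1", hairpin_sequence=hairpin, mature_offset=offset,
        )
        genome = plant_hairpins(genome, "g1", [(truth, "+"), (truth, "-")], rng)
        pattern = UniqueMature(sequence=mature, members=(parse_mirna_id("xaa-miR-1-5p"),))
        hits = find_exact_hits([pattern], genome, "g1")
        loci = cluster_hits(hits)
        assert len(loci) == 2

    def test_mature_with_n_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            build_hairpin("ACGTNACGTACGTACGTACGT", rng=rng)


class TestSimulateCounts:
    def mk_truths(self, n: int, rng) -> list[TruthRecord]:
        out = []
        for i in range(n):
            m = "".join(rng.choice(list("ACGT"), 21))
            out.append(
                TruthRecord(
                    name=f"xaa-miR-{i}-5p", mature_sequence=m, arm="5p",
                    hairpin_id=f"mir-{i}", hairpin_sequence=m, mature_offset=0,
                    expressed_intended=True,
                )
            )
        return out

    def test_unexpressed_truths_get_no_reads(self):
        rng = np.random.default_rng(3)
        truths = self.mk_truths(5, rng)
        for t in truths:
            t.expressed_intended = False
        tables = simulate_counts(truths, rng=rng, background_n=0)
        assert all(not t.expressed for t in truths)
        assert all(t.rows == {} for t in tables)

    def test_mean_total_matches_law_of_large_numbers(self):
        rng = np.random.default_rng(12)
        truths = self.mk_truths(200, rng)
        tables = simulate_counts(
            truths, mean=100, dispersion=1.0, n_experiments=4, rng=rng, background_n=0
        )
        totals = [
            sum(t.rows.get(tr.mature_sequence, 0) for t in tables) for tr in truths
        ]
        assert abs(np.mean(totals) - 400) / 400 < 0.1

    def test_seeded_tables_identical(self):
        rng1, rng2 = np.random.default_rng(4), np.random.default_rng(4)
        t1 = simulate_counts(self.mk_truths(10, np.random.default_rng(5)), rng=rng1)
        t2 = simulate_counts(self.mk_truths(10, np.random.default_rng(5)), rng=rng2)
        assert [t.rows for t in t1] == [t.rows for t in t2]

    def test_realized_expressed_flag_recomputed(self):
        rng = np.random.default_rng(6)
        truths = self.mk_truths(50, rng)
        simulate_counts(truths, mean=100, rng=rng, background_n=0)
        assert all(t.expressed for t in truths)  # mean 400 total >> cutoff 5


class TestScenario:
    def test_structure_of_reference_study(self, scenario):
        foreign = [t for t in scenario.truths if not t.is_target_species]
        known = [t for t in scenario.truths if t.is_target_species]
        assert len(foreign) == 20
        assert len(known) == 3
        assert sum(1 for t in foreign if t.expressed) == 12
        assert sum(1 for t in foreign if t.partner) == 4  # two full 5p/3p pairs
        assert sum(1 for t in foreign if t.on_known) == 1
        assert len(scenario.genomes) == 2
        for _gid, recs in scenario.genomes:
            assert sum(len(r) for r in recs) >= 200_000

    def test_every_planted_mature_present_at_truth_coordinates(self, scenario):
        genomes = {gid: {r.id: r for r in recs} for gid, recs in scenario.genomes}
        for t in scenario.truths:
            assert t.loci, t.name
            for locus in t.loci:
                seq = genomes[locus["genome_id"]][locus["scaffold"]].sequence
                found = seq[locus["start"] : locus["end"]]
                if locus["strand"] == "+":
                    assert found == t.mature_sequence
                else:
                    assert reverse_complement(found) == t.mature_sequence

    def test_catalog_and_annotation_consistency(self, scenario):
        catalog_seqs = {r.sequence for r in scenario.catalog_matures}
        assert all(t.mature_sequence in catalog_seqs for t in scenario.truths)
        # the known annotation covers exactly the target-species hairpins
        known_ids = {f.attributes["ID"] for f in scenario.known_gff}
        assert known_ids == {
            t.hairpin_id for t in scenario.truths if t.is_target_species
        }
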