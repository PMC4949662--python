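"""Synthetic genomes, catalogs and read tables with known planted truth.

The generator emulates the study conditions of homology-based miRNA
discovery: draft genome assemblies carrying evolutionary conserved pre-miRNA
hairpins, a multi-species mature/hairpin catalog that names those matures
under foreign species prefixes, collapsed small-RNA-seq count tables with
negative-binomially dispersed counts over the expressed matures, and an
existing target-species annotation.  Every planted feature is recorded in a
:class:`TruthRecord`, so each pipeline stage can be checked against ground
truth without downloading anything.

Planted hairpins are built as

    5' flank + mature + loop + mutated revcomp(mature) + revcomp(5' flank)

(arm-swapped for 3p plantings): the complementary flanks form the lower stem
below the Drosha cut, as in real pri-miRNAs, and the loop is drawn from
``{A, C}`` so it cannot pair with itself.  With ``stem_mismatches = 0`` the
construct folds to a single terminal loop with the mature fully paired.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .folding import evaluate_hairpin, fold
from .io import CountTable, GffFeature, SequenceRecord, reverse_complement

__all__ = [
    "TruthRecord",
    "Scenario",
    "make_genome",
    "build_hairpin",
    "plant_hairpin",
    "plant_hairpins",
    "simulate_counts",
    "make_scenario",
    "write_scenario",
]

BASES = "ACGT"


@dataclass
class TruthRecord:
    """Ground truth for one planted mature miRNA."""

    name: str
    mature_sequence: str
    arm: str
    hairpin_id: str
    hairpin_sequence: str
    mature_offset: int
    loci: list[dict] = field(default_factory=list)  # genome_id, scaffold, start, strand, hairpin_start
    expressed_intended: bool = False
    expressed: bool = False
    partner: Optional[str] = None  # partner mature sequence for a 5p/3p pair
    on_known: bool = False
    is_target_species: bool = False

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "mature_sequence": self.mature_sequence,
            "arm": self.arm,
            "hairpin_id": self.hairpin_id,
            "hairpin_sequence": self.hairpin_sequence,
            "mature_offset": self.mature_offset,
            "loci": self.loci,
            "expressed_intended": self.expressed_intended,
            "expressed": self.expressed,
            "partner": self.partner,
            "on_known": self.on_known,
            "is_target_species": self.is_target_species,
        }


def _random_seq(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list(BASES), size=length, p=p))


def make_genome(
    n_scaffolds: int,
    lengths: Sequence[int] | int,
    gc: float,
    seed: int | np.random.Generator,
) -> list[SequenceRecord]:
    """Generate i.i.d. background scaffolds with the given GC content."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if isinstance(lengths, int):
        lengths = [lengths] * n_scaffolds
    if len(lengths) != n_scaffolds:
        raise ValueError("lengths must match n_scaffolds")
    if not 0 < gc < 1:
        raise ValueError("gc must be in (0, 1)")
    records = []
    for i, L in enumerate(lengths):
        if L < 1000:
            raise ValueError("scaffold length must be at least 1 kb")
        records.append(
            SequenceRecord(id=f"scaffold_{i + 1}", sequence=_random_seq(rng, L, gc))
        )
    return records


def build_hairpin(
    mature: str,
    *,
    loop_len: int = 6,
    flank_len: int = 15,
    stem_mismatches: int = 0,
    arm: str = "5p",
    rng: np.random.Generator,
    star: str | None = None,
) -> tuple[str, int, str]:
    """Construct a planted hairpin; returns (hairpin, mature_offset, star).

    The star arm is the reverse complement of the mature with
    *stem_mismatches* random substitutions (or the explicit *star*, e.g. an
    already-drawn 3p partner).  For ``arm='3p'`` the construct is mirrored so
    the mature sits 3' of the loop.
    """
    if "N" in mature:
        raise ValueError("mature sequence must not contain N")
    if not 4 <= loop_len <= 15:
        raise ValueError("loop_len must be in [4, 15]")
    if star is None:
        star_list = list(reverse_complement(mature))
        for pos in rng.choice(len(star_list), size=stem_mismatches, replace=False):
            star_list[pos] = rng.choice([b for b in BASES if b != star_list[pos]])
        star = "".join(star_list)
    loop = "".join(rng.choice(["A", "C"], size=loop_len))
    flank5 = _random_seq(rng, flank_len)
    flank3 = reverse_complement(flank5)
    if arm == "5p":
        hairpin = flank5 + mature + loop + star + flank3
        offset = flank_len
    elif arm == "3p":
        hairpin = flank5 + star + loop + mature + flank3
        offset = flank_len + len(star) + loop_len
    else:
        raise ValueError(f"arm must be 5p or 3p, got {arm!r}")
    return hairpin, offset, star


def _insert(
    scaffolds: list[SequenceRecord],
    insertions: list[tuple[int, int, str]],
) -> tuple[list[SequenceRecord], list[int]]:
    """Insert sequences at (scaffold index, position); return new coordinates.

    Insertions are applied jointly so every returned start refers to the
    final, fully assembled scaffold.
    """
    per_scaffold: dict[int, list[tuple[int, int]]] = {}
    for order, (sc, pos, _seq) in enumerate(insertions):
        per_scaffold.setdefault(sc, []).append((pos, order))
    final_starts = [0] * len(insertions)
    new_records = list(scaffolds)
    for sc, items in per_scaffold.items():
        items.sort()
        seq = scaffolds[sc].sequence
        parts = []
        prev = 0
        offset = 0
        for pos, order in items:
            parts.append(seq[prev:pos])
            final_starts[order] = pos + offset
            ins = insertions[order][2]
            parts.append(ins)
            offset += len(ins)
            prev = pos
        parts.append(seq[prev:])
        new_records[sc] = SequenceRecord(id=scaffolds[sc].id, sequence="".join(parts))
    return new_records, final_starts


def plant_hairpins(
    genome: list[SequenceRecord],
    genome_id: str,
    plants: list[tuple[TruthRecord, str]],
    rng: np.random.Generator,
    *,
    margin: int = 200,
) -> list[SequenceRecord]:
    """Insert each truth record's hairpin at a uniform interior site.

    *plants* pairs a truth record with the strand to plant on; the genomic
    mature coordinates are appended to the record's loci.  Insertion (never
    overwriting) keeps the background statistics intact around the site.
    """
    insertions: list[tuple[int, int, str]] = []
    for truth, strand in plants:
        sc = int(rng.integers(len(genome)))
        pos = int(rng.integers(margin, len(genome[sc].sequence) - margin))
        seq = truth.hairpin_sequence if strand == "+" else reverse_complement(
            truth.hairpin_sequence
        )
        insertions.append((sc, pos, seq))
    new_genome, starts = _insert(genome, insertions)
    for (truth, strand), (sc, _pos, _seq), hp_start in zip(plants, insertions, starts):
        L = len(truth.mature_sequence)
        if strand == "+":
            m_start = hp_start + truth.mature_offset
        else:
            m_start = hp_start + (
                len(truth.hairpin_sequence) - truth.mature_offset - L
            )
        truth.loci.append(
            {
                "genome_id": genome_id,
                "scaffold": new_genome[sc].id,
                "start": m_start,
                "end": m_start + L,
                "strand": strand,
                "hairpin_start": hp_start,
                "hairpin_end": hp_start + len(truth.hairpin_sequence),
            }
        )
    return new_genome


def plant_hairpin(
    genome: list[SequenceRecord],
    mature: str,
    *,
    genome_id: str = "genome",
    loop_len: int = 6,
    flank_len: int = 15,
    stem_mismatches: int = 0,
    strand: str = "+",
    arm: str = "5p",
    seed: int | np.random.Generator = 0,
    name: str = "planted-miR-1",
) -> tuple[list[SequenceRecord], TruthRecord]:
    """Plant a single hairpin built around *mature*; returns (genome', truth)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    hairpin, offset, _star = build_hairpin(
        mature,
        loop_len=loop_len,
        flank_len=flank_len,
        stem_mismatches=stem_mismatches,
        arm=arm,
        rng=rng,
    )
    truth = TruthRecord(
        name=name,
        mature_sequence=mature,
        arm=arm,
        hairpin_id=name.rsplit("-5p", 1)[0].rsplit("-3p", 1)[0],
        hairpin_sequence=hairpin,
        mature_offset=offset,
    )
    new_genome = plant_hairpins(genome, genome_id, [(truth, strand)], rng)
    return new_genome, truth


def simulate_counts(
    truths: Sequence[TruthRecord],
    *,
    mean: float = 100.0,
    dispersion: float = 1.0,
    n_experiments: int = 4,
    cutoff: int = 5,
    background_n: int = 30,
    background_max: int = 10,
    rng: np.random.Generator,
    known_mean: float = 1000.0,
) -> list[CountTable]:
    """Draw per-experiment read counts and update realized expressed flags.

    Matures flagged ``expressed_intended`` draw negative-binomial counts with
    the stated mean and dispersion per experiment; target-species (already
    annotated) matures draw with *known_mean*; all other planted matures get
    no reads.  Background noise reads — random sequences at low counts —
    exercise exact-match specificity.  Each truth's ``expressed`` flag is
    recomputed from the realized total against the cutoff.
    """
    if mean <= 0 or dispersion <= 0:
        raise ValueError("mean and dispersion must be positive")

    def nb(m: float) -> int:
        # Gamma-Poisson mixture: variance m + m^2 / dispersion.
        p = dispersion / (dispersion + m)
        return int(rng.negative_binomial(dispersion, p))

    tables = [CountTable(experiment_id=f"exp{k + 1}") for k in range(n_experiments)]
    for truth in truths:
        m = known_mean if truth.is_target_species else mean
        draw = truth.expressed_intended or truth.is_target_species
        total = 0
        for t in tables:
            c = nb(m) if draw else 0
            if c:
                t.rows[truth.mature_sequence] = t.rows.get(truth.mature_sequence, 0) + c
            total += c
        truth.expressed = total > cutoff
    planted = {t.mature_sequence for t in truths}
    for t in tables:
        for _ in range(background_n):
            while True:
                noise = _random_seq(rng, int(rng.integers(20, 23)))
                if noise not in planted:
                    break
            t.rows[noise] = t.rows.get(noise, 0) + int(rng.integers(1, background_max + 1))
    return tables


@dataclass
class Scenario:
    """A complete synthetic study with ground truth."""

    genomes: list[tuple[str, list[SequenceRecord]]]
    catalog_matures: list[SequenceRecord]
    catalog_hairpins: list[SequenceRecord]
    known_matures: list[SequenceRecord]
    known_gff: list[GffFeature]
    tables: list[CountTable]
    truths: list[TruthRecord]
    target_prefix: str
    cutoff: int

    @property
    def primary_genome(self) -> str:
        return self.genomes[0][0]


def _clean_mature(
    rng: np.random.Generator,
    existing: set[str],
    *,
    length_range: tuple[int, int] = (20, 23),
    loop_len: int,
    flank_len: int,
    stem_mismatches: int,
    max_tries: int = 200,
) -> tuple[str, str, int, str]:
    """Draw a mature whose planted hairpin passes the default stem-loop screen.

    Returns (mature, hairpin, mature_offset, star).  Rejection sampling keeps
    the generator honest: the screen is the package's own classifier, so a
    planted positive is by construction a clean stem-loop, not a tuned one.
    """
    for _ in range(max_tries):
        L = int(rng.integers(length_range[0], length_range[1] + 1))
        mature = _random_seq(rng, L)
        if mature in existing or mature == reverse_complement(mature):
            continue
        hairpin, offset, star = build_hairpin(
            mature,
            loop_len=loop_len,
            flank_len=flank_len,
            stem_mismatches=stem_mismatches,
            rng=rng,
        )
        if star in existing or star == mature:
            continue
        fr = fold(hairpin)
        ev5 = evaluate_hairpin(fr, (offset, offset + L))
        star_offset = offset + L + loop_len
        ev3 = evaluate_hairpin(fr, (star_offset, star_offset + len(star)))
        if ev5.passes and ev3.passes and fr.score_density >= 0.8:
            return mature, hairpin, offset, star
    raise RuntimeError("could not draw a clean planted hairpin")


def make_scenario(
    seed: int,
    *,
    n_singles_expressed: int = 7,
    n_singles_unexpressed: int = 8,
    n_pairs: int = 2,
    n_on_known: int = 1,
    n_extra_known: int = 2,
    n_decoys: int = 10,
    n_genomes: int = 2,
    scaffolds_per_genome: int = 4,
    scaffold_len: int = 50_000,
    gc: float = 0.42,
    flank_len: int = 15,
    loop_len: int = 6,
    stem_mismatches: int = 2,
    cutoff: int = 5,
    count_mean: float = 100.0,
    dispersion: float = 1.0,
    n_experiments: int = 4,
    target_prefix: str = "cgr",
) -> Scenario:
    """Build the reference synthetic study.

    Defaults plant 20 conserved foreign matures — 2 full 5p/3p pairs (4
    matures), 1 new arm on an already annotated precursor, 7 further expressed
    singletons and 8 unexpressed singletons — plus ``n_extra_known`` planted
    target-species hairpins, across ``n_genomes`` assemblies of
    ``scaffolds_per_genome × scaffold_len``.  Foreign matures are emitted
    under 1–4 fabricated species prefixes with matching hairpin entries;
    decoy matures absent from every genome exercise specificity.
    """
    rng = np.random.default_rng(seed)
    foreign = ["xaa", "xbb", "xcc", "xdd"]
    existing: set[str] = set()
    truths: list[TruthRecord] = []
    catalog_matures: list[SequenceRecord] = []
    catalog_hairpins: list[SequenceRecord] = []
    known_matures: list[SequenceRecord] = []

    def emit_foreign(base: str, arm: str, mature: str, hairpin: str) -> str:
        """Register a foreign mature under 1-4 fake species; returns first id."""
        k = int(rng.integers(1, len(foreign) + 1))
        prefixes = sorted(rng.choice(foreign, size=k, replace=False))
        first = None
        for p in prefixes:
            mid = f"{p}-miR-{base}-{arm}"
            catalog_matures.append(SequenceRecord(id=mid, sequence=mature))
            hid = f"{p}-mir-{base}"
            if not any(h.id == hid for h in catalog_hairpins):
                catalog_hairpins.append(SequenceRecord(id=hid, sequence=hairpin))
            first = first or mid
        return first

    serial = 100

    # --- 5p/3p pairs: both arms in the foreign catalog, both expressed.
    pair_truths: list[tuple[TruthRecord, TruthRecord]] = []
    for _ in range(n_pairs):
        serial += 1
        mature, hairpin, offset, star = _clean_mature(
            rng, existing, loop_len=loop_len, flank_len=flank_len,
            stem_mismatches=stem_mismatches,
        )
        existing.update((mature, star))
        name5 = emit_foreign(str(serial), "5p", mature, hairpin)
        name3 = emit_foreign(str(serial), "3p", star, hairpin)
        star_offset = offset + len(mature) + loop_len
        t5 = TruthRecord(
            name=name5, mature_sequence=mature, arm="5p",
            hairpin_id=f"mir-{serial}", hairpin_sequence=hairpin,
            mature_offset=offset, expressed_intended=True, partner=star,
        )
        t3 = TruthRecord(
            name=name3, mature_sequence=star, arm="3p",
            hairpin_id=f"mir-{serial}", hairpin_sequence=hairpin,
            mature_offset=star_offset, expressed_intended=True, partner=mature,
        )
        truths.extend((t5, t3))
        pair_truths.append((t5, t3))

    # --- new arm on an already annotated precursor: the target species has
    # the 5p arm, discovery should find the 3p star arm on the same hairpin.
    on_known_truths: list[TruthRecord] = []
    known_hairpin_truths: list[TruthRecord] = []
    for _ in range(n_on_known):
        serial += 1
        mature, hairpin, offset, star = _clean_mature(
            rng, existing, loop_len=loop_len, flank_len=flank_len,
            stem_mismatches=stem_mismatches,
        )
        existing.update((mature, star))
        kid = f"{target_prefix}-miR-{serial}-5p"
        catalog_matures.append(SequenceRecord(id=kid, sequence=mature))
        catalog_hairpins.append(
            SequenceRecord(id=f"{target_prefix}-mir-{serial}", sequence=hairpin)
        )
        known_matures.append(SequenceRecord(id=kid, sequence=mature))
        tk = TruthRecord(
            name=kid, mature_sequence=mature, arm="5p",
            hairpin_id=f"{target_prefix}-mir-{serial}", hairpin_sequence=hairpin,
            mature_offset=offset, is_target_species=True,
        )
        name3 = emit_foreign(str(serial), "3p", star, hairpin)
        t3 = TruthRecord(
            name=name3, mature_sequence=star, arm="3p",
            hairpin_id=f"mir-{serial}", hairpin_sequence=hairpin,
            mature_offset=offset + len(mature) + loop_len,
            expressed_intended=True, on_known=True,
        )
        truths.extend((tk, t3))
        known_hairpin_truths.append(tk)
        on_known_truths.append(t3)

    # --- additional already annotated target-species hairpins (excluded).
    for _ in range(n_extra_known):
        serial += 1
        mature, hairpin, offset, _star = _clean_mature(
            rng, existing, loop_len=loop_len, flank_len=flank_len,
            stem_mismatches=stem_mismatches,
        )
        existing.add(mature)
        kid = f"{target_prefix}-miR-{serial}-5p"
        catalog_matures.append(SequenceRecord(id=kid, sequence=mature))
        catalog_hairpins.append(
            SequenceRecord(id=f"{target_prefix}-mir-{serial}", sequence=hairpin)
        )
        known_matures.append(SequenceRecord(id=kid, sequence=mature))
        tk = TruthRecord(
            name=kid, mature_sequence=mature, arm="5p",
            hairpin_id=f"{target_prefix}-mir-{serial}", hairpin_sequence=hairpin,
            mature_offset=offset, is_target_species=True,
        )
        truths.append(tk)
        known_hairpin_truths.append(tk)

    # --- singleton foreign matures, expressed and unexpressed.
    singles: list[TruthRecord] = []
    for i in range(n_singles_expressed + n_singles_unexpressed):
        serial += 1
        mature, hairpin, offset, _star = _clean_mature(
            rng, existing, loop_len=loop_len, flank_len=flank_len,
            stem_mismatches=stem_mismatches,
        )
        existing.add(mature)
        name = emit_foreign(str(serial), "5p", mature, hairpin)
        t = TruthRecord(
            name=name, mature_sequence=mature, arm="5p",
            hairpin_id=f"mir-{serial}", hairpin_sequence=hairpin,
            mature_offset=offset, expressed_intended=i < n_singles_expressed,
        )
        truths.append(t)
        singles.append(t)

    # --- decoy foreign matures never planted in any genome.
    for _ in range(n_decoys):
        serial += 1
        while True:
            decoy = _random_seq(rng, int(rng.integers(20, 24)))
            if decoy not in existing:
                break
        existing.add(decoy)
        emit_foreign(str(serial), "5p", decoy,
                     decoy + "".join(rng.choice(["A", "C"], size=10)) + reverse_complement(decoy))

    # --- genomes: every hairpin in the primary genome; expressed hairpins and
    # half the unexpressed ones also in the later genomes.
    hairpin_plants: dict[str, list[TruthRecord]] = {}
    for t in truths:
        hairpin_plants.setdefault(t.hairpin_sequence, []).append(t)
    all_hairpins = list(hairpin_plants)
    secondary_hairpins = [
        hp for hp in all_hairpins
        if any(t.expressed_intended or t.is_target_species for t in hairpin_plants[hp])
        or (rng.random() < 0.5)
    ]

    genomes: list[tuple[str, list[SequenceRecord]]] = []
    strand_cycle = ["+", "-"]
    for g in range(n_genomes):
        gid = f"genome{g + 1}"
        bg = make_genome(scaffolds_per_genome, scaffold_len, gc, rng)
        chosen = all_hairpins if g == 0 else secondary_hairpins
        plants: list[tuple[TruthRecord, str]] = []
        for idx, hp in enumerate(chosen):
            strand = strand_cycle[idx % 2]
            rep = hairpin_plants[hp][0]
            plants.append((rep, strand))
        genome = plant_hairpins(bg, gid, plants, rng)
        # propagate the locus to every mature living on the planted hairpin
        for hp in chosen:
            rep = hairpin_plants[hp][0]
            locus = rep.loci[-1]
            for t in hairpin_plants[hp][1:]:
                L = len(t.mature_sequence)
                if locus["strand"] == "+":
                    m_start = locus["hairpin_start"] + t.mature_offset
                else:
                    m_start = locus["hairpin_start"] + (
                        len(hp) - t.mature_offset - L
                    )
                t.loci.append({**locus, "start": m_start, "end": m_start + L})
        genomes.append((gid, genome))

    # --- existing annotation on the primary genome.
    known_gff: list[GffFeature] = []
    for tk in known_hairpin_truths:
        locus = next(l for l in tk.loci if l["genome_id"] == genomes[0][0])
        known_gff.append(
            GffFeature(
                seqid=locus["scaffold"],
                type="miRNA_primary_transcript",
                start=locus["hairpin_start"],
                end=locus["hairpin_end"],
                strand=locus["strand"],
                attributes={"ID": tk.hairpin_id, "Name": tk.hairpin_id},
            )
        )

    tables = simulate_counts(
        truths,
        mean=count_mean,
        dispersion=dispersion,
        n_experiments=n_experiments,
        cutoff=cutoff,
        rng=rng,
    )
    return Scenario(
        genomes=genomes,
        catalog_matures=catalog_matures,
        catalog_hairpins=catalog_hairpins,
        known_matures=known_matures,
        known_gff=known_gff,
        tables=tables,
        truths=truths,
        target_prefix=target_prefix,
        cutoff=cutoff,
    )


def write_scenario(scenario: Scenario, outdir: str | Path) -> dict[str, Path]:
    """Write a scenario to disk in the pipeline's input formats."""
    from .io import write_fasta, write_gff3

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    paths["catalog_matures"] = outdir / "catalog_mature.fasta"
    write_fasta(scenario.catalog_matures, paths["catalog_matures"])
    paths["catalog_hairpins"] = outdir / "catalog_hairpin.fasta"
    write_fasta(scenario.catalog_hairpins, paths["catalog_hairpins"])
    paths["known_matures"] = outdir / "known_mature.fasta"
    write_fasta(scenario.known_matures, paths["known_matures"])
    paths["known_gff"] = outdir / "known_precursors.gff3"
    write_gff3(scenario.known_gff, paths["known_gff"])
    for gid, records in scenario.genomes:
        p = outdir / f"{gid}.fasta"
        write_fasta(records, p)
        paths[gid] = p
    for table in scenario.tables:
        p = outdir / f"counts_{table.experiment_id}.tsv"
        with open(p, "w") as fh:
            for seq in sorted(table.rows):
                fh.write(f"{seq}\t{table.rows[seq]}\n")
        paths[table.experiment_id] = p
    paths["truth"] = outdir / "truth.json"
    with open(paths["truth"], "w") as fh:
        json.dump([t.to_dict() for t in scenario.truths], fh, indent=1)
    return paths
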