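"""End-to-end orchestration of the discovery pipeline.

Stage order: collapse the catalog → exclude target-species entries → exact
matching per genome → locus clustering → representative selection by read
count → precursor extraction → folding and stem-loop evaluation → expression
cutoff → arm pairing and reconciliation with known annotation → ledger and
reports.  Per-stage counts are logged at INFO, so a run transcript reads like
the discovery ledger itself.  Reruns on identical inputs produce byte
identical outputs: every collection is explicitly ordered and nothing draws
randomness.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import annotate, catalog, cluster, expression, folding, match, precursor
from .io import (
    CountTable,
    GffFeature,
    SequenceRecord,
    read_count_table,
    read_fasta,
    read_gff3,
    write_fasta,
    write_gff3,
)

__all__ = ["PipelineConfig", "PipelineResult", "CandidateReport", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything a run needs; every judgment threshold is a config key."""

    mature_catalog: Path
    hairpin_catalog: Path
    genomes: list[tuple[str, Path]]
    count_tables: list[tuple[str, Path]]
    out_dir: Path
    known_mature_fasta: Optional[Path] = None
    known_precursor_gff: Optional[Path] = None
    target_prefix: str = "cgr"
    cutoff: int = 5
    strict_cutoff: bool = True
    default_flank: int = 25
    primary_genome: Optional[str] = None
    min_score_density: float = 0.8
    thresholds: folding.HairpinThresholds = field(default_factory=folding.HairpinThresholds)
    prior_mature: Optional[int] = None
    prior_precursors: Optional[int] = None
    count_table_header: bool = False

    def __post_init__(self) -> None:
        self.mature_catalog = Path(self.mature_catalog)
        self.hairpin_catalog = Path(self.hairpin_catalog)
        self.genomes = [(gid, Path(p)) for gid, p in self.genomes]
        self.count_tables = [(eid, Path(p)) for eid, p in self.count_tables]
        self.out_dir = Path(self.out_dir)
        if self.known_mature_fasta:
            self.known_mature_fasta = Path(self.known_mature_fasta)
        if self.known_precursor_gff:
            self.known_precursor_gff = Path(self.known_precursor_gff)
        if self.primary_genome is None and self.genomes:
            self.primary_genome = self.genomes[0][0]
        if self.cutoff < 0:
            raise ValueError("cutoff must be non-negative")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw.update(overrides)
        genomes = [(g["id"], g["path"]) for g in raw.pop("genomes")]
        tables = [(t["id"], t["path"]) for t in raw.pop("count_tables", [])]
        th = raw.pop("thresholds", None)
        kwargs = dict(raw, genomes=genomes, count_tables=tables)
        if th:
            kwargs["thresholds"] = folding.HairpinThresholds(**th)
        return cls(**kwargs)

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        d["thresholds"] = dataclasses.asdict(self.thresholds)

        def conv(v):
            if isinstance(v, Path):
                return str(v)
            if isinstance(v, list):
                return [conv(x) for x in v]
            if isinstance(v, tuple):
                return [conv(x) for x in v]
            if isinstance(v, dict):
                return {k: conv(x) for k, x in v.items()}
            return v

        return {k: conv(v) for k, v in d.items()}


@dataclass
class LocationReport:
    """One genomic location of a candidate in its assigned genome."""

    locus: cluster.CandidateLocus
    cand: precursor.PrecursorCandidate
    fold: folding.FoldResult
    evaluation: folding.HairpinEvaluation


@dataclass
class CandidateReport:
    """Everything the pipeline decided about one candidate miRNA."""

    sequence: str
    display_name: str
    members: list[str]
    genome_occurrence: list[str]
    chosen_genome: str
    locations: list[LocationReport]
    expr: Optional[expression.ExpressionSummary] = None
    hairpin_pass: bool = False
    fail_reasons: list[str] = field(default_factory=list)
    dual_locus: bool = False
    bin: str = ""
    provisional_id: str = ""
    known_match: Optional[annotate.KnownMatch] = None
    paired_with: str = ""

    @property
    def primary(self) -> LocationReport:
        return self.locations[0]

    @property
    def arm(self) -> str:
        return self.primary.evaluation.mature_arm

    @property
    def total_count(self) -> int:
        return self.expr.total if self.expr else 0


@dataclass
class PipelineResult:
    config: PipelineConfig
    ledger: annotate.AnnotationLedger
    candidates: list[CandidateReport]
    occurrence: pd.DataFrame
    merged_into: dict[str, str]
    pairings: list[annotate.ArmPairing]
    out_dir: Path


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)

    # --- catalog ------------------------------------------------------------
    matures = read_fasta(config.mature_catalog)
    hairpins = read_fasta(config.hairpin_catalog)
    kept, excluded, contexts = catalog.prepare_queries(
        matures, hairpins, config.target_prefix, default_flank=config.default_flank
    )
    logger.info("catalog: %d records, %d unique kept, %d excluded (%s)",
                len(matures), len(kept), len(excluded), config.target_prefix)
    _write_audit(kept, excluded, out / "catalog_audit.tsv")

    # --- expression tables (needed early for representative selection) ------
    tables = [
        read_count_table(path, eid, header=config.count_table_header)
        for eid, path in config.count_tables
    ]
    totals = expression.totals_by_sequence([u.sequence for u in kept], tables)

    # --- matching, clustering, extraction per genome ------------------------
    kept_seqs = {u.sequence for u in kept}
    excluded_seqs = {u.sequence for u in excluded}
    aligned_kept: set[str] = set()
    aligned_excluded: set[str] = set()
    hits_by_genome: dict[str, list[match.GenomeHit]] = {}
    locations_by_seq: dict[str, dict[str, list[LocationReport]]] = {}

    for gid, gpath in config.genomes:
        genome = read_fasta(gpath)
        scaffold_by_id = {r.id: r for r in genome}
        hits = match.find_exact_hits(kept + excluded, genome, gid)
        hits_by_genome[gid] = hits
        for h in hits:
            if h.pattern.sequence in excluded_seqs:
                aligned_excluded.add(h.pattern.sequence)
            else:
                aligned_kept.add(h.pattern.sequence)
        _write_hits(hits, out / f"hits_{gid}.tsv")

        kept_hits = [h for h in hits if h.pattern.sequence in kept_seqs]
        loci = cluster.cluster_hits(kept_hits)
        logger.info("%s: %d hits (%d kept), %d loci", gid, len(hits), len(kept_hits), len(loci))
        for locus in loci:
            rep = cluster.select_representative(locus, totals)
            ctx = contexts[rep.sequence]
            rep_hits = sorted(
                (h for h in locus.hits if h.pattern.sequence == rep.sequence),
                key=lambda h: (h.start, h.end),
            )
            hit = rep_hits[0]
            cand = precursor.extract_precursor(scaffold_by_id[hit.scaffold], hit, ctx)
            fr = folding.fold(cand.sequence)
            ev = folding.evaluate_hairpin(
                fr, cand.mature_interval,
                clipped_fraction=cand.clipped_fraction,
                thresholds=config.thresholds,
            )
            locations_by_seq.setdefault(rep.sequence, {}).setdefault(gid, []).append(
                LocationReport(locus=locus, cand=cand, fold=fr, evaluation=ev)
            )

    n_unique_aligned = len(aligned_kept) + len(aligned_excluded)
    logger.info("aligned uniques: %d (%d excluded as %s) -> %d candidates",
                n_unique_aligned, len(aligned_excluded), config.target_prefix,
                len(aligned_kept))

    # --- unify candidates across genomes ------------------------------------
    uniq_by_seq = {u.sequence: u for u in kept}
    genome_order = [gid for gid, _ in config.genomes]
    if config.primary_genome in genome_order:
        genome_order = [config.primary_genome] + [
            g for g in genome_order if g != config.primary_genome
        ]
    candidates: list[CandidateReport] = []
    for seq in sorted(locations_by_seq, key=lambda s: uniq_by_seq[s].display_name):
        per_genome = locations_by_seq[seq]
        chosen = next(g for g in genome_order if g in per_genome)
        locs = sorted(
            per_genome[chosen], key=lambda lr: (lr.locus.scaffold, lr.locus.start)
        )
        candidates.append(
            CandidateReport(
                sequence=seq,
                display_name=uniq_by_seq[seq].display_name,
                members=[m.full for m in uniq_by_seq[seq].members],
                genome_occurrence=sorted(per_genome),
                chosen_genome=chosen,
                locations=locs,
            )
        )
    # sequences that aligned but were absorbed into another representative's locus
    merged_into: dict[str, str] = {}
    rep_seqs = set(locations_by_seq)
    for seq in sorted(aligned_kept - rep_seqs):
        # find the representative whose locus contains this sequence
        owner = ""
        for gid in genome_order:
            for h in hits_by_genome.get(gid, []):
                if h.pattern.sequence != seq:
                    continue
                for cand in candidates:
                    for lr in cand.locations:
                        if (
                            lr.locus.genome_id == h.genome_id
                            and lr.locus.scaffold == h.scaffold
                            and lr.locus.strand == h.strand
                            and lr.locus.start <= h.start < lr.locus.end
                        ):
                            owner = cand.display_name
                            break
                    if owner:
                        break
                if owner:
                    break
            if owner:
                break
        merged_into[seq] = owner
    n_locus_clusters = len(candidates)
    logger.info("locus clustering: %d candidate miRNAs", n_locus_clusters)

    # --- folding screen + expression ----------------------------------------
    n_hairpin_pass = 0
    n_expressed = 0
    for cand in candidates:
        ev = cand.primary.evaluation
        fr = cand.primary.fold
        reasons = list(ev.fail_reasons)
        if fr.score_density < config.min_score_density:
            reasons.append(
                f"score_density={fr.score_density:.2f} < {config.min_score_density}"
            )
        cand.hairpin_pass = not reasons
        cand.fail_reasons = reasons
        cand.expr = expression.summarize_expression(
            cand.sequence, tables, cutoff=config.cutoff, strict=config.strict_cutoff
        )
        if cand.hairpin_pass:
            n_hairpin_pass += 1
            if cand.expr.expressed:
                n_expressed += 1
    logger.info("stem-loop screen: %d/%d pass; expressed (> %d reads): %d",
                n_hairpin_pass, n_locus_clusters, config.cutoff, n_expressed)

    # --- dual loci, arm pairing, known annotation ---------------------------
    expressed = [c for c in candidates if c.hairpin_pass and c.expr.expressed]
    n_dual_extra = 0
    arm_inputs: list[annotate.ArmCandidate] = []
    arm_owner: dict[str, CandidateReport] = {}
    for cand in expressed:
        distinct: list[LocationReport] = []
        seen_hp: set[str] = set()
        for lr in cand.locations:
            if lr.cand.sequence not in seen_hp:
                seen_hp.add(lr.cand.sequence)
                distinct.append(lr)
        cand.dual_locus = len(distinct) > 1
        n_dual_extra += len(distinct) - 1
        for idx, lr in enumerate(distinct):
            aid = f"{cand.display_name}@{idx}"
            arm_owner[aid] = cand
            arm_inputs.append(
                annotate.ArmCandidate(
                    candidate_id=aid,
                    scaffold=lr.locus.scaffold,
                    strand=lr.locus.strand,
                    span=(lr.cand.genomic_start, lr.cand.genomic_end),
                    arm=lr.evaluation.mature_arm,
                    total_count=cand.total_count,
                )
            )
    pairings = annotate.pair_arms(arm_inputs)
    n_arm_pairs = sum(1 for p in pairings if p.is_pair)
    for p in pairings:
        if p.is_pair:
            five = arm_owner[p.five_p.candidate_id]
            three = arm_owner[p.three_p.candidate_id]
            five.paired_with = three.display_name
            three.paired_with = five.display_name

    known_precursors: list[tuple[str, str, str, int, int]] = []
    if config.known_precursor_gff:
        for f in read_gff3(config.known_precursor_gff):
            if f.type == "miRNA_primary_transcript":
                known_precursors.append(
                    (f.attributes.get("ID", f.seqid), f.seqid, f.strand, f.start, f.end)
                )
    known_mature_rows: list[tuple[str, str, str]] = []
    if config.known_mature_fasta:
        for rec in read_fasta(config.known_mature_fasta):
            mid = catalog.parse_mirna_id(rec.id)
            known_mature_rows.append((rec.id, mid.arm, rec.sequence))

    n_on_known = 0
    for cand in expressed:
        km = None
        if known_precursors and cand.chosen_genome == config.primary_genome:
            lr = cand.primary
            km = annotate.match_known(
                cand.display_name,
                lr.locus.scaffold,
                lr.locus.strand,
                (lr.cand.hit.start, lr.cand.hit.end),
                known_precursors,
            )
        if km is None and known_mature_rows:
            km = annotate.match_known_by_sequence(
                cand.display_name, cand.primary.cand.sequence, cand.arm,
                known_mature_rows,
            )
        if km is not None:
            cand.known_match = km
            n_on_known += 1
    logger.info("locations: %d (+%d dual); arm pairs: %d; on known hairpins: %d",
                n_expressed + n_dual_extra, n_dual_extra, n_arm_pairs, n_on_known)

    # --- bins ---------------------------------------------------------------
    for cand in candidates:
        if not cand.hairpin_pass:
            cand.bin = "no_hairpin"
        elif not cand.expr.expressed:
            cand.bin = "conserved_not_expressed"
        elif cand.known_match is not None:
            cand.bin = "on_known_hairpin"
        else:
            cand.bin = "expressed_novel"

    # --- provisional ids, ordered by descending total read count ------------
    for n, cand in enumerate(
        sorted(expressed, key=lambda c: (-c.total_count, c.display_name)), start=1
    ):
        arm_suffix = cand.arm if cand.arm in ("5p", "3p") else "x"
        cand.provisional_id = f"{config.target_prefix}-can-{n}-{arm_suffix}"

    # --- ledger -------------------------------------------------------------
    prior_mature = config.prior_mature
    if prior_mature is None:
        prior_mature = len(known_mature_rows)
    prior_precursors = config.prior_precursors
    if prior_precursors is None:
        prior_precursors = len(known_precursors)
    ledger = annotate.compute_ledger(
        n_unique_aligned=n_unique_aligned,
        n_annotated_excluded=len(aligned_excluded),
        n_hairpin_pass=n_hairpin_pass,
        n_expressed=n_expressed,
        n_dual_locus=n_dual_extra,
        n_arm_pairs=n_arm_pairs,
        n_on_known_hairpin=n_on_known,
        prior_mature=prior_mature,
        prior_precursors=prior_precursors,
        n_locus_clusters=n_locus_clusters,
    )

    occurrence = match.occurrence_matrix(kept + excluded, hits_by_genome)
    occurrence = occurrence.loc[occurrence.any(axis=1)]

    result = PipelineResult(
        config=config,
        ledger=ledger,
        candidates=candidates,
        occurrence=occurrence,
        merged_into=merged_into,
        pairings=pairings,
        out_dir=out,
    )
    _write_outputs(result, tables)
    return result


# --- writers ----------------------------------------------------------------


def _write_audit(kept, excluded, path: Path) -> None:
    rows = []
    for u, flag in [(u, False) for u in kept] + [(u, True) for u in excluded]:
        rows.append(
            {
                "sequence": u.sequence,
                "members": ",".join(m.full for m in u.members),
                "excluded": flag,
            }
        )
    pd.DataFrame(rows).sort_values(["excluded", "sequence"]).to_csv(
        path, sep="\t", index=False
    )


def _write_hits(hits, path: Path) -> None:
    rows = [
        {
            "pattern": h.pattern.display_name,
            "genome": h.genome_id,
            "scaffold": h.scaffold,
            "start": h.start,
            "end": h.end,
            "strand": h.strand,
            "palindromic": h.palindromic,
        }
        for h in hits
    ]
    pd.DataFrame(
        rows, columns=["pattern", "genome", "scaffold", "start", "end", "strand", "palindromic"]
    ).to_csv(path, sep="\t", index=False)


def _write_outputs(result: PipelineResult, tables: list[CountTable]) -> None:
    out = result.out_dir
    cfg = result.config
    candidates = result.candidates

    loci_rows = []
    for cand in candidates:
        for lr in cand.locations:
            loci_rows.append(
                {
                    "candidate": cand.display_name,
                    "genome": lr.locus.genome_id,
                    "scaffold": lr.locus.scaffold,
                    "start": lr.locus.start,
                    "end": lr.locus.end,
                    "strand": lr.locus.strand,
                    "n_hits": len(lr.locus.hits),
                    "representative": cand.sequence,
                }
            )
    pd.DataFrame(
        loci_rows,
        columns=["candidate", "genome", "scaffold", "start", "end", "strand",
                 "n_hits", "representative"],
    ).to_csv(out / "loci.tsv", sep="\t", index=False)

    write_fasta(
        [
            SequenceRecord(
                id=f"{cand.display_name}_{lr.locus.genome_id}_{lr.locus.scaffold}_{lr.cand.genomic_start}",
                sequence=lr.cand.sequence,
            )
            for cand in candidates
            for lr in cand.locations
        ],
        out / "precursor_candidates.fasta",
    )

    struct_rows = []
    for cand in candidates:
        lr = cand.primary
        struct_rows.append(
            {
                "candidate": cand.display_name,
                "sequence": lr.cand.sequence,
                "dotbracket": lr.fold.dotbracket,
                "pair_score": lr.fold.pair_score,
                "score_density": round(lr.fold.score_density, 4),
                "n_terminal_loops": lr.evaluation.n_terminal_loops,
                "paired_fraction": round(lr.evaluation.paired_fraction, 4),
                "mature_paired_fraction": round(lr.evaluation.mature_paired_fraction, 4),
                "max_interior_unpaired_run": lr.evaluation.max_interior_unpaired_run,
                "mature_arm": lr.evaluation.mature_arm,
                "clipped": lr.cand.clipped,
                "passes": cand.hairpin_pass,
                "fail_reasons": ";".join(cand.fail_reasons),
            }
        )
    pd.DataFrame(struct_rows).to_csv(out / "structures.tsv", sep="\t", index=False)
    _write_html_report(struct_rows, out / "report.html")

    expr_rows = []
    for cand in candidates:
        row = {"candidate": cand.display_name, "sequence": cand.sequence}
        for t in tables:
            row[t.experiment_id] = cand.expr.per_experiment.get(t.experiment_id, 0)
        row["total"] = cand.total_count
        row["expressed"] = cand.expr.expressed
        expr_rows.append(row)
    pd.DataFrame(expr_rows).to_csv(out / "expression.tsv", sep="\t", index=False)

    result.occurrence.to_csv(out / "occurrence.tsv", sep="\t")

    expressed = [c for c in candidates if c.bin in ("expressed_novel", "on_known_hairpin")]
    write_fasta(
        [
            SequenceRecord(id=c.provisional_id, sequence=c.sequence,
                           description=c.display_name)
            for c in sorted(expressed, key=lambda c: c.provisional_id)
        ],
        out / "novel_mature.fasta",
    )
    write_fasta(
        [
            SequenceRecord(
                id=f"{c.provisional_id}_hairpin", sequence=c.primary.cand.sequence
            )
            for c in sorted(expressed, key=lambda c: c.provisional_id)
        ],
        out / "novel_hairpins.fasta",
    )

    features: list[GffFeature] = []
    for c in expressed:
        for idx, lr in enumerate(c.locations):
            pid = f"{c.provisional_id}.pre.{idx}"
            features.append(
                GffFeature(
                    seqid=lr.locus.scaffold,
                    type="miRNA_primary_transcript",
                    start=lr.cand.genomic_start,
                    end=lr.cand.genomic_end,
                    strand=lr.locus.strand,
                    attributes={"ID": pid, "Name": pid, "genome": c.chosen_genome},
                )
            )
            features.append(
                GffFeature(
                    seqid=lr.locus.scaffold,
                    type="miRNA",
                    start=lr.cand.hit.start,
                    end=lr.cand.hit.end,
                    strand=lr.locus.strand,
                    attributes={
                        "ID": f"{c.provisional_id}.{idx}",
                        "Name": c.provisional_id,
                        "Parent": pid,
                        "conserved_from": c.display_name,
                    },
                )
            )
    write_gff3(features, out / "annotation.gff3")

    master_rows = []
    for cand in candidates:
        lr = cand.primary
        master_rows.append(
            {
                "candidate": cand.display_name,
                "provisional_id": cand.provisional_id,
                "sequence": cand.sequence,
                "members": ",".join(cand.members),
                "genomes": ",".join(cand.genome_occurrence),
                "chosen_genome": cand.chosen_genome,
                "scaffold": lr.locus.scaffold,
                "strand": lr.locus.strand,
                "locus_start": lr.locus.start,
                "locus_end": lr.locus.end,
                "arm": cand.arm,
                "total_count": cand.total_count,
                "hairpin_pass": cand.hairpin_pass,
                "expressed": bool(cand.expr and cand.expr.expressed),
                "dual_locus": cand.dual_locus,
                "on_hairpin_with": (
                    cand.known_match.known_precursor_id
                    if cand.known_match
                    else cand.paired_with
                ),
                "bin": cand.bin,
            }
        )
    pd.DataFrame(master_rows).to_csv(out / "master_table.tsv", sep="\t", index=False)

    with open(out / "ledger.json", "w") as fh:
        json.dump(result.ledger.to_dict(), fh, indent=1, sort_keys=True)
    ledger_df = pd.DataFrame(
        sorted(result.ledger.to_dict().items()), columns=["quantity", "value"]
    )
    ledger_df.to_csv(out / "ledger.tsv", sep="\t", index=False)

    inputs = [cfg.mature_catalog, cfg.hairpin_catalog]
    inputs += [p for _, p in cfg.genomes] + [p for _, p in cfg.count_tables]
    if cfg.known_mature_fasta:
        inputs.append(cfg.known_mature_fasta)
    if cfg.known_precursor_gff:
        inputs.append(cfg.known_precursor_gff)
    manifest = {
        "config": cfg.to_jsonable(),
        "config_sha256": hashlib.sha256(
            json.dumps(cfg.to_jsonable(), sort_keys=True).encode()
        ).hexdigest(),
        "inputs": {str(p): _sha256(p) for p in sorted(inputs, key=str)},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)


def _write_html_report(struct_rows: list[dict], path: Path) -> None:
    """Minimal per-candidate structure report for eyeball review."""
    parts = [
        "<html><head><title>candidate stem-loops</title></head><body>",
        "<h1>Candidate stem-loop report</h1>",
    ]
    for row in struct_rows:
        parts.append(
            "<div><h3>{candidate}</h3><pre>{sequence}\n{dotbracket}</pre>"
            "<p>score {pair_score} (density {score_density}), "
            "loops {n_terminal_loops}, paired {paired_fraction}, "
            "mature paired {mature_paired_fraction}, arm {mature_arm}, "
            "passes: {passes} {fail_reasons}</p></div>".format(**row)
        )
    parts.append("</body></html>")
    path.write_text("\n".join(parts))
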