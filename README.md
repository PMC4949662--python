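# mirhunt

Homology-based discovery of conserved microRNAs in draft genome assemblies.

Many species — the Chinese hamster (*Cricetulus griseus*) and its CHO
production cell lines are the motivating case — have sparse miRNA
annotation even though multiple genome assemblies exist. Because mature
miRNAs are among the most strongly conserved sequences in animal genomes,
a fast and surprisingly productive way to extend a species' miRNome is to
take every mature miRNA annotated in *any* species, look for exact copies
in the target assemblies, and keep the hits that behave like real miRNAs:
they fold into a clean pre-miRNA stem-loop and they show up in small-RNA
sequencing reads. `mirhunt` implements that discovery pipeline end to end,
for users who work with draft assemblies and collapsed small-RNA-seq read
tables and want standard GFF3/FASTA annotation out the other side.

## The pipeline

1. **Collapse** the multi-species mature catalog to unique sequences and
   **exclude** any sequence already annotated in the target species.
2. **Match** each query exactly against every assembly, both strands
   (exact identity is the operational definition of conservation here).
3. **Cluster** overlapping hits on each scaffold/strand into candidate
   loci — shifted, length-varying homologs from many species are one
   candidate, not many — and keep the member with the highest summed read
   count as the **representative**.
4. **Extract** the putative precursor around each hit, reusing the flank
   lengths of the originating species' hairpin (conservation of the mature
   is assumed to extend to its precursor).
5. **Fold** each precursor by weighted base-pair maximization
   (Nussinov-style dynamic programming, GC=3 / AU=2 / GU=1, minimum loop
   3 nt) and **screen** it for stem-loop quality: exactly one terminal
   loop, paired fraction ≥ 0.5, mature ≥ 60 % paired and on one arm of the
   stem, no interior loop/bulge longer than 10 nt, pair-score density
   ≥ 0.8.
6. **Expression filter**: sum exact-match read counts over all
   experiments; a candidate is expressed when the total exceeds the cutoff
   (default: more than 5 reads).
7. **Annotate**: pair 5p/3p candidates sharing a precursor span, flag
   candidates sitting on already annotated precursors, detect dual-locus
   miRNAs, and emit GFF3 + FASTA plus the stage-by-stage **discovery
   ledger**, whose identities tie every count together:

   ```
   candidates        = aligned uniques − already annotated
   not expressed     = hairpin-positive − expressed
   locations         = expressed + dual-locus extras
   distinct hairpins = locations − arm pairs
   novel hairpins    = distinct hairpins − on-known-hairpin
   new totals        = priors + novel  (with % growth over priors)
   ```

A synthetic-data module (`mirhunt.synthetic`) generates genomes with
planted conserved hairpins, fabricated multi-species catalogs and
negative-binomial read tables with full ground truth, so the whole
pipeline is testable without downloading genomes or miRBase.

## Worked example

Generate a synthetic study and run the pipeline on it:

```sh
mirhunt simulate --seed 3 --out sim
# write a config pointing at the generated files, then:
mirhunt -v run --config sim_config.yaml
```

The `run` command prints the discovery ledger; with seed 3 (20 planted
conserved matures, 12 expressed, 2 arm pairs, 1 new arm on a known
precursor, 3 already-annotated hairpins):

```json
{
 "n_unique_aligned": 23,
 "n_annotated_excluded": 3,
 "n_candidates": 20,
 "n_locus_clusters": 20,
 "n_hairpin_pass": 20,
 "n_expressed": 12,
 "n_not_expressed": 8,
 "n_arm_pairs": 2,
 "n_on_known_hairpin": 1,
 "n_novel_precursors": 9,
 "total_mature": 15,
 "total_precursors": 12,
 "pct_mature_increase": 400.0,
 "pct_precursor_increase": 300.0
}
```

Read: 23 unique catalog sequences matched the assemblies, 3 were already
annotated in the target species, all 20 remaining candidates folded into
acceptable stem-loops, 12 were expressed above the read cutoff, and after
merging the 2 5p/3p pairs and the 1 candidate on a known precursor, 9
novel precursors remain — growing the synthetic miRNome from 3 to 15
matures and from 3 to 12 precursors. The output directory contains the
full artifacts: `annotation.gff3`, `novel_mature.fasta`,
`novel_hairpins.fasta`, `structures.tsv` (+ `report.html`),
`expression.tsv`, `occurrence.tsv` (the per-assembly presence matrix),
`master_table.tsv` and `ledger.json`.

The library surface mirrors the stages — `collapse_unique`,
`find_exact_hits`, `cluster_hits`, `extract_precursor`, `fold`,
`evaluate_hairpin`, `summarize_expression`, `pair_arms`, `compute_ledger`,
`run_pipeline` — see `docs/methods.md` for the model and every tunable
threshold.

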