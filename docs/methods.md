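# Methods

This note documents the model behind each pipeline stage, the tunable
parameters with their defaults and rationale, what the synthetic generator
does and does not emulate, and the numerical/design choices made where the
problem was genuinely open.

## Conservation model and exact matching

The discovery model treats exact sequence identity of a foreign mature
miRNA within the target genome as the operational definition of
evolutionary conservation. This is deliberately strict: it recovers only
deeply conserved miRNAs, trades sensitivity for a near-zero false-match
rate, and makes every downstream count interpretable. Matching is
performed by a seed dictionary over the query set (15-nt seed, full-string
verification), streaming the genome scaffold by scaffold; both strands are
searched and a `-` strand hit is reported in forward coordinates, so the
forward slice reverse-complements to the query. All occurrences are
reported, including overlaps; matches never cross scaffold boundaries, and
windows containing `N` can never equal an N-free query. Palindromic
queries (equal to their own reverse complement) would report one location
twice; they are collapsed to a single `+` hit carrying a `palindromic`
flag. Queries are restricted to 15–30 nt without `N`; catalog records
outside that envelope are dropped with a warning, since exact matching
cannot use ambiguous queries and sequences outside the mature length range
are not plausible miRNAs.

## Locus clustering and representatives

Hits on the same scaffold and strand are merged into a candidate locus
when connected by a chain of interval overlaps of at least one base
(half-open touching is not overlap). Opposite strands never merge: sense
and antisense products are distinct transcripts. The criterion in the
underlying manual procedure — homologs "differ in length and/or are
shifted" — is not quantified anywhere, so single-base overlap connectivity
is used as the weakest defensible rule; it cannot split a genuine stack of
homologs, and spurious chains are practically impossible at mature-miRNA
densities. The locus representative is the member with the highest summed
read count across experiments, with deterministic tie-breaks (longer
sequence, then lexicographically smaller) so fully unexpressed loci are
still reproducible. Clustering is per genome; a candidate found in several
assemblies is unified afterwards by representative sequence identity, with
per-assembly presence tracked in the occurrence matrix. A candidate whose
representative sits in two loci of the primary assembly with *different*
extracted hairpin sequences is a dual-locus miRNA: it contributes an extra
genomic location, not an extra mature sequence.

## Precursor extraction

Flank lengths are taken from the originating species' hairpin — the
assumption being that a conserved mature implies a conserved precursor.
The originating hairpin is located by miRBase naming (strip the arm
suffix, lowercase `miR`; multi-copy precursors matched by id prefix in
lexicographic order, first hairpin containing the mature wins). When one
unique sequence has members in several species with different flank
geometries, the member with the longest total precursor is used: a longer
context cannot truncate the real hairpin, and one length is used for all
of that candidate's loci. When no context can be found at all, symmetric
25-nt flanks are used (`default_flank`). Extraction is strand-aware and
always returns the transcript-oriented sequence with `upstream_len` bases
before the mature; on the `-` strand the genomic window mirrors the flanks
before reverse-complementing. Windows truncated by scaffold edges — a
routine event in draft assemblies with 10^5–10^7 scaffolds — are flagged
`clipped` and fail classification when more than 20 % of the intended
precursor was lost (`max_clipped_fraction = 0.2`).

## Folding and the stem-loop screen

Precursors are folded by weighted base-pair maximization: a Nussinov-style
dynamic program over pseudoknot-free structures with pair weights GC = 3,
AU = 2, GU = 1, a minimum hairpin loop of 3 nt (steric minimum), and `N`
never pairing. The traceback is deterministic — on score ties, pairing the
interval ends beats bifurcating, and among bifurcations the smallest split
point wins — so identical inputs always give identical structures. The
weights order pairs by thermodynamic stability without a full energy
model; what drives the pipeline is not an absolute energy but the shape of
the structure, which is quantified from the dot-bracket string alone:

| parameter | default | meaning |
|---|---|---|
| `n_terminal_loops` | must equal 1 | the stem-loop motif |
| `min_paired_fraction` | 0.5 | overall stem quality |
| `min_mature_paired_fraction` | 0.6 | mature located in the stem |
| `max_interior_unpaired_run` | 10 nt | no large interior loops or bulges |
| mature arm | must not span the loop | Drosha/Dicer geometry |
| `max_clipped_fraction` | 0.2 | scaffold-edge truncation |
| `min_score_density` | 0.8 per nt | proxy for low folding free energy |

These thresholds are this package's quantification of what a curator
checks when judging a pre-miRNA plot by eye; they were calibrated on the
synthetic positives (planted hairpins with up to two stem mismatches must
pass) and negatives (dinucleotide-shuffled versions must mostly fail) and
are all exposed in the run configuration and recorded in output metadata.
The score-density check is applied at the classification stage, not inside
the structure evaluator, so that two candidates with identical dot-bracket
structures always receive identical structural evaluations regardless of
base composition. An adapter to an external MFE folder with the same
dot-bracket contract (`folding.fold_external`) is provided for users who
prefer thermodynamic structures; the default pipeline never calls it.

## Expression evidence

Read counts are summed per candidate across all experiments — raw sums,
no depth normalization — because the evidence question is existential
(is this mature present in any condition?), not comparative. Only reads
exactly identical to the candidate mature count; an optional isomiR
window is deliberately absent from the default path since the upstream
catalogs and read tables are themselves exact-sequence collapsed. The
expressed flag requires `total > cutoff` with `cutoff = 5`: the strict
reading of "more than five reads". The boundary is genuinely ambiguous in
the field's usage, so both the cutoff and the strictness are config keys
(`cutoff`, `strict_cutoff`). The low-expression summary statistic
(`fraction_below_median`) compares novel totals against the lower median
of the already-annotated set, strictly below.

## Arm pairing and reconciliation

Two expressed candidates merge onto one hairpin when their precursor
spans overlap reciprocally by at least 50 % on the same scaffold and
strand and their arms are one 5p and one 3p (arm labels come from the
folded structure, not the catalog name). Reciprocal overlap is robust to
flank-length differences between the two candidates' originating species;
no published criterion exists for this step. When more than two
candidates crowd one span, the best-expressed eligible pair wins and the
rest remain singletons, so pairs plus singletons always account for every
location. A candidate lying inside an already annotated precursor
(coordinate containment preferred, single-base overlap recorded as the
weaker relation) complements the known hairpin's other arm instead of
adding a novel precursor; when known precursors exist only as sequences,
a fallback checks whether the candidate's precursor contains a known
mature of the complementary arm. Novel candidates receive provisional ids
`<prefix>-can-<n>-<arm>` ordered by descending total read count.

## The discovery ledger

Every run ends in a ledger whose derived quantities follow fixed
arithmetic identities (see the README); `compute_ledger` validates its
inputs and raises naming the violated identity rather than emitting an
inconsistent report. Percentages are rounded half-up to one decimal.
Logging at INFO level prints each stage count as it is established, so a
verbose run transcript reads as the ledger.

## Synthetic data: what it emulates, what it does not

The generator emulates the *structure* of a real study: draft assemblies
(i.i.d. background at configurable GC, default 0.42 for a mammalian
genome), planted conserved hairpins on both strands, a multi-species
catalog naming each planted mature under 1–4 fabricated species prefixes
with matching hairpin entries, decoy catalog entries absent from every
assembly, an existing target-species annotation (mature FASTA + precursor
GFF3), and collapsed read tables with negative-binomial counts
(per-experiment mean 100, dispersion 1, 4 experiments — dispersed counts
typical of small-RNA libraries; already-annotated matures draw at mean
1000) plus low-count random background reads. Planted hairpins are built
as `flank + mature + loop + star + revcomp(flank)`: the star arm is the
reverse complement of the mature carrying the configured number of stem
mismatches (the reference study conditions use 2), the complementary
flanks form the lower stem below the Drosha site as in real pri-miRNAs,
and the loop is drawn from `{A, C}` so it cannot self-pair — with zero
mismatches the construct provably folds to a single terminal loop with
the mature fully paired. Mature sequences are rejection-sampled until the
finished construct passes the package's own stem-loop screen, so planted
positives are clean by construction rather than by tuning.

The reference scenario (`make_scenario`) plants 20 foreign conserved
matures — two full 5p/3p pairs, one new arm on an annotated precursor,
seven further expressed singletons, eight unexpressed singletons — plus
three annotated target-species hairpins, across two assemblies of
4 × 50 kb scaffolds; expressed hairpins occur in both assemblies,
unexpressed ones in one or both, exercising the occurrence matrix. These
problem sizes keep a full run around a second while touching every
pipeline branch.

What the generator does **not** emulate: repeats and segmental
duplications (the main source of multi-mapping ambiguity in real
assemblies), sequencing error and adapter artifacts (inputs are already
collapsed), isomiR heterogeneity, clustered miRNA polycistrons, and
realistic base composition beyond global GC. Passing the planted-recovery
suite therefore demonstrates that the machinery is correct — every
planted miRNA is found, binned and annotated exactly — not that the
thresholds are optimal for any particular real genome; on real data the
stem-loop screen's selectivity depends on assembly quality and catalog
breadth in ways no simulation of this kind can certify.

## Degenerate inputs and numerical conventions

All internal coordinates are 0-based half-open; conversion to GFF3's
1-based inclusive convention happens only in the writer, and the reader
inverts it. RNA `U` is normalized to DNA `T` on every input path.
Duplicate count-table rows are summed; zero-count rows are retained and
contribute nothing. Empty FASTA files are format errors; absent hairpin
contexts, unexpressed candidates and disjoint known annotations are
values, not errors. Sequences shorter than 10 nt are rejected by the
folder. Reruns on identical inputs are byte-identical: every collection
is explicitly ordered and the pipeline draws no randomness.

## Known limitations

Exact matching cannot find miRNAs with any target-species substitution —
by design, the method misses everything non-conserved or imperfectly
conserved. Pair-weight maximization over-pairs relative to thermodynamic
folding, so the structural thresholds are calibrated for this scorer and
should be re-calibrated if the external MFE backend is substituted.
Cross-assembly unification is by exact representative identity, not
synteny; a mature conserved with one substitution between assemblies
would appear as two candidates. Arm pairing assumes both arms were
assigned to the same (primary) assembly.
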