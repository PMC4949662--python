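"""Exact multi-pattern matching of mature miRNA queries against genome scaffolds.

Exact occurrence of a foreign mature sequence in the target genome is the
operational definition of evolutionary conservation here.  Both strands are
searched; a ``-`` strand hit is reported in forward-strand coordinates, so the
forward slice of the scaffold reverse-complements to the query.

The scan uses a seed dictionary: every query is keyed by its first 15 bases
(queries are 15–30 nt), the genome is swept once per scaffold and each seed
hit is verified against the full query.  Scaffolds are streamed one at a
time; the index lives over the (small) pattern set, never over the genome.
Windows containing ``N`` can never equal an N-free query, so ambiguity in the
assembly is handled for free.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .catalog import UniqueMature
from .io import SequenceRecord, reverse_complement

__all__ = ["GenomeHit", "find_exact_hits", "occurrence_matrix"]

SEED_LEN = 15


@dataclass(frozen=True)
class GenomeHit:
    """One exact occurrence of a query in a genome, forward-strand coordinates."""

    pattern: UniqueMature
    genome_id: str
    scaffold: str
    start: int
    end: int
    strand: str
    palindromic: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start


def _build_seed_index(
    patterns: Sequence[UniqueMature],
) -> dict[str, list[tuple[str, UniqueMature, str, bool]]]:
    """Map 15-nt seeds to (full sequence to verify, pattern, strand, palindromic)."""
    index: dict[str, list[tuple[str, UniqueMature, str, bool]]] = {}
    for pat in patterns:
        seq = pat.sequence
        if len(seq) < SEED_LEN:
            raise ValueError(
                f"pattern {pat.display_name} is {len(seq)} nt; minimum is {SEED_LEN}"
            )
        if "N" in seq:
            raise ValueError(f"pattern {pat.display_name} contains N")
        rc = reverse_complement(seq)
        if seq == rc:
            # Palindrome: one location would otherwise be reported on both
            # strands; keep the + strand hit and flag it.
            index.setdefault(seq[:SEED_LEN], []).append((seq, pat, "+", True))
        else:
            index.setdefault(seq[:SEED_LEN], []).append((seq, pat, "+", False))
            index.setdefault(rc[:SEED_LEN], []).append((rc, pat, "-", False))
    return index


def find_exact_hits(
    patterns: Sequence[UniqueMature],
    genome: Iterable[SequenceRecord],
    genome_id: str,
) -> list[GenomeHit]:
    """Report every exact occurrence of every pattern on both strands.

    Overlapping and repeated occurrences are all reported; matches never span
    scaffold boundaries.  Output order is (scaffold, start, strand, pattern
    display name).
    """
    index = _build_seed_index(patterns)
    hits: list[GenomeHit] = []
    for scaffold in genome:
        seq = scaffold.sequence
        n = len(seq)
        for i in range(n - SEED_LEN + 1):
            bucket = index.get(seq[i : i + SEED_LEN])
            if bucket is None:
                continue
            for probe, pat, strand, palin in bucket:
                if seq.startswith(probe, i):
                    hits.append(
                        GenomeHit(
                            pattern=pat,
                            genome_id=genome_id,
                            scaffold=scaffold.id,
                            start=i,
                            end=i + len(probe),
                            strand=strand,
                            palindromic=palin,
                        )
                    )
    hits.sort(key=lambda h: (h.scaffold, h.start, h.strand, h.pattern.display_name))
    return hits


def occurrence_matrix(
    patterns: Sequence[UniqueMature],
    hits_by_genome: Mapping[str, Sequence[GenomeHit]],
) -> pd.DataFrame:
    """Boolean pattern × genome presence matrix (the Venn-diagram substrate).

    A row of all ``False`` marks a query absent from every assembly; such
    queries are dropped from candidacy by the pipeline.
    """
    genome_ids = list(hits_by_genome)
    data = {
        gid: {pat.display_name: False for pat in patterns} for gid in genome_ids
    }
    for gid, hits in hits_by_genome.items():
        for hit in hits:
            data[gid][hit.pattern.display_name] = True
    frame = pd.DataFrame(data, columns=genome_ids)
    frame.index.name = "pattern"
    return frame
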