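"""Cluster genome hits into candidate loci.

Matures from many species typically land on the same genomic location in
slightly shifted, length-varying copies; each such stack is one possible new
miRNA, not many.  Hits on the same scaffold and strand are merged into a
locus when connected by a chain of ≥1 nt interval overlaps (half-open touch
is not overlap), and the member with the highest summed read count becomes
the locus representative — the sequence that is actually carried forward as
the annotation candidate.  ``+`` and ``-`` hits never merge: sense and
antisense products are distinct.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .catalog import UniqueMature
from .match import GenomeHit

__all__ = ["CandidateLocus", "cluster_hits", "select_representative"]


@dataclass
class CandidateLocus:
    """A maximal overlap-connected stack of hits on one scaffold and strand."""

    genome_id: str
    scaffold: str
    strand: str
    start: int
    end: int
    hits: list[GenomeHit] = field(default_factory=list)
    representative: UniqueMature | None = None

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)

    def patterns(self) -> list[UniqueMature]:
        """Distinct member patterns, deterministic order."""
        seen: dict[str, UniqueMature] = {}
        for hit in self.hits:
            seen.setdefault(hit.pattern.sequence, hit.pattern)
        return sorted(seen.values(), key=lambda p: p.display_name)


def cluster_hits(hits: Sequence[GenomeHit]) -> list[CandidateLocus]:
    """Merge hits into loci by transitive interval overlap.

    Two hits share a locus iff they are connected by a chain of intervals
    overlapping in at least one base on the same genome, scaffold and strand.
    Every hit lands in exactly one locus; loci on one scaffold+strand are
    pairwise non-overlapping.  For sorted intervals this is a single sweep:
    a new hit extends the open locus iff it starts before the locus end.
    """
    groups: dict[tuple[str, str, str], list[GenomeHit]] = {}
    for hit in hits:
        groups.setdefault((hit.genome_id, hit.scaffold, hit.strand), []).append(hit)

    loci: list[CandidateLocus] = []
    for (genome_id, scaffold, strand), members in sorted(groups.items()):
        members.sort(key=lambda h: (h.start, h.end, h.pattern.display_name))
        current: CandidateLocus | None = None
        for hit in members:
            if current is not None and hit.start < current.end:
                current.hits.append(hit)
                current.end = max(current.end, hit.end)
            else:
                current = CandidateLocus(
                    genome_id=genome_id,
                    scaffold=scaffold,
                    strand=strand,
                    start=hit.start,
                    end=hit.end,
                    hits=[hit],
                )
                loci.append(current)
    loci.sort(key=lambda l: (l.genome_id, l.scaffold, l.start, l.strand))
    return loci


def select_representative(
    locus: CandidateLocus, totals: Mapping[str, int]
) -> UniqueMature:
    """Pick the locus member with the highest summed read count.

    *totals* maps mature sequence to its summed count over all experiments
    (absent means 0).  Ties are broken toward the longer sequence, then the
    lexicographically smaller one, so the choice is deterministic even in the
    fully unexpressed case.  The chosen pattern is stored on the locus.
    """
    best = min(
        locus.patterns(),
        key=lambda p: (-totals.get(p.sequence, 0), -len(p.sequence), p.sequence),
    )
    locus.representative = best
    return best
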