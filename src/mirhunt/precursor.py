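"""Extract putative pre-miRNA sequences around genome hits.

The flank lengths come from the originating species' precursor (conservation
of the mature is assumed to extend to its hairpin), so the candidate precursor
has exactly the geometry of the known one.  Extraction is strand-aware: the
returned sequence is always 5'→3' in transcript orientation, with
``upstream_len`` bases preceding the mature.  Hits too close to a scaffold
edge are truncated and flagged ``clipped``; draft assemblies with millions of
short scaffolds make this a routine, not exceptional, case.
"""

from __future__ import annotations

from dataclasses import dataclass

from .catalog import HairpinContext
from .io import SequenceRecord, reverse_complement
from .match import GenomeHit

__all__ = ["PrecursorCandidate", "extract_precursor"]


@dataclass
class PrecursorCandidate:
    """An extracted candidate hairpin in transcript orientation."""

    hit: GenomeHit
    sequence: str
    mature_start: int
    mature_end: int
    clipped: bool
    clipped_fraction: float
    context: HairpinContext
    genomic_start: int
    genomic_end: int

    @property
    def mature_interval(self) -> tuple[int, int]:
        return (self.mature_start, self.mature_end)

    @property
    def mature_sequence(self) -> str:
        return self.sequence[self.mature_start : self.mature_end]


def extract_precursor(
    scaffold: SequenceRecord, hit: GenomeHit, ctx: HairpinContext
) -> PrecursorCandidate:
    """Cut the candidate precursor around *hit* using *ctx* flank lengths.

    On ``+`` the genomic window is [start − upstream, end + downstream); on
    ``-`` it is [start − downstream, end + upstream) reverse-complemented, so
    in both cases ``upstream_len`` bases precede the mature in the returned
    transcript-oriented sequence.  Overhangs beyond the scaffold are truncated
    with ``clipped=True`` and the lost fraction recorded.
    """
    if scaffold.id != hit.scaffold:
        raise ValueError(f"scaffold {scaffold.id} does not carry hit on {hit.scaffold}")
    n = len(scaffold.sequence)
    if not (0 <= hit.start < hit.end <= n):
        raise ValueError(f"hit [{hit.start}, {hit.end}) outside scaffold of length {n}")

    up, down = ctx.upstream_len, ctx.downstream_len
    if hit.strand == "+":
        left_want, right_want = up, down
    else:
        left_want, right_want = down, up
    left = min(left_want, hit.start)
    right = min(right_want, n - hit.end)
    window = scaffold.sequence[hit.start - left : hit.end + right]

    if hit.strand == "+":
        seq = window
        mature_start = left
    else:
        seq = reverse_complement(window)
        mature_start = right
    mature_end = mature_start + hit.length

    intended = up + hit.length + down
    lost = (left_want - left) + (right_want - right)
    clipped = lost > 0

    cand = PrecursorCandidate(
        hit=hit,
        sequence=seq,
        mature_start=mature_start,
        mature_end=mature_end,
        clipped=clipped,
        clipped_fraction=lost / intended if intended else 0.0,
        context=ctx,
        genomic_start=hit.start - left,
        genomic_end=hit.end + right,
    )
    # On '-' the genomic slice is revcomp(pattern), so either way the
    # transcript-oriented mature slice must equal the pattern itself.
    expected = hit.pattern.sequence
    if cand.mature_sequence != expected:
        raise RuntimeError(
            f"extraction contract violated at {hit.scaffold}:{hit.start}: "
            f"mature slice {cand.mature_sequence} != pattern {expected}"
        )
    return cand
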