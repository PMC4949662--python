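"""Arm pairing, reconciliation with existing annotation, and the discovery ledger.

Two expressed candidates whose precursor spans coincide on the genome and
whose matures sit on opposite arms of the stem are the 5p/3p products of one
hairpin and must be annotated on a single precursor.  Candidates falling
inside an already annotated precursor complement its known arm rather than
adding a novel hairpin.  The ledger ties every stage count together with the
arithmetic identities that the pipeline must satisfy by construction:

    candidates         = aligned uniques − already-annotated excluded
    not expressed      = hairpin-positive − expressed
    locations          = expressed + dual-locus extras
    distinct hairpins  = locations − arm pairs
    novel hairpins     = distinct hairpins − on-known-hairpin
    new totals         = priors + novel, with percent growth over priors
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

__all__ = [
    "ArmCandidate",
    "ArmPairing",
    "KnownMatch",
    "AnnotationLedger",
    "LedgerError",
    "pair_arms",
    "match_known",
    "match_known_by_sequence",
    "compute_ledger",
]


class LedgerError(ValueError):
    """Raised when stage counts violate a ledger identity."""


@dataclass(frozen=True)
class ArmCandidate:
    """An expressed candidate location entering arm pairing."""

    candidate_id: str
    scaffold: str
    strand: str
    span: tuple[int, int]
    arm: str  # 5p | 3p | loop_spanning
    total_count: int


@dataclass
class ArmPairing:
    """One precursor with its 5p and/or 3p mature candidates."""

    hairpin_id: str
    five_p: Optional[ArmCandidate]
    three_p: Optional[ArmCandidate]

    @property
    def is_pair(self) -> bool:
        return self.five_p is not None and self.three_p is not None

    @property
    def members(self) -> list[ArmCandidate]:
        return [c for c in (self.five_p, self.three_p) if c is not None]


@dataclass(frozen=True)
class KnownMatch:
    candidate_id: str
    known_precursor_id: str
    relation: str  # contained | overlapping


def _reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    inter = min(a[1], b[1]) - max(a[0], b[0])
    if inter <= 0:
        return 0.0
    return min(inter / (a[1] - a[0]), inter / (b[1] - b[0]))


def pair_arms(
    candidates: Sequence[ArmCandidate], *, min_reciprocal_overlap: float = 0.5
) -> list[ArmPairing]:
    """Merge 5p/3p candidates sharing a precursor span into pairings.

    Two candidates pair iff they lie on the same scaffold and strand, their
    precursor spans overlap reciprocally by at least *min_reciprocal_overlap*,
    and their arms are one 5p and one 3p.  When more than two candidates crowd
    one span, the best-expressed eligible pair wins (greedy on summed counts);
    every remaining candidate becomes a singleton pairing, so pairs plus
    singletons always account for every input location.
    """
    eligible: list[tuple[int, str, str, ArmCandidate, ArmCandidate]] = []
    for i, a in enumerate(candidates):
        for b in candidates[i + 1 :]:
            if a.scaffold != b.scaffold or a.strand != b.strand:
                continue
            if {a.arm, b.arm} != {"5p", "3p"}:
                continue
            if _reciprocal_overlap(a.span, b.span) < min_reciprocal_overlap:
                continue
            five, three = (a, b) if a.arm == "5p" else (b, a)
            eligible.append(
                (-(a.total_count + b.total_count), five.candidate_id,
                 three.candidate_id, five, three)
            )
    eligible.sort(key=lambda t: t[:3])

    used: set[str] = set()
    pairings: list[ArmPairing] = []
    for _neg, _fid, _tid, five, three in eligible:
        if five.candidate_id in used or three.candidate_id in used:
            continue
        used.update((five.candidate_id, three.candidate_id))
        pairings.append(
            ArmPairing(hairpin_id=f"{five.candidate_id}|{three.candidate_id}",
                       five_p=five, three_p=three)
        )
    for c in candidates:
        if c.candidate_id in used:
            continue
        pairings.append(
            ArmPairing(
                hairpin_id=c.candidate_id,
                five_p=c if c.arm == "5p" else None,
                three_p=c if c.arm == "3p" else None,
            )
        )
        # loop-spanning arms (should not reach pairing) fall through as
        # three_p=None/five_p=None singletons; record them on 5p side.
        if c.arm not in ("5p", "3p"):
            pairings[-1].five_p = c
    pairings.sort(key=lambda p: p.hairpin_id)
    return pairings


def match_known(
    candidate_id: str,
    scaffold: str,
    strand: str,
    mature_interval: tuple[int, int],
    known_precursors: Sequence[tuple[str, str, str, int, int]],
) -> Optional[KnownMatch]:
    """Match a candidate mature against annotated precursor intervals.

    *known_precursors* rows are (id, scaffold, strand, start, end), 0-based
    half-open.  Containment beats overlap; among equal relations the
    lexicographically first precursor id wins.  Returns ``None`` if disjoint
    from every known precursor.
    """
    best: Optional[KnownMatch] = None
    rank = {"contained": 0, "overlapping": 1}
    for kid, kscaffold, kstrand, kstart, kend in sorted(known_precursors):
        if kscaffold != scaffold or kstrand != strand:
            continue
        if mature_interval[0] >= kstart and mature_interval[1] <= kend:
            relation = "contained"
        elif min(mature_interval[1], kend) - max(mature_interval[0], kstart) >= 1:
            relation = "overlapping"
        else:
            continue
        m = KnownMatch(candidate_id=candidate_id, known_precursor_id=kid, relation=relation)
        if best is None or rank[relation] < rank[best.relation]:
            best = m
    return best


def match_known_by_sequence(
    candidate_id: str,
    precursor_sequence: str,
    candidate_arm: str,
    known_matures: Sequence[tuple[str, str, str]],
) -> Optional[KnownMatch]:
    """Sequence-space fallback when known loci have no genome coordinates.

    A candidate sits on a known hairpin if its extracted precursor contains an
    annotated mature of the complementary arm.  *known_matures* rows are
    (id, arm, sequence).
    """
    complement = {"5p": "3p", "3p": "5p"}.get(candidate_arm)
    if complement is None:
        return None
    for kid, karm, kseq in sorted(known_matures):
        if karm == complement and kseq in precursor_sequence:
            return KnownMatch(candidate_id=candidate_id, known_precursor_id=kid,
                              relation="contained")
    return None


@dataclass
class AnnotationLedger:
    """Stage-by-stage discovery bookkeeping with derived totals."""

    n_unique_aligned: int
    n_annotated_excluded: int
    n_candidates: int
    n_locus_clusters: int
    n_hairpin_pass: int
    n_expressed: int
    n_not_expressed: int
    n_dual_locus: int
    n_locations: int
    n_arm_pairs: int
    n_distinct_precursors: int
    n_on_known_hairpin: int
    n_novel_precursors: int
    prior_mature: int
    prior_precursors: int
    total_mature: int
    total_precursors: int
    pct_mature_increase: float
    pct_precursor_increase: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def _pct(novel: int, prior: int) -> float:
    if prior == 0:
        if novel == 0:
            return 0.0
        raise LedgerError("cannot compute percent increase over a prior of 0")
    q = (Decimal(100) * Decimal(novel) / Decimal(prior)).quantize(
        Decimal("0.1"), rounding=ROUND_HALF_UP
    )
    return float(q)


def compute_ledger(
    *,
    n_unique_aligned: int,
    n_annotated_excluded: int,
    n_hairpin_pass: int,
    n_expressed: int,
    n_dual_locus: int,
    n_arm_pairs: int,
    n_on_known_hairpin: int,
    prior_mature: int,
    prior_precursors: int,
    n_locus_clusters: int | None = None,
) -> AnnotationLedger:
    """Derive the full discovery ledger from the primary stage counts.

    Every derived quantity follows the identities in the module docstring;
    inconsistent inputs raise :class:`LedgerError` naming the violated
    identity.  Percentages are rounded half-up to one decimal.
    """
    counts = {
        "n_unique_aligned": n_unique_aligned,
        "n_annotated_excluded": n_annotated_excluded,
        "n_hairpin_pass": n_hairpin_pass,
        "n_expressed": n_expressed,
        "n_dual_locus": n_dual_locus,
        "n_arm_pairs": n_arm_pairs,
        "n_on_known_hairpin": n_on_known_hairpin,
        "prior_mature": prior_mature,
        "prior_precursors": prior_precursors,
    }
    for name, value in counts.items():
        if value < 0:
            raise LedgerError(f"{name} = {value} is negative")

    n_candidates = n_unique_aligned - n_annotated_excluded
    if n_candidates < 0:
        raise LedgerError(
            "n_candidates = n_unique_aligned - n_annotated_excluded is negative "
            f"({n_unique_aligned} - {n_annotated_excluded})"
        )
    if n_locus_clusters is None:
        n_locus_clusters = n_candidates
    if n_hairpin_pass > n_locus_clusters:
        raise LedgerError(
            f"n_hairpin_pass ({n_hairpin_pass}) exceeds n_locus_clusters ({n_locus_clusters})"
        )
    if n_expressed > n_hairpin_pass:
        raise LedgerError(
            f"n_expressed ({n_expressed}) exceeds n_hairpin_pass ({n_hairpin_pass})"
        )
    n_not_expressed = n_hairpin_pass - n_expressed
    n_locations = n_expressed + n_dual_locus
    n_distinct_precursors = n_locations - n_arm_pairs
    if n_distinct_precursors < 0:
        raise LedgerError(
            f"n_arm_pairs ({n_arm_pairs}) exceeds n_locations ({n_locations})"
        )
    n_novel_precursors = n_distinct_precursors - n_on_known_hairpin
    if n_novel_precursors < 0:
        raise LedgerError(
            f"n_on_known_hairpin ({n_on_known_hairpin}) exceeds distinct precursors "
            f"({n_distinct_precursors})"
        )
    return AnnotationLedger(
        n_unique_aligned=n_unique_aligned,
        n_annotated_excluded=n_annotated_excluded,
        n_candidates=n_candidates,
        n_locus_clusters=n_locus_clusters,
        n_hairpin_pass=n_hairpin_pass,
        n_expressed=n_expressed,
        n_not_expressed=n_not_expressed,
        n_dual_locus=n_dual_locus,
        n_locations=n_locations,
        n_arm_pairs=n_arm_pairs,
        n_distinct_precursors=n_distinct_precursors,
        n_on_known_hairpin=n_on_known_hairpin,
        n_novel_precursors=n_novel_precursors,
        prior_mature=prior_mature,
        prior_precursors=prior_precursors,
        total_mature=prior_mature + n_expressed,
        total_precursors=prior_precursors + n_novel_precursors,
        pct_mature_increase=_pct(n_expressed, prior_mature),
        pct_precursor_increase=_pct(n_novel_precursors, prior_precursors),
    )
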