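"""Build the query set from a multi-species mature-miRNA catalog.

Identical mature sequences shared across species are collapsed to one query;
sequences already annotated in the target species are excluded (an already
known sequence cannot be a novel discovery, even when other species share it).
For each query the originating precursor is located in the hairpin catalog so
its flank lengths can be reused when extracting candidate precursors from the
target genome — the working assumption being that conservation of the mature
implies conservation of the surrounding hairpin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .io import MirnaId, SequenceRecord, parse_mirna_id

__all__ = [
    "UniqueMature",
    "HairpinContext",
    "collapse_unique",
    "exclude_species",
    "hairpin_context",
    "prepare_queries",
]

logger = logging.getLogger(__name__)

MIN_MATURE_LEN = 15
MAX_MATURE_LEN = 30


@dataclass(frozen=True)
class UniqueMature:
    """One distinct mature sequence and every catalog member that carries it."""

    sequence: str
    members: tuple[MirnaId, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("UniqueMature requires at least one member")

    @property
    def display_name(self) -> str:
        return self.members[0].full

    def has_species(self, prefix: str) -> bool:
        return any(m.species_prefix == prefix for m in self.members)


@dataclass(frozen=True)
class HairpinContext:
    """Position of a mature miRNA within its originating precursor.

    ``upstream_len``/``downstream_len`` are the flank lengths (in transcript
    orientation) that the discovery step reuses when cutting a candidate
    precursor out of the target genome.
    """

    mirna_id: MirnaId
    hairpin_id: str
    upstream_len: int
    downstream_len: int
    mature_offset: int
    hairpin_len: int

    @property
    def total_len(self) -> int:
        return self.hairpin_len


def collapse_unique(matures: Sequence[SequenceRecord]) -> list[UniqueMature]:
    """Collapse catalog records with identical sequences into unique queries.

    Members of each entry are sorted by (species prefix, name); entries are
    returned sorted by display name then sequence, so output is deterministic
    regardless of catalog order.  Idempotent by construction.
    """
    by_seq: dict[str, list[MirnaId]] = {}
    for rec in matures:
        by_seq.setdefault(rec.sequence, []).append(parse_mirna_id(rec.id))
    uniques = [
        UniqueMature(sequence=seq, members=tuple(sorted(set(ids))))
        for seq, ids in by_seq.items()
    ]
    uniques.sort(key=lambda u: (u.display_name, u.sequence))
    return uniques


def exclude_species(
    uniques: Iterable[UniqueMature], prefix: str
) -> tuple[list[UniqueMature], list[UniqueMature]]:
    """Partition queries into (kept, excluded) by target-species membership.

    An entry is excluded as soon as ANY member belongs to the target species:
    such a sequence is already annotated there and is not a novel candidate.
    """
    kept: list[UniqueMature] = []
    excluded: list[UniqueMature] = []
    for u in uniques:
        (excluded if u.has_species(prefix) else kept).append(u)
    return kept, excluded


def _hairpin_name(mature_id: MirnaId) -> str:
    name = mature_id.name
    for suffix in ("-5p", "-3p"):
        if name.endswith(suffix):
            name = name[: -len(suffix)]
    return f"{mature_id.species_prefix}-{name}".replace("miR", "mir").lower()


def hairpin_context(
    mature: SequenceRecord, hairpins: Sequence[SequenceRecord]
) -> Optional[HairpinContext]:
    """Locate *mature* inside its originating hairpin by miRBase naming.

    The hairpin id is the mature id with the arm suffix stripped and ``miR``
    lowercased (``xxx-miR-9-5p`` → ``xxx-mir-9``); multi-copy precursors
    (``xxx-mir-9-1``, ``xxx-mir-9-2``) are matched by prefix and scanned in
    lexicographic id order, the first hairpin actually containing the mature
    sequence winning.  Returns ``None`` — absence is a value, not an error —
    when no named hairpin contains the mature.
    """
    target = _hairpin_name(parse_mirna_id(mature.id))
    candidates = [
        h
        for h in hairpins
        if h.id.lower() == target or h.id.lower().startswith(target + "-")
    ]
    for hp in sorted(candidates, key=lambda h: h.id):
        offset = hp.sequence.find(mature.sequence)
        if offset < 0:
            continue
        return HairpinContext(
            mirna_id=parse_mirna_id(mature.id),
            hairpin_id=hp.id,
            upstream_len=offset,
            downstream_len=len(hp.sequence) - offset - len(mature.sequence),
            mature_offset=offset,
            hairpin_len=len(hp.sequence),
        )
    return None


def default_context(mature_id: MirnaId, mature_len: int, flank: int = 25) -> HairpinContext:
    """Symmetric fallback context when no originating hairpin is found."""
    return HairpinContext(
        mirna_id=mature_id,
        hairpin_id="(default)",
        upstream_len=flank,
        downstream_len=flank,
        mature_offset=flank,
        hairpin_len=2 * flank + mature_len,
    )


def prepare_queries(
    matures: Sequence[SequenceRecord],
    hairpins: Sequence[SequenceRecord],
    target_prefix: str,
    *,
    default_flank: int = 25,
) -> tuple[list[UniqueMature], list[UniqueMature], dict[str, HairpinContext]]:
    """Filter, collapse and contextualize the catalog in one pass.

    Records containing ``N`` or outside the 15–30 nt mature length range are
    dropped with a warning (exact matching cannot use ambiguous or implausible
    queries).  Returns (kept, excluded, context-by-sequence); context of a
    unique sequence with members from several species is the member context
    with the LONGEST total precursor (ties: lexicographically first member),
    falling back to symmetric ``default_flank`` flanks when no member's
    hairpin can be located.
    """
    usable: list[SequenceRecord] = []
    rec_by_id: dict[str, SequenceRecord] = {}
    for rec in matures:
        if "N" in rec.sequence:
            logger.warning("dropping catalog mature %s: contains N", rec.id)
            continue
        if not (MIN_MATURE_LEN <= len(rec.sequence) <= MAX_MATURE_LEN):
            logger.warning(
                "dropping catalog mature %s: length %d outside [%d, %d]",
                rec.id, len(rec.sequence), MIN_MATURE_LEN, MAX_MATURE_LEN,
            )
            continue
        usable.append(rec)
        rec_by_id.setdefault(rec.id, rec)

    uniques = collapse_unique(usable)
    kept, excluded = exclude_species(uniques, target_prefix)

    contexts: dict[str, HairpinContext] = {}
    for u in kept:
        best: Optional[HairpinContext] = None
        for member in u.members:
            rec = rec_by_id.get(member.full)
            if rec is None:
                continue
            ctx = hairpin_context(rec, hairpins)
            if ctx is None:
                continue
            if best is None or ctx.total_len > best.total_len:
                best = ctx
        if best is None:
            logger.info("no hairpin context for %s; using %d nt flanks",
                        u.display_name, default_flank)
            best = default_context(u.members[0], len(u.sequence), default_flank)
        contexts[u.sequence] = best
    return kept, excluded, contexts
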