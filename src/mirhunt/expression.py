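"""Small-RNA-seq expression evidence for candidate miRNAs.

Counts of reads exactly identical to the candidate mature are summed across
experiments — raw sums, no depth normalization — so evidence from different
culture conditions and cell lines accumulates.  A candidate is called
expressed when its summed count strictly exceeds the cutoff (default 5, i.e.
"more than five reads"); the strictness is configurable because the boundary
reading is genuinely ambiguous in practice.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .io import CountTable

__all__ = ["ExpressionSummary", "summarize_expression", "fraction_below_median"]

DEFAULT_CUTOFF = 5


@dataclass
class ExpressionSummary:
    sequence: str
    per_experiment: dict[str, int]
    total: int
    expressed: bool


def summarize_expression(
    sequence: str,
    tables: Sequence[CountTable],
    *,
    cutoff: int = DEFAULT_CUTOFF,
    strict: bool = True,
) -> ExpressionSummary:
    """Sum exact-match read counts for *sequence* over all experiments.

    ``strict=True`` (default) requires ``total > cutoff`` for the expressed
    flag; ``strict=False`` relaxes to ``>=``.  Experiments without the
    sequence contribute 0, so adding experiments can only increase the total.
    """
    per_experiment = {t.experiment_id: t.get(sequence) for t in tables}
    total = sum(per_experiment.values())
    expressed = total > cutoff if strict else total >= cutoff
    return ExpressionSummary(
        sequence=sequence,
        per_experiment=per_experiment,
        total=total,
        expressed=expressed,
    )


def lower_median(values: Sequence[int]) -> int:
    """Median taking the lower of the two central values for even n."""
    if not values:
        raise ValueError("median of empty sequence")
    ordered = sorted(values)
    return ordered[(len(ordered) - 1) // 2]


def fraction_below_median(
    novel_totals: Sequence[int], known_totals: Sequence[int]
) -> float:
    """Fraction of novel candidates expressed below the known-set median.

    Newly found conserved miRNAs tend to sit in the low tail of the read-count
    distribution of already annotated ones; this statistic quantifies that.
    Strictly-below comparison against the lower median of *known_totals*.
    """
    if not novel_totals:
        raise ValueError("no novel totals given")
    med = lower_median(known_totals)
    return sum(1 for t in novel_totals if t < med) / len(novel_totals)


def totals_by_sequence(
    sequences: Sequence[str], tables: Sequence[CountTable]
) -> Mapping[str, int]:
    """Summed counts for many sequences at once (locus-representative input)."""
    return {
        seq: sum(t.get(seq) for t in tables)
        for seq in sequences
    }
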