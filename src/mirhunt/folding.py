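"""Secondary-structure prediction and stem-loop quality scoring.

Candidate precursors are folded by weighted base-pair maximization (Nussinov
dynamic programming with GC=3, AU=2, GU=1 and a 3 nt minimum hairpin loop).
The score plays the role a thermodynamic free energy plays in MFE folders:
what drives the discovery pipeline is not the absolute energy but whether the
candidate folds into a single clean stem-loop with the mature in the stem —
the classic criteria a curator applies when judging a pre-miRNA by eye.
:func:`evaluate_hairpin` quantifies exactly those criteria from the
dot-bracket string alone:

* exactly one terminal (hairpin) loop — the stem-loop motif;
* a high overall paired fraction and a highly paired mature;
* no large interior loops or bulges;
* the mature on one arm of the stem, not spanning the loop.

An optional external backend (:func:`fold_external`) shells out to an MFE
folder producing the same dot-bracket contract, for users who prefer
thermodynamic structures; nothing downstream changes.
"""

from __future__ import annotations

import subprocess
from dataclasses import dataclass, field

__all__ = [
    "FoldResult",
    "HairpinEvaluation",
    "HairpinThresholds",
    "fold",
    "evaluate_hairpin",
    "pairs_from_dotbracket",
    "dotbracket_from_pairs",
    "fold_external",
]

MIN_LOOP = 3
PAIR_WEIGHTS: dict[tuple[str, str], int] = {
    ("G", "C"): 3, ("C", "G"): 3,
    ("A", "T"): 2, ("T", "A"): 2,
    ("G", "T"): 1, ("T", "G"): 1,
}
MIN_FOLD_LEN = 10


@dataclass(frozen=True)
class FoldResult:
    sequence: str
    dotbracket: str
    pair_score: int
    pairs: tuple[tuple[int, int], ...]

    @property
    def score_density(self) -> float:
        return self.pair_score / len(self.sequence)

    @property
    def paired_fraction(self) -> float:
        return 2 * len(self.pairs) / len(self.sequence)


@dataclass(frozen=True)
class HairpinThresholds:
    """Pass thresholds quantifying manual stem-loop review."""

    min_paired_fraction: float = 0.5
    min_mature_paired_fraction: float = 0.6
    max_interior_unpaired_run: int = 10
    max_clipped_fraction: float = 0.2


@dataclass
class HairpinEvaluation:
    n_terminal_loops: int
    paired_fraction: float
    mature_paired_fraction: float
    max_interior_unpaired_run: int
    mature_arm: str
    passes: bool
    fail_reasons: list[str] = field(default_factory=list)


def _weight(a: str, b: str) -> int:
    return PAIR_WEIGHTS.get((a, b), 0)


def fold(sequence: str, *, min_loop: int = MIN_LOOP) -> FoldResult:
    """Fold *sequence* by weighted pair maximization.

    Maximizes the summed pair weight over all pseudoknot-free structures with
    hairpin loops of at least *min_loop* nt.  ``N`` never pairs.  Traceback is
    deterministic: on ties, pairing the interval ends beats bifurcating, and
    among bifurcations the smallest split point wins.
    """
    s = sequence.upper().replace("U", "T")
    n = len(s)
    if n < MIN_FOLD_LEN:
        raise ValueError(f"sequence of length {n} is below the folding minimum {MIN_FOLD_LEN}")
    if set(s) - set("ACGTN"):
        raise ValueError(f"sequence contains non-nucleotide characters: {sorted(set(s) - set('ACGTN'))}")

    # W[i][j]: best score on s[i..j] inclusive; 0 for spans too short to pair.
    W = [[0] * n for _ in range(n)]
    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            best = 0
            for k in range(i, j):
                v = W[i][k] + W[k + 1][j]
                if v > best:
                    best = v
            w = _weight(s[i], s[j])
            if w and W[i + 1][j - 1] + w >= best:
                best = W[i + 1][j - 1] + w
            W[i][j] = best

    pairs: list[tuple[int, int]] = []
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if j - i < min_loop + 1 or W[i][j] == 0:
            continue
        w = _weight(s[i], s[j])
        if w and W[i + 1][j - 1] + w == W[i][j]:
            pairs.append((i, j))
            stack.append((i + 1, j - 1))
            continue
        for k in range(i, j):
            if W[i][k] + W[k + 1][j] == W[i][j]:
                stack.append((i, k))
                stack.append((k + 1, j))
                break

    pairs.sort()
    score = sum(_weight(s[i], s[j]) for i, j in pairs)
    return FoldResult(
        sequence=s,
        dotbracket=dotbracket_from_pairs(pairs, n),
        pair_score=score,
        pairs=tuple(pairs),
    )


def dotbracket_from_pairs(pairs: list[tuple[int, int]] | tuple, n: int) -> str:
    db = ["."] * n
    for i, j in pairs:
        db[i], db[j] = "(", ")"
    return "".join(db)


def pairs_from_dotbracket(db: str) -> list[tuple[int, int]]:
    stack: list[int] = []
    pairs: list[tuple[int, int]] = []
    for idx, c in enumerate(db):
        if c == "(":
            stack.append(idx)
        elif c == ")":
            if not stack:
                raise ValueError("unbalanced dot-bracket string")
            pairs.append((stack.pop(), idx))
    if stack:
        raise ValueError("unbalanced dot-bracket string")
    pairs.sort()
    return pairs


def _dot_runs(db: str) -> list[tuple[int, int]]:
    """Maximal '.' runs as half-open intervals."""
    runs = []
    i = 0
    n = len(db)
    while i < n:
        if db[i] == ".":
            j = i
            while j < n and db[j] == ".":
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def evaluate_hairpin(
    fold_result: FoldResult | str,
    mature_interval: tuple[int, int],
    *,
    clipped_fraction: float = 0.0,
    thresholds: HairpinThresholds | None = None,
) -> HairpinEvaluation:
    """Score a folded candidate against stem-loop criteria.

    Operates purely on the dot-bracket string and the mature interval, so two
    candidates with identical structures evaluate identically regardless of
    sequence content.  A terminal loop is a maximal unpaired run immediately
    enclosed by ``(`` on the left and ``)`` on the right; interior runs
    exclude terminal loops and the dangling ends.
    """
    th = thresholds or HairpinThresholds()
    db = fold_result.dotbracket if isinstance(fold_result, FoldResult) else fold_result
    n = len(db)
    m_start, m_end = mature_interval
    if not (0 <= m_start < m_end <= n):
        raise ValueError(f"mature interval [{m_start}, {m_end}) outside structure of length {n}")

    runs = _dot_runs(db)
    terminal_loops = [
        (a, b) for a, b in runs if a > 0 and b < n and db[a - 1] == "(" and db[b] == ")"
    ]
    interior = [
        (a, b)
        for a, b in runs
        if (a, b) not in terminal_loops and a > 0 and b < n
    ]
    max_interior = max((b - a for a, b in interior), default=0)

    paired = n - sum(b - a for a, b in runs)
    paired_fraction = paired / n
    mature_paired = sum(1 for k in range(m_start, m_end) if db[k] != ".")
    mature_paired_fraction = mature_paired / (m_end - m_start)

    if terminal_loops:
        loop_a, loop_b = terminal_loops[0]
        if m_end <= loop_a:
            arm = "5p"
        elif m_start >= loop_b:
            arm = "3p"
        else:
            arm = "loop_spanning"
    else:
        arm = "loop_spanning"

    reasons: list[str] = []
    if len(terminal_loops) != 1:
        reasons.append(f"terminal_loops={len(terminal_loops)} (need exactly 1 stem-loop)")
    if paired_fraction < th.min_paired_fraction:
        reasons.append(f"paired_fraction={paired_fraction:.2f} < {th.min_paired_fraction}")
    if mature_paired_fraction < th.min_mature_paired_fraction:
        reasons.append(
            f"mature_paired_fraction={mature_paired_fraction:.2f} < {th.min_mature_paired_fraction}"
        )
    if max_interior > th.max_interior_unpaired_run:
        reasons.append(
            f"max_interior_unpaired_run={max_interior} > {th.max_interior_unpaired_run}"
        )
    if arm == "loop_spanning":
        reasons.append("mature spans the terminal loop")
    if clipped_fraction > th.max_clipped_fraction:
        reasons.append(
            f"clipped_fraction={clipped_fraction:.2f} > {th.max_clipped_fraction}"
        )

    return HairpinEvaluation(
        n_terminal_loops=len(terminal_loops),
        paired_fraction=paired_fraction,
        mature_paired_fraction=mature_paired_fraction,
        max_interior_unpaired_run=max_interior,
        mature_arm=arm,
        passes=not reasons,
        fail_reasons=reasons,
    )


def fold_external(sequence: str, *, command: str = "RNAfold") -> FoldResult:
    """Fold with an external MFE folder emitting dot-bracket (e.g. RNAfold).

    Provided as an alternative backend; the default pipeline never calls it.
    The returned object satisfies the same contract as :func:`fold`, with
    ``pair_score`` recomputed from the reported structure under the package's
    pair weights so downstream density checks stay comparable.
    """
    rna = sequence.upper().replace("T", "U")
    proc = subprocess.run(
        [command, "--noPS"], input=rna + "\n", capture_output=True, text=True, check=True
    )
    lines = [l for l in proc.stdout.splitlines() if l.strip()]
    structure = lines[1].split()[0]
    pairs = pairs_from_dotbracket(structure)
    s = sequence.upper().replace("U", "T")
    score = sum(_weight(s[i], s[j]) for i, j in pairs)
    return FoldResult(sequence=s, dotbracket=structure, pair_score=score, pairs=tuple(pairs))
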