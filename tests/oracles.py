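"""Independent brute-force oracles used to check the fast implementations.

Each oracle deliberately uses a different algorithmic formulation from the
code under test: naive O(n*m) scanning instead of a seed index, exhaustive
backtracking over all structures instead of dynamic programming, and an
explicit overlap graph instead of a sweep merge.
"""

from __future__ import annotations

import random

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
PAIR_WEIGHTS = {
    ("G", "C"): 3, ("C", "G"): 3,
    ("A", "T"): 2, ("T", "A"): 2,
    ("G", "T"): 1, ("T", "G"): 1,
}


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def naive_hits(pattern: str, scaffold: str) -> list[tuple[int, int, str]]:
    """All exact occurrences of pattern on both strands, forward coordinates."""
    out = []
    m = len(pattern)
    rc = revcomp(pattern)
    for i in range(len(scaffold) - m + 1):
        window = scaffold[i : i + m]
        if window == pattern:
            out.append((i, i + m, "+"))
        if window == rc and rc != pattern:
            out.append((i, i + m, "-"))
    return out


def brute_fold_score(s: str, min_loop: int = 3) -> int:
    """Maximum pair weight by exhaustive backtracking over all structures.

    Leftmost-position recursion: position i is unpaired, or pairs with some
    k > i + min_loop inside the interval.  Exponential; fine for n <= 14.
    """

    def best(i: int, j: int) -> int:
        if j - i < min_loop + 1:
            return 0
        top = best(i + 1, j)
        for k in range(i + min_loop + 1, j + 1):
            w = PAIR_WEIGHTS.get((s[i], s[k]), 0)
            if w:
                top = max(top, w + best(i + 1, k - 1) + best(k + 1, j))
        return top

    return best(0, len(s) - 1)


def overlap_components(intervals: list[tuple[int, int]]) -> list[set[int]]:
    """Connected components of the >=1 nt interval-overlap graph (networkx)."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(range(len(intervals)))
    for a in range(len(intervals)):
        for b in range(a + 1, len(intervals)):
            s1, e1 = intervals[a]
            s2, e2 = intervals[b]
            if min(e1, e2) - max(s1, s2) >= 1:
                g.add_edge(a, b)
    return [set(c) for c in nx.connected_components(g)]


def dinucleotide_shuffle(seq: str, rng: random.Random, max_tries: int = 200) -> str:
    """Shuffle preserving dinucleotide composition (Euler-walk retry method)."""
    if len(seq) < 3:
        return seq
    edges: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    n_edges = len(seq) - 1
    for _ in range(max_tries):
        pool = {k: v[:] for k, v in edges.items()}
        for v in pool.values():
            rng.shuffle(v)
        walk = [seq[0]]
        node = seq[0]
        while pool.get(node):
            node = pool[node].pop()
            walk.append(node)
        if len(walk) == n_edges + 1:
            return "".join(walk)
    return seq  # degenerate composition; identity is a valid shuffle
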