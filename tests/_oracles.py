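"""Independent oracles used by the test suite.

These deliberately avoid the package's alignment engine and clustering
code paths: the global-score oracle is a memoized three-state suffix
recursion over the alignment definition (match/mismatch, gap-in-query,
gap-in-target with affine costs), itself cross-checked against a true
path enumeration at tiny lengths; the local oracle maximizes the global
oracle over all substring pairs; the greedy-clustering oracle is a
from-scratch restatement of the cd-hit-style rule.
"""

from __future__ import annotations

from functools import lru_cache

from rhodoquant.align import SubstitutionMatrix, global_align, percent_identity


def oracle_global_score(
    a: str, b: str, matrix: SubstitutionMatrix, gap_open: int, gap_extend: int
) -> int:
    """Optimal global score by memoized recursion over suffixes.

    State: (i, j, last_move) where last_move distinguishes whether the
    previous column was a gap in the query ('GQ'), a gap in the target
    ('GT'), or neither — exactly what affine costs need.
    """

    @lru_cache(maxsize=None)
    def best(i: int, j: int, last: str) -> int:
        if i == len(a) and j == len(b):
            return 0
        options = []
        if i < len(a) and j < len(b):
            options.append(matrix.score(a[i], b[j]) + best(i + 1, j + 1, "D"))
        if j < len(b):
            cost = gap_extend if last == "GQ" else gap_open
            options.append(-cost + best(i, j + 1, "GQ"))
        if i < len(a):
            cost = gap_extend if last == "GT" else gap_open
            options.append(-cost + best(i + 1, j, "GT"))
        return max(options)

    return best(0, 0, "D")


def enumerate_global_score(
    a: str, b: str, matrix: SubstitutionMatrix, gap_open: int, gap_extend: int
) -> int:
    """True exhaustive enumeration of every gapped alignment (tiny n only).

    Builds each alignment column by column and scores the complete
    alignment; no memoization, so this is literally a max over all paths.
    """
    best = [None]

    def extend(i: int, j: int, score: int, last: str) -> None:
        if i == len(a) and j == len(b):
            if best[0] is None or score > best[0]:
                best[0] = score
            return
        if i < len(a) and j < len(b):
            extend(i + 1, j + 1, score + matrix.score(a[i], b[j]), "D")
        if j < len(b):
            cost = gap_extend if last == "GQ" else gap_open
            extend(i, j + 1, score - cost, "GQ")
        if i < len(a):
            cost = gap_extend if last == "GT" else gap_open
            extend(i + 1, j, score - cost, "GT")

    extend(0, 0, 0, "D")
    return best[0]


def oracle_local_score(
    a: str, b: str, matrix: SubstitutionMatrix, gap_open: int, gap_extend: int
) -> int:
    """Optimal local score: max of the global oracle over substring pairs."""
    best = 0
    for i in range(len(a)):
        for k in range(i + 1, len(a) + 1):
            for j in range(len(b)):
                for m in range(j + 1, len(b) + 1):
                    s = oracle_global_score(
                        a[i:k], b[j:m], matrix, gap_open, gap_extend
                    )
                    if s > best:
                        best = s
    return best


def brute_greedy_clusters(records, threshold: float) -> list[tuple[str, list[str]]]:
    """Independent restatement of the greedy rule: visit by length
    descending (ties by id), join the first founded cluster whose
    representative identity (shorter-sequence denominator) reaches the
    threshold, else found a new cluster. Returns (rep_id, member_ids)
    in founding order.
    """
    clusters: list[tuple[object, list[str]]] = []
    for rec in sorted(records, key=lambda r: (-len(r.sequence), r.id)):
        for rep, members in clusters:
            aln = global_align(rec.sequence, rep.sequence)
            if percent_identity(aln, "shorter_seq") >= threshold:
                members.append(rec.id)
                break
        else:
            clusters.append((rec, [rec.id]))
    return [(rep.id, members) for rep, members in clusters]
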