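"""Pairwise protein alignment with affine gap penalties.

This module is the alignment engine behind candidate screening, reference
position mapping and OTU clustering. It wraps Biopython's C dynamic
programming core (:class:`Bio.Align.PairwiseAligner`) behind a small,
typed surface that fixes the conventions the rest of the package relies
on:

* affine penalties where the *first* column of a gap costs ``gap_open``
  and every further column of the same gap costs ``gap_extend``;
* a 21-letter alphabet (20 standard residues plus ``X``, which scores 0
  against everything);
* deterministic choice among co-optimal tracebacks (the aligner's first
  enumerated optimal alignment);
* 1-based inclusive spans and an emitted gapped alignment whose score can
  be recomputed exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache
from typing import Literal

import numpy as np
from Bio import Align as _bioalign
from Bio.Align import substitution_matrices as _submat

from .errors import InvalidCharacterError, InvalidInputError, UndefinedIdentityError

logger = logging.getLogger(__name__)

#: The 20 standard amino acids, alphabetical one-letter codes.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Full alphabet accepted by the engine (standard residues + ambiguity X).
ALPHABET = AMINO_ACIDS + "X"

Mode = Literal["global", "local"]
IdentityDenominator = Literal["shorter_seq", "alignment_columns"]


@dataclass(frozen=True)
class SubstitutionMatrix:
    """A symmetric integer substitution matrix over :data:`ALPHABET`.

    ``scores`` maps every ordered residue pair to an integer; symmetry is
    enforced at construction. Use :meth:`blosum62` for the package default
    (BLOSUM62 with ``X`` neutralized to 0 against everything) or
    :meth:`from_match_mismatch` for simple test matrices.
    """

    name: str
    scores: tuple[tuple[int, ...], ...]  # 21x21, indexed by ALPHABET order

    def __post_init__(self) -> None:
        n = len(ALPHABET)
        if len(self.scores) != n or any(len(row) != n for row in self.scores):
            raise InvalidInputError(
                f"substitution matrix must be {n}x{n} over {ALPHABET!r}"
            )
        for i in range(n):
            for j in range(i):
                if self.scores[i][j] != self.scores[j][i]:
                    raise InvalidInputError(
                        f"matrix {self.name!r} not symmetric at "
                        f"({ALPHABET[i]},{ALPHABET[j]})"
                    )

    def score(self, a: str, b: str) -> int:
        """Score of aligning residue ``a`` against residue ``b``."""
        try:
            return self.scores[ALPHABET.index(a)][ALPHABET.index(b)]
        except ValueError as exc:
            bad = a if a not in ALPHABET else b
            raise InvalidCharacterError(bad, "substitution lookup") from exc

    def to_biopython(self) -> _submat.Array:
        """The matrix as a :class:`Bio.Align.substitution_matrices.Array`."""
        arr = np.array(self.scores, dtype=float)
        return _submat.Array(alphabet=ALPHABET, dims=2, data=arr)

    @classmethod
    def from_match_mismatch(
        cls, match: int, mismatch: int, name: str = "match_mismatch"
    ) -> "SubstitutionMatrix":
        """Uniform match/mismatch matrix (X still scores 0 vs anything)."""
        n = len(ALPHABET)
        rows = []
        for i in range(n):
            row = []
            for j in range(n):
                if ALPHABET[i] == "X" or ALPHABET[j] == "X":
                    row.append(0)
                else:
                    row.append(match if i == j else mismatch)
            rows.append(tuple(row))
        return cls(name=name, scores=tuple(rows))

    @classmethod
    def blosum62(cls) -> "SubstitutionMatrix":
        """BLOSUM62 restricted to the 20 standard residues, with ``X`` = 0.

        The neutral ``X`` departs from NCBI's BLOSUM62 (which penalizes X)
        so that ambiguous positions neither reward nor punish an alignment.
        """
        return _blosum62_cached()


@lru_cache(maxsize=1)
def _blosum62_cached() -> SubstitutionMatrix:
    raw = _submat.load("BLOSUM62")
    n = len(ALPHABET)
    rows = []
    for i in range(n):
        row = []
        for j in range(n):
            a, b = ALPHABET[i], ALPHABET[j]
            if a == "X" or b == "X":
                row.append(0)
            else:
                row.append(int(raw[a, b]))
        rows.append(tuple(row))
    return SubstitutionMatrix(name="BLOSUM62", scores=tuple(rows))


@dataclass(frozen=True)
class PairwiseAlignment:
    """An emitted pairwise alignment.

    ``aligned_query``/``aligned_target`` are equal-length gapped strings
    with no gap–gap column. Spans are 1-based inclusive positions in the
    ungapped sequences; a local alignment with no positive-scoring pair is
    represented with empty strings, score 0 and spans ``(0, 0)``.
    """

    query_id: str
    target_id: str
    aligned_query: str
    aligned_target: str
    score: int
    mode: Mode
    query_span: tuple[int, int]
    target_span: tuple[int, int]
    query_length: int
    target_length: int

    @property
    def is_empty(self) -> bool:
        return len(self.aligned_query) == 0

    def recomputed_score(
        self, matrix: SubstitutionMatrix, gap_open: int, gap_extend: int
    ) -> int:
        """Score of the emitted gapped strings under the given scheme.

        Walks the alignment column by column; the first column of each gap
        run costs ``gap_open`` and subsequent columns ``gap_extend``. Used
        by tests and by the engine's own self-check.
        """
        total = 0
        in_gap_q = in_gap_t = False
        for qa, ta in zip(self.aligned_query, self.aligned_target):
            if qa == "-" and ta == "-":
                raise InvalidInputError("gap-gap column in alignment")
            if qa == "-":
                total -= gap_extend if in_gap_q else gap_open
                in_gap_q, in_gap_t = True, False
            elif ta == "-":
                total -= gap_extend if in_gap_t else gap_open
                in_gap_q, in_gap_t = False, True
            else:
                total += matrix.score(qa, ta)
                in_gap_q = in_gap_t = False
        return total


def clean_sequence(seq: str, where: str = "sequence") -> str:
    """Uppercase ``seq``, strip ``*`` stop characters, validate the alphabet.

    Raises :class:`InvalidInputError` on an empty result and
    :class:`InvalidCharacterError` naming the first offending symbol.
    """
    if not isinstance(seq, str):
        raise InvalidInputError(f"{where}: sequence must be a string")
    up = seq.upper()
    if "*" in up:
        logger.warning("%s: stripping %d stop character(s) '*'", where, up.count("*"))
        up = up.replace("*", "")
    if not up:
        raise InvalidInputError(f"{where}: empty sequence")
    for ch in up:
        if ch not in ALPHABET:
            raise InvalidCharacterError(ch, where)
    return up


def _make_aligner(
    matrix: SubstitutionMatrix, gap_open: int, gap_extend: int, mode: Mode
) -> _bioalign.PairwiseAligner:
    aligner = _bioalign.PairwiseAligner()
    aligner.substitution_matrix = matrix.to_biopython()
    aligner.open_gap_score = -float(gap_open)
    aligner.extend_gap_score = -float(gap_extend)
    aligner.mode = mode
    return aligner


def _check_penalties(gap_open: int, gap_extend: int) -> None:
    if gap_extend < 0 or gap_open < gap_extend:
        raise InvalidInputError(
            f"require gap_open >= gap_extend >= 0, got open={gap_open} "
            f"extend={gap_extend}"
        )


def _emit(
    aln: _bioalign.Alignment,
    query: str,
    target: str,
    query_id: str,
    target_id: str,
    score: int,
    mode: Mode,
) -> PairwiseAlignment:
    # Biopython aligns (seqA, seqB); we pass (query, target), so row 0 of
    # the coordinate matrix indexes the query.
    coords = aln.coordinates
    q0, q1 = int(coords[0, 0]), int(coords[0, -1])
    t0, t1 = int(coords[1, 0]), int(coords[1, -1])
    gapped_q: list[str] = []
    gapped_t: list[str] = []
    for k in range(coords.shape[1] - 1):
        qa, qb = int(coords[0, k]), int(coords[0, k + 1])
        ta, tb = int(coords[1, k]), int(coords[1, k + 1])
        if qa == qb:  # gap in query
            gapped_q.append("-" * (tb - ta))
            gapped_t.append(target[ta:tb])
        elif ta == tb:  # gap in target
            gapped_q.append(query[qa:qb])
            gapped_t.append("-" * (qb - qa))
        else:
            gapped_q.append(query[qa:qb])
            gapped_t.append(target[ta:tb])
    return PairwiseAlignment(
        query_id=query_id,
        target_id=target_id,
        aligned_query="".join(gapped_q),
        aligned_target="".join(gapped_t),
        score=score,
        mode=mode,
        query_span=(q0 + 1, q1),
        target_span=(t0 + 1, t1),
        query_length=len(query),
        target_length=len(target),
    )


def global_align(
    a: str,
    b: str,
    matrix: SubstitutionMatrix | None = None,
    gap_open: int = 11,
    gap_extend: int = 1,
    query_id: str = "query",
    target_id: str = "target",
) -> PairwiseAlignment:
    """Optimal Needleman–Wunsch global alignment of ``a`` (query) vs ``b``.

    Defaults are BLOSUM62 with open=11/extend=1 (BLASTP's conventions; the
    opening column itself costs 11). Deterministic: among co-optimal
    alignments the aligner's first enumerated traceback is returned.
    """
    matrix = matrix or SubstitutionMatrix.blosum62()
    _check_penalties(gap_open, gap_extend)
    qa = clean_sequence(a, f"query {query_id}")
    ta = clean_sequence(b, f"target {target_id}")
    aligner = _make_aligner(matrix, gap_open, gap_extend, "global")
    result = aligner.align(qa, ta)
    best = result[0]
    score = int(round(result.score))
    return _emit(best, qa, ta, query_id, target_id, score, "global")


def local_align(
    a: str,
    b: str,
    matrix: SubstitutionMatrix | None = None,
    gap_open: int = 11,
    gap_extend: int = 1,
    query_id: str = "query",
    target_id: str = "target",
) -> PairwiseAlignment:
    """Optimal Smith–Waterman local alignment of ``a`` (query) vs ``b``.

    The score is never negative; when no residue pair scores positively the
    empty alignment (score 0, spans ``(0, 0)``) is returned.
    """
    matrix = matrix or SubstitutionMatrix.blosum62()
    _check_penalties(gap_open, gap_extend)
    qa = clean_sequence(a, f"query {query_id}")
    ta = clean_sequence(b, f"target {target_id}")
    aligner = _make_aligner(matrix, gap_open, gap_extend, "local")
    result = aligner.align(qa, ta)
    score = int(round(result.score))
    if score <= 0 or len(result) == 0:
        return PairwiseAlignment(
            query_id=query_id,
            target_id=target_id,
            aligned_query="",
            aligned_target="",
            score=0,
            mode="local",
            query_span=(0, 0),
            target_span=(0, 0),
            query_length=len(qa),
            target_length=len(ta),
        )
    return _emit(result[0], qa, ta, query_id, target_id, score, "local")


def percent_identity(
    aln: PairwiseAlignment,
    denominator: IdentityDenominator = "shorter_seq",
) -> float:
    """Fraction of identical columns, in [0, 1].

    ``matches`` counts columns with identical residues (gap columns never
    match). ``shorter_seq`` divides by the length of the shorter *full*
    sequence — the cd-hit convention under which the 82% OTU threshold is
    applied; ``alignment_columns`` divides by the alignment length.
    """
    if denominator == "shorter_seq":
        denom = min(aln.query_length, aln.target_length)
    elif denominator == "alignment_columns":
        denom = len(aln.aligned_query)
    else:  # pragma: no cover - guarded by Literal type
        raise InvalidInputError(f"unknown denominator {denominator!r}")
    if denom == 0:
        raise UndefinedIdentityError(
            f"identity undefined: zero {denominator} denominator"
        )
    matches = sum(
        1
        for qa, ta in zip(aln.aligned_query, aln.aligned_target)
        if qa == ta and qa != "-"
    )
    return matches / denom


def alignment_to_tsv_row(aln: PairwiseAlignment) -> str:
    """One TSV line: query, target, mode, score, identity, spans."""
    try:
        ident = f"{percent_identity(aln):.4f}"
    except UndefinedIdentityError:
        ident = "NA"
    return "\t".join(
        [
            aln.query_id,
            aln.target_id,
            aln.mode,
            str(aln.score),
            ident,
            f"{aln.query_span[0]}-{aln.query_span[1]}",
            f"{aln.target_span[0]}-{aln.target_span[1]}",
        ]
    )
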