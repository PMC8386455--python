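"""Reference position mapping, pump/color calls and position profiles.

Proteorhodopsin function is read off four residues in a fixed reference
numbering: the proton-pumping triad D97/T101/E108 (aspartate proton
acceptor, threonine, glutamate proton donor) and the spectral tuning
switch at 105 (leucine/methionine absorb green light, glutamine blue).
Each query protein is mapped onto the reference numbering by a single
optimal global alignment, after which the calls are pure functions of the
mapped residues.

The bundled coordinate template (``data/pr_reference_synthetic.fasta``)
is a synthetic proteorhodopsin-like record with the canonical residues
planted at 1-based positions 97/101/105/108; any annotated reference can
be substituted via :class:`AnnotatedReference`.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from typing import Iterable, Literal, Mapping

from .align import PairwiseAlignment, SubstitutionMatrix, global_align
from .errors import InvalidInputError
from .io import ProteinRecord

#: Sentinel for a reference position that aligns to a gap in the query.
GAP = "-"

KEY_POSITIONS = (97, 101, 105, 108)
PUMP_POSITIONS = (97, 101, 108)
EXPECTED_PUMP_RESIDUES: Mapping[int, str] = {97: "D", 101: "T", 108: "E"}
GREEN_RESIDUES = frozenset({"L", "M"})
BLUE_RESIDUE = "Q"

PumpCall = Literal["functional", "non_canonical", "undetermined"]
ColorCall = Literal["green", "blue", "unknown", "undetermined"]


@dataclass(frozen=True)
class AnnotatedReference:
    """A reference protein with its key positions located.

    ``key_positions`` maps each reference-numbering position to a 1-based
    index in ``record.sequence``; for the bundled template the mapping is
    the identity (position 97 is residue 97 of the record).
    """

    record: ProteinRecord
    key_positions: Mapping[int, int] = field(
        default_factory=lambda: {p: p for p in KEY_POSITIONS}
    )

    def __post_init__(self) -> None:
        missing = [p for p in KEY_POSITIONS if p not in self.key_positions]
        if missing:
            raise InvalidInputError(f"reference missing key positions {missing}")
        idx = [self.key_positions[p] for p in KEY_POSITIONS]
        if sorted(idx) != idx or len(set(idx)) != len(idx):
            raise InvalidInputError("key position indices must be strictly increasing")
        n = len(self.record.sequence)
        if idx[0] < 1 or idx[-1] > n:
            raise InvalidInputError("key position index outside reference sequence")
        for pos, expected in EXPECTED_PUMP_RESIDUES.items():
            actual = self.residue_at(pos)
            if actual != expected:
                raise InvalidInputError(
                    f"reference residue at position {pos} is {actual!r}, "
                    f"expected {expected!r}"
                )

    def residue_at(self, position: int) -> str:
        return self.record.sequence[self.key_positions[position] - 1]


@dataclass(frozen=True)
class ResidueAnnotation:
    """Per-protein mapped residues and the derived functional calls."""

    query_id: str
    residue_at: Mapping[int, str]  # position -> residue or GAP
    query_index: Mapping[int, int | None]  # position -> 1-based index or None
    pump_call: PumpCall
    color_call: ColorCall


@dataclass(frozen=True)
class PositionProfile:
    """Residue counts/frequencies at one reference position (logo data)."""

    position: int
    counts: Mapping[str, int]
    frequencies: Mapping[str, float]
    gap_count: int


@lru_cache(maxsize=1)
def load_bundled_reference() -> AnnotatedReference:
    """The synthetic coordinate template shipped as package data."""
    from Bio import SeqIO

    ref_path = resources.files("rhodoquant.data") / "pr_reference_synthetic.fasta"
    with resources.as_file(ref_path) as p:
        rec = next(SeqIO.parse(str(p), "fasta"))
    return AnnotatedReference(record=ProteinRecord(id=rec.id, sequence=str(rec.seq)))


def map_reference_positions(
    query: ProteinRecord,
    ref: AnnotatedReference,
    matrix: SubstitutionMatrix | None = None,
    gap_open: int = 11,
    gap_extend: int = 1,
) -> dict[int, int | None]:
    """Map each key position to a 1-based query index (None when gapped).

    A single optimal global alignment of the query against the reference
    determines the column correspondence; a reference index whose column
    holds a query gap maps to None.
    """
    aln = global_align(
        query.sequence,
        ref.record.sequence,
        matrix=matrix,
        gap_open=gap_open,
        gap_extend=gap_extend,
        query_id=query.id,
        target_id=ref.record.id,
    )
    return _positions_from_alignment(aln, ref)


def _positions_from_alignment(
    aln: PairwiseAlignment, ref: AnnotatedReference
) -> dict[int, int | None]:
    wanted = {ref.key_positions[p]: p for p in KEY_POSITIONS}
    out: dict[int, int | None] = {p: None for p in KEY_POSITIONS}
    qi = ti = 0  # ungapped indices consumed so far
    for qa, ta in zip(aln.aligned_query, aln.aligned_target):
        if qa != "-":
            qi += 1
        if ta != "-":
            ti += 1
            if ti in wanted:
                out[wanted[ti]] = qi if qa != "-" else None
    return out


def classify_pump(residues: Mapping[int, str]) -> PumpCall:
    """Proton-pump call from residues at 97/101/108.

    ``functional`` iff exactly (D, T, E); ``non_canonical`` when all three
    are mapped but any differs (e.g. the lysine-108 variant);
    ``undetermined`` when any position is a gap.
    """
    vals = [residues.get(p, GAP) for p in PUMP_POSITIONS]
    if any(v == GAP for v in vals):
        return "undetermined"
    if all(v == EXPECTED_PUMP_RESIDUES[p] for p, v in zip(PUMP_POSITIONS, vals)):
        return "functional"
    return "non_canonical"


def classify_color(residue_105: str) -> ColorCall:
    """Spectral tuning call from the residue at 105.

    L/M -> green, Q -> blue, gap -> undetermined; any other residue is
    reported as ``unknown`` rather than coerced to a color.
    """
    if residue_105 == GAP:
        return "undetermined"
    if residue_105 in GREEN_RESIDUES:
        return "green"
    if residue_105 == BLUE_RESIDUE:
        return "blue"
    return "unknown"


def annotate_protein(
    query: ProteinRecord,
    ref: AnnotatedReference | None = None,
    matrix: SubstitutionMatrix | None = None,
    gap_open: int = 11,
    gap_extend: int = 1,
) -> ResidueAnnotation:
    """Map the key positions of ``query`` and derive both calls."""
    ref = ref or load_bundled_reference()
    mapping = map_reference_positions(query, ref, matrix, gap_open, gap_extend)
    residues = {
        p: (query.sequence[i - 1] if i is not None else GAP)
        for p, i in mapping.items()
    }
    return ResidueAnnotation(
        query_id=query.id,
        residue_at=residues,
        query_index=mapping,
        pump_call=classify_pump(residues),
        color_call=classify_color(residues[105]),
    )


def annotate_proteins(
    queries: Iterable[ProteinRecord],
    ref: AnnotatedReference | None = None,
    **kwargs,
) -> list[ResidueAnnotation]:
    ref = ref or load_bundled_reference()
    return [annotate_protein(q, ref, **kwargs) for q in queries]


def position_profile(
    annotations: Iterable[ResidueAnnotation], position: int
) -> PositionProfile:
    """Residue counts and frequencies at one key position.

    Frequencies are over non-gap residues; gaps are counted separately.
    """
    if position not in KEY_POSITIONS:
        raise InvalidInputError(
            f"position must be one of {KEY_POSITIONS}, got {position}"
        )
    anns = list(annotations)
    if not anns:
        raise InvalidInputError("cannot profile an empty annotation list")
    counter: Counter[str] = Counter()
    gaps = 0
    for ann in anns:
        res = ann.residue_at.get(position, GAP)
        if res == GAP:
            gaps += 1
        else:
            counter[res] += 1
    total = sum(counter.values())
    freqs = {r: c / total for r, c in counter.items()} if total else {}
    return PositionProfile(
        position=position, counts=dict(counter), frequencies=freqs, gap_count=gaps
    )


def annotations_to_tsv(annotations: Iterable[ResidueAnnotation]) -> str:
    """TSV table: query_id, res97, res101, res105, res108, calls."""
    lines = ["query_id\tres97\tres101\tres105\tres108\tpump_call\tcolor_call"]
    for ann in annotations:
        lines.append(
            "\t".join(
                [ann.query_id]
                + [ann.residue_at.get(p, GAP) for p in KEY_POSITIONS]
                + [ann.pump_call, ann.color_call]
            )
        )
    return "\n".join(lines) + "\n"
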