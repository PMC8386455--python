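"""Proteorhodopsin candidate screening and curation.

Two routes produce candidate hits: an internal local-alignment search
against a reference panel (a stand-in for a DIAMOND/BLASTP similarity
search), and an importer for external tabular hits (outfmt-6 style),
which takes precedence when supplied. Curation then applies the study's
two rules: a candidate is retained iff it is longer than 100 amino acids
AND its global alignment to the annotated reference covers the
proton-pumping C-helix region (non-gap query residues at >= 3 of the 4
key positions 97/101/105/108). Residue *identity* at those positions is
deliberately not a curation criterion — a pump-dead variant (e.g. a
lysine at 108) stays in the set and is reported downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .align import SubstitutionMatrix, local_align
from .annotate import KEY_POSITIONS, AnnotatedReference, map_reference_positions
from .errors import ConfigurationError, FormatError, InvalidInputError
from .io import ProteinRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScreenConfig:
    """Thresholds and reference panel for screening.

    ``min_length_aa`` follows the study's "larger than 100 amino acids"
    rule, read strictly (a 100-aa protein fails). ``evalue_max_import``
    is the cutoff applied to imported external hits (1e-7, the E-value
    bound of the original similarity search).
    """

    reference_panel: tuple[ProteinRecord, ...] = ()
    min_length_aa: int = 100
    min_bitlike_score: float = 50.0
    evalue_max_import: float = 1e-7

    def __post_init__(self) -> None:
        if self.min_length_aa <= 0:
            raise ConfigurationError("min_length_aa must be positive")
        if self.evalue_max_import <= 0:
            raise ConfigurationError("evalue_max_import must be positive")


@dataclass(frozen=True)
class ScreenResult:
    """Curation outcome for one candidate."""

    record: ProteinRecord
    best_hit_id: str | None
    score: float | None
    passed_length: bool
    domain_region_covered: bool
    covered_positions: tuple[int, ...] = field(default=())

    @property
    def retained(self) -> bool:
        return self.passed_length and self.domain_region_covered


def search_candidates(
    queries: list[ProteinRecord],
    cfg: ScreenConfig,
    matrix: SubstitutionMatrix | None = None,
) -> list[tuple[str, str, int]]:
    """Best local-alignment hit per query against the reference panel.

    Queries whose best score falls below ``min_bitlike_score`` are
    dropped. Among tied hits the lexicographically smaller panel id wins;
    output rows are sorted by score descending then query id.
    """
    if not cfg.reference_panel:
        raise ConfigurationError("search requires a nonempty reference panel")
    matrix = matrix or SubstitutionMatrix.blosum62()
    rows: list[tuple[str, str, int]] = []
    for query in queries:
        best_id: str | None = None
        best_score = -1
        for panel_rec in sorted(cfg.reference_panel, key=lambda r: r.id):
            aln = local_align(
                query.sequence,
                panel_rec.sequence,
                matrix=matrix,
                query_id=query.id,
                target_id=panel_rec.id,
            )
            if aln.score > best_score:
                best_score = aln.score
                best_id = panel_rec.id
        if best_id is not None and best_score >= cfg.min_bitlike_score:
            rows.append((query.id, best_id, best_score))
        else:
            logger.info(
                "query %s dropped: best panel score %s < %s",
                query.id,
                best_score,
                cfg.min_bitlike_score,
            )
    rows.sort(key=lambda r: (-r[2], r[1], r[0]))
    return rows


_REQUIRED_HIT_COLUMNS = ("query_id", "subject_id", "evalue", "bitscore")
_OUTFMT6_ALIASES = {"qseqid": "query_id", "sseqid": "subject_id"}


def import_external_hits(
    hit_table: str | Path | pd.DataFrame, cfg: ScreenConfig
) -> list[tuple[str, str, float]]:
    """Import external (BLAST/DIAMOND outfmt-6 style) hits.

    Rows with E-value above ``cfg.evalue_max_import`` are dropped; the
    best surviving row per query is the one with lowest E-value, ties
    broken by highest bitscore then subject id.
    """
    if isinstance(hit_table, pd.DataFrame):
        df = hit_table.copy()
    else:
        df = pd.read_csv(hit_table, sep="\t")
    df = df.rename(columns=_OUTFMT6_ALIASES)
    for col in _REQUIRED_HIT_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"hit table missing required column {col!r}")
    evalues = pd.to_numeric(df["evalue"], errors="coerce")
    bad = df.index[evalues.isna()]
    if len(bad):
        # +2: header line plus 1-based numbering
        raise FormatError(
            f"unparseable evalue at line {int(bad[0]) + 2}: "
            f"{df.loc[bad[0], 'evalue']!r}"
        )
    df["evalue"] = evalues
    df["bitscore"] = pd.to_numeric(df["bitscore"], errors="coerce")
    kept = df[df["evalue"] <= cfg.evalue_max_import]
    best = (
        kept.sort_values(
            ["query_id", "evalue", "bitscore", "subject_id"],
            ascending=[True, True, False, True],
        )
        .groupby("query_id", sort=True)
        .first()
        .reset_index()
    )
    return [
        (row.query_id, row.subject_id, float(row.evalue))
        for row in best.itertuples(index=False)
    ]


def curate_candidates(
    candidates: list[ProteinRecord],
    reference: AnnotatedReference,
    cfg: ScreenConfig | None = None,
    matrix: SubstitutionMatrix | None = None,
    hits: dict[str, tuple[str, float]] | None = None,
) -> list[ScreenResult]:
    """Apply the length and C-helix coverage rules to each candidate.

    ``hits`` optionally attaches (best_hit_id, score) per query id for
    reporting. Every rejection is logged with the rule that failed; an
    unalignable query yields ``domain_region_covered=False``, never an
    exception.
    """
    cfg = cfg or ScreenConfig()
    results: list[ScreenResult] = []
    for rec in candidates:
        passed_length = len(rec) > cfg.min_length_aa
        try:
            mapping = map_reference_positions(rec, reference, matrix=matrix)
            covered = tuple(p for p in KEY_POSITIONS if mapping[p] is not None)
        except InvalidInputError as exc:
            logger.warning("candidate %s unalignable: %s", rec.id, exc)
            covered = ()
        domain_covered = len(covered) >= 3
        if not passed_length:
            logger.info(
                "candidate %s rejected: length %d <= %d",
                rec.id,
                len(rec),
                cfg.min_length_aa,
            )
        if not domain_covered:
            logger.info(
                "candidate %s rejected: C-helix coverage %d/4 key positions",
                rec.id,
                len(covered),
            )
        hit = hits.get(rec.id) if hits else None
        results.append(
            ScreenResult(
                record=rec,
                best_hit_id=hit[0] if hit else None,
                score=hit[1] if hit else None,
                passed_length=passed_length,
                domain_region_covered=domain_covered,
                covered_positions=covered,
            )
        )
    return results


def screen_results_to_tsv(results: list[ScreenResult]) -> str:
    lines = [
        "query_id\tlength\tbest_hit_id\tscore\tpassed_length"
        "\tdomain_region_covered\tretained"
    ]
    for res in results:
        lines.append(
            "\t".join(
                [
                    res.record.id,
                    str(len(res.record)),
                    res.best_hit_id or "NA",
                    "NA" if res.score is None else f"{res.score:g}",
                    str(res.passed_length),
                    str(res.domain_region_covered),
                    str(res.retained),
                ]
            )
        )
    return "\n".join(lines) + "\n"
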