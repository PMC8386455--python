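"""qPCR standard-curve quantification and 16S-corrected relative abundance.

A dilution series of known template copies defines the log-linear
standard curve Cq = intercept + slope * log10(copies); amplification
efficiency is E = 10^(-1/slope) - 1 (slope -3.3219 means perfect
doubling, E = 100%). Sample copies are back-calculated from the mean Cq
of (typically triplicate) reactions.

The relative abundance of proteorhodopsin-bearing bacteria divides
PR-gene genome equivalents by 16S-gene genome equivalents, assuming 1.9
copies of the 16S rRNA gene and 1 copy of the PR gene per genome.
Values above 1 are flagged, never clamped. A below-detection assay is
represented as an absent measurement (no Cq), never as zero copies.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from statistics import mean, pstdev

from scipy import stats as _stats

from .errors import (
    DegenerateNormalizerError,
    InvalidCurveError,
    InvalidInputError,
    MismatchError,
)

logger = logging.getLogger(__name__)

#: Slope window corresponding to ~80-115% amplification efficiency.
ACCEPTABLE_SLOPE_RANGE = (-3.9, -3.0)


@dataclass(frozen=True)
class StandardCurve:
    """A fitted qPCR standard curve for one assay."""

    assay_id: str
    points: tuple[tuple[float, float], ...]  # (known_copies, cq)
    slope: float
    intercept: float
    r_squared: float

    @property
    def efficiency(self) -> float:
        """Amplification efficiency E = 10^(-1/slope) - 1."""
        return 10.0 ** (-1.0 / self.slope) - 1.0


@dataclass(frozen=True)
class QpcrMeasurement:
    assay_id: str
    sample_id: str
    cq_replicates: tuple[float, ...]
    copies: float
    copies_cv: float


@dataclass(frozen=True)
class QpcrConfig:
    """Genome copy-number assumptions for the 16S correction."""

    ss16_copies_per_genome: float = 1.9
    pr_copies_per_genome: float = 1.0
    taxa_assays: tuple[str, ...] = ("SAR11", "SAR92", "Flavo-NASB")

    def __post_init__(self) -> None:
        if self.ss16_copies_per_genome <= 0 or self.pr_copies_per_genome <= 0:
            raise InvalidInputError("copies-per-genome constants must be positive")


def fit_standard_curve(
    points: list[tuple[float, float]], assay_id: str = "assay"
) -> StandardCurve:
    """Least-squares fit of Cq against log10(known copies).

    Requires >= 3 points with distinct log10 copies. Warns when the slope
    leaves the ~80-115% efficiency window instead of failing: a sloppy
    curve is still a curve, and the caller sees r^2 and efficiency.
    """
    if len(points) < 3:
        raise InvalidCurveError(
            f"standard curve needs >= 3 dilution points, got {len(points)}"
        )
    for copies, _ in points:
        if copies <= 0:
            raise InvalidCurveError(f"known copies must be positive, got {copies}")
    x = [math.log10(copies) for copies, _ in points]
    y = [cq for _, cq in points]
    if len(set(x)) < 2:
        raise InvalidCurveError("dilution points are collinear in log10(copies)")
    fit = _stats.linregress(x, y)
    slope, intercept = float(fit.slope), float(fit.intercept)
    r_squared = float(fit.rvalue) ** 2
    if slope >= 0:
        raise InvalidCurveError(
            f"standard curve slope must be negative, got {slope:.3f}"
        )
    lo, hi = ACCEPTABLE_SLOPE_RANGE
    if not (lo <= slope <= hi):
        logger.warning(
            "assay %s: slope %.3f outside [%.1f, %.1f] "
            "(efficiency %.0f%% outside ~80-115%%)",
            assay_id,
            slope,
            lo,
            hi,
            100 * (10.0 ** (-1.0 / slope) - 1.0),
        )
    return StandardCurve(
        assay_id=assay_id,
        points=tuple((float(c), float(q)) for c, q in points),
        slope=slope,
        intercept=intercept,
        r_squared=r_squared,
    )


def quantify_copies(
    curve: StandardCurve,
    cq_replicates: list[float],
    sample_id: str = "sample",
) -> QpcrMeasurement:
    """Back-calculate template copies from replicate Cq values.

    The point estimate inverts the curve at the *mean Cq* (standard qPCR
    practice); the CV is computed from per-replicate back-calculated
    copies to expose replicate scatter on the copy scale.
    """
    if not cq_replicates:
        raise InvalidInputError("need at least one Cq replicate")
    for cq in cq_replicates:
        if not (0.0 <= cq <= 60.0):
            logger.warning(
                "sample %s assay %s: suspect Cq value %.2f outside [0, 60]",
                sample_id,
                curve.assay_id,
                cq,
            )
    mean_cq = mean(cq_replicates)
    copies = 10.0 ** ((mean_cq - curve.intercept) / curve.slope)
    per_rep = [10.0 ** ((cq - curve.intercept) / curve.slope) for cq in cq_replicates]
    cv = pstdev(per_rep) / mean(per_rep) if len(per_rep) > 1 else 0.0
    return QpcrMeasurement(
        assay_id=curve.assay_id,
        sample_id=sample_id,
        cq_replicates=tuple(float(c) for c in cq_replicates),
        copies=copies,
        copies_cv=cv,
    )


def pr_relative_abundance(
    pr: QpcrMeasurement,
    ss16: QpcrMeasurement,
    cfg: QpcrConfig | None = None,
) -> float:
    """PR-bearing fraction: PR genome equivalents / 16S genome equivalents.

    (pr.copies / 1 PR copy per genome) / (ss16.copies / 1.9 16S copies
    per genome). Invariant to scaling both assays' template by the same
    factor. Values > 1 are logged as flagged, never clamped.
    """
    cfg = cfg or QpcrConfig()
    if pr.sample_id != ss16.sample_id:
        raise MismatchError(
            f"PR and 16S measurements are from different samples "
            f"({pr.sample_id!r} vs {ss16.sample_id!r})"
        )
    if ss16.copies <= 0:
        raise DegenerateNormalizerError("16S copies must be positive")
    pr_genomes = pr.copies / cfg.pr_copies_per_genome
    cell_genomes = ss16.copies / cfg.ss16_copies_per_genome
    fraction = pr_genomes / cell_genomes
    if fraction > 1.0:
        logger.warning(
            "sample %s assay %s: PR-bearing fraction %.3f > 1 (flagged)",
            pr.sample_id,
            pr.assay_id,
            fraction,
        )
    return fraction


def total_pr_fraction(per_taxon: dict[str, float]) -> float:
    """Sum of per-taxon PR-bearing fractions ('total PR')."""
    if not per_taxon:
        raise InvalidInputError("no per-taxon fractions to sum")
    return float(sum(per_taxon.values()))


def curve_summary_tsv(curves: list[StandardCurve]) -> str:
    lines = ["assay_id\tslope\tintercept\tr_squared\tefficiency\tn_points"]
    for c in curves:
        lines.append(
            f"{c.assay_id}\t{c.slope:.4f}\t{c.intercept:.4f}"
            f"\t{c.r_squared:.5f}\t{c.efficiency:.4f}\t{len(c.points)}"
        )
    return "\n".join(lines) + "\n"


def measurements_to_tsv(rows: list[QpcrMeasurement]) -> str:
    lines = ["assay_id\tsample_id\tn_replicates\tmean_cq\tcopies\tcopies_cv"]
    for m in rows:
        lines.append(
            f"{m.assay_id}\t{m.sample_id}\t{len(m.cq_replicates)}"
            f"\t{mean(m.cq_replicates):.3f}\t{m.copies:.6g}\t{m.copies_cv:.4f}"
        )
    return "\n".join(lines) + "\n"
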