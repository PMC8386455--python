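"""Housekeeping-normalized relative expression from metatranscriptomes.

Relative expression of a gene (or gene class) is its length-normalized
transcript coverage divided by the *mean* transcript coverage of the
three constitutively expressed housekeeping families rplB, rpoB and
EF-Tu. The statistic is sequencing-depth invariant and equals 1.0 on
average over the housekeeping families themselves. recA is excluded
from the RNA normalizer by contract (non-constitutive expression).

The color partition splits proteorhodopsin transcript coverage between
blue- and green-tuned variants; the study's headline pattern — green
genes dominate the DNA while blue variants dominate transcription — is
exactly the kind of inversion this pair of statistics exposes.
"""

from __future__ import annotations

from dataclasses import dataclass

from .abundance import AbundanceConfig
from .counts import GeneCountTable, class_coverage
from .errors import (
    ConfigurationError,
    DegenerateNormalizerError,
    MismatchError,
)


@dataclass(frozen=True)
class ExpressionResult:
    sample_id: str
    gene_or_class: str
    relative_expression: float


@dataclass(frozen=True)
class ColorPartition:
    sample_id: str
    blue_fraction: float
    green_fraction: float
    unknown_mass: float


def _mean_hk_coverage(sub, cfg: AbundanceConfig, sample_id: str) -> float:
    covs = []
    for fam in cfg.housekeeping_set_rna:
        if fam == "recA":
            raise ConfigurationError("recA cannot normalize transcription")
        c = class_coverage(sub, fam)
        if c <= 0:
            raise DegenerateNormalizerError(
                f"housekeeping family {fam!r} has zero transcript coverage "
                f"in sample {sample_id!r}"
            )
        covs.append(c)
    return sum(covs) / len(covs)


def transcript_relative_abundance(
    table: GeneCountTable,
    sample_id: str,
    target: str,
    cfg: AbundanceConfig | None = None,
) -> ExpressionResult:
    """Relative expression of ``target`` (a gene_class or a gene_id).

    ``target`` is first matched against gene classes, then against
    individual gene ids; coverage sums over the matched rows.
    """
    cfg = cfg or AbundanceConfig()
    sub = table.sample(sample_id)
    hk_mean = _mean_hk_coverage(sub, cfg, sample_id)
    by_class = sub[sub["gene_class"] == target]
    matched = by_class if len(by_class) else sub[sub["gene_id"] == target]
    cov = float(matched["coverage"].sum()) if len(matched) else 0.0
    return ExpressionResult(
        sample_id=sample_id,
        gene_or_class=target,
        relative_expression=cov / hk_mean,
    )


def color_transcript_partition(
    table: GeneCountTable, sample_id: str
) -> ColorPartition:
    """Blue vs green share of colored PR transcript coverage.

    Unknown-color PR coverage is reported separately and excluded from
    the denominator, so blue_fraction + green_fraction == 1.
    """
    sub = table.sample(sample_id)
    pr = sub[sub["gene_class"] == "PR"].copy()
    pr["color"] = pr["color"].fillna("unknown")
    blue = float(pr.loc[pr["color"] == "blue", "coverage"].sum())
    green = float(pr.loc[pr["color"] == "green", "coverage"].sum())
    unknown = float(pr.loc[~pr["color"].isin(["blue", "green"]), "coverage"].sum())
    colored = blue + green
    if colored <= 0:
        raise DegenerateNormalizerError(
            f"no colored PR transcript coverage in sample {sample_id!r}"
        )
    return ColorPartition(
        sample_id=sample_id,
        blue_fraction=blue / colored,
        green_fraction=green / colored,
        unknown_mass=unknown,
    )


def gene_fold_ratio(expr_a: ExpressionResult, expr_b: ExpressionResult) -> float:
    """Fold ratio of two relative-expression results from one sample."""
    if expr_a.sample_id != expr_b.sample_id:
        raise MismatchError(
            f"cannot compare expression across samples "
            f"({expr_a.sample_id!r} vs {expr_b.sample_id!r})"
        )
    if expr_b.relative_expression <= 0:
        raise DegenerateNormalizerError(
            f"zero relative expression for {expr_b.gene_or_class!r}"
        )
    return expr_a.relative_expression / expr_b.relative_expression


def expression_results_to_tsv(results: list[ExpressionResult]) -> str:
    lines = ["sample_id\tgene_or_class\trelative_expression"]
    for r in results:
        lines.append(f"{r.sample_id}\t{r.gene_or_class}\t{r.relative_expression:.6g}")
    return "\n".join(lines) + "\n"
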