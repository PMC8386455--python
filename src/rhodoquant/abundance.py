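"""Metagenomic fraction of proteorhodopsin-bearing bacteria.

A single-copy housekeeping gene occurs once per bacterial genome, so the
ratio of length-normalized proteorhodopsin (PR) coverage to a
housekeeping family's coverage estimates the fraction of cells carrying
a PR gene. The estimator averages that ratio over four families (recA,
rplB, rpoB, EF-Tu):

    pr_fraction = mean_h [ C_PR / C_h ],   C = sum(count / gene_length)

with PR coverage pooled over all PR genes before each ratio. recA is a
valid DNA normalizer but not an RNA one (its expression is not
constitutive in these waters), which is why the RNA path uses a reduced
housekeeping set. Fractions above 1 are possible for a ratio of noisy
coverages; they are flagged, never clamped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping

from .counts import GeneCountTable, class_coverage
from .errors import ConfigurationError, DegenerateNormalizerError

DNA_HOUSEKEEPING = ("recA", "rplB", "rpoB", "EF-Tu")
RNA_HOUSEKEEPING = ("rplB", "rpoB", "EF-Tu")


@dataclass(frozen=True)
class AbundanceConfig:
    housekeeping_set_dna: tuple[str, ...] = DNA_HOUSEKEEPING
    housekeeping_set_rna: tuple[str, ...] = RNA_HOUSEKEEPING

    def __post_init__(self) -> None:
        if not set(self.housekeeping_set_rna) < set(self.housekeeping_set_dna):
            raise ConfigurationError(
                "RNA housekeeping set must be a proper subset of the DNA set"
            )
        if "recA" in self.housekeeping_set_rna:
            raise ConfigurationError(
                "recA is not constitutively expressed; it must not be used "
                "to normalize transcription"
            )


@dataclass(frozen=True)
class AbundanceResult:
    sample_id: str
    per_housekeeping_ratio: Mapping[str, float]
    pr_fraction: float
    flag_gt1: bool = field(default=False)


def pr_bearing_fraction(
    table: GeneCountTable,
    sample_id: str,
    cfg: AbundanceConfig | None = None,
) -> AbundanceResult:
    """Estimate the PR-bearing cell fraction in one metagenome sample.

    Raises :class:`DegenerateNormalizerError` naming the first
    housekeeping family with zero coverage.
    """
    cfg = cfg or AbundanceConfig()
    sub = table.sample(sample_id)
    c_pr = class_coverage(sub, "PR")
    ratios: dict[str, float] = {}
    for fam in cfg.housekeeping_set_dna:
        c_h = class_coverage(sub, fam)
        if c_h <= 0:
            raise DegenerateNormalizerError(
                f"housekeeping family {fam!r} has zero coverage in "
                f"sample {sample_id!r}"
            )
        ratios[fam] = c_pr / c_h
    fraction = sum(ratios.values()) / len(ratios)
    return AbundanceResult(
        sample_id=sample_id,
        per_housekeeping_ratio=ratios,
        pr_fraction=fraction,
        flag_gt1=fraction > 1.0,
    )


def otu_relative_abundance(
    table: GeneCountTable, sample_id: str
) -> dict[str, float]:
    """Per-OTU share of total PR coverage in a sample (sums to 1).

    Genes without an OTU label are pooled under ``"unassigned"``.
    """
    sub = table.sample(sample_id)
    pr = sub[sub["gene_class"] == "PR"].copy()
    total = float(pr["coverage"].sum())
    if total <= 0:
        raise DegenerateNormalizerError(
            f"total PR coverage is zero in sample {sample_id!r}"
        )
    pr["otu_id"] = pr["otu_id"].fillna("unassigned")
    shares = pr.groupby("otu_id")["coverage"].sum() / total
    return {str(k): float(v) for k, v in shares.sort_index().items()}


def color_gene_partition(
    table: GeneCountTable, sample_id: str, gene_class: str = "PR"
) -> dict[str, float]:
    """Blue/green share of colored PR gene coverage (DNA side).

    Returns blue_fraction + green_fraction over colored coverage plus the
    unknown-color coverage mass, mirroring the transcript partition.
    """
    sub = table.sample(sample_id)
    pr = sub[sub["gene_class"] == gene_class].copy()
    pr["color"] = pr["color"].fillna("unknown")
    blue = float(pr.loc[pr["color"] == "blue", "coverage"].sum())
    green = float(pr.loc[pr["color"] == "green", "coverage"].sum())
    unknown = float(pr.loc[~pr["color"].isin(["blue", "green"]), "coverage"].sum())
    colored = blue + green
    if colored <= 0:
        raise DegenerateNormalizerError(
            f"no colored {gene_class} coverage in sample {sample_id!r}"
        )
    return {
        "blue_fraction": blue / colored,
        "green_fraction": green / colored,
        "unknown_mass": unknown,
    }


def abundance_results_to_tsv(results: list[AbundanceResult]) -> str:
    fams = sorted({f for r in results for f in r.per_housekeeping_ratio})
    header = ["sample_id"] + [f"ratio_{f}" for f in fams] + ["pr_fraction", "flag_gt1"]
    lines = ["\t".join(header)]
    for r in results:
        row = [r.sample_id]
        row += [f"{r.per_housekeeping_ratio.get(f, float('nan')):.6g}" for f in fams]
        row += [f"{r.pr_fraction:.6g}", str(r.flag_gt1)]
        lines.append("\t".join(row))
    return "\n".join(lines) + "\n"
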