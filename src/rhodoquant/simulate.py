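"""Ground-truthed synthetic inputs for every stage of the pipeline.

The generator emulates the structure the estimators assume, not raw
sequencing: a community of bacterial taxa, each genome carrying exactly
one copy of the four single-copy housekeeping genes and zero or one
proteorhodopsin (PR) gene of known color; Poisson read counts
proportional to cell abundance x gene length x depth; transcript counts
additionally scaled by per-gene-class expression multipliers; and qPCR
Cq values drawn around a log-linear standard curve. Reads themselves
are abstracted away — counts are generated at the gene level because
read mapping is upstream of this package.

Every generator is a pure function of (specification, seed), and every
simulated sample carries analytic truths (PR-bearing fraction, color
shares, expression ratios) computed from the specification without
simulation, so recovery tests compare estimates against closed-form
truth, never against a second simulation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Mapping

import numpy as np
import pandas as pd
import yaml

from .annotate import (
    KEY_POSITIONS,
    AnnotatedReference,
    load_bundled_reference,
    map_reference_positions,
)
from .counts import GeneCountTable
from .errors import InvalidInputError, InvalidSpecError
from .io import ProteinRecord

#: Residues sampled for substitutions (standard 20).
_AAS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

HK_FAMILIES = ("recA", "rplB", "rpoB", "EF-Tu")
RETINAL_FAMILIES = ("blh", "crtB", "crtY")

#: Reference positions whose residues define the pump triad (never mutated
#: by the panel generator) and the tuning switch set per color.
_PROTECTED = (97, 101, 105, 108)


@dataclass(frozen=True)
class TaxonSpec:
    taxon_id: str
    relative_cell_abundance: float
    has_pr: bool = False
    pr_color: Literal["green", "blue"] | None = None
    pr_gene_length: int = 750
    expression_multipliers: Mapping[str, float] = field(default_factory=dict)

    def multiplier(self, gene_class: str) -> float:
        return float(self.expression_multipliers.get(gene_class, 1.0))


@dataclass(frozen=True)
class CommunitySpec:
    """Ground-truth community: who is there, who carries PR, who expresses.

    Invariants: abundances sum to 1 (+-1e-9); every taxon carries all four
    housekeeping families; PR-bearers carry exactly one PR gene (and, when
    ``retinal_gene_lengths`` is set, one copy of each retinal-pathway
    gene blh/crtB/crtY — PR without retinal would be a dark pigment).
    """

    taxa: tuple[TaxonSpec, ...]
    hk_gene_lengths: Mapping[str, int] = field(
        default_factory=lambda: {"recA": 1060, "rplB": 830, "rpoB": 4070, "EF-Tu": 1190}
    )
    retinal_gene_lengths: Mapping[str, int] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.taxa:
            raise InvalidSpecError("community needs at least one taxon")
        total = sum(t.relative_cell_abundance for t in self.taxa)
        if abs(total - 1.0) > 1e-9:
            raise InvalidSpecError(
                f"taxon abundances must sum to 1 (+-1e-9), got {total!r}"
            )
        missing = set(HK_FAMILIES) - set(self.hk_gene_lengths)
        if missing:
            raise InvalidSpecError(f"missing housekeeping gene lengths: {missing}")
        for t in self.taxa:
            if t.relative_cell_abundance < 0:
                raise InvalidSpecError(f"negative abundance for {t.taxon_id}")
            if t.has_pr and t.pr_color not in ("green", "blue"):
                raise InvalidSpecError(
                    f"PR-bearing taxon {t.taxon_id} needs pr_color green|blue"
                )

    # -- analytic truths ---------------------------------------------------

    @property
    def pr_bearing_fraction(self) -> float:
        return sum(t.relative_cell_abundance for t in self.taxa if t.has_pr)

    @property
    def green_gene_share(self) -> float:
        """Green share of PR gene (DNA) coverage = green cell share of PR."""
        green = sum(
            t.relative_cell_abundance
            for t in self.taxa
            if t.has_pr and t.pr_color == "green"
        )
        total = self.pr_bearing_fraction
        if total == 0:
            raise InvalidSpecError("no PR-bearing taxa")
        return green / total

    @property
    def blue_transcript_fraction(self) -> float:
        """Blue share of PR transcript coverage (abundance x multiplier)."""
        blue = green = 0.0
        for t in self.taxa:
            if not t.has_pr:
                continue
            mass = t.relative_cell_abundance * t.multiplier("PR")
            if t.pr_color == "blue":
                blue += mass
            else:
                green += mass
        if blue + green == 0:
            raise InvalidSpecError("no PR transcription in spec")
        return blue / (blue + green)

    def expected_relative_expression(self, gene_class: str) -> float:
        """Analytic relative expression of a gene class vs mean HK."""
        target = 0.0
        for t in self.taxa:
            if gene_class == "PR":
                if t.has_pr:
                    target += t.relative_cell_abundance * t.multiplier("PR")
            elif gene_class in RETINAL_FAMILIES:
                if t.has_pr and self.retinal_gene_lengths:
                    target += t.relative_cell_abundance * t.multiplier(gene_class)
            else:
                target += t.relative_cell_abundance * t.multiplier(gene_class)
        hk = [
            sum(t.relative_cell_abundance * t.multiplier(f) for t in self.taxa)
            for f in ("rplB", "rpoB", "EF-Tu")
        ]
        return target / (sum(hk) / len(hk))

    @property
    def otu_shares(self) -> dict[str, float]:
        """Per-OTU DNA share; one OTU per PR-bearing taxon, by abundance."""
        bearers = sorted(
            (t for t in self.taxa if t.has_pr),
            key=lambda t: (-t.relative_cell_abundance, t.taxon_id),
        )
        total = self.pr_bearing_fraction
        return {
            f"OTU{i:02d}": t.relative_cell_abundance / total
            for i, t in enumerate(bearers, start=1)
        }

    # -- (de)serialization --------------------------------------------------

    @classmethod
    def from_yaml(cls, path) -> "CommunitySpec":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        taxa = tuple(
            TaxonSpec(
                taxon_id=t["taxon_id"],
                relative_cell_abundance=float(t["relative_cell_abundance"]),
                has_pr=bool(t.get("has_pr", False)),
                pr_color=t.get("pr_color"),
                pr_gene_length=int(t.get("pr_gene_length", 750)),
                expression_multipliers={
                    k: float(v)
                    for k, v in (t.get("expression_multipliers") or {}).items()
                },
            )
            for t in raw["taxa"]
        )
        return cls(
            taxa=taxa,
            hk_gene_lengths={
                k: int(v)
                for k, v in (
                    raw.get("hk_gene_lengths")
                    or {"recA": 1060, "rplB": 830, "rpoB": 4070, "EF-Tu": 1190}
                ).items()
            },
            retinal_gene_lengths=(
                {k: int(v) for k, v in raw["retinal_gene_lengths"].items()}
                if raw.get("retinal_gene_lengths")
                else None
            ),
            seed=int(raw.get("seed", 0)),
        )


@dataclass(frozen=True)
class SimulatedSample:
    """A simulated count table plus the analytic truths it was drawn from."""

    sample_id: str
    counts: GeneCountTable
    truth: dict


# ---------------------------------------------------------------------------
# protein panel generation
# ---------------------------------------------------------------------------


def mutate_positions(
    record: ProteinRecord,
    reference: AnnotatedReference,
    edits: Mapping[int, str],
) -> ProteinRecord:
    """Replace residues at reference-numbered positions of ``record``.

    Positions are mapped through the optimal global alignment to the
    reference; an unmappable (gapped) position is an error. Everything
    outside the edited indices is untouched.
    """
    if not edits:
        return record
    mapping = map_reference_positions(record, reference)
    seq = list(record.sequence)
    for pos, residue in edits.items():
        if pos not in mapping:
            raise InvalidInputError(f"position {pos} is not a key position")
        idx = mapping[pos]
        if idx is None:
            raise InvalidInputError(
                f"position {pos} is unmappable (gap) in record {record.id}"
            )
        seq[idx - 1] = residue
    return record.with_sequence("".join(seq))


def _pr_variant(
    rng: np.random.Generator,
    ref_seq: str,
    protected_idx: set[int],
    tuning_idx: int,
    color: Literal["green", "blue"],
    max_sub_fraction: float = 0.12,
) -> str:
    seq = list(ref_seq)
    n_sub = int(rng.integers(5, max(6, int(max_sub_fraction * len(seq))) + 1))
    candidates = [i for i in range(len(seq)) if i not in protected_idx]
    for i in rng.choice(candidates, size=n_sub, replace=False):
        choices = [a for a in _AAS if a != seq[i]]
        seq[i] = str(rng.choice(choices))
    if color == "green":
        seq[tuning_idx] = "L" if rng.random() < 0.5 else "M"
    else:
        seq[tuning_idx] = "Q"
    return "".join(seq)


def _decoy(
    rng: np.random.Generator,
    ref_seq: str,
    core_span: tuple[int, int],
    sub_fraction: float = 0.35,
) -> str:
    """A rhodopsin-like sequence with the C-helix block deleted.

    Flanks keep enough similarity that the optimal global alignment
    anchors them, forcing a gap block across the key positions — so the
    decoy fails the coverage-based curation rule by construction.
    """
    lo, hi = core_span  # 1-based inclusive reference positions to delete
    seq = [c for i, c in enumerate(ref_seq, start=1) if not (lo <= i <= hi)]
    n_sub = int(sub_fraction * len(seq))
    for i in rng.choice(len(seq), size=n_sub, replace=False):
        choices = [a for a in _AAS if a != seq[i]]
        seq[i] = str(rng.choice(choices))
    return "".join(seq)


def generate_reference_panel(
    n_green: int,
    n_blue: int,
    n_decoys: int,
    seed: int,
    reference: AnnotatedReference | None = None,
) -> tuple[list[ProteinRecord], AnnotatedReference, pd.DataFrame]:
    """PR-like variants plus decoys, with a ground-truth table.

    Variants derive from the reference by bounded random substitutions
    that never touch the pump triad (97/101/108); the tuning residue 105
    is set to L/M (green) or Q (blue). Decoys lack the C-helix region
    entirely. Byte-identical output under a fixed seed.
    """
    if min(n_green, n_blue, n_decoys) < 0:
        raise InvalidInputError("panel counts must be non-negative")
    reference = reference or load_bundled_reference()
    ref_seq = reference.record.sequence
    protected = {reference.key_positions[p] - 1 for p in _PROTECTED}
    tuning_idx = reference.key_positions[105] - 1
    rng = np.random.default_rng(seed)
    records: list[ProteinRecord] = []
    truth_rows: list[dict] = []
    for i in range(n_green):
        seq = _pr_variant(rng, ref_seq, protected, tuning_idx, "green")
        rec = ProteinRecord(id=f"PRG{i + 1:03d}", sequence=seq)
        records.append(rec)
        truth_rows.append(
            {"id": rec.id, "class": "green", "residue_105": seq[tuning_idx]}
        )
    for i in range(n_blue):
        seq = _pr_variant(rng, ref_seq, protected, tuning_idx, "blue")
        rec = ProteinRecord(id=f"PRB{i + 1:03d}", sequence=seq)
        records.append(rec)
        truth_rows.append({"id": rec.id, "class": "blue", "residue_105": "Q"})
    for i in range(n_decoys):
        seq = _decoy(rng, ref_seq, core_span=(91, 120))
        rec = ProteinRecord(id=f"DEC{i + 1:03d}", sequence=seq)
        records.append(rec)
        truth_rows.append({"id": rec.id, "class": "decoy", "residue_105": None})
    truth = pd.DataFrame(truth_rows, columns=["id", "class", "residue_105"])
    return records, reference, truth


# ---------------------------------------------------------------------------
# community catalogs and count simulation
# ---------------------------------------------------------------------------


def generate_community(spec: CommunitySpec) -> pd.DataFrame:
    """Gene catalog: one row per (taxon, gene) with abundance and lengths.

    Columns: taxon, gene_id, gene_class, gene_length, color, otu_id,
    abundance, multiplier. OTU ids label each PR-bearing taxon's PR gene
    in descending-abundance order, matching ``spec.otu_shares``.
    """
    otu_by_taxon: dict[str, str] = {}
    bearers = sorted(
        (t for t in spec.taxa if t.has_pr),
        key=lambda t: (-t.relative_cell_abundance, t.taxon_id),
    )
    for i, t in enumerate(bearers, start=1):
        otu_by_taxon[t.taxon_id] = f"OTU{i:02d}"

    rows: list[dict] = []
    for t in spec.taxa:
        for fam in HK_FAMILIES:
            rows.append(
                {
                    "taxon": t.taxon_id,
                    "gene_id": f"{t.taxon_id}_{fam}",
                    "gene_class": fam,
                    "gene_length": int(spec.hk_gene_lengths[fam]),
                    "color": None,
                    "otu_id": None,
                    "abundance": t.relative_cell_abundance,
                    "multiplier": t.multiplier(fam),
                }
            )
        if t.has_pr:
            rows.append(
                {
                    "taxon": t.taxon_id,
                    "gene_id": f"{t.taxon_id}_PR",
                    "gene_class": "PR",
                    "gene_length": t.pr_gene_length,
                    "color": t.pr_color,
                    "otu_id": otu_by_taxon[t.taxon_id],
                    "abundance": t.relative_cell_abundance,
                    "multiplier": t.multiplier("PR"),
                }
            )
            if spec.retinal_gene_lengths:
                for fam in RETINAL_FAMILIES:
                    rows.append(
                        {
                            "taxon": t.taxon_id,
                            "gene_id": f"{t.taxon_id}_{fam}",
                            "gene_class": fam,
                            "gene_length": int(spec.retinal_gene_lengths[fam]),
                            "color": None,
                            "otu_id": None,
                            "abundance": t.relative_cell_abundance,
                            "multiplier": t.multiplier(fam),
                        }
                    )
    return pd.DataFrame(rows)


def _truth(spec: CommunitySpec) -> dict:
    truth = {
        "pr_bearing_fraction": spec.pr_bearing_fraction,
        "otu_shares": spec.otu_shares,
    }
    try:
        truth["green_gene_share"] = spec.green_gene_share
        truth["blue_transcript_fraction"] = spec.blue_transcript_fraction
        truth["relative_expression"] = {
            cls: spec.expected_relative_expression(cls)
            for cls in ("PR",) + (RETINAL_FAMILIES if spec.retinal_gene_lengths else ())
        }
    except InvalidSpecError:
        pass
    return truth


def _simulate_counts(
    catalog: pd.DataFrame,
    spec: CommunitySpec,
    depth: float,
    seed: int,
    sample_id: str,
    use_multipliers: bool,
) -> SimulatedSample:
    if depth <= 0:
        raise InvalidInputError(f"depth must be positive, got {depth}")
    rng = np.random.default_rng(seed)
    lam = catalog["abundance"] * catalog["gene_length"] * depth
    if use_multipliers:
        lam = lam * catalog["multiplier"]
    counts = rng.poisson(lam.to_numpy(dtype=float))
    df = pd.DataFrame(
        {
            "sample_id": sample_id,
            "gene_id": catalog["gene_id"],
            "gene_class": catalog["gene_class"],
            "gene_length": catalog["gene_length"],
            "count": counts,
            "otu_id": catalog["otu_id"],
            "color": catalog["color"],
            "taxon": catalog["taxon"],
        }
    )
    return SimulatedSample(
        sample_id=sample_id, counts=GeneCountTable(df), truth=_truth(spec)
    )


def simulate_gene_counts(
    spec: CommunitySpec,
    depth: float,
    seed: int,
    sample_id: str = "metaG",
    catalog: pd.DataFrame | None = None,
) -> SimulatedSample:
    """Poisson metagenome read counts: count ~ Pois(abundance x length x depth).

    Expected coverage of every gene is abundance x depth, so the
    PR-bearing fraction estimator is exercised exactly under its model.
    """
    catalog = catalog if catalog is not None else generate_community(spec)
    return _simulate_counts(catalog, spec, depth, seed, sample_id, False)


def simulate_transcript_counts(
    spec: CommunitySpec,
    depth: float,
    seed: int,
    sample_id: str = "metaT",
    catalog: pd.DataFrame | None = None,
) -> SimulatedSample:
    """Poisson transcript counts with per-gene expression multipliers."""
    catalog = catalog if catalog is not None else generate_community(spec)
    if (catalog["multiplier"] <= 0).any():
        raise InvalidInputError("expression multipliers must be positive")
    return _simulate_counts(catalog, spec, depth, seed, sample_id, True)


# ---------------------------------------------------------------------------
# qPCR simulation
# ---------------------------------------------------------------------------


def simulate_qpcr_run(
    true_copies: Mapping[str, float],
    slope: float = -3.4,
    intercept: float = 38.0,
    noise_sd: float = 0.0,
    n_replicates: int = 3,
    seed: int = 0,
    sample_id: str = "sample",
    standard_decades: tuple[int, int] = (8, 2),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Standards (decade dilutions 10^8..10^2) and sample Cq tables.

    Cq = intercept + slope*log10(copies) + N(0, noise_sd), independently
    per standard point and per sample replicate. With ``noise_sd=0`` the
    round trip through curve fitting and quantification is exact.
    """
    if slope >= 0:
        raise InvalidInputError("standard-curve slope must be negative")
    if noise_sd < 0:
        raise InvalidInputError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    hi, lo = standard_decades
    std_rows = []
    for assay in sorted(true_copies):
        for exp10 in range(hi, lo - 1, -1):
            copies = 10.0**exp10
            cq = intercept + slope * exp10 + (rng.normal(0, noise_sd) if noise_sd else 0)
            std_rows.append({"assay_id": assay, "known_copies": copies, "cq": cq})
    sample_rows = []
    for assay in sorted(true_copies):
        copies = float(true_copies[assay])
        if copies <= 0:
            raise InvalidInputError(f"true copies for {assay} must be positive")
        base = intercept + slope * math.log10(copies)
        for rep in range(1, n_replicates + 1):
            cq = base + (rng.normal(0, noise_sd) if noise_sd else 0)
            sample_rows.append(
                {"assay_id": assay, "sample_id": sample_id, "replicate": rep, "cq": cq}
            )
    return pd.DataFrame(std_rows), pd.DataFrame(sample_rows)


# ---------------------------------------------------------------------------
# study-scale default community
# ---------------------------------------------------------------------------


def default_community(seed: int = 0) -> CommunitySpec:
    """The packaged study-scale community.

    Ten taxa; three carry PR, at cell abundances 0.07 (green, a
    Flavobacteriia-like lineage), 0.05 (green, SAR92-like) and 0.05
    (blue, SAR11-like): a PR-bearing fraction of 0.17 with a green gene
    share of ~71%. Expression multipliers put the blue PR far above the
    green ones (the SAR11 pattern: blue dominates transcription despite
    green dominating the DNA) and plant the retinal pathway genes at a
    15:1 PR:blh transcription ratio. Housekeeping genes use typical
    bacterial CDS lengths and multiplier 1.
    """
    pr_transcript_mass = 0.05 * 30.0 + (0.07 + 0.05) * 5.0  # = 2.1
    pr_total = 0.17
    blh_mult = pr_transcript_mass / (15.0 * pr_total)
    retinal = {"blh": blh_mult, "crtB": 0.5, "crtY": 0.5}
    bearers = [
        TaxonSpec(
            "Flavo_NASB",
            0.07,
            has_pr=True,
            pr_color="green",
            pr_gene_length=750,
            expression_multipliers={"PR": 5.0, **retinal},
        ),
        TaxonSpec(
            "SAR92",
            0.05,
            has_pr=True,
            pr_color="green",
            pr_gene_length=762,
            expression_multipliers={"PR": 5.0, **retinal},
        ),
        TaxonSpec(
            "SAR11",
            0.05,
            has_pr=True,
            pr_color="blue",
            pr_gene_length=741,
            expression_multipliers={"PR": 30.0, **retinal},
        ),
    ]
    others = [
        TaxonSpec(f"nonPR{i:02d}", ab)
        for i, ab in enumerate(
            [0.20, 0.15, 0.13, 0.12, 0.10, 0.08, 0.05], start=1
        )
    ]
    return CommunitySpec(
        taxa=tuple(bearers + others),
        retinal_gene_lengths={"blh": 900, "crtB": 930, "crtY": 1150},
        seed=seed,
    )
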