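"""Pipeline orchestration: screen -> annotate -> cluster -> quantify.

Stages communicate through on-disk TSV contracts so that any stage can
be run standalone and real mapper/search outputs can be substituted for
the internal stand-ins. A stage whose inputs are absent from the
configuration is skipped; a failing stage halts the run with its name
and input context, and downstream stages are marked not-run. Outputs
are deterministic: no timestamps, locale- or path-order-dependent
content, so re-running an unchanged configuration reproduces the run
directory byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .abundance import (
    AbundanceConfig,
    abundance_results_to_tsv,
    color_gene_partition,
    otu_relative_abundance,
    pr_bearing_fraction,
)
from .annotate import annotate_proteins, annotations_to_tsv, load_bundled_reference
from .cluster import (
    ClusterConfig,
    assignments_to_tsv,
    cluster_greedy,
    cluster_summary_tsv,
)
from .counts import GeneCountTable
from .errors import PipelineStageError, RhodoquantError
from .io import read_fasta
from .qpcr import (
    QpcrConfig,
    curve_summary_tsv,
    fit_standard_curve,
    measurements_to_tsv,
    pr_relative_abundance,
    quantify_copies,
)
from .screen import (
    ScreenConfig,
    curate_candidates,
    import_external_hits,
    screen_results_to_tsv,
    search_candidates,
)
from .transcription import (
    color_transcript_partition,
    expression_results_to_tsv,
    transcript_relative_abundance,
)

logger = logging.getLogger(__name__)

STAGES = ("screen", "annotate", "cluster", "abundance", "transcription", "qpcr")

#: Gene classes whose expression the transcription stage reports.
EXPRESSION_TARGETS = ("PR", "blh", "crtB", "crtY")


@dataclass
class StageRecord:
    status: str = "not-run"  # ok | skipped | failed | not-run
    n_records: int = 0
    outputs: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    message: str = ""


@dataclass
class RunSummary:
    output_dir: Path
    stages: dict[str, StageRecord]
    results: dict = field(default_factory=dict)

    def to_manifest(self) -> dict:
        return {
            "rhodoquant_version": __version__,
            "stages": {
                name: {
                    "status": rec.status,
                    "n_records": rec.n_records,
                    "outputs": sorted(rec.outputs),
                    "warnings": rec.warnings,
                    "message": rec.message,
                }
                for name, rec in self.stages.items()
            },
        }


@dataclass(frozen=True)
class PipelineConfig:
    """Validated pipeline configuration (usually loaded from YAML)."""

    output_dir: Path
    screen: dict = field(default_factory=dict)
    cluster: dict = field(default_factory=dict)
    abundance: dict = field(default_factory=dict)
    transcription: dict = field(default_factory=dict)
    qpcr: dict = field(default_factory=dict)
    truth: str | None = None
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        base = path.parent

        def _resolve(section: dict, keys: tuple[str, ...]) -> dict:
            out = dict(section)
            for key in keys:
                if key in out and out[key] is not None:
                    p = Path(out[key])
                    out[key] = str(p if p.is_absolute() else base / p)
            return out

        truth = raw.get("truth")
        if truth is not None:
            p = Path(truth)
            truth = str(p if p.is_absolute() else base / p)
        cfg = cls(
            output_dir=Path(raw.get("output_dir", "rhodoquant_run")),
            screen=_resolve(raw.get("screen") or {}, ("proteins", "panel", "hits")),
            cluster=dict(raw.get("cluster") or {}),
            abundance=_resolve(raw.get("abundance") or {}, ("counts",)),
            transcription=_resolve(raw.get("transcription") or {}, ("counts",)),
            qpcr=_resolve(raw.get("qpcr") or {}, ("standards", "samples")),
            truth=truth,
            seed=int(raw.get("seed", 0)),
            log_level=str(raw.get("log_level", "INFO")),
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for section in (self.screen, self.abundance, self.transcription, self.qpcr):
            for key, value in section.items():
                if key in {"proteins", "panel", "hits", "counts", "standards",
                           "samples"} and value is not None:
                    if not Path(value).exists():
                        raise PipelineStageError(
                            "config", f"referenced file does not exist: {value}"
                        )


def _write(outdir: Path, name: str, text: str, rec: StageRecord) -> None:
    path = outdir / name
    path.write_text(text)
    rec.outputs.append(name)


def run_pipeline(cfg: PipelineConfig) -> RunSummary:
    """Execute the configured stages in dependency order."""
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary = RunSummary(
        output_dir=outdir, stages={name: StageRecord() for name in STAGES}
    )
    if cfg.truth:
        with open(cfg.truth) as fh:
            summary.results["truth"] = json.load(fh)
    halted = False
    for stage in STAGES:
        rec = summary.stages[stage]
        if halted:
            rec.status = "not-run"
            continue
        runner = _STAGE_RUNNERS[stage]
        try:
            ran = runner(cfg, outdir, summary, rec)
            rec.status = "ok" if ran else "skipped"
        except RhodoquantError as exc:
            rec.status = "failed"
            rec.message = str(exc)
            logger.error("stage %s failed: %s", stage, exc)
            halted = True
    manifest = summary.to_manifest()
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    if halted:
        failed = [s for s, r in summary.stages.items() if r.status == "failed"][0]
        raise PipelineStageError(failed, summary.stages[failed].message)
    return summary


# ---------------------------------------------------------------------------
# stage runners (return False when skipped)
# ---------------------------------------------------------------------------


def _run_screen(cfg, outdir, summary, rec) -> bool:
    section = cfg.screen
    if not section.get("proteins"):
        return False
    proteins = read_fasta(section["proteins"])
    reference = load_bundled_reference()
    screen_cfg = ScreenConfig(
        reference_panel=tuple(read_fasta(section["panel"])) if section.get("panel") else (),
        min_length_aa=int(section.get("min_length_aa", 100)),
        min_bitlike_score=float(section.get("min_bitlike_score", 50.0)),
        evalue_max_import=float(section.get("evalue_max_import", 1e-7)),
    )
    hits: dict[str, tuple[str, float]] = {}
    candidates = proteins
    if section.get("hits"):
        imported = import_external_hits(section["hits"], screen_cfg)
        hits = {q: (s, e) for q, s, e in imported}
        candidates = [p for p in proteins if p.id in hits]
    elif screen_cfg.reference_panel:
        found = search_candidates(proteins, screen_cfg)
        hits = {q: (s, sc) for q, s, sc in found}
        candidates = [p for p in proteins if p.id in hits]
    results = curate_candidates(candidates, reference, screen_cfg, hits=hits)
    retained = [r.record for r in results if r.retained]
    for r in results:
        if not r.retained:
            rec.warnings.append(
                f"{r.record.id}: rejected "
                f"(length={'ok' if r.passed_length else 'fail'}, "
                f"domain={'ok' if r.domain_region_covered else 'fail'})"
            )
    _write(outdir, "screen_results.tsv", screen_results_to_tsv(results), rec)
    rec.n_records = len(retained)
    summary.results["retained"] = retained
    return True


def _run_annotate(cfg, outdir, summary, rec) -> bool:
    retained = summary.results.get("retained")
    if not retained:
        return False
    anns = annotate_proteins(retained)
    _write(outdir, "annotations.tsv", annotations_to_tsv(anns), rec)
    from .annotate import KEY_POSITIONS, position_profile

    lines = ["position\tresidue\tcount\tfrequency\tgap_count"]
    for pos in KEY_POSITIONS:
        prof = position_profile(anns, pos)
        for res in sorted(prof.counts):
            lines.append(
                f"{pos}\t{res}\t{prof.counts[res]}"
                f"\t{prof.frequencies[res]:.4f}\t{prof.gap_count}"
            )
    _write(outdir, "position_profiles.tsv", "\n".join(lines) + "\n", rec)
    non_functional = [a.query_id for a in anns if a.pump_call != "functional"]
    if non_functional:
        rec.warnings.append(f"non-canonical pump triad: {sorted(non_functional)}")
    rec.n_records = len(anns)
    summary.results["annotations"] = anns
    return True


def _run_cluster(cfg, outdir, summary, rec) -> bool:
    retained = summary.results.get("retained")
    if not retained:
        return False
    ccfg = ClusterConfig(
        identity_threshold=float(cfg.cluster.get("identity_threshold", 0.82))
    )
    assignments = cluster_greedy(retained, ccfg)
    _write(outdir, "clusters.tsv", assignments_to_tsv(assignments), rec)
    _write(outdir, "cluster_summary.tsv", cluster_summary_tsv(assignments), rec)
    rec.n_records = len(assignments)
    summary.results["clusters"] = assignments
    return True


def _run_abundance(cfg, outdir, summary, rec) -> bool:
    if not cfg.abundance.get("counts"):
        return False
    table = GeneCountTable.from_tsv(cfg.abundance["counts"])
    results = [pr_bearing_fraction(table, s) for s in table.sample_ids]
    for r in results:
        if r.flag_gt1:
            rec.warnings.append(f"{r.sample_id}: PR fraction {r.pr_fraction:.3f} > 1")
    _write(outdir, "abundance.tsv", abundance_results_to_tsv(results), rec)
    share_lines = ["sample_id\totu_id\tshare"]
    color_lines = ["sample_id\tblue_fraction\tgreen_fraction\tunknown_mass"]
    for s in table.sample_ids:
        for otu, share in otu_relative_abundance(table, s).items():
            share_lines.append(f"{s}\t{otu}\t{share:.6g}")
        try:
            part = color_gene_partition(table, s)
            color_lines.append(
                f"{s}\t{part['blue_fraction']:.6g}\t{part['green_fraction']:.6g}"
                f"\t{part['unknown_mass']:.6g}"
            )
        except RhodoquantError:
            pass
    _write(outdir, "otu_shares.tsv", "\n".join(share_lines) + "\n", rec)
    _write(outdir, "dna_color_partition.tsv", "\n".join(color_lines) + "\n", rec)
    rec.n_records = len(results)
    summary.results["abundance"] = results
    return True


def _run_transcription(cfg, outdir, summary, rec) -> bool:
    if not cfg.transcription.get("counts"):
        return False
    table = GeneCountTable.from_tsv(cfg.transcription["counts"])
    acfg = AbundanceConfig()
    expr = [
        transcript_relative_abundance(table, s, target, acfg)
        for s in table.sample_ids
        for target in EXPRESSION_TARGETS
    ]
    _write(outdir, "expression.tsv", expression_results_to_tsv(expr), rec)
    lines = ["sample_id\tblue_fraction\tgreen_fraction\tunknown_mass"]
    partitions = {}
    for s in table.sample_ids:
        try:
            part = color_transcript_partition(table, s)
            partitions[s] = part
            lines.append(
                f"{s}\t{part.blue_fraction:.6g}\t{part.green_fraction:.6g}"
                f"\t{part.unknown_mass:.6g}"
            )
        except RhodoquantError:
            rec.warnings.append(f"{s}: no colored PR transcript coverage")
    _write(outdir, "rna_color_partition.tsv", "\n".join(lines) + "\n", rec)
    rec.n_records = len(expr)
    summary.results["expression"] = expr
    summary.results["rna_color_partition"] = partitions
    return True


def _run_qpcr(cfg, outdir, summary, rec) -> bool:
    section = cfg.qpcr
    if not (section.get("standards") and section.get("samples")):
        return False
    qcfg = QpcrConfig(
        ss16_copies_per_genome=float(section.get("ss16_copies_per_genome", 1.9)),
        pr_copies_per_genome=float(section.get("pr_copies_per_genome", 1.0)),
    )
    standards = pd.read_csv(section["standards"], sep="\t")
    samples = pd.read_csv(section["samples"], sep="\t")
    curves = {
        assay: fit_standard_curve(
            list(zip(grp["known_copies"], grp["cq"])), assay_id=assay
        )
        for assay, grp in standards.groupby("assay_id", sort=True)
    }
    measurements = []
    for (assay, sample), grp in samples.groupby(["assay_id", "sample_id"], sort=True):
        measurements.append(
            quantify_copies(curves[assay], grp["cq"].tolist(), sample_id=sample)
        )
    _write(outdir, "qpcr_curves.tsv", curve_summary_tsv(sorted(
        curves.values(), key=lambda c: c.assay_id)), rec)
    _write(outdir, "qpcr_measurements.tsv", measurements_to_tsv(measurements), rec)

    by_sample: dict[str, dict[str, object]] = {}
    for m in measurements:
        by_sample.setdefault(m.sample_id, {})[m.assay_id] = m
    lines = ["sample_id\tassay_id\tpr_fraction"]
    fractions: dict[str, dict[str, float]] = {}
    for sample in sorted(by_sample):
        assays = by_sample[sample]
        ss16 = assays.get("16S")
        if ss16 is None:
            rec.warnings.append(f"{sample}: no 16S assay; fractions not computed")
            continue
        per_taxon = {}
        for assay in sorted(assays):
            if assay == "16S":
                continue
            frac = pr_relative_abundance(assays[assay], ss16, qcfg)
            per_taxon[assay] = frac
            if frac > 1:
                rec.warnings.append(f"{sample}/{assay}: fraction {frac:.3f} > 1")
            lines.append(f"{sample}\t{assay}\t{frac:.6g}")
        if per_taxon:
            lines.append(f"{sample}\ttotal_PR\t{sum(per_taxon.values()):.6g}")
            fractions[sample] = per_taxon
    _write(outdir, "qpcr_fractions.tsv", "\n".join(lines) + "\n", rec)
    rec.n_records = len(measurements)
    summary.results["qpcr_fractions"] = fractions
    return True


_STAGE_RUNNERS = {
    "screen": _run_screen,
    "annotate": _run_annotate,
    "cluster": _run_cluster,
    "abundance": _run_abundance,
    "transcription": _run_transcription,
    "qpcr": _run_qpcr,
}


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------


def emit_report(summary: RunSummary) -> str:
    """Human-readable consolidated report; also written to report.txt."""
    ran = [s for s, r in summary.stages.items() if r.status == "ok"]
    if not ran:
        raise PipelineStageError("report", "no stage ran; nothing to report")
    lines = ["# rhodoquant run report", ""]
    lines.append("## Stage status")
    for name in STAGES:
        rec = summary.stages[name]
        lines.append(f"- {name}: {rec.status} ({rec.n_records} records)")
    retained = summary.results.get("retained")
    if retained is not None:
        lines += ["", "## Screening", f"retained proteins: {len(retained)}"]
    anns = summary.results.get("annotations")
    if anns:
        pump = sum(1 for a in anns if a.pump_call == "functional")
        colors = {c: sum(1 for a in anns if a.color_call == c)
                  for c in ("green", "blue", "unknown", "undetermined")}
        lines += [
            "",
            "## Annotation",
            f"functional pump triad: {pump}/{len(anns)}",
            f"color calls: {colors}",
        ]
    clusters = summary.results.get("clusters")
    if clusters:
        lines += ["", "## Clustering", f"PR OTUs: {len(clusters)}"]
        for otu in clusters:
            lines.append(
                f"- {otu.otu_id}: {len(otu.member_ids)} member(s), "
                f"rep {otu.representative_id}"
            )
    abund = summary.results.get("abundance")
    if abund:
        lines += ["", "## Metagenomic PR-bearing fraction"]
        for r in abund:
            flag = "  [>1 flagged]" if r.flag_gt1 else ""
            lines.append(f"- {r.sample_id}: {r.pr_fraction:.4f}{flag}")
    expr = summary.results.get("expression")
    if expr:
        lines += ["", "## Relative expression (vs mean HK)"]
        for e in expr:
            lines.append(
                f"- {e.sample_id} {e.gene_or_class}: {e.relative_expression:.3f}"
            )
    qfracs = summary.results.get("qpcr_fractions")
    if qfracs:
        lines += ["", "## qPCR PR-bearing fractions (16S-corrected)"]
        for sample in sorted(qfracs):
            for assay in sorted(qfracs[sample]):
                lines.append(f"- {sample} {assay}: {qfracs[sample][assay]:.4f}")
            lines.append(f"- {sample} total_PR: {sum(qfracs[sample].values()):.4f}")
    truth = summary.results.get("truth")
    if truth:
        lines += ["", "## Truth vs estimate (synthetic run)"]
        if abund and "pr_bearing_fraction" in truth:
            t = truth["pr_bearing_fraction"]
            for r in abund:
                lines.append(
                    f"- {r.sample_id} pr_fraction: est {r.pr_fraction:.4f} "
                    f"truth {t:.4f} delta {r.pr_fraction - t:+.4f}"
                )
        parts = summary.results.get("rna_color_partition") or {}
        if "blue_transcript_fraction" in truth:
            t = truth["blue_transcript_fraction"]
            for s, part in parts.items():
                lines.append(
                    f"- {s} blue_fraction: est {part.blue_fraction:.4f} "
                    f"truth {t:.4f} delta {part.blue_fraction - t:+.4f}"
                )
        rel = truth.get("relative_expression") or {}
        for e in expr or []:
            if e.gene_or_class in rel:
                t = rel[e.gene_or_class]
                lines.append(
                    f"- {e.sample_id} relexp[{e.gene_or_class}]: "
                    f"est {e.relative_expression:.4f} truth {t:.4f} "
                    f"delta {e.relative_expression - t:+.4f}"
                )
    warnings = [
        f"{name}: {w}" for name in STAGES for w in summary.stages[name].warnings
    ]
    lines += ["", "## Flags"]
    lines += [f"- {w}" for w in warnings] if warnings else ["- none"]
    text = "\n".join(lines) + "\n"
    (summary.output_dir / "report.txt").write_text(text)
    return text


# ---------------------------------------------------------------------------
# bundled demo
# ---------------------------------------------------------------------------


def write_demo_inputs(directory: str | Path, seed: int = 0) -> Path:
    """Generate a full synthetic input set + config; returns the config path.

    The demo mirrors the packaged study-scale community: a protein panel
    for screening, DNA and RNA count tables, and a simulated qPCR run
    whose true per-taxon fractions are recoverable.
    """
    from .io import write_fasta
    from .simulate import (
        default_community,
        generate_reference_panel,
        simulate_gene_counts,
        simulate_qpcr_run,
        simulate_transcript_counts,
    )

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    panel, _, _ = generate_reference_panel(6, 3, 2, seed=seed)
    write_fasta(panel, directory / "proteins.faa")
    write_fasta(panel[:4], directory / "panel.faa")

    spec = default_community(seed=seed)
    dna = simulate_gene_counts(spec, depth=2000.0, seed=seed + 1)
    rna = simulate_transcript_counts(spec, depth=2000.0, seed=seed + 2)
    dna.counts.to_tsv(directory / "dna_counts.tsv")
    rna.counts.to_tsv(directory / "rna_counts.tsv")

    total_16s = 2.0e5
    genomes = total_16s / 1.9
    true_copies = {"16S": total_16s}
    assay_names = {"SAR11": "SAR11", "SAR92": "SAR92", "Flavo_NASB": "Flavo-NASB"}
    for taxon in spec.taxa:
        if taxon.has_pr:
            assay = assay_names.get(taxon.taxon_id, taxon.taxon_id)
            true_copies[assay] = genomes * taxon.relative_cell_abundance
    standards, samples = simulate_qpcr_run(
        true_copies, noise_sd=0.1, seed=seed + 3, sample_id="ChileBay_2m"
    )
    standards.to_csv(directory / "qpcr_standards.tsv", sep="\t", index=False)
    samples.to_csv(directory / "qpcr_samples.tsv", sep="\t", index=False)

    truth = dict(dna.truth)
    truth["qpcr_true_fractions"] = {
        assay: true_copies[assay] / genomes
        for assay in sorted(true_copies)
        if assay != "16S"
    }
    (directory / "truth.json").write_text(
        json.dumps(truth, indent=2, sort_keys=True) + "\n"
    )

    config = {
        "output_dir": str(directory / "run"),
        "seed": seed,
        "screen": {"proteins": "proteins.faa", "panel": "panel.faa"},
        "cluster": {"identity_threshold": 0.82},
        "abundance": {"counts": "dna_counts.tsv"},
        "transcription": {"counts": "rna_counts.tsv"},
        "qpcr": {"standards": "qpcr_standards.tsv", "samples": "qpcr_samples.tsv"},
        "truth": "truth.json",
    }
    config_path = directory / "config.yml"
    config_path.write_text(yaml.safe_dump(config, sort_keys=True))
    return config_path
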