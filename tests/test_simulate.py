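"""Synthetic community generator: determinism, truths, round trips."""

import numpy as np
import pandas as pd
import pytest

from rhodoquant.abundance import pr_bearing_fraction
from rhodoquant.annotate import annotate_protein
from rhodoquant.errors import InvalidInputError, InvalidSpecError
from rhodoquant.io import read_fasta, write_fasta
from rhodoquant.simulate import (
    CommunitySpec,
    TaxonSpec,
    default_community,
    generate_community,
    generate_reference_panel,
    mutate_positions,
    simulate_gene_counts,
    simulate_qpcr_run,
    simulate_transcript_counts,
)
from rhodoquant.transcription import transcript_relative_abundance


class TestReferencePanel:
    def test_color_calls_forced_by_construction(self):
        panel, ref, truth = generate_reference_panel(1, 1, 0, seed=7)
        calls = [annotate_protein(rec, ref).color_call for rec in panel]
        assert calls == ["green", "blue"]

    def test_same_seed_is_byte_identical(self):
        a, _, ta = generate_reference_panel(3, 3, 3, seed=41)
        b, _, tb = generate_reference_panel(3, 3, 3, seed=41)
        assert [(r.id, r.sequence) for r in a] == [(r.id, r.sequence) for r in b]
        pd.testing.assert_frame_equal(ta, tb)

    def test_different_seed_differs(self):
        a, _, _ = generate_reference_panel(3, 0, 0, seed=1)
        b, _, _ = generate_reference_panel(3, 0, 0, seed=2)
        assert [r.sequence for r in a] != [r.sequence for r in b]

    def test_negative_counts_rejected(self):
        with pytest.raises(InvalidInputError):
            generate_reference_panel(-1, 0, 0, seed=0)

    def test_fasta_round_trip_lossless(self, tmp_path):
        panel, _, _ = generate_reference_panel(2, 2, 2, seed=13)
        path = tmp_path / "panel.faa"
        write_fasta(panel, path)
        back = read_fasta(path)
        assert [(r.id, r.sequence) for r in back] == [
            (r.id, r.sequence) for r in panel
        ]


class TestMutatePositions:
    def test_k108_makes_pump_non_canonical(self):
        panel, ref, _ = generate_reference_panel(1, 0, 0, seed=5)
        mutant = mutate_positions(panel[0], ref, {108: "K"})
        assert annotate_protein(mutant, ref).pump_call == "non_canonical"

    def test_empty_edits_identical(self):
        panel, ref, _ = generate_reference_panel(1, 0, 0, seed=5)
        assert mutate_positions(panel[0], ref, {}) == panel[0]

    def test_only_target_residue_changes(self):
        panel, ref, _ = generate_reference_panel(1, 0, 0, seed=5)
        mutant = mutate_positions(panel[0], ref, {105: "Q"})
        diffs = [
            i for i, (a, b) in enumerate(zip(panel[0].sequence, mutant.sequence))
            if a != b
        ]
        assert len(diffs) == 1


class TestCommunitySpec:
    def test_truth_fraction_half(self):
        spec = CommunitySpec(
            taxa=(
                TaxonSpec("a", 0.5, has_pr=True, pr_color="green"),
                TaxonSpec("b", 0.5),
            )
        )
        assert spec.pr_bearing_fraction == pytest.approx(0.5)

    def test_truth_fraction_seventeen_percent(self):
        abund = [0.05, 0.07, 0.05] + [0.83 / 7] * 7
        taxa = [
            TaxonSpec(f"t{i}", a, has_pr=i < 3, pr_color="green" if i < 3 else None)
            for i, a in enumerate(abund)
        ]
        assert CommunitySpec(taxa=tuple(taxa)).pr_bearing_fraction == pytest.approx(0.17)

    def test_single_taxon_all_pr(self):
        spec = CommunitySpec(taxa=(TaxonSpec("a", 1.0, has_pr=True, pr_color="blue"),))
        assert spec.pr_bearing_fraction == 1.0

    def test_abundances_must_sum_to_one(self):
        with pytest.raises(InvalidSpecError):
            CommunitySpec(taxa=(TaxonSpec("a", 0.4), TaxonSpec("b", 0.4)))

    def test_pr_taxon_needs_color(self):
        with pytest.raises(InvalidSpecError):
            CommunitySpec(taxa=(TaxonSpec("a", 1.0, has_pr=True),))

    def test_catalog_invariants(self):
        catalog = generate_community(default_community())
        hk = catalog[catalog["gene_class"].isin(["recA", "rplB", "rpoB", "EF-Tu"])]
        assert hk.groupby("taxon").size().eq(4).all()  # every taxon: 4 HK genes
        pr = catalog[catalog["gene_class"] == "PR"]
        assert pr.groupby("taxon").size().eq(1).all()  # PR-bearers: exactly 1

    def test_yaml_round_trip(self, tmp_path):
        spec = default_community()
        path = tmp_path / "spec.yml"
        import yaml

        payload = {
            "taxa": [
                {
                    "taxon_id": t.taxon_id,
                    "relative_cell_abundance": t.relative_cell_abundance,
                    "has_pr": t.has_pr,
                    "pr_color": t.pr_color,
                    "pr_gene_length": t.pr_gene_length,
                    "expression_multipliers": dict(t.expression_multipliers),
                }
                for t in spec.taxa
            ],
            "hk_gene_lengths": dict(spec.hk_gene_lengths),
            "retinal_gene_lengths": dict(spec.retinal_gene_lengths),
        }
        path.write_text(yaml.safe_dump(payload))
        back = CommunitySpec.from_yaml(path)
        assert back.pr_bearing_fraction == spec.pr_bearing_fraction
        assert back.blue_transcript_fraction == spec.blue_transcript_fraction


class TestCountSimulation:
    def test_seed_determinism(self):
        spec = default_community()
        a = simulate_gene_counts(spec, depth=50.0, seed=9)
        b = simulate_gene_counts(spec, depth=50.0, seed=9)
        pd.testing.assert_frame_equal(a.counts.df, b.counts.df)

    def test_high_depth_estimate_near_truth(self):
        spec = default_community()
        sample = simulate_gene_counts(spec, depth=1000.0, seed=4)
        res = pr_bearing_fraction(sample.counts, "metaG")
        assert res.pr_fraction == pytest.approx(spec.pr_bearing_fraction, rel=0.01)

    def test_unit_multipliers_give_unit_expression(self):
        taxa = (
            TaxonSpec("a", 0.6, has_pr=True, pr_color="green"),
            TaxonSpec("b", 0.4),
        )
        spec = CommunitySpec(taxa=taxa)
        sample = simulate_transcript_counts(spec, depth=2000.0, seed=2)
        res = transcript_relative_abundance(sample.counts, "metaT", "rplB")
        assert res.relative_expression == pytest.approx(1.0, rel=0.02)

    def test_truth_attached_to_sample(self):
        spec = default_community()
        sample = simulate_transcript_counts(spec, depth=10.0, seed=1)
        assert sample.truth["pr_bearing_fraction"] == pytest.approx(0.17)
        assert sample.truth["blue_transcript_fraction"] == pytest.approx(5 / 7)
        assert sample.truth["relative_expression"]["PR"] == pytest.approx(2.1)

    def test_counts_tsv_round_trip(self, tmp_path):
        from rhodoquant.counts import GeneCountTable

        sample = simulate_gene_counts(default_community(), depth=20.0, seed=3)
        path = tmp_path / "c.tsv"
        sample.counts.to_tsv(path)
        back = GeneCountTable.from_tsv(path)
        pd.testing.assert_frame_equal(
            back.df[["sample_id", "gene_id", "count"]],
            sample.counts.df[["sample_id", "gene_id", "count"]],
        )


class TestQpcrSimulation:
    def test_seed_determinism(self):
        a = simulate_qpcr_run({"PR": 1e4, "16S": 1e5}, noise_sd=0.2, seed=6)
        b = simulate_qpcr_run({"PR": 1e4, "16S": 1e5}, noise_sd=0.2, seed=6)
        pd.testing.assert_frame_equal(a[0], b[0])
        pd.testing.assert_frame_equal(a[1], b[1])

    def test_standards_span_decades(self):
        std, _ = simulate_qpcr_run({"PR": 1e4}, noise_sd=0.0, seed=0)
        assert sorted(std["known_copies"]) == [10.0**e for e in range(2, 9)]

    def test_positive_slope_rejected(self):
        with pytest.raises(InvalidInputError):
            simulate_qpcr_run({"PR": 1e4}, slope=3.4)
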