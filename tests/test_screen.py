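"""Candidate screening: search, external-hit import, curation rules."""

import pandas as pd
import pytest

from rhodoquant.errors import ConfigurationError, FormatError
from rhodoquant.io import ProteinRecord
from rhodoquant.screen import (
    ScreenConfig,
    curate_candidates,
    import_external_hits,
    search_candidates,
)
from rhodoquant.simulate import generate_reference_panel, mutate_positions


@pytest.fixture(scope="module")
def panel_and_ref():
    panel, ref, truth = generate_reference_panel(4, 4, 0, seed=11)
    return panel, ref, truth


class TestSearch:
    def test_identical_query_finds_self(self, panel_and_ref, blosum62):
        panel, _, _ = panel_and_ref
        cfg = ScreenConfig(reference_panel=tuple(panel))
        query = ProteinRecord(id="q1", sequence=panel[2].sequence)
        hits = search_candidates([query], cfg)
        assert hits == [
            ("q1", panel[2].id, sum(blosum62.score(c, c) for c in query.sequence))
        ]

    def test_dissimilar_query_dropped(self, panel_and_ref):
        panel, _, _ = panel_and_ref
        cfg = ScreenConfig(reference_panel=tuple(panel), min_bitlike_score=50)
        query = ProteinRecord(id="allG", sequence="G" * 120)
        assert search_candidates([query], cfg) == []

    def test_tie_broken_by_lexicographic_id(self, panel_and_ref):
        panel, _, _ = panel_and_ref
        seq = panel[0].sequence
        twins = (
            ProteinRecord(id="zz_twin", sequence=seq),
            ProteinRecord(id="aa_twin", sequence=seq),
        )
        cfg = ScreenConfig(reference_panel=twins)
        hits = search_candidates([ProteinRecord(id="q", sequence=seq)], cfg)
        assert hits[0][1] == "aa_twin"

    def test_empty_panel_rejected(self):
        with pytest.raises(ConfigurationError):
            search_candidates([ProteinRecord(id="q", sequence="MKT")], ScreenConfig())


class TestImportExternalHits:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["query_id", "subject_id", "evalue", "bitscore"])

    def test_evalue_threshold(self):
        cfg = ScreenConfig()
        table = self._table(
            [("q1", "s1", 1e-8, 200.0), ("q2", "s2", 1e-6, 180.0)]
        )
        hits = import_external_hits(table, cfg)
        assert hits == [("q1", "s1", 1e-8)]  # 1e-6 > 1e-7 dropped

    def test_best_row_per_query_by_evalue(self):
        cfg = ScreenConfig()
        table = self._table(
            [("q1", "sA", 1e-9, 100.0), ("q1", "sB", 1e-12, 90.0)]
        )
        assert import_external_hits(table, cfg) == [("q1", "sB", 1e-12)]

    def test_outfmt6_column_aliases(self):
        cfg = ScreenConfig()
        df = pd.DataFrame(
            [("q1", "s1", 1e-8, 55.0)],
            columns=["qseqid", "sseqid", "evalue", "bitscore"],
        )
        assert import_external_hits(df, cfg) == [("q1", "s1", 1e-8)]

    def test_missing_column_named(self):
        df = pd.DataFrame([("q1", "s1", 1e-8)], columns=["query_id", "subject_id", "evalue"])
        with pytest.raises(FormatError, match="bitscore"):
            import_external_hits(df, ScreenConfig())

    def test_unparseable_evalue_reports_line(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text(
            "query_id\tsubject_id\tevalue\tbitscore\n"
            "q1\ts1\t1e-8\t100\n"
            "q2\ts2\tnot_a_number\t90\n"
        )
        with pytest.raises(FormatError, match="line 3"):
            import_external_hits(path, ScreenConfig())


class TestCuration:
    def test_short_protein_fails_length_rule(self, reference):
        # a perfect 99-aa window containing the whole C-helix region
        window = reference.record.sequence[19:118]  # covers positions 20..118
        rec = ProteinRecord(id="short", sequence=window)
        (res,) = curate_candidates([rec], reference)
        assert res.domain_region_covered
        assert not res.passed_length
        assert not res.retained

    def test_exactly_100_aa_fails_strict_rule(self, reference):
        window = reference.record.sequence[18:118]
        rec = ProteinRecord(id="aa100", sequence=window)
        (res,) = curate_candidates([rec], reference)
        assert len(rec) == 100 and not res.retained

    def test_functional_pr_retained(self, panel_and_ref):
        panel, ref, _ = panel_and_ref
        results = curate_candidates(panel, ref)
        assert all(r.retained for r in results)

    def test_k108_variant_still_retained(self, panel_and_ref):
        panel, ref, _ = panel_and_ref
        mutant = mutate_positions(panel[0], ref, {108: "K"})
        (res,) = curate_candidates([mutant], ref)
        assert res.retained  # triad identity is reported downstream, not curated on

    def test_decoys_fail_domain_coverage(self):
        panel, ref, _ = generate_reference_panel(0, 0, 6, seed=3)
        results = curate_candidates(panel, ref)
        assert all(not r.domain_region_covered for r in results)

    def test_truncation_monotonicity(self, panel_and_ref):
        panel, ref, _ = panel_and_ref
        rec = panel[1]
        (full,) = curate_candidates([rec], ref)
        assert full.retained
        truncated = ProteinRecord(id=rec.id, sequence=rec.sequence[:95])
        (cut,) = curate_candidates([truncated], ref)
        assert not cut.retained

    def test_internal_and_external_routes_agree(self, panel_and_ref, blosum62):
        """Searching the internal panel or importing the equivalent hit
        table must retain the same curated set."""
        panel, ref, _ = panel_and_ref
        queries = panel[:4]
        cfg = ScreenConfig(reference_panel=tuple(panel))
        internal = search_candidates(queries, cfg)
        table = pd.DataFrame(
            [(q, s, 1e-30, sc) for q, s, sc in internal],
            columns=["query_id", "subject_id", "evalue", "bitscore"],
        )
        external = import_external_hits(table, cfg)
        int_ids = {q for q, _, _ in internal}
        ext_ids = {q for q, _, _ in external}
        assert int_ids == ext_ids
        retained_int = {
            r.record.id
            for r in curate_candidates([q for q in queries if q.id in int_ids], ref)
            if r.retained
        }
        retained_ext = {
            r.record.id
            for r in curate_candidates([q for q in queries if q.id in ext_ids], ref)
            if r.retained
        }
        assert retained_int == retained_ext
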