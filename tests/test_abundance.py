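"""Single-copy-gene normalized abundance: examples, invariants, recovery."""

import numpy as np
import pandas as pd
import pytest

from rhodoquant.abundance import (
    AbundanceConfig,
    otu_relative_abundance,
    pr_bearing_fraction,
)
from rhodoquant.counts import GeneCountTable, gene_coverage
from rhodoquant.errors import (
    ConfigurationError,
    DegenerateNormalizerError,
    FormatError,
    InvalidInputError,
    NotFoundError,
)
from rhodoquant.simulate import CommunitySpec, TaxonSpec, simulate_gene_counts

HK = ("recA", "rplB", "rpoB", "EF-Tu")


def make_table(rows):
    return GeneCountTable(
        pd.DataFrame(
            rows,
            columns=["sample_id", "gene_id", "gene_class", "gene_length", "count",
                     "otu_id", "color"],
        )
    )


@pytest.fixture
def uniform_table():
    rows = [("s1", "pr1", "PR", 1000, 100, "OTU01", "green")]
    rows += [("s1", f"hk_{fam}", fam, 1000, 100, None, None) for fam in HK]
    return make_table(rows)


class TestGeneCoverage:
    @pytest.mark.parametrize(
        "count, length, expected", [(100, 1000, 0.1), (0, 500, 0.0), (150, 750, 0.2)]
    )
    def test_examples(self, count, length, expected):
        assert gene_coverage(count, length) == pytest.approx(expected)

    def test_zero_length_rejected(self):
        with pytest.raises(InvalidInputError):
            gene_coverage(10, 0)


class TestTableValidation:
    def test_missing_column_named(self):
        with pytest.raises(FormatError, match="gene_length"):
            GeneCountTable(
                pd.DataFrame({"sample_id": ["s"], "gene_id": ["g"],
                              "gene_class": ["PR"], "count": [1]})
            )

    def test_duplicate_gene_rejected(self):
        rows = [("s1", "g1", "PR", 100, 1, None, None)] * 2
        with pytest.raises(InvalidInputError, match="duplicate"):
            make_table(rows)

    def test_unknown_gene_class_rejected(self):
        with pytest.raises(FormatError, match="mystery"):
            make_table([("s1", "g1", "mystery", 100, 1, None, None)])

    def test_tsv_round_trip(self, uniform_table, tmp_path):
        path = tmp_path / "counts.tsv"
        uniform_table.to_tsv(path)
        back = GeneCountTable.from_tsv(path)
        pd.testing.assert_frame_equal(
            back.df[["sample_id", "gene_id", "count"]],
            uniform_table.df[["sample_id", "gene_id", "count"]],
        )


class TestPrBearingFraction:
    def test_equal_coverages_give_one(self, uniform_table):
        res = pr_bearing_fraction(uniform_table, "s1")
        assert res.pr_fraction == pytest.approx(1.0)
        assert all(v == pytest.approx(1.0) for v in res.per_housekeeping_ratio.values())
        assert not res.flag_gt1

    def test_known_ratio(self):
        rows = [("s1", "pr1", "PR", 1000, 50, "OTU01", "green")]  # coverage 0.05
        rows += [("s1", f"hk_{f}", f, 1000, 250, None, None) for f in HK]  # 0.25
        res = pr_bearing_fraction(make_table(rows), "s1")
        assert res.pr_fraction == pytest.approx(0.20)

    def test_fraction_above_one_flagged_not_clamped(self):
        rows = [("s1", "pr1", "PR", 1000, 500, "OTU01", "green")]
        rows += [("s1", f"hk_{f}", f, 1000, 100, None, None) for f in HK]
        res = pr_bearing_fraction(make_table(rows), "s1")
        assert res.pr_fraction == pytest.approx(5.0)
        assert res.flag_gt1

    def test_zero_housekeeping_names_family(self):
        rows = [("s1", "pr1", "PR", 1000, 100, None, None),
                ("s1", "hk_recA", "recA", 1000, 0, None, None)]
        rows += [("s1", f"hk_{f}", f, 1000, 100, None, None) for f in HK[1:]]
        with pytest.raises(DegenerateNormalizerError, match="recA"):
            pr_bearing_fraction(make_table(rows), "s1")

    def test_missing_sample(self, uniform_table):
        with pytest.raises(NotFoundError):
            pr_bearing_fraction(uniform_table, "nope")

    def test_scale_invariance_exact(self, uniform_table):
        base = pr_bearing_fraction(uniform_table, "s1")
        scaled = pr_bearing_fraction(uniform_table.scaled(7.0), "s1")
        assert scaled.pr_fraction == base.pr_fraction
        assert scaled.per_housekeeping_ratio == base.per_housekeeping_ratio

    def test_reca_forbidden_in_rna_set(self):
        with pytest.raises(ConfigurationError):
            AbundanceConfig(housekeeping_set_rna=("recA", "rplB", "rpoB"))


class TestOtuShares:
    def test_single_otu(self, uniform_table):
        assert otu_relative_abundance(uniform_table, "s1") == {"OTU01": pytest.approx(1.0)}

    def test_known_shares(self):
        rows = [
            ("s1", "prA", "PR", 1000, 300, "A", "green"),  # coverage 0.3
            ("s1", "prB", "PR", 1000, 100, "B", "blue"),   # coverage 0.1
        ]
        rows += [("s1", f"hk_{f}", f, 1000, 100, None, None) for f in HK]
        shares = otu_relative_abundance(make_table(rows), "s1")
        assert shares == {"A": pytest.approx(0.75), "B": pytest.approx(0.25)}

    def test_random_shares_match_hand_computation(self):
        rng = np.random.default_rng(5)
        lengths = rng.integers(300, 1500, size=5)
        counts = rng.integers(1, 500, size=5)
        rows = [
            ("s1", f"pr{i}", "PR", int(lengths[i]), int(counts[i]), f"OTU{i:02d}", "green")
            for i in range(5)
        ]
        rows += [("s1", f"hk_{f}", f, 1000, 100, None, None) for f in HK]
        shares = otu_relative_abundance(make_table(rows), "s1")
        covs = counts / lengths
        for i in range(5):
            assert shares[f"OTU{i:02d}"] == pytest.approx(covs[i] / covs.sum())
        assert sum(shares.values()) == pytest.approx(1.0, abs=1e-12)

    def test_zero_pr_coverage_degenerate(self):
        rows = [("s1", "pr1", "PR", 1000, 0, "A", "green")]
        rows += [("s1", f"hk_{f}", f, 1000, 100, None, None) for f in HK]
        with pytest.raises(DegenerateNormalizerError):
            otu_relative_abundance(make_table(rows), "s1")


class TestPoissonRecovery:
    def test_estimator_tracks_truth_at_high_depth(self):
        spec = CommunitySpec(
            taxa=(
                TaxonSpec("pr_taxon", 0.17, has_pr=True, pr_color="green"),
                TaxonSpec("other", 0.83),
            )
        )
        sample = simulate_gene_counts(spec, depth=1000.0, seed=17)
        res = pr_bearing_fraction(sample.counts, "metaG")
        assert res.pr_fraction == pytest.approx(0.17, rel=0.01)

    def test_estimator_unbiased_over_replicates(self):
        spec = CommunitySpec(
            taxa=(
                TaxonSpec("pr_taxon", 0.30, has_pr=True, pr_color="blue"),
                TaxonSpec("other", 0.70),
            )
        )
        estimates = [
            pr_bearing_fraction(
                simulate_gene_counts(spec, depth=5.0, seed=1000 + i).counts, "metaG"
            ).pr_fraction
            for i in range(100)
        ]
        estimates = np.asarray(estimates)
        se = estimates.std(ddof=1) / np.sqrt(len(estimates))
        assert abs(estimates.mean() - 0.30) <= 3 * se
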