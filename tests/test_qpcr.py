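"""qPCR standard curves, copy quantification and the 16S correction."""

import math

import numpy as np
import pytest

from rhodoquant.errors import (
    DegenerateNormalizerError,
    InvalidCurveError,
    InvalidInputError,
    MismatchError,
)
from rhodoquant.qpcr import (
    QpcrConfig,
    QpcrMeasurement,
    fit_standard_curve,
    pr_relative_abundance,
    quantify_copies,
    total_pr_fraction,
)
from rhodoquant.simulate import simulate_qpcr_run


def decade_points(slope=-3.5, intercept=38.0, hi=8, lo=2):
    return [(10.0**e, intercept + slope * e) for e in range(hi, lo - 1, -1)]


class TestFitStandardCurve:
    def test_noiseless_fit_recovers_line(self):
        curve = fit_standard_curve(decade_points())
        assert curve.slope == pytest.approx(-3.5)
        assert curve.intercept == pytest.approx(38.0)
        assert curve.r_squared == pytest.approx(1.0)

    def test_perfect_doubling_efficiency(self):
        slope = -1.0 / math.log10(2.0)  # -3.3219...
        curve = fit_standard_curve(decade_points(slope=slope))
        assert curve.efficiency == pytest.approx(1.0)

    def test_efficiency_formula_inverts(self):
        curve = fit_standard_curve(decade_points(slope=-3.6))
        assert -1.0 / math.log10(1.0 + curve.efficiency) == pytest.approx(curve.slope)

    def test_too_few_points_rejected(self):
        with pytest.raises(InvalidCurveError):
            fit_standard_curve(decade_points()[:2])

    def test_collinear_x_rejected(self):
        with pytest.raises(InvalidCurveError):
            fit_standard_curve([(1e5, 21.0), (1e5, 21.1), (1e5, 20.9)])

    def test_positive_slope_rejected(self):
        with pytest.raises(InvalidCurveError):
            fit_standard_curve(decade_points(slope=+3.5))

    def test_out_of_range_slope_warns(self, caplog):
        with caplog.at_level("WARNING"):
            fit_standard_curve(decade_points(slope=-4.5))
        assert any("outside" in rec.message for rec in caplog.records)

    def test_noisy_slope_recovery(self):
        rng = np.random.default_rng(3)
        slopes = []
        for i in range(200):
            pts = [
                (10.0**e, 38.0 - 3.5 * e + rng.normal(0, 0.15))
                for e in range(8, 1, -1)
            ]
            slopes.append(fit_standard_curve(pts).slope)
        slopes = np.asarray(slopes)
        se = slopes.std(ddof=1) / np.sqrt(len(slopes))
        assert abs(slopes.mean() - (-3.5)) <= 3 * se


@pytest.fixture(scope="module")
def curve():
    return fit_standard_curve(decade_points())


class TestQuantifyCopies:
    def test_single_cq(self, curve):
        m = quantify_copies(curve, [24.0])
        assert m.copies == pytest.approx(1.0e4)  # (38-24)/3.5 = 4

    def test_cq_at_intercept_gives_one_copy(self, curve):
        assert quantify_copies(curve, [38.0]).copies == pytest.approx(1.0)

    def test_round_trip_noiseless(self, curve):
        for true in (1e2, 1e5, 10**7.5):
            cq = 38.0 - 3.5 * math.log10(true)
            m = quantify_copies(curve, [cq, cq, cq])
            assert m.copies == pytest.approx(true)
            assert m.copies_cv == pytest.approx(0.0)

    def test_triplicate_with_noise_close(self, curve):
        rng = np.random.default_rng(8)
        cq_true = 38.0 - 3.5 * 5.0
        cqs = [cq_true + rng.normal(0, 0.1) for _ in range(3)]
        m = quantify_copies(curve, cqs)
        assert m.copies == pytest.approx(1e5, rel=0.15)
        assert m.copies_cv > 0

    def test_empty_replicates_rejected(self, curve):
        with pytest.raises(InvalidInputError):
            quantify_copies(curve, [])

    def test_suspect_cq_warns(self, curve, caplog):
        with caplog.at_level("WARNING"):
            quantify_copies(curve, [75.0])
        assert any("suspect" in rec.message for rec in caplog.records)


def measurement(assay, sample, copies):
    return QpcrMeasurement(
        assay_id=assay, sample_id=sample, cq_replicates=(20.0,), copies=copies,
        copies_cv=0.0,
    )


class TestPrRelativeAbundance:
    def test_ten_percent(self):
        frac = pr_relative_abundance(
            measurement("PR", "s", 1.0e4), measurement("16S", "s", 1.9e5)
        )
        assert frac == pytest.approx(0.10)  # 1.9e5/1.9 = 1e5 genomes

    def test_above_one_flagged_value_kept(self, caplog):
        with caplog.at_level("WARNING"):
            frac = pr_relative_abundance(
                measurement("PR", "s", 1.9e5), measurement("16S", "s", 1.9e5)
            )
        assert frac == pytest.approx(1.9)
        assert any("> 1" in rec.message for rec in caplog.records)

    def test_template_amount_invariance(self):
        base = pr_relative_abundance(
            measurement("PR", "s", 5e3), measurement("16S", "s", 4e5)
        )
        scaled = pr_relative_abundance(
            measurement("PR", "s", 5e4), measurement("16S", "s", 4e6)
        )
        assert scaled == pytest.approx(base)

    def test_sample_mismatch_rejected(self):
        with pytest.raises(MismatchError):
            pr_relative_abundance(
                measurement("PR", "s1", 1e4), measurement("16S", "s2", 1e5)
            )

    def test_zero_16s_rejected(self):
        with pytest.raises(DegenerateNormalizerError):
            pr_relative_abundance(
                measurement("PR", "s", 1e4), measurement("16S", "s", 0.0)
            )

    def test_total_sums_per_taxon(self):
        assert total_pr_fraction({"SAR11": 0.05, "SAR92": 0.03}) == pytest.approx(0.08)

    def test_bad_config_rejected(self):
        with pytest.raises(InvalidInputError):
            QpcrConfig(ss16_copies_per_genome=0.0)


class TestSimulatedRoundTrip:
    def test_noiseless_simulation_inverts_exactly(self):
        true = {"PR": 2.5e4, "16S": 1.9e5}
        standards, samples = simulate_qpcr_run(true, noise_sd=0.0, seed=1)
        for assay, grp in standards.groupby("assay_id"):
            curve = fit_standard_curve(
                list(zip(grp["known_copies"], grp["cq"])), assay_id=assay
            )
            cqs = samples[samples["assay_id"] == assay]["cq"].tolist()
            m = quantify_copies(curve, cqs)
            assert m.copies == pytest.approx(true[assay])
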