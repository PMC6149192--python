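"""cfDNA qPCR quantification, ratio biomarker, and load regression."""

import math

import numpy as np
import pandas as pd
import pytest

from pdxkit import plasma as pl
from pdxkit import simulate as sim
from pdxkit.config import SimulationConfig
from pdxkit.errors import AnalysisError, ValidationError


def qpcr_table(sample_cts, calibrator_cts, sample_id="S"):
    """Build a tidy measurement table from target -> Ct maps."""
    rows = []
    for sid, cts in ((sample_id, sample_cts), ("calibrator", calibrator_cts)):
        for target, ct in cts.items():
            rows.append({"sample_id": sid, "target": target, "replicate": 1, "ct": ct})
    return pd.DataFrame(rows)


class TestQpcrCopyNumber:
    def test_sample_identical_to_calibrator_is_diploid(self):
        cts = {"CCND1": 26.0, "CDKN2A": 27.0, "RAD52": 25.0}
        calls = pl.qpcr_copy_number(qpcr_table(cts, cts), "S")
        for target in cts:
            assert calls[target].copy_number == pytest.approx(2.0)

    def test_one_cycle_early_doubles(self):
        calls = pl.qpcr_copy_number(
            qpcr_table({"CCND1": 25.0, "RAD52": 25.0},
                       {"CCND1": 26.0, "RAD52": 25.0}),
            "S",
        )
        assert calls["CCND1"].copy_number == pytest.approx(4.0)

    def test_non_detect_reported_as_zero_with_flag(self):
        calls = pl.qpcr_copy_number(
            qpcr_table({"CDKN2A": np.nan, "RAD52": 25.0},
                       {"CDKN2A": 27.0, "RAD52": 25.0}),
            "S",
        )
        assert calls["CDKN2A"].copy_number == 0.0
        assert calls["CDKN2A"].non_detect

    def test_missing_control_target_is_error(self):
        with pytest.raises(AnalysisError, match="RAD52"):
            pl.qpcr_copy_number(
                qpcr_table({"CCND1": 25.0}, {"CCND1": 25.0, "RAD52": 25.0}), "S"
            )

    def test_discordant_replicates_flagged(self):
        rows = [
            {"sample_id": "S", "target": "CCND1", "replicate": 1, "ct": 25.0},
            {"sample_id": "S", "target": "CCND1", "replicate": 2, "ct": 25.8},
            {"sample_id": "S", "target": "RAD52", "replicate": 1, "ct": 25.0},
            {"sample_id": "calibrator", "target": "CCND1", "replicate": 1, "ct": 26.0},
            {"sample_id": "calibrator", "target": "RAD52", "replicate": 1, "ct": 25.0},
        ]
        calls = pl.qpcr_copy_number(pd.DataFrame(rows), "S")
        assert calls["CCND1"].discordant_replicates

    @pytest.mark.parametrize("cn", [0.5, 2.0, 4.0, 22.0])
    def test_zero_noise_round_trip_exact(self, cn):
        c = SimulationConfig(seed=51)
        table = sim.gen_qpcr(c, {"CCND1": cn}, sample_id="S")
        calls = pl.qpcr_copy_number(table, "S")
        assert calls["CCND1"].copy_number == pytest.approx(cn, rel=1e-12)

    def test_efficiency_aware_round_trip(self):
        c = SimulationConfig(seed=51, qpcr_efficiency=0.9)
        table = sim.gen_qpcr(c, {"CCND1": 6.0}, sample_id="S")
        calls = pl.qpcr_copy_number(table, "S", efficiency=0.9)
        assert calls["CCND1"].copy_number == pytest.approx(6.0, rel=1e-12)


class TestCnvRatio:
    def test_diploid_baseline(self):
        assert pl.cnv_ratio(2.0, 2.0) == (1.0, False)

    def test_cutoff_scale_arithmetic(self):
        assert pl.cnv_ratio(8.0, 2.0)[0] == pytest.approx(4.0)

    def test_denominator_floor_flagged(self):
        ratio, floored = pl.cnv_ratio(2.0, 0.0, epsilon=0.05)
        assert ratio == pytest.approx(40.0)
        assert floored

    def test_negative_rejected(self):
        with pytest.raises(ValidationError):
            pl.cnv_ratio(-1.0, 2.0)


class TestLoadRegression:
    def reference_fit(self):
        return pl.RegressionFit(slope=11.11, intercept=-36.93, pearson_r=1.0, n=3)

    def test_exact_points_recover_printed_coefficients(self):
        x = np.array([3.5, 4.5, 5.5])
        samples = pd.DataFrame(
            {"ebv_copies_per_ml": 10.0 ** x, "ratio": 11.11 * x - 36.93}
        )
        fit = pl.fit_load_regression(samples)
        assert fit.slope == pytest.approx(11.11, abs=1e-9)
        assert fit.intercept == pytest.approx(-36.93, abs=1e-9)
        assert fit.pearson_r == pytest.approx(1.0, abs=1e-12)

    def test_constant_ratio_convention(self):
        samples = pd.DataFrame(
            {"ebv_copies_per_ml": [1e3, 1e4, 1e5], "ratio": [2.0, 2.0, 2.0]}
        )
        fit = pl.fit_load_regression(samples)
        assert fit.slope == 0.0
        assert fit.pearson_r == 0.0

    def test_equal_loads_undefined_slope(self):
        samples = pd.DataFrame(
            {"ebv_copies_per_ml": [1e4] * 5, "ratio": [1, 2, 3, 4, 5.0]}
        )
        with pytest.raises(AnalysisError):
            pl.fit_load_regression(samples)

    def test_recovered_slope_within_2_se(self):
        c = SimulationConfig(seed=52, plasma_noise_sd=2.0)
        cohort = sim.gen_plasma_cohort(c, 200, load_range=(5e3, 1e6))
        fit = pl.fit_load_regression(cohort)
        x = np.log10(cohort["ebv_copies_per_ml"])
        resid_sd = np.std(
            cohort["ratio"] - (fit.slope * x + fit.intercept), ddof=2
        )
        se = resid_sd / (np.std(x, ddof=1) * math.sqrt(len(cohort) - 1))
        assert abs(fit.slope - 11.11) < 2 * se

    def test_mean_slope_over_50_cohorts_within_10_percent(self):
        # n = 22 per cohort, noise sd 2, loads 5e3-1e6
        slopes = []
        for seed in range(50):
            c = SimulationConfig(seed=seed, plasma_noise_sd=2.0)
            cohort = sim.gen_plasma_cohort(c, 22, load_range=(5e3, 1e6))
            slopes.append(pl.fit_load_regression(cohort).slope)
        assert abs(np.mean(slopes) - 11.11) / 11.11 < 0.10

    def test_fit_on_own_predictions_is_perfect(self):
        fit = self.reference_fit()
        loads = np.array([6e3, 2e4, 9e4, 4e5, 1e6])
        samples = pd.DataFrame(
            {
                "ebv_copies_per_ml": loads,
                "ratio": [pl.ratio_at_load(fit, v) for v in loads],
            }
        )
        refit = pl.fit_load_regression(samples)
        assert refit.slope == pytest.approx(11.11, abs=1e-9)
        assert refit.intercept == pytest.approx(-36.93, abs=1e-9)
        assert refit.pearson_r == pytest.approx(1.0, abs=1e-9)


class TestRatioAtLoad:
    def test_printed_fit_at_5000(self):
        fit = pl.RegressionFit(11.11, -36.93, 1.0, 22)
        assert pl.ratio_at_load(fit, 5_000) == pytest.approx(4.17, abs=0.01)

    def test_printed_fit_at_100k(self):
        fit = pl.RegressionFit(11.11, -36.93, 1.0, 22)
        assert pl.ratio_at_load(fit, 100_000) == pytest.approx(11.11 * 5 - 36.93)

    def test_flat_fit_constant(self):
        fit = pl.RegressionFit(0.0, 7.0, 0.0, 22)
        for load in (10, 1e4, 1e7):
            assert pl.ratio_at_load(fit, load) == 7.0

    def test_strictly_increasing_when_slope_positive(self):
        fit = pl.RegressionFit(11.11, -36.93, 1.0, 22)
        loads = [1e3, 5e3, 1e4, 1e5, 1e6]
        preds = [pl.ratio_at_load(fit, v) for v in loads]
        assert preds == sorted(preds)
        assert len(set(preds)) == len(preds)

    def test_non_positive_load_rejected(self):
        with pytest.raises(ValidationError):
            pl.ratio_at_load(pl.RegressionFit(1, 0, 0, 3), 0)


class TestGeneLoadCorrelation:
    def test_monotone_gene_is_perfectly_correlated(self):
        loads = np.array([1e3, 1e4, 1e5, 1e6])
        samples = pd.DataFrame(
            {"ebv_copies_per_ml": loads, "cn_ccnd1": np.log10(loads) * 2}
        )
        assert pl.gene_load_correlation(samples, "CCND1") == pytest.approx(1.0)

    def test_independent_gene_near_zero(self):
        rng = np.random.default_rng(53)
        samples = pd.DataFrame(
            {
                "ebv_copies_per_ml": 10 ** rng.uniform(3, 6, 200),
                "cn_rad52": 2 + rng.normal(0, 0.1, 200),
            }
        )
        assert abs(pl.gene_load_correlation(samples, "RAD52")) < 0.15

    def test_cdkn2a_negatively_correlated_in_high_load_cohorts(self):
        # one-copy loss becomes likelier with load, so r < 0
        rs = [
            pl.gene_load_correlation(
                sim.gen_plasma_cohort(SimulationConfig(seed=seed), 22), "CDKN2A"
            )
            for seed in range(30)
        ]
        assert np.mean(rs) < 0

    def test_zero_variance_error(self):
        samples = pd.DataFrame(
            {"ebv_copies_per_ml": [1e3, 1e4, 1e5], "cn_rad52": [2.0, 2.0, 2.0]}
        )
        with pytest.raises(AnalysisError):
            pl.gene_load_correlation(samples, "RAD52")


class TestClassifyCandidate:
    def test_diploid_ratio_not_candidate(self):
        assert not pl.classify_candidate("p", 1.0).candidate

    def test_worked_example_ratio_is_candidate(self):
        fit = pl.RegressionFit(11.11, -36.93, 1.0, 22)
        ratio = pl.ratio_at_load(fit, 5_000)
        assert ratio == pytest.approx(4.17, abs=0.01)
        assert pl.classify_candidate("p", ratio).candidate

    def test_boundary_is_strict(self):
        call = pl.classify_candidate("p", 4.0, cutoff=4.0)
        assert not call.candidate


class TestMethodConcordance:
    def test_qpcr_vs_read_density_on_same_truth(self):
        """Per-gene qPCR CN vs read-density CN correlate r >= 0.89.

        Five tumors x three genes with planted copy numbers; qPCR Cts carry
        0.15-cycle noise and the exome counts Poisson noise.
        """
        from pdxkit import wescnv

        truths = {
            "S1": {"CCND1": 6, "CDKN2A": 0, "RAD52": 2},
            "S2": {"CCND1": 4, "CDKN2A": 1, "RAD52": 2},
            "S3": {"CCND1": 2, "CDKN2A": 2, "RAD52": 2},
            "S4": {"CCND1": 3, "CDKN2A": 1, "RAD52": 2},
            "S5": {"CCND1": 8, "CDKN2A": 2, "RAD52": 2},
        }
        genes = ["CCND1", "CDKN2A", "RAD52"]
        models = [
            wescnv.GeneModel(gene_id=g, chromosome="autosome", exon_intervals=((0, 2000),))
            for g in genes
        ] + [
            wescnv.GeneModel(gene_id=f"BG{i:02d}", chromosome="autosome",
                             exon_intervals=((0, 2000),))
            for i in range(40)
        ]
        qpcr_cn, wes_cn = [], []
        for i, (sid, truth) in enumerate(truths.items()):
            c = SimulationConfig(seed=540 + i, depth=100.0,
                                 qpcr_ct_noise_sd=0.15, planted_cnv=dict(truth))
            table = sim.gen_qpcr(c, {g: float(v) for g, v in truth.items()}, sample_id=sid)
            calls = pl.qpcr_copy_number(table, sid)
            tumor, normals = sim.gen_coverage(c, models)
            td = wescnv.read_density(tumor, models)
            nd = normals.apply(lambda col: wescnv.read_density(col, models))
            prof = wescnv.to_copy_number(td, wescnv.panel_baseline(nd), models)
            for g in genes:
                qpcr_cn.append(calls[g].copy_number)
                wes_cn.append(prof.cn[g])
        r = np.corrcoef(qpcr_cn, wes_cn)[0, 1]
        assert r >= 0.89
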