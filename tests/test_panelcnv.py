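"""Amplicon-panel preprocessing and gene-level copy number."""

import math

import numpy as np
import pandas as pd
import pytest

from pdxkit import panelcnv
from pdxkit.errors import AnalysisError, ValidationError


def make_panel(counts_by_amp, genes=None, pools=None, samples=("N1", "N2")):
    """counts_by_amp: amplicon_id -> tuple of per-sample counts."""
    idx = list(counts_by_amp)
    data = {
        "gene_id": [genes.get(a, "G1") if genes else "G1" for a in idx],
        "pool": [pools.get(a, 1) if pools else 1 for a in idx],
    }
    for j, s in enumerate(samples):
        data[s] = [counts_by_amp[a][j] for a in idx]
    return pd.DataFrame(data, index=pd.Index(idx, name="amplicon_id"))


def brute_force_percentile(values, q):
    """Linear-interpolation percentile, independent of numpy."""
    xs = sorted(values)
    pos = (len(xs) - 1) * q / 100.0
    lo = math.floor(pos)
    hi = math.ceil(pos)
    return xs[lo] + (xs[hi] - xs[lo]) * (pos - lo)


def brute_force_cv(values):
    n = len(values)
    mean = sum(values) / n
    sd = math.sqrt(sum((v - mean) ** 2 for v in values) / (n - 1))
    return sd / mean


class TestFilterAmplicons:
    def test_twenty_distinct_means_remove_exactly_one(self):
        counts = {f"a{i:02d}": (100 + 10 * i, 100 + 10 * i) for i in range(20)}
        panel = make_panel(counts)
        retained, report, _ = panelcnv.filter_amplicons(panel, ["N1", "N2"])
        assert report["reason"].tolist() == ["low_count"]
        assert report.index.tolist() == ["a00"]
        assert len(retained) == 19

    def test_percentile_threshold_matches_brute_force(self):
        counts = {f"a{i:02d}": (50 + 17 * i, 50 + 17 * i) for i in range(9)}
        panel = make_panel(counts)
        _, _, thr = panelcnv.filter_amplicons(panel, ["N1", "N2"])
        means = [sum(v) / 2 for v in counts.values()]
        assert thr == pytest.approx(brute_force_percentile(means, 5), abs=1e-12)

    def test_constant_amplicon_never_cv_removed(self):
        counts = {"flat": (300, 300), **{f"a{i}": (300 + i + 1, 300 - i) for i in range(19)}}
        panel = make_panel(counts)
        retained, report, _ = panelcnv.filter_amplicons(panel, ["N1", "N2"])
        assert "flat" not in report[report["reason"] == "high_cv"].index

    def test_cv_hand_arithmetic(self):
        # counts (100, 300): mean 200, sample sd sqrt(2)*100 -> CV ~0.707 >= 0.3
        counts = {f"a{i:02d}": (100 + 5 * i, 100 + 5 * i) for i in range(19)}
        counts["noisy"] = (100, 300)
        panel = make_panel(counts)
        _, report, _ = panelcnv.filter_amplicons(panel, ["N1", "N2"])
        assert report.loc["noisy", "reason"] == "high_cv"
        assert report.loc["noisy", "value"] == pytest.approx(
            brute_force_cv([100, 300]), abs=1e-12
        )
        # the (10, 30) pattern has the same CV, scale-free
        assert brute_force_cv([10, 30]) == pytest.approx(0.5 * 2**0.5, abs=1e-12)

    def test_reapplication_with_established_threshold_is_idempotent(self):
        rng = np.random.default_rng(0)
        base = rng.uniform(50, 500, 50)
        counts = {f"a{i:02d}": tuple(rng.poisson(base[i], 2)) for i in range(50)}
        panel = make_panel(counts)
        retained, _, thr = panelcnv.filter_amplicons(panel, ["N1", "N2"])
        retained2, report2, _ = panelcnv.filter_amplicons(
            retained, ["N1", "N2"], mean_threshold=thr
        )
        pd.testing.assert_frame_equal(retained, retained2)
        assert report2.empty

    def test_raising_cv_threshold_monotone(self):
        rng = np.random.default_rng(1)
        counts = {f"a{i:02d}": tuple(rng.poisson(100, 2)) for i in range(40)}
        panel = make_panel(counts)
        removed = [
            len(panelcnv.filter_amplicons(panel, ["N1", "N2"], cv_threshold=cv)[1])
            for cv in (0.05, 0.1, 0.3, 1.0)
        ]
        assert removed == sorted(removed, reverse=True)

    def test_all_removed_is_error(self):
        panel = make_panel({"a": (0, 0), "b": (0, 0)})
        with pytest.raises(AnalysisError):
            panelcnv.filter_amplicons(panel, ["N1", "N2"])


class TestPoolNormalize:
    def test_single_pool_is_identity_scale(self):
        panel = make_panel({f"a{i}": (i + 1, 2 * i + 1) for i in range(5)})
        out = panelcnv.pool_normalize(panel)
        np.testing.assert_allclose(out[["N1", "N2"]], panel[["N1", "N2"]].astype(float))

    def test_two_pool_median_halving(self):
        # pool medians 100 and 200; the global (all-amplicon) median is 100,
        # so pool-2 counts are exactly halved
        counts = {"p1a": (90, 90), "p1b": (100, 100), "p1c": (100, 100),
                  "p1d": (110, 110),
                  "p2a": (40, 40), "p2b": (200, 200), "p2c": (300, 300)}
        pools = {"p1a": 1, "p1b": 1, "p1c": 1, "p1d": 1,
                 "p2a": 2, "p2b": 2, "p2c": 2}
        panel = make_panel(counts, pools=pools)
        out = panelcnv.pool_normalize(panel)
        assert out.loc["p2a", "N1"] == pytest.approx(20.0)
        assert out.loc["p2b", "N1"] == pytest.approx(100.0)
        assert out.loc["p2c", "N1"] == pytest.approx(150.0)
        # relative values within a pool preserved
        assert out.loc["p2c", "N1"] / out.loc["p2a", "N1"] == pytest.approx(300 / 40)

    def test_amplicon_order_irrelevant(self):
        counts = {"a": (10, 20), "b": (30, 40), "c": (50, 60), "d": (5, 80)}
        pools = {"a": 1, "b": 1, "c": 2, "d": 2}
        panel = make_panel(counts, pools=pools)
        perm = panel.iloc[[2, 0, 3, 1]]
        out1 = panelcnv.pool_normalize(panel).sort_index()
        out2 = panelcnv.pool_normalize(perm).sort_index()
        pd.testing.assert_frame_equal(out1, out2)

    def test_empty_pool_median_error(self):
        panel = make_panel({"a": (0, 0), "b": (100, 100)}, pools={"a": 1, "b": 2})
        with pytest.raises(AnalysisError):
            panelcnv.pool_normalize(panel)


class TestGeneCopyNumber:
    def background(self, n=7, value=100):
        return {f"bg{i}": (value, value, value) for i in range(n)}

    def make(self, counts, genes):
        idx = list(counts)
        data = {
            "gene_id": [genes.get(a, "BG") for a in idx],
            "pool": [1] * len(idx),
            "TUM": [counts[a][0] for a in idx],
            "N1": [counts[a][1] for a in idx],
            "N2": [counts[a][2] for a in idx],
        }
        return pd.DataFrame(data, index=pd.Index(idx, name="amplicon_id"))

    def test_tumor_equal_normal_gives_diploid(self):
        counts = {**self.background(), "g1": (100, 100, 100)}
        panel = self.make(counts, {"g1": "G1"})
        prof = panelcnv.gene_copy_number(panel, "TUM", ["N1", "N2"])
        assert prof.cn.to_numpy() == pytest.approx(2.0)

    def test_median_of_ratios_hand_arithmetic(self):
        # gene with amplicon ratios 1.4 / 1.5 / 1.6 on a diploid background
        counts = {
            **self.background(),
            "g1a": (140, 100, 100), "g1b": (150, 100, 100), "g1c": (160, 100, 100),
        }
        panel = self.make(counts, {"g1a": "G1", "g1b": "G1", "g1c": "G1"})
        prof = panelcnv.gene_copy_number(panel, "TUM", ["N1", "N2"])
        assert prof.cn["G1"] == pytest.approx(3.0)

    def test_global_tumor_scaling_cancels(self):
        counts = {
            **self.background(),
            "g1a": (200, 100, 100), "g1b": (210, 100, 100), "g1c": (190, 100, 100),
        }
        panel = self.make(counts, {"g1a": "G1", "g1b": "G1", "g1c": "G1"})
        scaled = panel.copy()
        scaled["TUM"] = scaled["TUM"] * 11
        p1 = panelcnv.gene_copy_number(panel, "TUM", ["N1", "N2"])
        p2 = panelcnv.gene_copy_number(scaled, "TUM", ["N1", "N2"])
        pd.testing.assert_series_equal(p1.cn, p2.cn)

    def test_planted_cn4_recovered_within_half_copy(self):
        rng = np.random.default_rng(5)
        counts = {}
        genes = {}
        for i in range(92):  # diploid background
            mean = rng.uniform(100, 400)
            counts[f"bg{i:03d}"] = tuple(rng.poisson(mean, 3))
        for i in range(8):  # planted CN 4 gene, 8 amplicons
            mean = rng.uniform(100, 400)
            t = rng.poisson(mean * 2)
            n1, n2 = rng.poisson(mean, 2)
            counts[f"amp4_{i}"] = (t, n1, n2)
            genes[f"amp4_{i}"] = "GAIN4"
        panel = self.make(counts, genes)
        prof = panelcnv.gene_copy_number(panel, "TUM", ["N1", "N2"])
        assert abs(prof.cn["GAIN4"] - 4.0) < 0.5

    def test_no_amplicons_is_error(self):
        panel = self.make({}, {})
        with pytest.raises(AnalysisError):
            panelcnv.gene_copy_number(panel, "TUM", ["N1", "N2"])


class TestPanelVsReadDensityConcordance:
    def test_same_truth_profiles_agree(self):
        """Panel-based and read-density-based CN of one truth correlate r > 0.9.

        Scaled-down panel: 40 genes x 10 amplicons each, planted gains and
        losses, Poisson counts for both assays.
        """
        from pdxkit import simulate as sim, wescnv
        from pdxkit.config import SimulationConfig

        rng = np.random.default_rng(6)
        genes = [f"PG{i:02d}" for i in range(40)]
        truth = {g: 2 for g in genes}
        for g, cn in zip(genes[:8], [0, 1, 1, 3, 3, 4, 6, 6]):
            truth[g] = cn

        # amplicon panel: 10 amplicons per gene
        counts, gmap = {}, {}
        for g in genes:
            for j in range(10):
                mean = rng.uniform(100, 300)
                t = rng.poisson(mean * truth[g] / 2)
                n1, n2, n3 = rng.poisson(mean, 3)
                counts[f"{g}_a{j}"] = (t, n1, n2, n3)
                gmap[f"{g}_a{j}"] = g
        idx = list(counts)
        panel = pd.DataFrame(
            {
                "gene_id": [gmap[a] for a in idx],
                "pool": [hash(a) % 4 + 1 for a in idx],
                "TUM": [counts[a][0] for a in idx],
                "N1": [counts[a][1] for a in idx],
                "N2": [counts[a][2] for a in idx],
                "N3": [counts[a][3] for a in idx],
            },
            index=pd.Index(idx, name="amplicon_id"),
        )
        retained, _, _ = panelcnv.filter_amplicons(panel, ["N1", "N2", "N3"])
        normalized = panelcnv.pool_normalize(retained)
        panel_prof = panelcnv.gene_copy_number(normalized, "TUM", ["N1", "N2", "N3"])

        # read-density profile of the same truth on matching gene models
        c = SimulationConfig(seed=61, n_genes=40, depth=100.0,
                             planted_cnv={g: truth[g] for g in genes})
        models = [
            wescnv.GeneModel(gene_id=g, chromosome="autosome",
                             exon_intervals=((0, 2000),))
            for g in genes
        ]
        tumor, normals = sim.gen_coverage(c, models)
        td = wescnv.read_density(tumor, models)
        nd = normals.apply(lambda col: wescnv.read_density(col, models))
        wes_prof = wescnv.to_copy_number(td, wescnv.panel_baseline(nd), models)

        res = wescnv.cn_correlation(panel_prof, wes_prof)
        assert res.pearson_r > 0.9
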