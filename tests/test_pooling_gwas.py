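import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from poolgwas import pooling_gwas as pg
from poolgwas import synthetic_data as sd
from poolgwas.io_formats import PooledIntensityTable, read_pool_intensities

from .oracles import combined_z_oracle, mean_and_eps2


def _table(rows):
    df = pd.DataFrame(
        rows, columns=["snp_id", "chrom", "pos", "pool", "replicate", "green_raw", "red_raw"]
    )
    df["failed"] = (df["green_raw"] == 0) & (df["red_raw"] == 0)
    return PooledIntensityTable(df)


class TestComputeRaf:
    @pytest.mark.parametrize(
        "green, red, expected",
        [(300.0, 100.0, 0.75), (0.0, 500.0, 0.0), (7.0, 7.0, 0.5), (123.4, 123.4, 0.5)],
    )
    def test_direct_ratio(self, green, red, expected):
        assert pg.compute_raf(green, red) == pytest.approx(expected)

    def test_both_zero_is_missing(self):
        assert np.isnan(pg.compute_raf(0.0, 0.0))


class TestQcFilter:
    def test_insufficient_replicates_in_one_pool_drops_snp(self):
        rows = [("rs1", "1", 10, "case", r, 5.0, 5.0) for r in (1, 2, 3)]
        rows += [("rs1", "1", 10, "control", r, 5.0, 5.0) for r in (1, 2)]
        filtered, report = pg.qc_filter(_table(rows))
        assert len(filtered) == 0
        assert report.dropped["rs1"] == "insufficient replicates"

    @pytest.mark.parametrize("chrom", ["X", "Y", "MT"])
    def test_non_autosomal_dropped(self, chrom):
        rows = [(f"rs1", chrom, 10, p, r, 5.0, 5.0)
                for p in ("case", "control") for r in (1, 2, 3)]
        filtered, report = pg.qc_filter(_table(rows))
        assert len(filtered) == 0
        assert report.dropped["rs1"] == "non-autosomal"

    def test_mixed_fixture_counts(self):
        rows = []
        # rs_fail: one failed case replicate leaves 2 case reps -> dropped
        for r in (1, 2, 3):
            rows.append(("rs_fail", "1", 10, "case", r, 0.0 if r == 1 else 5.0,
                         0.0 if r == 1 else 5.0))
            rows.append(("rs_fail", "1", 10, "control", r, 5.0, 5.0))
        # rs_y on chrY
        for p in ("case", "control"):
            for r in (1, 2, 3):
                rows.append(("rs_y", "Y", 20, p, r, 5.0, 5.0))
        # three clean SNPs
        for snp in ("rs_a", "rs_b", "rs_c"):
            for p in ("case", "control"):
                for r in (1, 2, 3):
                    rows.append((snp, "2", 30, p, r, 4.0, 6.0))
        filtered, report = pg.qc_filter(_table(rows))
        assert report.n_failed_rows == 1
        assert report.n_non_autosomal == 1
        assert report.n_insufficient_replicates == 1
        assert set(filtered.data["snp_id"]) == {"rs_a", "rs_b", "rs_c"}


class TestSummarizePools:
    def test_closed_form_vk_and_zero_eps(self):
        rows = [("rs1", "1", 10, p, r, 50.0, 50.0)
                for p in ("case", "control") for r in (1, 2, 3)]
        s = pg.summarize_pools(_table(rows), 200, 200).loc["rs1"]
        assert s["f1"] == pytest.approx(0.5)
        assert s["v1"] == pytest.approx(0.5 * 0.5 / 400)
        assert s["eps2_1"] == 0.0

    def test_hand_arithmetic_eps2(self):
        # case replicate RAFs 0.4, 0.5, 0.6 -> eps^2 = (0.01+0+0.01)/(3*2)
        rafs = [0.4, 0.5, 0.6]
        rows = [("rs1", "1", 10, "case", r + 1, f * 100, (1 - f) * 100)
                for r, f in enumerate(rafs)]
        rows += [("rs1", "1", 10, "control", r, 50.0, 50.0) for r in (1, 2, 3)]
        s = pg.summarize_pools(_table(rows), 200, 200).loc["rs1"]
        assert s["f1"] == pytest.approx(0.5)
        assert s["eps2_1"] == pytest.approx(0.02 / 6, abs=1e-15)

    def test_matches_bruteforce_on_synthetic_fixture(self):
        table, _ = sd.simulate_pooled_experiment(100, n_spiked=5, seed=7)
        summary = pg.summarize_pools(table, 200, 200)
        df = table.data.copy()
        df["raf"] = df["green_raw"] / (df["green_raw"] + df["red_raw"])
        for snp, snp_rows in df.groupby("snp_id"):
            for pool, col_f, col_e in (("case", "f1", "eps2_1"), ("control", "f2", "eps2_2")):
                reps = snp_rows.loc[snp_rows["pool"] == pool, "raf"].tolist()
                fbar, eps2 = mean_and_eps2(reps)
                assert summary.loc[snp, col_f] == pytest.approx(fbar, abs=1e-12)
                assert summary.loc[snp, col_e] == pytest.approx(eps2, abs=1e-12)


def _summary_frame(f1, f2, n_case, n_control, e1, e2):
    return pd.DataFrame(
        {
            "chrom": ["1"], "pos": [100],
            "f1": [f1], "f2": [f2], "n1": [3], "n2": [3],
            "N1": [n_case], "N2": [n_control],
            "v1": [f1 * (1 - f1) / (2 * n_case)],
            "v2": [f2 * (1 - f2) / (2 * n_control)],
            "eps2_1": [e1], "eps2_2": [e2],
        },
        index=pd.Index(["rs1"], name="snp_id"),
    )


class TestCombinedZTest:
    def test_null_identity(self):
        res = pg.combined_z_test(_summary_frame(0.3, 0.3, 200, 200, 1e-4, 1e-4)).iloc[0]
        assert res["t1"] == 0 and res["tcomb"] == 0 and res["p_value"] == 1.0

    def test_tcomb_equals_t1_without_replicate_error(self):
        res = pg.combined_z_test(_summary_frame(0.3, 0.25, 200, 200, 0.0, 0.0)).iloc[0]
        assert res["tcomb"] == pytest.approx(res["t1"], rel=1e-15)

    def test_agrees_with_independent_evaluator(self):
        res = pg.combined_z_test(_summary_frame(0.30, 0.25, 200, 200, 1e-4, 1e-4)).iloc[0]
        t1, tcomb, z = combined_z_oracle(0.30, 0.25, 200, 200, 1e-4, 1e-4)
        assert res["t1"] == pytest.approx(t1, rel=1e-12)
        assert res["tcomb"] == pytest.approx(tcomb, rel=1e-12)
        assert res["z"] == pytest.approx(z, rel=1e-12)

    def test_degenerate_all_variances_zero_unequal_means_flagged(self):
        frame = _summary_frame(1.0, 0.0, 200, 200, 0.0, 0.0)
        res = pg.combined_z_test(frame).iloc[0]
        assert res["flagged_infinite"]
        assert 0 < res["p_value"] <= 5e-324

    @given(
        f1=st.floats(0.05, 0.95), f2=st.floats(0.05, 0.95),
        e1=st.floats(1e-8, 1e-3), e2=st.floats(1e-8, 1e-3),
    )
    def test_pool_swap_symmetry(self, f1, f2, e1, e2):
        a = pg.combined_z_test(_summary_frame(f1, f2, 200, 200, e1, e2)).iloc[0]
        b = pg.combined_z_test(_summary_frame(f2, f1, 200, 200, e2, e1)).iloc[0]
        assert a["t1"] == pytest.approx(b["t1"], rel=1e-12)
        assert a["tcomb"] == pytest.approx(b["tcomb"], rel=1e-12)
        assert a["z"] == pytest.approx(-b["z"], rel=1e-12)
        assert a["delta_raf"] == pytest.approx(-b["delta_raf"], rel=1e-12)

    @given(
        f1=st.floats(0.05, 0.95), f2=st.floats(0.05, 0.95),
        e1=st.floats(0, 1e-3), bump=st.floats(1e-6, 1e-3),
    )
    def test_tcomb_monotone_decreasing_in_replicate_error(self, f1, f2, e1, bump):
        lo = pg.combined_z_test(_summary_frame(f1, f2, 200, 200, e1, 1e-5)).iloc[0]
        hi = pg.combined_z_test(_summary_frame(f1, f2, 200, 200, e1 + bump, 1e-5)).iloc[0]
        assert hi["tcomb"] <= lo["tcomb"] + 1e-15

    def test_tcomb_never_exceeds_t1(self):
        res = pg.combined_z_test(_summary_frame(0.4, 0.2, 200, 200, 5e-4, 2e-4)).iloc[0]
        assert res["tcomb"] <= res["t1"]


class TestGenomewideHits:
    def test_printed_top_loci_all_selected(self, discovery_p):
        results = pd.DataFrame(
            {
                "snp_id": list(discovery_p) + ["rs_null1", "rs_null2"],
                "chrom": "1", "pos": 1,
                "p_value": list(discovery_p.values()) + [2e-7, 0.5],
            }
        )
        hits = pg.genomewide_hits(results, alpha=1.0e-7)
        assert list(hits["snp_id"]) == [
            "rs117503120", "rs4483616", "rs5998634", "rs16866133"
        ]

    def test_boundary_p_not_a_hit(self):
        results = pd.DataFrame(
            {"snp_id": ["rs1"], "chrom": "1", "pos": 1, "p_value": [1.0e-7]}
        )
        assert len(pg.genomewide_hits(results, alpha=1.0e-7)) == 0

    def test_empty_input(self):
        results = pd.DataFrame({"snp_id": [], "chrom": [], "pos": [], "p_value": []})
        assert len(pg.genomewide_hits(results)) == 0


class TestPlotData:
    def test_qq_single_point(self):
        qq = pg.qq_points([0.01])
        assert qq["expected"].iloc[0] == pytest.approx(-np.log10(0.5))
        assert qq["observed"].iloc[0] == pytest.approx(2.0)

    def test_qq_uniform_grid_close_to_diagonal(self):
        qq = pg.qq_points(np.arange(0.1, 1.0, 0.1))
        assert np.max(np.abs(qq["expected"] - qq["observed"])) < 0.31

    def test_qq_empty(self):
        assert len(pg.qq_points([])) == 0

    def test_manhattan_coordinates_monotone_within_chromosome(self):
        results = pd.DataFrame(
            {
                "snp_id": ["a", "b", "c", "d"],
                "chrom": ["1", "1", "2", "2"],
                "pos": [100, 200, 50, 150],
                "p_value": [0.5, 0.1, 0.9, 0.2],
            }
        )
        man = pg.manhattan_points(results)
        assert man["genome_coord"].is_monotonic_increasing
        assert man["neg_log10_p"].iloc[1] == pytest.approx(1.0)


class TestRafCorrelation:
    def test_identical_vectors(self):
        assert pg.raf_correlation([0.1, 0.5, 0.9], [0.1, 0.5, 0.9]) == pytest.approx(1.0)

    def test_sign_invariance(self):
        assert pg.raf_correlation([0.0, 1.0], [1.0, 0.0]) == pytest.approx(1.0)

    def test_matches_textbook_formula(self):
        x = [0.1, 0.2, 0.35, 0.4, 0.52, 0.6, 0.66, 0.7, 0.85, 0.9]
        y = [0.12, 0.18, 0.30, 0.45, 0.50, 0.66, 0.60, 0.75, 0.80, 0.95]
        n = len(x)
        sx, sy = sum(x), sum(y)
        sxx = sum(v * v for v in x)
        syy = sum(v * v for v in y)
        sxy = sum(a * b for a, b in zip(x, y))
        r = (n * sxy - sx * sy) / (
            ((n * sxx - sx * sx) ** 0.5) * ((n * syy - sy * sy) ** 0.5)
        )
        assert pg.raf_correlation(x, y) == pytest.approx(r * r, rel=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            pg.raf_correlation([0.5, 0.5], [0.1, 0.9])
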