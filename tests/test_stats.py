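"""Comparison construction, (AN)(C)OVA fitting, FDR, sweeps, reporting."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from callothick.simulate import CohortSpec, build_cohort, moment_matched_cohort
from callothick.stats import (
    ComparisonDesign,
    benjamini_hochberg,
    build_comparison,
    continuous_lq_analysis,
    fit_anova,
    report,
    segmentwise_analysis,
    threshold_sweep,
)
from conftest import THICK_COLS


def _design_from(df, rh="cRH", other="MH", scheme="A"):
    return ComparisonDesign(table=df, scheme=scheme, rh_level=rh, other_level=other)


class TestBuildComparison:
    def test_scheme_a_drops_clh(self, cohort600):
        df, _ = cohort600
        design = build_comparison(df, "A")
        assert set(design.table["group"]) == {"cRH", "MH"}
        assert design.excluded.get("cLH", 0) == (df["witelson"] == "cLH").sum()

    def test_scheme_c_drops_no_preference(self, cohort600):
        df, _ = cohort600
        design = build_comparison(df, "C")
        assert set(design.table["group"]) <= {"dRH", "dLH"}
        assert "none" not in set(design.table["group"])

    def test_ncrh_union(self, cohort600):
        df, _ = cohort600
        design = build_comparison(df, "NcRH")
        n_ncrh = (design.table["group"] == "NcRH").sum()
        assert n_ncrh == (df["witelson"] != "cRH").sum()

    def test_tiny_cell_rejected(self):
        df = pd.DataFrame(
            {
                "witelson": ["cRH"] * 10 + ["MH"] * 3,
                "sex": ["female", "male"] * 5 + ["female"] * 3,
                "area_mm2": np.arange(13.0),
            }
        )
        with pytest.raises(ValueError, match="cell"):
            build_comparison(df, "A")


class TestFitAnova:
    def test_group_f_approximates_squared_t_in_balanced_null(self):
        rng = np.random.default_rng(8)
        n = 1000
        df = pd.DataFrame(
            {
                "group": np.repeat(["cRH", "MH"], n),
                "sex": np.tile(["female", "male"], n),
                "y": rng.standard_normal(2 * n),
            }
        )
        res = fit_anova(_design_from(df), "y")
        a = df.loc[df.group == "cRH", "y"]
        b = df.loc[df.group == "MH", "y"]
        t, _ = sps.ttest_ind(b, a)
        assert res.group.F == pytest.approx(t**2, rel=0.02)

    def test_emm_equal_raw_means_when_balanced(self):
        rng = np.random.default_rng(9)
        df = pd.DataFrame(
            {
                "group": np.repeat(["cRH", "MH"], 40),
                "sex": np.tile(["female", "male"], 40),
                "y": rng.standard_normal(80),
            }
        )
        res = fit_anova(_design_from(df), "y")
        for level in ("cRH", "MH"):
            raw = df.loc[df.group == level, "y"].mean()
            assert res.emm[level][0] == pytest.approx(raw)

    def test_constant_dependent_flagged(self, cohort600):
        df, _ = cohort600
        design = build_comparison(df, "A")
        design.table = design.table.assign(const=1.0)
        res = fit_anova(design, "const")
        assert res.zero_variance and res.group.F == 0.0 and res.group.p == 1.0

    def test_relabeling_flips_d_sign_only(self, cohort600):
        df, _ = cohort600
        design = build_comparison(df, "A")
        res = fit_anova(design, "area_mm2")
        swapped = ComparisonDesign(design.table, "A", "MH", "cRH")
        res2 = fit_anova(swapped, "area_mm2")
        assert res2.d == pytest.approx(-res.d)
        assert res2.group.F == pytest.approx(res.group.F)
        assert res2.group.p == pytest.approx(res.group.p)

    def test_moment_matched_effect_size(self):
        df = moment_matched_cohort(694, 690, 94, 636, 385, seed=0)
        df = df.rename(columns={"group_label": "group"})
        res = fit_anova(_design_from(df), "area_mm2")
        assert res.emm["cRH"][0] == pytest.approx(694.0)
        assert res.emm["MH"][0] == pytest.approx(690.0)
        assert res.sigma_resid == pytest.approx(94.0)
        assert res.d == pytest.approx(-4 / 94)

    def test_ancova_with_unrelated_covariate_matches_anova(self):
        rng = np.random.default_rng(10)
        n = 4000
        df = pd.DataFrame(
            {
                "group": rng.choice(["cRH", "MH"], n),
                "sex": rng.choice(["female", "male"], n),
                "y": rng.standard_normal(n),
                "cov": rng.standard_normal(n),
            }
        )
        plain = fit_anova(_design_from(df), "y")
        adjusted = fit_anova(_design_from(df), "y", covariate="cov")
        assert abs(adjusted.d - plain.d) < 0.02

    def test_null_pvalues_uniform(self):
        """Group-effect p-values under the null are U(0,1): rejection rate
        at several alphas within Monte-Carlo error (500 fixed-design reps)."""
        rng = np.random.default_rng(11)
        n, reps = 200, 500
        df = pd.DataFrame(
            {
                "group": np.repeat(["cRH", "MH"], n // 2),
                "sex": np.tile(["female", "male"], n // 2),
            }
        )
        from callothick.stats import _batch_model, _pm_codes

        design = _design_from(df)
        g, s = _pm_codes(design)
        Y = rng.standard_normal((n, reps))
        m = _batch_model(g, s, Y, None)
        for alpha in (0.05, 0.25, 0.5):
            frac = np.mean(m["p_g"] <= alpha)
            assert frac == pytest.approx(alpha, abs=3 * np.sqrt(alpha * (1 - alpha) / reps))


class TestSegmentwise:
    def test_batch_route_matches_statsmodels(self, cohort600):
        df, _ = cohort600
        design = build_comparison(df, "B")
        segmap = segmentwise_analysis(design, THICK_COLS, covariate="fbv_13")
        for seg in (0, 17, 99):
            single = fit_anova(design, THICK_COLS[seg], covariate="fbv_13")
            assert segmap.F[seg] == pytest.approx(single.group.F, rel=1e-8)
            assert segmap.p[seg] == pytest.approx(single.group.p, rel=1e-8)
            assert segmap.d[seg] == pytest.approx(single.d, rel=1e-8)
            assert segmap.d_lo[seg] == pytest.approx(single.d_ci95[0], rel=1e-6)
            assert segmap.eta2_interaction[seg] == pytest.approx(
                single.eta2_interaction, rel=1e-6
            )
            assert segmap.sex_d[seg] == pytest.approx(single.sex_d, rel=1e-6)

    def test_fdr_implies_uncorrected(self):
        spec = CohortSpec(
            n=800, seed=21, injected_effects=[("witelson", "MH", range(40, 61), 0.6)]
        )
        df, _ = build_cohort(spec)
        design = build_comparison(df, "A")
        segmap = segmentwise_analysis(design, THICK_COLS)
        assert segmap.fdr_significant.any()
        assert np.all(~segmap.fdr_significant | segmap.uncorrected_significant)

    def test_all_p_one_yields_no_flags(self):
        reject, p_adj = benjamini_hochberg(np.ones(100))
        assert not reject.any()
        np.testing.assert_allclose(p_adj, 1.0)

    def test_bh_matches_stepup_oracle(self):
        p = np.concatenate([[0.001, 0.02, 0.03], np.linspace(0.05, 0.97, 97)])
        reject, _ = benjamini_hochberg(p, q=0.05)
        # direct step-up enumeration
        order = np.argsort(p)
        m = len(p)
        k_max = 0
        for rank, idx in enumerate(order, start=1):
            if p[idx] <= 0.05 * rank / m:
                k_max = rank
        oracle = np.zeros(m, bool)
        oracle[order[:k_max]] = True
        np.testing.assert_array_equal(reject, oracle)


class TestContinuousLQ:
    def test_recovers_injected_slope(self, cohort600):
        df, _ = cohort600
        rng = np.random.default_rng(30)
        c = -0.01
        work = df.copy()
        for col in THICK_COLS[:20]:
            work[col] = c * work["abs_lq"] + rng.standard_normal(len(work))
        res = continuous_lq_analysis(work, THICK_COLS[:20])
        cover = np.abs(res.slope - c) <= 2.6 * res.se
        assert cover.mean() >= 0.9

    def test_permuted_predictor_rarely_flagged(self, cohort600):
        df, _ = cohort600
        rng = np.random.default_rng(31)
        work = df.copy()
        work["abs_lq"] = rng.permutation(work["abs_lq"].to_numpy())
        res = continuous_lq_analysis(work, THICK_COLS)
        assert res.fdr_significant.sum() <= 2

    def test_constant_predictor_rejected(self, cohort600):
        df, _ = cohort600
        work = df.copy()
        work["abs_lq"] = 80.0
        with pytest.raises(ValueError):
            continuous_lq_analysis(work, THICK_COLS[:5])


class TestThresholdSweep:
    def test_threshold_80_equals_habib_partition(self, cohort600):
        df, _ = cohort600
        consistent = df["abs_lq"] >= 80
        assert (consistent == (df["habib"] != "MH")).all()

    def test_monotone_group_sizes_and_fit(self, cohort600):
        df, _ = cohort600
        thresholds = [10, 30, 50, 70, 90]
        results = threshold_sweep(df, thresholds, "area_mm2")
        sizes = []
        for T in thresholds:
            assert T in results
            sizes.append((df["abs_lq"] >= T).sum())
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))

    def test_out_of_range_threshold(self, cohort600):
        df, _ = cohort600
        with pytest.raises(ValueError):
            threshold_sweep(df, [5.0], "area_mm2")


class TestReport:
    def test_roundtrip_and_summaries(self, cohort600, tmp_path):
        df, _ = cohort600
        design = build_comparison(df, "A")
        res = fit_anova(design, "area_mm2")
        segmap = segmentwise_analysis(design, THICK_COLS)
        bundle = report(
            [({"comparison": "A", "variant": "absolute"}, res)],
            [({"comparison": "A", "variant": "absolute"}, segmap)],
            out_dir=tmp_path,
        )
        back = pd.read_csv(tmp_path / "area_results.csv")
        assert back.loc[0, "F"] == pytest.approx(res.group.F, rel=1e-9)
        assert back.loc[0, "d"] == pytest.approx(res.d, rel=1e-9)
        seg_back = pd.read_csv(tmp_path / "segments_A_absolute.csv")
        np.testing.assert_allclose(seg_back["d"], segmap.d, rtol=1e-9)
        summary = bundle["segment_summaries"][0]
        assert summary["min_d"] == pytest.approx(segmap.d.min())
        assert 1 <= summary["min_d_segment"] <= 100

    def test_empty_report_writes_header_only(self, tmp_path):
        report([], [], out_dir=tmp_path)
        text = (tmp_path / "area_results.csv").read_text().strip().splitlines()
        assert len(text) == 1 and "comparison" in text[0]

    def test_three_variants_per_comparison_present(self, cohort600, tmp_path):
        from callothick.io import RunConfig, run_full_analysis

        df, _ = cohort600
        cfg = RunConfig(out_dir=str(tmp_path), comparisons=("A",))
        bundle = run_full_analysis(df, cfg)
        assert sorted(bundle["area"]["variant"]) == [
            "absolute",
            "covariate",
            "relative",
        ]
        assert len(bundle["segments"]) == 3
        assert not bundle["failures"]
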