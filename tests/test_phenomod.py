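"""Phenotype-model tests: LS-means, split-plot ANOVA, variance components,
heritability, growth response and the trade-off correlation."""

import numpy as np
import pandas as pd
import pytest

from pgrscan import phenomod, synthgen
from pgrscan.types import MOCK, INOCULATED, PGRScanError, VarianceComponents


def balanced_scores(seed=0, acc_means=None, n_acc=6, reps=8, noise=0.0):
    """Hand-built balanced one-treatment score table (no covariate effects)."""
    rng = np.random.default_rng(seed)
    acc_means = acc_means if acc_means is not None else rng.uniform(2, 6, n_acc)
    rows = []
    for trt in (MOCK, INOCULATED):
        for b in (1, 2):
            for a in range(n_acc):
                for r in range(reps):
                    y = acc_means[a] + rng.normal(0, noise)
                    rows.append((b, trt, 1, r + 1, f"acc{a}", f"pop{a % 3}",
                                 5, False, 14, y, 4.0))
    return pd.DataFrame(rows, columns=[
        "block", "treatment", "plate", "well", "accession_id", "population_id",
        "germ_day", "is_control", "dai", "score", "plate_control_mean",
    ])


class TestLSMeans:
    def test_balanced_equals_group_means(self):
        sc = balanced_scores(noise=0.0)
        gv = phenomod.fit_lsmeans(sc, model="model5", dai=14)
        mock = gv[gv["treatment"] == MOCK].set_index("unit")["value"]
        direct = sc[(sc["treatment"] == MOCK)].groupby("accession_id")["score"].mean()
        np.testing.assert_allclose(mock.sort_index(), direct.sort_index(), atol=1e-10)

    def test_shift_equivariance(self, small_scores):
        gv = phenomod.fit_lsmeans(small_scores, model="model2", dai=14)
        shifted = small_scores.copy()
        shifted["score"] = shifted["score"] + 3.0
        gv2 = phenomod.fit_lsmeans(shifted, model="model2", dai=14)
        np.testing.assert_allclose(gv2["value"], gv["value"] + 3.0, atol=1e-9)

    def test_matches_normal_equations_oracle(self, small_scores):
        """Accession LS-means agree with a direct normal-equations solve."""
        trt, dai = MOCK, 21
        df = small_scores[
            (small_scores["treatment"] == trt) & (small_scores["dai"] == dai)
            & ~small_scores["is_control"]
        ]
        blocks = sorted(df["block"].unique())
        accs = sorted(df["accession_id"].unique())
        # full-rank cell-means-style encoding, solved via the normal equations
        X = np.column_stack(
            [np.ones(len(df))]
            + [(df["block"] == b).to_numpy(float) for b in blocks[1:]]
            + [(df["accession_id"] == a).to_numpy(float) for a in accs[1:]]
            + [df["germ_day"].to_numpy(float), df["plate_control_mean"].to_numpy(float)]
        )
        y = df["score"].to_numpy(float)
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        nb = len(blocks)
        expected = {}
        for i, a in enumerate(accs):
            preds = []
            for j, b in enumerate(blocks):
                x = np.zeros(X.shape[1])
                x[0] = 1.0
                if j > 0:
                    x[j] = 1.0
                if i > 0:
                    x[nb - 1 + i] = 1.0
                x[-2] = df["germ_day"].mean()
                x[-1] = df["plate_control_mean"].mean()
                preds.append(x @ beta)
            expected[a] = np.mean(preds)
        gv = phenomod.fit_lsmeans(small_scores, model="model5", dai=dai, treatments=[trt])
        got = gv.set_index("unit")["value"]
        for a in accs:
            assert got[a] == pytest.approx(expected[a], abs=1e-8)

    def test_row_order_invariance(self, small_scores):
        gv = phenomod.fit_lsmeans(small_scores, model="model2", dai=14)
        shuffled = small_scores.sample(frac=1.0, random_state=4).reset_index(drop=True)
        gv2 = phenomod.fit_lsmeans(shuffled, model="model2", dai=14)
        pd.testing.assert_frame_equal(
            gv.sort_values(["unit", "treatment"]).reset_index(drop=True),
            gv2.sort_values(["unit", "treatment"]).reset_index(drop=True),
        )


class TestSplitPlotAnova:
    def test_treatment_label_swap_symmetry(self, small_scores):
        at = phenomod.splitplot_anova(small_scores, dai=14)
        swapped = small_scores.copy()
        swapped["treatment"] = swapped["treatment"].map(
            {MOCK: INOCULATED, INOCULATED: MOCK}
        )
        at2 = phenomod.splitplot_anova(swapped, dai=14)
        f1 = at.set_index("term")["F"]
        f2 = at2.set_index("term")["F"]
        assert f1["Treatment"] == pytest.approx(f2["Treatment"], rel=1e-9)

    def test_split_plot_stratum_used(self, small_scores):
        at = phenomod.splitplot_anova(small_scores, dai=14).set_index("term")
        assert at.loc["Block", "stratum"] == "block x treatment"
        assert at.loc["Treatment", "stratum"] == "block x treatment"
        assert at.loc["Population", "stratum"] == "residual"
        assert at.loc["Block", "df_den"] == at.loc["Block x Treatment", "df_num"]

    def test_strong_treatment_effect_detected(self):
        # 4 blocks so the whole-plot stratum has 3 denominator df; with the
        # study's 2 blocks that stratum has a single df and cannot reach
        # p < 0.001 however large the effect
        design = synthgen.build_design(
            n_pop=4, n_acc_per_pop=2, n_blocks=6, plates_per_cell=2,
            reps_per_treatment=36, seed=2,
        )
        eff = synthgen.PhenotypeEffects(
            treatment_effect={14: 2.0, 21: 2.0, 28: 2.0}, tradeoff_slope=0.0,
            qtl_coupling=0.0, response_noise_sd=0.0, plate_sd=0.0,
        )
        sc = synthgen.simulate_phenotypes(design, effects=eff, seed=1)
        at = phenomod.splitplot_anova(sc, dai=14).set_index("term")
        assert at.loc["Treatment", "p"] < 0.001

    def test_germination_effect_detected(self, small_scores):
        at = phenomod.splitplot_anova(small_scores, dai=21).set_index("term")
        assert at.loc["Germination date", "p"] < 1e-6


class TestVarianceComponents:
    def test_zero_noise_distinct_accessions(self):
        sc = balanced_scores(acc_means=np.array([2, 3, 4, 5, 6, 7.0]), noise=0.0)
        vc = phenomod.variance_components(sc, dai=14, treatment=MOCK)
        assert vc.VR == pytest.approx(0.0, abs=1e-10)
        assert vc.VF > 0

    def test_pure_noise_vf_near_zero(self):
        ests = []
        for seed in range(30):
            sc = balanced_scores(seed=seed, acc_means=np.zeros(6), noise=1.0)
            vc = phenomod.variance_components(sc, dai=14, treatment=MOCK)
            ests.append(vc.VF / vc.VR)
        assert np.median(ests) < 0.05

    def test_single_level_error(self):
        sc = balanced_scores()
        sc["block"] = 1
        with pytest.raises(PGRScanError):
            phenomod.variance_components(sc, dai=14, treatment=MOCK)

    def test_reml_close_to_mom_on_balanced(self):
        sc = balanced_scores(seed=3, acc_means=np.arange(6) * 0.8, noise=0.5)
        vc = phenomod.variance_components(sc, dai=14, treatment=MOCK)
        vr = phenomod.variance_components(sc, dai=14, treatment=MOCK, reml=True)
        assert vr.VF == pytest.approx(vc.VF, rel=0.2, abs=0.05)
        assert vr.VR == pytest.approx(vc.VR, rel=0.2)


class TestHeritability:
    @pytest.mark.parametrize(
        "vf,vb,vr,b,n,expected",
        [(1, 0, 0, 2, 2, 1.0), (0, 1, 1, 2, 2, 0.0), (1, 1, 1, 2, 2, 0.5)],
    )
    def test_arithmetic(self, vf, vb, vr, b, n, expected):
        vc = VarianceComponents(VF=vf, VB=vb, VR=vr, b_blocks=b, n_blocks=n)
        assert phenomod.heritability(vc) == pytest.approx(expected)

    def test_alternate_reading(self):
        vc = VarianceComponents(VF=1, VB=1, VR=1, b_blocks=2, n_blocks=2)
        assert phenomod.heritability(vc, reading="vr-over-bn") == pytest.approx(
            1 / (1 + 0.5 + 0.25)
        )

    def test_monotonicity(self):
        base = VarianceComponents(VF=1, VB=0.5, VR=0.5, b_blocks=2, n_blocks=2)
        h = phenomod.heritability(base)
        more_vr = VarianceComponents(VF=1, VB=0.5, VR=1.0, b_blocks=2, n_blocks=2)
        more_vf = VarianceComponents(VF=2, VB=0.5, VR=0.5, b_blocks=2, n_blocks=2)
        assert phenomod.heritability(more_vr) < h < phenomod.heritability(more_vf)

    def test_zero_blocks_error(self):
        vc = VarianceComponents(VF=1, VB=0, VR=0, b_blocks=0, n_blocks=2)
        with pytest.raises(PGRScanError):
            phenomod.heritability(vc)

    def test_strong_genetics_min_pvalue(self):
        sc = balanced_scores(acc_means=np.arange(6) * 2.0, noise=0.2)
        h2, p = phenomod.heritability_pvalue(sc, dai=14, treatment=MOCK,
                                             n_perm=99, seed=0)
        assert h2 > 0.9
        assert p == pytest.approx(1 / 100)

    def test_perm_count_floor(self):
        with pytest.raises(PGRScanError):
            phenomod.heritability_pvalue(balanced_scores(), dai=14,
                                         treatment=MOCK, n_perm=50)


class TestPGR:
    def test_arithmetic(self):
        gv = pd.DataFrame({
            "level": ["population"] * 6,
            "unit": ["a", "a", "b", "b", "c", "c"],
            "treatment": [MOCK, INOCULATED] * 3,
            "dai": [14] * 6,
            "value": [4, 4, 2, 3, 5, 4],
        })
        pgr = phenomod.compute_pgr(gv).set_index("unit")["pgr"]
        assert pgr["a"] == pytest.approx(0.0)
        assert pgr["b"] == pytest.approx(50.0)
        assert pgr["c"] == pytest.approx(-20.0)

    def test_zero_mock_error(self):
        gv = pd.DataFrame({
            "level": ["population"] * 2, "unit": ["a", "a"],
            "treatment": [MOCK, INOCULATED], "dai": [14, 14], "value": [0.0, 1.0],
        })
        with pytest.raises(PGRScanError):
            phenomod.compute_pgr(gv)

    def test_sign_matches_difference(self, small_scores):
        gv = phenomod.fit_lsmeans(small_scores, model="model2", dai=28)
        pgr = phenomod.compute_pgr(gv)
        wide = gv.pivot_table(index="unit", columns="treatment", values="value")
        merged = pgr.merge(wide, on="unit")
        assert np.all(
            np.sign(merged["pgr"]) == np.sign(merged[INOCULATED] - merged[MOCK])
        )


class TestTradeoff:
    def test_perfect_negative(self):
        gv = pd.DataFrame({
            "level": ["population"] * 5, "unit": list("abcde"),
            "treatment": [MOCK] * 5, "dai": [14] * 5,
            "value": [1.0, 2.0, 3.0, 4.0, 5.0],
        })
        pgr = pd.DataFrame({
            "level": ["population"] * 5, "unit": list("abcde"),
            "dai": [14] * 5, "pgr": [50, 30, 10, -10, -30.0],
        })
        rho, p = phenomod.tradeoff_test(pgr, gv, dai=14)
        assert rho == pytest.approx(-1.0)

    def test_generator_tradeoff_negative_all_dais(self):
        design = synthgen.build_design(
            n_pop=20, n_acc_per_pop=2, n_blocks=2, plates_per_cell=6, seed=9
        )
        sc = synthgen.simulate_phenotypes(design, seed=7)
        for dai in (14, 21, 28):
            gv = phenomod.fit_lsmeans(sc, model="model2", dai=dai)
            pgr = phenomod.compute_pgr(gv)
            rho, _ = phenomod.tradeoff_test(pgr, gv, dai=dai)
            assert rho < 0
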