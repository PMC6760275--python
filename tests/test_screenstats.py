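"""Mixed-model fitting, z-scores, FDR and significance calls."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cardioscreen.screenstats import (
    DegenerateDesignError,
    adjust_fdr,
    classify_numeric_feature,
    feature_calls,
    fit_lmm,
    hipsc_pipeline,
    order_compounds,
    zscore_matrix,
    zscore_vs_dmso,
)
from cardioscreen.sim import ScreenDesign, simulate_screen


def _null_screen(seed, plates=3):
    design = ScreenDesign(features=("qtc",), plates=plates, sigma_plate=1.0,
                          sigma_error=1.0, sigma_compound=0.0, seed=seed)
    return simulate_screen(design)[0]


class TestFitLmm:
    def test_matches_statsmodels_reml(self):
        """Independent oracle: statsmodels MixedLM with crossed variance
        components on the same data."""
        import statsmodels.formula.api as smf
        design = ScreenDesign(features=("qtc",), plates=4, sigma_plate=0.8,
                              sigma_error=1.0, sigma_compound=1.0, seed=42)
        table, _ = simulate_screen(design)
        fit = fit_lmm(table, "qtc")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sm_fit = smf.mixedlm(
                "value ~ C(row)", table, groups=np.ones(len(table)),
                vc_formula={"plate": "0 + C(plate)",
                            "compound": "0 + C(compound)"},
            ).fit(reml=True)
        assert fit.sigma_plate**2 == pytest.approx(sm_fit.vcomp[1], rel=0.01)
        assert fit.sigma_compound**2 == pytest.approx(sm_fit.vcomp[0], rel=0.01)
        assert fit.sigma_error**2 == pytest.approx(sm_fit.scale, rel=0.01)

    def test_null_effects_within_three_sd(self):
        hits = total = 0
        for s in range(30):
            fit = fit_lmm(_null_screen(s), "qtc")
            for c in fit.alpha:
                total += 1
                a0 = fit.alpha["DMSO"]
                hits += abs(fit.alpha[c] - a0) < 3 * np.hypot(
                    fit.alpha_sd[c], fit.alpha_sd["DMSO"])
        assert hits / total >= 0.99

    def test_planted_effect_has_largest_alpha(self):
        design = ScreenDesign(features=("qtc",), plates=3, sigma_plate=1.0,
                              sigma_error=1.0,
                              effects={"qtc": {"drug02": 5.0}}, seed=9)
        table, _ = simulate_screen(design)
        fit = fit_lmm(table, "qtc")
        assert max(fit.alpha, key=fit.alpha.get) == "drug02"

    def test_zero_plate_variance_recovered_at_boundary(self):
        design = ScreenDesign(features=("qtc",), plates=3, sigma_plate=0.0,
                              sigma_error=1.0, sigma_compound=0.0, seed=11)
        table, _ = simulate_screen(design)
        fit = fit_lmm(table, "qtc")
        assert fit.sigma_plate < 0.1 * fit.sigma_error

    def test_single_plate_design_rejected(self):
        table = _null_screen(0)
        with pytest.raises(DegenerateDesignError):
            fit_lmm(table[table["plate"] == "plate0"], "qtc")


class TestZScores:
    def test_dmso_z_is_exactly_zero(self):
        z = zscore_vs_dmso(fit_lmm(_null_screen(1), "qtc"))
        assert z["DMSO"] == 0.0

    def test_null_z_sd_close_to_one(self):
        zs = []
        for s in range(40):
            z = zscore_vs_dmso(fit_lmm(_null_screen(s), "qtc"))
            zs += [v for c, v in z.items() if c != "DMSO"]
        assert np.std(zs) == pytest.approx(1.0, rel=0.15)


class TestFdr:
    def test_single_p_unchanged(self):
        assert adjust_fdr([0.04])[0] == pytest.approx(0.04)

    def test_hand_computed_step_up(self):
        # 0.01*4/1, 0.02*4/2, 0.03*4/3, 0.04*4/4 then monotone -> all 0.04
        adj = adjust_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adj, 0.04)

    def test_all_ones(self):
        assert np.allclose(adjust_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_permutation_invariance(self, rng):
        p = rng.random(20)
        perm = rng.permutation(20)
        assert np.allclose(adjust_fdr(p)[perm], adjust_fdr(p[perm]))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_fdr([0.5, 1.5])


class TestCalls:
    def test_ventricular_bpm_uses_strict_cutoff(self):
        assert not classify_numeric_feature(4.0, 0.01, "ventricular_bpm")
        assert classify_numeric_feature(4.0, 0.001, "ventricular_bpm")

    def test_one_sided_features_need_positive_z(self):
        assert not classify_numeric_feature(-4.0, 0.001, "cardiac_arrest")
        assert classify_numeric_feature(4.0, 0.001, "cardiac_arrest")
        assert not classify_numeric_feature(-4.0, 0.001, "arrhythmic_beats")

    def test_two_sided_feature_below_cutoff(self):
        assert classify_numeric_feature(3.0, 0.01, "qtc")


class TestOrdering:
    def test_all_zero_rows_alphabetical(self):
        z = pd.DataFrame(0.0, index=["c", "a", "b"], columns=["f1", "f2"])
        assert order_compounds(z) == ["a", "b", "c"]

    def test_scaled_row_outranks_copy(self):
        z = pd.DataFrame({"f": [1.0, 2.0]}, index=["orig", "scaled"])
        assert order_compounds(z) == ["scaled", "orig"]

    def test_matches_brute_force_sort(self, rng):
        z = pd.DataFrame(rng.normal(size=(12, 4)),
                         index=[f"c{i:02d}" for i in range(12)])
        expected = sorted(z.index,
                          key=lambda c: (-z.loc[c].abs().sum(), c))
        assert order_compounds(z) == expected

    def test_zscore_matrix_pivot(self):
        calls = feature_calls(_null_screen(3), "qtc")
        m = zscore_matrix(calls)
        assert m.shape == (7, 1)


class TestHipscPipeline:
    def _triplicate_data(self, seed, effect_t3=0.0):
        rng = np.random.default_rng(seed)
        rows = []
        compounds = ["DMSO", "c01", "c02", "c03"]
        for plate in range(4):
            gamma = rng.normal(0, 0.3)
            for ci, comp in enumerate(compounds):
                for tp in ("T1", "T2", "T3"):
                    eff = effect_t3 if (comp == "c01" and tp == "T3") else 0.0
                    base = 1.0 + gamma + eff + rng.normal(0, 0.2)
                    for rep in range(3):
                        rows.append({
                            "compound": comp, "plate": f"p{plate}",
                            # rows rotate across plates so the row effect
                            # stays separable from the compound effect
                            "row": "ABCD"[(ci + plate) % 4], "replicate": rep,
                            "feature": "bpm", "timepoint": tp,
                            "value": base + rng.normal(0, 0.05),
                        })
        return pd.DataFrame(rows)

    def test_triplicate_averaging_is_mean(self):
        df = self._triplicate_data(0)
        df["value"] = 2.5  # identical replicates
        out = hipsc_pipeline(df)
        assert set(out["timepoint"]) == {"T1", "T2", "T3"}
        assert not out["call"].any()

    def test_planted_t3_effect_detected_only_at_t3(self):
        out = hipsc_pipeline(self._triplicate_data(1, effect_t3=3.0))
        c1 = out[out["compound"] == "c01"].set_index("timepoint")
        assert bool(c1.loc["T3", "call"])
        assert not bool(c1.loc["T1", "call"])

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError):
            hipsc_pipeline(pd.DataFrame({"compound": ["a"]}))
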