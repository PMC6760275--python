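"""Ground-truth guarantees of the synthetic generators."""

import numpy as np
import pandas as pd
import pytest

from cardioscreen.sim import (
    FaersSimConfig,
    FlowSimParams,
    HeartSimParams,
    ScreenDesign,
    simulate_calcium_trace,
    simulate_faers,
    simulate_heart_video,
    simulate_screen,
    simulate_vessel_video,
)


class TestHeartVideo:
    def test_scheduled_event_count_matches_rate(self):
        # floor(200 beats/min / 60 * 40 s) = 133 scheduled contractions
        _, truth = simulate_heart_video(
            HeartSimParams(ventricular_bpm=200, fps=75.9, duration=40.0,
                           noise_sd=0.0, seed=0)
        )
        assert len(truth["ventricular_beat_times"]) == 133

    def test_arrest_window_sets_longest_gap_exactly(self):
        _, truth = simulate_heart_video(
            HeartSimParams(ventricular_bpm=180, duration=20.0,
                           arrest_windows=((10.0, 2.0),), seed=1)
        )
        assert truth["longest_gap_s"] == pytest.approx(2.0)

    def test_av_ratio_doubles_atrial_events(self):
        _, truth = simulate_heart_video(
            HeartSimParams(ventricular_bpm=120, duration=10.0, av_ratio=2,
                           seed=2)
        )
        assert (len(truth["atrial_beat_times"])
                == 2 * len(truth["ventricular_beat_times"]))

    def test_rendered_diameters_match_parameters_within_one_px(self):
        from cardioscreen.kymo import chamber_extent_trace, extract_kymograph, \
            place_chamber_lines
        from cardioscreen.pipeline import default_heart_axis
        stack, truth = simulate_heart_video(
            HeartSimParams(ventricular_bpm=150, duration=6.0,
                           dia_diameter_um=120, sys_diameter_um=80, seed=3)
        )
        v_line, _ = place_chamber_lines(default_heart_axis(stack, truth))
        trace = chamber_extent_trace(extract_kymograph(stack, v_line))
        px = stack.pixel_size_um
        assert trace.extent_um.max() == pytest.approx(120, abs=px)
        assert trace.extent_um.min() == pytest.approx(80, abs=px)

    def test_seed_reproducibility(self):
        a, ta = simulate_heart_video(HeartSimParams(duration=3.0, seed=7))
        b, tb = simulate_heart_video(HeartSimParams(duration=3.0, seed=7))
        assert np.array_equal(a.frames, b.frames)
        assert ta["ventricular_beat_times"] == tb["ventricular_beat_times"]

    @pytest.mark.parametrize("bad", [
        dict(av_ratio=0),
        dict(sys_diameter_um=130.0),
        dict(fps=-1.0),
    ])
    def test_invalid_parameters_rejected(self, bad):
        with pytest.raises(ValueError):
            simulate_heart_video(HeartSimParams(duration=2.0, **bad))


class TestVesselVideo:
    def test_constant_velocity_ground_truth(self):
        _, truth = simulate_vessel_video(
            FlowSimParams(mean_velocity_um_s=500.0, pulsatility=0.0,
                          duration=4.0, seed=0)
        )
        assert np.allclose(truth["velocity_um_s"], 500.0)

    def test_zero_mean_oscillation_has_zero_net_displacement(self):
        # a whole number of oscillation cycles -> closed displacement loop
        _, truth = simulate_vessel_video(FlowSimParams(
            mean_velocity_um_s=0.0, oscillation_amplitude_um_s=300.0,
            heart_bpm=120.0, duration=10.0, seed=1,
        ))
        period_um = 300.0 / (2 * np.pi * 2.0)
        assert abs(truth["net_displacement_um"]) < 2 * period_um

    def test_pulsatile_ground_truth_quantiles(self):
        # per-frame quantiles of v(t) = 300 (1 + 0.5 sin wt): the arcsine
        # law gives p90 = 300 (1 + 0.5 cos(0.1 pi)) = 442.7, p10 = 157.3
        _, truth = simulate_vessel_video(FlowSimParams(
            mean_velocity_um_s=300.0, pulsatility=0.5, duration=10.0, seed=2,
        ))
        v = np.asarray(truth["velocity_um_s"])
        assert np.percentile(v, 90) == pytest.approx(442.65, rel=0.02)
        assert np.percentile(v, 10) == pytest.approx(157.35, rel=0.02)


class TestCalciumTrace:
    def test_peak_count_and_amplitude(self):
        _, trace, truth = simulate_calcium_trace(
            bpm=60, amplitude=2.0, peak_width_s=0.5, fps=50, duration=10.0,
            noise_sd=0.0,
        )
        assert truth["n_peaks"] == 10
        assert trace.max() - np.percentile(trace, 10) == pytest.approx(2.0, abs=0.02)

    def test_triangle_width_ground_truth(self):
        # similar triangles: width at 10 % of a 1.0 s base is 0.9 s
        _, _, truth = simulate_calcium_trace(
            bpm=30, amplitude=1.0, peak_width_s=1.0, fps=50, duration=10.0,
        )
        assert truth["ppkw"] == pytest.approx(0.9)
        assert truth["pkw"] == pytest.approx(0.5)

    def test_peak_wider_than_period_rejected(self):
        with pytest.raises(ValueError):
            simulate_calcium_trace(bpm=120, peak_width_s=0.8, fps=50,
                                   duration=5.0)


class TestScreen:
    def test_no_variance_means_constant_response(self):
        design = ScreenDesign(
            features=("qtc",), plates=2, sigma_plate=0.0, sigma_error=0.0,
            sigma_compound=0.0, mu=5.0, seed=0,
        )
        table, _ = simulate_screen(design)
        assert np.allclose(table["value"], 5.0)

    def test_planted_effect_recovered_as_mean_difference(self):
        # Monte-Carlo oracle: with alpha = +5 sigma_e for one compound, the
        # raw mean difference vs DMSO converges to alpha
        diffs = []
        for s in range(30):
            design = ScreenDesign(
                features=("qtc",), plates=2, sigma_plate=0.5, sigma_error=1.0,
                effects={"qtc": {"drug01": 5.0}}, seed=s,
            )
            table, _ = simulate_screen(design)
            g = table.groupby("compound")["value"].mean()
            diffs.append(g["drug01"] - g["DMSO"])
        se = np.std(diffs) / np.sqrt(len(diffs))
        assert np.mean(diffs) == pytest.approx(5.0, abs=3 * se + 0.15)

    def test_large_plate_variance_dominates_between_plate_spread(self):
        design = ScreenDesign(
            features=("qtc",), plates=2, sigma_plate=20.0, sigma_error=1.0,
            sigma_compound=0.0, seed=4,
        )
        table, _ = simulate_screen(design)
        within = table.groupby("plate")["value"].var().mean()
        total = table["value"].var()
        assert within < 0.2 * total

    def test_missing_dmso_rejected(self):
        with pytest.raises(ValueError):
            ScreenDesign(compounds=("drug00", "drug01"))


class TestFaersTable:
    def test_null_model_reporting_fractions_are_uniform(self):
        table, _ = simulate_faers(FaersSimConfig(n_reports=4000, seed=0))
        ev = "bradycardia"
        frac = (
            table.assign(hit=table["events"].str.split(";").apply(lambda e: ev in e))
            .groupby("primary_suspect")["hit"].mean()
        )
        # all drugs share the base reporting probability (0.05)
        assert frac.max() - frac.min() < 0.05

    def test_planted_enrichment_visible_in_counts(self):
        table, _ = simulate_faers(FaersSimConfig(
            n_reports=4000,
            planted_associations=(("drugA", "torsades de pointes", 4.0),),
            seed=1,
        ))
        hit = table["events"].str.split(";").apply(
            lambda e: "torsades de pointes" in e
        )
        by_drug = table.assign(hit=hit).groupby("primary_suspect")["hit"].mean()
        background = by_drug.drop("drugA").mean()
        assert by_drug["drugA"] == pytest.approx(4 * background, rel=0.35)

    def test_duplicate_rate_binomial(self):
        table, truth = simulate_faers(
            FaersSimConfig(n_reports=1000, duplicate_rate=0.1, seed=2)
        )
        n_dup = len(truth["duplicate_pairs"])
        assert len(table) == 1000 + n_dup
        # binomial(1000, 0.1): mean 100, SD 9.5
        assert 100 - 3 * 9.5 <= n_dup <= 100 + 3 * 9.5

    def test_reproducibility(self):
        a, _ = simulate_faers(FaersSimConfig(n_reports=200, seed=5))
        b, _ = simulate_faers(FaersSimConfig(n_reports=200, seed=5))
        pd.testing.assert_frame_equal(a, b)
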