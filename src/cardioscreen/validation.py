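"""Parameter-recovery and calibration suites.

Each function simulates study-condition inputs with :mod:`cardioscreen.sim`,
runs the corresponding analysis path end to end, and summarises how well the
generative truth is recovered.  These suites back the package's validation
claims; they are also what ``scripts/acceptance.py`` reports.

Problem sizes reflect the screen's acquisition settings (40 s heart videos
at 75.9 fps, 12 subjects per compound, and so on); Monte-Carlo replicate
counts are chosen so that each summary statistic is stable to well within
the tolerance it is compared against.
"""

from __future__ import annotations

import numpy as np

from cardioscreen.faers import (
    GaParams,
    _encode_attrs,
    _mentions_drug,
    _target_dists,
    attribute_distance,
    classify_faers,
    drug_event_prr,
    select_backgrounds,
)
from cardioscreen.pipeline import analyze_flow, analyze_heart, default_heart_axis
from cardioscreen.screenstats import feature_calls, fit_lmm, zscore_vs_dmso
from cardioscreen.sim import (
    FaersSimConfig,
    FlowSimParams,
    HeartSimParams,
    ScreenDesign,
    simulate_faers,
    simulate_heart_video,
    simulate_screen,
    simulate_vessel_video,
)


def heart_recovery(n_videos: int = 50, seed: int = 0) -> dict:
    """Recover rate, ejection fraction and arrest from simulated hearts.

    Videos span 100-300 beats/min, 20-70 % ejection fraction and arrest
    windows of 0-2 s, at the acquisition defaults (40 s, 75.9 fps).
    Returns worst-case absolute errors: beat rate as a relative error,
    ejection fraction in percentage points, arrest in frames, plus the
    RMS beat-time error in frames and the beat-count agreement.
    """
    rng = np.random.default_rng(seed)
    bpm_err, ef_err, arrest_err, rms_frames = [], [], [], []
    counts_match = 0
    for i in range(n_videos):
        bpm = rng.uniform(100, 300)
        ef = rng.uniform(20, 70)
        arrest = float(rng.choice([0.0, 1.0, 2.0]))
        dia = 120.0
        sys_ = dia * (1 - ef / 100) ** (1 / 3)
        params = HeartSimParams(
            ventricular_bpm=bpm,
            dia_diameter_um=dia,
            sys_diameter_um=sys_,
            arrest_windows=((15.0, arrest),) if arrest else (),
            seed=int(rng.integers(2**31)),
        )
        stack, truth = simulate_heart_video(params)
        feats = analyze_heart(stack, default_heart_axis(stack, truth))
        tt = np.asarray(truth["ventricular_beat_times"])
        true_bpm = 60.0 / np.median(np.diff(tt))
        bpm_err.append(abs(feats.ventricular_bpm - true_bpm) / true_bpm)
        ef_err.append(
            abs(feats.ejection_fraction - truth["ejection_fraction_spherical"])
        )
        arrest_err.append(
            abs(feats.cardiac_arrest - truth["longest_gap_s"]) * stack.fps
        )
        # beat times vs schedule
        from cardioscreen.kymo import (
            chamber_extent_trace,
            detect_beats,
            extract_kymograph,
            place_chamber_lines,
        )
        v_line, _ = place_chamber_lines(default_heart_axis(stack, truth))
        beats = detect_beats(chamber_extent_trace(extract_kymograph(stack, v_line)))
        if beats.n_beats == len(tt):
            counts_match += 1
            rms_frames.append(
                float(np.sqrt(np.mean((beats.beat_times - tt) ** 2)) * stack.fps)
            )
    return {
        "n_videos": n_videos,
        "max_bpm_rel_err": float(np.max(bpm_err)),
        "max_ef_err_points": float(np.max(ef_err)),
        "max_arrest_err_frames": float(np.max(arrest_err)),
        "beat_count_exact_fraction": counts_match / n_videos,
        "max_beat_time_rms_frames": float(np.max(rms_frames)) if rms_frames else float("nan"),
    }


def flag_recovery(kind: str, n_seeds: int = 20, seed: int = 0,
                  duration: float = 10.0) -> float:
    """Fraction of simulations whose AV-block or bigeminy flag is correct.

    ``kind`` is ``"av"`` (2:1 conduction) or ``"bigeminy"``.  Shorter
    videos than the full 40 s recordings suffice here because the flags
    depend only on interval patterns, not on long-horizon statistics.
    """
    rng = np.random.default_rng(seed)
    correct = 0
    for _ in range(n_seeds):
        s = int(rng.integers(2**31))
        if kind == "av":
            params = HeartSimParams(
                ventricular_bpm=100, av_ratio=2, duration=duration, seed=s
            )
        elif kind == "bigeminy":
            params = HeartSimParams(
                ventricular_bpm=150, bigeminy=True, duration=duration, seed=s
            )
        else:
            raise ValueError(kind)
        stack, truth = simulate_heart_video(params)
        feats = analyze_heart(stack, default_heart_axis(stack, truth))
        if kind == "av":
            correct += feats.av_coupling_defect and abs(feats.av_ratio - 2) < 0.2
        else:
            correct += feats.bigeminy
    return correct / n_seeds


def flow_recovery(seed: int = 0, n_osc_seeds: int = 20) -> dict:
    """Constant-flow recovery error and the oscillatory no-flow flag rate."""
    rng = np.random.default_rng(seed)
    stack, truth = simulate_vessel_video(
        FlowSimParams(mean_velocity_um_s=500.0, seed=int(rng.integers(2**31)))
    )
    feats = analyze_flow(stack)
    const_err = abs(feats.median - 500.0) / 500.0

    no_flow = 0
    for _ in range(n_osc_seeds):
        stack, truth = simulate_vessel_video(FlowSimParams(
            mean_velocity_um_s=0.0, oscillation_amplitude_um_s=300.0,
            seed=int(rng.integers(2**31)),
        ))
        no_flow += analyze_flow(stack).no_flow
    return {
        "constant_rel_err": float(const_err),
        "oscillatory_no_flow_fraction": no_flow / n_osc_seeds,
    }


def lmm_null_fpr(replicates: int = 500, seed: int = 0,
                 subjects: int = 12) -> dict:
    """Per-feature false-positive rate of the call pipeline on null screens.

    Each replicate simulates a compact screen (7 compounds + DMSO on 2
    plates, 12 subjects per compound, no compound effects) and counts
    compounds called significant after BH adjustment at the .05 cutoff.
    """
    rng = np.random.default_rng(seed)
    calls_made = 0
    calls_total = 0
    for _ in range(replicates):
        design = ScreenDesign(
            features=("qtc",), plates=2, subjects_per_compound=subjects,
            sigma_plate=1.0, sigma_error=1.0, sigma_compound=0.0,
            seed=int(rng.integers(2**31)),
        )
        table, _ = simulate_screen(design)
        calls = feature_calls(table, "qtc")
        calls_made += int(calls["call"].sum())
        calls_total += len(calls)
    return {
        "replicates": replicates,
        "false_positive_rate": calls_made / calls_total,
    }


def lmm_power(effect_sd_units: float = 3.0, replicates: int = 100,
              seed: int = 0) -> float:
    """Detection power for one compound with a planted effect of
    ``effect_sd_units`` residual SDs, at the .05 adjusted-p cutoff."""
    rng = np.random.default_rng(seed)
    detected = 0
    for _ in range(replicates):
        design = ScreenDesign(
            features=("qtc",), plates=2, sigma_plate=1.0, sigma_error=1.0,
            effects={"qtc": {"drug03": effect_sd_units}},
            seed=int(rng.integers(2**31)),
        )
        table, _ = simulate_screen(design)
        calls = feature_calls(table, "qtc").set_index("compound")
        detected += bool(calls.loc["drug03", "call"])
    return detected / replicates


def lmm_null_z_sd(replicates: int = 80, seed: int = 0) -> float:
    """Empirical SD of the DMSO-contrast z-scores under the null model."""
    rng = np.random.default_rng(seed)
    zs: list[float] = []
    for _ in range(replicates):
        design = ScreenDesign(
            features=("qtc",), plates=3, sigma_plate=1.0, sigma_error=1.0,
            sigma_compound=0.0, seed=int(rng.integers(2**31)),
        )
        table, _ = simulate_screen(design)
        z = zscore_vs_dmso(fit_lmm(table, "qtc"))
        zs += [v for c, v in z.items() if c != "DMSO"]
    return float(np.std(zs))


#: GA settings for the report-level suites: fewer generations and pools
#: than the screening default because the averaged PRR stabilises long
#: before the matcher converges fully.
_SUITE_GA = GaParams(population=30, generations=20)


def prr_null(n_seeds: int = 20, n_reports: int = 1000, seed: int = 0,
             n_pools: int = 10) -> dict:
    """Mean PRR of null drug-event associations (no planted enrichment).

    A single null pair at this table size is dominated by binomial noise
    (roughly ten event reports per pool), so each simulated table
    contributes several drug-event pairs; the suite reports their overall
    mean, which under the null should sit near 1 (slightly above, since
    averaging reciprocal pool rates is convex).
    """
    rng = np.random.default_rng(seed)
    drugs = ("drugA", "drugB", "drugC", "drugD")
    events = ("bradycardia", "palpitations")
    per_seed = []
    for _ in range(n_seeds):
        table, _ = simulate_faers(
            FaersSimConfig(n_reports=n_reports, seed=int(rng.integers(2**31)))
        )
        vals = []
        for drug in drugs:
            pools = select_backgrounds(
                drug, table, n_pools=n_pools, ga=_SUITE_GA,
                seed=int(rng.integers(2**31)),
            )
            from cardioscreen.faers import prr as _prr
            drug_pool = table[_mentions_drug(table, drug)]
            for event in events:
                vals.append(float(np.mean(
                    [_prr(drug_pool, table.iloc[p], event) for p in pools]
                )))
        per_seed.append(float(np.mean(vals)))
    return {"per_seed": per_seed, "mean_prr": float(np.mean(per_seed))}


def prr_planted(n_seeds: int = 20, n_reports: int = 5000, ratio: float = 4.0,
                seed: int = 0, n_pools: int = 10) -> dict:
    """Detection rate of a planted relative-reporting enrichment.

    A drug-event pair is planted at ``ratio`` times the base reporting
    probability; the drug is called positive when the mean PRR of its MCE
    is 2 or above.
    """
    rng = np.random.default_rng(seed)
    positives = 0
    prrs = []
    for _ in range(n_seeds):
        table, _ = simulate_faers(FaersSimConfig(
            n_reports=n_reports,
            planted_associations=(("drugA", "torsades de pointes", ratio),),
            seed=int(rng.integers(2**31)),
        ))
        pos, assoc = classify_faers(
            "drugA", table, n_pools=n_pools, ga=_SUITE_GA,
            seed=int(rng.integers(2**31)),
        )
        positives += pos
        prrs.append(assoc.mean_prr)
    return {
        "positive_fraction": positives / n_seeds,
        "mean_prr": float(np.mean(prrs)),
    }


def ga_vs_uniform(n_seeds: int = 20, n_reports: int = 1500, seed: int = 0) -> dict:
    """Paired comparison of GA-matched vs uniformly drawn background pools.

    On report tables with drug-niche covariate structure, measures the
    summed total-variation attribute distance of one GA pool vs one
    uniform pool per seed; returns the fraction of seeds where the GA
    pool is closer and the mean distances.
    """
    rng = np.random.default_rng(seed)
    ga_wins = 0
    ga_d, unif_d = [], []
    for _ in range(n_seeds):
        s = int(rng.integers(2**31))
        table, _ = simulate_faers(FaersSimConfig(n_reports=n_reports, seed=s))
        mask = _mentions_drug(table, "drugA").to_numpy()
        attrs = _encode_attrs(
            table, sorted(set(table["primary_suspect"]) - {"drugA"})
        )
        target = _target_dists(attrs, np.flatnonzero(mask))
        bg = np.flatnonzero(~mask)
        m = int(mask.sum())
        pool_rng = np.random.default_rng(s + 1)
        unif = pool_rng.choice(bg, size=m, replace=False)
        pools = select_backgrounds(
            "drugA", table, n_pools=1, ga=_SUITE_GA, seed=s + 2
        )
        d_ga = attribute_distance(attrs, pools[0], target)
        d_u = attribute_distance(attrs, unif, target)
        ga_d.append(d_ga)
        unif_d.append(d_u)
        ga_wins += d_ga < d_u
    return {
        "ga_win_fraction": ga_wins / n_seeds,
        "mean_ga_distance": float(np.mean(ga_d)),
        "mean_uniform_distance": float(np.mean(unif_d)),
    }
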