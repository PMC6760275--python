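"""Cardiac, hemodynamic and calcium-transient feature extraction.

Cardiac features come from a detected :class:`~cardioscreen.kymo.BeatSeries`
and chamber-extent traces: beat rate, rate-corrected QT interval (with the
zebrafish-adapted Framingham linear correction QTc = QT + 0.154 (2.66 - RR)),
longest beat-free period (cardiac arrest), percentage of arrhythmic beats,
ejection fraction from diastolic vs systolic diameters, maximal diameter,
and the atrioventricular coupling / bigeminy flags.  Hemodynamic features
come from vessel kymographs via row-to-row cross-correlation; systolic and
diastolic velocities are the 90th and 10th percentiles of the signed
velocity distribution.  The calcium-transient features are the five
plate-reader measures (bpm, ampl, auc, pkw, ppkw).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from cardioscreen.kymo import BeatSeries, ChamberTrace, Kymograph, detect_beats


# ---------------------------------------------------------------------------
# cardiac features
# ---------------------------------------------------------------------------


def beat_rate(beats: BeatSeries) -> float:
    """Beat rate in beats/min, 60 / median RR; 0 with fewer than 2 beats."""
    if beats.n_beats < 2:
        return 0.0
    return 60.0 / float(np.median(beats.rr_intervals))


def average_bpm(ventricular_bpm: float, atrial_bpm: float) -> float:
    """Arithmetic mean of the two chamber rates (the headline rate)."""
    return 0.5 * (ventricular_bpm + atrial_bpm)


def arrhythmia_pct(beats: BeatSeries, tol: float = 0.20) -> float:
    """Percentage of RR intervals deviating more than `tol` from the median.

    Undefined (NaN) with fewer than 3 intervals.
    """
    rr = beats.rr_intervals
    if rr.size < 3:
        return float("nan")
    med = np.median(rr)
    return 100.0 * float(np.mean(np.abs(rr - med) > tol * med))


def cardiac_arrest(beats: BeatSeries, duration_s: float) -> float:
    """Longest beat-free period in seconds, counting both recording edges."""
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    if beats.n_beats == 0:
        return float(duration_s)
    t = beats.beat_times
    gaps = np.concatenate([[t[0]], np.diff(t), [duration_s - t[-1]]])
    return float(gaps.max())


def qt_interval(beats: BeatSeries) -> float:
    """Mean ventricular contraction duration (offset - onset) across beats.

    This half-prominence contraction width is the video proxy for the QT
    interval.  NaN without any beat.
    """
    if beats.n_beats == 0:
        return float("nan")
    return float(np.mean(beats.offsets - beats.onsets))


def qtc(qt_s: float, rr_s: float, rr_from_bpm: bool = False) -> float:
    """Rate-corrected QT: QTc = QT + 0.154 (2.66 - RR), RR in seconds.

    With ``rr_from_bpm`` the alternative documented convention
    RR = 6.6e-3 * bpm is applied to the supplied beat rate instead of an
    RR interval in seconds (the two conventions are mutually inconsistent;
    the seconds reading is the default).
    """
    if qt_s <= 0 or rr_s <= 0:
        raise ValueError("qt and rr must be positive")
    rr = 6.6e-3 * rr_s if rr_from_bpm else rr_s
    return qt_s + 0.154 * (2.66 - rr)


def ejection_fraction(
    dia_diameter_um: float, sys_diameter_um: float, mode: str = "spherical"
) -> float:
    """Ejection fraction (%) from diastolic and systolic diameters.

    ``spherical`` treats the chamber as a sphere, 100 (1 - (sys/dia)^3);
    ``linear`` is fractional shortening, 100 (1 - sys/dia).
    """
    if not 0 < sys_diameter_um <= dia_diameter_um:
        raise ValueError("need 0 < systolic <= diastolic diameter")
    ratio = sys_diameter_um / dia_diameter_um
    if mode == "spherical":
        return 100.0 * (1.0 - ratio**3)
    if mode == "linear":
        return 100.0 * (1.0 - ratio)
    raise ValueError(f"unknown mode {mode!r}")


def max_diameter(trace: ChamberTrace) -> float:
    """Maximal chamber extent over the recording (diastolic diameter, um)."""
    ext = trace.extent_um[trace.extent_um > 0]
    if ext.size == 0:
        return float("nan")
    return float(ext.max())


def _bimodal_rr(rr: np.ndarray, gap_factor: float = 0.25) -> bool:
    """Crude bimodality check: a clear gap in the sorted RR values."""
    if rr.size < 4:
        return False
    s = np.sort(rr)
    gaps = np.diff(s)
    return bool(gaps.max() > gap_factor * np.median(rr))


def av_coupling(
    atrial: BeatSeries,
    ventricular: BeatSeries,
    ratio_tol: float = 0.1,
    autocorr_cut: float = -0.5,
) -> tuple[float, bool, bool]:
    """Atrioventricular coupling ratio and the AV-defect / bigeminy flags.

    ratio = atrial count / ventricular count; an AV coupling defect is
    flagged when the ratio departs from 1 by more than ``ratio_tol``.
    Bigeminy (alternating short/long ventricular coupling intervals) is
    flagged when the lag-1 autocorrelation of the ventricular RR intervals
    is at most ``autocorr_cut`` and the RR distribution is bimodal.
    """
    if ventricular.n_beats == 0:
        raise ValueError("no ventricular beats: flag no_beating instead")
    ratio = atrial.n_beats / ventricular.n_beats
    av_defect = abs(ratio - 1.0) > ratio_tol

    rr = ventricular.rr_intervals
    bigeminy = False
    if rr.size >= 4:
        d = rr - rr.mean()
        denom = float(np.dot(d, d))
        if denom > 0:
            lag1 = float(np.dot(d[:-1], d[1:])) / denom
            bigeminy = lag1 <= autocorr_cut and _bimodal_rr(rr)
    return float(ratio), bool(av_defect), bool(bigeminy)


@dataclass
class CardiacFeatureSet:
    """All numerical cardiac features and flags for one subject."""

    ventricular_bpm: float
    atrial_bpm: float
    average_bpm: float
    qtc: float
    cardiac_arrest: float
    arrhythmic_beats: float
    ejection_fraction: float
    max_diameter: float
    av_ratio: float
    av_coupling_defect: bool
    bigeminy: bool
    no_beating: bool


def cardiac_features(
    ventricle: ChamberTrace,
    atrium: ChamberTrace,
    duration_s: float | None = None,
    ef_mode: str = "spherical",
    **beat_kwargs,
) -> CardiacFeatureSet:
    """End-to-end cardiac feature set from the two chamber traces."""
    duration = duration_s or len(ventricle.extent_um) / ventricle.fps
    vb = detect_beats(ventricle, **beat_kwargs)
    ab = detect_beats(atrium, **beat_kwargs)
    v_bpm, a_bpm = beat_rate(vb), beat_rate(ab)
    no_beating = vb.n_beats < 2

    qt = qt_interval(vb)
    rr = float(np.median(vb.rr_intervals)) if vb.n_beats >= 2 else float("nan")
    qtc_val = qtc(qt, rr) if np.isfinite(qt) and np.isfinite(rr) else float("nan")

    ext = ventricle.extent_um[ventricle.extent_um > 0]
    if ext.size:
        dia, sys_ = float(ext.max()), float(ext.min())
        ef = ejection_fraction(dia, sys_, mode=ef_mode)
    else:
        dia, ef = float("nan"), float("nan")

    if no_beating:
        ratio, av_defect, bigem = float("nan"), False, False
    else:
        ratio, av_defect, bigem = av_coupling(ab, vb)
    return CardiacFeatureSet(
        ventricular_bpm=v_bpm,
        atrial_bpm=a_bpm,
        average_bpm=average_bpm(v_bpm, a_bpm),
        qtc=qtc_val,
        cardiac_arrest=cardiac_arrest(vb, duration),
        arrhythmic_beats=arrhythmia_pct(vb),
        ejection_fraction=ef,
        max_diameter=dia,
        av_ratio=ratio,
        av_coupling_defect=av_defect,
        bigeminy=bigem,
        no_beating=no_beating,
    )


# ---------------------------------------------------------------------------
# blood-flow velocimetry
# ---------------------------------------------------------------------------


@dataclass
class FlowFeatureSet:
    """Signed blood-cell velocities along a vessel and their summary."""

    velocity_um_s: np.ndarray  # per frame pair, masked NaN where featureless
    mean: float
    median: float
    p10: float  # diastolic velocity
    p90: float  # systolic velocity
    no_flow: bool


def flow_velocity_trace(kymo: Kymograph, max_shift_px: int | None = None) -> np.ndarray:
    """Signed per-frame velocity (um/s) from a vessel kymograph.

    Each consecutive row pair is aligned by circular cross-correlation with
    sub-pixel parabolic refinement; the displacement times pixel size times
    frame rate is the velocity.  Rows without cells (flat profiles) yield
    NaN.
    """
    m = kymo.matrix.astype(float)
    n_t, n_x = m.shape
    if max_shift_px is None:
        max_shift_px = n_x // 3
    rows = m - m.mean(axis=1, keepdims=True)
    sd = rows.std(axis=1)
    flat = sd < 1e-6

    f = np.fft.rfft(rows, axis=1)
    # circular cross-correlation; peak lag = displacement of row t+1 vs row t
    cc = np.fft.irfft(f[1:] * np.conj(f[:-1]), n=n_x, axis=1)
    shifts = np.fft.fftfreq(n_x, 1 / n_x).astype(int)  # 0,1,...,-1
    window = np.abs(shifts) <= max_shift_px

    vel = np.full(n_t - 1, np.nan)
    for i in range(n_t - 1):
        if flat[i] or flat[i + 1]:
            continue
        c = cc[i]
        cw = np.where(window, c, -np.inf)
        k = int(np.argmax(cw))
        # parabolic refinement on the circular neighbourhood
        y0, y1, y2 = c[(k - 1) % n_x], c[k], c[(k + 1) % n_x]
        denom = y0 - 2 * y1 + y2
        frac = 0.0 if denom == 0 else 0.5 * (y0 - y2) / denom
        frac = float(np.clip(frac, -0.5, 0.5))
        vel[i] = (shifts[k] + frac) * kymo.pixel_size_um * kymo.fps
    return vel


def flow_summary(
    velocity_um_s: np.ndarray,
    fps: float,
    cell_diameter_um: float = 7.0,
) -> FlowFeatureSet:
    """Summary statistics of a signed velocity trace and the no-flow flag.

    ``no_flow`` is true when the net displacement over the whole recording
    is smaller than one cell diameter — covering both stopped flow and the
    zero-net oscillation where cells merely move back and forth.
    """
    v = np.asarray(velocity_um_s, dtype=float)
    ok = np.isfinite(v)
    if ok.sum() < 10:
        raise ValueError("need at least 10 measurable frames")
    vv = v[ok]
    net_um = float(np.nansum(v)) / fps
    return FlowFeatureSet(
        velocity_um_s=v,
        mean=float(vv.mean()),
        median=float(np.median(vv)),
        p10=float(np.percentile(vv, 10)),
        p90=float(np.percentile(vv, 90)),
        no_flow=bool(abs(net_um) < cell_diameter_um),
    )


# ---------------------------------------------------------------------------
# calcium transients
# ---------------------------------------------------------------------------


@dataclass
class TransientFeatureSet:
    """The five calcium-transient plate-reader features."""

    bpm: float
    ampl: float
    auc: float
    pkw: float
    ppkw: float


def _width_at_level(
    t: np.ndarray, y: np.ndarray, peak: int, level: float
) -> float:
    """Interpolated width of the peak at an absolute level."""
    i = peak
    while i > 0 and y[i] > level:
        i -= 1
    if y[i] > level:
        left = t[i]
    else:
        left = t[i] + (level - y[i]) / (y[i + 1] - y[i]) * (t[i + 1] - t[i])
    j = peak
    while j < len(y) - 1 and y[j] > level:
        j += 1
    if y[j] > level:
        right = t[j]
    else:
        right = t[j - 1] + (level - y[j - 1]) / (y[j] - y[j - 1]) * (t[j] - t[j - 1])
    return float(right - left)


def transient_features(
    trace: np.ndarray,
    fps: float,
    min_prominence: float = 0.2,
) -> TransientFeatureSet:
    """Extract bpm, ampl, auc, pkw and ppkw from a calcium-transient trace.

    The baseline is the 10th percentile of the trace; amplitude is the mean
    peak height above baseline; auc the mean per-beat area above baseline;
    pkw / ppkw the mean widths at 50 % / 10 % of each peak's amplitude.
    A flat trace yields bpm 0 and NaN for the rest.
    """
    y = np.asarray(trace, dtype=float)
    t = np.arange(len(y)) / fps
    rng_ = y.max() - y.min()
    if rng_ <= 0:
        return TransientFeatureSet(0.0, *([float("nan")] * 4))
    baseline = float(np.percentile(y, 10))
    peaks, _ = signal.find_peaks(y, prominence=min_prominence * rng_)
    if peaks.size < 2:
        return TransientFeatureSet(0.0, *([float("nan")] * 4))

    # rate from peak spacing (robust to partial periods at the edges)
    bpm = 60.0 / float(np.median(np.diff(t[peaks])))
    amps = y[peaks] - baseline
    ampl = float(amps.mean())

    pkw_list, ppkw_list, auc_list = [], [], []
    mids = ((peaks[:-1] + peaks[1:]) // 2).tolist()
    bounds = [0] + mids + [len(y) - 1]
    for k, p in enumerate(peaks):
        pkw_list.append(_width_at_level(t, y, p, baseline + 0.5 * amps[k]))
        ppkw_list.append(_width_at_level(t, y, p, baseline + 0.1 * amps[k]))
        lo, hi = bounds[k], bounds[k + 1]
        seg = np.clip(y[lo : hi + 1] - baseline, 0, None)
        auc_list.append(float(np.trapezoid(seg, t[lo : hi + 1])))
    return TransientFeatureSet(
        bpm=bpm,
        ampl=ampl,
        auc=float(np.mean(auc_list)),
        pkw=float(np.mean(pkw_list)),
        ppkw=float(np.mean(ppkw_list)),
    )
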