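"""Synthetic data generators with machine-readable ground truth.

Every generator emulates one of the pipeline's input modalities:

* :func:`simulate_heart_video` — a two-chamber zebrafish larva heart
  (bright atrium and ventricle on a dark background) beating with a
  configurable rate, arrhythmic jitter, arrest windows, atrioventricular
  conduction ratio and bigeminy, at the screen's acquisition settings
  (75.9 fps, 40 s, 1.23 um/px by default);
* :func:`simulate_vessel_video` — pulsatile particle flow in a straight
  vessel at 70.5 fps, including the zero-net-flow oscillation phenotype
  where blood cells merely move back and forth;
* :func:`simulate_calcium_trace` — calcium-transient fluorescence traces
  with the five plate-reader features as ground truth;
* :func:`simulate_screen` — plate-structured screen datasets drawn from
  the additive mixed model y = mu + beta_row + gamma_plate + alpha_compound
  + error;
* :func:`simulate_faers` — adverse-event report tables with planted
  drug-event enrichments, drug-niche covariate structure and near-duplicate
  reports.

All generators are bit-reproducible for a fixed seed and return the ground
truth needed to score every downstream extractor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from cardioscreen.formats import VideoStack

# ---------------------------------------------------------------------------
# heart videos
# ---------------------------------------------------------------------------


@dataclass
class HeartSimParams:
    """Parameters of the two-chamber heart simulator.

    The ventricle's minor (horizontal) diameter oscillates between
    ``dia_diameter_um`` at diastole and ``sys_diameter_um`` at peak systole;
    each beat is a raised-cosine contraction pulse centred on the scheduled
    beat time.  Arrhythmia is multiplicative lognormal jitter on the
    inter-beat intervals; bigeminy alternates short/long coupling intervals
    (0.6x / 1.4x the base period); ``av_ratio`` atrial beats occur per
    ventricular beat.
    """

    ventricular_bpm: float = 150.0
    atrial_bpm: float | None = None  # defaults to ventricular rate
    fps: float = 75.9
    duration: float = 40.0
    dia_diameter_um: float = 120.0
    sys_diameter_um: float = 80.0
    av_delay: float = 0.06
    arrhythmia_jitter: float = 0.0
    arrest_windows: tuple[tuple[float, float], ...] = ()
    av_ratio: int = 1
    bigeminy: bool = False
    contraction_width_s: float | None = None  # default 0.45 * base period
    noise_sd: float = 4.0
    frame_shape: tuple[int, int] = (256, 256)
    pixel_size_um: float = 1.23
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fps <= 0 or self.duration <= 0:
            raise ValueError("fps and duration must be positive")
        if not 0 < self.sys_diameter_um <= self.dia_diameter_um:
            raise ValueError("need 0 < sys_diameter_um <= dia_diameter_um")
        if self.av_ratio < 1:
            raise ValueError("av_ratio must be >= 1")
        if self.atrial_bpm is None:
            self.atrial_bpm = self.ventricular_bpm


def _beat_schedule(
    bpm: float,
    duration: float,
    jitter: float,
    bigeminy: bool,
    arrest_windows: Sequence[tuple[float, float]],
    rng: np.random.Generator,
    margin: float = 0.0,
) -> np.ndarray:
    """Beat times: base period 60/bpm, first beat one period in.

    Jitter multiplies each interval by a lognormal factor with unit mean.
    Bigeminy alternates 0.6x / 1.4x coupling intervals.  An arrest window
    (start, length) replaces the beats inside it by one beat exactly at the
    window start and one exactly at its end, so the longest beat-free gap
    equals the window length by construction.  ``margin`` keeps the final
    beat at least that far from the end of the recording, so its rendered
    contraction pulse completes inside the video and the scheduled count
    equals the observable count.
    """
    base = 60.0 / bpm
    duration = duration - margin
    windows = sorted(arrest_windows)
    times: list[float] = []
    t = 0.0
    k = 0
    wi = 0
    while True:
        factor = (0.6 if k % 2 == 0 else 1.4) if bigeminy else 1.0
        dt = base * factor
        if jitter > 0:
            dt *= rng.lognormal(mean=-0.5 * jitter**2, sigma=jitter)
        t_next = t + dt
        if wi < len(windows) and t_next > windows[wi][0]:
            start, length = windows[wi]
            # keep beats resolvable: a beat closer to the window start than
            # a contraction width would merge with it, so shift it onto the
            # window start rather than inserting a second one
            min_sep = max(2 * margin, 0.2)
            if times and start - times[-1] < min_sep:
                times[-1] = start
            elif start > t:
                times.append(start)
            t = start + length
            if t >= duration:
                break
            times.append(t)
            wi += 1
            k += 1
            continue
        if t_next >= duration:
            break
        times.append(t_next)
        t = t_next
        k += 1
    return np.array(times)


def _atrial_schedule(
    ventricular: np.ndarray, av_ratio: int, av_delay: float
) -> np.ndarray:
    """Atrial beat times: av_ratio beats preceding each ventricular beat."""
    if ventricular.size == 0:
        return np.array([])
    intervals = np.diff(np.concatenate([[0.0], ventricular]))
    out = []
    for t_v, dt in zip(ventricular, intervals):
        for m in range(av_ratio - 1, -1, -1):
            out.append(t_v - av_delay - m * dt / av_ratio)
    out = np.array(out)
    return out[out >= 0]


def _contraction_pulse(
    frame_times: np.ndarray, beats: np.ndarray, width: float
) -> np.ndarray:
    """Raised-cosine contraction pulses (1 at the beat, 0 outside +-w/2).

    Overlapping pulses combine by maximum so the chamber never contracts
    below the systolic diameter.
    """
    pulse = np.zeros_like(frame_times)
    half = width / 2.0
    for tb in beats:
        i0 = np.searchsorted(frame_times, tb - half)
        i1 = np.searchsorted(frame_times, tb + half)
        seg = 0.5 * (1 + np.cos(2 * np.pi * (frame_times[i0:i1] - tb) / width))
        np.maximum(pulse[i0:i1], seg, out=pulse[i0:i1])
    return pulse


def _render_chamber(
    frames: np.ndarray,
    xs: np.ndarray,
    ys: np.ndarray,
    cx: float,
    cy: float,
    semi_x: np.ndarray,
    semi_y: float,
    amplitude: float,
    edge_px: float = 0.7,
) -> None:
    """Add a soft-edged ellipse per frame, vectorised over a frame chunk.

    ``semi_x`` is per-frame; the edge is a linear ramp about 2*edge_px wide
    crossing half-intensity exactly at the geometric boundary, so a
    mid-level threshold recovers the true diameter.
    """
    semi_x = semi_x.astype(np.float32)[:, None, None]
    dx2 = ((xs - np.float32(cx)) ** 2)[None, None, :]
    dy2 = (((ys - np.float32(cy)) / np.float32(semi_y)) ** 2)[None, :, None]
    q = dx2 / semi_x**2 + dy2
    # approximate signed distance from the boundary in pixels
    dist = (np.sqrt(q) - np.float32(1.0)) * np.minimum(semi_x, np.float32(semi_y))
    edge = np.clip(
        np.float32(0.5) - dist / np.float32(2 * edge_px),
        np.float32(0.0), np.float32(1.0),
    )
    np.maximum(frames, np.float32(amplitude) * edge, out=frames)


def longest_gap(beat_times: np.ndarray, duration: float) -> float:
    """Longest beat-free interval, counting both recording edges."""
    if beat_times.size == 0:
        return float(duration)
    gaps = np.concatenate(
        [[beat_times[0]], np.diff(beat_times), [duration - beat_times[-1]]]
    )
    return float(gaps.max())


def simulate_heart_video(params: HeartSimParams) -> tuple[VideoStack, dict]:
    """Render a pulsating two-chamber heart video plus its ground truth.

    Returns the video stack and a dict with the scheduled beat times per
    chamber, the longest beat-free gap, the true diastolic/systolic
    diameters (hence ejection fraction), the AV ratio and the bigeminy flag.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    n_frames = int(round(p.duration * p.fps))
    h, w = p.frame_shape
    times = np.arange(n_frames) / p.fps

    width = p.contraction_width_s or 0.45 * 60.0 / p.ventricular_bpm
    v_beats = _beat_schedule(
        p.ventricular_bpm, p.duration, p.arrhythmia_jitter, p.bigeminy,
        p.arrest_windows, rng, margin=width / 2,
    )
    if p.av_ratio > 1 or p.atrial_bpm == p.ventricular_bpm:
        a_beats = _atrial_schedule(v_beats, p.av_ratio, p.av_delay)
    else:
        a_beats = _beat_schedule(
            p.atrial_bpm, p.duration, p.arrhythmia_jitter, False, (), rng,
            margin=width / 2,
        ) - p.av_delay
        a_beats = a_beats[a_beats >= 0]
    v_pulse = _contraction_pulse(times, v_beats, width)
    a_width = width / max(p.av_ratio, 1)
    a_pulse = _contraction_pulse(times, a_beats, a_width)

    px = p.pixel_size_um
    dia_px, sys_px = p.dia_diameter_um / px, p.sys_diameter_um / px
    v_diam = dia_px - (dia_px - sys_px) * v_pulse
    a_scale = 0.85
    a_diam = a_scale * (dia_px - (dia_px - sys_px) * a_pulse)
    # geometry: heart axis vertical at the frame centre; ventricle at 25 %
    # of the axis, atrium at 75 %
    cx = w / 2.0
    cy_v, cy_a = 0.37 * h, 0.64 * h
    semi_y_v = 0.55 * dia_px
    semi_y_a = 0.50 * a_scale * dia_px

    # render only the bounding box that the chambers can reach
    pad = 8.0
    x0 = max(0, int(cx - dia_px / 2 - pad))
    x1 = min(w, int(np.ceil(cx + dia_px / 2 + pad)))
    y0 = max(0, int(cy_v - semi_y_v - pad))
    y1 = min(h, int(np.ceil(cy_a + semi_y_a + pad)))
    xs = np.arange(x0, x1, dtype=np.float32)
    ys = np.arange(y0, y1, dtype=np.float32)

    background, amplitude = 10.0, 200.0
    frames = np.full((n_frames, h, w), np.uint8(round(background)),
                     dtype=np.uint8)
    # chamber-specific y bands inside the ROI
    yv0 = max(0, int(cy_v - semi_y_v - pad)) - y0
    yv1 = min(h, int(np.ceil(cy_v + semi_y_v + pad))) - y0
    ya0 = max(0, int(cy_a - semi_y_a - pad)) - y0
    ya1 = min(h, int(np.ceil(cy_a + semi_y_a + pad))) - y0

    # seeded noise slab, cyclically reused with random spatial rolls: a
    # rendering economy that keeps per-pixel noise white within each reuse
    # period while avoiding fresh draws for every frame
    slab_len = min(n_frames, 512)
    if p.noise_sd > 0:
        slab = p.noise_sd * rng.standard_normal(
            (slab_len, len(ys), len(xs)), dtype=np.float32
        )
    chunk = 256
    for i0 in range(0, n_frames, chunk):
        i1 = min(i0 + chunk, n_frames)
        roi = np.full((i1 - i0, len(ys), len(xs)), np.float32(background))
        _render_chamber(
            roi[:, yv0:yv1, :], xs, ys[yv0:yv1], cx, cy_v,
            (v_diam[i0:i1] / 2).astype(np.float32), semi_y_v, amplitude,
        )
        _render_chamber(
            roi[:, ya0:ya1, :], xs, ys[ya0:ya1], cx, cy_a,
            (a_diam[i0:i1] / 2).astype(np.float32), semi_y_a, amplitude,
        )
        if p.noise_sd > 0:
            idx = np.arange(i0, i1) % slab_len
            roll = (int(rng.integers(len(ys))), int(rng.integers(len(xs))))
            roi += np.roll(slab[idx], roll, axis=(1, 2))
        np.clip(roi, 0, 255, out=roi)
        frames[i0:i1, y0:y1, x0:x1] = roi.astype(np.uint8)

    stack = VideoStack(frames=frames, fps=p.fps, pixel_size_um=px,
                       modality="heart")
    ef_spherical = 100.0 * (1 - (p.sys_diameter_um / p.dia_diameter_um) ** 3)
    truth = {
        "ventricular_beat_times": v_beats.tolist(),
        "atrial_beat_times": a_beats.tolist(),
        "ventricular_bpm": p.ventricular_bpm,
        "longest_gap_s": longest_gap(v_beats, p.duration),
        "dia_diameter_um": p.dia_diameter_um,
        "sys_diameter_um": p.sys_diameter_um,
        "ejection_fraction_spherical": ef_spherical,
        "av_ratio": p.av_ratio,
        "bigeminy": p.bigeminy,
        "contraction_width_s": width,
        "axis": {"start": [cx, cy_v - semi_y_v / 2],
                 "end": [cx, cy_a + semi_y_a / 2]},
        "ventricle_line_y": cy_v,
        "atrium_line_y": cy_a,
    }
    return stack, truth


# ---------------------------------------------------------------------------
# vessel videos
# ---------------------------------------------------------------------------


@dataclass
class FlowSimParams:
    """Parameters of the pulsatile vessel-flow simulator.

    Particles (blood cells) advect along a straight horizontal vessel with
    velocity ``v(t) = mean * (1 + pulsatility * sin(2 pi f_heart t))``.
    ``mean_velocity_um_s = 0`` with an ``oscillation_amplitude_um_s`` gives
    the zero-net-flow phenotype where cells merely move back and forth.
    """

    fps: float = 70.5
    duration: float = 10.0
    mean_velocity_um_s: float = 500.0
    pulsatility: float = 0.0
    oscillation_amplitude_um_s: float = 0.0  # used when mean velocity is 0
    heart_bpm: float = 120.0
    cell_density: float = 8.0  # cells per 100 um of vessel
    cell_diameter_um: float = 7.0
    noise_sd: float = 2.0
    frame_shape: tuple[int, int] = (64, 256)
    pixel_size_um: float = 1.23
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fps <= 0 or self.duration <= 0:
            raise ValueError("fps and duration must be positive")
        if self.pulsatility < 0:
            raise ValueError("pulsatility must be >= 0")
        if self.cell_density <= 0:
            raise ValueError("cell_density must be positive")


def simulate_vessel_video(params: FlowSimParams) -> tuple[VideoStack, dict]:
    """Render particles advected along a straight horizontal vessel.

    The particle field is periodic in x (cells leaving one end re-enter at
    the other), so circular cross-correlation of kymograph rows recovers the
    displacement without edge losses.  Ground truth stores the velocity
    sampled at every frame time and the net displacement over the video.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    n_frames = int(round(p.duration * p.fps))
    h, w = p.frame_shape
    times = np.arange(n_frames) / p.fps
    f = p.heart_bpm / 60.0
    omega = 2 * np.pi * f

    v_t = p.mean_velocity_um_s * (1 + p.pulsatility * np.sin(omega * times))
    # displacement integral (closed form of the sinusoid)
    disp = p.mean_velocity_um_s * (
        times + p.pulsatility * (1 - np.cos(omega * times)) / omega
    )
    if p.mean_velocity_um_s == 0 and p.oscillation_amplitude_um_s > 0:
        v_t = p.oscillation_amplitude_um_s * np.sin(omega * times)
        disp = p.oscillation_amplitude_um_s * (1 - np.cos(omega * times)) / omega

    px = p.pixel_size_um
    vessel_len_um = w * px
    n_cells = max(2, int(round(p.cell_density * vessel_len_um / 100.0)))
    x0 = rng.uniform(0, vessel_len_um, n_cells)
    band_half = 12.0  # um, vessel half-width
    y_cells = h / 2.0 + rng.uniform(-band_half * 0.7, band_half * 0.7, n_cells) / px

    sigma_px = (p.cell_diameter_um / 2.355) / px  # FWHM = cell diameter
    r = int(np.ceil(3 * sigma_px))
    stamp_off = np.arange(-r, r + 1)

    background, amplitude = 10.0, 200.0
    frames = np.full((n_frames, h, w), background, dtype=np.float32)
    for i in range(n_frames):
        xpix = ((x0 + disp[i]) % vessel_len_um) / px
        frame = frames[i]
        for xc, yc in zip(xpix, y_cells):
            ix, iy = int(round(xc)), int(round(yc))
            gx = np.exp(-0.5 * ((ix + stamp_off - xc) / sigma_px) ** 2)
            gy = np.exp(-0.5 * ((iy + stamp_off - yc) / sigma_px) ** 2)
            stamp = amplitude * gy[:, None] * gx[None, :]
            np.add.at(
                frame,
                (np.mod(iy + stamp_off, h)[:, None],
                 np.mod(ix + stamp_off, w)[None, :]),
                stamp,
            )
    if p.noise_sd > 0:
        frames += p.noise_sd * rng.standard_normal(frames.shape, dtype=np.float32)

    stack = VideoStack(frames=frames, fps=p.fps, pixel_size_um=px,
                       modality="vessel")
    truth = {
        "velocity_um_s": v_t.tolist(),
        "net_displacement_um": float(disp[-1] - disp[0]),
        "cell_diameter_um": p.cell_diameter_um,
        "vessel_line_y": h / 2.0,
    }
    return stack, truth


# ---------------------------------------------------------------------------
# calcium transients
# ---------------------------------------------------------------------------


def simulate_calcium_trace(
    bpm: float,
    amplitude: float = 2.0,
    peak_width_s: float = 0.5,
    fps: float = 8.0,
    duration: float = 60.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    baseline: float = 1.0,
    rise_fraction: float = 0.5,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Simulate a calcium-transient fluorescence trace.

    Peaks are triangular with base width ``peak_width_s``; ``rise_fraction``
    sets the time-to-peak as a fraction of the base (0.5 = symmetric,
    smaller = fast rise / slow decay).  Peak centres sit at (k + 1/2) beat
    periods, so a whole number of transients fits the recording.

    Returns ``(times, trace, truth)`` where the ground truth records the
    five plate-reader features: beat rate (bpm), amplitude above baseline
    (ampl), per-beat area above baseline (auc), width at half amplitude
    (pkw) and width at 10 % amplitude (ppkw).
    """
    if bpm <= 0 or fps <= 0 or duration <= 0:
        raise ValueError("bpm, fps and duration must be positive")
    period = 60.0 / bpm
    if peak_width_s > period:
        raise ValueError("peak_width_s cannot exceed the beat period")
    rng = np.random.default_rng(seed)
    times = np.arange(int(round(duration * fps))) / fps
    n_peaks = int(np.floor(duration / period))
    apex = (np.arange(n_peaks) + 0.5) * period

    trace = np.full_like(times, baseline)
    t_rise = rise_fraction * peak_width_s
    t_fall = peak_width_s - t_rise
    start = apex - t_rise
    for s in range(n_peaks):
        dt = times - start[s]
        up = (dt >= 0) & (dt < t_rise)
        down = (dt >= t_rise) & (dt <= peak_width_s)
        trace[up] += amplitude * dt[up] / t_rise
        trace[down] += amplitude * (1 - (dt[down] - t_rise) / t_fall)
    if noise_sd > 0:
        trace = trace + noise_sd * rng.standard_normal(len(times))

    truth = {
        "bpm": bpm,
        "ampl": amplitude,
        "auc": 0.5 * amplitude * peak_width_s,  # triangle area per beat
        "pkw": 0.5 * peak_width_s,              # width at half amplitude
        "ppkw": 0.9 * peak_width_s,             # width at 10 % amplitude
        "n_peaks": n_peaks,
        "baseline": baseline,
    }
    return times, trace, truth


# ---------------------------------------------------------------------------
# screen datasets
# ---------------------------------------------------------------------------


@dataclass
class ScreenDesign:
    """Generative truth of a plate-structured screen.

    Observations follow ``y = mu + beta_row + gamma_plate + alpha_compound
    + error`` with independent normal random effects: plates (days) have SD
    ``sigma_plate``, unplanted compounds draw their effect from
    ``N(0, sigma_compound)``, and residuals have SD ``sigma_error``.
    Planted effects in ``effects[feature][compound]`` override the random
    draw.  The DMSO reference (effect 0) appears on every plate, mirroring
    the screen design of 7 drugs + 1 negative control per imaging day with
    12 embryos per compound.
    """

    compounds: tuple[str, ...] = tuple(f"drug{i:02d}" for i in range(7)) + ("DMSO",)
    features: tuple[str, ...] = ("ventricular_bpm",)
    effects: dict = field(default_factory=dict)  # feature -> {compound: alpha}
    plates: int = 2
    rows: int = 8
    subjects_per_compound: int = 12
    sigma_plate: float = 1.0
    sigma_compound: float = 0.0
    sigma_error: float = 1.0
    mu: float = 0.0
    beta_row: tuple[float, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.sigma_plate, self.sigma_compound, self.sigma_error) < 0:
            raise ValueError("variance-component SDs must be >= 0")
        if self.rows > 8:
            raise ValueError("at most 8 rows (A-H)")
        if "DMSO" not in self.compounds:
            raise ValueError("the design must include a DMSO reference group")
        if self.beta_row is None:
            self.beta_row = (0.0,) * self.rows
        if len(self.beta_row) != self.rows:
            raise ValueError("beta_row length must equal the row count")


def simulate_screen(design: ScreenDesign) -> tuple[pd.DataFrame, dict]:
    """Draw a long-format screen dataset from the additive mixed model.

    Non-DMSO compounds are split round-robin over the plates; DMSO is
    replicated on every plate.  Within a plate, compounds occupy rows in a
    rotated order so row and compound are not confounded across plates.
    Returns the long table (compound, plate, row, subject, feature, value)
    and the generative truth (row effects, plate draws, per-feature compound
    effects and the three variance-component SDs).
    """
    d = design
    rng = np.random.default_rng(d.seed)
    others = [c for c in d.compounds if c != "DMSO"]
    per_plate: dict[int, list[str]] = {p: ["DMSO"] for p in range(d.plates)}
    for i, c in enumerate(others):
        per_plate[i % d.plates].append(c)
    for p, cs in per_plate.items():
        if len(cs) > d.rows:
            raise ValueError(
                f"plate {p} would hold {len(cs)} compounds but only "
                f"{d.rows} rows are available"
            )

    row_letters = "ABCDEFGH"[: d.rows]
    gamma = rng.normal(0.0, d.sigma_plate, d.plates)
    alphas: dict[str, dict[str, float]] = {}
    for feat in d.features:
        planted = d.effects.get(feat, {})
        alphas[feat] = {
            c: (0.0 if c == "DMSO" else float(
                planted.get(c, rng.normal(0.0, d.sigma_compound))
            ))
            for c in d.compounds
        }

    records = []
    for p in range(d.plates):
        for slot, comp in enumerate(per_plate[p]):
            for j in range(d.subjects_per_compound):
                # column-wise plating: a compound's replicates run down the
                # plate, so every row hosts several compounds and the row
                # location effect stays separable from compound effects
                r = (slot + j) % d.rows
                subject = f"P{p}_{comp}_{j:02d}"
                for feat in d.features:
                    eps = rng.normal(0.0, d.sigma_error)
                    y = (d.mu + d.beta_row[r] + gamma[p]
                         + alphas[feat][comp] + eps)
                    records.append(
                        (comp, f"plate{p}", row_letters[r], subject, feat, y)
                    )
    table = pd.DataFrame(
        records,
        columns=["compound", "plate", "row", "subject", "feature", "value"],
    )
    truth = {
        "alphas": alphas,
        "gamma_plate": gamma.tolist(),
        "beta_row": list(d.beta_row),
        "mu": d.mu,
        "sigma_plate": d.sigma_plate,
        "sigma_compound": d.sigma_compound,
        "sigma_error": d.sigma_error,
    }
    return table, truth


# ---------------------------------------------------------------------------
# adverse-event report tables
# ---------------------------------------------------------------------------

DEFAULT_DRUGS = tuple(f"drug{chr(ord('A') + i)}" for i in range(10))

#: Non-cardiac filler terms so the vocabulary is not purely cardiotoxic.
BACKGROUND_EVENTS = (
    "nausea", "headache", "rash", "dizziness", "fatigue",
    "diarrhoea", "insomnia", "pruritus",
)

INDICATIONS = (
    "hypertension", "depression", "diabetes", "asthma", "arthritis",
    "infection", "epilepsy", "allergy",
)

ROUTES = ("oral", "intravenous", "topical", "subcutaneous")
OUTCOMES = ("recovered", "recovering", "not recovered", "hospitalised", "fatal")


@dataclass
class FaersSimConfig:
    """Configuration of the spontaneous-report simulator.

    Each drug lives in a covariate niche (indication, age/weight
    distribution, gender balance, typical co-medications).  Event terms are
    drawn per report with base probabilities; a planted association
    ``(drug, event, ratio)`` multiplies that event's probability for
    reports whose primary suspect is the drug.  Exact duplicates (same
    content, deposit date a few days later) are appended at
    ``duplicate_rate``.
    """

    n_reports: int = 1000
    drugs: tuple[str, ...] = DEFAULT_DRUGS
    event_vocabulary: tuple[str, ...] | None = None  # default: 29 cardio + filler
    planted_associations: tuple[tuple[str, str, float], ...] = ()
    base_event_prob: float = 0.05
    duplicate_rate: float = 0.0
    n_niches: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.duplicate_rate < 1:
            raise ValueError("duplicate_rate must be in [0, 1)")
        for _, _, ratio in self.planted_associations:
            if ratio <= 0:
                raise ValueError("relative reporting ratios must be > 0")
        if self.event_vocabulary is None:
            from cardioscreen.faers import CARDIOTOX_TERMS
            self.event_vocabulary = CARDIOTOX_TERMS + BACKGROUND_EVENTS


def simulate_faers(config: FaersSimConfig) -> tuple[pd.DataFrame, dict]:
    """Generate a spontaneous adverse-event report table plus ground truth.

    Returns the report table (one row per report; multi-valued fields
    joined with ``;``) and a truth dict with the planted associations, the
    niche assignment of each drug and the ids of injected duplicate rows.
    """
    c = config
    rng = np.random.default_rng(c.seed)
    vocab = list(c.event_vocabulary)
    planted = {(d, e): r for d, e, r in c.planted_associations}

    niche_of = {d: i % c.n_niches for i, d in enumerate(c.drugs)}
    niche_age = rng.uniform(35, 70, c.n_niches)
    niche_weight = rng.uniform(60, 90, c.n_niches)
    niche_female = rng.uniform(0.3, 0.7, c.n_niches)
    niche_indication = [
        INDICATIONS[i % len(INDICATIONS)] for i in range(c.n_niches)
    ]
    # typical co-medications: drugs from the same niche
    niche_pool = {
        n: [d for d in c.drugs if niche_of[d] == n] for n in range(c.n_niches)
    }

    base_date = np.datetime64("2015-01-01")
    rows = []
    for i in range(c.n_reports):
        drug = c.drugs[rng.integers(len(c.drugs))]
        n = niche_of[drug]
        probs = np.full(len(vocab), c.base_event_prob)
        for k, term in enumerate(vocab):
            ratio = planted.get((drug, term))
            if ratio is not None:
                probs[k] = min(0.9, probs[k] * ratio)
        hits = rng.random(len(vocab)) < probs
        events = [vocab[k] for k in np.flatnonzero(hits)]
        if not events:
            events = [BACKGROUND_EVENTS[rng.integers(len(BACKGROUND_EVENTS))]]
        pool = [d for d in niche_pool[n] if d != drug]
        n_con = int(rng.integers(0, 3))
        concomitant = sorted(
            rng.choice(pool, size=min(n_con, len(pool)), replace=False)
        ) if pool and n_con else []
        event_date = base_date + np.timedelta64(int(rng.integers(0, 1400)), "D")
        deposit_date = event_date + np.timedelta64(int(rng.integers(1, 60)), "D")
        rows.append({
            "report_id": f"R{i:06d}",
            "primary_suspect": drug,
            "secondary_suspects": "",
            "concomitant": ";".join(concomitant),
            "events": ";".join(events),
            "indication": niche_indication[n],
            "route": ROUTES[rng.integers(len(ROUTES))],
            "gender": "F" if rng.random() < niche_female[n] else "M",
            "age": float(np.clip(rng.normal(niche_age[n], 12), 1, 100).round(1)),
            "weight": float(np.clip(rng.normal(niche_weight[n], 10), 30, 160).round(1)),
            "outcome": OUTCOMES[rng.integers(len(OUTCOMES))],
            "event_date": str(event_date),
            "deposit_date": str(deposit_date),
        })

    duplicates = []
    if c.duplicate_rate > 0:
        n_dup = int(rng.binomial(c.n_reports, c.duplicate_rate))
        picks = rng.choice(c.n_reports, size=n_dup, replace=False)
        for j, idx in enumerate(sorted(picks)):
            dup = dict(rows[idx])
            dup["report_id"] = f"D{j:06d}"
            dup["deposit_date"] = str(
                np.datetime64(rows[idx]["deposit_date"])
                + np.timedelta64(int(rng.integers(1, 4)), "D")
            )
            duplicates.append((rows[idx]["report_id"], dup["report_id"]))
            rows.append(dup)

    table = pd.DataFrame(rows)
    truth = {
        "planted_associations": list(c.planted_associations),
        "niche_of": niche_of,
        "duplicate_pairs": duplicates,
        "base_event_prob": c.base_event_prob,
    }
    return table, truth
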