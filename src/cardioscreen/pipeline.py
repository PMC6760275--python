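"""End-to-end analysis of a single video: line selection to feature set."""

from __future__ import annotations

import numpy as np

from cardioscreen.features import (
    CardiacFeatureSet,
    FlowFeatureSet,
    cardiac_features,
    flow_summary,
    flow_velocity_trace,
)
from cardioscreen.formats import VideoStack
from cardioscreen.kymo import (
    LineSelection,
    chamber_extent_trace,
    extract_kymograph,
    place_chamber_lines,
)


def analyze_heart(
    stack: VideoStack,
    axis: LineSelection,
    fractions: tuple[float, float] = (0.25, 0.75),
    line_length_factor: float = 1.0,
    ef_mode: str = "spherical",
    **beat_kwargs,
) -> CardiacFeatureSet:
    """Cardiac feature set from a heart video and its axis line selection.

    The ventricle and atrium sampling lines are placed perpendicular to the
    axis at the given fractions, each chamber's kymograph is reduced to an
    extent trace, and beats are detected on the contraction curves.
    """
    v_line, a_line = place_chamber_lines(axis, fractions, line_length_factor)
    v_trace = chamber_extent_trace(extract_kymograph(stack, v_line))
    a_trace = chamber_extent_trace(extract_kymograph(stack, a_line))
    return cardiac_features(
        v_trace, a_trace, duration_s=stack.duration_s, ef_mode=ef_mode,
        **beat_kwargs,
    )


def default_heart_axis(stack: VideoStack, truth: dict | None = None) -> LineSelection:
    """Axis line for a simulated heart video (from its ground truth when
    available, else the central vertical line)."""
    if truth is not None and "axis" in truth:
        a = truth["axis"]
        return LineSelection(tuple(a["start"]), tuple(a["end"]), label="axis")
    t, h, w = stack.frames.shape
    return LineSelection((w / 2, h * 0.25), (w / 2, h * 0.78), label="axis")


def analyze_flow(
    stack: VideoStack,
    line: LineSelection | None = None,
    cell_diameter_um: float = 7.0,
) -> FlowFeatureSet:
    """Flow feature set from a vessel video.

    The sampling line defaults to the horizontal mid-line of the frame
    (the simulated vessel's centreline).
    """
    t, h, w = stack.frames.shape
    if line is None:
        y = h / 2.0
        line = LineSelection((0.0, y), (w - 1.0, y), sampling_width_px=3,
                             label="vessel")
    kymo = extract_kymograph(stack, line)
    vel = flow_velocity_trace(kymo)
    return flow_summary(vel, stack.fps, cell_diameter_um=cell_diameter_um)


def heart_axis_fractions_line(
    stack: VideoStack, y_center: float
) -> LineSelection:
    """Horizontal full-width chamber line at a given y (pixel units)."""
    t, h, w = stack.frames.shape
    return LineSelection((1.0, y_center), (w - 2.0, y_center), label="ventricle")


def recovered_vs_truth_bpm(feature_bpm: float, truth: dict) -> float:
    """Relative error of a recovered beat rate against the schedule truth."""
    sched = np.asarray(truth["ventricular_beat_times"])
    if len(sched) < 2:
        return float("nan")
    true_bpm = 60.0 / float(np.median(np.diff(sched)))
    return abs(feature_bpm - true_bpm) / true_bpm
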