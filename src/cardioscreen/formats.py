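"""File formats, plate metadata and the controlled feature vocabulary.

Video stacks travel as multi-page TIFF plus a JSON sidecar carrying the
acquisition metadata (frame rate, pixel size, modality); plate layouts,
feature exports and calls travel as UTF-8 CSV with a header row.  The
feature vocabulary is frozen here so extractors and statistics cannot
drift apart.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

#: Closed vocabulary of per-subject feature names.  Zebrafish numerical
#: features and binary flags, plus the five calcium-transient features at
#: each of the three post-treatment time points.
ZEBRAFISH_NUMERIC_FEATURES = (
    "ventricular_bpm",
    "qtc",
    "cardiac_arrest",
    "arrhythmic_beats",
    "ejection_fraction",
    "max_diameter",
)
ZEBRAFISH_FLAG_FEATURES = (
    "av_coupling_defect",
    "bigeminy",
    "no_beating",
    "artery_no_flow",
    "vein_no_flow",
)
HIPSC_BASE_FEATURES = ("bpm", "ampl", "auc", "pkw", "ppkw")
HIPSC_TIMEPOINTS = ("T1", "T2", "T3")
HIPSC_FEATURES = tuple(
    f"{f}_{t}" for f in HIPSC_BASE_FEATURES for t in HIPSC_TIMEPOINTS
)

FEATURE_VOCABULARY = frozenset(
    ZEBRAFISH_NUMERIC_FEATURES + ZEBRAFISH_FLAG_FEATURES + HIPSC_FEATURES
)

PLATE_ROWS = tuple("ABCDEFGH")

#: Features where only an increase is pathological: the significance call
#: additionally requires a positive z-score.
ONE_SIDED_FEATURES = frozenset({"arrhythmic_beats", "cardiac_arrest"})


class MetadataError(ValueError):
    """Sidecar metadata missing or inconsistent."""


class FormatError(ValueError):
    """Malformed video stack or table."""


@dataclass
class VideoStack:
    """Time-ordered grayscale frames with acquisition metadata.

    Parameters
    ----------
    frames
        Array of shape ``(t, height, width)``; intensities in arbitrary units.
    fps
        Acquisition frame rate in frames per second.
    pixel_size_um
        Physical edge length of one pixel in micrometres.
    modality
        ``"heart"`` or ``"vessel"``.
    """

    frames: np.ndarray
    fps: float
    pixel_size_um: float
    modality: str = "heart"

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or self.frames.shape[0] < 2:
            raise FormatError(
                "frames must be a (t, h, w) array with at least 2 frames"
            )
        if self.fps <= 0:
            raise FormatError("fps must be positive")
        if self.pixel_size_um <= 0:
            raise FormatError("pixel_size_um must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps

    @property
    def times(self) -> np.ndarray:
        """Frame acquisition times in seconds (frame i at i / fps)."""
        return np.arange(self.n_frames) / self.fps


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_video(stack: VideoStack, path: str | Path) -> None:
    """Write a video stack as multi-page TIFF plus a JSON metadata sidecar."""
    path = Path(path)
    tifffile.imwrite(path, stack.frames, photometric="minisblack")
    meta = {
        "fps": stack.fps,
        "pixel_size_um": stack.pixel_size_um,
        "modality": stack.modality,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def read_video(path: str | Path) -> VideoStack:
    """Read a multi-page TIFF written by :func:`write_video`.

    Raises
    ------
    MetadataError
        If the JSON sidecar is absent or lacks required fields.
    FormatError
        If frames do not form a constant-shape stack.
    """
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise MetadataError(f"missing metadata sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    for key in ("fps", "pixel_size_um", "modality"):
        if key not in meta:
            raise MetadataError(f"sidecar {sidecar} lacks field {key!r}")
    frames = tifffile.imread(path)
    frames = np.asarray(frames)
    if frames.ndim != 3:
        raise FormatError(f"{path} is not a constant-shape multi-frame stack")
    return VideoStack(
        frames=frames,
        fps=float(meta["fps"]),
        pixel_size_um=float(meta["pixel_size_um"]),
        modality=str(meta["modality"]),
    )


@dataclass
class PlateLayout:
    """Well-to-compound mapping for one or more 96-well plates.

    One row per well: well id (A1..H12), plate/day identifier, compound,
    concentration and role (``treatment`` or ``DMSO-control``).  The default
    replicate count in this screen design is 12 embryos per compound, one
    embryo per well.
    """

    table: pd.DataFrame = field(repr=False)

    REQUIRED_COLUMNS = ("well", "plate", "compound", "role")

    def __post_init__(self) -> None:
        df = self.table
        missing = [c for c in self.REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"layout is missing columns {missing}")
        rows = df["well"].astype(str).str[0]
        bad = sorted(set(rows) - set(PLATE_ROWS))
        if bad:
            raise FormatError(f"well rows outside A-H: {bad}")
        cols = pd.to_numeric(df["well"].astype(str).str[1:], errors="coerce")
        if cols.isna().any() or (cols < 1).any() or (cols > 12).any():
            raise FormatError("well columns must be 1-12")
        dup = df.duplicated(subset=["plate", "well"])
        if dup.any():
            dups = df.loc[dup, ["plate", "well"]].to_records(index=False)
            raise FormatError(f"duplicate wells on a plate: {list(dups)[:5]}")
        for plate, grp in df.groupby("plate"):
            if not (grp["role"] == "DMSO-control").any():
                raise FormatError(f"plate {plate!r} has no DMSO-control well")
        self.table = df.assign(row=rows.values)

    @property
    def compounds(self) -> list[str]:
        return sorted(self.table["compound"].unique())


def read_layout(path: str | Path) -> PlateLayout:
    """Read and validate a plate-layout CSV."""
    return PlateLayout(pd.read_csv(path))


def write_layout(layout: PlateLayout, path: str | Path) -> None:
    out = layout.table.sort_values(["plate", "well"], kind="stable")
    out.to_csv(path, index=False)


FEATURE_COLUMNS = ("compound", "plate", "row", "subject", "feature", "value")


def validate_features(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a long-format feature table against the frozen vocabulary."""
    missing = [c for c in FEATURE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"feature table is missing columns {missing}")
    unknown = sorted(set(df["feature"]) - FEATURE_VOCABULARY)
    if unknown:
        raise FormatError(f"unknown feature names: {unknown}")
    return df


def read_features(path: str | Path) -> pd.DataFrame:
    """Read a long-format per-subject feature CSV (validated)."""
    return validate_features(pd.read_csv(path))


def write_features(df: pd.DataFrame, path: str | Path) -> None:
    """Write a feature table with stable column and row order."""
    df = validate_features(df)
    out = df.loc[:, list(FEATURE_COLUMNS)].sort_values(
        ["feature", "compound", "plate", "subject"], kind="stable"
    )
    out.to_csv(path, index=False)
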