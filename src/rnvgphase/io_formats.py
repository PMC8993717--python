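"""On-disk artifacts: gated frame stacks, phase images, feature/cohort tables.

The portable frame-stack layout is a directory of delimited-text matrices::

    study_dir/
        frame_000.csv ... frame_{F-1}.csv   one rows x cols matrix per frame
        mask.csv                            0/1 LV ROI matrix

Multi-frame DICOM reading is available when ``pydicom`` is installed
(``pip install rnvgphase[dicom]``).  All tables are plain CSV so every
reader/writer pair round-trips losslessly (bit-compatible for integer
counts, 6 significant digits for floats).
"""

from __future__ import annotations

import logging
import re
import sys
import time
from contextlib import contextmanager
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
import yaml

from rnvgphase.phase_extraction import AmplitudeImage, GatedFrameSeries, PhaseImage

logger = logging.getLogger(__name__)

FEATURE_COLUMNS = [
    "patient_id",
    "apen",
    "synchrony",
    "entropy",
    "phase_sd",
    "baseline_lvef",
    "max_lvef_drop",
    "group",
]

#: Default analysis configuration; a YAML config file and CLI flags override.
DEFAULT_CONFIG: dict = {
    "m": 2,
    "r": 7.0,
    "bins": 64,
    "amplitude_threshold": 0.05,
    "frames": 24,
    "total_counts": 5_000_000,
    "seed": 0,
}


@dataclass(frozen=True)
class ROIMask:
    """2-D boolean occupancy grid (row-major, 0-based, origin top-left)."""

    grid: np.ndarray

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=bool)
        if grid.ndim != 2:
            raise ValueError("ROI mask must be 2-D")
        object.__setattr__(self, "grid", grid)

    @property
    def n_pixels(self) -> int:
        return int(np.count_nonzero(self.grid))

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape


@dataclass(frozen=True)
class StudyBundle:
    """One gated study: frames, LV ROI, and acquisition descriptors."""

    patient_id: str
    frames: GatedFrameSeries
    roi: ROIMask
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.frames.shape != self.roi.shape:
            raise ValueError(
                f"frame shape {self.frames.shape} != ROI shape {self.roi.shape}"
            )


class FormatError(ValueError):
    """Raised when an on-disk artifact does not match its expected layout."""


_FRAME_RE = re.compile(r"^frame_(\d+)\.csv$")


def _read_matrix(path: Path) -> np.ndarray:
    try:
        arr = np.loadtxt(path, delimiter=",", ndmin=2)
    except Exception as exc:  # noqa: BLE001 - surface as format error
        raise FormatError(f"could not parse matrix file {path}: {exc}") from exc
    return arr


def _write_matrix(path: Path, arr: np.ndarray, fmt: str) -> None:
    np.savetxt(path, np.asarray(arr), delimiter=",", fmt=fmt)


def read_gated_study(path: str | Path, format_hint: str | None = None) -> StudyBundle:
    """Read a gated study from a frame directory or a multi-frame DICOM file.

    ``format_hint`` may be ``"framedir"`` or ``"dicom"``; when omitted it is
    inferred (directory vs file).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format_hint is None:
        format_hint = "framedir" if path.is_dir() else "dicom"
    if format_hint == "framedir":
        return _read_framedir(path)
    if format_hint == "dicom":
        return _read_dicom(path)
    raise ValueError(f"unknown format hint {format_hint!r}")


def _read_framedir(path: Path) -> StudyBundle:
    if not path.is_dir():
        raise FormatError(f"{path} is not a directory")
    frame_files: dict[int, Path] = {}
    for p in path.iterdir():
        m = _FRAME_RE.match(p.name)
        if m:
            frame_files[int(m.group(1))] = p
    if not frame_files:
        raise FormatError(f"no frame_NNN.csv files in {path}")
    indices = sorted(frame_files)
    if indices != list(range(len(indices))):
        missing = sorted(set(range(max(indices) + 1)) - set(indices))
        raise FormatError(f"missing frame indices {missing} in {path}")
    if len(indices) < 4:
        raise ValueError(f"study has {len(indices)} frames; at least 4 required")
    frames = [_read_matrix(frame_files[i]) for i in indices]
    shapes = {f.shape for f in frames}
    if len(shapes) != 1:
        raise FormatError(f"non-uniform frame shapes {sorted(shapes)} in {path}")
    counts = np.stack(frames)
    if np.any(counts < 0):
        raise FormatError(f"negative counts in {path}")
    mask_path = path / "mask.csv"
    if not mask_path.exists():
        raise FormatError(f"missing mask.csv in {path}")
    mask = _read_matrix(mask_path)
    if mask.shape != counts.shape[1:]:
        raise FormatError(f"mask shape {mask.shape} != frame shape {counts.shape[1:]}")
    meta_path = path / "meta.yaml"
    meta = yaml.safe_load(meta_path.read_text()) if meta_path.exists() else {}
    patient_id = str(meta.get("patient_id", path.name))
    meta.update({"n_frames": len(indices), "matrix": list(counts.shape[1:])})
    return StudyBundle(
        patient_id=patient_id,
        frames=GatedFrameSeries(counts=counts),
        roi=ROIMask(grid=mask > 0.5),
        meta=meta,
    )


def _read_dicom(path: Path) -> StudyBundle:
    try:
        import pydicom
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "DICOM support requires pydicom; install rnvgphase[dicom]"
        ) from exc
    ds = pydicom.dcmread(str(path))
    arr = ds.pixel_array
    if arr.ndim != 3:
        raise FormatError(f"{path} is not a multi-frame DICOM object")
    if arr.shape[0] < 4:
        raise ValueError(f"study has {arr.shape[0]} frames; at least 4 required")
    # No ROI in the DICOM object; default to full-image mask (caller replaces).
    mask = np.ones(arr.shape[1:], dtype=bool)
    meta = {
        "n_frames": int(arr.shape[0]),
        "matrix": list(arr.shape[1:]),
        "source": "dicom",
    }
    pid = str(getattr(ds, "PatientID", path.stem))
    return StudyBundle(
        patient_id=pid,
        frames=GatedFrameSeries(counts=arr.astype(float)),
        roi=ROIMask(grid=mask),
        meta=meta,
    )


def write_gated_study(study: StudyBundle, path: str | Path) -> None:
    """Write a study in the frame-directory layout (inverse of the reader)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    counts = study.frames.counts
    integral = np.all(counts == np.round(counts))
    fmt = "%d" if integral else "%.10g"
    for k in range(study.frames.n_frames):
        _write_matrix(path / f"frame_{k:03d}.csv", counts[k], fmt)
    _write_matrix(path / "mask.csv", study.roi.grid.astype(int), "%d")
    meta = dict(study.meta)
    meta["patient_id"] = study.patient_id
    (path / "meta.yaml").write_text(yaml.safe_dump(meta, sort_keys=True))


def write_phase_images(
    phase: PhaseImage,
    amplitude: AmplitudeImage,
    out_dir: str | Path,
    png: bool = False,
) -> None:
    """Write phase/amplitude/validity CSV matrices (and optional PNG previews)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    _write_matrix(out_dir / "phase.csv", phase.phase, "%.10g")
    _write_matrix(out_dir / "valid.csv", phase.valid.astype(int), "%d")
    _write_matrix(out_dir / "amplitude.csv", amplitude.amplitude, "%.10g")
    if png:
        _write_png(out_dir / "phase.png", phase.phase, 0.0, 360.0)
        amax = amplitude.amplitude.max()
        _write_png(out_dir / "amplitude.png", amplitude.amplitude, 0.0, max(amax, 1e-12))


def _write_png(path: Path, arr: np.ndarray, vmin: float, vmax: float) -> None:
    from PIL import Image

    scaled = np.clip((arr - vmin) / (vmax - vmin), 0.0, 1.0)
    Image.fromarray((scaled * 255).astype(np.uint8), mode="L").save(path)


def read_phase_images(in_dir: str | Path) -> tuple[PhaseImage, AmplitudeImage]:
    in_dir = Path(in_dir)
    phase = _read_matrix(in_dir / "phase.csv")
    valid = _read_matrix(in_dir / "valid.csv") > 0.5
    amp = _read_matrix(in_dir / "amplitude.csv")
    return PhaseImage(phase=phase, valid=valid), AmplitudeImage(amplitude=amp)


def write_feature_table(cohort: pd.DataFrame, path: str | Path) -> None:
    """Write a per-patient feature table as CSV (6 significant digits).

    Requires a non-empty frame containing at least the canonical feature
    columns; extra columns are preserved.
    """
    if len(cohort) == 0:
        raise ValueError("refusing to write an empty cohort table")
    missing = [c for c in FEATURE_COLUMNS if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort table missing columns: {missing}")
    ordered = FEATURE_COLUMNS + [c for c in cohort.columns if c not in FEATURE_COLUMNS]
    cohort[ordered].to_csv(path, index=False, float_format="%.6g")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in FEATURE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"feature table {path} missing columns: {missing}")
    return df


def load_config(path: str | Path | None = None, **overrides) -> dict:
    """Merge DEFAULT_CONFIG <- YAML file <- keyword overrides (None skipped)."""
    cfg = dict(DEFAULT_CONFIG)
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(loaded, dict):
            raise FormatError(f"config file {path} must contain a mapping")
        cfg.update(loaded)
    cfg.update({k: v for k, v in overrides.items() if v is not None})
    return cfg


def setup_logging(quiet: bool = False) -> None:
    """Log to standard error; ``quiet`` suppresses everything below WARNING."""
    logging.basicConfig(
        stream=sys.stderr,
        level=logging.WARNING if quiet else logging.INFO,
        format="%(levelname)s %(name)s: %(message)s",
        force=True,
    )


@contextmanager
def stage(name: str) -> Iterator[None]:
    """Log wall-clock timing of a pipeline stage."""
    t0 = time.perf_counter()
    logger.info("%s: started", name)
    try:
        yield
    finally:
        logger.info("%s: finished in %.2fs", name, time.perf_counter() - t0)
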