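"""First-harmonic Fourier phase/amplitude images and count-based LVEF.

Every pixel of a gated frame series carries a time-activity curve over one
averaged cardiac cycle.  Fitting the first Fourier harmonic to that curve
yields a per-pixel contraction amplitude and a phase angle: the cycle
fraction at which counts are minimal (end-systole).  A higher phase angle
therefore means later contraction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, NamedTuple

import numpy as np

if TYPE_CHECKING:  # pragma: no cover - typing only
    from rnvgphase.io_formats import StudyBundle

logger = logging.getLogger(__name__)

#: Default validity threshold: fraction of the maximum amplitude below which
#: a pixel's phase is considered noise-dominated.
DEFAULT_AMPLITUDE_THRESHOLD = 0.05


@dataclass(frozen=True)
class GatedFrameSeries:
    """Per-pixel time-activity counts over one averaged cardiac cycle.

    Parameters
    ----------
    counts
        Array of shape ``(F, rows, cols)``; frame 0 is the R wave
        (end-diastole).  Counts are non-negative; they are integer-valued
        for acquired/Poisson data but may be real for noise-free synthetic
        expectations.
    """

    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        if counts.ndim != 3:
            raise ValueError(f"counts must be 3-D (F, rows, cols); got shape {counts.shape}")
        if counts.shape[0] < 4:
            raise ValueError(f"need at least 4 frames, got {counts.shape[0]}")
        if not np.all(np.isfinite(counts)) or np.any(counts < 0):
            raise ValueError("counts must be finite and non-negative")
        object.__setattr__(self, "counts", counts)

    @property
    def n_frames(self) -> int:
        return self.counts.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape[1:]


@dataclass(frozen=True)
class HarmonicFit:
    """First-harmonic fit of a single time-activity curve.

    The fitted model is ``c_k = a0 + a1*cos(2*pi*k/F) + b1*sin(2*pi*k/F)``,
    equivalently ``c_k = a0 - A*cos(2*pi*k/F - 2*pi*phase_deg/360)`` — counts
    are minimal at cycle fraction ``phase_deg/360``.
    """

    a0: float
    a1: float
    b1: float
    amplitude: float
    phase_deg: float
    valid: bool


@dataclass(frozen=True)
class PhaseImage:
    """Per-pixel first-harmonic phase in degrees, with a validity mask."""

    phase: np.ndarray  # degrees in [0, 360)
    valid: np.ndarray  # bool, same shape

    def __post_init__(self) -> None:
        phase = np.asarray(self.phase, dtype=float)
        valid = np.asarray(self.valid, dtype=bool)
        if phase.shape != valid.shape:
            raise ValueError("phase and validity mask shapes differ")
        if np.any((phase[valid] < 0) | (phase[valid] >= 360)):
            raise ValueError("valid phases must lie in [0, 360) degrees")
        object.__setattr__(self, "phase", phase)
        object.__setattr__(self, "valid", valid)

    @property
    def shape(self) -> tuple[int, int]:
        return self.phase.shape


@dataclass(frozen=True)
class AmplitudeImage:
    """Per-pixel first-harmonic amplitude in counts."""

    amplitude: np.ndarray

    def __post_init__(self) -> None:
        amp = np.asarray(self.amplitude, dtype=float)
        if np.any(amp < 0):
            raise ValueError("amplitudes must be non-negative")
        object.__setattr__(self, "amplitude", amp)

    @property
    def shape(self) -> tuple[int, int]:
        return self.amplitude.shape


def _first_harmonic(counts: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (a0, amplitude, phase_deg) for curves stacked on axis 0."""
    counts = np.asarray(counts, dtype=float)
    f = counts.shape[0]
    a0 = counts.mean(axis=0)
    # DFT at the fundamental: X1 = sum_k c_k exp(-2*pi*i*k/F).
    # For c_k = a0 - A cos(2*pi*k/F - psi):  -X1 = A*(F/2)*exp(-i*psi).
    x1 = np.fft.fft(counts, axis=0)[1]
    amplitude = 2.0 * np.abs(x1) / f
    phase = np.mod(np.degrees(-np.angle(-x1)), 360.0)
    return a0, amplitude, phase


def fit_first_harmonic(curve: np.ndarray) -> HarmonicFit:
    """Fit the first Fourier harmonic to one time-activity curve.

    For a pure first-harmonic curve ``c_k = a0 - A*cos(2*pi*k/F - 2*pi*phi/360)``
    the fit is exact: the returned amplitude equals ``A`` and the returned
    phase equals ``phi`` (mod 360) to machine precision, for any ``F >= 4``.

    A constant curve has no defined phase: ``amplitude == 0`` and
    ``valid`` is False.
    """
    curve = np.asarray(curve, dtype=float)
    if curve.ndim != 1:
        raise ValueError("curve must be 1-D")
    if curve.size < 4:
        raise ValueError(f"need at least 4 frames, got {curve.size}")
    if not np.all(np.isfinite(curve)):
        raise ValueError("curve contains non-finite values")
    a0, amp, phase = _first_harmonic(curve)
    a0, amp, phase = float(a0), float(amp), float(phase)
    valid = amp > 0.0
    if not valid:
        phase = 0.0
    # cosine/sine coefficients of the standard expansion
    psi = np.radians(phase)
    a1 = -amp * float(np.cos(psi))
    b1 = -amp * float(np.sin(psi))
    return HarmonicFit(a0=a0, a1=a1, b1=b1, amplitude=amp, phase_deg=phase, valid=valid)


def extract_phase_amplitude(
    study: "StudyBundle",
    amplitude_threshold: float = DEFAULT_AMPLITUDE_THRESHOLD,
) -> tuple[PhaseImage, AmplitudeImage]:
    """Compute phase and amplitude images for every pixel of a gated study.

    Pixels whose amplitude falls below ``amplitude_threshold`` times the
    image maximum are marked invalid (their phase is noise).  Raises
    ``ValueError`` if no ROI pixel survives the threshold; ROI pixels that
    are individually invalid are logged.
    """
    if not 0.0 <= amplitude_threshold < 1.0:
        raise ValueError("amplitude_threshold must be in [0, 1)")
    counts = study.frames.counts
    _, amp, phase = _first_harmonic(counts)
    max_amp = float(amp.max())
    if max_amp <= 0.0:
        raise ValueError("all pixels have zero first-harmonic amplitude")
    valid = amp > amplitude_threshold * max_amp
    phase = np.where(valid, phase, 0.0)
    roi = study.roi.grid
    n_bad = int(np.count_nonzero(roi & ~valid))
    if n_bad:
        logger.warning("%d ROI pixel(s) below the amplitude validity threshold", n_bad)
    if not np.any(roi & valid):
        raise ValueError("no valid pixel inside the ROI after amplitude thresholding")
    return PhaseImage(phase=phase, valid=valid), AmplitudeImage(amplitude=amp)


class LVEFResult(NamedTuple):
    """Count-based ejection fraction in percent, with an overflow flag."""

    percent: float
    es_exceeds_ed: bool


def compute_lvef(
    ed_counts: float,
    es_counts: float,
    bg_per_pixel: float = 0.0,
    roi_npix_ed: int = 0,
    roi_npix_es: int = 0,
) -> LVEFResult:
    """Count-based LVEF from background-corrected ED and ES ROI counts.

    ``LVEF = 100 * (EDnet - ESnet) / EDnet`` where
    ``Xnet = X - bg_per_pixel * roi_npix_X``.  Raises ``ValueError`` when
    the net end-diastolic counts are non-positive.  ``es_exceeds_ed`` flags
    the (physically implausible) case ESnet > EDnet, which yields a
    negative ejection fraction.
    """
    ed_net = float(ed_counts) - float(bg_per_pixel) * int(roi_npix_ed)
    es_net = float(es_counts) - float(bg_per_pixel) * int(roi_npix_es)
    if ed_net <= 0:
        raise ValueError(f"net end-diastolic counts must be positive, got {ed_net}")
    if es_net < 0:
        raise ValueError(f"net end-systolic counts must be non-negative, got {es_net}")
    lvef = 100.0 * (ed_net - es_net) / ed_net
    return LVEFResult(percent=lvef, es_exceeds_ed=es_net > ed_net)


def study_lvef(study: "StudyBundle", bg_per_pixel: float = 0.0) -> LVEFResult:
    """LVEF of a study with ED = frame 0, ES = frame of minimal ROI counts."""
    roi = study.roi.grid
    roi_counts = study.frames.counts[:, roi].sum(axis=1)
    npix = int(np.count_nonzero(roi))
    es_frame = int(np.argmin(roi_counts))
    return compute_lvef(
        ed_counts=float(roi_counts[0]),
        es_counts=float(roi_counts[es_frame]),
        bg_per_pixel=bg_per_pixel,
        roi_npix_ed=npix,
        roi_npix_es=npix,
    )
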