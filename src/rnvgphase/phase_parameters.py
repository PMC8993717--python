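"""Dyssynchrony parameters computed over the LV region of a phase image.

The central statistic is approximate entropy (ApEn) evaluated on a 1-D
data series built from the ROI pixels in serpentine (boustrophedon) scan
order, so that consecutive series elements are spatially adjacent pixels.
Companion first-order parameters: synchrony (amplitude-weighted resultant
phasor length), normalized Shannon entropy of the phase histogram, and the
sample standard deviation of the ROI phases.

Conventions
-----------
* Template similarity uses the Chebyshev (maximum componentwise) distance
  with an inclusive tolerance ``r`` expressed in degrees of phase.
* Template counts include the self match, and both the length-``m`` and the
  length-``m+1`` counts run over the same ``N - m`` start positions, so each
  log ratio is a true conditional probability and ApEn is non-negative.
* Phase values are treated as linear (non-circular) quantities in ApEn, the
  histogram entropy, and phase SD; synchrony is inherently circular.

The synchrony and histogram-entropy formulas follow the forms established
in the dyssynchrony literature; the exact normalizations (amplitude-weighted
mean phasor magnitude, Shannon entropy over equal-width bins on [0, 360)
divided by ``ln(bins)``) are this package's documented choices.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np

from rnvgphase.phase_extraction import (
    AmplitudeImage,
    DEFAULT_AMPLITUDE_THRESHOLD,
    PhaseImage,
    extract_phase_amplitude,
    study_lvef,
)

if TYPE_CHECKING:  # pragma: no cover - typing only
    from rnvgphase.io_formats import ROIMask, StudyBundle

DEFAULT_BINS = 64


@dataclass(frozen=True)
class ApEnParams:
    """Template length ``m`` and tolerance ``r`` (degrees of phase)."""

    m: int = 2
    r: float = 7.0

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if not self.r > 0:
            raise ValueError("r must be > 0")


@dataclass(frozen=True)
class PhaseFeatureSet:
    """Per-study phase parameters plus the count-based ejection fraction."""

    apen: float
    synchrony: float
    entropy: float
    phase_sd: float
    lvef: float


def serpentine_series(phase: PhaseImage, roi: "ROIMask") -> np.ndarray:
    """Flatten ROI phase values in serpentine scan order.

    Rows are scanned top to bottom; counting from the topmost ROI row, even
    rows read left to right and odd rows right to left, so consecutive
    series elements are spatially adjacent.  Pixels outside the ROI or
    marked invalid are skipped without breaking the ordering.
    """
    mask = roi.grid & phase.valid
    if not np.any(mask):
        raise ValueError("ROI contains no valid pixels")
    rows = np.nonzero(mask.any(axis=1))[0]
    top = int(rows[0])
    out: list[np.ndarray] = []
    for row in rows:
        vals = phase.phase[row, mask[row]]
        if (row - top) % 2 == 1:
            vals = vals[::-1]
        out.append(vals)
    return np.concatenate(out)


def _template_matches(x: np.ndarray, m: int, r: float) -> np.ndarray:
    """Boolean matrix of length-``m`` template matches (Chebyshev <= r)."""
    close = np.abs(x[:, None] - x[None, :]) <= r
    match = close
    for k in range(1, m):
        match = match[:-1, :-1] & close[k:, k:]
    return match


def approximate_entropy(series: np.ndarray, params: ApEnParams) -> float:
    """Approximate entropy of a data series.

    ``ApEn = -(N-m)^{-1} * sum_i ln(C_{m+1}[i] / C_m[i])`` where ``C_m[i]``
    counts, over the shared start range ``i, j in 0..N-m-1``, the length-``m``
    templates within tolerance of template ``i`` (self match included) and
    ``C_{m+1}[i]`` the corresponding length-``m+1`` counts.  The result is
    always >= 0; it is 0 when every matching length-``m`` template also
    matches at length ``m+1`` (perfect regularity).
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("series must be 1-D")
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite values")
    m, r = params.m, params.r
    n = x.size
    if n < m + 2:
        raise ValueError(f"series length {n} < m + 2 = {m + 2}")
    match_m = _template_matches(x, m, r)          # (N-m+1)^2
    close = np.abs(x[:, None] - x[None, :]) <= r
    match_m1 = match_m[:-1, :-1] & close[m:, m:]  # (N-m)^2
    c_m = match_m[: n - m, : n - m].sum(axis=1)
    c_m1 = match_m1.sum(axis=1)
    return float(-np.mean(np.log(c_m1 / c_m)) + 0.0)  # +0.0 avoids -0.0


def synchrony(phase: PhaseImage, amplitude: AmplitudeImage, roi: "ROIMask") -> float:
    """Amplitude-weighted resultant length of the ROI phase phasors.

    ``|sum_j A_j exp(i*phi_j)| / sum_j A_j`` — equals 1 iff all ROI phases
    coincide, and decreases toward 0 as phase dispersion grows.
    """
    mask = roi.grid & phase.valid
    if not np.any(mask):
        raise ValueError("ROI contains no valid pixels")
    amps = amplitude.amplitude[mask]
    total = amps.sum()
    if total <= 0:
        raise ValueError("total ROI amplitude is zero")
    angles = np.radians(phase.phase[mask])
    resultant = np.abs(np.sum(amps * np.exp(1j * angles)))
    return float(min(resultant / total, 1.0))


def phase_entropy(phase: PhaseImage, roi: "ROIMask", bins: int = DEFAULT_BINS) -> float:
    """Normalized Shannon entropy of the ROI phase histogram.

    Histogram over ``bins`` equal-width bins covering [0, 360); entropy in
    nats divided by ``ln(bins)`` so the result lies in [0, 1] with 0 for a
    single occupied bin and 1 for an exactly uniform histogram.
    """
    if bins < 2:
        raise ValueError("bins must be >= 2")
    mask = roi.grid & phase.valid
    if not np.any(mask):
        raise ValueError("ROI contains no valid pixels")
    hist, _ = np.histogram(phase.phase[mask], bins=bins, range=(0.0, 360.0))
    p = hist[hist > 0] / hist.sum()
    return float(-np.sum(p * np.log(p)) / np.log(bins))


def phase_sd(phase: PhaseImage, roi: "ROIMask") -> float:
    """Sample standard deviation (ddof=1) of the ROI phases, in degrees."""
    mask = roi.grid & phase.valid
    n = int(np.count_nonzero(mask))
    if n < 2:
        raise ValueError("phase SD requires at least 2 valid ROI pixels")
    return float(np.std(phase.phase[mask], ddof=1))


def compute_features(
    study: "StudyBundle",
    params: ApEnParams = ApEnParams(),
    bins: int = DEFAULT_BINS,
    amplitude_threshold: float = DEFAULT_AMPLITUDE_THRESHOLD,
    bg_per_pixel: float = 0.0,
) -> PhaseFeatureSet:
    """All phase parameters plus LVEF for one gated study (deterministic)."""
    phase, amplitude = extract_phase_amplitude(study, amplitude_threshold)
    series = serpentine_series(phase, study.roi)
    return PhaseFeatureSet(
        apen=approximate_entropy(series, params),
        synchrony=synchrony(phase, amplitude, study.roi),
        entropy=phase_entropy(phase, study.roi, bins),
        phase_sd=phase_sd(phase, study.roi),
        lvef=study_lvef(study, bg_per_pixel).percent,
    )
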