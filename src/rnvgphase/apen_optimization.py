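"""Input-parameter (m, r) optimization for ApEn on phase images.

ApEn lacks relative consistency: as the tolerance ``r`` varies, the ApEn
curves of a normal and an abnormal phase image can cross, reversing which
condition scores higher.  This module sweeps ApEn over (m, r) grids,
locates those crossings ("flip points"), and recommends an operating
tolerance that stays clear of every observed flip.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from rnvgphase.io_formats import ROIMask
from rnvgphase.phase_extraction import PhaseImage
from rnvgphase.phase_parameters import ApEnParams, approximate_entropy, serpentine_series

#: Grids matching the tested optimization ranges.
DEFAULT_M_VALUES = (1, 2, 3, 4, 5)
DEFAULT_R_VALUES = tuple(np.arange(0.25, 21.0 + 1e-9, 0.25))


@dataclass(frozen=True)
class SweepGrid:
    """ApEn evaluated on an (image, m, r) grid."""

    image_ids: tuple[str, ...]
    m_values: tuple[int, ...]
    r_values: tuple[float, ...]
    apen: np.ndarray  # shape (n_images, n_m, n_r), all >= 0

    def __post_init__(self) -> None:
        apen = np.asarray(self.apen, dtype=float)
        expected = (len(self.image_ids), len(self.m_values), len(self.r_values))
        if apen.shape != expected:
            raise ValueError(f"apen shape {apen.shape} != {expected}")
        if np.any(apen < -1e-12):
            raise ValueError("ApEn grid contains negative values")
        object.__setattr__(self, "apen", apen)

    def to_frame(self) -> pd.DataFrame:
        """Long-format view: one row per (image_id, m, r)."""
        rows = [
            (img, m, r, self.apen[i, j, k])
            for i, img in enumerate(self.image_ids)
            for j, m in enumerate(self.m_values)
            for k, r in enumerate(self.r_values)
        ]
        return pd.DataFrame(rows, columns=["image_id", "m", "r", "apen"])


@dataclass(frozen=True)
class FlipPoint:
    """Tolerance at which normal and abnormal ApEn coincide."""

    r_star: float
    bracket: tuple[float, float]  # grid points enclosing the sign change
    sign_before: int  # sign of d = ApEn(abnormal) - ApEn(normal) at bracket[0]
    sign_after: int


@dataclass(frozen=True)
class RRecommendation:
    """Advisory operating tolerance with the evidence behind it."""

    r: float
    margin: float  # distance from r to the nearest flip bracket
    flip_brackets: tuple[tuple[float, float], ...]
    warnings: tuple[str, ...] = ()


def sweep_apen(
    images: list[tuple[PhaseImage, ROIMask]],
    m_values=DEFAULT_M_VALUES,
    r_values=DEFAULT_R_VALUES,
    image_ids: list[str] | None = None,
) -> SweepGrid:
    """Evaluate ApEn for every image over the (m, r) grid (deterministic)."""
    if not images:
        raise ValueError("no images supplied")
    m_values = tuple(int(m) for m in m_values)
    r_values = tuple(float(r) for r in r_values)
    if not m_values or not r_values:
        raise ValueError("m and r grids must be non-empty")
    if image_ids is None:
        image_ids = [f"img{i}" for i in range(len(images))]
    if len(image_ids) != len(images):
        raise ValueError("image_ids length mismatch")
    grid = np.empty((len(images), len(m_values), len(r_values)))
    for i, (phase, roi) in enumerate(images):
        series = serpentine_series(phase, roi)
        for j, m in enumerate(m_values):
            for k, r in enumerate(r_values):
                grid[i, j, k] = approximate_entropy(series, ApEnParams(m=m, r=r))
    return SweepGrid(
        image_ids=tuple(image_ids),
        m_values=m_values,
        r_values=r_values,
        apen=grid,
    )


def apen_profile(series: np.ndarray, m: int, r_values) -> np.ndarray:
    """ApEn of one series across a tolerance grid."""
    return np.array(
        [approximate_entropy(series, ApEnParams(m=m, r=float(r))) for r in r_values]
    )


def find_flip_points(
    normal: np.ndarray,
    abnormal: np.ndarray,
    m: int = 2,
    r_grid=DEFAULT_R_VALUES,
) -> list[FlipPoint]:
    """Locate every tolerance where the ApEn difference changes sign.

    ``d(r) = ApEn(abnormal) - ApEn(normal)`` is evaluated on the grid; a
    sign change between consecutive grid points is localized by linear
    interpolation, and an exact zero at a grid point is reported with a
    zero-width bracket.  A difference that is identically zero is
    degenerate (the series are ApEn-indistinguishable) and yields no flips.
    """
    r = np.asarray(list(r_grid), dtype=float)
    if r.size == 0:
        raise ValueError("empty tolerance grid")
    d = apen_profile(abnormal, m, r) - apen_profile(normal, m, r)
    if np.all(d == 0.0):
        return []
    flips: list[FlipPoint] = []
    sign = np.sign(d)
    for k in range(r.size):
        if sign[k] == 0.0 and r.size > 1:
            before = int(sign[k - 1]) if k > 0 else 0
            after = int(sign[k + 1]) if k < r.size - 1 else 0
            flips.append(
                FlipPoint(
                    r_star=float(r[k]),
                    bracket=(float(r[k]), float(r[k])),
                    sign_before=before,
                    sign_after=after,
                )
            )
    for k in range(r.size - 1):
        if sign[k] * sign[k + 1] < 0:
            # linear interpolation of the zero crossing
            r_star = r[k] + (r[k + 1] - r[k]) * d[k] / (d[k] - d[k + 1])
            flips.append(
                FlipPoint(
                    r_star=float(r_star),
                    bracket=(float(r[k]), float(r[k + 1])),
                    sign_before=int(sign[k]),
                    sign_after=int(sign[k + 1]),
                )
            )
    flips.sort(key=lambda fp: fp.r_star)
    return flips


def recommend_r(
    flip_points: list[list[FlipPoint]],
    r_grid=DEFAULT_R_VALUES,
    margin: float = 1.0,
) -> RRecommendation:
    """Pick the grid tolerance farthest from every observed flip bracket.

    ``flip_points`` holds one flip list per analyzed image pair.  The
    recommendation maximizes the distance from the union of flip brackets
    (widened by ``margin`` when reporting); with no flips anywhere the grid
    midpoint is returned with a warning.  Purely advisory.
    """
    if not flip_points:
        raise ValueError("no image pairs analyzed")
    r = np.asarray(list(r_grid), dtype=float)
    if r.size == 0:
        raise ValueError("empty tolerance grid")
    brackets = tuple(
        fp.bracket for per_pair in flip_points for fp in per_pair
    )
    warnings: list[str] = []
    if not brackets:
        mid = float(r[r.size // 2])
        warnings.append("no flip points observed on the grid; recommendation is the grid midpoint")
        return RRecommendation(r=mid, margin=np.inf, flip_brackets=(), warnings=tuple(warnings))
    lo = np.array([b[0] for b in brackets])
    hi = np.array([b[1] for b in brackets])
    # distance from each candidate r to the nearest bracket interval
    dist = np.min(
        np.maximum(0.0, np.maximum(lo[None, :] - r[:, None], r[:, None] - hi[None, :])),
        axis=1,
    )
    best = int(np.argmax(dist))
    if dist[best] < margin:
        warnings.append(
            f"best achievable clearance {dist[best]:.3g} is below the requested margin {margin:.3g}"
        )
    return RRecommendation(
        r=float(r[best]),
        margin=float(dist[best]),
        flip_brackets=brackets,
        warnings=tuple(warnings),
    )


def relative_consistency_warnings(grid: SweepGrid) -> list[str]:
    """Flag image pairs whose ApEn ordering reverses anywhere on the grid."""
    out: list[str] = []
    n = len(grid.image_ids)
    for i in range(n):
        for j in range(i + 1, n):
            d = grid.apen[i] - grid.apen[j]  # (n_m, n_r)
            if np.any(d > 0) and np.any(d < 0):
                out.append(
                    f"relative consistency violated: ApEn ordering of "
                    f"{grid.image_ids[i]!r} and {grid.image_ids[j]!r} reverses on the (m, r) grid"
                )
    return out
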