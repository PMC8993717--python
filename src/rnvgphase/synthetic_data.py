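"""Synthetic stand-ins for the unavailable clinical data.

Three generator families:

* radial-segment phase images — each LV ROI pixel is assigned to an equal
  angular sector about the ROI centroid and draws its phase from that
  sector's normal(mean, SD); presets emulate normal, MI, LBBB, and
  aneurysm contraction patterns;
* gated frame stacks consistent with a given phase/amplitude image pair,
  with optional Poisson counting noise (the inverse of phase extraction,
  enabling round-trip testing);
* two-group patient cohorts with baseline phase features and serial LVEF
  trajectories, calibrated by default to the published group summaries.

Every generator is a pure function of its seed: reruns are bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from rnvgphase.io_formats import ROIMask, StudyBundle
from rnvgphase.phase_extraction import AmplitudeImage, GatedFrameSeries, PhaseImage

MAX_PHASE = np.nextafter(360.0, 0.0)

PRESET_NAMES = ("normal", "mi", "lbbb", "aneurysm")

#: Baseline phase level and per-segment noise used by the presets.  The
#: noise SD (5 degrees) is pilot-tuned so the normal preset's ApEn at
#: (m=2, r=7), synchrony, and phase SD land inside the published normal
#: group's mean +/- 2 SD band; preset effect sizes (+60 MI shift, 0-45 LBBB
#: gradient, 150 aneurysm separation) are conventions, not measured values.
PRESET_BASE_MEAN = 140.0
PRESET_BASE_SD = 5.0
MI_SHIFT = 60.0
LBBB_GRADIENT = 45.0
ANEURYSM_SEPARATION = 150.0


@dataclass(frozen=True)
class SegmentSpec:
    """Equal angular sectors about the ROI centroid with per-sector moments."""

    means: tuple[float, ...]
    sds: tuple[float, ...]

    def __post_init__(self) -> None:
        means = tuple(float(v) for v in self.means)
        sds = tuple(float(v) for v in self.sds)
        if len(means) < 1 or len(means) != len(sds):
            raise ValueError("means and sds must be equal-length and non-empty")
        if not all(np.isfinite(means)):
            raise ValueError("segment means must be finite")
        if any(s < 0 for s in sds):
            raise ValueError("segment SDs must be >= 0")
        object.__setattr__(self, "means", means)
        object.__setattr__(self, "sds", sds)

    @property
    def n_segments(self) -> int:
        return len(self.means)


def make_lv_roi(
    grid_shape: tuple[int, int] = (64, 64),
    center: tuple[float, float] = (32.0, 32.0),
    semi_axes: tuple[float, float] = (10.0, 14.0),
) -> ROIMask:
    """Elliptical LV ROI: pixels with normalized elliptic distance <= 1.

    The ellipse (center and semi-axes in row/col pixel units) must fit
    inside the grid; an empty mask raises ``ValueError``.
    """
    nr, nc = grid_shape
    cr, cc = center
    ar, ac = semi_axes
    if ar < 0.5 or ac < 0.5:
        raise ValueError("semi-axes below half a pixel give a degenerate (empty) ellipse")
    if cr - ar < -0.5 or cr + ar > nr - 0.5 or cc - ac < -0.5 or cc + ac > nc - 0.5:
        raise ValueError("ellipse does not fit inside the grid")
    rows, cols = np.mgrid[0:nr, 0:nc]
    d2 = ((rows - cr) / ar) ** 2 + ((cols - cc) / ac) ** 2
    grid = d2 <= 1.0
    if not np.any(grid):
        raise ValueError("ellipse contains no pixels")
    return ROIMask(grid=grid)


def segment_labels(roi: ROIMask, n_segments: int) -> np.ndarray:
    """Angular sector index of every ROI pixel (full-grid int array, -1 outside).

    Sector 0 starts at 12 o'clock and sectors proceed clockwise (in display
    orientation: row index increases downward).
    """
    if n_segments < 1:
        raise ValueError("n_segments must be >= 1")
    grid = roi.grid
    rows, cols = np.nonzero(grid)
    cr, cc = rows.mean(), cols.mean()
    # display clockwise from 12 o'clock: up is -row, right is +col
    ang = np.mod(np.arctan2(cols - cc, -(rows - cr)), 2.0 * np.pi)
    idx = np.minimum((ang / (2.0 * np.pi / n_segments)).astype(int), n_segments - 1)
    labels = np.full(grid.shape, -1, dtype=int)
    labels[rows, cols] = idx
    return labels


def make_phase_image(
    roi: ROIMask,
    spec: SegmentSpec,
    seed: int | np.random.Generator = 0,
) -> PhaseImage:
    """Draw a per-segment normal phase image over the ROI, clamped to [0, 360).

    Values are clamped (not wrapped): wrapping would alias late contraction
    as early.
    """
    rng = np.random.default_rng(seed)
    labels = segment_labels(roi, spec.n_segments)
    phase = np.zeros(roi.shape, dtype=float)
    means = np.asarray(spec.means)[labels[roi.grid]]
    sds = np.asarray(spec.sds)[labels[roi.grid]]
    draws = rng.normal(means, sds)
    phase[roi.grid] = np.clip(draws, 0.0, MAX_PHASE)
    return PhaseImage(phase=phase, valid=roi.grid.copy())


def preset_spec(name: str, n_segments: int = 8) -> SegmentSpec:
    """Segment specification for a named contraction pattern."""
    base = np.full(n_segments, PRESET_BASE_MEAN)
    sds = tuple([PRESET_BASE_SD] * n_segments)
    if name == "normal":
        means = base
    elif name == "mi":
        # one contiguous apical sector contracting late
        means = base.copy()
        means[n_segments // 2] += MI_SHIFT
    elif name == "lbbb":
        means = base + np.linspace(0.0, LBBB_GRADIENT, n_segments)
    elif name == "aneurysm":
        means = base.copy()
        means[n_segments // 2 :] += ANEURYSM_SEPARATION
    else:
        raise ValueError(f"unknown preset {name!r}; expected one of {PRESET_NAMES}")
    return SegmentSpec(means=tuple(means), sds=sds)


def preset(
    name: str,
    roi: ROIMask,
    seed: int | np.random.Generator = 0,
    n_segments: int = 8,
) -> PhaseImage:
    """Phase image for a named preset (normal / mi / lbbb / aneurysm)."""
    return make_phase_image(roi, preset_spec(name, n_segments), seed)


def uniform_amplitude(roi: ROIMask, level: float = 20.0) -> AmplitudeImage:
    """Constant contraction amplitude inside the ROI, zero outside."""
    if level <= 0:
        raise ValueError("amplitude level must be positive")
    amp = np.where(roi.grid, float(level), 0.0)
    return AmplitudeImage(amplitude=amp)


def make_gated_study(
    phase: PhaseImage,
    amplitude: AmplitudeImage,
    f: int = 24,
    total_counts: float = 5_000_000,
    seed: int | np.random.Generator = 0,
    noise: str = "poisson",
    patient_id: str = "sim",
    pedestal: float = 1.0,
) -> StudyBundle:
    """Gated frame stack whose first harmonic reproduces (phase, amplitude).

    The per-pixel expected curve is ``a0_j - s*A_j*cos(2*pi*k/F - psi_j)``
    with ``a0_j = s*(A_j + pedestal)``; the common scale ``s`` is chosen so
    the summed expectation equals ``total_counts``.  Scaling the pedestal
    and the harmonic together preserves the modulation depth at any count
    budget: extraction recovers the input phase exactly (amplitude up to
    the factor ``s``).  The pedestal gives amplitude-free pixels a uniform
    background; ``pedestal < 0`` would force a negative count rate
    (``a0 < A``) and is rejected.  ``noise="poisson"`` draws integer
    counts; ``noise="none"`` returns the exact real-valued expectations,
    for which phase extraction is a lossless round trip.
    """
    if phase.shape != amplitude.shape:
        raise ValueError("phase and amplitude shapes differ")
    if f < 4:
        raise ValueError("need at least 4 frames")
    if total_counts <= 0:
        raise ValueError("total_counts must be positive")
    if pedestal < 0:
        raise ValueError("pedestal must be >= 0: a0 < amplitude is infeasible")
    if noise not in ("poisson", "none"):
        raise ValueError(f"unknown noise mode {noise!r}")
    amp = amplitude.amplitude
    scale = float(total_counts) / (f * (amp + pedestal).sum())
    a0 = scale * (amp + pedestal)
    psi = np.radians(phase.phase)
    k = np.arange(f).reshape(-1, 1, 1)
    expected = a0 - scale * amp * np.cos(2.0 * np.pi * k / f - psi)
    if noise == "poisson":
        rng = np.random.default_rng(seed)
        counts = rng.poisson(expected).astype(float)
    else:
        counts = expected
    return StudyBundle(
        patient_id=patient_id,
        frames=GatedFrameSeries(counts=counts),
        roi=ROIMask(grid=phase.valid.copy()),
        meta={"n_frames": f, "noise": noise, "total_counts": float(total_counts)},
    )


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

FEATURES = ("apen", "synchrony", "entropy", "phase_sd", "baseline_lvef")

#: Published two-group summaries (mean, SD) used as default generator
#: calibration — generator parameters, not reproduced results.
STABLE_MEANS = {
    "apen": 0.348,
    "synchrony": 0.991,
    "entropy": 0.559,
    "phase_sd": 7.90,
    "baseline_lvef": 73.5,
}
STABLE_SDS = {
    "apen": 0.107,
    "synchrony": 0.004,
    "entropy": 0.040,
    "phase_sd": 1.96,
    "baseline_lvef": 6.1,
}
CTRCD_MEANS = {
    "apen": 0.418,
    "synchrony": 0.989,
    "entropy": 0.584,
    "phase_sd": 8.91,
    "baseline_lvef": 64.5,
}
CTRCD_SDS = {
    "apen": 0.076,
    "synchrony": 0.004,
    "entropy": 0.028,
    "phase_sd": 1.78,
    "baseline_lvef": 6.7,
}

_FEATURE_BOUNDS = {
    "apen": (0.0, np.inf),
    "synchrony": (0.0, 1.0),
    "entropy": (0.0, 1.0),
    "phase_sd": (0.0, np.inf),
    "baseline_lvef": (55.0, 100.0),  # post-exclusion population
}

MAX_RESAMPLE = 1000


@dataclass(frozen=True)
class CohortSpec:
    """Two-group cohort generator parameters."""

    n_stable: int = 166
    n_ctrcd: int = 11
    stable_means: dict = field(default_factory=lambda: dict(STABLE_MEANS))
    stable_sds: dict = field(default_factory=lambda: dict(STABLE_SDS))
    ctrcd_means: dict = field(default_factory=lambda: dict(CTRCD_MEANS))
    ctrcd_sds: dict = field(default_factory=lambda: dict(CTRCD_SDS))
    rho_apen_lvef: float = 0.0  # within-group ApEn/LVEF correlation
    min_visits: int = 2  # total RNVGs incl. baseline
    max_visits: int = 9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_stable < 1 or self.n_ctrcd < 1:
            raise ValueError("group sizes must be >= 1")
        if not -1.0 < self.rho_apen_lvef < 1.0:
            raise ValueError("rho must lie in (-1, 1)")
        if not 2 <= self.min_visits <= self.max_visits:
            raise ValueError("need 2 <= min_visits <= max_visits")


def _group_cov(sds: dict, rho: float) -> np.ndarray:
    s = np.array([sds[f] for f in FEATURES])
    cov = np.diag(s**2)
    i, j = FEATURES.index("apen"), FEATURES.index("baseline_lvef")
    cov[i, j] = cov[j, i] = rho * s[i] * s[j]
    return cov


def _draw_features(
    rng: np.random.Generator, means: dict, sds: dict, rho: float, n: int
) -> np.ndarray:
    mu = np.array([means[f] for f in FEATURES])
    cov = _group_cov(sds, rho)
    lo = np.array([_FEATURE_BOUNDS[f][0] for f in FEATURES])
    hi = np.array([_FEATURE_BOUNDS[f][1] for f in FEATURES])
    out = np.empty((n, len(FEATURES)))
    for i in range(n):
        for attempt in range(MAX_RESAMPLE):
            row = rng.multivariate_normal(mu, cov)
            if np.all(row >= lo) and np.all(row <= hi):
                out[i] = row
                break
        else:
            raise RuntimeError(
                f"could not draw an in-range feature vector in {MAX_RESAMPLE} attempts"
            )
    return out


def _stable_followups(rng: np.random.Generator, baseline: float, n_fu: int) -> np.ndarray:
    """Follow-up LVEFs that never meet the CTRCD criterion."""
    for _ in range(MAX_RESAMPLE):
        fu = baseline + rng.normal(0.0, 3.0, size=n_fu)
        fu = np.clip(fu, 5.0, 100.0)
        drop = baseline - fu.min()
        if not (drop > 10.0 and fu.min() < 50.0):
            return fu
    raise RuntimeError("could not draw a stable LVEF trajectory")


def _ctrcd_followups(rng: np.random.Generator, baseline: float, n_fu: int) -> np.ndarray:
    """Follow-up LVEFs with a drop > 10 points to below 50%."""
    ceiling = min(baseline - 10.0, 50.0)
    nadir_target = ceiling - rng.uniform(1.0, 10.0)
    if nadir_target < 5.0:
        raise RuntimeError(
            f"CTRCD trajectory infeasible from baseline {baseline:.1f}"
        )
    fu = np.clip(baseline + rng.normal(0.0, 3.0, size=n_fu), nadir_target, 100.0)
    fu[rng.integers(n_fu)] = nadir_target
    return fu


def make_cohort(spec: CohortSpec = CohortSpec()) -> pd.DataFrame:
    """Generate a two-group cohort with baseline features and serial LVEFs.

    Returns a wide table: one row per patient with the baseline feature
    vector, follow-up LVEF columns ``lvef_f1..lvef_f{K}`` (NaN-padded),
    ``max_lvef_drop``, the intended ``group`` label, and an empty rule
    ``flag``.  The table satisfies its own labeling: :func:`label_groups`
    reproduces the intended group sizes exactly.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    plans = [("stable", spec.n_stable, spec.stable_means, spec.stable_sds)]
    plans.append(("ctrcd", spec.n_ctrcd, spec.ctrcd_means, spec.ctrcd_sds))
    max_fu = spec.max_visits - 1
    pid = 0
    for group, n, means, sds in plans:
        feats = _draw_features(rng, means, sds, spec.rho_apen_lvef, n)
        for i in range(n):
            rec = dict(zip(FEATURES, feats[i]))
            baseline = rec["baseline_lvef"]
            n_fu = int(rng.integers(spec.min_visits - 1, spec.max_visits))
            if group == "stable":
                fu = _stable_followups(rng, baseline, n_fu)
            else:
                fu = _ctrcd_followups(rng, baseline, n_fu)
            rec.update(
                {
                    "patient_id": f"P{pid:03d}",
                    "group": group,
                    "max_lvef_drop": baseline - fu.min(),
                }
            )
            for k in range(max_fu):
                rec[f"lvef_f{k + 1}"] = fu[k] if k < n_fu else np.nan
            rows.append(rec)
            pid += 1
    df = pd.DataFrame(rows)
    cols = (
        ["patient_id", *FEATURES, "max_lvef_drop", "group"]
        + [f"lvef_f{k + 1}" for k in range(max_fu)]
    )
    df = df[cols]
    return label_groups(df)


def label_groups(records: pd.DataFrame) -> pd.DataFrame:
    """Apply the LVEF-decline labeling rule to a cohort table.

    CTRCD iff (baseline - min follow-up) > 10 percentage points AND the
    minimum follow-up LVEF is below 50%.  Near-miss trajectories (only one
    of the two conditions holds) are labeled stable and flagged.  Requires
    a ``baseline_lvef`` column and at least one non-NaN ``lvef_f*`` value
    per record.
    """
    fu_cols = [c for c in records.columns if c.startswith("lvef_f")]
    if not fu_cols:
        raise ValueError("no follow-up LVEF columns (lvef_f*) present")
    fu = records[fu_cols].to_numpy(dtype=float)
    if np.all(np.isnan(fu), axis=1).any():
        raise ValueError("every record needs at least one follow-up LVEF")
    min_fu = np.nanmin(fu, axis=1)
    baseline = records["baseline_lvef"].to_numpy(dtype=float)
    drop = baseline - min_fu
    big_drop = drop > 10.0
    below_50 = min_fu < 50.0
    out = records.copy()
    out["max_lvef_drop"] = drop
    out["group"] = np.where(big_drop & below_50, "ctrcd", "stable")
    out["flag"] = np.where(
        big_drop ^ below_50, "discordant-lvef-criteria", ""
    )
    return out


def make_logistic_cohort(
    n: int,
    coef: tuple[float, float, float, float],
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Binary-outcome cohort from a known two-predictor interaction model.

    ``logit P(y=1) = b0 + b1*x1 + b2*x2 + b3*x1*x2`` with standard-normal
    predictors; used for parameter-recovery testing of the logistic stage.
    """
    rng = np.random.default_rng(seed)
    b0, b1, b2, b3 = coef
    x1 = rng.normal(size=n)
    x2 = rng.normal(size=n)
    eta = b0 + b1 * x1 + b2 * x2 + b3 * x1 * x2
    y = rng.random(n) < 1.0 / (1.0 + np.exp(-eta))
    return pd.DataFrame({"x1": x1, "x2": x2, "y": y.astype(int)})
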