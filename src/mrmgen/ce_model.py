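"""Collision-energy optimization by spline fitting of breakdown curves.

Each surviving fragment trace gives absolute intensity at the measured CEs.
A univariate interpolating spline (default degree 2, smoothing 0, so the
curve passes through every observed point) models the continuous CE-intensity
profile; the predicted optimal CE is the spline maximum, located by dense
grid search.  Predictions below a 5 eV floor, or outside the measured range,
are clamped to the floor — the practical lower limit of triple-quadrupole
collision cells.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy.interpolate import UnivariateSpline

from .fragment_tracking import FragmentTrace
from .spectra_io import ValidationError

logger = logging.getLogger("mrmgen")


@dataclass(frozen=True)
class SplineConfig:
    """Spline-fit and argmax-search settings.

    degree:     spline degree k (default 2; 3 also interpolates 4 points)
    smoothing:  FITPACK smoothing factor s (0 = exact interpolation)
    grid_step:  argmax search resolution in eV
    clamp_floor: lowest reportable CE (eV)
    ce_min/ce_max: measured CE range, also the argmax search window
    """

    degree: int = 2
    smoothing: float = 0.0
    grid_step: float = 0.1
    clamp_floor: float = 5.0
    ce_min: float = 0.0
    ce_max: float = 40.0

    def __post_init__(self) -> None:
        if self.degree < 1:
            raise ValidationError(f"degree must be >= 1, got {self.degree}")
        if self.smoothing < 0:
            raise ValidationError("smoothing must be >= 0")
        if self.grid_step <= 0:
            raise ValidationError("grid_step must be > 0")
        if self.clamp_floor < 0:
            raise ValidationError("clamp_floor must be >= 0")
        if not self.ce_min < self.ce_max:
            raise ValidationError("ce_min must be < ce_max")

    def grid(self) -> np.ndarray:
        """Dense evaluation grid over [ce_min, ce_max], inclusive."""
        n = int(round((self.ce_max - self.ce_min) / self.grid_step))
        return self.ce_min + self.grid_step * np.arange(n + 1)


@dataclass
class CEProfileFit:
    """Spline fit of one trace with its predicted optimal CE.

    ``optimal_ce`` is post-clamp when produced by :func:`predict_optimal_ce`;
    ``raw_ce`` keeps the unclamped argmax.  ``intensity_at_optimum`` is the
    spline maximum (used for ranking), which for an interpolant is never
    below the largest observed intensity.
    """

    trace: FragmentTrace
    optimal_ce: float
    intensity_at_optimum: float
    clamped: bool
    config: SplineConfig
    raw_ce: float


def _effective_degree(n_points: int, config: SplineConfig) -> int:
    degree = min(config.degree, 5)
    if n_points == 3:
        # 3-point traces are always fitted at <= quadratic
        degree = min(degree, 2)
    if degree > n_points - 1:
        degree = n_points - 1
        logger.info("trace has %d points; spline degree reduced to %d", n_points, degree)
    return degree


def fit_profile(trace: FragmentTrace, config: SplineConfig | None = None) -> CEProfileFit:
    """Fit the interpolating spline and locate its maximum (pre-clamp).

    The argmax is found on the dense grid over [ce_min, ce_max]; plateau ties
    resolve to the smallest CE (gentler fragmentation).  Traces with fewer
    points than degree+1 are fitted at a reduced degree with a logged notice.
    """
    config = config or SplineConfig()
    ces, intens = trace.detected_profile()
    if len(ces) == 0:
        raise ValidationError("cannot fit a trace with no detected CEs")
    if len(ces) == 1:
        # degenerate: single observation, the only defensible optimum is its CE
        logger.info("single-CE trace at m/z %.4f; optimum taken at the observed CE",
                    trace.representative_mz)
        return CEProfileFit(trace, float(ces[0]), float(intens[0]), False, config,
                            float(ces[0]))
    degree = _effective_degree(len(ces), config)
    spline = UnivariateSpline(ces, intens, k=degree, s=config.smoothing)
    grid = config.grid()
    values = spline(grid)
    # plateau ties resolve to the smallest CE attaining the maximum; the
    # tolerance absorbs interpolation round-off on flat profiles
    vmax = float(np.max(values))
    threshold = vmax - max(1e-9 * abs(vmax), 1e-12)
    idx = int(np.argmax(values >= threshold))
    raw = float(grid[idx])
    return CEProfileFit(trace, raw, float(values[idx]), False, config, raw)


def clamp_ce(raw_ce: float, config: SplineConfig | None = None) -> tuple[float, bool]:
    """Apply the reporting clamp: values below the floor or outside the
    measured CE range collapse to the floor."""
    config = config or SplineConfig()
    if not np.isfinite(raw_ce):
        raise ValidationError(f"raw_ce must be finite, got {raw_ce}")
    if raw_ce < config.clamp_floor or raw_ce < config.ce_min or raw_ce > config.ce_max:
        return config.clamp_floor, True
    return float(raw_ce), False


def predict_optimal_ce(trace: FragmentTrace, config: SplineConfig | None = None
                       ) -> CEProfileFit:
    """Full per-fragment CE prediction: spline fit, argmax, then clamp.

    ``optimal_ce`` is kept at full precision here; rounding to integer eV
    happens only when transition tables are written.
    """
    config = config or SplineConfig()
    fit = fit_profile(trace, config)
    ce, clamped = clamp_ce(fit.raw_ce, config)
    return replace(fit, optimal_ce=ce, clamped=clamped)
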