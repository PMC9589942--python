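"""Fit-error estimators comparing an experimental CRF against its reference.

Three complementary errors are used throughout the package:

* ``rms_at_points`` — root-mean-square difference between the experimental and
  reference curves at the sampled contrasts only (RMS_#points);
* ``rms_allpoints`` — the same RMS over a dense grid of contrasts spanning
  [0, 100]% (RMS_allpoints, 100 points by default), a continuous rather than
  discrete comparison;
* ``angle_error`` — the angle between the two parameter 4-vectors
  [Rmax, B, C50, n], in radians; scale-invariant, it compares parameter
  geometry rather than curve values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import CRFPoints, NRParams, evaluate_nre

__all__ = [
    "ErrorTriple",
    "rms_at_points",
    "rms_allpoints",
    "angle_error",
    "percent_variation",
    "mean_theoretical_rate",
    "error_triple",
    "ANGLE_REFERENCE",
]

#: default reference scale for expressing the angle error as a percentage
ANGLE_REFERENCE = np.pi / 2


@dataclass(frozen=True)
class ErrorTriple:
    """The three fit-error estimators for one fitted CRF vs its reference."""

    rms_points: float
    rms_allpoints: float
    angle: float

    def __post_init__(self) -> None:
        if self.rms_points < 0 or self.rms_allpoints < 0 or self.angle < 0:
            raise ValueError("errors must be non-negative")

    def as_dict(self) -> dict:
        return {
            "err_rms_points": self.rms_points,
            "err_rms_allpoints": self.rms_allpoints,
            "err_angle_rad": self.angle,
        }

    @property
    def angle_deg(self) -> float:
        return float(np.degrees(self.angle))


def _experimental_rates(experimental, contrasts: np.ndarray) -> np.ndarray:
    if isinstance(experimental, NRParams):
        return np.atleast_1d(evaluate_nre(experimental, contrasts))
    if isinstance(experimental, CRFPoints):
        if not np.allclose(experimental.contrasts, contrasts):
            raise ValueError("CRFPoints contrasts do not match the supplied contrasts")
        return experimental.mean_rates
    rates = np.asarray(experimental, dtype=float)
    if rates.shape != contrasts.shape:
        raise ValueError("experimental rates length does not match contrasts")
    return rates


def rms_at_points(experimental, theoretical: NRParams, contrasts) -> float:
    """RMS difference at exactly the supplied contrasts (spikes/s).

    ``experimental`` may be fitted parameters, a CRFPoints at the same
    contrasts, or a plain rate vector.
    """
    c = np.atleast_1d(np.asarray(contrasts, dtype=float))
    if c.size == 0:
        raise ValueError("contrasts must be non-empty")
    e = _experimental_rates(experimental, c)
    t = np.atleast_1d(evaluate_nre(theoretical, c))
    return float(np.sqrt(np.mean((e - t) ** 2)))


def rms_allpoints(experimental_fit: NRParams, theoretical: NRParams, n_grid: int = 100) -> float:
    """RMS difference between the two curves over ``n_grid`` contrasts on [0, 100]."""
    if n_grid < 2:
        raise ValueError("n_grid must be >= 2")
    grid = np.linspace(0.0, 100.0, n_grid)
    return rms_at_points(experimental_fit, theoretical, grid)


def _as_param_vector(p) -> np.ndarray:
    v = p.as_vector() if isinstance(p, NRParams) else np.asarray(p, dtype=float)
    if v.shape != (4,):
        raise ValueError("parameter vector must have 4 components [Rmax, B, C50, n]")
    return v


def angle_error(sigma_e, sigma_t) -> float:
    """Angle (radians) between the two parameter 4-vectors [Rmax, B, C50, n].

    arccos of the normalized dot product, clamped to [0, pi] against
    floating-point overshoot.  Raw parameter units are used without
    normalization, so mixed units (spikes/s, %, dimensionless) enter as-is.
    """
    e = _as_param_vector(sigma_e)
    t = _as_param_vector(sigma_t)
    ne, nt = np.linalg.norm(e), np.linalg.norm(t)
    if ne == 0 or nt == 0:
        raise ValueError("angle is undefined for a zero-length parameter vector")
    cosv = np.clip(np.dot(e, t) / (ne * nt), -1.0, 1.0)
    return float(np.arccos(cosv))


def percent_variation(error_value: float, reference_scale: float) -> float:
    """Express an error as a percentage of a reference scale.

    Conventions used by the dynamic-window analysis: RMS errors are referred
    to the mean reference-curve rate (``mean_theoretical_rate``); the angle is
    referred to pi/2 (the largest angle two non-negative parameter vectors can
    subtend).  Both references are explicit arguments so other normalizations
    remain possible.
    """
    if reference_scale <= 0:
        raise ValueError("reference_scale must be positive")
    if error_value < 0:
        raise ValueError("error_value must be non-negative")
    return 100.0 * error_value / reference_scale


def mean_theoretical_rate(params: NRParams, n_grid: int = 100) -> float:
    """Mean of the reference curve over a dense contrast grid on [0, 100]%."""
    grid = np.linspace(0.0, 100.0, n_grid)
    return float(np.mean(evaluate_nre(params, grid)))


def error_triple(
    fitted: NRParams, truth: NRParams, contrasts, n_grid: int = 100
) -> ErrorTriple:
    """All three errors of a fitted CRF against the known reference."""
    return ErrorTriple(
        rms_points=rms_at_points(fitted, truth, contrasts),
        rms_allpoints=rms_allpoints(fitted, truth, n_grid=n_grid),
        angle=angle_error(fitted, truth),
    )
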