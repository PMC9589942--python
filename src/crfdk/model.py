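"""Naka-Rushton contrast-response model and bounded multistart least-squares fitting.

The contrast response function (CRF) of a visual neuron — mean firing rate as a
function of stimulus contrast — is sigmoidal and is modelled here by the
Naka-Rushton equation

    r(c) = Rmax * c**n / (c**n + C50**n) + B

with ``Rmax`` the dynamic range (spikes/s), ``C50`` the half-saturation
contrast (%), ``n`` the exponent controlling the steepness of the transition,
and ``B`` the baseline (spontaneous) rate at 0% contrast.

Fitting follows the statsmodels convention: :class:`NakaRushtonModel` is built
from averaged rate data and its :meth:`~NakaRushtonModel.fit` returns a
:class:`NakaRushtonResults` object carrying the estimates, their approximate
standard errors, diagnostics and a ``summary()`` table.  The optimizer is a
bounded trust-region-reflective least-squares solve, restarted from many
random initial parameter vectors drawn uniformly inside the bound box; the
lowest-SSE solution is kept.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "NRParams",
    "FitBounds",
    "CRFPoints",
    "NakaRushtonModel",
    "NakaRushtonResults",
    "FitResult",
    "evaluate_nre",
    "derive_bounds",
    "fit_crf",
    "TooFewPointsError",
    "FitConvergenceError",
]

#: open lower bound used for C50 and n, whose domains exclude 0
_OPEN_EPS = 1e-6

#: minimal number of contrast points for a 4-parameter fit to be determined
MIN_POINTS = 4


class TooFewPointsError(ValueError):
    """Raised when fewer contrast points than free parameters are supplied."""


class FitConvergenceError(RuntimeError):
    """Raised when every restart of the least-squares solver failed."""


def _as_rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class NRParams:
    """The four Naka-Rushton parameters.

    Parameters
    ----------
    r_max : float
        Dynamic range in spikes/s; >= 0.
    c50 : float
        Half-saturation contrast in % of maximal contrast; > 0.
    n : float
        Dimensionless exponent; > 0.
    b : float
        Baseline rate in spikes/s; >= 0.
    """

    r_max: float
    c50: float
    n: float
    b: float

    def __post_init__(self) -> None:
        vals = (self.r_max, self.c50, self.n, self.b)
        if not all(math.isfinite(v) for v in vals):
            raise ValueError(f"non-finite Naka-Rushton parameter: {vals}")
        if self.r_max < 0 or self.b < 0:
            raise ValueError("r_max and b must be non-negative")
        if self.c50 <= 0 or self.n <= 0:
            raise ValueError("c50 and n must be strictly positive")

    def as_vector(self) -> np.ndarray:
        """Parameter 4-vector in the order [Rmax, B, C50, n] used by the angle metric."""
        return np.array([self.r_max, self.b, self.c50, self.n], dtype=float)

    @classmethod
    def from_vector(cls, vec: Sequence[float]) -> "NRParams":
        r_max, b, c50, n = (float(v) for v in vec)
        return cls(r_max=r_max, c50=c50, n=n, b=b)

    def to_dict(self) -> dict:
        return {"r_max": self.r_max, "c50": self.c50, "n": self.n, "b": self.b}

    @classmethod
    def from_dict(cls, d: dict) -> "NRParams":
        return cls(r_max=d["r_max"], c50=d["c50"], n=d["n"], b=d["b"])


def evaluate_nre(params: NRParams, contrasts) -> np.ndarray:
    """Evaluate the Naka-Rushton equation at the given contrasts (in %).

    ``c = 0`` is legal and returns the baseline ``b`` (the ``c**n`` term
    vanishes).  Raises ``ValueError`` for contrasts outside [0, 100] or
    non-finite input.
    """
    c = np.asarray(contrasts, dtype=float)
    if not np.all(np.isfinite(c)):
        raise ValueError("contrasts must be finite")
    if np.any(c < 0) or np.any(c > 100):
        raise ValueError("contrasts must lie in [0, 100] %")
    cn = np.power(c, params.n)
    out = params.r_max * cn / (cn + params.c50**params.n) + params.b
    return out if out.shape else float(out)


@dataclass(frozen=True)
class FitBounds:
    """Box constraints for the fit; all lower bounds are 0 (open for c50 and n).

    ``r_max_hi`` should be MAX + MAXERR, where MAX is the largest observed
    mean rate and MAXERR is two standard deviations of the per-trial rates at
    that contrast; the baseline shares the same ceiling.  ``c50_hi`` = 100 %
    and ``n_hi`` = 6 are fixed physiological constants.
    """

    r_max_hi: float
    b_hi: float
    c50_hi: float = 100.0
    n_hi: float = 6.0

    def __post_init__(self) -> None:
        if self.r_max_hi <= 0 or self.b_hi <= 0:
            raise ValueError("upper bounds must be positive")

    def lower(self) -> np.ndarray:
        # order [r_max, b, c50, n]; c50 and n are open at 0
        return np.array([0.0, 0.0, _OPEN_EPS, _OPEN_EPS])

    def upper(self) -> np.ndarray:
        return np.array([self.r_max_hi, self.b_hi, self.c50_hi, self.n_hi])

    def contains(self, params: NRParams, atol: float = 1e-9) -> bool:
        v = params.as_vector()
        return bool(np.all(v >= self.lower() - atol) and np.all(v <= self.upper() + atol))


@dataclass
class CRFPoints:
    """Averaged contrast-response data: one mean rate (and optional SD) per contrast."""

    contrasts: np.ndarray
    mean_rates: np.ndarray
    rate_sds: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.contrasts = np.asarray(self.contrasts, dtype=float)
        self.mean_rates = np.asarray(self.mean_rates, dtype=float)
        if self.contrasts.ndim != 1 or self.contrasts.size == 0:
            raise ValueError("contrasts must be a non-empty 1-D vector")
        if np.any(np.diff(self.contrasts) <= 0):
            raise ValueError("contrasts must be strictly increasing")
        if self.mean_rates.shape != self.contrasts.shape:
            raise ValueError("mean_rates length must match contrasts")
        if np.any(self.mean_rates < 0):
            raise ValueError("mean rates must be non-negative")
        if self.rate_sds is not None:
            self.rate_sds = np.asarray(self.rate_sds, dtype=float)
            if self.rate_sds.shape != self.contrasts.shape:
                raise ValueError("rate_sds length must match contrasts")

    def __len__(self) -> int:
        return self.contrasts.size

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"contrast_pct": self.contrasts, "mean_rate_hz": self.mean_rates}
        )
        df["rate_sd_hz"] = self.rate_sds if self.rate_sds is not None else np.nan
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CRFPoints":
        sds = None
        if "rate_sd_hz" in df.columns and not df["rate_sd_hz"].isna().all():
            sds = df["rate_sd_hz"].to_numpy()
        return cls(df["contrast_pct"].to_numpy(), df["mean_rate_hz"].to_numpy(), sds)

    @classmethod
    def from_csv(cls, path) -> "CRFPoints":
        return cls.from_frame(pd.read_csv(path))


def derive_bounds(points: CRFPoints) -> FitBounds:
    """Data-driven bound box: Rmax and B capped at MAX + MAXERR.

    MAX is the largest observed mean rate; MAXERR is two standard deviations
    of the per-trial rates at that contrast (0 when no SD is available, e.g. a
    single trial).  A tiny floor keeps the box non-degenerate for silent
    units.
    """
    i = int(np.argmax(points.mean_rates))
    maxrate = float(points.mean_rates[i])
    maxerr = 2.0 * float(points.rate_sds[i]) if points.rate_sds is not None else 0.0
    hi = max(maxrate + maxerr, 1e-3)
    return FitBounds(r_max_hi=hi, b_hi=hi)


def _heuristic_start(c, y, lo, hi) -> np.ndarray:
    """Data-driven initial guess: baseline = min rate, range = max-min,
    c50 at the half-rise contrast, n = 2."""
    b0 = float(np.min(y))
    r0 = max(float(np.max(y)) - b0, 1e-3)
    half = b0 + r0 / 2.0
    above = np.nonzero(y >= half)[0]
    c50_0 = float(c[above[0]]) if above.size else float(np.median(c))
    if c50_0 <= 0:
        c50_0 = float(np.median(c[c > 0])) if np.any(c > 0) else 10.0
    x0 = np.array([r0, b0, c50_0, 2.0])
    pad = 1e-8 * (hi - lo)
    return np.clip(x0, lo + pad, hi - pad)


class NakaRushtonModel:
    """Naka-Rushton model for averaged contrast-response data.

    Examples
    --------
    >>> model = NakaRushtonModel.from_arrays([0, 10, 25, 50, 75, 100],
    ...                                      [1.2, 3.0, 7.5, 12.0, 14.1, 15.0])
    >>> res = model.fit(n_restarts=50, seed=0)
    >>> res.params.r_max  # doctest: +SKIP
    """

    def __init__(self, points: CRFPoints):
        self.points = points

    @classmethod
    def from_arrays(cls, contrasts, mean_rates, rate_sds=None) -> "NakaRushtonModel":
        return cls(CRFPoints(contrasts, mean_rates, rate_sds))

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        contrast: str = "contrast_pct",
        rate: str = "mean_rate_hz",
        sd: str = "rate_sd_hz",
    ) -> "NakaRushtonModel":
        sds = df[sd].to_numpy() if sd in df.columns else None
        return cls.from_arrays(df[contrast].to_numpy(), df[rate].to_numpy(), sds)

    @classmethod
    def from_spikes(cls, spikes, window: float | None = None) -> "NakaRushtonModel":
        from .simulate import mean_firing_rates

        return cls(mean_firing_rates(spikes, window=window))

    def default_bounds(self) -> FitBounds:
        return derive_bounds(self.points)

    def fit(
        self,
        bounds: FitBounds | None = None,
        n_restarts: int = 500,
        seed: int | np.random.Generator | None = None,
        max_nfev: int = 1000,
        tol: float = 1e-11,
    ) -> "NakaRushtonResults":
        """Bounded multistart least-squares fit.

        ``n_restarts`` initial parameter vectors are drawn uniformly inside
        the bound box (plus one data-driven heuristic start); each is refined
        by the trust-region-reflective solver (ftol = xtol = gtol = ``tol``,
        at most ``max_nfev`` function evaluations) and the solution with the
        smallest SSE is returned.
        """
        pts = self.points
        if len(pts) < MIN_POINTS:
            raise TooFewPointsError(
                f"{len(pts)} contrast points supplied; a 4-parameter fit needs at "
                f"least {MIN_POINTS}"
            )
        if bounds is None:
            bounds = derive_bounds(pts)
        c = pts.contrasts
        y = pts.mean_rates
        lo, hi = bounds.lower(), bounds.upper()

        logc = np.where(c > 0, np.log(np.where(c > 0, c, 1.0)), 0.0)

        def resid(theta: np.ndarray) -> np.ndarray:
            r_max, b, c50, n = theta
            cn = np.power(c, n)
            return r_max * cn / (cn + c50**n) + b - y

        def jac(theta: np.ndarray) -> np.ndarray:
            # analytic Jacobian in [r_max, b, c50, n] order; at c=0 the
            # d/dn term cn*log(c) is 0 by the limit
            r_max, b, c50, n = theta
            cn = np.power(c, n)
            g = c50**n
            den = cn + g
            J = np.empty((c.size, 4))
            J[:, 0] = cn / den
            J[:, 1] = 1.0
            J[:, 2] = -r_max * cn * n * c50 ** (n - 1.0) / den**2
            J[:, 3] = r_max * (cn * logc * g - cn * g * np.log(c50)) / den**2
            return J

        rng = _as_rng(seed)
        starts = [_heuristic_start(c, y, lo, hi)]
        if n_restarts > 0:
            draws = rng.uniform(lo, hi, size=(n_restarts, 4))
            starts.extend(draws)

        best = None
        converged = False
        failures: list[str] = []
        for x0 in starts:
            try:
                sol = least_squares(
                    resid,
                    x0,
                    jac=jac,
                    bounds=(lo, hi),
                    method="trf",
                    ftol=tol,
                    xtol=tol,
                    gtol=tol,
                    max_nfev=max_nfev,
                )
            except Exception as exc:  # pragma: no cover - solver failures are rare
                failures.append(str(exc))
                continue
            if best is None or sol.cost < best.cost:
                best = sol
            if sol.status > 0:
                converged = True
        if best is None:
            raise FitConvergenceError(
                f"all {len(starts)} restarts failed; last errors: {failures[-3:]}"
            )
        params = NRParams.from_vector(best.x)
        sse = float(2.0 * best.cost)
        return NakaRushtonResults(
            model=self,
            params=params,
            sse=sse,
            converged=converged,
            n_restarts_used=len(starts),
            bounds=bounds,
            _jac=np.asarray(best.jac),
        )


class NakaRushtonResults:
    """Results of a Naka-Rushton fit: estimates, uncertainties, diagnostics."""

    def __init__(self, model, params, sse, converged, n_restarts_used, bounds, _jac=None):
        self.model = model
        self.params: NRParams = params
        self.sse: float = sse
        self.converged: bool = converged
        self.n_restarts_used: int = n_restarts_used
        self.bounds: FitBounds = bounds
        self._jac = _jac

    # -- diagnostics ------------------------------------------------------
    @property
    def nobs(self) -> int:
        return len(self.model.points)

    @property
    def df_resid(self) -> int:
        return self.nobs - 4

    @property
    def fittedvalues(self) -> np.ndarray:
        return evaluate_nre(self.params, self.model.points.contrasts)

    @property
    def resid(self) -> np.ndarray:
        return self.fittedvalues - self.model.points.mean_rates

    @property
    def scale(self) -> float:
        """Residual variance estimate SSE / (nobs - 4); NaN when saturated."""
        return self.sse / self.df_resid if self.df_resid > 0 else float("nan")

    def cov_params(self) -> np.ndarray:
        """Gauss-Newton covariance ``scale * (J'J)^-1`` at the optimum.

        Rows/columns follow the [Rmax, B, C50, n] vector order.  NaN-filled
        when the Jacobian is unavailable or singular (e.g. parameters pinned
        at a bound).
        """
        nan = np.full((4, 4), np.nan)
        if self._jac is None or self.df_resid <= 0:
            return nan
        jtj = self._jac.T @ self._jac
        try:
            cov = np.linalg.inv(jtj) * self.scale
        except np.linalg.LinAlgError:
            return nan
        return cov

    @property
    def bse(self) -> np.ndarray:
        """Approximate standard errors in [Rmax, B, C50, n] order."""
        with np.errstate(invalid="ignore"):
            return np.sqrt(np.diag(self.cov_params()))

    # -- prediction and simulation ---------------------------------------
    def predict(self, contrasts=None) -> np.ndarray:
        if contrasts is None:
            return self.fittedvalues
        return evaluate_nre(self.params, contrasts)

    def simulate(self, trial_length: float, n_repetitions: int, contrasts=None, seed=None):
        """Draw Poisson spike trains from the fitted curve (see crfdk.simulate)."""
        from .simulate import StimulusProtocol, simulate_experiment

        if contrasts is None:
            contrasts = self.model.points.contrasts
        protocol = StimulusProtocol(
            contrasts=tuple(np.asarray(contrasts, dtype=float)),
            trial_length=trial_length,
            n_repetitions=n_repetitions,
        )
        return simulate_experiment(self.params, protocol, seed=seed)

    # -- presentation ------------------------------------------------------
    def summary(self) -> str:
        names = ["Rmax", "B", "C50", "n"]
        units = ["spk/s", "spk/s", "%", "-"]
        est = self.params.as_vector()
        se = self.bse
        lines = [
            "Naka-Rushton contrast response fit",
            "=" * 46,
            f"{'nobs':<22}{self.nobs:>10d}",
            f"{'SSE':<22}{self.sse:>10.4g}",
            f"{'converged':<22}{str(self.converged):>10}",
            f"{'restarts':<22}{self.n_restarts_used:>10d}",
            "-" * 46,
            f"{'param':<8}{'estimate':>12}{'std err':>12}{'unit':>8}",
        ]
        for nm, e, s, u in zip(names, est, se, units):
            se_s = f"{s:12.4g}" if np.isfinite(s) else f"{'--':>12}"
            lines.append(f"{nm:<8}{e:12.5g}{se_s}{u:>8}")
        lines.append("=" * 46)
        return "\n".join(lines)

    def plot(self, ax=None, n_grid: int = 200):
        """Plot data points and the fitted curve (convenience only)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        pts = self.model.points
        ax.errorbar(
            pts.contrasts,
            pts.mean_rates,
            yerr=pts.rate_sds,
            fmt="ko",
            capsize=2,
            label="data",
        )
        grid = np.linspace(0, 100, n_grid)
        ax.plot(grid, evaluate_nre(self.params, grid), "r-", label="fit")
        ax.set_xlabel("contrast (%)")
        ax.set_ylabel("firing rate (spikes/s)")
        ax.legend()
        return ax

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "sse": self.sse,
            "converged": self.converged,
            "n_restarts_used": self.n_restarts_used,
        }

    def to_json(self, path=None) -> str:
        s = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(s)
        return s

    def __repr__(self) -> str:
        p = self.params
        return (
            f"<NakaRushtonResults Rmax={p.r_max:.3g} C50={p.c50:.3g} "
            f"n={p.n:.3g} B={p.b:.3g} sse={self.sse:.3g}>"
        )


#: alias matching the domain vocabulary: the output of a CRF fit
FitResult = NakaRushtonResults


def fit_crf(
    points: CRFPoints,
    bounds: FitBounds | None = None,
    n_restarts: int = 500,
    seed: int | np.random.Generator | None = None,
    **kwargs,
) -> NakaRushtonResults:
    """Functional wrapper: fit a CRF to averaged points (see NakaRushtonModel.fit)."""
    return NakaRushtonModel(points).fit(
        bounds=bounds, n_restarts=n_restarts, seed=seed, **kwargs
    )
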