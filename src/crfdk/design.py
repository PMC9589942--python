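"""Monte-Carlo optimization of experimental-condition patterns.

A *pattern* is the condition tuple {#contrast points, #trials, trial length}.
The sweep simulates, for every combination of functional Naka-Rushton
parameters and every pattern x contrast scale, a full experiment through the
Poisson cascade, refits the curve, and scores the three fit errors against the
known truth.  Recording time is the product of the pattern's factors, used on
a log10 axis; the trade-off ("optimization") point of a scale is where the
min-max-normalized error curve, with patterns sorted by error, first meets the
normalized log recording-time curve.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .metrics import error_triple
from .model import CRFPoints, NRParams, derive_bounds, evaluate_nre, fit_crf
from .scales import generate_scale
from .simulate import rates_from_counts, simulate_counts

__all__ = [
    "Pattern",
    "TABLE1_FUNCTIONAL",
    "TABLE1_CONDITIONS",
    "PROFILE_DEFAULTS",
    "functional_grid",
    "enumerate_patterns",
    "recording_time",
    "run_monte_carlo",
    "MonteCarloResult",
    "condition_profiles",
    "find_tradeoff_point",
    "TradeoffPoint",
]

#: functional (curve-shape) parameter values swept in the full study
TABLE1_FUNCTIONAL: dict[str, tuple] = {
    "r_max": (5.0, 7.0, 10.0, 16.0, 32.0),  # spikes/s
    "c50": (20.0, 40.0, 50.0, 60.0, 80.0),  # %
    "b": (1.0, 2.0, 4.0),  # spikes/s
    "n": (1.0, 2.0, 3.0, 6.0),
}

#: experimental-condition values swept in the full study
TABLE1_CONDITIONS: dict[str, tuple] = {
    "n_points": (4, 6, 8, 10, 15, 20),
    "n_trials": (1, 2, 4, 8, 16, 32, 64),
    "trial_length": (1.0, 2.0, 4.0, 6.0, 8.0, 16.0),
}

#: conditions held fixed when one condition is profiled in isolation
PROFILE_DEFAULTS: dict[str, float] = {"n_points": 6, "n_trials": 10, "trial_length": 2.0}

CONDITION_COLUMNS = ("n_points", "n_trials", "trial_length")
ERROR_COLUMNS = ("err_rms_points", "err_rms_allpoints", "err_angle_rad")


@dataclass(frozen=True)
class Pattern:
    """An experimental-condition tuple {#points, #trials, trial length (s)}."""

    n_points: int
    n_trials: int
    trial_length: float

    def __post_init__(self) -> None:
        if self.n_points < 4:
            raise ValueError("a pattern needs at least 4 contrast points")
        if self.n_trials < 1 or self.trial_length <= 0:
            raise ValueError("n_trials and trial_length must be positive")

    @property
    def recording_time(self) -> float:
        return recording_time(self)

    def as_tuple(self) -> tuple:
        return (self.n_points, self.n_trials, self.trial_length)

    def __str__(self) -> str:
        return f"{{{self.n_points}, {self.n_trials}, {self.trial_length:g}}}"


def recording_time(pattern: Pattern) -> float:
    """Total recording time in seconds: #points x trial length x #trials."""
    return pattern.n_points * pattern.trial_length * pattern.n_trials


def functional_grid(values: dict | None = None) -> list[NRParams]:
    """Cartesian product of functional parameter values as NRParams.

    Deterministic ordering: r_max-major, then c50, b, n.
    """
    v = dict(TABLE1_FUNCTIONAL if values is None else values)
    combos = itertools.product(v["r_max"], v["c50"], v["b"], v["n"])
    return [NRParams(r_max=r, c50=c, n=n, b=b) for r, c, b, n in combos]


def enumerate_patterns(conditions: dict | None = None) -> list[Pattern]:
    """Cartesian product of condition values, points-major then trials then length."""
    v = dict(TABLE1_CONDITIONS if conditions is None else conditions)
    for key in CONDITION_COLUMNS:
        if not v.get(key):
            raise ValueError(f"empty value list for condition {key!r}")
    return [
        Pattern(n_points=p, n_trials=t, trial_length=float(L))
        for p in v["n_points"]
        for t in v["n_trials"]
        for L in v["trial_length"]
    ]


@dataclass
class MonteCarloResult:
    """Raw sweep table plus metadata; one row per simulated experiment.

    Columns: the four truth parameters, the three conditions, ``scale_id``,
    ``replicate``, the three error columns, ``recording_time_s`` and
    ``failed``.
    """

    table: pd.DataFrame
    meta: dict = field(default_factory=dict)

    @property
    def n_failed(self) -> int:
        return int(self.table["failed"].sum())

    def pattern_errors(
        self, scale_id: int | None = None, error: str = "err_rms_points"
    ) -> pd.DataFrame:
        """Mean error and recording time per pattern (optionally one scale)."""
        df = self.table[~self.table["failed"]]
        if scale_id is not None:
            df = df[df["scale_id"] == scale_id]
        g = df.groupby(list(CONDITION_COLUMNS), as_index=False).agg(
            error=(error, "mean"), recording_time_s=("recording_time_s", "first")
        )
        return g

    def aggregate(self, by: list[str]) -> pd.DataFrame:
        """Mean and SEM of each error over the given grouping columns."""
        df = self.table[~self.table["failed"]]
        out = df.groupby(by)[list(ERROR_COLUMNS)].agg(["mean", "sem"])
        out.columns = ["_".join(col) for col in out.columns]
        return out.reset_index()


def run_monte_carlo(
    functional: list[NRParams] | None = None,
    patterns: list[Pattern] | None = None,
    scales=range(1, 11),
    n_replicates: int = 1,
    seed: int | None = None,
    n_restarts: int = 10,
    noiseless: bool = False,
) -> MonteCarloResult:
    """Sweep every (functional combo, pattern, scale, replicate) cell.

    Each cell simulates per-trial Poisson counts at the scale's contrasts,
    averages them to a CRF, refits with data-driven bounds, and scores the
    three errors against the generating truth.  ``noiseless=True`` replaces
    the Poisson draw by the exact rates (zero-noise limit).  Fit failures are
    recorded as flagged rows; the sweep never aborts.  Fully deterministic
    under a fixed seed.
    """
    if functional is None:
        functional = functional_grid()
    if patterns is None:
        patterns = enumerate_patterns()
    scales = list(scales)
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")

    root = np.random.SeedSequence(seed)
    n_cells = len(functional) * len(patterns) * len(scales) * n_replicates
    children = iter(root.spawn(n_cells))

    scale_cache: dict[tuple[int, int], np.ndarray] = {}
    rows: list[dict] = []
    for truth in functional:
        for pat in patterns:
            T = pat.trial_length
            for sid in scales:
                key = (sid, pat.n_points)
                if key not in scale_cache:
                    scale_cache[key] = generate_scale(sid, pat.n_points)
                contrasts = scale_cache[key]
                for rep in range(n_replicates):
                    rng = np.random.default_rng(next(children))
                    if noiseless:
                        y = np.atleast_1d(evaluate_nre(truth, contrasts))
                        sd = np.zeros_like(y)
                    else:
                        counts = simulate_counts(truth, contrasts, T, pat.n_trials, rng)
                        y, sd = rates_from_counts(counts, T)
                    row = {
                        **truth.to_dict(),
                        "n_points": pat.n_points,
                        "n_trials": pat.n_trials,
                        "trial_length": T,
                        "scale_id": sid,
                        "replicate": rep,
                        "recording_time_s": recording_time(pat),
                    }
                    try:
                        points = CRFPoints(contrasts, y, sd)
                        res = fit_crf(
                            points, derive_bounds(points), n_restarts=n_restarts, seed=rng
                        )
                        row.update(error_triple(res.params, truth, contrasts).as_dict())
                        row["failed"] = False
                    except Exception:
                        row.update(dict.fromkeys(ERROR_COLUMNS, np.nan))
                        row["failed"] = True
                    rows.append(row)
    table = pd.DataFrame(rows)
    meta = {
        "seed": seed,
        "n_replicates": n_replicates,
        "n_functional": len(functional),
        "n_patterns": len(patterns),
        "scales": scales,
        "n_restarts": n_restarts,
        "noiseless": noiseless,
    }
    return MonteCarloResult(table=table, meta=meta)


def condition_profiles(
    mc: MonteCarloResult,
    condition: str,
    defaults: dict | None = None,
) -> pd.DataFrame:
    """Marginal error profile of one condition, others fixed at declared defaults.

    Accepts the column names (``n_points``/``n_trials``/``trial_length``) or the
    aliases ``points``/``repetitions``/``length``.  Returns mean and SEM of each
    error per (scale_id, condition value).
    """
    aliases = {"points": "n_points", "repetitions": "n_trials", "length": "trial_length"}
    condition = aliases.get(condition, condition)
    if condition not in CONDITION_COLUMNS:
        raise ValueError(f"unknown condition {condition!r}")
    defaults = dict(PROFILE_DEFAULTS if defaults is None else defaults)
    others = [c for c in CONDITION_COLUMNS if c != condition]
    df = mc.table[~mc.table["failed"]]
    for o in others:
        df = df[df[o] == defaults[o]]
    if df[condition].nunique() < 1:
        raise ValueError(
            f"sweep contains no rows at the default values of {others}; "
            f"cannot profile {condition}"
        )
    out = df.groupby(["scale_id", condition])[list(ERROR_COLUMNS)].agg(["mean", "sem"])
    out.columns = ["_".join(col) for col in out.columns]
    return out.reset_index()


@dataclass(frozen=True)
class TradeoffPoint:
    """The pattern at which normalized error first meets normalized log time."""

    index: int  # position in the error-sorted sequence (0-based)
    pattern: Pattern | None
    time_s: float
    error: float
    crossed: bool  # False when the curves never genuinely cross


def _minmax(x: np.ndarray) -> np.ndarray:
    span = x.max() - x.min()
    if span == 0:
        return np.zeros_like(x)
    return (x - x.min()) / span


def find_tradeoff_point(
    errors,
    times,
    patterns: list[Pattern] | None = None,
    sort: str = "error",
) -> TradeoffPoint:
    """Locate the fit-performance vs recording-time trade-off point.

    Patterns are sorted by error ascending (or by time descending with
    ``sort="time_desc"``); recording times are log10-transformed; both curves
    are min-max normalized to [0, 1]; the crossing is the first index at which
    the normalized error meets or exceeds the normalized time.  If the curves
    never cross (or either curve is flat), the boundary index is returned with
    ``crossed=False``.
    """
    errors = np.asarray(errors, dtype=float)
    times = np.asarray(times, dtype=float)
    if errors.size != times.size or errors.size < 2:
        raise ValueError("need >= 2 aligned error/time values")
    if sort == "error":
        order = np.argsort(errors, kind="stable")
    elif sort == "time_desc":
        order = np.argsort(-times, kind="stable")
    else:
        raise ValueError("sort must be 'error' or 'time_desc'")
    e = _minmax(errors[order])
    t = _minmax(np.log10(times[order]))
    degenerate = np.ptp(errors[order]) == 0 or np.ptp(times[order]) == 0
    hits = np.nonzero(e >= t)[0]
    if hits.size and not degenerate:
        idx, crossed = int(hits[0]), True
    else:
        idx, crossed = int(hits[0]) if hits.size else errors.size - 1, False
    src = int(order[idx])
    return TradeoffPoint(
        index=idx,
        pattern=patterns[src] if patterns is not None else None,
        time_s=float(times[src]),
        error=float(errors[src]),
        crossed=crossed,
    )
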