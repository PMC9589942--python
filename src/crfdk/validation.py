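"""Ground-truth subsampling validation of condition patterns on rich recordings.

Given a recording dense in contrasts, trials and time (the reference protocol:
24 contrasts x 50 trials x 4 s), a per-unit "theoretical" CRF is fitted from
the complete data at the preferred direction.  Candidate patterns are then
scored by repeatedly subsampling the recording down to the pattern's
conditions (contrasts chosen by a scale and snapped to the measured list,
trials drawn without replacement, spikes truncated to the first
``trial_length`` seconds), refitting, and measuring the three errors against
the per-unit reference.  Patterns are ranked per unit, the ten smallest-error
patterns kept, and consensus patterns extracted across units, scales and
error kinds.  A growing-window analysis quantifies how the fit stabilizes as
more of each trial is used.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .design import Pattern, recording_time
from .metrics import (
    ANGLE_REFERENCE,
    ErrorTriple,
    error_triple,
    mean_theoretical_rate,
    percent_variation,
)
from .model import (
    CRFPoints,
    NakaRushtonResults,
    NRParams,
    derive_bounds,
    fit_crf,
)
from .scales import generate_scale, map_to_available
from .simulate import SPIKE_TABLE_COLUMNS

__all__ = [
    "GroundTruthRecording",
    "GroundTruth",
    "PatternScore",
    "ConsensusReport",
    "InfeasiblePatternError",
    "unit_inclusion_filter",
    "build_ground_truth",
    "subsample_pattern_errors",
    "rank_patterns",
    "consensus_patterns",
    "dynamic_window_errors",
    "recordings_from_table",
    "INCLUSION_THRESHOLD_HZ",
]

#: units firing below this rate at maximal contrast are excluded
INCLUSION_THRESHOLD_HZ = 3.0

ERROR_KINDS = ("rms_points", "rms_allpoints", "angle")
_KIND_COLUMNS = {
    "rms_points": "err_rms_points",
    "rms_allpoints": "err_rms_allpoints",
    "angle": "err_angle_rad",
}


class InfeasiblePatternError(ValueError):
    """A pattern asks for more than the recording holds; names the dimension."""

    def __init__(self, dimension: str, requested, available):
        self.dimension = dimension
        super().__init__(
            f"pattern infeasible in {dimension}: requested {requested}, "
            f"recording has {available}"
        )


@dataclass
class GroundTruthRecording:
    """Spike times of one unit organised by direction x contrast x trial.

    ``trains[di][ci][ti]`` is the sorted spike-time array for direction
    ``directions[di]``, contrast ``contrasts[ci]``, trial ``ti``.
    """

    unit_id: int | str
    directions: np.ndarray
    contrasts: np.ndarray
    n_trials: int
    trial_length: float
    trains: list  # list[list[list[np.ndarray]]]

    def __post_init__(self) -> None:
        self.directions = np.asarray(self.directions, dtype=float)
        self.contrasts = np.asarray(self.contrasts, dtype=float)
        if np.any(np.diff(self.contrasts) <= 0):
            raise ValueError("contrasts must be sorted strictly increasing")

    def direction_index(self, direction: float | None) -> int:
        if direction is None:
            return self.preferred_direction_index()
        matches = np.nonzero(np.isclose(self.directions, direction))[0]
        if matches.size == 0:
            raise ValueError(f"direction {direction} not in recording")
        return int(matches[0])

    def counts(self, direction: float | None = None, window: float | None = None) -> np.ndarray:
        """Spike counts in [0, window) per (contrast, trial) at one direction."""
        w = self.trial_length if window is None else float(window)
        if w <= 0 or w > self.trial_length + 1e-12:
            raise ValueError("window must lie in (0, trial_length]")
        di = self.direction_index(direction)
        out = np.empty((self.contrasts.size, self.n_trials), dtype=np.int64)
        for ci in range(self.contrasts.size):
            for ti in range(self.n_trials):
                out[ci, ti] = int(np.searchsorted(self.trains[di][ci][ti], w))
        return out

    def mean_rate_at_max_contrast(self, direction: float | None = None) -> float:
        """Mean rate at the maximal contrast; max over directions when None."""
        if direction is None:
            return max(
                float(self.counts(d)[-1].mean()) / self.trial_length
                for d in self.directions
            )
        return float(self.counts(direction)[-1].mean()) / self.trial_length

    def preferred_direction_index(self) -> int:
        """Direction maximizing the mean rate at maximal contrast (ties -> lowest index)."""
        rates = [
            self.counts(d)[-1].mean() / self.trial_length for d in self.directions
        ]
        return int(np.argmax(rates))

    @property
    def preferred_direction(self) -> float:
        return float(self.directions[self.preferred_direction_index()])

    def crf_points(
        self,
        direction: float | None = None,
        window: float | None = None,
        contrast_idx: np.ndarray | None = None,
        trial_idx: np.ndarray | None = None,
    ) -> CRFPoints:
        """Averaged CRF data from (a subset of) the recording."""
        w = self.trial_length if window is None else float(window)
        counts = self.counts(direction, w)
        if contrast_idx is not None:
            counts = counts[contrast_idx]
            contrasts = self.contrasts[contrast_idx]
        else:
            contrasts = self.contrasts
        if trial_idx is not None:
            counts = counts[:, trial_idx]
        rates = counts / w
        sd = rates.std(axis=1, ddof=1) if counts.shape[1] > 1 else np.zeros(len(contrasts))
        return CRFPoints(contrasts, rates.mean(axis=1), sd)

    def to_table(self) -> pd.DataFrame:
        rows = {k: [] for k in SPIKE_TABLE_COLUMNS}
        for di, d in enumerate(self.directions):
            for ci, c in enumerate(self.contrasts):
                for ti in range(self.n_trials):
                    times = self.trains[di][ci][ti]
                    rows["unit_id"].extend([self.unit_id] * times.size)
                    rows["direction_deg"].extend([float(d)] * times.size)
                    rows["contrast_pct"].extend([float(c)] * times.size)
                    rows["trial_idx"].extend([ti] * times.size)
                    rows["spike_time_s"].extend(times.tolist())
        return pd.DataFrame(rows)


def recordings_from_table(
    df: pd.DataFrame,
    trial_length: float,
    n_trials: int | None = None,
    contrasts: Sequence[float] | None = None,
    directions: Sequence[float] | None = None,
) -> list[GroundTruthRecording]:
    """Rebuild per-unit recordings from a flat spike table.

    Silent trials leave no rows, so ``n_trials`` (and ideally the contrast and
    direction lists) should be given explicitly; otherwise they are inferred
    from the table.
    """
    missing = [c for c in SPIKE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"spike table is missing columns: {missing}")
    if n_trials is None:
        n_trials = int(df["trial_idx"].max()) + 1 if len(df) else 1
    out = []
    for unit_id, unit_df in df.groupby("unit_id"):
        dirs = np.sort(unit_df["direction_deg"].unique()) if directions is None else np.asarray(directions, dtype=float)
        cons = np.sort(unit_df["contrast_pct"].unique()) if contrasts is None else np.asarray(contrasts, dtype=float)
        di_map = {float(d): i for i, d in enumerate(dirs)}
        ci_map = {float(c): i for i, c in enumerate(cons)}
        trains = [
            [[np.array([], dtype=float) for _ in range(n_trials)] for _ in cons]
            for _ in dirs
        ]
        for (d, c, t), grp in unit_df.groupby(["direction_deg", "contrast_pct", "trial_idx"]):
            trains[di_map[float(d)]][ci_map[float(c)]][int(t)] = np.sort(
                grp["spike_time_s"].to_numpy(dtype=float)
            )
        out.append(
            GroundTruthRecording(
                unit_id=unit_id,
                directions=dirs,
                contrasts=cons,
                n_trials=n_trials,
                trial_length=trial_length,
                trains=trains,
            )
        )
    return out


def unit_inclusion_filter(
    recording: GroundTruthRecording, threshold: float = INCLUSION_THRESHOLD_HZ
) -> bool:
    """True when the unit fires at least ``threshold`` spikes/s at maximal contrast.

    The rate is taken at the best (preferred) direction; the boundary is
    inclusive (a unit at exactly 3 spikes/s stays in).
    """
    return recording.mean_rate_at_max_contrast() >= threshold


@dataclass
class GroundTruth:
    """A unit's reference ("theoretical") CRF fitted from its complete recording."""

    unit_id: int | str
    direction: float
    params: NRParams
    points: CRFPoints
    fit: NakaRushtonResults


def build_ground_truth(
    recording: GroundTruthRecording,
    n_restarts: int = 500,
    seed: int | np.random.Generator | None = None,
) -> GroundTruth:
    """Fit the reference CRF from all contrasts, trials and time at the preferred direction."""
    di = recording.preferred_direction_index()
    direction = float(recording.directions[di])
    points = recording.crf_points(direction=direction)
    res = fit_crf(points, derive_bounds(points), n_restarts=n_restarts, seed=seed)
    return GroundTruth(
        unit_id=recording.unit_id,
        direction=direction,
        params=res.params,
        points=points,
        fit=res,
    )


@dataclass
class PatternScore:
    """Subsampling errors of one pattern x scale on one unit."""

    pattern: Pattern
    scale_id: int | None
    unit_id: int | str
    errors: pd.DataFrame  # one row per iteration, ERROR columns
    n_iterations: int
    n_failed: int = 0

    @property
    def mean(self) -> ErrorTriple:
        m = self.errors.mean()
        return ErrorTriple(
            m["err_rms_points"], m["err_rms_allpoints"], m["err_angle_rad"]
        )

    @property
    def sd(self) -> pd.Series:
        return self.errors.std(ddof=1)

    def mean_error(self, kind: str) -> float:
        return float(self.errors[_KIND_COLUMNS[kind]].mean())


def subsample_pattern_errors(
    recording: GroundTruthRecording,
    truth: NRParams,
    pattern: Pattern,
    scale_id: int | None,
    n_iterations: int = 100,
    seed: int | np.random.Generator | None = None,
    direction: float | None = None,
    n_restarts: int = 25,
) -> PatternScore:
    """Score one pattern by random subsampling from the ground-truth recording.

    Per iteration: the pattern's contrasts are the scale's points snapped to
    the measured list (``scale_id=None`` uses the recording's own contrasts,
    requiring ``n_points`` to equal their number); trials are sampled
    uniformly without replacement; spikes are truncated to the first
    ``trial_length`` seconds from stimulus onset; the CRF is refitted and all
    three errors against ``truth`` recorded.
    """
    if pattern.n_points > recording.contrasts.size:
        raise InfeasiblePatternError("n_points", pattern.n_points, recording.contrasts.size)
    if pattern.n_trials > recording.n_trials:
        raise InfeasiblePatternError("n_trials", pattern.n_trials, recording.n_trials)
    if pattern.trial_length > recording.trial_length + 1e-12:
        raise InfeasiblePatternError(
            "trial_length", pattern.trial_length, recording.trial_length
        )
    if scale_id is None:
        if pattern.n_points != recording.contrasts.size:
            raise ValueError(
                "identity mapping needs n_points == number of measured contrasts"
            )
        mapped = recording.contrasts
    else:
        mapped = map_to_available(
            generate_scale(scale_id, pattern.n_points), recording.contrasts
        )
    ci = np.searchsorted(recording.contrasts, mapped)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    counts = recording.counts(direction, window=pattern.trial_length)[ci]
    L = pattern.trial_length

    rows, n_failed = [], 0
    for _ in range(n_iterations):
        tsel = rng.choice(recording.n_trials, size=pattern.n_trials, replace=False)
        sub = counts[:, tsel]
        rates = sub / L
        y = rates.mean(axis=1)
        sd = rates.std(axis=1, ddof=1) if sub.shape[1] > 1 else np.zeros(y.size)
        try:
            points = CRFPoints(mapped, y, sd)
            res = fit_crf(points, derive_bounds(points), n_restarts=n_restarts, seed=rng)
            rows.append(error_triple(res.params, truth, mapped).as_dict())
        except Exception:
            n_failed += 1
    return PatternScore(
        pattern=pattern,
        scale_id=scale_id,
        unit_id=recording.unit_id,
        errors=pd.DataFrame(rows),
        n_iterations=n_iterations,
        n_failed=n_failed,
    )


def rank_patterns(
    scores: Iterable[PatternScore], error_kind: str = "rms_points", n_best: int = 10
) -> tuple[pd.DataFrame, list[Pattern]]:
    """Rank patterns from largest to smallest mean error; extract the minimizers.

    Ties are broken toward the shorter recording time.  Returns the full
    ranking table (worst first) and the ``n_best`` patterns with the smallest
    errors.
    """
    scores = list(scores)
    if error_kind not in _KIND_COLUMNS:
        raise ValueError(f"unknown error kind {error_kind!r}")
    df = pd.DataFrame(
        {
            "pattern": [s.pattern for s in scores],
            "scale_id": [s.scale_id for s in scores],
            "mean_error": [s.mean_error(error_kind) for s in scores],
            "recording_time_s": [recording_time(s.pattern) for s in scores],
        }
    )
    df = df.sort_values(
        ["mean_error", "recording_time_s"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    # bottom of the worst-first ranking = smallest errors; among ties prefer
    # the shorter recording time
    best = df.sort_values(
        ["mean_error", "recording_time_s"], ascending=[True, True], kind="stable"
    ).head(n_best)
    return df, list(best["pattern"])


@dataclass
class ConsensusReport:
    """Patterns recurring among the per-unit best lists, per error kind."""

    counts: dict  # error_kind -> {Pattern: occurrences}
    tier1: list  # [(Pattern, total occurrences)] present in all three error kinds
    tier2: list  # [(Pattern, total occurrences)] present in exactly two

    def to_dict(self) -> dict:
        def ser(items):
            return [
                {"pattern": list(p.as_tuple()), "count": int(c),
                 "recording_time_s": recording_time(p)}
                for p, c in items
            ]

        return {
            "tier1": ser(self.tier1),
            "tier2": ser(self.tier2),
            "counts": {
                kind: ser(sorted(d.items(), key=lambda kv: (-kv[1], recording_time(kv[0]))))
                for kind, d in self.counts.items()
            },
        }


def consensus_patterns(best_lists: Mapping[str, Iterable[Iterable[Pattern]]]) -> ConsensusReport:
    """Cross-error consensus from per-unit/per-scale best-pattern lists.

    ``best_lists`` maps each error kind to the collection of best-10 lists
    (one list per unit x scale).  Tier 1 patterns appear in the lists of all
    three error kinds, ordered by total occurrence count (ties -> shorter
    recording time); tier 2 patterns appear in exactly two.
    """
    counts: dict[str, dict[Pattern, int]] = {}
    for kind, lists in best_lists.items():
        d: dict[Pattern, int] = {}
        for lst in lists:
            for p in lst:
                d[p] = d.get(p, 0) + 1
        counts[kind] = d
    kinds = list(counts)
    all_patterns = set().union(*(d.keys() for d in counts.values())) if counts else set()

    def total(p: Pattern) -> int:
        return sum(d.get(p, 0) for d in counts.values())

    def order(ps):
        return sorted(ps, key=lambda p: (-total(p), recording_time(p), p.as_tuple()))

    tier1 = [p for p in all_patterns if all(p in counts[k] for k in kinds)]
    tier2 = [
        p
        for p in all_patterns
        if sum(p in counts[k] for k in kinds) == max(len(kinds) - 1, 1)
        and p not in tier1
    ]
    return ConsensusReport(
        counts=counts,
        tier1=[(p, total(p)) for p in order(tier1)],
        tier2=[(p, total(p)) for p in order(tier2)],
    )


def dynamic_window_errors(
    recordings: GroundTruthRecording | Sequence[GroundTruthRecording],
    truths: NRParams | Sequence[NRParams],
    window_grid: Sequence[float],
    n_bootstrap: int = 1000,
    seed: int | np.random.Generator | None = None,
    n_restarts: int = 25,
    ci_level: float = 0.95,
) -> pd.DataFrame:
    """Percent error variation as the analysis window grows from stimulus onset.

    For each window ``w`` the CRF is refitted from spikes in ``[0, w)`` at the
    preferred direction and the three errors against the unit's reference are
    expressed as percentages (RMS errors relative to the mean reference rate,
    the angle relative to pi/2).  The cohort mean and a bootstrap confidence
    interval (resampling units with replacement) are returned per window and
    metric; with a single unit the interval collapses to the point estimate.
    """
    if isinstance(recordings, GroundTruthRecording):
        recordings = [recordings]
        truths = [truths]
    truths = list(truths)
    if len(truths) != len(recordings):
        raise ValueError("one truth per recording is required")
    windows = np.asarray(window_grid, dtype=float)
    for rec in recordings:
        if np.any(windows <= 0) or np.any(windows > rec.trial_length + 1e-12):
            raise ValueError("window grid must lie within (0, trial_length]")

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_units = len(recordings)
    pct = np.full((n_units, windows.size, 3), np.nan)
    for ui, (rec, truth) in enumerate(zip(recordings, truths)):
        ref_rate = mean_theoretical_rate(truth)
        di = rec.preferred_direction_index()
        direction = float(rec.directions[di])
        for wi, w in enumerate(windows):
            points = rec.crf_points(direction=direction, window=w)
            res = fit_crf(points, derive_bounds(points), n_restarts=n_restarts, seed=rng)
            tri = error_triple(res.params, truth, points.contrasts)
            pct[ui, wi, 0] = percent_variation(tri.rms_points, ref_rate)
            pct[ui, wi, 1] = percent_variation(tri.rms_allpoints, ref_rate)
            pct[ui, wi, 2] = percent_variation(tri.angle, ANGLE_REFERENCE)

    alpha = (1.0 - ci_level) / 2.0
    boot_idx = rng.integers(0, n_units, size=(n_bootstrap, n_units))
    boot_means = pct[boot_idx].mean(axis=1)  # (n_bootstrap, n_windows, 3)
    lo = np.quantile(boot_means, alpha, axis=0)
    hi = np.quantile(boot_means, 1.0 - alpha, axis=0)
    mean = pct.mean(axis=0)

    metric_names = ["rms_points", "rms_allpoints", "angle"]
    rows = []
    for wi, w in enumerate(windows):
        for mi, name in enumerate(metric_names):
            rows.append(
                {
                    "window_s": float(w),
                    "metric": name,
                    "pct_variation_mean": float(mean[wi, mi]),
                    "pct_variation_lo": float(lo[wi, mi]),
                    "pct_variation_hi": float(hi[wi, mi]),
                    "n_units": n_units,
                }
            )
    return pd.DataFrame(rows)
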