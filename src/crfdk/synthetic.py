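"""Synthetic cohort generator emulating a rich cat visual-cortex dataset.

Produces single-unit recordings with the reference protocol dimensions — 24
printed contrast values, 50 repetitions of 4 s trials, 12 motion directions at
30-degree steps — driven by per-unit Naka-Rushton curves through the Poisson
cascade.  Each unit gets a randomly sampled truth and preferred direction;
off-preferred directions scale the contrast-driven component by a raised
cosine tuning lobe (plumbing only: the pipeline never fits direction tuning).
Optional firing-rate adaptation multiplies the within-trial rate by
``floor + (1 - floor) * exp(-t / tau)``; it is off by default so that the
memoryless theoretical model and the fixture agree.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .design import TABLE1_FUNCTIONAL
from .model import NRParams, evaluate_nre
from .simulate import draw_trial_spikes
from .validation import GroundTruthRecording

__all__ = [
    "CAT_CONTRASTS",
    "AdaptationSpec",
    "CohortSpec",
    "SyntheticUnit",
    "generate_cohort",
    "cohort_to_table",
    "truths_to_json",
]

#: the 24 measured contrast percentages of the reference protocol
CAT_CONTRASTS: tuple = (
    0.0, 3.0, 6.0, 8.5, 12.0, 17.0, 21.0, 26.0, 29.0, 32.0, 35.0, 38.0,
    41.0, 44.0, 48.0, 53.0, 57.0, 63.5, 70.0, 74.5, 79.0, 83.0, 91.0, 100.0,
)


@dataclass(frozen=True)
class AdaptationSpec:
    """Exponential firing-rate adaptation: rate x (floor + (1-floor) e^(-t/tau))."""

    tau: float
    floor: float

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if not 0.0 <= self.floor <= 1.0:
            raise ValueError("floor must lie in [0, 1]")

    def profile(self, t: np.ndarray) -> np.ndarray:
        return self.floor + (1.0 - self.floor) * np.exp(-t / self.tau)


@dataclass
class CohortSpec:
    """Study design of a synthetic cohort; defaults mirror the reference protocol."""

    n_units: int = 42
    contrasts: tuple = CAT_CONTRASTS
    n_trials: int = 50
    trial_length: float = 4.0
    directions: tuple = tuple(float(d) for d in range(0, 360, 30))
    r_max_values: tuple = TABLE1_FUNCTIONAL["r_max"]
    c50_values: tuple = TABLE1_FUNCTIONAL["c50"]
    n_values: tuple = TABLE1_FUNCTIONAL["n"]
    b_values: tuple = TABLE1_FUNCTIONAL["b"]
    adaptation: AdaptationSpec | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_units < 1 or self.n_trials < 1 or self.trial_length <= 0:
            raise ValueError("cohort dimensions must be positive")

    def to_json(self, path=None) -> str:
        d = asdict(self)
        s = json.dumps(d, indent=2)
        if path is not None:
            Path(path).write_text(s)
        return s

    @classmethod
    def from_json(cls, source) -> "CohortSpec":
        if isinstance(source, Path) or (
            isinstance(source, str) and not source.lstrip().startswith("{")
        ):
            d = json.loads(Path(source).read_text())
        else:
            d = json.loads(source)
        if d.get("adaptation") is not None:
            d["adaptation"] = AdaptationSpec(**d["adaptation"])
        for key in ("contrasts", "directions", "r_max_values", "c50_values",
                    "n_values", "b_values"):
            d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class SyntheticUnit:
    recording: GroundTruthRecording
    truth: NRParams
    preferred_direction: float


def _tuning_gain(delta_deg: float) -> float:
    """Raised-cosine direction tuning lobe, 1 at preferred, squared for width."""
    return float((0.5 * (1.0 + np.cos(np.radians(delta_deg)))) ** 2)


def sample_truth(spec: CohortSpec, rng: np.random.Generator) -> NRParams:
    """Draw one unit's Naka-Rushton truth uniformly from the spec's value lists."""
    return NRParams(
        r_max=float(rng.choice(spec.r_max_values)),
        c50=float(rng.choice(spec.c50_values)),
        n=float(rng.choice(spec.n_values)),
        b=float(rng.choice(spec.b_values)),
    )


def generate_cohort(spec: CohortSpec) -> list[SyntheticUnit]:
    """Generate the synthetic cohort; fully deterministic under spec.seed.

    Per unit the truth is sampled from the spec's parameter lists and a
    preferred direction is drawn; the contrast-driven component (rate above
    baseline) at other directions is scaled by the raised-cosine lobe, the
    spontaneous baseline being direction-independent.  Spikes come from the
    Poisson cascade, optionally thinned by the adaptation profile.
    """
    root = np.random.SeedSequence(spec.seed)
    unit_seqs = root.spawn(spec.n_units)
    contrasts = np.asarray(spec.contrasts, dtype=float)
    directions = np.asarray(spec.directions, dtype=float)
    profile = spec.adaptation.profile if spec.adaptation is not None else None

    units = []
    for ui, seq in enumerate(unit_seqs):
        rng = np.random.default_rng(seq)
        truth = sample_truth(spec, rng)
        pref = float(rng.choice(directions))
        driven = np.atleast_1d(evaluate_nre(truth, contrasts)) - truth.b
        trains = []
        for d in directions:
            gain = _tuning_gain(d - pref)
            rates = truth.b + gain * driven
            trains.append(
                [
                    [
                        draw_trial_spikes(rate, spec.trial_length, rng, profile)
                        for _ in range(spec.n_trials)
                    ]
                    for rate in rates
                ]
            )
        rec = GroundTruthRecording(
            unit_id=ui,
            directions=directions,
            contrasts=contrasts,
            n_trials=spec.n_trials,
            trial_length=spec.trial_length,
            trains=trains,
        )
        units.append(SyntheticUnit(recording=rec, truth=truth, preferred_direction=pref))
    return units


def cohort_to_table(units: list[SyntheticUnit]) -> pd.DataFrame:
    """Flat spike table for a whole cohort (one row per spike)."""
    return pd.concat([u.recording.to_table() for u in units], ignore_index=True)


def truths_to_json(units: list[SyntheticUnit], path=None) -> str:
    """Sidecar JSON mapping unit id to its generating truth and preferred direction."""
    d = {
        str(u.recording.unit_id): {
            **u.truth.to_dict(),
            "preferred_direction_deg": u.preferred_direction,
        }
        for u in units
    }
    s = json.dumps(d, indent=2)
    if path is not None:
        Path(path).write_text(s)
    return s
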