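"""Nonlinear-Poisson cascade: Naka-Rushton drive to inhomogeneous Poisson spikes.

The simulated neuron has no temporal receptive-field stage: within a trial at
contrast ``c`` the rate is constant at ``r(c)`` from the Naka-Rushton curve,
and spikes form a homogeneous Poisson process in the trial window.  Because
the rate changes across randomly ordered stimuli, the overall process is
inhomogeneous.  Spike trains are drawn with the order-statistics construction
(Poisson count, then sorted uniform times); an optional rate profile in
``[0, 1]`` (used for firing-rate adaptation) is applied by thinning.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .model import CRFPoints, NRParams, evaluate_nre

__all__ = [
    "StimulusProtocol",
    "SpikeTrainSet",
    "simulate_experiment",
    "simulate_counts",
    "mean_firing_rates",
    "psth",
    "draw_trial_spikes",
]

SPIKE_TABLE_COLUMNS = ["unit_id", "direction_deg", "contrast_pct", "trial_idx", "spike_time_s"]


@dataclass(frozen=True)
class StimulusProtocol:
    """Contrast presentation protocol: which contrasts, how long, how often."""

    contrasts: tuple
    trial_length: float
    n_repetitions: int
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.trial_length <= 0:
            raise ValueError("trial_length must be positive")
        if self.n_repetitions < 1:
            raise ValueError("n_repetitions must be >= 1")
        if len(self.contrasts) == 0:
            raise ValueError("at least one contrast is required")

    @property
    def total_time(self) -> float:
        return len(self.contrasts) * self.trial_length * self.n_repetitions

    def presentation_order(self, rng: np.random.Generator) -> list[tuple[float, int]]:
        """Randomized (contrast, repetition) presentation sequence.

        Stored with the simulation output for provenance; the memoryless model
        itself is insensitive to presentation order.
        """
        pairs = [(float(c), r) for c in self.contrasts for r in range(self.n_repetitions)]
        idx = rng.permutation(len(pairs))
        return [pairs[i] for i in idx]


@dataclass
class SpikeTrainSet:
    """Spike times organised by contrast x repetition.

    ``trains[ci][rep]`` is the sorted array of spike times (s, within
    ``[0, trial_length)``) for the trial at ``contrasts[ci]``, repetition
    ``rep``.
    """

    contrasts: np.ndarray
    trial_length: float
    n_repetitions: int
    trains: list  # list[list[np.ndarray]]
    provenance: dict = field(default_factory=dict)

    def counts(self, window: float | None = None) -> np.ndarray:
        """Spike counts in [0, window) as an (n_contrasts, n_repetitions) array."""
        w = self.trial_length if window is None else float(window)
        if w <= 0 or w > self.trial_length + 1e-12:
            raise ValueError("window must lie in (0, trial_length]")
        out = np.empty((len(self.contrasts), self.n_repetitions), dtype=np.int64)
        for ci, reps in enumerate(self.trains):
            for ri, times in enumerate(reps):
                out[ci, ri] = int(np.searchsorted(times, w, side="left"))
        return out

    def total_spikes(self) -> int:
        return int(sum(t.size for reps in self.trains for t in reps))

    def to_table(self, unit_id=0, direction_deg: float = 0.0) -> pd.DataFrame:
        """Flat spike-table with one row per spike (empty trials contribute no rows)."""
        rows = {k: [] for k in SPIKE_TABLE_COLUMNS}
        for ci, reps in enumerate(self.trains):
            c = float(self.contrasts[ci])
            for ri, times in enumerate(reps):
                rows["unit_id"].extend([unit_id] * times.size)
                rows["direction_deg"].extend([direction_deg] * times.size)
                rows["contrast_pct"].extend([c] * times.size)
                rows["trial_idx"].extend([ri] * times.size)
                rows["spike_time_s"].extend(times.tolist())
        return pd.DataFrame(rows)

    @classmethod
    def from_table(
        cls,
        df: pd.DataFrame,
        trial_length: float,
        n_repetitions: int | None = None,
        contrasts: Sequence[float] | None = None,
    ) -> "SpikeTrainSet":
        """Rebuild from a spike table.  Trial count and contrast list can be
        given explicitly (recommended: silent trials leave no rows)."""
        if n_repetitions is None:
            n_repetitions = int(df["trial_idx"].max()) + 1 if len(df) else 1
        if contrasts is None:
            contrasts = np.sort(df["contrast_pct"].unique())
        contrasts = np.asarray(contrasts, dtype=float)
        trains = [
            [np.array([], dtype=float) for _ in range(n_repetitions)]
            for _ in contrasts
        ]
        cidx = {float(c): i for i, c in enumerate(contrasts)}
        for (c, r), grp in df.groupby(["contrast_pct", "trial_idx"]):
            trains[cidx[float(c)]][int(r)] = np.sort(grp["spike_time_s"].to_numpy(dtype=float))
        return cls(contrasts, float(trial_length), int(n_repetitions), trains)


def draw_trial_spikes(
    rate: float,
    trial_length: float,
    rng: np.random.Generator,
    rate_profile: Callable[[np.ndarray], np.ndarray] | None = None,
) -> np.ndarray:
    """One trial of Poisson spiking at constant ``rate`` (spikes/s).

    ``rate_profile`` maps times to a multiplier in [0, 1]; spikes are thinned
    by it (the peak rate stays ``rate``).
    """
    count = rng.poisson(rate * trial_length)
    times = np.sort(rng.uniform(0.0, trial_length, size=count))
    if rate_profile is not None and times.size:
        keep = rng.uniform(size=times.size) < rate_profile(times)
        times = times[keep]
    return times


def simulate_experiment(
    truth: NRParams,
    protocol: StimulusProtocol,
    seed: int | np.random.Generator | None = None,
    rate_profile: Callable[[np.ndarray], np.ndarray] | None = None,
) -> SpikeTrainSet:
    """Simulate a full contrast experiment for one model neuron.

    For each trial at contrast ``c`` spikes are drawn from a Poisson process
    with constant rate ``r(c)``; the randomized presentation order is stored
    for provenance.  Fully reproducible under a fixed seed.
    """
    if isinstance(seed, np.random.Generator):
        rng = seed
    else:
        rng = np.random.default_rng(protocol.seed if seed is None else seed)
    contrasts = np.asarray(protocol.contrasts, dtype=float)
    rates = np.atleast_1d(evaluate_nre(truth, contrasts))
    order = protocol.presentation_order(rng)
    trains = []
    for rate in rates:
        trains.append(
            [
                draw_trial_spikes(rate, protocol.trial_length, rng, rate_profile)
                for _ in range(protocol.n_repetitions)
            ]
        )
    return SpikeTrainSet(
        contrasts=contrasts,
        trial_length=protocol.trial_length,
        n_repetitions=protocol.n_repetitions,
        trains=trains,
        provenance={"truth": truth.to_dict(), "order": order},
    )


def simulate_counts(
    truth: NRParams,
    contrasts,
    trial_length: float,
    n_repetitions: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-trial spike counts only, shape (n_contrasts, n_repetitions).

    The count in a trial at contrast c is Poisson(r(c) * T) — the sufficient
    statistic for rate estimation; used by the design sweeps where individual
    spike times are never needed.
    """
    rates = np.atleast_1d(evaluate_nre(truth, np.asarray(contrasts, dtype=float)))
    lam = rates[:, None] * trial_length
    return rng.poisson(np.broadcast_to(lam, (rates.size, n_repetitions)))


def rates_from_counts(counts: np.ndarray, window: float) -> tuple[np.ndarray, np.ndarray]:
    """Mean rate and across-trial SD of per-trial rates from a count matrix."""
    rates = counts / window
    mean = rates.mean(axis=1)
    sd = rates.std(axis=1, ddof=1) if counts.shape[1] > 1 else np.zeros(counts.shape[0])
    return mean, sd


def mean_firing_rates(spikes: SpikeTrainSet, window: float | None = None) -> CRFPoints:
    """Average firing rate per contrast over the first ``window`` seconds.

    rate(c) = total spikes in [0, window) / (window * n_repetitions); the SD
    of the per-trial rates is recorded alongside.
    """
    w = spikes.trial_length if window is None else float(window)
    if w <= 0:
        raise ValueError("window must be positive")
    counts = spikes.counts(window=w)
    mean, sd = rates_from_counts(counts, w)
    return CRFPoints(spikes.contrasts, mean, sd)


def psth(spikes: SpikeTrainSet, bin_width: float = 0.05) -> pd.DataFrame:
    """Peri-stimulus time histogram per contrast, in spikes/s.

    Returns a DataFrame indexed by bin centre (s) with one column per
    contrast; counts are averaged over repetitions and scaled by the bin
    width.  The bin width must divide the trial length to within 1%.
    """
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    T = spikes.trial_length
    n_bins = int(round(T / bin_width))
    if n_bins < 1 or abs(n_bins * bin_width - T) > 0.01 * T:
        raise ValueError(f"bin width {bin_width} does not divide trial length {T}")
    edges = np.linspace(0.0, T, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    data = {}
    for ci, reps in enumerate(spikes.trains):
        allspikes = np.concatenate(reps) if reps else np.array([])
        hist, _ = np.histogram(allspikes, bins=edges)
        data[float(spikes.contrasts[ci])] = hist / (spikes.n_repetitions * bin_width)
    return pd.DataFrame(data, index=pd.Index(centers, name="time_s"))
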