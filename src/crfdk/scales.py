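"""The ten contrast spacings ("scales" or metrics) used to place sample points.

A scale is a rule assigning contrast percentages to a requested number of
sample points.  Linear scales space points evenly between two fractional
bounds; logarithmic scales space them between two decades 10**a and 10**b,
and both are weighted by 100 to obtain percentages.  Every scale except
scale 6 contains an explicit point at 0% contrast (the blank), placed first;
the remaining points follow the scale's stated spacing.  Scale 6 is scale 5's
spacing without the blank, so a fit on scale-6 points must estimate the
baseline from non-zero contrasts only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ScaleSpec", "SCALES", "generate_scale", "map_to_available"]


@dataclass(frozen=True)
class ScaleSpec:
    scale_id: int
    kind: str  # "linear" | "logarithmic"
    lower: float  # decade exponent (log) or fraction of full contrast (linear)
    upper: float
    includes_zero: bool
    description: str


SCALES: dict[int, ScaleSpec] = {
    1: ScaleSpec(1, "linear", 0.0, 1.0, True, "Linearly spaced"),
    2: ScaleSpec(2, "logarithmic", -1.2, 0.0, True, "Concentrated around 0"),
    3: ScaleSpec(3, "logarithmic", -1.0, -0.15, True, "Concentrated around 0.25"),
    4: ScaleSpec(4, "logarithmic", -0.3, 0.0, True, "Concentrated around 1"),
    5: ScaleSpec(5, "logarithmic", -0.7, 0.0, True, "Concentrated around 0.75"),
    6: ScaleSpec(6, "logarithmic", -0.5, 0.0, False, "Same as 5 without 0"),
    7: ScaleSpec(7, "logarithmic", -0.5, -0.15, True, "Concentrated around 0.5"),
    8: ScaleSpec(8, "linear", 0.1, 0.9, True, "Same as 7 but linearly spaced"),
    9: ScaleSpec(9, "linear", 0.25, 0.75, True, "Same as 8 but less spread out"),
    10: ScaleSpec(10, "logarithmic", -0.7, -0.1, True, "Log-concentrated around 0.5"),
}


def generate_scale(scale_id: int, n_points: int) -> np.ndarray:
    """Contrast percentages for one scale at the requested point count.

    For scales that include the blank, the first element is exactly 0% and the
    remaining ``n_points - 1`` elements follow the scale's spacing between its
    bounds (for scale 1 the spacing itself starts at 0, so no extra point is
    prepended).  Scale 6 draws all ``n_points`` from its log spacing and has
    no 0.
    """
    if scale_id not in SCALES:
        raise ValueError(f"unknown scale_id {scale_id!r}; valid ids are 1..10")
    if n_points < 4:
        raise ValueError("n_points must be at least 4 (4-parameter fit)")
    spec = SCALES[scale_id]
    natural_zero = spec.kind == "linear" and spec.lower == 0.0
    k = n_points if (not spec.includes_zero or natural_zero) else n_points - 1
    if spec.kind == "linear":
        body = np.linspace(spec.lower, spec.upper, k)
    else:
        body = np.logspace(spec.lower, spec.upper, k)
    pts = 100.0 * body
    if spec.includes_zero and not natural_zero:
        pts = np.concatenate(([0.0], pts))
    return pts


def _nearest(value: float, available: np.ndarray) -> float:
    """Nearest available contrast; ties broken toward the lower value."""
    d = np.abs(available - value)
    best = d.min()
    # ties -> lower contrast wins; available is sorted ascending
    return float(available[np.nonzero(d == best)[0][0]])


def map_to_available(scale_contrasts, available) -> np.ndarray:
    """Snap scale contrasts onto a measured-contrast list.

    Each requested contrast is replaced by its nearest available value (ties
    broken toward the lower contrast).  Collisions are collapsed and the
    vector is re-padded with the unused available values closest to the
    requested contrasts, so the returned vector always has the requested
    length and strictly increasing unique values.
    """
    req = np.asarray(scale_contrasts, dtype=float)
    avail = np.asarray(available, dtype=float)
    if avail.size == 0:
        raise ValueError("available contrast list is empty")
    if np.any(np.diff(avail) <= 0):
        raise ValueError("available contrasts must be sorted strictly increasing")
    if req.size > avail.size:
        raise ValueError(
            f"requested {req.size} contrasts but only {avail.size} are available"
        )
    chosen: list[float] = []
    for v in req:
        m = _nearest(v, avail)
        if m not in chosen:
            chosen.append(m)
    while len(chosen) < req.size:
        unused = np.array([a for a in avail if a not in chosen])
        # pick the unused value closest to any requested contrast (tie -> lower)
        dists = np.min(np.abs(unused[:, None] - req[None, :]), axis=1)
        chosen.append(float(unused[np.nonzero(dists == dists.min())[0][0]]))
    return np.sort(np.asarray(chosen))
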