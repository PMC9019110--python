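"""Protein decay kinetics and axonal polarity morphometrics.

Cycloheximide (CHX) blocks translation, so the remaining protein fraction
decays as N(t) = N(0)·exp(−k·t); ordinary least squares on
ln(fraction) vs time (free intercept) gives the decay rate k and
half-life t½ = ln2/k.  The free intercept absorbs normalization error in
the t=0 reference; no plateau term is fitted — with complete
translational shutoff and fractions normalized to t=0 a single
exponential is the minimal model.

Steady-state protein abundance under constant synthesis is
synthesis/degradation, so the relative steady state of two isoforms is
synthesis_ratio × (t½_a / t½_b).

The axonal polarity index P = (Ia − Id)/(Ia + Id) contrasts mean axonal
(Ia) and dendritic (Id) marker intensity per cell: +1 fully axonal,
−1 fully dendritic, 0 uniform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DecayCourse",
    "DecayFit",
    "fit_decay",
    "steady_state_ratio",
    "polarity_index",
    "polarity_table",
]

LN2 = float(np.log(2.0))


@dataclass(frozen=True)
class DecayCourse:
    """A CHX-chase time course: remaining fraction, normalized to t=0."""

    label: str
    timepoints: tuple[float, ...]  # hours, strictly increasing, first = 0
    fractions: tuple[float, ...]  # fraction remaining; fractions[0] = 1

    def __post_init__(self) -> None:
        t = np.asarray(self.timepoints, dtype=float)
        f = np.asarray(self.fractions, dtype=float)
        if t.size != f.size:
            raise ValueError("timepoints and fractions must have equal length")
        if t.size == 0 or t[0] != 0.0:
            raise ValueError("timepoints must start at 0")
        if np.any(np.diff(t) <= 0):
            raise ValueError("timepoints must be strictly increasing")
        if f[0] != 1.0:
            raise ValueError("fraction at t=0 must be 1 (course is t0-normalized)")
        if np.any(f <= 0):
            raise ValueError("fractions must be positive (log-transformable)")


@dataclass(frozen=True)
class DecayFit:
    label: str
    rate: float  # k, per hour
    half_life: float  # ln2 / k, hours
    intercept: float  # fitted ln(fraction) at t = 0
    r_squared: float
    model: str = "log-linear OLS, free intercept, no plateau"


def fit_decay(course: DecayCourse) -> DecayFit:
    """Fit a single-exponential decay to a CHX-chase course.

    Requires at least 3 timepoints.  A non-decaying course (fitted slope
    ≥ 0) is an error rather than a negative half-life.
    """
    t = np.asarray(course.timepoints, dtype=float)
    f = np.asarray(course.fractions, dtype=float)
    if t.size < 3:
        raise ValueError("decay fit needs at least 3 timepoints")
    res = stats.linregress(t, np.log(f))
    if res.slope >= 0:
        raise ValueError(f"course {course.label!r} is not decaying (slope {res.slope:.3g} >= 0)")
    k = -float(res.slope)
    return DecayFit(
        label=course.label,
        rate=k,
        half_life=LN2 / k,
        intercept=float(res.intercept),
        r_squared=float(res.rvalue) ** 2,
    )


def steady_state_ratio(half_life_a: float, half_life_b: float, synthesis_ratio: float = 1.0) -> float:
    """Relative steady-state abundance a/b implied by the two half-lives.

    From steady state = synthesis/k with k = ln2/t½, the degradation
    constants cancel into the half-life ratio; the result is homogeneous
    of degree 1 in ``synthesis_ratio`` and invariant under common scaling
    of both half-lives.
    """
    if half_life_a <= 0 or half_life_b <= 0:
        raise ValueError("half-lives must be positive")
    if synthesis_ratio <= 0:
        raise ValueError("synthesis_ratio must be positive")
    return synthesis_ratio * half_life_a / half_life_b


def polarity_index(axonal_intensity: float, dendritic_intensity: float) -> float:
    """P = (Ia − Id)/(Ia + Id); NaN when both intensities are zero."""
    ia, idn = float(axonal_intensity), float(dendritic_intensity)
    if ia < 0 or idn < 0:
        raise ValueError("intensities must be non-negative")
    total = ia + idn
    if total == 0:
        return float("nan")
    return (ia - idn) / total


def polarity_table(measurements: pd.DataFrame) -> pd.DataFrame:
    """Per-cell polarity indices from a (cell_id, Ia, Id) intensity table.

    Returns the input with a ``polarity`` column; cells with zero total
    intensity get NaN and are excluded from group means downstream
    (group aggregation is the arithmetic mean of per-cell P).
    """
    required = {"cell_id", "Ia", "Id"}
    missing = required - set(measurements.columns)
    if missing:
        raise ValueError(f"polarity table missing column(s) {sorted(missing)}")
    out = measurements.copy()
    out["polarity"] = [polarity_index(a, d) for a, d in zip(out["Ia"], out["Id"])]
    return out
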