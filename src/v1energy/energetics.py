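"""FRET ATP-sensor trial-series normalization and decay half-time.

The ATeam-style sensor is read out as the YFP/CFP fluorescence ratio,
averaged across somatic ROIs per trial.  After ATP-synthesis blockade
the ratio decays toward a plateau; the series is bound to [0, 1] by
subtracting the mean of the last three trials (the plateau) and dividing
by the (plateau-subtracted) mean of the pre-drug baseline trials.  The
half-time is the time at which the normalized signal first falls below
0.5, located by linear interpolation between the bracketing trials and
reported in minutes from drug application.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator


@dataclass
class FretExperiment:
    """Per-trial mean YFP/CFP ratio with a drug-onset marker at time 0.

    Baseline trials carry negative timestamps (minutes before drug
    application); post-drug trials positive ones.  At least one baseline
    and three post-drug trials are required (the plateau is estimated
    from the last three).
    """

    times_min: np.ndarray
    ratios: np.ndarray
    n_baseline: int
    label: str = "visual stimulation"

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.ratios = np.asarray(self.ratios, dtype=float)
        if self.times_min.shape != self.ratios.shape or self.times_min.ndim != 1:
            raise ValueError("times and ratios must be equal-length 1-D arrays")
        if np.any(np.diff(self.times_min) <= 0):
            raise ValueError("trial timestamps must be strictly increasing")
        if self.n_baseline < 1:
            raise ValueError("need >= 1 baseline trial")
        if self.n_post < 3:
            raise ValueError("need >= 3 post-drug trials (plateau = last three)")
        if np.any(self.times_min[: self.n_baseline] >= 0) or np.any(
            self.times_min[self.n_baseline :] <= 0
        ):
            raise ValueError("baseline trials must precede drug onset (time 0)")

    @property
    def n_post(self) -> int:
        return len(self.times_min) - self.n_baseline


def fret_ratio(yfp, cfp) -> float:
    """Mean YFP/CFP ratio across ROIs for one trial.

    The ratio is formed per ROI and then averaged across ROIs.

    Raises
    ------
    ValueError
        If any CFP value is non-positive.
    """
    yfp = np.asarray(yfp, dtype=float)
    cfp = np.asarray(cfp, dtype=float)
    if yfp.shape != cfp.shape:
        raise ValueError("yfp and cfp must have equal shape")
    if np.any(cfp <= 0):
        raise ValueError("CFP fluorescence must be positive")
    return float(np.mean(yfp / cfp))


@dataclass
class NormalizedFretTrace:
    """Trial series normalized so baseline maps to 1 and plateau to 0."""

    times_min: np.ndarray
    values: np.ndarray
    n_baseline: int
    baseline_ratio: float
    plateau_ratio: float


def normalize_fret(exp: FretExperiment, atol: float = 1e-12) -> NormalizedFretTrace:
    """Bound a FRET trial series between 0 and 1.

    ``normalized = (ratio - plateau) / (baseline - plateau)`` with the
    plateau the mean of the last three trials and the baseline the mean
    of the pre-drug trials, so the baseline maps to 1 and the plateau to
    0 by construction.

    Raises
    ------
    ValueError
        If baseline and plateau coincide (no decay; degenerate
        experiment).
    """
    plateau = float(np.mean(exp.ratios[-3:]))
    baseline = float(np.mean(exp.ratios[: exp.n_baseline]))
    if abs(baseline - plateau) <= atol:
        raise ValueError("baseline equals plateau: degenerate experiment with no decay")
    values = (exp.ratios - plateau) / (baseline - plateau)
    return NormalizedFretTrace(
        times_min=exp.times_min.copy(), values=values,
        n_baseline=exp.n_baseline, baseline_ratio=baseline, plateau_ratio=plateau,
    )


@dataclass
class HalfTimeResult:
    """First downward 0.5-crossing of a normalized FRET trace."""

    half_time_min: float
    crossing_index: int
    interpolation_fraction: float
    censored: bool = False


def decay_half_time(trace: NormalizedFretTrace) -> HalfTimeResult:
    """Time for the normalized FRET signal to decay to 50% of baseline.

    The first pair of consecutive trials bracketing a downward 0.5
    crossing after drug onset is located and the crossing time linearly
    interpolated; reported in minutes from drug application.  A trace
    that never falls below 0.5 is censored (``half_time_min`` is NaN and
    ``censored`` is True), not a number to aggregate.
    """
    t, v = trace.times_min, trace.values
    for i in range(len(v) - 1):
        if t[i + 1] <= 0:
            continue  # crossings must occur after drug onset
        if v[i] > 0.5 >= v[i + 1]:
            frac = (v[i] - 0.5) / (v[i] - v[i + 1])
            t_cross = t[i] + frac * (t[i + 1] - t[i])
            return HalfTimeResult(
                half_time_min=float(t_cross), crossing_index=i,
                interpolation_fraction=float(frac),
            )
    return HalfTimeResult(
        half_time_min=float("nan"), crossing_index=-1,
        interpolation_fraction=float("nan"), censored=True,
    )


class FretHalfTime(BaseEstimator):
    """Estimator wrapper: normalize a FRET experiment and fit its half-time.

    Attributes after ``fit``
    ------------------------
    half_time_ : float
        Minutes from drug onset to 50% decay (NaN when censored).
    censored_ : bool
    normalized_ : NormalizedFretTrace
    result_ : HalfTimeResult
    """

    def fit(self, experiment: FretExperiment, y=None):
        self.normalized_ = normalize_fret(experiment)
        self.result_ = decay_half_time(self.normalized_)
        self.half_time_ = self.result_.half_time_min
        self.censored_ = self.result_.censored
        return self
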