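"""Synthetic FRET ATP-sensor experiments with a known decay half-time.

Emulates the blockade protocol: a few baseline trials, then ATP-synthesis
inhibitors applied at time zero followed by a run of post-drug trials
(defaults: 3 baseline + 30 post, one trial per minute) during which the
YFP/CFP ratio decays from its baseline level toward a plateau.

The downstream normalization estimates the plateau from the *last three
trials*, so a pure exponential — which never actually reaches its
asymptote — would make the recovered half-time systematically shorter
than the generating time constant implies.  The generator therefore
emits a shifted exponential that reaches the plateau exactly at the
first of the last three trials, with its rate solved numerically so the
*normalized* trace crosses 0.5 exactly at the requested half-time.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq

from v1energy.energetics import FretExperiment


def simulate_fret_experiment(
    half_time_min: float,
    baseline_trials: int = 3,
    post_trials: int = 30,
    noise: float = 0.0,
    seed: int = 0,
    trial_interval_min: float = 1.0,
    baseline_ratio: float = 2.0,
    plateau_ratio: float = 1.0,
) -> FretExperiment:
    """Simulate one animal's FRET decay experiment.

    Baseline trials sit at negative timestamps (drug application at
    time 0); post-drug trial ``j`` at ``j * trial_interval_min``.  The
    ratio is flat at ``baseline_ratio`` before the drug and decays to
    ``plateau_ratio`` afterwards such that the normalized signal crosses
    0.5 exactly at ``half_time_min``.  ``noise`` is the per-trial
    Gaussian SD in ratio units.

    Raises
    ------
    ValueError
        For a non-positive half-time, too few trials, degenerate
        baseline/plateau separation, or a half-time too long to cross
        before the plateau.
    """
    if not np.isfinite(half_time_min) or half_time_min <= 0:
        raise ValueError(f"half-time must be positive and finite, got {half_time_min}")
    if baseline_trials < 1:
        raise ValueError("need >= 1 baseline trial")
    if post_trials < 3:
        raise ValueError("need >= 3 post-drug trials (plateau = last three)")
    if not np.isfinite(baseline_ratio) or not np.isfinite(plateau_ratio):
        raise ValueError("degenerate baseline/plateau levels")
    if baseline_ratio <= plateau_ratio:
        raise ValueError("baseline ratio must exceed the plateau ratio")
    if trial_interval_min <= 0:
        raise ValueError("trial interval must be > 0")

    t_plateau = (post_trials - 2) * trial_interval_min  # first of the last three
    if half_time_min >= t_plateau / 2.0:
        raise ValueError(
            f"half-time {half_time_min} min cannot be reached before the plateau "
            f"at {t_plateau} min (needs half_time < {t_plateau / 2.0:g})"
        )

    # shifted exponential g(t) = (e^{-t/tau} - E) / (1 - E), E = e^{-T/tau},
    # clipped at zero from the plateau onward; solve tau so g(half_time) = 1/2
    h, t_p = half_time_min, t_plateau

    def half_mismatch(tau: float) -> float:
        return np.exp(-h / tau) - 0.5 - 0.5 * np.exp(-t_p / tau)

    tau = brentq(half_mismatch, 1e-6, 1e6)

    t_base = -trial_interval_min * np.arange(baseline_trials, 0, -1)
    t_post = trial_interval_min * np.arange(1, post_trials + 1)
    times = np.concatenate([t_base, t_post])

    e_p = np.exp(-t_p / tau)
    g = (np.exp(-t_post / tau) - e_p) / (1.0 - e_p)
    g = np.clip(g, 0.0, None)
    ratios = np.concatenate(
        [np.full(baseline_trials, baseline_ratio),
         plateau_ratio + (baseline_ratio - plateau_ratio) * g]
    )
    if noise > 0:
        rng = np.random.default_rng(seed)
        ratios = ratios + rng.normal(0.0, noise, size=ratios.shape)
    return FretExperiment(times_min=times, ratios=ratios, n_baseline=baseline_trials)
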