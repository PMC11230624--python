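"""Synthetic drifting-grating imaging sessions with known ground truth.

Emulates layer-2/3 populations responding to the standard protocol: 2-s
full-field gratings at 12 drift directions and several spatial
frequencies, interleaved with 4-s grey screens, >= 10 repeats per
stimulus, sampled at 40 Hz.  Each neuron's trial-mean dF/F response
amplitude at a direction equals its generating double-Gaussian tuning
curve at that direction (attenuated away from its preferred spatial
frequency); the evoked waveform is a stimulus-locked drive convolved
with a single-exponential calcium-indicator kernel, normalized so the
downstream 2-s-window response extraction recovers the amplitude
exactly in the noiseless case.  Noise is additive Gaussian on dF/F.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from v1energy.containers import RoiTraceSet, StimulusProtocol
from v1energy.tuning import double_gaussian

#: the 12-direction drifting-grating set, 0-330 deg in 30-deg steps
DEFAULT_DIRECTIONS = tuple(float(d) for d in range(0, 360, 30))
DEFAULT_SFS = (0.02, 0.04, 0.16, 0.32)


@dataclass
class NeuronGroundTruth:
    """Generating double-Gaussian parameters for one simulated neuron.

    ``c`` (offset), ``rp`` (preferred-direction amplitude), ``rn``
    (null-direction amplitude) in dF/F units; ``theta_pref`` in
    [0, 360) degrees; ``sigma`` (tuning width) in degrees; ``sf_pref``
    the preferred spatial frequency in cycles/degree; ``noise`` the
    per-frame dF/F noise SD; ``trial_noise`` the SD of the additive
    trial-to-trial jitter of the evoked response amplitude (dF/F),
    modelling the biological response variability that dominates
    trial-level scatter in real recordings and does not average down
    within a response window.  Non-responsive neurons must have
    ``rp == rn == 0``.
    """

    c: float = 0.0
    rp: float = 1.0
    rn: float = 0.3
    theta_pref: float = 0.0
    sigma: float = 30.0
    sf_pref: float = 0.04
    noise: float = 0.0
    trial_noise: float = 0.0
    responsive: bool = True

    def __post_init__(self) -> None:
        if not (self.rp >= self.rn >= 0):
            raise ValueError("require rp >= rn >= 0")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if not (0 <= self.theta_pref < 360):
            raise ValueError("theta_pref must lie in [0, 360)")
        if self.noise < 0 or self.trial_noise < 0:
            raise ValueError("noise must be >= 0")
        if not self.responsive and (self.rp != 0 or self.rn != 0):
            raise ValueError("non-responsive neurons must have rp = rn = 0")

    def amplitude(self, direction_deg: float, sf_cpd: float, sf_attenuation: float) -> float:
        """Trial-mean response amplitude for one stimulus condition."""
        a = float(
            double_gaussian(direction_deg, self.c, self.rp, self.rn, self.theta_pref, self.sigma)
        )
        if sf_cpd != self.sf_pref:
            a *= sf_attenuation
        return a


@dataclass
class SimulationConfig:
    """Session-level constants of a simulated grating experiment.

    The defaults are the study conditions: 40-Hz acquisition, 2-s
    gratings, 4-s grey screens, 12 directions in 30-deg steps, four
    spatial frequencies, 10 repeats per stimulus, and a GCaMP6s-like
    single-exponential indicator decay (tau = 1.5 s).  ``seed`` is
    mandatory; identical (config, seed) pairs give bit-identical output.
    """

    seed: int
    n_trials: int = 10
    frame_rate: float = 40.0
    grating_s: float = 2.0
    grey_s: float = 4.0
    directions: tuple[float, ...] = DEFAULT_DIRECTIONS
    sfs: tuple[float, ...] = DEFAULT_SFS
    indicator_tau_s: float = 1.5
    sf_attenuation: float = 0.5
    baseline_fluorescence: float = 100.0
    quiet_s: float = 10.0

    def __post_init__(self) -> None:
        if len(self.directions) == 0:
            raise ValueError("direction list must be non-empty")
        if self.frame_rate <= 0:
            raise ValueError("frame rate must be > 0")
        if self.n_trials < 1:
            raise ValueError("need >= 1 trial per stimulus")
        if self.grating_s <= 0:
            raise ValueError("grating duration must be > 0")
        if self.grating_s + self.grey_s < 4.0:
            # the 4-s analysis window must fit inside one event cycle
            raise ValueError("grating + grey screen too short for the response windows")
        if self.indicator_tau_s <= 0:
            raise ValueError("indicator tau must be > 0")


def _unit_transient(config: SimulationConfig) -> np.ndarray:
    """Evoked dF/F waveform whose best 2-s-window mean is exactly 1.

    A boxcar drive spanning the grating convolved with a normalized
    exponential indicator kernel, truncated (with a smooth 0.5-s taper)
    1 s before the next grating's baseline window so consecutive events
    never interact, then scaled so the maximum response-window mean over
    frame-aligned placements inside the analysis window equals 1.
    """
    fr = config.frame_rate
    n_grating = int(round(config.grating_s * fr))
    support_s = config.grating_s + config.grey_s - 1.0 - 1.0 / fr
    n_support = int(round(support_s * fr))
    drive = np.zeros(n_support)
    drive[:n_grating] = 1.0
    tk = np.arange(n_support) / fr
    kernel = np.exp(-tk / config.indicator_tau_s)
    kernel /= kernel.sum()
    transient = np.convolve(drive, kernel)[:n_support]
    n_taper = min(int(round(0.5 * fr)), n_support // 4)
    if n_taper > 0:
        taper = 0.5 * (1.0 + np.cos(np.linspace(0.0, np.pi, n_taper)))
        transient[-n_taper:] *= taper
    # normalize against the extraction scheme: best 2-s mean in the 4-s window
    n_resp = int(round(2.0 * fr))
    n_full = int(round(4.0 * fr))
    csum = np.concatenate([[0.0], np.cumsum(transient)])
    n_placements = min(n_full, n_support) - n_resp + 1
    means = (csum[n_resp : n_resp + n_placements] - csum[:n_placements]) / n_resp
    peak = means.max()
    if peak <= 0:
        raise ValueError("degenerate transient: non-positive windowed peak")
    return transient / peak


def simulate_grating_session(
    config: SimulationConfig,
    truths: list[NeuronGroundTruth],
    return_truth: bool = False,
):
    """Simulate a full grating session for a population of neurons.

    Events run block-wise: for each spatial frequency and repeat, the
    directions are presented once in random order, each as ``grating_s``
    of stimulus followed by ``grey_s`` of grey screen, after a quiet
    lead-in.  Returns ``(RoiTraceSet, StimulusProtocol)``; with
    ``return_truth`` a third element carries the noiseless ground-truth
    dF/F matrix and the per-event amplitude table.

    Raises
    ------
    ValueError
        On invalid config or an empty truth list.
    """
    if len(truths) == 0:
        raise ValueError("need at least one neuron ground truth")
    rng = np.random.default_rng(config.seed)
    fr = config.frame_rate
    event_len_s = config.grating_s + config.grey_s

    onsets, dirs, sfs_col, trials = [], [], [], []
    t = config.quiet_s
    for sf in config.sfs:
        for rep in range(config.n_trials):
            for d in rng.permutation(np.asarray(config.directions, dtype=float)):
                onsets.append(t)
                dirs.append(float(d))
                sfs_col.append(float(sf))
                trials.append(rep)
                t += event_len_s
    total_s = t + config.quiet_s
    n_frames = int(round(total_s * fr))

    events = pd.DataFrame(
        dict(
            onset_s=onsets,
            direction_deg=dirs,
            sf_cpd=sfs_col,
            duration_s=config.grating_s,
            trial=trials,
        )
    )
    protocol = StimulusProtocol(events=events, grey_s=config.grey_s)

    transient = _unit_transient(config)
    n_support = len(transient)
    onset_frames = np.round(events["onset_s"].to_numpy() * fr).astype(int)

    n_neurons = len(truths)
    true_dff = np.zeros((n_neurons, n_frames))
    amp_rows = []
    for i, truth in enumerate(truths):
        for onset_f, d, sf, rep in zip(
            onset_frames, events["direction_deg"], events["sf_cpd"], events["trial"]
        ):
            a = truth.amplitude(d, sf, config.sf_attenuation)
            if truth.trial_noise > 0:
                a += float(rng.normal(0.0, truth.trial_noise))
            if a != 0.0:
                true_dff[i, onset_f : onset_f + n_support] += a * transient
            amp_rows.append(
                dict(neuron=f"roi{i:03d}", direction_deg=d, sf_cpd=sf,
                     trial=int(rep), amplitude=a)
            )

    dff = true_dff.copy()
    for i, truth in enumerate(truths):
        if truth.noise > 0:
            dff[i] += rng.normal(0.0, truth.noise, size=n_frames)

    fluorescence = config.baseline_fluorescence * (1.0 + dff)
    traces = RoiTraceSet(fluorescence=fluorescence, frame_rate=fr)
    if return_truth:
        return traces, protocol, dict(true_dff=true_dff, amplitudes=pd.DataFrame(amp_rows))
    return traces, protocol


def random_population(
    n_neurons: int,
    rng: np.random.Generator,
    fraction_responsive: float = 0.7,
    rp_range: tuple[float, float] = (1.0, 2.0),
    sigma_range: tuple[float, float] = (20.0, 40.0),
    noise: float = 0.2,
    trial_noise: float = 0.15,
    sfs: tuple[float, ...] = DEFAULT_SFS,
) -> list[NeuronGroundTruth]:
    """Mixed tuned / non-responsive population with realistic variability.

    Responsive neurons get a uniform preferred direction, a null lobe up
    to half the preferred amplitude, a preferred spatial frequency drawn
    from ``sfs``, per-frame dF/F noise ``noise`` and trial-to-trial
    amplitude jitter ``trial_noise``; the rest are non-responsive
    (rp = rn = 0) with the same noise levels.
    """
    truths = []
    n_resp = int(round(fraction_responsive * n_neurons))
    for i in range(n_neurons):
        if i < n_resp:
            rp = float(rng.uniform(*rp_range))
            truths.append(
                NeuronGroundTruth(
                    c=float(rng.uniform(0.0, 0.1)),
                    rp=rp,
                    rn=float(rng.uniform(0.0, 0.5 * rp)),
                    theta_pref=float(rng.uniform(0.0, 360.0)),
                    sigma=float(rng.uniform(*sigma_range)),
                    sf_pref=float(rng.choice(sfs)),
                    noise=noise,
                    trial_noise=trial_noise,
                    responsive=True,
                )
            )
        else:
            truths.append(
                NeuronGroundTruth(
                    c=0.0, rp=0.0, rn=0.0, theta_pref=0.0, sigma=30.0,
                    sf_pref=float(sfs[0]), noise=noise, trial_noise=trial_noise,
                    responsive=False,
                )
            )
    return truths
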