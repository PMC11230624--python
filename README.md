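# v1energy

Analysis toolkit for visual-cortex tuning and energy usage in a 2×2
sex × diet (ad-libitum control, CTR, vs food-restricted, FR) mouse
design: two-photon calcium-imaging trace processing, drifting-grating
tuning quantification, FRET ATP-sensor decay kinetics, pupillometry,
and cohort-level statistics.  A synthetic-data module generates every
input the pipeline consumes with known ground truth, so the whole chain
is testable end to end without any recordings.

It is written for systems neuroscientists who want a reproducible,
scripted version of the standard analysis chain for this kind of
experiment — from raw ROI fluorescence to figure-legend statistics.

## What it computes

**ΔF/F.** Per ROI, baseline fluorescence F₀ is the 5th percentile of
the trace after zero-phase low-pass filtering (1 Hz cutoff, 60th-order
Hamming FIR), and ΔF/F = (F − F₀)/F₀.  The response to a grating is the
highest 2-s-window mean ΔF/F inside the 4-s window from grating onset,
minus the mean in the 1 s before onset.

**Direction tuning.** Direction-mean responses are fitted with the
two-lobed tuning curve

    R(θ) = C + Rp·exp(−angdir(θ−θp)²/2σ²) + Rn·exp(−angdir(θ−θp−180)²/2σ²)

where `angdir` wraps angular differences onto [0°, 180°].  The fit
(k = 5 parameters) is compared against a flat line at zero (k = 0) with
BIC = n·ln(σ̄²) + k·ln(n); a neuron is *grating-responsive* when
BIC_null − BIC_Gauss ≥ 10.  Selectivity is one minus the circular
variance of the non-negative mean responses,

    OSI = |Σₖ R(θₖ)e^{2iθₖ}| / Σₖ R(θₖ),   DSI = |Σₖ R(θₖ)e^{iθₖ}| / Σₖ R(θₖ),

with per-animal summaries as the median over responsive neurons.

**ATP usage.** The YFP/CFP FRET ratio of an ATP sensor, recorded over
trials before and after ATP-synthesis blockade, is bound to [0, 1]
(plateau = mean of the last three trials → 0; pre-drug baseline → 1);
the decay half-time is the interpolated first downward 0.5 crossing, in
minutes from drug application.

**Pupil diameter.** Frames are median-filtered, contrast-stretched and
Otsu-thresholded; the largest non-border dark region is kept and an
ellipse fitted from its second-order moments, with d = 2√(a·b).

**Cohort statistics.** Two-way (sex × diet) ANOVA with pooled error
(df = N − 4) feeding unadjusted Fisher-LSD pairwise contrasts, JZS
Bayes factors (Cauchy prior on effect size, scale r = 1/√2; BF₁₀ > 3
evidence for an effect, < 1/3 for its absence), and percent/fold
changes of FR vs CTR.

## Worked example

```python
import numpy as np
from v1energy.simulate import (SimulationConfig, NeuronGroundTruth,
                               simulate_grating_session, simulate_fret_experiment)
from v1energy.traces import compute_dff, extract_grating_response
from v1energy.tuning import analyze_session
from v1energy.energetics import FretHalfTime

config = SimulationConfig(seed=1, n_trials=10, sfs=(0.04, 0.16))
truths = [
    NeuronGroundTruth(c=0.05, rp=1.2, rn=0.4, theta_pref=60.0, sigma=30.0,
                      sf_pref=0.04, noise=0.2, trial_noise=0.15),
    NeuronGroundTruth(c=0.0, rp=0.0, rn=0.0, sf_pref=0.04,
                      noise=0.2, trial_noise=0.15, responsive=False),
]
traces, protocol = simulate_grating_session(config, truths)
table = extract_grating_response(compute_dff(traces), protocol)
result = analyze_session(table)
print(result[["neuron", "responsive", "theta_pref", "osi", "dsi", "delta_bic"]].round(3))

fit = FretHalfTime().fit(simulate_fret_experiment(half_time_min=8.0, noise=0.02, seed=1))
print(f"FRET decay half-time: {fit.half_time_:.2f} min")
```

prints

```
   neuron  responsive  theta_pref    osi    dsi  delta_bic
0  roi000        True      61.143  0.479  0.412    312.245
1  roi001       False     301.226  0.199  0.086      9.369
FRET decay half-time: 7.88 min
```

The tuned neuron (true preferred direction 60°) is classified
responsive with its preferred direction recovered to ~1°, while the
non-responsive neuron's ΔBIC of 9.4 stays below the 10-point threshold
(its nominal `theta_pref` is meaningless noise).  The FRET half-time of
a simulated 8-min-decay experiment with trial noise is recovered to
about a tenth of a minute.

A tidy per-animal cohort CSV can be analysed from the shell:

```bash
v1energy report cohort.csv --endpoint serum_leptin
```

which prints cell means ± SEM, Fisher-LSD contrasts (t, df, p) and
Bayes factors in figure-legend form.

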