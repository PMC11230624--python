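"""dF/F extraction and per-trial grating-response quantification.

Baseline fluorescence F0 is the 5th percentile of each ROI's trace after
zero-phase low-pass filtering (1 Hz cutoff, 60th-order windowed-sinc
FIR); dF/F = (F - F0) / F0.  The visual response to a grating is the
highest mean dF/F in any 2-s window inside the 4-s window spanning the
2-s grating plus the first 2 s of the following grey screen, minus the
mean dF/F in the 1 s immediately before grating onset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import filtfilt, firwin
from sklearn.base import BaseEstimator, TransformerMixin

from v1energy.containers import RoiTraceSet, StimulusProtocol

logger = logging.getLogger(__name__)


@dataclass
class DffTraceSet:
    """dF/F per ROI per frame, with the per-ROI baseline F0 retained."""

    dff: np.ndarray
    f0: np.ndarray
    frame_rate: float
    roi_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.dff = np.asarray(self.dff, dtype=float)
        self.f0 = np.asarray(self.f0, dtype=float)
        if self.dff.ndim != 2:
            raise ValueError("dff must be 2-D (n_rois, n_frames)")
        if self.f0.shape != (self.dff.shape[0],):
            raise ValueError("f0 must have one entry per ROI")
        if not np.all(np.isfinite(self.dff)):
            raise ValueError("dff contains non-finite values")
        if not self.roi_ids:
            self.roi_ids = [f"roi{i:03d}" for i in range(self.dff.shape[0])]


class DeltaFOverF(BaseEstimator, TransformerMixin):
    """Percentile-baseline dF/F transformer for ROI fluorescence matrices.

    ``fit`` computes the per-ROI baseline F0 as the ``baseline_percentile``-th
    percentile of the low-pass-filtered trace; ``transform`` returns
    (F - F0) / F0.  Filtering is a ``filter_order``-order Hamming-window
    FIR low-pass at ``cutoff_hz``, applied forward-backward (zero phase)
    with reflection padding at the edges.

    Parameters
    ----------
    frame_rate : float
        Acquisition rate in Hz; sets the filter's digital cutoff.
    cutoff_hz : float, default 1.0
    filter_order : int, default 60
    baseline_percentile : float, default 5.0
    """

    def __init__(
        self,
        frame_rate: float = 40.0,
        cutoff_hz: float = 1.0,
        filter_order: int = 60,
        baseline_percentile: float = 5.0,
    ):
        self.frame_rate = frame_rate
        self.cutoff_hz = cutoff_hz
        self.filter_order = filter_order
        self.baseline_percentile = baseline_percentile

    def _validate(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.ndim != 2:
            raise ValueError("expected a (n_rois, n_frames) matrix")
        # filtfilt's default padlen for a FIR of order m is 3*(m+1)
        min_len = 3 * (self.filter_order + 1) + 1
        if X.shape[1] < min_len:
            raise ValueError(
                f"trace length {X.shape[1]} shorter than filter warm-up ({min_len})"
            )
        if not np.all(np.isfinite(X)):
            raise ValueError("fluorescence contains non-finite values")
        return X

    def smooth(self, X) -> np.ndarray:
        """Zero-phase low-pass filter each ROI trace (reflection padding)."""
        X = self._validate(X)
        taps = firwin(
            self.filter_order + 1, self.cutoff_hz, fs=self.frame_rate, window="hamming"
        )
        return filtfilt(taps, [1.0], X, axis=1, padtype="even")

    def fit(self, X, y=None):
        smoothed = self.smooth(X)
        self.f0_ = np.percentile(smoothed, self.baseline_percentile, axis=1)
        if np.any(self.f0_ <= 0):
            bad = np.nonzero(self.f0_ <= 0)[0]
            raise ValueError(f"non-positive baseline F0 for ROI index(es) {bad.tolist()}")
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "f0_"):
            raise AttributeError("transformer is not fitted")
        X = self._validate(X)
        return (X - self.f0_[:, None]) / self.f0_[:, None]


def compute_dff(traces: RoiTraceSet, **kwargs) -> DffTraceSet:
    """Convert raw ROI fluorescence to dF/F with a percentile baseline.

    Thin wrapper over :class:`DeltaFOverF` using the trace set's frame
    rate; see that class for the filter and baseline definitions.
    """
    est = DeltaFOverF(frame_rate=traces.frame_rate, **kwargs)
    dff = est.fit(traces.fluorescence).transform(traces.fluorescence)
    return DffTraceSet(
        dff=dff, f0=est.f0_, frame_rate=traces.frame_rate, roi_ids=list(traces.roi_ids)
    )


def extract_grating_response(
    dff: DffTraceSet,
    protocol: StimulusProtocol,
    response_window_s: float = 2.0,
    analysis_window_s: float = 4.0,
    baseline_window_s: float = 1.0,
) -> pd.DataFrame:
    """Baseline-subtracted response of every neuron to every grating event.

    For each event the response is the maximum, over frame-aligned
    placements, of the ``response_window_s`` mean dF/F inside the
    ``analysis_window_s`` window starting at grating onset, minus the
    mean dF/F in the ``baseline_window_s`` immediately before onset.
    Responses may be negative.  Events whose windows fall outside the
    recording are dropped with a log entry.

    Returns a tidy frame with columns ``neuron, direction_deg, sf_cpd,
    trial, response``.
    """
    fr = dff.frame_rate
    n_rois, n_frames = dff.dff.shape
    w_resp = int(round(response_window_s * fr))
    w_full = int(round(analysis_window_s * fr))
    w_base = int(round(baseline_window_s * fr))
    if not (0 < w_resp <= w_full):
        raise ValueError("response window must be positive and fit the analysis window")

    # running means of the response window via a cumulative sum
    csum = np.concatenate(
        [np.zeros((n_rois, 1)), np.cumsum(dff.dff, axis=1)], axis=1
    )
    win_means = (csum[:, w_resp:] - csum[:, :-w_resp]) / w_resp  # start frame indexed

    rows: list[dict] = []
    n_dropped = 0
    for ev in protocol.events.itertuples(index=False):
        onset = int(round(ev.onset_s * fr))
        if onset - w_base < 0 or onset + w_full > n_frames:
            n_dropped += 1
            logger.warning(
                "event at %.2f s dropped: windows outside the recording", ev.onset_s
            )
            continue
        baseline = dff.dff[:, onset - w_base : onset].mean(axis=1)
        n_placements = w_full - w_resp + 1
        best = win_means[:, onset : onset + n_placements].max(axis=1)
        resp = best - baseline
        for i in range(n_rois):
            rows.append(
                dict(
                    neuron=dff.roi_ids[i],
                    direction_deg=float(ev.direction_deg),
                    sf_cpd=float(ev.sf_cpd),
                    trial=int(ev.trial),
                    response=float(resp[i]),
                )
            )
    if n_dropped:
        logger.warning("%d event(s) dropped from the response table", n_dropped)
    return pd.DataFrame(rows)
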