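"""Shared in-memory containers for trace processing and stimulus structure."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class RoiTraceSet:
    """Raw per-ROI fluorescence time series sharing one frame clock.

    Parameters
    ----------
    fluorescence : ndarray of shape (n_rois, n_frames)
        Mean pixel fluorescence per ROI per frame, arbitrary units.
    frame_rate : float
        Acquisition rate in Hz (two-photon resonant scanning, 40 Hz typical).
    roi_ids : sequence of str, optional
        Stable ROI identifiers; defaults to ``roi000, roi001, ...``.
    """

    fluorescence: np.ndarray
    frame_rate: float
    roi_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.fluorescence.ndim != 2:
            raise ValueError("fluorescence must be a 2-D (n_rois, n_frames) array")
        if not np.isfinite(self.frame_rate) or self.frame_rate <= 0:
            raise ValueError(f"frame rate must be positive, got {self.frame_rate}")
        if not self.roi_ids:
            self.roi_ids = [f"roi{i:03d}" for i in range(self.fluorescence.shape[0])]
        if len(self.roi_ids) != self.fluorescence.shape[0]:
            raise ValueError("roi_ids length must match the number of ROIs")

    @property
    def n_rois(self) -> int:
        return self.fluorescence.shape[0]

    @property
    def n_frames(self) -> int:
        return self.fluorescence.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate


@dataclass
class StimulusProtocol:
    """Ordered drifting-grating events defining the trial structure.

    ``events`` has one row per grating presentation with columns
    ``onset_s`` (grating onset from recording start), ``direction_deg``
    (drift direction, [0, 360)), ``sf_cpd`` (spatial frequency,
    cycles/degree), ``duration_s`` (grating duration) and ``trial``
    (repeat index per direction x SF).  Gratings are followed by a grey
    screen of ``grey_s`` seconds.
    """

    events: pd.DataFrame
    grey_s: float = 4.0

    _REQUIRED = ("onset_s", "direction_deg", "sf_cpd", "duration_s")

    def __post_init__(self) -> None:
        missing = [c for c in self._REQUIRED if c not in self.events.columns]
        if missing:
            raise ValueError(f"protocol events missing columns: {missing}")
        if len(self.events) == 0:
            raise ValueError("protocol contains no events")
        if "trial" not in self.events.columns:
            self.events = self.events.copy()
            self.events["trial"] = self.events.groupby(
                ["direction_deg", "sf_cpd"]
            ).cumcount()
        if not self.events["onset_s"].is_monotonic_increasing:
            self.events = self.events.sort_values("onset_s").reset_index(drop=True)

    @property
    def directions(self) -> np.ndarray:
        return np.sort(self.events["direction_deg"].unique())

    @property
    def spatial_frequencies(self) -> np.ndarray:
        return np.sort(self.events["sf_cpd"].unique())

    def __len__(self) -> int:
        return len(self.events)
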