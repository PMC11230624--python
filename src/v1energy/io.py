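"""File formats: HDF5 trace containers, protocol/response/cohort CSV,
multi-page TIFF pupil stacks, YAML simulation configs."""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile
import yaml

from v1energy.containers import RoiTraceSet, StimulusProtocol
from v1energy.simulate.gratings import SimulationConfig

PROTOCOL_COLUMNS = ["onset_s", "direction_deg", "sf_cpd", "duration_s", "trial"]


def save_traces(path, traces: RoiTraceSet) -> None:
    """Write a RoiTraceSet to HDF5 (datasets: fluorescence, roi_ids; attr frame_rate)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("fluorescence", data=traces.fluorescence)
        f.create_dataset(
            "roi_ids", data=np.array(traces.roi_ids, dtype=h5py.string_dtype())
        )
        f.attrs["frame_rate"] = traces.frame_rate


def load_traces(path) -> RoiTraceSet:
    with h5py.File(path, "r") as f:
        return RoiTraceSet(
            fluorescence=f["fluorescence"][()],
            frame_rate=float(f.attrs["frame_rate"]),
            roi_ids=[s.decode() if isinstance(s, bytes) else str(s) for s in f["roi_ids"][()]],
        )


def save_protocol(path, protocol: StimulusProtocol) -> None:
    protocol.events[PROTOCOL_COLUMNS].to_csv(path, index=False)


def load_protocol(path, grey_s: float = 4.0) -> StimulusProtocol:
    return StimulusProtocol(events=pd.read_csv(path), grey_s=grey_s)


def save_responses(path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False)


def load_responses(path) -> pd.DataFrame:
    return pd.read_csv(path)


def save_cohort(path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False)


def load_cohort(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    required = {"animal_id", "sex", "diet", "endpoint", "value"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"cohort table missing columns: {sorted(missing)}")
    return table


def save_pupil_stack(path, stack: np.ndarray) -> None:
    """Write a frame stack as a multi-page 8-bit grayscale TIFF."""
    data = np.clip(np.asarray(stack), 0, 255).astype(np.uint8)
    tifffile.imwrite(path, data, photometric="minisblack")


def load_pupil_stack(path) -> np.ndarray:
    stack = tifffile.imread(path)
    return stack[None] if stack.ndim == 2 else stack


def load_simulation_config(path) -> SimulationConfig:
    """Read a SimulationConfig from YAML; the seed is mandatory."""
    with open(path) as f:
        raw = yaml.safe_load(f) or {}
    if "seed" not in raw:
        raise ValueError("simulation config must specify a seed")
    for key in ("directions", "sfs"):
        if key in raw:
            raw[key] = tuple(float(x) for x in raw[key])
    return SimulationConfig(**raw)


def save_simulation_config(path, config: SimulationConfig) -> None:
    data = {
        k: (list(v) if isinstance(v, tuple) else v)
        for k, v in vars(config).items()
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
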