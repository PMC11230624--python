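"""Synthetic 2x2 sex-by-diet cohort endpoint tables.

Cell specifications mirror how group summaries are printed in figure
legends: a mean, a dispersion and an animal count per (sex, diet) cell.
Dispersion can be given directly as an SD or derived from a printed 95%
confidence interval assuming a normal-theory (z) interval:
``SEM = half-width / 1.96``, ``SD = SEM * sqrt(n)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

_Z95 = 1.959963984540054


@dataclass
class CellSpec:
    """One (sex, diet) cell: endpoint mean, SD and number of animals."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"each cell needs n >= 2 animals, got {self.n}")
        if self.sd < 0:
            raise ValueError("dispersion must be >= 0")

    @classmethod
    def from_ci95(cls, mean: float, ci_low: float, ci_high: float, n: int) -> "CellSpec":
        """Build a cell from a printed mean and normal-theory 95% CI."""
        if ci_high < ci_low:
            raise ValueError("CI bounds out of order")
        sem = (ci_high - ci_low) / 2.0 / _Z95
        return cls(mean=mean, sd=sem * np.sqrt(n), n=n)


@dataclass
class CohortSpec:
    """Per-cell endpoint specification for one 2x2 cohort."""

    endpoint: str
    cells: dict = field(default_factory=dict)  # (sex, diet) -> CellSpec
    units: str = ""

    def __post_init__(self) -> None:
        for key, cell in self.cells.items():
            if not (isinstance(key, tuple) and len(key) == 2):
                raise ValueError("cell keys must be (sex, diet) tuples")
            if not isinstance(cell, CellSpec):
                self.cells[key] = CellSpec(**cell)


def simulate_cohort(spec: CohortSpec, seed: int = 0) -> pd.DataFrame:
    """Draw per-animal endpoint values for every cell of a cohort spec.

    Values are normal draws with the cell's mean and SD; exactly ``n``
    rows per cell, deterministic under the seed.  Returns a tidy frame
    with columns ``animal_id, sex, diet, endpoint, value``.
    """
    rng = np.random.default_rng(seed)
    rows = []
    counter = 0
    for (sex, diet), cell in sorted(spec.cells.items()):
        draws = rng.normal(cell.mean, cell.sd, size=cell.n)
        for v in draws:
            rows.append(
                dict(
                    animal_id=f"animal{counter:03d}", sex=sex, diet=diet,
                    endpoint=spec.endpoint, value=float(v),
                )
            )
            counter += 1
    return pd.DataFrame(rows)


def leptin_cohort_spec() -> CohortSpec:
    """Serum-leptin fixture: printed group means, 95% CIs and n per cell.

    CTR/FR males 6.45/1.84 ng/ml (n = 17/19), CTR/FR females 3.94/2.83
    ng/ml (n = 23/11); dispersions derived from the printed CIs.
    """
    return CohortSpec(
        endpoint="serum_leptin",
        units="ng/ml",
        cells={
            ("male", "CTR"): CellSpec.from_ci95(6.45, 4.47, 8.43, 17),
            ("male", "FR"): CellSpec.from_ci95(1.84, 0.90, 2.79, 19),
            ("female", "CTR"): CellSpec.from_ci95(3.94, 2.53, 5.35, 23),
            ("female", "FR"): CellSpec.from_ci95(2.83, 1.20, 4.47, 11),
        },
    )
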