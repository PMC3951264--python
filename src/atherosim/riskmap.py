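"""(LDL, HDL) risk map: relative plaque-weight change on a lipid grid.

For every pair (L0, H0) on the grid the scenario is integrated to the
horizon (100 days by default) and the relative change
``R = (W(t_h) - W(0)) / W(0)`` recorded.  The plane is then partitioned
into region I (high risk, R >= t_high), region III (no risk,
R <= t_none) and the intermediate region II.  The published full-scale
map uses 121 LDL x 21 HDL points over 70-190 / 40-60 mg/dL; reduced
grids are supported for desk-scale runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import run_scenario

__all__ = ["RiskMatrix", "default_grids", "sweep", "classify"]

#: default region thresholds on the relative change at the horizon
#: (the source work prints no numeric thresholds; repo convention)
T_HIGH = 0.10
T_NONE = -0.10


@dataclass
class RiskMatrix:
    """Relative plaque-weight change over an (L0, H0) grid.

    ``R[i, j]`` is the relative change for ``H_grid[i]`` and ``L_grid[j]``
    (HDL indexes rows, LDL columns, matching the published 21 x 121 map).
    ``labels`` holds region codes "I"/"II"/"III" (empty string where the
    scenario failed), ``horizon`` the evaluation time in days.
    """

    L_grid: np.ndarray
    H_grid: np.ndarray
    R: np.ndarray
    horizon: float
    labels: np.ndarray = field(default_factory=lambda: np.array([]))
    thresholds: tuple[float, float] = (T_HIGH, T_NONE)

    def __post_init__(self):
        self.L_grid = np.asarray(self.L_grid, dtype=float)
        self.H_grid = np.asarray(self.H_grid, dtype=float)
        self.R = np.asarray(self.R, dtype=float)
        if self.R.shape != (len(self.H_grid), len(self.L_grid)):
            raise ValueError(
                f"matrix shape {self.R.shape} does not match grids "
                f"({len(self.H_grid)}, {len(self.L_grid)})"
            )

    def region(self, L0: float, H0: float) -> str:
        j = int(np.argmin(np.abs(self.L_grid - L0)))
        i = int(np.argmin(np.abs(self.H_grid - H0)))
        return str(self.labels[i, j])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, h0 in enumerate(self.H_grid):
            for j, l0 in enumerate(self.L_grid):
                rows.append(
                    {
                        "L0_mgdl": l0,
                        "H0_mgdl": h0,
                        "R": self.R[i, j],
                        "region": str(self.labels[i, j]) if self.labels.size else "",
                    }
                )
        return pd.DataFrame(rows)


def default_grids(n_l: int = 121, n_h: int = 21) -> tuple[np.ndarray, np.ndarray]:
    """Published grid: equidistant points over 70-190 and 40-60 mg/dL."""
    return np.linspace(70.0, 190.0, n_l), np.linspace(40.0, 60.0, n_h)


def sweep(
    L_grid,
    H_grid,
    horizon: float = 100.0,
    h: float = 2.5e-3,
    dt: float = 0.5,
    thresholds: tuple[float, float] = (T_HIGH, T_NONE),
    **scenario_kwargs,
) -> RiskMatrix:
    """Integrate every (L0, H0) pair and build the classified risk matrix.

    Individual scenario failures leave NaN cells (recorded, not fatal).
    Cells are independent; the loop is deliberately simple so callers can
    fan it out by splitting the grid.
    """
    L_grid = np.asarray(L_grid, dtype=float)
    H_grid = np.asarray(H_grid, dtype=float)
    if np.any(np.diff(L_grid) < 0) or np.any(np.diff(H_grid) < 0):
        raise ValueError("grids must be sorted ascending")
    R = np.full((len(H_grid), len(L_grid)), np.nan)
    for i, h0 in enumerate(H_grid):
        for j, l0 in enumerate(L_grid):
            res = run_scenario(
                L0=float(l0), H0=float(h0), horizon=horizon, h=h, dt=dt, **scenario_kwargs
            )
            if res.completed:
                R[i, j] = res.relative_change(horizon)
    rm = RiskMatrix(L_grid, H_grid, R, horizon, thresholds=thresholds)
    return classify(rm, thresholds)


def classify(rm: RiskMatrix, thresholds: tuple[float, float] = (T_HIGH, T_NONE)) -> RiskMatrix:
    """Label each cell I (R >= t_high), III (R <= t_none) or II.

    Idempotent; raising ``t_high`` can only shrink region I.  Failed
    (NaN) cells get an empty label.
    """
    t_high, t_none = thresholds
    if not t_high > t_none:
        raise ValueError(f"need t_high > t_none, got {thresholds!r}")
    labels = np.full(rm.R.shape, "II", dtype=object)
    labels[rm.R >= t_high] = "I"
    labels[rm.R <= t_none] = "III"
    labels[~np.isfinite(rm.R)] = ""
    rm.labels = labels
    rm.thresholds = (t_high, t_none)
    return rm
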