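"""Global sensitivity of the plaque weight: LHS design + PRCC.

Latin hypercube sampling draws each parameter uniformly from its range
with exactly one value per equiprobable stratum; the partial rank
correlation coefficient (PRCC) then measures the monotone association
between each parameter and the plaque weight at the horizon while
controlling for all other parameters: rank-transform everything, regress
the parameter ranks and the output ranks on the remaining parameters'
ranks, and correlate the residuals.  Significance uses the t statistic
with ``n - 2 - (k - 1)`` degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import qmc

from .parameters import SensitivityRange, default_sensitivity_ranges
from .simulate import run_scenario

__all__ = ["SampleDesign", "PrccResult", "lhs_sample", "prcc", "run_sensitivity"]


@dataclass
class SampleDesign:
    """n x k matrix of parameter values from a Latin hypercube."""

    names: list[str]
    values: np.ndarray  # (n, k)
    seed: int

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.names):
            raise ValueError("design must be n x k with one column per parameter")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.names)


@dataclass
class PrccResult:
    """Per-parameter PRCC and p-value against the output."""

    names: list[str]
    prcc: np.ndarray
    p_value: np.ndarray
    n_used: int
    output: str = "plaque weight at horizon"

    def __getitem__(self, name: str) -> float:
        return float(self.prcc[self.names.index(name)])

    def p_of(self, name: str) -> float:
        return float(self.p_value[self.names.index(name)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"parameter": self.names, "prcc": self.prcc, "p_value": self.p_value}
        )


def lhs_sample(
    ranges: list[SensitivityRange] | None = None, n: int = 100, seed: int = 0
) -> SampleDesign:
    """Stratified uniform design over the parameter ranges.

    Each column's sorted values fall one per stratum of width
    ``(upper-lower)/n`` (the LHS property); reproducible for a fixed seed.
    """
    ranges = ranges if ranges is not None else default_sensitivity_ranges()
    if not ranges:
        raise ValueError("no parameter ranges supplied")
    if n < 2:
        raise ValueError("need at least two samples")
    sampler = qmc.LatinHypercube(d=len(ranges), seed=seed)
    unit = sampler.random(n)
    lows = np.array([r.lower for r in ranges])
    highs = np.array([r.upper for r in ranges])
    values = qmc.scale(unit, lows, highs)
    return SampleDesign([r.name for r in ranges], values, seed)


def prcc(design: SampleDesign, outputs: np.ndarray) -> PrccResult:
    """Partial rank correlation of each design column with the output.

    Missing outputs (failed runs) are dropped with their rows.  Raises
    when the remaining sample leaves no residual degrees of freedom.
    """
    y = np.asarray(outputs, dtype=float)
    if y.shape != (design.n,):
        raise ValueError(f"expected {design.n} outputs, got shape {y.shape}")
    keep = np.isfinite(y)
    X = design.values[keep]
    y = y[keep]
    n, k = X.shape
    dof = n - 2 - (k - 1)
    if dof <= 0:
        raise ValueError(f"too few samples (n={n}) for {k} parameters")

    rX = np.apply_along_axis(stats.rankdata, 0, X)
    ry = stats.rankdata(y)
    coeffs = np.empty(k)
    for j in range(k):
        others = np.column_stack(
            [np.ones(n), np.delete(rX, j, axis=1)]
        )
        # residuals of the j-th parameter's ranks and the output's ranks
        # after removing the other parameters' (rank) linear effects
        beta_x, *_ = np.linalg.lstsq(others, rX[:, j], rcond=None)
        beta_y, *_ = np.linalg.lstsq(others, ry, rcond=None)
        ex = rX[:, j] - others @ beta_x
        ey = ry - others @ beta_y
        denom = np.linalg.norm(ex) * np.linalg.norm(ey)
        coeffs[j] = float(ex @ ey / denom) if denom > 0 else 0.0
    coeffs = np.clip(coeffs, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = coeffs * np.sqrt(dof / (1.0 - coeffs**2))
    p = 2.0 * stats.t.sf(np.abs(t), dof)
    p = np.where(np.abs(coeffs) >= 1.0, np.finfo(float).tiny, p)
    return PrccResult(list(design.names), coeffs, p, n)


def run_sensitivity(
    n: int = 100,
    seed: int = 0,
    horizon: float = 300.0,
    h: float = 5.0e-3,
    dt: float = 0.5,
    ranges: list[SensitivityRange] | None = None,
    max_failed_fraction: float = 0.10,
    **scenario_kwargs,
) -> tuple[PrccResult, SampleDesign, np.ndarray]:
    """Full pipeline: sample, simulate every draw, compute PRCC.

    Lipid levels (L0/H0) sampled in g/cm^3 are converted back to mg/dL for
    the scenario interface; all other sampled parameters are overrides in
    model units.  Failed simulations are dropped (NaN output); more than
    ``max_failed_fraction`` failures raises.  Coarse meshes are the
    intended operating point (the observable is a domain integral).
    """
    design = lhs_sample(ranges, n=n, seed=seed)
    outputs = np.full(design.n, np.nan)
    for i in range(design.n):
        draw = dict(zip(design.names, design.values[i]))
        L0 = draw.pop("L0") / 1.0e-5  # g/cm^3 -> mg/dL
        H0 = draw.pop("H0") / 1.0e-5
        res = run_scenario(
            L0=L0, H0=H0, horizon=horizon, h=h, dt=dt, overrides=draw, **scenario_kwargs
        )
        if res.completed:
            outputs[i] = res.weights[-1]
    failed = int(np.sum(~np.isfinite(outputs)))
    if failed > max_failed_fraction * design.n:
        raise RuntimeError(
            f"{failed}/{design.n} sensitivity runs failed; design flagged invalid"
        )
    return prcc(design, outputs), design, outputs
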