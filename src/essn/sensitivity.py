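"""Latin hypercube sampling and partial rank correlation sensitivity analysis.

The calibration workflow samples the parameter space with LHS (one draw in
each of N equal-probability strata per parameter, strata paired across
parameters by independent random permutations), runs the model once per
sample, and measures the monotone association between each parameter and
the output with the partial rank correlation coefficient (PRCC): the
correlation of the rank residuals after regressing out all other
parameters.  Significance uses the standard t statistic

    t = r * sqrt((N - 2 - k) / (1 - r^2)),   df = N - 2 - k,

with k the number of controlled covariates.  PRCC values near +1 (-1)
flag positive (negative) monotone input-output relationships; the p-value
separates genuine small correlations from noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ParameterSpace",
    "DesignMatrix",
    "PRCCResult",
    "lhs_sample",
    "rank_transform",
    "prcc",
    "prcc_over_time",
]


@dataclass(frozen=True)
class ParameterSpace:
    """Ordered uniform ranges, one per parameter: (name, lower, upper)."""

    ranges: tuple[tuple[str, float, float], ...]

    def __post_init__(self):
        object.__setattr__(self, "ranges", tuple((n, float(a), float(b)) for n, a, b in self.ranges))
        names = [n for n, *_ in self.ranges]
        if len(set(names)) != len(names):
            raise ValueError("parameter names must be unique")
        for n, a, b in self.ranges:
            if not a < b:
                raise ValueError(f"parameter {n!r}: lower bound {a} must be < upper bound {b}")

    @property
    def names(self) -> list[str]:
        return [n for n, *_ in self.ranges]

    @property
    def k(self) -> int:
        return len(self.ranges)


@dataclass
class DesignMatrix:
    """An N x k LHS design: sampled values plus the stratum of each cell."""

    space: ParameterSpace
    values: np.ndarray  # (N, k)
    strata: np.ndarray  # (N, k) integer stratum index per cell
    seed: int

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.space.names)

    def rows(self) -> list[dict[str, float]]:
        names = self.space.names
        return [dict(zip(names, row)) for row in self.values]


def lhs_sample(space: ParameterSpace, n: int, seed: int) -> DesignMatrix:
    """Latin hypercube sample of ``n`` points over uniform ranges.

    Each column is partitioned into ``n`` equal-width (hence, for uniform
    marginals, equal-probability) strata; one uniform draw is placed in
    each stratum and the strata are paired across columns by independent
    seeded permutations.  Reproducible for a fixed seed.
    """
    if n < 1:
        raise ValueError(f"sample size must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    k = space.k
    strata = np.empty((n, k), dtype=int)
    values = np.empty((n, k))
    for j, (name, lo, hi) in enumerate(space.ranges):
        perm = rng.permutation(n)
        u = rng.uniform(size=n)
        points = (perm + u) / n  # one point in each stratum [i/n, (i+1)/n)
        strata[:, j] = perm
        values[:, j] = lo + points * (hi - lo)
    return DesignMatrix(space=space, values=values, strata=strata, seed=seed)


def rank_transform(values: Sequence[float]) -> np.ndarray:
    """Ranks 1..N with ties receiving average ranks."""
    arr = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("rank_transform requires finite values")
    return stats.rankdata(arr, method="average")


def _rank_residuals(col: np.ndarray, controls: np.ndarray) -> np.ndarray:
    """Residual of a ranked vector after OLS on ranked controls + intercept."""
    n = col.shape[0]
    design = np.column_stack([np.ones(n), controls]) if controls.size else np.ones((n, 1))
    beta, *_ = np.linalg.lstsq(design, col, rcond=None)
    return col - design @ beta


def prcc(design: DesignMatrix, output: Sequence[float], j: int | str) -> tuple[float, float]:
    """Partial rank correlation of design column ``j`` with the output.

    All columns and the output are rank-transformed; the target column and
    the output are each regressed on the remaining k columns; the PRCC is
    the Pearson correlation of the two residual vectors.  The two-sided
    p-value comes from the t statistic with N - 2 - k degrees of freedom.
    Requires N > k + 2 and a non-degenerate (non-constant) design.
    """
    if isinstance(j, str):
        j = design.space.names.index(j)
    X = design.values
    y = np.asarray(output, dtype=float)
    n, kp1 = X.shape
    if y.shape != (n,):
        raise ValueError(f"output length {y.shape} does not match design rows {n}")
    k = kp1 - 1  # controlled covariates
    if n <= k + 2:
        raise ValueError(f"need N > k + 2 (N={n}, k={k})")
    for col in range(kp1):
        if np.ptp(X[:, col]) == 0:
            raise ValueError(f"degenerate design: column {design.space.names[col]!r} is constant")

    ranks = np.column_stack([rank_transform(X[:, c]) for c in range(kp1)])
    ry = rank_transform(y)
    controls = np.delete(ranks, j, axis=1)
    res_x = _rank_residuals(ranks[:, j], controls)
    res_y = _rank_residuals(ry, controls)
    denom = np.linalg.norm(res_x) * np.linalg.norm(res_y)
    if denom == 0:
        return 0.0, 1.0
    r = float(np.clip(res_x @ res_y / denom, -1.0, 1.0))
    df = n - 2 - k
    if abs(r) >= 1.0:
        return r, 0.0
    t = r * np.sqrt(df / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df)
    return r, float(p)


@dataclass
class PRCCResult:
    """Time-resolved PRCCs: one coefficient and p-value per (time, parameter)."""

    times: np.ndarray
    parameters: list[str]
    values: np.ndarray  # (n_times, k)
    p_values: np.ndarray
    n: int
    n_controlled: int
    alpha: float = 0.01

    def significant(self, alpha: float | None = None) -> np.ndarray:
        return self.p_values < (self.alpha if alpha is None else alpha)

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format export: time, parameter, prcc, p_value, significant."""
        rows = []
        sig = self.significant()
        for i, t in enumerate(self.times):
            for j, name in enumerate(self.parameters):
                rows.append(
                    {
                        "time": t,
                        "parameter": name,
                        "prcc": self.values[i, j],
                        "p_value": self.p_values[i, j],
                        "significant": bool(sig[i, j]),
                    }
                )
        return pd.DataFrame(rows)


def prcc_over_time(
    design: DesignMatrix,
    trajectories: Sequence,
    output_selector: Callable,
    times: Sequence[float],
    alpha: float = 0.01,
    bonferroni: bool = False,
) -> PRCCResult:
    """PRCC of every design parameter against a trajectory output over time.

    ``output_selector(trajectory, time)`` maps each of the N trajectories
    (one per design row) to a scalar output at a time point; a PRCC and
    p-value are computed per (time, parameter).  ``bonferroni`` optionally
    scales the significance level by the number of parameters.
    """
    if len(trajectories) != design.n:
        raise ValueError(
            f"need one trajectory per design row ({design.n}), got {len(trajectories)}"
        )
    times = np.asarray(list(times), dtype=float)
    k = design.space.k
    outputs = np.empty((len(times), design.n))
    for r, traj in enumerate(trajectories):
        for i, t in enumerate(times):
            outputs[i, r] = output_selector(traj, t)
    values = np.empty((len(times), k))
    pvals = np.empty((len(times), k))
    for i in range(len(times)):
        for j in range(k):
            values[i, j], pvals[i, j] = prcc(design, outputs[i], j)
    eff_alpha = alpha / k if bonferroni else alpha
    return PRCCResult(
        times=times,
        parameters=design.space.names,
        values=values,
        p_values=pvals,
        n=design.n,
        n_controlled=k - 1,
        alpha=eff_alpha,
    )
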