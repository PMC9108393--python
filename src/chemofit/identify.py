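"""Post-fit analyses: identifiability scans, residual maps, group differences.

With count data alone (and no cytokine readouts), some parameter
combinations are practically unidentifiable: the PBMC influx at the
seeding boundary depends on the product ``zeta * rho_tilde``, so the
reservoir density and the cytokine outflux coefficient trade off
reciprocally.  A two-parameter objective scan makes such ridges visible.

Residual maps aggregate signed (data - model) discrepancies across
experiments in (time, space); group-difference surfaces contrast the
aggregate binned counts of two experimental conditions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .calibrate import FitSpec, make_objective, expected_counts
from .params import StateSolution
from .quantify import BinnedCounts

__all__ = ["ContourScan", "scan_grid", "contour_scan", "residual_map",
           "group_difference", "LOG_DISPLAY_FLOOR"]

#: floor applied before log10 display of objective values
LOG_DISPLAY_FLOOR = 1e-12


@dataclass
class ContourScan:
    """Objective values on a rectangular grid of two parameters."""

    param_names: tuple[str, str]
    values_a: np.ndarray          # grid for the first parameter (rows)
    values_b: np.ndarray          # grid for the second parameter (columns)
    objective: np.ndarray         # (len(values_a), len(values_b)), raw scale
    fixed: dict

    def __post_init__(self) -> None:
        if self.objective.shape != (len(self.values_a), len(self.values_b)):
            raise ValueError("objective matrix shape inconsistent with grids")
        if not np.all(np.isfinite(self.objective)):
            raise ValueError("objective matrix must be finite (penalty-substituted)")

    def log10_objective(self) -> np.ndarray:
        """Objective on the display (log10) scale, floored at a tiny value."""
        return np.log10(np.maximum(self.objective, LOG_DISPLAY_FLOOR))

    def row_argmin(self, rtol: float = 1e-9) -> np.ndarray:
        """For each value of the first parameter, the minimising second value.

        Where a row is flat at its minimum (e.g. a parameter that has no
        effect in part of the subspace), the largest minimiser is reported,
        i.e. the upper envelope of the minimising set.
        """
        out = np.empty(len(self.values_a))
        for i, row in enumerate(self.objective):
            m = row.min()
            tol = rtol * max(abs(m), 1.0)
            out[i] = self.values_b[np.nonzero(row <= m + tol)[0][-1]]
        return out

    def to_frame(self) -> pd.DataFrame:
        a, b = np.meshgrid(self.values_a, self.values_b, indexing="ij")
        return pd.DataFrame({
            self.param_names[0]: a.ravel(),
            self.param_names[1]: b.ravel(),
            "objective": self.objective.ravel(),
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def scan_grid(f: Callable[[float, float], float], names: tuple[str, str],
              range_a: Sequence[float], range_b: Sequence[float],
              resolution: int | tuple[int, int] = 10,
              fixed: dict | None = None) -> ContourScan:
    """Evaluate a two-argument objective on a rectangular grid."""
    res_a, res_b = (resolution, resolution) if np.isscalar(resolution) else resolution
    if res_a < 2 or res_b < 2:
        raise ValueError("resolution must be >= 2 per axis")
    va = np.linspace(range_a[0], range_a[1], res_a)
    vb = np.linspace(range_b[0], range_b[1], res_b)
    mat = np.empty((res_a, res_b))
    for i, a in enumerate(va):
        for j, b in enumerate(vb):
            mat[i, j] = f(a, b)
    return ContourScan(param_names=tuple(names), values_a=va, values_b=vb,
                       objective=mat, fixed=dict(fixed or {}))


def contour_scan(data: BinnedCounts, spec: FitSpec, pair: tuple[str, str],
                 ranges: tuple[Sequence[float], Sequence[float]],
                 resolution: int | tuple[int, int] = 10) -> ContourScan:
    """Objective landscape over a two-parameter subspace.

    Both parameters of ``pair`` must be free in ``spec``; all other free
    parameters are held at the baseline values.  Ranges are in natural
    parameter units; the stored objective is on the raw scale (apply
    :meth:`ContourScan.log10_objective` for display).
    """
    for name in pair:
        if name not in spec.free_names:
            raise ValueError(f"{name!r} is not a free parameter of the fit spec")
    f_theta = make_objective(data, spec)
    theta0 = spec.params_to_theta(spec.baseline)
    ia, ib = (spec.free_names.index(p) for p in pair)

    def f(a: float, b: float) -> float:
        theta = theta0.copy()
        theta[ia] = np.log10(a) if spec.is_log(pair[0]) else a
        theta[ib] = np.log10(b) if spec.is_log(pair[1]) else b
        return f_theta(theta)

    fixed = {n: getattr(spec.baseline, n) for n in spec.free_names
             if n not in pair}
    return scan_grid(f, pair, ranges[0], ranges[1], resolution, fixed)


def residual_map(fits: Sequence[tuple[BinnedCounts, StateSolution]],
                 roi_length_um: float) -> pd.DataFrame:
    """Signed residuals (data - model) summed across experiments.

    All fits must share bin edges and imaging times.  Negative entries mean
    the model overestimates the data.  Returns a long-format frame
    (time_h, bin_index, bin_center_um, residual).
    """
    if len(fits) == 0:
        raise ValueError("need at least one (data, solution) pair")
    data0, _ = fits[0]
    edges, times = data0.bin_edges_um, data0.times
    total = np.zeros_like(data0.counts, dtype=float)
    for data, sol in fits:
        if (not np.allclose(data.bin_edges_um, edges)
                or not np.allclose(data.times, times)):
            raise ValueError("all fits must share bin edges and times")
        pred = expected_counts(sol, edges, times, roi_length_um)
        total += data.counts.astype(float) - pred
    centers = 0.5 * (edges[:-1] + edges[1:])
    nt, nb = total.shape
    return pd.DataFrame({
        "time_h": np.repeat(times, nb),
        "bin_index": np.tile(np.arange(nb), nt),
        "bin_center_um": np.tile(centers, nt),
        "residual": total.ravel(),
    })


def group_difference(datasets: Sequence[tuple[str, BinnedCounts]],
                     group_a: str = "D66-ESK",
                     group_b: str = "DP47") -> pd.DataFrame:
    """Aggregate count difference between two conditions in (time, space).

    Entry (t, b) is the summed count for ``group_a`` minus the summed count
    for ``group_b``.  Returns a long-format frame
    (time_h, bin_index, bin_center_um, difference).
    """
    groups = {group_a: None, group_b: None}
    edges = times = None
    for label, data in datasets:
        if label not in groups:
            continue
        if edges is None:
            edges, times = data.bin_edges_um, data.times
        elif (not np.allclose(data.bin_edges_um, edges)
              or not np.allclose(data.times, times)):
            raise ValueError("all datasets must share bin edges and times")
        acc = groups[label]
        groups[label] = (data.counts.astype(float) if acc is None
                         else acc + data.counts)
    for label, acc in groups.items():
        if acc is None:
            raise ValueError(f"no datasets labelled {label!r}")
    diff = groups[group_a] - groups[group_b]
    centers = 0.5 * (edges[:-1] + edges[1:])
    nt, nb = diff.shape
    return pd.DataFrame({
        "time_h": np.repeat(times, nb),
        "bin_index": np.tile(np.arange(nb), nt),
        "bin_center_um": np.tile(centers, nt),
        "difference": diff.ravel(),
    })
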