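"""Mapping model solutions onto binned-count data and the fit objective.

The model's PBMC density is integrated across each data bin to give a
real-valued expected count per (time, bin); the objective is the unweighted
sum of squared differences between observed bin counts and these expected
counts over all time points.  The expected count is the raw integral of the
density over the bin — the reservoir density ``rho_tilde`` absorbs the
overall count scale, so no separate amplitude parameter is introduced.

Free parameters are optimised either in log10 space (scale parameters:
motilities, rates, saturation constant, reservoir density) or linearly
(geometry and boundary coefficients), as declared in the :class:`FitSpec`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import yaml

from .params import ModelParams, SpatialGrid, StateSolution
from .model import simulate, SolverError, NoSteadyStateError
from .quantify import BinnedCounts

__all__ = ["FitSpec", "expected_counts", "objective", "make_objective"]

#: parameters fitted on a log10 scale by default
LOG_SCALE_DEFAULT = frozenset({
    "D_rho_bar", "D_alpha_bar", "chi_bar", "mu_rho", "mu_alpha",
    "xi", "eta1", "eta2", "kappa", "nu", "k", "rho_tilde",
})


@dataclass
class FitSpec:
    """Declaration of the free parameters and the simulation setup for a fit.

    Parameters
    ----------
    free_names : ordered names of the fitted ModelParams fields.
    bounds : per-parameter (lower, upper) in natural units.
    baseline : full parameter set supplying the fixed values.
    log_scale : per-parameter flag; defaults to True for scale parameters.
    n_cells : finite-volume resolution used during fitting.
    output_times : times (h) at which the solution is compared to data.
    roi_length_um : physical length of the imaged region mapped onto [0, 1].
    """

    free_names: list[str]
    bounds: dict[str, tuple[float, float]]
    baseline: ModelParams
    roi_length_um: float
    output_times: np.ndarray
    log_scale: dict[str, bool] = field(default_factory=dict)
    n_cells: int = 200

    def __post_init__(self) -> None:
        self.output_times = np.asarray(self.output_times, dtype=float)
        valid = set(ModelParams().to_dict())
        for name in self.free_names:
            if name not in valid:
                raise ValueError(f"unknown parameter {name!r}")
            lo, hi = self.bounds[name]
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError(f"bounds for {name!r} must be finite with lo < hi")
            if self.is_log(name) and lo <= 0:
                raise ValueError(f"log-scaled parameter {name!r} needs positive bounds")

    def is_log(self, name: str) -> bool:
        return self.log_scale.get(name, name in LOG_SCALE_DEFAULT)

    @property
    def dim(self) -> int:
        return len(self.free_names)

    def transformed_bounds(self) -> list[tuple[float, float]]:
        """Bounds in optimiser space (log10 applied where flagged)."""
        out = []
        for name in self.free_names:
            lo, hi = self.bounds[name]
            if self.is_log(name):
                out.append((np.log10(lo), np.log10(hi)))
            else:
                out.append((float(lo), float(hi)))
        return out

    def theta_to_params(self, theta: Sequence[float]) -> ModelParams:
        """Build the full parameter set from an optimiser-space vector."""
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (self.dim,):
            raise ValueError(f"theta must have shape ({self.dim},)")
        changes = {}
        for name, v in zip(self.free_names, theta):
            changes[name] = float(10.0 ** v) if self.is_log(name) else float(v)
        return self.baseline.replace(**changes)

    def params_to_theta(self, params: ModelParams) -> np.ndarray:
        vals = []
        for name in self.free_names:
            v = getattr(params, name)
            vals.append(np.log10(v) if self.is_log(name) else v)
        return np.asarray(vals, dtype=float)

    def grid(self) -> SpatialGrid:
        return SpatialGrid.for_params(self.baseline, self.n_cells)

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "free_names": list(self.free_names),
            "bounds": {k: list(v) for k, v in self.bounds.items()},
            "baseline": self.baseline.to_dict(),
            "roi_length_um": self.roi_length_um,
            "output_times": self.output_times.tolist(),
            "log_scale": dict(self.log_scale),
            "n_cells": self.n_cells,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FitSpec":
        return cls(
            free_names=list(d["free_names"]),
            bounds={k: tuple(v) for k, v in d["bounds"].items()},
            baseline=ModelParams.from_dict(d["baseline"]),
            roi_length_um=float(d["roi_length_um"]),
            output_times=np.asarray(d["output_times"], dtype=float),
            log_scale={k: bool(v) for k, v in d.get("log_scale", {}).items()},
            n_cells=int(d.get("n_cells", 200)),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "FitSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def expected_counts(solution: StateSolution, bin_edges_um: np.ndarray,
                    times: Sequence[float], roi_length_um: float) -> np.ndarray:
    """Integral of the PBMC density over each data bin at each time.

    Entry (t, b) is ``int_bin rho(x, t) dx`` with bins mapped from physical
    micrometres onto the nondimensional domain via ``roi_length_um``.
    Finite-volume cell averages are integrated exactly (midpoint rule per
    cell, partial cells weighted by their overlap fraction).
    """
    edges = np.asarray(bin_edges_um, dtype=float) / roi_length_um
    if edges[0] < -1e-12 or edges[-1] > 1 + 1e-12 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be increasing and map into [0, 1]")
    times = np.asarray(times, dtype=float)
    t_idx = []
    for t in times:
        matches = np.nonzero(np.isclose(solution.times, t, atol=1e-9))[0]
        if len(matches) == 0:
            raise ValueError(f"time {t} h not among solution output times")
        t_idx.append(matches[0])

    grid = solution.grid
    faces = grid.faces
    n_bins = len(edges) - 1
    # overlap length between FV cell i and bin b
    lo = np.maximum(faces[:-1][None, :], edges[:-1][:, None])
    hi = np.minimum(faces[1:][None, :], edges[1:][:, None])
    w = np.clip(hi - lo, 0.0, None)            # (n_bins, n_cells)
    return solution.rho[t_idx] @ w.T           # (n_times, n_bins)


def _penalty(counts: np.ndarray) -> float:
    """Finite stand-in objective for failed simulations."""
    return 1e3 * float(np.sum(np.asarray(counts, dtype=float) ** 2))


def objective(data: BinnedCounts, spec: FitSpec, theta: Sequence[float]) -> float:
    """Sum-of-squares distance between bin counts and the model solution.

    Simulates the model at ``theta`` (optimiser space) and returns
    ``sum_t sum_b (count - expected)^2`` over all data times and bins.
    Solver failures yield a large finite penalty (1000x the objective of
    the all-zero prediction) rather than an exception, so a surrogate-based
    optimiser can keep going.
    """
    params = spec.theta_to_params(theta)
    try:
        grid = SpatialGrid.for_params(params, spec.n_cells)
        sol = simulate(params, grid, spec.output_times)
        pred = expected_counts(sol, data.bin_edges_um, data.times,
                               spec.roi_length_um)
    except (SolverError, NoSteadyStateError, FloatingPointError):
        return _penalty(data.counts)
    return float(np.sum((data.counts.astype(float) - pred) ** 2))


def make_objective(data: BinnedCounts, spec: FitSpec) -> Callable[[np.ndarray], float]:
    """Bind data and spec into a pure function of the free-parameter vector."""
    def f(theta: np.ndarray) -> float:
        return objective(data, spec, theta)
    return f
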