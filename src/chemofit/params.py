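"""Model parameters, spatial grid and solution containers.

The model describes a 1-D cross-section of a three-lane microfluidic chip:
immune cells (PBMCs) enter at ``x = 0`` from the seeding channel, migrate
through a collagen matrix channel occupied by resident macrophages and may
reach the epithelial-tissue channel beyond the interface at ``x = x_t``.
Space is nondimensionalised to the unit interval; time is kept in hours.
A physical region-of-interest length (in micrometres) maps data coordinates
onto [0, 1].
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = ["ModelParams", "SpatialGrid", "StateSolution"]


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the infiltration model.

    Rates are per hour; space is nondimensional on [0, 1].  The matrix
    (middle) channel occupies ``0 < x < x_t`` and the epithelial (top)
    channel ``x_t < x < 1``.  Motility and diffusivity are reduced in the
    top channel by the factors ``mu_rho`` / ``mu_alpha`` (> 1).

    Attributes
    ----------
    D_rho_bar : PBMC random-motility coefficient in the matrix channel.
    D_alpha_bar : cytokine diffusivity in the matrix channel.
    chi_bar : chemotactic coefficient scale in the matrix channel.
    mu_rho : reduction factor (> 1) for cell motility and chemotaxis in
        the top channel.
    mu_alpha : reduction factor (> 1) for cytokine diffusivity in the top
        channel.
    xi : sink rate accounting for cells leaving the imaged region
        sideways, 1/h.
    eta1 : macrophage-derived cytokine production rate, uniform over the
        matrix channel, conc/h.
    eta2 : target-engagement cytokine release rate per unit PBMC density
        in the top channel, conc/(density*h); zero for a non-targeting
        control compound.
    kappa : cytokine uptake rate by PBMCs, 1/(density*h).
    nu : cytokine degradation rate, 1/h.
    k : receptor-law saturation constant (concentration units).
    zeta : cytokine outflux coefficient at x = 0, per nondim length.
    rho_tilde : constant PBMC source density in the seeding channel.
    x_t : matrix/epithelium interface position, in (0, 1).
    """

    D_rho_bar: float = 0.002
    D_alpha_bar: float = 0.05
    chi_bar: float = 2.0
    mu_rho: float = 1000.0
    mu_alpha: float = 2.0
    xi: float = 0.08
    eta1: float = 0.05
    eta2: float = 0.0
    kappa: float = 0.0
    nu: float = 0.0
    k: float = 10.0
    zeta: float = 0.5
    rho_tilde: float = 100.0
    x_t: float = 0.5

    def __post_init__(self) -> None:
        nonneg = (
            "D_rho_bar", "D_alpha_bar", "chi_bar", "xi", "eta1", "eta2",
            "kappa", "nu", "zeta", "rho_tilde",
        )
        for name in nonneg:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.k <= 0:
            raise ValueError(f"k must be > 0, got {self.k}")
        if self.mu_rho <= 1 or self.mu_alpha <= 1:
            raise ValueError("mu_rho and mu_alpha must be > 1")
        if not 0 < self.x_t < 1:
            raise ValueError(f"x_t must lie in (0, 1), got {self.x_t}")

    # -- piecewise coefficient helpers -------------------------------------

    def d_rho(self, x: np.ndarray) -> np.ndarray:
        """Piecewise-constant PBMC diffusivity D_rho(x)."""
        return np.where(np.asarray(x) < self.x_t, self.D_rho_bar,
                        self.D_rho_bar / self.mu_rho)

    def d_alpha(self, x: np.ndarray) -> np.ndarray:
        """Piecewise-constant cytokine diffusivity D_alpha(x)."""
        return np.where(np.asarray(x) < self.x_t, self.D_alpha_bar,
                        self.D_alpha_bar / self.mu_alpha)

    def chi_tilde(self, x: np.ndarray) -> np.ndarray:
        """Piecewise-constant chemotactic coefficient scale."""
        return np.where(np.asarray(x) < self.x_t, self.chi_bar,
                        self.chi_bar / self.mu_rho)

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        return cls(**d)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "ModelParams":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ModelParams":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def replace(self, **changes) -> "ModelParams":
        return replace(self, **changes)


@dataclass(frozen=True)
class SpatialGrid:
    """Uniform finite-volume grid on [0, 1] with the channel interface on a face.

    The interface position is snapped to the nearest interior face so that
    no cell straddles the coefficient discontinuity.
    """

    n_cells: int
    x_t: float

    def __post_init__(self) -> None:
        if self.n_cells < 2:
            raise ValueError("need at least 2 cells")
        if not 0 < self.x_t < 1:
            raise ValueError("x_t must lie in (0, 1)")
        # snap x_t onto the nearest interior face
        idx = int(round(self.x_t * self.n_cells))
        idx = min(max(idx, 1), self.n_cells - 1)
        object.__setattr__(self, "interface_face_index", idx)
        object.__setattr__(self, "x_t", idx / self.n_cells)

    interface_face_index: int = field(init=False)

    @property
    def h(self) -> float:
        return 1.0 / self.n_cells

    @property
    def faces(self) -> np.ndarray:
        return np.linspace(0.0, 1.0, self.n_cells + 1)

    @property
    def cell_centers(self) -> np.ndarray:
        return (np.arange(self.n_cells) + 0.5) / self.n_cells

    @classmethod
    def for_params(cls, params: ModelParams, n_cells: int = 200) -> "SpatialGrid":
        return cls(n_cells=n_cells, x_t=params.x_t)


@dataclass
class StateSolution:
    """PDE solution sampled at requested output times.

    ``rho`` and ``alpha`` are (n_times, n_cells) arrays of cell-average
    values.  ``influx_record`` holds the chemotactic PBMC influx through
    x = 0 at each output time (cells per unit nondim length per hour);
    ``alpha_outflux_record`` the diffusive cytokine outflux there.
    """

    grid: SpatialGrid
    times: np.ndarray
    rho: np.ndarray
    alpha: np.ndarray
    influx_record: np.ndarray
    alpha_outflux_record: np.ndarray

    def __post_init__(self) -> None:
        nt, nc = len(self.times), self.grid.n_cells
        if self.rho.shape != (nt, nc) or self.alpha.shape != (nt, nc):
            raise ValueError("state matrix shapes inconsistent with grid/times")

    def total_cells(self) -> np.ndarray:
        """Integral of rho over the domain at each output time."""
        return self.rho.sum(axis=1) * self.grid.h

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (time_h, x, rho, alpha) for plotting/export."""
        x = self.grid.cell_centers
        nt = len(self.times)
        return pd.DataFrame({
            "time_h": np.repeat(self.times, len(x)),
            "x": np.tile(x, nt),
            "rho": self.rho.ravel(),
            "alpha": self.alpha.ravel(),
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)
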