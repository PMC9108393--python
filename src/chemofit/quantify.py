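"""Declumped cell counting and spatial binning of segmented-particle tables.

Upstream image analysis (z-projection, thresholding, watershed, particle
analysis) exports one record per segmented region with its position along
the infiltration axis and its area.  Watershed segmentation can fail to
separate tightly clumped cells, so region areas above a threshold are
interpreted as multiple co-located cells: the count is the area divided by
the single-cell threshold area (50 um^2, a PBMC being < 10 um across),
rounded half-up, with a minimum of one.  Any region above 75 um^2 therefore
counts as at least two cells.

The spatial distribution at each imaging time is summarised by splitting
the region of interest into equal-width bins (20 by default) and counting
declumped cells per bin.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "CELL_AREA_UM2",
    "declump",
    "bin_counts",
    "summarize_infiltration",
    "BinnedCounts",
    "read_particle_table",
    "write_particle_table",
]

#: threshold single-cell area in um^2
CELL_AREA_UM2 = 50.0

PARTICLE_COLUMNS = ["experiment_id", "condition", "time_h", "x_um", "area_um2"]


def declump(area_um2, threshold: float = CELL_AREA_UM2):
    """Number of cells in a segmented region of the given area.

    ``max(1, round_half_up(area / threshold))`` — rounding half-up so the
    stated boundary is consistent: areas of exactly 1.5x the threshold
    count as two cells.

    Accepts a scalar or an array; returns int or an int array.
    """
    area = np.asarray(area_um2, dtype=float)
    if np.any(area <= 0):
        raise ValueError("particle area must be positive")
    counts = np.maximum(1, np.floor(area / threshold + 0.5).astype(int))
    return counts if counts.ndim else int(counts)


@dataclass
class BinnedCounts:
    """Integer declumped cell counts per imaging time and spatial bin."""

    bin_edges_um: np.ndarray        # length n_bins + 1, equal width over ROI
    times: np.ndarray               # imaging times, hours
    counts: np.ndarray              # (n_times, n_bins) integer matrix

    def __post_init__(self) -> None:
        self.bin_edges_um = np.asarray(self.bin_edges_um, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.times), len(self.bin_edges_um) - 1):
            raise ValueError("count matrix shape inconsistent with times/edges")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")

    @property
    def n_bins(self) -> int:
        return len(self.bin_edges_um) - 1

    @property
    def roi_length_um(self) -> float:
        return float(self.bin_edges_um[-1])

    def totals(self) -> np.ndarray:
        """Declumped total cell count per time point."""
        return self.counts.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        nt, nb = self.counts.shape
        return pd.DataFrame({
            "time_h": np.repeat(self.times, nb),
            "bin_index": np.tile(np.arange(nb), nt),
            "bin_left_um": np.tile(self.bin_edges_um[:-1], nt),
            "bin_right_um": np.tile(self.bin_edges_um[1:], nt),
            "count": self.counts.ravel(),
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "BinnedCounts":
        times = np.sort(df["time_h"].unique())
        nb = int(df["bin_index"].max()) + 1
        edges = np.empty(nb + 1)
        first = df[df["time_h"] == times[0]].sort_values("bin_index")
        edges[:-1] = first["bin_left_um"].to_numpy()
        edges[-1] = first["bin_right_um"].to_numpy()[-1]
        counts = (df.pivot_table(index="time_h", columns="bin_index",
                                 values="count", aggfunc="sum")
                  .reindex(index=times, columns=range(nb))
                  .to_numpy())
        return cls(bin_edges_um=edges, times=times, counts=counts.astype(int))

    @classmethod
    def from_csv(cls, path) -> "BinnedCounts":
        return cls.from_frame(pd.read_csv(path))


def _validate_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in PARTICLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"particle table missing columns: {missing}")
    return table


def bin_counts(table: pd.DataFrame, roi_length_um: float,
               n_bins: int = 20) -> BinnedCounts:
    """Bin declumped cell counts by position for each imaging time.

    Bins are half-open ``[a, b)`` except the last, which is closed so the
    bins partition the region of interest exactly.  Each particle
    contributes ``declump(area)`` cells to the bin containing its position.
    """
    _validate_table(table)
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    pos = table["x_um"].to_numpy(dtype=float)
    bad = (pos < 0) | (pos > roi_length_um)
    if np.any(bad):
        rows = table.index[bad].tolist()
        raise ValueError(
            f"positions outside the region of interest [0, {roi_length_um}] "
            f"in rows {rows[:10]}{'...' if len(rows) > 10 else ''}")

    times = np.sort(table["time_h"].unique())
    edges = np.linspace(0.0, roi_length_um, n_bins + 1)
    counts = np.zeros((len(times), n_bins), dtype=int)
    cells = declump(table["area_um2"].to_numpy())
    cells = np.atleast_1d(cells)
    bin_idx = np.minimum((pos / roi_length_um * n_bins).astype(int), n_bins - 1)
    t_idx = np.searchsorted(times, table["time_h"].to_numpy())
    np.add.at(counts, (t_idx, bin_idx), cells)
    return BinnedCounts(bin_edges_um=edges, times=times, counts=counts)


def summarize_infiltration(table: pd.DataFrame, at_time_h: float) -> pd.DataFrame:
    """Per-condition infiltration summaries at one imaging time.

    Returns one row per condition with the mean declumped total per
    experiment and the mean distance travelled per cell (the recorded
    position along the infiltration axis, each region weighted by its
    declumped cell count).  Conditions with no records get NaN statistics
    and ``n_experiments = 0``.
    """
    _validate_table(table)
    if at_time_h not in set(table["time_h"].unique()):
        raise ValueError(f"time {at_time_h} h not present in the table")
    snap = table[table["time_h"] == at_time_h].copy()
    snap["cells"] = np.atleast_1d(declump(snap["area_um2"].to_numpy()))

    rows = []
    for cond, grp in snap.groupby("condition", sort=True):
        per_exp = grp.groupby("experiment_id")["cells"].sum()
        total_cells = grp["cells"].sum()
        mean_dist = (float((grp["x_um"] * grp["cells"]).sum() / total_cells)
                     if total_cells > 0 else float("nan"))
        rows.append({
            "condition": cond,
            "n_experiments": len(per_exp),
            "mean_total_cells": float(per_exp.mean()),
            "mean_distance_um": mean_dist,
        })
    return pd.DataFrame(rows)


def read_particle_table(path) -> pd.DataFrame:
    """Read a particle table CSV and validate its schema."""
    df = pd.read_csv(path)
    _validate_table(df)
    if np.any(df["area_um2"].to_numpy() <= 0):
        raise ValueError("particle areas must be strictly positive")
    return df


def write_particle_table(table: pd.DataFrame, path) -> None:
    _validate_table(table)
    table.to_csv(path, index=False, columns=PARTICLE_COLUMNS)
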