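"""Synthetic particle tables with the structure of the chip imaging study.

The generator emulates the data exported by the upstream image-analysis
pipeline: per-experiment tables of segmented regions (time, position along
the infiltration axis, area).  A study comprises 16 experiments — 8 with a
non-targeting control compound (condition ``DP47``, no target-induced
cytokine release, ``eta2 = 0``) and 8 with a cytotoxic compound
(``D66-ESK``, ``eta2 > 0``) — imaged every 2 h out to 48 h, with the
matrix/epithelium interface at 350 um in a 700 um region of interest.

Counts per (time, bin) are drawn from a Poisson distribution around the
model's expected bin counts (or rounded means in noise-free mode), cells
are placed uniformly within their bin, and region areas are drawn from a
singleton/clump mixture so that declumping is exercised.  Counts are
independent across frames — a deliberate simplification (real cells
persist between images), adequate because only binned counts feed the
fitting objective.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

from .params import ModelParams, SpatialGrid, StateSolution
from .model import simulate
from .quantify import BinnedCounts, CELL_AREA_UM2, declump, bin_counts
from .calibrate import expected_counts

__all__ = [
    "StudyDesign",
    "control_params",
    "toxic_params",
    "generate_experiment",
    "generate_dataset",
]

CONTROL_LABEL = "DP47"
TOXIC_LABEL = "D66-ESK"


def control_params() -> ModelParams:
    """Ground-truth parameters for the control (non-targeting) condition.

    Chosen so a default study reproduces the qualitative phases seen on
    chip: infiltration building over roughly the first day, the leading
    cells reaching the interface around 12 h, accumulation against the
    epithelial interface, and a saturating total of a few hundred cells.
    """
    return ModelParams()  # eta2 = 0: no target-induced release


def toxic_params() -> ModelParams:
    """Ground truth for the cytotoxic condition: target-induced release on.

    Identical to the control except ``eta2 > 0``: once infiltrating cells
    cross into the epithelial channel, target engagement releases extra
    chemoattractant, amplifying recruitment after the arrival of the
    leading cells.
    """
    return ModelParams(eta2=0.02)


@dataclass(frozen=True)
class StudyDesign:
    """Layout and noise model of a synthetic infiltration study."""

    n_control: int = 8
    n_toxic: int = 8
    interval_h: float = 2.0
    horizon_h: float = 48.0
    roi_length_um: float = 700.0
    interface_um: float = 350.0
    params_control: ModelParams = field(default_factory=control_params)
    params_toxic: ModelParams = field(default_factory=toxic_params)
    noise: str = "poisson"            # "poisson" or "none"
    n_bins: int = 20
    n_cells: int = 200
    clump_probability: float = 0.1
    area_median_um2: float = 40.0
    area_sigma_log: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_control < 1 or self.n_toxic < 1:
            raise ValueError("need at least one experiment per condition")
        n_frames = self.horizon_h / self.interval_h
        if abs(n_frames - round(n_frames)) > 1e-9:
            raise ValueError("horizon must be a multiple of the imaging interval")
        if not 0 < self.interface_um < self.roi_length_um:
            raise ValueError("interface must lie inside the region of interest")
        if self.noise not in ("poisson", "none"):
            raise ValueError("noise must be 'poisson' or 'none'")
        for cond, p in (("control", self.params_control), ("toxic", self.params_toxic)):
            expect_xt = self.interface_um / self.roi_length_um
            if abs(p.x_t - expect_xt) > 1e-9:
                raise ValueError(
                    f"{cond} parameters have x_t={p.x_t}, inconsistent with "
                    f"interface {self.interface_um}/{self.roi_length_um} um")

    @property
    def times(self) -> np.ndarray:
        return np.arange(0.0, self.horizon_h + 0.5 * self.interval_h,
                         self.interval_h)

    def params_for(self, condition: str) -> ModelParams:
        if condition == CONTROL_LABEL:
            return self.params_control
        if condition == TOXIC_LABEL:
            return self.params_toxic
        raise ValueError(f"condition {condition!r} not defined in the design")

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "n_control", "n_toxic", "interval_h", "horizon_h",
            "roi_length_um", "interface_um", "noise", "n_bins", "n_cells",
            "clump_probability", "area_median_um2", "area_sigma_log", "seed")}
        d["params_control"] = self.params_control.to_dict()
        d["params_toxic"] = self.params_toxic.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StudyDesign":
        d = dict(d)
        for key in ("params_control", "params_toxic"):
            if key in d and isinstance(d[key], dict):
                d[key] = ModelParams.from_dict(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "StudyDesign":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


@lru_cache(maxsize=32)
def _expected_matrix_cached(params: ModelParams, n_cells: int,
                            times_key: tuple, n_bins: int,
                            roi_length_um: float) -> np.ndarray:
    """Expected bin-count matrix at the ground truth (memoised: the PDE
    solve is shared across replicate experiments of one condition)."""
    grid = SpatialGrid.for_params(params, n_cells)
    times = np.asarray(times_key)
    sol = simulate(params, grid, times)
    edges = np.linspace(0.0, roi_length_um, n_bins + 1)
    return expected_counts(sol, edges, times, roi_length_um)


def expected_bin_counts(design: StudyDesign, condition: str) -> np.ndarray:
    """Ground-truth expected counts per (time, bin) for one condition."""
    return _expected_matrix_cached(
        design.params_for(condition), design.n_cells,
        tuple(design.times.tolist()), design.n_bins, design.roi_length_um)


def _draw_singleton_area(rng: np.random.Generator, design: StudyDesign) -> float:
    """Lognormal single-cell area, truncated below the two-cell boundary
    so a singleton always declumps back to one cell."""
    upper = 1.5 * CELL_AREA_UM2
    for _ in range(100):
        a = rng.lognormal(np.log(design.area_median_um2), design.area_sigma_log)
        if a < upper:
            return a
    return design.area_median_um2


def _draw_clump_area(rng: np.random.Generator, design: StudyDesign,
                     m: int) -> float:
    """Area of an m-cell clump: sum of m singleton draws, resampled until
    it declumps back to exactly m (count-consistent by construction)."""
    for _ in range(50):
        a = sum(rng.lognormal(np.log(design.area_median_um2),
                              design.area_sigma_log) for _ in range(m))
        if declump(a) == m:
            return a
    return m * CELL_AREA_UM2


def generate_experiment(design: StudyDesign, condition: str,
                        seed: int | np.random.Generator,
                        experiment_id: str | None = None) -> pd.DataFrame:
    """Generate one experiment's particle table.

    Per (time, bin) the cell count is Poisson around the model's expected
    bin count (or the rounded mean in noise-free mode); cells are placed
    uniformly within the bin.  In Poisson mode each cell may merge into a
    clump with its neighbours (probability ``clump_probability``), giving
    multi-cell regions whose areas declump back to the correct count; in
    noise-free mode every region is a singleton so binned declumped counts
    reproduce the rounded expected counts exactly.
    """
    rng = np.random.default_rng(seed)
    mean = expected_bin_counts(design, condition)
    edges = np.linspace(0.0, design.roi_length_um, design.n_bins + 1)
    times = design.times
    if experiment_id is None:
        experiment_id = f"{condition}-{seed if isinstance(seed, int) else 'rng'}"

    recs: list[tuple] = []
    for it, t in enumerate(times):
        for ib in range(design.n_bins):
            mu = mean[it, ib]
            n = (int(np.floor(mu + 0.5)) if design.noise == "none"
                 else int(rng.poisson(mu)))
            if n == 0:
                continue
            left, right = edges[ib], edges[ib + 1]
            remaining = n
            while remaining > 0:
                # group consecutive cells into one clumped region
                m = 1
                if design.noise == "poisson":
                    while (m < remaining and m < 4
                           and rng.random() < design.clump_probability):
                        m += 1
                pos = rng.uniform(left, right)
                area = (_draw_singleton_area(rng, design) if m == 1
                        else _draw_clump_area(rng, design, m))
                recs.append((experiment_id, condition, float(t), pos, area))
                remaining -= m
    return pd.DataFrame(recs, columns=[
        "experiment_id", "condition", "time_h", "x_um", "area_um2"])


def generate_dataset(design: StudyDesign) -> tuple[pd.DataFrame,
                                                   list[tuple[str, BinnedCounts]]]:
    """Generate the full study: all experiments plus per-experiment bin counts.

    Per-experiment seeds are spawned from the design's master seed, so the
    whole dataset is reproducible from the design alone.  Returns the
    concatenated particle table and a list of (condition, BinnedCounts)
    pairs in experiment order.
    """
    ss = np.random.SeedSequence(design.seed)
    children = ss.spawn(design.n_control + design.n_toxic)
    tables = []
    binned: list[tuple[str, BinnedCounts]] = []
    labels = ([CONTROL_LABEL] * design.n_control
              + [TOXIC_LABEL] * design.n_toxic)
    for i, (label, child) in enumerate(zip(labels, children)):
        rng = np.random.default_rng(child)
        table = generate_experiment(design, label, rng,
                                    experiment_id=f"exp{i:02d}-{label}")
        tables.append(table)
        bc = bin_counts(table, design.roi_length_um, design.n_bins) \
            if len(table) else BinnedCounts(
                bin_edges_um=np.linspace(0, design.roi_length_um,
                                         design.n_bins + 1),
                times=design.times,
                counts=np.zeros((len(design.times), design.n_bins), dtype=int))
        # ensure every imaging time appears even if no cells were detected
        bc = _align_times(bc, design)
        binned.append((label, bc))
    return pd.concat(tables, ignore_index=True), binned


def _align_times(bc: BinnedCounts, design: StudyDesign) -> BinnedCounts:
    times = design.times
    counts = np.zeros((len(times), design.n_bins), dtype=int)
    for i, t in enumerate(bc.times):
        j = int(np.argmin(np.abs(times - t)))
        counts[j] = bc.counts[i]
    return BinnedCounts(bin_edges_um=bc.bin_edges_um, times=times,
                        counts=counts)
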