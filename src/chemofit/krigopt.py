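"""Kriging-based global optimisation with expected improvement.

An efficient-global-optimisation (EGO) style workflow for expensive,
deterministic objectives such as a PDE-fit sum of squares:

1. evaluate the objective on a Latin hypercube design;
2. fit an anisotropic Matern-5/2 Gaussian-process (ordinary Kriging)
   surrogate to the log10 of the observed values;
3. propose a batch of candidates from distinct criteria — maximum expected
   improvement (maximised with differential evolution), minimum predictive
   mean, maximum predictive standard deviation, then constant-liar EI
   repeats;
4. evaluate the true objective at the batch, update the surrogate;
5. on stagnation, shrink the search box around the incumbent; stop on
   budget exhaustion or a negligible maximum expected improvement.

All randomness flows from a single seed, so runs are exactly reproducible.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import differential_evolution
from scipy.stats import norm, qmc
from sklearn.exceptions import ConvergenceWarning
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern

__all__ = [
    "latin_hypercube",
    "SurrogateModel",
    "fit_kriging",
    "expected_improvement",
    "propose_batch",
    "reduce_domain",
    "optimize",
    "OptimResult",
    "OptimizationError",
]

#: candidates closer than this (unit-box distance) to an existing point are dropped
DEDUPE_RADIUS = 1e-3

_DE_SETTINGS = dict(strategy="rand1bin", maxiter=100, popsize=15,
                    mutation=0.8, recombination=0.9, tol=1e-6,
                    polish=False, init="latinhypercube",
                    updating="deferred", vectorized=True)


class OptimizationError(RuntimeError):
    """Raised when no finite objective value could be obtained."""

    def __init__(self, message: str, history: pd.DataFrame | None = None):
        super().__init__(message)
        self.history = history


def latin_hypercube(n: int, d: int, seed=None) -> np.ndarray:
    """Latin hypercube sample of ``n`` points in the ``d``-dimensional unit box.

    Every dimension has exactly one point in each of the ``n`` equal strata.
    Deterministic for a fixed seed.
    """
    if n < 1 or d < 1:
        raise ValueError("n and d must be >= 1")
    sampler = qmc.LatinHypercube(d=d, seed=seed)
    return sampler.random(n)


@dataclass
class SurrogateModel:
    """A fitted ordinary-Kriging surrogate on unit-box-scaled inputs."""

    X: np.ndarray                  # (n, d) training inputs, unit box
    y: np.ndarray                  # (n,) training values (already transformed)
    gpr: GaussianProcessRegressor
    nugget: float

    @property
    def dim(self) -> int:
        return self.X.shape[1]

    def predict(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Predictive mean and standard deviation at ``X`` (n, d)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        mu, sd = self.gpr.predict(X, return_std=True)
        return mu, sd

    @property
    def length_scales(self) -> np.ndarray:
        return np.atleast_1d(self.gpr.kernel_.k2.length_scale)


def _dedupe(X: np.ndarray, y: np.ndarray, radius: float) -> tuple[np.ndarray, np.ndarray]:
    """Drop near-duplicate training points, keeping the best value of each group."""
    order = np.argsort(y)          # best first, so kept point has the best y
    keep: list[int] = []
    for i in order:
        if all(np.linalg.norm(X[i] - X[j]) >= radius for j in keep):
            keep.append(i)
    keep_sorted = sorted(keep)
    return X[keep_sorted], y[keep_sorted]


def fit_kriging(X: np.ndarray, y: np.ndarray, nugget: float = 1e-10,
                n_restarts: int = 5, seed=None) -> SurrogateModel:
    """Fit an anisotropic Matern-5/2 Gaussian process to (X, y).

    Inputs are expected in (or scaled to) the unit box.  Hyperparameters
    (per-dimension length scales, signal variance) maximise the marginal
    likelihood with multi-restart L-BFGS; the constant trend is handled by
    target normalisation (ordinary Kriging).  Ill-conditioned covariance
    triggers automatic nugget escalation.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n, d = X.shape
    if n < d + 2:
        raise ValueError(f"need at least d + 2 = {d + 2} points, got {n}")
    if not np.all(np.isfinite(y)):
        raise ValueError("training values must be finite")
    X, y = _dedupe(X, y, DEDUPE_RADIUS)

    kernel = ConstantKernel(1.0, (1e-8, 1e8)) * Matern(
        length_scale=np.full(X.shape[1], 0.3),
        length_scale_bounds=(1e-3, 1e3), nu=2.5)
    current = nugget
    last_exc: Exception | None = None
    for _ in range(8):
        gpr = GaussianProcessRegressor(
            kernel=kernel, alpha=max(current, 1e-12), normalize_y=True,
            n_restarts_optimizer=n_restarts, random_state=_to_int_seed(seed))
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                gpr.fit(X, y)
            return SurrogateModel(X=X, y=y, gpr=gpr, nugget=current)
        except np.linalg.LinAlgError as exc:
            last_exc = exc
            current = max(current * 100, 1e-10 * 100)
            warnings.warn(f"covariance ill-conditioned; nugget escalated to {current:g}")
    raise RuntimeError(f"Kriging fit failed even with nugget {current:g}") from last_exc


def _to_int_seed(seed) -> int | None:
    if seed is None or isinstance(seed, (int, np.integer)):
        return None if seed is None else int(seed)
    if isinstance(seed, np.random.Generator):
        return int(seed.integers(2**31 - 1))
    return int(seed)


def expected_improvement(model: SurrogateModel, x: np.ndarray,
                         f_min: float) -> np.ndarray | float:
    """Expected improvement of candidate(s) ``x`` over the best value ``f_min``.

    ``EI = (f_min - mu) Phi(z) + sigma phi(z)`` with
    ``z = (f_min - mu) / sigma``; at ``sigma = 0`` it degenerates to
    ``max(0, f_min - mu)``.
    """
    x = np.asarray(x, dtype=float)
    scalar = x.ndim == 1
    mu, sd = model.predict(np.atleast_2d(x))
    imp = f_min - mu
    pos = sd > 0
    safe_sd = np.where(pos, sd, 1.0)
    z = imp / safe_sd
    ei = np.where(pos, imp * norm.cdf(z) + sd * norm.pdf(z),
                  np.maximum(imp, 0.0))
    ei = np.maximum(ei, 0.0)
    return float(ei[0]) if scalar else ei


def _de_maximize(acq: Callable[[np.ndarray], np.ndarray], d: int,
                 rng: np.random.Generator) -> tuple[np.ndarray, float]:
    """Maximise an acquisition over the unit box with differential evolution."""
    def neg(xT):  # vectorized: xT has shape (d, S)
        X = np.atleast_2d(np.asarray(xT, dtype=float).T)
        return -acq(X)

    res = differential_evolution(
        neg, bounds=[(0.0, 1.0)] * d,
        seed=int(rng.integers(2**31 - 1)), **_DE_SETTINGS)
    return np.clip(res.x, 0.0, 1.0), -float(np.atleast_1d(res.fun)[0])


def _min_dist(x: np.ndarray, pts: np.ndarray) -> float:
    if len(pts) == 0:
        return np.inf
    return float(np.min(np.linalg.norm(pts - x[None, :], axis=1)))


def propose_batch(model: SurrogateModel, q: int, f_min: float | None = None,
                  rng: np.random.Generator | None = None,
                  return_criteria: bool = False):
    """Propose ``q`` pairwise-distinct candidates in the unit box.

    Candidates come from distinct criteria in order: maximum expected
    improvement (via differential evolution), minimum predictive mean,
    maximum predictive standard deviation, then constant-liar EI repeats
    (the surrogate is re-conditioned on the pending candidates with the
    lying value ``f_min``).  Candidates that collapse onto training points
    or each other are replaced by a fresh random point.
    """
    if q < 1:
        raise ValueError("q must be >= 1")
    rng = np.random.default_rng(rng)
    if f_min is None:
        f_min = float(np.min(model.y))
    d = model.dim

    chosen: list[np.ndarray] = []
    criteria: list[str] = []
    max_ei = 0.0

    def admissible(x: np.ndarray) -> bool:
        pool = np.vstack([model.X] + [c[None, :] for c in chosen]) \
            if chosen else model.X
        return _min_dist(x, pool) >= DEDUPE_RADIUS

    def push(x: np.ndarray, label: str) -> None:
        if admissible(x):
            chosen.append(x)
            criteria.append(label)
        else:
            # collapse onto an existing point: fall back to a fresh random draw
            for _ in range(100):
                cand = rng.random(d)
                if admissible(cand):
                    chosen.append(cand)
                    criteria.append("random_fallback")
                    return
            warnings.warn("could not find an admissible fallback point")

    # 1. max EI
    x_ei, ei_val = _de_maximize(
        lambda X: expected_improvement(model, X, f_min), d, rng)
    max_ei = ei_val
    push(x_ei, "max_ei")

    # 2. min predictive mean
    if len(chosen) < q:
        x_mu, _ = _de_maximize(lambda X: -model.predict(X)[0], d, rng)
        push(x_mu, "min_mean")

    # 3. max predictive sd
    if len(chosen) < q:
        x_sd, _ = _de_maximize(lambda X: model.predict(X)[1], d, rng)
        push(x_sd, "max_sd")

    # 4+. constant-liar EI: re-condition on pending points at the lie f_min
    while len(chosen) < q:
        X_aug = np.vstack([model.X] + [c[None, :] for c in chosen])
        y_aug = np.concatenate([model.y, np.full(len(chosen), f_min)])
        liar_gpr = GaussianProcessRegressor(
            kernel=model.gpr.kernel_, alpha=max(model.nugget, 1e-10),
            normalize_y=True, optimizer=None)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            liar_gpr.fit(X_aug, y_aug)
        liar = SurrogateModel(X=X_aug, y=y_aug, gpr=liar_gpr, nugget=model.nugget)
        x_cl, _ = _de_maximize(
            lambda X: expected_improvement(liar, X, f_min), d, rng)
        push(x_cl, "constant_liar")

    batch = np.vstack(chosen[:q])
    if return_criteria:
        return batch, criteria[:q], max_ei
    return batch


def reduce_domain(bounds: Sequence[tuple[float, float]], incumbent: np.ndarray,
                  shrink_factor: float) -> list[tuple[float, float]]:
    """Shrink the search box around the incumbent.

    The box is recentred on the incumbent with each width scaled by
    ``shrink_factor`` and clipped to the original bounds.
    """
    if not 0 < shrink_factor < 1:
        raise ValueError("shrink_factor must be in (0, 1)")
    incumbent = np.asarray(incumbent, dtype=float)
    out = []
    for (lo, hi), c in zip(bounds, incumbent):
        if not lo <= c <= hi:
            raise ValueError("incumbent must lie within the bounds")
        half = 0.5 * (hi - lo) * shrink_factor
        new_lo, new_hi = max(lo, c - half), min(hi, c + half)
        out.append((new_lo, new_hi))
    return out


@dataclass
class OptimResult:
    """Outcome of a surrogate-based optimisation run."""

    x: np.ndarray                      # incumbent point (original units)
    fun: float                         # incumbent objective value
    history: pd.DataFrame              # point, objective, batch, criterion
    bounds: list[tuple[float, float]]  # final (possibly reduced) bounds
    initial_bounds: list[tuple[float, float]]
    n_evaluations: int
    n_reductions: int
    termination: str
    seed: int | None

    def to_json(self, path=None) -> str:
        payload = {
            "x": np.asarray(self.x).tolist(),
            "fun": self.fun,
            "bounds": [list(b) for b in self.bounds],
            "initial_bounds": [list(b) for b in self.initial_bounds],
            "n_evaluations": self.n_evaluations,
            "n_reductions": self.n_reductions,
            "termination": self.termination,
            "seed": self.seed,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def history_to_csv(self, path) -> None:
        self.history.to_csv(path, index=False)


def _scale_to_unit(X: np.ndarray, bounds) -> np.ndarray:
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    return (X - lo) / (hi - lo)


def _scale_from_unit(U: np.ndarray, bounds) -> np.ndarray:
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    return lo + U * (hi - lo)


def optimize(f: Callable[[np.ndarray], float],
             bounds: Sequence[tuple[float, float]],
             budget: int = 500, q: int = 4, seed: int | None = None,
             init_size: int | None = None,
             log_objective: bool = True,
             shrink_factor: float = 0.5,
             stagnation_batches: int = 5,
             stagnation_rtol: float = 1e-3,
             max_reductions: int = 4,
             ei_tol: float = 1e-6) -> OptimResult:
    """Surrogate-based global minimisation of an expensive objective.

    Runs the full workflow: Latin-hypercube initial design (``10 d`` points
    by default), Kriging surrogate on log10-transformed values, batched
    proposals from distinct acquisition criteria, domain reduction after
    ``stagnation_batches`` consecutive batches with relative improvement
    below ``stagnation_rtol`` (at most ``max_reductions`` times, factor
    ``shrink_factor``), terminating when the evaluation budget is exhausted
    or the maximum expected improvement falls below
    ``ei_tol * |incumbent|``.
    """
    bounds = [(float(lo), float(hi)) for lo, hi in bounds]
    d = len(bounds)
    if init_size is None:
        init_size = 10 * d
    if budget < init_size:
        raise ValueError(f"budget ({budget}) must cover the initial design ({init_size})")
    rng = np.random.default_rng(seed)

    X_all: list[np.ndarray] = []
    y_all: list[float] = []
    records: list[dict] = []

    def evaluate(x: np.ndarray, batch: int, criterion: str) -> float:
        try:
            val = float(f(np.asarray(x, dtype=float)))
        except Exception as exc:  # noqa: BLE001 - objective failures are data
            warnings.warn(f"objective raised at {x}: {exc}")
            val = np.nan
        X_all.append(np.asarray(x, dtype=float))
        y_all.append(val)
        records.append({**{f"x{i}": x[i] for i in range(d)},
                        "objective": val, "batch": batch,
                        "criterion": criterion})
        return val

    # --- initial design ---------------------------------------------------
    design = _scale_from_unit(
        latin_hypercube(init_size, d, seed=int(rng.integers(2**31 - 1))), bounds)
    for x in design:
        evaluate(x, 0, "lhs_init")

    def finite_mask() -> np.ndarray:
        return np.isfinite(np.asarray(y_all))

    if not finite_mask().any():
        raise OptimizationError("objective failed at every initial point",
                                history=pd.DataFrame(records))

    def incumbent() -> tuple[np.ndarray, float]:
        y_arr = np.asarray(y_all)
        ok = np.isfinite(y_arr)
        i = np.flatnonzero(ok)[np.argmin(y_arr[ok])]
        return np.asarray(X_all[i]), float(y_arr[i])

    current_bounds = list(bounds)
    n_reductions = 0
    stagnant = 0
    termination = "budget"
    batch_idx = 0

    # transform for surrogate fitting
    def transform(y: np.ndarray) -> np.ndarray:
        if log_objective:
            return np.log10(np.maximum(y, 1e-300) + 1e-16)
        return y

    while len(y_all) < budget:
        batch_idx += 1
        _, best_before = incumbent()

        X_arr = np.asarray(X_all)
        y_arr = np.asarray(y_all)
        ok = np.isfinite(y_arr)
        # penalise failed evaluations at the worst finite level so the
        # surrogate stays aware of infeasible regions
        y_fit = y_arr.copy()
        y_fit[~ok] = np.max(y_arr[ok])
        U = _scale_to_unit(X_arr, current_bounds)
        inside = np.all((U >= -1e-9) & (U <= 1 + 1e-9), axis=1)
        if inside.sum() < d + 2:  # after reduction, keep global information
            inside[:] = True
        model = fit_kriging(np.clip(U[inside], -2, 3), transform(y_fit[inside]),
                            seed=int(rng.integers(2**31 - 1)))
        f_min_t = float(np.min(transform(np.array([best_before]))))

        q_eff = min(q, budget - len(y_all))
        batch, criteria, max_ei = propose_batch(
            model, q_eff, f_min=f_min_t, rng=rng, return_criteria=True)
        for u, crit in zip(batch, criteria):
            evaluate(_scale_from_unit(u, current_bounds), batch_idx, crit)

        _, best_after = incumbent()
        rel_impr = (best_before - best_after) / max(abs(best_before), 1e-12)
        stagnant = stagnant + 1 if rel_impr < stagnation_rtol else 0

        if max_ei < ei_tol * max(abs(f_min_t), 1e-12):
            termination = "ei_tolerance"
            break
        if stagnant >= stagnation_batches:
            if n_reductions < max_reductions:
                x_inc, _ = incumbent()
                current_bounds = reduce_domain(
                    current_bounds, np.clip(
                        x_inc,
                        [b[0] for b in current_bounds],
                        [b[1] for b in current_bounds]), shrink_factor)
                n_reductions += 1
                stagnant = 0
            else:
                termination = "stagnation"
                break

    x_best, f_best = incumbent()
    return OptimResult(
        x=x_best, fun=f_best, history=pd.DataFrame(records),
        bounds=current_bounds, initial_bounds=list(bounds),
        n_evaluations=len(y_all), n_reductions=n_reductions,
        termination=termination, seed=seed)
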