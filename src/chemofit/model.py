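"""Finite-volume solution of the reaction–diffusion–chemotaxis system.

Two fields evolve on the nondimensional domain [0, 1]:

* ``rho(x, t)`` — infiltrating PBMC density,
* ``alpha(x, t)`` — concentration of a generic chemoattractant cytokine.

The governing equations are

    drho/dt   = d/dx( D_rho(x) drho/dx ) - d/dx( chi(x, alpha) rho dalpha/dx )
                - xi * rho
    dalpha/dt = d/dx( D_alpha(x) dalpha/dx ) + eta1 * 1{x < x_t}
                + eta2 * rho * 1{x > x_t} - kappa * rho * alpha - nu * alpha

with a receptor-law chemotactic sensitivity
``chi(x, a) = chi_tilde(x) * k / (k + a)**2`` that saturates at high
cytokine concentration.  Coefficients are piecewise constant with a
discontinuity at the matrix/epithelium interface ``x_t``.

Boundary conditions: at x = 1 both total fluxes vanish.  At x = 0 the
cytokine obeys a Robin outflux condition ``dalpha/dx = zeta * alpha`` and
the PBMC influx equals the chemotactic flux drawn from a constant reservoir
density ``rho_tilde`` in the seeding channel, which combines with the Robin
condition to ``influx = chi(0, a0) * zeta * a0 * rho_tilde``.

Discretisation: uniform cell-centred finite volumes; harmonic-mean face
diffusivities (exact for the piecewise-constant jump at ``x_t``, which is
constructed to lie on a face); chemotaxis treated as face advection with a
central-difference cytokine gradient and first-order upwinding of ``rho``
for positivity.  Time integration is method-of-lines with LSODA on an
interleaved (banded-Jacobian) state vector.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import solve_banded

from .params import ModelParams, SpatialGrid, StateSolution

__all__ = [
    "chemotactic_sensitivity",
    "steady_state_alpha",
    "rhs",
    "simulate",
    "NoSteadyStateError",
    "SolverError",
]


class NoSteadyStateError(ValueError):
    """No cytokine steady state exists (nu = zeta = 0 with production)."""


class SolverError(RuntimeError):
    """The time integrator failed to meet its tolerances."""


def chemotactic_sensitivity(x, alpha, params: ModelParams):
    """Receptor-law chemotactic sensitivity chi(x, alpha).

    Equals ``chi_tilde(x) * k / (k + alpha)**2``: proportional to the free
    receptor fraction, so it vanishes as the attractant saturates the
    receptors.  ``chi_tilde`` drops by the factor ``mu_rho`` in the top
    channel.
    """
    x = np.asarray(x, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    if np.any(alpha < 0):
        raise ValueError("alpha must be nonnegative")
    if np.any(x < 0) or np.any(x > 1):
        raise ValueError("x must lie in [0, 1]")
    out = params.chi_tilde(x) * params.k / (params.k + alpha) ** 2
    return out if out.ndim else float(out)


def _harmonic_faces(cell_values: np.ndarray) -> np.ndarray:
    """Harmonic mean of adjacent cell coefficients at interior faces."""
    a, b = cell_values[:-1], cell_values[1:]
    with np.errstate(divide="ignore", invalid="ignore"):
        hm = 2.0 * a * b / (a + b)
    return np.where(a + b > 0, hm, 0.0)


def _boundary_alpha(alpha_cell0: float, zeta: float, h: float) -> float:
    """Cytokine value on the x = 0 face from the Robin condition.

    One-sided gradient between face and first cell centre:
    ``(a_c - a_b) / (h/2) = zeta * a_b``  =>  ``a_b = a_c / (1 + zeta h / 2)``.
    """
    return alpha_cell0 / (1.0 + 0.5 * zeta * h)


def _coefficients(params: ModelParams, grid: SpatialGrid):
    """Per-cell and per-face transport coefficients (precomputable)."""
    xc = grid.cell_centers
    d_rho = params.d_rho(xc)
    d_alpha = params.d_alpha(xc)
    chi_t = params.chi_tilde(xc)
    return {
        "d_rho_face": _harmonic_faces(d_rho),
        "d_alpha_face": _harmonic_faces(d_alpha),
        "chi_face": _harmonic_faces(chi_t),
        "in_matrix": xc < grid.x_t,   # production support for eta1
        "in_tissue": xc > grid.x_t,   # production support for eta2 * rho
    }


def steady_state_alpha(params: ModelParams, grid: SpatialGrid) -> np.ndarray:
    """Steady cytokine profile used as the initial condition.

    Solves the linear two-point boundary-value problem

        d/dx( D_alpha(x) d a/dx ) + eta1 * 1{x < x_t} - nu * a = 0

    with ``da/dx = zeta a`` at x = 0 and zero flux at x = 1, on the same
    finite-volume stencil as :func:`rhs` (so the discrete time derivative of
    the returned profile is zero to machine precision when ``rho = 0`` and
    ``eta2``/``kappa`` terms are inactive).
    """
    n, h = grid.n_cells, grid.h
    coef = _coefficients(params, grid)
    d_face = coef["d_alpha_face"]
    nu, zeta, eta1 = params.nu, params.zeta, params.eta1

    if nu == 0.0 and zeta == 0.0 and eta1 > 0.0:
        raise NoSteadyStateError(
            "cytokine production with no degradation and no outflux has no steady state"
        )

    # banded system: rows = cells; -(G_{i+1} - G_i)/h + eta1*1 - nu*a = 0
    ab = np.zeros((3, n))     # diagonals for solve_banded (upper, main, lower)
    rhs_vec = -eta1 * coef["in_matrix"].astype(float)

    main = np.full(n, -nu)
    upper = np.zeros(n)
    lower = np.zeros(n)
    # interior faces j = 1..n-1 between cells j-1 and j
    w = d_face / h**2
    main[:-1] -= w
    upper[1:] += w
    main[1:] -= w
    lower[:-1] += w
    # x = 0 face: G_0 = -D1 * zeta * a_b, a_b = a_0 / (1 + zeta h/2)
    d0 = params.D_alpha_bar
    main[0] -= d0 * zeta / (1.0 + 0.5 * zeta * h) / h
    # x = 1 face: zero flux, nothing to add

    ab[0, :] = upper
    ab[1, :] = main
    ab[2, :] = lower
    try:
        alpha = solve_banded((1, 1), ab, rhs_vec)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise NoSteadyStateError(str(exc)) from exc
    if not np.all(np.isfinite(alpha)):
        raise NoSteadyStateError("steady-state system is singular")
    # guard against tiny negative round-off in the homogeneous case
    alpha[(alpha < 0) & (alpha > -1e-12)] = 0.0
    return alpha


def rhs(rho: np.ndarray, alpha: np.ndarray, params: ModelParams,
        grid: SpatialGrid, coef: dict | None = None):
    """Finite-volume time derivatives (drho/dt, dalpha/dt).

    Fluxes are positive in the +x direction.  The boundary fluxes at x = 0
    are substituted directly: PBMC influx ``chi(0, a_b) zeta a_b rho_tilde``
    and cytokine outflux ``-D_alpha zeta a_b`` (i.e. leaving the domain).
    """
    if not (np.all(np.isfinite(rho)) and np.all(np.isfinite(alpha))):
        raise FloatingPointError("non-finite state values")
    if coef is None:
        coef = _coefficients(params, grid)
    n, h = grid.n_cells, grid.h
    k = params.k

    # cytokine gradient and face values at interior faces
    dadx = (alpha[1:] - alpha[:-1]) / h
    a_face = 0.5 * (alpha[1:] + alpha[:-1])
    a_face = np.maximum(a_face, 0.0)

    # --- rho fluxes -------------------------------------------------------
    flux_rho = np.empty(n + 1)
    # diffusion
    diff = -coef["d_rho_face"] * (rho[1:] - rho[:-1]) / h
    # chemotactic advection, upwinded in rho
    vel = coef["chi_face"] * k / (k + a_face) ** 2 * dadx
    adv = np.where(vel >= 0, vel * rho[:-1], vel * rho[1:])
    flux_rho[1:-1] = diff + adv
    a_b = _boundary_alpha(alpha[0], params.zeta, h)
    a_b = max(a_b, 0.0)
    chi0 = params.chi_bar * k / (k + a_b) ** 2
    flux_rho[0] = chi0 * params.zeta * a_b * params.rho_tilde  # influx
    flux_rho[-1] = 0.0

    # --- alpha fluxes -----------------------------------------------------
    flux_alpha = np.empty(n + 1)
    flux_alpha[1:-1] = -coef["d_alpha_face"] * (alpha[1:] - alpha[:-1]) / h
    flux_alpha[0] = -params.D_alpha_bar * params.zeta * a_b  # outflux (leaves at x=0)
    flux_alpha[-1] = 0.0

    drho = -(flux_rho[1:] - flux_rho[:-1]) / h - params.xi * rho
    dalpha = (
        -(flux_alpha[1:] - flux_alpha[:-1]) / h
        + params.eta1 * coef["in_matrix"]
        + params.eta2 * rho * coef["in_tissue"]
        - params.kappa * rho * alpha
        - params.nu * alpha
    )
    return drho, dalpha


def boundary_influx(alpha: np.ndarray, params: ModelParams, grid: SpatialGrid) -> float:
    """Chemotactic PBMC influx through x = 0 for a given cytokine profile."""
    a_b = max(_boundary_alpha(alpha[0], params.zeta, grid.h), 0.0)
    chi0 = params.chi_bar * params.k / (params.k + a_b) ** 2
    return chi0 * params.zeta * a_b * params.rho_tilde


def simulate(params: ModelParams, grid: SpatialGrid,
             output_times: Sequence[float],
             rtol: float = 1e-6, atol: float = 1e-9) -> StateSolution:
    """Integrate the model from its resting initial condition.

    The initial state is ``rho = 0`` with the cytokine at the steady profile
    maintained by macrophage production (:func:`steady_state_alpha`).
    Output is interpolated at the requested times by the adaptive stiff
    integrator (LSODA, banded Jacobian).
    """
    times = np.asarray(output_times, dtype=float)
    if times.ndim != 1 or len(times) < 1:
        raise ValueError("output_times must be a nonempty 1-D sequence")
    if times[0] != 0.0 or np.any(np.diff(times) <= 0):
        raise ValueError("output_times must start at 0 and be strictly increasing")

    n = grid.n_cells
    coef = _coefficients(params, grid)
    alpha0 = steady_state_alpha(params, grid)
    y0 = np.zeros(2 * n)
    y0[1::2] = alpha0  # interleaved state keeps the Jacobian banded

    def fun(t, y):
        drho, dalpha = rhs(y[0::2], y[1::2], params, grid, coef)
        out = np.empty_like(y)
        out[0::2] = drho
        out[1::2] = dalpha
        return out

    if len(times) == 1:  # only t = 0 requested
        rho_mat = np.zeros((1, n))
        alpha_mat = alpha0[None, :].copy()
    else:
        sol = solve_ivp(
            fun, (0.0, float(times[-1])), y0, method="LSODA",
            t_eval=times, rtol=rtol, atol=atol, lband=3, uband=3,
        )
        if not sol.success:
            raise SolverError(f"time integration failed: {sol.message}")
        rho_mat = sol.y[0::2, :].T.copy()
        alpha_mat = sol.y[1::2, :].T.copy()

    # floor tiny negative undershoot from the adaptive integrator
    for mat in (rho_mat, alpha_mat):
        neg = mat < 0
        if np.any(mat[neg] < -1e-6):
            raise SolverError("solution significantly negative; tolerances unmet")
        mat[neg] = 0.0

    influx = np.array([boundary_influx(alpha_mat[i], params, grid)
                       for i in range(len(times))])
    a_b = np.maximum(
        _boundary_alpha(alpha_mat[:, 0], params.zeta, grid.h), 0.0)
    outflux = params.D_alpha_bar * params.zeta * a_b

    return StateSolution(grid=grid, times=times, rho=rho_mat, alpha=alpha_mat,
                         influx_record=influx, alpha_outflux_record=outflux)
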