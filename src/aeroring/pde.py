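"""Implicit finite-difference solver for the coupled density/oxygen system.

The continuum model couples cell density rho (cells/mm^2, treated as a line
density in the reduced 1-D geometry) and oxygen C (%O2):

    d rho/dt = D lap(rho) - div(a(C, grad C) rho) + r(C) rho
    d C/dt   = Doxy lap(C) - b(C) rho

in planar (x) or radial (r) symmetry. Two advection closures are supported:

- ``mean_field``: a = lambda(C) * dC/dx with lambda the sigmoidal aerotactic
  sensitivity (amplitude in um^2 min^-1 %^-1, see
  :func:`aeroring.params.meanfield_aero_amplitude`),
- ``go_or_grow``: a = a0 * sign(dC/dx) where C < C0, zero otherwise
  (``two_threshold`` additionally switches advection off below C0p).

Division r(C) = r0 where C > C0, zero below. Consumption uses the capped
ramp b(C) = min(b0, b0*C/C0p), which vanishes with C and keeps the oxygen
field non-negative for a sufficiently small time step.

Time stepping is backward (implicit) for both fields: one tridiagonal solve
updates rho with donor-cell upwind advection frozen at the old oxygen field,
then one tridiagonal solve updates C using the freshly updated density.
Boundary conditions: no-flux for rho at both ends; C is clamped to
``Cboundary`` at the outer end and no-flux at the inner end (symmetry axis
in radial geometry).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_banded

from aeroring.params import MeanFieldParams


@dataclass
class ScalarField1D:
    """A scalar field on a uniform 1-D grid.

    ``origin`` is the coordinate of the first node (um); radial grids are
    cell-centered (origin = dx/2) so the symmetry axis carries no node.
    """

    values: np.ndarray
    dx: float
    geometry: str = "planar"    # "planar" | "radial"
    origin: float = 0.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 3:
            raise ValueError("field needs >= 3 nodes on a 1-D grid")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("field values must be finite")
        if self.dx <= 0:
            raise ValueError("dx must be positive")
        if self.geometry not in ("planar", "radial"):
            raise ValueError(f"unknown geometry {self.geometry!r}")
        if self.geometry == "radial" and self.origin < 0:
            raise ValueError("radial origin must be >= 0")

    @property
    def x(self) -> np.ndarray:
        return self.origin + self.dx * np.arange(self.values.size)

    def copy(self) -> "ScalarField1D":
        return ScalarField1D(self.values.copy(), self.dx, self.geometry, self.origin)


@dataclass
class PDESolution:
    """Snapshots and front trajectory of a simulation run."""

    times: np.ndarray                    # minutes
    rho_snapshots: list
    C_snapshots: list
    front_times: np.ndarray              # minutes
    front_positions: np.ndarray          # um; NaN where C never crosses C0
    params: MeanFieldParams = None
    model: str = ""


def consumption(C: ScalarField1D | np.ndarray, params: MeanFieldParams) -> np.ndarray:
    """Per-cell consumption rate b(C) = min(b0, b0*C/C0p), %O2 min^-1 cell^-1."""
    vals = C.values if isinstance(C, ScalarField1D) else np.asarray(C, dtype=float)
    return np.minimum(params.b0, params.b0 * vals / params.C0p)


def _interface_gradient(C: np.ndarray, dx: float) -> np.ndarray:
    """One-sided oxygen difference (C_i - C_{i-1})/dx at interfaces i-1/2."""
    return np.diff(C) / dx


def advection_speed(
    C: ScalarField1D, model: str, params: MeanFieldParams
) -> np.ndarray:
    """Advection velocity at the n-1 cell interfaces, um/min (positive = +x).

    The donor-cell scheme needs velocities at interfaces; the sign of the
    one-sided oxygen difference across each interface selects the donor node.
    """
    vals = C.values
    g = _interface_gradient(vals, C.dx)
    Cface = 0.5 * (vals[1:] + vals[:-1])
    if model == "mean_field":
        lam = params.aero_amplitude / (
            1.0 + np.exp((Cface - params.C0) / 0.2)
        )
        return lam * g
    if model in ("go_or_grow", "two_threshold"):
        a = np.where(Cface < params.C0, params.a0 * np.sign(g), 0.0)
        if model == "two_threshold":
            a = np.where(Cface < params.C0p, 0.0, a)
        return a
    raise ValueError(f"unknown model {model!r}")


def _radii(field_: ScalarField1D):
    """Node radii and interface radii for the metric factors (planar -> ones)."""
    n = field_.values.size
    if field_.geometry == "planar":
        return np.ones(n), np.ones(n - 1)
    r = field_.x
    return r, 0.5 * (r[1:] + r[:-1])


def step(
    rho: ScalarField1D,
    C: ScalarField1D,
    params: MeanFieldParams,
    dt: float,
    model: str = "go_or_grow",
):
    """Advance (rho, C) by one implicit time step of length ``dt`` minutes.

    rho update: backward-Euler diffusion + donor-cell upwind advection
    (velocities frozen at the old C) + implicit growth, as one tridiagonal
    solve. C update: backward-Euler diffusion with consumption coefficient
    b(C^n) applied to the new density, as a second tridiagonal solve.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if rho.values.size != C.values.size or rho.dx != C.dx:
        raise ValueError("rho and C must share the grid")
    n = rho.values.size
    dx = rho.dx
    rnode, rface = _radii(rho)

    a_face = advection_speed(C, model, params)
    # division shuts off below C0 in every model variant
    r_growth = np.where(C.values > params.C0, params.r0, 0.0)

    D = params.D
    lo = np.zeros(n)   # sub-diagonal (row i, col i-1)
    di = np.zeros(n)   # diagonal
    up = np.zeros(n)   # super-diagonal (row i, col i+1)

    # diffusion: -(D/ (rnode dx^2)) [rface_{i+1/2}(rho_{i+1}-rho_i) - rface_{i-1/2}(rho_i - rho_{i-1})]
    wR = np.zeros(n)
    wL = np.zeros(n)
    wR[:-1] = D * rface / (rnode[:-1] * dx * dx)   # coupling to i+1
    wL[1:] = D * rface / (rnode[1:] * dx * dx)     # coupling to i-1
    di += dt * (wR + wL)
    up[:-1] -= dt * wR[:-1]
    lo[1:] -= dt * wL[1:]

    # advection, conservative donor-cell: flux at interface i-1/2 is
    # a_face * rho_donor * rface; donor = left node if a_face > 0 else right.
    ap = np.maximum(a_face, 0.0)
    am = np.minimum(a_face, 0.0)
    # divergence row i: (F_{i+1/2} - F_{i-1/2}) / (rnode_i dx)
    # F_{i+1/2} = rface_i * (ap_i * rho_i + am_i * rho_{i+1})
    coefR_own = rface * ap / dx    # contribution of rho_i to F_{i+1/2}
    coefR_nb = rface * am / dx     # contribution of rho_{i+1}
    di[:-1] += dt * coefR_own / rnode[:-1]
    up[:-1] += dt * coefR_nb / rnode[:-1]
    di[1:] -= dt * coefR_nb / rnode[1:]
    lo[1:] -= dt * coefR_own / rnode[1:]

    # growth (implicit)
    di -= dt * r_growth
    di += 1.0

    ab = np.zeros((3, n))
    ab[0, 1:] = up[:-1]
    ab[1, :] = di
    ab[2, :-1] = lo[1:]
    try:
        rho_new = solve_banded((1, 1), ab, rho.values)
    except np.linalg.LinAlgError as exc:   # pragma: no cover - defensive
        raise RuntimeError(f"singular tridiagonal system in rho update: {exc}")

    # --- oxygen update ---
    b = consumption(C, params)
    Doxy = params.Doxy
    lo = np.zeros(n)
    di = np.ones(n)
    up = np.zeros(n)
    wR = np.zeros(n)
    wL = np.zeros(n)
    wR[:-1] = Doxy * rface / (rnode[:-1] * dx * dx)
    wL[1:] = Doxy * rface / (rnode[1:] * dx * dx)
    di += dt * (wR + wL)
    up[:-1] -= dt * wR[:-1]
    lo[1:] -= dt * wL[1:]
    rhs = C.values - dt * b * rho_new
    # Dirichlet at the outer end
    di[-1] = 1.0
    lo[-1] = 0.0
    rhs[-1] = params.Cboundary
    ab = np.zeros((3, n))
    ab[0, 1:] = up[:-1]
    ab[1, :] = di
    ab[2, :-1] = lo[1:]
    try:
        C_new = solve_banded((1, 1), ab, rhs)
    except np.linalg.LinAlgError as exc:   # pragma: no cover - defensive
        raise RuntimeError(f"singular tridiagonal system in C update: {exc}")

    return (
        ScalarField1D(rho_new, dx, rho.geometry, rho.origin),
        ScalarField1D(C_new, dx, C.geometry, C.origin),
    )


def front_position(C: ScalarField1D, C0: float) -> float:
    """Rightmost linear-interpolated crossing of C through C0, um (NaN if none)."""
    v = C.values
    below = v < C0
    if not below.any() or below.all():
        return math.nan
    idx = np.where(below[:-1] & ~below[1:])[0]
    if idx.size == 0:
        return math.nan
    i = idx[-1]
    frac = (C0 - v[i]) / (v[i + 1] - v[i])
    x = C.x
    return x[i] + frac * (x[i + 1] - x[i])


def simulate(
    init_rho: ScalarField1D,
    init_C: ScalarField1D,
    params: MeanFieldParams,
    t_end: float,
    dt: float = 0.02,
    model: str = "go_or_grow",
    snapshot_every: float = 30.0,
    front_every: float = 1.0,
) -> PDESolution:
    """Run the solver to ``t_end`` minutes, recording snapshots and the front.

    The front is the rightmost point where C crosses C0, recorded every
    ``front_every`` minutes; field snapshots are kept every
    ``snapshot_every`` minutes. Aborts with a diagnostic if the density
    develops NaNs or goes negative beyond round-off tolerance.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    rho, C = init_rho.copy(), init_C.copy()
    nsteps = int(round(t_end / dt))
    snap_stride = max(1, int(round(snapshot_every / dt)))
    front_stride = max(1, int(round(front_every / dt)))
    times, rhos, Cs = [0.0], [rho.copy()], [C.copy()]
    ftimes, fpos = [0.0], [front_position(C, params.C0)]
    tol = -1e-9 * max(1.0, float(np.max(rho.values)))
    for k in range(1, nsteps + 1):
        rho, C = step(rho, C, params, dt, model)
        if not np.all(np.isfinite(rho.values)) or np.min(rho.values) < tol:
            raise RuntimeError(
                f"density lost positivity/finiteness at t = {k * dt:.3f} min "
                f"(min rho = {np.min(rho.values):.3e})"
            )
        if k % front_stride == 0:
            ftimes.append(k * dt)
            fpos.append(front_position(C, params.C0))
        if k % snap_stride == 0:
            times.append(k * dt)
            rhos.append(rho.copy())
            Cs.append(C.copy())
    return PDESolution(
        times=np.asarray(times),
        rho_snapshots=rhos,
        C_snapshots=Cs,
        front_times=np.asarray(ftimes),
        front_positions=np.asarray(fpos),
        params=params,
        model=model,
    )


def measure_front_speed(sol: PDESolution, window: tuple[float, float]) -> float:
    """Least-squares slope of the front trajectory over ``window`` (min), um/min."""
    t0, t1 = window
    m = (sol.front_times >= t0) & (sol.front_times <= t1)
    m &= np.isfinite(sol.front_positions)
    if m.sum() < 2:
        raise ValueError("need >= 2 front positions inside the window")
    coeffs = np.polyfit(sol.front_times[m], sol.front_positions[m], 1)
    return float(coeffs[0])


def total_mass(rho: ScalarField1D) -> float:
    """Discrete integral of rho with the geometry's metric (per radian if radial)."""
    rnode, _ = _radii(rho)
    return float(np.sum(rho.values * rnode) * rho.dx)
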