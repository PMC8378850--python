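"""Synthetic-data generators with known ground truth.

Every generator is deterministic at fixed seed and its ground truth is
recoverable by the matching analysis operator (ring fitting, bias and
diffusion estimation, oxygen reconstruction), which is what the test suite
exercises. The generators emulate the study's data modalities:

- 2-D cell-position point clouds with a dense outward ring over a diffuse
  bulk (spot-assay morphology),
- cell trajectories with tunable diffusion constant and drift,
- fluorescence sensor image pairs obeying the Stern--Volmer forward model,
- the microfluidic oxygen gradient,
- initial density/oxygen profiles for the continuum solvers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from aeroring.params import MeanFieldParams
from aeroring.pde import ScalarField1D


@dataclass
class SyntheticTruth:
    """Ground-truth record of a generated dataset."""

    generator: str
    seed: int
    params: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# point clouds

def ring_intensity(r, position, width, peak_density, baseline_density, extent):
    """Radial intensity (cells/mm^2) of the ring point process.

    baseline inside ``extent``, plus a Gaussian ring of the given peak excess.
    """
    r = np.asarray(r, dtype=float)
    base = np.where(r <= extent, baseline_density, 0.0)
    return base + (peak_density - baseline_density) * np.exp(
        -((r - position) ** 2) / (2.0 * width**2)
    )


def gen_ring_positions(
    position: float = 1500.0,
    width: float = 150.0 / 2.355,
    peak_density: float = 1900.0,
    baseline_density: float = 475.0,
    field_radius: float = 3000.0,
    seed: int = 0,
):
    """Sample an inhomogeneous Poisson point process with a ring morphology.

    Densities in cells/mm^2, lengths in um. Sampling is by thinning of a
    uniform process at the maximal intensity, so the expected count per
    annulus equals the integral of :func:`ring_intensity` exactly.
    Returns ``(positions, truth)`` with positions an (N, 2) array centred
    on the origin.
    """
    rng = np.random.default_rng(seed)
    lam_max = max(peak_density, baseline_density)       # cells/mm^2
    area_mm2 = math.pi * (field_radius / 1000.0) ** 2
    n = rng.poisson(lam_max * area_mm2)
    r = field_radius * np.sqrt(rng.random(n))
    theta = 2.0 * math.pi * rng.random(n)
    lam = ring_intensity(r, position, width, peak_density, baseline_density, field_radius)
    keep = rng.random(n) < lam / lam_max
    r, theta = r[keep], theta[keep]
    pos = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
    truth = SyntheticTruth(
        "ring_positions", seed,
        dict(position=position, width=width, peak_density=peak_density,
             baseline_density=baseline_density, field_radius=field_radius),
    )
    return pos, truth


# ---------------------------------------------------------------------------
# tracks

def gen_tracks(
    n_tracks: int = 100,
    duration: float = 60.0,
    frame_interval: float = 1.0,
    D: float = 28.2,
    drift=None,
    start_box: float = 1000.0,
    seed: int = 0,
):
    """Generate 2-D random-walk tracks with diffusion D (um^2/min) and drift.

    ``drift`` is None, a constant (vx, vy) in um/min, or a callable
    ``drift(xy) -> (n, 2)`` evaluated at the current positions (use for
    radial or gradient-dependent bias fields). Starting points are uniform
    in a centred square of half-side ``start_box``. Returns
    ``(tracks, truth)`` where tracks is a list of (t, x, y) arrays.
    """
    if D < 0:
        raise ValueError("D must be non-negative")
    rng = np.random.default_rng(seed)
    nsteps = int(round(duration / frame_interval))
    times = np.arange(nsteps + 1) * frame_interval
    xy = rng.uniform(-start_box, start_box, size=(n_tracks, 2))
    sd = math.sqrt(2.0 * D * frame_interval)
    traj = np.empty((n_tracks, nsteps + 1, 2))
    traj[:, 0] = xy
    for k in range(1, nsteps + 1):
        if drift is None:
            v = 0.0
        elif callable(drift):
            v = np.asarray(drift(xy), dtype=float)
        else:
            v = np.asarray(drift, dtype=float)
        xy = xy + v * frame_interval + rng.normal(0.0, sd, size=(n_tracks, 2))
        traj[:, k] = xy
    tracks = [
        np.column_stack([times, traj[i, :, 0], traj[i, :, 1]])
        for i in range(n_tracks)
    ]
    truth = SyntheticTruth(
        "tracks", seed,
        dict(D=D, drift="callable" if callable(drift) else drift,
             frame_interval=frame_interval, duration=duration),
    )
    return tracks, truth


def radial_drift(speed: float, center=(0.0, 0.0)):
    """Outward radial drift field of constant magnitude ``speed`` (um/min)."""
    c = np.asarray(center, dtype=float)

    def field_(xy):
        d = np.asarray(xy, dtype=float) - c
        r = np.linalg.norm(d, axis=-1, keepdims=True)
        r = np.where(r == 0, 1.0, r)
        return speed * d / r

    return field_


# ---------------------------------------------------------------------------
# sensor images

def gen_sensor_images(
    C_map,
    K=4.0,
    Bg=15.0,
    I0=60.0,
    noise: float = 0.0,
    seed: int = 0,
):
    """Forward Stern--Volmer sensor image pair ``(I, I21)``.

    I(C) = Bg + (I0 - Bg)/(1 + K*C) plus Gaussian noise of the given s.d.
    ``K``, ``Bg``, ``I0`` may be scalars or maps broadcastable to ``C_map``
    (spatially varying film sensitivity and background). ``I21`` is the
    reference image of the same film at uniform 21 % O2.
    """
    C = np.asarray(C_map, dtype=float)
    if np.any(C < 0) or np.any(C > 21):
        raise ValueError("oxygen map must lie in [0, 21] %")
    rng = np.random.default_rng(seed)
    K = np.broadcast_to(np.asarray(K, dtype=float), C.shape)
    Bg = np.broadcast_to(np.asarray(Bg, dtype=float), C.shape)
    I0 = np.broadcast_to(np.asarray(I0, dtype=float), C.shape)
    I = Bg + (I0 - Bg) / (1.0 + K * C)
    I21 = Bg + (I0 - Bg) / (1.0 + K * 21.0)
    if noise > 0:
        I = I + rng.normal(0.0, noise, C.shape)
        I21 = I21 + rng.normal(0.0, noise, C.shape)
    truth = SyntheticTruth("sensor_images", seed, dict(K=np.asarray(K), Bg=np.asarray(Bg), I0=np.asarray(I0), noise=noise))
    return I, I21, truth


def microfluidic_oxygen(x_px):
    """Frozen microfluidic oxygen profile, % O2, vs position in pixels.

    C(x) = 21.38 / (1 + exp(0.031 * (x - 200))), the logistic fit to the
    measured device gradient (x in 10-um pixels).
    """
    x = np.asarray(x_px, dtype=float)
    return 21.38 / (1.0 + np.exp(0.031 * (x - 200.0)))


# ---------------------------------------------------------------------------
# initial profiles for the continuum solvers

#: areal densities (cells/mm^2) of the three concentric seeding tiers:
#: 2-pixel cells at centre pitch (2+g) x (1+g) pixels for gaps g = 1, 2, 3
SPOT_TIER_DENSITIES = (1e6 / 600.0, 1e6 / 1200.0, 1e6 / 2000.0)
SPOT_TIER_RADII = (300.0, 600.0, 900.0)


def quasi_static_oxygen(
    rho: ScalarField1D, params: MeanFieldParams, n_iter: int = 100, tol: float = 1e-10
) -> ScalarField1D:
    """Steady-state oxygen field in equilibrium with a frozen density.

    Oxygen relaxes orders of magnitude faster than the cells move
    (Doxy/D = 4000), so the appropriate initial condition solves
    Doxy lap(C) = b(C) rho with C = Cboundary at the outer end and no flux
    at the inner end. The capped-ramp consumption is linearized as
    b(C)rho = k(C_prev) * C (Picard iteration), which keeps the tridiagonal
    system diagonally dominant and the iterates positive.
    """
    from scipy.linalg import solve_banded

    from aeroring.pde import _radii

    n = rho.values.size
    dx = rho.dx
    rnode, rface = _radii(rho)
    Cv = np.full(n, params.Cboundary)
    wR = np.zeros(n)
    wL = np.zeros(n)
    wR[:-1] = params.Doxy * rface / (rnode[:-1] * dx * dx)
    wL[1:] = params.Doxy * rface / (rnode[1:] * dx * dx)
    for _ in range(n_iter):
        # b(C)*rho = k*C with k = b0*rho/max(C, C0p)
        k = params.b0 * rho.values / np.maximum(Cv, params.C0p)
        di = wR + wL + k
        up = np.zeros(n)
        lo = np.zeros(n)
        up[:-1] = -wR[:-1]
        lo[1:] = -wL[1:]
        rhs = np.zeros(n)
        di[-1], lo[-1], rhs[-1] = 1.0, 0.0, params.Cboundary
        ab = np.zeros((3, n))
        ab[0, 1:] = up[:-1]
        ab[1, :] = di
        ab[2, :-1] = lo[1:]
        C_new = solve_banded((1, 1), ab, rhs)
        if np.max(np.abs(C_new - Cv)) < tol * params.Cboundary:
            Cv = C_new
            break
        Cv = C_new
    return ScalarField1D(Cv, dx, rho.geometry, rho.origin)


def gen_initial_profiles(
    kind: str,
    params: MeanFieldParams,
    dx: float = 1.0,
    front_at: float = 2000.0,
    plateau_density: float = 500.0,
):
    """Initial ``(rho, C)`` fields for the continuum solvers.

    ``spot``: radial three-tier step profile matching the Potts seeding
    densities, atmospheric oxygen everywhere (cells have not yet consumed).

    ``near_wave``: planar profile close to the expected traveling wave --
    the explicit Go-or-Grow density profile (large-bias exponential, or the
    marginal (c1*z + 1)*exp(-sqrt(r0/D) z) form in the small-bias regime)
    with its threshold cusp at ``front_at`` and plateau ``plateau_density``,
    in freshly oxygenated medium (C = Cboundary everywhere, as at the start
    of an experiment). The oxygen field self-organizes its depletion zone
    and threshold crossing within the first simulated hour; front speeds are
    measured after that transient.
    """
    if kind == "spot":
        n = int(round(params.L / dx))
        r = (np.arange(n) + 0.5) * dx
        rho = np.select(
            [r < SPOT_TIER_RADII[0], r < SPOT_TIER_RADII[1], r < SPOT_TIER_RADII[2]],
            list(SPOT_TIER_DENSITIES),
            0.0,
        )
        rho_f = ScalarField1D(rho, dx, "radial", origin=dx / 2)
        C_f = ScalarField1D(np.full(n, params.Cboundary), dx, "radial", origin=dx / 2)
        return rho_f, C_f

    if kind == "near_wave":
        from aeroring.waves import speed_formula, explicit_profile

        n = int(round(params.L / dx)) + 1
        x = np.arange(n) * dx
        z = x - front_at
        crit = math.sqrt(params.r0 * params.D)
        if params.a0 > crit:
            prof = explicit_profile(params.a0, params.r0, params.D, "elementary")
            shape = prof(z)
        else:
            # marginal small-bias profile at the Fisher speed
            lam = math.sqrt(params.r0 / params.D)
            c1 = lam - params.a0 / params.D
            shape = np.where(z < 0, 1.0, (c1 * z + 1.0) * np.exp(-lam * z))

        rho_f = ScalarField1D(plateau_density * shape, dx, "planar")
        C_f = ScalarField1D(np.full(n, params.Cboundary), dx, "planar")
        return rho_f, C_f

    raise ValueError(f"unknown initial-profile kind {kind!r}")
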