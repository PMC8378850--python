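"""Measurement operators for ring morphology, kymographs, tracks, and biases.

These operators are applied identically to experimental-style synthetic data
(point clouds and tracks) and to Potts simulation output, mirroring the
study's quantification pipeline: radial density profiles in concentric
annuli, Gaussian-with-baseline ring fits, ring speed from position-vs-time
regression, radial velocity biases from projected track displacements, and
per-track effective diffusion constants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit


@dataclass
class RadialProfile:
    """Binned cell density (cells/mm^2) vs distance from the colony centre."""

    bin_centers: np.ndarray     # um
    density: np.ndarray         # cells/mm^2
    counts: np.ndarray          # raw counts per annulus
    time: float = 0.0           # min


@dataclass
class RingFit:
    """Gaussian-with-baseline fit of a ring density profile."""

    position: float             # um
    width: float                # um (Gaussian sigma)
    peak_density: float         # cells/mm^2 (baseline + height)
    baseline_density: float     # cells/mm^2
    converged: bool = True

    @property
    def density_ratio(self) -> float:
        """Peak-to-baseline density ratio (the shape-speed input)."""
        return self.peak_density / self.baseline_density


def colony_center(positions_over_time) -> np.ndarray:
    """Centre of mass of all detections pooled over all times."""
    allpos = np.concatenate([np.asarray(p, dtype=float) for p in positions_over_time])
    return allpos.mean(axis=0)


def radial_profile(
    positions,
    center=(0.0, 0.0),
    bin_width: float = 50.0,
    r_max: float | None = None,
    time: float = 0.0,
) -> RadialProfile:
    """Count cells in concentric annuli and divide by each annulus area."""
    pos = np.asarray(positions, dtype=float)
    if pos.size == 0:
        raise ValueError("need at least one position")
    r = np.linalg.norm(pos - np.asarray(center, dtype=float), axis=1)
    if r_max is None:
        r_max = r.max() + bin_width
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    counts, _ = np.histogram(r, bins=edges)
    areas_mm2 = math.pi * (edges[1:] ** 2 - edges[:-1] ** 2) / 1e6
    if np.any(areas_mm2 <= 0):
        raise ValueError("zero-area annulus")
    centers = 0.5 * (edges[1:] + edges[:-1])
    return RadialProfile(centers, counts / areas_mm2, counts, time)


def kymograph(profiles):
    """Stack radial profiles into a (times, bin_centers, density[t, r]) kymograph.

    All profiles must share their binning.
    """
    times = np.array([p.time for p in profiles])
    centers = profiles[0].bin_centers
    for p in profiles[1:]:
        if p.bin_centers.size != centers.size or not np.allclose(p.bin_centers, centers):
            raise ValueError("profiles must share the radial binning")
    dens = np.vstack([p.density for p in profiles])
    return times, centers, dens


def fit_ring(
    profile: RadialProfile,
    density_floor: float = 500.0,
    min_bins: int = 5,
) -> RingFit:
    """Fit baseline + height * exp(-(r - r0)^2 / (2 w^2)) to a stripped profile.

    Bins below ``density_floor`` (cells/mm^2) are discarded first, removing
    the empty field around the colony so the baseline is the bulk density
    behind the ring.
    """
    keep = profile.density >= density_floor
    if keep.sum() < min_bins:
        raise ValueError(
            f"only {int(keep.sum())} bins survive the {density_floor} cells/mm^2 "
            f"strip; need >= {min_bins}"
        )
    r = profile.bin_centers[keep]
    d = profile.density[keep]

    def model(x, baseline, height, r0, w):
        return baseline + height * np.exp(-((x - r0) ** 2) / (2.0 * w**2))

    i0 = int(np.argmax(d))
    p0 = [float(np.median(d)), float(d[i0] - np.median(d)), float(r[i0]), 100.0]
    try:
        popt, _ = curve_fit(
            model, r, d, p0=p0,
            bounds=([0, 0, 0, 1.0], [np.inf, np.inf, np.inf, np.inf]),
            maxfev=10000,
        )
        converged = True
    except RuntimeError:
        popt, converged = p0, False
    baseline, height, r0, w = popt
    return RingFit(
        position=float(r0), width=float(abs(w)),
        peak_density=float(baseline + height), baseline_density=float(baseline),
        converged=converged,
    )


def ring_speed(
    fits,
    times,
    transient_radius: float = 900.0,
) -> float:
    """Least-squares slope of ring position vs time, um/min.

    Fits whose ring still lies inside ``transient_radius`` (the initial
    colony) are excluded: the ring speed is only constant once it has left
    the seeding spot.
    """
    times = np.asarray(times, dtype=float)
    ok = np.array(
        [f.converged and f.position > transient_radius for f in fits], dtype=bool
    )
    if ok.sum() < 3:
        raise ValueError("need >= 3 converged post-transient ring fits")
    pos = np.array([f.position for f in fits])
    return float(np.polyfit(times[ok], pos[ok], 1)[0])


def radial_bias(
    tracks,
    center=(0.0, 0.0),
    lag: float = 1.0,
    bin_width: float = 100.0,
    r_max: float | None = None,
):
    """Mean radially projected velocity per distance bin, um/min.

    Displacements over time lag ``lag`` (min) are projected on the outward
    radial direction at the displacement start and divided by the lag.
    Returns ``(bin_centers, mean_bias, sem, n)`` with NaN for empty bins.
    """
    c = np.asarray(center, dtype=float)
    rs, vs = [], []
    for tr in tracks:
        tr = np.asarray(tr, dtype=float)
        t, xy = tr[:, 0], tr[:, 1:3]
        if t[-1] - t[0] < lag:
            continue
        stride = max(1, int(round(lag / (t[1] - t[0]))))
        eff_lag = (t[stride] - t[0]) if stride < len(t) else None
        if eff_lag is None or eff_lag <= 0:
            continue
        d = xy[stride:] - xy[:-stride]
        rel = xy[:-stride] - c
        rnorm = np.linalg.norm(rel, axis=1)
        rnorm[rnorm == 0] = np.inf
        proj = np.sum(d * rel, axis=1) / rnorm
        rs.append(np.linalg.norm(rel, axis=1))
        vs.append(proj / eff_lag)
    if not rs:
        raise ValueError("no track spans the requested lag")
    r = np.concatenate(rs)
    v = np.concatenate(vs)
    if r_max is None:
        r_max = r.max() + bin_width
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    idx = np.digitize(r, edges) - 1
    nb = len(edges) - 1
    mean = np.full(nb, np.nan)
    sem = np.full(nb, np.nan)
    n = np.zeros(nb, dtype=int)
    for b in range(nb):
        sel = idx == b
        n[b] = sel.sum()
        if n[b]:
            mean[b] = v[sel].mean()
            sem[b] = v[sel].std(ddof=1) / math.sqrt(n[b]) if n[b] > 1 else np.nan
    centers = 0.5 * (edges[1:] + edges[:-1])
    return centers, mean, sem, n


def diffusion_constant(track) -> float:
    """End-to-end displacement estimator of the effective diffusion constant.

    D = |x(T) - x(0)|^2 / (4 T), um^2/min. This is the study's estimator;
    it is unbiased for a pure random walk but conflates drift with
    diffusion (a pure drift of speed v over duration T reports v^2 T / 4).
    """
    tr = np.asarray(track, dtype=float)
    T = tr[-1, 0] - tr[0, 0]
    if T <= 0:
        raise ValueError("track duration must be positive")
    disp2 = float(np.sum((tr[-1, 1:3] - tr[0, 1:3]) ** 2))
    return disp2 / (4.0 * T)


def oxygen_at_ring(ring_times, ring_positions, O2_times, O2_x, O2_kymograph):
    """Sample an oxygen kymograph at the ring trajectory (bilinear).

    ``O2_kymograph`` has shape (len(O2_times), len(O2_x)). Returns C(t) at
    each ring time/position; raises if the ring leaves the field extent.
    """
    from scipy.interpolate import RegularGridInterpolator

    ring_times = np.asarray(ring_times, dtype=float)
    ring_positions = np.asarray(ring_positions, dtype=float)
    interp = RegularGridInterpolator(
        (np.asarray(O2_times, dtype=float), np.asarray(O2_x, dtype=float)),
        np.asarray(O2_kymograph, dtype=float),
        bounds_error=True,
    )
    try:
        return interp(np.column_stack([ring_times, ring_positions]))
    except ValueError as exc:
        raise ValueError(f"ring trajectory outside the oxygen field extent: {exc}")
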