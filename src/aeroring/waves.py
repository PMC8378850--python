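"""Closed-form and semi-analytic traveling-wave results for the Go-or-Grow model.

The elementary Go-or-Grow model couples cell density rho(t,x) and oxygen
C(t,x): below the threshold C0 cells advect up-gradient at constant speed a0
without dividing ("go"); above C0 they divide at rate r0 and diffuse without
bias ("grow"). In the frame z = x - sigma*t of a front moving at speed sigma
(oxygen increasing towards z -> +inf, threshold crossing pinned at z = 0)
the density satisfies a piecewise-constant-coefficient ODE that is solvable
in closed form, yielding the speed dichotomy

    sigma = a0 + r0*D/a0   if a0 >= sqrt(r0*D)   (large bias, pushed)
    sigma = 2*sqrt(r0*D)   if a0 <= sqrt(r0*D)   (small bias, pulled Fisher front)

and the division/diffusion contribution fraction phi = 2*sqrt(r0*D)/sigma.

A structural variant adds a second threshold C0p < C0 below which cells stop
sensing gradients; its wave speed solves an implicit equation obtained from
the continuously differentiable oxygen profile, located by bisection inside
the bracket [2*sqrt(r0*D), a0 + r0*D/a0].
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from aeroring.params import MeanFieldParams


@dataclass
class WaveSpeedResult:
    """Front speed with regime classification."""

    sigma: float          # um/min
    regime: str           # "small_bias" | "large_bias"
    phi: float            # 2*sqrt(r0*D)/sigma, in (0, 1]

    def __iter__(self):
        return iter((self.sigma, self.regime, self.phi))


def fisher_speed(r0: float, D: float) -> float:
    """Fisher-KPP spreading speed 2*sqrt(r0*D), um/min."""
    return 2.0 * math.sqrt(r0 * D)


def speed_formula(a0: float, r0: float, D: float) -> WaveSpeedResult:
    """Closed-form Go-or-Grow wave speed and its regime.

    Large bias (a0 > sqrt(r0*D)): sigma = a0 + r0*D/a0, a pushed wave.
    Small bias (a0 <= sqrt(r0*D)): sigma = 2*sqrt(r0*D), the pulled Fisher
    speed, independent of aerotaxis. The two branches agree at equality.
    """
    if a0 < 0 or r0 <= 0 or D <= 0:
        raise ValueError("require a0 >= 0, r0 > 0, D > 0")
    crit = math.sqrt(r0 * D)
    if a0 > crit:
        sigma = a0 + r0 * D / a0
        regime = "large_bias"
    else:
        sigma = 2.0 * crit
        regime = "small_bias"
    return WaveSpeedResult(sigma=sigma, regime=regime, phi=2.0 * crit / sigma)


def shape_speed_estimate(L_ring: float, density_ratio: float, r0: float) -> float:
    """Wave-speed estimate from the shape of the density profile, um/min.

    Integrating the traveling-wave equation over the line balances the flux
    of new cells against the front motion; with division confined to roughly
    the front half of a ring of length ``L_ring`` whose peak density exceeds
    the bulk by ``density_ratio``, this gives sigma ~ r0 * L * ratio / 2.
    """
    if L_ring < 0 or density_ratio < 0 or r0 <= 0:
        raise ValueError("inputs must be positive (r0 strictly)")
    return r0 * L_ring * density_ratio / 2.0


def phi_heatmap(a0_values, doubling_times_min, D: float = 30.0):
    """phi = 2*sqrt(r0*D)/sigma over a (doubling time, a0) grid.

    Returns an array of shape (len(doubling_times_min), len(a0_values)).
    The separatrix between pulled (phi = 1) and pushed (phi < 1) regimes is
    the curve a0 = sqrt(r0*D).
    """
    a0s = np.asarray(a0_values, dtype=float)
    tds = np.asarray(doubling_times_min, dtype=float)
    out = np.empty((tds.size, a0s.size))
    for i, td in enumerate(tds):
        r0 = math.log(2) / td
        for j, a0 in enumerate(a0s):
            out[i, j] = speed_formula(a0, r0, D).phi
    return out


@dataclass
class TravelingWaveProfile:
    """Piecewise-explicit traveling-wave density profile rho(z).

    Elementary variant (h = inf): rho = A*B for z < 0 and A*exp(mu_minus*z)
    for z > 0 with mu_minus = -a0/D (the decay root selected by the flux-jump
    relation D*[rho'](0) = -a0*rho(0)).

    Two-threshold variant: a plateau for z < -h, A*(B + E*exp(-(sigma-a0)/D z))
    on (-h, 0), and A*exp(-mu z) for z > 0. NOTE the sign convention differs
    between variants, following the respective derivations: the elementary
    profile uses the signed root mu_minus = -a0/D (rho ~ e^{mu_minus z}),
    the two-threshold profile uses the positive rate
    mu = (sigma + sqrt(sigma^2 - 4 D r0))/(2 D) (rho ~ e^{-mu z}).
    """

    a0: float
    r0: float
    D: float
    sigma: float
    variant: str            # "elementary" | "two_threshold"
    A: float = 1.0          # overall amplitude (density units)
    h: float = math.inf     # threshold gap, um (two_threshold only)
    mu: float = 0.0         # decay rate used in the z > 0 branch, 1/um
    B: float = 1.0          # plateau coefficient
    E: float = 0.0          # boundary-layer coefficient

    def __call__(self, z):
        z = np.asarray(z, dtype=float)
        lam = (self.sigma - self.a0) / self.D
        rho = np.empty_like(z)
        left = z < -self.h
        mid = (~left) & (z < 0)
        right = z >= 0
        rho[left] = self.A * (self.B + self.E * math.exp(lam * self.h))
        rho[mid] = self.A * (self.B + self.E * np.exp(-lam * z[mid]))
        rho[right] = self.A * np.exp(-self.mu * z[right])
        return rho

    @property
    def plateau(self) -> float:
        """Density far behind the front, rho(z -> -inf)."""
        lam = (self.sigma - self.a0) / self.D
        if math.isinf(self.h):
            return self.A * self.B
        return self.A * (self.B + self.E * math.exp(lam * self.h))


def explicit_profile(
    a0: float,
    r0: float,
    D: float,
    variant: str = "elementary",
    h: float | None = None,
    A: float = 1.0,
) -> TravelingWaveProfile:
    """Construct the explicit traveling-wave density profile.

    ``elementary``: requires the large-bias regime (a0 > sqrt(r0*D)); the
    profile is a plateau joined to a pure exponential of rate a0/D. At the
    regime boundary a0 = sqrt(r0*D) the z > 0 branch degenerates to
    (c1*z + c2)*exp(-sqrt(r0/D)*z); strictly-small-bias explicit profiles
    are not constructed.

    ``two_threshold``: requires ``h`` (spatial gap between the two oxygen
    thresholds) and a candidate speed ``sigma`` given through
    :func:`two_threshold_speed`; use that function instead to obtain a
    self-consistent profile.
    """
    crit = math.sqrt(r0 * D)
    if variant == "elementary":
        if a0 < crit:
            raise ValueError(
                "elementary explicit profile requires the large-bias regime "
                f"a0 >= sqrt(r0*D) = {crit:.4g}; got a0 = {a0}"
            )
        sigma = a0 + r0 * D / a0
        # mu_minus = -a0/D; store the positive decay rate for the e^{-mu z} form
        return TravelingWaveProfile(
            a0=a0, r0=r0, D=D, sigma=sigma, variant="elementary",
            A=A, h=math.inf, mu=a0 / D, B=1.0, E=0.0,
        )
    if variant == "two_threshold":
        if h is None or not h > 0:
            raise ValueError("two_threshold variant requires a positive gap h")
        sigma = _sigma_of_h(a0, r0, D, h)
        return _two_threshold_profile(a0, r0, D, sigma, h, A)
    raise ValueError(f"unknown variant {variant!r}")


def _mu_plus(sigma: float, r0: float, D: float) -> float:
    """Positive decay rate (sigma + sqrt(sigma^2 - 4 D r0)) / (2 D), 1/um."""
    disc = sigma * sigma - 4.0 * D * r0
    if disc < 0:
        if disc > -1e-12 * sigma * sigma:
            disc = 0.0
        else:
            raise ValueError("sigma below the Fisher speed: no real decay rate")
    return (sigma + math.sqrt(disc)) / (2.0 * D)


def _two_threshold_profile(a0, r0, D, sigma, h, A=1.0) -> TravelingWaveProfile:
    mu = _mu_plus(sigma, r0, D)
    B = (sigma - mu * D) / (sigma - a0)
    E = (mu * D - a0) / (sigma - a0)
    return TravelingWaveProfile(
        a0=a0, r0=r0, D=D, sigma=sigma, variant="two_threshold",
        A=A, h=h, mu=mu, B=B, E=E,
    )


def _gap_of_sigma(a0: float, r0: float, D: float, sigma: float) -> float:
    """Threshold gap h(sigma) from the flux-matching relation at z = -h.

    exp((sigma-a0)/D * h) = a0*(sigma - mu*D) / (sigma*(a0 - mu*D)).
    h -> +inf as sigma approaches the elementary speed (mu*D -> a0), where
    the second threshold is pushed infinitely far behind the front and the
    elementary model is recovered. At sigma = a0 both sides are degenerate
    (0/0); the limit is taken by symmetric evaluation.
    """
    lam = (sigma - a0) / D
    if abs(lam) * D < 1e-7 * max(sigma, a0):
        d = 1e-6 * max(sigma, a0)
        return 0.5 * (
            _gap_of_sigma(a0, r0, D, sigma + d) + _gap_of_sigma(a0, r0, D, sigma - d)
        )
    mu = _mu_plus(sigma, r0, D)
    rhs = a0 * (sigma - mu * D) / (sigma * (a0 - mu * D))
    if rhs <= 0:
        return math.nan
    return math.log(rhs) / lam


def _sigma_of_h(a0: float, r0: float, D: float, h: float) -> float:
    """Invert h(sigma) on the bracket (h is monotone increasing in sigma).

    For gaps beyond the resolvable sliver near the elementary speed the
    inversion saturates at the upper bracket end, which is the correct
    h -> inf limit to machine precision.
    """
    from scipy.optimize import brentq

    lo = 2.0 * math.sqrt(r0 * D)
    hi = a0 + r0 * D / a0
    lo_ = lo + 1e-12 * (hi - lo)
    hi_ = hi - 1e-14 * hi
    f = lambda s: _gap_of_sigma(a0, r0, D, s) - h
    flo, fhi = f(lo_), f(hi_)
    if flo >= 0:
        return lo_
    if fhi <= 0:          # gap unresolvable in sigma: elementary limit
        return hi_
    return brentq(f, lo_, hi_, xtol=1e-15, rtol=8.9e-16)


def two_threshold_residual(sigma: float, p: MeanFieldParams, h: float | None = None) -> float:
    """Residual of the implicit oxygen-consistency equation at speed ``sigma``.

    For a candidate sigma, the gap h follows from the flux-matching relation
    (or is supplied directly when iterating over h); the oxygen profile
    (consumption b0 per cell, no non-negativity constraint -- consistent with
    cells being insensitive below C0p) is solved piecewise in closed form per
    unit amplitude, and the linear matching conditions determine the
    amplitude A and the integration constants. The residual is C(-h) - C0p:
    a traveling wave exists where it vanishes.

    The numerically delicate product E*exp(lam*h) is eliminated through the
    flux-matching identity E*exp(lam*h) = -a0*B/sigma, which keeps the
    residual well conditioned arbitrarily close to the elementary limit.
    """
    a0, r0, D = p.a0, p.r0, p.D
    Doxy, b0, C0, C0p, Cb = p.Doxy, p.b0, p.C0, p.C0p, p.Cboundary
    if h is None:
        h = _gap_of_sigma(a0, r0, D, sigma)
    if not math.isfinite(h) or h <= 0:
        return math.nan
    mu = _mu_plus(sigma, r0, D)
    lam = (sigma - a0) / D          # 1/um, rho boundary-layer rate
    s = sigma / Doxy                # 1/um, oxygen homogeneous rate
    B = (sigma - mu * D) / (sigma - a0)
    E = (mu * D - a0) / (sigma - a0)
    Eehl = -a0 * B / sigma          # E * exp(lam*h), via flux matching at -h
    P = B + Eehl                    # plateau density per unit A

    # Particular solutions of Doxy*C'' + sigma*C' = b0*rho, per unit A:
    # z < -h   : rho = P                -> F*z with F = b0*P/sigma
    # -h< z <0 : rho = B + E e^{-lam z} -> H*z + I e^{-lam z}
    # z > 0    : rho = e^{-mu z}        -> Lc e^{-mu z}
    F = b0 * P / sigma
    H = b0 * B / sigma
    Ifac = b0 / (lam * (Doxy * lam - sigma))
    I = Ifac * E
    Iehl = Ifac * Eehl              # I * exp(lam*h), stable form
    Lc = b0 / (mu * (Doxy * mu - sigma))

    # Full solution:
    # C1 = A*F*z + G                                 (z < -h)
    # C2 = A*(H*z + I e^{-lam z}) + J + K e^{-s z}   (-h < z < 0)
    # C3 = A*Lc e^{-mu z} + M e^{-s z} + Cb          (z > 0)
    # Unknowns (A, J, K, M, G); conditions: C2(0)=C0, C3(0)=C0, C2'=C3' at 0,
    # C1'=C2' and C1=C2 at z=-h. Residual: C1(-h) - C0p.
    ehs = math.exp(s * h)
    Amat = np.array(
        [
            [I, 1.0, 1.0, 0.0, 0.0],                      # C2(0) = C0
            [Lc, 0.0, 0.0, 1.0, 0.0],                     # C3(0) = C0 - Cb
            [H - lam * I + mu * Lc, 0.0, -s, s, 0.0],     # C2'(0) = C3'(0)
            [F - H + lam * Iehl, 0.0, s * ehs, 0.0, 0.0],     # C1'(-h) = C2'(-h)
            [-F * h + H * h - Iehl, -1.0, -ehs, 0.0, 1.0],    # C1(-h) = C2(-h)
        ]
    )
    bvec = np.array([C0, C0 - Cb, 0.0, 0.0, 0.0])
    try:
        A, J, K, M, G = np.linalg.solve(Amat, bvec)
    except np.linalg.LinAlgError:
        return math.nan
    return (-F * A * h + G) - C0p


def two_threshold_speed(p: MeanFieldParams, rtol: float = 1e-6, h_max: float = 1e7):
    """Wave speed of the two-threshold Go-or-Grow model by dichotomy search.

    Returns ``(sigma, h)``. The speed lies in the bracket between the Fisher
    speed 2*sqrt(r0*D) and the elementary large-bias speed a0 + r0*D/a0,
    where the residual is monotone; because the gap h diverges as sigma
    approaches the elementary speed, the dichotomy runs over h (monotone in
    sigma through the flux-matching relation), which stays well conditioned
    when the root is exponentially close to the upper end. In the small-bias
    regime (a0 <= sqrt(r0*D)) the wave is pulled and the Fisher speed is
    returned with h = inf.
    """
    a0, r0, D = p.a0, p.r0, p.D
    crit = math.sqrt(r0 * D)
    lo = 2.0 * crit
    if a0 <= crit:
        return lo, math.inf
    hi = a0 + r0 * D / a0

    def res_h(h: float) -> float:
        return two_threshold_residual(_sigma_of_h(a0, r0, D, h), p, h=h)

    h_lo = _gap_of_sigma(a0, r0, D, lo + 1e-9 * (hi - lo))
    if not math.isfinite(h_lo) or h_lo <= 0:
        h_lo = 1e-3
    f_lo = res_h(h_lo)
    if f_lo <= 0:
        # oxygen already below C0p at the minimal admissible gap: the wave
        # sits at the lower (Fisher) end of the bracket
        return lo, h_lo
    h_hi = 2 * h_lo
    f_hi = res_h(h_hi)
    while f_hi > 0 and h_hi < h_max:
        h_hi *= 2.0
        f_hi = res_h(h_hi)
    if f_hi > 0:
        raise RuntimeError(
            "no sign change of the implicit-speed residual: "
            f"f(h={h_lo:.6g}) = {f_lo:.6g}, f(h={h_hi:.6g}) = {f_hi:.6g}"
        )
    a, b = h_lo, h_hi
    sig_a, sig_b = _sigma_of_h(a0, r0, D, a), _sigma_of_h(a0, r0, D, b)
    while abs(sig_b - sig_a) > rtol * sig_b and (b - a) > 1e-9 * b:
        m = 0.5 * (a + b)
        fm = res_h(m)
        if not math.isfinite(fm):
            raise RuntimeError(f"residual not finite at h = {m:.6g}")
        if fm > 0:
            a, sig_a = m, _sigma_of_h(a0, r0, D, m)
        else:
            b, sig_b = m, _sigma_of_h(a0, r0, D, m)
    h_root = 0.5 * (a + b)
    return _sigma_of_h(a0, r0, D, h_root), h_root


def potts_unit_conversions(
    cell_O2_mol_per_s: float = 1.2e-16,
    px_um: float = 10.0,
    step_s: float = 0.1,
    confinement_um: float = 50.0,
    solubility_uM: float = 250.0,
    pixels_per_cell: int = 2,
    doubling_time_h: float = 8.0,
    reference_density_mm2: float = 500.0,
):
    """Reproduce the arithmetic chain converting physical rates to Potts units.

    Returns a dict with:

    - ``mol_per_pixel_at_21``: moles of O2 in the medium column above one
      pixel at saturation (defines the 21-unit scale),
    - ``consumption_per_pixel``: %O2 units pixel^-1 step^-1 consumed by an
      occupied pixel,
    - ``boundary_flux_mol_m2_s``: areal O2 consumption flux b*rho at the
      reference density, mol m^-2 s^-1,
    - ``division_prob`` and its printed one-significant-figure rounding.
    """
    if min(cell_O2_mol_per_s, px_um, step_s, confinement_um, solubility_uM) <= 0:
        raise ValueError("all physical inputs must be positive")
    pixel_area_m2 = (px_um * 1e-6) ** 2
    column_volume_L = pixel_area_m2 * (confinement_um * 1e-6) * 1e3
    mol_per_pixel = solubility_uM * 1e-6 * column_volume_L
    units_per_mol = 21.0 / mol_per_pixel
    consumption_per_pixel = (
        cell_O2_mol_per_s / pixels_per_cell * step_s * units_per_mol
    )
    rho_per_m2 = reference_density_mm2 * 1e6
    boundary_flux = cell_O2_mol_per_s * rho_per_m2
    division_prob = 1.0 / (doubling_time_h * 3600.0 / step_s)
    exp = math.floor(math.log10(division_prob))
    return {
        "mol_per_pixel_at_21": mol_per_pixel,
        "consumption_per_pixel": consumption_per_pixel,
        "boundary_flux_mol_m2_s": boundary_flux,
        "division_prob": division_prob,
        "division_prob_printed": round(division_prob, -exp),
    }
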