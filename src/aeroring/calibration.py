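"""Stern--Volmer calibration of porphyrin oxygen-sensing films.

A PtTFPP/PDMS film is quenched by oxygen: with background Bg (medium and
coverslip autofluorescence plus camera read noise RN), zero-oxygen intensity
I0 and sensitivity K, the measured intensity obeys

    (I0 - Bg) / (I(C) - Bg) = 1 + K * C.

K and Bg are fitted per ROI of the calibration ramp (they vary with film
thickness and illumination, and are mutually uncorrelated). For covered
films, where a direct I0 is unavailable, I0 and Bg are reconstructed from
the pre-experiment reference image I(21%): Bg = alpha * I(21%) + beta (the
background line calibrated on an uncovered film) and I0 = R * I(21%), with
R = I0_U / I(21%)_U. A measured I0* taken under nominal nitrogen carries a
residual oxygen level C0* (default 0.15 %), corrected by
I0 = I0* (1 + K C0*). Error bars are half the max-min spread of the oxygen
map over the stated perturbations of Bg, I(21%) and I0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit


@dataclass
class CalibrationModel:
    """Per-ROI Stern--Volmer parameters plus the global reconstruction data."""

    K: float                     # Stern-Volmer constant, 1/%O2
    Bg: float                    # background intensity, a.u.
    I0: float                    # zero-oxygen intensity, a.u.
    alpha: float = 0.0           # background line Bg = alpha*I21 + beta
    beta: float = 0.0
    R: float = float("nan")      # I0_U / I(21%)_U
    RN: float = 0.0              # camera read noise, a.u.
    residuals: np.ndarray | None = None

    def intensity_from_oxygen(self, C):
        """Forward model I(C) = Bg + (I0 - Bg)/(1 + K C)."""
        return self.Bg + (self.I0 - self.Bg) / (1.0 + self.K * np.asarray(C, dtype=float))

    def oxygen_from_intensity(self, I):
        """Invert the Stern--Volmer relation: C = ((I0-Bg)/(I-Bg) - 1)/K."""
        I = np.asarray(I, dtype=float)
        return ((self.I0 - self.Bg) / (I - self.Bg) - 1.0) / self.K


def fit_stern_volmer(C_levels, intensities) -> CalibrationModel:
    """Fit (K, Bg, I0) to one ROI's intensity ramp at known oxygen levels.

    Requires at least three distinct levels including one near zero and one
    at 21 % so that I0 and the saturated branch are both constrained.
    """
    C = np.asarray(C_levels, dtype=float)
    I = np.asarray(intensities, dtype=float)
    if np.unique(C).size < 3:
        raise ValueError("need >= 3 distinct oxygen levels")
    if C.min() > 1.0 or C.max() < 20.0:
        raise ValueError("ramp must include a level near 0 and one at 21 %")
    if np.ptp(I) == 0:
        raise ValueError("degenerate (constant) intensities")

    def model(c, K, Bg, I0):
        return Bg + (I0 - Bg) / (1.0 + K * c)

    I0_guess = I[np.argmin(C)]
    Bg_guess = max(I.min() - 0.1 * np.ptp(I), 1e-6)
    popt, _ = curve_fit(
        model, C, I, p0=[4.0, Bg_guess, I0_guess],
        bounds=([1e-6, 0.0, 0.0], [np.inf, np.inf, np.inf]), maxfev=20000,
    )
    K, Bg, I0 = map(float, popt)
    res = I - model(C, *popt)
    return CalibrationModel(K=K, Bg=Bg, I0=I0, residuals=res)


def background_line(I21_values, Bg_values):
    """Least-squares line Bg = alpha * I(21%) + beta across ROIs.

    Returns ``(alpha, beta, max_rel_dev)`` where the last is the maximum
    deviation from the line relative to the mean background (diagnostic;
    ~10 % of Bg* on the water-filled setup, ~2 % in HL5 medium).
    """
    x = np.asarray(I21_values, dtype=float)
    y = np.asarray(Bg_values, dtype=float)
    if x.size < 2:
        raise ValueError("need >= 2 ROIs")
    if np.ptp(x) == 0:
        raise ValueError("all I(21%) identical: background line undefined")
    alpha, beta = np.polyfit(x, y, 1)
    dev = np.max(np.abs(y - (alpha * x + beta))) / max(np.mean(y), 1e-300)
    return float(alpha), float(beta), float(dev)


def read_sensor_image(path):
    """Load a single-channel sensor frame from TIFF as float64."""
    import tifffile

    return np.asarray(tifffile.imread(path), dtype=float)


def write_sensor_image(path, image) -> None:
    """Write a single-channel image (e.g. a reconstructed oxygen map) to TIFF."""
    import tifffile

    tifffile.imwrite(path, np.asarray(image, dtype=np.float32))


def roi_grid(image, roi: int = 64):
    """Mean intensity per ROI tile (default 64x64 px); trims partial tiles."""
    img = np.asarray(image, dtype=float)
    nx, ny = img.shape[0] // roi, img.shape[1] // roi
    tiles = img[: nx * roi, : ny * roi].reshape(nx, roi, ny, roi)
    return tiles.mean(axis=(1, 3))


def correct_residual_I0(I0_star, K, C0_star: float = 0.15):
    """True I0 from a zero-ramp image with residual oxygen C0*.

    Under nominal nitrogen a residual C0* ~ 0.15 % remains (tubing and
    chamber leaks); the dye's nonlinearity then underestimates I0 by the
    factor 1 + K*C0* (1.75 at K = 5).
    """
    return np.asarray(I0_star, dtype=float) * (1.0 + K * C0_star)


def reconstruct_oxygen_map(
    I_image,
    I21_image,
    alpha: float,
    beta: float,
    R: float,
    K_map=None,
    RN: float = 0.0,
    Bg_rel_err: float = 0.10,
    I21_rel_err: float = 0.02,
    I0_factor: float = 1.75,
):
    """Pixelwise oxygen map with (max-min)/2 error bars.

    The background image is alpha*I21 + beta and the reconstituted
    zero-oxygen image is R*I21. By default the sensitivity map is derived
    from the same images -- K = ((I0-Bg)/(I21-Bg) - 1)/21 per pixel -- and
    then C = ((I0-Bg)/(I-Bg) - 1)/K. Because K and C use the same I0, an
    error on I0 largely cancels except at deeply hypoxic levels, which is
    what keeps the map usable despite the large residual-oxygen uncertainty.
    Passing an explicit ``K_map`` fixes the sensitivity instead.

    The error map is half the (max - min) spread of C when each stated
    error source is explored in turn around the nominal map: Bg*
    (background minus read noise) by ±``Bg_rel_err`` (10 % on the
    water-filled setup, 2 % in HL5), I(21%) by ±``I21_rel_err`` of its
    read-noise-corrected signal, and I0 by the factor ``I0_factor`` (up and
    down; 1.75 is the worst case of skipping the residual-oxygen correction
    at K = 5). Pixels with I <= Bg are masked (NaN) and counted.
    """
    I = np.asarray(I_image, dtype=float)
    I21 = np.asarray(I21_image, dtype=float)
    K_fixed = None if K_map is None else np.broadcast_to(
        np.asarray(K_map, dtype=float), I.shape
    )

    def cmap(bg_scale, i21_err, i0_fac):
        I21p = I21 + i21_err * (I21 - RN)
        Bg = alpha * I21p + beta
        Bg = RN + (Bg - RN) * bg_scale
        I0 = R * I21p * i0_fac
        denom = I - Bg
        denom21 = I21p - Bg
        with np.errstate(divide="ignore", invalid="ignore"):
            if K_fixed is None:
                K = ((I0 - Bg) / denom21 - 1.0) / 21.0
            else:
                K = K_fixed
            C = ((I0 - Bg) / denom - 1.0) / K
        C = np.where((denom <= 0) | (K <= 0), np.nan, C)
        return C

    C_nom = cmap(1.0, 0.0, 1.0)
    n_masked = int(np.sum(~np.isfinite(C_nom)))
    lo = C_nom.copy()
    hi = C_nom.copy()
    probes = [
        (1.0 - Bg_rel_err, 0.0, 1.0),
        (1.0 + Bg_rel_err, 0.0, 1.0),
        (1.0, -I21_rel_err, 1.0),
        (1.0, I21_rel_err, 1.0),
        (1.0, 0.0, 1.0 / I0_factor),
        (1.0, 0.0, I0_factor),
    ]
    for bs, ie, i0f in probes:
        C = cmap(bs, ie, i0f)
        lo = np.fmin(lo, C)
        hi = np.fmax(hi, C)
    err = (hi - lo) / 2.0
    return C_nom, err, n_masked
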