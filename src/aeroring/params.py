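"""Model parameters and unit conventions shared across the package.

Oxygen is measured in % O2 throughout (0--21 scale, 21% = atmospheric).
Lengths are in micrometres and times in minutes for the continuum models;
the Potts model uses its own lattice units (1 pixel = 10 um, 1 Monte Carlo
step = 0.1 s) with oxygen in the same % scale.

The molar anchor of the % scale: under the measured 50 um vertical
confinement, the oxygen available at saturation above one 10x10 um pixel is
1.25e-15 mol, defined to be 21 units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, asdict
from pathlib import Path

import yaml

#: moles of O2 above one pixel at atmospheric saturation (= 21 % units)
MOL_PER_PIXEL_AT_21 = 1.25e-15
#: moles of O2 per % unit above one pixel
MOL_PER_PIXEL_PER_PERCENT = MOL_PER_PIXEL_AT_21 / 21.0


class ParameterError(ValueError):
    """Raised when a parameter violates its physical constraints."""


def _microfluidic_gradient_at(C: float) -> float:
    """Magnitude of the microfluidic oxygen gradient, %O2/um, at level ``C``.

    The device gradient is the logistic profile C(x) = 21.38/(1+exp(0.031(x-200)))
    with x in 10-um pixels; its slope at a given concentration is
    0.031 * C * (1 - C/21.38) per pixel.
    """
    s = C / 21.38
    return 21.38 * 0.031 * s * (1.0 - s) / 10.0


def meanfield_aero_amplitude(bias_um_min: float = 1.0, C_ref: float = 0.4) -> float:
    """Amplitude of the mean-field aerotactic sensitivity, um^2 min^-1 %^-1.

    The aerotactic response curve lambda(C) is only published in Potts energy
    units (amplitude 800). For the continuum model the advection speed is
    a = lambda_mf(C) * dC/dr, so the amplitude must carry units of
    um^2 min^-1 %^-1. It is fixed by requiring that, in the microfluidic
    reference gradient at the deeply hypoxic level ``C_ref`` (default 0.4 %,
    where the cell bias was measured), the resulting advection speed equals
    the measured bias (default 1 um/min).
    """
    sigmoid = 1.0 / (1.0 + math.exp((C_ref - 0.7) / 0.2))
    return bias_um_min / (sigmoid * _microfluidic_gradient_at(C_ref))


@dataclass
class MeanFieldParams:
    """Parameters of the continuum density/oxygen model.

    Attributes
    ----------
    D : cell diffusion constant, um^2/min
    Doxy : oxygen diffusion constant in medium, um^2/min
    r0 : cell division rate, 1/min (default: doubling time 480 min)
    b0 : per-cell O2 consumption rate, %O2 min^-1 cell^-1 (density in cells/mm^2)
    C0 : upper oxygen threshold (division off / aerotaxis on below), %O2
    C0p : lower oxygen threshold (aerotaxis off below; consumption ramp), %O2
    a0 : Go-or-Grow advection speed, um/min
    Cboundary : oxygen held at the domain edge, %O2
    L : half-domain size, um
    aero_amplitude : mean-field aerotactic sensitivity amplitude,
        um^2 min^-1 %^-1 (see :func:`meanfield_aero_amplitude`)
    """

    D: float = 30.0
    Doxy: float = 1.2e5
    r0: float = math.log(2) / 480.0
    b0: float = 0.01
    C0: float = 0.7
    C0p: float = 0.1
    a0: float = 1.0
    Cboundary: float = 21.0
    L: float = 9000.0
    aero_amplitude: float = field(default_factory=meanfield_aero_amplitude)

    def __post_init__(self) -> None:
        for name in ("D", "Doxy", "r0", "b0", "a0", "L", "aero_amplitude"):
            v = getattr(self, name)
            if name == "a0":
                if v < 0:
                    raise ParameterError(f"{name} must be non-negative, got {v}")
            elif not v > 0:
                raise ParameterError(f"{name} must be strictly positive, got {v}")
        if not (0 <= self.C0p < self.C0 < self.Cboundary):
            raise ParameterError(
                f"thresholds must satisfy 0 <= C0p < C0 < Cboundary, "
                f"got C0p={self.C0p}, C0={self.C0}, Cboundary={self.Cboundary}"
            )

    @property
    def doubling_time(self) -> float:
        """Cell doubling time, minutes."""
        return math.log(2) / self.r0


@dataclass
class PottsParams:
    """Parameters of the cellular Potts model (lattice units).

    Energies are dimensionless; oxygen in %O2; 1 pixel = 10 um and
    1 Monte Carlo step = 0.1 s are fixed calibrations.
    """

    lambda_v: float = 800.0          # volume-constraint stiffness
    V_target: int = 2                # target cell volume, pixels
    lambda_aero_max: float = 800.0   # aerotaxis sigmoid amplitude
    aero_midpoint: float = 0.7       # %O2
    aero_width: float = 0.2          # %O2
    T_base: float = 85.0             # effective temperature at high O2
    T_amp: float = 105.0             # aerokinetic temperature increase
    T_midpoint: float = 0.7          # %O2
    T_width: float = 1.0             # %O2
    consumption_per_pixel: float = 0.1   # %O2 units pixel^-1 step^-1
    leak_coeff: float = 0.001        # %O2 units pixel^-1 step^-1 at C=0
    division_prob: float = 1.0 / 288000.0  # per cell per step (full precision)
    division_cutoff: float = 0.7     # %O2; no division below
    px_um: float = 10.0              # fixed: 1 pixel = 10 um
    step_s: float = 0.1              # fixed: 1 MCS = 0.1 s
    Dox_px: float = 2.0              # oxygen diffusion, pixel^2/step
    neighborhood: str = "moore"      # copy-attempt dialect: moore | vonneumann

    def __post_init__(self) -> None:
        for name in (
            "lambda_v", "V_target", "lambda_aero_max", "aero_width", "T_base",
            "T_amp", "T_width", "consumption_per_pixel", "px_um", "step_s", "Dox_px",
        ):
            if not getattr(self, name) > 0:
                raise ParameterError(
                    f"{name} must be strictly positive, got {getattr(self, name)}"
                )
        for name in ("leak_coeff", "division_prob", "division_cutoff"):
            if getattr(self, name) < 0:
                raise ParameterError(
                    f"{name} must be non-negative, got {getattr(self, name)}"
                )
        if self.neighborhood not in ("moore", "vonneumann"):
            raise ParameterError(
                f"neighborhood must be 'moore' or 'vonneumann', got {self.neighborhood!r}"
            )

    @property
    def rounded_division_prob(self) -> float:
        """Division probability rounded to one significant figure (3e-6).

        The full-precision value 1/288000 (doubling time 8 h at 10 steps/s)
        is used in simulations to avoid compounding rounding error.
        """
        exp = math.floor(math.log10(self.division_prob))
        return round(self.division_prob, -exp)

    def lambda_aero(self, C):
        """Aerotactic strength sigmoid: max/(1+exp((C-mid)/width))."""
        import numpy as np

        return self.lambda_aero_max / (
            1.0 + np.exp((np.asarray(C, dtype=float) - self.aero_midpoint) / self.aero_width)
        )

    def temperature(self, C):
        """Effective (aerokinetic) temperature: base + amp/(1+exp((C-mid)/width))."""
        import numpy as np

        return self.T_base + self.T_amp / (
            1.0 + np.exp((np.asarray(C, dtype=float) - self.T_midpoint) / self.T_width)
        )

    @property
    def Dox_um2_per_s(self) -> float:
        """Oxygen diffusivity implied by Dox_px, in um^2/s (2e3 at defaults)."""
        return self.Dox_px * self.px_um**2 / self.step_s


def _build(cls, config: dict):
    names = {f.name for f in fields(cls)}
    kwargs = {k: v for k, v in config.items() if k in names}
    return cls(**kwargs), names


def load_params(config: dict | str | Path | None = None):
    """Build ``(MeanFieldParams, PottsParams)`` from a flat key/value config.

    ``config`` may be a dict, a path to a YAML file, or None (all defaults).
    Keys must belong to the field names of either parameter set; unspecified
    keys take the published defaults.
    """
    if config is None:
        config = {}
    elif isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh) or {}
    if not isinstance(config, dict):
        raise ParameterError("config must be a flat key/value mapping")
    mf, mf_names = _build(MeanFieldParams, config)
    potts, potts_names = _build(PottsParams, config)
    unknown = set(config) - mf_names - potts_names
    if unknown:
        raise ParameterError(f"unknown parameter names: {sorted(unknown)}")
    return mf, potts


def dump_params(mf: MeanFieldParams, potts: PottsParams, path: str | Path) -> None:
    """Serialize both parameter sets to a flat YAML document."""
    doc = {**asdict(mf), **asdict(potts)}
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)
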