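"""Buoyancy frequency, heat-budget diffusivity, thermocline methane flux.

The vertical methane input to the surface mixed layer is a Fick's-law flux
``F_z = K_z * dC/dz`` across the SML base (depth positive downward, so a
methane peak below the SML gives dC/dz > 0 and a positive flux INTO the
layer -- the sign convention used throughout the package). The basin-scale
diffusivity ``K_z`` comes from the heat-budget method: the rate of change
of heat content below a depth, divided by the local temperature gradient
and the planar area,

    K_z(z) = -(d/dt integral_z^z_max A(z') T(z') dz') / (A(z) dT/dz),

which assumes vertical turbulent diffusion is the only heat transport below
the depth considered (no solar heating below the SML, no geothermal flux).
Where the temperature gradient falls below a floor the method degenerates
and the cell is flagged undefined (NaN), never zero-filled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import LakeGeometry, ValidationError
from .gas_exchange import InsufficientDataError

G = 9.80665  # m s-2
SECONDS_PER_DAY = 86400.0
DEFAULT_GRADIENT_FLOOR = 0.01  # degC m-1; below this the heat budget degenerates

# UNESCO (Millero & Poisson) fresh-water density polynomial, S = 0
_RHO_COEF = (999.842594, 6.793952e-2, -9.095290e-3, 1.001685e-4,
             -1.120083e-6, 6.536332e-9)


def water_density(temp_c: np.ndarray | float) -> np.ndarray | float:
    """Fresh-water density [kg m-3] from temperature [degC]."""
    t = np.asarray(temp_c, dtype=float)
    rho = sum(c * t**i for i, c in enumerate(_RHO_COEF))
    return float(rho) if np.isscalar(temp_c) else rho


@dataclass
class ProfileSeries:
    """A rectangular depth x date grid of temperature or methane values.

    ``depths`` strictly increasing [m, 1-m grid in practice]; ``values``
    shaped (n_depths, n_dates). Methane grids must be non-negative.
    """

    dates: pd.DatetimeIndex
    depths: np.ndarray
    values: np.ndarray
    variable: str = "temperature"

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.dates = pd.DatetimeIndex(self.dates)
        if np.any(np.diff(self.depths) <= 0):
            raise ValidationError("depths must be strictly increasing")
        if self.values.shape != (self.depths.size, self.dates.size):
            raise ValidationError(
                f"values shape {self.values.shape} != "
                f"(n_depths={self.depths.size}, n_dates={self.dates.size})")
        if self.variable == "ch4" and np.nanmin(self.values) < 0:
            raise ValidationError("negative methane concentration")

    def column(self, date_index: int) -> np.ndarray:
        return self.values[:, date_index]

    @classmethod
    def from_long(cls, frame: pd.DataFrame, variable: str = "temperature",
                  ) -> "ProfileSeries":
        """Build from a long table with columns ``date, depth_m, value``."""
        pivot = frame.pivot_table(index="depth_m", columns="date", values="value")
        if pivot.isna().any().any():
            raise ValidationError("profile grid is not rectangular")
        return cls(dates=pd.DatetimeIndex(pivot.columns),
                   depths=pivot.index.to_numpy(dtype=float),
                   values=pivot.to_numpy(dtype=float), variable=variable)


@dataclass
class DiffusivityProfile:
    """Basin-scale K_z [m^2 s-1] on a depth grid; NaN marks undefined cells."""

    depths: np.ndarray
    K_z: np.ndarray
    method: str = "heat_budget"

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths, dtype=float)
        self.K_z = np.asarray(self.K_z, dtype=float)
        if np.nanmin(self.K_z, initial=0.0) < -1e-18:
            raise ValidationError("negative diffusivity")


def buoyancy_frequency(depths: np.ndarray, temp_c: np.ndarray) -> np.ndarray:
    """Squared buoyancy frequency N^2 [s-2] of a temperature profile.

    ``N^2 = -(g/rho) d rho/dz`` with z positive upward; with depth positive
    downward this is ``+(g/rho) d rho/d(depth)``, so density increasing with
    depth (stable stratification) gives N^2 > 0. Centred differences inside,
    one-sided at the boundaries.
    """
    depths = np.asarray(depths, dtype=float)
    temp_c = np.asarray(temp_c, dtype=float)
    if depths.size < 2:
        raise InsufficientDataError("buoyancy frequency needs >= 2 depths")
    rho = water_density(temp_c)
    drho_dz = np.gradient(rho, depths)
    return G / rho * drho_dz


def heat_budget_diffusivity(temp_series: ProfileSeries, geometry: LakeGeometry,
                            gradient_floor: float = DEFAULT_GRADIENT_FLOOR,
                            ) -> list[DiffusivityProfile]:
    """Heat-budget K_z profiles, one per consecutive date pair.

    For each pair the heat content below every grid depth is integrated
    hypsometrically (trapezoid), differenced over the calendar-day interval,
    and divided by ``A(z) * dT/dz`` evaluated on the time-averaged profile.
    Cells with ``|dT/dz| < gradient_floor`` or a non-positive estimate are
    flagged NaN.
    """
    if temp_series.dates.size < 2:
        raise InsufficientDataError("heat budget needs >= 2 dates")
    depths = temp_series.depths
    hyps = geometry.hypsometry
    if depths[-1] > hyps["depth_m"].to_numpy()[-1] + 1e-9:
        raise ValidationError("hypsometry does not cover the profile depths")
    area = np.interp(depths, hyps["depth_m"], hyps["area_m2"])
    if np.any(area <= 0):
        raise ValidationError("zero planar area at a profile depth")

    profiles: list[DiffusivityProfile] = []
    for j in range(temp_series.dates.size - 1):
        t0 = temp_series.column(j)
        t1 = temp_series.column(j + 1)
        dt_s = (temp_series.dates[j + 1] - temp_series.dates[j]).total_seconds()
        if dt_s <= 0:
            raise ValidationError("dates must be strictly increasing")
        heat0 = _heat_below(depths, area, t0)
        heat1 = _heat_below(depths, area, t1)
        tmid = 0.5 * (t0 + t1)
        grad = np.gradient(tmid, depths)
        kz = np.full(depths.size, np.nan)
        defined = np.abs(grad) >= gradient_floor
        with np.errstate(divide="ignore", invalid="ignore"):
            est = -(heat1 - heat0) / dt_s / (area * grad)
        kz[defined] = est[defined]
        kz[kz < 0] = np.nan  # upgradient estimates are artefacts, not mixing
        profiles.append(DiffusivityProfile(depths=depths.copy(), K_z=kz))
    return profiles


def _heat_below(depths: np.ndarray, area: np.ndarray, temp: np.ndarray,
                ) -> np.ndarray:
    """Hypsometric integral of A*T from each depth to the bottom [degC m^3]."""
    integrand = area * temp
    total = np.trapezoid(integrand, depths)
    cumulative = np.concatenate(
        [[0.0], np.cumsum(0.5 * (integrand[1:] + integrand[:-1]) * np.diff(depths))])
    return total - cumulative


@dataclass
class ThermoclineFlux:
    """F_z result with its provenance: the K_z used and the gradient."""

    flux_mmol_m2_d: float
    K_z_used: float
    gradient_nmol_l_m: float
    defined: bool = True
    window: tuple[float, float] = field(default=(0.0, 0.0))


def thermocline_flux(kz_profile: DiffusivityProfile, ch4_depths: np.ndarray,
                     ch4_nmol_l: np.ndarray, sml_thickness: float,
                     ) -> ThermoclineFlux:
    """Diffusive methane flux into the SML across its base [mmol m-2 d-1].

    Uses the 1-m finite-difference concentration gradient centred at the SML
    base and, conservatively, the maximum defined K_z within the bottom 3 m
    of the SML. Positive flux means methane enters the SML from below
    (concentration increasing with depth).
    """
    ch4_depths = np.asarray(ch4_depths, dtype=float)
    ch4_nmol_l = np.asarray(ch4_nmol_l, dtype=float)
    d = float(sml_thickness)
    if ch4_depths[0] > d - 1.0 - 1e-9 or ch4_depths[-1] < d + 1.0 - 1e-9:
        raise ValidationError(
            "CH4 profile must cover the SML base +/- 1 m for the gradient")
    c_below = float(np.interp(d + 1.0, ch4_depths, ch4_nmol_l))
    c_above = float(np.interp(d - 1.0, ch4_depths, ch4_nmol_l))
    gradient = (c_below - c_above) / 2.0  # nmol l-1 per m, positive downward

    window = (d - 3.0, d)
    in_window = (kz_profile.depths >= window[0] - 1e-9) & (
        kz_profile.depths <= window[1] + 1e-9)
    kz_cells = kz_profile.K_z[in_window]
    kz_cells = kz_cells[np.isfinite(kz_cells)]
    if kz_cells.size == 0:
        return ThermoclineFlux(np.nan, np.nan, gradient, defined=False,
                               window=window)
    kz = float(np.max(kz_cells))

    # K_z [m2 s-1] * dC/dz [nmol l-1 m-1 = 1e-6 mol m-4] -> mol m-2 s-1
    flux_mol_m2_d = kz * gradient * 1e-6 * SECONDS_PER_DAY
    return ThermoclineFlux(flux_mmol_m2_d=flux_mol_m2_d * 1e3, K_z_used=kz,
                           gradient_nmol_l_m=gradient, window=window)
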