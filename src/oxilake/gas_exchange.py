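"""Floating-chamber fluxes, k600--wind regression, wind-based emission.

Surface emission ``F_S`` is measured directly with a floating chamber when
deployments exist, otherwise estimated from wind speed through a linear
gas-transfer relation ``k600 = slope * U10 + intercept`` fitted to
chamber-derived transfer velocities. ``k600`` is the transfer velocity
normalised to a Schmidt number of 600; the methane-specific velocity is
``k_CH4 = k600 * (Sc_CH4(T)/600)^(-n)`` with ``n = 1/2`` for a wavy surface
(configurable to 2/3 for smooth/low-wind regimes).

Schmidt number: Wanninkhof's freshwater CH4 polynomial. Equilibrium
concentration: the Wiesenburg--Guinasso atmospheric-solubility fit at zero
salinity. At temperate summer conditions (1.9 ppm CH4, ~20 degC) the
equilibrium is ~3 nmol l-1, two orders of magnitude below the observed SML
oversaturation, so emission is essentially proportional to the surface
concentration.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import ValidationError

R_GAS = 8.314462618  # J mol-1 K-1
P_ATM = 101325.0  # Pa
DEFAULT_ATM_PPM = 1.9
DEFAULT_SC_EXPONENT = 0.5

# Wanninkhof (1992) freshwater CH4 Schmidt-number polynomial coefficients
_SC_CH4_FRESH = (1897.8, -114.28, 3.2902, -0.039061)

# Wiesenburg & Guinasso (1979) atmospheric-equilibrium fit, nmol l-1 track
_WG_A = (-415.2807, 596.8104, 379.2599, -62.0757)


class InsufficientDataError(ValidationError):
    """Fewer observations than the operation requires."""


class DegenerateGradientError(ValueError):
    """Air--water concentration gradient vanishes while flux does not."""


def schmidt_number_ch4(temp_c: float | np.ndarray) -> float | np.ndarray:
    """Schmidt number of CH4 in fresh water at ``temp_c`` [degC]."""
    a0, a1, a2, a3 = _SC_CH4_FRESH
    t = np.asarray(temp_c, dtype=float)
    sc = a0 + a1 * t + a2 * t**2 + a3 * t**3
    return float(sc) if np.isscalar(temp_c) else sc


def equilibrium_concentration(temp_c: float | np.ndarray,
                              atm_ppm: float = DEFAULT_ATM_PPM,
                              ) -> float | np.ndarray:
    """Atmospheric-equilibrium dissolved CH4 [nmol l-1] in fresh water.

    ``atm_ppm`` is the atmospheric mixing ratio in ppm (mole fraction 1e-6).
    """
    t_k = np.asarray(temp_c, dtype=float) + 273.15
    a1, a2, a3, a4 = _WG_A
    ln_c = (np.log(atm_ppm * 1e-6)
            + a1 + a2 * (100.0 / t_k) + a3 * np.log(t_k / 100.0)
            + a4 * (t_k / 100.0))
    c = np.exp(ln_c)
    return float(c) if np.isscalar(temp_c) else c


# ---------------------------------------------------------------------------
# Chamber flux
# ---------------------------------------------------------------------------

@dataclass
class ChamberDeployment:
    """A floating-chamber time series.

    ``times_min`` minutes since deployment (strictly increasing, >= 3
    points); ``headspace_ppm`` chamber CH4 mixing ratio [ppm];
    ``chamber_volume_l`` headspace volume [l] (15 l as deployed);
    ``footprint_area_m2`` water surface enclosed [m^2];
    ``water_temperature_c`` for the air-side molar volume and, downstream,
    the Schmidt number; ``surface_concentration_nmol_l`` dissolved CH4 at
    the surface; ``atmospheric_ppm`` ambient mixing ratio.
    """

    times_min: np.ndarray
    headspace_ppm: np.ndarray
    chamber_volume_l: float = 15.0
    footprint_area_m2: float = 0.196  # ~50 cm diameter ring
    water_temperature_c: float = 20.0
    surface_concentration_nmol_l: float | None = None
    atmospheric_ppm: float = DEFAULT_ATM_PPM

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.headspace_ppm = np.asarray(self.headspace_ppm, dtype=float)
        if self.times_min.size < 3:
            raise InsufficientDataError("chamber deployment needs >= 3 time points")
        if np.any(np.diff(self.times_min) <= 0):
            raise ValidationError("chamber times must be strictly increasing")
        if self.chamber_volume_l <= 0 or self.footprint_area_m2 <= 0:
            raise ValidationError("chamber volume and footprint must be positive")
        if np.any(self.headspace_ppm < 0):
            raise ValidationError("negative chamber concentration")


def chamber_flux(dep: ChamberDeployment) -> float:
    """Areal CH4 flux [mmol m-2 d-1] from the headspace enrichment slope.

    The chamber CH4 amount is ``ppm * 1e-6 * p V / (R T)`` (ideal gas at
    1 atm and the water temperature); the flux is the least-squares slope of
    amount versus time divided by the footprint area. Negative values
    (influx) are permitted.
    """
    t_k = dep.water_temperature_c + 273.15
    mol_per_ppm = 1e-6 * P_ATM * dep.chamber_volume_l * 1e-3 / (R_GAS * t_k)
    amount_mmol = dep.headspace_ppm * mol_per_ppm * 1e3
    days = dep.times_min / (60.0 * 24.0)
    slope = stats.linregress(days, amount_mmol).slope  # mmol d-1
    return float(slope / dep.footprint_area_m2)


# ---------------------------------------------------------------------------
# Transfer velocities
# ---------------------------------------------------------------------------

def k600_from_flux(flux_mmol_m2_d: float, surface_conc_nmol_l: float,
                   temp_c: float, atm_ppm: float = DEFAULT_ATM_PPM,
                   sc_exponent: float = DEFAULT_SC_EXPONENT) -> float:
    """Invert a measured areal flux to a k600 transfer velocity [cm h-1].

    ``k_CH4 = F / (C_surface - C_eq)``, then ``k600 = k_CH4 *
    (Sc_CH4(T)/600)^(sc_exponent)``.

    Raises
    ------
    DegenerateGradientError
        If the air--water gradient vanishes (including zero flux, where the
        transfer velocity is undetermined rather than zero).
    """
    c_eq = equilibrium_concentration(temp_c, atm_ppm)
    delta = surface_conc_nmol_l - c_eq  # nmol l-1 == umol m-3
    if abs(delta) < 1e-9 or flux_mmol_m2_d == 0.0:
        raise DegenerateGradientError(
            "air-water gradient or flux vanishes; k cannot be inferred")
    delta_mol_m3 = delta * 1e-6
    k_m_d = flux_mmol_m2_d * 1e-3 / delta_mol_m3
    k_cm_h = k_m_d * 100.0 / 24.0
    sc = schmidt_number_ch4(temp_c)
    return float(k_cm_h * (sc / 600.0) ** sc_exponent)


def k_ch4_from_k600(k600_cm_h: float | np.ndarray, temp_c: float | np.ndarray,
                    sc_exponent: float = DEFAULT_SC_EXPONENT,
                    ) -> float | np.ndarray:
    """Methane-specific transfer velocity [cm h-1] from k600."""
    sc = schmidt_number_ch4(temp_c)
    return k600_cm_h * (600.0 / np.asarray(sc)) ** sc_exponent


@dataclass(frozen=True)
class K600WindModel:
    """Linear k600(U10) relation with its fit statistics.

    ``k600 [cm h-1] = slope * U10 [m s-1] + intercept``.
    """

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int

    def __post_init__(self) -> None:
        if not 0 <= self.r_squared <= 1 + 1e-12:
            raise ValidationError("r_squared must lie in [0, 1]")

    def k600(self, u10: float | np.ndarray) -> float | np.ndarray:
        return self.slope * np.asarray(u10, dtype=float) + self.intercept


def fit_k600_wind(u10: np.ndarray, k600: np.ndarray) -> K600WindModel:
    """Ordinary least squares of k600 on wind speed.

    Two points fit exactly (R^2 = 1) and emit an overfit warning; a
    degenerate design (all wind speeds equal) raises.
    """
    u10 = np.asarray(u10, dtype=float)
    k600 = np.asarray(k600, dtype=float)
    if u10.size < 2:
        raise InsufficientDataError("k600-wind regression needs >= 2 pairs")
    if np.ptp(u10) == 0:
        raise np.linalg.LinAlgError("degenerate design: all wind speeds equal")
    if u10.size == 2:
        warnings.warn("two-point k600-wind fit is an exact interpolation "
                      "(R^2 = 1); treat as overfit", stacklevel=2)
    with warnings.catch_warnings():
        # constant k600 yields an R^2 of 0/0; define it as 0
        warnings.simplefilter("ignore", category=RuntimeWarning)
        res = stats.linregress(u10, k600)
    r2 = 0.0 if np.ptp(k600) == 0 else float(res.rvalue**2)
    p = 1.0 if math.isnan(res.pvalue) else float(res.pvalue)
    return K600WindModel(slope=float(res.slope), intercept=float(res.intercept),
                         r_squared=r2, p_value=p, n=int(u10.size))


def estimate_emission(model: K600WindModel, u10_series: np.ndarray,
                      surface_conc_nmol_l: float | np.ndarray,
                      temp_c: float | np.ndarray,
                      atm_ppm: float = DEFAULT_ATM_PPM,
                      sc_exponent: float = DEFAULT_SC_EXPONENT,
                      ) -> tuple[float, float, np.ndarray]:
    """Wind-based surface emission over a U10 series.

    Per time step: ``k600 -> k_CH4 -> F = k_CH4 * (C_surface - C_eq)``.

    Returns
    -------
    (mean, sd, per_step) : flux in mmol m-2 d-1; sd uses the n-1 denominator
    (0 for a single step).
    """
    u10 = np.atleast_1d(np.asarray(u10_series, dtype=float))
    if u10.size == 0:
        raise InsufficientDataError("empty wind series")
    if np.any(u10 < 0):
        raise ValidationError("negative wind speed")
    c_eq = equilibrium_concentration(temp_c, atm_ppm)
    delta_mol_m3 = (np.asarray(surface_conc_nmol_l, dtype=float) - c_eq) * 1e-6
    k600 = model.k600(u10)
    k_m_d = np.asarray(k_ch4_from_k600(k600, temp_c, sc_exponent)) / 100.0 * 24.0
    flux = k_m_d * delta_mol_m3 * 1e3  # mmol m-2 d-1
    flux = np.broadcast_to(flux, u10.shape).astype(float)
    sd = float(np.std(flux, ddof=1)) if flux.size > 1 else 0.0
    return float(np.mean(flux)), sd, flux
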