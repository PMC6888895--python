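"""Lake geometry and the unit system shared by all pipeline stages.

The mass balance treats the surface mixed layer (SML) as a control volume
whose shape is derived from the lake's hypsometry (depth--area relation).
Four geometric quantities drive the budget:

* ``A_tot`` -- lake surface area [m^2], the emission surface,
* ``A_th``  -- planar area at the SML base (top of the thermocline) [m^2],
  the surface through which vertical diffusion acts,
* ``A_sed`` -- littoral sediment surface inside the SML [m^2], the surface
  through which lateral sediment methane enters,
* ``volume_sml`` (often written as the forall symbol) -- SML volume [m^3].

Budget terms are carried either whole-system (mol d-1) or normalised
per volume (nmol l-1 d-1) / per area (mmol m-2 d-1); :class:`Quantity`
converts between the tracks given a :class:`LakeGeometry`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

MOLAR_MASS_CH4 = 16.04  # g mol-1

SedimentAreaConvention = Literal["frustum", "projected"]


class ValidationError(ValueError):
    """Raised when an input table or parameter violates a precondition."""


class UnitError(ValueError):
    """Raised for undefined unit conversions or inconsistent unit pairs."""


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LakeGeometry:
    """Planar areas and SML volume derived from hypsometry.

    Attributes
    ----------
    hypsometry : pandas.DataFrame
        Columns ``depth_m`` (0 at the surface, positive downward) and
        ``area_m2`` (planar area), monotone non-increasing with depth.
    sml_thickness : float
        SML thickness [m].
    A_tot, A_th, A_sed : float
        Planar surface area, planar area at the SML base, and littoral
        sediment surface within the SML [m^2].
    volume_sml : float
        Hypsometric volume of the SML [m^3].
    """

    hypsometry: pd.DataFrame = field(repr=False)
    sml_thickness: float
    A_tot: float
    A_th: float
    A_sed: float
    volume_sml: float

    def __post_init__(self) -> None:
        if not (self.A_tot > 0 and self.A_th > 0 and self.volume_sml > 0):
            raise ValidationError("areas and volume must be strictly positive")
        if self.A_th > self.A_tot * (1 + 1e-12):
            raise ValidationError("A_th cannot exceed A_tot")
        if self.sml_thickness > 0 and not self.A_sed > 0:
            raise ValidationError("A_sed must be positive for a finite SML")


def _interp_area(depths: np.ndarray, areas: np.ndarray, z: float) -> float:
    return float(np.interp(z, depths, areas))


def derive_geometry(
    hypsometry: pd.DataFrame,
    sml_thickness: float,
    convention: SedimentAreaConvention = "frustum",
) -> LakeGeometry:
    """Derive SML geometry from a depth--area table.

    Parameters
    ----------
    hypsometry : pandas.DataFrame
        Columns ``depth_m`` and ``area_m2``; depth 0 must be present (or the
        shallowest entry is taken as the surface), areas monotone
        non-increasing with depth.
    sml_thickness : float
        SML thickness [m]; must lie inside the table's depth range.
    convention : {"frustum", "projected"}
        Littoral sediment area model. ``"frustum"`` sums the lateral surface
        of the conical frusta between successive depth contours (circular
        equivalent radii); ``"projected"`` uses the planar ring
        ``A_tot - A_th``. The frustum exceeds the projection by the bottom
        slope's slant factor.

    Returns
    -------
    LakeGeometry

    Raises
    ------
    ValidationError
        Non-monotone hypsometry or missing columns.
    ValueError
        ``sml_thickness`` outside the table's depth range.
    """
    required = {"depth_m", "area_m2"}
    if not required.issubset(hypsometry.columns):
        raise ValidationError(f"hypsometry must have columns {sorted(required)}")
    table = hypsometry.sort_values("depth_m").reset_index(drop=True)
    depths = table["depth_m"].to_numpy(dtype=float)
    areas = table["area_m2"].to_numpy(dtype=float)
    if np.any(np.diff(depths) <= 0):
        raise ValidationError("duplicate depths in hypsometry")
    if np.any(np.diff(areas) > 1e-9 * areas[0]):
        raise ValidationError("hypsometric area must be non-increasing with depth")
    if np.any(areas < 0):
        raise ValidationError("negative area in hypsometry")
    if not (depths[0] <= 0 <= depths[-1]):
        # tolerate tables starting at the surface without an explicit 0 row
        if depths[0] > 0:
            raise ValueError("hypsometry must start at the surface (depth 0)")
    if not 0 < sml_thickness < depths[-1]:
        raise ValueError(
            f"sml_thickness {sml_thickness} m outside hypsometry range "
            f"(0, {depths[-1]}] m"
        )

    a_tot = _interp_area(depths, areas, 0.0)
    a_th = _interp_area(depths, areas, sml_thickness)

    # SML volume: trapezoidal integral of area over [0, sml_thickness],
    # with the SML base inserted as an integration knot.
    zs = np.unique(np.concatenate([depths[depths < sml_thickness], [0.0, sml_thickness]]))
    zs = zs[(zs >= 0.0) & (zs <= sml_thickness)]
    volume = float(np.trapezoid(np.interp(zs, depths, areas), zs))

    if convention == "projected":
        a_sed = a_tot - a_th
    elif convention == "frustum":
        radii = np.sqrt(np.interp(zs, depths, areas) / math.pi)
        dr = -np.diff(radii)  # radius shrinks with depth
        dz = np.diff(zs)
        a_sed = float(np.sum(math.pi * (radii[:-1] + radii[1:]) * np.hypot(dr, dz)))
    else:  # pragma: no cover - guarded by Literal type
        raise ValueError(f"unknown A_sed convention {convention!r}")

    if sml_thickness > 0 and a_sed <= 0:
        # vertical-walled basin: the frustum degenerates to the wall surface
        a_sed = max(a_sed, 0.0)
        if a_sed == 0.0 and convention == "projected":
            raise ValidationError(
                "projected A_sed is zero for a vertical-walled basin; "
                "use the frustum convention"
            )

    return LakeGeometry(
        hypsometry=table,
        sml_thickness=float(sml_thickness),
        A_tot=a_tot,
        A_th=a_th,
        A_sed=a_sed,
        volume_sml=volume,
    )


def cylinder_geometry(area_m2: float, max_depth_m: float, sml_thickness: float,
                      ) -> LakeGeometry:
    """Geometry of an idealised vertical-walled (cylindrical) basin.

    The SML volume is exactly ``area * sml_thickness`` and the littoral
    sediment surface is the cylinder wall between the surface and the SML
    base (used for enclosure-like systems that have no littoral zone slope).
    """
    radius = math.sqrt(area_m2 / math.pi)
    table = pd.DataFrame({"depth_m": [0.0, max_depth_m], "area_m2": [area_m2, area_m2]})
    return LakeGeometry(
        hypsometry=table,
        sml_thickness=float(sml_thickness),
        A_tot=float(area_m2),
        A_th=float(area_m2),
        A_sed=2 * math.pi * radius * sml_thickness,
        volume_sml=float(area_m2 * sml_thickness),
    )


# ---------------------------------------------------------------------------
# Units
# ---------------------------------------------------------------------------

WHOLE_SYSTEM_UNITS = {"mol d-1", "kg d-1"}
PER_VOLUME_UNITS = {"nmol l-1 d-1"}
PER_AREA_UNITS = {"mmol m-2 d-1"}
OTHER_UNITS = {"cm h-1", "m2 s-1"}
ALL_UNITS = WHOLE_SYSTEM_UNITS | PER_VOLUME_UNITS | PER_AREA_UNITS | OTHER_UNITS

# planar area a per-area rate refers to, by budget role
AREA_ROLE = {"F_S": "A_tot", "F_L": "A_sed", "F_z": "A_th"}


@dataclass(frozen=True)
class Quantity:
    """A value with one of the budget's units.

    Conversions: mol d-1 <-> kg d-1 via the CH4 molar mass; whole-system
    <-> per-volume via the SML volume; whole-system <-> per-area via the
    planar area matching the term's role (emission over ``A_tot``, lateral
    input over ``A_sed``, thermocline diffusion over ``A_th``).
    """

    value: float
    unit: str

    def __post_init__(self) -> None:
        if self.unit not in ALL_UNITS:
            raise UnitError(f"unknown unit {self.unit!r}")

    def to(self, target_unit: str, geometry: LakeGeometry | None = None,
           area_role: str = "F_S") -> "Quantity":
        return convert(self, target_unit, geometry=geometry, area_role=area_role)


def _to_mol_per_day(q: Quantity, geometry: LakeGeometry | None, area_role: str) -> float:
    if q.unit == "mol d-1":
        return q.value
    if q.unit == "kg d-1":
        return q.value * 1e3 / MOLAR_MASS_CH4
    if q.unit == "nmol l-1 d-1":
        _need_geometry(geometry, q.unit)
        # nmol l-1 = umol m-3 = 1e-6 mol m-3
        return q.value * 1e-6 * geometry.volume_sml
    if q.unit == "mmol m-2 d-1":
        _need_geometry(geometry, q.unit)
        return q.value * 1e-3 * _role_area(geometry, area_role)
    raise UnitError(f"no conversion path from {q.unit!r}")


def _from_mol_per_day(value: float, target: str, geometry: LakeGeometry | None,
                      area_role: str) -> float:
    if target == "mol d-1":
        return value
    if target == "kg d-1":
        return value * MOLAR_MASS_CH4 / 1e3
    if target == "nmol l-1 d-1":
        _need_geometry(geometry, target)
        return value / geometry.volume_sml * 1e6
    if target == "mmol m-2 d-1":
        _need_geometry(geometry, target)
        return value / _role_area(geometry, area_role) * 1e3
    raise UnitError(f"no conversion path to {target!r}")


def _need_geometry(geometry: LakeGeometry | None, unit: str) -> None:
    if geometry is None:
        raise UnitError(f"geometry required to convert {unit!r}")


def _role_area(geometry: LakeGeometry, area_role: str) -> float:
    try:
        return getattr(geometry, AREA_ROLE[area_role])
    except KeyError:
        raise UnitError(f"unknown area role {area_role!r}") from None


def convert(q: Quantity, target_unit: str, geometry: LakeGeometry | None = None,
            area_role: str = "F_S") -> Quantity:
    """Convert a budget quantity between unit tracks.

    ``area_role`` selects which planar area a per-area rate refers to
    (``"F_S"`` -> ``A_tot``, ``"F_L"`` -> ``A_sed``, ``"F_z"`` -> ``A_th``).
    Round trips are identities to 1e-12 relative. ``cm h-1`` and ``m2 s-1``
    have no cross conversions.
    """
    if target_unit not in ALL_UNITS:
        raise UnitError(f"unknown unit {target_unit!r}")
    if q.unit == target_unit:
        return Quantity(q.value, q.unit)
    if q.unit in OTHER_UNITS or target_unit in OTHER_UNITS:
        raise UnitError(f"no conversion between {q.unit!r} and {target_unit!r}")
    mol_d = _to_mol_per_day(q, geometry, area_role)
    return Quantity(_from_mol_per_day(mol_d, target_unit, geometry, area_role),
                    target_unit)


# ---------------------------------------------------------------------------
# Flux components
# ---------------------------------------------------------------------------

@dataclass
class FluxComponent:
    """One mass-balance term as mean +/- SD in a declared unit."""

    mean: float
    sd: float
    unit: str

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValidationError("sd must be non-negative")
        if self.unit not in ALL_UNITS:
            raise UnitError(f"unknown unit {self.unit!r}")


@dataclass
class FluxComponentSet:
    """The budget terms of the SML methane balance.

    ``F_S`` surface emission, ``F_L`` lateral sediment input, ``F_z``
    thermocline diffusive input; ``P_net`` internal (oxic) production and
    ``MOx`` oxidation when known. ``alpha`` is the oxidised fraction of
    internal production (0.3 during stratification, 0 otherwise). River and
    ebullition terms are fixed at zero for this system.
    """

    F_S: FluxComponent
    F_L: FluxComponent
    F_z: FluxComponent
    P_net: FluxComponent | None = None
    MOx: FluxComponent | None = None
    season: str = "stratified"
    alpha: float = 0.3

    def __post_init__(self) -> None:
        if not 0 <= self.alpha < 1:
            raise ValidationError("alpha must lie in [0, 1)")
        units = {self.F_S.unit, self.F_L.unit, self.F_z.unit}
        if len(units) != 1:
            raise UnitError(f"inconsistent component units {sorted(units)}")
        if self.season not in {"stratified", "non_stratified"}:
            raise ValidationError(f"unknown season {self.season!r}")

    @property
    def unit(self) -> str:
        return self.F_S.unit
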