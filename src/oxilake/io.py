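"""Configuration, file I/O and the end-to-end analysis pipeline.

The pipeline ties the stages into the budget chain: hypsometry -> geometry;
chamber deployments + wind -> k600 relation -> surface emission; temperature
series -> heat-budget diffusivity -> thermocline flux; components ->
steady-state closure (Monte Carlo) -> production and its contribution to
emission. All file writes are atomic (temp file + rename) and every result
echoes its configuration, seed and iteration count.
"""

from __future__ import annotations

import json
import os
import tempfile
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import gas_exchange, massbalance, mixing, scaling
from .core import (ALL_UNITS, FluxComponent, FluxComponentSet, LakeGeometry,
                   UnitError, ValidationError, derive_geometry)

CONFIG_SCHEMA_VERSION = 1


# ---------------------------------------------------------------------------
# Atomic writes
# ---------------------------------------------------------------------------

def atomic_write_text(path: str | Path, text: str) -> None:
    """Write via a temp file in the same directory, then rename."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w", encoding="utf-8") as handle:
            handle.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_json(path: str | Path, payload: dict) -> None:
    atomic_write_text(path, json.dumps(payload, indent=2, sort_keys=True))


# ---------------------------------------------------------------------------
# Readers (strict about columns and units)
# ---------------------------------------------------------------------------

def read_hypsometry(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    if not {"depth_m", "area_m2"}.issubset(frame.columns):
        raise ValidationError(
            f"{path}: hypsometry CSV needs columns depth_m, area_m2")
    return frame


def read_profiles(path: str | Path, variable: str) -> mixing.ProfileSeries:
    frame = pd.read_csv(path)
    if not {"date", "depth_m", "value"}.issubset(frame.columns):
        raise ValidationError(f"{path}: profile CSV needs date, depth_m, value")
    return mixing.ProfileSeries.from_long(frame, variable=variable)


def read_wind(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    if not {"timestamp", "u10_ms"}.issubset(frame.columns):
        raise ValidationError(f"{path}: wind CSV needs timestamp, u10_ms")
    return frame


def read_chambers(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    required = {"deployment", "minutes", "ch4_ppm"}
    if not required.issubset(frame.columns):
        raise ValidationError(f"{path}: chamber CSV needs {sorted(required)}")
    return frame


def read_components(path: str | Path, site: str | None = None,
                    unit: str = "nmol l-1 d-1") -> FluxComponentSet:
    """Read a ``site, season, term, mean, sd, unit`` table into a component set.

    Unknown units are rejected, never guessed.
    """
    frame = pd.read_csv(path)
    required = {"site", "season", "term", "mean", "sd", "unit"}
    if not required.issubset(frame.columns):
        raise ValidationError(f"{path}: components CSV needs {sorted(required)}")
    bad = set(frame["unit"]) - ALL_UNITS
    if bad:
        raise UnitError(f"{path}: unknown units {sorted(bad)}")
    if site is not None:
        frame = frame[frame["site"] == site]
    frame = frame[frame["unit"] == unit]
    comps: dict[str, FluxComponent] = {}
    for term in ("F_S", "F_L", "F_z"):
        rows = frame[frame["term"] == term]
        if rows.empty:
            raise ValidationError(f"{path}: missing component {term} in {unit}")
        comps[term] = FluxComponent(float(rows["mean"].iloc[0]),
                                    float(rows["sd"].iloc[0]), unit)
    season = str(frame["season"].iloc[0])
    return FluxComponentSet(season=season, **comps)


def load_config(path: str | Path) -> dict:
    with open(path, "r", encoding="utf-8") as handle:
        cfg = yaml.safe_load(handle)
    if not isinstance(cfg, dict):
        raise ValidationError(f"{path}: config must be a mapping")
    cfg.setdefault("schema_version", CONFIG_SCHEMA_VERSION)
    return cfg


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Everything one pipeline run depends on, echoed into its outputs."""

    input_dir: str
    output_dir: str
    sml_thickness_m: float = 6.0
    site: str | None = None
    alpha: float = 0.3
    mox_scope: str = "internal_only"
    season: str = "stratified"
    sc_exponent: float = gas_exchange.DEFAULT_SC_EXPONENT
    atm_ppm: float = gas_exchange.DEFAULT_ATM_PPM
    iterations: int = massbalance.DEFAULT_ITERATIONS
    seed: int = 0
    log_level: str = "INFO"
    extras: dict = field(default_factory=dict)

    def echo(self) -> dict[str, Any]:
        payload = {k: v for k, v in self.__dict__.items() if k != "extras"}
        payload["schema_version"] = CONFIG_SCHEMA_VERSION
        payload.update(self.extras)
        return payload


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name for diagnosis."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def analyze_campaign(hypsometry: pd.DataFrame, temperature: mixing.ProfileSeries,
                     ch4: mixing.ProfileSeries, wind: pd.DataFrame,
                     chambers: pd.DataFrame, components: FluxComponentSet,
                     cfg: RunConfig) -> dict:
    """Run the full budget analysis on in-memory campaign tables.

    Returns a result dictionary with the fitted k600 relation, the
    emission estimate, the diffusivity-based thermocline flux, the Monte
    Carlo production summary, and the oxic contribution, plus a verbatim
    configuration echo.
    """
    try:
        geometry = derive_geometry(hypsometry, cfg.sml_thickness_m)
    except Exception as exc:
        raise PipelineError("geometry", str(exc)) from exc

    k_model, emission = _emission_stage(chambers, wind, cfg)
    f_z, kz_median = _diffusion_stage(temperature, ch4, geometry, cfg)

    try:
        balance_cfg = massbalance.BalanceConfig(
            season=cfg.season, alpha=cfg.alpha, mox_scope=cfg.mox_scope)
        measured = FluxComponentSet(
            F_S=FluxComponent(emission["mean_mmol_m2_d"],
                              emission["sd_mmol_m2_d"], "mmol m-2 d-1"),
            F_L=_as_areal(components.F_L, geometry, "F_L"),
            F_z=FluxComponent(f_z.flux_mmol_m2_d, 0.0, "mmol m-2 d-1"),
            season=cfg.season, alpha=cfg.alpha)
        mc = massbalance.monte_carlo_pnet(measured, geometry, balance_cfg,
                                          n=cfg.iterations, seed=cfg.seed)
        pnet = massbalance.solve_pnet(measured, geometry, balance_cfg)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("mass_balance", str(exc)) from exc

    try:
        pnet_total = pnet.value * 1e-6 * geometry.volume_sml  # mol d-1
        lateral_total = (_as_areal(components.F_L, geometry, "F_L").mean
                         * 1e-3 * geometry.A_sed)
        diffusive_total = f_z.flux_mmol_m2_d * 1e-3 * geometry.A_th
        omc_pct = scaling.omc(pnet_total, lateral_total, diffusive_total)
    except Exception as exc:
        raise PipelineError("omc", str(exc)) from exc

    return {
        "config": cfg.echo(),
        "geometry": {"A_tot_m2": geometry.A_tot, "A_th_m2": geometry.A_th,
                     "A_sed_m2": geometry.A_sed,
                     "volume_sml_m3": geometry.volume_sml},
        "k600_model": {"slope": k_model.slope, "intercept": k_model.intercept,
                       "r_squared": k_model.r_squared,
                       "p_value": k_model.p_value, "n": k_model.n},
        "emission": emission,
        "thermocline_flux": {"mean_mmol_m2_d": f_z.flux_mmol_m2_d,
                             "K_z_used_m2_s": f_z.K_z_used,
                             "K_z_median_m2_s": kz_median,
                             "gradient_nmol_l_m": f_z.gradient_nmol_l_m},
        "p_net": {"deterministic_nmol_l_d": pnet.value,
                  "monte_carlo": mc.summary()},
        "omc_pct": omc_pct,
        "sources_mol_d": {"oxic_production": pnet_total,
                          "lateral_input": lateral_total,
                          "thermocline_diffusion": diffusive_total},
    }


def _emission_stage(chambers: pd.DataFrame, wind: pd.DataFrame, cfg: RunConfig):
    try:
        pairs_u, pairs_k = [], []
        for _, group in chambers.groupby("deployment"):
            dep = gas_exchange.ChamberDeployment(
                times_min=group["minutes"].to_numpy(),
                headspace_ppm=group["ch4_ppm"].to_numpy(),
                chamber_volume_l=float(group["chamber_volume_l"].iloc[0]),
                footprint_area_m2=float(group["footprint_area_m2"].iloc[0]),
                water_temperature_c=float(group["water_temp_c"].iloc[0]),
                surface_concentration_nmol_l=float(
                    group["surface_conc_nmol_l"].iloc[0]),
                atmospheric_ppm=float(group["atm_ppm"].iloc[0]))
            flux = gas_exchange.chamber_flux(dep)
            pairs_k.append(gas_exchange.k600_from_flux(
                flux, dep.surface_concentration_nmol_l,
                dep.water_temperature_c, dep.atmospheric_ppm,
                cfg.sc_exponent))
            pairs_u.append(float(group["u10_ms"].iloc[0]))
        k_model = gas_exchange.fit_k600_wind(np.array(pairs_u),
                                             np.array(pairs_k))
        surface_conc = float(chambers["surface_conc_nmol_l"].iloc[0])
        temp = float(chambers["water_temp_c"].iloc[0])
        mean, sd, _ = gas_exchange.estimate_emission(
            k_model, wind["u10_ms"].to_numpy(), surface_conc, temp,
            cfg.atm_ppm, cfg.sc_exponent)
        return k_model, {"mean_mmol_m2_d": mean, "sd_mmol_m2_d": sd,
                         "surface_conc_nmol_l": surface_conc}
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("gas_exchange", str(exc)) from exc


def _diffusion_stage(temperature: mixing.ProfileSeries,
                     ch4: mixing.ProfileSeries, geometry: LakeGeometry,
                     cfg: RunConfig):
    try:
        kz_profiles = mixing.heat_budget_diffusivity(temperature, geometry)
        stack = np.vstack([p.K_z for p in kz_profiles])
        with warnings.catch_warnings():
            # depths where every date-pair is undefined stay NaN
            warnings.simplefilter("ignore", category=RuntimeWarning)
            kz_median = np.nanmedian(stack, axis=0)
        kz = mixing.DiffusivityProfile(depths=kz_profiles[0].depths,
                                       K_z=kz_median)
        ch4_mean = np.nanmean(ch4.values, axis=1)
        f_z = mixing.thermocline_flux(kz, ch4.depths, ch4_mean,
                                      cfg.sml_thickness_m)
        if not f_z.defined:
            raise ValidationError("K_z undefined in the bottom-3-m window")
        window = (kz.depths >= cfg.sml_thickness_m - 3 - 1e-9) & (
            kz.depths <= cfg.sml_thickness_m + 1e-9)
        med = float(np.nanmedian(kz.K_z[window]))
        return f_z, med
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("vertical_mixing", str(exc)) from exc


def _as_areal(comp: FluxComponent, geometry: LakeGeometry,
              role: str) -> FluxComponent:
    from .core import Quantity, convert
    if comp.unit == "mmol m-2 d-1":
        return comp
    mean = convert(Quantity(comp.mean, comp.unit), "mmol m-2 d-1", geometry,
                   area_role=role).value
    sd = convert(Quantity(comp.sd, comp.unit), "mmol m-2 d-1", geometry,
                 area_role=role).value
    return FluxComponent(mean, abs(sd), "mmol m-2 d-1")


def run_pipeline(cfg: RunConfig) -> dict:
    """Load a campaign directory, analyse it, write result files.

    Expects the CSV bundle written by the synthetic generator (or files of
    the same shape): ``hypsometry.csv``, ``temperature.csv``, ``ch4.csv``,
    ``wind.csv``, ``chambers.csv``, ``components.csv``. Writes
    ``results.json`` and a small Markdown report; reruns with the same
    inputs and seed are byte-identical.
    """
    in_dir = Path(cfg.input_dir)
    missing = [name for name in ("hypsometry", "temperature", "ch4", "wind",
                                 "chambers", "components")
               if not (in_dir / f"{name}.csv").exists()]
    if missing:
        raise PipelineError("io", f"missing input files in {in_dir}: "
                                  f"{', '.join(m + '.csv' for m in missing)}")
    hyps = read_hypsometry(in_dir / "hypsometry.csv")
    temperature = read_profiles(in_dir / "temperature.csv", "temperature")
    ch4 = read_profiles(in_dir / "ch4.csv", "ch4")
    wind = read_wind(in_dir / "wind.csv")
    chambers = read_chambers(in_dir / "chambers.csv")
    components = read_components(in_dir / "components.csv", site=cfg.site)
    results = analyze_campaign(hyps, temperature, ch4, wind, chambers,
                               components, cfg)
    out = Path(cfg.output_dir)
    write_json(out / "results.json", results)
    atomic_write_text(out / "report.md", render_report(results))
    return results


def render_report(results: dict) -> str:
    """Human-readable Markdown summary of one pipeline run.

    Percentages are rounded to integers here, at the report layer only.
    """
    mc = results["p_net"]["monte_carlo"]
    src = results["sources_mol_d"]
    geo = results["geometry"]
    lines = [
        "# SML methane mass balance",
        "",
        f"- Surface area: {geo['A_tot_m2'] / 1e6:.2f} km^2; "
        f"SML volume: {geo['volume_sml_m3']:.3g} m^3; "
        f"littoral sediment area: {geo['A_sed_m2'] / 1e6:.2f} km^2",
        f"- k600 = {results['k600_model']['slope']:.2f} * U10 + "
        f"{results['k600_model']['intercept']:.2f} cm h^-1 "
        f"(R^2 = {results['k600_model']['r_squared']:.2f}, "
        f"n = {results['k600_model']['n']})",
        "",
        "| term | mol d^-1 | kg d^-1 | nmol l^-1 d^-1 |",
        "|---|---|---|---|",
    ]
    from .core import MOLAR_MASS_CH4
    v = geo["volume_sml_m3"]
    for label, total in [("Surface emission",
                          results["emission"]["mean_mmol_m2_d"] * 1e-3
                          * geo["A_tot_m2"]),
                         ("Lateral sediment input", src["lateral_input"]),
                         ("Thermocline diffusion",
                          src["thermocline_diffusion"]),
                         ("Internal (oxic) production",
                          src["oxic_production"])]:
        lines.append(f"| {label} | {total:.0f} | "
                     f"{total * MOLAR_MASS_CH4 / 1e3:.1f} | "
                     f"{total / v * 1e6:.0f} |")
    lines += [
        "",
        f"- Monte Carlo P_net: {mc['mean']:.0f} +/- {mc['sd']:.0f} "
        f"{mc['unit']} ({round(100 * mc['p_positive'])}% positive; "
        f"n = {mc['n_iterations']}, seed = {mc['seed']})",
        f"- Oxic methane contribution: {round(results['omc_pct'])}%",
        "",
    ]
    return "\n".join(lines)
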