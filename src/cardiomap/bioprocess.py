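"""Bioreactor process calculations for perfused stirred-tank cardiomyocyte expansion.

Covers the four quantitative pieces of the expansion bioprocess:

* dissolved-oxygen setpoint conversion between % O2 (v/v in the gas phase)
  and % air saturation of the medium,
* constant power-input-per-volume (P/V) agitation scale-up between vessels,
* specific metabolite production/consumption rates from a perfusion mass
  balance, and
* the cell expansion factor.

Internally SI-ish units are used (rev/s, m, kg/m^3, W); the interfaces speak
the lab's units: rpm, mM, cells/mL and days.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ScaleUpSpec",
    "PerfusionSeries",
    "SpecificRate",
    "do_to_air_saturation",
    "air_saturation_to_o2",
    "power_per_volume",
    "scaleup_speed",
    "specific_rates",
    "expansion_factor",
]

#: O2 fraction of air used for DO conversions, % v/v.  21.0 (not 20.95) so
#: that 10 / 5 / 15 % O2 map to the conventional 47.6 / 23.8 / 71.4 % air
#: saturation setpoints.
O2_IN_AIR_PCT = 21.0


# ---------------------------------------------------------------------------
# Dissolved oxygen


def do_to_air_saturation(pct_o2: float, o2_in_air_pct: float = O2_IN_AIR_PCT) -> float:
    """Convert an oxygen setpoint in % O2 (v/v) to % air saturation.

    A medium equilibrated with a gas containing ``pct_o2`` % oxygen sits at
    ``pct_o2 / o2_in_air_pct * 100`` % of air saturation (Henry's law is
    linear in the O2 partial pressure).  E.g. 10% O2 -> 47.6% air sat.
    """
    if pct_o2 < 0:
        raise ValueError(f"pct_o2 must be non-negative, got {pct_o2}")
    if o2_in_air_pct <= 0:
        raise ValueError("o2_in_air_pct must be positive")
    return pct_o2 / o2_in_air_pct * 100.0


def air_saturation_to_o2(pct_air_sat: float, o2_in_air_pct: float = O2_IN_AIR_PCT) -> float:
    """Inverse of :func:`do_to_air_saturation`."""
    if pct_air_sat < 0:
        raise ValueError(f"pct_air_sat must be non-negative, got {pct_air_sat}")
    return pct_air_sat * o2_in_air_pct / 100.0


# ---------------------------------------------------------------------------
# Constant-P/V scale-up


@dataclass(frozen=True)
class ScaleUpSpec:
    """Impeller/vessel parameters for power-input scale-up.

    Parameters
    ----------
    power_number : unitless impeller power number Np (turbulent regime).
    density_kg_m3 : liquid density rho.
    impeller_diameter_m : impeller diameter Di.
    working_volume_m3 : working volume V.
    speed_rpm : agitation speed N in rpm; ``None`` for the vessel whose
        speed is to be determined.
    """

    power_number: float
    density_kg_m3: float
    impeller_diameter_m: float
    working_volume_m3: float
    speed_rpm: float | None = None

    def __post_init__(self) -> None:
        for name in ("power_number", "density_kg_m3", "impeller_diameter_m", "working_volume_m3"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be strictly positive, got {v}")
        if self.speed_rpm is not None and self.speed_rpm <= 0:
            raise ValueError(f"speed_rpm must be strictly positive, got {self.speed_rpm}")

    @property
    def speed_rev_s(self) -> float:
        if self.speed_rpm is None:
            raise ValueError("speed_rpm is not set on this spec")
        return self.speed_rpm / 60.0


def power_per_volume(spec: ScaleUpSpec) -> float:
    """Impeller power input per working volume, W/m^3.

    P = Np * rho * N^3 * Di^5 in the turbulent regime (N in rev/s), so
    P/V = Np * rho * N^3 * Di^5 / V.
    """
    n = spec.speed_rev_s
    return (
        spec.power_number
        * spec.density_kg_m3
        * n**3
        * spec.impeller_diameter_m**5
        / spec.working_volume_m3
    )


def scaleup_speed(source: ScaleUpSpec, target: ScaleUpSpec) -> tuple[float, float]:
    """Agitation speed of the target vessel holding P/V constant.

    Equating Np*rho*N^3*Di^5/V between vessels and solving for the target
    speed:

        N_t = [ (N^3 rho Di^5 Np / V)_source * (V / (rho Di^5 Np))_target ]^(1/3)

    Returns
    -------
    (speed_rpm, pv_w_m3) : the target agitation speed in rpm and the common
        power input per volume (identical for both vessels by construction).
    """
    pv = power_per_volume(source)
    n_target = (
        pv
        * target.working_volume_m3
        / (target.power_number * target.density_kg_m3 * target.impeller_diameter_m**5)
    ) ** (1.0 / 3.0)
    return n_target * 60.0, pv


# ---------------------------------------------------------------------------
# Perfusion mass balance


@dataclass
class PerfusionSeries:
    """Metabolite + cell-density time series from a perfused culture.

    ``conc_mM`` is the culture (outlet) concentration Cout at each sample
    time; ``cin_mM`` the feed concentration; ``dilution_per_day`` the
    dilution rate D = feed rate / working volume.
    """

    time_day: np.ndarray
    conc_mM: np.ndarray
    cells_per_ml: np.ndarray
    cin_mM: float
    dilution_per_day: float

    def __post_init__(self) -> None:
        self.time_day = np.asarray(self.time_day, dtype=float)
        self.conc_mM = np.asarray(self.conc_mM, dtype=float)
        self.cells_per_ml = np.asarray(self.cells_per_ml, dtype=float)
        if not (self.time_day.shape == self.conc_mM.shape == self.cells_per_ml.shape):
            raise ValueError("time_day, conc_mM and cells_per_ml must have equal length")
        if self.time_day.ndim != 1:
            raise ValueError("series must be one-dimensional")
        if self.time_day.size and np.any(np.diff(self.time_day) <= 0):
            raise ValueError("time_day must be strictly ascending")
        if np.any(self.cells_per_ml <= 0):
            raise ValueError("cells_per_ml must be strictly positive")
        if self.dilution_per_day < 0:
            raise ValueError("dilution_per_day must be non-negative")

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {
                "time_day": self.time_day,
                "conc_mM": self.conc_mM,
                "cells_per_ml": self.cells_per_ml,
            }
        )
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, cin_mM: float, dilution_per_day: float) -> "PerfusionSeries":
        df = pd.read_csv(path)
        required = {"time_day", "conc_mM", "cells_per_ml"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"CSV missing required columns: {sorted(missing)}")
        return cls(
            time_day=df["time_day"].to_numpy(),
            conc_mM=df["conc_mM"].to_numpy(),
            cells_per_ml=df["cells_per_ml"].to_numpy(),
            cin_mM=cin_mM,
            dilution_per_day=dilution_per_day,
        )


@dataclass
class SpecificRate:
    """Interval-wise specific rates q in pmol / cell / day.

    Sign convention: production positive, consumption negative.
    ``t_start_day``/``t_end_day`` are the endpoints of each sample interval.
    """

    q_pmol_cell_day: np.ndarray
    t_start_day: np.ndarray
    t_end_day: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.q_pmol_cell_day)
        if not (len(self.t_start_day) == len(self.t_end_day) == n):
            raise ValueError("interval arrays must share length")


def specific_rates(series: PerfusionSeries) -> SpecificRate:
    """Specific production/consumption rate per sampling interval.

    For each consecutive sample pair the perfusion mass balance

        q = [ dC/dt - D * (Cin - Cout_mean) ] / Xv_mean

    is evaluated with dC/dt the finite difference of the culture
    concentration, Cout_mean and Xv_mean the arithmetic interval means of the
    sampled concentration and viable-cell density.  The bracket is in
    mM/day = mmol L^-1 day^-1; dividing by cells/mL and converting yields
    pmol cell^-1 day^-1 (factor 1e6).
    """
    t = series.time_day
    if t.size < 2:
        raise ValueError("at least 2 samples required for specific rates")
    c = series.conc_mM
    x = series.cells_per_ml
    dt = np.diff(t)
    dcdt = np.diff(c) / dt  # mM / day
    c_mean = 0.5 * (c[:-1] + c[1:])
    x_mean = 0.5 * (x[:-1] + x[1:])
    if np.any(x_mean == 0):
        raise ZeroDivisionError("mean viable-cell density is zero on some interval")
    bracket = dcdt - series.dilution_per_day * (series.cin_mM - c_mean)  # mM/day
    # mM/day / (cells/mL): 1 mmol/L = 1e6 pmol/mL  ->  q in pmol/cell/day
    q = bracket * 1e6 / x_mean
    return SpecificRate(q_pmol_cell_day=q, t_start_day=t[:-1], t_end_day=t[1:])


def expansion_factor(cells_per_ml: np.ndarray) -> float:
    """Ratio of the maximum cell concentration to the day-0 concentration."""
    x = np.asarray(cells_per_ml, dtype=float)
    if x.size == 0:
        raise ValueError("empty cell-concentration series")
    if x[0] <= 0:
        raise ValueError("day-0 concentration must be positive")
    return float(np.max(x) / x[0])
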