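"""Thermal bioenergetics coupled to kinetic bioaccumulation in a fish.

A round-goby-like ectotherm experiences a sinusoidal annual temperature
cycle (optionally warmed by a constant offset).  Consumption follows a
thermal performance curve anchored at the lower critical limit CT_min, the
optimum T_opt and the upper critical limit CT_max; respiration (and the
physiological rates that ride on it: gill ventilation, biotransformation)
follows a Q10 exponential.  Daily growth from the energy balance drives
growth dilution, and whole-body chemical concentration follows first-order
uptake/loss kinetics:

    dC/dt = k1*C_wd + kD*C_diet - (k2 + kE + kG + kM) * C

with constant freely dissolved water (C_wd) and dietary (C_diet)
concentrations.  Scanning log K_OW x biotransformation half-life under
+2/+3 degC offsets and forming daily year-3 concentration ratios
(offset / baseline) is the analysis endpoint: ratios > 1 mean more
bioaccumulation under warming.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import DAYS_PER_YEAR

LN2 = math.log(2.0)


@dataclass(frozen=True)
class ThermalTraits:
    """Thermal performance landmarks of the fish (degC).

    ``CT_max`` is the functional upper limit at which consumption has
    collapsed to zero (this sits below the acute lethal limit).  ``Q10``
    governs respiration and the other metabolically driven rates;
    ``T_ref_b`` is the physiological reference temperature at which the
    Q10 multiplier equals 1.
    """

    CT_min: float = 2.0
    T_opt: float = 26.0
    CT_max: float = 30.0
    Q10: float = 2.0
    T_ref_b: float = 20.0

    def __post_init__(self):
        if not self.CT_min < self.T_opt < self.CT_max:
            raise ValueError("require CT_min < T_opt < CT_max")
        if self.Q10 <= 0:
            raise ValueError("Q10 must be positive")


@dataclass(frozen=True)
class BioenergeticParams:
    """Wisconsin-style bioenergetic coefficients (specific rates, g/g/d).

    Maximum consumption is CA * W**CB scaled by the proportion ``p``
    actually fed and the thermal multiplier; respiration is RA * W**RB
    scaled by the Q10 multiplier.  ``egestion_frac`` and ``sda_frac``
    (specific dynamic action + excretion) reduce consumed energy to
    assimilated energy; energy densities convert prey mass to fish mass.
    """

    CA: float = 0.25
    CB: float = -0.27
    p: float = 0.4
    egestion_frac: float = 0.15
    sda_frac: float = 0.25
    RA: float = 0.02
    RB: float = -0.2
    ED_prey: float = 4500.0     # J/g
    ED_fish: float = 5500.0     # J/g
    W0: float = 1.0             # g
    starvation_floor: float = 0.1   # g; weight is clamped here
    gill_efficiency: float = 0.25       # effective gill chemical-uptake
    #   efficiency, a single constant standing for the hydrophobicity-
    #   dependent efficiency averaged over the scanned logKOW range
    ventilation_coeff: float = 1400.0   # L/d per kg^0.65
    f_lipid: float = 0.05
    f_lipid_prey: float = 0.03          # prey lipid fraction (diet exposure)
    diet_assim_max: float = 0.5         # dietary assimilation at low KOW
    diet_assim_kow_coeff: float = 3e-7  # hydrophobicity penalty on uptake
    egestion_rate_frac: float = 0.3     # kE as a fraction of kD

    def __post_init__(self):
        for name in ("egestion_frac", "sda_frac", "p", "f_lipid",
                     "f_lipid_prey", "diet_assim_max"):
            if not 0.0 < getattr(self, name) < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")
        for name in ("CA", "RA", "ED_prey", "ED_fish", "W0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def assimilation(self) -> float:
        return 1.0 - self.egestion_frac - self.sda_frac


@dataclass(frozen=True)
class FishChemical:
    """Chemical seen by the fish: hydrophobicity, biotransformation, exposure.

    ``C_wd`` is the freely dissolved water concentration (mol/m3) and
    ``C_diet`` the dietary concentration (mol/g); both are held constant
    through the simulation.  When ``C_diet`` is not given it defaults to a
    prey equilibrated with the water column:
    C_diet = f_lipid_prey * K_OW * C_wd[mol/L] / 1000, so hydrophilic
    chemicals carry a negligible dietary load and hydrophobic ones
    biomagnify through food.  ``HL_B`` is the biotransformation half-life
    in days at the physiological reference temperature.
    """

    logKOW: float
    HL_B: float
    C_wd: float = 1e-6
    C_diet: float | None = None
    f_lipid_prey: float = 0.03

    def __post_init__(self):
        if self.HL_B <= 0:
            raise ValueError("HL_B must be positive")
        if self.C_diet is None:
            object.__setattr__(
                self, "C_diet",
                self.f_lipid_prey * 10.0 ** self.logKOW
                * self.C_wd * 1e-3 / 1000.0)
        if self.C_wd < 0 or self.C_diet < 0:
            raise ValueError("exposure concentrations must be non-negative")


@dataclass
class BioaccTrajectory:
    """Daily weight, concentration and temperature over the simulation."""

    day: np.ndarray
    weight: np.ndarray          # g
    concentration: np.ndarray   # mol/g
    temperature: np.ndarray     # degC


#: Baseline Lake-Erie-like annual cycle: the phase puts the maximum in
#: early August, the peak (24 degC) just below the goby's T_opt.
DEFAULT_CYCLE = {"mean": 13.5, "amplitude": 10.5, "phase": 124.0}


def annual_temperature(day, mean: float = DEFAULT_CYCLE["mean"],
                       amplitude: float = DEFAULT_CYCLE["amplitude"],
                       phase: float = DEFAULT_CYCLE["phase"],
                       offset: float = 0.0):
    """Sinusoidal annual water temperature (degC).

    T = mean + offset + amplitude * sin(2*pi*(day - phase)/365); the offset
    shifts the annual average only.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be non-negative")
    day = np.asarray(day, dtype=float)
    T = mean + offset + amplitude * np.sin(
        2.0 * np.pi * (day - phase) / DAYS_PER_YEAR)
    return T if T.ndim else float(T)


def temperature_series(years: int = 5, offset: float = 0.0,
                       mean: float = DEFAULT_CYCLE["mean"],
                       amplitude: float = DEFAULT_CYCLE["amplitude"],
                       phase: float = DEFAULT_CYCLE["phase"]) -> np.ndarray:
    """Daily temperatures for a multi-year run (length years*365 + 1)."""
    days = np.arange(years * DAYS_PER_YEAR + 1)
    return annual_temperature(days, mean, amplitude, phase, offset)


def thermal_performance(T, traits: ThermalTraits, role: str = "consumption"):
    """Dimensionless thermal multiplier for a physiological rate.

    Consumption: 0 at/below CT_min, smooth sin^2 rise to 1 at T_opt, steep
    smooth fall to 0 at/above CT_max.  Respiration: uncapped Q10
    exponential Q10**((T - T_ref_b)/10).
    """
    T = np.asarray(T, dtype=float)
    if role == "respiration":
        out = traits.Q10 ** ((T - traits.T_ref_b) / 10.0)
    elif role == "consumption":
        out = np.zeros_like(T)
        rise = (T > traits.CT_min) & (T <= traits.T_opt)
        fall = (T > traits.T_opt) & (T < traits.CT_max)
        out[rise] = np.sin(np.pi / 2.0 * (T[rise] - traits.CT_min)
                           / (traits.T_opt - traits.CT_min)) ** 2
        out[fall] = np.sin(np.pi / 2.0 * (traits.CT_max - T[fall])
                           / (traits.CT_max - traits.T_opt)) ** 2
    else:
        raise ValueError(f"unknown role {role!r}")
    return out if out.ndim else float(out)


def specific_growth_rate(W, T, traits: ThermalTraits,
                         params: BioenergeticParams):
    """Specific growth dW/dt / W (1/d) from the daily energy balance."""
    cons = params.p * params.CA * np.asarray(W, float) ** params.CB \
        * thermal_performance(T, traits, "consumption")
    resp = params.RA * np.asarray(W, float) ** params.RB \
        * thermal_performance(T, traits, "respiration")
    return params.assimilation * cons * params.ED_prey / params.ED_fish - resp


def simulate_growth(traits: ThermalTraits, params: BioenergeticParams,
                    temperatures: np.ndarray,
                    W0: float | None = None) -> np.ndarray:
    """Daily Euler integration of the energy balance.

    Weight is clamped at the starvation floor (prolonged exposure below
    CT_min burns reserves but does not kill the model fish).
    """
    if W0 is None:
        W0 = params.W0
    if W0 <= 0:
        raise ValueError("W0 must be positive")
    T = np.asarray(temperatures, dtype=float)
    W = np.empty_like(T)
    W[0] = W0
    for t in range(len(T) - 1):
        g = specific_growth_rate(W[t], T[t], traits, params)
        w_next = W[t] * (1.0 + g)
        if not np.isfinite(w_next):
            raise ValueError(f"non-finite weight at day {t}")
        W[t + 1] = max(w_next, params.starvation_floor)
    return W


def rate_constants(W, T, chemical: FishChemical,
                   params: BioenergeticParams, traits: ThermalTraits,
                   growth_rate=None) -> dict:
    """First-order uptake/loss rate constants (1/d) at state (W, T).

    k1 (L water / g fish / d) from gill ventilation scaled by the
    respiration multiplier; k2 = k1 / (f_lipid * K_OW / 1000), the
    lipid-partitioning equilibrium; kD from the realized feeding rate and
    a dietary assimilation efficiency that declines with hydrophobicity
    (1 / (a*K_OW + 1/e_max)); kE proportional to kD; kG the specific growth
    rate (negative while starving: shrinking concentrates the burden); kM
    the biotransformation rate ln2/HL_B carried on the same Q10 multiplier
    as the other metabolic rates.
    """
    W = np.asarray(W, dtype=float)
    if np.any(W <= 0):
        raise ValueError("weight must be positive")
    phi_r = thermal_performance(T, traits, "respiration")
    phi_c = thermal_performance(T, traits, "consumption")
    # ventilation: L/d = coeff * (W/1000 kg)^0.65; per gram of fish
    k1 = params.gill_efficiency * params.ventilation_coeff \
        * (W / 1000.0) ** 0.65 / W * phi_r
    k2 = k1 / (params.f_lipid * 10.0 ** chemical.logKOW / 1000.0)
    feeding = params.p * params.CA * W ** params.CB * phi_c   # g food/g/d
    e_diet = 1.0 / (params.diet_assim_kow_coeff * 10.0 ** chemical.logKOW
                    + 1.0 / params.diet_assim_max)
    kD = e_diet * feeding
    kE = params.egestion_rate_frac * kD
    if growth_rate is None:
        growth_rate = specific_growth_rate(W, T, traits, params)
    kM = LN2 / chemical.HL_B * phi_r
    return {"k1": k1, "k2": k2, "kD": kD, "kE": kE,
            "kG": growth_rate, "kM": kM}


def closed_form_steady_state(chemical: FishChemical, W: float, T: float,
                             params: BioenergeticParams,
                             traits: ThermalTraits) -> float:
    """Algebraic steady state at constant weight and temperature (kG = 0)."""
    k = rate_constants(W, T, chemical, params, traits, growth_rate=0.0)
    uptake = k["k1"] * chemical.C_wd * 1e-3 + k["kD"] * chemical.C_diet
    return uptake / (k["k2"] + k["kE"] + k["kM"])


def _integrate_concentration(uptake: np.ndarray,
                             loss: np.ndarray) -> np.ndarray:
    """Exact piecewise-constant-rate update of dC/dt = u - loss*C.

    Each daily step uses C(t+1) = C e^(-loss) + u*(1 - e^(-loss))/loss,
    which is exact for rates held constant over the day and remains stable
    for arbitrarily fast loss (HL_B down to 0.1 d and below).
    """
    n_cells, n_steps = uptake.shape
    C = np.zeros((n_cells, n_steps + 1))
    ex = np.exp(-loss)
    with np.errstate(invalid="ignore", divide="ignore"):
        fac = np.where(np.abs(loss) > 1e-12, (1.0 - ex) / loss,
                       1.0 - loss / 2.0)
    for t in range(n_steps):
        C[:, t + 1] = C[:, t] * ex[:, t] + uptake[:, t] * fac[:, t]
    return C


def simulate_bioaccumulation(chemical: FishChemical,
                             traits: ThermalTraits | None = None,
                             params: BioenergeticParams | None = None,
                             temperatures: np.ndarray | None = None,
                             years: int = 5) -> BioaccTrajectory:
    """Full daily simulation: growth plus chemical kinetics.

    Raises ValueError if the integration produces negative concentrations.
    """
    traits = traits or ThermalTraits()
    params = params or BioenergeticParams()
    if temperatures is None:
        temperatures = temperature_series(years)
    T = np.asarray(temperatures, dtype=float)
    W = simulate_growth(traits, params, T)
    growth = np.empty_like(W)
    growth[:-1] = (W[1:] - W[:-1]) / W[:-1]
    growth[-1] = growth[-2]
    k = rate_constants(W, T, chemical, params, traits, growth_rate=growth)
    uptake = (k["k1"] * chemical.C_wd * 1e-3
              + k["kD"] * chemical.C_diet)[None, :-1]
    loss = (k["k2"] + k["kE"] + k["kG"] + k["kM"])[None, :-1]
    C = _integrate_concentration(uptake, loss)[0]
    if np.any(C < 0):
        raise ValueError("negative concentration in integration")
    return BioaccTrajectory(day=np.arange(len(T)), weight=W,
                            concentration=C, temperature=T)


# -- the warming-scenario scan -----------------------------------------

SEASON_WINDOWS = {"spring": (60, 151), "summer": (152, 243),
                  "autumn": (244, 334)}

DEFAULT_LOGKOW_GRID = tuple(float(k) for k in range(0, 9))
DEFAULT_HLB_GRID = (0.1, 1.0, 10.0, 100.0, 1000.0)


def _scan_concentrations(cells: list[FishChemical], offset: float,
                         traits: ThermalTraits, params: BioenergeticParams,
                         years: int, cycle: dict) -> np.ndarray:
    T = temperature_series(years, offset=offset, **cycle)
    W = simulate_growth(traits, params, T)
    growth = np.empty_like(W)
    growth[:-1] = (W[1:] - W[:-1]) / W[:-1]
    growth[-1] = growth[-2]
    phi_r = thermal_performance(T, traits, "respiration")
    phi_c = thermal_performance(T, traits, "consumption")
    k1 = params.gill_efficiency * params.ventilation_coeff \
        * (W / 1000.0) ** 0.65 / W * phi_r
    feeding = params.p * params.CA * W ** params.CB * phi_c
    kow = np.array([c.logKOW for c in cells])
    hlb = np.array([c.HL_B for c in cells])
    cwd = np.array([c.C_wd for c in cells])
    cdiet = np.array([c.C_diet for c in cells])
    k2 = k1[None, :] / (params.f_lipid * 10.0 ** kow[:, None] / 1000.0)
    kM = (LN2 / hlb)[:, None] * phi_r[None, :]
    e_diet = 1.0 / (params.diet_assim_kow_coeff * 10.0 ** kow
                    + 1.0 / params.diet_assim_max)
    kD = e_diet[:, None] * feeding[None, :]
    kE = params.egestion_rate_frac * kD
    uptake = (k1[None, :] * cwd[:, None] * 1e-3
              + kD * cdiet[:, None])[:, :-1]
    loss = (k2 + kE + growth[None, :] + kM)[:, :-1]
    return _integrate_concentration(uptake, loss)


def ratio_scan(logKOW_grid=DEFAULT_LOGKOW_GRID, HLB_grid=DEFAULT_HLB_GRID,
               offsets=(2.0, 3.0), traits: ThermalTraits | None = None,
               params: BioenergeticParams | None = None,
               years: int = 5, analysis_year: int = 3,
               cycle: dict | None = None,
               C_wd: float = 1e-6,
               C_diet: float | None = None) -> pd.DataFrame:
    """Seasonal concentration-ratio summary over the chemical grid.

    For every (log K_OW, HL_B) cell and warming offset the daily ratio
    r(t) = C_offset(t) / C_baseline(t) is evaluated over the analysis year
    and reduced to the maximum over the spring+autumn windows, the minimum
    over the summer window, and the annual extremes.
    """
    traits = traits or ThermalTraits()
    params = params or BioenergeticParams()
    cycle = dict(DEFAULT_CYCLE, **(cycle or {}))
    cells = [FishChemical(logKOW=k, HL_B=h, C_wd=C_wd, C_diet=C_diet)
             for k in logKOW_grid for h in HLB_grid]
    if not (1 <= analysis_year <= years):
        raise ValueError("analysis_year must lie within the simulation")

    C_base = _scan_concentrations(cells, 0.0, traits, params, years, cycle)
    t = np.arange(years * DAYS_PER_YEAR + 1)
    doy = t % DAYS_PER_YEAR + 1
    in_year = (t >= (analysis_year - 1) * DAYS_PER_YEAR) \
        & (t < analysis_year * DAYS_PER_YEAR)
    spring = in_year & (doy >= SEASON_WINDOWS["spring"][0]) \
        & (doy <= SEASON_WINDOWS["spring"][1])
    summer = in_year & (doy >= SEASON_WINDOWS["summer"][0]) \
        & (doy <= SEASON_WINDOWS["summer"][1])
    autumn = in_year & (doy >= SEASON_WINDOWS["autumn"][0]) \
        & (doy <= SEASON_WINDOWS["autumn"][1])

    rows = []
    for offset in offsets:
        C_off = _scan_concentrations(cells, offset, traits, params,
                                     years, cycle)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = C_off / C_base
        for i, cell in enumerate(cells):
            ri = r[i]
            if not np.all(np.isfinite(ri[in_year])):
                rows.append({"logKOW": cell.logKOW, "HL_B_d": cell.HL_B,
                             "offset_C": offset, "failed": True})
                continue
            rows.append({
                "logKOW": cell.logKOW, "HL_B_d": cell.HL_B,
                "offset_C": offset, "failed": False,
                "max_ratio_spring_autumn": float(
                    max(ri[spring].max(), ri[autumn].max())),
                "min_ratio_summer": float(ri[summer].min()),
                "max_ratio_annual": float(ri[in_year].max()),
                "min_ratio_annual": float(ri[in_year].min())})
    return pd.DataFrame(rows)


def scan_summary(scan: pd.DataFrame) -> dict:
    """Headline numbers from a ratio scan (percent / fold conventions).

    * max spring/autumn increase, percent, over the whole grid (+3 offset);
    * max summer fold-decrease (reciprocal of the minimum summer ratio);
    * POP-like sub-grid (logKOW 6-8, HL_B >= 100 d): max annual percent
      increase and decrease over both offsets.
    """
    ok = scan[~scan["failed"]]
    t3 = ok[ok["offset_C"] == 3.0]
    pop = ok[(ok["logKOW"] >= 6) & (ok["logKOW"] <= 8)
             & (ok["HL_B_d"] >= 100)]
    return {
        "max_spring_autumn_increase_pct": float(
            (t3["max_ratio_spring_autumn"].max() - 1.0) * 100.0),
        "max_summer_fold_decrease": float(
            1.0 / t3["min_ratio_summer"].min()),
        "pop_max_increase_pct": float(
            (pop["max_ratio_annual"].max() - 1.0) * 100.0),
        "pop_max_decrease_pct": float(
            (1.0 - pop["min_ratio_annual"].min()) * 100.0)}
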