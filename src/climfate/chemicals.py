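"""Temperature-dependent physical-chemical properties and hypothetical-chemical grids.

A neutral organic chemical is described by its partitioning triplet at a
reference temperature (log K_OW, log K_AW, log K_OA, linked by the
thermodynamic triangle K_OW = K_AW * K_OA), the internal energies of phase
change that set the van't Hoff temperature dependence of each coefficient,
and medium-specific degradation half-lives with Arrhenius activation
energies.  Chemical-space scans are built from grids of such records
spanning a wide range of partitioning behaviour.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .constants import R_J_MOL_K

MEDIA = ("air", "water", "soil", "sediment")

#: Default internal energy of octanol-water phase change, kJ/mol
DEFAULT_DU_OW = -20.0

#: Default linear map from log K_OA to the internal energy of
#: octanol-air phase change, kJ/mol: dU_OA = -(intercept + slope*logKOA).
#: Sorption to octanol becomes more exothermic for heavier chemicals.
DU_OA_INTERCEPT = 10.0
DU_OA_SLOPE = 3.5

#: Default activation energies for degradation, kJ/mol: OH-radical
#: chemistry in air vs. condensed-phase hydrolysis/biodegradation.
DEFAULT_EA = {"air": 10.0, "water": 30.0, "soil": 30.0, "sediment": 30.0}

#: Default reference half-lives (hours) for hypothetical persistent chemicals.
DEFAULT_HALFLIVES = {"air": 1_000.0, "water": 10_000.0,
                     "soil": 30_000.0, "sediment": 30_000.0}

T_REF_DEFAULT = 298.15

_CSV_COLUMNS = ["name", "logKOW", "logKAW", "logKOA", "dU_OW", "dU_OA",
                "dU_AW", "dU_A", "hl_air_h", "hl_water_h", "hl_soil_h",
                "hl_sed_h", "Ea_air", "Ea_water", "Ea_soil", "Ea_sed",
                "T_ref_K"]


def derive_dU_AW(dU_OW: float, dU_OA: float) -> float:
    """Internal energy of air-water phase change from the other two legs.

    Internally consistent property data require dU_AW = dU_OW - dU_OA, the
    energetic analogue of the partitioning triangle.
    """
    return dU_OW - dU_OA


def adjust_partition_coefficient(K_ref: float, dU: float,
                                 T_ref: float, T: float) -> float:
    """van't Hoff temperature adjustment of a partition coefficient.

    K(T) = K_ref * exp(-(dU*1000/R) * (1/T - 1/T_ref)) with dU in kJ/mol.
    Positive dU means K increases with temperature.

    Raises ValueError for non-positive K_ref or temperatures.
    """
    if K_ref <= 0:
        raise ValueError(f"K_ref must be positive, got {K_ref}")
    if T_ref <= 0:
        raise ValueError(f"T_ref must be positive, got {T_ref}")
    if T <= 0:
        raise ValueError(f"T must be positive, got {T}")
    return K_ref * math.exp(-(dU * 1000.0 / R_J_MOL_K) * (1.0 / T - 1.0 / T_ref))


def adjust_halflife(HL_ref: float, Ea: float, T_ref: float, T: float) -> float:
    """Arrhenius temperature adjustment of a degradation half-life (hours).

    The rate constant k = ln2/HL follows
    k(T) = k(T_ref) * exp(-(Ea*1000/R) * (1/T - 1/T_ref)),
    so warming with Ea > 0 shortens the half-life.
    """
    if HL_ref <= 0:
        raise ValueError(f"HL_ref must be positive, got {HL_ref}")
    if T_ref <= 0 or T <= 0:
        raise ValueError("temperatures must be positive")
    return HL_ref * math.exp((Ea * 1000.0 / R_J_MOL_K) * (1.0 / T - 1.0 / T_ref))


@dataclass(frozen=True)
class Chemical:
    """A neutral organic chemical with temperature-dependent properties.

    Partition coefficients are stored as log10 values at ``T_ref`` (K);
    ``dU_*`` are internal energies of phase change (kJ/mol); ``halflife_ref``
    maps medium -> hours and ``Ea`` maps medium -> kJ/mol.  ``dU_A`` is the
    (negative, condensation-convention) internal energy of vaporization used
    only for emission-temperature scaling.
    """

    name: str
    logKOW_ref: float
    logKAW_ref: float
    logKOA_ref: float
    dU_OW: float = DEFAULT_DU_OW
    dU_OA: float = -45.0
    dU_AW: float = None  # type: ignore[assignment]
    dU_A: float = -80.0
    halflife_ref: dict = field(default_factory=lambda: dict(DEFAULT_HALFLIVES))
    Ea: dict = field(default_factory=lambda: dict(DEFAULT_EA))
    T_ref: float = T_REF_DEFAULT

    def __post_init__(self):
        if self.dU_AW is None:
            object.__setattr__(self, "dU_AW", derive_dU_AW(self.dU_OW, self.dU_OA))
        if abs(self.logKOW_ref - (self.logKAW_ref + self.logKOA_ref)) > 1e-9:
            raise ValueError(
                f"{self.name}: logKOW_ref must equal logKAW_ref + logKOA_ref "
                f"(got {self.logKOW_ref} vs {self.logKAW_ref + self.logKOA_ref})")
        if abs(self.dU_AW - derive_dU_AW(self.dU_OW, self.dU_OA)) > 1e-9:
            raise ValueError(f"{self.name}: dU_AW must equal dU_OW - dU_OA")
        if self.T_ref <= 0:
            raise ValueError(f"{self.name}: T_ref must be positive")
        for medium in MEDIA:
            if medium not in self.halflife_ref:
                raise ValueError(f"{self.name}: missing half-life for {medium}")
            if self.halflife_ref[medium] <= 0:
                raise ValueError(
                    f"{self.name}: halflife_ref[{medium}] must be positive")

    # temperature-dependent coefficients (linear, not log, scale) -------

    def K_AW(self, T: float) -> float:
        return adjust_partition_coefficient(10.0 ** self.logKAW_ref,
                                            self.dU_AW, self.T_ref, T)

    def K_OW(self, T: float) -> float:
        return adjust_partition_coefficient(10.0 ** self.logKOW_ref,
                                            self.dU_OW, self.T_ref, T)

    def K_OA(self, T: float) -> float:
        return adjust_partition_coefficient(10.0 ** self.logKOA_ref,
                                            self.dU_OA, self.T_ref, T)

    def halflife(self, medium: str, T: float) -> float:
        """Degradation half-life (hours) in ``medium`` at temperature T."""
        return adjust_halflife(self.halflife_ref[medium], self.Ea[medium],
                               self.T_ref, T)


def du_oa_from_logkoa(logKOA: float, intercept: float = DU_OA_INTERCEPT,
                      slope: float = DU_OA_SLOPE) -> float:
    """Configured dU_OA(logKOA) relation: -(intercept + slope*logKOA) kJ/mol."""
    return -(intercept + slope * logKOA)


def make_chemspace_grid(logKOA_min: float = 4.0, logKOA_max: float = 14.0,
                        logKAW_min: float = -6.0, logKAW_max: float = 1.0,
                        step: float = 0.5,
                        template: Chemical | None = None,
                        du_oa_intercept: float = DU_OA_INTERCEPT,
                        du_oa_slope: float = DU_OA_SLOPE) -> list[Chemical]:
    """Hypothetical persistent chemicals on a (log K_OA, log K_AW) grid.

    One chemical per grid node; log K_OW is set to log K_OA + log K_AW so the
    thermodynamic triangle holds by construction, and dU_OA follows the
    configured linear relation in log K_OA (dU_AW is recomputed).  The default
    bounds cover the region occupied by known POPs (log K_AW -1..-5,
    log K_OA 7..13) with margin.
    """
    if logKOA_max <= logKOA_min or logKAW_max <= logKAW_min:
        raise ValueError("grid axis maxima must exceed minima")
    if step <= 0:
        raise ValueError("step must be positive")
    if template is None:
        template = Chemical(name="template", logKOW_ref=0.0, logKAW_ref=0.0,
                            logKOA_ref=0.0, dU_OW=DEFAULT_DU_OW, dU_OA=-45.0)
    koa_axis = np.arange(logKOA_min, logKOA_max + 1e-9, step)
    kaw_axis = np.arange(logKAW_min, logKAW_max + 1e-9, step)
    chems = []
    for logKOA in koa_axis:
        for logKAW in kaw_axis:
            dU_OA = du_oa_from_logkoa(logKOA, du_oa_intercept, du_oa_slope)
            chems.append(replace(
                template,
                name=f"chem_KOA{logKOA:g}_KAW{logKAW:g}",
                logKOA_ref=float(logKOA), logKAW_ref=float(logKAW),
                logKOW_ref=float(logKOA + logKAW),
                dU_OA=dU_OA, dU_AW=derive_dU_AW(template.dU_OW, dU_OA)))
    if not chems:
        raise ValueError("empty chemical grid")
    return chems


def pcb153() -> Chemical:
    """Reference chemical with PCB-153-like properties.

    Conventional literature-style defaults (editable): partitioning triplet
    6.9 / -2.0 / 8.9, PCB-typical phase-change energies, and long
    chemical-specific degradation half-lives.
    """
    return Chemical(
        name="PCB-153",
        logKOW_ref=6.9, logKAW_ref=-2.0, logKOA_ref=8.9,
        dU_OW=-25.0, dU_OA=-75.0, dU_AW=50.0, dU_A=-85.0,
        halflife_ref={"air": 1_700.0, "water": 55_000.0,
                      "soil": 55_000.0, "sediment": 170_000.0},
        Ea=dict(DEFAULT_EA))


# CSV interchange ------------------------------------------------------

def chemicals_to_csv(chems: list[Chemical], path) -> None:
    rows = []
    for c in chems:
        rows.append({
            "name": c.name, "logKOW": c.logKOW_ref, "logKAW": c.logKAW_ref,
            "logKOA": c.logKOA_ref, "dU_OW": c.dU_OW, "dU_OA": c.dU_OA,
            "dU_AW": c.dU_AW, "dU_A": c.dU_A,
            "hl_air_h": c.halflife_ref["air"],
            "hl_water_h": c.halflife_ref["water"],
            "hl_soil_h": c.halflife_ref["soil"],
            "hl_sed_h": c.halflife_ref["sediment"],
            "Ea_air": c.Ea["air"], "Ea_water": c.Ea["water"],
            "Ea_soil": c.Ea["soil"], "Ea_sed": c.Ea["sediment"],
            "T_ref_K": c.T_ref})
    pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(path, index=False)


def chemicals_from_csv(path) -> list[Chemical]:
    df = pd.read_csv(path)
    missing = set(_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"chemical CSV missing columns: {sorted(missing)}")
    chems = []
    for _, r in df.iterrows():
        chems.append(Chemical(
            name=str(r["name"]), logKOW_ref=float(r["logKOW"]),
            logKAW_ref=float(r["logKAW"]), logKOA_ref=float(r["logKOA"]),
            dU_OW=float(r["dU_OW"]), dU_OA=float(r["dU_OA"]),
            dU_AW=float(r["dU_AW"]), dU_A=float(r["dU_A"]),
            halflife_ref={"air": float(r["hl_air_h"]),
                          "water": float(r["hl_water_h"]),
                          "soil": float(r["hl_soil_h"]),
                          "sediment": float(r["hl_sed_h"])},
            Ea={"air": float(r["Ea_air"]), "water": float(r["Ea_water"]),
                "soil": float(r["Ea_soil"]), "sediment": float(r["Ea_sed"])},
            T_ref=float(r["T_ref_K"])))
    return chems
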