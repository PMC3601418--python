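"""Steady-state fugacity mass balance: Z-values, D-values, solver, metrics.

The fugacity formalism expresses concentration as C = Z * f, where Z
(mol m-3 Pa-1) is the capacity of a phase for the chemical and f (Pa) its
escaping tendency.  Transport and transformation processes are conductances
D (mol Pa-1 h-1) so that every rate is D * f.  At steady state the linear
balance (losses - gains) f = E is solved for the fugacity vector; all
derived outputs (concentrations, masses, inventory, overall persistence)
follow from f.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chemicals import Chemical
from .constants import R_J_MOL_K
from .world import Compartment, World, EmissionMap, HALFLIFE_MEDIUM

LN2 = math.log(2.0)

#: Karickhoff-style organic-carbon/octanol proportionality.
KOC_FACTOR = 0.35

#: Mineral/organic solid densities used to convert L/kg-style sorption
#: coefficients to volumetric Z values, kg/m3.
SOLIDS_DENSITY = 2400.0
PARTICLE_DENSITY = 1500.0

#: Aerosol particle-gas partitioning (Harner-Bidleman-style):
#: log Kp(m3/ug) = logKOA + log10(f_om) - 11.91, converted to a volume
#: basis with the aerosol density below (ug/m3 of particle).
AEROSOL_F_OM = 0.2
AEROSOL_DENSITY_UG_M3 = 2.0e12


@dataclass
class TransportParams:
    """Mass-transfer coefficients and particle velocities (editable table).

    Conventional multimedia-model values; all lengths m, times h.
    """

    mtc_air_side_water: float = 3.0        # air film over water, m/h
    mtc_water_side: float = 0.03           # water film, m/h
    mtc_air_side_soil: float = 1.0         # air boundary layer over soil, m/h
    mtc_soil_air_phase: float = 0.0017     # diffusion in soil air, m/h
    mtc_soil_water_phase: float = 1e-5     # diffusion in soil water, m/h
    mtc_sediment_water: float = 1e-4       # water-sediment diffusion, m/h
    dep_velocity: float = 4.6e-8           # suspended-solids deposition, m/h
    resusp_velocity: float = 1.1e-8        # sediment resuspension, m/h
    burial_velocity: float = 2.2e-8        # sediment burial, m/h
    soil_solids_runoff: float = 2.3e-8     # soil-solids washoff, m/h
    soil_water_runoff_frac: float = 0.4    # fraction of rain running off soil
    scavenging_ratio: float = 2.0e5        # rain particle washout
    dry_dep_velocity: float = 7.2          # aerosol dry deposition, m/h


@dataclass
class ZValues:
    """Pure-phase and bulk fugacity capacities for one compartment."""

    air: float = 0.0
    water: float = 0.0
    octanol: float = 0.0
    organic_carbon: float = 0.0
    aerosol: float = 0.0
    solid: float = 0.0
    particle: float = 0.0
    bulk: float = 0.0


def compute_z_values(chemical: Chemical, compartment: Compartment,
                     T: float | None = None) -> ZValues:
    """Fugacity capacities of a compartment at temperature T.

    Z_air = 1/(R*T); Z_water = Z_air / K_AW(T); Z_octanol = K_OW(T)*Z_water;
    organic-carbon-rich solids scale Z_water by Koc = 0.35*K_OW (converted to
    a volume basis with the solid density); aerosol Z comes from a
    K_OA-based particle-gas relation.  The bulk value is the
    volume-fraction-weighted sum over the compartment's subphases.
    """
    if T is None:
        T = compartment.temperature
    K_AW = chemical.K_AW(T)
    if K_AW == 0:
        raise ValueError("K_AW(T) must be non-zero")
    z = ZValues()
    z.air = 1.0 / (R_J_MOL_K * T)
    z.water = z.air / K_AW
    K_OW = chemical.K_OW(T)
    z.octanol = K_OW * z.water

    def z_oc_solid(f_oc: float, density: float) -> float:
        # Koc [L/kg] * f_oc * density [kg/m3] / 1000 [L/m3] -> volumetric
        return KOC_FACTOR * K_OW * f_oc * density / 1000.0 * z.water

    z.organic_carbon = KOC_FACTOR * K_OW * z.water
    logKOA_T = math.log10(chemical.K_OA(T))
    kp = 10.0 ** (logKOA_T + math.log10(AEROSOL_F_OM) - 11.91)  # m3/ug
    z.aerosol = kp * AEROSOL_DENSITY_UG_M3 * z.air

    m = compartment.medium
    if m == "air":
        z.bulk = (1.0 - compartment.frac_aerosol) * z.air \
            + compartment.frac_aerosol * z.aerosol
    elif m in ("freshwater", "ocean"):
        z.particle = z_oc_solid(compartment.f_oc, PARTICLE_DENSITY)
        z.bulk = (1.0 - compartment.frac_particles) * z.water \
            + compartment.frac_particles * z.particle
    elif m == "soil":
        z.solid = z_oc_solid(compartment.f_oc, SOLIDS_DENSITY)
        z.bulk = compartment.frac_air * z.air \
            + compartment.frac_water * z.water \
            + compartment.frac_solids * z.solid
    elif m == "sediment":
        z.solid = z_oc_solid(compartment.f_oc, SOLIDS_DENSITY)
        z.bulk = compartment.frac_water * z.water \
            + compartment.frac_solids * z.solid
    else:  # pragma: no cover - media are validated upstream
        raise ValueError(f"unknown medium {m!r}")
    return z


@dataclass
class FateSystem:
    """Assembled linear system for one chemical in one world.

    ``matrix`` is (losses - gains): diagonal entries are total-loss D values
    of each compartment, off-diagonal entry (i, j) is minus the gain of i
    from j.  ``deg_d`` and ``burial_d`` are the non-recoverable loss
    conductances used for the mass-balance and persistence metrics.
    """

    labels: list = field(default_factory=list)      # (region, medium)
    matrix: np.ndarray = None                       # mol Pa-1 h-1
    emissions: np.ndarray = None                    # mol/h
    z_bulk: np.ndarray = None                       # mol m-3 Pa-1
    z_water: np.ndarray = None                      # dissolved-phase Z
    volumes: np.ndarray = None                      # m3
    deg_d: np.ndarray = None
    burial_d: np.ndarray = None

    def index(self, region: str, medium: str) -> int:
        return self.labels.index((region, medium))


def _diffusion_series(area: float, *conductance_velocities) -> float:
    """Two-film style series resistance; each term is (velocity * Z)."""
    return area / sum(1.0 / g for g in conductance_velocities)


def compute_d_values(chemical: Chemical, world: World,
                     emissions: EmissionMap | None = None,
                     params: TransportParams | None = None) -> FateSystem:
    """Populate the full D-value matrix for a chemical in a world.

    Degradation D = (ln2 / HL_m(T)) * V * Z_bulk per compartment;
    inter-region advection D = flow * Z_bulk of the source air/ocean;
    intermedia transfers cover air-water two-film exchange, rain
    dissolution, wet/dry aerosol deposition, air-soil diffusion, soil
    runoff, and water-sediment diffusion/deposition/resuspension/burial
    (burial being a permanent loss).  Temperature acts through Z(T) and
    HL(T); precipitation through the rain-driven terms.
    """
    p = params or TransportParams()
    labels = [(code, medium) for code in world.codes
              for medium in ("air", "freshwater", "sediment", "soil", "ocean")]
    n = len(labels)
    idx = {lab: i for i, lab in enumerate(labels)}
    A = np.zeros((n, n))
    deg_d = np.zeros(n)
    burial_d = np.zeros(n)
    z_bulk = np.zeros(n)
    z_water = np.zeros(n)
    volumes = np.zeros(n)

    zvals = {}
    for code, region in world.regions.items():
        for medium, comp in region.compartments.items():
            z = compute_z_values(chemical, comp)
            zvals[(code, medium)] = z
            i = idx[(code, medium)]
            z_bulk[i] = z.bulk
            z_water[i] = z.water
            volumes[i] = comp.volume
            hl = chemical.halflife(HALFLIFE_MEDIUM[medium], comp.temperature)
            deg_d[i] = (LN2 / hl) * comp.volume * z.bulk

    def add_transfer(src, dst, d):
        if d == 0.0:
            return
        A[idx[src], idx[src]] += d
        A[idx[dst], idx[src]] -= d

    for code, region in world.regions.items():
        air = region.compartments["air"]
        z_air = zvals[(code, "air")]

        for water_medium in ("freshwater", "ocean"):
            area = air.areas.get(water_medium)
            if area is None:
                raise ValueError(f"{code}: air-{water_medium} area missing")
            zw = zvals[(code, water_medium)]
            d_diff = _diffusion_series(
                area, p.mtc_air_side_water * z_air.air,
                p.mtc_water_side * zw.water)
            d_rain = air.rain_rate * area * zw.water
            d_wet = air.rain_rate * p.scavenging_ratio * air.frac_aerosol \
                * area * z_air.aerosol
            d_dry = p.dry_dep_velocity * air.frac_aerosol * area * z_air.aerosol
            add_transfer((code, "air"), (code, water_medium),
                         d_diff + d_rain + d_wet + d_dry)
            add_transfer((code, water_medium), (code, "air"), d_diff)

        area_soil = air.areas.get("soil")
        if area_soil is None:
            raise ValueError(f"{code}: air-soil area missing")
        z_soil = zvals[(code, "soil")]
        d_soil_diff = _diffusion_series(
            area_soil, p.mtc_air_side_soil * z_air.air,
            p.mtc_soil_air_phase * z_air.air
            + p.mtc_soil_water_phase * z_soil.water)
        d_rain_soil = air.rain_rate * area_soil * z_soil.water
        d_wet_soil = air.rain_rate * p.scavenging_ratio * air.frac_aerosol \
            * area_soil * z_air.aerosol
        d_dry_soil = p.dry_dep_velocity * air.frac_aerosol * area_soil \
            * z_air.aerosol
        add_transfer((code, "air"), (code, "soil"),
                     d_soil_diff + d_rain_soil + d_wet_soil + d_dry_soil)
        add_transfer((code, "soil"), (code, "air"), d_soil_diff)

        # soil -> freshwater runoff (dissolved + solids)
        area_runoff = region.compartments["soil"].areas.get("freshwater",
                                                            area_soil)
        d_runoff = area_runoff * (
            p.soil_water_runoff_frac * air.rain_rate * z_soil.water
            + p.soil_solids_runoff * z_soil.solid)
        add_transfer((code, "soil"), (code, "freshwater"), d_runoff)

        # freshwater <-> sediment
        area_sed = region.compartments["sediment"].areas.get("freshwater")
        if area_sed is None:
            raise ValueError(f"{code}: sediment-freshwater area missing")
        z_fw = zvals[(code, "freshwater")]
        z_sed = zvals[(code, "sediment")]
        d_sw_diff = area_sed * p.mtc_sediment_water * z_fw.water
        d_dep = area_sed * p.dep_velocity * z_fw.particle
        d_resusp = area_sed * p.resusp_velocity * z_sed.solid
        add_transfer((code, "freshwater"), (code, "sediment"),
                     d_sw_diff + d_dep)
        add_transfer((code, "sediment"), (code, "freshwater"),
                     d_sw_diff + d_resusp)
        i_sed = idx[(code, "sediment")]
        burial_d[i_sed] = area_sed * p.burial_velocity * z_sed.solid
        A[i_sed, i_sed] += burial_d[i_sed]

        # inter-region advection
        for dest, q in region.air_outflows.items():
            add_transfer((code, "air"), (dest, "air"), q * z_air.bulk)
        for dest, q in region.ocean_outflows.items():
            add_transfer((code, "ocean"), (dest, "ocean"),
                         q * zvals[(code, "ocean")].bulk)

    A[np.diag_indices(n)] += deg_d

    E = np.zeros(n)
    if emissions is not None:
        for (code, medium), rate in emissions.rates.items():
            E[idx[(code, medium)]] += rate

    return FateSystem(labels=labels, matrix=A, emissions=E, z_bulk=z_bulk,
                      z_water=z_water, volumes=volumes, deg_d=deg_d,
                      burial_d=burial_d)


@dataclass
class FateResult:
    """Steady-state solution of a :class:`FateSystem`."""

    labels: list
    fugacity: np.ndarray            # Pa
    conc_bulk: np.ndarray           # mol/m3
    conc_dissolved: np.ndarray      # mol/m3, water media (Z_water * f)
    masses: np.ndarray              # mol
    inventory: float                # mol
    p_ov: float                     # hours
    degradation_loss: float         # mol/h
    advection_loss: float           # mol/h (burial + boundary outflow)
    mass_balance_residual: float    # relative

    def get(self, region: str, medium: str, what: str = "conc_bulk") -> float:
        i = self.labels.index((region, medium))
        return float(getattr(self, what)[i])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, (region, medium) in enumerate(self.labels):
            rows.append({"region": region, "medium": medium,
                         "fugacity_Pa": self.fugacity[i],
                         "conc_bulk_mol_m3": self.conc_bulk[i],
                         "conc_dissolved_mol_m3": self.conc_dissolved[i],
                         "mass_mol": self.masses[i]})
        return pd.DataFrame(rows)


def solve_steady_state(system: FateSystem) -> FateResult:
    """Solve (losses - gains) f = E and derive all output metrics.

    Raises ValueError for singular systems or (numerically) negative
    fugacities, reporting the residual diagnostics.
    """
    A, E = system.matrix, system.emissions
    try:
        f = np.linalg.solve(A, E)
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"singular fate system: {exc}") from exc
    scale = np.max(np.abs(f)) if np.max(np.abs(f)) > 0 else 1.0
    if np.any(f < -1e-12 * scale):
        raise ValueError(
            f"negative fugacities in solution (min {f.min():.3e})")
    f = np.clip(f, 0.0, None)
    conc_bulk = system.z_bulk * f
    conc_dissolved = system.z_water * f
    masses = conc_bulk * system.volumes
    inventory = float(masses.sum())
    deg_rate = float(np.dot(system.deg_d, f))
    burial_rate = float(np.dot(system.burial_d, f))
    total_in = float(E.sum())
    total_out = deg_rate + burial_rate
    residual = abs(total_in - total_out) / total_in if total_in > 0 else 0.0
    p_ov = inventory / deg_rate if deg_rate > 0 else math.inf
    return FateResult(labels=system.labels, fugacity=f, conc_bulk=conc_bulk,
                      conc_dissolved=conc_dissolved, masses=masses,
                      inventory=inventory, p_ov=p_ov,
                      degradation_loss=deg_rate, advection_loss=burial_rate,
                      mass_balance_residual=residual)


def dynamic_solve(system: FateSystem, horizon: float, step: float,
                  M0: np.ndarray | None = None) -> pd.DataFrame:
    """Explicit time integration of dM/dt = E - (losses - gains) f.

    Used to verify the steady-state solution; returns a tidy trajectory of
    masses.  Raises ValueError when the step is too large for stability.
    """
    if horizon <= 0 or step <= 0:
        raise ValueError("horizon and step must be positive")
    vz = system.volumes * system.z_bulk
    tau_min = float(np.min(vz / np.diag(system.matrix)))
    if step > tau_min:
        raise ValueError(
            f"step {step} h exceeds the fastest response time {tau_min:.3g} h")
    n_steps = int(np.ceil(horizon / step))
    M = np.zeros_like(vz) if M0 is None else np.asarray(M0, dtype=float).copy()
    times = [0.0]
    traj = [M.copy()]
    for k in range(n_steps):
        f = M / vz
        M = M + step * (system.emissions - system.matrix @ f)
        if not np.all(np.isfinite(M)) or np.any(M < -1e-9 * max(M.max(), 1.0)):
            raise ValueError(f"unstable integration at t={k * step} h")
        M = np.clip(M, 0.0, None)
        times.append((k + 1) * step)
        traj.append(M.copy())
    out = pd.DataFrame(np.array(traj),
                       columns=[f"{r}:{m}" for r, m in system.labels])
    out.insert(0, "time_h", times)
    return out


def export_result_csv(result: FateResult, path) -> None:
    """Tidy CSV per compartment plus a one-row summary."""
    df = result.to_frame()
    df.to_csv(path, index=False, float_format="%.10g")
    summary = pd.DataFrame([{"region": "ALL", "medium": "summary",
                             "fugacity_Pa": np.nan,
                             "conc_bulk_mol_m3": np.nan,
                             "conc_dissolved_mol_m3": np.nan,
                             "mass_mol": result.inventory,
                             "p_ov_h": result.p_ov}])
    summary.to_csv(path, index=False, mode="a", header=False,
                   float_format="%.10g")
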