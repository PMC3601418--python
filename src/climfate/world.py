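"""Reduced multi-region world, climate-scenario perturbations and emissions.

The world stands in for a global multi-region box model: a small set of
interconnected regions (Arctic ARC, northern Europe NEU, southern Africa
SAF, and a rest-of-world reservoir ROW), each holding five bulk
compartments (air, freshwater, sediment, soil, surface ocean).  Regions
are linked by closed atmospheric and surface-ocean circulation along the
chain ARC <-> NEU <-> ROW <-> SAF.  A climate scenario perturbs regional
temperatures, precipitation and (optionally) circulation; comparing model
output between the baseline and perturbed worlds is the analysis endpoint.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, asdict

import pandas as pd
import yaml

from .constants import R_J_MOL_K

MEDIA = ("air", "freshwater", "sediment", "soil", "ocean")

#: Media whose degradation half-life key differs from the compartment name.
HALFLIFE_MEDIUM = {"air": "air", "freshwater": "water", "ocean": "water",
                   "soil": "soil", "sediment": "sediment"}


@dataclass
class Compartment:
    """One bulk environmental compartment of a region.

    ``areas`` maps a neighbouring medium name to the interfacial area (m2).
    Subphase volume fractions: ``frac_aerosol`` (air), ``frac_particles``
    (water columns), ``frac_solids``/``frac_water``/``frac_air`` (soil and
    sediment).  ``f_oc`` is the organic-carbon fraction of the solids and
    ``rain_rate`` (m/h) applies to air only.
    """

    medium: str
    volume: float
    temperature: float
    areas: dict = field(default_factory=dict)
    frac_aerosol: float = 0.0
    frac_particles: float = 0.0
    frac_solids: float = 0.0
    frac_water: float = 0.0
    frac_air: float = 0.0
    f_oc: float = 0.0
    rain_rate: float = 0.0

    def __post_init__(self):
        if self.medium not in MEDIA:
            raise ValueError(f"unknown medium {self.medium!r}")
        if self.volume <= 0:
            raise ValueError(f"{self.medium}: volume must be positive")
        if self.temperature <= 0:
            raise ValueError(f"{self.medium}: temperature must be positive")
        for name in ("frac_aerosol", "frac_particles", "frac_solids",
                     "frac_water", "frac_air", "f_oc"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{self.medium}: {name} must lie in [0, 1]")
        if self.rain_rate < 0:
            raise ValueError(f"{self.medium}: rain_rate must be non-negative")


@dataclass
class Region:
    """A region: one compartment per medium plus outgoing circulation links."""

    code: str
    compartments: dict = field(default_factory=dict)
    air_outflows: dict = field(default_factory=dict)   # region code -> m3/h
    ocean_outflows: dict = field(default_factory=dict)

    def __post_init__(self):
        if set(self.compartments) != set(MEDIA):
            raise ValueError(
                f"{self.code}: exactly one compartment per medium required")
        for flows in (self.air_outflows, self.ocean_outflows):
            for dest, q in flows.items():
                if q < 0:
                    raise ValueError(f"{self.code}->{dest}: flow must be >= 0")


@dataclass
class World:
    """An ordered collection of regions."""

    regions: dict = field(default_factory=dict)

    @property
    def codes(self) -> list[str]:
        return list(self.regions)

    def compartment(self, code: str, medium: str) -> Compartment:
        return self.regions[code].compartments[medium]


@dataclass(frozen=True)
class ClimateDelta:
    """Per-region climate perturbation.

    ``dT`` shifts the annual-mean temperature of every compartment (K),
    ``dPrecip`` scales the rain rate by (1 + dPrecip), and the optional
    scale factors multiply atmospheric / oceanic circulation flows.
    """

    region: str
    dT: float = 0.0
    dPrecip: float = 0.0
    wind_scale: float = 1.0
    current_scale: float = 1.0

    def __post_init__(self):
        if self.dPrecip <= -1.0:
            raise ValueError(
                f"{self.region}: dPrecip must exceed -1 (got {self.dPrecip})")
        if self.wind_scale < 0 or self.current_scale < 0:
            raise ValueError(f"{self.region}: scale factors must be >= 0")


#: Default perturbations, inside the projected envelopes of +1.1..+6.4 K
#: warming and -20..+20% precipitation change, with Arctic amplification.
DEFAULT_DELTAS = (
    ClimateDelta("ARC", dT=5.0, dPrecip=0.15),
    ClimateDelta("NEU", dT=3.0, dPrecip=0.10),
    ClimateDelta("SAF", dT=3.5, dPrecip=-0.10),
    ClimateDelta("ROW", dT=3.0, dPrecip=0.0),
)


# -- default parameter table (conventional multimedia-model values) ----

DEFAULT_GEOMETRY = {
    "air_height_m": 1000.0,
    "soil_depth_m": 0.10,
    "freshwater_depth_m": 20.0,
    "ocean_depth_m": 100.0,
    "sediment_depth_m": 0.03,
    "land_frac": 0.29,
    "freshwater_frac": 0.01,
    "ocean_frac": 0.70,
    "aerosol_vf": 2e-11,
    "freshwater_solids_vf": 5e-6,
    "ocean_solids_vf": 1e-6,
    "soil_air_vf": 0.2,
    "soil_water_vf": 0.3,
    "soil_solids_vf": 0.5,
    "sediment_water_vf": 0.8,
    "sediment_solids_vf": 0.2,
    "f_oc_soil": 0.02,
    "f_oc_fw_particles": 0.20,
    "f_oc_ocean_particles": 0.20,
    "f_oc_sediment": 0.04,
    "rain_rate_m_h": 8.5e-5,          # ~0.74 m/yr
    "air_residence_h": 168.0,         # one week per regional air shed
    "ocean_residence_h": 43_800.0,    # five years per mixed-layer box
}

DEFAULT_REGION_AREAS = {   # m2; ROW absorbs the remainder of the globe
    "ARC": 2.6e13, "NEU": 1.1e13, "SAF": 1.2e13, "ROW": 4.4e14,
}

DEFAULT_REGION_TEMPS = {   # plausible annual means, K
    "ARC": 268.0, "NEU": 283.0, "SAF": 293.0, "ROW": 288.0,
}

#: Circulation chain (both directions carry the same flow, so the
#: circulation is closed by construction).
CHAIN = (("ARC", "NEU"), ("NEU", "ROW"), ("ROW", "SAF"))


def _build_region(code: str, area: float, T: float, g: dict) -> Region:
    a_land = area * g["land_frac"]
    a_fw = area * g["freshwater_frac"]
    a_ocean = area * g["ocean_frac"]
    comps = {
        "air": Compartment(
            "air", volume=area * g["air_height_m"], temperature=T,
            areas={"soil": a_land, "freshwater": a_fw, "ocean": a_ocean},
            frac_aerosol=g["aerosol_vf"], rain_rate=g["rain_rate_m_h"]),
        "soil": Compartment(
            "soil", volume=a_land * g["soil_depth_m"], temperature=T,
            areas={"air": a_land, "freshwater": a_land},
            frac_air=g["soil_air_vf"], frac_water=g["soil_water_vf"],
            frac_solids=g["soil_solids_vf"], f_oc=g["f_oc_soil"]),
        "freshwater": Compartment(
            "freshwater", volume=a_fw * g["freshwater_depth_m"], temperature=T,
            areas={"air": a_fw, "sediment": a_fw},
            frac_particles=g["freshwater_solids_vf"],
            f_oc=g["f_oc_fw_particles"]),
        "sediment": Compartment(
            "sediment", volume=a_fw * g["sediment_depth_m"], temperature=T,
            areas={"freshwater": a_fw},
            frac_water=g["sediment_water_vf"],
            frac_solids=g["sediment_solids_vf"], f_oc=g["f_oc_sediment"]),
        "ocean": Compartment(
            "ocean", volume=a_ocean * g["ocean_depth_m"], temperature=T,
            areas={"air": a_ocean},
            frac_particles=g["ocean_solids_vf"],
            f_oc=g["f_oc_ocean_particles"]),
    }
    return Region(code=code, compartments=comps)


def default_world(n_regions: int = 4, geometry: dict | None = None,
                  region_areas: dict | None = None,
                  region_temps: dict | None = None) -> World:
    """Fully parameterized default world.

    Only the reduced 4-region configuration is packaged; a 30-region
    parameterization would require the regional climate-projection tables
    that are not shipped with this package.
    """
    if n_regions != 4:
        raise ValueError(
            f"unsupported n_regions={n_regions}; packaged default is 4 "
            "(a 30-region parameterization requires external region tables)")
    g = dict(DEFAULT_GEOMETRY, **(geometry or {}))
    areas = dict(DEFAULT_REGION_AREAS, **(region_areas or {}))
    temps = dict(DEFAULT_REGION_TEMPS, **(region_temps or {}))
    world = World(regions={
        code: _build_region(code, areas[code], temps[code], g)
        for code in ("ARC", "NEU", "SAF", "ROW")})
    for a, b in CHAIN:
        va = world.compartment(a, "air").volume
        vb = world.compartment(b, "air").volume
        q_air = min(va, vb) / g["air_residence_h"]
        world.regions[a].air_outflows[b] = q_air
        world.regions[b].air_outflows[a] = q_air
        oa = world.compartment(a, "ocean").volume
        ob = world.compartment(b, "ocean").volume
        q_oc = min(oa, ob) / g["ocean_residence_h"]
        world.regions[a].ocean_outflows[b] = q_oc
        world.regions[b].ocean_outflows[a] = q_oc
    return world


def apply_climate_scenario(world: World,
                           deltas: tuple[ClimateDelta, ...] | list[ClimateDelta],
                           ) -> World:
    """Return a new world with the climate perturbations applied.

    Every compartment of a named region is warmed by dT, the regional rain
    rate is scaled by (1 + dPrecip) and circulation outflows are scaled by
    the optional wind/current factors.  The input world is left unmodified.
    """
    out = copy.deepcopy(world)
    for d in deltas:
        if d.region not in out.regions:
            raise ValueError(f"unknown region code {d.region!r}")
        region = out.regions[d.region]
        for comp in region.compartments.values():
            comp.temperature += d.dT
        region.compartments["air"].rain_rate *= (1.0 + d.dPrecip)
        for dest in region.air_outflows:
            region.air_outflows[dest] *= d.wind_scale
        for dest in region.ocean_outflows:
            region.ocean_outflows[dest] *= d.current_scale
    return out


@dataclass
class EmissionMap:
    """Emission rates (mol/h) keyed by (region code, medium)."""

    rates: dict = field(default_factory=dict)

    def __post_init__(self):
        if any(v < 0 for v in self.rates.values()):
            raise ValueError("emission rates must be non-negative")
        if not any(v > 0 for v in self.rates.values()):
            raise ValueError("at least one emission rate must be positive")

    def scaled(self, factor: float) -> "EmissionMap":
        return EmissionMap({k: v * factor for k, v in self.rates.items()})


def build_emission_map(world: World, mode: str = "air_temperate",
                       source_rate: float = 1_000.0,
                       arctic_fraction: float = 1e-3,
                       custom: dict | None = None) -> EmissionMap:
    """Emission map for a fate run.

    ``air_temperate`` emits ``source_rate`` mol/h to the air of every
    non-Arctic region and ``arctic_fraction * source_rate`` to Arctic air
    (emissions to the Arctic itself are very low).  ``custom`` takes a
    user table {(region, medium): mol/h}.
    """
    if mode == "air_temperate":
        rates = {}
        for code in world.codes:
            rate = source_rate * (arctic_fraction if code == "ARC" else 1.0)
            rates[(code, "air")] = rate
        return EmissionMap(rates)
    if mode == "custom":
        if not custom or not any(v > 0 for v in custom.values()):
            raise ValueError("custom emission table must have a positive entry")
        for (code, medium) in custom:
            if code not in world.regions or medium not in MEDIA:
                raise ValueError(f"unknown emission target ({code}, {medium})")
        return EmissionMap(dict(custom))
    raise ValueError(f"unknown emission mode {mode!r}")


def scale_emission_with_temperature(E_ref: float, dU_A: float,
                                    T_ref: float, T: float) -> float:
    """Temperature scaling of a passive-volatilization emission rate.

    E(T) = E_ref * exp((dU_A*1000/R) * (1/T - 1/T_ref)); with the negative
    (exothermic-condensation) convention for dU_A, warming increases the
    emission rate.  OFF by default in scenario runs, which assume no change
    to primary emission rates.
    """
    if E_ref < 0:
        raise ValueError(f"E_ref must be non-negative, got {E_ref}")
    return E_ref * math.exp((dU_A * 1000.0 / R_J_MOL_K) * (1.0 / T - 1.0 / T_ref))


# -- serialization -----------------------------------------------------

def world_to_dict(world: World) -> dict:
    return {"regions": {code: asdict(region)
                        for code, region in world.regions.items()}}


def world_from_dict(data: dict) -> World:
    regions = {}
    for code, rd in data["regions"].items():
        comps = {m: Compartment(**cd) for m, cd in rd["compartments"].items()}
        regions[code] = Region(code=code, compartments=comps,
                               air_outflows=dict(rd.get("air_outflows", {})),
                               ocean_outflows=dict(rd.get("ocean_outflows", {})))
    return World(regions=regions)


def save_world(world: World, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(world_to_dict(world), fh, sort_keys=False)


def load_world(path) -> World:
    with open(path) as fh:
        return world_from_dict(yaml.safe_load(fh))


def world_parameter_table(world: World) -> pd.DataFrame:
    """Flattened per-compartment parameter table for audit."""
    rows = []
    for code, region in world.regions.items():
        for medium, c in region.compartments.items():
            rows.append({
                "region": code, "medium": medium, "volume_m3": c.volume,
                "temperature_K": c.temperature, "rain_rate_m_h": c.rain_rate,
                "frac_aerosol": c.frac_aerosol,
                "frac_particles": c.frac_particles,
                "frac_solids": c.frac_solids, "frac_water": c.frac_water,
                "frac_air": c.frac_air, "f_oc": c.f_oc})
    return pd.DataFrame(rows)
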