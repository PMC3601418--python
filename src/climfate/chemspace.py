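"""Baseline-vs-climate-scenario scans over the chemical partitioning space.

For every hypothetical chemical on a (log K_OA, log K_AW) grid the
steady-state fate model is solved under the baseline and the perturbed
world, and the five reported outputs (air bulk concentration, soil bulk
concentration, freely dissolved freshwater, sediment pore-water and freely
dissolved surface-ocean concentrations) are reduced to ratio maps
r = output_perturbed / output_baseline per region.  Ratios above 1 mean the
scenario raises the exposure-relevant concentration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chemicals import Chemical, make_chemspace_grid
from .fugacity import TransportParams, compute_d_values, solve_steady_state
from .world import (World, ClimateDelta, EmissionMap, DEFAULT_DELTAS,
                    apply_climate_scenario, build_emission_map,
                    scale_emission_with_temperature, default_world)

#: The five reported outputs: (medium, which concentration field).
OUTPUTS = {
    "air": ("air", "conc_bulk"),
    "soil": ("soil", "conc_bulk"),
    "freshwater_dissolved": ("freshwater", "conc_dissolved"),
    "sediment_porewater": ("sediment", "conc_dissolved"),
    "ocean_dissolved": ("ocean", "conc_dissolved"),
}

REPORT_REGIONS = ("ARC", "NEU", "SAF")


@dataclass
class RatioMap:
    """Grids of scenario/baseline output ratios.

    ``ratios[(region, output)]`` is a matrix indexed by
    (log K_OA, log K_AW) axis positions.
    """

    logKOA_axis: np.ndarray
    logKAW_axis: np.ndarray
    ratios: dict = field(default_factory=dict)

    def frame(self, region: str, output: str) -> pd.DataFrame:
        """Tidy logKOA, logKAW, ratio rows for one (region, output)."""
        mat = self.ratios[(region, output)]
        koa, kaw = np.meshgrid(self.logKOA_axis, self.logKAW_axis,
                               indexing="ij")
        return pd.DataFrame({"logKOA": koa.ravel(), "logKAW": kaw.ravel(),
                             "ratio": mat.ravel()})


def _outputs_of(result) -> dict:
    out = {}
    for name, (medium, what) in OUTPUTS.items():
        for region, med in result.labels:
            if med == medium:
                out[(region, name)] = result.get(region, medium, what)
    return out


def run_pair(world: World, deltas=DEFAULT_DELTAS,
             chemicals: list[Chemical] | None = None,
             emissions: EmissionMap | None = None,
             params: TransportParams | None = None,
             regions=None) -> RatioMap:
    """Solve baseline and perturbed steady states over the chemical grid.

    Deterministic; any solver failure aborts with the offending grid node
    named.  Emission rates are identical in both runs (ratio maps are
    invariant to their magnitude by linearity).
    """
    if chemicals is None:
        chemicals = make_chemspace_grid()
    if emissions is None:
        emissions = build_emission_map(world)
    regions = tuple(regions or world.codes)
    perturbed = apply_climate_scenario(world, deltas)

    koa_axis = np.array(sorted({c.logKOA_ref for c in chemicals}))
    kaw_axis = np.array(sorted({c.logKAW_ref for c in chemicals}))
    rmap = RatioMap(logKOA_axis=koa_axis, logKAW_axis=kaw_axis)
    for region in regions:
        for output in OUTPUTS:
            rmap.ratios[(region, output)] = np.full(
                (len(koa_axis), len(kaw_axis)), np.nan)

    koa_pos = {v: i for i, v in enumerate(koa_axis)}
    kaw_pos = {v: j for j, v in enumerate(kaw_axis)}
    for chem in chemicals:
        try:
            base = solve_steady_state(
                compute_d_values(chem, world, emissions, params))
            pert = solve_steady_state(
                compute_d_values(chem, perturbed, emissions, params))
        except ValueError as exc:
            raise ValueError(f"fate solve failed at grid node {chem.name}: "
                             f"{exc}") from exc
        b, g = _outputs_of(base), _outputs_of(pert)
        i = koa_pos[chem.logKOA_ref]
        j = kaw_pos[chem.logKAW_ref]
        for region in regions:
            for output in OUTPUTS:
                denom = b[(region, output)]
                rmap.ratios[(region, output)][i, j] = (
                    g[(region, output)] / denom if denom > 0 else np.nan)
    return rmap


def summarize_ratios(rmap: RatioMap) -> pd.DataFrame:
    """Per-(region, output) and overall reductions of a ratio map.

    Reports the maximum fold-change max(r, 1/r), the median absolute
    deviation from unity in percent, the fraction of grid cells within
    +-20% of unity, and the grid location of the extreme ratios.
    """
    if not rmap.ratios:
        raise ValueError("empty ratio map")
    rows = []

    def _summary(region, output, mat):
        r = mat[np.isfinite(mat)]
        fold = np.maximum(r, 1.0 / r)
        k = int(np.argmax(np.where(np.isfinite(mat),
                                   np.maximum(mat, 1.0 / mat), -np.inf)))
        i, j = np.unravel_index(k, mat.shape)
        return {"region": region, "output": output,
                "max_fold_change": float(fold.max()),
                "median_abs_dev_pct": float(np.median(np.abs(r - 1.0)) * 100),
                "frac_within_20pct": float(np.mean(np.abs(r - 1.0) <= 0.2)),
                "extreme_logKOA": float(rmap.logKOA_axis[i]),
                "extreme_logKAW": float(rmap.logKAW_axis[j]),
                "max_ratio": float(r.max()), "min_ratio": float(r.min())}

    for (region, output), mat in rmap.ratios.items():
        rows.append(_summary(region, output, mat))
    all_mat = np.stack(list(rmap.ratios.values()))
    pooled = all_mat[np.isfinite(all_mat)]
    rows.append({"region": "ALL", "output": "ALL",
                 "max_fold_change": float(
                     np.maximum(pooled, 1.0 / pooled).max()),
                 "median_abs_dev_pct": float(
                     np.median(np.abs(pooled - 1.0)) * 100),
                 "frac_within_20pct": float(
                     np.mean(np.abs(pooled - 1.0) <= 0.2)),
                 "extreme_logKOA": np.nan, "extreme_logKAW": np.nan,
                 "max_ratio": float(pooled.max()),
                 "min_ratio": float(pooled.min())})
    return pd.DataFrame(rows)


def run_reference_chemical(chemical: Chemical, world: World,
                           deltas=DEFAULT_DELTAS,
                           emissions: EmissionMap | None = None,
                           params: TransportParams | None = None,
                           emission_temperature_scaling: bool = False,
                           ) -> dict:
    """Scenario/baseline ratios for a single reference chemical.

    Returns regional air-concentration ratios plus the total-inventory and
    overall-persistence ratios.  By default primary emission rates are held
    unchanged between the scenarios; with
    ``emission_temperature_scaling=True`` the perturbed-run emissions are
    scaled by the chemical's dU_A and the regional warming.
    """
    if emissions is None:
        emissions = build_emission_map(world)
    perturbed = apply_climate_scenario(world, deltas)
    emissions_pert = emissions
    if emission_temperature_scaling:
        rates = {}
        for (code, medium), rate in emissions.rates.items():
            T0 = world.compartment(code, medium).temperature
            T1 = perturbed.compartment(code, medium).temperature
            rates[(code, medium)] = scale_emission_with_temperature(
                rate, chemical.dU_A, T0, T1)
        emissions_pert = EmissionMap(rates)
    base = solve_steady_state(
        compute_d_values(chemical, world, emissions, params))
    pert = solve_steady_state(
        compute_d_values(chemical, perturbed, emissions_pert, params))
    out = {"inventory_ratio": pert.inventory / base.inventory,
           "p_ov_ratio": pert.p_ov / base.p_ov,
           "air_ratio": {}}
    for code in world.codes:
        out["air_ratio"][code] = (pert.get(code, "air", "conc_bulk")
                                  / base.get(code, "air", "conc_bulk"))
    return out


def uncertainty_screen(chemical: Chemical, property_cv: dict,
                       n: int = 1000, seed: int = 0,
                       world: World | None = None,
                       output=("ARC", "air"), metric: str = "concentration",
                       dT_range=(1.1, 6.4), dPrecip_range=(-0.2, 0.2),
                       ) -> pd.DataFrame:
    """Monte Carlo variance split: chemical inputs vs climate inputs.

    Chemical partition coefficients and half-lives are perturbed
    log-normally with the given coefficients of variation
    (``property_cv`` keys: ``partition``, ``halflife``); climate deltas are
    drawn uniformly within the projected envelopes.  The screened output is
    the chosen compartment's scenario concentration (``metric =
    "concentration"``, in log10, so the split compares the chemical-input
    uncertainty of an exposure estimate with the climate-scenario signal)
    or the scenario/baseline ratio (``metric = "ratio"``).  Reports the
    variance share of each input group (each in [0, 1]; an interaction
    remainder absorbs the rest).
    """
    if metric not in ("concentration", "ratio"):
        raise ValueError(f"unknown metric {metric!r}")
    if n < 100:
        raise ValueError("n must be at least 100")
    if any(v < 0 for v in property_cv.values()):
        raise ValueError("coefficients of variation must be non-negative")
    if world is None:
        world = default_world(4)
    emissions = build_emission_map(world)
    rng = np.random.default_rng(seed)
    cv_k = property_cv.get("partition", 0.0)
    cv_hl = property_cv.get("halflife", 0.0)
    # log-normal sigma from cv
    sig_k = np.sqrt(np.log1p(cv_k ** 2))
    sig_hl = np.sqrt(np.log1p(cv_hl ** 2))

    def sample_chemical() -> Chemical:
        from dataclasses import replace
        d_kaw = np.log10(np.exp(rng.normal(0.0, sig_k)))
        d_koa = np.log10(np.exp(rng.normal(0.0, sig_k)))
        hl = {m: v * np.exp(rng.normal(0.0, sig_hl))
              for m, v in chemical.halflife_ref.items()}
        return replace(chemical,
                       logKAW_ref=chemical.logKAW_ref + d_kaw,
                       logKOA_ref=chemical.logKOA_ref + d_koa,
                       logKOW_ref=chemical.logKOW_ref + d_kaw + d_koa,
                       halflife_ref=hl)

    def sample_deltas():
        dT = rng.uniform(*dT_range)
        dP = rng.uniform(*dPrecip_range)
        return tuple(ClimateDelta(code, dT=dT, dPrecip=dP)
                     for code in world.codes)

    center_deltas = tuple(
        ClimateDelta(code, dT=float(np.mean(dT_range)),
                     dPrecip=float(np.mean(dPrecip_range)))
        for code in world.codes)

    def evaluate(chem: Chemical, deltas) -> float:
        pert = solve_steady_state(compute_d_values(
            chem, apply_climate_scenario(world, deltas), emissions))
        if metric == "concentration":
            return float(np.log10(pert.get(*output, "conc_bulk")))
        base = solve_steady_state(compute_d_values(chem, world, emissions))
        return pert.get(*output, "conc_bulk") / base.get(*output, "conc_bulk")

    groups = {
        "chemical": [evaluate(sample_chemical(), center_deltas)
                     for _ in range(n)],
        "climate": [evaluate(chemical, sample_deltas()) for _ in range(n)],
        "both": [evaluate(sample_chemical(), sample_deltas())
                 for _ in range(n)],
    }
    var_total = float(np.var(groups["both"]))
    rows = []
    for name in ("chemical", "climate"):
        var = float(np.var(groups[name]))
        share = var / var_total if var_total > 0 else 0.0
        rows.append({"input_group": name, "variance": var,
                     "variance_share": min(share, 1.0)})
    explained = sum(r["variance_share"] for r in rows)
    rows.append({"input_group": "interaction_remainder",
                 "variance": var_total,
                 "variance_share": max(0.0, 1.0 - explained)})
    return pd.DataFrame(rows)
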