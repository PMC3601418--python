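# Methods

`climfate` implements two linked model experiments that ask the same
question at two scales: *how much does a plausible end-of-century climate
perturbation change chemical exposure, relative to everything else we are
uncertain about?*

## 1. Multimedia fate model and the partitioning-space scan

### Model

The fate engine is a steady-state Level-III-style fugacity model.  A world
is a set of regions (default four: Arctic `ARC`, northern-Europe-like
`NEU`, southern-Africa-like `SAF`, and a rest-of-world reservoir `ROW`),
each with five bulk compartments (air, freshwater, sediment, soil, surface
ocean).  Concentration is C = Z·f with Z the fugacity capacity
(mol m⁻³ Pa⁻¹) and f the fugacity (Pa); every transport or transformation
process is a conductance D (mol Pa⁻¹ h⁻¹).  At steady state

    (losses − gains) · f = E,

a dense linear system (20×20 for the default world) solved by LU
factorization; iterative methods are unnecessary at this size.  Outputs:
fugacities, bulk and freely dissolved concentrations, masses, the total
inventory, a degradation/burial loss budget, and the overall persistence
P_OV = inventory / total degradation rate.  A forward-Euler dynamic
integrator exists solely to verify the steady state.

Z-values: Z_air = 1/(RT); Z_water = Z_air/K_AW(T); organic-carbon-rich
solids use a Karickhoff-style Koc = 0.35·K_OW (volume basis via solid
density 2400 kg/m³, suspended particles 1500 kg/m³); aerosol uses a
Harner–Bidleman-style particle–gas relation
log Kp = log K_OA + log f_OM − 11.91 with f_OM = 0.2 and particle density
2 g/cm³.  D-values cover degradation (ln2/HL·V·Z), two-film air–water
exchange (air-side 3 m/h, water-side 0.03 m/h), rain dissolution, wet
(scavenging ratio 2×10⁵) and dry (7.2 m/h) aerosol deposition, air–soil
diffusion (boundary layer 1 m/h in series with soil-phase transfer),
soil runoff (40% of rain plus a 2.3×10⁻⁸ m/h solids washoff), and
water–sediment diffusion (10⁻⁴ m/h), deposition (4.6×10⁻⁸ m/h),
resuspension (1.1×10⁻⁸ m/h) and burial (2.2×10⁻⁸ m/h, a permanent loss).
These are conventional multimedia-model values collected in one editable
`TransportParams` table.

Temperature enters through van't Hoff corrections of the partition
coefficients, K(T) = K_ref·exp(−(ΔU·10³/R)(1/T − 1/T_ref)), and Arrhenius
corrections of the degradation rate constants; precipitation enters
through every rain-driven D term.  The thermodynamic triangle
K_OW = K_AW·K_OA is enforced at the reference temperature and preserved at
all temperatures by the internal-energy constraint ΔU_AW = ΔU_OW − ΔU_OA.

### Chemicals

Hypothetical persistent chemicals live on a (log K_OA, log K_AW) grid,
default 4→14 × −6→1 at step 0.5 (315 chemicals), which covers the region
occupied by known POPs (log K_AW −1..−5, log K_OA 7..13) with margin.
ΔU_OW is −20 kJ/mol; ΔU_OA follows the configurable linear map
−(10 + 3.5·log K_OA) kJ/mol, so sorption to octanol is more exothermic for
heavier chemicals; activation energies default to 10 kJ/mol in air and
30 kJ/mol in condensed media; reference half-lives are 1 000 h (air),
10 000 h (water) and 30 000 h (soil, sediment) — persistent by
construction.  A PCB-153-like reference chemical (6.9/−2.0/8.9 triplet,
ΔU_AW = 50 kJ/mol, chemical-specific half-lives) ships as an editable
fixture; its values are conventional literature-style defaults.

### Scenario and what the defaults emulate

The default world is a *reduced* stand-in for a ~30-region global model:
region areas, 1 000 m atmospheric mixing height, 10 cm soil, 20 m
freshwater, 100 m ocean mixed layer, 3 cm sediment, one-week regional air
residence and five-year ocean-box residence are round, conventional
values.  The default climate deltas (ARC +5.0 K/+15% precipitation, NEU
+3.0 K/+10%, SAF +3.5 K/−10%, ROW +3.0 K/0%) sit inside the projected
end-of-century envelopes (+1.1..+6.4 K, ±20% precipitation) with Arctic
amplification.  Emissions go to air of the non-Arctic regions (Arctic
receives 0.1% of a source region); because the model is linear, all ratio
maps are invariant to the emission magnitude.  Seasonality is not
resolved: the fate experiment compares annual-mean steady states.

What passing tests do **not** show about the real system: the reduced
world has no vegetation, snow/ice or permafrost compartments, no gridded
transport, and its Arctic couples to a single source region, so Arctic
ratios are more sensitive than a many-region world would give — the
Arctic air response of the reference chemical (≈+39%) is stronger than a
finer regional resolution would be expected to produce.

### Emission–temperature scaling

Passive volatilization from stockpiles can be scaled as
E(T) = E_ref·exp((ΔU_A·10³/R)(1/T − 1/T_ref)) with ΔU_A negative
(condensation convention), so warming increases the source.  It is OFF by
default: the scenario runs hold primary emissions unchanged.

### Uncertainty screen

A seeded Monte Carlo perturbs (a) chemical inputs — partition coefficients
and half-lives, log-normally with user coefficients of variation — and
(b) climate deltas, uniformly within the projected envelopes, and splits
the variance of a chosen output between the two groups (plus an
interaction remainder).  The default output is the log10 scenario
concentration of Arctic air, so the split compares the chemical-input
uncertainty of an exposure estimate against the climate-scenario signal;
with the default CVs (0.3 partitioning, 0.5 half-lives) the chemical group
dominates.

## 2. Bioenergetics–bioaccumulation experiment

### Model

A round-goby-like ectotherm follows a Wisconsin-style daily energy
balance.  Consumption is p·CA·W^CB·φ_C(T) with a thermal performance
curve φ_C that is zero at/below CT_min, rises smoothly (sin²) to 1 at
T_opt and falls steeply (sin² over the narrower upper interval) to zero
at/above CT_max; respiration is RA·W^RB·Q10^((T−T_ref_b)/10), deliberately
uncapped above CT_max.  Assimilated energy (1 − egestion − SDA/excretion)
converts to growth via the prey/fish energy-density ratio; weight is
clamped at a starvation floor (0.1 g).

Whole-body concentration follows first-order kinetics,

    dC/dt = k1·C_wd + kD·C_diet − (k2 + kE + kG + kM)·C,

with gill uptake k1 from an allometric ventilation rate
(1 400 L d⁻¹ kg⁻⁰·⁶⁵, effective uptake efficiency 0.25) riding on the
respiration multiplier; elimination k2 = k1/(f_lipid·K_OW/1000) with 5%
body lipid; dietary uptake kD from the realized feeding rate times an
assimilation efficiency 1/(3×10⁻⁷·K_OW + 2) that declines with
hydrophobicity; egestion kE = 0.3·kD; growth dilution kG = (dW/dt)/W
(negative while starving — shrinkage concentrates the burden); and
biotransformation kM = ln2/HL_B carried on the same Q10 multiplier as the
other metabolic rates, because biotransformation is enzymatic.  Without
that last coupling, warming raises uptake with no matching metabolic loss
and the model cannot reproduce the damped responses the experiment is
designed to show.

Exposure is constant in time: C_wd = 10⁻⁶ mol/m³ freely dissolved, and by
default the diet is a prey equilibrated with the water column
(C_diet = f_lipid,prey·K_OW·C_wd[mol/L]/1000, prey lipid 3%), so
hydrophilic chemicals carry negligible dietary load and hydrophobic ones
biomagnify.  Each daily step uses the exact exponential update for
piecewise-constant rates, C(t+1) = C·e^(−λ) + u(1 − e^(−λ))/λ, which is
unconditionally stable down to HL_B = 0.1 d and below (an explicit Euler
with sub-stepping would need thousands of sub-steps per day for the
fastest cells).

### Temperature scenario and calibration

The baseline cycle is a Lake-Erie-like sinusoid, mean 13.5 °C, amplitude
10.5 °C, phase 124 d (peak ~24 °C in early August); offsets (+1/+2/+3 °C)
shift the mean only.  Measured round-goby bioenergetic coefficients
are not bundled with the package, so the trait set (CT_min 2 °C, T_opt 26 °C, CT_max 30 °C as
a *functional* consumption limit, Q10 = 2, reference 20 °C) and the
bioenergetic coefficients (CA 0.25, CB −0.27, p 0.4, RA 0.02, RB −0.2)
were calibrated once, before any test was frozen, to reproduce the
qualitative behaviour the experiment is defined by: year-3 weight ordering
baseline < +1 < +2 > +3 (~52 → 62 → 70 → 66 g from a 1 g start), spring
and autumn concentration increases with summer decreases for
fast-metabolizing hydrophobics, and strongly damped responses for
POP-like cells (log K_OW 6–8, HL_B ≥ 100 d).  They were not revisited
afterwards.

### Scan and reductions

The scan covers log K_OW 0–8 (step 1) × HL_B ∈ {0.1, 1, 10, 100, 1000} d —
45 cells — under +2 and +3 °C, five simulated years, with year 3 analyzed.
Season windows are meteorological: spring days 60–151, summer 152–243,
autumn 244–334.  Reported per cell: maximum ratio over spring+autumn,
minimum over summer, annual extremes; ratios > 1 mean more bioaccumulation
under warming.

Known limitation: with Q10-uncapped respiration and a +3 °C growth
response that returns toward baseline, the annual mean uptake under +3 °C
rises ~20% with little extra growth dilution, so the POP-like sub-grid
shows maximum increases around 20% rather than ≤10%; an extensive
pre-freeze parameter exploration found no set consistent with the other
required behaviours that removes this.  The package reports the computed
value as-is.

## Numerical choices and degenerate inputs

* Linear solves: `numpy.linalg.solve`; singular systems and (numerically)
  negative fugacities are rejected with diagnostics.
* Mass balance closes to <10⁻⁹ relative (emissions vs degradation+burial).
* The dynamic verifier refuses steps larger than the fastest compartment
  response time.
* The exponential concentration update switches to its series expansion
  for |λ| < 10⁻¹², and tolerates transiently negative λ (starvation with
  negligible losses).
* Zero-rain worlds make every rain-driven D term exactly zero; zero
  emissions give exactly zero everywhere; zero climate deltas reproduce
  baseline output to machine precision.

## Problem sizes

Default runs are desk-scale by construction: the partitioning scan is
315 chemicals × 2 steady states of a 20×20 system (<1 s); the
bioaccumulation scan is 3 growth simulations and 45×2 kinetic
integrations over 1 825 days (<1 s); the acceptance script recomputes
everything in about a second.
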