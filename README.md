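# oxilake

Mass-balance estimation of **oxic methane production** (OMP) in the
surface mixed layer (SML) of stratified lakes, with Monte Carlo
uncertainty propagation and an empirical scaling of the oxic contribution
to lake morphology.

## The problem

Oxygen-rich lake surface waters are persistently oversaturated in methane
(the "methane paradox"): the observed surface emission cannot always be
explained by transport from anoxic sediments alone. A whole-system budget
of the SML makes the missing source quantifiable. Treating the SML as a
control volume of volume $\forall$ bounded by the lake surface
($A_\mathrm{tot}$), the top of the thermocline ($A_\mathrm{th}$), and the
littoral sediments ($A_\mathrm{sed}$), the balance reads

$$\frac{\partial C}{\partial t}\forall
  = A_\mathrm{th} F_z + A_\mathrm{sed} F_L + P_\mathrm{net}\forall
  - \left(MOx\,\forall + A_\mathrm{tot} F_S\right),$$

with $F_S$ the surface emission, $F_L$ the lateral littoral sediment
input, $F_z$ the diffusive thermocline input, $MOx$ methanotrophic
oxidation (parameterised as a fraction $\alpha$ of production; 0.3 during
stratification, 0 otherwise), and $P_\mathrm{net}$ the internal (oxic)
production solved for as the residual under steady state. Component
uncertainty is propagated by drawing each term from an untruncated normal
distribution (9999 iterations) and applying the closure per draw.

The relative importance of the oxic source is the **oxic methane
contribution**

$$OMC = \frac{100\, P_\mathrm{net}\forall}
  {P_\mathrm{net}\forall + A_\mathrm{sed}F_L + A_\mathrm{th}F_z}\ [\%],$$

which across lakes decays approximately as
$OMC = a\,e^{-b\,A_\mathrm{sed}/\forall}$ — larger lakes have
proportionally less littoral sediment per unit SML volume, so the oxic
source dominates their emission.

The supporting stages are implemented end to end: floating-chamber flux
reduction and the linear $k_{600}(U_{10})$ gas-transfer regression for
wind-based emission estimates; heat-budget basin-scale diffusivity $K_z$
from temperature profile series and the Fick's-law thermocline flux
$F_z = K_z\,\partial C/\partial z$; hypsometric geometry derivation; the
enclosure/open-water comparison that isolates the lateral input; and
emission-weighted global upscaling of the scaling curve over a lake size
inventory. A synthetic-campaign generator with known ground truth
exercises every stage without field data.

## Worked example

```python
import oxilake as ox
from oxilake.core import FluxComponent, FluxComponentSet
from oxilake.massbalance import BalanceConfig

# per-volume budget terms (mean, SD) in nmol l-1 d-1, stratified season
ne = FluxComponentSet(F_S=FluxComponent(90, 52, "nmol l-1 d-1"),
                      F_L=FluxComponent(36, 6, "nmol l-1 d-1"),
                      F_z=FluxComponent(5, 5, "nmol l-1 d-1"))
mc = ox.monte_carlo_pnet(ne, None, BalanceConfig(alpha=0.3), n=9999, seed=1)
print(f"P_net = {mc.mean:.1f} +/- {mc.sd:.1f} nmol l-1 d-1 "
      f"({100*mc.p_positive:.0f}% positive)")

print(f"OMC NE = {ox.omc(752, 372, 56):.1f}%   OMC S = {ox.omc(470, 423, 41):.1f}%")

model = ox.OmcScalingModel(a=87.49, b=7.61)
print(f"50% threshold x* = {ox.omc_threshold(model, 50):.4f} m2 m-3")
```

prints

```
P_net = 69.3 +/- 75.1 nmol l-1 d-1 (82% positive)
OMC NE = 63.7%   OMC S = 50.3%
50% threshold x* = 0.0735 m2 m-3
```

The Monte Carlo mean and spread show that the oxic source is required by
the budget but individually uncertain (82% of draws positive); the OMC
values say that roughly two thirds (larger basin) and half (smaller
basin) of the surface emission originate from oxic production; and the
threshold is the sediment-area-to-volume ratio below which the fitted
scaling curve predicts oxic dominance (>50%).

A full pipeline run on a synthetic campaign:

```sh
oxilake simulate --preset stechlin_s --seed 7 --out campaign/
oxilake report --input-dir campaign/ --out-dir results/ --seed 7
```

writes `results/results.json` (machine-readable, config echoed) and
`results/report.md` (budget table in mol d⁻¹ / kg d⁻¹ / nmol l⁻¹ d⁻¹).

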