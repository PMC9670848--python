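# semifate

Chamber relative-rate kinetics and a two-media (surface water + atmosphere)
first-order fate model for semivolatile contaminants.

The motivating system is 4-isobutylacetophenone (IBAP), the toxic
phototransformation product of the drug ibuprofen (IBP). IBP enters rivers
and lakes from wastewater, is photodegraded there, and a significant
fraction of it becomes IBAP — which, unlike its ionizable parent, is
semivolatile. IBAP therefore partitions between water and air, and its
overall fate can only be judged by treating the two compartments jointly:
how fast is it destroyed in water, how fast does it volatilize, and how
fast does gas-phase •OH remove it once airborne?

`semifate` implements both halves of that analysis as a tested library:

1. **Gas-phase reactivity from chamber decay data.** In a simulation
   chamber every loss process is first order, so log-depletions add. After
   subtracting wall loss, the corrected log-depletions of a target T and a
   reference R exposed to the same •OH field obey

   ```
   ln([T]0/[T]t) − k_WL,T (t − t0) = (k_T/k_ref) · [ ln([R]0/[R]t) − k_WL,R (t − t0) ]
   ```

   so an OLS fit gives the rate-constant ratio k_T/k_ref as its slope,
   regardless of the •OH time profile. Multiplying by the recommended
   k(ref + •OH) yields the second-order rate constant, with the reference's
   10% relative uncertainty propagated in quadrature. Determinations
   against several references are combined by inverse-variance weighting.
   Pseudo-first-order rates k_g = k₂·[•OH] and lifetimes τ = 1/(k₂·[•OH])
   follow, as does the steady-state [•OH] sustained by dark
   tetramethylethylene (TME) ozonolysis, the standard NOx-free •OH source.

2. **Closed-form two-media fate model.** With all rates first order
   (day⁻¹), the network

   ```
   IBP_w  --k_f-->  IBAP_w  --k_vol-->  IBAP_g  --k_g-->  lost
     |                 |
    k_d              k_d'
   ```

   (k_f ≤ k_d: formation is one channel of parent degradation) has the
   Bateman solutions

   ```
   [IBP_w](t)  = exp(−k_d t)
   [IBAP_w](t) = k_f/(K − k_d) · (e^(−k_d t) − e^(−K t)),   K = k_vol + k_d'
   [IBAP_g](t) = k_f k_vol · Σ_i e^(−k_i t) / Π_{j≠i} (k_j − k_i),  k_i ∈ {k_d, K, k_g}
   ```

   all as fractions of the initial aqueous parent. Summary fractions:
   f = k_f/k_d (parent converted to product), v = k_vol/(k_vol + k_d')
   (product removed by volatilization), and per-pathway degradation
   fractions F_j = k_j/(k_vol + k_d') when the aqueous sink is split into
   process rates. Two bounding scenarios ship built in: `fast` (shallow,
   low-DOC, high-nitrate water) and `slow` (deep, high-DOC water), for
   which v ≈ 10% and ≈ 60% respectively — in DOC-rich deep water, most of
   the product escapes to the gas phase before water chemistry destroys it.

A synthetic-data module generates chamber decay pairs and noisy fate
trajectories with the exact statistical structure the fitters assume, so
every stage is testable end to end without instrument data.

## Worked example

```python
import numpy as np
from semifate import (ChamberRecipe, generate_chamber_pair, relative_rate_fit,
                      ratio_to_rate_constant, REFERENCE_COMPOUNDS, OhField,
                      atmospheric_lifetime, load_scenario, fractions, trends)

# a synthetic chamber run: true ratio 1.55 vs a DME-like reference, 2% noise
recipe = ChamberRecipe(true_ratio=1.55, seed=42)
target, reference = generate_chamber_pair(recipe)
fit = relative_rate_fit(target, reference, k_wl_target=3.1e-4)
print(f"slope = {fit.slope:.3f} +/- {fit.sigma_slope:.3f}  (r^2 = {fit.r_squared:.4f})")

k = ratio_to_rate_constant(fit, REFERENCE_COMPOUNDS["DME"])
print(f"k = ({k.value*1e12:.2f} +/- {k.sigma*1e12:.2f}) x 1e-12 cm^3 molecule^-1 s^-1")
print(f"lifetime = {atmospheric_lifetime(k.value, OhField(1.13e6)):.2f} days")

slow = load_scenario("slow")
rep = fractions(slow)
print(f"f = {rep.f:.3f}, v = {rep.v:.3f}")
```

prints

```
slope = 1.523 +/- 0.018  (r^2 = 0.9960)
k = (4.31 +/- 0.43) x 1e-12 cm^3 molecule^-1 s^-1
lifetime = 2.38 days
f = 0.250, v = 0.634
```

The fitted slope recovers the generating ratio 1.55 within its 2σ band; the
derived rate constant carries the 10% reference-uncertainty floor; and in
the slow scenario a quarter of the degraded parent becomes the product, of
which 63% volatilizes.

The same operations are scriptable from the shell:

```sh
semifate synth chamber --seed 42 --true-ratio 1.55 --out runs/
semifate relrate runs/chamber.csv --target target --reference reference \
        --k-wl-target 3.1e-4 --ref-compound DME
semifate gas --k2 4.7e-12
semifate simulate --scenario slow --t-max 300 --out trends.csv
semifate report
```

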