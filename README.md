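# airdisparity

Tools for decomposing and simulating disparities in air-pollution
exposure between demographic groups.

Communities of color and other marginalized groups are systematically
exposed to higher-than-average concentrations of pollutants such as
PM₂.₅ and NO₂. Emission cuts alone shrink the *absolute* exposure gap
but leave the *relative* gap — the spatial bias in where pollution sits
relative to where a group lives — untouched. This package implements the
decomposition that makes that mechanism explicit, and a deterministic
toy city in which policy pathways can be simulated and compared by how
fast they eliminate disparities.

## The decomposition

For a group α, write its population-weighted mean exposure as
PWM_α = Σᵢ Pᵢ,α Cᵢ / Σᵢ Pᵢ,α. The absolute disparity
D_A = PWM_α − PWM_T (concentration units, relative to the total
population T) factors exactly as

```
D_A = E × XF̄ × D_R
```

- **E** — emission rate of the source (e.g. g/s),
- **XF̄** = PWM_T / E — population-average exposure factor, the
  concentration analogue of an intake fraction: how much average
  exposure a unit of emissions produces, set by dispersion and by how
  close the source sits to people,
- **D_R** = (PWM_α − PWM_T) / PWM_T — relative disparity in decimal
  form, the spatial-bias lever (may be negative for an under-exposed
  group).

Each factor is an independently controllable policy lever; the identity
holds in any consistent unit system.

## The illustrative city

A 200×200 cell grid holds two equal-sized groups: total density peaks at
the center and falls linearly with radius, while group α's share of each
cell rises linearly from west to east. A single source at (x₀, y₀)
produces a radial Gaussian field C(x, y) = E/(n·u·H) ·
exp(−[(x−x₀)² + (y−y₀)²]/2σ²) with u = 5 m/s, H = 100 m, σ = 40 cells;
an optional first-order loss multiplies each cell by exp(−k·d/u) to
emulate a shorter-lived pollutant. Three scenario archetypes cut
emissions linearly from 10 g/s to ~0 over 1000 steps:

1. `reduce_E` — the source stays put (only E falls),
2. `reduce_E_XF` — the source also moves north toward the sparse
   periphery (XF̄ falls, the east-side bias and D_R persist),
3. `reduce_E_XF_DR` — the source moves diagonally away from both the
   overburdened east side and the dense center until D_R crosses zero,
   then continues radially outward (all three levers fall).

## Worked example

```python
import airdisparity as ad

city = ad.build_city(n=200)
params = ad.DispersionParams()          # u=5 m/s, H=100 m, sigma=40 cells

results = {}
for kind in ad.SCENARIO_KINDS:
    spec = ad.make_scenario(kind, city, params, n_steps=1000,
                            initial_emissions=10.0,
                            source_start=(150.0, 100.0))
    results[kind] = ad.run_scenario(city, spec, params)

start = results["reduce_E"].group_records("alpha").iloc[0]
print(f"start: E={start.E:g} g/s  XF={start.XF_bar:.3e}  "
      f"D_R={start.D_R:.4f}  D_A={start.D_A:.3e}")

changes = ad.summarize_at_fraction(results["reduce_E_XF_DR"], 0.5)["alpha"]
print("scenario 3 changes at the 50% star:",
      {k: round(v, 2) for k, v in changes.items()})

for kind, res in results.items():
    r = ad.emission_reduction_at_zero_disparity(res, "alpha")
    print(f"{kind:<16} eliminates |D_A| at emission fraction {r:g}")

saving = ad.compare_scenarios(results["reduce_E"],
                              results["reduce_E_XF_DR"], "alpha")
print(f"emission-reduction saving of scenario 3 over scenario 1: {saving:.1f}%")
```

prints

```
start: E=10 g/s  XF=2.756e-06  D_R=0.3465  D_A=9.550e-06
scenario 3 changes at the 50% star: {'E': -50.0, 'XF_bar': -0.55, 'D_R': -100.0, 'D_A': -100.0}
reduce_E         eliminates |D_A| at emission fraction 1
reduce_E_XF      eliminates |D_A| at emission fraction 1
reduce_E_XF_DR   eliminates |D_A| at emission fraction 0.499
emission-reduction saving of scenario 3 over scenario 1: 50.1%
```

At the start, group α is exposed 34.65% above average (D_R = 0.3465).
Halving emissions under scenario 3 has already driven both disparities
to zero (the −100% entries), while scenarios 1 and 2 only reach zero
absolute disparity when emissions themselves are (essentially) fully
eliminated — only a pathway that also reduces the relative disparity
finishes early, here with about 50% less emission reduction.

The same pipeline is available from a shell:

```
airdisparity simulate --scenario reduce_E        --out r1.csv
airdisparity simulate --scenario reduce_E_XF_DR  --out r3.csv
airdisparity report  --results r1.csv --at 0.5
airdisparity compare --a r1.csv --b r3.csv --group alpha
```

plus `decompose` for user-supplied concentration/population rasters
(plain CSV) and `fixtures` for small test grids. Signed percent changes
follow the value, not its magnitude: a relative disparity moving from
0.1 to 0.12 prints as +20%, with |change| reported in a separate column.

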