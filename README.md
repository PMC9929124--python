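# levinsfert

Long-term fertilization experiments in grasslands consistently reshape
plant communities in three ways: species richness falls, initially
dominant species are displaced by ones that were rare or absent, and the
rank abundance diagram (RAD) gets steeper. `levinsfert` implements a
theoretical-community-ecology model that reproduces all three trends from
competition alone: a Levins (colonization) patch-occupancy model with
hierarchical displacement competition and a saturating
competition–fecundity trade-off, in which fertilization is a scheduled
change of the trade-off parameters. It is aimed at theoretical ecologists
who want to compute equilibrium and transient community structure under
this model and run in-model fertilization experiments.

## The model

A habitat of many sites hosts `n` potential species ranked by competitive
ability (`i = 1` best). Sites are empty or hold one species; a superior
colonizer instantly displaces an inferior resident ("displacement
competition"). With `p_i` the fraction of sites held by species `i`,
basal colonization rate `q` and disturbance (extinction) rate `m`:

    dp_i/dt = q f_i p_i (1 − Σ_{j≤i} p_j) − q (Σ_{j<i} f_j p_j) p_i − m p_i

Competitiveness is costly: fecundity rises with competitive inferiority,
saturating at a ceiling `α` with saturation intensity `β`:

    f_i = α (1 − e^(−βi/n)) / (1 + e^(−βi/n)) = α tanh(βi / 2n)

Because each species' equilibrium depends only on better competitors, the
equilibrium follows from a single forward pass over ranks,

    p_i* = 1 − Σ_{j<i} p_j* − (1/f_i)(Σ_{j<i} f_j p_j* + m/q)   if positive, else 0,

and a species can only persist at all when `f_i > m/q`. Fertilization is
modelled as a switch from a baseline trade-off `f0` (α=2, β=4) to a
fertilized one, `f1` (α=3, β=16) or `f2` (α=3, β=18), at a scheduled
time; transient dynamics are integrated with a small immigration term
(1e-10) so extinct species can respond. Communities are summarized as
RADs after excluding species below a 1e-5 relative-abundance detection
threshold.

## Worked example

```python
from levinsfert import (CommunityParams, preset_profile, solve_equilibrium,
                        build_rad, compare_communities, rad_slope, evenness)

params = CommunityParams(q=0.3, m=0.2)
eq0 = solve_equilibrium(preset_profile("f0"), params)   # before fertilization
eq1 = solve_equilibrium(preset_profile("f1"), params)   # after
rad0, rad1 = build_rad(eq0.frequencies), build_rad(eq1.frequencies)
comp = compare_communities(eq0.frequencies, eq1.frequencies, k=8)

print(f"richness before: {rad0.richness}  after: {rad1.richness}")
print(f"slope before:   {rad_slope(rad0):+.4f}  after: {rad_slope(rad1):+.4f}")
print(f"occupied fraction before: {eq0.occupied_fraction:.4f}  after: {eq1.occupied_fraction:.4f}")
print(f"new species: {len(comp.new)}  lost: {len(comp.lost)}  retained: {len(comp.retained)}")
```

prints

```
richness before: 48  after: 31
slope before:   -0.0823  after: -0.1377
occupied fraction before: 0.4120  after: 0.5286
new species: 8  lost: 25  retained: 23
```

Fertilization here drops detectable richness from 48 to 31 species,
steepens the RAD slope (log10 abundance per rank), raises total site
occupancy (the biomass proxy), and brings in 8 species that were
undetectable before — the labeled-SAD reordering signature.

The same experiments are available from the shell:

```sh
levinsfert equilibrium --preset f1 --out eq_f1.csv
levinsfert scenario --before f0 --after f2 --out runs/f0_to_f2
levinsfert sweep --out sweep.csv                 # richness/biomass surfaces
levinsfert fluctuate --magnitude 0.05 --replicates 50 --seed 1 --out fluct.csv
```

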