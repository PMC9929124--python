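# Methods

## Model

`levinsfert` implements a patch-occupancy (Levins/colonization) model of a
community of `n` potential plant species competing for identical sites.
Species are totally ordered by competitive ability; competition is by
displacement, so an encounter between a resident and a superior colonizing
propagule always ends with the superior species holding the site. The
state is the vector of site-occupancy frequencies `p_1..p_n`, governed by

    dp_i/dt = q f_i p_i (1 − Σ_{j≤i} p_j) − q (Σ_{j<i} f_j p_j) p_i − m p_i,

with `q` the basal colonization rate (probability a propagule arrives and
reaches the colony growth stage), `m` the disturbance/extinction rate per
unit time, and `f_i` the species' reproductive rate. The model assumes a
spatially implicit, well-mixed habitat; no site heterogeneity, no age
structure, and a strict, fertilization-invariant competitive hierarchy.

Competitiveness trades off against fecundity through the saturating form
`f_i = α tanh(βi/2n)`, which is identical to
`α(1−e^(−βi/n))/(1+e^(−βi/n))` but numerically stabler at large `β`.
Fertilization is represented as a parameter switch: raising `α` models an
overall fecundity gain, raising `β` models stronger saturation (the gain
concentrating in the initially low-fecundity, competitive species).

## Parameters and defaults

| parameter | meaning | unit | default |
|---|---|---|---|
| `n` | size of the species pool | species | 80 |
| `q` | basal colonization rate | probability per propagule | 0.3 |
| `m` | extinction rate | probability per unit time | 0.2 |
| `α, β` | trade-off ceiling / saturation | rate, dimensionless | presets f0 (2, 4), f1 (3, 16), f2 (3, 18) |
| immigration | constant inflow per species | frequency per time | 1e-10 (dynamics only) |
| switch time | fertilization event | time | 10,000 |
| horizon | end of a scenario run | time | 90,000 |
| threshold | RAD detection cutoff | relative abundance | 1e-5 |

These defaults are the standard parameterization of the fertilization
scenarios; every experiment driver accepts overrides.

## Equilibrium

Because `dp_i/dt` involves only species `j ≤ i`, the fixed point is
computed by one forward pass over ranks, assigning each species the
positive branch of its fixed-point expression or zero. Only species
already assigned a positive frequency contribute to the running sums; this
is forced by consistency with the dynamics' fixed points, since a species
at zero frequency exerts no competitive pressure. Computed frequencies
below 1e-15 are treated as zero — ten orders of magnitude below the
detection threshold — to keep denormal noise out of the running sums. A
species with nonpositive fecundity (possible only through hand-built
profiles) is assigned zero rather than raising. The recursion deliberately
excludes immigration; immigration-dressed equilibria are obtained by long
integration of the dynamics.

## Dynamics

Transients are integrated with SciPy's `solve_ivp` (LSODA by default),
relative tolerance 1e-9 and absolute tolerance 1e-13, tight enough to
resolve frequencies near the 1e-10 immigration floor. The fertilization
switch is handled exactly by stopping the integrator at the event time and
restarting with the new fecundity profile. Sampled states are clipped at
zero (integrator noise can produce tiny negatives). The immigration term
defaults to a constant `+ε` on every derivative — the simplest form that
keeps every species rescuable from extinction — with
`ε (1 − Σ_{j≤i} p_j)` (inflow proportional to accessible sites) available
as an option; at `ε = 1e-10` the two are numerically indistinguishable.
Simulations never force convergence: runs report whatever state the
horizon reaches, which is essential because transient community
composition can remain off-equilibrium for tens of thousands of time
units. The default initial condition for scenario runs is a uniform
inoculum `p_i(0) = 1e-3`, from which the pre-fertilization community
assembles during the 10,000 time units before the switch.

## RADs and community comparison

A rank abundance diagram keeps the species whose abundance clears the
1e-5 threshold and sorts them by decreasing abundance, ties broken toward
the better competitor. The threshold is applied to *relative* abundance
`p_i / Σp` by default; applying it to raw site frequency is available as a
convention switch, and the experiment drivers report richness under both,
because the two differ for species within a factor `1/Σp` of the cutoff.
The relative convention is the default because it is the one under which
the standard scenarios yield 31 (f1) and 28 (f2) detectable species.
Summaries: richness (count), RAD slope (least-squares slope of log10
abundance against rank; more negative = steeper), Pielou-style evenness
(Shannon entropy of the detectable abundances over log richness), and the
biomass proxy (total occupied fraction, i.e. one minus the empty-site
frequency). Labeled-SAD comparisons partition the union of two detectable
sets into new/lost/retained species and track where the top-k
pre-treatment species rank afterwards. The before/after species totals are
the robust quantities here; the new-vs-retained split is recorded but not
given special status.

## Experiments

*Fertilization scenario*: equilibria and RAD comparison for the trade-off
pair, plus the full transient with immigration, snapshot RADs every 1,000
time units after the switch, and richness/occupancy time series.
*Sweep*: equilibrium richness and occupied fraction over an (α, β) grid;
the default grid α ∈ [1.5, 4] × β ∈ [2, 24] (26 × 45) brackets all preset
values with margin. *Decomposition*: equilibria for the four combinations
of baseline/fertilized α and β, separating the fecundity-increment effect
from the saturation effect. *Fluctuation*: each of 50 replicates (a
default chosen as ample for a qualitative majority statement) multiplies
both trade-off curves by independent per-species factors drawn uniformly
from [1−δ, 1+δ] (δ = 0.05), the simplest bounded reading of "±5%"
fluctuation, then recomputes both equilibria; drawing one set of factors
shared by the pre/post pair is exposed as an option (default: independent
draws, since nothing pins the fluctuations to persistent species
identities). All randomness flows from a single seed through
`numpy.random.SeedSequence`, so replicate summaries are exactly
reproducible.

## Numerical choices and verification scales

The equilibrium recursion is O(n) and exact to rounding; its output is
verified as a fixed point of the dynamics (residual < 1e-10) and against
long ODE integration. Convergence of the ODE route to the recursion
equilibrium is algebraic, not exponential — species poised near the
persistence margin decay roughly like 1/t — so the equivalence tests
integrate to 3e7 time units to reach 1e-6 per-species agreement; this
costs well under a second at n = 80. Test oracles are kept independent of
the implementation: derivative checks expand the three summations in
scalar loops, and the brute-force equilibrium oracle formulates the
right-hand side with lower-triangular matrix products instead of running
sums.

## What the model does and does not show

All inputs are synthetic by construction — the model is the object of
study, and there is no data-fitting step. Passing tests establish the
internal consistency of the two computational routes and the qualitative
fertilization trends (richness decline, reordering, slope steepening,
occupancy response, transient richness peak, robustness to trade-off
fluctuation). They do not establish that any real community follows the
displacement-competition mechanism: real fertilization responses involve
trait plasticity, multiple limiting resources, light asymmetry and soil
feedbacks that are outside this model. Transient *shapes* also depend on
unreported numerical details (initial conditions, integrator), so they
should be read qualitatively; the equilibria themselves are exact.

## Known limitations

Exactly one fertilization event per run; no stochastic (finite-site) or
spatially explicit version; no analytic continuous-competitiveness
solution; no fitting of trade-off parameters to empirical fecundity data.
Perturbed trade-offs may be non-monotone, which is supported everywhere
downstream, but profiles with zero or negative fecundity are rejected at
construction.
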