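# webstab

Stochastic bioenergetic food-web simulations for studying how **response
diversity** — variation among species in their responses to environmental
fluctuations — shapes the temporal stability of complex, multi-trophic
communities.

`webstab` is aimed at theoretical ecologists who want to (i) simulate
allometrically parameterized food webs under correlated environmental
mortality noise, (ii) decompose the temporal stability of community biomass
into population-level and asynchrony-level mechanisms, and (iii) quantify,
with a piecewise path model, how environmental stochasticity, response
diversity, species richness and food-web structure drive each mechanism.

## Model

Food webs are drawn from the niche model (rejection-sampled to be
cannibal-free and connected). Biomass dynamics follow the allometric
bioenergetic model: for consumers

dB_i/dt = Σ_j x_i y_i B_i F_ij − Σ_j x_j y_j B_j F_ji / e_ij − x_i B_i − d_{i,t} B_i

and for primary producers

dB_i/dt = r_i B_i G_i − Σ_j x_j y_j B_j F_ji / e_ij − d_{i,t} B_i,

with logistic producer growth G_i, a multi-resource Holling type-III
functional response F_ij with predator interference c, and quarter-power
allometry x_i = 0.88 M_i^(−1/4), d_i = 0.4 M_i^(−1/4), M_i = Z^(TL_i − 1)
(Z the predator–prey mass ratio).

The environment enters through stochastic mortality: d_{i,t} = d_i e^{ε_{i,t}},
where ε is a mean-reverting Ornstein–Uhlenbeck process with stationary
standard deviation σ_e (environmental stochasticity), mixed across species
to a uniform pairwise correlation ρ. Response diversity is 1 − ρ.

Temporal stability of total biomass, S_com = μ_tot/σ_tot, is partitioned
exactly as

S_com = S_pop × φ,  φ = SAE × CPE,  CPE = CPE_env × CPE_int,
S_com = S_pop × PFE × CPE_int with PFE = SAE × CPE_env,

separating population stability (S_pop), statistical averaging (SAE),
environmentally driven compensation (CPE_env, computed on the mortality-flux
matrix B d_i e^ε) and interaction-driven compensation (CPE_int). A factorial
ensemble over (S, C, σ_e, ρ, Z, c) feeds a piecewise structural equation
model with standardized coefficients and total effects, plus a mixed linear
model that decomposes the stability–richness slope.

## Worked example

```python
import webstab

web = webstab.generate_niche_web(S=15, C=0.15, seed=11)
result = webstab.simulate_community(web, Z=10.0, c=0.5,
                                    sigma_e=0.3, rho=0.5, seed=42)
p = webstab.full_partition(result)
print(f"survivors {result.n_survivors}/{web.n_species}")
print(f"S_com {p.s_com:.2f} = S_pop {p.s_pop:.2f} x phi {p.phi:.2f}")
print(f"phi = SAE {p.sae:.2f} x CPE_env {p.cpe_env:.2f} x CPE_int {p.cpe_int:.2f}")
```

prints

```
survivors 11/15
S_com 9.08 = S_pop 4.35 x phi 2.09
phi = SAE 2.78 x CPE_env 0.61 x CPE_int 1.22
```

Of the 15 species, 11 persist. Total biomass is fairly steady (coefficient
of variation 1/9.08 ≈ 11%) even though the average population fluctuates
over twice as strongly (1/4.35): asynchrony among species (φ = 2.09) buffers
the community. Most of that asynchrony is statistical averaging (SAE = 2.78),
dampened by the partially correlated environmental responses
(CPE_env = 0.61 < 1 at ρ = 0.5) and slightly amplified by trophic
interactions (CPE_int = 1.22).

The ensemble and analysis stages run from the shell:

```sh
webstab experiment --seed 1 --out results.csv
webstab analyse --results results.csv --out analysis/
```

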