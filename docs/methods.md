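# Methods

## The dynamical model

`webstab` simulates biomass dynamics of food webs with the allometric
bioenergetic model. Consumers gain biomass from their resources at rate
x_i y_i B_i F_ij, lose biomass to their own consumers, to metabolism
(x_i B_i) and to natural mortality (d_{i,t} B_i). Producers grow
logistically with competition (intraspecific α_ii = 1, interspecific
α_ij = 0.5) toward a shared carrying capacity and lose biomass to herbivory
and mortality; producers carry no explicit metabolic-loss term. The
functional response

F_ij = ω_ij B_j^h / (B0^h + c_i B_i + Σ_k ω_ik B_k^h)

uses uniform preferences ω_ij = 1/(number of resources of i), half-saturation
B0 = 0.5, Hill exponent h = 2 (Holling type III; the sigmoid response keeps
deterministic dynamics free of visible oscillations) and predator
interference c ∈ [0, 1]. Predation losses are divided by the assimilation
efficiency (e = 0.45 when the resource is a producer, e = 0.85 otherwise),
the standard bioenergetic bookkeeping in which the consumer's gain is e
times the biomass removed from the resource. A `literal_assimilation` toggle
multiplies by e instead, for comparison with formulations that typeset the
loss term that way.

All physiological rates follow quarter-power allometry from body masses
M_i = Z^(TL_i − 1): metabolism x_i = 0.88 M_i^(−1/4) (ectotherm constant)
and baseline mortality d_i = 0.4 M_i^(−1/4) (an `equal_mortality` toggle
sets d_i = 0.4 for every species). Trophic levels are prey-averaged,
TL_i = 1 + mean TL of i's resources, solved as a linear system so feeding
loops are handled; producers sit at exactly 1. The predator–prey mass ratio
Z spans 1–100 and is sampled log-uniformly (it ranges over two decades, so a
uniform draw would concentrate mass in the top decade).

The per-producer carrying capacity is standardized by the number of
producers, K_i = (1 + 0.5 (S_prod − 1))/S_prod × K′ with K′ = 10, so the
total basal energy input does not rise trivially with the number of
producers; `standardize_k=False` disables this.

## Environmental stochasticity and response diversity

Mortality fluctuates as d_{i,t} = d_i e^{ε_{i,t}}, which keeps rates
positive. ε is built from independent Ornstein–Uhlenbeck processes with unit
mean-reversion rate and stationary law N(0, σ_e²) — the diffusion is scaled
by √2 so the stationary sd equals σ_e exactly (the `literal_ou_diffusion`
toggle drops the scaling) — simulated by exact discretization
a_{t+Δt} = a_t e^{−Δt} + N(0, σ_e²(1 − e^{−2Δt})), started at stationarity
with a 10-time-unit burn-in. Cross-species correlation is imposed by the
lower Cholesky factor of the equicorrelation matrix (unit diagonal,
off-diagonal ρ), which preserves the marginal sd and produces pairwise
correlation ρ; ρ = 1 uses the rank-one limit (one shared process). Response
diversity is 1 − ρ. Mixing by the covariance matrix itself (entries
ρ σ_e²) is dimensionally inconsistent with ε ~ N(0, σ_e²) and is available
only behind `literal_covariance_mixing`.

σ_e spans 0.1–0.6 on a six-level grid and ρ spans 0–1 on a five-level grid;
the grid spreads (population sd 0.17 and 0.35) are part of the design and
are what the standardized coefficients are expressed against.

## Simulation protocol

Euler–Maruyama-style stepping at Δt = 0.1 (Δt = 0.05 after an instability —
any non-finite value or a >10× single-step biomass change — in which case
the whole run restarts at the finer step), initial biomass uniform on
[0.5, 1], recording every 1.0 time unit. A run integrates 2000 time units;
the last 500 recorded points are analysed. Species dipping below 10⁻⁶ are
set to exactly zero for the rest of the run. If an extinction falls inside
the 500-point window, the run continues for another 1000 time units from
its final state, with the noise stream extended (never regenerated), until
the window is clean. Then disconnected species — consumers with no surviving
prey and, by default, producers with no surviving consumer
(`remove_unconsumed_producers=False` disables the latter, since an
unconsumed producer is dynamically viable) — are zeroed and the run extended
again. Extensions are capped (default 10); runs hitting the cap are flagged
unconverged and excluded from the results table. An optional `rebuild_web`
variant resets preferences, trophic levels and masses on the surviving
sub-web after removals.

The producer-removal rule means a community that loses all consumers
collapses entirely; roughly a third of ensemble runs end this way, so
ensemble medians are reported over runs with survivors. It also makes
one-species outcomes impossible under defaults; the stability partition
still implements the single-survivor convention (φ = SAE = CPE = 1, flagged)
for direct use on external data.

The integration kernel is compiled with numba and checked step-for-step
against the pure-numpy right-hand side in the test suite; runs are
bit-reproducible given the master seed, which is split into independent
streams for web generation, initial biomass and noise so treatments can
share common random numbers.

## Stability partition

On the recorded window (sample sds, ddof = 1; all-zero columns drop out of
the sums): S_com = μ_tot/σ_tot, S_pop = μ_tot/Σσ_i, φ = Σσ_i/σ_tot,
SAE = Σσ_i/√(Σσ_i²), CPE = √(Σσ_i²)/σ_tot. CPE_env applies the CPE statistic
to the mortality-flux matrix B_d[t,i] = B[t,i] d_i e^{ε[t,i]} — the part of
the biomass fluctuation directly forced by the environment — using exactly
the stored noise of the same window; CPE_int = CPE/CPE_env and
PFE = SAE × CPE_env. Every identity holds to 1e−10 by construction and is
asserted on every simulated run. Runs with constant total biomass are
flagged undefined rather than dropped silently.

## The ensemble and the statistical stage

The default ensemble crosses 200 niche webs (S uniform on [10, 60], target C
uniform on [0.02, 0.38], Z log-uniform on [1, 100], c uniform on [0, 1],
σ_e from its grid) with the five ρ levels — 1000 runs, about a minute on one
CPU. (S, C) pairs for which the niche model cannot produce a cannibal-free
connected web within the rejection budget are re-drawn, which truncates the
high-S × high-C corner exactly as rejection sampling must. The ensemble size
was set for stability of the statistical stage: the slope model estimates
fifteen partially collinear coefficients, and with only a few hundred usable
runs their signs vary from seed to seed, while at ~700 usable runs the
standardized path coefficients are reproducible to a few hundredths across
seeds.

The path model is fitted piecewise — one OLS regression per endogenous node —
with standardized coefficients r_δ = b·sd(x)/sd(y). The arrangement:
log S_com on log S_pop and log φ; log φ on log PFE and log CPE_int; and each
of log S_pop, log PFE, log CPE_int on realized richness, weighted trophic
level, connectance, mean interaction strength, σ_e and response diversity,
with Z and c as controls (omnivory is excluded, collinear with trophic
level). Structure covariates are treated as exogenous regressors; the edge
set is a configurable argument. Total effects are path-sums of products of
direct standardized coefficients, computed in closed form from the nilpotent
edge-coefficient matrix. Significance testing is deliberately omitted:
point estimates and sds carry the information at these sample sizes.

The slope model regresses log S_com on the same covariates plus the two-way
interactions of richness with each structure variable, with response
diversity and with σ_e, and the three-way interactions richness × structure
× response diversity and richness × structure × σ_e, with a random
intercept per web (statsmodels MixedLM; falls back to within-web demeaning
when the mixed fit fails). Predictors are centred before products are
formed; the stability–richness slope at a covariate point is the sum of all
richness-bearing coefficients times the centred values of their partner
variables. Variance inflation factors are reported; richness and mean
interaction strength are strongly correlated in the ensemble, so some
interaction terms exceed VIF 3.

## Synthetic results-table generator

`generate_synthetic_table` emulates the output of the experiment stage
without simulation: exogenous columns follow the design grids (σ_e and ρ
exactly, hence grid sds 0.17/0.35) and plausible ranges for the structure
covariates; endogenous columns follow a user-specified acyclic linear
Gaussian system (default: a system with the qualitative structure described
above) plus N(0, noise_sd) residuals. It exists as the oracle for the
statistical stage — OLS recovery of known coefficients — and deliberately
omits features of simulated data: nonlinearity, endogenous structure
covariates, selection through extinction and collapse, and
heteroskedasticity. Passing recovery tests therefore validates the fitting
machinery, not the ecological realism of the fitted model.

## Numerical choices and known limitations

- Sample sds with ddof = 1 throughout; window fixed at 500 points.
- The weighted trophic level is the biomass-weighted mean Σ B̄_i TL_i / Σ B̄_i
  over survivors (`literal_wtl` evaluates the inverse-biomass-weighted sum
  Σ TL_i/B̄_i instead, which is not an average and is kept only for
  comparison).
- Community mean interaction strength averages the time-averaged flux matrix
  I_ij = ⟨x_i y_i B_i F_ij⟩ over its nonzero entries.
- Connectance and trophic levels are static properties of the initial web;
  richness, wTL, omnivory and interaction strengths describe the realized
  (post-extinction) community.
- Assimilation efficiencies are the literature convention (0.45/0.85); the
  original parameterization of this choice is not printed in the sources the
  package was built from, and consumer persistence is sensitive to it — our
  full-collapse rate (~32%) is likely higher than in comparable production
  ensembles.
- At reduced ensemble scale the stability–richness slope at zero response
  diversity is indistinguishable from zero (point estimates ≈ +0.004 at
  ensemble-mean covariates) rather than clearly negative; the dominant
  response-diversity gradient of the slope reproduces robustly. See the test
  suite for exactly what is and is not asserted.
- No demographic stochasticity, temperature dependence, nutrient dynamics,
  adaptive foraging, or structured (within-trophic-level) response
  diversity.
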