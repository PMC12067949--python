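# Methods

## Model

`larvopt` simulates an *Aedes albopictus* metapopulation on a network of N
breeding sites.  Site i carries three state variables: larvae L_i
(individuals), nearby adults A_i (individuals) and larvicide mass c_i
(grams).  Between treatments the dynamics are

    dL_i/dt = α(T_max) A_i − (μ(T_max) + δ_L(T_min)) L_i − L_i²/K_i − τ c_i L_i / V_i
    dA_i/dt = ½ μ(T_max) L_i − δ_A(T_min) A_i − Σ_j m_ij (A_i − A_j)
    dc_i/dt = −κ_c c_i − κ_L c_i L_i / V_i

and a treatment at time t_k adds ξ_k^i γ^i grams to c_i instantaneously
(impulsive control: the application time is negligible against the season).

Assumptions worth keeping in mind:

* **No egg or pupal stages, no diapause.**  Only larvae and adults are
  modeled; half of emerging adults are assumed female.  There is no egg bank
  to reseed the population in spring, so winter survival of the modeled
  stages has to stand in for it (see the vital-rate caps below).
* **Closed system.**  No immigration from outside the site network, no
  mechanical site removal, no predation.
* **Rainfall fills sites; it never flushes larvae out**, and no secondary
  breeding sites form when the main ones dry.
* **Daily piecewise-constant forcing.**  Temperatures and the 21-day
  cumulative rainfall R21 are held constant within each calendar day.
  Development/reproduction rates (μ, α) take the daily maximum temperature;
  death rates (δ_L, δ_A) the daily minimum — each group is evaluated in the
  temperature range where it varies most.

### Water and carrying capacity

V_i(R21) = max(min(ν_R · R21 · area_i, V_i^max), V_floor) litres, with
mm·m² = L making the units consistent; K_i = ν_K V_i.  The printed form of
the volume relation omits the surface area, but the volume is described as
proportional to area and rainfall, and per-site heterogeneity is what the
spatial analyses rest on, so the area factor is kept.  V_floor (default
0.1 L) represents residual moisture: both loss terms divide by V_i, so a
mathematically dry site would be singular.  The floor keeps the
right-hand side Lipschitz; it is configurable.

### Parameters

| symbol | meaning | default | units |
| --- | --- | --- | --- |
| κ_c | intrinsic larvicide decay | 0.089 | day⁻¹ |
| κ_L | larvicide removal by larval ingestion | 0.021 | L·larva⁻¹·day⁻¹ |
| τ | larvicide toxicity | 407.66 | L·g⁻¹·day⁻¹ |
| ν_R | water retention fraction | 0.75 | — |
| ν_K | larvae per litre of water | 106.7 | larvae·L⁻¹ |
| σ | dispersal strength | 12.59 | m·day⁻¹ |
| s | Weibull kernel shape | 1.323 | — (must exceed 1) |
| λ | Weibull kernel scale | 110.3 | m |
| γ^i | per-application dose | {10, 20, 30} | g |
| t_min | minimal spacing between rounds | 21 | days |
| V_floor | residual site moisture | 0.1 | L |
| season | treatment window | Apr 1 – Oct 31 | — |

The larvicide constants come from residual-activity bioassays, the kernel
shape/scale from urban mark–release–recapture work, and the remaining
constants from the source study's calibration; all are overridable through
`ModelParams`.

### Vital rates

The temperature responses are injected, not hard-coded (`VitalRates` holds
four callables).  Two families ship with the package:

* `albopictus_rates()` — Brière curves q·T·(T−T₀)·√(T_m−T) for birth and
  development (optima near 31–33 °C, peak birth ≈ 8 larvae·adult⁻¹·day⁻¹,
  peak development ≈ 0.10 day⁻¹) and saturating U-shaped quadratics for the
  death rates (minima 0.024/0.027 day⁻¹ near 25/23 °C, caps 0.15/0.08
  day⁻¹).  A smooth parameterization consistent with the published
  thermal-performance literature for the species — a documented default,
  not a fit to any specific dataset.
* `synthetic_rates()` — Gaussian bumps and capped quadratics with the same
  magnitudes, used throughout the test-suite so tests never depend on an
  external reference.

The death-rate caps are a deliberate choice: without an egg bank, unbounded
low-temperature mortality drives the population to ~1e-12 adults by April,
after which the entire season is a single exponential ascent and any small
early treatment acts as a kill-switch — a regime in which budget scarcity is
meaningless.  With saturating mortality the population collapses steeply in
winter but recovers by late spring, saturates near carrying capacity by
early summer, and rebounds within weeks of a treatment wave — the regime in
which the timing and allocation questions the package answers actually
arise.

## Numerical scheme

The kill term τ·c_i/V_i spans orders of magnitude (a freshly treated
near-dry site kills larvae at >10³ day⁻¹), so explicit adaptive Runge–Kutta
between impulses is either unstable or extremely slow at the ~10⁴
schedule evaluations the optimizer needs.  The integrator is instead a
two-stage exponential (ETD2-type) fixed-step scheme:

* the dispersal operator (constant over the year) is applied **exactly**
  through a one-time eigendecomposition of its graph Laplacian;
* the linear-in-own-state decay coefficients of L and c (which contain the
  stiff kill and logistic terms) use exact exponential factors, averaged
  between the two stages;
* cross-couplings get a trapezoidal (φ₂) correction;
* days on which the kill rate is large *while larvae are present* are
  subdivided (`stiff_target`, default ≤ 20 units of kill rate per substep)
  so the larvicide-consumption interplay — which sets how fast the product
  is eaten and hence how long a site stays protected — is resolved;
* impulses are exact state resets at the start of the containing day
  (treatment times snap to day boundaries for forcing consistency), and the
  state is clipped at zero (the first stage is positivity-preserving; the
  correction can undershoot by a rounding-level amount).

Fixed points of the scheme coincide exactly with the ODE equilibria, which
is why the constant-forcing equilibrium test passes to four significant
figures at any step size.  Accuracy of the seasonal objective J: the
population traverses ~7 decades with months of sustained exponential
growth, so local truncation error amplifies roughly linearly in time.
Measured on the standard synthetic scenario, halving the default step
dt = 0.05 day changes J by ≲0.05% (uncontrolled) and ≲0.02% (controlled);
a reference adaptive solver at rtol 10⁻⁶ shows the same amplification.  J
values are therefore quoted to ~0.1% at the default settings.  The
optimizer ranks candidates at a coarser fidelity (eval_dt = 0.2–0.5 day,
looser stiffness target) and re-evaluates finalists at full fidelity;
rankings are insensitive at the ≫0.2% J differences that separate
candidate schedules.

## Optimization

Each restart starts from a random feasible schedule (times
rejection-sampled under the 21-day spacing; allocation by shuffled greedy
fill of the budget).  An iteration proposes up to `candidates_per_iter`
mutations of the incumbent — every treatment time jittered uniformly within
a window, then repaired to the season and spacing constraints; a random
fraction of treated site-round slots removed and the budget refilled from
random untreated slots — evaluates J for each, and adopts the best proposal
if it improves.  The jitter window (initial ±30 days) and swap fraction
(initial 20%) decay by 0.95 per iteration.  A restart stops at `max_iters`
or after one full iteration without improvement; the phrase describing the
stopping rule in the source is ambiguous, and the early-stop-on-stagnation
reading is the only one consistent with iterative refinement.  Defaults
(900 candidates, 70 iterations, 25 restarts, keep the best 10) mirror the
study design; tests and the acceptance script use reduced settings
(100 candidates, 20 iterations, 1–2 restarts) to fit interactive budgets.
With identical seeds the search is bitwise reproducible.

## Routine strategy

Four rounds exactly 7 weeks apart, first round within the first 18 calendar
days of the season; at each round, sites are ranked by their *simulated*
larval count at that moment — computed sequentially, so earlier rounds
affect later rankings (the source does not state a measurement protocol;
sequential simulation is the only self-consistent in-silico reading) — and
selected greedily while the per-round budget C/4 admits each site's dose.
Unspent per-round remainder is dropped, not rolled over.

## Statistical analyses

* **Dose-response fits** include the origin (0, 0) as the no-larvicide
  anchor: with it, ordinary least squares reproduces all three published
  linear R² values (0.992 / 0.963 / 0.734) from the published four-point
  reduction curves; without it, none reproduce.  The exponential
  alternative is fixed as ΔJ = a(1 − e^{−bc}) — a saturating decrease
  through the origin; the published exponential R² values are not
  reproducible because the fitted form is not stated, so they are not
  asserted.  Model comparison uses plain Gaussian AIC with identical point
  sets and parameter counts.
* **Climate deviations** at treatment times are percentages of the season
  mean (April–October) of the daily temperature midpoint (T_min + T_max)/2
  or of R21.  The default test is a one-sample Wilcoxon signed-rank of the
  treatment-time deviations against the season *median* deviation (an
  all-zero difference sample returns p = 1); a two-sample Mann–Whitney and
  a seeded Monte-Carlo permutation test are available as flags, because the
  source's pairing is ambiguous.  Percentage deviations are not invariant
  to adding a constant to the underlying variable; deviations in native
  units would be.
* **Treatment-probability GLMM**: treated ~ standardized covariates
  (log V^max, log area, log dose, mean neighbor distance, neighbor count
  within λ, weighted local clustering) with a random intercept over budget
  levels, fitted by a Laplace (profile-likelihood) approximation that
  matches `lme4::glmer` to ~4 decimals on seeded data.  Backward deletion
  drops one covariate per step while the small-sample-corrected AICc
  improves, preferring covariates whose variance inflation factor exceeds
  10 when removing them improves.  Classification accuracy uses the 0.5
  threshold with fitted group intercepts, and a 2×2 confusion matrix is
  reported.  Note the statistical limit of AICc selection: a null covariate
  survives a drop-test iff its Wald z² > 2, i.e. with probability ≈ 16%, so
  exact support recovery is a ~50% event per replicate in a design with
  four null covariates, regardless of sample size.  Sign recovery and
  retention of strong true effects are the reliable properties and are what
  the test-suite asserts per seed.
* **Moran's I** uses inverse-distance weights, zero diagonal,
  row-standardized, with a seeded permutation p-value (999 permutations)
  and null expectation −1/(n−1).
* **Local clustering** is networkx's weighted (geometric-mean/intensity)
  clustering coefficient on the complete graph with weights 1/d normalized
  by the maximum weight.

## Synthetic data

The generators emulate the study system's structure, not any particular
station record:

* **Weather**: Tmin/Tmax sinusoids (means 12/20 °C, amplitudes 7 °C,
  warmest day ≈ July 26) plus Gaussian noise (sd 1.5 °C, Tmax clamped ≥
  Tmin); rainfall as Bernoulli occurrence with a semiannual cycle
  (0.22 ± 0.10, wettest mid-April and mid-October, driest mid-July —
  the Mediterranean mid-summer dry-down) times gamma amounts (shape 0.8,
  scale 12 mm).  Season means land at ≈ 19.5 °C and ≈ 25–65 mm R21
  across seeds, matching the reported year ranges (19.6–21.1 °C,
  26.7–54.6 mm) in central tendency.
* **Sites**: 70 sites around three cluster centers 150 m apart (spread
  25 m), log-normal areas (median 1 m²), V^max = area × log-normal
  effective depth (median ≈ 0.12 m), which makes size covariates positively
  correlated as in real drain inventories; doses assigned by the k-means
  grouping.
* **Allocation datasets** draw treated ~ Bernoulli(logit⁻¹(Xβ + u_budget))
  with known β and fixed random-intercept draws, for parameter-recovery
  testing (the full design reproduces the 25,200-record layout: 70 sites ×
  3 years × 3 budgets × 10 simulations × 4 rounds).

What passing tests on these generators does *not* show: agreement with any
real station's rainfall autocorrelation, real drain geometry, or the actual
magnitude of the published ΔJ values, which depend on the 2020–2022 weather
of the study site and 25-restart optimizations.  The synthetic comparison
establishes the ordering and rough shape of the dose-response, not its
printed numbers.

## Degenerate inputs and tie-breaks

Coincident distinct sites are allowed in the dispersal kernel (rate 0 for
s > 1) but rejected where inverse-distance weights are needed (Moran's I,
local clustering).  Constant values are rejected by Moran's I; an
all-treated or all-untreated response aborts the GLMM with a diagnostic, as
does quasi-complete separation (|β| > 25 or a singular information matrix).
Greedy selections break ties by lowest site index; k-means uses 25 seeded
restarts, making the grouping invariant to site order.

## Known limitations

* No egg/diapause stage: winter dynamics are a surrogate, and multi-year
  carry-over is deliberately absent (each simulated year is independent).
* The objective counts adults only; visitor exposure or disease
  transmission weighting is out of scope.
* Budget accounting covers product mass only, not labor or travel.
* The routine strategy's larval ranking uses simulated abundances; field
  programs would use surveillance counts with observation error.
* J is tolerance-dependent at the ~0.1% level (see the numerical scheme);
  comparisons between strategies are orders of magnitude larger than this.
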