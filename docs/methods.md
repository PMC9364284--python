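# Methods

## Model and assumptions

The package designs and simulates experiments in which `K` treatment arms
are each compared pairwise against one shared control on a binary endpoint,
either in a single stage (`J = 1`, the multi-arm RCT) or in `J ≥ 2` stages
with interim analyses (MAMS). Experimental units are independent
Bernoulli draws: probability `p0` of success under control, `p0 + δ_k` under
treatment `k`. Allocation is equal across the `K + 1` groups and across
stages (the cumulative allocation of each group grows linearly in the stage
index). Unequal allocation, non-binary endpoints and boundary families other
than the O'Brien–Fleming upper / constant lower pair are out of scope.

All probability computations use the asymptotic Gaussian model of the
stagewise pairwise statistics: writing `n_j` for the cumulative per-group
size at stage `j` and `θ_k` for the standardized effect of arm `k`,

* `E[Z_kj] = θ_k √(n_j/2)`;
* `Corr(Z_kj, Z_kj') = √(n_j/n_j')` for `j ≤ j'` (Brownian information
  structure);
* `Corr(Z_kj, Z_k'j) = 1/2` for `k ≠ k'` (shared control), and
  `(1/2)√(n_j/n_j')` across both arm and stage.

## Two effect scales

Two standardized effect scales appear, and they are deliberately different:

* **Design scale** (sample sizing): the effect is routed through the odds
  ratio `OR = p1(1−p0)/(p0(1−p1))` and the ordinal-score (proportional-odds)
  standard deviation, `θ = log(OR)·√((1−Σπ³)/3)` with `π = (p0, 1−p0)`.
* **Simulation scale** (trial replication): the effect is the probability
  `ν = Φ(δ/√(2 p0(1−p0)))` that a treated observation beats a control
  observation, converted to a drift `√2·Φ⁻¹(ν) = δ/√(p0(1−p0))`.

The two scales agree at `δ = 0` and diverge slowly with `δ` and with `p0`
far from 1/2. One visible consequence: a design sized to 90% power on the
design scale can simulate to ~96% power at `p0 = 0.3, δ = 0.3` (simulation
scale larger) but to ~82% at `p0 = 0.7, δ = 0.1` (design scale larger). This
mirror of the sizing-versus-replication pipeline is intentional; the test
suite pins the behaviour rather than hiding it.

## Boundaries, error rate, power

Efficacy bounds follow `u_j = C √(J/j)`; the futility bound is 0 at every
interim. At the final stage an arm is rejected iff `Z_kJ ≥ u_J`; any other
outcome is a non-rejection (internally encoded by setting the stored final
lower bound equal to the final upper bound, which is probability-equivalent).
Futility bounds are binding in every computation.

The familywise error rate is the probability, under the global null, that
*any* arm crosses its upper bound at some stage before crossing its lower
bound. It is evaluated by conditioning on the standardized control-arm path:
given that path the arms are independent, and each arm's non-rejection
probability is a one-dimensional Markov recursion over its continuation
regions. The outer expectation over control paths is a tensor-product
Gauss–Legendre rule over the control's stage increments, truncated at ±6
standard deviations, 20 nodes per dimension by default (the error of the
20-node rule on these smooth integrands is below 1e-6; doubling the nodes
moves the FWER by less than 1e-7). `C` is found with Brent's method on the
strictly decreasing map `C ↦ FWER(C)`; `C` depends only on
`(K, J, α, shapes)` under equal allocation — it is invariant to rescaling
the information sequence — and is cached accordingly.

**Power event.** Power is the *marginal* probability that the designated
effective arm crosses its upper bound before its lower bound, ignoring the
other arms. At `J = 1` this is exactly the classical many-to-one power; the
required per-group size then has the closed form `n = 2((C + z_β)/θ)²`,
which the multi-stage machinery reproduces and the tests assert. (An
alternative power event — "rejected *and* best" — coincides with the
marginal one at `J = 1`; the marginal definition is adopted throughout
because it reproduces the single-stage totals exactly and the multi-stage
totals within rounding.)

**Sample-size search and rounding.** With boundaries fixed, power is
strictly increasing in the stage size `n`; the continuous solution is found
by bracketing and Brent's method, then rounded **up** to the next integer
per group per stage. The reported planned total is `J(K+1)n`; the continuous
solution is also reported because published totals that are not multiples of
the group count necessarily reflect some other rounding convention —
reproduction is therefore asserted at ±1%.

## Trial simulation

The engine simulates per-group cumulative standardized scores from
independent stage increments (so all stage/arm correlations are implied, not
imposed) and applies the stopping rules:

* futility (`Z ≤ l_j`): that arm stops accruing; the trial continues;
* efficacy (`Z ≥ u_j`): the entire trial stops at that interim
  (simultaneous stopping); every arm crossing at that interim is flagged
  rejected — ties need no adjudication for any reported metric;
* the trial also ends when every arm has been dropped, or after stage `J`.

Sample accounting: each treatment group contributes its cumulative
allocation through its own stop stage; the control group accrues until the
trial stops. This makes the best case (everything stops at the first
interim) exactly the stage-1 total `(K+1)n` and the worst case the planned
ceiling `J(K+1)n`.

The **expected sample size** (ESS) is the mean of the per-replicate sample
used; the engine also reports the replicate min/max, the marginal rejection
rate of the designated arm (power), the any-rejection rate (FWER under the
global null) and the mean number of stages executed (used for per-stage
costs).

## Synthetic outcomes

`mamsim.outcomes` generates the raw data the study assumes — i.i.d.
Bernoulli streams per group — and builds the stagewise score statistics
(difference of cumulative proportions standardized by the pooled-null
variance; an unpooled variant differs at O(1/n) and is not exposed). A
degenerate pooled variance forces equal proportions, so the statistic is 0
by convention. This Bernoulli path validates the Gaussian engine: under the
global null the empirical stage and arm correlations match the design
model, and power/FWER agree between the two modes within Monte-Carlo error
at moderate group sizes (≥50 per group per stage).

What the generator does **not** emulate: covariates and stratification,
time trends in the baseline rate, overdispersion or clustering, delayed or
missing responses. Passing tests therefore certify the design arithmetic
and the stopping logic under the stated i.i.d. model, not robustness of the
boundaries to real-world messiness at small samples, where the normal
approximation to binomial proportions is also at its weakest.

## Study pipeline defaults

* Scenario grid: `p0 ∈ {0.10, 0.30, 0.50, 0.70}` × `δ ∈ {0.02, 0.05, 0.10,
  0.15, 0.20, 0.25, 0.30, 0.40}`, cells with `δ ≥ 1 − p0` excluded (30
  feasible cells); hypothesis configurations: global null and least
  favorable configuration.
* Power curves on total sizes `{150, 300, 600, 900, 1200, 1800, 2400,
  3000}` (all divisible into the 5 or 15 allocation cells).
* Misestimation: baseline `p0 = 0.30`, true `δ = 0.20`, assumption error
  grid `ε ∈ {−0.10, …, +0.10}` in steps of 0.01 by default (the grid is a
  package choice, user-overridable; differences are reported against the
  `ε = 0` row). Designs are sized for `δ + ε` and simulated under the true
  `δ`.
* Costs: $1,000 per sampling unit, $0 per stage by default; with a positive
  per-stage cost the RCT is charged one stage and a MAMS case is charged
  its executed stages (J in the worst case, 1 in the best, the simulated
  mean under the LFC).
* Replications: 10⁴ per cell in the test suite and pipeline defaults, 10⁵
  for the per-scenario headline estimates in the acceptance script. At 10⁴
  replicates the Monte-Carlo standard error of a power estimate is ≤0.005
  and of the budget-scenario ESS about 1 unit, which is comfortably inside
  every band the tests assert.
* Randomness: all streams derive from numpy `SeedSequence` spawning with a
  single base seed (default 12,345). Reproducibility is bitwise for
  identical configuration and package version; agreement with other
  implementations of the same design is statistical, not bitwise, because
  generator states are not portable.

## Known limitations

* Equal allocation only; the O'Brien–Fleming/constant boundary pair only.
* Binary endpoints only (the ordinal-score effect scale generalises, but no
  other endpoint family is wired through).
* The familywise computation enumerates `quadrature_points**J` control
  paths; fine for the `J ≤ 3`-stage designs studied here, increasingly
  expensive beyond `J ≈ 4`.
* ESS conventions (control accrual until trial stop) match the printed
  best/worst envelopes exactly; other sample-accounting conventions would
  shift LFC expected sample sizes by a few units.
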