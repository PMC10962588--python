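# Methods

## Setting

`bmams` designs and evaluates multi-arm multi-stage (MAMS) trials in which
`K − 1` active arms are compared against a shared control over `J` stages,
outcomes are normal with known standard deviations `σ_k`, and an *ordering*
among the active-arm means is plausible but not certain — for example doses,
durations or nested combinations of a treatment.  The null hypotheses are
`H0k : θ(k) = μ(k) − μ(0) ≤ 0`.

## Model and posterior

The prior links consecutive treatment means through normal differences:

    μ(1) ~ N(μ0(1), 1/τ01),   δ(k) ~ N(δ0(k), 1/τd(k)),   μ(k+1) = μ(k) − δ(k),

and the control mean has an independent prior `μ(0) ~ N(μ0(0), 1/τ00)`.
Because the differences are normal rather than sign-constrained, the ordering
is *soft*: the prior correlates the arms and expresses how confident one is
in the monotone relationship, but allows reversals.  Marginally the active
means are jointly normal, `N(μ, Ω)`, with `μ_s = μ0(1) − Σ_{r<s} δ0(r)`,
`Ω_ss = 1/τ01 + Σ_{r<s} 1/τd(r)` and `Ω_st = Ω_mm`, `m = min(s, t)`.

With known outcome variances the posterior is conjugate:

    μ_active | data ~ N(Γ_j⁻¹ a_j, Γ_j⁻¹),
    Γ_j = Ω⁻¹ + N_j Σ⁻¹,   a_j = Ω⁻¹ μ + Σ⁻¹ N_j Ȳ_j,

with `N_j` the diagonal of cumulative per-arm sample sizes and `Σ` the
diagonal outcome covariance; the control posterior is the univariate
conjugate normal with precision `τ00 + n_j(0)/σ0²`.  Control and active
block are a priori independent and receive disjoint data, so the posterior
factorizes; the package states this explicitly and uses it in the contrast
probability

    P(θ(k) > 0 | data) = Φ((E μ(k) − E μ(0)) / √(Var μ(k) + Var μ(0))).

All matrix work uses Cholesky (SPD) solves; `Γ_j` is never inverted
entrywise.  Arms that have stopped accruing keep their cumulative data in
every later update; their rows of the data-precision term simply stop
growing, so matrix shapes are stable across stages.

Precisions must be strictly positive; `1e-6` is the conventional
"uninformative" setting (prior SD 1000 mL against outcome SD 340 mL in the
case study).  Exactly-zero precisions are rejected rather than treated as a
limit.

## Decision rule and threshold families

At stage `j` each active arm's `P(θ(k) > 0 | data)` is compared with an
efficacy threshold `η_j` (stop the arm, reject `H0k`, with `≥`) and a
futility threshold `ϵ_j` (drop the arm, with `<`); otherwise the arm and
control continue.  An efficacy stop does **not** terminate the trial — the
remaining arms proceed, so every hypothesis receives a terminal decision and
reject-all power is increased.  At the final stage `η_J = ϵ_J` forces
resolution.

The triangular family is defined on the z-scale,

    z_η,j = z1 · ((1 + t_j)/√t_j) · (√t_1/(1 + t_1)),
    z_ϵ,j = z1 · ((3 t_j − 1)/√t_j) · (√t_1/(1 + t_1)),

with `z1 = Φ⁻¹(η1)` and information fractions `t_j`, mapped back through Φ.
With one interim at `t_1 = 1/2` this gives `z_ϵ,1 = z1/3` and
`z_η,2 = z1 · 2√0.5/1.5`; the case-study's reference rows
(0.9927 → 0.9893, 0.7922) and (0.9906 → 0.9866, 0.7832) and the frequentist
z-bounds (2.482 → 2.340, 0.827) all follow from this shape, which is why the
package adopts it as the canonical parametrization.  A Pocock-style family
(flat efficacy bound on the z-scale; futility interpolating linearly to the
final bound — the futility shape is a package choice, not canonical) is
provided for comparison.

## Analytic operating characteristics

Because the posterior is a linear map of the cumulative means, every
threshold comparison is a half-space event in the observed data: with
`c_i = [Γ_j⁻¹ Σ⁻¹ N_j]_{k,i}`, `γ = [Γ_j⁻¹ Ω⁻¹ μ]_k` and
`c_0 = I_j⁰/(τ00 + I_j⁰)`,

    P(θ(k) > 0 | data) < q   ⇔   S_{k,j} = Σ_i c_i Ȳ_j(i) − c_0 Ȳ_j(0) < U_{k,j}(q),
    U_{k,j}(q) = −γ + μ0(0) τ00/(τ00 + I_j⁰) + z_q √v_jk,

with `v_jk` the posterior-variance sum.  Under true means the `S_{k,j}` are
jointly normal with `Cov(Ȳ_j(i), Ȳ_j*(i)) = σ_i²/n_j*(i)` for `j ≤ j*`
(the classic `√t` group-sequential correlation while an arm accrues; a
frozen arm's cumulative mean stops changing).

The probability of any *joint stopping pattern* (each arm assigned futility
or efficacy at a stage) is therefore a multivariate-normal rectangle
probability of dimension at most `(K−1)·J`.  Crucially the coefficients of
`S_{k,j}` at `j ≥ 2` depend on which arms froze earlier, so each pattern is
evaluated under its own accrual history: arms freeze at resolution, control
accrues while at least one arm is active.  Summing the `J^(K−1)`
all-futility patterns gives the probability of rejecting nothing (hence the
family-wise error rate under a null), the all-efficacy patterns give
reject-all power, and the full set of `(2J)^(K−1)` patterns partitions the
outcome space — the partition summing to 1 is a standing test.  A guard
rejects `(2J)^(K−1) > 1296` (K ≤ 5, J ≤ 3), beyond which enumeration is not
practical.

Rectangle probabilities use `scipy.stats.multivariate_normal.cdf` (Genz
randomized-QMC) with absolute tolerance `1e-7`, `releps=0`, and a fixed
internal seed (`bmams.analytic.QUADRATURE_SEED`), making every integral —
and hence calibration — bit-reproducible.

Error control is *weak*: the family-wise error rate is controlled at the
assumed value of the control mean.  The decision statistics' means depend on
the true `μ(0)` whenever the coefficients do not sum to zero
(`Σ c_i − c_0 ≠ 0`, inevitable once priors are informative), so the scan
over true control means (`run_fwer_scan`) is part of the standard analysis:
with the uninformative prior the inflation is mild (~2.6% at one prior SD),
with an informative control prior it is severe (~28% at three prior SDs).

## Calibration

Given α, β, an alternative `θ`, and null configurations (a global null plus
partial nulls, each at an assumed control mean), the search grids
`z1 = Φ⁻¹(η1)` in steps of 0.001 over [1.5, 3.5] and, at each grid point,
finds the smallest per-arm per-stage `n` meeting the reject-all power target
by bisection (power is monotone in `n`; verified empirically).  Feasibility
requires reject-any ≤ α under each global null and reject-all ≤ α under each
partial null — the partial-null constraint is on rejecting *all* hypotheses,
which is weaker than strong family-wise control.  Raising `z1` tightens all
bounds, so feasibility at the power-minimal `n` is monotone in `z1` and the
optimum (minimal total sample size, ties to the smallest `η1`) is the
smallest feasible grid point, found by binary search with boundary
verification; `full_scan=True` audits the whole grid.

The case-study calibrations are numerically razor-edged: at the reference
`(η1, n)` for the informative variants the reject-all power sits within
about `5e-4` of the 0.80 target, so the chosen integer `n` can move by one
grid cell (±6 patients in the total) depending on the integrator's
tolerance.  At tolerance `1e-7` this package calibrates the uninformative
variant to exactly 102/arm/stage (total 612, `η1 = 0.9935`), the
informative-difference variant to 97 (582) and the informative-control
variant to 81 (486).

## Simulation

`simulate_trial` accrues `n_stage` patients per active arm and per control
per stage in a single batch (no staggered entry), forms cumulative means,
computes exact posterior probabilities through cached linear-form
coefficients (identical to `posterior_update` + `prob_effect_positive`, one
solve per accrual state rather than per replicate), and applies the decision
rule.  Control stops accruing only when every arm has resolved; expected
sample size counts all randomized patients including control, so the maximum
is `K·J·n_stage`.  Replicates use independent substreams spawned from a
master seed (`numpy.random.SeedSequence`), making summaries bit-reproducible
and replicates independently re-runnable.  The frequentist comparator uses
the same mechanics with two-sample z-statistics against explicit z-bounds.

The generator emulates exactly the idealised conditions of the analytic
calculation — normal outcomes, known variances, batch accrual, no dropout,
no staggered entry or overrunning patients, and immediately observed
outcomes.  Passing simulation-vs-analytic tests therefore validates the
probability calculus, not robustness to real-trial complications
(heteroscedasticity, delayed outcomes, accrual drift), which are out of
scope.

## Numerical choices and degenerate inputs

* Threshold ties follow the rule literally: `≥ η` rejects, `< ϵ` drops.
* PSD checks use a relative tolerance of `1e-8`; the joint covariance of the
  path statistics is validated before integration.
* Zero accrual on an arm with a nonzero statistic coefficient raises a
  degenerate-variance error; zero accrual with flat contribution is allowed
  (posterior = prior).
* Rectangle probabilities are clipped to [0, 1]; one-dimensional rectangles
  use the exact normal CDF.
* Default experiment size is 1e4 replicates (the case study's), with a
  1e3-replicate smoke profile on the CLI.

## Known limitations

* Outcome variances are treated as known; unknown-variance and non-normal
  endpoints are not supported.
* Only weak error-rate control at assumed control-mean values; no strong
  family-wise control (and none is claimed).
* Analytic expected sample size is not exposed as public API (simulation
  reports it; the path-probability dump makes the analytic value easy to
  assemble, and the test suite does so as a cross-check).
* Enumeration is exponential in arms and stages; practical limits K ≤ 5,
  J ≤ 3 are enforced.
* Per-hypothesis analytic power sums the patterns in which an arm succeeds;
  it is verified against simulation only, since no closed-form reference
  exists for mixed patterns.
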