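# Methods

This note records the statistical model behind `trialsens`, the numerical
choices made in implementing it, and what the simulation-based checks do and
do not establish.

## Data and model

The observed data per arm `τ ∈ {c, t}` are `(y_τ, m_τ, n_τ)`: observed
failures, non-missing responses, randomized subjects, with
`0 ≤ y_τ ≤ m_τ ≤ n_τ`.  Failure is coded 1 ("dead"), success 0 ("alive").

Missingness follows a selection model: given assignment to arm τ, a success
is missing with probability `π_τ` and a failure with probability `r_τ π_τ`.
Each subject therefore lands in one of four multinomial cells

    fail-observed  p_τ(1 − r_τ π_τ)      fail-missing  p_τ r_τ π_τ
    succ-observed  (1 − p_τ)(1 − π_τ)    succ-missing  (1 − p_τ) π_τ

and the simulator draws exactly this multinomial, once per arm.  Useful
closed forms:

* marginal missingness `q_τ = (1 − p_τ + r_τ p_τ) π_τ`;
* failure rate among observed responses
  `p̃_τ = p_τ(1 − r_τ π_τ) / (1 − q_τ)`.

The ratio `r_τ` is the sensitivity parameter: all observable consequences of
the deviation from MAR are functions of `(r_c, r_t)`, and `r = 1` gives
`p̃ = p` (ignorable missingness) for any `π`.  Models may be specified by
`π_τ` or by `q_τ`; internally `π` is canonical, and a `q` specification is
inverted per arm as `π = q / (1 − p + r p)` (rejected when it would imply a
missingness probability above one).  Expected tables carry real-valued
counts — all design-stage formulas are evaluated at expectations, and
rounding would bias them.

## Plausibility regions

Credible deviations from MAR are described by an ellipse on the
`γ_τ = log r_τ` scale,

    (γ_t + γ_c)² + (γ_t − γ_c)²/(1 − e²) ≤ 4 (log a)²,

major axis along `γ_c = γ_t`: same-signed deviations are considered more
plausible than opposite-signed ones, and reciprocal deviations equally
plausible.  Defaults: `e = 0.9`; presets `a = 2` ("optimistic") and `a = 5`
("skeptical").  The scale must satisfy `a ≥ 1` (an `a < 1` ellipse is the
same region as its reciprocal).  Boundary membership uses a relative
tolerance of 1e-9 on the quadratic form so that exact vertices such as
`(a, a)` test as contained.

## Score test at a fixed sensitivity point

With `logit p_τ = ζ + η z_τ` (`z_c = 0, z_t = 1`), the full-table likelihood
contributes, besides the usual binomial terms, a factor
`(1 + e^{ζ+ηz_τ+γ_τ})^{n_τ−m_τ}` for the missing responses; the remaining
factor depends only on the known `(γ_τ, π_τ)` and cancels from every score,
so it is never computed.  Writing `g(r, p) = r p / (1 − p + r p)` — the
failure probability among missing subjects implied by the model — the
constrained null estimate `p̂(r_c, r_t)` solves

    Σ_τ [ y_τ − n_τ p + (n_τ − m_τ) g(r_τ, p) ] = 0,

the score in the treatment direction is
`U = y_t − n_t p̂ + (n_t − m_t) g(r_t, p̂)` (arm-t counts throughout), its
variance `V = (V_c⁻¹ + V_t⁻¹)⁻¹` with
`V_τ = p̂(1−p̂)[n_τ − (n_τ−m_τ) r_τ/(1−p̂+r_τ p̂)²]`, and the reported
statistic is `Z(r_c, r_t) = −U/√V`, positive when arm t fares better.

Numerical choices:

* **Root finding.**  The score equation is solved by bracketed bisection on
  `[1e-12, 1 − 1e-12]` with 64 iterations; the bracket is valid whenever the
  table has at least one observed failure and one observed success (the
  equation is positive at 0⁺ and negative at 1⁻), and the final residual is
  orders of magnitude below 1e-10 across `r ∈ [1e-12, 1e12]`.  Bisection was
  chosen over Newton for unconditional robustness and because it vectorizes:
  the same kernel evaluates whole grids of `(table, r_c, r_t)` combinations
  at once, which is what makes the region scans and the design double
  minimization cheap.
* **Limits.**  `r = 0` and `r = ∞` are accepted as inputs and handled by the
  analytic limits `g → 0` or `1` and variance kernel `→ 0`; they reproduce
  the worst/best-case imputed complete-case statistics exactly.
* **Identities as checks.**  `Z(1,1)` equals the complete-case `Z̃`
  algebraically; the test suite verifies this to 1e-9 on random tables, and
  verifies the statistic against an independent numerical oracle
  (constrained MLE by scalar likelihood maximization, finite-difference
  score, profile information).

## Region-wide minimization and the robust rule

`H0` is rejected robustly iff `min Z ≥ z_crit` over the region (ties
reject).  The default critical value is `Φ⁻¹(0.975)` at full precision; the
literal 1.96 used in the published decision grids is available as an
argument/flag.  The minimizer evaluates a 101×101 lattice over the region's
bounding box in `γ`-space (filtered to the ellipse, always including the MAR
point and the four vertices) plus 512 boundary points, then polishes the
best boundary angle with a bounded scalar search; the polished value is
never allowed above the raw grid minimum.  In every case examined the
minimum lies on the boundary, but interior points are always scanned rather
than assumed away.  Doubling the resolution moves the worked-example minima
by well under 0.005.

A caution this package's exact minimization surfaced: the minimum over an
ellipse of same-signed-preferring shape is *not* generally at the
anti-diagonal vertex.  Because `p̃` falls roughly linearly in `r` while the
region constrains log-ratios, same-signed pairs far from 1 can produce
larger between-arm distortions than opposite-signed pairs.  Two published
readings that implicitly evaluate the opposite-signed extreme (the
small-trial worst-case rejection probability of about 5.5%, and one
borderline robust-decision entry whose exact region minimum is 1.9499, a
hair under 1.96) disagree with the exact optimum for this reason; the
package reports the exact values.

## Operating characteristics of the complete-case test

Under a true mechanism with `p_t = p_c`, the complete-case test rejects with
asymptotic probability

    Φ((−z σ₀ − μ)/σ₁) + 1 − Φ((z σ₀ − μ)/σ₁),

where `μ = p̃_c − p̃_t`, `σ₀` is the pooled null-style standard error and
`σ₁` the unpooled one, both computed at the expected complete-case sizes
`m̄_τ = (1 − q_τ) n_τ`.  Conditioning on `m̄_τ` ignores the binomial
variation in how many responses are observed; the Monte-Carlo routine (which
simulates full multinomial tables and applies the test, counting undefined
statistics as non-rejections) serves as the oracle for this approximation
and agrees within Monte-Carlo error at the sample sizes used (n ≥ 100,
checked at 10⁴–2×10⁵ replicates).  The worst case over a region is found by
the same lattice-plus-boundary scan with a boundary polish, two-sided
`|Z̃| ≥ 1.96` by default, one-sided available.

## Design

`n*` is the per-group complete-data size: the smallest `n` for which the
complete-case Z evaluated on the no-missingness expected table reaches
`z_{1−α} + z_{1−β}` (closed form `(z_α + z_β)² · 2 p̄(1−p̄)/(p_c − p_t)²`).
The standard design panels pin `n*` to the conventional round values (100,
1000, 10000) for their stated rates, as is customary; the formula lands
within a few percent of these.

Because the distribution of the minimized statistic is intractable,
expectation and minimization are exchanged: for each analysis point
`(r_c, r_t)`, `θ_R(r_c, r_t)` is the minimum over true mechanisms
`(R_c, R_t) ∈ R` of the score statistic evaluated on the real-valued
expected table at size `n*` — with the design's marginal missingness `q`
held fixed across mechanisms, so `π` varies with `R` — and the inflation
factor is `[(z_{1−α} + z_{1−β}) / min θ_R]²`.  The double minimization uses
a 61×61 lattice plus 256 boundary points for both grids (the true-mechanism
axis is processed in chunks for cache efficiency); halving the resolution
moves the minimized θ by less than 0.001 in the standard settings, so no
smooth polish is applied here.  A `rounded_z` option substitutes the
two-decimal z-sum 3.24 to reproduce published arithmetic.  With the MAR
singleton region this machinery recovers the usual `1/(1−q)` inflation to
within under 0.01.

`θ_min ≤ 0` means the desired power is unattainable at any sample size — an
adversarial (true, analysis) pair keeps the one-sided rejection probability
from approaching 1 (indeed drives it toward 0 when `θ_min < 0`); the scan
over ascending region scales locates the crossing (the infinite inflation
boundary).  The expected-table approximation is validated two ways in the
test suite: simulated robust-rejection rates at the computed `n_required`
under the least favorable mechanism recover the target power within
Monte-Carlo error (500 replicates), and for an unattainable design the
simulated rejection rate falls, not rises, as `n` grows from 10³ to 10⁴.

## The simulator and the limits of what the tests show

The synthetic generator draws exactly the model's per-arm multinomial — no
covariates, no dependence between arms, missingness depending on the
outcome only through the two-point `(π_τ, r_τ π_τ)` mechanism, and fixed
`n_τ`.  Passing tests therefore establish internal correctness (formulas,
limits, minimizations, power arithmetic) under the stated model; they say
nothing about misspecification of the selection mechanism itself —
covariate-driven missingness, non-binary outcomes, or regions of a
different shape — which is precisely the structural uncertainty the
plausibility region is meant to bracket, not resolve.

## Defaults

| parameter | default | meaning |
|---|---|---|
| `e` | 0.9 | region eccentricity (same-signed deviations favoured) |
| `a` | 2 / 5 | optimistic / skeptical preset scales |
| `z_crit` | `Φ⁻¹(0.975)` | robust-rule critical value (flag for literal 1.96) |
| `alpha`, `beta` | 0.025, 0.10 | one-sided size, type-II error (90% power) |
| region scan | 101×101 + 512 | analysis-time lattice + boundary points |
| design scan | 61×61 + 256 | double-minimization lattice + boundary points |
| MC replicates | 10⁴ | operating-characteristic simulations |
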