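# Methods

## The law and its parameterization

The half-logistic exponentiated inverse Rayleigh distribution (HLEIRD) is the
type-I half-logistic transform of the exponentiated inverse Rayleigh (EIR)
baseline.  Writing z = (σ/x)², b = 1 − e^{−z} and u = b^θ with θ = αλ:

    F(x) = (1 − u)/(1 + u),
    f(x) = 4 θ σ² e^{−z} b^{θ−1} / [x³ (1 + u)²],
    S(x) = 2u/(1 + u),
    h(x) = 2 θ σ² e^{−z} / [x³ b (1 + u)],
    Q(p) = σ [−ln(1 − ((1−p)/(1+p))^{1/θ})]^{−1/2}.

σ (same units as the data) is a pure scale: X/σ has the law with σ = 1.  The
two shapes enter only through the product θ = αλ.  Consequences, embraced
throughout rather than papered over:

* **Identifiability ridge.**  The parameter triple (σ, α, λ) is not
  identifiable; (θ, σ) is.  `HleirdParams` always recomputes θ = αλ, every
  objective function is a function of (θ, σ) alone (the test suite asserts
  exact invariance under (α, λ) → (cα, λ/c)), and all optimizers work on
  (log θ, log σ).  The reported (α, λ) split is a labeling convention: α = 1
  by default, the caller's start split otherwise.  A "free" three-parameter
  mode exists for comparison with conventional unconstrained fits; the split
  it returns is start-dependent by construction and flagged as such.
* F is increasing in each shape (u = b^θ shrinks as θ grows, since b < 1) and
  decreasing in σ.  The test suite pins these directions.
* The right tail satisfies f(x) ~ 2θσ²x^{−3}, so E[X^r] exists iff r < 2.
  The mean is the only finite integer moment; the moment generating function
  diverges for every t > 0 and is exposed for t ≤ 0 only (a Laplace
  transform computed by quadrature).  The all-orders transform series is
  formal and not exposed as a numeric function.

## Numerical evaluation

All probability computations route through expm1/log1p: b = −expm1(−z),
log b kept explicitly so that u = exp(θ log b) never forms (1 − e^{−z})^θ by
naive powering; 1 − u is computed as −expm1(θ log b).  The quantile evaluates
−ln(1 − r^{1/θ}) as −log1p(−e^{lr}) with lr = ln r / θ, which keeps full
relative accuracy in the far right tail (e^{lr} → 0) where the naive form
rounds to log 1 = 0.

## Series expansions

pdf^ν admits the double expansion Σ_{j,k} c_{j,k} g_k(x) with generalized
binomial coefficients C(−2ν, j) and C(θj + (θ−1)ν, k), computed via the
falling-factorial product (valid for real upper argument).  Two numerical
facts shape the implementation:

* Termwise integration (moments, entropies) produces an outer alternating
  j-series whose terms decay only like (log j)^{−1/2} — not geometrically —
  so partial sums are useless.  The outer series is summed by iterated
  averaging of partial sums (Euler / van Wijngaarden), which reaches ~1e−10
  by a few dozen terms; convergence is certified by agreement between
  successive term counts against `SeriesControl.abs_tol` (default 1e−10,
  caps 200×200 terms), otherwise `SeriesTruncationError` reports the
  attained tail.
* Alternating binomial sums cancel catastrophically in double precision (the
  largest inner term is ~2^a for upper argument a, i.e. one lost digit per
  ~3.3 units of a), so the inner k-sums run in arbitrary precision (mpmath)
  with working precision scaled as 30 + 0.31·a_max digits.  When the inner
  exponent is a nonnegative integer (any integer θ for moments) the inner
  sum is exact and finite; for fractional exponents it is truncated with an
  integral-comparison tail bound on the eventually one-signed k^{−a−1} decay,
  and small θ converges slowly — the error is then reported, never hidden.

The pointwise reconstruction of pdf^ν uses the same Euler averaging in double
precision (the outer ratio u → 1 as x → 0, so plain geometric stopping would
stall near the left tail).

Integrated series values are validated against adaptive-quadrature oracles
(`raw_moment_quadrature`, entropy `method="quadrature"`), which are the
independent authority.  The Rényi/q-entropy series requires order δ > 1/3
(the integral of f^δ diverges otherwise) and uses the octile-normalizing
constant ½ σ^{1−3δ} (δ+k)^{(1−3δ)/2} Γ((3δ−1)/2) obtained by direct
integration of g_k.

## Estimators

All five estimators act on the sorted sample x_(1) ≤ … ≤ x_(n) (n ≥ 3):

| method | objective | notes |
|---|---|---|
| MLE  | max ℓ = Σ log f(x_i) | analytic score; BFGS polish |
| LSE  | min Σ [F(x_(i)) − i/(n+1)]² | plotting positions i/(n+1) |
| WLSE | min Σ w_i [F(x_(i)) − i/(n+1)]², w_i = (n+1)²(n+2)/(i(n−i+1)) | |
| CVME | min 1/(12n) + Σ [F(x_(i)) − (2i−1)/(2n)]² | equals the W statistic |
| MPS  | max (n+1)^{−1} Σ log D_i, D_i = F(x_(i)) − F(x_(i−1)) | F(x_(0)) = 0, F(x_(n+1)) = 1 |

Optimization: coarse grid over log θ ∈ [−3, 5] (17 points) with σ matched to
the sample median through the closed-form median, Nelder-Mead refinement from
the five best grid points (xatol 1e−10, fatol 1e−12), and for the MLE an
analytic-gradient BFGS polish.  The free three-parameter mode uses L-BFGS-B
with the analytic score (MLE) or Nelder-Mead (distance criteria) from the
caller's start.

**Ties and MPS.**  Exact ties make a spacing identically zero and the MPS
objective −∞.  The Cheng–Amin convention is used: a tied spacing's log D_i is
replaced by the log-density at the tied point.  Both embedded fiber datasets
contain exact ties, so this is exercised on real data, not only in tests.

**Uncertainty.**  Wald standard errors and intervals (default level 95%,
standard normal quantile) come from the observed information of the
identifiable (θ, σ) pair (central-difference Hessian of −ℓ at the optimum).
A 3×3 version on (σ, α, λ) is also reported via the pseudo-inverse of the
observed information (finite differences of the analytic score, symmetrized);
that matrix is singular along the ridge, so those standard errors are
split-dependent and carry a `ridge_degenerate` flag.  Standard errors are
attached to MLE results only; the distance estimators report point estimates
and criterion values.

## Goodness of fit and model selection

With u_i = F(x_(i)) at the fitted parameters: the two-sided K-S sup-distance
over both step envelopes, A² = −n − (1/n) Σ (2i−1)[ln u_i + ln(1 − u_{n+1−i})],
and W = 1/(12n) + Σ (u_i − (2i−1)/(2n))² (algebraically the CVME criterion;
cross-checked against an independent implementation in scipy).  Default
p-values are the simple-hypothesis ("case 0") asymptotics with fitted
parameters treated as known — the Kolmogorov limit law, the Marsaglia &
Marsaglia (2004) ADinf approximation (~1e−5 accurate), and the Cramér–von
Mises limit law — because that is the convention under which the published
fiber-strength tables reproduce.  These p-values are optimistic when
parameters are estimated from the same data; a parametric-bootstrap mode is
provided for the honest version and is deliberately not the default.

Information criteria use natural logarithms: AIC = −2ℓ + 2q, CAIC = −2ℓ +
q(ln n + 1), BIC = −2ℓ + q ln n, HQIC = −2ℓ + 2q ln ln n, with q = 3 for the
HLEIRD (the conventional count for the three named parameters, and the one
under which the reference AIC values reproduce) and q = 1 or 2 for the
competitors.  Comparison tables rank by ascending AIC; a failed fit yields a
flagged NaN row ranked last, never a silently missing one.

### Competitor models

Only the EIR baseline has a canonical form here; the one-parameter relatives
follow conventions consistent with it: IRD F = e^{−(σ/x)²} (EIRD with α = 1),
RD F = 1 − e^{−(x/σ)²}, IWD F = e^{−(σ/x)^α}.  The RD convention is
corroborated empirically — its closed-form MLE √(mean x²) reproduces the
published scale 2.5001 on the 20 mm fiber data.  IRD and RD have closed-form
MLEs; EIRD profiles out α given σ and IWD profiles out σ given α, leaving
bounded one-dimensional searches (the IWD route is cross-checked against
scipy's Fréchet fit).  Absolute criteria for IRD/RD/IWD depend on these
parameterization choices and should be read as diagnostics.

## Synthetic data and the Monte Carlo study

The generator is exact inverse-transform sampling X = Q(U) through the
closed-form quantile, seeded per call with no global state; samples are
i.i.d. and exactly model-distributed, so simulation error is purely Monte
Carlo.  What the generator does **not** emulate about real lifetime data:
censoring, rounding/measurement ties (ties in the fiber data are handled, but
the generator never produces them), covariates, or model misspecification —
passing simulation tests therefore demonstrates estimator behaviour under the
model, not robustness off it.

The estimator-comparison study draws, for each cell (truth, n), the same
replicate samples for all methods; each replicate's fit starts at the true
parameter values in the free three-parameter mode.  On the ridge the
individual α, λ columns are meaningful only under such a fixed-start
convention (documented as this package's choice); σ and θ are the robust
quantities.  Defaults mirror the published study conditions: eight truth
triples (σ, α ∈ {0.5, 1} crossed with λ ∈ {1, 2}), n ∈ {20, 40, 70, 100, 150},
10000 replicates.  Methods are ranked per cell by MSE summed over the three
parameters, average ranks on ties, rank sums aggregated into an overall
ordering.  Replicates whose optimizer fails are excluded and counted; a cell
above a 1% failure share is flagged.

Problem sizes in the shipped checks: the acceptance script runs the full
10000-replicate cell for the σ-MSE at n = 150; the test suite runs the same
cell at 1000 replicates with the Monte Carlo tolerance widened by √10, and
the ranking check on a reduced grid (two truths, n ∈ {70, 150}, 300
replicates, all five methods) — sizes chosen so the whole suite stays
desk-scale while keeping Monte Carlo error well below the asserted margins.

## Reproduction notes and known limitations

* The reference analysis of the 10 mm fiber dataset is internally
  inconsistent: its printed MLE log-likelihood exceeds the true maximum of
  the likelihood surface (verified by profiling θ), and its printed
  parameter estimates reproduce neither its log-likelihood nor its K-S
  distance.  This package reports the honest optimum (AIC 124.704 vs the
  printed 123.524; K-S 0.1270 vs 0.1362).  The corresponding acceptance
  tests are left failing with this explanation in their docstrings rather
  than tuned to match.  The 20 mm dataset's log-likelihood and AIC reproduce
  to printed precision; its printed GOF triple is likewise not attainable at
  any single parameter point, and the honest values agree to ~2%.
* Series moments/entropies converge slowly for small fractional θ (inner
  binomial tails decay like k^{−θ(j+1)}); the quadrature routes are the
  recommended fallback there and the series reports its attained tail rather
  than returning a silently wrong value.
* Wald intervals are asymptotic; no profile-likelihood or bootstrap
  intervals are implemented.  Censoring is not supported.  Bayesian
  estimation is out of scope.
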