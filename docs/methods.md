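# Methods

## The model

The package analyses a short multivariate annual series — the motivating
application is a six-indicator panel for Nigeria 2006–2018: malaria
incidence as a disease-burden proxy (BD), life expectancy at birth (LFE),
population growth (POP) and three wealth-creation proxies (EB, TIS, PRR) —
with a reduced-form vector autoregression

    y_t = c + B_1 y_{t-1} + ... + B_q y_{t-q} + u_t,   u_t ~ N(0, Σ_u),

estimated by Bayesian inference.  With 13 annual observations and a VAR(2)
in four variables there are nine regressors per equation for eleven usable
rows: the unrestricted least-squares fit is barely identified and its
residual covariance is singular.  Shrinkage priors are therefore not a
refinement here but the thing that makes the analysis possible.

## Priors

**Minnesota (Litterman).**  Every equation is centered on a random walk
with drift: prior mean 1 for the own first-lag coefficient, 0 for everything
else including the intercept.  The prior covariance `V0` is diagonal; for
the coefficient of lag `l` of variable `j` in equation `i`:

| block                  | prior variance                                   |
|------------------------|--------------------------------------------------|
| own lag (`j = i`)      | `(λ1 / d(l))²`                                   |
| cross lag (`j ≠ i`)    | `(λ1 λ2 / d(l))² (σ_i / σ_j)²`                   |
| intercept              | `(λ3 σ_i)²`                                      |

with decay `d(l) = l^λ4` (harmonic; `λ4 = 1` halves the prior standard
deviation at lag 2, i.e. linear decay) or `d(l) = λ4^{-(l-1)}` (geometric).
`σ_i` is the residual standard deviation of a univariate AR(q) with
intercept fitted to variable `i` (degrees of freedom `T_eff − q − 1`).  The
σ-ratio enters as a ratio of standard deviations squared into the variance,
which makes prior variances unit-consistent.  This is the standard Litterman
layout: a formulation in which a constant `q²` divisor replaced the per-lag
decay would leave the lag-decay parameter λ4 with nothing to act on, so the
lag-indexed form is used, with λ1 scaling the own and cross blocks jointly.

Defaults: λ1 = 0.1 (informative), λ2 = 0.5, λ3 = 0.1, λ4 = 1 — the
tight-overall / nonzero-cross / small-intercept / linear-decay regime the
application calls for.  All four are exposed everywhere.

**Normal-Wishart.**  The conjugate matric-normal–inverse-Wishart family:
`C | Σ ~ MN(B0, Ω0, Σ)` with the same random-walk mean, Kronecker row scale
`Ω0` reproducing the Minnesota per-lag variances (so the implied marginal
variance of an own first-lag coefficient is λ1²), and `Σ ~ IW(S0, ν0)` with
`S0 = diag(σ_i²)`, `ν0 = N + 2`, which makes the prior expectation of the
error covariance exactly `diag(σ_i²)`.  The Kronecker structure cannot carry
a per-pair cross-variable weight, so λ2 is effectively 1 in this family —
a known limitation of the conjugate form, not of the implementation.

## Posterior inference

Three routes, all seeded and reproducible:

1. **Analytic Minnesota posterior** (`compute_posterior_minnesota`): Σ_u is
   held fixed at the diagonal of the OLS residual covariance; each equation
   then has a Gaussian posterior with precision `V0⁻¹ + X'X/σ_i²`
   (generalized ridge).  Coordinates with zero prior variance stay clamped
   at the prior mean.  This is the classic fixed-Σ Litterman computation and
   the oracle the tests check against.
2. **Minnesota Gibbs sampler** (`draw_posterior`, `sigma_mode="gibbs"`,
   the default): the independent-Normal / inverse-Wishart model — the
   Minnesota Normal prior on coefficients, a weakly informative
   `IW(diag(diag(Σ_ols)), N+2)` prior on Σ — sampled by alternating
   `vec(C) | Σ` (Gaussian, full cross-equation GLS precision) and `Σ | C`
   (inverse Wishart).  Draws therefore carry error-covariance uncertainty
   into the impulse-response bands; with Σ fixed instead, every draw shares
   one Cholesky factor and the horizon-0 band collapses to a point, which
   would make the bands uninterpretable as credible sets.  Burn-in defaults
   to 100 iterations from an OLS-based starting point; the conjugate
   i.i.d. routes use none.
3. **Normal-Wishart conjugate draws**: exact i.i.d. sampling,
   `Σ ~ IW(S_n, ν_n)` then `C | Σ` matric normal.

Stacking convention everywhere: each equation's coefficients are
`[intercept, lag-1 block, …, lag-q block]` and the stacked vector
concatenates equations (`vec` of the K×N coefficient matrix).

**Degenerate-sample regularization.**  Where a full positive-definite Σ is
needed for orthogonalization but the OLS residual covariance is singular
(short samples), the package uses the inverse-Wishart posterior mean under a
diagonal prior, `(diag(diag(Σ_ols)) + E'E) / (N + 2 + T_eff − N − 1)`.
This shrinks toward the diagonal, is always positive definite, and converges
to the OLS covariance as T grows.

## Identification and dynamic analysis

Recursive (Cholesky) identification in a configurable variable ordering.
Per posterior draw the moving-average matrices are computed by companion
propagation and right-multiplied by the draw's lower-triangular factor; the
shock size is one standard deviation of the orthogonalized innovation.  The
central estimate is the pointwise posterior **median** (robust to occasional
explosive draws, which are retained rather than rejected; a rejection switch
exists).  Bands are pointwise equal-tailed quantiles; the default level is
90% (5th/95th percentiles) with 95% available — both conventions appear in
applied work and the package supports either rather than guessing one.

FEVD shares are cumulative squared orthogonalized MA coefficients,
normalized per (variable, horizon), summarized as posterior-median shares
renormalized to sum to one.  Ordering-robustness runs reuse the same
posterior draws across orderings (the ordering only enters the
orthogonalization), so differences isolate the identification choice; the
summary records, per shock–response pair, whether the cumulative-response
sign agrees across all orderings.

## Hyperparameter sensitivity

The grid defaults to λ1 ∈ {0.01, 0.1, 0.2}, λ2 ∈ {0.2, 0.5, 1},
λ3 ∈ {0.01, 0.1}, λ4 ∈ {1, 2} (36 points).  Each pair is scored by the
**sign of the cumulative IRF** over the horizon (peak-sign available as an
alternative statistic); consistency is the percentage of grid points whose
sign matches the modal sign — an exact rational number, since the default
scoring uses the deterministic analytic posterior mean with the regularized
Σ.  Influence of each λ is measured by sweeping it alone with the other
three held at the middle element of their sorted grid values and counting
the pairs whose sign is not constant along the sweep; the flagged
hyperparameter is the argmax.  In both the synthetic fixture runs and the
motivating study, overall tightness λ1 dominates.

## Forecast evaluation

The last `h` rows (default 2) are withheld; each model is fitted once on
the remainder and iterated forward `h` steps (direct h-step recursion, not
one-step refitting).  Bayesian point forecasts use posterior-mean
coefficients; averaging the recursion over posterior draws is available
behind a flag.  Scores are per-variable RMSE and MAE on the modeling scale.
RMSE ≥ MAE holds by construction and is asserted on all outputs.

## Synthetic data

`generate_var_panel` simulates exact Gaussian VAR(q) paths; stable DGPs
(companion spectral radius < 1) discard a 50-period burn-in so the sample is
effectively stationary, unstable ones start at the given initial values.
`nigeria_like_fixture` reproduces the documented qualitative trends of the
six indicators — BD falling ~420 → ~280 (minimum 2016) then rebounding, LFE
rising ~49 → ~54, bell-shaped POP on the raw growth-rate scale (~0.026),
steadily rising EB, late-surging TIS, upward PRR — as smooth deterministic
curves plus seeded Gaussian jitter with σ = 1% of each column's range,
clipped at 2.5σ so every shape contract holds for every seed.  The fixture
emulates *shapes*, not the actual World Bank series: passing tests
demonstrate that the machinery behaves correctly on data of this size and
character, not that any substantive conclusion about Nigeria is reproduced.
Variables carry transform tags (`level` / `log` / `growth-rate`) as
metadata; the package applies no transform, since the appropriate convention
is application-dependent.

## Calibration and recovery studies

* **Credible-set coverage** (`bvarburden.calibration`): 200 panels of
  length T = 60 from a fixed stable bivariate VAR(1)
  (`B1 = [[0.5, 0.1], [0.2, 0.4]]`, drift `(0.5, 0.3)`,
  `Σ = [[1, 0.3], [0.3, 0.8]]`); each fitted with the loose Minnesota prior
  (λ = (10, 1, 10, 1)), 1000 Gibbs draws, equal-tailed 95% sets for every
  IRF cell at horizons 0–4, pooled over cells and replicates.  These sizes
  keep the study a minute-scale computation while leaving Monte-Carlo error
  well under the tolerance of interest.
* **Parameter recovery**: persistent near-random-walk VAR(2)
  (own first lags 0.85/0.8, small cross and lag-2 terms) at T = 200 with
  λ1 = 0.2 — the data regime the prior is designed for.  Generic, less
  persistent VAR(2)s sit at a higher noise floor: unrestricted OLS itself
  has a median max-abs coefficient error near 0.13 there, and shrinkage
  toward the random walk cannot repair a misspecified center.

## Known limitations

* Identification is recursive only; sign restrictions and theory-based
  structural schemes are out of scope.
* The Normal-Wishart family cannot express per-pair cross-variable
  tightness (λ2 ≡ 1).
* Lag-order selection uses the Schwarz criterion on the common sample; in
  severely short samples higher orders can be numerically degenerate
  (singular residual covariance) and are reported as unusable (+inf).
* Point forecasts condition on posterior-mean coefficients; full predictive
  uncertainty is only propagated when draw-averaged forecasting is enabled.
* The fixture's jitter model (independent, clipped Gaussian) does not
  emulate serial correlation of measurement error in real indicator series.
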