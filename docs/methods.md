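# Methods

## The scientific problem

Temporary price discounts raise sales of sugar-sweetened beverages (SSBs)
while they run; the open question is whether they also leave a *lagged*
(carryover) elevation of sales after the promotion ends, e.g. through
purchase reinforcement after try-out purchases. `promolag` estimates both
the immediate and the lagged component from weekly, item-level supermarket
transaction records, aggregated to beverage categories.

## Exposure and outcome construction

Sales are standardized to 240 ml servings (the FDA single serving for
beverages), so heterogeneous package sizes are comparable. An item's weekly
percent discount is the percent decrease of its serving-standardized net
price from its serving-standardized baseline (regular) price; a net price
above baseline counts as a 0% discount. The category exposure `x_t` is the
market-share-weighted mean of item discounts, with weights equal to each
item's share of the category's serving-standardized sales that week
(period-wide shares are available as an option: `weights="period"`).
Display and flyer promotion covariates are the same share-weighted
proportions of promoted items; the category regular price is the
share-weighted baseline price per serving. The outcome is the natural log
of total category servings. Weeks with zero servings (never observed at
store scale, but possible in small simulations) are flagged missing and
skipped by the likelihood rather than imputed.

## Model

For one category, with `y_t` the log servings in week `t = 1..T`:

    y_t  = mu_t + beta * K_t + rho * y_{t-1} + gamma' z_t
           + sum_m [ a_m sin(2 pi m w_t / 52) + b_m cos(2 pi m w_t / 52) ]
           + eps_t,             eps_t ~ N(0, sigma_obs^2)
    mu_t = mu_{t-1} + u_t,      u_t   ~ N(0, sigma_rw^2)
    K_t  = x_t + lambda * K_{t-1}

`beta * K_t` is the Koyck geometric distributed lag
`sum_h beta lambda^h x_{t-h}`: `beta` is the effect of a 1% discount on log
sales in the discounting week (x100: approximate percent change of sales),
and `lambda` the weekly decay of the carryover. Three constraint regimes
are supported: `monotonic` (0 < lambda < 1, decaying carryover — the
primary specification), `dip` (-1 < lambda < 0, an oscillating
post-promotion dip), and `none` (lambda = 0, the immediate-only baseline
used in attribution). The random-walk intercept `mu_t` captures local level
shifts and slow trends; one annual harmonic (configurable) captures
seasonality and is never subject to covariate selection; the AR(1) term on
observed lagged log sales is structural. Candidate covariates `z_t` are the
display and flyer proportions, the category regular price, a statutory
holiday indicator, and mean daytime temperature. Continuous covariates are
centered and scaled to unit SD before fitting; the holiday indicator enters
as 0/1 and the discount exposure is never rescaled, so `beta` keeps its
per-1%-discount interpretation.

Initialization choices: the lag state warm-starts at its fixed point under
sustained week-1 exposure, `K_0 = x_1 / (1 - lambda)` (`k0_policy="zero"`
is available; the difference decays like `lambda^t` and is negligible at
T=311). The AR term for week 1 conditions on week 1's own value (the
standard conditional-likelihood treatment of the initial observation).

Priors: `beta ~ N(0, 1)` per percent discount; `lambda` and `rho` uniform
on their constrained intervals; covariate and harmonic coefficients
`N(0, 1)` (covariates are standardized first); `sigma_obs ~ halfN(0, 1)`;
`sigma_rw ~ halfN(0, 0.1)` (a weekly intercept step of 0.1 on the log scale
is already a ~10% level shift, so this is weakly informative at store
scale); `mu_1 ~ N(0, 100^2)` (diffuse). All priors are proper and
overridable through `PriorSet`; individual scalars can be fixed via
`KoyckDLMSpec.fixed`, which removes them from sampling and from the prior.

## Inference

Because the intercept is a *scalar* Gaussian random walk, it is integrated
out exactly by a scalar Kalman filter: the sampler only explores the ~8
structural parameters against the marginal likelihood (prediction-error
decomposition). This dominates schemes that sample the T-dimensional latent
path jointly (centered or non-centered): the posterior dimension drops from
~320 to ~8 and the small-`sigma_rw` funnel disappears entirely. The error
scales are proposed on the log scale with the Jacobian correction — the
documented reparameterization for the random-walk scale. Sampling uses the
emcee affine-invariant ensemble with differential-evolution moves (~5x the
effective sample size of the default stretch move on the correlated
`(beta, lambda, rho)` posterior); runs are reproducible per seed. For each
retained draw the intercept path is then sampled *exactly* from its
conditional posterior by forward-filter backward-sampling (FFBS), giving
full parameter-plus-path draws for attribution.

Diagnostics: split-R-hat and effective sample size are computed with the
walkers treated as chains. This is conservative for ensemble samplers on
short runs (walkers are not independent chains), so R-hat slightly above
1.01 triggers a warning, never an error. Divergence counts are reported as
0 (the ensemble sampler has no divergences in the HMC sense), and
`target_accept` is accepted in `SamplerConfig` for config compatibility but
is inert. Credible intervals use linear interpolation of the empirical
quantile function (numpy's default), frozen for reproducibility.

## Model comparison

WAIC is computed from a pointwise log-likelihood matrix as
`WAIC = -2 (lppd - p_waic)` with the variance-form penalty
(`p_waic = sum_t var_s(ll_st)`, sample variance with `ddof=1`).
The pointwise likelihood is the **marginal one-step-ahead predictive
density** from the Kalman filter, not the density conditional on the
sampled intercept path. The conditional form lets the random walk absorb
residual structure and rewards exactly the models that overfit the path; in
regime comparisons it makes the monotonic model (compensating through a
spuriously negative AR coefficient) indistinguishable from a true
post-promotion-dip model even when the marginal likelihood separates them
by dozens of log units. The marginal form is the natural prediction-error
decomposition for dynamic linear models and restores that separation.

Covariate selection is an exhaustive WAIC search over all subsets of up to
five candidates (32 fits, shared seed), with harmonics, discounting terms
and the AR term present in every candidate. Ties within one Monte-Carlo SE
of the pairwise WAIC difference are broken toward the smaller model, then
lexicographically, so the ranking is independent of candidate ordering.
The lag-regime sensitivity analysis refits the chosen model under the
`dip` constraint and reports both WAICs and the preferred regime.

## Attribution

Per posterior draw, three fitted-sales paths are exponentiated and summed
over weeks: the full model; the same draw with `lambda := 0` and the Koyck
state *recomputed* (immediate effect only); and `beta := 0` (no discounting
effect). Excess-lag servings are the first difference, total
discount-attributable servings the second, and their ratio (x100, on the
posterior-mean scale) is the share of discount-driven sales due to
carryover alone. Both counterfactual arms condition on the *observed*
lagged sales in the AR term (one-step-ahead fitted values), so the contrast
isolates the discounting channel rather than compounding through the AR
feedback; `dynamic_ar=True` switches to full counterfactual propagation,
whose totals necessarily differ. Servings are rounded only at presentation.
The impulse-response summary traces `100 * beta * lambda^h` per draw over
lags `h = 0..10` by default (the visible decay at realistic `lambda` is
complete within 2-3 weeks).

## Synthetic store

The generator emulates six years (311 weeks) of item-level transactions
for five SSB categories (109 soda items, 152 fruit drinks, 36 sports &
energy drinks, 22 coffees & teas, 29 drinkable yogurts) in a single
Montreal supermarket. Category log sales follow exactly the model above
with known parameters; below the category level:

* item market shares are persistent (one Dirichlet draw per item) with
  small weekly log-normal share noise;
* discounts arrive as geometric-duration promotion spells (mean ~2 weeks),
  one depth per spell, synchronized across the category by a log-AR(1)
  "flyer cycle" multiplier on the weekly spell start rate. Spell rates,
  depths and cycle SDs were calibrated jointly so each category's weekly
  percent-discount mean *and* interquartile range match the published
  store values — the between-week exposure spread is what identifies the
  lag coefficient, so matching the IQR (not just the mean) is a study
  condition, not a cosmetic choice;
* display and flyer flags are drawn conditionally on discount status;
* category servings are allocated to items by the weekly share weights and
  converted to units at each item's package volume, rounded to integers by
  default (`round_units=False` gives the exact continuous allocation used
  by the round-trip oracle); item prices are kept in float cents so
  discount depths are exact.

The emitted category series is produced by running the emitted item table
through the aggregation module, so re-aggregation reproduces it by
construction. Baseline per-serving prices, weekly serving magnitudes and
the mean/IQR of discounting match the published store tables; weekly
medians of a single realization wander ~±25% around those targets because
of the random-walk intercept (the long-run level is within ~5%).

The holiday calendar (11 fixed weeks/year) and the Montreal-like
temperature sinusoid are synthetic placeholders — the original data sources
for these covariates are not public. The generator does not model
within-category cannibalization, store switching, shopper behaviour, or
price-elastic share shifts toward discounted items; passing recovery tests
therefore show that the *estimator* works when the model is true at the
category level, not that the model is true of any real store.

## Known limitations and measured behaviour

* Frequentist coverage of the 95% credible intervals at a fixed truth
  (T=311, beta=0.012, lambda=0.4, soda-like store conditions) is ~90%, not
  95%: the random-walk intercept absorbs part of the persistent exposure
  effect, pulling the (beta, lambda) posterior slightly toward zero.
  Posterior widths are otherwise well calibrated (across-replicate SD of
  posterior means matches the average posterior SD). This is a property of
  the model at fixed parameters, not a sampler defect — the conjugate
  degenerate limit matches its closed form to within Monte-Carlo error.
* lambda and rho are partially confounded: an AR(1) coefficient pushed
  negative can mimic a post-promotion dip. Marginal-likelihood WAIC (see
  above) separates the regimes decisively at study scale; conditional WAIC
  does not.
* With near-constant exposure the lag coefficient is unidentified — its
  posterior approaches the prior. Week-to-week discount variability is the
  information source; study-scale profiles carry it by calibration.
* Default sampler settings (4 x 1000 draws after 1000 warmup steps) are
  desk-scale choices; the validation experiments use 2 x 300 to 4 x 750
  draws per fit with 500-2000 warmup steps, and T=311 throughout.
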