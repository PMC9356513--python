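# promolag

Bayesian Koyck distributed-lag dynamic linear models for weekly retail
price-promotion time series.

Price discounts raise sales of sugar-sweetened beverages while they run.
Whether they also leave a *lagged* elevation of sales after the promotion
ends — carryover through purchase reinforcement — is what this package
estimates, for public-health and food-environment researchers working with
item-level supermarket scanner data. It provides:

* **aggregation** of item-level weekly transactions into category-level
  series: serving-standardized sales (240 ml servings), market-share-weighted
  percent discounting, share-weighted display/flyer proportions and regular
  prices, with a keyword filter for artificially sweetened ("diet") items;
* **a Koyck distributed-lag dynamic linear model** of log weekly sales

  ```
  y_t  = mu_t + beta*K_t + rho*y_{t-1} + gamma'z_t + seasonal harmonics + eps_t
  mu_t = mu_{t-1} + u_t                      (random-walk intercept)
  K_t  = x_t + lambda*K_{t-1}                (Koyck lag state)
  ```

  so the effect of a 1% discount `h` weeks ago is `beta*lambda^h`: `beta`
  (x100) is the immediate percent change of sales per 1% discount, `lambda`
  in (0, 1) the weekly decay of the carryover (a `-1 < lambda < 0` regime
  captures a post-promotion dip instead);
* **posterior inference** by ensemble MCMC on the Kalman-marginalized
  likelihood, with the intercept path recovered by forward-filter
  backward-sampling; posterior means/medians and 95% credible intervals;
* **WAIC model comparison**: exhaustive covariate-subset selection and the
  lag-regime sensitivity analysis;
* **attribution**: impulse-response curves `100*beta*lambda^h` and the
  posterior excess servings due to the lagged effect alone vs total
  discounting, from exponentiated fitted-sales counterfactuals;
* **a synthetic store generator** with known ground truth (five beverage
  categories, 311 weeks, realistic item counts, sales magnitudes, discount
  depths and promotion-cycle dynamics) so the whole pipeline is testable
  without proprietary scanner data.

## Worked example

```python
import promolag as pl

# simulate the default five-category store (311 weeks) and pull out the
# lag-bearing category
sim = pl.simulate_scenario(pl.ScenarioConfig(seed=1))
series = sim.series["sports_energy"]          # ground truth: beta=0.012, lambda=0.35

spec = pl.KoyckDLMSpec(covariates=("holiday", "temperature"))
draws = pl.fit(series, spec, pl.SamplerConfig(n_chains=4, n_warmup=2000,
                                              n_draws=1000, seed=1, n_walkers=32))
print(pl.summarize(draws, ["beta", "lam"]).table.round(3))

attr = pl.excess_sales(draws, series, spec)
print(attr.summary.round(0))
print(f"lagged share of discount-attributable servings: {attr.ratio_pct:.1f}%")
```

Output from this exact run:

```
           mean  median   q2.5  q97.5
beta      0.012   0.012  0.010  0.015
beta_pct  1.240   1.246  0.964  1.498
lam       0.364   0.364  0.201  0.509
                   mean   median     q2.5    q97.5
excess_lag      27051.0  26212.0  12734.0  45063.0
total_discount  68569.0  67870.0  53123.0  86234.0
lagged share of discount-attributable servings: 39.5%
```

Read: a 1% category discount lifts sports/energy-drink sales by ~1.2% in
the discounting week (95% CrI 1.0–1.5%), and the carryover decays by
`lambda ~ 0.36` per week — both intervals covering the generating truth
(1.2%, 0.35). Over the six simulated years, ~27,000 servings are
attributable to the lagged effect alone, about 40% of all
discount-attributable servings (for a sustained exposure the lagged share
approaches `lambda`, so ~0.35 is exactly what this ground truth implies).

A YAML-driven end-to-end run (simulate → aggregate → select → fit →
sensitivity → attribute, with a reproducibility manifest) is available as

```bash
promolag run --config config.yaml
```

and each stage is also a subcommand (`simulate`, `ingest`, `aggregate`,
`fit`, `select`, `sensitivity`, `attribute`).

See `docs/methods.md` for the model, priors, inference scheme, WAIC
definition, and what the synthetic store does and does not emulate.

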