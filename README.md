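# bycatchsurv

Survival analysis for pelagic sharks hooked as bycatch on longlines, built
for fishery scientists and stock-assessment analysts working with observer
programme records and pop-up archival satellite tags.

Retention bans only help a shark population recover if hooked animals
actually survive the encounter. That survival has two components: the shark
must be alive when the gear is hauled back (**at-vessel survival**, AVS),
and — if released — it must survive the weeks that follow (**post-release
survival**, PRS). Overall **bycatch survival** is their product,

    BS_i = AVS_i × PRS,

and is what a stock assessment needs. `bycatchsurv` implements the full
estimation chain:

- **AVS** — mixed-effects logistic regression of haul-back fate on fishing
  and environmental covariates (fork length, hook depth, leader length,
  soak time, mainline length, SST; scaled and centred) with a calendar-year
  random intercept, fitted by adaptive Gauss–Hermite quadrature. A fixed
  35-model candidate set is ranked by ΔAIC and Akaike weights
  w_i = exp(−Δ_i/2)/Σ exp(−Δ_j/2); inference uses the best AIC-competitive
  model whose every term is informative (85% CI excluding 0); predictive
  skill is measured by leave-one-out cross-validated AUC.
- **PRS** — fates are classified from each tag's 5-minute depth–temperature
  trace (sinking to the 1800 m emergency release, static on the seafloor,
  ingestion by an endothermic predator, premature detachment, or survival),
  expanded into daily encounter histories, and fed to a Bayesian known-fate
  model, y_it ~ Bern(φ · y_i,t−1) with φ = expit(β₀), sampled by
  random-walk Metropolis (3 × 8000 iterations, 6000 burn-in, thin 10, flat
  prior, Gelman–Rubin R̂ < 1.1). PRS to 28 days is φ²⁸ per posterior
  sample.
- **BS** — Monte Carlo propagation: per region, 1000 replicates × 1000
  simulated sharks with covariates drawn from the region's observed
  mean/covariance (truncated at plausibility bounds), AVS from the selected
  model, PRS drawn from the posterior, fates by Bernoulli draws.

Because raw observer records are confidential, the package ships a
synthetic-data generator with the same statistical structure (truncated
multivariate-normal covariates per region, logistic fates, year random
intercepts, five tag-fate scenarios) plus the published summary tables —
including the 27-tag deployment log, from which the post-release analysis
is exactly reproducible.

## Worked example

```python
import bycatchsurv as b

# Post-release survival from the packaged 27-tag deployment log
histories = b.build_encounter_histories(b.fixtures.tag_deployments())
posterior = b.KnownFateModel(histories).fit_mcmc(seed=1)
print(posterior.summary())
```

```
Known-fate daily survival model (random-walk Metropolis)
  sharks: 27   transitions: 638   deaths: 3
  daily survival phi: 0.9953 (95% CrI 0.9890-0.9992)   MLE 0.9953
  28-day PRS: 0.878 (95% CrI 0.734-0.977)
  R-hat: 0.9982   converged: True   mean acceptance: 0.23
```

Three of the 27 tagged sharks died (days 10, 14 and 23 post-release; one a
tag-ingestion signature), five tags detached early and are censored, and 19
sharks completed the 28-day deployment. Daily survival is 0.995 — matching
the closed-form MLE 635/638 — and survival to 28 days is ≈ 0.88, with a
wide interval reflecting only three deaths.

```python
# At-vessel survival on synthetic records, then regional bycatch survival
records = b.generate_observer_records(b.default_config(seed=0,
                                                       n_per_region=2000))
spec = b.ModelSpec.from_formula("FL + ML + SST + ST")
fits, ranking, scaling = b.fit_candidate_set(records, specs=[spec])
print(fits[0].summary())

result = b.simulate_bycatch(b.summarize_region(records, "NED"),
                            fits[0], posterior, seed=2)
print(result.summary())
```

```
AVS model: FL + ML + SST + ST
Mixed-effects logistic regression (adaptive GH quadrature)
  nobs: 12000   groups: 21   logLik: -6868.159   AIC: 13748.32
  random-intercept SD: 0.0613
  term                        coef        se      2.5%     97.5%
  intercept                 0.9770    0.0251    0.9278    1.0262
  FL                       -0.0681    0.0217   -0.1107   -0.0256
  ML                       -0.1329    0.0218   -0.1757   -0.0901
  SST                      -0.2860    0.0220   -0.3292   -0.2428
  ST                       -0.3374    0.0220   -0.3805   -0.2943

Bycatch survival, region NED: BS = 0.674 (95% interval 0.560-0.753) from
1000 replicates of 1000 sharks [mean AVS 0.766, mean PRS 0.879]
```

All four covariate effects are negative — longer soaks, warmer water,
longer mainlines and larger sharks lower the odds of surviving to the
vessel — with soak time the strongest, and the cool, shallow-set northern
region ends up with higher bycatch survival than the warm southern regions
under the same fleet-wide PRS.

A command-line interface mirrors the library
(`bycatchsurv simulate-data | fit-avs | classify-fates | fit-prs |
simulate-bycatch | run-all | report`); every run writes a manifest with
seeds and file digests so results are exactly reproducible.

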