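# fastdisc

Delay discounting under state manipulations: simulation, Bayesian
estimation, and hypothesis comparison for inter-temporal choice studies.

## The scientific problem

When people are hungry (or otherwise deprived), they devalue delayed
rewards more steeply. The open question is *how far that change reaches*:
does hunger raise the discount rate only for food (the in-domain
commodity), also for money (which can buy food), for everything equally,
or partially for everything? `fastdisc` implements the full analysis
chain for a within-participant study design that can answer this: each
participant completes adaptive inter-temporal choice sessions for three
commodities (food, money, music downloads) in both a control and a fasted
state, and the per-participant changes in log discount rate are compared
across six candidate models of valuation change.

## The models

**Choice level.** Subjective value follows the hyperbolic discount
function V = R / (1 + kD), with k in days⁻¹ (half-life of value = 1/k).
A session of binary choices between an immediate amount A and a delayed
amount B at delay D_B is modelled with a lapse-contaminated probit rule:

    α ~ Exponential(0.1)          # comparison acuity
    ε ~ Beta(1.1, 10.9)           # lapse rate
    log k ~ Normal(log(1/50), 2.5)
    P_t = ε + (1 − 2ε) · Φ((V_B − V_A)/α)
    R_t ~ Bernoulli(P_t)

fitted by MCMC separately per participant × condition × commodity.
Trials are chosen adaptively: the delayed reward is fixed per commodity
(20 for money/music, 10 for food), delays live on a 19-point geometric
grid from 1 hour to 1 year, and each next (A, D_B) maximizes the expected
Shannon information gain about the session parameters.

**Group level.** Per-participant changes Δ_{p,c} = log k(fasted) −
log k(control) are modelled as Cauchy-distributed around per-commodity
group locations; six location patterns (trait-only, in-domain-only,
monetary fungibility, negative spillover, spillover, state-only) are fit
by maximum likelihood and compared by AIC/BIC and Akaike/Schwarz weights
w_m = exp(−½Δ_m) / Σᵢ exp(−½Δᵢ).

## Worked example

```python
import numpy as np
import fastdisc as fd

# simulate one adaptive session for a known responder and refit it
truth = fd.ChoiceParams(log_k=-3.0, alpha=0.5, epsilon=0.01)
space = fd.DesignSpace.for_commodity("money")
session = fd.run_simulated_session(truth, space, rng_seed=1)
post = fd.fit_posterior(session, rng_seed=2)
print(round(post.point_log_k, 2), round(fd.half_life(np.exp(post.point_log_k)), 1))
# -2.98 19.7   -> the 35-trial session recovers log k = -3 (half-life ~20 days)

# six-model comparison on a change table with a clear spillover pattern
rng = np.random.default_rng(0)
deltas = rng.standard_cauchy((50, 3)) * 0.5 + np.array([2.0, 0.5, 0.5])
table = fd.compare_all(deltas)
print(table.loc[table.wAIC.idxmax(), "model"], round(table.wAIC.max(), 3))
# spillover 1.0  -> the generating model takes essentially all the weight
print(round(fd.spillover_ratio(deltas), 1))
# 32.2  -> out-of-domain change is roughly a third of the in-domain change
```

The first block prints the fitted log discount rate (−2.98, true −3.0)
and the implied half-life in days; the second shows the comparison
selecting the generating "spillover" model and the spillover ratio —
mean out-of-domain change as a percentage of the mean food change.

A command-line pipeline wraps the same machinery:

```bash
fastdisc simulate --seed 1 --out run/          # trials.csv + ground truth
fastdisc fit run/trials.csv --out run/         # posterior summaries + deltas
fastdisc compare run/estimated_deltas.csv --out run/   # model comparison
```

Configuration is a flat `key = value` file passed via `--config` (keys:
`n_participants`, `generative_model` and its parameters, `cauchy_scale`,
`choice_alpha`, `choice_epsilon`, `b_food/b_money/b_music`, sampler
settings `n_walkers/n_samples/n_warmup`, `n_bic`, `n_boot`, `ci_level`).
Every output CSV carries `#`-prefixed metadata (version, seed, config
hash).

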