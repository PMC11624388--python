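# cownet

Predicting the day-to-day social networks of dairy cows from indoor
positioning data.

Dairy cows housed in freestall barns form meaningful, individually
differentiated social relationships, and disruptions of those relationships
(illness, regrouping, stress) show up in their spatial behavior. Ultra-wideband
real-time location systems on commercial farms record each cow's position once
per second, which makes it possible to build daily proximity networks and ask:
*how predictable is tomorrow's social network from the last few days?*

`cownet` implements that entire analysis pathway for researchers in applied
ethology and precision livestock farming:

1. **Trajectories** — read per-second `(x, y)` fixes, fill gaps (about a third
   of the day on real installations, mostly single missing seconds) with
   modified Akima (makima) interpolation, and assign every fix to a functional
   barn area (*resting* = cubicles + inner alleys, *feeding* = feed tables +
   outer alleys) from a polygon geometry config.
2. **Contact networks** — count, per dyad and per area, the seconds two cows
   spend within 2.5 m of each other (the span of two adjacent 1.25 m
   cubicles), discard daily contacts shorter than 600 s, and emit one binary
   network per day per area over a fixed roster.
3. **Dyadic covariates** — the additive genetic relationship matrix **A** from
   the pedigree (tabular method), the *kindergarten* indicator (born ≤ 7 days
   apart on the same farm), and parity classes {1, 2, 3+}.
4. **STERGM core** — separable temporal exponential random graph models: each
   transition decomposes into a *formation* phase (new ties given prior
   absence) and a *persistence* phase (retained ties given prior presence),

   P(Y⁺ = y⁺ | Y_{t-1}) ∝ exp(θ⁺·g(y⁺)),  y⁺ ⊇ y_{t-1},
   P(Y⁻ = y⁻ | Y_{t-1}) ∝ exp(θ⁻·g(y⁻)),  y⁻ ⊆ y_{t-1},
   Y_t = Y⁻ ∪ (Y⁺ \ Y_{t-1}),

   with terms for edges, parity endpoint classes and parity homophily, kinship
   and kindergarten edge covariates (model **M1**), plus triangles (**M2**).
   Estimation is pooled maximum pseudolikelihood over 5-day sliding windows —
   exact conditional maximum likelihood for the dyad-independent M1 — and
   simulation is Metropolis–Hastings over free dyads with convergence and
   degeneracy diagnostics.
5. **Prediction & evaluation** — simulate 100 next-day networks per window,
   score them against the observed day with graph correlation (Pearson over
   dyad vectors) and Spearman correlations of degree / betweenness /
   eigenvector centralities, and compare against a naive baseline that
   randomly permutes cow identities 100 times.
6. **Synthetic data** — generators for herds with known pedigree structure,
   network series from known STERGM coefficients, and per-second trajectories
   that provably realize a target contact network, so the full pipeline is
   testable end to end with ground truth.

## Worked example

```python
from cownet import (
    ModelSpec, build_dyad_covariates, enumerate_windows, generate_herd,
    generate_network_series, naive_baseline, predict_scenario,
)
from cownet.synthetic import SimulationConfig

# a 75-cow herd with full sibs, half sibs, kindergarten pairs, parities 1/2/3+
herd, pedigree = generate_herd(75, n_founder_pairs=10, seed=1)
cov = build_dyad_covariates(pedigree, herd, herd["cow_id"])

# 14 daily networks from known coefficients with strongly persistent ties
cfg = SimulationConfig.strong_persistence(n_cows=75, n_days=14, seed=4)
series = generate_network_series(cov, cfg, area="resting")

# fit the first 5-day window, predict day 6, score against the observation
scen = enumerate_windows(14, 5, group="G1", area="resting", model="M1")[0]
summary, fit = predict_scenario(series, cov, ModelSpec.m1(), scen, n_sim=100, seed=0)
print(f"graph corr {summary.graph_corr_mean:.2f} +/- {summary.graph_corr_sd:.2f}")
print(f"degree rho {summary.degree_rho_mean:.2f} +/- {summary.degree_rho_sd:.2f}")

naive = naive_baseline(series[4], series[5], n_perm=100, seed=1)
print(f"naive graph corr {naive.graph_corr_mean:.2f} +/- {naive.graph_corr_sd:.2f}")
print(f"naive degree rho {naive.degree_rho_mean:.2f} +/- {naive.degree_rho_sd:.2f}")
```

Output:

```
graph corr 0.48 +/- 0.02
degree rho 0.71 +/- 0.05
naive graph corr -0.00 +/- 0.02
naive degree rho -0.01 +/- 0.12
```

The fitted model recovers the generator's structure (the window's formation
fit here is `edges -2.75, kinship 1.50, kindergarten 0.80, ...` against true
values −2.6, 1.2 and 0.7) and predicts the next day far above the naive
floor, whose scores sit at their exact permutation expectation of zero. The
positive degree correlation means individual social roles — who is highly
connected — carry over to the predicted day, not just the overall amount of
contact.

A command-line interface mirrors the library:
`cownet simulate`, `cownet contacts`, `cownet fit`, `cownet predict`,
`cownet evaluate`, and `cownet report` (full study: 2 groups × 2 areas ×
9 sliding windows × {M1, M2} = 72 scenario rows). See `cownet --help`.

## Documentation

`docs/methods.md` describes the models, the estimation and simulation
choices, the synthetic-data generators and their limits, and the numerical
conventions (thresholds, tie-breaking, degenerate inputs).
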