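# Methods

This note documents the models and procedures `cownet` implements, the
parameters that matter, the synthetic-data generators, and the numerical
conventions. It is the package's own account of its science; every empirical
number quoted here is computed by the test suite or the acceptance script.

## From positions to daily networks

**Input.** Per-second position fixes `(cow_id, timestamp, x, y)` in meters,
one civil day per file; timestamps ISO-8601 or epoch seconds (auto-detected).
Days are indexed 0–86399 s from local midnight. Duplicate (cow, second) rows
keep the last record; rows outside the requested day are dropped with a
warning.

**Gap filling.** Real installations lose roughly a third of fixes, mostly as
isolated single seconds. Interior gaps are filled by modified Akima (makima)
interpolation applied independently to x(t) and y(t) over the observed
seconds (scipy's `Akima1DInterpolator(method="makima")`; an independently
hand-coded implementation of the makima slope formula serves as the oracle in
the tests). Makima's down-weighting of oscillating slopes keeps filled tracks
from overshooting on dwell segments, which is what cow trajectories mostly
are. Two choices are deliberate:

* leading/trailing gaps take the nearest observed value rather than spline
  extrapolation, which can exit the barn polygon;
* a cow-day with fewer than two observed fixes cannot be interpolated; the
  cow becomes an isolated node for that day, with a warning.

Observed fixes are never altered; after filling, observed + filled = 86400.

**Functional areas.** The barn is a rectangle partitioned into named
polygons: *resting* (cubicles + inner alleys), *feeding* (feed tables + outer
alleys), and *excluded* (areas the cows cannot normally occupy, e.g. the
strip toward the milking parlor). Assignment tests polygons in the order
resting → feeding → excluded with closed boundaries; anything outside all
polygons, including fixes recorded while a cow is out of the pen, is
excluded. Geometry comes from a YAML config; `default_barn()` provides a
74 × 33 m synthetic stand-in preserving the center-resting / flank-feeding
arrangement of the study barn, whose exact floor plan is not published in
machine-readable form.

**Contacts.** A contact-second for a dyad requires Euclidean distance
≤ 2.5 m *and* both cows assigned to the same functional area at that second;
excluded-area seconds never count, and each second counts toward at most one
area. The 2.5 m radius is the span of two adjacent 1.25 m cubicles — the
largest separation of two cows lying side by side. Daily per-area tallies are
thresholded at 600 s (10 min): contacts of *less* than 600 s are treated as
stochastic encounters and dropped, so a dyad at exactly 600 s keeps its edge.
Distances are computed on the interpolated 1-s fixes with no temporal
smoothing, and the hardware's ~0.8 m accuracy is not modeled. Both thresholds
are parameters (`radius`, `min_seconds`) with those defaults.

## Dyadic covariates

* **Kinship** — the additive relationship matrix A by the tabular method in
  parents-first order: `a(i,i) = 1 + 0.5·a(sire_i, dam_i)`,
  `a(i,j) = 0.5·(a(j, sire_i) + a(j, dam_i))`, unknown parents contributing
  zero. The dense A itself is the edge covariate, so the tabular method is
  preferred over A-inverse recursions; inbreeding is handled implicitly
  (diagonal 1 + F). Parents referenced but not listed are treated as founders
  with a warning; cycles raise an error naming the cycle.
* **Kindergarten** — 1 iff two cows were born at most 7 days apart
  (inclusive, a parameter) on the same farm; calves reared together tend to
  maintain preferential contacts as adults.
* **Parity** — classes 1, 2, 3+ (raw parity ≥ 3 maps to 3+).

The kinship matrix from any valid pedigree is symmetric positive
semidefinite (property-tested via smallest eigenvalue ≥ −1e−8), and
restricting a pedigree to the roster's ancestors leaves the roster submatrix
unchanged.

## The STERGM

A transition between consecutive daily networks is decomposed into the
formation network y⁺ = y_{t−1} ∪ y_t and the persistence network
y⁻ = y_{t−1} ∩ y_t. Formation models new ties on dyads empty at t−1;
persistence models tie survival on dyads present at t−1 (the
positive-persistence formulation — the coefficient is the attraction of
keeping a tie, not a dissolution rate). The two phases are conditionally
independent given y_{t−1} and recompose as y_t = y⁻ ∪ (y⁺ \ y_{t−1}).

**Terms.** `edges` (intercept); endpoint counts for parity classes 2 and 3+
(class 1 reference); a same-parity homophily indicator; kinship and
kindergarten as edge covariates; `triangles` (change statistic: the number of
common neighbors of the dyad). M1 = exogenous terms only (dyad-independent);
M2 = M1 + triangles. The phrase "effects of parity of both cows" is
ambiguous between factor and homophily parameterizations, so both endpoint
and homophily terms are included by default and each is individually
droppable; both phases get the full term set by default, also configurable.

**Estimation.** Pooled maximum pseudolikelihood: for each window (default 5
consecutive days → 4 transitions), every (transition, free dyad) pair
contributes a logistic-regression row — response the dyad's phase-target
state, predictors the change statistics evaluated in the phase-target network
conditional on its remaining observed state. For dyad-independent term sets
the pseudolikelihood *is* the exact conditional likelihood, so M1's MPLE is
the exact MLE (verified against direct likelihood maximization over full
enumeration on 5-node fixtures, agreement to 1e−6). For M2 the MPLE is the
standard approximation; an MCMC-MLE refinement is an extension point, not
implemented. Fits are flagged non-converged on separation (including constant
responses), non-finite standard errors, or optimizer failure — flagged, not
raised — and non-converged windows are excluded from accuracy comparisons. A
window with zero free dyads in a phase (e.g. a completely empty series) is an
error.

**Simulation.** Metropolis–Hastings with uniform single-dyad toggle
proposals over the phase's free dyads, started at y_{t−1}: 20 full burn-in
sweeps (one sweep = one proposal per free dyad), one sample per independent
chain, per-sample RNG streams derived from the root seed by counter. The
numba-compiled kernel needs only the precomputed exogenous linear predictor
plus a common-neighbor count when triangles are active. Sampler exactness is
verified two ways: per-dyad tie frequencies against closed-form logistic
probabilities for dyad-independent models, and total-variation distance
< 0.05 against the fully enumerated ERGM distribution on 4-node M2 models
with 10,000 draws.

**Degeneracy.** ERGMs with triangle terms can concentrate on near-empty or
near-complete graphs. `assess_degeneracy` simulates at the fitted
coefficients and flags the fit when any sufficient statistic's simulated mean
sits more than 3 simulated SDs from its observed window mean, or when
simulated networks are near-uniform (mean density outside [0.05, 0.95]); fits
with non-finite standard errors are flagged without simulating.

## Prediction and evaluation

Sliding windows: days [d, d+4] fit the model, day d+5 is the target; 14 days
give 9 windows per group × area, 36 scenarios over 2 groups × 2 areas. Per
scenario, 100 networks are simulated from the window's last observed day and
scored against the observed target day:

* **graph correlation** — Pearson correlation of the strict-upper-triangle
  dyad vectors (equivalently, covariance of the adjacency matrices over their
  SDs); undefined for an empty or complete network, in which case the score
  is NaN with a warning and is dropped, counted, from summaries;
* **centrality rank correlations** — Spearman (average ranks on ties) of
  per-node degree, betweenness (igraph's exact algorithm), and eigenvector
  centrality (principal eigenvector of the adjacency; on disconnected graphs
  this localizes on the dominant component, and an empty graph returns a
  constant vector → NaN sentinel).

The **naive baseline** uniformly permutes node labels 100 times, preserving
structure while destroying identity. By default the target-day network's
labels are permuted and scored against its unpermuted form; a switch permutes
the previous day's network instead (the wording "identifications of the
consecutive networks were permuted" supports either; their expectations
coincide). The exact expectation of both scores under uniform relabeling is
0 — verified by enumerating all permutations at small n; note the value
−1/(n−1) sometimes quoted for permuted self-correlations applies to pairs of
coordinates within one permutation, not to the mean score here.
Summaries report per-scenario means and SDs across the 100 networks (as in
box-plot presentations); no pooled tests or multiplicity corrections.

Pairwise correlograms (graph correlation for every day pair, tabulated by
lag) show whether the series is dynamic: day-to-day correlations below ~0.2
and decaying with lag motivate short windows — window lengths are a
parameter, default 5.

## Synthetic data: what it emulates, what it does not

**Herds.** Three generations: founders, a middle generation, and the herd.
Deterministic construction guarantees full-sib pairs (a = 0.5), paternal
half-sibs (0.25), birth batches of four within 3 days on a shared farm
(kindergarten dyads), and parities covering all three classes — so every
model term has variation (coverage is property-tested).

**Network series.** Day 0 is Erdős–Rényi at `initial_density`; later days
are STERGM transitions sampled with the *same* Metropolis–Hastings machinery
the inference uses (one shared implementation avoids oracle/implementation
drift; the independent check is the exhaustive-enumeration oracle at ≤ 5
nodes). Default coefficients put the stationary density near 0.1 and the
day-to-day autocorrelation near 0.17 — sparse, weakly persistent networks of
the kind observed on farms (consecutive-day graph correlations under ~0.2).
A `strong_persistence` variant (persistence intercept +1.1, tie survival
~0.75) produces strongly autocorrelated series for calibration runs where
next-day structure is genuinely predictable.

**Trajectories.** Bout-based movement, not a gait model: each cow owns one
anchor point per area (grid spacing ≥ 3.2 m, ≥ 0.6 m inside polygon
boundaries, ±0.15 m per-second jitter). Target-network edges are scheduled as
700-s meetings in vertex-disjoint rounds (greedy matching peel) at the
lower-indexed cow's anchor; afterwards cows alternate between their two
areas in 1800-s bouts. Geometry guarantees every tied dyad accrues ≥ 600
same-area contact seconds and every untied dyad accrues none, so the 0%
missingness round trip through interpolation and contact extraction is exact
(asserted in the tests, which also recover ≥ 99% of edges at 33.34%
missingness — in the runs performed, recovery there is exact as well).
Missingness deletes whole seconds per cow in runs with geometric lengths
(p = 0.85, so ≥ 80% of runs are single seconds, matching the observed
dropout pattern), runs separated by at least one observed second.

Passing tests on these data show the machinery is correct under the model's
own assumptions. They do not show robustness to what the generator omits:
positional noise (~0.8 m on real hardware), gradual movement between areas,
milking-parlor absences, oestrus or sickness behavior, or regrouping events.

## Problem sizes and numerical conventions

* Round-trip checks run 40 cows × 86,400 s; parameter recovery runs 75 cows ×
  5 days × 20 replicate seeds; the full pipeline calibration runs 2 groups ×
  2 areas × 14 days × {M1, M2} with 100 simulations and 100 permutations per
  scenario — sizes chosen to exercise study scale while keeping the whole
  suite in a few minutes.
* All generators and samplers are pure functions of (inputs, seed); per-
  sample streams come from `SeedSequence([root, counter])`.
* Logistic fits use statsmodels Newton with separation converted to a
  non-convergence flag; `edges` is the intercept column (no separate
  constant).
* Correlation sentinels: zero-variance inputs → NaN + warning, dropped and
  counted (`n_undefined`) rather than imputed.
* Distance and duration thresholds are closed (≤ 2.5 m, ≥ 600 s); the
  kindergarten window is closed (≤ 7 d).

## Known limitations

* MPLE standard errors for M2 ignore dyad dependence and are optimistic; use
  the degeneracy diagnostics and treat M2 inference qualitatively.
* The trajectory generator cannot schedule networks so dense that the
  meeting rounds exceed the day (roughly, maximum degree × 700 s > 86,400 s).
* Persistence cannot be estimated on a day with no ties (and formation on a
  complete day); such windows raise a fit error.
* The naive baseline's two interpretations coincide in expectation but not
  in variance; SDs are comparable only within one mode.
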