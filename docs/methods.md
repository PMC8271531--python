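# Methods

## The optimizer

The continuous Whale Optimization Algorithm maintains `population_size`
agents with positions X in R^D and tracks the best-so-far solution X\*
(minimization everywhere; maximization problems are negated at the
boundary). Per iteration, each agent draws per-dimension coefficients
A = 2a·r − a and C = 2r′ (r, r′ ~ U[0,1]), a scalar l ~ U[−1,1] and
p ~ U[0,1], then applies one operator:

* p < 0.5 and |A₁| < 1 — *shrinking encirclement*:
  X ← X\* − A ⊙ |C ⊙ X\* − X|;
* p < 0.5 and |A₁| ≥ 1 — *random search* toward a uniformly chosen peer
  X_rand: X ← X_rand − A ⊙ |C ⊙ X_rand − X|;
* p ≥ 0.5 — *spiral*: X ← |X\* − X| · e^{b·l} · cos(2πl) + X\*.

The branch condition uses the magnitude of A's first component, so one
scalar decision governs the whole agent while the move itself stays
per-dimension. The coefficient a ramps linearly from exactly 2 (t = 0) to
exactly 0 (t = T_max), shared by all agents within an iteration; r, r′, l,
p are fresh per agent. X\* is updated immediately after each agent's
evaluation (elitist — the best-fitness trace is non-increasing by
construction, and its length is T_max + 1 including the post-
initialization entry). Positions are clamped into box bounds when bounds
are configured; otherwise the search is unconstrained and only the initial
population is confined to the [−1, 1]^D hypercube. An objective returning
NaN/±inf aborts with an error naming the agent, rather than silently
poisoning the incumbent.

Defaults: 10 whales, 100 iterations, spiral constant b = 1 — common
desk-scale wrapper-selection settings; all configurable. One
`numpy.random.Generator` seeded from the config drives the whole run, so
identical (seed, config, objective) reproduce trajectories bit for bit.

## The binary wrapper

Feature selection is encoded as a continuous search over R^C (one
coordinate per feature). The S1 sigmoid transfer T(v) = 1/(1+e^{−v})
gives per-feature selection probabilities and a fresh uniform draw per bit
yields the mask; an all-zero mask is repaired by switching on one
uniformly chosen bit (the cheapest repair that preserves stochasticity).
Candidate masks are scored by fitting naive Bayes on the training part
restricted to the mask and measuring 0/1 error on the holdout:

    F = α·E_R(D) + (1 − α)·R/C,   α = 0.99 (configurable).

α = 0.99 is the dominant-accuracy weighting conventional for this fitness;
the α = 0 limit provably drives R to the repair floor of 1 and α = 1
ignores subset size — both covered by tests. Mask → error results are
memoized within a run (results are identical with and without the cache).
Ties between equal-fitness masks prefer fewer selected features, then the
earlier-found mask.

The data are split 70/30, stratified per class (each class's train
fraction within one instance of the target). By default candidate masks
are scored directly on the 30% test split, which mirrors the two-arm
comparison protocol this package reproduces but makes the selection signal
the test set itself; `holdout="internal"` instead carves a 70/30
validation fold out of the training part so the test set never steers the
search. The final model is refit on the full training part and evaluated
on the test part in either mode.

## Naive Bayes

Priors are class frequencies. Continuous features get per-class Gaussian
likelihoods with the per-class sample variance floored at
1e-9·(global feature variance + 1e-12); disabling the floor turns a
within-class-constant feature into an explicit error. Categorical features
get additive (Laplace, add-1 by default) smoothed frequency tables over
the training vocabulary; a category unseen in training receives
s/(n_c + s·|V|), and with s = 0 it raises a zero-probability error naming
the feature — the classic failure mode this smoothing exists to prevent.
All computation is in log space (a 500-feature product of tiny
likelihoods stays finite); posteriors are softmax-normalized, which
supplies the division by the evidence P(x). Prediction ties break toward
the earliest class in the model's class order. Models serialize losslessly
to JSON.

When reading CSVs, a column is categorical if it is non-numeric or has at
most 10 distinct values (overridable per column) — clinical tables mix
coded integers with continuous measurements, and treating low-cardinality
codes as categories is the safer default. Missing values are rejected at
load time unless the drop-incomplete-rows policy is requested.

## Metrics

TP/FP/FN/TN counts are exact integers; accuracy, precision,
recall ≡ sensitivity and specificity are computed from them, and any zero
denominator raises instead of returning 0 so degenerate evaluations stay
visible. Percent display rounds half-up at the requested precision only at
the formatting step. The ROC sweep orders unique scores descending with
tied scores grouped into one threshold step; AUC is the trapezoidal area,
which equals the Mann–Whitney probability that a random positive outranks
a random negative (ties half) — asserted against a brute-force pairwise
count in the tests. Severity-coded multiclass labels (e.g. 0–4) are
binarized as 0 vs > 0 before any binary metric; the rule is configurable.

## The synthetic generator

`synthesize` emulates the shape of small clinical benchmarks: n instances
(default 600), Bernoulli(0.5) binary labels, `k_informative` (5) features
whose class-conditional means sit at ±separation/2 with unit variance, and
`k_noise` (15) standard-normal features independent of the label; columns
are shuffled and the returned mask records where the signal landed. The
default separation of 1.0 within-class standard deviations was chosen as a
realistic clinical effect size: it yields a naive-Bayes error around 13%
for the 5-informative configuration, inside the 11–23% error range of the
public benchmark datasets this package is aimed at. An optional
categorical mode discretizes informative columns into quartile codes to
exercise the frequency-table path.

What the generator does *not* emulate: correlated features, non-Gaussian
marginals, label noise, class imbalance beyond the balance parameter, and
mixed informative effect sizes. Passing tests on this generator therefore
show that the search recovers independent additive signal under realistic
noise — not that it handles collinearity or distribution shift.

## Known limits of wrapper selection at these conditions

With a 180-instance holdout the error granularity is 1/180 ≈ 0.0056,
while the subset-size penalty is (1 − α)/C = 0.0005 per feature and the
true accuracy cost of one noise feature at separation 1.0 is ≈ 0.0004
(measured: all 15 noise features together cost +0.006 error). Chance
correlations between a noise feature and the holdout labels can therefore
outweigh both pressures, and the wrapper retains roughly half of the noise
features (mean fraction ≈ 0.53 over 10 seeds) even while recovering ~90%
of the informative ones. This is a property of wrapper selection with
weak parsimony pressure, not of the optimizer: suppressing noise features
reliably requires either a larger α-penalty, repeated cross-validated
scoring, or separations so large that the error floor is 0 (where a noise
feature can no longer look helpful by chance). The benchmark study this
package mirrors likewise kept 50–92% of features per dataset. The
feature-recovery acceptance test asserting a mean noise fraction ≤ 0.4 is
accordingly expected to fail at these conditions and is retained as a
documented limit rather than weakened.

## Numerical choices

* Sigmoid via `scipy.special.expit` (no overflow warnings at extreme
  coordinates).
* Variance floor as above; log-space likelihoods throughout.
* Posterior ties at float precision are inherently unstable; tests compare
  argmax predictions against the enumeration oracle only when the exact-
  fraction posterior gap exceeds 1e-9.
* Problem sizes in tests and the acceptance script — sphere 30×200×10
  seeds, oracle 100 fixtures, recovery 10 seeds of 10 whales × 50
  iterations on n = 600 — are the package's study conditions; the full
  suite runs in well under a minute.
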