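# Methods

## Problem and model

Clinicians often need a three-way call — high, intermediate or low risk —
rather than a continuous prognostic index. With censored follow-up there
are no per-patient class labels to train on, so `survarea` judges a
candidate risk group by the survival curve it induces and optimizes that
judgement directly.

For a group G with Kaplan-Meier estimate S(t) on the common horizon
[0, t_N], the objective is the exact integral of the step function

    A(G) = Σ_i S_i (t_{i+1} − t_i),     0 ≤ A ≤ t_N,

with S = 1 before the first event and the final segment extended flat to
t_N. A low-risk classifier maximizes A; a high-risk classifier maximizes
the complement A′ = t_N − A. Because a lone long-lived (or short-lived)
patient nearly attains the extreme, a hard minimum group size m is
enforced: any group with fewer than m members scores exactly 0, and
higher is always better. Maximizing A implicitly pushes up the group's
median survival time and end survival rate, the quantities used to
compare risk groupings.

Each classifier is a fully connected multilayer perceptron with one
hidden layer of four tanh units and a single tanh output; the sign of
the output answers "is this patient in the group?" (output 0 maps to
"not in group", the conservative choice with respect to the size floor).
Thresholding after the output tanh is mathematically identical to
thresholding the pre-activation; we keep the tanh for symmetry with the
hidden layer. Biases are included throughout, so the genome length is
(d + 1)·4 + 5 for d inputs. Four hidden units reflect the limited
non-linear complexity of tabular clinical covariates; the architecture
is fixed, not evolved.

## Genetic training

The objective is piecewise constant in the weights (the KM curve changes
only when a patient's membership flips), so gradient methods do not
apply. A steady-state genetic algorithm evolves flat weight vectors:

1. initialize `population_size` genomes with N(0, 1) weights (a scale
   consistent with z-normalized inputs) and score them;
2. select two parents by binary tournament — two uniform picks with
   replacement, the fitter wins;
3. clone the parents and, with probability `crossover_prob`, swap the
   segment between two pivots drawn uniformly with replacement from the
   L + 1 boundary positions (equal pivots leave clones — the empty
   segment is a legal crossover);
4. mutate each weight independently with probability `mutation_prob` by
   adding N(0, `mutation_std`) noise;
5. score the children, insert them while the parents remain, and discard
   the two lowest-fitness individuals (ties broken oldest-first, keeping
   runs deterministic under a fixed seed);
6. repeat; a generation has elapsed after `population_size` births, and
   the run returns the best genome ever evaluated, whether or not it
   survived culling.

Defaults (population 200, P_C = 0.75, P_M = 0.5, mutation sd 1.5, 1000
generations) are values that transfer well across tabular survival
datasets. If every evaluated group violates the size floor the run's
best fitness is 0 and a diagnostic warning is raised.

`t_N` is fixed per training run as the maximum follow-up of the full
training dataset handed to the ensemble — not per subgroup and not per
bootstrap bag — because A and A′ are only comparable across candidate
groups (and across ensemble members) on a shared horizon.

## Ensemble and vote fusion

34 classifiers are trained by default: 17 hunting a high-risk group
(objective A′) and 17 a low-risk group (objective A), each on its own
bootstrap resample of the training data (bagging) for diversity. Member
seeds derive from the master seed and the member index through a seed
sequence, so ensembles are bit-reproducible.

At prediction time, with h of k high-half votes and l of k low-half
votes for a subject: if neither half reaches a within-majority
(votes > k/2) the label is intermediate; if both do and h = l it is
intermediate; otherwise the majority-holding side with more votes wins.
k is kept odd so a half's in-vs-not vote cannot tie. The prose rule
"most votes between high and low wins" admits a second reading
(`vote_rule="plurality"`); for odd k the two readings coincide — a lone
within-majority necessarily also holds the most votes — and a property
test asserts this. The design does not extend beyond three groups, and
vote counts are not interpreted as calibrated probabilities.

## Preprocessing

Categorical columns are expanded into one indicator per level (missing
value → all-zero row; unseen level at transform time → all-zero row).
Missing numeric entries are imputed with the column mean — imputation
precedes normalization because the mean is only well-defined on the raw
scale — and every column is then z-normalized with the sample (n − 1)
standard deviation. Constant columns are dropped with a warning. All
statistics are fitted once (on training data) and replayed on new data,
so no test-set information leaks into the transform. The train/test
split holds out 1/4 of subjects, stratified on the censoring indicator
with per-stratum rounding (residual to the larger stratum), keeping the
test set's censored fraction within one subject of the cohort's.

## Evaluation

Groups are compared by size, median survival time (smallest t with
S(t) ≤ 0.5, undefined when the curve never reaches 0.5 — note some
libraries use strict < at an exact 0.5 plateau; we use ≤), end survival
rate S(t_N), and the low-minus-high end-survival difference, whose
negative sign flags crossing survival curves. For comparator prognostic
indices (e.g. a Cox linear predictor), `index_to_groups` labels the
n_high largest and n_low smallest values, with boundary ties broken by
stable input order; the learned cut values transfer to new data, where
group sizes may deviate. Cross-validation is repeated, censoring-
stratified k-fold (default 3-fold × 10); within a validation fold the
horizon is the fold's maximum follow-up so end-survival rates are
comparable across models.

## Synthetic cohorts

The generator plants known risk structure: stratum s (proportion p_s,
hazard multiplier h_s) draws event times from the Weibull
proportional-hazards model S_s(t) = exp(−h_s (t/scale)^shape), shape 1
giving exponential times. Censoring is an independent exponential
variable whose rate is calibrated to the requested expected censored
fraction — in closed form for exponential events, otherwise by Brent
root-finding on a substituted quadrature that stays numerically stable
at any rate. Covariates are the one-hot stratum indicators plus
optional pure-noise Gaussian columns; latent stratum labels are returned
separately and never enter the covariates. The generator emulates the
censoring range of real registry cohorts (roughly 28–86%) but not their
covariate distributions, measurement noise on the informative signal,
informative censoring, or time-varying effects — so recovery tests
demonstrate that the pipeline finds planted, learnable structure, not
that it matches any particular clinical dataset.

## Numerical and design choices

- KM estimation is an in-package numpy routine because it runs in the
  GA's inner loop (~1e5 subgroup evaluations per run); tests verify it
  against lifelines to 1e−12 on hundreds of random censored datasets.
  Events at a tied time are processed before censorings (the standard
  risk-set convention). Subjects with time 0 are retained.
- The area is computed as an exact rectangle sum, not a quadrature; the
  identity A + A′ = t_N holds to one ulp (A′ is literally t_N − A).
- Membership threshold: raw output > 0 strictly; exact 0 votes "out".
- Default minimum group size when unspecified: a quarter of the training
  data, the common quartile convention for risk groups; in comparator
  studies m is typically set externally to match another model's sizes.
- Degenerate inputs: empty datasets, all-missing columns, m ≥ n,
  mismatched dimensions and malformed curves raise ValueError with the
  offending quantity named; degenerate all-zero-fitness runs warn.

## Problem sizes in the shipped checks

The test suite and the acceptance script run scaled-down study
conditions chosen to keep the full pipeline exercised end to end:
oracle comparisons on 500 random datasets (n ≤ 30); exhaustive
objective enumeration over all 2^12 masks; GA optimality on a
20-subject enumerable instance (population 50, 100 generations, 20
seeds); and strata recovery on n = 600 cohorts with 1:3:9 hazards at
30% censoring using a 6-member ensemble (population 50, 100
generations, 10 seeds). Full-scale defaults (34 members, population
200, 1000 generations) are what `RiskGroupModel.fit` uses unless
configured otherwise.

## Known limitations

- Exactly three risk groups; the one-vs-rest + two-half vote design
  does not generalize to more.
- Mean imputation only; no multiple imputation or model-based filling.
- The objective ignores covariate balance and calendar effects; groups
  are defined solely by predicted membership.
- GA training is stochastic; different seeds give different (similarly
  fit) ensembles. All randomness is reproducible from the master seed.
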