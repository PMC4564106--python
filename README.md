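# survarea

Risk-group discovery in censored survival data by neuroevolution on the
area under the Kaplan-Meier curve.

## The problem

Treatment decisions and trial stratification often need a categorical
call — is this patient **high**, **intermediate** or **low** risk? —
rather than a continuous prognostic index. Censoring makes this hard to
pose as ordinary classification: for censored patients the "true" risk
class is unknowable, so there are no labels to fit. What *can* be
judged is the Kaplan-Meier survival curve of a predicted group.

`survarea` trains small neural classifiers to optimize that judgement
directly. For a candidate group with KM curve S(t) on the horizon
[0, t_N],

    A = Σ_i S_i (t_{i+1} − t_i),        A′ = t_N − A,

low-risk classifiers maximize the area A, high-risk classifiers maximize
the complement A′, and a hard minimum group size m zeroes the score of
any group smaller than m (otherwise the optimum is a single extreme
survivor). Optimizing A implicitly improves median survival time and
end survival rate. The objective is piecewise constant in the weights,
so each classifier — a one-hidden-layer tanh perceptron answering
"in the group or not?" — is trained by a steady-state genetic algorithm
(binary tournament, two-point crossover, Gaussian mutation, worst-two
replacement). An ensemble of bagged members, half high-risk and half
low-risk with an odd count per half, votes each patient into one of the
three groups; ties and no-majority cases fall to intermediate.

Intended users: biostatisticians and ML researchers working with
censored time-to-event data who want size-controllable, possibly
non-linear risk groups, and a reproducible baseline against prognostic-
index quantile cuts or recursive-partitioning trees.

## Worked example

```python
from survarea import (EnsembleConfig, GAConfig, RiskGroupModel, SimSpec,
                      simulate)

# a synthetic cohort with planted hazard strata (1 : 3 : 9) and 30% censoring
data, _ = simulate(SimSpec(n=400,
                           strata=((0.4, 1.0), (0.3, 3.0), (0.3, 9.0)),
                           censor_rate=0.3, p_noise=2, seed=11))

cfg = EnsembleConfig(size=6, ga=GAConfig(population_size=50, generations=100))
res = RiskGroupModel(data, config=cfg).fit(seed=11)
print(res.summary())
```

prints

```
Risk-group ensemble (area-under-survival-curve objective)
==========================================================
members: 6 (3 high + 3 low), hidden nodes: 4
min group sizes: high=100 low=100; horizon t_N=3.00773
GA: pop=50 gens=100 P_C=0.75 P_M=0.5 M_std=1.5
----------------------------------------------------------
              size  median_survival  end_survival
group                                            
high           103          0.06621             0
intermediate   193           0.2958             0
low            104             0.83       0.04784
----------------------------------------------------------
end-survival difference (low - high): 0.04784
```

The ensemble recovers the planted structure: the predicted low-risk
group's median survival (0.83) is an order of magnitude above the
high-risk group's (0.066), group sizes respect the floor of a quarter
of the cohort, and the positive low-minus-high end-survival difference
(0.048) confirms the curves have not crossed by the horizon. With 30%
censoring both extreme groups' curves still reach zero or near zero by
t_N, which is why end survival is 0 for the high and intermediate
groups.

The same pipeline is available from the shell:

```
survarea simulate --n 400 --strata '0.4,1;0.3,3;0.3,9' --censor-rate 0.3 \
         --p-noise 2 --seed 11 --out cohort.csv
survarea train    --data cohort.csv --out ens/ --size 6 \
         --population-size 50 --generations 100 --seed 11
survarea predict  --ensemble ens/ --data cohort.csv --out pred.csv
survarea evaluate --predictions pred.csv --data cohort.csv --out-prefix eval
```

Real cohorts load from CSV (`time`, `event` columns plus covariates) via
`SurvivalDataset.from_csv`, or — with R's `survival` package installed —
through `survarea.rdatasets.load_dataset("pbc")` and friends.

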