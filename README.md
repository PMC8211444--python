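# mmsdina

Bayesian estimation and comparison of cognitive diagnosis models with
multiple solution strategies: the DINA model, the multiple-strategy
MS-DINA model, and the mixture multiple-strategy MMS-DINA model.

## The problem

Cognitive diagnosis models classify examinees as masters or non-masters of
fine-grained skills ("attributes") from binary test responses.  The DINA
model is conjunctive: examinee *i* answers item *j* correctly, up to slip
and guess noise, only when the profile
α<sub>i</sub> ∈ {0,1}<sup>K</sup> satisfies every attribute the item's
Q-matrix row requires,

> P(u<sub>ij</sub> = 1 | α<sub>i</sub>) = (1 − s<sub>j</sub>)<sup>η<sub>ij</sub></sup> g<sub>j</sub><sup>1−η<sub>ij</sub></sup>,  η<sub>ij</sub> = ∏<sub>k</sub> α<sub>ik</sub><sup>q<sub>jk</sub></sup>.

Real items can often be solved by *different* attribute sets (strategies).
With one Q-matrix per strategy, MS-DINA keeps a single (s, g) per item and
sets η to the maximum over strategies, while the mixture MMS-DINA model
lets each examinee latently use one strategy c<sub>i</sub> with mixing
proportions π and gives every strategy its own item parameters:

> P(u<sub>ij</sub> = 1 | α<sub>i</sub>) = ∑<sub>m</sub> π<sub>m</sub> (1 − s<sub>jm</sub>)<sup>η<sub>ijm</sub></sup> g<sub>jm</sub><sup>1−η<sub>ijm</sub></sup>,  α<sub>ik</sub> | c<sub>i</sub>=m ~ Bernoulli(μ<sub>m</sub>).

The package estimates all three by MCMC (Metropolis-Hastings within
Gibbs), compares them by DIC and LPML (stabilized conditional predictive
ordinates), scores attribute classification and parameter recovery in
replicated simulation studies, and diagnoses convergence with the
Brooks-Gelman PSRF.  Intended users: psychometricians and methodologists
studying multiple-strategy problem solving, and anyone needing a
reproducible Python implementation of these models.

## Worked example

```python
import mmsdina as md

# a two-strategy design shipped with the package: 30 items, 5 attributes
design = md.SimulationDesign(model="mmsdina", N=1000,
                             qmatrix="table2_J30_K5_M2",
                             replications=2, rng_seed=11)
config = md.ChainConfig(iterations=3000, burn_in=1500)

data = md.simulate_dataset(design, 0)          # truths: s=0.3, g=0.1
draws = md.run_chain(data.responses, design.resolve_qmatrix(),
                     config=config)            # MMS-DINA fit
crit = md.compute_fit_criteria(draws)
print(round(crit.dic, 1), round(crit.lpml, 1))

result = md.run_recovery_study(design, config) # simulate -> fit -> score
print(result["table"].round(3))
print({k: round(v, 3) for k, v in result["classification"].items()
       if k != "h"})
```

Output (seed 11):

```
24032.4 -13344.1
   strategy  s_ABias  s_AMSE  s_ASD  g_ABias  g_AMSE  g_ASD
0         1    0.036   0.003  0.051     0.02   0.001  0.014
1         2    0.037   0.003  0.051     0.02   0.001  0.014
{'t': 0.608, 'v': 0.849, 'z': 0.014}
```

Reading it: the average absolute bias of the strategy-1 slipping estimates
across the 30 items is 0.036 (truth 0.3), their mean squared error 0.003,
and the average posterior standard deviation 0.051; 60.8% of examinees are
classified correctly on all five attributes, 84.9% on at least four, and
only 1.4% are severely misclassified.  DIC (smaller = better) and LPML
(larger = better) are the model-comparison criteria for this fit.

A thin CLI mirrors the library: `mmsdina simulate | fit | compare |
diagnose` (see `mmsdina --help`); every run writes a `manifest.json` that
makes it bit-reproducible.

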