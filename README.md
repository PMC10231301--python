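# maskddm

Tools for studying how face masks reshape emotion communication, through the
lens of the drift–diffusion model (DDM). The package re-creates, as a tested
and reusable pipeline, the inference machinery of a two-alternative
forced-choice masked-expression judgment study: participants view facial
expressions of six emotions (anger, disgust, fear, happiness, sadness,
surprise) with the lower or upper half of the face occluded or unoccluded,
and judge as quickly and accurately as possible whether each face shows a
given emotion. Because the original photographs and human data are not part
of this package, a first-class synthetic-data module generates complete
study datasets from a diffusion process with known ground truth, so every
stage of the analysis can be validated end to end.

## The model

Each judgment is modelled as a Wiener diffusion between two absorbing
boundaries separated by *a*, starting at relative position *z*, with drift
rate *v* (evidence units/s) and unit diffusion coefficient; the response
time adds a non-decision time *t*. Accuracy coding is used: the upper
boundary is the correct response, so larger *v* means faster evidence
accumulation toward the correct judgment. The full model includes
across-trial variabilities — drift drawn Normal(*v*, *sv*²), start point
Uniform(*z* ± *sz*/2), non-decision time Uniform(*t* ± *st*/2).

Inference proceeds hierarchically: one drift coefficient per mask condition
(lower / upper / none), participant random intercepts on drift with group
SD σᵤ, and shared *a*, *z*, *t*, *sv* estimated once across mask conditions.
The likelihood kernel is the Wiener first-passage-time (WFPT) density,
evaluated by the standard two-regime series expansion; posterior sampling
uses adaptive Metropolis-within-Gibbs, drawing 5000 samples and discarding
the first 200 as burn-in. Hypothesis tests are posterior probabilities of
contrasts, e.g. P(v_lower > v_none), computed as the fraction of retained
draws satisfying the contrast.

Around the diffusion model sit the behavioural analyses: mixed binomial
logistic regressions of emotion ratings on mask condition (participant
random intercepts, Gauss–Hermite marginal likelihood), mixed linear models
of log response times with mask × accuracy interactions, cluster-bootstrap
95% confidence intervals (participants resampled, 1,000 iterations by
default), chance-level tests, and the staged false-positive cascade over
all 30 incongruent expression/judgment pairings.

## Worked example

```python
from maskddm import hier
from maskddm.simulate import simulate_drift_cells

truth = {"lower": 0.8, "upper": 1.1, "none": 1.5}   # drift per mask condition
trials = simulate_drift_cells(truth, n_participants=40, trials_per_cell=18,
                              seed=3)
model, draws = hier.fit_mask_drift(trials, seed=5)
print(draws.draws[["v_lower", "v_upper", "v_none", "a", "t"]].mean().round(3))
print(hier.posterior_prob(draws, "v_lower > v_none"))
```

Output:

```
v_lower    0.773
v_upper    1.070
v_none     1.520
a          1.844
t          0.336
dtype: float64
HypothesisTestResult(label='v_lower > v_none', probability=0.0,
                     contrast='v_lower > v_none')
```

The posterior means sit close to the generating drifts (0.8 / 1.1 / 1.5),
the shared boundary separation and non-decision time are recovered (true
1.8 and 0.35 s), and the posterior probability that the lower-mask drift
exceeds the no-mask drift is 0 — the sampler detects the simulated
masked-face deficit in evidence accumulation.

The full pipeline (design → simulate → exclusions → regressions →
hierarchical DDM → reports) runs from one config and one seed:

```bash
maskddm run --profile demo --seed 1 --out runs/demo
maskddm validate runs/demo
```

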