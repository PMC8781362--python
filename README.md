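# ewsdir — directional early-warning signals for diary mood data

`ewsdir` implements a *directional* critical-slowing-down (CSD) indicator
for intensive longitudinal self-report data (daily diaries, experience
sampling). It is aimed at researchers in computational psychiatry and
complex-systems psychology who want to ask not only *whether* a person's
mood system is destabilizing, but *which way* it is heading — toward
symptom worsening or toward remission — and to benchmark that prediction
against a permutation chance level at cohort scale.

## The indicator

As a bistable dynamical system loses resilience near a fold (saddle-node)
bifurcation, fluctuations along the destabilizing direction grow and become
skewed toward the basin the system is about to fall into. Within each
sliding window of a person's mood series (an occasion × variable matrix
*X*, either individual items or positive/negative sum scores), the package
computes the first principal component of the window covariance matrix
*C*:

- **length** — the explained-variance ratio
  *R* = λ₁ / tr *C* ∈ [0, 1], where λ₁ is the largest eigenvalue of *C*;
- **direction** — the sample skewness
  *g₁* = m₃ / m₂^{3/2} of the scores projected on the unit eigenvector
  **v**, whose sign orients the component toward the heavier tail.

The per-window **predicted change** is the vector *R* · sign(*g₁*) · **v**;
its component along the negative-valence variables, tracked over windows
advancing one occasion at a time, forms a per-person indicator series.
Short "deviant" sign runs caused by near-zero skews are corrected by
flipping (or, alternatively, windows with nonsignificant skews are
dropped). The monotone trend of the series is summarized by Kendall's
tau-b against window order: a significant positive tau classifies the
person as heading toward *worsening*, a significant negative tau toward
*improvement*.

At cohort level, each classification is matched against the observed
direction of the person's interview severity change (a 0–450 sum score
before and after the diary period). Accuracy is benchmarked by shuffling
every person's occasion order (destroying temporal structure while keeping
the marginal distribution), rerunning the entire pipeline 200 times, and
comparing the observed accuracy with the mean shuffled accuracy via a
pooled two-proportion z-test.

Because no cohort diary data of this kind can be shared publicly, the
package ships a first-class synthetic generator: a latent fold-normal-form
process d*x* = (*x* − *x*³ + *c*(t)) d*t* + σ d*W* whose control parameter
*c* is slowly ramped toward the fold at *c\** = 2/(3√3), rendered into
bounded mood items with occasion-level missingness and interview-style
severity sums.

## Worked example

```python
import numpy as np
import ewsdir as e

sim = e.strong_transition_config(n_persons=20, seed=7)
cohort = e.generate_cohort(sim)

cfg = e.AnalysisConfig(window_size=60, granularity="sums",
                       skew_correction="flip_runs")
trends = e.run_cohort(cohort.diaries, cfg)
changes = e.symptom_changes(cohort.persons)
ev = e.evaluate_cohort(trends, changes)
null = e.permutation_null(cohort.diaries, changes, cfg, n_permutations=200,
                          rng=np.random.default_rng(8),
                          p_observed=ev.accuracy / 100.0)

print(f"accuracy        {ev.accuracy:.2f}%  ({ev.n_matched}/{ev.n_total})")
print(f"true positives  {ev.tpr:.2f}%  ({ev.n_matched}/{ev.n_significant})")
print(f"chance level    {null.mean_accuracy:.2f}%  (200 permutations)")
print(f"z = {null.z:.2f}, one-sided P = {null.p_one_sided:.4f}")
t0 = trends[0]
print(f"first person: tau = {t0.tau:.2f}, P = {t0.p_value:.3f}, class = {t0.trend_class}")
```

This prints:

```
accuracy        100.00%  (20/20)
true positives  100.00%  (20/20)
chance level    41.58%  (200 permutations)
z = -4.06, one-sided P = 0.0000
first person: tau = 0.61, P = 0.000, class = worsen
```

Every one of the 20 simulated persons undergoes a full basin switch, and
the indicator recovers each person's direction; shuffled data still match
by chance in ~42% of persons (shuffled bistable series remain bimodal, so
some directional signal survives in the marginals), and the z-test shows
the temporal signal is far beyond that chance level. On cohorts with weak
or no transitions the observed and shuffled accuracies coincide.

The same pipeline is available from the shell:

```
ewsdir simulate --seed 7 --n-persons 20 --out sim/
ewsdir run --diary sim/diary.csv --items sim/items.csv --out run/
ewsdir evaluate --trends run/trends.tsv --changes sim/persons.csv \
    --diary sim/diary.csv --items sim/items.csv --permutations 200 \
    --seed 8 --out eval/
```

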