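# Methods

## Model and procedure

The package estimates the *direction* of critical slowing down (CSD) in a
multivariate mood time series. The working assumption is that a person's
mood system behaves like a bistable stochastic dynamical system near a
fold (saddle-node) bifurcation: as the occupied basin loses stability,
fluctuations along the soft direction grow (rising variance), dominate the
covariance structure (rising first-eigenvalue share), and become skewed
toward the basin the system is about to fall into. The pipeline runs in
five stages:

1. **Preprocessing** (`preprocess`). Diary items are restricted to an
   explicit, valence-balanced list, affinely mapped onto a common rating
   scale, and — for the cohort setting — collapsed into per-occasion sums
   of positive and of negative items. Occasions with any missing item are
   treated as wholly missing: sums over different item subsets would not
   be comparable across occasions.
2. **Windowed PCA** (`indicator`). Windows of `window_size` consecutive
   occasions advance one occasion at a time. Within each window the
   covariance matrix of the (complete-case) rows is eigendecomposed;
   R = λ₁/tr C is the explained-variance ratio and the unit eigenvector
   **v** the loading pattern. PCA is on the covariance, not the
   correlation, matrix; variables are not standardized within windows, so
   the eigenvalue retains its variance units.
3. **Orientation**. Eigenvectors are sign-ambiguous, so **v** is
   canonicalized to a non-negative loading on the negative-valence
   reference variable (the negative-valence variable of largest absolute
   loading). Direction is then carried entirely by the sample skewness
   g₁ = m₃/m₂^{3/2} of the projected scores: the per-window predicted
   change is R·sign(g₁)·**v**, pointing toward the heavier tail. A g₁ of
   exactly 0 inherits the previous window's sign (else +1), avoiding
   spurious flips on symmetric windows.
4. **Sign correction**. Near-zero skews produce spurious 180° reversals
   across consecutive windows. Two schemes are implemented:
   `flip_runs` (default) negates every maximal constant-sign run of
   length ≤ `max_flip_run` that is flanked on both sides by opposite-sign
   runs, repeating left-to-right to a fixpoint (boundary runs are never
   flipped — they have no two flanks); `drop_nonsignificant` instead
   removes windows whose skewness fails a two-sided D'Agostino z-test at
   `alpha_skew` (windows with fewer than 8 usable occasions are removed
   as untestable).
5. **Trend and evaluation** (`trend`, `evaluate`). Kendall's tau-b of the
   predicted change in negative states against window order classifies a
   person (significant positive → worsen, significant negative → improve,
   else none; two-sided test, direction read from the sign). Cohort
   accuracy is the share of persons whose class matches the direction of
   their interview severity change; the chance level is the mean accuracy
   over 200 reruns of the *entire* pipeline on data whose occasion order
   has been independently shuffled per person. Observed and chance
   accuracies are compared with a pooled two-proportion z-test with equal
   nominal sizes, z = (p_null − p_obs)/√(p̄(1−p̄)·2/n), one-sided lower
   tail, so z < 0 means the indicator beats chance.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `window_size` | 60 (sums), 150 (items) | occasions per window; smaller windows overfit the PCA, larger ones smooth over trends |
| `min_complete` | 0.5 | minimum non-missing fraction for a window to be used |
| `skew_correction` | `flip_runs` | scheme for near-zero-skew reversals |
| `max_flip_run` | 1 | longest deviant run eligible for flipping |
| `alpha_skew` | 0.05 | significance level of the skewness test (drop scheme) |
| `alpha_trend` | 0.05 | significance level of the tau classification |
| `granularity` | `sums` | analyze items or positive/negative sum scores |

The step size is fixed at one occasion: with series of ~183 occasions and
windows of 60 this yields n − w + 1 ≈ 124 windows per person, matching the
windows-per-person arithmetic of unit steps.

The tau variant is tau-b (tie-corrected); p-values come from
`scipy.stats.kendalltau` (exact enumeration for short tie-free series,
otherwise the tie-corrected normal approximation). The skewness estimator
is the unadjusted moment ratio g₁; the D'Agostino p-value is computed
directly from (g₁, n) and matches `scipy.stats.skewtest` on raw scores.

An `end_window` argument to `kendall_trend` restricts the trend to windows
ending at or before a cutoff, e.g. a known transition: after a completed
basin switch the windows describe the settled new state, and the
destabilization trend is a pre-transition statement.

## The synthetic generator

`synthetic` generates cohorts from the fold normal form
dx = (x − x³ + c(t))dt + σ dW (Euler–Maruyama, one step of `dt` per
occasion). It is the simplest system exhibiting CSD with a controllable
transition direction: for |c| < c* = 2/(3√3) two stable states coexist
(x ≈ −1 low, x ≈ +1 high negative affect); ramping c linearly toward the
fold erodes the occupied basin. Per person one of three scenarios is
simulated: *increase* (ramp toward the high-symptom attractor),
*decrease* (mirror image), *none* (constant c). A single latent dimension
drives all items — the analysis itself reduces to one component, and
higher-dimensional destabilization would only dilute the indicator.

Rendering: negative items read mid-scale + bᵢ·x + noise, positive items
mid-scale − aⱼ·x + noise, loadings uniform on `loading_range`, clipped to
the rating scale. Defaults emulate a daily-diary cohort — 183 occasions,
28 items (14 per valence) on 0–100, 11.45% of occasions missing
completely at random (whole diary entries, since an entry is completed or
skipped as a unit). Severity sums are affine maps (offset 70, slope 55,
rounded, clipped to 0–450) of the mean latent state over the first/last 7
occasions, mirroring a short-recall interview at each end; typical cohorts
span roughly sums 5–140, within the plausible 0–450 range. Defaults
dt = 0.1, σ = 0.12, c ramp −0.2 → 0.55 put the fold crossing in the last
third of the diary with modest signal; `strong_transition_config`
(σ = 0.10, ramp −0.25 → 0.85, item noise 4) is the regime where every
transition person completes a full basin switch — the setting in which
directional CSD is expected to work.

What the generator does *not* emulate: bounded/discrete response styles,
circadian and weekly cycles, measurement reactivity, item-specific
dynamics, multi-attractor landscapes, or non-MCAR missingness. Passing
tests on this generator show the pipeline correctly recovers direction
when the data-generating process matches the CSD theory; they do not show
that real mood data follow that process.

## Numerical choices

- Windows with fewer than max(3, `min_complete`·w) complete occasions are
  skipped and logged; windows whose covariance trace is ≤ 1e-10 are
  flagged degenerate and excluded (on noise-free constant data every
  window is degenerate and the indicator series is empty, which downstream
  yields an undefined trend classified as none, not an error).
- The two-variable (sums) path is computed from sliding raw moments in
  O(n) with closed-form 2×2 eigenstructure; series are globally centered
  first to keep the raw-moment differences well conditioned. It agrees
  with the general eigendecomposition path to ~1e-9 and makes the
  200-fold permutation null affordable (a 60-person, 200-permutation
  null runs in ~17 s on one CPU).
- R is clipped to [0, 1]; eigenvector fallbacks cover the Cxy ≈ 0 cases;
  an exactly isotropic window (measure zero) orients along the
  negative-valence axis.
- In the pooled z-test a pooled proportion of exactly 0 or 1 yields an
  undefined (NaN) z rather than ±∞.
- The true-positive rate follows the reporting convention
  all-matches / significant-trends; a person whose symptoms did not change
  can match with a *non*significant trend, so the strict variant
  (matches-with-significant-trend / significant-trends) is also computed
  and written to the summary.
- Quantile-subset accuracies use strict exceedance of the empirical
  (1−q)-quantile of |Δseverity|; empty subsets are reported as undefined
  and logged.

## Known limitations

- **Serial dependence inflates the trend test.** Adjacent windows share
  w − 1 of w occasions, so the indicator series is strongly
  autocorrelated, while the tau p-value assumes exchangeable
  observations. On stationary no-transition cohorts the share of
  "significant" trends is ~60–70%, far above the nominal 5% — the
  classification is a ranking device, not a calibrated test. The
  permutation null is the package's honest chance benchmark precisely
  because it reruns the full, equally-inflated pipeline on
  time-destroyed data: on null cohorts observed and shuffled accuracies
  are statistically indistinguishable, and only genuine temporal
  structure separates them.
- Shuffled bistable series remain bimodal, so permutation accuracy on
  strong-transition cohorts sits well above naive 1/3 guessing; the
  comparison of interest is observed vs. shuffled, not shuffled vs. a
  theoretical floor.
- The per-component magnitudes of the predicted-change vector depend on
  the (unit-eigenvector) scaling convention; Kendall's tau is invariant
  to any fixed positive rescaling, so only signs and orderings of the
  components are interpreted.
- Persons simulated without a transition still show small nonzero
  severity deltas (interview noise), so their realised change direction
  is rarely "equal"; cohort accuracy on null cohorts is therefore driven
  by chance sign agreement, as in real cohorts.
- Item-level analysis can produce ambiguous loading patterns in short
  windows; the sums pipeline exists exactly for that regime, at the cost
  of collapsing within-valence structure.
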