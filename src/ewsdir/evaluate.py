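"""Cohort-level scoring of the indicator against observed symptom change.

A person's trend class (worsen / improve / none) is matched against the
direction of their interview severity change (increase / decrease / equal).
Cohort accuracy is benchmarked against a time-shuffling permutation null:
each person's occasion order is shuffled, destroying the temporal structure
the indicator relies on, the whole pipeline is rerun, and the mean accuracy
over permutations is taken as the chance level.  Observed and chance
accuracies are compared with a pooled two-sample proportion z-test.
"""
from __future__ import annotations

import dataclasses
import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .indicator import SUMS, AnalysisConfig, compute_indicator
from .preprocess import NEGATIVE, DiaryTimeSeries, ValenceSums, valence_sums
from .trend import IMPROVE, NONE, WORSEN, TrendResult, kendall_trend

logger = logging.getLogger(__name__)

INCREASE = "increase"
DECREASE = "decrease"
EQUAL = "equal"

#: trend class -> symptom direction counted as a correct prediction
MATCHING = {WORSEN: INCREASE, IMPROVE: DECREASE, NONE: EQUAL}


class EvaluationError(ValueError):
    """Raised for inconsistent evaluation inputs."""


@dataclasses.dataclass
class SymptomChange:
    """Interview severity sums before and after the diary period."""

    person_id: str
    baseline_sum: float
    post_sum: float

    @property
    def delta(self) -> float:
        return self.post_sum - self.baseline_sum

    @property
    def direction(self) -> str:
        if self.delta > 0:
            return INCREASE
        if self.delta < 0:
            return DECREASE
        return EQUAL


@dataclasses.dataclass
class CohortEvaluation:
    """Per-person match flags and cohort accuracy summaries (percent)."""

    matches: pd.DataFrame
    accuracy: float
    tpr: float
    tpr_strict: float
    quantile_accuracy: dict[float, float | None]
    n_total: int
    n_significant: int
    n_matched: int


@dataclasses.dataclass
class PermutationResult:
    """Accuracy distribution under time-shuffled data."""

    n_permutations: int
    accuracies: np.ndarray
    mean_accuracy: float
    z: float
    p_one_sided: float


def match_direction(trend: TrendResult, change: SymptomChange) -> bool:
    """True iff the trend class corresponds to the observed change direction."""
    if trend.person_id != change.person_id:
        raise EvaluationError(
            f"paired records for different persons: "
            f"{trend.person_id!r} vs {change.person_id!r}"
        )
    return MATCHING[trend.trend_class] == change.direction


def evaluate_cohort(
    trends: Iterable[TrendResult],
    changes: Iterable[SymptomChange],
    quantiles: Sequence[float] = (0.5, 0.25, 0.10),
) -> CohortEvaluation:
    """Score every person and summarise cohort accuracy.

    ``accuracy`` is the percentage of all persons whose trend matched their
    symptom change.  ``tpr`` follows the reporting convention of dividing
    *all* matches by the number of persons with a significant trend (a
    matched person may have a nonsignificant trend when their symptoms did
    not change); ``tpr_strict`` restricts the numerator to matches with a
    significant trend.  For each quantile q the accuracy is recomputed in
    the subset whose |delta| strictly exceeds the empirical (1-q)-quantile
    of cohort |delta|.
    """
    trend_by_id = {t.person_id: t for t in trends}
    change_by_id = {c.person_id: c for c in changes}
    if set(trend_by_id) != set(change_by_id):
        missing = set(trend_by_id) ^ set(change_by_id)
        raise EvaluationError(f"person ids do not align: {sorted(missing)}")
    if not trend_by_id:
        raise EvaluationError("empty cohort")

    rows = []
    for pid in trend_by_id:
        t, c = trend_by_id[pid], change_by_id[pid]
        rows.append(
            {
                "person_id": pid,
                "trend_class": t.trend_class,
                "tau": t.tau,
                "direction": c.direction,
                "delta": c.delta,
                "matched": match_direction(t, c),
                "significant": t.trend_class in (WORSEN, IMPROVE),
            }
        )
    df = pd.DataFrame(rows).sort_values("person_id").reset_index(drop=True)
    n_total = len(df)
    n_matched = int(df["matched"].sum())
    n_significant = int(df["significant"].sum())
    accuracy = 100.0 * n_matched / n_total
    tpr = 100.0 * n_matched / n_significant if n_significant else float("nan")
    strict = int((df["matched"] & df["significant"]).sum())
    tpr_strict = 100.0 * strict / n_significant if n_significant else float("nan")

    abs_delta = df["delta"].abs().to_numpy()
    quantile_accuracy: dict[float, float | None] = {}
    for q in quantiles:
        cut = float(np.quantile(abs_delta, 1.0 - q))
        subset = df[df["delta"].abs() > cut]
        if subset.empty:
            logger.warning("quantile %.2f subset empty (cut=%.3f)", q, cut)
            quantile_accuracy[q] = None
        else:
            quantile_accuracy[q] = 100.0 * subset["matched"].mean()
    return CohortEvaluation(
        matches=df,
        accuracy=accuracy,
        tpr=tpr,
        tpr_strict=tpr_strict,
        quantile_accuracy=quantile_accuracy,
        n_total=n_total,
        n_significant=n_significant,
        n_matched=n_matched,
    )


def compare_proportions(
    p_observed: float, p_null: float, n: int
) -> tuple[float, float]:
    """Pooled two-sample proportion z-test with equal nominal sizes n.

    z = (p_null - p_observed) / sqrt(p_bar (1 - p_bar) (2 / n)) with
    p_bar the unweighted mean of the two proportions; the one-sided p comes
    from the standard-normal lower tail, so z is negative (and p small) when
    the observed accuracy exceeds the chance level.
    """
    if not (0.0 <= p_observed <= 1.0 and 0.0 <= p_null <= 1.0):
        raise EvaluationError("proportions must lie in [0, 1]")
    if n < 1:
        raise EvaluationError("n must be >= 1")
    p_bar = 0.5 * (p_observed + p_null)
    if p_bar in (0.0, 1.0):
        return float("nan"), float("nan")
    se = np.sqrt(p_bar * (1.0 - p_bar) * (2.0 / n))
    z = (p_null - p_observed) / se
    return float(z), float(stats.norm.cdf(z))


# ---------------------------------------------------------------------------
# pipeline helpers


def run_cohort(
    inputs: Sequence[DiaryTimeSeries | ValenceSums],
    config: AnalysisConfig,
) -> list[TrendResult]:
    """Indicator + trend for every person; per-person failures are logged."""
    trends = []
    for data in inputs:
        series = compute_indicator(data, config)
        trends.append(kendall_trend(series, alpha_trend=config.alpha_trend))
    return trends


def _shuffled_trend(
    data: DiaryTimeSeries | ValenceSums,
    config: AnalysisConfig,
    rng: np.random.Generator,
) -> TrendResult:
    """Trend of one person after shuffling their occasion order."""
    if config.granularity == SUMS:
        sums = data if isinstance(data, ValenceSums) else valence_sums(data)
        perm = rng.permutation(len(sums.pos_sum))
        shuffled: DiaryTimeSeries | ValenceSums = ValenceSums(
            person_id=sums.person_id,
            occasions=sums.occasions,
            pos_sum=sums.pos_sum[perm],
            neg_sum=sums.neg_sum[perm],
            n_items_pos=sums.n_items_pos,
            n_items_neg=sums.n_items_neg,
        )
    else:
        if not isinstance(data, DiaryTimeSeries):
            raise EvaluationError("item-level shuffling requires a DiaryTimeSeries")
        perm = rng.permutation(data.n_occasions)
        ratings = pd.DataFrame(
            data.ratings.to_numpy(dtype=float)[perm],
            index=data.ratings.index,
            columns=data.ratings.columns,
        )
        shuffled = DiaryTimeSeries(
            data.person_id, ratings, data.valence, data.scale, dict(data.meta)
        )
    series = compute_indicator(shuffled, config)
    return kendall_trend(series, alpha_trend=config.alpha_trend, diagnostic=False)


def permutation_null(
    inputs: Sequence[DiaryTimeSeries | ValenceSums],
    changes: Iterable[SymptomChange],
    config: AnalysisConfig,
    n_permutations: int = 200,
    rng: np.random.Generator | None = None,
    p_observed: float | None = None,
    max_retries: int = 5,
) -> PermutationResult:
    """Chance-level accuracy by rerunning the pipeline on time-shuffled data.

    Each permutation independently shuffles every person's occasion order
    (missingness marks travel with their occasions; symptom changes are
    untouched) and records the resulting cohort accuracy.  The mean over
    ``n_permutations`` (default 200) permutations is the chance level; if
    ``p_observed`` is given, the pooled proportion z and one-sided p are
    computed against it.
    """
    if rng is None:
        rng = np.random.default_rng()
    changes = list(changes)
    n = len(changes)
    if config.granularity == SUMS:
        # precompute sum scores once; shuffling commutes with summation
        inputs = [
            d if isinstance(d, ValenceSums) else valence_sums(d) for d in inputs
        ]
    accuracies = np.empty(n_permutations)
    for i in range(n_permutations):
        for attempt in range(max_retries):
            try:
                trends = [_shuffled_trend(d, config, rng) for d in inputs]
                accuracies[i] = evaluate_cohort(trends, changes).accuracy
                break
            except EvaluationError:
                raise
            except Exception:  # degenerate shuffle: retry with a fresh one
                logger.exception("permutation %d failed (attempt %d)", i, attempt + 1)
                if attempt == max_retries - 1:
                    raise
    mean_accuracy = float(accuracies.mean())
    if p_observed is not None:
        z, p = compare_proportions(p_observed, mean_accuracy / 100.0, n)
    else:
        z, p = float("nan"), float("nan")
    return PermutationResult(
        n_permutations=n_permutations,
        accuracies=accuracies,
        mean_accuracy=mean_accuracy,
        z=z,
        p_one_sided=p,
    )


def symptom_changes(persons: pd.DataFrame) -> list[SymptomChange]:
    """SymptomChange records from a (person_id, baseline_sum, post_sum) table."""
    return [
        SymptomChange(str(r.person_id), float(r.baseline_sum), float(r.post_sum))
        for r in persons.itertuples(index=False)
    ]
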