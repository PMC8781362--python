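"""Kendall-tau trend of the predicted-change series and person classification.

A person whose predicted change in negative mental states rises
significantly over the diary period (positive Kendall tau, two-sided
P < alpha) is classified as heading toward symptom worsening; a significant
negative tau as heading toward improvement; anything else as no trend.
"""
from __future__ import annotations

import dataclasses
import logging
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .indicator import IndicatorSeries

logger = logging.getLogger(__name__)

WORSEN = "worsen"
IMPROVE = "improve"
NONE = "none"

MIN_WINDOWS = 3


@dataclasses.dataclass
class TrendResult:
    """Kendall tau of neg_change against window order, with classification."""

    person_id: str
    tau: float
    p_value: float
    trend_class: str
    n_windows: int
    tau_pos: float = float("nan")  # diagnostic: trend of pos_change


def classify(tau: float, p_value: float, alpha: float) -> str:
    if np.isnan(tau) or np.isnan(p_value) or p_value >= alpha:
        return NONE
    return WORSEN if tau > 0 else IMPROVE if tau < 0 else NONE


def kendall_trend(
    indicator: IndicatorSeries,
    alpha_trend: float = 0.05,
    end_window: int | None = None,
    diagnostic: bool = True,
) -> TrendResult:
    """Tau-b trend of the predicted change in negative mental states.

    ``end_window`` optionally restricts the trend to windows ending at or
    before that occasion (e.g. to stop at a known transition).  Fewer than
    3 windows yield an undefined trend classified as no-trend.  With
    ``diagnostic`` the positive-state trend ``tau_pos`` is also computed.
    """
    w = indicator.windows
    if end_window is not None:
        w = w[w["window_index"] <= end_window]
    order = w["window_index"].to_numpy()
    neg = w["neg_change"].to_numpy()
    n = len(w)
    if n < MIN_WINDOWS:
        logger.warning(
            "person %s: only %d usable windows, trend undefined",
            indicator.person_id, n,
        )
        return TrendResult(indicator.person_id, float("nan"), float("nan"), NONE, n)
    tau, p = stats.kendalltau(order, neg)
    if diagnostic:
        tau_pos, _ = stats.kendalltau(order, w["pos_change"].to_numpy())
    else:
        tau_pos = float("nan")
    return TrendResult(
        person_id=indicator.person_id,
        tau=float(tau),
        p_value=float(p),
        trend_class=classify(float(tau), float(p), alpha_trend),
        n_windows=n,
        tau_pos=float(tau_pos),
    )


def classify_cohort(trends: Iterable[TrendResult]) -> dict:
    """Cohort-level counts and percentages of trend classes.

    Also reports the mean and range of |tau| among persons with a
    significant trend.
    """
    trends = list(trends)
    n = len(trends)
    counts = {c: sum(t.trend_class == c for t in trends) for c in (WORSEN, IMPROVE, NONE)}
    sig_taus = np.array(
        [abs(t.tau) for t in trends if t.trend_class in (WORSEN, IMPROVE)]
    )
    return {
        "n_persons": n,
        "counts": counts,
        "percent": {c: 100.0 * k / n if n else float("nan") for c, k in counts.items()},
        "n_significant": int(counts[WORSEN] + counts[IMPROVE]),
        "mean_abs_tau_significant": float(sig_taus.mean()) if sig_taus.size else float("nan"),
        "range_abs_tau_significant": (
            (float(sig_taus.min()), float(sig_taus.max())) if sig_taus.size else None
        ),
    }


def trends_frame(trends: Iterable[TrendResult]) -> pd.DataFrame:
    """Tidy per-person trend table (person_id, n_windows, tau, p, class)."""
    return pd.DataFrame(
        [
            {
                "person_id": t.person_id,
                "n_windows": t.n_windows,
                "tau": t.tau,
                "p_value": t.p_value,
                "trend_class": t.trend_class,
            }
            for t in trends
        ]
    )
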