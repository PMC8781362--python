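"""Diary preprocessing: item selection, scale harmonization, valence sum scores.

Raw diary tables arrive as one rating per (person, occasion, item).  Analysis
operates on per-person occasion x item matrices with an equal number of
positive- and negative-valence mood items, all items on a common rating scale.
For cohort-scale data the per-occasion sums of positive and of negative items
replace the individual items, which stabilises the orientation of the first
principal component in short windows.
"""
from __future__ import annotations

import dataclasses
import logging
from collections import Counter
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

POSITIVE = "positive"
NEGATIVE = "negative"
VALENCES = (POSITIVE, NEGATIVE)


class PreprocessError(ValueError):
    """Raised when diary data violate a preprocessing contract."""


@dataclasses.dataclass
class DiaryTimeSeries:
    """One person's diary: an occasion x item rating matrix plus item metadata.

    Parameters
    ----------
    person_id
        Identifier of the diarist.
    ratings
        DataFrame indexed by strictly increasing occasion numbers (1-based),
        one column per item; ``NaN`` marks a missing rating.
    valence
        Item id -> ``"positive"`` | ``"negative"``.
    scale
        Item id -> ``(min, max)`` rating bounds.
    meta
        Free-form provenance (e.g. rescaling maps applied).
    """

    person_id: str
    ratings: pd.DataFrame
    valence: Mapping[str, str]
    scale: Mapping[str, tuple[float, float]]
    meta: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        occ = np.asarray(self.ratings.index)
        if len(occ) and not np.all(np.diff(occ) > 0):
            raise PreprocessError(
                f"occasions of person {self.person_id!r} are not strictly increasing"
            )
        for item in self.ratings.columns:
            if self.valence.get(item) not in VALENCES:
                raise PreprocessError(
                    f"item {item!r} lacks a positive/negative valence label"
                )
            if item not in self.scale:
                raise PreprocessError(f"item {item!r} lacks rating-scale bounds")
            lo, hi = self.scale[item]
            col = self.ratings[item].to_numpy(dtype=float)
            ok = np.isnan(col) | ((col >= lo - 1e-9) & (col <= hi + 1e-9))
            if not ok.all():
                bad = col[~ok][0]
                raise PreprocessError(
                    f"rating {bad} of item {item!r} outside scale [{lo}, {hi}]"
                )

    @property
    def occasions(self) -> np.ndarray:
        return self.ratings.index.to_numpy()

    @property
    def n_occasions(self) -> int:
        return len(self.ratings)

    def items_by_valence(self, valence: str) -> list[str]:
        return [c for c in self.ratings.columns if self.valence[c] == valence]


@dataclasses.dataclass
class ValenceSums:
    """Per-occasion sum scores of positive and of negative mood items."""

    person_id: str
    occasions: np.ndarray
    pos_sum: np.ndarray
    neg_sum: np.ndarray
    n_items_pos: int
    n_items_neg: int

    def matrix(self) -> np.ndarray:
        """Occasion x 2 array with columns (pos_sum, neg_sum)."""
        return np.column_stack([self.pos_sum, self.neg_sum])


def select_balanced_items(
    series: DiaryTimeSeries, item_list: Sequence[str]
) -> DiaryTimeSeries:
    """Restrict the diary to an explicit, valence-balanced item list.

    Raises if any requested item is unknown or if the list does not contain
    equally many positive- and negative-valence items.
    """
    unknown = [i for i in item_list if i not in series.ratings.columns]
    if unknown:
        raise LookupError(f"unknown items requested: {unknown}")
    counts = Counter(series.valence[i] for i in item_list)
    n_pos, n_neg = counts.get(POSITIVE, 0), counts.get(NEGATIVE, 0)
    if n_pos != n_neg:
        raise PreprocessError(
            f"item list is valence-imbalanced: {n_pos} positive vs {n_neg} negative"
        )
    return DiaryTimeSeries(
        person_id=series.person_id,
        ratings=series.ratings.loc[:, list(item_list)].copy(),
        valence={i: series.valence[i] for i in item_list},
        scale={i: series.scale[i] for i in item_list},
        meta=dict(series.meta),
    )


def harmonize_scales(
    series: DiaryTimeSeries, target_scale: tuple[float, float] | None = None
) -> DiaryTimeSeries:
    """Affinely map every item onto a common rating scale.

    The target defaults to the most common (min, max) bounds among the items;
    items already on the target scale are left untouched.  An item on
    [-3, 3] mapped to [0, 7] transforms as v -> (v + 3) * 7 / 6.  Applied
    mappings are recorded under ``meta["rescaled"]``.
    """
    if target_scale is None:
        counts = Counter(tuple(series.scale[i]) for i in series.ratings.columns)
        target_scale = counts.most_common(1)[0][0]
    t_lo, t_hi = map(float, target_scale)
    ratings = series.ratings.copy()
    scale = dict(series.scale)
    rescaled: dict[str, dict[str, float]] = {}
    for item in ratings.columns:
        lo, hi = map(float, scale[item])
        if (lo, hi) == (t_lo, t_hi):
            continue
        if hi <= lo:
            raise PreprocessError(f"item {item!r} has degenerate bounds [{lo}, {hi}]")
        slope = (t_hi - t_lo) / (hi - lo)
        ratings[item] = t_lo + (ratings[item] - lo) * slope
        scale[item] = (t_lo, t_hi)
        rescaled[item] = {"from_min": lo, "from_max": hi, "slope": slope}
    meta = dict(series.meta)
    if rescaled:
        meta.setdefault("rescaled", {}).update(rescaled)
        logger.debug(
            "person %s: rescaled %d items to [%g, %g]",
            series.person_id, len(rescaled), t_lo, t_hi,
        )
    return DiaryTimeSeries(series.person_id, ratings, series.valence, scale, meta)


def valence_sums(series: DiaryTimeSeries) -> ValenceSums:
    """Sum positive and negative items per occasion.

    An occasion with *any* missing item yields missing sums for both
    valences: partial sums over different item subsets would not be
    comparable across occasions.
    """
    pos_items = series.items_by_valence(POSITIVE)
    neg_items = series.items_by_valence(NEGATIVE)
    if len(pos_items) != len(neg_items):
        raise PreprocessError(
            f"valence_sums requires a balanced series, got "
            f"{len(pos_items)} positive vs {len(neg_items)} negative items"
        )
    complete = series.ratings.notna().all(axis=1).to_numpy()
    pos = series.ratings[pos_items].sum(axis=1).to_numpy(dtype=float)
    neg = series.ratings[neg_items].sum(axis=1).to_numpy(dtype=float)
    pos[~complete] = np.nan
    neg[~complete] = np.nan
    return ValenceSums(
        person_id=series.person_id,
        occasions=series.occasions.copy(),
        pos_sum=pos,
        neg_sum=neg,
        n_items_pos=len(pos_items),
        n_items_neg=len(neg_items),
    )
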