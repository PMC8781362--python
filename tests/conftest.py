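import numpy as np
import pandas as pd
import pytest

from ewsdir.indicator import IndicatorSeries
from ewsdir.preprocess import NEGATIVE, POSITIVE, DiaryTimeSeries


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_diary(values, valences, person_id="p001", scale=(0.0, 100.0), items=None):
    """Build a DiaryTimeSeries from an occasion x item array of floats.

    ``scale`` is either one (min, max) pair for all items or a dict keyed by
    item id.
    """
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    if items is None:
        items = [f"it{j}" for j in range(p)]
    ratings = pd.DataFrame(values, index=np.arange(1, n + 1), columns=items)
    if not isinstance(scale, dict):
        scale = {i: scale for i in items}
    return DiaryTimeSeries(
        person_id=person_id,
        ratings=ratings,
        valence=dict(zip(items, valences)),
        scale=scale,
    )


def make_indicator(neg_change, signs=None, person_id="p001", R=None, g1=None):
    """Hand-built two-variable IndicatorSeries for trend/correction tests."""
    neg_change = np.asarray(neg_change, dtype=float)
    n = len(neg_change)
    signs = (
        np.sign(neg_change).astype(int)
        if signs is None
        else np.asarray(signs, dtype=int)
    )
    signs[signs == 0] = 1
    R = np.abs(neg_change) if R is None else np.asarray(R, dtype=float)
    g1 = signs * 0.5 if g1 is None else np.asarray(g1, dtype=float)
    pos_change = -0.5 * neg_change
    windows = pd.DataFrame(
        {
            "window_index": np.arange(1, n + 1),
            "n_used": np.full(n, 60),
            "R": R,
            "g1": g1,
            "sign": signs,
            "pos_change": pos_change,
            "neg_change": neg_change,
            "corrected": np.zeros(n, dtype=bool),
        }
    )
    return IndicatorSeries(
        person_id=person_id,
        windows=windows,
        var_names=["pos_sum", "neg_sum"],
        valences=[POSITIVE, NEGATIVE],
        predicted=np.column_stack([pos_change, neg_change]),
        loadings=np.tile([-0.6, 0.8], (n, 1)),
    )
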