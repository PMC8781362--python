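"""Directional critical-slowing-down indicator via moving-window PCA.

Within each sliding window of the diary, the first principal component of
the window covariance matrix gives (i) the share of variance it explains,
R = lambda_1 / sum(lambda) -- the "length" of the indicator vector -- and
(ii) the skewness g1 of the scores projected on it, whose sign orients the
vector toward the heavier tail of the fluctuations, i.e. toward the state
the system is drifting to.  The per-window predicted-change vector is

    predicted_change = R * sign(g1) * loadings,

whose components along the negative- and positive-valence variables form the
per-person indicator series.  Two corrections for near-zero skews are
available: flipping short deviant sign runs, or dropping windows whose
skewness is not significantly different from zero.
"""
from __future__ import annotations

import dataclasses
import logging
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import NEGATIVE, POSITIVE, DiaryTimeSeries, ValenceSums, valence_sums

logger = logging.getLogger(__name__)

#: Absolute window-covariance trace below which a window counts as constant.
DEGENERATE_TRACE = 1e-10

#: Minimum sample size of the D'Agostino skewness z-test.
MIN_SKEWTEST_N = 8

FLIP_RUNS = "flip_runs"
DROP_NONSIGNIFICANT = "drop_nonsignificant"
NO_CORRECTION = "none"

ITEMS = "items"
SUMS = "sums"


class AnalysisError(ValueError):
    """Raised when analysis inputs violate a contract."""


class DegenerateWindowError(AnalysisError):
    """Raised for a window with (numerically) zero total variance."""


@dataclasses.dataclass
class AnalysisConfig:
    """Tunable parameters of the moving-window indicator.

    ``window_size`` defaults to 60 occasions, the sum-score cohort setting;
    the single-subject item-level setting uses 150.  ``min_complete`` is the
    fraction of a window that must be non-missing for the window to enter
    the analysis.
    """

    window_size: int = 60
    step: int = 1
    min_complete: float = 0.5
    skew_correction: str = FLIP_RUNS
    max_flip_run: int = 1
    alpha_skew: float = 0.05
    alpha_trend: float = 0.05
    granularity: str = SUMS

    def validate(self, series_length: int | None = None) -> None:
        if self.window_size < 2:
            raise AnalysisError("window_size must be >= 2")
        if series_length is not None and self.window_size > series_length:
            raise AnalysisError(
                f"window_size {self.window_size} exceeds series length {series_length}"
            )
        if self.step < 1:
            raise AnalysisError("step must be >= 1")
        if not 0.0 < self.min_complete <= 1.0:
            raise AnalysisError("min_complete must be in (0, 1]")
        if self.skew_correction not in (FLIP_RUNS, DROP_NONSIGNIFICANT, NO_CORRECTION):
            raise AnalysisError(f"unknown skew_correction {self.skew_correction!r}")
        if self.granularity not in (ITEMS, SUMS):
            raise AnalysisError(f"unknown granularity {self.granularity!r}")
        if self.max_flip_run < 1:
            raise AnalysisError("max_flip_run must be >= 1")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        return cls(**d)


@dataclasses.dataclass
class WindowIndicator:
    """Indicator quantities of a single window."""

    window_index: int
    R: float
    g1: float
    loadings: np.ndarray
    sign: int
    predicted_change: np.ndarray
    n_used: int


@dataclasses.dataclass
class IndicatorSeries:
    """Ordered per-window indicator records of one person.

    ``windows`` holds one row per retained window: window_index (occasion at
    the window end), n_used, R, g1, sign, pos_change, neg_change, corrected.
    ``predicted`` is the aligned n_windows x n_vars matrix of full
    predicted-change vectors and ``loadings`` the oriented unit eigenvectors.
    ``skipped`` records (window_index, reason) for excluded windows.
    """

    person_id: str
    windows: pd.DataFrame
    var_names: list[str]
    valences: list[str]
    predicted: np.ndarray
    loadings: np.ndarray
    skipped: list[tuple[int, str]] = dataclasses.field(default_factory=list)

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    @property
    def neg_change(self) -> np.ndarray:
        return self.windows["neg_change"].to_numpy()

    @property
    def pos_change(self) -> np.ndarray:
        return self.windows["pos_change"].to_numpy()


# ---------------------------------------------------------------------------
# window primitives


def slide_windows(
    values: np.ndarray,
    config: AnalysisConfig,
    occasions: np.ndarray | None = None,
) -> Iterator[tuple[int, np.ndarray]]:
    """Yield (window_index, complete-case matrix) for each retained window.

    Windows span ``window_size`` consecutive occasions and advance by
    ``step``; occasions with any missing value are dropped within a window,
    and windows with fewer than ``min_complete * window_size`` complete
    occasions (or fewer than 3) are skipped with a log entry.
    """
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    config.validate(series_length=n)
    if occasions is None:
        occasions = np.arange(1, n + 1)
    w = config.window_size
    min_rows = max(3, int(np.ceil(config.min_complete * w)))
    complete = np.all(np.isfinite(values), axis=1)
    for start in range(0, n - w + 1, config.step):
        rows = complete[start : start + w]
        end_index = int(occasions[start + w - 1])
        if rows.sum() < min_rows:
            logger.debug(
                "window ending at %d skipped: %d/%d complete occasions",
                end_index, int(rows.sum()), w,
            )
            yield end_index, None  # sentinel for "skipped"
            continue
        yield end_index, values[start : start + w][rows]


def first_component(
    window_matrix: np.ndarray, neg_cols: Sequence[int] | None = None
) -> tuple[np.ndarray, float, np.ndarray]:
    """First principal component of one window: (loadings, R, scores).

    Columns are centered within the window and the covariance matrix
    eigendecomposed; R is the top eigenvalue over the trace.  The
    eigenvector's sign ambiguity is resolved by requiring a non-negative
    loading on the negative-valence reference variable (the negative-valence
    column of largest absolute loading), so that direction is carried by the
    projected-score skewness alone.
    """
    X = np.asarray(window_matrix, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise AnalysisError("window matrix must be 2-D with >= 2 variables")
    if X.shape[0] < 2:
        raise AnalysisError("window must contain >= 2 complete occasions")
    if not np.all(np.isfinite(X)):
        raise AnalysisError("window matrix contains missing values")
    Xc = X - X.mean(axis=0)
    cov = Xc.T @ Xc / X.shape[0]
    trace = float(np.trace(cov))
    if trace <= DEGENERATE_TRACE:
        raise DegenerateWindowError("window has zero total variance")
    eigvals, eigvecs = np.linalg.eigh(cov)
    lam1 = float(eigvals[-1])
    loadings = eigvecs[:, -1].copy()
    R = min(max(lam1 / trace, 0.0), 1.0)
    loadings = _orient(loadings, neg_cols)
    scores = Xc @ loadings
    return loadings, R, scores


def _orient(loadings: np.ndarray, neg_cols: Sequence[int] | None) -> np.ndarray:
    """Canonical eigenvector orientation (negative-valence loading >= 0)."""
    if neg_cols is not None and len(neg_cols) > 0:
        neg_cols = np.asarray(neg_cols)
        ref = neg_cols[np.argmax(np.abs(loadings[neg_cols]))]
        pivot = loadings[ref]
    else:
        pivot = loadings[np.argmax(np.abs(loadings))]
    if pivot < 0:
        return -loadings
    if pivot == 0:
        nz = np.nonzero(loadings)[0]
        if nz.size and loadings[nz[0]] < 0:
            return -loadings
    return loadings


def projected_skewness(scores: np.ndarray) -> float:
    """Moment-based sample skewness g1 = m3 / m2^(3/2) of projected scores."""
    scores = np.asarray(scores, dtype=float)
    if scores.size < 3:
        raise AnalysisError("skewness requires >= 3 scores")
    d = scores - scores.mean()
    m2 = float(np.mean(d**2))
    if m2 == 0.0:
        return 0.0
    m3 = float(np.mean(d**3))
    return m3 / m2**1.5


def directional_vector(
    loadings: np.ndarray, R: float, g1: float, prev_sign: int | None = None
) -> tuple[int, np.ndarray]:
    """Skew-oriented predicted-change vector of one window.

    Returns (sign, R * sign * loadings): the vector points toward the
    heavier tail of the projected scores.  A tied skewness (g1 == 0)
    inherits the previous window's sign (else +1) to avoid spurious flips.
    """
    if g1 > 0:
        sign = 1
    elif g1 < 0:
        sign = -1
    else:
        sign = prev_sign if prev_sign in (1, -1) else 1
    return sign, R * sign * np.asarray(loadings, dtype=float)


def skew_pvalue(g1, n):
    """Two-sided p of the D'Agostino (1970) skewness z-test from (g1, n).

    Vectorized transformation of the sample skewness to an approximately
    standard-normal deviate; requires n >= 8 (smaller n yields NaN).
    Matches ``scipy.stats.skewtest`` evaluated on the raw scores.
    """
    g1 = np.asarray(g1, dtype=float)
    n = np.asarray(n, dtype=float)
    with np.errstate(all="ignore"):
        y = g1 * np.sqrt((n + 1.0) * (n + 3.0) / (6.0 * (n - 2.0)))
        beta2 = (
            3.0 * (n**2 + 27.0 * n - 70.0) * (n + 1.0) * (n + 3.0)
            / ((n - 2.0) * (n + 5.0) * (n + 7.0) * (n + 9.0))
        )
        W2 = -1.0 + np.sqrt(2.0 * (beta2 - 1.0))
        delta = 1.0 / np.sqrt(0.5 * np.log(W2))
        alpha = np.sqrt(2.0 / (W2 - 1.0))
        y = np.where(y == 0.0, 1.0, y)
        Z = delta * np.log(y / alpha + np.sqrt((y / alpha) ** 2 + 1.0))
        p = 2.0 * stats.norm.sf(np.abs(Z))
        p = np.where(n >= MIN_SKEWTEST_N, p, np.nan)
    return p if p.ndim else float(p)


# ---------------------------------------------------------------------------
# per-person analysis


def analyze_matrix(
    values: np.ndarray,
    config: AnalysisConfig,
    valences: Sequence[str],
    person_id: str = "",
    var_names: Sequence[str] | None = None,
    occasions: np.ndarray | None = None,
) -> IndicatorSeries:
    """Window-by-window indicator over an occasion x variable matrix.

    Reference implementation valid for any number of variables; missing
    occasions are rows of NaN.
    """
    values = np.asarray(values, dtype=float)
    if var_names is None:
        var_names = [f"v{j}" for j in range(values.shape[1])]
    valences = list(valences)
    if len(valences) != values.shape[1]:
        raise AnalysisError("one valence label per variable is required")
    neg_cols = [j for j, v in enumerate(valences) if v == NEGATIVE]
    pos_cols = [j for j, v in enumerate(valences) if v == POSITIVE]

    rows, predicted, loadings_out, skipped = [], [], [], []
    prev_sign: int | None = None
    for end_index, win in slide_windows(values, config, occasions):
        if win is None:
            skipped.append((end_index, "incomplete"))
            continue
        try:
            loadings, R, scores = first_component(win, neg_cols=neg_cols)
        except DegenerateWindowError:
            skipped.append((end_index, "degenerate"))
            logger.debug("window ending at %d degenerate (zero variance)", end_index)
            continue
        g1 = projected_skewness(scores)
        sign, change = directional_vector(loadings, R, g1, prev_sign)
        prev_sign = sign
        rows.append(
            {
                "window_index": end_index,
                "n_used": win.shape[0],
                "R": R,
                "g1": g1,
                "sign": sign,
                "pos_change": float(change[pos_cols].sum()),
                "neg_change": float(change[neg_cols].sum()),
                "corrected": False,
            }
        )
        predicted.append(change)
        loadings_out.append(loadings)
    return _assemble(person_id, rows, predicted, loadings_out, var_names,
                     valences, skipped)


def analyze_sums(
    sums: ValenceSums, config: AnalysisConfig, person_id: str | None = None
) -> IndicatorSeries:
    """Vectorized indicator over the (pos_sum, neg_sum) series.

    Equivalent to :func:`analyze_matrix` on the two-column sum matrix but
    computed from sliding raw moments in O(n), which makes the 200-fold
    permutation null affordable at cohort scale.  The 2x2 covariance
    eigenproblem is solved in closed form and the projected-score skewness
    from central bivariate moments up to order three.
    """
    pid = person_id if person_id is not None else sums.person_id
    pos = np.asarray(sums.pos_sum, dtype=float)
    neg = np.asarray(sums.neg_sum, dtype=float)
    n = len(pos)
    config.validate(series_length=n)
    w = config.window_size
    occ = np.asarray(sums.occasions)

    mask = np.isfinite(pos) & np.isfinite(neg)
    # global centering improves conditioning of the raw-moment differences
    x = np.where(mask, pos - (pos[mask].mean() if mask.any() else 0.0), 0.0)
    y = np.where(mask, neg - (neg[mask].mean() if mask.any() else 0.0), 0.0)
    m = mask.astype(float)

    def win(a: np.ndarray) -> np.ndarray:
        cs = np.concatenate([[0.0], np.cumsum(a)])
        return cs[w:] - cs[:-w]

    starts = np.arange(0, n - w + 1, config.step)
    sel = starts  # window start offsets into the length n-w+1 arrays
    k = win(m)[sel]
    Sx, Sy = win(x)[sel], win(y)[sel]
    Sxx, Sxy, Syy = win(x * x)[sel], win(x * y)[sel], win(y * y)[sel]
    Sx3, Sx2y = win(x**3)[sel], win(x * x * y)[sel]
    Sxy2, Sy3 = win(x * y * y)[sel], win(y**3)[sel]
    ends = occ[starts + w - 1].astype(int)

    with np.errstate(invalid="ignore", divide="ignore"):
        kk = np.where(k > 0, k, 1.0)
        mx, my = Sx / kk, Sy / kk
        Cxx = np.maximum(Sxx / kk - mx**2, 0.0)
        Cyy = np.maximum(Syy / kk - my**2, 0.0)
        Cxy = Sxy / kk - mx * my
        tr = Cxx + Cyy
        disc = np.sqrt(((Cxx - Cyy) / 2.0) ** 2 + Cxy**2)
        lam1 = tr / 2.0 + disc
        R = np.where(tr > 0, np.clip(lam1 / np.where(tr > 0, tr, 1.0), 0.0, 1.0), 0.0)

        v1, v2 = Cxy.copy(), lam1 - Cxx
        nrm = np.hypot(v1, v2)
        weak = nrm <= 1e-12 * np.maximum(tr, DEGENERATE_TRACE)
        v1 = np.where(weak, lam1 - Cyy, v1)
        v2 = np.where(weak, Cxy, v2)
        nrm = np.hypot(v1, v2)
        still = nrm <= 1e-12 * np.maximum(tr, DEGENERATE_TRACE)
        v1 = np.where(still, 0.0, v1)
        v2 = np.where(still, 1.0, v2)
        nrm = np.where(still, 1.0, nrm)
        v1, v2 = v1 / nrm, v2 / nrm
        # orientation: loading on the negative-valence sum >= 0
        flip = (v2 < 0) | ((v2 == 0) & (v1 < 0))
        v1, v2 = np.where(flip, -v1, v1), np.where(flip, -v2, v2)

        m30 = Sx3 / kk - 3.0 * mx * (Sxx / kk) + 2.0 * mx**3
        m21 = Sx2y / kk - my * (Sxx / kk) - 2.0 * mx * (Sxy / kk) + 2.0 * mx**2 * my
        m12 = Sxy2 / kk - mx * (Syy / kk) - 2.0 * my * (Sxy / kk) + 2.0 * my**2 * mx
        m03 = Sy3 / kk - 3.0 * my * (Syy / kk) + 2.0 * my**3
        m3s = v1**3 * m30 + 3.0 * v1**2 * v2 * m21 + 3.0 * v1 * v2**2 * m12 + v2**3 * m03
        g1 = np.where(lam1 > 0, m3s / np.where(lam1 > 0, lam1, 1.0) ** 1.5, 0.0)

    min_rows = max(3, int(np.ceil(config.min_complete * w)))
    usable = k >= min_rows
    degenerate = usable & (tr <= DEGENERATE_TRACE)
    keep = usable & ~degenerate

    skipped = [(int(e), "incomplete") for e in ends[~usable]]
    skipped += [(int(e), "degenerate") for e in ends[degenerate]]

    e_k, kept_k = ends[keep], k[keep].astype(int)
    R_k, g1_k = R[keep], g1[keep]
    v1_k, v2_k = v1[keep], v2[keep]

    sign = np.where(g1_k > 0, 1.0, np.where(g1_k < 0, -1.0, np.nan))
    if np.isnan(sign).any():
        sign = pd.Series(sign).ffill().fillna(1.0).to_numpy()
    pos_change = R_k * sign * v1_k
    neg_change = R_k * sign * v2_k

    windows = pd.DataFrame(
        {
            "window_index": e_k.astype(int),
            "n_used": kept_k,
            "R": R_k,
            "g1": g1_k,
            "sign": sign.astype(int),
            "pos_change": pos_change,
            "neg_change": neg_change,
            "corrected": np.zeros(len(e_k), dtype=bool),
        }
    )
    skipped.sort()
    return IndicatorSeries(
        person_id=pid,
        windows=windows,
        var_names=["pos_sum", "neg_sum"],
        valences=[POSITIVE, NEGATIVE],
        predicted=np.column_stack([pos_change, neg_change]),
        loadings=np.column_stack([v1_k, v2_k]),
        skipped=skipped,
    )


def _assemble(person_id, rows, predicted, loadings, var_names, valences, skipped):
    columns = ["window_index", "n_used", "R", "g1", "sign",
               "pos_change", "neg_change", "corrected"]
    windows = pd.DataFrame(rows, columns=columns)
    p = len(var_names)
    return IndicatorSeries(
        person_id=person_id,
        windows=windows,
        var_names=list(var_names),
        valences=list(valences),
        predicted=np.array(predicted).reshape(len(rows), p) if rows else np.empty((0, p)),
        loadings=np.array(loadings).reshape(len(rows), p) if rows else np.empty((0, p)),
        skipped=list(skipped),
    )


# ---------------------------------------------------------------------------
# sign corrections


def correct_sign_flips(
    indicator: IndicatorSeries, config: AnalysisConfig
) -> IndicatorSeries:
    """Reverse short deviant sign runs in the per-window direction sequence.

    Every maximal constant-sign run of length <= ``max_flip_run`` flanked on
    both sides by opposite-sign runs has its predicted-change vectors
    negated (the "vector flip"); e.g. signs (+,+,-,+,+) become all +.
    Passes repeat left-to-right until a fixpoint; boundary runs are never
    flipped.
    """
    signs = indicator.windows["sign"].to_numpy().copy()
    flipped = np.zeros(len(signs), dtype=bool)
    while True:
        runs = _sign_runs(signs)
        target = None
        for j in range(1, len(runs) - 1):
            lo, hi = runs[j]
            if hi - lo <= config.max_flip_run:
                target = (lo, hi)
                break
        if target is None:
            break
        lo, hi = target
        signs[lo:hi] *= -1
        flipped[lo:hi] = True  # runs only ever merge, so no flip is undone
    out = _copy_series(indicator)
    if flipped.any():
        w = out.windows
        mult = np.where(flipped, -1.0, 1.0)
        w["sign"] = (w["sign"].to_numpy() * np.where(flipped, -1, 1)).astype(int)
        w["pos_change"] = w["pos_change"].to_numpy() * mult
        w["neg_change"] = w["neg_change"].to_numpy() * mult
        w["corrected"] = w["corrected"].to_numpy() | flipped
        out.predicted = out.predicted * mult[:, None]
        logger.debug(
            "person %s: flipped %d window(s)", out.person_id, int(flipped.sum())
        )
    return out


def drop_nonsignificant_skews(
    indicator: IndicatorSeries, config: AnalysisConfig
) -> IndicatorSeries:
    """Remove windows whose projected-score skewness is compatible with zero.

    A window is retained only if the two-sided D'Agostino skewness z-test on
    its ``n_used`` scores rejects at ``alpha_skew``; windows too small for
    the test (n_used < 8) are removed as untestable.  Removals are logged in
    ``skipped``.
    """
    w = indicator.windows
    p = skew_pvalue(w["g1"].to_numpy(), w["n_used"].to_numpy())
    testable = w["n_used"].to_numpy() >= MIN_SKEWTEST_N
    keep = testable & (p < config.alpha_skew)
    skipped = list(indicator.skipped)
    for idx, e in zip(np.nonzero(~keep)[0], w["window_index"].to_numpy()[~keep]):
        reason = "nonsignificant_skew" if testable[idx] else "untestable_skew"
        skipped.append((int(e), reason))
    out = IndicatorSeries(
        person_id=indicator.person_id,
        windows=w.loc[keep].reset_index(drop=True),
        var_names=list(indicator.var_names),
        valences=list(indicator.valences),
        predicted=indicator.predicted[keep],
        loadings=indicator.loadings[keep],
        skipped=sorted(skipped),
    )
    logger.debug(
        "person %s: dropped %d/%d windows with nonsignificant skew",
        out.person_id, int((~keep).sum()), len(w),
    )
    return out


def _sign_runs(signs: np.ndarray) -> list[tuple[int, int]]:
    """Maximal constant-sign runs as half-open (start, stop) index pairs."""
    runs = []
    start = 0
    for i in range(1, len(signs) + 1):
        if i == len(signs) or signs[i] != signs[start]:
            runs.append((start, i))
            start = i
    return runs


def _copy_series(series: IndicatorSeries) -> IndicatorSeries:
    return IndicatorSeries(
        person_id=series.person_id,
        windows=series.windows.copy(),
        var_names=list(series.var_names),
        valences=list(series.valences),
        predicted=series.predicted.copy(),
        loadings=series.loadings.copy(),
        skipped=list(series.skipped),
    )


# ---------------------------------------------------------------------------
# public entry point


def compute_indicator(
    data: DiaryTimeSeries | ValenceSums,
    config: AnalysisConfig,
) -> IndicatorSeries:
    """Full per-person indicator: windows -> PCA -> direction -> correction.

    With ``granularity="sums"`` the analysis runs on the positive/negative
    sum scores (computing them first if a raw diary is supplied); with
    ``"items"`` it runs on the individual item matrix.
    """
    config.validate()
    if config.granularity == SUMS:
        sums = data if isinstance(data, ValenceSums) else valence_sums(data)
        series = analyze_sums(sums, config)
    else:
        if not isinstance(data, DiaryTimeSeries):
            raise AnalysisError("item-level analysis requires a DiaryTimeSeries")
        series = analyze_matrix(
            data.ratings.to_numpy(dtype=float),
            config,
            valences=[data.valence[c] for c in data.ratings.columns],
            person_id=data.person_id,
            var_names=list(data.ratings.columns),
            occasions=data.occasions,
        )
    if config.skew_correction == FLIP_RUNS:
        series = correct_sign_flips(series, config)
    elif config.skew_correction == DROP_NONSIGNIFICANT:
        series = drop_nonsignificant_skews(series, config)
    return series
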