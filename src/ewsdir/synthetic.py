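"""Synthetic diary cohorts driven by a bistable latent mood process.

The generator realises the dynamical scenario the indicator is built for: a
one-dimensional latent state x governed by the normal form of the fold
(saddle-node) bifurcation,

    dx = (x - x^3 + c(t)) dt + sigma dW,

with two stable states (x ~ -1: low negative affect, x ~ +1: high negative
affect) for |c| below the fold point c* = 2 / (3*sqrt(3)).  Slowly ramping the
control parameter c erodes the stability of the occupied basin, producing
critical slowing down (rising variance and skewness toward the opposing
basin) before an abrupt transition.  The latent state is rendered into
bounded mood items (negative-valence items load positively on x, positive
items negatively), whole diary occasions are dropped at random, and
interview-style severity sums are derived from the latent level at the start
and end of the diary period.
"""
from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from .preprocess import NEGATIVE, POSITIVE, DiaryTimeSeries

logger = logging.getLogger(__name__)

#: |c| at which one basin of x - x^3 + c vanishes (discriminant root).
FOLD_C = 2.0 / (3.0 * np.sqrt(3.0))

#: Latent level beyond which the trajectory counts as having arrived in the
#: opposing basin (midway between the unstable ridge and the far attractor).
BASIN_CROSSING = 0.5

#: Affine map from mean latent state to the 0-450 interview severity scale.
SEVERITY_OFFSET = 70.0
SEVERITY_SLOPE = 55.0
#: Occasions averaged at each end of the diary for the severity sums.
SEVERITY_SPAN = 7

#: Latent magnitude treated as numerical blow-up of the Euler scheme.
STATE_BOUND = 10.0

INCREASE, DECREASE, NONE = "increase", "decrease", "none"
DIRECTIONS = (INCREASE, DECREASE, NONE)


class SimulationError(RuntimeError):
    """Raised when the stochastic integration leaves the admissible range."""


class ConfigError(ValueError):
    """Raised for invalid simulation configurations."""


@dataclasses.dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    Defaults emulate a daily-diary cohort: up to 183 evening diaries of
    28 mood items (14 per valence) on a 0-100 visual-analogue scale, with
    11.45% of occasions missing and interview severity sums on 0-450.
    """

    n_persons: int = 122
    n_occasions: int = 183
    n_pos_items: int = 14
    n_neg_items: int = 14
    scale_min: float = 0.0
    scale_max: float = 100.0
    missing_rate: float = 0.1145
    dt: float = 0.1
    sigma: float = 0.12
    c_start: float = -0.2
    c_end: float = 0.55
    loading_range: tuple[float, float] = (15.0, 30.0)
    item_noise_sd: float = 6.0
    transition_fraction: float = 0.4
    seed: int = 0

    def validate(self) -> None:
        if not self.scale_min < self.scale_max:
            raise ConfigError("scale_min must be < scale_max")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigError(f"missing_rate {self.missing_rate} outside [0, 1)")
        if self.dt <= 0:
            raise ConfigError("dt must be > 0")
        if self.n_occasions < 2:
            raise ConfigError("n_occasions must be >= 2")
        if self.sigma < 0 or self.item_noise_sd < 0:
            raise ConfigError("noise levels must be >= 0")
        if not 0.0 <= self.transition_fraction <= 0.5:
            raise ConfigError("transition_fraction must be in [0, 0.5]")
        lo, hi = self.loading_range
        if not 0 <= lo <= hi:
            raise ConfigError("loading_range must satisfy 0 <= lo <= hi")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["loading_range"] = list(self.loading_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "loading_range" in d:
            d["loading_range"] = tuple(d["loading_range"])
        return cls(**d)


@dataclasses.dataclass
class LatentTrajectory:
    """Latent state and control parameter per occasion."""

    x: np.ndarray
    c: np.ndarray
    transition_occasion: int | None

    def __post_init__(self) -> None:
        if len(self.x) != len(self.c):
            raise ConfigError("x and c must have equal length")
        n = len(self.x)
        if self.transition_occasion is not None and not (
            1 <= self.transition_occasion <= n
        ):
            raise ConfigError("transition_occasion outside [1, n_occasions]")


@dataclasses.dataclass
class SyntheticCohort:
    """Generated diaries plus per-person ground truth.

    ``persons`` has one row per diary with columns person_id, direction
    (simulated scenario), transition_occasion, baseline_sum, post_sum and
    truth; truth is the realised symptom-change direction, i.e. the sign of
    post_sum - baseline_sum mapped to {increase, decrease, none}.
    """

    diaries: list[DiaryTimeSeries]
    persons: pd.DataFrame

    @property
    def baseline_sum(self) -> pd.Series:
        return self.persons.set_index("person_id")["baseline_sum"]

    @property
    def post_sum(self) -> pd.Series:
        return self.persons.set_index("person_id")["post_sum"]

    @property
    def truth(self) -> pd.Series:
        return self.persons.set_index("person_id")["truth"]


def stable_root(c: float, basin: str) -> float:
    """Stable equilibrium of x - x^3 + c in the requested basin.

    ``basin`` is ``"low"`` (x < 0) or ``"high"`` (x > 0); raises if that
    basin does not exist at this c.
    """
    roots = np.roots([1.0, 0.0, -1.0, -c])
    real = np.sort(roots[np.abs(roots.imag) < 1e-9].real)
    stable = [r for r in real if 1.0 - 3.0 * r * r < 0.0]
    want = [r for r in stable if (r < 0) == (basin == "low")]
    if not want:
        raise ConfigError(f"no stable {basin!r} basin at c={c:.4f}")
    return float(want[0] if basin == "low" else want[-1])


def simulate_latent_transition(
    config: SimulationConfig,
    direction: str,
    rng: np.random.Generator | None = None,
    x0: float | None = None,
) -> LatentTrajectory:
    """Integrate the fold normal form with a ramped control parameter.

    ``direction="increase"`` starts in the low basin and ramps c from
    ``c_start`` to ``c_end`` (toward the high-negative-affect attractor);
    ``"decrease"`` is the mirror image; ``"none"`` holds c at ``c_start``.
    Euler-Maruyama with one step of size ``dt`` per occasion.  ``x0``
    overrides the default start at the occupied basin's stable root.
    """
    config.validate()
    if direction not in DIRECTIONS:
        raise ConfigError(f"direction must be one of {DIRECTIONS}, got {direction!r}")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_occasions
    if direction == INCREASE:
        c = np.linspace(config.c_start, config.c_end, n)
        if x0 is None:
            x0 = stable_root(c[0], "low")
    elif direction == DECREASE:
        c = np.linspace(-config.c_start, -config.c_end, n)
        if x0 is None:
            x0 = stable_root(c[0], "high")
    else:
        c = np.full(n, config.c_start)
        if x0 is None:
            x0 = stable_root(c[0], "low")

    x = np.empty(n)
    x[0] = x0
    noise = rng.standard_normal(n - 1) * config.sigma * np.sqrt(config.dt)
    for t in range(n - 1):
        x[t + 1] = x[t] + (x[t] - x[t] ** 3 + c[t]) * config.dt + noise[t]
        if not np.isfinite(x[t + 1]) or abs(x[t + 1]) > STATE_BOUND:
            raise SimulationError(
                f"latent state diverged at occasion {t + 2} "
                f"(dt={config.dt}, sigma={config.sigma}): reduce dt or sigma"
            )

    start_side = np.sign(x0) if x0 != 0 else -1.0
    crossed = np.nonzero(-start_side * x > BASIN_CROSSING)[0]
    transition = int(crossed[0]) + 1 if crossed.size else None
    return LatentTrajectory(x=x, c=c, transition_occasion=transition)


def render_items(
    traj: LatentTrajectory,
    config: SimulationConfig,
    rng: np.random.Generator,
    person_id: str = "p001",
) -> DiaryTimeSeries:
    """Render the latent state into bounded mood-item ratings.

    Negative-valence item i reads midscale + b_i * x + noise, positive item j
    reads midscale - a_j * x + noise, with per-item loadings a, b drawn
    uniformly from ``loading_range``; values are clipped to the rating scale.
    """
    if not np.all(np.isfinite(traj.x)):
        raise SimulationError("latent trajectory contains non-finite values")
    config.validate()
    n = len(traj.x)
    mid = 0.5 * (config.scale_min + config.scale_max)
    lo, hi = config.loading_range
    pos_items = [f"pos_{j + 1:02d}" for j in range(config.n_pos_items)]
    neg_items = [f"neg_{i + 1:02d}" for i in range(config.n_neg_items)]
    a = rng.uniform(lo, hi, size=config.n_pos_items)
    b = rng.uniform(lo, hi, size=config.n_neg_items)
    x = traj.x[:, None]
    pos_vals = mid - x * a[None, :]
    neg_vals = mid + x * b[None, :]
    values = np.concatenate([pos_vals, neg_vals], axis=1)
    if config.item_noise_sd > 0:
        values = values + rng.normal(0.0, config.item_noise_sd, size=values.shape)
    values = np.clip(values, config.scale_min, config.scale_max)
    items = pos_items + neg_items
    ratings = pd.DataFrame(values, index=np.arange(1, n + 1), columns=items)
    valence = {i: POSITIVE for i in pos_items} | {i: NEGATIVE for i in neg_items}
    scale = {i: (config.scale_min, config.scale_max) for i in items}
    return DiaryTimeSeries(person_id, ratings, valence, scale)


def induce_missingness(
    series: DiaryTimeSeries, missing_rate: float, rng: np.random.Generator
) -> DiaryTimeSeries:
    """Blank whole diary occasions independently with the given probability.

    Diary entries are completed or skipped as a unit, so missingness is
    occasion-level and completely at random; series length is preserved.
    """
    if not 0.0 <= missing_rate < 1.0:
        raise ConfigError(f"missing_rate {missing_rate} outside [0, 1)")
    ratings = series.ratings.copy()
    missing = rng.random(len(ratings)) < missing_rate
    ratings.iloc[missing, :] = np.nan
    meta = dict(series.meta)
    meta["n_missing_occasions"] = int(missing.sum())
    return DiaryTimeSeries(series.person_id, ratings, series.valence, series.scale, meta)


def derive_symptom_scores(
    traj: LatentTrajectory, config: SimulationConfig
) -> tuple[int, int]:
    """Interview-style severity sums at baseline and post.

    Affine maps of the mean latent state over the first and last
    ``SEVERITY_SPAN`` occasions, rounded to integers (the interview sums
    items scored 0/1/2) and clipped to [0, 450].
    """
    if len(traj.x) < 2 * SEVERITY_SPAN:
        raise ConfigError(
            f"trajectory must have >= {2 * SEVERITY_SPAN} occasions for severity sums"
        )

    def to_sum(mean_x: float) -> int:
        raw = SEVERITY_OFFSET + SEVERITY_SLOPE * mean_x
        return int(np.clip(np.round(raw), 0, 450))

    baseline = to_sum(float(np.mean(traj.x[:SEVERITY_SPAN])))
    post = to_sum(float(np.mean(traj.x[-SEVERITY_SPAN:])))
    return baseline, post


def generate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate a full cohort: latent paths, items, missingness, severity.

    ``transition_fraction`` of persons are simulated toward the
    high-symptom attractor (direction increase), an equal share toward the
    low-symptom attractor, and the remainder with a constant control
    parameter.  The recorded ``truth`` is the realised sign of
    post_sum - baseline_sum.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_inc = int(round(config.transition_fraction * config.n_persons))
    n_dec = n_inc
    n_none = config.n_persons - n_inc - n_dec
    directions = [INCREASE] * n_inc + [DECREASE] * n_dec + [NONE] * n_none

    diaries: list[DiaryTimeSeries] = []
    rows = []
    for k, direction in enumerate(directions):
        pid = f"p{k + 1:03d}"
        traj = simulate_latent_transition(config, direction, rng)
        series = render_items(traj, config, rng, person_id=pid)
        series = induce_missingness(series, config.missing_rate, rng)
        baseline, post = derive_symptom_scores(traj, config)
        delta = post - baseline
        truth = INCREASE if delta > 0 else DECREASE if delta < 0 else NONE
        diaries.append(series)
        rows.append(
            {
                "person_id": pid,
                "direction": direction,
                "transition_occasion": traj.transition_occasion,
                "baseline_sum": baseline,
                "post_sum": post,
                "truth": truth,
            }
        )
    persons = pd.DataFrame(rows)
    logger.info(
        "generated cohort: %d persons (%d increase, %d decrease, %d none), seed=%d",
        config.n_persons, n_inc, n_dec, n_none, config.seed,
    )
    return SyntheticCohort(diaries=diaries, persons=persons)


def strong_transition_config(
    n_persons: int = 60, seed: int = 0, n_occasions: int = 183
) -> SimulationConfig:
    """Cohort preset with pronounced, low-noise basin switches.

    Every person undergoes a full transition (half toward each attractor):
    a deep control-parameter ramp with modest dynamical and observation
    noise, the regime in which the directional indicator is expected to work.
    """
    return SimulationConfig(
        n_persons=n_persons,
        n_occasions=n_occasions,
        sigma=0.10,
        item_noise_sd=4.0,
        c_start=-0.25,
        c_end=0.85,
        transition_fraction=0.5,
        seed=seed,
    )
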