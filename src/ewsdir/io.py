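"""Reading and writing the pipeline's tabular formats.

Diary data travel as long-format CSV (person_id, occasion, item_id,
valence, value; an empty value marks a skipped diary entry) with a
companion item-metadata CSV (item_id, valence, scale_min, scale_max).
Severity sums are a per-person CSV (person_id, baseline_sum, post_sum).
Every run writes a JSON manifest with the config snapshot, seed, input
digests and per-stage counters, which fully determines a rerun.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .evaluate import CohortEvaluation, PermutationResult, SymptomChange
from .indicator import AnalysisConfig, IndicatorSeries
from .preprocess import DiaryTimeSeries
from .synthetic import SimulationConfig, SyntheticCohort
from .trend import TrendResult, trends_frame

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """Raised for malformed input tables."""


# ---------------------------------------------------------------------------
# cohort output


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> dict[str, Path]:
    """Write diary.csv, items.csv and persons.csv for a synthetic cohort."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    frames = []
    for d in cohort.diaries:
        long = d.ratings.reset_index(names="occasion").melt(
            id_vars="occasion", var_name="item_id", value_name="value"
        )
        long.insert(0, "person_id", d.person_id)
        long["valence"] = long["item_id"].map(d.valence)
        frames.append(long)
    diary = pd.concat(frames, ignore_index=True)
    diary = diary.sort_values(["person_id", "occasion", "item_id"])
    diary_path = out / "diary.csv"
    diary[["person_id", "occasion", "item_id", "valence", "value"]].to_csv(
        diary_path, index=False
    )

    d0 = cohort.diaries[0]
    items = pd.DataFrame(
        {
            "item_id": list(d0.ratings.columns),
            "valence": [d0.valence[i] for i in d0.ratings.columns],
            "scale_min": [d0.scale[i][0] for i in d0.ratings.columns],
            "scale_max": [d0.scale[i][1] for i in d0.ratings.columns],
        }
    )
    items_path = out / "items.csv"
    items.to_csv(items_path, index=False)

    persons_path = out / "persons.csv"
    cohort.persons.to_csv(persons_path, index=False)
    return {"diary": diary_path, "items": items_path, "persons": persons_path}


# ---------------------------------------------------------------------------
# diary input


def read_items(items_csv: str | Path) -> pd.DataFrame:
    items = pd.read_csv(items_csv)
    required = {"item_id", "valence", "scale_min", "scale_max"}
    if not required.issubset(items.columns):
        raise FormatError(
            f"items file lacks columns {sorted(required - set(items.columns))}"
        )
    return items


def read_diaries(
    diary_csv: str | Path, items_csv: str | Path
) -> list[DiaryTimeSeries]:
    """Load long-format diary data into per-person time series.

    Occasions must be positive integers per person; occasions absent from
    the file (or with empty values) are treated as missing diary entries on
    the 1..max(occasion) grid.
    """
    diary = pd.read_csv(diary_csv)
    required = {"person_id", "occasion", "item_id", "value"}
    if not required.issubset(diary.columns):
        raise FormatError(
            f"diary file lacks columns {sorted(required - set(diary.columns))}"
        )
    if diary.empty:
        raise FormatError(f"diary file {diary_csv} contains no rows")
    items = read_items(items_csv)
    valence = dict(zip(items["item_id"], items["valence"]))
    scale = {
        r.item_id: (float(r.scale_min), float(r.scale_max))
        for r in items.itertuples(index=False)
    }
    unknown = set(diary["item_id"]) - set(valence)
    if unknown:
        raise FormatError(f"diary contains items missing from metadata: {sorted(unknown)}")

    out = []
    for pid, grp in diary.groupby("person_id", sort=True):
        wide = grp.pivot(index="occasion", columns="item_id", values="value")
        # absent occasions (skipped diary entries) become all-NaN rows
        wide = wide.reindex(np.arange(1, int(grp["occasion"].max()) + 1))
        wide = wide.reindex(columns=items["item_id"].tolist())
        out.append(DiaryTimeSeries(str(pid), wide, valence, scale))
    logger.info("read %d diaries from %s", len(out), diary_csv)
    return out


def read_wide_diaries(
    wide_csv: str | Path, mapping_csv: str | Path
) -> list[DiaryTimeSeries]:
    """Wide layout: one row per (person_id, occasion), one column per item.

    The mapping file is an item-metadata CSV whose item_id values name the
    wide columns to use.
    """
    wide = pd.read_csv(wide_csv)
    if not {"person_id", "occasion"}.issubset(wide.columns):
        raise FormatError("wide diary file needs person_id and occasion columns")
    items = read_items(mapping_csv)
    missing = set(items["item_id"]) - set(wide.columns)
    if missing:
        raise FormatError(f"wide file lacks item columns {sorted(missing)}")
    long = wide.melt(
        id_vars=["person_id", "occasion"],
        value_vars=items["item_id"].tolist(),
        var_name="item_id",
        value_name="value",
    )
    tmp = Path(wide_csv).with_suffix(".long.tmp.csv")
    try:
        long.to_csv(tmp, index=False)
        return read_diaries(tmp, mapping_csv)
    finally:
        tmp.unlink(missing_ok=True)


def read_changes(changes_csv: str | Path) -> list[SymptomChange]:
    df = pd.read_csv(changes_csv)
    required = {"person_id", "baseline_sum", "post_sum"}
    if not required.issubset(df.columns):
        raise FormatError(
            f"changes file lacks columns {sorted(required - set(df.columns))}"
        )
    return [
        SymptomChange(str(r.person_id), float(r.baseline_sum), float(r.post_sum))
        for r in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# analysis output


def indicator_frame(series_list: Iterable[IndicatorSeries]) -> pd.DataFrame:
    """Tidy per-window indicator table across persons."""
    frames = []
    for s in series_list:
        df = s.windows.copy()
        df.insert(0, "person_id", s.person_id)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def write_indicators(series_list: Iterable[IndicatorSeries], path: str | Path) -> None:
    indicator_frame(series_list).to_csv(path, index=False)


def write_trends(trends: Iterable[TrendResult], path: str | Path) -> None:
    trends_frame(trends).to_csv(path, sep="\t", index=False)


def read_trends(path: str | Path) -> list[TrendResult]:
    df = pd.read_csv(path, sep="\t")
    return [
        TrendResult(
            person_id=str(r.person_id),
            tau=float(r.tau),
            p_value=float(r.p_value),
            trend_class=str(r.trend_class),
            n_windows=int(r.n_windows),
        )
        for r in df.itertuples(index=False)
    ]


def write_summary(
    evaluation: CohortEvaluation,
    path: str | Path,
    permutation: PermutationResult | None = None,
    config: AnalysisConfig | None = None,
    seed: int | None = None,
) -> dict:
    """Summary JSON: accuracy, TPR, quantile accuracies, permutation z/p."""
    summary: dict = {
        "n_total": evaluation.n_total,
        "n_matched": evaluation.n_matched,
        "n_significant": evaluation.n_significant,
        "accuracy_percent": round(evaluation.accuracy, 2),
        "true_positive_rate_percent": round(evaluation.tpr, 2),
        "true_positive_rate_strict_percent": round(evaluation.tpr_strict, 2),
        "quantile_accuracy_percent": {
            str(q): (None if v is None else round(v, 2))
            for q, v in evaluation.quantile_accuracy.items()
        },
    }
    if permutation is not None:
        summary["permutation"] = {
            "n_permutations": permutation.n_permutations,
            "mean_accuracy_percent": round(permutation.mean_accuracy, 2),
            "z": None if np.isnan(permutation.z) else round(permutation.z, 3),
            "p_one_sided": (
                None if np.isnan(permutation.p_one_sided)
                else round(permutation.p_one_sided, 4)
            ),
        }
    if config is not None:
        cfg = config.to_dict()
        summary["config"] = cfg
        summary["config_sha256"] = hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()
        ).hexdigest()
    if seed is not None:
        summary["seed"] = seed
    Path(path).write_text(json.dumps(summary, indent=2) + "\n")
    return summary


# ---------------------------------------------------------------------------
# manifest


def file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    path: str | Path,
    config: SimulationConfig | AnalysisConfig | dict | None,
    seed: int | None,
    inputs: Sequence[str | Path] = (),
    counters: dict | None = None,
) -> dict:
    from . import __version__

    if dataclasses.is_dataclass(config):
        config = config.to_dict()  # type: ignore[union-attr]
    manifest = {
        "version": __version__,
        "config": config,
        "seed": seed,
        "inputs": {str(p): file_digest(p) for p in inputs},
        "counters": counters or {},
    }
    Path(path).write_text(json.dumps(manifest, indent=2) + "\n")
    logger.info("manifest written to %s (seed=%s)", path, seed)
    return manifest


def load_config(path: str | Path | None, cls, **overrides):
    """Build a config dataclass from a YAML/JSON file plus CLI overrides."""
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise FormatError(f"config file {path} must contain a mapping")
    data.update({k: v for k, v in overrides.items() if v is not None})
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise FormatError(f"unknown config fields for {cls.__name__}: {sorted(unknown)}")
    return cls.from_dict(data)
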