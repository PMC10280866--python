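"""Screening-performance metrics: TD, ATD, recall curves, RRF@X, WSS@Y.

All metrics are computed from the ordered labeling log of a trial.  With N
records of which R are relevant:

* recall(s) — relevant found in the first s steps, divided by R.  Priors
  count as screened steps and the relevant prior counts toward the numerator,
  so curves start above zero.
* RRF@X — 100 * recall(floor(X/100 * N)): the proportion of relevant records
  found after screening X% of the pool.
* WSS@Y — with s* the first step where recall >= Y,
  100 * ((N - s*)/N - (1 - Y)): work saved relative to random-order
  screening at recall level Y.  Negative for worse-than-random orders.
* TD — for one relevant record, the step at which it was labeled.  In trials
  where the record served as a prior its TD is undefined and excluded.
* ATD — TD summarized over records and trials, as a percent of N.  The
  record-ATD averages each record's TD over trials first, then over records;
  the simulation-ATD averages within each trial first, then over trials.
  The two orders coincide on complete designs (no prior exclusions) and
  generally differ otherwise.

Trial-level spread is reported as mean / sample SD / SEM; between-model
spread as median / MAD (raw, no consistency constant).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .corpus import LabeledCorpus
from .engine import ScreeningResult

__all__ = [
    "MetricError",
    "RecallCurve",
    "TDRecord",
    "recall_curve",
    "rrf_at",
    "wss_at",
    "time_to_discovery",
    "record_atd",
    "simulation_atd",
    "aggregate_trials",
    "aggregate_models",
    "mean_recall_curve",
    "metrics_table",
    "aggregate_metrics_table",
]


class MetricError(Exception):
    """A metric is undefined for the given input."""


@dataclass(frozen=True)
class RecallCurve:
    """Step-function recall: at step s, proportion_screened = s/N."""

    recall: np.ndarray  # length N, recall after each step
    n_records: int
    n_relevant: int

    @property
    def proportion_screened(self) -> np.ndarray:
        return np.arange(1, self.n_records + 1) / self.n_records


def _found_counts(result: ScreeningResult) -> np.ndarray:
    return np.cumsum(result.labels_in_order)


def recall_curve(result: ScreeningResult, n_relevant: int) -> RecallCurve:
    """Cumulative recall after each step (priors included)."""
    if n_relevant < 1:
        raise MetricError("n_relevant must be >= 1")
    found = _found_counts(result)
    if found[-1] != n_relevant:
        raise MetricError(
            f"log contains {found[-1]} relevant events but n_relevant={n_relevant}"
        )
    return RecallCurve(recall=found / n_relevant, n_records=result.n_records, n_relevant=n_relevant)


def rrf_at(result: ScreeningResult, n_relevant: int, x_percent: float) -> float:
    """Relevant Records Found after screening x% of the pool, on a 0-100 scale."""
    if not 0 < x_percent <= 100:
        raise MetricError(f"x_percent must be in (0, 100], got {x_percent}")
    recall_curve(result, n_relevant)  # validates the relevant count
    s = max(int(math.floor(x_percent / 100.0 * result.n_records)), 1)
    found = int(_found_counts(result)[s - 1])
    return 100.0 * found / n_relevant


def wss_at(result: ScreeningResult, n_relevant: int, recall_level: float) -> float:
    """Work Saved over Sampling at a recall level, on a 0-100 scale.

    s* is the first step whose recall reaches the level (no interpolation);
    WSS = 100 * ((N - s*)/N - (1 - level)).  May be negative.
    """
    if not 0 < recall_level <= 1:
        raise MetricError(f"recall_level must be in (0, 1], got {recall_level}")
    curve = recall_curve(result, n_relevant)
    s_star = int(np.argmax(curve.recall >= recall_level)) + 1
    return 100.0 * ((result.n_records - s_star) / result.n_records - (1.0 - recall_level))


@dataclass(frozen=True)
class TDRecord:
    """Per-trial Times to Discovery of one relevant record.

    ``per_trial`` maps trial -> step, or None where the record was a prior
    (no discovery happened; excluded from the average).
    """

    record_id: str
    per_trial: dict[int, int | None]

    @property
    def defined(self) -> list[int]:
        return [v for v in self.per_trial.values() if v is not None]

    @property
    def average_record_td(self) -> float:
        vals = self.defined
        if not vals:
            raise MetricError(f"record {self.record_id!r} was a prior in every trial; TD undefined")
        return sum(vals) / len(vals)


def time_to_discovery(results: Sequence[ScreeningResult], record_id: str) -> TDRecord:
    """TD of one relevant record across trials (prior trials excluded)."""
    per_trial: dict[int, int | None] = {}
    for r in results:
        step = r.step_of(record_id)  # KeyError if absent
        label = next(lab for s, rid, lab in r.events if rid == record_id)
        if label != 1:
            raise MetricError(f"record {record_id!r} is not relevant")
        per_trial[r.trial] = None if record_id in r.prior_ids else step
    return TDRecord(record_id=record_id, per_trial=per_trial)


def _relevant_ids(results: Sequence[ScreeningResult]) -> list[str]:
    return [rid for _, rid, lab in results[0].events if lab == 1]


def record_atd(results: Sequence[ScreeningResult], corpus: LabeledCorpus | None = None) -> float:
    """Record-first ATD as a percent of N.

    Average each relevant record's TD over the trials where it was not a
    prior, then average those over records; records that were priors in every
    trial are excluded.
    """
    if not results:
        raise MetricError("no screening results")
    n = results[0].n_records
    if corpus is not None:
        rel_ids = [r.record_id for r in corpus if r.label == 1]
    else:
        rel_ids = _relevant_ids(results)
    avgs = []
    for rid in rel_ids:
        td = time_to_discovery(results, rid)
        if td.defined:
            avgs.append(td.average_record_td)
        else:
            warnings.warn(
                f"record {rid!r} was a prior in every trial; excluded from record-ATD",
                stacklevel=2,
            )
    if not avgs:
        raise MetricError("no relevant record has a defined TD")
    return 100.0 * (sum(avgs) / len(avgs)) / n


def simulation_atd(results: Sequence[ScreeningResult], corpus: LabeledCorpus | None = None) -> float:
    """Trial-first ATD as a percent of N.

    Average TDs of the non-prior relevant records within each trial, then
    average the per-trial means over trials.
    """
    if not results:
        raise MetricError("no screening results")
    n = results[0].n_records
    per_run = []
    for r in results:
        tds = [s for s, rid, lab in r.events if lab == 1 and rid not in r.prior_ids]
        if tds:
            per_run.append(sum(tds) / len(tds))
    if not per_run:
        raise MetricError("no trial has a defined TD")
    return 100.0 * (sum(per_run) / len(per_run)) / n


def aggregate_trials(values: Sequence[float]) -> tuple[float, float | None, float | None]:
    """(mean, sample SD, SEM) across trials; dispersion None for a single value."""
    vals = np.asarray(values, dtype=float)
    if vals.size == 0:
        raise MetricError("cannot aggregate an empty list")
    if vals.size == 1:
        return float(vals[0]), None, None
    sd = float(np.std(vals, ddof=1))
    return float(np.mean(vals)), sd, sd / math.sqrt(vals.size)


def aggregate_models(values: Sequence[float]) -> tuple[float, float]:
    """(median, MAD) across models; MAD is the raw median absolute deviation."""
    vals = np.asarray(values, dtype=float)
    if vals.size == 0:
        raise MetricError("cannot aggregate an empty list")
    med = float(np.median(vals))
    return med, float(np.median(np.abs(vals - med)))


def mean_recall_curve(
    results: Sequence[ScreeningResult], n_relevant: int
) -> pd.DataFrame:
    """Pointwise mean recall and SEM band across trials.

    Returns a frame with columns step, proportion_screened, mean_recall, sem.
    """
    if not results:
        raise MetricError("no screening results")
    n = results[0].n_records
    if any(r.n_records != n for r in results):
        raise MetricError("results mix different corpus sizes")
    curves = np.stack([recall_curve(r, n_relevant).recall for r in results])
    mean = curves.mean(axis=0)
    if len(results) > 1:
        sem = curves.std(axis=0, ddof=1) / math.sqrt(len(results))
    else:
        sem = np.zeros(n)
    return pd.DataFrame(
        {
            "step": np.arange(1, n + 1),
            "proportion_screened": np.arange(1, n + 1) / n,
            "mean_recall": mean,
            "sem": sem,
        }
    )


def metrics_table(
    results: Sequence[ScreeningResult],
    n_relevant: int,
    rrf_levels: Sequence[float] = (10,),
    wss_levels: Sequence[float] = (95,),
    dataset: str = "dataset",
    classifier: str = "",
    features: str = "",
) -> pd.DataFrame:
    """Per-trial metric rows: ATD (trial-level), WSS@Y, RRF@X, on 0-100 scales."""
    rows = []
    for r in results:
        row: dict[str, object] = {
            "dataset": dataset,
            "classifier": classifier,
            "features": features,
            "trial": r.trial,
            "atd": simulation_atd([r]),
        }
        for y in wss_levels:
            row[f"wss{int(y)}"] = wss_at(r, n_relevant, y / 100.0)
        for x in rrf_levels:
            row[f"rrf{int(x)}"] = rrf_at(r, n_relevant, x)
        rows.append(row)
    return pd.DataFrame(rows)


def aggregate_metrics_table(table: pd.DataFrame) -> pd.DataFrame:
    """Mean / SD / SEM across trials for each metric column of a metrics table."""
    metric_cols = [c for c in table.columns if c not in ("dataset", "classifier", "features", "trial")]
    rows = []
    for (ds, clf, feat), grp in table.groupby(["dataset", "classifier", "features"], sort=False):
        row: dict[str, object] = {"dataset": ds, "classifier": clf, "features": feat}
        for c in metric_cols:
            mean, sd, sem = aggregate_trials(grp[c].tolist())
            row[f"{c}_mean"] = mean
            row[f"{c}_sd"] = sd
            row[f"{c}_sem"] = sem
        rows.append(row)
    return pd.DataFrame(rows)
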