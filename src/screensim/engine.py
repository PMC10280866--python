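"""The screening simulation engine.

A simulation re-enacts title/abstract screening with an active-learning model
on a fully labeled corpus: the recorded labels play the human reviewer.  Each
trial starts from a prior set of one relevant and one irrelevant record, then
loops — rebalance the labeled set (dynamic resampling), fit the classifier,
query the single highest-scoring unlabeled record (certainty-based selection,
batch size 1), reveal its true label — until the pool is exhausted.  Every
trial therefore ends with all records labeled and recall exactly 1.

Trials are repeated (default 15) with prior sets drawn independently per
trial; the prior sets depend only on the corpus and the master seed, so every
model simulated on the same corpus sees the same priors and is directly
comparable.

Seed discipline: the master seed fans out through named ``SeedSequence``
substreams — (0, trial) for priors, (1, trial) for the trial's run stream,
(2,) for embedding training — so changing the number of trials never
perturbs earlier trials.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .balance import DRParams, dynamic_resample
from .classifiers import ModelConfig, fit_and_score
from .corpus import DataError, LabeledCorpus
from .features import FeatureMatrix, extract_paragraph_vectors, extract_tfidf

__all__ = [
    "PriorSet",
    "ScreeningResult",
    "PriorError",
    "sample_priors",
    "simulate_run",
    "simulate_trials",
    "extract_features",
    "write_results_jsonl",
    "read_results_jsonl",
]


class PriorError(Exception):
    """No valid prior pair can be drawn from the corpus."""


@dataclass(frozen=True)
class PriorSet:
    """The two prior records (one relevant, one irrelevant) of a trial."""

    relevant_id: str
    irrelevant_id: str
    trial: int


@dataclass(frozen=True)
class ScreeningResult:
    """One trial's full ordered labeling log.

    ``events`` holds (step, record_id, label) for steps 1..N; steps 1 and 2
    are the relevant and irrelevant prior.  Every corpus record appears
    exactly once.  A log that replays an externally given ordering (e.g. a
    random-order baseline) carries no prior structure: ``prior_ids = ()``.
    """

    trial: int
    seed: int
    prior_ids: tuple[str, ...]
    events: tuple[tuple[int, str, int], ...]
    n_records: int

    def __post_init__(self) -> None:
        if len(self.events) != self.n_records:
            raise DataError(
                f"trial {self.trial}: {len(self.events)} events for {self.n_records} records"
            )
        steps = [e[0] for e in self.events]
        if steps != list(range(1, self.n_records + 1)):
            raise DataError(f"trial {self.trial}: steps are not consecutive 1..N")
        if len({e[1] for e in self.events}) != self.n_records:
            raise DataError(f"trial {self.trial}: a record appears more than once")
        if self.prior_ids:
            if (self.events[0][1], self.events[1][1]) != self.prior_ids:
                raise DataError(f"trial {self.trial}: events 1-2 do not match the priors")
            if (self.events[0][2], self.events[1][2]) != (1, 0):
                raise DataError(
                    f"trial {self.trial}: priors must be one relevant then one irrelevant"
                )

    @property
    def labels_in_order(self) -> np.ndarray:
        return np.array([e[2] for e in self.events], dtype=int)

    def step_of(self, record_id: str) -> int:
        for step, rid, _ in self.events:
            if rid == record_id:
                return step
        raise KeyError(record_id)


def sample_priors(corpus: LabeledCorpus, n_trials: int, seed: int) -> list[PriorSet]:
    """Draw one (relevant, irrelevant) prior pair per trial.

    Each class member is drawn uniformly from its class, from an independent
    seeded substream per trial.  The same seed and corpus always give the
    same list, which is reused for every model on that corpus.
    """
    labels = np.array(corpus.labels)
    rel = np.flatnonzero(labels == 1)
    irr = np.flatnonzero(labels == 0)
    if rel.size == 0 or irr.size == 0:
        raise PriorError("corpus must contain at least one record of each class")
    priors = []
    for t in range(1, n_trials + 1):
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(0, t)))
        priors.append(
            PriorSet(
                relevant_id=corpus[int(rng.choice(rel))].record_id,
                irrelevant_id=corpus[int(rng.choice(irr))].record_id,
                trial=t,
            )
        )
    return priors


def extract_features(corpus: LabeledCorpus, config: ModelConfig) -> FeatureMatrix:
    """Feature matrix for a model config (computed once per corpus)."""
    hp = dict(getattr(config, "feature_params", {}) or {})
    if config.feature_kind == "tfidf":
        return extract_tfidf(corpus, **hp)
    d2v_seed = int(
        np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(2,))).integers(2**31)
    )
    return extract_paragraph_vectors(corpus, seed=d2v_seed, **hp)


def simulate_run(
    features: FeatureMatrix,
    labels: Sequence[int],
    config: ModelConfig,
    priors: PriorSet,
    run_seed: int,
    record_ids: Sequence[str] | None = None,
) -> ScreeningResult:
    """One full screening trial: label priors, then fit-rank-query-label to exhaustion.

    Ties in relevance score break toward the lowest record index.  Fully
    deterministic given the seeds.
    """
    labels = np.asarray(labels, dtype=int)
    n = labels.size
    if n < 3:
        raise DataError(f"pool of {n} records is too small to simulate")
    if features.n != n:
        raise DataError("feature matrix and labels disagree on N")
    ids = list(record_ids) if record_ids is not None else [f"{i:06d}" for i in range(n)]
    id_to_idx = {rid: i for i, rid in enumerate(ids)}
    i_rel = id_to_idx[priors.relevant_id]
    i_irr = id_to_idx[priors.irrelevant_id]
    if labels[i_rel] != 1 or labels[i_irr] != 0:
        raise PriorError("prior labels do not match the corpus labels")

    rng = np.random.default_rng(np.random.SeedSequence(run_seed, spawn_key=(3,)))
    clf_seed = int(np.random.default_rng(np.random.SeedSequence(run_seed, spawn_key=(4,))).integers(2**31))
    spec = type(config.classifier)(
        kind=config.classifier.kind,
        hyperparameters=config.classifier.hyperparameters,
        seed=clf_seed,
    )

    labeled: list[int] = [i_rel, i_irr]
    in_pool = np.ones(n, dtype=bool)
    in_pool[[i_rel, i_irr]] = False
    events: list[tuple[int, str, int]] = [
        (1, ids[i_rel], int(labels[i_rel])),
        (2, ids[i_irr], int(labels[i_irr])),
    ]
    step = 3
    while in_pool.any():
        pool = np.flatnonzero(in_pool)  # ascending: argmax tie-breaks to lowest index
        train = dynamic_resample(labeled, labels[labeled], N=n, params=config.balance, rng=rng)
        scores = fit_and_score(spec, features, train, labels[train], pool)
        chosen = int(pool[int(np.argmax(scores))])
        events.append((step, ids[chosen], int(labels[chosen])))
        in_pool[chosen] = False
        labeled.append(chosen)
        step += 1
    return ScreeningResult(
        trial=priors.trial,
        seed=run_seed,
        prior_ids=(priors.relevant_id, priors.irrelevant_id),
        events=tuple(events),
        n_records=n,
    )


def simulate_trials(
    corpus: LabeledCorpus,
    config: ModelConfig,
    seed: int | None = None,
    features: FeatureMatrix | None = None,
    priors: Sequence[PriorSet] | None = None,
) -> list[ScreeningResult]:
    """Run ``config.n_trials`` independent trials on a corpus.

    Features are computed once and priors sampled once; each trial runs with
    its own derived seed.  ``features``/``priors`` may be passed in to share
    them across models on the same corpus.
    """
    corpus.validate_for_simulation()
    if seed is None:
        seed = config.seed
    if features is None:
        features = extract_features(corpus, config)
    if priors is None:
        priors = sample_priors(corpus, config.n_trials, seed)
    results = []
    for prior in priors[: config.n_trials]:
        run_seed = int(
            np.random.default_rng(
                np.random.SeedSequence(seed, spawn_key=(1, prior.trial))
            ).integers(2**31)
        )
        results.append(
            simulate_run(
                features,
                corpus.labels,
                config,
                prior,
                run_seed,
                record_ids=corpus.record_ids,
            )
        )
    return results


# ---------------------------------------------------------------------------
# Screening-log interchange: JSON Lines, one object per trial
# ---------------------------------------------------------------------------


def write_results_jsonl(results: Iterable[ScreeningResult], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for r in results:
            obj = {
                "trial": r.trial,
                "seed": r.seed,
                "prior_record_ids": list(r.prior_ids),
                "events": [
                    {"step": s, "record_id": rid, "label": lab} for s, rid, lab in r.events
                ],
            }
            fh.write(json.dumps(obj, sort_keys=True) + "\n")


def read_results_jsonl(path: str | Path) -> list[ScreeningResult]:
    results = []
    with Path(path).open(encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            obj = json.loads(line)
            events = tuple(
                (e["step"], e["record_id"], int(e["label"])) for e in obj["events"]
            )
            results.append(
                ScreeningResult(
                    trial=obj["trial"],
                    seed=obj["seed"],
                    prior_ids=tuple(obj["prior_record_ids"]),
                    events=events,
                    n_records=len(events),
                )
            )
    return results
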