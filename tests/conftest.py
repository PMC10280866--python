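"""Shared fixtures: tiny hand-built corpora and screening-log factories."""

from __future__ import annotations

import numpy as np
import pytest

from screensim import (
    LabeledCorpus,
    LabeledRecord,
    ScreeningResult,
    SynthSpec,
    generate_corpus,
)


def make_corpus(rows: list[tuple[str, str, str, int]]) -> LabeledCorpus:
    return LabeledCorpus(
        records=tuple(LabeledRecord(record_id=r, title=t, abstract=a, label=l) for r, t, a, l in rows)
    )


def make_result(
    labels: list[int], trial: int = 1, seed: int = 0, with_priors: bool = False
) -> ScreeningResult:
    """Screening log straight from an ordered label list.

    With ``with_priors`` the first two steps (which must then be labeled 1, 0)
    are marked as the trial's prior records.
    """
    ids = [f"r{i}" for i in range(len(labels))]
    events = tuple((i + 1, ids[i], labels[i]) for i in range(len(labels)))
    priors = (ids[0], ids[1]) if with_priors else ()
    return ScreeningResult(
        trial=trial, seed=seed, prior_ids=priors, events=events, n_records=len(labels)
    )


def random_order_result(n: int, r: int, rng: np.random.Generator, trial: int = 1) -> ScreeningResult:
    """Log of a uniformly random screening order with r relevant among n."""
    labels = np.zeros(n, dtype=int)
    labels[rng.choice(n, size=r, replace=False)] = 1
    ids = [f"r{i}" for i in range(n)]
    events = tuple((i + 1, ids[i], int(labels[i])) for i in range(n))
    return ScreeningResult(trial=trial, seed=0, prior_ids=(), events=events, n_records=n)


@pytest.fixture
def toy_corpus() -> LabeledCorpus:
    """Six records, two relevant sharing token 'xx', four irrelevant sharing 'yy'."""
    return make_corpus(
        [
            ("a", "xx study", "xx xx topic one", 1),
            ("b", "xx trial", "xx xx topic two", 1),
            ("c", "yy survey", "yy yy other three", 0),
            ("d", "yy review", "yy yy other four", 0),
            ("e", "yy report", "yy yy other five", 0),
            ("f", "yy note", "yy yy other six", 0),
        ]
    )


@pytest.fixture(scope="session")
def synth_small() -> LabeledCorpus:
    """Separable synthetic pool small enough for per-test simulation."""
    return generate_corpus(SynthSpec(n_records=120, prevalence=0.1, separability=0.9, seed=42))
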