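"""Synthetic labeled screening corpora with controllable class separability.

The generator emulates the composition of real title/abstract screening pools:
a few thousand candidate records of which only a small fraction (typically
1-5%) is relevant.  Each record's tokens are drawn from a two-component
mixture: with probability ``separability`` from the record's class-specific
signal vocabulary, otherwise from a vocabulary shared by both classes.  At
separability 1 the class vocabularies are disjoint and any reasonable text
classifier can separate the classes; at 0 the class-conditional token
distributions are identical and no ranking can beat random screening.

Labels are assigned deterministically (exactly round(prevalence * N) relevant
records), then the record order is shuffled so that record index carries no
label signal — the engine's index tie-breaking must not leak labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .corpus import LabeledCorpus, LabeledRecord
from .balance import _round_half_away

__all__ = ["SynthSpec", "GenerationError", "generate_corpus"]


class GenerationError(Exception):
    """The spec cannot produce a valid corpus."""


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of a synthetic screening corpus.

    vocab_sizes = (relevant-signal, irrelevant-signal, shared) type counts;
    doc_length = (mean, sd) of record token counts, truncated at 10.
    """

    n_records: int = 2000
    prevalence: float = 0.05
    separability: float = 0.8
    vocab_sizes: tuple[int, int, int] = (300, 1000, 2000)
    doc_length: tuple[float, float] = (60.0, 15.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.prevalence < 1:
            raise GenerationError(f"prevalence must be in (0, 1), got {self.prevalence}")
        if not 0 <= self.separability <= 1:
            raise GenerationError(f"separability must be in [0, 1], got {self.separability}")
        if self.n_records < 10:
            raise GenerationError(f"n_records must be >= 10, got {self.n_records}")
        if min(self.vocab_sizes) < 2 or self.doc_length[0] < 10:
            raise GenerationError("vocabularies too small or documents too short for diversity")


def _vocab(prefix: str, size: int) -> np.ndarray:
    return np.array([f"{prefix}{i:05d}" for i in range(size)])


def generate_corpus(spec: SynthSpec) -> LabeledCorpus:
    """Generate a labeled corpus; deterministic per seed.

    Exactly round(prevalence * N) records are relevant.  Titles are the first
    5 tokens, abstracts the rest.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_records
    n_rel = int(_round_half_away(spec.prevalence * n))
    if not 1 <= n_rel < n:
        raise GenerationError(f"prevalence {spec.prevalence} yields {n_rel} relevant of {n}")

    signal = {1: _vocab("rel", spec.vocab_sizes[0]), 0: _vocab("irr", spec.vocab_sizes[1])}
    shared = _vocab("com", spec.vocab_sizes[2])

    labels = np.array([1] * n_rel + [0] * (n - n_rel))
    records = []
    for i in range(n):
        lab = int(labels[i])
        length = max(int(round(rng.normal(*spec.doc_length))), 10)
        from_signal = rng.random(length) < spec.separability
        n_sig = int(from_signal.sum())
        tokens = np.empty(length, dtype=object)
        tokens[from_signal] = rng.choice(signal[lab], size=n_sig)
        tokens[~from_signal] = rng.choice(shared, size=length - n_sig)
        records.append((lab, tokens))

    order = rng.permutation(n)
    out = []
    for pos, j in enumerate(order):
        lab, tokens = records[j]
        out.append(
            LabeledRecord(
                record_id=f"rec{pos:06d}",
                title=" ".join(tokens[:5]),
                abstract=" ".join(tokens[5:]),
                label=lab,
            )
        )
    return LabeledCorpus(records=tuple(out))
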