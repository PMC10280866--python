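"""Dynamic resampling (DR): class rebalancing of the labeled training set.

Screening corpora are heavily imbalanced (typically 1-5% relevant), and the
labeled training set at any point of an active-learning run inherits that
imbalance.  DR rebalances before each classifier fit: relevant records are
oversampled and irrelevant records undersampled so that the training-set
size is preserved.  The target class ratio is not fixed but evolves with
screening progress: it depends on the training-set size n, the pool size N,
and the current relevant/irrelevant ratio.

Concretely, with relevant-class weight w1 = a * (n/N)**(-alpha) and
irrelevant-class weight w0 = b, the target relevant fraction is

    rho = w1*n1 / (w1*n1 + w0*n0).

Early in screening n/N is small, w1 is large and the training set is pushed
strongly toward the relevant class; as screening progresses (n -> N) the
correction decays toward the mild constant ratio a:b.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["DRParams", "TrainingComposition", "BalanceError", "dr_target_counts", "dynamic_resample"]


class BalanceError(Exception):
    """Rebalancing is impossible (e.g., a single-class training set)."""


@dataclass(frozen=True)
class DRParams:
    """Dynamic-resampling parameters.

    a: relevant-weight scale (> 0); alpha: decay exponent (>= 0);
    b: irrelevant-weight scale (> 0).
    """

    a: float = 2.155
    alpha: float = 0.94
    b: float = 0.789

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > 0 and self.alpha >= 0):
            raise ValueError(f"invalid DR parameters: a={self.a}, alpha={self.alpha}, b={self.b}")


@dataclass(frozen=True)
class TrainingComposition:
    """Class composition of the labeled training set inside a pool of size N."""

    n1: int  # relevant in training set
    n0: int  # irrelevant in training set
    N: int  # total pool size

    def __post_init__(self) -> None:
        if self.n1 < 1 or self.n0 < 1:
            raise BalanceError(
                f"both classes must be present in the training set (n1={self.n1}, n0={self.n0})"
            )
        if self.n > self.N:
            raise ValueError(f"training set larger than pool (n={self.n}, N={self.N})")

    @property
    def n(self) -> int:
        return self.n1 + self.n0


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def dr_target_counts(comp: TrainingComposition, params: DRParams = DRParams()) -> tuple[int, int]:
    """Target (relevant, irrelevant) counts for the rebalanced training set.

    The total n is preserved; the relevant target is clamped to [1, n-1] so
    both classes always survive rebalancing.
    """
    w1 = params.a * (comp.n / comp.N) ** (-params.alpha)
    w0 = params.b
    rho = (w1 * comp.n1) / (w1 * comp.n1 + w0 * comp.n0)
    n1_target = min(max(_round_half_away(rho * comp.n), 1), comp.n - 1)
    return n1_target, comp.n - n1_target


def dynamic_resample(
    train_indices: Sequence[int],
    labels: Sequence[int],
    N: int,
    params: DRParams = DRParams(),
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Rebalanced training multiset of exactly len(train_indices) indices.

    ``labels`` gives the binary label of each entry of ``train_indices``
    (positionally aligned).  Relevant indices are drawn uniformly with
    replacement; irrelevant indices are drawn without replacement when
    undersampling (the usual case), with replacement otherwise.  The output is
    the relevant block followed by the irrelevant block, so a fixed rng state
    reproduces the multiset exactly.
    """
    if rng is None:
        rng = np.random.default_rng()
    idx = np.asarray(train_indices, dtype=int)
    lab = np.asarray(labels, dtype=int)
    if idx.shape != lab.shape:
        raise ValueError("train_indices and labels must align")
    rel = idx[lab == 1]
    irr = idx[lab == 0]
    comp = TrainingComposition(n1=rel.size, n0=irr.size, N=N)
    n1_t, n0_t = dr_target_counts(comp, params)
    rel_draw = rng.choice(rel, size=n1_t, replace=True)
    irr_draw = rng.choice(irr, size=n0_t, replace=n0_t > irr.size)
    return np.concatenate([rel_draw, irr_draw])
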