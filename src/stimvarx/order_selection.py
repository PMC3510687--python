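"""Cross-validated selection of the autoregressive order.

The score for a candidate order combines, per held-out block, the mean
square one-step prediction error with the mean square error of the
model's average evoked response against the measured average response;
each term is normalized by the median of its own error surface so the
two receive roughly equal emphasis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import EpochSet, MVARXModel, fit_ols, one_step_predict, simulate_evoked

__all__ = [
    "CVPartition",
    "CVResult",
    "partition_cv",
    "default_n_partitions",
    "cv_components",
    "select_order",
    "segment_evoked",
]


@dataclass
class CVPartition:
    """Train/test epoch index sets; test sets are disjoint contiguous blocks."""

    train_sets: list[list[int]]
    test_sets: list[list[int]]

    @property
    def M(self) -> int:
        return len(self.test_sets)


@dataclass
class CVResult:
    p_grid: list[int]
    cv_e: np.ndarray      # (M, len(p_grid))
    cv_eps: np.ndarray    # (M, len(p_grid))
    w_e: float
    w_eps: float
    score: np.ndarray     # (len(p_grid),)
    selected_p: int


def default_n_partitions(J: int, target_block: int = 3) -> int:
    """Number of partitions giving test blocks of roughly ``target_block`` epochs."""
    return int(min(J, max(2, round(J / target_block))))


def partition_cv(J: int, M: int) -> CVPartition:
    """Deterministic contiguous-block partition of ``J`` epochs into ``M`` folds.

    Test blocks are consecutive runs of epochs with sizes differing by at
    most one, so each block spans roughly the same amount of time.
    """
    if not 2 <= M <= J:
        raise ValueError(f"require 2 <= M <= J, got M={M}, J={J}")
    bounds = np.linspace(0, J, M + 1).round().astype(int)
    test_sets = [list(range(bounds[m], bounds[m + 1])) for m in range(M)]
    train_sets = [
        [j for j in range(J) if j not in set(ts)] for ts in test_sets
    ]
    return CVPartition(train_sets=train_sets, test_sets=test_sets)


def segment_evoked(
    model: MVARXModel, epochs: EpochSet
) -> list[np.ndarray]:
    """Model evoked response for each epoch, driven by the whole train.

    The stimulus train of the entire session is presented to the model
    (zero initial conditions at session start, state carried across
    epochs) and the resulting trace is cut at each epoch's position, so
    responses still decaying from earlier stimuli are represented.
    """
    if epochs.session_x is None or epochs.starts is None:
        raise ValueError("epochs lack session-level input/positions")
    y_e = simulate_evoked(model, epochs.session_x)
    out = []
    for s, e in zip(epochs.starts, epochs.epochs):
        out.append(y_e[:, s : s + e.shape[1]])
    return out


def cv_components(
    epochs: EpochSet,
    p: int,
    ell: int,
    train_idx: Sequence[int],
    test_idx: Sequence[int],
) -> tuple[float, float]:
    """One-step and average-response errors for a single partition.

    Fits at order ``(p, ell)`` on the training epochs, then on the test
    block computes (a) the mean square one-step prediction error and
    (b) the mean square difference between the measured average response
    and the model's average evoked response over the test epochs.
    """
    if not len(test_idx):
        raise ValueError("empty test set")
    model = fit_ols(epochs.subset(list(train_idx)), p=p, ell=ell)
    test = epochs.subset(list(test_idx))
    return cv_components_for_model(model, test)


def cv_components_for_model(model: MVARXModel, test: EpochSet) -> tuple[float, float]:
    """Error components of a fitted model on a held-out epoch set."""
    n0 = model.n0
    _, resids = one_step_predict(model, test)
    per_epoch = [np.sum(r**2) / r.shape[1] for r in resids]
    cv_e = float(np.mean(per_epoch))

    N = test.lengths[0]
    if any(L != N for L in test.lengths):
        raise ValueError("average-response error requires equal-length epochs")
    y_bar = np.mean([e for e in test.epochs], axis=0)
    y_hat_bar = np.mean(segment_evoked(model, test), axis=0)
    cv_eps = float(np.sum((y_bar - y_hat_bar) ** 2) / N)
    return cv_e, cv_eps


def select_order(
    epochs: EpochSet,
    p_grid: Sequence[int] | None = None,
    ell: int = 10,
    M: int | None = None,
) -> CVResult:
    """Pick the AR order minimizing the weighted cross-validation score.

    Both error surfaces are computed over the full (order, partition)
    grid first; the weights are their medians over all entries (so the
    two error types get approximately equal emphasis); the score for
    order ``p`` averages the weighted sum over partitions. Ties break
    toward the smaller order.
    """
    grid = sorted(p_grid) if p_grid is not None else list(range(1, 31))
    if not grid:
        raise ValueError("empty order grid")
    if M is None:
        M = default_n_partitions(epochs.J)
    part = partition_cv(epochs.J, M)
    cv_e = np.empty((M, len(grid)))
    cv_eps = np.empty((M, len(grid)))
    for k, p in enumerate(grid):
        for m in range(M):
            cv_e[m, k], cv_eps[m, k] = cv_components(
                epochs, p, ell, part.train_sets[m], part.test_sets[m]
            )
    w_e = float(np.median(cv_e)) or 1.0
    w_eps = float(np.median(cv_eps)) or 1.0
    score = np.mean(cv_e / w_e + cv_eps / w_eps, axis=0)
    best = int(np.argmin(score))  # first minimum; grid ascending => smallest p
    return CVResult(
        p_grid=grid, cv_e=cv_e, cv_eps=cv_eps, w_e=w_e, w_eps=w_eps,
        score=score, selected_p=grid[best],
    )
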