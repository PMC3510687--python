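"""Leave-one-out Mahalanobis rejection of outlying epochs.

For each epoch ``m`` the time-varying mean and covariance of the other
epochs are computed, the squared Mahalanobis distance of epoch ``m`` from
that ensemble is summed over time, and epochs whose distance exceeds the
chi-squared mean plus ``n_sd`` standard deviations are rejected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import EpochSet

__all__ = [
    "OutlierReport",
    "loo_moments",
    "mahalanobis_d2",
    "d2_threshold",
    "reject_outliers",
    "merge_contiguous",
]

log = logging.getLogger(__name__)

_COND_LIMIT = 1e10
_LOADING = 1e-6


@dataclass
class OutlierReport:
    d2: np.ndarray
    threshold: float
    retained: list[int]
    rejected: list[int]


def _check(epochs: EpochSet) -> int:
    N = epochs.lengths[0]
    if any(L != N for L in epochs.lengths):
        raise ValueError("outlier detection requires equal-length epochs")
    if epochs.J < 3:
        raise ValueError("need at least 3 epochs (covariance divides by J-2)")
    return N


def loo_moments(epochs: EpochSet, m: int) -> tuple[np.ndarray, np.ndarray]:
    """Leave-one-out time-varying mean and covariance.

    Returns ``mu`` of shape (N, d) and ``sigma`` of shape (N, d, d)
    computed over the J-1 epochs other than ``m``, with 1/(J-1) and
    1/(J-2) normalizations respectively.
    """
    N = _check(epochs)
    J, d = epochs.J, epochs.d
    if not 0 <= m < J:
        raise IndexError(f"epoch index {m} out of range")
    others = np.stack([epochs.epochs[j] for j in range(J) if j != m])  # (J-1, d, N)
    mu = others.mean(axis=0).T  # (N, d)
    dev = others - mu.T[None, :, :]  # (J-1, d, N)
    sigma = np.einsum("jdn,jen->nde", dev, dev) / (J - 2)
    return mu, sigma


def mahalanobis_d2(epochs: EpochSet, m: int, regularize: bool = True) -> float:
    """Squared Mahalanobis distance of epoch ``m`` from the others.

    Sums, over time, the quadratic form of epoch ``m``'s deviation from
    the leave-one-out mean under the leave-one-out covariance. Covariance
    matrices with condition number above 1e10 receive diagonal loading
    ``1e-6 * (tr(Sigma)/d) * I`` when ``regularize`` is enabled.
    """
    mu, sigma = loo_moments(epochs, m)
    y = epochs.epochs[m].T  # (N, d)
    d = epochs.d
    total = 0.0
    n_loaded = 0
    for n in range(y.shape[0]):
        S = sigma[n]
        if regularize:
            try:
                cond = np.linalg.cond(S)
            except np.linalg.LinAlgError:  # pragma: no cover
                cond = np.inf
            if not np.isfinite(cond) or cond > _COND_LIMIT:
                S = S + _LOADING * (np.trace(S) / d) * np.eye(d)
                n_loaded += 1
        dev = y[n] - mu[n]
        try:
            sol = np.linalg.solve(S, dev)
        except np.linalg.LinAlgError:
            raise np.linalg.LinAlgError(
                f"singular covariance at sample {n}; enable regularization"
            )
        total += float(dev @ sol)
    if n_loaded:
        log.info("mahalanobis_d2(m=%d): diagonal loading at %d samples", m, n_loaded)
    return total


def d2_threshold(N: int, d: int, n_sd: float = 60.0) -> float:
    """Rejection threshold: chi-squared mean plus ``n_sd`` standard deviations.

    A well-behaved epoch's distance is approximately chi-squared with
    ``N * d`` degrees of freedom, so the threshold is
    ``N*d + n_sd * sqrt(2*N*d)``.
    """
    nd = N * d
    return nd + n_sd * np.sqrt(2.0 * nd)


def reject_outliers(
    epochs: EpochSet, n_sd: float = 60.0, regularize: bool = True
) -> tuple[EpochSet, OutlierReport]:
    """Remove epochs whose leave-one-out distance exceeds the threshold."""
    N = _check(epochs)
    d2 = np.array([mahalanobis_d2(epochs, m, regularize) for m in range(epochs.J)])
    thr = d2_threshold(N, epochs.d, n_sd)
    retained = [m for m in range(epochs.J) if d2[m] <= thr]
    rejected = [m for m in range(epochs.J) if d2[m] > thr]
    if not retained:
        raise ValueError("all epochs rejected; nothing left for model fitting")
    report = OutlierReport(d2=d2, threshold=float(thr),
                           retained=retained, rejected=rejected)
    return epochs.subset(retained), report


def merge_contiguous(epochs: EpochSet) -> EpochSet:
    """Merge surviving adjacent fixed-length epochs into maximal segments.

    After rejection, model-fitting epochs are the maximum contiguous
    stretches of retained data: epochs whose windows abut in the parent
    session are concatenated into variable-length segments, minimizing
    the data lost to initial conditions.
    """
    if epochs.starts is None:
        raise ValueError("epochs lack session start positions; cannot merge")
    order = np.argsort(epochs.starts)
    merged_y: list[np.ndarray] = []
    merged_x: list[np.ndarray] = []
    merged_starts: list[int] = []
    cur_y: list[np.ndarray] = []
    cur_x: list[np.ndarray] = []
    cur_start = cur_end = None
    for i in order:
        s = epochs.starts[i]
        L = epochs.epochs[i].shape[1]
        if cur_end is not None and s == cur_end:
            cur_y.append(epochs.epochs[i])
            cur_x.append(epochs.inputs[i])
            cur_end = s + L
        else:
            if cur_y:
                merged_y.append(np.hstack(cur_y))
                merged_x.append(np.concatenate(cur_x))
                merged_starts.append(cur_start)
            cur_y, cur_x = [epochs.epochs[i]], [epochs.inputs[i]]
            cur_start, cur_end = s, s + L
    if cur_y:
        merged_y.append(np.hstack(cur_y))
        merged_x.append(np.concatenate(cur_x))
        merged_starts.append(cur_start)
    return EpochSet(
        epochs=merged_y, inputs=merged_x, fs=epochs.fs,
        channel_names=epochs.channel_names, stim_offset=None,
        starts=merged_starts, session_x=epochs.session_x,
    )
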