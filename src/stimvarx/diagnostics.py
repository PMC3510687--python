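"""Model validation: residual whiteness testing and evoked-fit metrics.

The whiteness test is a kernel-weighted portmanteau statistic over lagged
residual covariance matrices (Bartlett lag window), asymptotically
standard normal when the residuals are serially uncorrelated; a
one-sided rejection declares serial correlation. The fit metrics quantify
agreement between measured and model-average evoked responses (NMSD,
RRMS, NMRD) and one-step prediction quality (NMSE).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import norm

from .core import EpochSet, MVARXModel, fit_ols, one_step_predict
from .order_selection import CVPartition, segment_evoked

__all__ = [
    "WhitenessResult",
    "FitMetrics",
    "bartlett_window",
    "kernel_width",
    "residual_autocov",
    "whiteness_test",
    "average_cv_responses",
    "fit_metrics",
    "fit_unconnected",
    "unconnected_residuals",
]


@dataclass
class WhitenessResult:
    T: float
    L: int
    N_c: int
    alpha: float
    z_crit: float
    reject: bool


@dataclass
class FitMetrics:
    nmsd: np.ndarray   # per channel
    rrms: np.ndarray   # per channel
    nmrd: float
    nmse: float


def bartlett_window(L: int) -> np.ndarray:
    """Triangular lag weights ``q(j) = 1 - j/L`` for ``j = 0..L`` (``q(L)=0``)."""
    if L < 1:
        raise ValueError("L must be >= 1")
    j = np.arange(L + 1, dtype=float)
    return 1.0 - j / L


def kernel_width(N_c: int) -> int:
    """Lag-window width rule ``L = ceil(3 * N_c**0.3)``."""
    if N_c < 1:
        raise ValueError("N_c must be >= 1")
    return int(math.ceil(3.0 * N_c**0.3))


def _as_resid_list(residuals) -> list[np.ndarray]:
    if isinstance(residuals, np.ndarray):
        residuals = [residuals]
    return [np.atleast_2d(np.asarray(r, dtype=float)) for r in residuals]


def effective_samples(residuals, L: int) -> int:
    """``N_c = sum_j N_j - (J - 1) L``."""
    rs = _as_resid_list(residuals)
    return int(sum(r.shape[1] for r in rs) - (len(rs) - 1) * L)


def residual_autocov(residuals, r: int, L: int) -> np.ndarray:
    """Lag-``r`` residual covariance estimate, normalized by ``N_c``.

    Cross-products ``w[n] w[n+r]^T`` are accumulated over all valid
    within-epoch pairs (``n = 0..N_j-r-1``) and divided by
    ``N_c = sum_j N_j - (J-1) L``.
    """
    rs = _as_resid_list(residuals)
    if not 0 <= r <= L:
        raise ValueError("require 0 <= r <= L")
    J = len(rs)
    if rs[-1].shape[1] <= (J - 1) * L:
        raise ValueError(
            f"last epoch has {rs[-1].shape[1]} samples but (J-1)L = {(J - 1) * L}; "
            "merge epochs into longer segments or lower L"
        )
    N_c = effective_samples(rs, L)
    d = rs[0].shape[0]
    C = np.zeros((d, d))
    for w in rs:
        Nj = w.shape[1]
        if r < Nj:
            C += w[:, : Nj - r] @ w[:, r:].T
    return C / N_c


def whiteness_test(residuals, alpha: float = 0.1, L: int | None = None) -> WhitenessResult:
    """Portmanteau test of residual serial uncorrelatedness.

    The statistic sums ``q(r)^2 tr[C(r)^T C(0)^{-1} C(r) C(0)^{-1}]`` over
    lags 1..L, centers by ``d^2 M(q)`` and scales by ``sqrt(2 d^2 V(q))``,
    where ``M`` and ``V`` are finite-sample kernel functionals. Rejection
    (one-sided, level ``alpha``) indicates serial correlation. If ``L`` is
    omitted it is set by the width rule, solved jointly with ``N_c``.
    """
    rs = _as_resid_list(residuals)
    d = rs[0].shape[0]
    total = sum(r.shape[1] for r in rs)
    J = len(rs)
    if L is None:
        L = kernel_width(total)
        for _ in range(50):  # N_c depends on L when J > 1; iterate to fixed point
            N_c = total - (J - 1) * L
            if N_c < 1:
                raise ValueError("epochs too short for the kernel width rule")
            L_new = kernel_width(N_c)
            if L_new == L:
                break
            L = L_new
    N_c = effective_samples(rs, L)
    q = bartlett_window(L)
    C0 = residual_autocov(rs, 0, L)
    try:
        C0_inv = np.linalg.inv(C0)
    except np.linalg.LinAlgError:
        raise np.linalg.LinAlgError("lag-0 residual covariance is singular")
    acc = 0.0
    for r in range(1, L + 1):
        if q[r] == 0.0:
            continue
        Cr = residual_autocov(rs, r, L)
        acc += q[r] ** 2 * float(np.trace(Cr.T @ C0_inv @ Cr @ C0_inv))
    i = np.arange(1, L)
    M_q = float(np.sum((1.0 - i / N_c) * q[1:L] ** 2))
    i2 = np.arange(1, L - 1)
    V_q = float(np.sum((1.0 - i2 / N_c) * (1.0 - (i2 + 1) / N_c) * q[1 : L - 1] ** 4))
    T = (N_c * acc - d**2 * M_q) / math.sqrt(2.0 * d**2 * V_q)
    z_crit = float(norm.ppf(1.0 - alpha))
    return WhitenessResult(T=float(T), L=L, N_c=N_c, alpha=alpha,
                           z_crit=z_crit, reject=bool(T > z_crit))


def average_cv_responses(
    epochs: EpochSet,
    models: Sequence[MVARXModel],
    partition: CVPartition,
) -> tuple[np.ndarray, np.ndarray]:
    """Two-phase averages of measured and model evoked responses.

    Phase one averages within each held-out test block (measured epochs,
    and the per-block model's whole-train evoked response cut at the same
    epochs); phase two averages those block averages over all partitions.
    """
    if len(models) != partition.M:
        raise ValueError("need one model per partition")
    meas_blocks = []
    model_blocks = []
    for model, test_idx in zip(models, partition.test_sets):
        test = epochs.subset(test_idx)
        meas_blocks.append(np.mean(test.epochs, axis=0))
        model_blocks.append(np.mean(segment_evoked(model, test), axis=0))
    return np.mean(meas_blocks, axis=0), np.mean(model_blocks, axis=0)


def fit_metrics(
    y_bar: np.ndarray,
    y_hat_bar: np.ndarray,
    residuals: Sequence[np.ndarray],
    epochs: EpochSet,
) -> FitMetrics:
    """Evoked-response and one-step prediction quality metrics.

    NMSD(i): per-channel normalized mean-squared difference of the
    average responses. RRMS(i): channel root energy relative to the
    strongest channel. NMRD: the same mismatch pooled over channels.
    NMSE: mean-squared one-step prediction error (predicted samples only)
    over mean-squared signal energy (all samples).
    """
    y_bar = np.atleast_2d(np.asarray(y_bar, dtype=float))
    y_hat_bar = np.atleast_2d(np.asarray(y_hat_bar, dtype=float))
    if y_bar.shape != y_hat_bar.shape:
        raise ValueError("average response shapes differ")
    energy = np.sum(y_bar**2, axis=1)
    if np.all(energy == 0):
        raise ValueError("all-zero measured average response; metrics undefined")
    nmsd = np.sum((y_bar - y_hat_bar) ** 2, axis=1) / energy
    root = np.sqrt(energy)
    rrms = root / root.max()
    nmrd = float(np.sum((y_bar - y_hat_bar) ** 2) / np.sum(y_bar**2))

    rs = _as_resid_list(residuals)
    n_pred = sum(r.shape[1] for r in rs)
    num = sum(float(np.sum(r**2)) for r in rs) / n_pred
    n_all = sum(epochs.lengths)
    den = sum(float(np.sum(e**2)) for e in epochs.epochs) / n_all
    if den == 0:
        raise ValueError("zero-energy epochs; NMSE undefined")
    return FitMetrics(nmsd=nmsd, rrms=rrms, nmrd=nmrd, nmse=float(num / den))


def fit_unconnected(epochs: EpochSet, p: int, ell: int = 10) -> list[MVARXModel]:
    """Fit ``d`` independent univariate ARX models, one per channel.

    The comparison model without inter-channel coupling: each channel is
    regressed on its own past and the stimulus only.
    """
    models = []
    for i in range(epochs.d):
        sub = EpochSet(
            epochs=[e[[i], :] for e in epochs.epochs],
            inputs=list(epochs.inputs),
            fs=epochs.fs,
            channel_names=None if epochs.channel_names is None
            else [epochs.channel_names[i]],
            stim_offset=epochs.stim_offset,
            starts=epochs.starts,
            session_x=epochs.session_x,
        )
        models.append(fit_ols(sub, p=p, ell=ell))
    return models


def unconnected_residuals(
    models: Sequence[MVARXModel], epochs: EpochSet
) -> list[np.ndarray]:
    """Stacked per-epoch residuals of the unconnected (univariate) models."""
    per_channel = []
    for i, model in enumerate(models):
        sub = EpochSet(
            epochs=[e[[i], :] for e in epochs.epochs],
            inputs=list(epochs.inputs),
            fs=epochs.fs,
        )
        _, resids = one_step_predict(model, sub)
        per_channel.append(resids)
    out = []
    for j in range(epochs.J):
        out.append(np.vstack([per_channel[i][j] for i in range(epochs.d)]))
    return out
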