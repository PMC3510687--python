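"""MVARX model container, joint OLS estimation, and simulation primitives.

The model of order ``(p, ell)`` describes a ``d``-channel recording as

    y[n] = sum_{i=1..p} A_i y[n-i] + sum_{i=0..ell} b_i x[n-i] + w[n]

where ``x`` is a scalar exogenous input (the stimulus trigger), the
``A_i`` are d x d coupling matrices, ``B = [b_0, ..., b_ell]`` collects
the per-channel input filters, and ``w`` is zero-mean noise with
covariance ``Q``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.linalg


__all__ = [
    "MVARXModel",
    "EpochSet",
    "RegressionBlocks",
    "build_regression",
    "fit_ols",
    "simulate_evoked",
    "one_step_predict",
    "decompose",
    "spectral_radius",
    "companion_matrix",
]


@dataclass
class MVARXModel:
    """Multivariate autoregressive model with a scalar exogenous input.

    Parameters
    ----------
    A : ndarray, shape (p, d, d)
        Autoregressive coefficient matrices; ``A[i-1][m, n]`` is the
        influence of channel ``n`` on channel ``m`` at lag ``i``.
    B : ndarray, shape (d, ell + 1)
        Input filter bank; row ``i`` is the stimulus-to-channel-``i``
        impulse response over lags ``0..ell``.
    Q : ndarray, shape (d, d)
        Innovation covariance (symmetric positive semidefinite).
    fs : float
        Sampling rate of the analysis data in Hz.
    channel_names : list of str, optional
    """

    A: np.ndarray
    B: np.ndarray
    Q: np.ndarray
    fs: float = 100.0
    channel_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.A = np.atleast_3d(np.asarray(self.A, dtype=float))
        self.B = np.atleast_2d(np.asarray(self.B, dtype=float))
        self.Q = np.atleast_2d(np.asarray(self.Q, dtype=float))
        p, d, d2 = self.A.shape
        if d != d2:
            raise ValueError(f"A blocks must be square, got {d} x {d2}")
        if self.B.shape[0] != d:
            raise ValueError("B must have one row per channel")
        if self.Q.shape != (d, d):
            raise ValueError("Q must be d x d")
        if not np.allclose(self.Q, self.Q.T, atol=1e-10):
            raise ValueError("Q must be symmetric")

    @property
    def d(self) -> int:
        return self.A.shape[1]

    @property
    def p(self) -> int:
        return self.A.shape[0]

    @property
    def ell(self) -> int:
        return self.B.shape[1] - 1

    @property
    def n0(self) -> int:
        """Number of initial-condition samples, ``max(p, ell)``."""
        return max(self.p, self.ell)

    @property
    def theta(self) -> np.ndarray:
        """Stacked coefficient matrix ``[A_1, ..., A_p, B]``, d x (dp+ell+1)."""
        p, d, _ = self.A.shape
        return np.hstack([self.A.transpose(1, 0, 2).reshape(d, d * p), self.B])

    @classmethod
    def from_theta(
        cls,
        theta: np.ndarray,
        Q: np.ndarray,
        p: int,
        ell: int,
        fs: float = 100.0,
        channel_names: list[str] | None = None,
    ) -> "MVARXModel":
        theta = np.asarray(theta, dtype=float)
        d = theta.shape[0]
        if theta.shape[1] != d * p + ell + 1:
            raise ValueError("theta has wrong number of columns")
        A = theta[:, : d * p].reshape(d, p, d).transpose(1, 0, 2)
        B = theta[:, d * p :]
        return cls(A=A, B=B, Q=np.asarray(Q, dtype=float), fs=fs,
                   channel_names=channel_names)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "d": self.d,
            "p": self.p,
            "ell": self.ell,
            "fs": self.fs,
            "channel_names": self.channel_names,
            "A": [Ai.tolist() for Ai in self.A],
            "B": self.B.tolist(),
            "Q": self.Q.tolist(),
        }

    @classmethod
    def from_dict(cls, obj: dict) -> "MVARXModel":
        return cls(
            A=np.array(obj["A"], dtype=float),
            B=np.array(obj["B"], dtype=float),
            Q=np.array(obj["Q"], dtype=float),
            fs=float(obj["fs"]),
            channel_names=obj.get("channel_names"),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "MVARXModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class EpochSet:
    """A collection of stimulus-aligned epochs with aligned input segments.

    ``epochs[j]`` is a ``d x N_j`` array and ``inputs[j]`` the matching
    length-``N_j`` exogenous input. Epoch lengths may vary (contiguous
    segments after outlier rejection). ``starts`` records each epoch's
    start sample in the parent continuous session and ``session_x`` the
    full-session input; both are needed to reconstruct whole-train evoked
    responses.
    """

    epochs: list[np.ndarray]
    inputs: list[np.ndarray]
    fs: float = 100.0
    channel_names: list[str] | None = None
    stim_offset: int | None = None
    starts: list[int] | None = None
    session_x: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.epochs) != len(self.inputs):
            raise ValueError("epochs and inputs must have equal length")
        self.epochs = [np.atleast_2d(np.asarray(e, dtype=float)) for e in self.epochs]
        self.inputs = [np.asarray(x, dtype=float).ravel() for x in self.inputs]
        if not self.epochs:
            raise ValueError("EpochSet must contain at least one epoch")
        d = self.epochs[0].shape[0]
        for j, (e, x) in enumerate(zip(self.epochs, self.inputs)):
            if e.shape[0] != d:
                raise ValueError(f"epoch {j} has {e.shape[0]} channels, expected {d}")
            if e.shape[1] != x.shape[0]:
                raise ValueError(f"epoch {j} and its input differ in length")
            if e.shape[1] < 1:
                raise ValueError(f"epoch {j} is empty")

    @property
    def J(self) -> int:
        return len(self.epochs)

    @property
    def d(self) -> int:
        return self.epochs[0].shape[0]

    @property
    def lengths(self) -> list[int]:
        return [e.shape[1] for e in self.epochs]

    def subset(self, indices: Sequence[int]) -> "EpochSet":
        idx = list(indices)
        return EpochSet(
            epochs=[self.epochs[i] for i in idx],
            inputs=[self.inputs[i] for i in idx],
            fs=self.fs,
            channel_names=self.channel_names,
            stim_offset=self.stim_offset,
            starts=None if self.starts is None else [self.starts[i] for i in idx],
            session_x=self.session_x,
        )


@dataclass
class RegressionBlocks:
    """Per-epoch regression blocks ``Y_j = Theta Z_j + W_j``."""

    Y: list[np.ndarray]
    Z: list[np.ndarray]
    p: int
    ell: int
    n0: int
    N_t: int = field(init=False)

    def __post_init__(self) -> None:
        self.N_t = sum(y.shape[1] for y in self.Y)

    def stacked(self) -> tuple[np.ndarray, np.ndarray]:
        return np.hstack(self.Y), np.hstack(self.Z)


def companion_matrix(A: np.ndarray) -> np.ndarray:
    """dp x dp companion form of the AR coefficient stack ``A`` (p, d, d)."""
    A = np.atleast_3d(np.asarray(A, dtype=float))
    p, d, _ = A.shape
    F = np.zeros((d * p, d * p))
    F[:d, :] = A.transpose(1, 0, 2).reshape(d, d * p)
    if p > 1:
        F[d:, : d * (p - 1)] = np.eye(d * (p - 1))
    return F


def spectral_radius(model: MVARXModel | np.ndarray) -> float:
    """Largest eigenvalue magnitude of the AR companion matrix."""
    A = model.A if isinstance(model, MVARXModel) else model
    return float(np.max(np.abs(np.linalg.eigvals(companion_matrix(A)))))


def build_regression(epochs: EpochSet, p: int, ell: int) -> RegressionBlocks:
    """Assemble per-epoch regression blocks for OLS estimation.

    Regressor vector for time ``n`` (0-based within an epoch):
    ``z = [y[n-1], ..., y[n-p], x[n], x[n-1], ..., x[n-ell]]`` with
    target columns contributed for ``n = n0 .. N_j - 1``, ``n0 = max(p, ell)``.
    """
    if p < 1 or ell < 0:
        raise ValueError("require p >= 1 and ell >= 0")
    n0 = max(p, ell)
    d = epochs.d
    Ys: list[np.ndarray] = []
    Zs: list[np.ndarray] = []
    for j, (y, x) in enumerate(zip(epochs.epochs, epochs.inputs)):
        Nj = y.shape[1]
        if Nj < n0 + 1:
            raise ValueError(
                f"epoch {j} has {Nj} samples; need at least n0+1 = {n0 + 1}"
            )
        ncols = Nj - n0
        Z = np.empty((d * p + ell + 1, ncols))
        for i in range(1, p + 1):
            Z[(i - 1) * d : i * d, :] = y[:, n0 - i : Nj - i]
        for i in range(0, ell + 1):
            Z[d * p + i, :] = x[n0 - i : Nj - i]
        Ys.append(y[:, n0:])
        Zs.append(Z)
    return RegressionBlocks(Y=Ys, Z=Zs, p=p, ell=ell, n0=n0)


def fit_ols(
    epochs: EpochSet,
    p: int,
    ell: int = 10,
    rcond: float = 1e-10,
) -> MVARXModel:
    """Joint ordinary least-squares estimate of ``(Theta, Q)``.

    Theta solves the stacked normal equations via a rank-revealing
    least-squares factorization; ``Q`` is the residual outer-product
    average with ``N_t = sum_j N_j - n0 J`` in the denominator. With
    Gaussian innovations this is also the maximum-likelihood estimate.
    """
    blocks = build_regression(epochs, p, ell)
    Y, Z = blocks.stacked()
    nparam = Z.shape[0]
    if Z.shape[1] < nparam:
        raise ValueError(
            f"only {Z.shape[1]} regression columns for {nparam} parameters; "
            "lower p/ell or provide more data"
        )
    theta_t, _, rank, _ = scipy.linalg.lstsq(Z.T, Y.T, lapack_driver="gelsd")
    if rank < nparam:
        raise ValueError(
            f"rank-deficient normal equations (rank {rank} < {nparam}); "
            "lower p/ell or provide more (persistently exciting) data"
        )
    theta = theta_t.T
    resid = Y - theta @ Z
    Q = (resid @ resid.T) / blocks.N_t
    Q = 0.5 * (Q + Q.T)
    return MVARXModel.from_theta(
        theta, Q, p=p, ell=ell, fs=epochs.fs, channel_names=epochs.channel_names
    )


def simulate_evoked(model: MVARXModel, x: np.ndarray) -> np.ndarray:
    """Deterministic evoked component driven by the full input sequence.

    Iterates the noise-free recursion from zero initial conditions,
    carrying state continuously across the whole stimulus train.
    Returns a ``d x T`` array.
    """
    x = np.asarray(x, dtype=float).ravel()
    T = x.shape[0]
    d, p, ell = model.d, model.p, model.ell
    # FIR drive precomputed for all n: u[:, n] = sum_i b_i x[n-i]
    u = np.zeros((d, T))
    for i in range(ell + 1):
        if i == 0:
            u += model.B[:, [0]] * x[None, :]
        else:
            u[:, i:] += model.B[:, [i]] * x[None, : T - i]
    F = companion_matrix(model.A)
    state = np.zeros(d * p)
    y = np.empty((d, T))
    for n in range(T):
        state = F @ state
        state[:d] += u[:, n]
        y[:, n] = state[:d]
    return y


def one_step_predict(
    model: MVARXModel, epochs: EpochSet
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """One-step predictions and residuals per epoch.

    Predictions are defined for samples ``n0 .. N_j - 1`` of each epoch
    (0-based); residual = measured - predicted. For the model returned by
    :func:`fit_ols` on the same data, the residuals coincide with the OLS
    residual blocks.
    """
    blocks = build_regression(epochs, model.p, model.ell)
    theta = model.theta
    preds = [theta @ Z for Z in blocks.Z]
    resids = [Y - P for Y, P in zip(blocks.Y, preds)]
    return preds, resids


def decompose(
    model: MVARXModel, y: np.ndarray, x: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Split a continuous recording into evoked and spontaneous components.

    ``y_e`` is the deterministic response to ``x`` from zero initial
    conditions; ``y_s = y - y_e`` is the noise-driven remainder.
    """
    y = np.atleast_2d(np.asarray(y, dtype=float))
    y_e = simulate_evoked(model, x)
    if y_e.shape != y.shape:
        raise ValueError(f"shape mismatch: y {y.shape} vs evoked {y_e.shape}")
    return y_e, y - y_e
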