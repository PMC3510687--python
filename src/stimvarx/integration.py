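"""Gaussian integrated information for stable MVAR systems.

Only the autoregressive coupling ``A`` and innovation covariance ``Q``
enter: the stationary joint distribution is Gaussian, so the stationary
covariance, lagged covariances, and past-given-present conditional
covariances are available in closed form (companion-form Lyapunov
equation plus the autocovariance recursion). Effective information of a
bipartition is the divergence, in bits, between the joint conditional
and the product of the parts' marginal conditionals; integrated
information is its value at the minimum-information bipartition.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import scipy.linalg
from scipy.stats import mannwhitneyu

from .core import MVARXModel, companion_matrix, spectral_radius

__all__ = [
    "StationaryMoments",
    "Bipartition",
    "PhiProfile",
    "stationary_moments",
    "conditional_cov",
    "effective_information",
    "enumerate_bipartitions",
    "minimum_information_bipartition",
    "phi_profile",
    "compare_conditions",
]

log = logging.getLogger(__name__)

_MAX_EXHAUSTIVE_D = 20


@dataclass
class StationaryMoments:
    """Stationary covariance ``sigma`` and lagged covariances ``gamma``.

    ``gamma[t - 1]`` is ``E{y[n - t] y[n]^T}`` for ``t = 1..rho``.
    """

    sigma: np.ndarray
    gamma: list[np.ndarray]

    @property
    def rho(self) -> int:
        return len(self.gamma)

    def lagged(self, tau: int) -> np.ndarray:
        if tau == 0:
            return self.sigma
        if not 1 <= tau <= self.rho:
            raise ValueError(f"lag {tau} outside computed range 1..{self.rho}")
        return self.gamma[tau - 1]


@dataclass(frozen=True)
class Bipartition:
    """Disjoint, exhaustive, non-empty split of channels {0..d-1}."""

    M1: tuple[int, ...]
    M2: tuple[int, ...]

    def __post_init__(self) -> None:
        s1, s2 = set(self.M1), set(self.M2)
        if not s1 or not s2:
            raise ValueError("both parts must be non-empty")
        if s1 & s2:
            raise ValueError("parts must be disjoint")

    @property
    def parts(self) -> tuple[tuple[int, ...], tuple[int, ...]]:
        return self.M1, self.M2


@dataclass
class PhiProfile:
    taus: np.ndarray
    phi: np.ndarray
    mib: list[Bipartition]
    fs: float

    @property
    def phi_max(self) -> float:
        return float(np.max(self.phi))

    @property
    def tau_argmax(self) -> int:
        return int(self.taus[int(np.argmax(self.phi))])


def stationary_moments(model: MVARXModel, rho: int | None = None) -> StationaryMoments:
    """Closed-form stationary and lagged covariances of the AR part.

    Solves the discrete Lyapunov equation for the companion-form state
    covariance (which yields lags ``0..p-1`` as blocks) and extends to
    higher lags with the recursion
    ``Gamma_t = sum_i Gamma_{t-i} A_i^T`` (with ``Gamma_{-k} = Gamma_k^T``).
    """
    sr = spectral_radius(model)
    if sr >= 1.0:
        raise ValueError(f"unstable model (spectral radius {sr:.4f} >= 1)")
    d, p = model.d, model.p
    if rho is None:
        rho = max(p - 1, 1)
    if rho < p - 1:
        raise ValueError(f"rho must be >= p - 1 = {p - 1}")
    F = companion_matrix(model.A)
    Qc = np.zeros((d * p, d * p))
    Qc[:d, :d] = model.Q
    S = scipy.linalg.solve_discrete_lyapunov(F, Qc)
    S = 0.5 * (S + S.T)
    sigma = S[:d, :d]
    # block (t, 0) of the state covariance is E{y[n-t] y[n]^T}
    gamma: list[np.ndarray] = [
        S[t * d : (t + 1) * d, :d] for t in range(1, p)
    ]

    def lag(t: int) -> np.ndarray:
        if t == 0:
            return sigma
        if t > 0:
            return gamma[t - 1]
        return gamma[-t - 1].T

    for t in range(p, rho + 1):
        g = np.zeros((d, d))
        for i in range(1, p + 1):
            g += lag(t - i) @ model.A[i - 1].T
        gamma.append(g)
    return StationaryMoments(sigma=sigma, gamma=gamma)


def conditional_cov(
    moments: StationaryMoments,
    tau: int,
    subset: Sequence[int] | None = None,
) -> np.ndarray:
    """Covariance of the state ``tau`` samples in the past given the present.

    ``Sigma - Gamma_tau Sigma^{-1} Gamma_tau^T`` evaluated on the full
    system or on the marginal blocks of a channel subset (the subset is
    marginalized, not refitted).
    """
    sigma = moments.sigma
    gamma_t = moments.lagged(tau)
    if subset is not None:
        idx = np.asarray(list(subset), dtype=int)
        sigma = sigma[np.ix_(idx, idx)]
        gamma_t = gamma_t[np.ix_(idx, idx)]
    try:
        sol = np.linalg.solve(sigma, gamma_t.T)
    except np.linalg.LinAlgError:
        raise np.linalg.LinAlgError("singular stationary covariance block")
    out = sigma - gamma_t @ sol
    return 0.5 * (out + out.T)


def _logdet2(S: np.ndarray) -> float:
    sign, logdet = np.linalg.slogdet(S)
    if sign <= 0:
        raise np.linalg.LinAlgError("non-positive determinant in phi computation")
    return logdet / math.log(2.0)


def effective_information(
    model: MVARXModel | StationaryMoments,
    tau: int,
    partition: Bipartition,
    rho: int | None = None,
) -> float:
    """Effective information (bits) of a bipartition at lag ``tau``.

    ``0.5 * [-log2 det Sigma(y[n-tau] | y[n])
    + sum_i log2 det Sigma(m_i[n-tau] | m_i[n])]``; zero when the two
    parts are dynamically independent, symmetric in the two parts.
    """
    moments = _as_moments(model, tau, rho)
    val = -_logdet2(conditional_cov(moments, tau))
    for part in partition.parts:
        val += _logdet2(conditional_cov(moments, tau, subset=part))
    return 0.5 * val


def _as_moments(
    model: MVARXModel | StationaryMoments, tau: int, rho: int | None
) -> StationaryMoments:
    if isinstance(model, StationaryMoments):
        return model
    need = max(tau, model.p - 1, 1) if rho is None else rho
    return stationary_moments(model, rho=need)


def enumerate_bipartitions(d: int) -> list[Bipartition]:
    """All ``2**(d-1) - 1`` canonical bipartitions (channel 0 in part one)."""
    if d < 2:
        raise ValueError("need at least 2 channels to bipartition")
    rest = list(range(1, d))
    out = []
    for k in range(0, d - 1):
        for extra in combinations(rest, k):
            m1 = (0,) + extra
            m2 = tuple(i for i in rest if i not in extra)
            out.append(Bipartition(M1=m1, M2=m2))
    return out


def _entropy_bits(sigma_block: np.ndarray) -> float:
    """Differential entropy (bits) of a zero-mean Gaussian block."""
    k = sigma_block.shape[0]
    return 0.5 * (k * math.log2(2.0 * math.pi * math.e) + _logdet2(sigma_block))


def minimum_information_bipartition(
    model: MVARXModel | StationaryMoments,
    tau: int,
    max_channels: int = _MAX_EXHAUSTIVE_D,
) -> tuple[Bipartition, float, list[tuple[Bipartition, float, float]]]:
    """Exhaustive search for the minimum-information bipartition.

    Each candidate's effective information is normalized by the smaller
    part's Gaussian entropy; the returned integrated information is the
    *unnormalized* effective information at the minimizing partition.
    Partitions whose normalizer is non-positive are excluded (logged).
    Returns ``(mib, phi_bits, table)`` where the table rows are
    ``(partition, phi, normalized score)``.
    """
    moments = _as_moments(model, tau, None)
    d = moments.sigma.shape[0]
    if d < 2:
        raise ValueError("need at least 2 channels")
    if d > max_channels:
        raise ValueError(
            f"d = {d} exceeds exhaustive-search cap {max_channels}; "
            "raise max_channels explicitly to override"
        )
    table: list[tuple[Bipartition, float, float]] = []
    best: tuple[float, Bipartition, float] | None = None
    n_excluded = 0
    for part in enumerate_bipartitions(d):
        phi = effective_information(moments, tau, part)
        k2 = min(
            _entropy_bits(moments.sigma[np.ix_(part.M1, part.M1)]),
            _entropy_bits(moments.sigma[np.ix_(part.M2, part.M2)]),
        )
        if k2 <= 0:
            n_excluded += 1
            continue
        score = phi / k2
        table.append((part, phi, score))
        if best is None or score < best[0]:
            best = (score, part, phi)
    if n_excluded:
        log.warning("excluded %d bipartitions with non-positive entropy "
                    "normalizer", n_excluded)
    if best is None:
        raise ValueError("all bipartitions have non-positive normalizers")
    return best[1], best[2], table


def phi_profile(
    model: MVARXModel,
    tau_grid: Sequence[int] | None = None,
    max_channels: int = _MAX_EXHAUSTIVE_D,
) -> PhiProfile:
    """Integrated information over a grid of lags.

    Default grid is 1..30 samples (10-300 ms at 100 Hz). The stationary
    moments are computed once up to the largest lag and reused.
    """
    taus = np.asarray(sorted(tau_grid) if tau_grid is not None
                      else range(1, 31), dtype=int)
    if taus.size == 0 or taus[0] < 1:
        raise ValueError("lag grid must contain lags >= 1")
    moments = stationary_moments(model, rho=max(int(taus[-1]), model.p - 1, 1))
    phis = np.empty(taus.size)
    mibs: list[Bipartition] = []
    for k, tau in enumerate(taus):
        mib, phi, _ = minimum_information_bipartition(
            moments, int(tau), max_channels=max_channels
        )
        phis[k] = phi
        mibs.append(mib)
    return PhiProfile(taus=taus, phi=phis, mib=mibs, fs=model.fs)


def compare_conditions(
    phi_max_a: Sequence[float], phi_max_b: Sequence[float]
) -> float:
    """Two-sided rank-sum p-value for equal medians of two phi samples.

    Uses the exact null distribution when sample sizes permit (no ties),
    falling back to the normal approximation otherwise.
    """
    a = np.asarray(list(phi_max_a), dtype=float)
    b = np.asarray(list(phi_max_b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each condition needs at least 2 values")
    res = mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return float(res.pvalue)
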