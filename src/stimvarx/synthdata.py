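"""Synthetic MVARX systems and stimulation sessions.

Generates ground-truth models and sessions mirroring the target recording
structure (8-12 channels, 30-pulse trains at 1 s inter-stimulus interval,
100 Hz analysis rate), plus injectable outlier epochs and high-rate raw
sessions with conduction artifacts for exercising the preprocessing chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.signal

from .core import MVARXModel, companion_matrix, simulate_evoked, spectral_radius

__all__ = [
    "StimulusTrain",
    "SessionData",
    "random_stable_mvarx",
    "simulate_session",
    "inject_outliers",
    "make_raw_session",
]


@dataclass
class StimulusTrain:
    """Pulse times (sample indices at the analysis rate) for one session."""

    pulse_times: np.ndarray
    isi: int = 100
    pulse_waveform: np.ndarray = field(
        default_factory=lambda: np.array([1.0])
    )

    def __post_init__(self) -> None:
        self.pulse_times = np.asarray(self.pulse_times, dtype=int)
        self.pulse_waveform = np.asarray(self.pulse_waveform, dtype=float)
        if self.pulse_times.size < 1:
            raise ValueError("need at least one pulse")
        if np.any(np.diff(self.pulse_times) <= 0):
            raise ValueError("pulse_times must be strictly increasing")
        if self.isi <= 0:
            raise ValueError("isi must be positive")

    @property
    def n_pulses(self) -> int:
        return int(self.pulse_times.size)

    @classmethod
    def regular(cls, n_pulses: int = 30, isi: int = 100, start: int = 100) -> "StimulusTrain":
        """Default train: ``n_pulses`` unit impulses every ``isi`` samples."""
        return cls(pulse_times=start + isi * np.arange(n_pulses), isi=isi)

    def input_sequence(self, n_samples: int) -> np.ndarray:
        """Length-``n_samples`` exogenous input with the waveform at each pulse."""
        x = np.zeros(n_samples)
        w = self.pulse_waveform
        for t in self.pulse_times:
            if t >= n_samples:
                continue
            stop = min(t + w.size, n_samples)
            x[t:stop] += w[: stop - t]
        return x


@dataclass
class SessionData:
    """Continuous multichannel recording plus aligned exogenous input."""

    y: np.ndarray
    x: np.ndarray
    fs: float
    channel_names: list[str] | None = None
    truth: dict | None = None

    def __post_init__(self) -> None:
        self.y = np.atleast_2d(np.asarray(self.y, dtype=float))
        self.x = np.asarray(self.x, dtype=float).ravel()
        if self.y.shape[1] != self.x.shape[0]:
            raise ValueError("y and x must share the sample count")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.y.shape[0] < 1:
            raise ValueError("need at least one channel")
        if self.channel_names is None:
            self.channel_names = [f"ch{i}" for i in range(self.y.shape[0])]

    @property
    def d(self) -> int:
        return self.y.shape[0]

    @property
    def n_samples(self) -> int:
        return self.y.shape[1]


def random_stable_mvarx(
    d: int,
    p: int,
    ell: int = 10,
    spectral_radius_target: float = 0.8,
    seed: int = 0,
    fs: float = 100.0,
    input_gain: float = 1.0,
    noise_scale: float = 1.0,
) -> MVARXModel:
    """Random MVARX model whose companion matrix has the requested radius.

    Coefficients are drawn i.i.d. Gaussian and each lag block ``A_i`` is
    rescaled by ``(target / rho)**i``, which scales every companion
    eigenvalue by ``target / rho`` -- the radius hits the target without
    rejection sampling. ``Q = noise_scale * (W W^T / d + 0.1 I)`` from a
    random ``W`` is strictly positive definite.
    """
    if d < 1 or p < 1 or ell < 0:
        raise ValueError("require d >= 1, p >= 1, ell >= 0")
    if not 0.0 < spectral_radius_target < 1.0:
        raise ValueError("spectral_radius_target must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    A = rng.standard_normal((p, d, d)) / np.sqrt(d * p)
    rho = spectral_radius(A)
    if rho == 0.0:  # pragma: no cover - zero draw has probability zero
        A[0] += 0.1 * np.eye(d)
        rho = spectral_radius(A)
    scale = spectral_radius_target / rho
    for i in range(p):
        A[i] *= scale ** (i + 1)
    B = input_gain * rng.standard_normal((d, ell + 1))
    W = rng.standard_normal((d, d))
    Q = noise_scale * (W @ W.T / d + 0.1 * np.eye(d))
    return MVARXModel(A=A, B=B, Q=Q, fs=fs,
                      channel_names=[f"ch{i}" for i in range(d)])


def simulate_session(
    model: MVARXModel,
    train: StimulusTrain,
    n_samples: int,
    burn_in: int = 200,
    seed: int = 0,
) -> SessionData:
    """Forward-simulate the generative recursion with Gaussian innovations.

    ``burn_in`` noise-only samples are run before t=0 so the spontaneous
    component is near-stationary when recording starts. ``truth`` stores
    the generating model, the deterministic evoked component (noise-free
    recursion over the same input from zero initial conditions at session
    start), and the noise-only component; the three satisfy
    ``y = evoked + spontaneous`` exactly.
    """
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    if spectral_radius(model) >= 1.0:
        raise ValueError("model is unstable (spectral radius >= 1)")
    if burn_in < model.p:
        raise ValueError("burn_in must be at least the AR order p")
    rng = np.random.default_rng(seed)
    d, p = model.d, model.p
    x = train.input_sequence(n_samples)
    # innovations for burn-in + session; eigh factor handles semidefinite Q
    evals, evecs = np.linalg.eigh(model.Q)
    Lq = evecs * np.sqrt(np.clip(evals, 0.0, None))
    w = Lq @ rng.standard_normal((d, burn_in + n_samples))
    # spontaneous component: AR recursion driven by noise only,
    # simulated via the companion form
    F = companion_matrix(model.A)
    state = np.zeros(d * p)
    y_s = np.empty((d, n_samples))
    for n in range(burn_in + n_samples):
        state = F @ state
        state[:d] += w[:, n]
        if n >= burn_in:
            y_s[:, n - burn_in] = state[:d]
    y_e = simulate_evoked(model, x)
    return SessionData(
        y=y_e + y_s,
        x=x,
        fs=model.fs,
        channel_names=model.channel_names,
        truth={"model": model, "evoked": y_e, "spontaneous": y_s, "train": train},
    )


def inject_outliers(
    session: SessionData,
    epoch_indices,
    scale: float = 10.0,
    seed: int = 0,
    epoch_length: int = 100,
    pre: int = 12,
) -> SessionData:
    """Add a slow large-amplitude transient to the designated epochs.

    The transient is a half-sine spanning one epoch with amplitude
    ``scale`` times the per-channel standard deviation (randomly signed
    per channel), mimicking slow-wave contamination. Samples outside the
    chosen epochs are bit-identical to the input.
    """
    if session.truth is not None and "train" in session.truth:
        train: StimulusTrain = session.truth["train"]
        starts = train.pulse_times - pre
    else:
        raise ValueError("session lacks a stimulus train; cannot locate epochs")
    epoch_indices = sorted(set(int(i) for i in epoch_indices))
    if any(i < 0 or i >= starts.size for i in epoch_indices):
        raise ValueError("epoch index out of range")
    y = session.y.copy()
    if epoch_indices and scale != 0.0:
        rng = np.random.default_rng(seed)
        sd = session.y.std(axis=1)
        bump = np.sin(np.pi * np.arange(epoch_length) / (epoch_length - 1))
        for i in epoch_indices:
            s = int(starts[i])
            stop = min(s + epoch_length, session.n_samples)
            signs = np.where(rng.random(session.d) < 0.5, -1.0, 1.0)
            y[:, s:stop] += (scale * sd * signs)[:, None] * bump[: stop - s][None, :]
    return SessionData(
        y=y, x=session.x.copy(), fs=session.fs,
        channel_names=session.channel_names, truth=session.truth,
    )


def make_raw_session(
    session: SessionData,
    fs_raw: float = 1000.0,
    artifact_amplitude: float = 50.0,
    artifact_width: int = 5,
    seed: int = 0,
) -> SessionData:
    """Band-limited upsampling to the raw rate plus conduction artifacts.

    Returns a session whose ``x`` is a binary trigger channel (1 at pulse
    samples at the raw rate) and whose ``y`` carries a sharp biphasic
    artifact of the given amplitude (in units of per-channel SD) at each
    trigger. ``truth['clean_raw']`` stores the artifact-free raw signal.
    """
    factor = fs_raw / session.fs
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError("fs_raw must be an integer multiple of session fs")
    factor = int(round(factor))
    y_raw = scipy.signal.resample_poly(session.y, factor, 1, axis=1)
    T_raw = y_raw.shape[1]
    if session.truth is None or "train" not in session.truth:
        raise ValueError("session lacks a stimulus train")
    train: StimulusTrain = session.truth["train"]
    pulses_raw = train.pulse_times * factor
    trigger = np.zeros(T_raw)
    trigger[pulses_raw[pulses_raw < T_raw]] = 1.0
    y = y_raw.copy()
    if artifact_amplitude != 0.0:
        rng = np.random.default_rng(seed)
        sd = y_raw.std(axis=1)
        # sharp biphasic spike, a few samples wide at the raw rate
        t = np.arange(artifact_width)
        shape = np.sin(2 * np.pi * t / artifact_width) * np.exp(-t / artifact_width)
        for tp in pulses_raw:
            if tp >= T_raw:
                continue
            stop = min(tp + artifact_width, T_raw)
            gains = artifact_amplitude * sd * (0.5 + rng.random(session.d))
            y[:, tp:stop] += gains[:, None] * shape[: stop - tp][None, :]
    truth = dict(session.truth)
    truth["clean_raw"] = y_raw
    truth["pulses_raw"] = pulses_raw
    return SessionData(y=y, x=trigger, fs=fs_raw,
                       channel_names=session.channel_names, truth=truth)
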