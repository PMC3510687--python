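"""Artifact cleaning, anti-alias downsampling, and epoch segmentation.

The cleaning stage blends each channel with its median-filtered version
inside a short Tukey-weighted window around every stimulus, removing the
sharp conduction artifact while leaving everything outside the window
bit-identical. The downsampling stage applies a linear-phase FIR lowpass
(delay-compensated, so latencies are preserved) and decimates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.ndimage
import scipy.signal

from .core import EpochSet
from .synthdata import SessionData

__all__ = [
    "CleaningConfig",
    "DownsampleConfig",
    "tukey_median_clean",
    "antialias_downsample",
    "segment_epochs",
    "trigger_times",
]


@dataclass
class CleaningConfig:
    """Tukey-windowed median filter parameters (durations in ms)."""

    median_order: int = 19
    flat_top_ms: float = 10.0
    taper_ms: float = 9.0

    def __post_init__(self) -> None:
        if self.median_order < 1 or self.median_order % 2 == 0:
            raise ValueError("median_order must be a positive odd integer")
        if self.flat_top_ms <= 0 or self.taper_ms <= 0:
            raise ValueError("durations must be positive")

    @property
    def halfwidth_ms(self) -> float:
        return self.flat_top_ms + self.taper_ms


@dataclass
class DownsampleConfig:
    """Anti-alias lowpass + decimation parameters."""

    passband_hz: float = 48.0
    stopband_hz: float = 49.9
    factor: int = 10
    min_stopband_atten_db: float = 40.0

    def __post_init__(self) -> None:
        if not 0 < self.passband_hz < self.stopband_hz:
            raise ValueError("require 0 < passband < stopband")
        if self.factor < 1:
            raise ValueError("factor must be >= 1")

    def validate_fs(self, fs: float) -> None:
        if abs(fs / self.factor - round(fs / self.factor)) > 1e-9:
            raise ValueError(f"fs = {fs} not divisible by factor {self.factor}")
        if self.stopband_hz > (fs / self.factor) / 2:
            raise ValueError("stopband edge exceeds post-decimation Nyquist")


def _tukey_weights(halfwidth: int, flat: int) -> np.ndarray:
    """Weights over offsets -halfwidth..halfwidth: 1 on |t| <= flat,
    cosine taper down to 0 at |t| = halfwidth, 0 beyond."""
    t = np.abs(np.arange(-halfwidth, halfwidth + 1, dtype=float))
    w = np.zeros_like(t)
    w[t <= flat] = 1.0
    taper = (t > flat) & (t <= halfwidth)
    w[taper] = 0.5 * (1.0 + np.cos(np.pi * (t[taper] - flat) / (halfwidth - flat)))
    return w


def tukey_median_clean(
    raw: SessionData,
    trigger_times: np.ndarray,
    cfg: CleaningConfig | None = None,
) -> SessionData:
    """Replace data near each stimulus with a median-filtered blend.

    Output is ``w * median_filtered + (1 - w) * raw`` where the weight
    ``w`` is 1 within ``flat_top_ms`` of a trigger, tapers to 0 over
    ``taper_ms``, and is 0 elsewhere; samples with ``w = 0`` are returned
    bit-identical. Median filtering uses reflect padding at the edges.
    """
    cfg = cfg or CleaningConfig()
    trig = np.asarray(trigger_times, dtype=int)
    T = raw.n_samples
    if trig.size and (trig.min() < 0 or trig.max() >= T):
        raise ValueError("trigger times out of bounds")
    ms = raw.fs / 1000.0
    halfwidth = int(round(cfg.halfwidth_ms * ms))
    flat = int(round(cfg.flat_top_ms * ms))
    if trig.size > 1:
        gaps = np.diff(np.sort(trig))
        bad = np.nonzero(gaps <= 2 * halfwidth)[0]
        if bad.size:
            s = np.sort(trig)
            raise ValueError(
                f"stimulus windows overlap: triggers at {s[bad[0]]} and "
                f"{s[bad[0] + 1]} are closer than {2 * halfwidth + 1} samples"
            )
    w = np.zeros(T)
    win = _tukey_weights(halfwidth, flat)
    for t in trig:
        lo = max(0, t - halfwidth)
        hi = min(T, t + halfwidth + 1)
        w[lo:hi] = np.maximum(w[lo:hi], win[lo - (t - halfwidth) : hi - (t - halfwidth)])
    med = scipy.ndimage.median_filter(
        raw.y, size=(1, cfg.median_order), mode="reflect"
    )
    y = raw.y + w[None, :] * (med - raw.y)
    return SessionData(y=y, x=raw.x.copy(), fs=raw.fs,
                       channel_names=raw.channel_names, truth=raw.truth)


def design_lowpass(fs: float, cfg: DownsampleConfig) -> np.ndarray:
    """Linear-phase FIR lowpass meeting the config's band edges (odd length)."""
    width = cfg.stopband_hz - cfg.passband_hz
    numtaps, beta = scipy.signal.kaiserord(cfg.min_stopband_atten_db,
                                           width / (fs / 2))
    if numtaps % 2 == 0:
        numtaps += 1
    cutoff = 0.5 * (cfg.passband_hz + cfg.stopband_hz)
    return scipy.signal.firwin(numtaps, cutoff, window=("kaiser", beta), fs=fs)


def _zero_phase_filter(sig: np.ndarray, taps: np.ndarray) -> np.ndarray:
    """Apply an odd-length linear-phase FIR with exact delay compensation."""
    delay = (taps.size - 1) // 2
    sig2 = np.atleast_2d(sig)
    padded = np.pad(sig2, ((0, 0), (delay, delay)), mode="reflect")
    out = scipy.signal.fftconvolve(padded, taps[None, :], mode="valid")
    return out if sig.ndim == 2 else out[0]


def antialias_downsample(
    session: SessionData,
    cfg: DownsampleConfig | None = None,
    binary_trigger: bool = False,
) -> SessionData:
    """Lowpass filter (zero net delay) and decimate data and input.

    The exogenous input is passed through the identical filter chain so
    its shape matches what the recording channels saw; with
    ``binary_trigger=True`` the input is instead rebuilt as a unit
    impulse at each decimated trigger position (synthetic workflows).
    """
    cfg = cfg or DownsampleConfig()
    cfg.validate_fs(session.fs)
    taps = design_lowpass(session.fs, cfg)
    y = _zero_phase_filter(session.y, taps)[:, :: cfg.factor]
    if binary_trigger:
        x = np.zeros(y.shape[1])
        pulses = trigger_times(session.x) // cfg.factor
        x[pulses[pulses < x.size]] = 1.0
    else:
        x = _zero_phase_filter(session.x, taps)[:: cfg.factor]
    return SessionData(y=y, x=x, fs=session.fs / cfg.factor,
                       channel_names=session.channel_names, truth=session.truth)


def trigger_times(trigger: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Sample indices of rising edges in a (near-)binary trigger channel."""
    t = np.asarray(trigger, dtype=float) > threshold
    edges = np.nonzero(t & ~np.concatenate(([False], t[:-1])))[0]
    return edges


def segment_epochs(
    y: np.ndarray,
    x: np.ndarray,
    stim_times: np.ndarray,
    pre: int = 12,
    length: int = 100,
    fs: float = 100.0,
    channel_names: list[str] | None = None,
) -> EpochSet:
    """Cut stimulus-aligned fixed-length epochs from a continuous recording.

    Epoch ``j`` covers samples ``[stim_times[j] - pre, stim_times[j] - pre
    + length)``; the stimulus falls at within-epoch index ``pre``. The
    input is segmented identically and the full-session input is retained
    for whole-train evoked reconstruction.
    """
    y = np.atleast_2d(np.asarray(y, dtype=float))
    x = np.asarray(x, dtype=float).ravel()
    stim = np.asarray(stim_times, dtype=int)
    if np.any(np.diff(stim) <= 0):
        raise ValueError("stim_times must be strictly increasing")
    T = y.shape[1]
    starts = stim - pre
    if starts.size and (starts.min() < 0 or (starts + length).max() > T):
        raise ValueError("epoch window out of bounds")
    epochs = [y[:, s : s + length].copy() for s in starts]
    inputs = [x[s : s + length].copy() for s in starts]
    return EpochSet(
        epochs=epochs, inputs=inputs, fs=fs, channel_names=channel_names,
        stim_offset=pre, starts=list(int(s) for s in starts), session_x=x.copy(),
    )
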