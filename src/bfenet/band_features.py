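"""Band decomposition and windowed differential entropy from raw signals.

This is the optional front end for users without precomputed DE features:
zero-phase Butterworth band-pass filtering into the five canonical EEG bands
followed by per-window Gaussian differential entropy

    DE(x) = 0.5 * ln(2 * pi * e * var(x))    [nats],

computed over non-overlapping windows. Band edges follow the convention
used with the SEED datasets (delta 1-3, theta 4-7, alpha 8-13, beta 14-30,
gamma 31-50 Hz) and are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, sosfiltfilt


@dataclass(frozen=True)
class BandDefinition:
    name: str
    low_hz: float
    high_hz: float

    def __post_init__(self):
        if not 0 < self.low_hz < self.high_hz:
            raise ValueError(f"band {self.name}: need 0 < low < high")


DEFAULT_BANDS = (
    BandDefinition("delta", 1.0, 3.0),
    BandDefinition("theta", 4.0, 7.0),
    BandDefinition("alpha", 8.0, 13.0),
    BandDefinition("beta", 14.0, 30.0),
    BandDefinition("gamma", 31.0, 50.0),
)


def bandpass_split(
    signal: np.ndarray,
    fs: float,
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
    order: int = 4,
) -> np.ndarray:
    """Zero-phase band-pass decomposition along the last axis.

    Returns an array with a leading band axis; each output has the same
    length as the input (forward-backward filtering, no phase shift).
    """
    signal = np.asarray(signal, dtype=np.float64)
    nyq = fs / 2.0
    out = []
    for band in bands:
        if band.high_hz >= nyq:
            raise ValueError(
                f"band {band.name} ({band.low_hz}-{band.high_hz} Hz) reaches the "
                f"Nyquist frequency {nyq} Hz"
            )
        sos = butter(order, [band.low_hz, band.high_hz], btype="bandpass", fs=fs, output="sos")
        out.append(sosfiltfilt(sos, signal, axis=-1))
    return np.stack(out)


def compute_de(window: np.ndarray) -> float:
    """Gaussian differential entropy of one window, 0.5*ln(2*pi*e*var)."""
    window = np.asarray(window, dtype=np.float64).ravel()
    if window.size < 2:
        raise ValueError("window must contain at least 2 samples")
    var = window.var()  # population variance
    if var <= 0:
        raise ValueError("zero-variance window has undefined differential entropy")
    return float(0.5 * np.log(2.0 * np.pi * np.e * var))


def window_features(
    raw: np.ndarray,
    fs: float,
    window_s: float = 1.0,
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
    var_floor: float | None = None,
) -> np.ndarray:
    """DE features over non-overlapping windows: (channels, n_windows, n_bands).

    ``raw`` is (channels, samples). The recording is first band-split, then
    each window of ``window_s`` seconds contributes one DE value per channel
    and band. ``var_floor``, if given, substitutes for zero window variance
    instead of raising.
    """
    raw = np.atleast_2d(np.asarray(raw, dtype=np.float64))
    n = round(window_s * fs)
    if abs(n - window_s * fs) > 1e-9 or n < 2:
        raise ValueError(f"window_s * fs must be an integer >= 2, got {window_s * fs}")
    n_windows = raw.shape[1] // n
    if n_windows < 1:
        raise ValueError(
            f"recording of {raw.shape[1]} samples shorter than one window ({n})"
        )
    split = bandpass_split(raw, fs, bands)  # (B, C, samples)
    trimmed = split[:, :, : n_windows * n].reshape(len(bands), raw.shape[0], n_windows, n)
    var = trimmed.var(axis=-1)
    if var_floor is not None:
        var = np.maximum(var, var_floor)
    elif np.any(var <= 0):
        raise ValueError("zero-variance window encountered; pass var_floor to clamp")
    de = 0.5 * np.log(2.0 * np.pi * np.e * var)  # (B, C, W)
    return np.transpose(de, (1, 2, 0))


def moving_average_smooth(features: np.ndarray, width: int = 5) -> np.ndarray:
    """Simple causal moving-average smoother along the window axis.

    A deliberately plain stand-in for the linear-dynamical-system smoothing
    that ships with the SEED features; provided so raw-signal pipelines have
    a comparable smoothing step.
    """
    if width < 1:
        raise ValueError("width must be >= 1")
    x = np.asarray(features, dtype=np.float64)
    out = np.empty_like(x)
    csum = np.cumsum(x, axis=1)
    for t in range(x.shape[1]):
        lo = max(0, t - width + 1)
        total = csum[:, t, :] - (csum[:, lo - 1, :] if lo > 0 else 0)
        out[:, t, :] = total / (t - lo + 1)
    return out
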