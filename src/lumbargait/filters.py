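"""Signal-conditioning primitives shared by the turn-segmentation and
event-detection stages.

All filters are zero-phase: timing of gait events is the quantity of
interest, so causal phase lag is unacceptable.  The Savitzky-Golay
smoother is implemented with an orthogonal (Legendre) polynomial basis and
a QR factorisation per frame so that very high polynomial orders (the
event stage uses order 50 over an 801-sample frame) remain numerically
well conditioned; a plain monomial Vandermonde would be singular to
working precision at that order.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import signal

from .errors import ParameterError

__all__ = [
    "bandpass_butterworth",
    "rectify",
    "savitzky_golay",
    "median_filter",
    "scale_frame",
]

#: Sampling rate (Hz) at which the default frame lengths are quoted.
REFERENCE_FS = 128.0


def bandpass_butterworth(
    x: np.ndarray, fs: float, low: float = 1.0, high: float = 50.0, order: int = 4
) -> np.ndarray:
    """Zero-phase Butterworth band-pass.

    The filter is designed with ``order`` poles per band edge and applied
    forward-backward (``sosfiltfilt``), which doubles the effective order
    and cancels the phase response.  The DC component is removed by the
    high-pass edge.

    Parameters
    ----------
    x : array_like
        Input samples.
    fs : float
        Sampling rate in Hz.
    low, high : float
        Pass-band edges in Hz; must satisfy ``0 < low < high < fs / 2``.
    order : int
        Butterworth design order.
    """
    if fs <= 0:
        raise ParameterError(f"sampling rate must be positive, got {fs}")
    if not 0 < low < high < fs / 2:
        raise ParameterError(
            f"band edges must satisfy 0 < low < high < fs/2, got "
            f"low={low}, high={high}, fs={fs}"
        )
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ParameterError("expected a 1-D signal")
    if len(x) <= 3 * order:
        raise ParameterError(
            f"signal of length {len(x)} too short for an order-{order} filter"
        )
    sos = signal.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x)


def rectify(x: np.ndarray) -> np.ndarray:
    """Full-wave rectification (elementwise absolute value)."""
    return np.abs(np.asarray(x, dtype=float))


@lru_cache(maxsize=8)
def _sg_projection(frame_len: int, polyorder: int) -> np.ndarray:
    """Orthonormal basis Q (frame_len x (polyorder+1)) of the polynomial
    space over the frame, built from a Legendre-Vandermonde + QR."""
    xs = np.linspace(-1.0, 1.0, frame_len)
    V = np.polynomial.legendre.legvander(xs, polyorder)
    Q, _ = np.linalg.qr(V)
    return Q


def savitzky_golay(x: np.ndarray, polyorder: int, frame_len: int) -> np.ndarray:
    """Savitzky-Golay smoothing: per-frame least-squares polynomial fit
    evaluated at the frame centre.

    Interior samples equal the local least-squares fit of degree
    ``polyorder`` over the centred ``frame_len``-sample window.  Edges are
    handled by mirror (reflect) padding, which keeps the output band
    limited near the boundaries; boundary regions are discarded downstream
    anyway when regions of interest touching segment edges are dropped.

    Parameters
    ----------
    x : array_like
        Input samples; ``len(x) >= frame_len``.
    polyorder : int
        Degree of the local polynomial, ``< frame_len``.
    frame_len : int
        Odd window length in samples.
    """
    x = np.asarray(x, dtype=float)
    if frame_len % 2 == 0:
        raise ParameterError(f"frame_len must be odd, got {frame_len}")
    if not 0 <= polyorder < frame_len:
        raise ParameterError(
            f"polyorder must satisfy 0 <= polyorder < frame_len, got "
            f"{polyorder} vs {frame_len}"
        )
    if len(x) < frame_len:
        raise ParameterError(
            f"signal of length {len(x)} shorter than frame ({frame_len})"
        )
    half = frame_len // 2
    Q = _sg_projection(frame_len, polyorder)
    # Weights of the centre-sample evaluation of the LS fit: row `half` of
    # the projection matrix Q Q^T.
    w = Q @ Q[half]
    xp = np.pad(x, half, mode="reflect")
    return np.convolve(xp, w[::-1], mode="valid")


def median_filter(x: np.ndarray, order: int = 10) -> np.ndarray:
    """1-D running median of window length ``order``.

    Even orders are supported with the usual order-statistic convention:
    the median of an even window is the mean of the two central order
    statistics, and the window is right-aligned on the current sample
    (samples ``i - order//2 .. i + order//2 - 1``).  Edges use edge-value
    padding.
    """
    x = np.asarray(x, dtype=float)
    if order < 1:
        raise ParameterError(f"median order must be >= 1, got {order}")
    if order == 1:
        return x.copy()
    left = order // 2
    right = order - left - 1
    xp = np.pad(x, (left, right), mode="edge")
    windows = np.sort(sliding_window_view(xp, order), axis=1)
    if order % 2 == 1:
        return windows[:, order // 2]
    return 0.5 * (windows[:, order // 2 - 1] + windows[:, order // 2])


def scale_frame(frame_at_reference: int, fs: float) -> int:
    """Scale a frame length quoted at 128 Hz to another sampling rate.

    Frame lengths are durations in disguise (e.g. 1101 samples = 8.6 s at
    128 Hz), so they scale proportionally with ``fs`` and are rounded to
    the nearest odd integer.
    """
    if fs <= 0:
        raise ParameterError(f"sampling rate must be positive, got {fs}")
    n = int(round(frame_at_reference * fs / REFERENCE_FS))
    if n % 2 == 0:
        n += 1
    return max(n, 3)
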