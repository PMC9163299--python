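"""Trace conditioning: decimation, Hampel artifact rejection, leaky integration.

The raw extracellular signal is AC-coupled multi-unit activity; the analysis
operates on its integrated envelope.  The conditioning chain is

    decimate (anti-aliased 1/k resampling)
      -> Hampel filter (sliding median/MAD artifact replacement)
      -> rectify + leaky integrator (first-order envelope, y[n] = d*y[n-1] + |x[n]|)

Artifacts are *replaced* by the local window median (and reported), never
deleted, so the time base that burst periods depend on is preserved.  The
Hampel window is interpreted at the post-decimation rate, and the leak decay
is a dimensionless per-sample multiplier at that same rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.ndimage import uniform_filter1d

from .io_traces import Recording

__all__ = [
    "ConditioningParams",
    "decimate",
    "hampel_filter",
    "leaky_integrate",
    "condition",
]

#: Scale factor turning a median absolute deviation into a consistent
#: estimate of the Gaussian standard deviation.
MAD_SCALE = 1.4826


@dataclass(frozen=True)
class ConditioningParams:
    """Parameters of the conditioning chain.

    Defaults follow common practice for integrated XII rootlet traces
    sampled at 20 kHz: resample at 1/10 rate, Hampel with a 0.5 s window and
    a 5-sigma threshold, leaky-integrator decay 0.98 per (post-decimation)
    sample.
    """

    decimation_factor: int = 10
    hampel_window_s: float = 0.5
    hampel_nsigma: float = 5.0
    leak_decay: float = 0.98
    rectify: bool = True

    def __post_init__(self) -> None:
        if self.decimation_factor < 1:
            raise ValueError("decimation_factor must be >= 1")
        if self.hampel_window_s <= 0:
            raise ValueError("hampel_window_s must be positive")
        if self.hampel_nsigma <= 0:
            raise ValueError("hampel_nsigma must be positive")
        if not 0.0 < self.leak_decay < 1.0:
            raise ValueError("leak_decay must lie in (0, 1)")


def decimate(rec: Recording, factor: int) -> Recording:
    """Resample at 1/factor rate: centered moving average of width ``factor``
    (anti-alias) followed by take-every-kth.  Output length is floor(n/k)."""
    factor = int(factor)
    if factor < 1:
        raise ValueError("decimation factor must be >= 1")
    n = len(rec)
    if factor > n:
        raise ValueError(f"decimation factor {factor} exceeds trace length {n}")
    if factor == 1:
        return rec.copy_with(rec.samples)
    smoothed = uniform_filter1d(rec.samples, size=factor, mode="nearest")
    out = smoothed[::factor][: n // factor]
    return rec.copy_with(out, rate_hz=rec.rate_hz / factor)


def _hampel_core(x: np.ndarray, half: int, nsigma: float) -> tuple[np.ndarray, np.ndarray]:
    """Sliding median/MAD outlier replacement with edge-truncated windows.

    Sample i is compared against the median and MAD of x[max(0,i-half) : i+half+1];
    deviations strictly greater than nsigma * MAD_SCALE * MAD are replaced by
    the window median.  Strict inequality means constant windows (MAD = 0,
    deviation 0) never flag, while an isolated spike above a flat stretch
    (MAD = 0, deviation > 0) always does.
    """
    n = x.size
    y = x.copy()
    flagged = np.zeros(n, dtype=np.bool_)
    for i in range(n):
        lo = i - half
        if lo < 0:
            lo = 0
        hi = i + half + 1
        if hi > n:
            hi = n
        w = x[lo:hi]
        med = np.median(w)
        mad = np.median(np.abs(w - med))
        if np.abs(x[i] - med) > nsigma * MAD_SCALE * mad:
            y[i] = med
            flagged[i] = True
    return y, flagged


try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    _hampel_jit = njit(cache=True)(_hampel_core)
except Exception:  # pragma: no cover
    _hampel_jit = None


def hampel_filter(
    rec: Recording, window_s: float = 0.5, nsigma: float = 5.0
) -> tuple[Recording, np.ndarray]:
    """Replace artifact samples by the local sliding-window median.

    ``window_s`` is the total centered window length; it must span at least
    3 samples at the recording's rate.  Returns the cleaned recording and
    the array of flagged sample indices.
    """
    win = int(round(window_s * rec.rate_hz))
    if win < 3:
        raise ValueError(
            f"Hampel window of {window_s} s spans only {win} samples at "
            f"{rec.rate_hz} Hz; need at least 3"
        )
    half = win // 2
    core = _hampel_jit if _hampel_jit is not None else _hampel_core
    y, flagged = core(np.ascontiguousarray(rec.samples), half, float(nsigma))
    return rec.copy_with(y), np.flatnonzero(flagged)


def leaky_integrate(rec: Recording, decay: float = 0.98) -> Recording:
    """First-order leaky integrator y[n] = decay*y[n-1] + x_in[n].

    The input is rectified first (x_in = |x|); integrating the raw AC-coupled
    signal would cancel to near zero.  Set ``rectify=False`` via
    :func:`condition` params only for already-rectified envelopes.
    """
    return _leaky(rec, decay, rectify=True)


def _leaky(rec: Recording, decay: float, rectify: bool) -> Recording:
    if not 0.0 < decay < 1.0:
        raise ValueError(f"decay must lie in (0, 1), got {decay}")
    x = np.abs(rec.samples) if rectify else rec.samples
    # y[n] - decay*y[n-1] = x[n]  <=>  IIR filter b=[1], a=[1, -decay]
    y = signal.lfilter([1.0], [1.0, -decay], x)
    return rec.copy_with(y)


def condition(rec: Recording, params: ConditioningParams | None = None) -> tuple[Recording, np.ndarray]:
    """Full conditioning chain; returns the conditioned trace and the indices
    (post-decimation) of samples the Hampel stage replaced."""
    params = params or ConditioningParams()
    dec = decimate(rec, params.decimation_factor)
    cleaned, flagged = hampel_filter(dec, params.hampel_window_s, params.hampel_nsigma)
    integrated = _leaky(cleaned, params.leak_decay, params.rectify)
    return integrated, flagged
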