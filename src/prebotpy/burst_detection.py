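"""Burst calling on the conditioned, normalized envelope trace.

A burst is a local maximum of the integrated trace with topographic
prominence above threshold; peaks closer together than a refractory
distance are resolved in favour of the higher (ties to the earlier) peak.
Onset and offset are the nearest half-prominence crossings on each side of
the peak, which makes burst width robust to slow baseline drift.

Because the prominence threshold is expressed on a normalized trace, the
default normalization divides by the 95th percentile of the baseline
window: a threshold of 0.2 then means "20% of a typical baseline burst
peak", and detection is invariant to the arbitrary gain of the recording.

Implausible bursts are never removed silently; they receive review flags so
that the screening step stays auditable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal

from .conditioning import MAD_SCALE
from .io_traces import Recording

__all__ = [
    "Burst",
    "DetectionParams",
    "BurstTable",
    "normalize_trace",
    "detect_bursts",
    "burst_features",
    "screen_bursts",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Burst:
    """A single detected burst with its per-burst features.

    ``height`` is the maximum of the trace during the burst, ``width_s`` the
    half-prominence width, ``area`` the integral of the conditioned trace
    over [onset, offset], and ``period_to_next_s`` the time to the next
    burst's peak (absent for the last burst of a trace or epoch).
    """

    peak_t_s: float
    onset_t_s: float
    offset_t_s: float
    height: float
    width_s: float
    area: float
    period_to_next_s: float | None = None

    def __post_init__(self) -> None:
        if not self.onset_t_s <= self.peak_t_s <= self.offset_t_s:
            raise ValueError("burst must satisfy onset <= peak <= offset")


@dataclass(frozen=True)
class DetectionParams:
    """Peak-calling parameters on the normalized trace.

    ``min_prominence`` is topographic prominence (height above the higher of
    the two bracketing minima separating the peak from larger peaks);
    ``min_distance_s`` is the minimum spacing between reported peaks.
    """

    min_prominence: float = 0.2
    min_distance_s: float = 15.0
    normalization: str = "baseline-robust-max"

    def __post_init__(self) -> None:
        if self.min_prominence <= 0:
            raise ValueError("min_prominence must be positive")
        if self.min_distance_s <= 0:
            raise ValueError("min_distance_s must be positive")
        if self.normalization not in ("baseline-robust-max", "zscore", "none"):
            raise ValueError(f"unknown normalization {self.normalization!r}")


@dataclass
class BurstTable:
    """Ordered bursts of one slice (optionally one epoch) plus review flags."""

    slice_id: str = ""
    epoch_label: str = ""
    bursts: list[Burst] = field(default_factory=list)
    review_flags: set[int] = field(default_factory=set)

    def __len__(self) -> int:
        return len(self.bursts)

    @property
    def peak_times_s(self) -> np.ndarray:
        return np.array([b.peak_t_s for b in self.bursts])

    @property
    def periods_s(self) -> np.ndarray:
        return np.array(
            [b.period_to_next_s for b in self.bursts if b.period_to_next_s is not None]
        )

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "slice_id": self.slice_id,
                "epoch": self.epoch_label,
                "peak_t_s": b.peak_t_s,
                "onset_t_s": b.onset_t_s,
                "offset_t_s": b.offset_t_s,
                "height": b.height,
                "width_s": b.width_s,
                "area": b.area,
                "period_to_next_s": b.period_to_next_s,
                "flag": i in self.review_flags,
            }
            for i, b in enumerate(self.bursts)
        ]
        return pd.DataFrame(rows)


def normalize_trace(
    trace: Recording,
    mode: str = "baseline-robust-max",
    baseline_window: tuple[float, float] | None = None,
) -> Recording:
    """Normalize the conditioned trace so prominence thresholds are unitless.

    baseline-robust-max divides by the 95th percentile of the trace inside
    ``baseline_window`` (seconds); zscore uses the robust (median/MAD)
    standardization of the whole trace; none is the identity.
    """
    x = trace.samples
    if mode == "none":
        return trace.copy_with(x)
    if mode == "baseline-robust-max":
        if baseline_window is None:
            raise ValueError("baseline_window is required for baseline-robust-max")
        i0 = int(np.floor(baseline_window[0] * trace.rate_hz))
        i1 = int(np.ceil(baseline_window[1] * trace.rate_hz))
        seg = x[max(i0, 0) : min(i1, x.size)]
        if seg.size == 0:
            raise ValueError("baseline window contains no samples")
        denom = float(np.percentile(seg, 95))
        if denom <= 0:
            raise ValueError("baseline 95th percentile is not positive; cannot normalize")
        return trace.copy_with(x / denom)
    if mode == "zscore":
        med = float(np.median(x))
        mad = float(np.median(np.abs(x - med)))
        if mad <= 0:
            raise ValueError("MAD of trace is zero; cannot z-score")
        return trace.copy_with((x - med) / (MAD_SCALE * mad))
    raise ValueError(f"unknown normalization mode {mode!r}")


def _enforce_min_distance(
    peaks: np.ndarray, heights: np.ndarray, min_dist: int
) -> np.ndarray:
    """Greedy refractory selection: process candidates from highest to lowest
    (ties to the earlier index) and keep a peak only if no already-kept peak
    lies within ``min_dist`` samples."""
    order = np.lexsort((peaks, -heights))  # height desc, then index asc
    kept: list[int] = []
    for idx in order:
        p = peaks[idx]
        if all(abs(p - peaks[k]) >= min_dist for k in kept):
            kept.append(idx)
    return np.sort(peaks[kept])


def detect_bursts(trace: Recording, params: DetectionParams | None = None) -> BurstTable:
    """Call bursts on a conditioned, normalized trace.

    Returns an empty table (not an error) when no peak clears the prominence
    threshold.  Onset/offset are linearly interpolated half-prominence
    crossings; periods are successive peak-time differences.
    """
    params = params or DetectionParams()
    x = trace.samples
    table = BurstTable(slice_id=trace.slice_id)
    if x.size == 0:
        return table
    candidates, props = signal.find_peaks(x, prominence=params.min_prominence)
    if candidates.size == 0:
        return table
    min_dist = max(int(round(params.min_distance_s * trace.rate_hz)), 1)
    peaks = _enforce_min_distance(candidates, x[candidates], min_dist)
    prominences, _, _ = signal.peak_prominences(x, peaks)
    widths, width_heights, left_ips, right_ips = signal.peak_widths(
        x, peaks, rel_height=0.5
    )
    rate = trace.rate_hz
    bursts: list[Burst] = []
    for i, p in enumerate(peaks):
        onset = left_ips[i] / rate
        offset = right_ips[i] / rate
        i0, i1 = int(np.floor(left_ips[i])), int(np.ceil(right_ips[i])) + 1
        seg = x[i0:i1]
        bursts.append(
            Burst(
                peak_t_s=p / rate,
                onset_t_s=onset,
                offset_t_s=offset,
                height=float(seg.max()) if seg.size else float(x[p]),
                width_s=offset - onset,
                area=float(seg.sum() / rate),
                period_to_next_s=(peaks[i + 1] - p) / rate if i + 1 < len(peaks) else None,
            )
        )
    table.bursts = bursts
    return table


def burst_features(trace: Recording, table: BurstTable) -> BurstTable:
    """Recompute per-burst features from the trace over [onset, offset].

    ``detect_bursts`` already fills features; this entry point recomputes
    them (e.g. after editing onsets/offsets) from first principles:
    height = max of trace in the burst, width = offset - onset, area =
    sum of samples in the burst divided by the rate.
    """
    rate = trace.rate_hz
    x = trace.samples
    out: list[Burst] = []
    for b in table.bursts:
        i0 = int(np.floor(b.onset_t_s * rate))
        i1 = int(np.ceil(b.offset_t_s * rate)) + 1
        seg = x[max(i0, 0) : min(i1, x.size)]
        if seg.size == 0:
            raise ValueError(f"burst at {b.peak_t_s} s has an empty sample window")
        out.append(
            replace(
                b,
                height=float(seg.max()),
                width_s=b.offset_t_s - b.onset_t_s,
                area=float(seg.sum() / rate),
            )
        )
    return BurstTable(table.slice_id, table.epoch_label, out, set(table.review_flags))


@dataclass(frozen=True)
class PlausibilityRules:
    """Bands outside which a burst is flagged for human review."""

    width_band_s: tuple[float, float] = (0.1, 30.0)
    height_band: tuple[float, float] = (0.0, np.inf)


def screen_bursts(table: BurstTable, rules: PlausibilityRules | None = None) -> BurstTable:
    """Flag implausible bursts for review; nothing is removed.

    This replaces ad-hoc manual false-positive checking with an auditable
    flag-and-review mechanism: exclusion happens only through an explicit
    accept/reject decision downstream.
    """
    rules = rules or PlausibilityRules()
    flags = set(table.review_flags)
    for i, b in enumerate(table.bursts):
        ok_width = rules.width_band_s[0] <= b.width_s <= rules.width_band_s[1]
        ok_height = rules.height_band[0] <= b.height <= rules.height_band[1]
        if not (ok_width and ok_height):
            flags.add(i)
            log.info(
                "burst %d at %.2f s flagged for review (width %.3g s, height %.3g)",
                i, b.peak_t_s, b.width_s, b.height,
            )
    return BurstTable(table.slice_id, table.epoch_label, list(table.bursts), flags)
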