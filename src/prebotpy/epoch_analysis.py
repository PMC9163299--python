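"""Per-epoch aggregation of burst features and baseline normalization.

Each drug epoch is summarized by the arithmetic means of its burst features
and by the coefficient of variation of the burst period (sample SD / mean,
the standard irregularity measure for respiratory rhythms).  Feature means
are then expressed as ratios to the baseline epoch of the same slice, and
irregularity as the difference in CV from baseline, which removes the
arbitrary units of the recording and the slice-to-slice spread of intrinsic
rhythm frequency.

Bursts are assigned to the epoch whose *analysis window* contains their
peak.  A period straddling an epoch boundary is kept only when both bursts
fall inside the same analysis window; otherwise it is dropped (and the drop
is visible in the burst table), never prorated.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .burst_detection import Burst, BurstTable
from .io_traces import EpochPlan

__all__ = [
    "EpochSummary",
    "assign_epochs",
    "summarize_epoch",
    "normalize_to_baseline",
    "summaries_to_frame",
]

log = logging.getLogger(__name__)


@dataclass
class EpochSummary:
    """Mean burst features of one slice x epoch, optionally baseline-normalized."""

    slice_id: str
    epoch_label: str
    n_bursts: int
    mean_period_s: float = math.nan
    mean_height: float = math.nan
    mean_width_s: float = math.nan
    mean_area: float = math.nan
    cv_period: float = math.nan
    normalized_period: float = math.nan
    normalized_height: float = math.nan
    normalized_width: float = math.nan
    normalized_area: float = math.nan
    delta_cv: float = math.nan


def assign_epochs(table: BurstTable, plan: EpochPlan) -> dict[str, BurstTable]:
    """Partition a burst table by epoch analysis window.

    Returns a mapping ``label -> BurstTable``; bursts outside every analysis
    window are ignored with a log entry.  ``period_to_next_s`` survives only
    when the next burst lies in the same analysis window.
    """
    by_label: dict[str, list[Burst]] = {e.label: [] for e in plan}
    bursts = table.bursts
    for i, b in enumerate(bursts):
        epoch = plan.epoch_of(b.peak_t_s)
        if epoch is None:
            log.info(
                "burst at %.2f s falls outside all analysis windows; ignored", b.peak_t_s
            )
            continue
        period = b.period_to_next_s
        if period is not None:
            nxt = bursts[i + 1] if i + 1 < len(bursts) else None
            nxt_epoch = plan.epoch_of(nxt.peak_t_s) if nxt is not None else None
            if nxt_epoch is None or nxt_epoch.label != epoch.label:
                period = None  # boundary-straddling period: dropped, not prorated
        by_label[epoch.label].append(replace(b, period_to_next_s=period))
    return {
        label: BurstTable(table.slice_id, label, blist)
        for label, blist in by_label.items()
    }


def summarize_epoch(table: BurstTable) -> EpochSummary:
    """Arithmetic feature means and period CV for one epoch.

    Period statistics need at least two bursts (one period) and the CV needs
    at least two periods; unavailable statistics are reported as NaN rather
    than raising.
    """
    bursts = table.bursts
    s = EpochSummary(table.slice_id, table.epoch_label, n_bursts=len(bursts))
    if not bursts:
        return s
    s.mean_height = float(np.mean([b.height for b in bursts]))
    s.mean_width_s = float(np.mean([b.width_s for b in bursts]))
    s.mean_area = float(np.mean([b.area for b in bursts]))
    periods = table.periods_s
    if periods.size >= 1:
        s.mean_period_s = float(np.mean(periods))
    if periods.size >= 2:
        s.cv_period = float(np.std(periods, ddof=1) / np.mean(periods))
    return s


def normalize_to_baseline(summaries: list[EpochSummary]) -> list[EpochSummary]:
    """Express epoch means as ratios to the baseline epoch of the same slice.

    ``delta_cv`` is the difference (not ratio) of period CVs, since CV is
    already dimensionless.  Raises if the baseline summary is missing or has
    a zero mean for any normalized feature.
    """
    baselines = [s for s in summaries if s.epoch_label == "baseline"]
    if len(baselines) != 1:
        raise ValueError(f"expected exactly one baseline summary, got {len(baselines)}")
    base = baselines[0]
    pairs = [
        ("mean_period_s", "normalized_period"),
        ("mean_height", "normalized_height"),
        ("mean_width_s", "normalized_width"),
        ("mean_area", "normalized_area"),
    ]
    out: list[EpochSummary] = []
    for s in summaries:
        s = replace(s)
        for raw, norm in pairs:
            b = getattr(base, raw)
            v = getattr(s, raw)
            if not math.isnan(v):
                if b == 0 or math.isnan(b):
                    raise ValueError(f"baseline {raw} is zero or undefined; cannot normalize")
                setattr(s, norm, v / b)
        if not math.isnan(s.cv_period) and not math.isnan(base.cv_period):
            s.delta_cv = s.cv_period - base.cv_period
        out.append(s)
    return out


def summaries_to_frame(summaries: list[EpochSummary]) -> pd.DataFrame:
    """Delimited-table schema consumed by :mod:`prebotpy.group_stats`."""
    return pd.DataFrame([vars(s) for s in summaries])
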