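"""End-to-end convenience: raw trace -> conditioned trace -> bursts ->
baseline-normalized epoch summaries.

This is the composition the individual modules define; it exists so that
scripts, the CLI, and recovery tests run the exact same chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .burst_detection import (
    BurstTable,
    DetectionParams,
    PlausibilityRules,
    detect_bursts,
    normalize_trace,
    screen_bursts,
)
from .conditioning import ConditioningParams, condition
from .epoch_analysis import (
    EpochSummary,
    assign_epochs,
    normalize_to_baseline,
    summarize_epoch,
)
from .io_traces import EpochPlan, Recording

__all__ = ["PipelineParams", "PipelineResult", "analyze_recording"]


@dataclass(frozen=True)
class PipelineParams:
    conditioning: ConditioningParams = field(default_factory=ConditioningParams)
    detection: DetectionParams = field(default_factory=DetectionParams)
    screening: PlausibilityRules = field(default_factory=PlausibilityRules)


@dataclass
class PipelineResult:
    conditioned: Recording
    bursts: BurstTable
    by_epoch: dict[str, BurstTable]
    summaries: list[EpochSummary]

    def summary_for(self, label: str) -> EpochSummary:
        return next(s for s in self.summaries if s.epoch_label == label)


def analyze_recording(
    rec: Recording, plan: EpochPlan, params: PipelineParams | None = None
) -> PipelineResult:
    """Run the full analysis chain on one recording.

    Conditioning (decimate, Hampel, leaky integrator), normalization to the
    baseline analysis window, prominence-based burst detection with
    plausibility screening, epoch assignment, per-epoch summaries and
    baseline normalization.
    """
    params = params or PipelineParams()
    conditioned, _ = condition(rec, params.conditioning)
    normalized = normalize_trace(
        conditioned,
        mode=params.detection.normalization,
        baseline_window=plan.baseline.analysis_window,
    )
    table = detect_bursts(normalized, params.detection)
    table = screen_bursts(table, params.screening)
    by_epoch = assign_epochs(table, plan)
    summaries = [summarize_epoch(t) for t in by_epoch.values()]
    summaries = normalize_to_baseline(summaries)
    return PipelineResult(normalized, table, by_epoch, summaries)
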