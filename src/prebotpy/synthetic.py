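"""Synthetic XII-rootlet-like recordings and period samples with ground truth.

The generator implements the statistical phenomenology the analysis
pipeline assumes, not the biophysics of the preBotzinger network:

* burstlet timing is a gamma renewal process — intervals with mean equal to
  the baseline period times the epoch's dose multiplier, and coefficient of
  variation ``jitter_cv`` (gamma keeps intervals positive and makes the CV
  a direct parameter);
* each burstlet is transmitted into a full motor burst with probability
  1 - dropout_p; transmission failures fuse consecutive intervals, so the
  observed period distribution develops modes near integer multiples of the
  burstlet period — the signature the multimodality analysis looks for;
* the recorded trace is a sum of double-exponential burst envelopes
  (rise/decay) on Gaussian noise, with a slow linear amplitude rundown
  emulating the gradual electrode/rootlet signal loss seen in long slice
  recordings;
* dose multipliers come from a DoseResponseModel evaluated at each epoch's
  PGE2 concentration; an optional per-epoch CV scale emulates the increased
  period irregularity under 10 nM PGE2.

All randomness flows from a single seed; per-operation substreams are
derived deterministically, so identical configs give identical data.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io_traces import EpochPlan, Recording, default_epoch_plan
from .receptor_model import DoseResponseModel

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "generate_period_sample",
    "synthesize_recording",
    "simulate_experiment_battery",
    "gaussian_cluster_dataset",
]


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for the generator.

    Defaults: a slow inspiratory-like rhythm (baseline period 3 s, i.e.
    ~0.33 Hz), 10% period jitter, no dropout, envelope rise 0.05 s / decay
    0.3 s with unit peak amplitude, 1%/min amplitude rundown, 5% noise, and
    a trace rate of 2 kHz (a 20 kHz acquisition after 1/10 resampling; set
    rate_hz=20000 for raw-rate traces).
    """

    seed: int = 0
    rate_hz: float = 2000.0
    baseline_period_s: float = 3.0
    jitter_cv: float = 0.10
    dropout_p: float = 0.0
    burst_rise_s: float = 0.05
    burst_decay_s: float = 0.3
    peak_amp: float = 1.0
    rundown_per_min: float = 0.01
    noise_sd: float = 0.05
    dose_model: DoseResponseModel = field(default_factory=DoseResponseModel)
    epoch_plan: EpochPlan = field(default_factory=lambda: default_epoch_plan(["drug"]))
    epoch_conc_nM: dict[str, float] = field(default_factory=dict)
    epoch_multipliers: dict[str, float] = field(default_factory=dict)
    epoch_cv_scale: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout_p < 1.0:
            raise ValueError("dropout_p must lie in [0, 1)")
        if self.jitter_cv < 0:
            raise ValueError("jitter_cv must be >= 0")
        if self.baseline_period_s <= 0:
            raise ValueError("baseline_period_s must be positive")
        if min(self.burst_rise_s, self.burst_decay_s) <= 0:
            raise ValueError("burst kernel time constants must be positive")

    def multiplier_for(self, label: str) -> float:
        """Dose multiplier of an epoch: explicit override, else the dose
        model at the epoch's concentration, else 1 (baseline/no drug)."""
        if label in self.epoch_multipliers:
            return self.epoch_multipliers[label]
        conc = self.epoch_conc_nM.get(label, 0.0)
        return self.dose_model.multiplier(conc)

    def cv_for(self, label: str) -> float:
        return self.jitter_cv * self.epoch_cv_scale.get(label, 1.0)


@dataclass
class GroundTruth:
    """What the generator actually did, for pipeline validation."""

    event_times_s: np.ndarray  # every burstlet
    transmitted_times_s: np.ndarray  # events surviving dropout
    epoch_multipliers: dict[str, float]
    true_mean_period: dict[str, float]
    true_cv: dict[str, float]


def _draw_intervals(rng: np.random.Generator, n: int, mean: float, cv: float) -> np.ndarray:
    if cv == 0:
        return np.full(n, mean)
    shape = 1.0 / cv**2
    return rng.gamma(shape, mean / shape, size=n)


def generate_period_sample(
    cfg: SynthConfig, epoch_label: str = "baseline", n: int = 60
) -> tuple[np.ndarray, GroundTruth]:
    """Draw ``n`` observed burst periods for one epoch.

    Burstlet intervals are gamma with mean baseline_period x multiplier and
    CV jitter_cv; each burstlet survives with probability 1 - dropout_p and
    observed periods are differences between consecutive surviving events.
    With dropout, an observed period is a sum of k+1 intervals with
    probability (1-p) p^k, hence the modes at integer multiples.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng([cfg.seed, zlib.crc32(epoch_label.encode()), n])
    mult = cfg.multiplier_for(epoch_label)
    mean = cfg.baseline_period_s * mult
    cv = cfg.cv_for(epoch_label)
    events = np.array([])
    transmitted = np.array([])
    n_draw = max(int(np.ceil((n + 1) / (1.0 - cfg.dropout_p))) + 8, 16)
    while transmitted.size < n + 1:
        extra = _draw_intervals(rng, n_draw, mean, cv)
        start = events[-1] if events.size else 0.0
        new_events = start + np.cumsum(extra)
        events = np.concatenate([events, new_events])
        keep = rng.random(events.size - transmitted.size) < (1.0 - cfg.dropout_p)
        transmitted = np.concatenate([transmitted, new_events[keep[: new_events.size]]])
    periods = np.diff(transmitted)[:n]
    gt = GroundTruth(
        event_times_s=events,
        transmitted_times_s=transmitted,
        epoch_multipliers={epoch_label: mult},
        true_mean_period={epoch_label: mean / (1.0 - cfg.dropout_p)},
        true_cv={epoch_label: cv},
    )
    return periods, gt


def _burst_kernel(rate_hz: float, rise_s: float, decay_s: float) -> np.ndarray:
    """Unit-peak double-exponential envelope (1-exp(-t/rise)) * exp(-t/decay)."""
    t_end = rise_s * 8 + decay_s * 8
    t = np.arange(0.0, t_end, 1.0 / rate_hz)
    k = (1.0 - np.exp(-t / rise_s)) * np.exp(-t / decay_s)
    peak = k.max()
    return k / peak if peak > 0 else k


def synthesize_recording(cfg: SynthConfig) -> tuple[Recording, GroundTruth]:
    """Render a full multi-epoch recording plus its ground truth.

    Event sampling runs continuously across epochs (phase carries over);
    within each epoch the interval mean is scaled by that epoch's dose
    multiplier.  Amplitudes decline linearly by ``rundown_per_min`` per
    minute, floored at zero.
    """
    rng = np.random.default_rng([cfg.seed, 0x5EED])
    plan = cfg.epoch_plan
    total_s = plan.epochs[-1].end_s
    mults = {e.label: cfg.multiplier_for(e.label) for e in plan}

    events: list[float] = []
    t = 0.0
    # draw intervals one at a time so each interval uses the multiplier of
    # the epoch the preceding event falls in
    while t < total_s:
        epoch = next((e for e in plan if e.start_s <= t < e.end_s), plan.epochs[-1])
        mean = cfg.baseline_period_s * mults[epoch.label]
        cv = cfg.cv_for(epoch.label)
        iv = _draw_intervals(rng, 1, mean, cv)[0]
        t += iv
        if t < total_s:
            events.append(t)
    events_arr = np.array(events)
    keep = rng.random(events_arr.size) < (1.0 - cfg.dropout_p)
    transmitted = events_arr[keep]

    n_samples = int(round(total_s * cfg.rate_hz))
    trace = rng.normal(0.0, cfg.noise_sd, size=n_samples) if cfg.noise_sd > 0 else np.zeros(n_samples)
    kernel = _burst_kernel(cfg.rate_hz, cfg.burst_rise_s, cfg.burst_decay_s)
    for ev in transmitted:
        i0 = int(round(ev * cfg.rate_hz))
        amp = cfg.peak_amp * max(0.0, 1.0 - cfg.rundown_per_min * ev / 60.0)
        i1 = min(i0 + kernel.size, n_samples)
        if i0 < n_samples:
            trace[i0:i1] += amp * kernel[: i1 - i0]

    true_mean = {}
    true_cv = {}
    for e in plan:
        in_epoch = transmitted[(transmitted >= e.analysis_start_s) & (transmitted < e.end_s)]
        per = np.diff(in_epoch)
        true_mean[e.label] = float(np.mean(per)) if per.size else float("nan")
        true_cv[e.label] = (
            float(np.std(per, ddof=1) / np.mean(per)) if per.size >= 2 else float("nan")
        )
    rec = Recording(
        samples=trace,
        rate_hz=cfg.rate_hz,
        slice_id=f"synthetic-{cfg.seed}",
        meta={"synthetic": True, "dropout_p": cfg.dropout_p},
    )
    gt = GroundTruth(events_arr, transmitted, mults, true_mean, true_cv)
    return rec, gt


def simulate_experiment_battery(
    n_slices: int,
    conditions: dict[str, float],
    cfg: SynthConfig | None = None,
    seed: int = 0,
    n_periods: int = 30,
    between_slice_sd: float = 0.2,
) -> pd.DataFrame:
    """Simulate a multi-slice experiment at the epoch-summary level.

    Each slice gets a lognormal baseline period (log-SD ``between_slice_sd``
    around the configured baseline), then one epoch per condition with the
    given period multipliers.  Returns the long-format table consumed by
    group_stats: one row per slice x condition with the baseline-normalized
    mean period as response.
    """
    if n_slices < 2:
        raise ValueError("need at least 2 slices")
    cfg = cfg or SynthConfig()
    rows = []
    for s in range(n_slices):
        srng = np.random.default_rng([seed, s])
        base = cfg.baseline_period_s * np.exp(srng.normal(0.0, between_slice_sd))
        scfg = replace(
            cfg,
            seed=int(srng.integers(2**31)),
            baseline_period_s=float(base),
            epoch_multipliers={**cfg.epoch_multipliers, **conditions},
        )
        base_per, _ = generate_period_sample(scfg, "baseline", n_periods)
        for cond in conditions:
            per, _ = generate_period_sample(scfg, cond, n_periods)
            rows.append(
                {
                    "slice_id": f"slice{s:02d}",
                    "condition": cond,
                    "response": float(np.mean(per) / np.mean(base_per)),
                }
            )
    return pd.DataFrame(rows)


def gaussian_cluster_dataset(
    n_clusters: int = 12,
    obs_per_cluster: int = 2,
    effect: float = 0.25,
    rho: float = 0.5,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> pd.DataFrame:
    """Exchangeable-correlation Gaussian data for estimator calibration.

    Each cluster contributes one control and ``obs_per_cluster - 1`` treated
    observations; y = 1 + effect*treated + b_cluster + e with
    Var(b) = rho*noise_sd^2 and Var(e) = (1-rho)*noise_sd^2, giving an
    exchangeable within-cluster correlation of exactly ``rho``.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for c in range(n_clusters):
        b = rng.normal(0.0, np.sqrt(rho) * noise_sd)
        for j in range(obs_per_cluster):
            treated = j > 0
            e = rng.normal(0.0, np.sqrt(1.0 - rho) * noise_sd)
            rows.append(
                {
                    "slice_id": f"c{c:02d}",
                    "condition": "treated" if treated else "control",
                    "response": 1.0 + (effect if treated else 0.0) + b + e,
                }
            )
    return pd.DataFrame(rows)
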