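# prebotpy

Burst-rhythm analysis for hypoglossal (XII) rootlet recordings of the
preBötzinger-complex inspiratory rhythm, plus a mechanistic synthetic-
recording generator so every stage of the pipeline can be validated against
known ground truth.

## Who this is for

Slice electrophysiologists analysing integrated XII nerve output — rhythmic
inspiratory-like bursts at roughly 0.1–0.5 Hz riding on noise — under drug
exposure protocols (e.g. PGE2 dose series), and anyone who needs the
statistics that go with such experiments: burst-period irregularity,
multimodality of the period distribution as a read-out of burstlet
transmission failure, and repeated-measures group inference across slices.

## What it computes

1. **Conditioning** — resample at 1/k rate (anti-aliased), Hampel filter
   (sliding median/MAD, flagged artifacts replaced, never deleted), then a
   rectified leaky integrator `y[n] = λ·y[n−1] + |x[n]|` (λ = 0.98 per
   sample) giving the classic ∫XII envelope.
2. **Burst detection** — local maxima with topographic prominence ≥ 0.2 on
   the baseline-normalized envelope, refractory distance 15 s (higher peak
   wins, ties to the earlier); onset/offset at half-prominence crossings;
   per-burst height, width, area and period; auditable plausibility flags
   instead of silent manual deletion.
3. **Epoch analysis** — per-epoch feature means, period CV = s/μ, all
   normalized to each slice's baseline epoch; ΔCV for irregularity.
4. **Distribution statistics** — iterative two-sided Smirnov–Grubbs outlier
   exclusion with the exact t-quantile critical value
   `G_crit = ((n−1)/√n)·√(t²/(n−2+t²))`; Hartigan's dip statistic (minimal
   sup-norm distance between the empirical CDF and the nearest unimodal
   CDF, computed via the greatest-convex-minorant / least-concave-majorant
   cycling algorithm) with a seeded bootstrap p-value; BIC-selected
   Gaussian-mixture mode decomposition and a check of whether higher modes
   sit at integer multiples of the first (the fingerprint of burstlet
   dropout).
5. **Group statistics** — Gaussian GEE with slice clusters, exchangeable
   working correlation and a bias-reduced cluster sandwich covariance;
   Bonferroni-adjusted Wald contrasts.
6. **Receptor model** — single-site occupancy θ = c/(c+K_d) over the
   prostanoid family (EP3 0.33 nM, EP4 0.59 nM, EP2 13 nM, EP1 25 nM, FP
   119 nM, DP2 307 nM) mapped to a burst-period multiplier
   m = 1 + a₃·θ_EP3 − a₂·θ_EP2: high-affinity EP3 saturates first and slows
   the rhythm, low-affinity EP2 catches up at micromolar doses and speeds
   it — a biphasic dose response.
7. **Synthetic data** — gamma-renewal burstlet trains with transmission
   dropout, dose-dependent period multipliers, double-exponential burst
   envelopes, amplitude rundown and Gaussian noise, with full ground truth.

## Worked example

```bash
prebotpy simulate --out demo --seed 5 --baseline-period 10 \
    --condition PGE2_10nM:10 --noise-sd 0.05
prebotpy analyze --trace demo.f32 --plan demo.plan.json --out demo \
    --min-distance 5 --dip-boot 500
```

prints

```
baseline: n=59 mean_period=10.13s normalized=1.000 cv=0.095
PGE2_10nM: n=48 mean_period=12.59s normalized=1.242 cv=0.102
```

The simulated slice had a 10 s baseline period; 10 nM PGE2 maps (through
the empirical dose-response table) to a 1.25× period multiplier, and the
full pipeline — conditioning, detection, epoch assignment, baseline
normalization — recovers a normalized period of 1.242 from the noisy trace
(the remaining 0.008 is period-sampling noise, not bias).  Burst tables,
epoch summaries and per-epoch dip tests are written alongside as
`demo.bursts.csv`, `demo.summary.csv`, `demo.dip.json`.

The same chain as a library call:

```python
from prebotpy.io_traces import default_epoch_plan
from prebotpy.synthetic import SynthConfig, synthesize_recording
from prebotpy.pipeline import analyze_recording

plan = default_epoch_plan(["PGE2_10nM"])
cfg = SynthConfig(seed=5, baseline_period_s=10.0, epoch_plan=plan,
                  epoch_conc_nM={"PGE2_10nM": 10.0})
rec, truth = synthesize_recording(cfg)
result = analyze_recording(rec, plan)
print(result.summary_for("PGE2_10nM").normalized_period)
```

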