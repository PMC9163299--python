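# Methods

This note documents the models, algorithms, parameter choices and known
limitations behind `prebotpy`.  Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Signal model and conditioning

The input is a single-channel AC-coupled extracellular recording of XII
rootlet output, sampled uniformly (20 kHz acquisition is typical; the
package treats the rate as metadata).  Analysis operates on the integrated
envelope, produced by three stages:

**Decimation.** Resampling at 1/k rate is a centered moving average of
width k followed by take-every-kth (length ⌊n/k⌋).  The moving average is
a deliberately cheap, phase-preserving anti-alias filter; burst envelopes
live far below the post-decimation Nyquist frequency, so filter sharpness
is irrelevant here.

**Hampel filter.** Window of 0.5 s (interpreted at the post-decimation
rate), threshold 5 robust standard deviations (1.4826·MAD).  Windows are
centered and truncated at the edges.  A flagged sample is *replaced* by its
window median and its index reported; deletion would distort the time base
that burst periods depend on.  The comparison is a strict inequality, so
constant windows (MAD = 0, deviation 0) never flag, while an isolated
spike above a flat stretch (MAD = 0, deviation > 0) always does — the two
degenerate cases that motivate the rule.

**Leaky integrator.** `y[n] = λ·y[n−1] + |x[n]|` with λ = 0.98 per
post-decimation sample.  Rectification precedes integration because the
raw signal is AC-coupled; integrating it unrectified would cancel toward
zero.  Both the rectification and the rate at which λ applies are
configuration-exposed, since conventions differ between labs.  Impulse and
step responses have the closed forms λⁿ and (1−λⁿ⁺¹)/(1−λ) → 50, which the
tests verify to 1e-9.

## Burst detection

Bursts are local maxima of the conditioned, normalized trace with
topographic prominence ≥ 0.2 and minimum separation 15 s (the package
defaults; the distance must be chosen below the shortest physiological
period — see *Validation conditions*).  Among peaks closer than the
refractory distance the higher survives, ties resolved to the earlier.
Prominence units are fixed by normalization: the default divides the trace
by the 95th percentile of the baseline analysis window, so 0.2 means "20%
of a typical baseline burst peak" and detection is invariant to amplifier
gain.  Onset and offset are the nearest half-prominence crossings
(linearly interpolated); burst width is their difference — a definition
chosen for robustness to baseline drift, with alternatives selectable.
Height is the trace maximum within the burst and area the within-burst sum
divided by the rate.  Implausible bursts (width or height outside
configurable bands) are flagged for review, never silently removed.

The leaky integrator delays the envelope peak by a roughly constant lag
(~0.3 s at the defaults); periods, being peak-time differences, are
unaffected.

## Epoch analysis

The standard protocol is a 10-min baseline analysed in full, then 20-min
drug exposures of which only the final 10 min are analysed (rhythm
stabilization).  A burst belongs to the epoch whose analysis window
contains its peak; a period straddling a window boundary is dropped, not
prorated.  Per-epoch summaries are arithmetic means of burst features and
the period CV (sample SD over mean, n−1 denominator, appropriate at the
small per-epoch burst counts).  Feature means are normalized to the
slice's baseline mean; irregularity is reported as ΔCV = CV_epoch −
CV_baseline.  Rundown of burst height/width over the recording is *not*
detrended — inference designs compare against time-matched controls
instead.

## Dip statistic and multimodality inference

Burstlet theory separates rhythm generation (burstlet timing) from pattern
generation (burst production).  If a modulator reduces the fraction of
burstlets that trigger full bursts, observed periods become sums of
consecutive burstlet intervals and the period distribution develops modes
at integer multiples of the base period.  A unimodal distribution instead
indicates modulation of the rhythm itself.

The dip statistic is the minimal sup-norm distance between the empirical
CDF and the class of unimodal CDFs (convex, then concave, with an atom
permitted at the mode).  The implementation is the classical
greatest-convex-minorant / least-concave-majorant cycling algorithm in CDF
count units; it returns the dip and the modal interval, satisfies
dip ∈ [1/(2n), 1/4] for samples with two distinct values, and is affine
invariant.  It is validated two ways: against hand-derived closed forms
(evenly spaced data attain 1/(2n); two tight equal clusters approach 1/4),
and — exactly, to 1e-10 — against an independent brute-force oracle that
solves the defining minimization as linear programs over every mode
placement (each data point with an atom, each inter-gap position for the
mode, with the chord-coupling constraints that bound how steeply a
unimodal CDF may cross the modal gap).

**Calibration.** The p-value is a seeded bootstrap: the proportion of null
samples of the same size whose dip exceeds the observed one.  The default
null is uniform(0,1) — Hartigan's classical calibration and the least
favourable unimodal shape.  For peaked unimodal data this is conservative:
under a gamma null with shape 100 (the generator's 10% jitter), measured
size at n=60 is below 1% at nominal 5%.  `dip_test` therefore also accepts
a precomputed null table, and `bootstrap_null_dips` builds one for any
reference distribution; with a matched gamma null the measured size is
~5%, i.e. the bootstrap machinery itself is correctly calibrated, and
power against 30% dropout at n=60 is roughly 75% — far above 3× the size.
Null tables are cached and shareable across tests at the same n, which is
what makes thousand-replicate calibration runs cheap.

**Mode decomposition.** The mode report fits Gaussian mixtures with 1–3
components, selects by BIC (5 restarts, variance floor 1e-9, fixed seed),
and reports mean ± SD ± weight per component, means ascending.  The
burstlet-consistency check compares each higher mode's ratio to the first
mode against the nearest integer ≥ 2 with 15% tolerance; the implied
burstlet fraction is the first mode's weight.  A ratio like 1.54 (e.g.
modes at 0.93 and 1.43 of baseline) is flagged as inconsistent with pure
transmission failure.

**Grubbs exclusion.** Outliers are removed iteratively (one extreme per
round, argmax |x−mean|) using the exact two-sided critical value
G_crit(n, α) = ((n−1)/√n)·√(t²/(n−2+t²)), t the α/(2n) quantile of t with
n−2 df.  Samples with n < 3 or zero SD are returned unchanged.

## Group inference

Gaussian GEE with the slice as cluster and condition as the only
covariate, on baseline-normalized responses.  Working correlation is
exchangeable by default (repeated epochs within a slice); independence is
available for sensitivity.  Standard errors come from the cluster sandwich;
because slice experiments rarely exceed ~20 clusters, the default is the
bias-reduced (Mancl–DeRouen) variant, under which simulated 95% CI
coverage at 12 clusters is ~0.95 and the null rejection rate of a single
contrast ~0.05–0.07, versus ~0.09 for the plain sandwich.  Contrasts are
Wald z-tests with Bonferroni adjustment p_adj = min(1, k·p).  Degenerate
constant-response data short-circuit to a zero-effect fit with a warning.
No further small-sample machinery (t references, score tests) is used —
a documented limitation.

## Receptor-occupancy dose-response model

Single-site occupancy θ_r = c/(c + K_d,r) with the published affinities
(EP3 0.33, EP4 0.59, EP2 13, EP1 25, FP 119, DP2 307 nM), linearly mapped
to a period multiplier m = 1 + a₃·θ_EP3 − a₂·θ_EP2, floored at 0.1.
Receptors other than EP2/EP3 are computed but carry zero gain by default,
matching the observation that antagonizing them leaves the biphasic
response intact.  Antagonists are modelled as a full block (θ = 0),
appropriate for saturating antagonist doses; competitive shifts are left
as an extension hook.  Gains calibrated to m(1 nM) = 1.21 and
m(1000 nM) = 0.76 give a₂ ≈ 0.582, a₃ ≈ 0.335 and imply m(10 nM) ≈ 1.07 —
a one-site linear model cannot reach the observed +25% at 10 nM.  That
residual is retained as a falsifiable model note (possible cooperative or
network amplification) rather than hidden behind extra parameters.
Blocking EP2 and EP3 together forces m ≡ 1; with both gains positive and
K_d,EP3 < K_d,EP2 the profile crosses 1 exactly once on a log grid.

## Synthetic data: what it emulates, and what it does not

Burstlet intervals are gamma-distributed (positivity; CV as a direct
parameter), with mean = baseline period × dose multiplier and CV =
jitter_cv (default 0.10).  Dropout thins events independently with
probability p, so observed periods are sums of k+1 intervals with
geometric weights — mean observed period = base/(1−p), the renewal
identity the tests verify, and the mechanism by which apparent slowing can
be distinguished from true rhythm slowing via multimodality.  Traces sum
unit-peak double-exponential envelopes (rise 0.05 s, decay 0.3 s) with
linear amplitude rundown (default 1%/min) on Gaussian noise (default SD
5% of peak).  Dose multipliers scale only the interval mean; an optional
per-epoch CV scale reproduces the increased irregularity seen at
intermediate doses (a scale of 1.6 on a 0.10 baseline CV yields
ΔCV ≈ +0.06 through the full pipeline).

Not emulated: biophysical network dynamics, burst-shape changes under
drugs, electrode drift other than linear amplitude rundown, correlated or
non-Gaussian noise, and recording artifacts beyond what the Hampel stage
is tested on.  Passing recovery tests therefore demonstrates that the
*analysis* is correct and well-calibrated under the stated statistical
structure — not that real recordings satisfy that structure.

## Validation conditions (problem sizes)

Chosen to exercise every claim at desk scale: dip-oracle agreement on 200
random samples of n ≤ 8; dip size/power with 1000 replicates of n = 60
periods against 2000-sample bootstrap null tables; end-to-end recovery on
20 seeds per dose condition with a 10 s baseline period (inside the 0.1–
0.5 Hz physiological band) and a 5 s detection refractory — the refractory
must undercut the shortest expected period (7.6 s at the 0.76× dose), which
the 15 s default would not; detection fidelity on 50 seeds of 25-burst
traces at 5% noise; GEE calibration with 500 replicates of 12 clusters × 2
observations.  The acceptance script re-runs the same battery at slightly
reduced replicate counts and finishes in about a minute.

## Known limitations

* The dip test's uniform null is conservative for peaked unimodal data;
  matched-null calibration is provided but requires choosing a reference
  family.
* Mode decomposition reports mixture-component SDs; if a published "±"
  value were a standard error the comparison would need rescaling.
* The GEE layer offers no time/epoch-order covariates and no likelihood-
  based alternatives (mixed models).
* The receptor model is single-site and linear in occupancy by design; it
  underpredicts the intermediate-dose effect (see above).
* Binary trace I/O stores float32; round-trips are bit-exact only for
  float32-representable samples.
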