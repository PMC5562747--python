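# Methods

This note documents the models, parameter choices and numerical decisions
behind `organchip`, and what the synthetic-data validation does and does
not demonstrate about real chip data.

## Motion quantification

The contraction signal is the per-frame-pair count of supra-threshold
pixels in the absolute difference of consecutive grayscale frames. Counts
(not summed difference intensity) are the primary statistic because a
count of "moving pixels" is directly comparable across clips and robustly
verifiable against ground truth; the summed intensity is available as a
secondary output.

* **Grayscale conversion** uses fixed luma weights 0.299/0.587/0.114;
  16-bit input is rescaled linearly by its own maximum onto [0, 255] so
  thresholds always operate on one scale. Frame rate is mandatory when the
  container carries no metadata — a beat rate is meaningless without it.
* **Threshold.** Automatic mode sets τ = mean + k·SD (k = 3 by default)
  over the pooled difference values of the whole clip. This is
  parameter-light, adapts to the clip's own noise, and for pure Gaussian
  fluctuation admits ~0.1% of pixels per frame — a small, stable floor.
  A perfectly static clip (all differences zero) returns a sentinel τ = 1
  so zero motion is reported as zero counts. Counting uses strict
  inequality (> τ); ties are excluded.
* **Smoothing.** A length-preserving moving average over 0.1 s (symmetric
  edge padding) is applied after counting. Counts are integer-valued
  before smoothing and bounded by the frame area.

Two invariances are tested: adding a constant to every pixel leaves counts
unchanged, and raising the threshold multiplier never increases any count.

## Beat detection and metrics

Beats are strict interior local maxima of the smoothed trace whose
topographic prominence is at least 20% of the trace's dynamic range,
accepted greedily in order of decreasing prominence (ties to the earlier
sample) subject to a 0.25 s refractory spacing (maximum detectable rate
240 BPM, above any physiological organoid rate here). Prominence is
range-relative so the same defaults work across magnifications and
organoid sizes; consequently the peak set is invariant to positive
rescaling of the trace. The implementation is held exactly equal to an
independent brute-force enumerator on short traces (property-tested).

BPM is 60 / mean(IBI) rather than peak-count / duration, which is robust
to partial beats at clip edges; both estimators are reported. With fewer
than two peaks BPM is 0 and the cessation logic decides the interpretation.

**Cessation** uses a dual criterion: (a) no qualifying peak in the trailing
window (10 s default), or (b) the trace's fluctuations sit below its own
noise floor. The noise-floor test is spectral: beating concentrates
variance at the beat frequency, so the peak periodogram component stands
orders of magnitude above the broadband median, whereas white measurement
noise tops out near ln(n_bins) ≈ 9; the threshold ratio is 50, far from
both regimes. A range-based test was rejected because fast near-continuous
beating (~150 BPM) leaves little low-frequency range and was falsely
flagged.

## Viability quantification

Per-channel global Otsu threshold, 8-connected labeling, removal of
objects under 20 px. Viability is computed from object **counts** — the
live/dead readout is a ratio of cells — with the stained-area ratio as a
secondary statistic. A blank (zero-variance) channel yields zero objects
with a warning. Dual-positive objects (green centroid inside a red object
or vice versa) are counted once, as dead by default (EthD-1 entry implies
a compromised membrane); the attribution is configurable. Projected
macro-confocal images are treated as single 2-D planes; no 3-D
segmentation is attempted.

## Pharmacology readouts

* Percent change: 100·(treated − baseline)/baseline; a zero baseline is a
  distinct error (cessation, not a definable change).
* Dose-response: R(c) = R_max·cⁿ/(cⁿ + EC50ⁿ), constrained through the
  origin (the zero-dose point carries no free intercept). Fitting is
  multistart nonlinear least squares (Hill coefficients {0.5, 1, 2, 4} ×
  EC50 log-spaced over the dose range; EC50 and n optimized in log space,
  bounds 0.05 ≤ n ≤ 10); ties resolve to the smallest n. An all-zero
  response vector returns R_max ≈ 0 flagged unidentifiable.
* Blockade: inhibition(d) = 1 − R(d)/R_control with a monotonicity flag.
* Time-course classification applies banded rules with precedence
  ceased → stable → increase_then_decrease → sustained_increase →
  sustained_decrease; the stable band default is 15% so that a mild (~10%)
  antagonist-alone effect classifies as stable. Trajectories matching no
  rule (e.g. a dip that recovers inside the band) fall back to stable.

## Chip simulator

**Clearance.** One well-mixed recirculating compartment: continuous
recirculation at ~10 µL/min is fast relative to the multi-hour experiment
timescales, so a single concentration governs all modules and
C(t) = C₀·e^(−kt). The default k = ln 3 / 48 ≈ 0.0229 h⁻¹ is calibrated to
the on-chip LC-MS observation of a 3-fold propranolol drop over 48 h. A
consequence recorded in every simulation's ground truth: an 18 h
pre-incubation reduces the antagonist by 3^(18/48) ≈ 1.51-fold at the
moment of agonist addition. Modes without functional 3-D liver tissue
(cardiac-only, 2-D hepatocytes) use k = 0 — 2-D cultures showed no
restorative metabolism. The agonist is treated as uncleared over its
≤ 2 h response window; this is a declared simplification. The closed form
is verified against an ODE integration of dC/dt = −kC to 1e−6 relative.

**Beat-rate response.** Competitive (surmountable) antagonism with a
Gaddum/Schild EC50 shift and a basal adrenergic tone E_basal that gives the
antagonist something to suppress at zero agonist. The shipped defaults are
**calibrated, not measured**: (R_max, EC50, K_i, n, E_basal) are fitted by
multistart least squares to four percent-change anchors — +40% at 0.5 µM
agonist, −10% at 0.1 µM antagonist alone, +25% at the
partially-cleared antagonist concentration (0.066 µM) with 0.5 µM agonist,
and +5% (essentially blocked) at the uncleared 0.1 µM antagonist with
0.5 µM agonist. The fit reaches all four anchors with negligible residual
(rss < 1e−20, shipped with the parameter file `data/pd_defaults.json`).
The solution requires a steep Hill coefficient (n ≈ 4.4): a purely
competitive n = 1 model cannot produce both near-complete block at 0.1 µM
and substantial recovery after a mere 1.5-fold clearance. A side effect of
this steepness is that the modeled agonist curve is nearly saturated
already at 0.1 µM, steeper than a typical experimental dose series; the
anchors, not the dose series, drive the calibration. B₀ is fixed at
60 BPM; all percent-change outputs are independent of its value.

**Three-tissue scenario.** Phenomenological by design — the reported
observations are effects (an early ~+60% beat-rate increase under IL-1β,
complete cessation by ~144 h of exposure), not receptor mechanisms with
rates. With lung tissue present, IL-8 and IL-1β accumulate at zero-order
rates after the bleomycin event (40 and 15 pg/mL/day; plausible ELISA-scale
values chosen once, as the reports give figure-level trends, not numbers).
The beat rate follows a piecewise-linear IL-1β effect curve: rise to +60%
over 24 h, plateau through 96 h, linear decline to cessation at 144 h
post-exposure. IL-8 has no beat-rate effect, and bleomycin has no direct
cardiac effect, so a cardiac-only run is flat. A single-bolus cytokine
challenge uses the same curve but ends at −30% below baseline at 144 h
rather than full cessation (bolus exposure, no continuous production).

## Synthetic-data generator

Videos render a bright disk (foreground 180, background 20, 8-bit) whose
radius contracts as r(t) = R·(1 − a·w(t)) with rest radius 40 px on a
128×128 canvas, amplitude a = 0.1, 30 fps, 30 s, additive Gaussian pixel
noise (SD 2 by default) and optional linear background drift; edges are
anti-aliased over 1 px so sub-pixel radius changes register smoothly. The
contraction pulse w is an asymmetric raised cosine of **fixed duration
0.35 s** (30% rise, 70% relaxation, clipped to 90% of the instantaneous
cycle): systole duration is roughly constant in time across physiological
rates, and a pulse scaled as a fixed fraction of the cycle would stretch to
0.6 s at 30 BPM and split each beat's motion burst into two refractory-
separated peaks. Beat onsets integrate the instantaneous rate, so
time-varying trajectories (steps, cessation) are supported; the realized
pulse count and onset times are recorded as ground truth. All randomness
derives from one explicit seed per artifact; identical seeds are
bit-identical.

LIVE/DEAD images place non-overlapping disks (radius 3–5 px, ≥3 px gaps so
Gaussian blur keeps objects separable) on a 384×384 canvas by rejection
sampling, green for live and red for dead, then blur and noise.

**What passing these tests shows — and does not.** Recovery on generator
output validates the analysis chain end to end (thresholding, counting,
peak logic, segmentation arithmetic) under controlled noise. Real chip
videos additionally contain texture, focus drift, illumination flicker,
debris and non-rigid deformation; real stained images contain overlapping
and dim cells, uneven staining and 3-D projection artifacts. Performance
on those is not established here — threshold and prominence defaults are
the tunable entry points for real data.

## Problem sizes and tolerances

Default validation sizes: 30 s × 30 fps × 128² videos; 20 synthetic
LIVE/DEAD images of 10–200 cells; 200 random traces of ≤ 200 samples for
oracle equivalence; 50 noisy replicates for dose-response recovery. These
sizes give stable statistics (e.g. ±2 BPM over ~30–75 beats) while keeping
the whole suite around half a minute. Numerical tolerances: optimizer-level
(<1%) for noiseless fits, ±2 BPM / ±1 peak for video recovery, 3
percentage points for noisy viability, 1e−6 relative for the clearance
closed form vs ODE.

## Known limitations

* The motion threshold rule is a declared substitute for the original
  (unpublished) analysis constant; no claim is made that it matches.
* The pharmacodynamic defaults are anchor-calibrated and steep (n ≈ 4.4);
  they reproduce the anchor set, not an independently measured dose series.
* No physiologically based pharmacokinetics (partitioning, protein
  binding, metabolite pharmacology) and no electrophysiology; cytokine
  dynamics are phenomenological.
* Video containers other than TIFF require an ffmpeg-capable imageio
  backend at runtime.
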