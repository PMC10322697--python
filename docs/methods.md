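# Methods

`motormap` analyzes stereo-EEG (sEEG) recorded during a cued motor task
(hand / tongue / foot movements interleaved with rest) together with
surface EMG from each effector. This note documents the models and
procedures implemented, the choices made where the design was open, and
what the synthetic test bed does and does not establish.

## Signal model and preprocessing

Depth-electrode voltages are recorded against a distant reference and
rereferenced in a bipolar fashion: every pair of adjacent contacts on
the same lead segment is differenced (`pair = proximal − distal`, in
contact-index order), and the pair's position is the contact midpoint.
Rereferencing is linear, cancels lead-wide common-mode signal exactly,
and yields `contacts − 1` pairs per segment. EMG channels pass through
untouched.

Movement epochs are re-timed from the visual cue to the actual EMG
burst, because reaction times vary by tens to hundreds of
milliseconds. The detector is an automated stand-in for manual
annotation: a burst is a stretch where the conditioned EMG envelope
exceeds its rest baseline by 3 sd for at least 200 ms, and the reported
onset/offset are then refined to the quarter-peak crossings of that
trial's envelope. The refinement matters: the raw sustained-threshold
crossing fires on the smoothing kernel's leading tail and is early by
~100 ms or more, while the quarter-peak crossing marks where the burst
reaches 25% of its amplitude — equivalent to a 5× baseline criterion
for a typical burst ~20× baseline — and recovers synthetic ground-truth
onsets with a median error of a few milliseconds. Both the threshold
and the fraction are configurable (`EmgEpochParams`). An effector
without an EMG channel falls back to shifting its cue times by the mean
EMG-cue delay of the other effectors.

## Trial spectra and the signed r² statistic

Each epoch gets a Welch PSD (1 s Hann windows, 0.5 s overlap, constant
detrend, 1–300 Hz at 1 Hz resolution). Because field potentials follow
a 1/f power law, each trial PSD is divided bin-wise by the channel's
mean PSD across all trials; broadband power is then the mean normalized
power over 65–115 Hz, a range above most oscillations that avoids mains
noise at 60 and 120 Hz.

Movement trials of each type are compared only against the rest epochs
that **followed** that movement type, so that the post-movement beta
rebound contaminates both sides of its own comparison and no other.
The per-channel, per-movement effect measure is the signed
cross-correlation r²:

    r² = sign(m̄ − r̄) · (m̄ − r̄)² · N_m N_r / (σ²_{m∪r} · N²)

with `m`, `r` the movement and rest broadband samples and `σ²_{m∪r}`
the population (divide-by-N) variance of the pooled samples. With the
population variance this is exactly the signed squared point-biserial
correlation between samples and group labels, bounded by ±1 (the
property-test oracle). The 0/0 case (equal means) is defined as 0.
P-values come from an unpaired two-sample t-test on the same samples.
Under the null at 20/20 trials, r² follows approximately
Beta(1/2, 19): its 95th percentile is ≈ 0.09, which is the calibration
bound the tests assert for inactive channels.

## Somatotopy and shared representation

Per channel, the three movement r² values (negatives clipped to zero)
are placed on unit vectors e^{iπ/6} (hand), e^{i5π/6} (tongue),
e^{i3π/2} (foot) and summed. The phase points at the preferred
movement, the magnitude measures somatotopic selectivity, and equal
activation cancels (the vectors are 120° apart). Shared representation
("overlap") is the geometric mean ∛(r²_H·r²_T·r²_F) with any
movement failing p < 0.05 contributing zero. High overlap with low
vector magnitude is the signature of shared-representation (RMA)
sites. Display masks use 50% of the within-session maximum (magnitude
and overlap) and a 1%-of-maximum cutoff for single-movement maps.

## Broadband timecourses, EMG conditioning and latency

The broadband power timecourse band-passes the voltage in five 10 Hz
bands spanning 65–115 Hz (third-order Butterworth, zero-phase), squares
the analytic (Hilbert) amplitude per band, and sums the five series;
splitting into narrow bands first keeps the 1/f slope from letting the
lowest band dominate. Mains noise at 60/120/180 Hz is notched out
(zero-phase, Q = 30) before the band decomposition: the band grid
avoids the line frequencies, but third-order edges are gentle enough
that a strong 60 Hz line leaks into the 65–75 Hz band and measurably
skews the envelope and every statistic downstream of it. The summed
series is logged, z-scored over the run, smoothed with a Gaussian
kernel (sd 50 ms by default; the kernel is a free choice), exponentiated
and centered by subtracting 1. Note that only the *median* of the
result is 0 at rest by construction; the mean retains the positive skew
of the exponential. EMG is band-passed 25–400 Hz, notched at
60/120/180 Hz, rectified, enveloped (Gaussian, sd 25 ms) and passed
through the same log / z / smooth / exp chain. Rectify-then-envelope
order was chosen; log of zero is guarded by flooring at the 1st
percentile of positive values, and a constant (dead) channel
conditions to a constant without NaNs.

Brain–EMG latency is the lag of the peak of a sliding dot product
between the two series over ±2 s in one-sample steps, positive lag
meaning brain leads EMG; both series are mean-subtracted so DC does not
dominate. Two window modes exist. The whole-run profile (series-level
default) satisfies the exact shifted-copy identity, but on realistic
signals its peak is skewed ~15 ms by cross-trial and baseline
correlation mass — measurable by simulating a zero-lag ground truth.
When movement epochs are known, the profile is instead summed over
matched per-trial windows (each effector's EMG-timed epochs, ±0.5 s
margin, template extended by the lag range); this estimator measured
unbiased at both 0 and 100 ms generator lead with roughly half the
spread, and is what the pipeline and the latency tables use. Peaks on
the ±2 s boundary are flagged unreliable.

## Parcellation by k-means and the penalty exponent

Channels are embedded in a 3-D feature space of signed r² (foot, hand,
tongue on x, y, z; negatives kept, unlike the maps). Lloyd's k-means
with k-means++ seeding (`scipy.cluster.vq.kmeans2`, 100 iterations) is
rerun over many random restarts for k = 1…20; each restart selects the
k minimizing `N^α · ΣD²` (N clusters, summed squared distance of each
channel to its centroid), the selected k is the mode over restarts
(ties toward smaller k), and the final labels come from the
minimum-error restart at that k. Degenerate (identical) features give
k = 1.

The exponent α is the only real knob. The within-parcel error sum of
converged k-means decays at least as fast as k^(−2/3) on 3-D residuals,
so for α ≤ 1 the penalty is monotone decreasing and selection runs away
to k_max — no global minimum exists; very large α collapses toward one
cluster. The default α = 3/2 sits between those regimes and, at the
problem sizes used here (tens to hundreds of channels), recovers the
constructed group count reliably (verified on well-separated Gaussian
blob sets and on generator sessions). Selection is scale-covariant
(multiplying all features by c > 0 changes nothing) and best-of-restart
inertia is checked for monotonicity in k (flagged, not fatal).

One small-sample caveat: under the null, an inactive channel's r² has a
heavy right tail, and in a single 66-channel session one channel per
few sessions lands far enough from the origin that k-means profitably
isolates it, flipping the selected k from 5 to 6. Pooling channels
across a few sessions into one feature space — the aggregation used for
group-level parcellation — dilutes such singletons below the penalty
step and stabilizes the selection; the acceptance script pools four
sessions for this reason.

Clusters are named from centroid geometry: near-origin → inactive
(max component < 0.1), balanced high components (min > 0.5·max) → RMA,
a single dominant axis (second component < 0.5·max) → that effector,
anything else → unlabeled. Convex-hull depth (distance from each
recording site to the nearest point on the hull of the cortical
surface, via exact point-to-triangle distances over `scipy.spatial`
hull facets) supports the observation that shared-representation sites
sit deeper than somatotopic ones.

## Decoding

Channel groups come from the move-vs-rest tests: RMA = p < 0.05 for
every movement; somatotopic = p < 0.05/3 (Bonferroni over three
movements) for exactly one movement; channels significant for two
movements, or none, are excluded. Features are per-trial 65–115 Hz
broadband power of the group's channels; classes are hand, tongue,
foot and rest (all rest trials kept). Classification is LDA with
pooled covariance and stratified threefold cross-validation, seeded.
Class priors are set uniform (¼ each) so chance is 0.25 despite rest
being three times as frequent; with empirical priors a shuffled-label
control converges to the majority-class rate instead, which makes the
null uninterpretable. Movement-only accuracy is scored from the same
fitted four-class models on the movement trials — never retrained on
three classes, whose covariance would be underdetermined at these trial
counts. A singular pooled covariance triggers a Ledoit–Wolf shrinkage
refit (logged); stratification is likewise a robustness addition at
n = 20 trials per movement.

## The synthetic test bed

The generator emits monopolar contacts plus EMG channels with known
ground truth, and its defaults define the study conditions: 1,200 Hz,
20 trials per movement (3 s cue + 3 s rest), channel plan
10/10/10 somatotopic + 6 RMA + 30 inactive, broadband gain g_bb = 3
(65–115 Hz move/rest power ratio), beta suppression g_beta = 0.5 over
10–30 Hz, brain leading EMG by τ = 100 ms, EMG onset jitter sd 50 ms
around a 150 ms reaction delay, mains sinusoids at 60/120/180 Hz
(5/2/1 µV), 1/f² spectra at 20 µV rms, and a 7 Hz lead-wide common
mode. Where the effect structure was open, the choices were:

* **Band-limited modulation.** One colored-noise realization is
  partitioned in the frequency domain into low / beta (10–30 Hz) /
  broadband (65–200 Hz) components (disjoint support ⇒ independent),
  and the beta and broadband amplitudes are cross-faded with 100 ms
  raised-cosine ramps tied to each trial's jittered movement interval,
  the brain envelope leading the EMG interval by τ. This modulates band
  power without edge clicks.
* **Effect-size variability.** Each (channel, movement) draws a
  mean-one log-normal multiplier (sd 0.25 in log units) on the excess
  gain g_bb − 1. Real motor maps are not uniform, and without this an
  RMA channel responds identically to all three movements, making
  movement-identity decoding from RMA sites impossible in principle
  rather than hard in practice.
* **Nonspecific beta.** Beta suppression applies to every active
  channel during every movement (configurable to per-class via
  `beta_scope`), matching the widespread, movement-unspecific character
  of pericentral beta desynchronization; this is what collapses the
  beta-band parcellation to two clusters (active vs not) while the
  broadband parcellation resolves five.
* **Bipolar structure.** A segment with P ground-truth channels is
  emitted as P+1 contacts built by cumulative subtraction
  (`contact_{j+1} = contact_j − pair_j`) on top of the common-mode
  sinusoid, so adjacent-pair rereferencing recovers each synthesized
  signal exactly and demonstrably cancels the common mode. Contact
  variance consequently grows along a segment — a bookkeeping
  convenience, not a biophysical claim.
* **EMG.** Near-zero Gaussian baseline plus 25–400 Hz band-limited
  bursts at 20× baseline, ramped with the same raised cosine; the
  stored ground-truth onset/offset are the times the burst envelope
  crosses 5× the baseline sd. The `beta-only` preset sets g_bb = 1
  (no broadband response) and keeps the nonspecific beta suppression.

What the generator does **not** emulate: volume conduction and spatial
correlation between leads, artifacts (movement, pulse, electrode pops),
nonstationary background (sleep/drowsiness drift), imperfect task
compliance, and any biophysically detailed neural-mass dynamics.
Passing tests therefore establish that the pipeline recovers the
structure it assumes when that structure is present at realistic
effect sizes and SNR — not that the assumptions hold in any particular
clinical recording.

## Problem sizes and numerics

The test suite and the acceptance script run on scaled problems chosen
as reasonable simulation sizes: single 66-channel sessions for
statistics, maps and decoding; four pooled sessions (264 channels) for
the group-level cluster-count experiments (1,000 restarts, k = 1…20);
twenty small sessions (three channels, 12 trials per movement) for
latency recovery; and four 84-channel inactive-only sessions (≈1,000
channel-movement tests at 20/20 trials) for null calibration. k-means
uses 100 Lloyd iterations per restart; Welch windows are 1 s with 50%
overlap; all randomness flows from explicit seeds, and the full
pipeline is bit-reproducible for a fixed configuration and seed.

## Known limitations

* The EMG onset detector is a calibrated surrogate for manual
  annotation; its quarter-peak convention is matched to burst-like EMG
  and will bias on slowly recruiting muscles.
* The whole-run latency profile carries a small (~15 ms) skew on
  realistic signals; use the windowed estimator when epochs are known.
* The penalty-based cluster-count selection is sensitive to singleton
  outliers at small channel counts (see above) and, like any k-means
  procedure, assumes roughly isotropic clusters in r² space.
* Normalized broadband is centered at zero only in median; averaging
  exponentiated traces across channels weights high-variance channels
  more.
* The overlap score uses uncorrected p < 0.05 gating; with many
  channels some somatotopic sites will leak small nonzero overlap.
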