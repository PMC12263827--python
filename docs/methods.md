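# Methods

This note documents the models and numerical choices behind `entolidar`: the
forward signal model the synthetic survey generator uses, the feature
pipeline, the cluster-count diversity statistic and its calibration, and the
stratification summaries. It also states what the synthetic study does and
does not establish about real lidar data.

## Signal model

A transit is modeled as two nonnegative intensity channels sampled at
dt = 0.3 ms per channel. With a 10 kHz line rate shared over a three-state
acquisition cycle, each polarization channel sees an effective 3333 Hz
rate, putting the per-channel Nyquist limit at 1666.7 Hz — consistent with
an analysis band ending at 1666 Hz and with ≥ 80 samples in a 25 ms
transit.

The wing component is a truncated harmonic series
`w(t) = Σ_{k=1..n} d^(k−1) cos(2πk·f0·t + kφ)` rectified at zero: wing
glints are flashes of nonnegative intensity, and the rectification itself
contributes overtone mixing, as in real signals. The per-harmonic amplitude
ratio `d` (harmonic_decay) is a specularity proxy — mirror-like wings
produce sharp glints and rich overtones. The rectified glint train is split
between channels with amplitudes √(1−r) and √r (r = depol_ratio), so the
co- and de-polarized wing powers sum exactly to the total wing power. The
body glint is a raised-cosine envelope over the transit, fully
co-polarized; for durations ≥ 25 ms its spectrum stays below the 40 Hz
analysis edge, which is what lets a 25 ms moving-average detrend remove it
without touching the modulation band. Additive Gaussian detector noise is
applied last and clipped at zero.

Individual wingbeat frequencies are lognormal around the class mean
(`wbf_cv`, default 0.25 — the within-species spread scale reported for real
insects); transit durations are lognormal in log-milliseconds.

## Survey schedule and arrivals

The default schedule spans three days from local midnight, cycling seven
elevation angles (0, 3, 6, 10, 13, 17, 20°) with a 30 s dwell and a 215 s
repositioning pause per angle, minus four daily 7-min refuel gaps. Those
defaults give a duty fraction of 0.120: the instrument records 12% of the
survey span, which is why activity rates must be effort-compensated.
Arrivals per class follow an inhomogeneous Poisson process: a base rate in
events/hour modulated by a von Mises mixture over the 24 h clock
(normalized so a day's expected total is rate × 24), thinned to the
operational intervals. Geometry (range, elevation) is drawn consistently
with the class's layer preference; the 0° transect sits at the 1.8 m
instrument height inside the shrub band.

Noise fragments contain no injected periodicity: Gaussian noise around a
positive baseline (white, or mixed with a frequency-shaped 1/f component),
with lengths drawn like accepted events so they survive the selection
filter.

## Feature pipeline

Selection keeps transits with duration strictly over 25 ms AND ≥ 80
samples. Per channel, the body envelope is removed by a 25 ms moving
average, a Hann taper applied, and a ≥ 4× zero-padded periodogram computed.
The 80 log-spaced bins (exact geometric progression 40 → 1666 Hz, ratio
≈ 1.0483 per bin ≈ 4.8%) receive the *integrated* periodogram power within
their edges, so a narrow harmonic peak contributes its full power to the
covering bin wherever it sits; bins narrower than the dense resolution fall
back to interpolated power density × bin width. Integration rather than
center sampling matters: center sampling loses peaks that fall between
centers for long transits, which inflates within-class distances. The
combined (co+de) spectrum feeds the diversity analysis; per-channel band
powers give the degree of linear polarization. A floor of 1e−12 × total
power keeps logarithms finite.

The fundamental estimator scores a harmonic comb over every candidate on
the dense periodogram: the score of f0 is the 1/k-weighted mean log power
at k·f0, k = 1..4 (harmonics beyond Nyquist dropped, weights
renormalized). Log powers punish missing harmonics; the 1/k weighting
punishes a missing *fundamental* hardest, rejecting octave errors both
down (half the true f0 lacks its own line) and up (twice f0 lacks even
harmonics). The best candidate is refined by parabolic interpolation of the
comb score and discarded if its score is not prominent (≥ 2 natural-log
units) above the candidate median — pure noise mostly returns "undefined".
On noiseless 500 ms renders of the three reference wing types the
estimator is exact to < 0.01 Hz; at 20 dB SNR, ≥ 95% of transits with
durations 80–400 ms are recovered within max(1/T, one dense-grid step).

## Diversity statistic (NoC)

Spectra are reduced to shapes (normalized by total power, natural-log
transformed) and compared by Euclidean distance, making the metric
sensitive to harmonic structure rather than brightness. The condensed
distances are clustered agglomeratively — single linkage by default — and
the N−1 merge heights form the linkage sequence.

Sorted in descending order the linkage values decline roughly as a power
law in rank: a scale-free background. The sequence is detrended by
`Z_comp(p) = ((N−1)/p)^β Z(p)` with β the *signed* median of consecutive
log-log slopes (negative for a declining sequence), and
`NoC = #{ Z_comp(p) > median(Z_comp) + IQR(Z_comp) }` with
linear-interpolation quantiles and a strict inequality. The statistic
counts linkages that break *above* the power-law trend of the bulk —
merges joining groups more distinct than the background at any scale.

Two indexing conventions are implemented (`detrend_order`): the default
`rank_desc` just described, and `merge` (p = merge order, β the absolute
median slope), which satisfies the same closed-form identity (an exact
power law compensates to a constant) and is kept for comparison. The
descending-rank form is the operational default because its behavior is
the scientifically meaningful one across every ensemble we simulated:
unstructured clouds (iid noise, scale-free backgrounds) yield NoC ≈ 0, and
K well separated classes yield ≈ K−1. Under the merge-order form, the
med+IQR rule flags a roughly constant ~19% of all merges for *any* random
ensemble — including pure noise — because a random merge-height curve is
always convex against a single power law in log merge order; that form
cannot serve as a richness statistic.

Other recorded choices: single linkage as the pipeline default (the
monotone method under which gap merges between class manifolds stand out
most stably; average/complete/ward are config options), β by median of
consecutive slopes (global log-log fit as option), natural logs throughout
(the base only rescales distances and cannot change NoC), and the tree cut
into max(NoC, 1) groups with labels ordered by descending cluster size.

**Negative control.** Noise fragments run through the identical pipeline.
Across seeds, 500-fragment white-noise ensembles give NoC = 0: the
clustering machinery alone manufactures essentially no clusters.

**Calibration and limits of the richness proxy.** NoC counts
distinguishable spectral groups, not species:

- *Recovery regime.* For libraries whose within-class spread is small
  relative to class separation (the `build_class_library` fixture
  generator: within-class wingbeat σ = min(0.02, separation·ln(ratio)/8)),
  NoC recovers K−1..K for K = 5 and K = 10 (median over seeds 4–5 and
  9–11 with 60 events/class).
- *Blending regime.* At species-level spread (~25%), adjacent class
  manifolds overlap in wingbeat and blend into a continuum; within-class
  and between-class distances differ by < 2× where the outlier criterion
  needs roughly an order of magnitude, and NoC honestly drops toward 0.
  No reading of the statistic can count classes in this regime — the
  information is destroyed in the shape metric, not mishandled by the
  clustering (nearest-neighbor class purity stays high while class
  *separability as groups* vanishes).
- *Saturation.* With many simultaneous groups (K ≈ 20 at 3-bin
  separation) the K−1 gap heights themselves form a smooth, near
  scale-free sequence that the detrending absorbs; measured medians fall
  to ~10–12. The statistic is a lower bound that saturates as richness
  grows — consistent with its use as a relative, not absolute, richness
  proxy.

## Stratification

Beam height is straight-line geometry h0 + R·sin(elevation) with
h0 = 1.8 m; layers are half-open, lower-inclusive: shrub below 2.5 m
(heights under the nominal 1.5 m floor are still shrub — the partition is
exhaustive), canopy 2.5–25 m, open sky above. Diel classes come from
configurable dawn (05:30–07:30) and dusk (17:30–19:30) windows bracketing
twilight at a near-equatorial site; crepuscular = dawn ∪ dusk for the
temporal ternary.

Activity is counted in 10-min bins and divided by each bin's operational
fraction; bins with fraction < 0.1 are reported missing, not zero — a gap
is absent effort, not absent insects. For a homogeneous Poisson process
thinned by the default duty mask the mean compensated rate is unbiased
within 5% (verified over 50 replicates). Day profiles are across-day means
with sample standard deviations (0 for a single day). Ternary coordinates
use x = c2 + c3/2, y = (√3/2)·c3 with dot area ∝ √(cluster size).

Per-(day, layer) diversity runs one independent clustering per cell (≥ 3
events; days split at local midnight); no state is shared across cells.
With layer-resident classes and identical generative settings per day, the
per-layer NoC varies across days by ≲ 30% of its mean (median over seeds),
and a canopy configured with twice the shrub's classes scores higher in
nearly every seed.

## Problem sizes

The test and acceptance studies run at desk scale, chosen to keep the full
suite in tens of seconds to a few minutes while leaving the statistics
stable: 500 noise fragments × 10 seeds for the negative control; 60
events/class × 10 seeds for recovery at K ∈ {5, 10, 20}; 3-day surveys
with ~1000–2000 events for the stratified analyses; 50 replicates for
compensation unbiasedness. The default end-to-end run (5 classes, 3 days,
~1100 events) completes in seconds and is byte-identical on rerun with the
same seed.

## What the synthetic study does not show

The generator emulates harmonic structure, polarization split, diel and
vertical preferences, duty cycling and detector noise — not speckle or
atmospheric turbulence, range-dependent beam overlap, multi-insect
overlapping transits, or the range/probe-volume inequality across
elevation angles (flagged in outputs, not corrected). Passing tests
demonstrate the pipeline's internal correctness and the statistic's
behavior on data with known structure; they do not certify species-level
interpretation of clusters in field data, where one species may span
several clusters and several species may share one.
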