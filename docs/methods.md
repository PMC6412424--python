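# Methods

## Model and procedure

`ecgparafit` treats ECG delineation as repeated local curve fitting. For
a uniformly sampled voltage sequence `y(n)`, n = 0…N−1, and a half-width
`w`, every admissible center `i ∈ {w, …, N−w−1}` gets a vertex-centered
parabola `y'(j) = a (i − j)² + v` fitted by ordinary least squares over
the `m = 2w + 1` window samples. Substituting `x = (i − j)²` reduces
this to a simple linear regression with closed-form solutions

```
a = ( m Σxy − Σx Σy ) / ( m Σx² − (Σx)² )
v = ( Σx² Σy − Σxy Σx ) / ( m Σx² − (Σx)² )
```

and the quadratic-mean error `ε(i) = mean( (y − y')² )`. Because the
regressor is symmetric about the center, the window's odd (linear)
component is orthogonal to it: a pure ramp yields `a = 0`,
`v = mean(y)`, and all of the slope's variance lands in `ε`. Three
consequences drive the detector:

* `ε(i)` dips sharply when a symmetric extremum sits at the center —
  its strict local minima (middle of an `ε[i−2] > ε[i−1] < ε[i]`
  triplet; plateaus count once, at their leftmost index) are the peak
  candidates;
* the sign of `a` distinguishes maxima (`a < 0`) from minima (`a > 0`),
  and |a| measures steepness, so a floor on |a| rejects the false
  minima of `ε` that near-linear stretches produce;
* conversely, centers with |a| below a flatness ceiling *and* small `ε`
  lie on the isoelectric line.

The full chain: (1) condition the record; (2) detect R with the wide
window and estimate the isoelectric level; (3) cut the record into
fixed-width windows centered on each interior R; (4) delineate P, Q, S,
T inside each beat with the narrow window; (5) optionally score against
reference marks by tolerance matching.

## Preprocessing

Butterworth low-pass, order 10, cutoff 100 Hz (the upper edge of the
diagnostic ECG band), applied zero-phase (`sosfiltfilt`, even-reflection
padding). Zero-phase matters: a causal pass would delay peaks by several
samples and eat directly into the 10 ms scoring tolerance. The effective
magnitude response is the square of the designed one (two passes).

Baseline wander is removed by subtracting a least-squares polynomial of
order 8 fitted to the whole record against the *normalized* index
`n/N` — at order 8 over 10⁴ samples a raw-index Vandermonde system is
numerically unusable, while the normalized fit matches a generic
normal-equations solve to ~1e−9. Limitation: an order-8 polynomial
tracks at most ~2 cycles of wander, so on a 20 s record it suppresses
drift below ≈0.1 Hz well but attenuates 0.2 Hz wander only partially
(~3× in power). For heavy wander on long records, detrend in segments or
raise the order.

## Windows and thresholds

| parameter | default | units | meaning |
|---|---|---|---|
| R half-width | `round(0.030 fs)` | samples | wide window; 31-sample length at 500 Hz, sized to the R deflection within a 70–100 ms QRS |
| small-wave half-width | `round(0.012 fs)` | samples | narrow window; 13-sample length at 500 Hz, sized to the shortest wave (Q, 20–30 ms) |
| `a_min_r` | 5e−4 | mV/sample² | |a| floor for R candidates; also rejects P/T with the wide window (their fitted |a| ≈ 3–5e−4) |
| `a_max_iso` | 1e−4 | mV/sample² | flatness ceiling for isoelectric centers |
| `eps_max_iso` | 0.01 | mV² | fit-error ceiling for isoelectric centers |
| `a_min_small` | 1e−4 | mV/sample² | |a| floor for narrow-window candidates; below the broad T's ≈3e−4, above flat stretches |
| `upper_margin` | 0.08 | mV | maxima must rise this far above the isoelectric level |
| `lower_margin` | 0.04 | mV | minima must fall this far below it |
| `min_peak_distance_ms` | 40 | ms | same-polarity refractory between small-wave detections |
| `r_refractory_ms` | 200 | ms | minimum R–R distance (300 bpm ceiling) |
| `sensitivity_tolerance_ms` | 10 | ms | scoring tolerance |

Half-widths round half away from zero with a floor of 1. All `a`
thresholds are in mV/sample², hence tied to a mV-scaled signal at
500 Hz; at another rate they rescale as `(fs/500)²` (the same wave has
`fs²`-times the curvature per sample²). The amplitude margins follow the
rule of sitting slightly inside the smallest rendered wave excursions:
the default morphology's P rises ≈0.13–0.15 mV; its Q dips only
≈0.05–0.07 mV below baseline because the R upstroke partially fills the
dip — hence the asymmetric defaults. Both are data-dependent and are the
first knobs to retune on a new recording chain.

Rationale for reading the printed |a| limits as magnitude conditions: in
the `x = (i−j)² ≥ 0` basis an upward peak fits with `a < 0`, so a
literal one-sided threshold would reject every upward R; the sign is
used separately to classify maxima vs minima.

## Detection details

*R peaks*: wide-window `ε` minima with `a < 0` and |a| > `a_min_r`;
candidates within the refractory distance collapse greedily to the
largest |a|.

*Isoelectric level*: the **median** of `y` over centers passing both the
flatness and error ceilings. The median, not the mean: with the default
ceilings, the gentle shoulders of T and P also qualify (their local
slope variance stays under `eps_max_iso`) and would bias a mean upward
by ~0.03 mV, while flat segments form the clear majority. If nothing
qualifies (no flat region at all), the overall signal median is used and
a warning is emitted.

*Beat segmentation*: half-width `round(mean RR / 2)` samples around each
interior R (window length `2·half + 1`); the first and last R only mark
the segmentation range, so K detected R's give K − 2 beats. Windows
overrunning the record edge are zero-padded and flagged.

*Small waves*: narrow-window `ε` minima of either sign, excluding those
within one half-width of R (the R apex's own minimum). Each candidate is
then snapped to the signal extremum within ±w samples: for a wave
narrower than the window (a sharp Q against the R upstroke) the `ε`
minimum sits up to ~3 samples off the true apex, and gating at the
shifted sample would read a slope value. Gates compare the snapped
*sample value* against the isoelectric margins (the fitted vertex `v`
underestimates sharp dips by up to ~30% through slope contamination; `v`
is still what the annotation's amplitude field reports). Same-polarity
survivors closer than `min_peak_distance_ms` collapse to the larger
excursion. Labels are positional: Q = nearest minimum before R, S =
nearest minimum after R, P = largest-amplitude maximum before Q, T =
largest-amplitude maximum after S; a wave that fails its gate is simply
absent — never substituted by a neighbour.

## Sensitivity metric

Per label, each reference point is matched to at most one same-label
detection with |Δt| ≤ tolerance (boundary inclusive), pairs taken
nearest-first; sensitivity = 100 × matched/total, pooled over records.
Pooling is point-level (per-record percentages weighted by beat count);
a record-level variant — the share of records whose every point of a
label matched — is available behind a flag. Greedy nearest-first equals
the maximum matching whenever each detection lies near a distinct
reference (the physiologic case, beat spacing ≫ tolerance); on
adversarially spaced inputs it can under-match. Labels with no reference
points are reported as undefined, not 0%.

## Synthetic generator

Each beat is a sum of five Gaussians on a constant baseline; defaults
P(−0.16 s, +0.15 mV, σ 0.025 s), Q(−0.03, −0.10, 0.008),
R(0, +1.0, 0.012), S(+0.03, −0.15, 0.010), T(+0.25, +0.30, 0.045) —
textbook lead-I morphology. R–R intervals are Gaussian (default mean
0.8 s; jitter truncated at ±3 sd), and noise terms are optional:
sinusoidal wander (default 0.2 Hz), 50/60 Hz powerline, white noise, and
band-limited EMG-like noise. A sum-of-Gaussians model was chosen over a
dynamical-system simulator precisely because the ground truth is
controllable: annotations are recomputed as the exact extrema of the
*rendered* noiseless signal (neighbouring waves shift an apex — the
rendered Q minimum sits ~2 samples left of its nominal center — and a
shallow wave can be swallowed entirely, in which case it is annotated as
absent). Same seed → bit-identical output; with zero R–R jitter the
noiseless component is identical across seeds while the noise varies.

What the generator does *not* emulate: multi-beat morphology change,
ectopy and arrhythmia, biphasic or inverted waves, respiratory amplitude
modulation, electrode motion artifacts. Tests passing on this generator
therefore demonstrate correctness of the machinery and the stated
robustness properties, not clinical-grade performance on pathological
recordings.

## Degenerate inputs and tie-breaks

Signals must be finite, ≥2 samples, fs > 0. Window fits require
`2w + 1 < N` and an in-range center; `w = 0` is rejected (the regressor
would be degenerate at w = 0 only; for w ≥ 1 the denominator
`mΣx² − (Σx)²` is strictly positive). `ε` plateaus report their leftmost
index. Two beats' windows may overlap with irregular rhythm; each beat
is delineated independently. Fewer than 3 detected R's → R annotations
only (nothing can be segmented). Empty candidate sets at any stage
propagate as empty results, never errors.

## Known limitations

* Shallow Q waves whose dip stays inside `lower_margin` of the
  isoelectric level are missed by construction — the method's documented
  failure mode, reproduced by the acceptance suite (Q sensitivity
  collapses while P/R/S/T stay at 100%).
* Fixed |a| thresholds assume mV scaling at ~500 Hz; apply the `(fs/500)²`
  rescaling, or retune, elsewhere.
* Whole-record polynomial detrending limits wander suppression on long
  records (see above).
* Peak detection only: wave onsets/offsets (PR/QT boundaries) are out of
  scope, as are multi-lead fusion and streaming operation.

## Problem sizes in the test suite

The synthetic benchmark uses 50 records × 20 beats at 500 Hz (~8 000
samples each) with ±10% morphology jitter, and a 20-record variant for
the shallow-Q check; the regression-core equivalence check uses 1 000
random windows. These sizes give stable percentages (900 small-wave
points per label) while keeping the whole suite in the tens of seconds.
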