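# Methods

## Problem setting

Remote photoplethysmography (rPPG) recovers the cardiac pulse from the tiny
periodic color fluctuations of skin in video. The package evaluates *where*
on the face that signal is best read: 28 named skin regions are defined as
polygons over the 468-point face-mesh keypoint convention, each region's
pixels are averaged per frame into a mean-RGB trace, the trace is converted
to a pulse estimate by one of four classical algorithms, heart rate (HR) is
read off the pulse spectrum in sliding windows, and the regions are scored
and ranked against contact ground truth.

## Region scheme and rasterization

Landmarks are pixel coordinates with the origin at the top-left pixel
corner; pixel (i, j) has center (j + 0.5, i + 0.5). Adapters converting
normalized face-mesh output multiply by frame width/height. A pixel belongs
to a region iff its center lies inside the polygon formed by the region's
keypoints in listed order (closed), under the even-odd rule; polygons are
clipped to the frame. The depth coordinate of mesh detectors is ignored —
region division is purely 2-D. The rasterizer is a ~20-line vectorized
even-odd crossing test, chosen over library rasterizers because the
pixel-center/even-odd contract is exactly testable against a brute-force
point-in-polygon oracle (and the test suite does exactly that).

Frames whose region mask is empty (landmarks off-frame, occlusion) yield an
invalid trace sample rather than fabricated data. Downstream, invalid gaps
of at most 1 s are linearly interpolated before pulse conversion; longer
gaps split the trace into independently processed segments, and HR windows
containing more than 20 % invalid samples are dropped from metric
computation.

## Pulse conversion (CHROM, POS, LGI, OMIT)

All four methods consume the (n, 3) mean-RGB trace:

- **CHROM** and **POS** run on 1.6 s sub-windows with Hann-weighted
  overlap-add (50 % hop), each sub-window's channels divided by their
  within-window mean. CHROM combines X = 3Rn − 2Gn and
  Y = 1.5Rn + Gn − 1.5Bn as X − αY with α = σ(X)/σ(Y); POS projects onto
  (0, 1, −1) and (−2, 1, 1) and combines as S1 + αS2 with α = σ(S1)/σ(S2).
  If a denominator σ falls below 1e−12 (constant channels), α is set to 0
  so degenerate inputs cannot produce NaN.
- **LGI** and **OMIT** operate on the full processing span. Both remove one
  channel-space direction u with the projector P = I − uuᵀ and return the
  second (green) component of the projected channel matrix. For LGI, u is
  the leading left singular vector of the 3×N channel matrix (computed from
  the 3×3 Gram matrix); for OMIT it is the first orthonormal column of the
  thin Householder QR of that matrix. P is invariant to the sign of u, so
  the output polarity is deterministic.

Outputs are zero-mean. Dividing by within-window means makes CHROM/POS
exactly invariant to a global gain on the trace; LGI/OMIT outputs scale
with the gain but their spectral peak location — the only quantity the HR
stage consumes — does not move.

Polarity note: with the generator's green-dominant gain vector, CHROM's
chrominance combination anticorrelates with the pulse waveform (its
windowed Pearson correlation against the reference is near −1 where the
other methods are near +1). The correlation metric is computed as defined,
without absolute values; rankings pool four methods, so the one inverted
component does not change the ordering behaviour.

## HR estimation

The pulse estimate is bandpass filtered to 0.65–4 Hz (39–240 BPM) with a
sixth-order Butterworth applied forward–backward (zero phase; evaluation is
offline, and only peak location matters, so the doubled effective order is
harmless). The filter is applied once to the full signal, before
windowing. Frame rates of 8 Hz or below cannot represent the 4 Hz cutoff
and are rejected.

Per 6 s window, hopping by 1 s (5 s overlap), the window is mean-removed,
Hann tapered, and treated as a single Welch segment — 6 s is too short for
meaningful sub-segmentation. The power spectrum is evaluated on a frequency
grid no coarser than 0.1 BPM and HR = 60 × the in-band argmax, stamped at
the window center. Numerically, the peak search is two-stage: a coarse FFT
(grid ≤ 0.025 Hz, several times finer than the Hann mainlobe of a 6 s
window, so the dominant lobe cannot be missed) locates the peak, then the
exact DTFT is evaluated on the 0.1 BPM grid within ±0.25 Hz of it. This is
equivalent to a zero-padded FFT argmax for any spectrum with a resolved
dominant peak and is an order of magnitude faster, which the seeded
simulation studies rely on.

Estimates and references with different time bases are aligned by linear
interpolation of the reference onto the estimate's timestamps; estimate
samples outside the reference span are dropped. Where a dataset provides
only contact PPG and no HR channel, the reference HR is computed by the
identical windowed estimator applied to the contact signal.

## Metrics and scoring

- **MAE** (BPM): mean absolute difference of the aligned HR pairs.
- **PCC**: mean over segments of the per-segment Pearson correlation
  between the filtered pulse estimate and the identically filtered,
  video-grid-resampled contact waveform. Segments reuse the 6 s / 5 s
  windows of the HR stage (the metric-window length is a package default,
  exposed in configuration). Zero-variance segments are excluded and
  counted in a diagnostics log.
- **SNR** (dB): per segment, the FFT power within ±12 BPM of the reference
  HR and of its first harmonic versus all other power,
  10·log10(signal/noise), averaged over segments. The per-segment reference
  HR is the median of the aligned reference inside the segment. Segment
  values are clamped to ±60 dB and the noise power floored at 1e−12 of the
  total so pure-tone edge cases stay finite.
- **Overall score**: per activity, each participant-aggregated metric
  (median over participants — applied to all three metrics alike) is
  min–max normalized across ROIs, MAE inverted, and the three components
  averaged; OS ∈ [0, 1] by construction, so no second normalization is
  applied (an optional per-activity renormalization flag exists). If a
  metric is constant across ROIs its component is set to 0.5 for every ROI
  (neutral) rather than dividing by zero.
- **Acceptance rate**: fraction of consecutive non-overlapping 25 s windows
  with MAE ≤ 10 BPM. The boundary counts as acceptable (≤, not <).
- **Bland–Altman**: mean and ±1.96 sample standard deviations of the per-
  25 s-window mean differences.

## Ranking

Per activity and method, ROI metrics are aggregated and scored; method
scores are pooled by averaging (the default, recorded in the report
metadata; per-method rankings are also available). Summed OS across
activities orders the ROIs descending; ties break by lower aggregated MAE,
then ROI index. ROIs missing any (activity, method) cell are excluded with
a warning. The advisory "top group" is the ranking prefix ending at the
first consecutive summed-OS gap above a threshold (default 0.3) — a
reproducible stand-in for boxing the leaders by eye.

## Synthetic data

The generator produces what the analysis assumes, not photorealistic video:
a phase-integrated quasi-periodic waveform p(t) = sin φ(t) + 0.3·sin 2φ(t)
with φ′(t) = 2π·HR(t)/60 and a piecewise-linear HR trajectory in 48–180
BPM; per-ROI traces baseline + amplitude(k)·p(t)·(0.4, 1.0, 0.6) — the
green-dominant gains reflect that green carries the strongest cardiac
information in reflectance video — plus white noise per channel,
illumination drift common to all channels and ROIs, and exponentially
decaying motion-burst transients at Poisson times. Amplitudes are in
0–255 intensity units; the defaults (0.2–3.0, glabella strongest, then
forehead/malars/upper nasal dorsum, the rest fading by index) put the
pulsatile contrast at the sub-percent level of real skin. Ground truth is
sampled at 60 Hz, deliberately different from the 25–35 Hz video rates, to
exercise alignment. Two activity presets set the noise scale: "cognitive"
(σ = 0.4, mild drift, rare weak bursts) and "motion" (σ = 0.8, stronger
drift, frequent strong bursts).

Default study conditions for the seeded simulation experiments: 6
participants × 2 activities, 30 s recordings at 30 fps, per-participant HR
drawn uniformly from 60–100 BPM with a ±12 BPM linear drift. The noise
monotonicity experiment uses 60 s recordings so each contributes at least
two 25 s acceptance windows.

The frame renderer paints each region polygon with its generating trace
color (uint8) on a static noise background, with optional bounded
random-walk rigid jitter and forced off-frame occlusion intervals; the
landmark records always match the painted polygons, so trace extraction
must round-trip to within quantization (0.5 intensity units).

The 468-point landmark template is synthetic: a procedurally relaxed
schematic layout (regions pulled toward regular polygons around
adjacency-spaced anchor centers, shared vertices averaged, one global
winding) — not a detector output. It is validated for simple,
positive-area, pairwise-disjoint polygons. Consequently, passing
render/extract tests demonstrate geometric correctness of the extraction
machinery, not robustness to real facial appearance, deformation, or
detector noise; likewise the noise taxonomy is an idealization of lighting
and motion artifacts, with no claim of physical fidelity.

## Known limitations

- Real-data effects — skin-tone diversity, facial deformation, detector
  jitter correlated with expression, hair/mask occlusion statistics — are
  outside the generator's scope; conclusions about region rankings on real
  video require the corresponding external datasets.
- The two-stage spectral peak search can disagree with a full fine-grid
  argmax when two spectral lobes are within a few percent in power; for HR
  signals this is the ambiguous case anyway.
- CHROM's output polarity inverts the correlation metric under the
  synthetic gain vector (see above).
- Simple polygons are assumed as listed; self-intersecting keypoint orders
  are rasterized under the even-odd rule without repair.
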