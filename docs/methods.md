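# Methods

## Ciliary spectral analysis

Each pixel of a high-speed video field is modelled as a periodic
intensity signal riding on a static background. The pipeline removes the
temporal mean (DC), applies an optional taper (rectangular, i.e. no
taper, by default), and takes the real FFT along time. The spectrum is
reported on the amplitude scale: magnitude 2·|X_k|/N at frequency
k·fps/N (|X_k|/N at the Nyquist bin when N is even, since that bin has
no conjugate partner; with a taper, N is replaced by the window sum —
coherent-gain correction). On this scale an on-bin sinusoid of amplitude
A yields magnitude A at its bin regardless of recording length, which
makes the beating threshold an intensity amplitude rather than an
N-dependent raw FFT modulus. Bin frequencies are computed as k·fps/N
directly so that on-bin frequencies are represented exactly in floating
point.

A pixel's dominant component is the largest-magnitude bin inside the
closed detection band [f_lo, f_hi] = [2, 60] Hz; ties break toward the
lower frequency (deterministic and reproducible). The DC bin is removed
before the search and the Nyquist bin is excluded from it. A pixel is
*beating* when its dominant in-band magnitude strictly exceeds the
threshold τ = 1 intensity unit. Field metrics follow: CBS is the
percentage of frame pixels beating (denominator = full frame; at the
default 1024 × 768 geometry that is 786,432 pixels), and CBF is the
unweighted arithmetic mean of the dominant frequency over beating pixels
(magnitude-weighted means were considered and rejected: a single field
CBF should not shift when bright and dim ciliated areas beat at the same
rate). A field with no beating pixels has CBS 0 and undefined (NaN)
CBF; such fields are excluded from CBF averages but counted.

Aggregation is hierarchical and unweighted: fields → well mean ± SEM,
wells → donor mean ± SEM (SEM = sample SD/√n, NaN for n = 1). Wells with
unequal field counts therefore contribute equally at the donor level, as
is conventional for nested replicates.

Accuracy expectations: a noiseless on-bin sinusoid in band with
amplitude above τ is recovered exactly (frequency) and to ~1e-9
(amplitude, float64). Off-bin frequencies land within one bin of the
truth plus the half-bin quantization, i.e. |error| ≤ 1.5·fps/N — 0.75 Hz
at the default 360 fps / 720 frames (0.5 Hz bins). Additive Gaussian
noise of sd 0.2 against amplitudes ≥ 2 leaves per-pixel dominant-bin
errors within one bin for ≥ 99% of pixels (the per-bin noise magnitude
scale is σ·√(2/N) ≈ 0.01, far below signal).

Full frames are processed in 64-row blocks so that a default-size stack
(720 × 768 × 1024) never materializes a float64 copy of itself plus its
spectrum at once.

## Mito stress-test analysis

Raw per-cycle OCR values are grouped into the four protocol segments
(baseline, oligomycin, FCCP, rotenone + antimycin A, validated to appear
in injection order). A segment's rate is the mean of its cycles by
default; `last`, `min` and `max` rules are available because plate-assay
conventions differ (minimum after oligomycin and maximum after FCCP are
common choices when drug response is slow). Per well:

- corrected state = (raw state − raw rot+antA) / protein µg for
  baseline, oligomycin and FCCP; the corrected rot+antA state is
  identically zero and not reported;
- negative corrected rates are retained with a warning rather than
  clamped — clamping at zero would bias ratios built from them;
- RCR = corrected FCCP / corrected oligomycin. The subtraction choice
  matters for this ratio (the protein normalization cancels); the
  package computes it from corrected rates and flags it undefined when
  the corrected oligomycin rate is not positive.

Replicate screening uses Tukey fences: on each plate, a well is omitted
when any corrected state lies outside [Q1 − 1.5·IQR, Q3 + 1.5·IQR] of
that state's across-well distribution (quartiles by linear
interpolation). The rule is deterministic and scale-free. With fewer
than four wells the fences are statistically meaningless, so nothing is
flagged and a warning is emitted. Note a small-sample caveat: with ~6
Gaussian wells the fences themselves are noisy and will occasionally
trim genuine replicates; the screen is meant for gross failures (its
contract: a 10× outlier well moves the flagged plate mean by < 1%), not
as a variance reducer, and can be disabled.

Plate means are computed over kept wells; donor summaries are unweighted
means of plate means (a plate that kept 5 wells counts the same as one
that kept 6), matching the convention of averaging independent
experiments rather than pooling replicates. Plate and donor RCR are
ratios of the corresponding FCCP and oligomycin means.

## Synthetic data

The video simulator superimposes rectangular sinusoidal patches
(frequency, amplitude, phase) on a constant background with optional
additive Gaussian noise; overlapping patches sum and are recorded in the
truth metadata. Defaults are the emulated acquisition: 1024 × 768
pixels, 360 fps, 720 frames, stored float32 (float64 available for
tests that need 1e-9 amplitude accuracy). The ground-truth mask marks
pixels covered by at least one patch with amplitude above the detection
threshold and frequency in band.

What the simulator does *not* emulate: cilia waveform shape and
harmonics, metachronal phase gradients, optical point-spread blur,
photobleaching drift, shot (Poisson) noise — the noise hook is additive
Gaussian only. Passing round-trip tests therefore demonstrates that the
spectral pipeline implements its stated definitions exactly, not that
those definitions are robust to every imaging artifact of real cultures.

The plate simulator draws cycle values as truth × well-factor + Gaussian
cycle noise. Defaults define the reference study condition: true rates
(B, O, F, R) = (100, 40, 150, 20) pmol O₂/min — a coupled, responsive
profile whose corrected normalized truth is (8.0, 2.0, 13.0) with RCR
6.5 — 6 wells/plate, 3 cycles/segment, protein 10 µg/well, cycle noise
2 pmol O₂/min (2% of baseline). Per-well multiplicative scatter and
protein variability default to zero so that the recovery properties are
exercised under pure i.i.d. cycle noise; both are configurable, as are
designated gross-outlier wells (a multiplier applied to a well's entire
trace). All randomness flows from the single spec seed; a multi-plate
study spawns per-plate generators from that seed.

## Statistics

The exact Mann–Whitney U test enumerates all C(n_x+n_y, n_x) equally
likely assignments of the pooled (tie-free) observations and reports
twice the smaller tail probability of the observed U, capped at 1 (the
doubling convention; at n = 3 + 3 the smallest attainable two-sided p is
0.1). Enumeration runs whenever both groups have ≤ 8 observations and no
ties — at those sizes it is cheap and exact, and avoids the anticonservative
small-sample behaviour of the normal approximation. Larger or
tied samples use the normal approximation with tie correction and a 0.5
continuity correction; the result records which path ran. The reported
statistic is min(U_x, U_y).

The two-sample t test defaults to the Student (pooled-variance) form,
with Welch behind a flag; both-groups-constant input returns t = 0,
p = 1 with a degeneracy note. Pearson correlation uses the
product-moment formula with p from the t transform on n − 2 degrees of
freedom. t and Pearson delegate to scipy.stats; the Mann–Whitney exact
path is implemented here and cross-checked against independent
enumeration in the tests.

## Problem sizes in tests

The test and acceptance runs use reduced geometries chosen so every
check still exercises the full pipeline: band sweeps and single-pixel
spectra run at the native 720 frames (0.5 Hz bins) on 2 × 2 frames;
patch-recovery runs use 16 × 16 fields at 720 frames; the designed-CBS
fields use 320 × 240 = 76,800 pixels (every target fraction in
{0, 5, 25, 50, 100}% is then a whole number of rows, which 1024 × 768
cannot provide for 5%) at 120 frames; bioenergetics recovery uses 200
independent 3-plate × 6-well studies. The default full-frame geometry
itself is asserted directly (1024 × 768 = 786,432).

## Known limitations

- CBF is defined per pixel by the dominant bin; sub-bin interpolation
  (e.g. parabolic peak refinement) is not implemented.
- The beating threshold is an amplitude in intensity units; recordings
  with different gain/bit depth need a rescaled τ.
- The outlier screen is per-plate and per-state with a fixed fence
  multiplier; no multiplicity control across states.
- Exact Mann–Whitney requires tie-free data; ties always route to the
  corrected normal approximation regardless of sample size.
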