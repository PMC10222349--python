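# Methods

## Problem

Peak tibial acceleration (PTA) — the per-footstrike maximum of the
acceleration measured at the distal tibia, either along the tibia's long axis
(*axial*, the sensor y-axis) or as the vector magnitude of all three axes
(*resultant*) — is a standard surrogate for impact loading in running
research.  The most common wearable accelerometers operate at ±16 g, but
overground running regularly produces tibial peaks above 20 g.  Beyond the
operating range the sensor saturates: the output rails at ±16 g, the signal
shows a flat cut-off and the true peak is lost.

This package implements (i) the spline-based restoration algorithm used to
reconstruct such clipped peaks, (ii) the event/peak-extraction chain that
turns a tri-axial trace into per-stride PTA values, (iii) the agreement
statistics used to validate restored peaks against a co-located ±200 g
reference accelerometer, and (iv) a synthetic dual-range signal generator
with exact per-stride ground truth, so the entire pipeline is testable
without access to recorded data.

## Restoration algorithm

Per axis, independently:

1. **Clip-run detection.**  A sample is railed when `|a| ≥ range − rail_tol`.
   Maximal constant-sign runs of railed samples are located; runs separated
   by fewer than `window_len` clean samples are merged into one run spanning
   both, so that every support window used in step 2 contains only clean
   samples.  `rail_tol` defaults to 0.05 g (≈ 0.3% of full scale): real
   sensors saturate near, not exactly at, the nominal rail.  The minimum run
   length is one sample — a single railed sample still marks an unobserved
   overshoot.

2. **Windowed spline interpolation.**  The `window_len = 3` samples
   immediately before and after the flat cut-off are interpolated by a
   spline of order 5 (polynomial degree 4).  With six support points and one
   interior knot placed by the averaged-interior-knot rule (the mean of the
   four interior sites, the placement that guarantees the Schoenberg–Whitney
   conditions), the interpolant is a C³ piecewise quartic.  It is evaluated
   at the clipped sample positions and those values replace the railed
   samples; all other samples are bit-identical to the input.  Because every
   polynomial of degree ≤ 4 lies in this spline space regardless of knot
   placement, restoration reproduces any quartic peak exactly — the invariant
   the test suite pins to ≤ 1e-6 g.

3. **Edge handling.**  A run within `window_len` samples of a series
   boundary has no full support window; it is skipped and counted in the
   restoration report rather than extrapolated (quartic extrapolation is
   numerically explosive).  No floor or cap is applied to restored values at
   restoration time; physically implausible reconstructions are handled by
   the analysis-stage rejection rule below.

Restoration is applied to the **raw, unfiltered** signal; filtering comes
afterwards.

## Processing chain

Identical for the raw low-range, restored low-range and high-range reference
streams:

* **Filter** — 2nd-order Butterworth low-pass at 85 Hz, applied
  forward–backward (zero phase).  Zero-phase filtering is the gait-analysis
  standard; it doubles the attenuation at the cut-off (−6 dB) but leaves
  peak times unshifted, which the 200 ms cross-stream matching depends on.
* **Resultant** — `sqrt(x² + y² + z²)` per sample.
* **Initial contacts** — local maxima of the resultant (minimum separation
  0.5 s, minimum prominence 4 g; both configurable — the published rule
  specifies neither), each mapped to the minimum of the resultant within the
  preceding 75 ms.  Two maxima sharing a minimum collapse to one contact.
* **Strides** — contact to contact; durations outside 0.4–1.6 s are dropped
  as implausible (guards against spurious contacts).
* **PTA** — axial and resultant maxima within the half-open window
  `[contact, contact + 0.40 × stride)`; first argmax on ties.
* **Matching** — each reference peak is paired with the nearest-in-time test
  peak within 200 ms, greedily by ascending |Δt| with ties broken by earlier
  reference time, each peak used at most once.  Streams are compared on the
  common time axis in seconds, never by sample index (the two sensors run at
  1125 and 1600 Hz).

## Agreement statistics

* **Rejection** — restored axial peaks with a value *strictly below* 16.0 g
  are rejected and counted: a reconstruction inside the operating range is
  physically implausible (no reconstruction would have been needed).  The
  rejected percentage is always reported.
* **Reference floor** — axial validation uses pairs whose reference (true)
  value is strictly above 16 g; resultant validation uses footstrikes whose
  stride window contains at least one reconstructed sample.
* **Bland–Altman** — mean and sample SD (n − 1) of the differences
  (test − reference; negative = underestimation); 95% limits of agreement
  = mean ± 1.96 · SD.  Mean, SD and LOA are reported separately.  Pairs are
  pooled across participants.
* **Strata** — right-open bins [16, 20), [20, 24), [24, 28) g on the
  reference value; pairs at ≥ 28 g stay in the overall summary only.
  (The boundary convention is a package choice; the published ranges leave
  boundary membership undefined.)
* **Effect sizes** — per participant, two-sample Welch t-tests (pooled
  variance available via `equal_var=True`) comparing the full-range peak
  sets of each low stream against the reference, with Cohen's d on the
  pooled SD and the conventional bins: trivial (|d| < 0.2), small (< 0.5),
  medium (< 0.8), large (≥ 0.8).

## Artificial-clipping experiment

To validate the restorer where truth is available within a single stream,
the axial channel of the raw low-range trace is clipped one-sidedly at
+15.0 g (all samples above 15.0 replaced by 15.0), restored with the same
3-sample window and order-5 spline, and run through the identical pipeline.
Original axial peaks in the inclusive band [15.0, 15.9] g are matched to the
restored-artificial peaks within 200 ms; restored peaks below 15.0 g are
rejected and counted; the kept pairs are summarised Bland–Altman style.

On synthetic cohorts this experiment carries a caveat the real-data version
shares in milder form: strides whose *true* peak exceeded the 16 g hardware
rail can land in the 15.0–15.9 g band after filtering (the clipped plateau
attenuates below the rail), and for those strides the "original" reference is
itself distorted.  The synthetic generator concentrates such artifact peaks
near the band, so the experiment's mean difference on synthetic cohorts runs
mildly positive (≈ +1 g) rather than near zero; the exactness of the
machinery is pinned separately by a test in which every peak is locally
polynomial and the experiment's differences vanish identically.

## Synthetic data generator

The generator builds a continuous-time model per stride and samples it
through two virtual ADCs on one clock: ±200 g at 1600 Hz (never saturates)
and ±16 g at 1125 Hz (hard-clipped).  Per stride, on the axial channel:

* a 1 g gravity baseline;
* a Gaussian dip (σ = 4 ms, depth 0.6 g + 0.05 × peak) at the contact time —
  the local minimum the contact-detection rule keys on;
* an impact transient 12 ms after contact: a **Gaussian-windowed 25 Hz
  cosine** (Gabor pulse) with envelope SD `impact_width_ms` (default 4 ms),
  amplitude set so the total model peaks exactly at a value drawn from a
  zero-truncated normal (default 14.30 ± 6.06 g);
* a slower "active" half-sine spanning the first 30% of the stride
  (relative amplitude `active_peak_gain`, default 0.35).

The x and z axes carry scaled (0.9 / 0.75), slightly lagged (1.5 / 2.5 ms)
copies of the impact plus their own baselines, which places the resultant
peaks near 20 g for 14.3 g axial peaks.  White noise (default SD 0.3 g) is
added independently per sensor and axis at sampling time.  Stride rate is
drawn per stride at 1.4 ± 0.1 Hz.

**Why a Gabor pulse.**  The impact shape is the one genuinely free choice in
the model, and it is pinned by two artifacts the pipeline must reproduce.
First, restoration error: an exponentially damped sine has an asymmetric,
flattish top, and the order-5 windowed spline *over*shoots such peaks —
the opposite of the underestimation the algorithm exhibits on real tibial
signals.  A symmetric bell top makes the spline undershoot, with error
growing as the true peak rises above the rail (measured on this family:
−0.06 / −0.21 / −0.58 / −1.46 g at true peaks 17 / 19 / 22 / 26 g).  Second,
the clipped-plateau length: with a 4 ms envelope the plateau is short
relative to the 85 Hz filter's response, so the *raw* clipped stream
registers peaks **below** the rail (the well-documented pile-up of artifact
peaks in the 13–16 g band); a wide-topped pulse instead produces a plateau
the zero-phase filter overshoots by ~4%.

**Ground truth** is evaluated densely (0.1 ms grid) on the noiseless model:
per-stride axial and resultant maxima over the first 40% of the stride, and
the contact time as the resultant's local minimum just before the impact —
the same definition the detection rule uses, so the event-recall oracle is
exact.

**Cohorts.**  Per-participant axial-peak means are drawn N(14.3, 2.0) with
within-participant SD 5.7 g, pooling to ≈ 14.3 ± √(5.7² + 2²) ≈ 6.06 g —
the study-level distribution — while giving participants the across-runner
spread that makes per-participant effect sizes informative.

**What the generator does not emulate:** surface-gradient and footstrike-
pattern structure (peaks are i.i.d. within a participant), left/right
asymmetry, non-white sensor noise, sensor misalignment drift, the lower
resolution of the high-range ADC (available as an option, off by default),
and any spectral detail of real tibial signals beyond the two artifacts
above.  Passing tests therefore demonstrate the pipeline's correctness and
its qualitative behaviour under clipping, not quantitative equivalence with
any recorded data set.

## Numerical choices and degenerate inputs

* Spline knots: explicit averaged-interior-knot vector passed to the
  B-spline interpolation routine; support coordinates are sample indices
  (uniform clock), keeping the basis well-conditioned.
* Bland–Altman with n < 2 pairs reports NaN SD/LOA and flags itself
  (`sd_defined = False`); empty strata are omitted from figures with a note.
* Welch test with two zero-variance groups: p = 1 and d = 0 when means are
  equal; d = ±inf (labelled large) otherwise.
* Peak-window ties: first argmax.  Stride windows are half-open so no sample
  is counted twice.
* Matching is greedy by |Δt|; at running stride rates (≥ 0.4 s spacing) and
  200 ms tolerance it coincides with the optimal assignment in ≥ 99% of
  pairs (verified against a linear-assignment oracle).
* Trace files are plain delimited text with a one-line metadata header;
  times are re-gridded onto the exact uniform clock on read to absorb text
  round-off.

## Problem sizes

The full synthetic study — the scale used by the end-to-end tests and the
acceptance script — is 24 participants × 800 strides (~570 s of dual-rate
recording each, ≈ 19,000 footstrikes pooled), which runs in about a minute
on one core.  Statistical micro-checks use 400–5000 strides; the Welch
type-I simulation uses 1000 replicates of n = 50 per group.

## Known limitations

* The restoration error magnitude depends on the impact shape; the synthetic
  family reproduces the direction and stratified growth of the error, not
  its exact size on any particular sensor or cohort.
* Contact detection parameters (prominence, separation) are tuned for
  running; walking or highly irregular gait would need different settings.
* Boundary clip runs are skipped, so peaks in the first/last ~3 samples of a
  recording are never restored.
* The artificial-clip experiment inherits band contamination from hardware-
  rail clipping (see above).
* No proportional-bias (regression-based) limits of agreement and no
  confidence intervals on the LOA bounds are computed.
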