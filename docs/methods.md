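# Methods

## Helmholtz model of the bulla

The bulla is modelled as a lumped-element Helmholtz resonator: a rigid
cavity of volume *V* driven through a neck of opening area *A* = πR² and
anatomical length *L*,

    f = (c / 2π) · √( A / (V · L_eff) ).

Assumptions: the cavity walls are rigid (the bulla is calcified, so
drying is not expected to change its geometry), the opening is a single
circular aperture of the measured diameter, the air column in the neck
moves as a unit, and the wavelength is large compared with the cavity
dimensions (at 3 kHz, λ ≈ 11 cm versus a ~2 cm bulla — comfortably in the
lumped regime).

**End correction.** The necks of real bullae are short relative to their
openings (often under 1 mm of anatomical neck against a 3–5 mm radius),
so the radiation mass just outside the aperture dominates. The effective
neck length is

    L_eff = L + k·R,     k = π/2 by default.

The constant is configurable (`AcousticConstants.end_correction`); the
classical flanged-opening value 1.7 is provided as an alternative. With
k = π/2 the model reproduces every resonance in the bundled 31-bulla
reference table to better than 0.5% from the printed geometry columns,
which is the tolerance used throughout (the geometry columns themselves
carry only 2–3 significant figures).

**Units.** The public API takes mm / mm³ / Hz; conversion to SI happens
once, inside `helmholtz_frequency`. Default speed of sound is
343 m s⁻¹ — dry air at 20 °C; the warm, humid air of a bird's airway is a
few percent faster, so the constant is overridable.

**Sensitivity analysis.** Opening diameter and neck length are hard to
measure on dried specimens and may be dynamically modulated in life.
`perturbation_analysis` recomputes the prediction over a grid of offsets
(±1 mm by default). Perturbations that make the diameter non-positive or
the neck negative are flagged invalid, never clamped — clamping would
silently fabricate geometry. The companion statistic
`mean_relative_parameter_change` expresses a fixed absolute error as a
mean percentage of the measured parameter (a 1 mm error is ~13–14% of a
typical opening diameter but ~70–77% of a typical neck length), and
`coefficient_of_variation` uses the sample (n−1) standard deviation.

**Tracheal tube.** For context the trachea is modelled as a stopped tube
(one open end), f_n = n·c/4L for odd n; a 14–18 cm duck trachea gives a
476–613 Hz fundamental, whose odd harmonics can coincide with bulla
predictions.

**Juvenile inversion.** `inverse_volume` solves the model for *V* at a
target frequency. With neck dimensions at half the adult mallard values,
a 4–5 kHz resonance (the band of the duckling second harmonic at one
month) implies a bulla volume of roughly 840–540 mm³.

## Spectral analysis of calls

All spectra are self-normalised to a 0 dB maximum: archive and laboratory
recordings carry no SPL calibration, and every downstream question is
about spectral shape. All dB-relative outputs are therefore invariant
under global gain.

- **Power spectra** are Welch-averaged periodograms (30 ms Hann windows,
  50% overlap — about 33 Hz resolution at 44.1 kHz).
- **Cepstral smoothing** lifters the dB spectrum in the quefrency domain
  (DCT), zeroing components above the cutoff quefrency 1/bandwidth:
  spectral ripple with period finer than the bandwidth (50 Hz by default)
  is removed, leaving the envelope. Only peak *positions* of smoothed
  spectra should be compared across software, since lifter shapes differ
  between implementations.
- **LPC envelopes** fit an all-pole model of order 2·n_peaks (default 60)
  by the autocorrelation/Levinson method after one-pole pre-emphasis
  (corner 50 Hz), then divide out the pre-emphasis response so the
  envelope describes the original signal. Below a few hundred Hz the
  de-tilted envelope carries a boundary artifact of up to ~15 dB (the
  all-pole fit cannot follow the pre-emphasis null at DC); call energy
  analysed here lies well above that region.
- **Fundamental estimation** is frame-wise normalised autocorrelation
  (25 ms frames, 10 ms hop, voicing threshold 0.45) over the central
  segment of the call (away from the frequency-modulated onset/offset).
  Among near-maximal autocorrelation lags the *shortest* local maximum is
  taken, which suppresses subharmonic octave errors; per-frame estimates
  more than 20% from their median are discarded before averaging. An
  unvoiced segment yields an explicit no-estimate (None), never 0.
- **Harmonic profiles** read the maximum level in bands k·FF ± 0.15·FF
  (k = 1, 2, 3) relative to the spectrum maximum; the fractional band
  tolerates the frequency modulation real calls show. With this reference
  the loudest harmonic sits at 0 dB and all values are ≤ 0.
- **Averaging** of call-type spectra is done in the dB domain by default
  (matching how combined spectra are plotted); power-domain averaging is
  a switch.
- **Peak detection** takes local maxima with ≥ 6 dB prominence, greedily
  pruned (loudest first) to a 200 Hz minimum separation.

## Resonance–peak matching

A prediction matches a call type when it falls within a tolerance
(500 and 1000 Hz by default — chosen to bracket the frequency shift a
±1 mm geometry error induces) of a detected spectral peak. Boundary
distances are inclusive; ties between equidistant peaks break toward the
lower frequency. A species counts as matched when *any* of its bullae
(left or right) matches *any* of its call types; a courtship-only mode
restricts the call types considered. A permutation utility estimates the
chance match rate by shuffling prediction–species assignments.

## Ontogeny

Per recording session (one bird, one age), the mean and n−1 standard
deviation of the fundamental and of each relative harmonic amplitude are
taken across the session's calls (nominally 15); a single-call session
flags its sd as NaN rather than 0. Trajectories average across birds per
age and sex; `sex_contrast` differences male minus female per shared age
with sds propagated in quadrature.

## Phylogenetic allometry

Independent contrasts follow the standard post-order pruning recursion:
daughter values are differenced and divided by √(t₁+t₂) of the adjusted
branch lengths, ancestral values are branch-length-weighted means, and
the ancestor's branch is extended by t₁t₂/(t₁+t₂). Contrast regression is
through the origin with R² about zero and a t-test on n−1 degrees of
freedom (n = number of contrasts). PGLS uses the Brownian covariance
(shared root-to-MRCA path length) with an intercept; its slope is
algebraically identical to the contrast slope on binary trees, which the
test-suite uses as a cross-check between the two independent
implementations. Polytomies are resolved to zero-length binary splits
(contrast values are unaffected). Traits default to log₁₀ scale — the
standard for allometry, making the slope the allometric exponent — with a
raw-scale option; the choice is recorded in the returned fit.

## Synthetic data

The generators emulate the study conditions with recoverable ground
truth:

- **Calls**: additive harmonic synthesis with a shared phase-continuous
  fundamental track (piecewise-linear, hat-shaped by default: 25%
  rise/fall around a plateau, 0.2 s, 44.1 kHz), per-harmonic gains in dB,
  and white Gaussian noise at a stated floor (−60 dB default).
- **Cohort**: 4 males + 4 females, 7 weekly sessions (days 4–46), 15
  calls per session; fundamental declines linearly from 3.4 kHz at day 4
  to 2.2 kHz at day 46 (so ~2.6 kHz at day 32, inside the observed
  2.2–2.7 kHz range); baseline harmonic gains 0/−25/−35 dB; males at day
  32 only get a +20 dB second-harmonic boost; per-bird (120 Hz) and
  per-call (40 Hz) frequency jitter and 1.5 dB gain jitter.
- **Specimens**: uniform geometry draws within the reference-table
  envelope, paired with their exact model resonances.
- **Planted-peak spectra**: Lorentzian bumps over a flat floor.
- **Trees and traits**: Kingman-coalescent random binary trees; Brownian
  x with y = slope·x plus an independent Brownian residual, so the
  contrast regression is unbiased for the planted slope.

Every generator is a pure function of its spec and seed. What passing
closed-loop tests show is that the analysis chain is self-consistent and
unbiased under the planted model; they do not certify performance on real
recordings, whose noise is coloured, whose calls overlap with background,
and whose harmonic structure is not exactly stationary.

## Numerical choices and limitations

- Tolerances: reference-table reproduction at 0.5% relative (printed
  input precision); inverse round trip at 1e−6 relative; PIC–PGLS
  equivalence at 1e−6 absolute.
- Problem sizes in the test-suite (100 seeded calls, 200 Brownian
  replicates on 16 tips, 50 random trees, the full 840-call default
  cohort) were chosen to make Monte-Carlo intervals tight enough to
  detect bias while keeping the suite fast.
- The model ignores bulla fenestrations, internal soft-tissue partitions
  and dynamic modulation of the opening, all of which would shift
  resonances in life.
- Whether observed 13/14/77/71% sensitivity figures refer to parameter-
  or frequency-space change is ambiguous in the source material for this
  kind of analysis; both are exposed (`mean_relative_parameter_change`
  for the former, `perturbation_analysis` for the latter).
- Species-level match counts on real archive audio depend on judgment
  about which call types to include; the matching module makes the rule
  explicit and configurable rather than reproducing any particular count.
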