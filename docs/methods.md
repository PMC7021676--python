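# Methods

This note documents the models, parameter choices and numerical
decisions behind `squeaktrace`, and what validation on the synthetic
generator does and does not establish about real recordings.

## Synthetic dyad generator

### Movement model

Each mouse follows a correlated random walk with speed and heading
modelled separately:

- **Speed** is an Ornstein–Uhlenbeck process on the 30 Hz frame clock:
  mean 8 cm/s, stationary SD 2 cm/s, relaxation time 180 s (reflected at
  zero). The long relaxation time is deliberate: it puts the SD of the
  167 ms post-emission acceleration statistic at ≈ 0.5 cm/s², the noise
  regime in which the response statistics have useful power at realistic
  event counts. Real mice modulate speed on faster timescales (published
  per-trajectory acceleration SDs are 1–3 cm/s²); the generator is
  smoother than life, which means power numbers measured here do not
  transfer to real data — only the *calibration* (type-I rate) and
  *unbiasedness* (kick recovery) properties do.
- **Heading** diffuses with SD 0.35 rad/frame and is steered toward the
  partner with gain `attraction_strength` (0–1, default 0.05; 0 gives
  statistically independent walks). Attraction can be delayed by
  `attraction_onset` seconds: the same-sex preset (onset 600 s) makes
  proximity — and therefore vocal output — develop late, the
  opposite-sex preset (onset 0) from the start. The two contexts differ
  only in parameter values, never in code paths.
- **Walls** reflect the *step direction* before the step is taken, so
  the step length — and hence the measured speed — is preserved at the
  boundary. (Reflecting the end position instead shortens steps near
  walls and injects ±1 cm/s² artifacts into the acceleration statistic.)

An earlier design applied attraction as an additive positional drift.
That couples attraction directly into the speed channel and makes
post-emission acceleration noise an order of magnitude larger; steering
decouples the two, which is why it was chosen.

### Emission model

Each mouse emits per frame with probability `emission_hazard_near`
(default 0.005) when the pair is closer than `near_threshold` (20 cm)
and `emission_hazard_far` (10⁻⁴) otherwise — a minimal encoding of the
empirical fact that mice vocalize almost exclusively near conspecifics.
The emitted call is a frequency-modulated chirp: duration 30–80 ms,
onset frequency 45–90 kHz, sweep up to ±25 kHz clipped to 32–108 kHz,
placed at the vocalizer's nose (centroid + 3 cm along heading).

### Audio

Calls are rendered by integrating the contour's instantaneous frequency
to a phase function, delaying each microphone by distance / 343 m/s
(fractional-sample, via the continuous phase), scaling by 1/r, and
adding independent Gaussian noise per channel. The stated SNR is tone
RMS over noise RMS at a 40 cm reference distance (roughly arena centre
to a perimeter microphone); received SNR varies ±6 dB with geometry.
The default microphone layout is 8 positions on the arena perimeter
(corners + edge midpoints) at 25 cm height; any non-degenerate layout
works. No reverberation, directivity or body occlusion is modelled —
localization accuracy on synthetic audio is therefore an upper bound.

### Response kick

`inject_response_kick` raises the receiver's speed by
`kick_magnitude/frame_rate` per frame for `kick_window` frames after
each emission (constant acceleration `kick_magnitude` over the window —
the quantity the acceleration estimator reads out exactly on a
constant-speed track), then relaxes linearly back over another window.
Kicks superpose additively; positions are re-integrated along the
original step directions so tracks stay kinematically consistent.
The relaxation phase deposits a small negative acceleration in the
10 frames after the window; at the default event rates this biases the
recovered kick by < 5%.

## Segmentation

Thomson's harmonic F-test with K = 5 Slepian tapers (NW = 3) against
F(2, 2K−2) at α = 0.05, repeated at NFFT 64/128/256 with 50% hop.
Numerical details:

- **Channel combination is a vote, not an OR.** At α = 0.05 per pixel,
  OR-ing 8 channels × 3 NFFTs yields ~70% noise-pixel density, which the
  11 × 15 box dilation turns into a fully active raster — the 1500-pixel
  rule stops meaning anything. A pixel therefore survives only when
  ≥ `min_channels` (default 5 of 8) channels detect it. True calls reach
  all microphones, so sensitivity is essentially unaffected while the
  voted false-alarm rate drops to ~5 × 10⁻⁵ per pixel.
- The vote runs on each NFFT's **native raster first**; the voted mask
  is then resampled to the common raster (that of NFFT 64: finest time,
  coarsest frequency) and OR-combined across NFFTs. Resampling uses
  interval max-pooling (each target bin collects every source bin within
  half a target step, and at least its nearest source bin) — plain
  nearest-neighbour gathering skips alternate rows when downsampling in
  frequency and cuts signals in half whenever the NFFT-64 test drops out
  at a half-bin crossing.
- The box convolution (binary dilation, 11 pixels in frequency × 15 in
  time) exists to bridge small gaps. Component size for the 1500-pixel
  rule is measured on the dilated mask; **timing and contours are read
  from the pre-dilation support**, so the box does not time-stretch
  calls.
- Contours are power-weighted mean frequencies per time column of the
  mean multitaper spectrogram. When two signals overlap ≥ 50% in time
  and one contour lies within ±10% of an integer multiple (≥ 2×) of the
  other, the higher one is dropped as a harmonic.

## Localization and MPI

All 28 pairwise delays are measured once per signal (generalized
cross-correlation on the bandpass-filtered signal segment, parabolic
sub-sample interpolation); each of the 8 leave-one-microphone-out
estimates solves a least-squares TDOA problem on the 21 pairs excluding
that microphone (2 cm coarse grid + Nelder-Mead refinement, clipped to
the arena; source height fixed at the floor). The probability density is
a bivariate Gaussian with the jackknife mean and the sample covariance
of the 8 estimates + 0.25 cm² on the diagonal (so 8 identical estimates
still yield a proper density), evaluated on a 0.5 cm grid, normalized
over the arena and floored at 10⁻¹² cm⁻² so the MPI denominator never
vanishes. The density form is isolated behind `build_density` and can
be swapped (e.g. for a kernel density over the 9 points). Assignment
requires max MPI ≥ 0.95; unassigned signals are excluded from all
downstream statistics.

## Response statistics

- Speed is centroid displacement × 30 Hz; undefined at frame 0 and at
  masked frames (windows touching undefined speeds are dropped and
  counted in the QC log).
- The 200 ms matching window is the 6 samples e−5 … e (the time up to
  and including emission); the acceleration window is the 5 speed
  differences over e … e+5. The acceleration telescopes to
  (v[e+5] − v[e]) × 30 / 5.
- Matching is greedy in chronological order with single-use controls;
  costs within 10⁻⁹ cm/s count as ties, broken by the earliest window
  start (this also makes the tie-break robust to float summation order).
  A globally optimal assignment could replace the greedy rule behind the
  same interface; the greedy rule is what the sequential description of
  the procedure implies.
- Relative-speed ties (vocalizer speed exactly equals receiver speed)
  classify as "slower" — measure-zero on real data, deterministic on
  synthetic.
- The control pool is not proximity-filtered (the 20 cm rule applies to
  signals only); a filtered pool is available behind a switch.
- The subsampling guard draws m = ⌈0.25 n⌉ pairs (or a caller-supplied
  size-matched m) 1000 times; p is twice the smaller tail fraction of
  the subsample means around zero, clipped to 1. In the epoch analysis a
  stratum counts as confirmed only when both the paired t-test and the
  subsampling null agree — under the null this happens at well below α,
  which is what makes the three-epoch specificity check reliable.
- Epoch bins are half-open [0, 10), [10, 20), [20, 30] minutes;
  recordings shorter than 30 minutes get proportional bins with a
  warning. Epoch controls are restricted to windows entirely inside the
  trajectory's epoch, and only temporally isolated signals (no other
  signal within 367 ms from either mouse) enter the epoch analysis.

## Validation problem sizes

The test suite validates the statistical guarantees at these scales
(chosen to give comfortable Monte-Carlo margins):

- attribution recovery: 100 events, mice ≥ 20 cm apart, 1 cm jackknife
  scatter — measured accuracy ≈ 100% of assigned signals;
- type-I calibration: 200 four-minute recordings without kick, all
  testable strata pooled (~650 paired t-tests) — measured ≈ 6%
  significant at α = 0.05, within the 2–9% acceptance band;
- kick recovery: 20-minute recordings, isolated signals only (~590
  matched pairs), kicks 0.5/1.0/2.0 cm/s² — recovered within 4%;
- epoch specificity: 20 thirty-minute recordings, kick confined to
  vocalizer-1 signals in minutes 0–10 — confirmed in epoch 1 and
  nowhere else in ≥ 18/20 seeds;
- segmentation: 14 chirps of 30–60 ms at 20 dB SNR in 8 s of audio —
  recall and precision ≥ 0.9; F-test false-alarm rate on pure noise
  within [0.03, 0.07] at α = 0.05.

## Known limitations

- The generator's speed process is smoother than real mouse locomotion
  (see above); passing power/recovery tests here says the estimator is
  unbiased and calibrated, not that any given real effect size is
  detectable.
- Localization assumes free-field propagation and a planar source; no
  reverberation, occlusion by the partner's body, or microphone
  directivity.
- The MPI machinery generalizes to M > 2 mice but is exercised only for
  dyads.
- Harmonic suppression uses contour ratios only; calls with strong
  subharmonics or noisy contours may evade it.
- In-vivo quantities (half-emission latencies, emission-distance
  medians, acceleration tables) are report formats here: the synthetic
  checks are directional, not numerical reproductions.
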