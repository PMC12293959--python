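# Methods

This note documents the models, estimators, parameter choices and known
limitations behind `betadyn`.

## Signal model and preprocessing

The pipeline operates on single-channel, artifact-cleaned recordings
sampled at 1 kHz (one MEG-like and one EMG-like channel per subject). All
analysis starts with a zero-phase frequency-domain band-pass to the beta
range: the transfer function is real, unity between 13 and 30 Hz, with
raised-cosine flanks of 2 Hz width centred on each band edge (half gain at
the edge itself). The 13–30 Hz cutoffs are the standard beta-band
definition; the flank width is a package choice — narrow enough to keep the 13–30 Hz passband intact on
10 s windows, wide enough to avoid ringing. Records are odd-reflection
padded to the FFT length before filtering: odd reflection keeps the value
and the first derivative continuous at the seams, which reduces circular
wrap-around leakage to below 10⁻⁴ in amplitude (an even reflection or zero
extension leaks ≈ 1% of a stopband tone into the passband). The low-pass
used for envelope normalization reuses the same machinery with a 0.1 Hz
cutoff and 0.05 Hz flank, padded on its own time scale (1/cutoff seconds).

Filtering is always applied to the full recording and only then segmented
into contiguous, non-overlapping 10 s windows (trailing remainder
discarded); per-window filtering would create 2×N window-edge transients.

## Delay embedding

Per window (the default; a shared-embedding mode exists), the delay τ is
the first strict local minimum of the average mutual information between
the series and its lagged copy, estimated with equal-width 16-bin
histograms (deterministic, no kernel bandwidths). Histogram AMI of strongly
periodic signals ripples through binning artifacts, so minimum detection
runs on a 5-sample moving average of the curve; if no minimum exists —
common for narrowband signals — the first lag where AMI drops below
AMI(0)/e is used, and as a last resort the maximum lag (flagged). The
embedding dimension m is the smallest dimension whose false-nearest-
neighbour fraction falls to ≤ 1%, with the canonical Kennel tolerances
(distance-ratio 15, attractor-size 2, Theiler exclusion = τ); if the
fraction never falls below threshold — expected for stochastic signals —
m_max (default 10) is used and flagged. For long series the FNN fraction
is estimated from 2000 evenly strided anchor points; the neighbour search
itself always covers every point, so only the Monte-Carlo resolution of
the fraction is reduced, not the neighbour structure.

## Lyapunov exponent (Rosenstein)

For every anchor point the nearest neighbour outside a Theiler window is
found; the divergence curve is the mean log distance between pairs after k
steps, restricted to pairs that can be followed over the whole fit span.
The Theiler window and the fit span both default to the window's mean
period (sampling rate divided by the power-weighted mean frequency),
following Rosenstein's recommendation. The exponent is the least-squares
slope over the most linear contiguous region of the curve — the span
(≥ ⅓ of the points) whose local finite-difference slopes have the smallest
standard deviation — times the sampling rate, giving units of 1/s. Region
selection matters: the first ~0.5 mean periods of the curve hold a steep
neighbour-realignment transient, and fitting from k = 0 would overestimate
the exponent by ~30% on the Lorenz benchmark; the plateau criterion brings
the 20 000-sample estimate to within ~12% of the Benettin tangent-space
value. For
non-chaotic inputs the curve has no exponential regime: a periodic orbit
yields slope ≈ 0, and iid noise yields a flat noisy plateau whose poor
linear fit (R² ≪ 1) is recorded in the diagnostics.

## Higuchi fractal dimension

Computed on the scalar window directly (the construction is defined for
scalar series, not embedded trajectories). Curve lengths L(k) are averaged
over the k offsets for k = 1…16; k_max = 16 sits on the standard stability
plateau for 10⁴-sample windows and is configurable. FD is the slope of
log L(k) vs log(1/k); values outside [1, 2] are kept but flagged. On
exact-covariance fractional Brownian motion the estimator reproduces the
theoretical FD = 2 − H to within 0.01–0.05 across H ∈ {0.3, 0.5, 0.7}.

## Correlation dimension (Grassberger–Procaccia)

Trajectories longer than `max_points` (default 2000) are thinned with an
even stride, keeping original time indices so the Theiler exclusion
(default: the window's mean period) stays exact. The correlation sum is
exact (sorted pairwise distances, no binning) on 24 log-spaced radii
between the 0.1th and 20th percentile of admissible pair distances. The
percentile band is a deliberate small-radius choice: the power law
C(r) ∝ r^ν holds well below the attractor diameter, while the large-radius
shoulder curves over smoothly and — having deceptively high linear-fit R² —
would bias any fit that includes it (on the Lorenz benchmark, a 1st–50th
percentile band underestimates ν by ≈ 0.4). Within the grid, the scaling
region is again the local-slope plateau (minimum slope spread, ≥ ⅓ of the
radii), and the dimension is the least-squares slope over it. With 4000
points the embedded Lorenz attractor gives ν ≈ 2.01 against 2.04 from a
brute-force correlation sum on the full 3-D state.

## Burstiness and envelope correlation

The analytic envelope (Hilbert transform of the band-passed record) is
divided by its 0.1 Hz low-passed version, isolating relative amplitude
fluctuations; burstiness is the coefficient of variation of this
normalized envelope over the whole recording (one value per
subject/modality), and cross-modal similarity is the Pearson correlation
of the two normalized envelopes. The first and last 0.5 s are trimmed
before both statistics (Hilbert edge region). For unmodulated Gaussian
narrowband noise the envelope is Rayleigh and CV → √(4/π − 1) ≈ 0.523,
the floor against which burst-driven CV increases are read. Envelope
statistics are computed on the full concatenated record rather than per
window, matching the per-subject definition of the burstiness statistic.

## Surrogates

Surrogates preserve the discrete-Fourier amplitude spectrum exactly and
draw positive-frequency phases iid uniform; DC and (even length) Nyquist
bins are untouched, so the output is real with the original mean. They are
generated from the raw full-length record and pushed through the identical
band-pass → segment → feature chain ("normalized to match the
preprocessing"), then reduced per record as mean over windows and mean
over realizations (default 100). A record is flagged when estimators fail
on > 10% of surrogate windows. On linear-Gaussian AR(2) cohorts the paired
original-vs-surrogate-mean t-test rejects at the nominal 5% rate (within
the 95% binomial band over 200 simulated cohorts of n = 17); on bursty
signals phase randomization destroys burst clustering, lowering the
surrogate envelope CV and correlation dimension relative to the original.

## Group statistics

All tests are two-sided at α = 0.05; no multiple-testing correction is
applied by default (a Holm option exists, off by default; outputs label raw
p-values). Paired comparisons report t, df = n − 1, p, Cohen's
d = mean(Δ)/SD(Δ) (so |t| = |d|√n), and post hoc power from the exact
noncentral t distribution (df = n − 1, noncentrality |d|√n) — at n = 17
this reproduces the textbook values, e.g. power 0.327 at d = 0.39 and
> 0.999 at d = 1.98; the normal approximation would not. Stability over
time is summarized per subject as the SD and mean of each feature across
windows, with a paired cross-modal test on the per-subject SDs.

## Synthetic data

The generators define the study conditions for all tests:

- **Lorenz / Rössler** — fixed-step RK4 (dt = 0.01 resp. 0.05), 10 resp.
  50 model-time-units of transient discarded; fixed-step integration keeps
  trajectories bit-reproducible across platforms, unlike adaptive solvers.
- **Fractional Brownian motion** — circulant-embedding (Davies–Harte)
  synthesis of fractional Gaussian noise, cumulatively summed: the
  increment covariance is exact, so FD = 2 − H holds without synthesis
  bias.
- **AR(2) linear null** — complex poles at radius 0.95 and angle 2π·20/fs,
  i.e. a beta-band-like resonance near 20 Hz with purely linear-Gaussian
  dynamics; used for surrogate type-I-error calibration.
- **bursty_beta** — per channel, a unit-variance 13–30 Hz Gaussian carrier
  multiplied by an envelope 1 + Σᵢ aᵢ·gauss(t − tᵢ; FWHM 150 ms), with
  Poisson burst times (default 1 burst/s) and Gamma(2, scale) amplitudes
  (default scale 1), plus additive white noise (SD 0.1). Channel envelopes
  mix an independent and a shared component,
  e_ch = (1 − ρ_sh)·e_indep + ρ_sh·e_shared, so the planted shared
  fraction ρ_sh controls the expected cross-modal envelope correlation.
  The burst rate, width and amplitude defaults are literature-motivated
  values for sensorimotor beta bursts (≈ 3-cycle events, of order one per
  second, a few times the background amplitude); they are parameters, not
  fitted constants. All randomness in a spec flows from one integer seed
  through `SeedSequence` children, one per stream, so paired channels are
  independently seeded yet jointly reproducible.

What the generator does *not* emulate: volume conduction and sensor
geometry, motor-unit action potential shapes and their rate coding,
non-Gaussian background spectra (1/f), nonstationary task effects, or any
true nonlinear deterministic dynamics in the carriers. Passing tests on
these cohorts therefore demonstrates that the pipeline recovers planted
amplitude-envelope structure and calibrates correctly against linear
nulls — not that real MEG/EMG signals are low-dimensional or chaotic.
Measured envelope correlations are attenuated relative to ρ_sh because
each channel's Rayleigh carrier fluctuations are independent (ρ_sh = 1
yields r ≈ 0.46 under default burst strength), mirroring how measurement
noise attenuates envelope coupling in real recordings.

## Numerical and design choices

- Estimation is deterministic end to end: histogram AMI, strided (not
  random) subsampling in FNN/LE/CD, and seeded surrogate streams; reruns
  of the pipeline are byte-identical.
- Degenerate inputs raise typed errors rather than returning NaN: constant
  windows (zero entropy / zero curve length), zero-variance differences in
  t-tests, all pairs Theiler-excluded, non-positive normalization
  envelopes. The pipeline excludes failing windows and logs the reason.
- Per-subject reductions are plain means over windows; windows are never
  overlapped.
- Embedding parameters are estimated per window by default because
  features are reported per window; a per-record mode
  (`per_window_embedding = false`) exists for speed and cross-window
  comparability.
- Problem sizes in the test suite and acceptance script are scaled to a
  single CPU: 20 000-sample Lorenz trajectories, 10 000-sample fBm, 40 s
  envelope-recovery records (20 seeds per condition), 8 s AR(2) records
  with 16 surrogates across 200 cohorts, and a 3-subject × 60 s cohort for
  the byte-identity rerun. The estimators themselves carry no built-in
  size limits beyond `max_points`/`max_anchors`.

## Known limitations

- The Lyapunov and correlation-dimension estimators presuppose a
  deterministic attractor; on stochastic signals they return descriptive
  statistics of neighbour divergence and pair scaling, not invariants, and
  the embedding dimension saturates at m_max (flagged).
- Scaling-region selection is automatic and reproducible but not
  infallible; the fit R², region bounds and point counts are always
  emitted so downstream users can filter on fit quality.
- FD is computed on scalar windows only; Higuchi's construction does not
  extend to embedded trajectories.
- Native EDF/FIF readers, overlapping windows, amplitude-adjusted (IAAFT)
  surrogates and burst *detection* (threshold crossing, duration
  statistics) are out of scope.
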