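# Methods

This note documents the models, estimators and numerical choices behind
`resteeg`, what the synthetic generator does and does not emulate, and the
known limitations. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Preprocessing chain

The chain is fully automated; every stage is a pure function of the
recording and a `ParamSet`, and the whole chain is deterministic given
`ParamSet.seed`.

**Line-noise removal.** The line frequency (from the BIDS sidecar) and its
harmonics below 0.95×Nyquist are estimated by least squares in sliding 2-s
Hann windows and subtracted with overlap-add, so amplitude and phase may
drift. Each (window, channel, harmonic) subtraction is gated by an F-test at
p = 1e-4: on line-free data the regression would otherwise remove
noise-level energy at the line frequency (~2–6 % RMS). Unlike a band-stop
filter, nothing is removed at neighbouring frequencies.

**Filtering.** All filters are linear-phase Hamming-window FIRs applied once
with the group delay compensated (reflect padding at the edges). Order
follows the Hamming rule `numtaps ≈ 3.3/(transition/fs)`. The high-pass has
its transition band at 0.25–0.75 Hz (−6 dB at 0.5 Hz) and an exact null
imposed at DC.

**Bad channels.** Three criteria over the EEG channels:

- *flat*: absolute successive difference < 1e-8 µV over a contiguous run
  longer than 5 s. This is evaluated on the **unfiltered** signal: any FIR
  stage smears neighbouring activity into a flat span (the high-pass kernel
  is ~6.6 s long), so exact flatness only survives on the signal as
  recorded — the same ordering the established EEGLAB chain uses.
- *noisy*: noise-to-signal ratio defined as std(component above 40 Hz) /
  std(component below 40 Hz), robust z-scored across channels
  (median / 1.4826·MAD), flagged above 4. The >40 Hz split and the robust
  estimator are this package's choices; only the criterion and the threshold
  are prescribed.
- *unpredictable*: in 5-s windows, the channel is predicted by
  spherical-spline interpolation from 50 random subsets of 25 % of the other
  channels; a window counts as predictable if the best subset correlates
  ≥ 0.8, and the channel is flagged if fewer than 80 % of windows are
  predictable. Window length, subset count and cutoff are package choices.
  The criterion is skipped when electrode positions are unavailable.

Fewer than 8 surviving channels is an error (the prediction criterion is
meaningless below that).

**ICA.** FastICA (scikit-learn) with the component count set to the
numerical rank of the data (channels − 1 after average reference), seeded
per repetition as `seed + r`. Formal convergence of the parallel FastICA
update routinely fails on rank-deficient EEG-like data because the
near-Gaussian background subspace has no identifiable rotation, while the
non-Gaussian artifact components stabilize long before; the decomposition
therefore records `converged` instead of aborting (a `strict=True` mode
raises). Determinism for a fixed seed holds either way.

**IC classification.** A heuristic scorer stands behind the same 7-class
probability interface a trained classifier would use. Evidence per class:
correlation with EOG channels and frontal <3 Hz dominance (Eye); positive
20–45 Hz log-spectral slope with high-frequency dominance (Muscle);
line-frequency bin dominance (Line Noise); kurtosis of the channel loadings
(Channel Noise); ~1 Hz periodic autocorrelation (Heart); a 6–30 Hz peak over
the 1/f fit, gated on the spectrum not being low-frequency dominated
(Brain); a constant 0.15 residual (Other). Scores are normalized to a
probability vector. The scorer is a documented stand-in: it is tuned to the
archetypes the simulator produces, not to the full variety of real EEG, and
any external classifier with the same interface can be plugged in. Only
components with P(Muscle) or P(Eye) > 0.8 are subtracted.

**Interpolation.** Spherical splines (stiffness m = 4, 50 Legendre terms,
1e-5 diagonal regularization, bordered system with a constant term) on the
best-fit sphere of the electrode cloud. Restores the original channel count
and order.

**Bad segments (ASR-style, removal mode).** Calibration: per-channel RMS in
1-s windows (50 % overlap) is robust z-scored across windows; a window
enters the calibration set iff fewer than 7.5 % of channels have z > 5.5;
error if < 5 s survives. The calibration model is the principal axes and
per-axis variances of the kept data, with the null subspace (relative
eigenvalue < 1e-7) excluded — after average referencing and interpolation
the data are rank deficient, and "deviation" along zero-variance axes is
numerical noise. Detection: sliding 0.5-s windows (0.25 s hop) are flagged
when the variance along any retained axis exceeds 20× the calibration
variance. Window lengths are package choices; the thresholds 7.5 % / 5.5 /
20 are the published defaults.

**Stabilization.** Stages 4–6 are repeated `n_ica_repetitions` (default 10)
times; the repetition whose bad-sample mask has the smallest L1 distance to
the per-sample mean mask wins (ties: lowest index). The selected
repetition's cleaned continuous data has its bad intervals excised, with a
boundary inserted at every cut.

**Epoching.** 2-s epochs, 50 % overlap, half-open sample intervals
`[start, start+L)`; an epoch is dropped iff a boundary lies strictly inside
`(start, end)`. A boundary exactly at an epoch start is fine — the epoch
begins a new continuous segment.

## Features

**Spectra.** DPSS multitapers with time–bandwidth NW = 2 on the 2-s epoch
(±1 Hz smoothing), i.e. 3 tapers, averaged over tapers, epochs and channels,
on 1–100 Hz. Epochs are zero-padded to `pad_to_s`. The published description
pads to 5 s yet quotes 0.1 Hz resolution (arithmetically 1/5 s = 0.2 Hz);
this package honors the stated 0.1 Hz grid with `pad_to_s = 10` by default —
the band edges 7.9/12.9/30.1 Hz are then exact grid points — and exposes the
parameter. Band membership is closed on both ends with a 1e-9 Hz tolerance.

**APF.** Peak maximum = highest strict interior local maximum of the global
spectrum in 8–12.9 Hz; absent (None) when the alpha range is monotone.
Center of gravity = power-weighted mean frequency over the closed band;
zero alpha power is an error.

**Source model and lead field.** The packaged atlas
(`data/atlas100_7networks_synthetic.tsv`) is a **synthetic stand-in** for a
100-parcel/7-network cortical parcellation: 100 quasi-uniform
Fibonacci-lattice points on a 0.07 m cortical shell (cap z > −0.25 of the
sphere), deterministically assigned to 7 network labels in
anterior–posterior bands, left/right-labelled by x-sign. It has the correct
interface and plausible geometry but no anatomical validity; any TSV with
columns `roi_index, roi_name, network, x, y, z` (meters, head RAS) replaces
it. The forward model is an analytic concentric three-shell sphere (relative
radii 0.87/0.92/1.00 fitted to the electrode cloud, conductivities
0.33/0.0042/0.33 S/m, 60 spherical-harmonic terms) solved per degree by
matching potential and radial current at the interfaces with a zero-flux
outer boundary; the free-medium special case is validated against the exact
dipole formula in the tests. A user lead-field HDF5 (`leadfield`,
(ROI × channel × 3), `channel_names` attribute) is accepted for realistic
geometry.

**LCMV.** Per band: covariance of band-passed epochs, regularized as
`C + 0.05·(tr C / n_ch)·I` (5 % of the mean sensor eigenvalue — the common
array-gain convention; the source description says only "5 %
regularization"). Free-orientation filter `W₃ = (LᵀC⁻¹L)⁻¹LᵀC⁻¹`; the
orientation is the dominant eigenvector of `W₃CW₃ᵀ` (maximum variance),
sign-fixed by making its first nonzero component positive; the final filter
is renormalized to exact unit gain along that orientation (unit-gain rather
than unit-noise-gain — the choice is documented, not prescribed).

**dwPLI.** Epochs are the observations (single taper per epoch at the
native 0.5 Hz resolution of a 2-s epoch). Band bins are the multiples of
0.5 Hz inside the closed interval, so alpha uses 8.0…12.5 Hz (12.9 is not
representable on that grid — a documented quantization). Negative debiased
values are retained; thresholding happens downstream, where they simply rank
below all positive connections.

**AEC.** Per epoch, the analytic signal is computed after a 10 % cosine
(Tukey) edge taper to limit Hilbert edge artifacts. Orthogonalization is
per pair and direction; a residual whose variance is negligible relative to
the reference envelope (scaled copies — pure zero-lag mixtures) yields 0.
Pairwise products are accumulated in float32 for speed; correlations are
reduced in float64.

**Graphs.** Proportional threshold keeps the top `ceil(density·P)` of the
P = n(n−1)/2 pairs by value, ties broken by (row, col) order. Efficiency
uses unweighted BFS distances with unreachable pairs contributing 0.
Smallworldness is Humphries–Gurney σ with C from all nodes and L from the
largest connected component (which must cover ≥ 90 % of nodes); the null
model is 10 degree-preserving edge-swap graphs (20·|E| attempted swaps,
seeded).

**Cluster permutation test.** Two-tailed, per-bin t statistics, cluster
threshold p < 0.05 on the t distribution, clusters = maximal sign-consistent
runs of adjacent bins, cluster statistic = summed t, null = max |cluster
sum| over sign-flip (paired) or label (unpaired) permutations, Monte-Carlo
p = (b+1)/(n+1) — the floor with 500 randomizations is 1/501 ≈ 0.002.

**JZS Bayes factor.** Two-sided, Cauchy prior on the standardized effect
with scale √2/2, computed by adaptive quadrature over the g-mixture
representation; the tests cross-check it against an independent fine-grid
integration over the effect size and against `pingouin`. The mass-univariate
driver (`group_stats.bf_matrix`, CLI `resteeg group`) loops the test over
the 4950 unordered ROI pairs.

## The synthetic generator

`simulate_recording` builds band-limited stochastic oscillators (FIR
band-passed Gaussian noise — peaks have realistic width set by `bandwidth_hz`)
at atlas ROI centroids with radial orientation, projects them through the
three-shell model (patterns normalized so `amplitude_uv` is the RMS
contribution at the best electrode), and adds (a) a spatially correlated 1/f
background — 40 random interior dipoles carrying 1/f^1-shaped noise, scaled
to `background_1f_uv` median channel RMS — and (b) independent white sensor
noise. Phase-lag coupling shares a Hilbert-shifted carrier; envelope
coupling multiplies both carriers by a shared log-normal modulator
(`exp(unit-variance low-passed noise)`), an operating point chosen so that
strength 1 produces orthogonalized AEC ≈ 0.5 at high SNR. Defaults describe
a plausible adult resting recording: 2 min, 40 standard 10-10 channels +
VEOG at 250 Hz, a 6 µV 10 Hz occipital source, a 2 µV 6 Hz frontal source,
3 µV background, 1 µV sensor noise.

Artifacts are injected afterwards and logged with realized sample ranges:
flat spans (zeroed), noisy channels (+10× median-RMS white noise), 0.5-s
Hanning² blinks (120 µV, frontal-weighted topography, mirrored on VEOG),
line noise (per-channel amplitudes 0.5–1× the configured level), and 500 µV
broadband bursts across all EEG channels.

`make_paired_dataset` emulates the eyes-closed/eyes-open contrast: per
subject two recordings identical except every alpha-band source amplitude is
scaled by `alpha_ratio` in the EO condition. Its default world is one
broadband alpha source spanning 8–12.9 Hz (center 10.45 Hz, bandwidth
4.9 Hz) plus a condition-independent theta source, 60 s per recording.
Because the two conditions share the subject's seed, the paired difference
is noise-free by construction — the test's power is limited only by
between-subject variability, which is what the emulation is meant to
exercise.

**What the generator does not emulate** — hence what a green test does and
does not establish: no biophysical neural-mass dynamics, no real electrode
noise spectra or impedance drift, no muscle/EMG artifacts (the Muscle
heuristic is exercised only weakly), no heartbeat artifact, no real head
geometry (the forward model is the same sphere used in reconstruction, so
source-recovery tests validate the estimator, not robustness to
forward-model mismatch), and no inter-channel correlated amplifier noise.
Detector scores (sensitivity/false positives) are statements about these
synthetic archetypes.

## Numerical choices and degenerate inputs

- Sample indexing is 0-based; all segment intervals half-open.
- Resampling is polyphase with the rate ratio as an exact fraction; events
  and boundaries are remapped proportionally (round to nearest).
- BrainVision I/O uses IEEE float32 multiplexed binary (lossless at the
  container's precision); EDF reading applies the physical/digital scaling
  per signal; unsupported formats are rejected with a clear message.
- Electrode coordinates: head RAS in meters; BIDS `coordsystem.json` units
  are converted, the CTF/ALS axis convention is rigidly rotated to RAS, and
  any other coordinate system is an error.
- The ASR calibration drops eigen-axes below 1e-7 of the largest eigenvalue.
- `binarize_proportional` rejects an all-equal matrix (threshold undefined);
  `smallworldness` rejects graphs whose largest component covers < 90 % of
  nodes and uses seeded rewiring for reproducibility.
- Zero-variance envelopes (AEC) give entry 0; a dwPLI bin with zero
  denominator gives 0 for that bin.

## Limitations

- The IC classifier is a heuristic; its probabilities are calibrated only in
  the ordinal sense needed for the > 0.8 rejection rule on clear artifacts.
- The spherical forward model ignores real head shape; absolute source
  localization accuracy is not a goal, ROI-level recovery is.
- The packaged atlas is synthetic (above); analyses that depend on true
  anatomical centroid positions must supply a real centroid table.
- Only BrainVision and EDF are read, and only continuous (non-ERP) epoching
  is supported.
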