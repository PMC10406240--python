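# Methods

This note records the models, numerical choices and limitations behind
`eegalign`, in the spirit of the methods documentation of packages such as
statsmodels or msprime. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Spectral estimation and iCOH

Cross-spectra are estimated per trial with a single Hann taper and averaged
across trials:
S_ij(f) = ⟨ X_i(f) X_j(f)* ⟩_trials, with X the tapered FFT. Coherency is
COH_ij(f) = S_ij(f) / √(S_ii(f) S_jj(f)) and band iCOH is the mean of
|Im COH_ij(f)| over the grid bins inside the band (closed interval).

Numerical choices:

* **Frequency grid.** Trials are zero-padded to the smallest multiple of
  fs/Δf samples at or above the trial length, and the finer grid subsampled
  back, so the grid step is *exactly* Δf (default 0.5 Hz). fs/Δf must be an
  integer; other combinations are rejected rather than silently approximated.
* **Bands.** delta 0.1–4 Hz, theta 4–7 Hz, alpha 7–13 Hz, beta 13–30 Hz.
  Band membership is closed-interval on grid bins, so on a 0.5 Hz grid the
  delta average effectively runs over the 8 bins 0.5…4.0 Hz.
* **Minimum trials.** Coherency from a single trial and taper has magnitude
  identically 1 (a degenerate estimate), so at least two trials are
  required. No multitaper smoothing is applied beyond trial averaging; with
  n independent estimates the |COH| noise floor scales as 1/√n, which the
  tests use as a bound.
* **Excluded bins.** Bins where any autospectrum is zero have undefined
  coherency; they are set to NaN with a warning and dropped from band means.
* **Correlation measure.** Band-limited Pearson correlation uses a
  zero-phase forward–backward 4th-order Butterworth band-pass (no artificial
  lag is introduced), a per-trial coefficient, the across-trial mean, and
  finally the absolute value. Taking |r| keeps the matrix nonnegative so the
  Perron–Frobenius argument behind the eigenvector ranks still applies; the
  sign convention is deliberate and documented here.

## Eigenvector alignment

For a symmetric connectivity matrix W, channels are embedded with the
eigenvectors at (1-based) ranks 2–4 of the algebraically-descending
eigenvalue ordering; channel i sits at (v2[i], v3[i], v4[i]) and the
alignment angle is θ_ij = arccos of the clamped normalised dot product, in
degrees. Rank 1 is the dominant eigenvector — for nonnegative W the
Perron–Frobenius vector, single-signed and unable to express division — and
is excluded by default. Ordering by descending magnitude is available as an
option for inputs that are not elementwise nonnegative.

* **Tie-breaking.** Eigenvector sign is fixed (first significant loading
  positive) and, within numerically degenerate eigenvalue groups, the
  orthonormal basis columns are ordered lexicographically by rounded
  loadings, so repeated runs and equivalent inputs give identical output.
  Degeneracy is real in idealised inputs (e.g. a complete graph, or exact
  equal-block matrices); results there depend on this documented convention.
  Notably, for an exact 3-block equal-weight matrix the 4th eigenvalue
  already belongs to the large degenerate "bulk" eigenspace, so community
  structure lives entirely in ranks 2–3; the community-recovery tests use
  ranks (2, 3) for the noise-free case.
* **Degenerate rows.** Embedding rows with near-zero norm have no direction;
  their angles are flagged NaN (never silently zeroed) and excluded jointly
  from downstream testing and ΔEA. An all-zero embedding raises.
* **Angles are in degrees**, matching the scale on which ΔEA values are
  reported.

## Null models and inference

A null model is a value-preserving randomisation of one subject's matrix:
the upper-triangle entries are permuted uniformly and mirrored, so the
multiset of connectivity values is preserved exactly while their arrangement
is destroyed. An ensemble (default 1000) cycles round-robin through the
group's subjects so each subject's value distribution is represented equally
(within one). Alignment matrices are computed for every null with the same
eigenvector ranks as the subjects.

Per channel pair, the subjects' angles (one per subject) are compared with
the null angles by Welch's unequal-variance t-test (the Behrens–Fisher
setting: the null sample is far larger and tighter than the subject sample).
Two-sided p-values are converted to Benjamini–Hochberg q-values within the
family of all testable pairs of that band/measure (pairs with undefined
angles are dropped from the family rather than diluting it); discoveries are
q < 0.05. Direction is labelled post hoc: "increased" alignment = subject
angles smaller than null, "decreased" = larger. Zero-variance degeneracies
are handled explicitly (equal means → p = 1; unequal → p = 0 with a
warning).

Nulls are built per band and per measure, not shared. A pair is
**consistent** when significant with the same direction in at least 3 of
the 4 bands; mixed directions never count. Artificially expanded cohorts
(each subject duplicated) inflate n and hence significance; the expansion
flag is carried through every report and marks results as illustrative.

## Robustness (ΔEA)

iCOH erases instantaneous coupling, so the lowest iCOH entries are the ones
most likely to misrepresent true connectivity. The robustness experiments
either erase the k lowest-reference-iCOH pairs from a correlation matrix or
set the k lowest pairs of an iCOH matrix to its maximum entry, recompute the
alignment, and report ΔEA = mean |θ_altered − θ_original| over defined
pairs. k = round(percent · n_pairs / 100) with half-away-from-zero rounding;
ties among equal reference values break by (row, column) index. Both
alteration modes preserve symmetry and change exactly 2k directional
entries.

## Distance-bounded reporting

Edge lists for display are restricted to sensor distances within
[min_mult · smallest pairwise distance, max_frac · y-coordinate range]
(defaults 2.5 and 0.65; y is the anterior–posterior axis). Neighbouring
sensors are near-always aligned (uninformative) and very distant ones
near-always anti-aligned, so the window highlights the informative middle
range. Both the y-range reading of "maximum y-axis distance" and the 3-D
Euclidean pairwise distance are configurable. Vendor-measured montage files
are not redistributed; a deterministic Fibonacci spherical-cap layout
generator provides synthetic montages for testing, and layouts load from
TSV (label, x_mm, y_mm, z_mm). Sparse montages can have an empty window
(minimum bound above maximum); this raises rather than returning an empty
report, and pipeline runs can disable the filter.

## Synthetic data generator

The generator emulates exactly the phenomena the measures are sensitive to:

* **Sources** are sinusoids with a random initial phase per trial and
  Ornstein–Uhlenbeck phase drift (mean-reversion 1 s⁻¹, diffusion
  0.6 rad·s^−½), giving high but imperfect within-trial coherence — a
  controllable stand-in for band-limited cortical rhythms.
* **Coupling** replaces a fraction `strength` of a target source's
  oscillation with a delayed copy of its driver's, so coupled pairs
  synchronise at phase 2πf·lag. Lags are quantised to whole samples; tests
  that check closed-form phases choose fs so the lag is exact. A
  quarter-cycle lag maximises visibility to iCOH (|sin| = 1).
* **Volume conduction** is an instantaneous Gaussian-decay projection
  exp(−d²/2·spread²) of sources onto sensors (spread 40 mm): a smooth
  leadfield surrogate, not a head-model forward solution.
* **Cohorts** share the coupling pattern; subject i uses seed
  `spec.seed + i`, with per-subject strength jitter drawn from a separate
  stream (so a jitter-free subject is bit-identical to a direct simulation)
  and an attenuation factor for impaired-like profiles.
* The canonical study condition (`coupled_oscillator_setup`) plants one
  driver/target pair per requested frequency, all pairs sharing the same two
  cortical sites ~15 mm below a 95 mm spherical-cap montage — one region
  driving another in several bands, which is what produces cross-band
  consistent structure. Sensor noise sd 0.5 against unit source amplitude.

What the generator does **not** emulate: realistic leadfields, ocular/muscle
artifacts, line noise, 1/f background spectra, nonstationary resting-state
dynamics, or heterogeneous per-subject anatomy. Passing tests therefore
demonstrate correctness of the estimators and the statistical machinery
under controlled conditions, not clinical validity on real recordings.

## Problem sizes

The test suite and acceptance script run everything at desk scale, chosen as
the smallest sizes at which the stochastic properties are comfortably
stable: the reproducibility analysis uses 15 subjects × 64 channels ×
50 two-second trials at 128 Hz with two 1000-model ensembles; property
checks use 8–32 channel cohorts, 100–1000 nulls, and 5–20 simulation
repeats. Combinatorial checks (8128 pairs, 500 directional edges) use the
full 128-channel frame, which is cheap.

## Known limitations

* Cross-spectra are averaged over trials before normalisation (the
  alternative — averaging per-trial coherencies — is not currently exposed).
* Multitaper smoothing beyond Hann + trial averaging is not implemented.
* Welch tests treat per-subject angles as independent samples per pair and
  pairs as separate hypotheses (dependence between pairs is handled only
  through BH's robustness, as is standard).
* The 60-channel vendor bounds depend on whether ocular channels are dropped
  before or after computing the spacing; both are possible via explicit
  layout files.
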