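# Methods

This note records the models implemented in `ramanlre`, the parameter
choices that matter, what the synthetic data does and does not emulate,
and the numerical decisions a maintainer would want to know.

## Low-rank estimation by Frank-Wolfe iterations

The denoiser approximates a spectral matrix `A` (samples × channels) by
a low-rank matrix built greedily from rank-1 atoms. Each iteration takes
the **full** leading rank-1 component `σ u vᵀ` of the residual `A − X`
as the search direction — not a unit-norm atom as in classical
nuclear-norm-ball Frank-Wolfe. With the scale `σ` included, a rank-1
input is reproduced exactly in one iteration (the line search returns
step 1), which anchors the algorithm's behavior; without it the convex
update could never reach the data's magnitude in one step.

**Stopping rule.** Iteration continues while
`σ(A − X^{i+1}) / σ₁(A) > m` and `i < N`. The constraint factor `m`
(default 0.005, sensible range 0.001–0.01) is interpreted relative to
the data's leading singular value so that it is dimensionless; `N`
defaults to 20. A third exit exists in practice: the convex update
`X ← (1−r)X + r·σuvᵀ` reaches a **fixed point** when no rank-1 direction
of the residual has positive inner product with the descent direction
(`⟨A−X, s−X⟩ ≤ 0`, line search returns exactly 0). From that state every
further iteration recomputes the identical direction and step, so the
implementation exits with `stop_reason='stalled'` instead of spinning to
`N`; the returned matrix is bit-identical to what looping would produce.
On heavily noisy matrices this fixed point is reached after 2–4
iterations and is what actually terminates the algorithm — the
singular-value criterion rarely fires there, because the residual's
leading singular value stays noise-dominated.

A consequence worth knowing: the convex combination shrinks earlier
atoms (after two steps with `r₂ = 0.16`, the first atom is weighted
0.84), so the estimate is a biased, very-low-rank reconstruction rather
than a truncated SVD. For calibration this is fine — regression models
rescale directions — and it is what makes the method strongly
noise-suppressing. `update_mode='additive'` (`X ← X + r·s`) is available
as a documented extension that does not shrink prior atoms; it behaves
like greedy truncated SVD and, run to `N = 20` on noisy data,
accumulates noise directions. The convex default is the method proper.

**ALS.** The leading singular triple is found by alternating
least-squares sweeps (`u ← Mv/‖Mv‖`, `v ← Mᵀu/‖Mᵀu‖`, `σ ← uᵀMv`),
stopping at relative σ-change below 1e-10 or 500 sweeps. The right
vector is initialized to the channel-wise mean of `|M|` — for spectra
the leading component is essentially all-positive, so this is close to
the answer and deterministic — with a seeded random fallback if that
mean is zero. Singular vectors are sign-fixed so the largest-magnitude
entry of `v` is positive. For (near-)degenerate leading singular pairs
the ALS limit depends on the initialization; this is accepted because
the rank-1 *matrix* the algorithm consumes is what matters, not the
individual factors. Convergence is geometric at rate `(σ₂/σ₁)²`; on
noisy residuals with tight spectra the 500-sweep cap can leave the
direction slightly unconverged, which the line search absorbs.

**Monotonicity guard.** The line search guarantees the residual norm
cannot increase mathematically; at rounding-error level a computed norm
could still tick up, in which case the step is rejected (equivalent to
choosing r = 0, which the search domain includes) and the iteration
terminates as stalled.

**Augmentation.** A small matrix (e.g. a 15-spectrum test set) gives the
factorization little to work with, so the raw training spectra are
stacked underneath before denoising and an index map recovers exactly
the test rows afterwards; donor rows are never evaluated. Blank
ensembles used for quantitation limits are the deliberate exception —
see below.

## Synthetic data

No instrument data ships with the package; the generator emulates the
statistical structure the method relies on, not any real substance:

- **Linear mixing, low rank.** Pure-component spectra are sums of
  Lorentzian/Gaussian bands on a 200–2000 cm⁻¹ axis at 1 cm⁻¹ spacing;
  noise-free intensities are `t · (C P + baseline)` for concentration
  design `C`, pure spectra `P` (counts/s) and integration time `t`. For
  simplex-closed designs the constant baseline lies inside the mixing
  span, so the noise-free rank equals the component count.
- **Default library.** Three components with interleaved, overlapping
  bands; the third is a weak scatterer (~4× smaller amplitudes) whose
  bands sit inside the others' clusters, emulating a low-signal analyte
  swamped by stronger ones. Pairwise cosine similarity of the endmembers
  is 0.25–0.40. The 1800–2000 cm⁻¹ region is kept band-free for noise
  estimation.
- **Designs.** Tablets: a simplex-lattice design thinned evenly to
  exactly 100 points. Solutions: a free two-component uniform design.
  Blanks: all-zero concentrations.
- **Noise vs integration time.** Detector noise is Gaussian with
  amplitude `gaussian_sd` (counts at 1 s). Under the default
  `snr_time_law='sqrt'` the amplitude scales with √t, so SNR ∝ √t
  (shot-noise-like physics); under `'linear'` it is constant, so SNR ∝ t
  (read-noise-dominated, and the regime in which SNR is proportional to
  exposure). Poisson shot noise on the expected counts can be enabled
  independently. Every benchmark records which law was used.
- **SNR calibration of the shipped fixture.** The benchmark scenario
  (`tablet_dataset`: 100 samples, 0.1 s) uses `gaussian_sd = 65`, chosen
  so the *nominal* SNR — noise-free signal peak over injected noise
  RMS — is ≈ 2.5 at 0.1 s. The empirical estimator (`compute_snr`: max
  over channels of the baseline-corrected intensity over the RMS of a
  signal-free window) reads higher (≈ 4.4) on such data, because the
  channel-wise maximum of ~1800 noisy channels is itself noise-inflated;
  that estimator saturates near 3.5 under heavy noise and cannot read
  2.5 regardless of the true noise level. Nominal SNR is therefore the
  calibration target; the estimator is reported as measured.
- **Rank diagnostic.** `rank_diagnostic` uses a separate low-noise
  acquisition (`gaussian_sd = 2.5`, 30 samples) so that the effective
  rank (singular values above 1% of σ₁) transitions inside the probed
  0.1–0.5 s range: rank 3 at 0.5 s, intermediate at 0.2 s, full at
  0.1 s. At the benchmark noise level the rank is saturated at
  `n_samples` for all probed times, which is the regime the benchmark
  deliberately operates in.

What the generator does **not** emulate: per-sample fluorescence
variation, cosmic-ray spikes, wavenumber calibration drift, detector
etaloning, or physically calibrated scattering cross-sections. Passing
benchmarks on this generator therefore demonstrate the method's
behavior under linear mixing with stationary Gaussian/Poisson noise,
not performance on any particular instrument's artifacts.

## Wavelet comparator

The conventional baseline: sym11 multilevel decomposition (default
depth 7, capped at the maximum useful level for the signal length — 6
for 1801 channels — with a logged warning), zeroing the deepest
approximation band (fluorescence background) and a configurable set of
detail bands counted from the finest. The module default zeroes only
the finest detail band. The *benchmark* operating point zeroes levels
{1, 2, 3}: those are the levels whose pseudo-frequency (sym11 at 1 cm⁻¹
sampling: ≈ 0.7/2^j cycles/cm⁻¹) lies strictly above the content of the
narrowest analyte band (fwhm 12 cm⁻¹ ≈ 0.042 cycles/cm⁻¹); level 4
(≈ 0.044) overlaps it and is kept. This operationalizes "optimally
selected to preserve the sharpest analyte peaks" without reference to
any downstream score. Boundary handling is symmetric extension, which
avoids edge spikes on baseline-heavy spectra; note that the symmetric
transform is redundant, so band-zeroing is only approximately a
projection — exact idempotence holds under `boundary_mode=
'periodization'`, where the transform is orthogonal.

## Calibration harness

- **Kennard-Stone split** (default 85/15 on 100 samples): seed with the
  maximal-distance pair, then greedily add the sample with the largest
  minimum distance to the selected set; all ties break toward the
  lowest index, making the split fully deterministic.
- **Grid search** with seeded k-fold CV (default k = 5; the paper-style
  phrase "k-folder" leaves k open). PLS components default 1–15; SVR
  grids default to powers of two 2⁻⁵…2⁷ for C, γ and ε. Ties in mean
  CV-RMSE go to the simpler model (fewer components, then the smaller
  (C, γ, ε) in ascending order), so the selection is independent of
  grid ordering. Grids and seeds are logged into every report.
- **Models.** PLS via the standard NIPALS latent-variable fit,
  mean-centering estimated on the training block only. SVR: RBF kernel,
  one regressor per component, spectra and targets standardized on
  training statistics and predictions un-standardized for reporting
  (whether the original work scaled SVM inputs is unstated; this choice
  is logged, not attributed).
- **Denoising placement.** Each preprocessing variant is applied once
  per train/test matrix (not refit inside CV folds), accepting the mild
  information sharing within the training matrix this implies; the
  low-rank variant denoises the training matrix as itself and the test
  block augmented with the raw training spectra.
- **Quantitation limit.** ICH-style `QL = 10 × SD(blank predictions)`
  per component, requiring ≥ 10 blank replicates, in concentration
  units. Blank ensembles are denoised **as their own matrix**, never
  augmented with calibration spectra: QL measures the blank-prediction
  noise of the pipeline, and stacking signal-bearing spectra under the
  blanks would align the retained low-rank directions with the signal
  subspace the regression vector lives in, defeating the measurement
  (and no analyst mixes calibration samples into a blank set).

## Problem sizes and replication protocol

Monte-Carlo claims (SNR ordering, rank diagnostic, benchmark orderings,
QL direction) use 15–50 replicates at 10–100 samples × 1801 channels;
these sizes give stable orderings while keeping any single check in the
tens of seconds. Replicates vary the data realization (the fixture
seed) while the analysis pipeline — split rule, CV fold seed, grids —
stays fixed, as when one procedure is applied to repeated acquisitions.

## Known limitations

- The convex Frank-Wolfe update underweights earlier atoms and stalls
  at a 2–3-atom estimate on noisy data; it is a denoiser for
  calibration, not an unbiased low-rank reconstruction.
- The singular-value stopping criterion is inactive in heavy noise
  (the fixed point fires first); `m` matters only for cleaner matrices.
- Train and test blocks are factorized separately (per the method's
  protocol), so their reconstructions can differ by a small relative
  gain; augmentation with the shared training spectra keeps this at the
  percent level but does not remove it.
- ALS accuracy for near-degenerate singular pairs is limited by the
  sweep cap; the objective value is insensitive, the factors are not.
- `effective_rank` uses a hard 1% relative threshold; ranks quoted for
  noisy matrices are specific to that convention.
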