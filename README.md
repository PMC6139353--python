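# ramanlre

Low-rank estimation (LRE) denoising and chemometric calibration for Raman
spectral data matrices.

## The problem

Quantitative Raman analysis of multi-component mixtures (e.g.
pharmaceutical tablets) regresses component concentrations on measured
spectra with PLS or support-vector models. At short detector integration
times the spectra are noisy — Raman scattering is weak — and calibration
accuracy collapses. But a noise-free spectral data matrix
`A ∈ R^{n_samples × n_channels}` is low rank: every spectrum is a linear
mixture of a few pure-component endmember spectra, so
`rank(A) ≤ n_components`, while noise is full rank. Replacing `A` by a
low-rank estimate separates signal from noise and restores calibration
accuracy. This package is aimed at spectroscopists and chemometricians who
want that denoising step, the conventional wavelet comparator, and the
full evaluation harness around them.

## The method

The denoiser solves `min_X ‖A − X‖_F` over low-rank `X` greedily with a
Frank-Wolfe scheme. Starting from `X⁰ = 0`, iteration `i`:

1. **Search direction** — the leading rank-1 component of the residual,
   `s^{i+1} = σ u vᵀ` where `(u, v, σ)` is the leading singular triple of
   `A − X^i`, estimated by alternating least squares (ALS):
   `u ← Mv/‖Mv‖`, `v ← Mᵀu/‖Mᵀu‖`, `σ ← uᵀMv` until convergence.
2. **Step length** — exact line search
   `r^{i+1} = argmin_{r∈[0,1]} ‖A − (X^i + r(s^{i+1} − X^i))‖_F`, which has
   the closed form `⟨A−X, s−X⟩_F / ‖s−X‖²_F` clipped to [0, 1].
3. **Update** — convex combination `X^{i+1} = (1−r)X^i + r s^{i+1}`.

Iteration stops when the residual's leading singular value falls below
`m · σ₁(A)` (the low-rank constraint factor `m`, typically 0.001–0.01),
at `N` iterations (typically 5–20), or at a Frank-Wolfe fixed point
(zero step). Around the denoiser the package provides:

- a synthetic generator of Raman-like mixture datasets (Lorentzian /
  Gaussian bands, simplex mixture designs, fluorescence baseline,
  integration-time-dependent noise),
- the conventional wavelet comparator (sym11 multilevel band-zeroing),
- Kennard-Stone train/test splitting, grid-searched PLS and ε-SVR
  calibration with k-fold CV, R²/RMSE metrics and ICH-style quantitation
  limits (10× the SD of blank predictions).

## Worked example

```python
from ramanlre import simulate as sim
from ramanlre.lowrank import LREConfig, lre_denoise

noisy, truth = sim.tablet_dataset(seed=0)   # 100 tablets, 0.1 s exposure
result = lre_denoise(noisy.intensities, LREConfig(max_iterations=20,
                                                  constraint_factor=0.005))
print(result.iterations_run, result.stop_reason)   # 2 stalled
print([round(x, 1) for x in result.residual_norms])
# [10003.4, 8894.2, 8858.2]
```

The residual Frobenius norm drops from 10003.4 (the raw noise + signal
mixture around the zero initialization) as the first step captures the
full leading rank-1 component (step length 1.0) and the second blends in
the next one (step length 0.16); the algorithm then reaches its fixed
point. Relative error to the noise-free truth falls from 1.79 (raw) to
0.40 (denoised). Running the calibration benchmark on the same dataset
(`examples/calibration_benchmark.py`) prints per-component test R²; the
mean over the three components orders

```
mean R^2: raw 0.8963, wt 0.9178, lre 0.9341
```

i.e. low-rank denoising beats both the raw spectra and the wavelet
comparator. `examples/` holds one short script per capability
(simulation, rank diagnostic, denoising, benchmark, quantitation limit),
and the same operations are scriptable via the thin CLI:

```bash
ramanlre simulate --out raw.csv
ramanlre denoise --in raw.csv --out lre.csv --max-iter 20 --constraint 0.005
ramanlre benchmark --config bench.yaml --out report.json
ramanlre report report.json --format md
```

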