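"""Synthetic Raman-like mixture datasets.

No instrument data ships with this package, so the generator emulates
the statistical structure the analysis relies on: each measured spectrum
is a concentration-weighted linear mixture of a few pure-component
spectra (hence the noise-free matrix has rank equal to the number of
components), a smooth fluorescence-like baseline sits underneath, the
signal scales with the detector integration time, and noise degrades
short-exposure spectra.

Two noise/integration-time regimes are available because the physics
and common practice disagree on the scaling: ``snr_time_law='sqrt'``
scales the Gaussian noise amplitude with sqrt(t) (shot-noise-like, SNR
~ sqrt(t)), while ``'linear'`` keeps it constant (detector-read-noise
dominated, SNR ~ t).  Poisson shot noise on the expected counts can be
switched on independently.

The default three-component peak library is deliberately synthetic: it
mimics overlapping pharmaceutical Raman bands (including one weakly
scattering component whose signal is nearly swamped by the others) but
reproduces no real substance.  The 1800-2000 cm^-1 region is kept
peak-free so SNR can be estimated from a signal-free window.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np

from .dataset import SpectralDataset, compute_snr

__all__ = [
    "PeakSpec",
    "MixtureDesign",
    "AcquisitionModel",
    "peak_profile",
    "component_spectrum",
    "generate_dataset",
    "default_axis",
    "default_component_library",
    "default_component_names",
    "simplex_lattice_design",
    "two_component_solution_design",
    "blank_design",
    "tablet_dataset",
    "blank_dataset",
    "noise_free",
    "rank_diagnostic",
    "NOISE_WINDOW_CM",
    "noise_window_indices",
    "mean_snr",
]

#: signal-free region reserved for noise estimation (cm^-1)
NOISE_WINDOW_CM = (1800.0, 2000.0)


@dataclasses.dataclass(frozen=True)
class PeakSpec:
    """One spectral band: center (cm^-1), FWHM (cm^-1), amplitude, shape."""

    center: float
    fwhm: float
    amplitude: float
    shape: str = "lorentzian"

    def __post_init__(self) -> None:
        if not self.fwhm > 0:
            raise ValueError("fwhm must be > 0")
        if not self.amplitude > 0:
            raise ValueError("amplitude must be > 0")
        if self.shape not in ("lorentzian", "gaussian"):
            raise ValueError("shape must be 'lorentzian' or 'gaussian'")


@dataclasses.dataclass(frozen=True)
class MixtureDesign:
    """Concentration design: ``(n_samples, n_components)`` matrix.

    ``closure='simplex'`` enforces nonnegative rows summing to 1 (solid
    tablets mixed in proportions); ``'free'`` places no constraint
    (solution concentrations).
    """

    concentrations: np.ndarray
    closure: str = "simplex"

    def __post_init__(self) -> None:
        conc = np.atleast_2d(np.asarray(self.concentrations, dtype=float))
        object.__setattr__(self, "concentrations", conc)
        if conc.shape[0] < 1:
            raise ValueError("design needs >= 1 sample")
        if self.closure not in ("simplex", "free"):
            raise ValueError("closure must be 'simplex' or 'free'")
        if self.closure == "simplex":
            if np.any(conc < 0) or np.any(np.abs(conc.sum(axis=1) - 1.0) > 1e-9):
                raise ValueError(
                    "simplex closure requires nonnegative rows summing to 1"
                )

    @property
    def n_samples(self) -> int:
        return self.concentrations.shape[0]

    @property
    def n_components(self) -> int:
        return self.concentrations.shape[1]


@dataclasses.dataclass(frozen=True)
class AcquisitionModel:
    """Exposure and noise model of one acquisition.

    ``gaussian_sd`` is the detector noise amplitude (counts) at a 1 s
    exposure; under ``snr_time_law='sqrt'`` it is scaled by sqrt(t),
    under ``'linear'`` it is applied as-is.  ``shot_noise`` draws the
    counts from a Poisson law on the expected (time-scaled) intensity.
    ``baseline_coeffs`` are polynomial coefficients (highest power
    first, numpy convention) in the normalized coordinate
    u = (wavenumber - min) / span, giving a fluorescence-like smooth
    background in counts per second.
    """

    integration_time: float = 1.0
    shot_noise: bool = False
    gaussian_sd: float = 65.0
    snr_time_law: str = "sqrt"
    baseline_coeffs: tuple[float, ...] = (5.0, 10.0, 20.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.integration_time > 0:
            raise ValueError("integration_time must be > 0")
        if self.gaussian_sd < 0:
            raise ValueError("gaussian_sd must be >= 0")
        if self.snr_time_law not in ("linear", "sqrt"):
            raise ValueError("snr_time_law must be 'linear' or 'sqrt'")


def peak_profile(axis: np.ndarray, peak: PeakSpec) -> np.ndarray:
    """Evaluate one band on the axis; value ``amplitude`` at the center.

    Lorentzian: a * (w/2)^2 / ((x-c)^2 + (w/2)^2); Gaussian:
    a * exp(-4 ln2 (x-c)^2 / w^2).  Both reach half the amplitude at
    c +/- fwhm/2.
    """
    x = np.asarray(axis, dtype=float)
    if x.size > 1 and np.any(np.diff(x) <= 0):
        raise ValueError("axis must be strictly increasing")
    d = x - peak.center
    if peak.shape == "lorentzian":
        hw = peak.fwhm / 2.0
        return peak.amplitude * hw**2 / (d**2 + hw**2)
    return peak.amplitude * np.exp(-4.0 * np.log(2.0) * d**2 / peak.fwhm**2)


def component_spectrum(axis: np.ndarray, peaks: Sequence[PeakSpec]) -> np.ndarray:
    """Pure-component spectrum: the sum of its band profiles (linear in
    amplitudes).  A peak centered outside the axis range triggers a
    warning, not an error."""
    x = np.asarray(axis, dtype=float)
    if len(peaks) == 0:
        raise ValueError("need at least one peak")
    out = np.zeros_like(x)
    for p in peaks:
        if not (x[0] <= p.center <= x[-1]):
            warnings.warn(
                f"peak center {p.center} cm^-1 outside axis "
                f"[{x[0]}, {x[-1]}]",
                stacklevel=2,
            )
        out += peak_profile(x, p)
    return out


def default_axis() -> np.ndarray:
    """200-2000 cm^-1 at 1 cm^-1 spacing (1801 channels)."""
    return np.arange(200.0, 2001.0, 1.0)


def default_component_library() -> list[list[PeakSpec]]:
    """Three overlapping synthetic component spectra (counts/s amplitudes).

    Components A and B are strong scatterers with interleaved bands;
    component C is a weak scatterer (~4x smaller amplitudes) whose bands
    sit inside A/B band clusters, so its signal rides on top of theirs.
    All bands stay below 1750 cm^-1, leaving 1800-2000 cm^-1 signal-free.
    """
    comp_a = [
        PeakSpec(420.0, 18.0, 600.0),
        PeakSpec(745.0, 14.0, 900.0),
        PeakSpec(1005.0, 12.0, 1000.0),
        PeakSpec(1320.0, 20.0, 700.0),
        PeakSpec(1605.0, 16.0, 800.0, "gaussian"),
    ]
    comp_b = [
        PeakSpec(520.0, 20.0, 700.0),
        PeakSpec(762.0, 16.0, 850.0),
        PeakSpec(1048.0, 14.0, 900.0),
        PeakSpec(1342.0, 18.0, 750.0),
        PeakSpec(1450.0, 22.0, 600.0, "gaussian"),
        PeakSpec(1622.0, 14.0, 700.0),
    ]
    comp_c = [
        PeakSpec(480.0, 18.0, 150.0),
        PeakSpec(754.0, 15.0, 200.0),
        PeakSpec(1026.0, 13.0, 250.0),
        PeakSpec(1333.0, 19.0, 180.0),
        PeakSpec(1580.0, 17.0, 220.0, "gaussian"),
    ]
    return [comp_a, comp_b, comp_c]


def default_component_names() -> tuple[str, ...]:
    return ("compA", "compB", "compC")


def simplex_lattice_design(n_samples: int = 100, n_components: int = 3) -> MixtureDesign:
    """Simplex-lattice mixture design thinned to exactly ``n_samples``.

    Lattice points {k/q} on the simplex for the smallest scale q whose
    lattice has >= n_samples points, enumerated lexicographically and
    thinned evenly (deterministically) down to the requested count.
    """
    if n_components < 2:
        raise ValueError("need >= 2 components")

    def lattice(q: int) -> list[tuple[int, ...]]:
        pts: list[tuple[int, ...]] = []

        def rec(prefix: tuple[int, ...], remaining: int, slots: int) -> None:
            if slots == 1:
                pts.append(prefix + (remaining,))
                return
            for k in range(remaining + 1):
                rec(prefix + (k,), remaining - k, slots - 1)

        rec((), q, n_components)
        return pts

    q = 1
    while len(lattice(q)) < n_samples:
        q += 1
    pts = lattice(q)
    keep = np.unique(np.round(np.linspace(0, len(pts) - 1, n_samples)).astype(int))
    conc = np.asarray([pts[i] for i in keep], dtype=float) / q
    return MixtureDesign(conc, closure="simplex")


def two_component_solution_design(
    n_samples: int = 100, seed: int = 0, low: float = 0.0, high: float = 1.0
) -> MixtureDesign:
    """Free (unclosed) two-component design with uniform random levels."""
    rng = np.random.default_rng(seed)
    conc = rng.uniform(low, high, size=(n_samples, 2))
    return MixtureDesign(conc, closure="free")


def blank_design(n_samples: int, n_components: int = 3) -> MixtureDesign:
    """All-zero concentrations: blank acquisitions of the solvent/baseline."""
    return MixtureDesign(np.zeros((n_samples, n_components)), closure="free")


def _baseline(axis: np.ndarray, coeffs: Sequence[float]) -> np.ndarray:
    if len(coeffs) == 0:
        return np.zeros_like(axis)
    span = axis[-1] - axis[0]
    u = (axis - axis[0]) / span if span > 0 else np.zeros_like(axis)
    return np.polyval(list(coeffs), u)


def generate_dataset(
    axis: np.ndarray,
    library: Sequence[Sequence[PeakSpec]],
    design: MixtureDesign,
    acq: AcquisitionModel,
    component_names: Sequence[str] | None = None,
) -> SpectralDataset:
    """Simulate an acquisition of the designed mixtures.

    The noise-free intensity is ``t * (C @ P + baseline)`` where C is the
    concentration design, P the pure-component spectra (counts/s) and t
    the integration time; noise follows the :class:`AcquisitionModel`.
    Deterministic for a given seed.  The returned dataset carries the
    true concentrations.
    """
    x = np.asarray(axis, dtype=float)
    if len(library) != design.n_components:
        raise ValueError(
            f"library has {len(library)} components, design {design.n_components}"
        )
    pure = np.vstack([component_spectrum(x, peaks) for peaks in library])
    t = acq.integration_time
    clean = t * (design.concentrations @ pure + _baseline(x, acq.baseline_coeffs))

    rng = np.random.default_rng(acq.seed)
    intens = clean
    if acq.shot_noise:
        intens = rng.poisson(np.clip(intens, 0.0, None)).astype(float)
    if acq.gaussian_sd > 0:
        sd = acq.gaussian_sd * (np.sqrt(t) if acq.snr_time_law == "sqrt" else 1.0)
        intens = intens + rng.normal(0.0, sd, size=intens.shape)

    names = tuple(component_names) if component_names is not None else tuple(
        f"comp{chr(ord('A') + i)}" for i in range(design.n_components)
    )
    return SpectralDataset(
        wavenumbers=x,
        intensities=intens,
        concentrations=design.concentrations.copy(),
        component_names=names,
        integration_time=t,
    )


def noise_free(acq: AcquisitionModel) -> AcquisitionModel:
    """Copy of the acquisition with every noise source switched off."""
    return dataclasses.replace(acq, shot_noise=False, gaussian_sd=0.0)


def tablet_dataset(
    seed: int = 0,
    integration_time: float = 0.1,
    n_samples: int = 100,
    gaussian_sd: float = 65.0,
    snr_time_law: str = "sqrt",
    shot_noise: bool = False,
    noise: bool = True,
) -> tuple[SpectralDataset, SpectralDataset]:
    """The shipped three-component low-SNR benchmark scenario.

    100 simplex-lattice tablet mixtures of the default component library
    on the default axis.  The default noise amplitude is calibrated so
    that at the default 0.1 s exposure the nominal SNR — the noise-free
    signal peak over the injected noise RMS — is ~2.5, the
    short-exposure regime where denoising matters most.  (The empirical
    max-based estimator of :func:`ramanlre.dataset.compute_snr` reads
    somewhat higher on such data because the channel-wise maximum is
    itself noise-inflated.)  Returns ``(noisy, truth)`` datasets sharing
    the design (``truth`` is the same acquisition with the noise off).
    """
    axis = default_axis()
    lib = default_component_library()
    design = simplex_lattice_design(n_samples, 3)
    acq = AcquisitionModel(
        integration_time=integration_time,
        shot_noise=shot_noise,
        gaussian_sd=gaussian_sd if noise else 0.0,
        snr_time_law=snr_time_law,
        seed=seed,
    )
    names = default_component_names()
    noisy = generate_dataset(axis, lib, design, acq, names)
    truth = generate_dataset(axis, lib, design, noise_free(acq), names)
    return noisy, truth


def blank_dataset(
    seed: int = 0,
    integration_time: float = 0.1,
    n_blanks: int = 16,
    gaussian_sd: float = 65.0,
    snr_time_law: str = "sqrt",
) -> SpectralDataset:
    """Blank acquisitions (baseline + noise only) for quantitation limits."""
    acq = AcquisitionModel(
        integration_time=integration_time,
        gaussian_sd=gaussian_sd,
        snr_time_law=snr_time_law,
        seed=seed,
    )
    return generate_dataset(
        default_axis(),
        default_component_library(),
        blank_design(n_blanks, 3),
        acq,
        default_component_names(),
    )


def rank_diagnostic(
    times: Sequence[float] = (0.5, 0.2, 0.1),
    n_seeds: int = 20,
    n_samples: int = 30,
    gaussian_sd: float = 2.5,
    base_seed: int = 0,
    relative_threshold: float = 0.01,
) -> dict[float, float]:
    """Mean effective rank of simulated matrices vs integration time.

    Reproduces the low-rank diagnostic: at long exposures the matrix
    rank collapses to the number of mixture components, and it rises as
    the exposure shortens and noise takes a larger share of the
    variance.  The default acquisition uses a low noise amplitude so the
    rank transition falls inside the probed 0.1-0.5 s range.
    """
    from .dataset import effective_rank

    out: dict[float, float] = {}
    for t in times:
        ranks = [
            effective_rank(
                tablet_dataset(
                    seed=base_seed + s,
                    integration_time=t,
                    n_samples=n_samples,
                    gaussian_sd=gaussian_sd,
                )[0].intensities,
                relative_threshold,
            )
            for s in range(n_seeds)
        ]
        out[float(t)] = float(np.mean(ranks))
    return out


def noise_window_indices(axis: np.ndarray) -> tuple[int, int]:
    """Channel index range of the reserved signal-free window."""
    x = np.asarray(axis, dtype=float)
    lo = int(np.searchsorted(x, NOISE_WINDOW_CM[0], side="left"))
    hi = int(np.searchsorted(x, NOISE_WINDOW_CM[1], side="right"))
    return lo, hi


def mean_snr(dataset: SpectralDataset) -> float:
    """Mean per-spectrum SNR using the reserved signal-free window."""
    win = noise_window_indices(dataset.wavenumbers)
    vals = [compute_snr(row, win).snr for row in dataset.intensities]
    return float(np.mean(vals))
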