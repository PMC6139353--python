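"""Spectral dataset container, CSV I/O and matrix diagnostics.

A :class:`SpectralDataset` bundles everything the pipeline passes around:
the wavenumber axis, the intensity matrix (samples x channels), optional
per-sample component concentrations, and acquisition metadata.  Two
diagnostics live here because every stage uses them: the peak-to-noise
SNR estimate and the effective (thresholded) rank of a spectral matrix.

Orientation convention: samples are rows, wavenumber channels are columns,
everywhere in this package.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import svdvals

__all__ = [
    "SpectralDataset",
    "SnrEstimate",
    "SpectralFormatError",
    "SpectralValidationError",
    "UndefinedSnrError",
    "read_dataset_csv",
    "write_dataset_csv",
    "compute_snr",
    "effective_rank",
]

#: float format used for CSV round-trip stability (9 significant digits)
FLOAT_FMT = "%.9g"


class SpectralFormatError(ValueError):
    """Raised when a CSV file cannot be parsed as a spectral dataset."""


class SpectralValidationError(ValueError):
    """Raised when dataset fields violate an invariant."""


class UndefinedSnrError(ValueError):
    """Raised when the noise-window RMS is zero but the peak is not."""


@dataclasses.dataclass
class SpectralDataset:
    """Raman spectral data matrix with its axis, targets and metadata.

    Parameters
    ----------
    wavenumbers
        Strictly increasing channel positions in cm^-1, length ``n_channels``.
    intensities
        ``(n_samples, n_channels)`` matrix of detector counts.
    concentrations
        Optional ``(n_samples, n_components)`` matrix of component
        concentrations (fractions or %); ``None`` for unlabeled data.
    component_names
        One name per concentration column.
    integration_time
        Detector exposure per spectrum in seconds (> 0).
    sample_ids
        One identifier per row; generated as ``s0000, s0001, ...`` if omitted.
    """

    wavenumbers: np.ndarray
    intensities: np.ndarray
    concentrations: np.ndarray | None = None
    component_names: tuple[str, ...] = ()
    integration_time: float = 1.0
    sample_ids: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float).ravel()
        self.intensities = np.atleast_2d(np.asarray(self.intensities, dtype=float))
        if self.concentrations is not None:
            self.concentrations = np.atleast_2d(
                np.asarray(self.concentrations, dtype=float)
            )
        self.component_names = tuple(self.component_names)
        if self.wavenumbers.size == 0:
            raise SpectralValidationError("wavenumber axis is empty")
        if np.any(np.diff(self.wavenumbers) <= 0):
            raise SpectralValidationError("wavenumbers must be strictly increasing")
        if self.intensities.shape[1] != self.wavenumbers.size:
            raise SpectralValidationError(
                f"intensity columns ({self.intensities.shape[1]}) != "
                f"axis length ({self.wavenumbers.size})"
            )
        if self.concentrations is not None:
            if self.concentrations.shape[0] != self.intensities.shape[0]:
                raise SpectralValidationError(
                    "concentration rows do not match intensity rows"
                )
            if len(self.component_names) != self.concentrations.shape[1]:
                raise SpectralValidationError(
                    "component_names length does not match concentration columns"
                )
        if not self.integration_time > 0:
            raise SpectralValidationError("integration_time must be > 0")
        if self.sample_ids is None:
            self.sample_ids = tuple(f"s{i:04d}" for i in range(self.n_samples))
        else:
            self.sample_ids = tuple(str(s) for s in self.sample_ids)
            if len(self.sample_ids) != self.n_samples:
                raise SpectralValidationError("sample_ids length != n_samples")

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_channels(self) -> int:
        return self.wavenumbers.size

    @property
    def n_components(self) -> int:
        return 0 if self.concentrations is None else self.concentrations.shape[1]

    def with_intensities(self, intensities: np.ndarray) -> "SpectralDataset":
        """Return a copy carrying a new intensity matrix of the same shape."""
        return dataclasses.replace(self, intensities=np.asarray(intensities, float))

    def window_indices(self, lo_cm: float, hi_cm: float) -> tuple[int, int]:
        """Half-open channel index range covering ``[lo_cm, hi_cm]`` cm^-1."""
        lo = int(np.searchsorted(self.wavenumbers, lo_cm, side="left"))
        hi = int(np.searchsorted(self.wavenumbers, hi_cm, side="right"))
        return lo, hi


@dataclasses.dataclass(frozen=True)
class SnrEstimate:
    """Peak-signal to RMS-noise ratio of a single spectrum."""

    snr: float
    peak_value: float
    noise_rms: float
    noise_window: tuple[int, int]


def write_dataset_csv(dataset: SpectralDataset, path) -> None:
    """Write a dataset to CSV with a deterministic layout.

    Layout: ``# key = value`` metadata lines, then a header row
    ``id, <wavenumbers...>, <component names...>`` and one row per sample.
    Floats are printed with 9 significant digits so that write -> read ->
    write is byte-identical.
    """
    ds = dataset
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"# integration_time = {FLOAT_FMT % ds.integration_time}\n")
        header = ["id"] + [FLOAT_FMT % w for w in ds.wavenumbers]
        header += list(ds.component_names)
        fh.write(",".join(header) + "\n")
        for i in range(ds.n_samples):
            row = [ds.sample_ids[i]]
            row += [FLOAT_FMT % x for x in ds.intensities[i]]
            if ds.concentrations is not None:
                row += [FLOAT_FMT % c for c in ds.concentrations[i]]
            fh.write(",".join(row) + "\n")


def read_dataset_csv(path) -> SpectralDataset:
    """Read a dataset written by :func:`write_dataset_csv`.

    Header tokens after ``id`` that parse as floats form the wavenumber
    axis; the remaining trailing tokens are component names whose columns
    hold concentrations.  Metadata lines start with ``#``.
    """
    meta: dict[str, str] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#"):
                key, _, val = line.lstrip("#").partition("=")
                meta[key.strip()] = val.strip()
            else:
                break
    try:
        frame = pd.read_csv(path, comment="#", dtype=str, header=0)
    except pd.errors.ParserError as exc:  # ragged rows etc.
        raise SpectralFormatError(f"cannot parse {path}: {exc}") from exc
    if frame.shape[1] < 2 or frame.columns[0] != "id":
        raise SpectralFormatError("first header field must be 'id'")

    tokens = list(frame.columns[1:])
    wavenumbers: list[float] = []
    split = len(tokens)
    for j, tok in enumerate(tokens):
        try:
            wavenumbers.append(float(tok))
        except ValueError:
            split = j
            break
    component_names = tokens[split:]
    for name in component_names:
        try:
            float(name)
        except ValueError:
            continue
        raise SpectralFormatError(
            "numeric header token found after component-name columns"
        )
    wn = np.asarray(wavenumbers[:split], dtype=float)
    if wn.size == 0:
        raise SpectralFormatError("no wavenumber columns in header")
    if np.any(np.diff(wn) <= 0):
        raise SpectralValidationError("wavenumber header is not strictly increasing")

    try:
        body = frame.iloc[:, 1:].to_numpy(dtype=float)
    except ValueError as exc:
        raise SpectralFormatError(f"non-numeric data cell: {exc}") from exc
    intens = body[:, :split] if body.size else np.empty((0, wn.size))
    conc = body[:, split:] if component_names and body.size else None
    if component_names and body.size == 0:
        conc = np.empty((0, len(component_names)))

    t = float(meta.get("integration_time", 1.0))
    if t <= 0:
        raise SpectralValidationError("integration_time metadata must be > 0")
    ids = tuple(frame.iloc[:, 0].astype(str)) if len(frame) else ()
    return SpectralDataset(
        wavenumbers=wn,
        intensities=intens.reshape(len(frame), wn.size),
        concentrations=conc,
        component_names=tuple(component_names),
        integration_time=t,
        sample_ids=ids,
    )


def compute_snr(spectrum: Sequence[float], noise_window: tuple[int, int]) -> SnrEstimate:
    """Estimate the SNR of one spectrum: peak value over RMS noise.

    The noise is taken from an explicit signal-free channel window
    ``[lo, hi)`` (at least 8 channels): it is mean-subtracted and its RMS
    is the noise amplitude.  The peak is the baseline-corrected maximum
    of the whole spectrum, where the baseline estimate is the mean of the
    noise window, which makes the estimate invariant to adding a constant
    offset.

    Returns an :class:`SnrEstimate`; SNR is 0 for an all-zero spectrum.
    """
    s = np.asarray(spectrum, dtype=float).ravel()
    lo, hi = int(noise_window[0]), int(noise_window[1])
    if not (0 <= lo < hi <= s.size):
        raise IndexError(f"noise window [{lo}, {hi}) outside spectrum of {s.size}")
    if hi - lo < 8:
        raise SpectralValidationError("noise window must span >= 8 channels")
    noise = s[lo:hi]
    mu = float(noise.mean())
    rms = float(np.sqrt(np.mean((noise - mu) ** 2)))
    peak = float(np.max(s - mu))
    if rms == 0.0:
        if peak <= 0.0 or not np.any(s):
            return SnrEstimate(0.0, peak, 0.0, (lo, hi))
        raise UndefinedSnrError("zero noise RMS with a nonzero peak")
    return SnrEstimate(peak / rms, peak, rms, (lo, hi))


def effective_rank(matrix: np.ndarray, relative_threshold: float = 0.01) -> int:
    """Number of singular values above ``relative_threshold * sigma_1``.

    This is the operational "rank" used for the low-rank diagnostic: a
    noise-free linear mixture of k endmember spectra has effective rank k,
    and added noise raises it.  Returns 0 for the zero matrix.
    """
    if not 0 < relative_threshold < 1:
        raise ValueError("relative_threshold must be in (0, 1)")
    m = np.atleast_2d(np.asarray(matrix, dtype=float))
    if m.size == 0:
        raise ValueError("matrix is empty")
    svals = svdvals(m)
    if svals[0] == 0.0:
        return 0
    return int(np.count_nonzero(svals > relative_threshold * svals[0]))
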