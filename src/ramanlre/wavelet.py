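"""Wavelet-transform comparator for spectral denoising.

The conventional baseline against which the low-rank denoiser is
benchmarked: a multilevel discrete wavelet decomposition (Symlet sym11,
7 levels by default) in which configured bands are zeroed before
reconstruction — the deepest approximation band to remove the
low-frequency fluorescence background, and the finest detail band(s) to
remove high-frequency noise.  Band-zeroing makes the operator a linear
projection, so it treats each spectrum independently and identically.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pywt

__all__ = ["WaveletConfig", "wavelet_denoise"]

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class WaveletConfig:
    """Which wavelet, how deep, and which bands to discard.

    ``detail_levels_zeroed`` counts from the finest scale: level 1 is the
    highest-frequency detail band.  With ``zero_approximation=False`` and
    no details zeroed the transform reconstructs the input exactly.
    """

    family: str = "sym11"
    level: int = 7
    zero_approximation: bool = True
    detail_levels_zeroed: frozenset[int] = frozenset({1})
    boundary_mode: str = "symmetric"

    def __post_init__(self) -> None:
        if self.level < 1:
            raise ValueError("level must be >= 1")
        bad = [d for d in self.detail_levels_zeroed if not 1 <= d <= self.level]
        if bad:
            raise ValueError(f"detail levels {bad} outside 1..{self.level}")


def wavelet_denoise(spectrum: np.ndarray, config: WaveletConfig | None = None) -> np.ndarray:
    """Denoise spectra by zeroing wavelet bands and reconstructing.

    Accepts a single spectrum or a (samples x channels) matrix; the
    transform runs along the last axis.  If the signal is too short for
    the requested depth the level is capped at the maximum useful
    decomposition level, with a logged warning.  Output has the input's
    shape.
    """
    cfg = config or WaveletConfig()
    x = np.asarray(spectrum, dtype=float)
    n = x.shape[-1]
    try:
        wave = pywt.Wavelet(cfg.family)
    except ValueError as exc:
        raise ValueError(f"unknown wavelet family {cfg.family!r}") from exc

    max_level = pywt.dwt_max_level(n, wave.dec_len)
    level = min(cfg.level, max_level)
    if level < 1:
        raise ValueError(f"signal of length {n} too short for {cfg.family}")
    if level < cfg.level:
        logger.warning(
            "capping wavelet level %d -> %d for signal length %d",
            cfg.level, level, n,
        )

    coeffs = pywt.wavedec(x, wave, mode=cfg.boundary_mode, level=level, axis=-1)
    if cfg.zero_approximation:
        coeffs[0] = np.zeros_like(coeffs[0])
    for d in cfg.detail_levels_zeroed:
        if d <= level:
            coeffs[-d] = np.zeros_like(coeffs[-d])
        else:
            logger.warning("detail level %d beyond capped depth %d; ignored", d, level)
    out = pywt.waverec(coeffs, wave, mode=cfg.boundary_mode, axis=-1)
    return out[..., :n]
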