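"""Single-level 3D stationary (undecimated) coif1 wavelet bank.

The stationary transform preserves the grid shape, so the same lesion mask
indexes every sub-band. Sub-band labels follow axis order: the first letter
is the filter applied along axis 0 (L = low-pass, H = high-pass), giving the
8 bands LLL ... HHH. PyWavelets' ``swtn`` does the filtering with periodic
boundary handling; odd-sized axes are edge-padded to even length and the
sub-bands cropped back, since the transform operates on dyadic lengths.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt

__all__ = ["WaveletBank", "wavelet_decompose", "wavelet_reconstruct", "SUBBANDS"]

WAVELET = "coif1"
SUBBANDS = ("LLL", "LLH", "LHL", "LHH", "HLL", "HLH", "HHL", "HHH")

_KEYMAP = {b: b.replace("L", "a").replace("H", "d").lower() for b in SUBBANDS}


@dataclass
class WaveletBank:
    """The 8 stationary-wavelet sub-bands of one volume, shape-preserving."""

    bands: dict[str, np.ndarray]
    original_shape: tuple[int, ...]

    def __post_init__(self):
        if set(self.bands) != set(SUBBANDS):
            raise ValueError(f"expected sub-bands {SUBBANDS}, got {sorted(self.bands)}")
        for name, arr in self.bands.items():
            if arr.shape != self.original_shape:
                raise ValueError(
                    f"sub-band {name} shape {arr.shape} != {self.original_shape}"
                )

    def __getitem__(self, band: str) -> np.ndarray:
        return self.bands[band]

    def items(self):
        return ((b, self.bands[b]) for b in SUBBANDS)


def _pad_even(data: np.ndarray) -> tuple[np.ndarray, tuple[slice, ...]]:
    pads = tuple((0, n % 2) for n in data.shape)
    crop = tuple(slice(0, n) for n in data.shape)
    if any(p[1] for p in pads):
        data = np.pad(data, pads, mode="edge")
    return data, crop


def wavelet_decompose(data: np.ndarray) -> WaveletBank:
    """Single-level undecimated separable coif1 transform of a 3D volume."""
    data = np.asarray(data, dtype=float)
    if data.ndim != 3:
        raise ValueError("expected a 3D volume")
    padded, crop = _pad_even(data)
    coeffs = pywt.swtn(padded, WAVELET, level=1, start_level=0)[0]
    bands = {band: coeffs[key][crop] for band, key in _KEYMAP.items()}
    return WaveletBank(bands=bands, original_shape=data.shape)


def wavelet_reconstruct(bank: WaveletBank) -> np.ndarray:
    """Invert the transform. Exact only for even-sized axes (cropped odd
    axes lose the padded boundary coefficients)."""
    if any(n % 2 for n in bank.original_shape):
        raise ValueError(
            "reconstruction requires even-sized axes; odd axes were cropped"
        )
    coeffs = [{key: bank.bands[band] for band, key in _KEYMAP.items()}]
    return pywt.iswtn(coeffs, WAVELET)
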