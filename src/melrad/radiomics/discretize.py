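"""Fixed-bin-width gray-level discretization.

Intensities are mapped to integer gray levels with a fixed bin width
(0.1 SUV by default), anchored at the in-region minimum:

    level(x) = floor(x / w) - floor(min / w) + 1,

so levels run 1..Ng and shifting all values by an exact multiple of the
width leaves the levels unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["DiscretizedRegion", "discretize", "discretize_volume"]

DEFAULT_BIN_WIDTH = 0.1


@dataclass
class DiscretizedRegion:
    """Integer gray levels for the in-mask voxels of one image.

    ``levels`` is a full-volume int array, 0 outside the mask and 1..Ng
    inside; the mapping is reproducible from ``bin_width`` and
    ``origin_bin`` (= floor(min / width)).
    """

    levels: np.ndarray
    mask: np.ndarray
    n_levels: int
    bin_width: float
    origin_bin: int

    def __post_init__(self):
        inside = self.levels[self.mask]
        if inside.size == 0:
            raise ValueError("discretized region is empty")
        if inside.min() < 1 or inside.max() != self.n_levels:
            raise ValueError("levels must span 1..Ng inside the mask")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    def level_values(self) -> np.ndarray:
        """Flat array of in-mask gray levels."""
        return self.levels[self.mask]


def discretize(values, bin_width: float = DEFAULT_BIN_WIDTH) -> np.ndarray:
    """Map a flat collection of intensities to gray levels 1..Ng."""
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0:
        raise ValueError("cannot discretize an empty region")
    if bin_width <= 0:
        raise ValueError("bin width must be > 0")
    bins = np.floor(values / bin_width)
    return (bins - np.floor(values.min() / bin_width) + 1).astype(np.int64)


def discretize_volume(
    image: np.ndarray, mask: np.ndarray, bin_width: float = DEFAULT_BIN_WIDTH
) -> DiscretizedRegion:
    """Discretize the in-mask voxels of a volume, preserving geometry."""
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if image.shape != mask.shape:
        raise ValueError("image and mask shapes differ")
    if not mask.any():
        raise ValueError("cannot discretize an empty region")
    if bin_width <= 0:
        raise ValueError("bin width must be > 0")
    vals = image[mask]
    origin_bin = int(np.floor(vals.min() / bin_width))
    levels = np.zeros(image.shape, dtype=np.int64)
    levels[mask] = np.floor(vals / bin_width).astype(np.int64) - origin_bin + 1
    return DiscretizedRegion(
        levels=levels,
        mask=mask,
        n_levels=int(levels[mask].max()),
        bin_width=float(bin_width),
        origin_bin=origin_bin,
    )
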