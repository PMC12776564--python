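"""Reconstruction pixel grid over the unit disk.

The network input domain is a square pixel raster inscribing the circular
thorax cross-section; pixels whose centers fall outside the unit circle are
out of support and carry no signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class PixelGridSpec:
    """Square pixel raster over ``[-1, 1]^2`` with circular support.

    Parameters
    ----------
    n : int
        Pixels per side (default 32, the community-standard GREIT output
        size and a convenient U-Net input size).
    extent : float
        Half-width of the square footprint in domain units.
    """

    n: int = 32
    extent: float = 1.0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"grid side must be >= 2, got {self.n}")
        if self.extent <= 0:
            raise ValueError("grid extent must be positive")

    @property
    def pixel_size(self) -> float:
        return 2.0 * self.extent / self.n

    def centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Pixel-center coordinate arrays ``(X, Y)``, each ``(n, n)``.

        Row index increases with y (row 0 is the bottom of the domain);
        column index increases with x.
        """
        c = -self.extent + self.pixel_size * (np.arange(self.n) + 0.5)
        return np.meshgrid(c, c)

    def support_mask(self, radius: float = 1.0) -> np.ndarray:
        """Boolean ``(n, n)`` mask of pixels whose center is inside the disk."""
        x, y = self.centers()
        return x * x + y * y <= radius * radius
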