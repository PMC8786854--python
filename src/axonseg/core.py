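"""Core raster containers shared by every pipeline stage.

Conventions used package-wide:

* rasters are 2-D numpy arrays indexed ``[row, col]`` (y-down);
* connectivity is 8-connectivity everywhere (connected components,
  adjacency tests, morphological dilation);
* physical scale is carried as nanometres per pixel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: 3x3 structuring element implementing the package-wide 8-connectivity.
STRUCT8 = np.ones((3, 3), dtype=bool)

#: Class codes of the three-class semantic representation.
BACKGROUND, FIBER, BORDER = 0, 1, 2


@dataclass
class GrayImage:
    """8-bit grayscale raster with its physical resolution.

    Parameters
    ----------
    pixels : ndarray of uint8, shape (H, W)
        Intensity raster.
    resolution_nm_per_px : float
        Physical size of one pixel in nanometres.
    """

    pixels: np.ndarray
    resolution_nm_per_px: float = 11.9

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 1:
            raise ValueError("GrayImage requires a non-empty 2-D raster")
        if self.pixels.dtype != np.uint8:
            if self.pixels.min() < 0 or self.pixels.max() > 255:
                raise ValueError("intensities outside the 8-bit range [0, 255]")
            self.pixels = self.pixels.astype(np.uint8)
        if self.resolution_nm_per_px <= 0:
            raise ValueError("resolution must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class InstanceMap:
    """Integer-labeled instance raster; 0 is background, k>0 a fiber id."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("InstanceMap requires a 2-D raster")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("InstanceMap requires an integer raster")
        if self.labels.min() < 0:
            raise ValueError("labels must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    @property
    def ids(self) -> np.ndarray:
        """Sorted array of positive instance ids present in the map."""
        u = np.unique(self.labels)
        return u[u > 0]

    @property
    def n_instances(self) -> int:
        return int(self.ids.size)


@dataclass
class ClassMap:
    """Categorical raster over {background=0, fiber=1, border=2}."""

    classes: np.ndarray

    def __post_init__(self) -> None:
        self.classes = np.asarray(self.classes, dtype=np.uint8)
        if self.classes.ndim != 2:
            raise ValueError("ClassMap requires a 2-D raster")
        if self.classes.max(initial=0) > BORDER:
            raise ValueError("class codes are restricted to {0, 1, 2}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.classes.shape
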