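"""Lightweight containers for detector images, stacks and derived maps.

All spatial quantities are in millimetres; images are row-major 2-D arrays
with the beam axis at the geometric centre of the field.  Maps derived from
normalized images carry an explicit validity mask: pixels excluded upstream
(e.g. because the reference intensity fell below the masking floor) stay
excluded downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Tuple

import numpy as np

__all__ = [
    "DetectorImage",
    "ImageStack",
    "NormalizedImage",
    "DeltaMuaMap",
    "ConcentrationMap",
]


@dataclass
class DetectorImage:
    """Exit-face intensity image accumulated by a transmittance measurement.

    Parameters
    ----------
    data : (H, W) ndarray
        Accumulated exit weight (photons or photon weight) per pixel.
    pixel_pitch : float
        Pixel size in mm.
    wavelength : float
        Illumination wavelength tag in nm.
    n_photons : int
        Photons launched to form the image (0 for synthetic images).
    seed : int
        RNG seed used to produce the image.
    """

    data: np.ndarray
    pixel_pitch: float
    wavelength: float
    n_photons: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("detector image must be 2-D")
        if np.any(self.data < 0):
            raise ValueError("detector image weights must be non-negative")
        if self.pixel_pitch <= 0:
            raise ValueError("pixel pitch must be positive")

    @property
    def field(self) -> Tuple[float, float]:
        """Physical field of view (height, width) in mm."""
        return (self.data.shape[0] * self.pixel_pitch,
                self.data.shape[1] * self.pixel_pitch)


@dataclass
class ImageStack:
    """Ordered set of transmittance images, one per inclusion grid position."""

    images: np.ndarray                # (N, H, W)
    positions: np.ndarray             # (N, 2) inclusion (x, y) offsets in mm
    center_index: int                 # index of the on-axis acquisition
    wavelength: float
    pixel_pitch: float
    provenance: str = "synthetic"     # "simulated" | "synthetic"

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=np.float64)
        self.positions = np.asarray(self.positions, dtype=np.float64)
        if self.images.ndim != 3:
            raise ValueError("stack must be (N, H, W)")
        if self.positions.shape != (self.images.shape[0], 2):
            raise ValueError("positions must be (N, 2)")
        if not 0 <= self.center_index < self.images.shape[0]:
            raise ValueError("center_index out of range")

    def __len__(self) -> int:
        return self.images.shape[0]

    @property
    def center_image(self) -> np.ndarray:
        return self.images[self.center_index]


@dataclass
class NormalizedImage:
    """Dimensionless ratio image I/I0 with a validity mask."""

    values: np.ndarray
    valid: np.ndarray
    pixel_pitch: float
    wavelength: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.values.shape != self.valid.shape:
            raise ValueError("values and mask shapes differ")
        if np.any(self.values[self.valid] <= 0):
            raise ValueError("normalized values must be positive on valid pixels")


@dataclass
class DeltaMuaMap:
    """Per-pixel absorption change relative to background, in mm^-1."""

    values: np.ndarray
    valid: np.ndarray
    wavelength: float
    pathlength_mm: float
    pixel_pitch: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.values.shape != self.valid.shape:
            raise ValueError("values and mask shapes differ")
        if not np.all(np.isfinite(self.values[self.valid])):
            raise ValueError("non-finite values on valid pixels")


@dataclass
class ConcentrationMap:
    """Retrieved absorber-concentration changes per pixel, in uM.

    Channels are relative to the normalization background (differences, so
    negative values are meaningful).
    """

    dye_uM: np.ndarray
    inks_uM: np.ndarray
    valid: np.ndarray
    pixel_pitch: float

    def __post_init__(self) -> None:
        self.dye_uM = np.asarray(self.dye_uM, dtype=np.float64)
        self.inks_uM = np.asarray(self.inks_uM, dtype=np.float64)
        self.valid = np.asarray(self.valid, dtype=bool)
        if not (self.dye_uM.shape == self.inks_uM.shape == self.valid.shape):
            raise ValueError("channel shapes differ")
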