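"""Transmittance image processing: normalization, contrast, MBLL, SSIM.

The processing chain mirrors the analysis of the two-wavelength phantom
transmittance experiment:

1. normalize the on-axis (inclusion-centred) image, either by the mean of
   the full 25-position stack or by a matched homogeneous-reference image;
2. read the inclusion contrast C = |1 - M| from the extremal normalized
   intensity M near the beam axis;
3. convert the normalized image to a map of absorption changes via the
   Modified Beer-Lambert law, dmua = -ln(I/I0) / L, with L the mean total
   pathlength of detected photons (one scalar per wavelength, from the
   slab diffusion model of the host);
4. unmix the two wavelengths' dmua maps into dye / ink concentration
   changes;
5. compare images (after 7-pixel median filtering and a central 128 x 128
   crop) with the structural similarity index (SSIM).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy.ndimage import median_filter as _nd_median

from .absorbers import ExtinctionSystem, unmix_map
from .images import (ConcentrationMap, DeltaMuaMap, DetectorImage, ImageStack,
                     NormalizedImage)

__all__ = [
    "ContrastResult",
    "normalize_stack",
    "normalize_by_reference",
    "compute_contrast",
    "mbll",
    "retrieve_concentration_maps",
    "median_filter",
    "central_crop",
    "ssim",
    "symmetrize",
]


@dataclass
class ContrastResult:
    """Extremal normalized intensity near the axis and derived contrast.

    ``M`` is the extremum (a minimum for absorbing inclusions) of the
    median-smoothed normalized image inside the central region of interest;
    the contrast is C = |1 - M|.  ``profile`` is the horizontal section of
    the smoothed image through the extremum row.
    """

    M: float
    contrast: float
    location: Tuple[int, int]       # (row, col) in image coordinates
    profile: np.ndarray


def _masked_ratio(num: np.ndarray, den: np.ndarray, floor: float
                  ) -> Tuple[np.ndarray, np.ndarray]:
    valid = (den > floor) & (num > 0)
    values = np.ones_like(num, dtype=np.float64)
    np.divide(num, den, out=values, where=valid)
    return values, valid


def normalize_stack(stack: ImageStack, n_expected: int = 25,
                    floor_rel: float = 1e-6,
                    include_center: bool = False) -> NormalizedImage:
    """Normalize the centre image by the mean over the grid positions.

    The stack mean serves as the reference intensity I0.  By default the
    centre image itself is left out of the mean: including it feeds its own
    attenuation dip back into the reference, which biases the normalized
    dip low by ~1/N regardless of how small the perturbation is
    (``include_center=True`` restores the plain all-images average).
    Pixels whose reference falls below ``floor_rel`` times its maximum
    (rarely reached by photons, hence carrying no information) are masked.
    """
    if len(stack) != n_expected:
        raise ValueError(
            f"stack has {len(stack)} images; the scan protocol requires "
            f"{n_expected}"
        )
    if include_center:
        mean = stack.images.mean(axis=0)
    else:
        others = [i for i in range(len(stack)) if i != stack.center_index]
        mean = stack.images[others].mean(axis=0)
    floor = floor_rel * float(mean.max())
    values, valid = _masked_ratio(stack.center_image, mean, floor)
    return NormalizedImage(values, valid, stack.pixel_pitch, stack.wavelength)


def normalize_by_reference(image: DetectorImage, reference: DetectorImage,
                           floor_rel: float = 1e-6) -> NormalizedImage:
    """Normalize an inclusion image by a matched homogeneous-medium image.

    Scaled-down alternative to the 25-position protocol: the reference run
    provides the unperturbed intensity I0 directly.  Zero-valued reference
    pixels are masked, never divided.
    """
    if image.data.shape != reference.data.shape:
        raise ValueError("image and reference shapes differ")
    if image.pixel_pitch != reference.pixel_pitch:
        raise ValueError("image and reference pixel pitch differ")
    floor = floor_rel * float(reference.data.max())
    values, valid = _masked_ratio(image.data, reference.data, floor)
    return NormalizedImage(values, valid, image.pixel_pitch, image.wavelength)


def symmetrize(data: np.ndarray) -> np.ndarray:
    """Average an image over the dihedral symmetries of the square.

    For an on-axis source and a laterally centred phantom the ideal exit
    image is invariant under x/y reflections and transposition; averaging
    the eight symmetry copies is a variance-reduction step that changes
    nothing in expectation for such scenes.
    """
    if data.shape[0] != data.shape[1]:
        raise ValueError("symmetrization needs a square image")
    out = data + data[::-1] + data[:, ::-1] + data[::-1, ::-1]
    out = out + out.T
    return out / 8.0


def median_filter(image: np.ndarray, size: int = 7) -> np.ndarray:
    """2-D median filter with edge replication; an odd ``size`` is required."""
    if size < 1 or size % 2 == 0:
        raise ValueError("median filter size must be odd and >= 1")
    return _nd_median(np.asarray(image, dtype=np.float64), size=size,
                      mode="nearest")


def central_crop(image: np.ndarray, side: int = 128) -> np.ndarray:
    """Centred square crop; ties favour the top-left corner."""
    h, w = image.shape[:2]
    if h < side or w < side:
        raise ValueError(f"image {h}x{w} smaller than crop {side}")
    r0 = (h - side) // 2
    c0 = (w - side) // 2
    return image[r0:r0 + side, c0:c0 + side]


def compute_contrast(norm: NormalizedImage, roi: int = 32,
                     median_size: int = 7) -> ContrastResult:
    """Contrast C = |1 - M| of the normalized image.

    The extremum M is read from the median-smoothed image inside the
    central ``roi`` x ``roi`` pixel window around the beam axis (the
    inclusion footprint); whichever of the windowed minimum or maximum
    deviates more from unity is taken, so both absorbing (dips) and
    transparent (peaks) perturbations are handled.
    """
    h, w = norm.values.shape
    if roi <= 0 or roi > min(h, w):
        raise ValueError("ROI empty or larger than the image")
    smooth = median_filter(np.where(norm.valid, norm.values, 1.0), median_size)
    r0 = (h - roi) // 2
    c0 = (w - roi) // 2
    window = smooth[r0:r0 + roi, c0:c0 + roi]
    imin = np.unravel_index(np.argmin(window), window.shape)
    imax = np.unravel_index(np.argmax(window), window.shape)
    vmin = window[imin]
    vmax = window[imax]
    if abs(1.0 - vmin) >= abs(1.0 - vmax):
        M, loc = float(vmin), imin
    else:
        M, loc = float(vmax), imax
    row, col = r0 + loc[0], c0 + loc[1]
    return ContrastResult(M=M, contrast=abs(1.0 - M), location=(row, col),
                          profile=smooth[row].copy())


def mbll(norm: NormalizedImage, pathlength_mm: float) -> DeltaMuaMap:
    """Modified Beer-Lambert inversion dmua = -ln(I/I0) / L, per pixel.

    ``pathlength_mm`` is the mean total pathlength of detected photons in
    the unperturbed medium; masked pixels propagate as invalid.
    """
    if pathlength_mm <= 0:
        raise ValueError("pathlength must be positive")
    values = np.full(norm.values.shape, np.nan)
    np.log(norm.values, out=values, where=norm.valid)
    values = -values / pathlength_mm
    values[~norm.valid] = np.nan
    return DeltaMuaMap(values, norm.valid.copy(), norm.wavelength,
                       pathlength_mm, norm.pixel_pitch)


def retrieve_concentration_maps(
    norm_l1: NormalizedImage,
    norm_l2: NormalizedImage,
    pathlength_l1: float,
    pathlength_l2: float,
    system: ExtinctionSystem,
) -> ConcentrationMap:
    """Two-wavelength retrieval: MBLL per wavelength, then pixelwise unmixing.

    Because the images are normalized to the (absorber-containing)
    background, the returned dye/ink channels are concentration *changes*
    relative to that background, in uM.
    """
    if norm_l1.values.shape != norm_l2.values.shape:
        raise ValueError("wavelength images are not co-registered (shape)")
    if norm_l1.pixel_pitch != norm_l2.pixel_pitch:
        raise ValueError("wavelength images are not co-registered (pitch)")
    d1 = mbll(norm_l1, pathlength_l1)
    d2 = mbll(norm_l2, pathlength_l2)
    return unmix_map(system, d1, d2)


# --- structural similarity --------------------------------------------------

def _gaussian_kernel1d(sigma: float, radius: int) -> np.ndarray:
    x = np.arange(-radius, radius + 1, dtype=np.float64)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def _windowed(img: np.ndarray, k1d: np.ndarray) -> np.ndarray:
    """Separable 'valid' correlation with an odd 1-D kernel."""
    from scipy.ndimage import correlate1d

    r = (len(k1d) - 1) // 2
    out = correlate1d(img, k1d, axis=0, mode="nearest")
    out = correlate1d(out, k1d, axis=1, mode="nearest")
    return out[r:img.shape[0] - r, r:img.shape[1] - r]


def ssim(a: np.ndarray, b: np.ndarray, data_range: Optional[float] = None,
         k1: float = 0.01, k2: float = 0.03, sigma: float = 1.5,
         win_size: int = 11) -> float:
    """Structural similarity index between two images.

    Direct implementation of the standard definition: local means,
    variances and covariance under an 11 x 11 Gaussian window (sigma 1.5),
    stabilisers C1 = (k1 R)^2, C2 = (k2 R)^2 with R the dynamic range, and
    the mean of the per-pixel SSIM map over the interior (full-window)
    region.  Identical inputs score exactly 1; the score is bounded by
    [-1, 1].  When ``data_range`` is omitted the maximum of the two images
    is used.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("images must share a shape")
    if win_size % 2 == 0 or win_size < 3:
        raise ValueError("window size must be odd and >= 3")
    if min(a.shape) < win_size:
        raise ValueError("image smaller than the SSIM window")
    if data_range is None:
        data_range = float(max(a.max(), b.max()))
    if data_range <= 0:
        raise ValueError("dynamic range must be positive")
    k = _gaussian_kernel1d(sigma, (win_size - 1) // 2)
    mu_a = _windowed(a, k)
    mu_b = _windowed(b, k)
    s_aa = _windowed(a * a, k) - mu_a * mu_a
    s_bb = _windowed(b * b, k) - mu_b * mu_b
    s_ab = _windowed(a * b, k) - mu_a * mu_b
    c1 = (k1 * data_range) ** 2
    c2 = (k2 * data_range) ** 2
    num = (2.0 * mu_a * mu_b + c1) * (2.0 * s_ab + c2)
    den = (mu_a ** 2 + mu_b ** 2 + c1) * (s_aa + s_bb + c2)
    return float(np.mean(num / den))
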