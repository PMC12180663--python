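"""End-to-end simulated transmittance experiments.

Couples the building blocks into the measurement protocols of the phantom
study: a Monte Carlo transmittance run of a tumor-archetype phantom,
normalization by a matched homogeneous-host run, and the contrast readout.
This is the desk-scale stand-in for the GPU campaign behind the published
contrast table (10^9 photons per grid position there; 10^7-photon
single-position runs with homogeneous-reference normalization here).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np

from .images import DetectorImage
from .mc import DetectorSpec, PathStats, simulate
from .phantom import fixture_phantom
from .pipeline import (ContrastResult, compute_contrast,
                       normalize_by_reference, symmetrize)

__all__ = ["CaseResult", "run_case", "mc_contrast", "table4_protocol",
           "CASES", "case_seed"]

#: The eight measured scenarios: archetype x host x wavelength.
CASES: Tuple[Tuple[str, str, float], ...] = tuple(
    (tumor, host, wl)
    for host in ("solid", "liquid")
    for wl in (670.0, 830.0)
    for tumor in ("FADN", "ADC")
)


def case_seed(base_seed: int, tag: str) -> int:
    """Stable per-run seed below 2^31 derived from a base seed and a label."""
    crc = zlib.crc32(tag.encode("utf-8"))
    h = np.random.SeedSequence(
        [int(base_seed) & 0x7FFFFFFF, crc & 0x7FFFFFFF]
    ).generate_state(1, np.uint64)[0]
    return int(h & np.uint64(0x7FFFFFFF))


@dataclass
class CaseResult:
    """One normalized-contrast measurement and its raw ingredients."""

    tumor: str
    host: str
    wavelength: float
    contrast: ContrastResult
    image: DetectorImage
    reference: DetectorImage
    stats: PathStats
    ref_stats: PathStats


def run_case(
    tumor: Optional[str],
    host: str,
    wavelength: float,
    n_photons: int,
    seed: int,
    voxel_size: float = 1.0,
    g: float = 0.0,
    detector: Optional[DetectorSpec] = None,
) -> Tuple[DetectorImage, PathStats]:
    """Simulate one exit-face image (``tumor=None`` = homogeneous reference)."""
    ph = fixture_phantom(tumor or "FADN", host, wavelength,
                         voxel_size=voxel_size, g=g,
                         include_inclusion=tumor is not None)
    if detector is None:
        # camera-faithful observable: radiance along the exit-face normal
        detector = DetectorSpec(mode="radiance")
    return simulate(ph, detector=detector, n_photons=n_photons, seed=seed,
                    wavelength=wavelength)


def mc_contrast(
    tumor: str,
    host: str,
    wavelength: float,
    n_photons: int = 10_000_000,
    seed: int = 0,
    reference: Optional[DetectorImage] = None,
    symmetrize_images: bool = True,
    voxel_size: float = 1.0,
    g: float = 0.0,
) -> CaseResult:
    """Contrast C = |1 - M| of one simulated scenario.

    The inclusion image is normalized by a matched homogeneous-host
    reference (supplied, or simulated with an independent seed), both
    optionally averaged over the exact dihedral symmetry of the on-axis
    geometry to reduce Monte Carlo pixel noise, then median-filtered, and
    the extremum is read inside the central region of interest.
    """
    img, stats = run_case(tumor, host, wavelength, n_photons,
                          case_seed(seed, f"{tumor}/{host}/{wavelength}"),
                          voxel_size=voxel_size, g=g)
    if reference is None:
        reference, ref_stats = run_case(
            None, host, wavelength, n_photons,
            case_seed(seed, f"ref/{host}/{wavelength}"),
            voxel_size=voxel_size, g=g)
    else:
        ref_stats = None
    if symmetrize_images:
        img_use = DetectorImage(symmetrize(img.data), img.pixel_pitch,
                                img.wavelength, img.n_photons, img.seed)
        ref_use = DetectorImage(symmetrize(reference.data),
                                reference.pixel_pitch, reference.wavelength,
                                reference.n_photons, reference.seed)
    else:
        img_use, ref_use = img, reference
    norm = normalize_by_reference(img_use, ref_use)
    contrast = compute_contrast(norm)
    return CaseResult(tumor=tumor, host=host, wavelength=wavelength,
                      contrast=contrast, image=img, reference=reference,
                      stats=stats, ref_stats=ref_stats)


def table4_protocol(
    seed: int = 0,
    n_photons: int = 10_000_000,
    hosts: Tuple[str, ...] = ("solid", "liquid"),
    wavelengths: Tuple[float, ...] = (670.0, 830.0),
    tumors: Tuple[str, ...] = ("FADN", "ADC"),
    **kwargs,
) -> Dict[Tuple[str, str, float], CaseResult]:
    """All archetype/host/wavelength contrasts, sharing reference runs.

    One homogeneous reference per (host, wavelength) serves both tumor
    archetypes, as in the physical experiment where the same unperturbed
    host is imaged once.
    """
    results: Dict[Tuple[str, str, float], CaseResult] = {}
    for host in hosts:
        for wl in wavelengths:
            reference, _ = run_case(None, host, wl, n_photons,
                                    case_seed(seed, f"ref/{host}/{wl}"),
                                    **kwargs)
            for tumor in tumors:
                results[(tumor, host, wl)] = mc_contrast(
                    tumor, host, wl, n_photons=n_photons, seed=seed,
                    reference=reference, **kwargs)
    return results
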