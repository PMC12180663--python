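"""Voxel Monte Carlo CW transmittance simulation.

Emulates the camera-side of the transmittance experiment: a pencil beam
enters the slab phantom at the illuminated face and every photon packet that
leaves through the opposite (camera) face is accumulated into an exit-face
image, together with pathlength statistics for the Modified Beer-Lambert
step.  The transport model is the standard tissue-optics weighted-packet
scheme: exponential step sampling against the local scattering coefficient,
implicit capture of absorption along every sub-step, Henyey-Greenstein
scattering, unpolarized Fresnel reflection/refraction at refractive-index
steps, and Russian roulette for low-weight packets.

Determinism contract: a run is a pure function of (phantom, source,
detector geometry, n_photons, seed).  Each photon owns a counter-based RNG
stream derived from (seed, photon index), so identical inputs give
bit-identical images and tallies.

Source power normalization: packets start with unit weight just inside the
illuminated face, i.e. all fractions (transmittance, reflectance, ...) are
relative to the power coupled into the slab.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Optional, Tuple

import numpy as np

from . import _kernel
from .images import DetectorImage
from .phantom import HOST_LABEL, VoxelPhantom

__all__ = [
    "SourceSpec",
    "DetectorSpec",
    "PathStats",
    "simulate",
    "sample_scattering",
    "fresnel_boundary",
    "roulette",
]


@dataclass(frozen=True)
class SourceSpec:
    """Pencil beam entering the illuminated (z = 0) face along +z."""

    x: float = 0.0
    y: float = 0.0


@dataclass(frozen=True)
class DetectorSpec:
    """Exit-face camera: square pixel grid centred on the beam axis.

    The default 128 pixels at 0.625 mm pitch image an 80 mm x 80 mm field,
    matching the camera field of the physical experiment.  All photons
    crossing the exit face are tallied regardless of exit angle.

    ``mode`` selects the imaged observable:

    * ``"flux"`` - angle-integrated photon flux through each pixel (every
      exiting packet scores its weight);
    * ``"radiance"`` - the radiance leaving the face along the normal,
      which is what a lens focused on the exit plane actually collects.
      It is reconstructed per pixel from two angular moments of the
      exiting packets under a two-term (P1) model of the exit radiance,
      L(mu) = (phi + 3 J mu) / 4 pi, with the Fresnel escape-cone moments
      of the face mismatch folded in.  Steep-angle photons, which carry a
      laterally blurred view of interior structure, are thereby
      de-emphasised exactly as a camera de-emphasises them.

    ``cos_min`` optionally discards packets below an exit-direction cosine
    (a hard numerical aperture cut); it applies to either mode.
    """

    npix: int = 128
    pitch: float = 0.625
    mode: str = "flux"
    cos_min: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in ("flux", "radiance"):
            raise ValueError(f"unknown detector mode {self.mode!r}")

    @property
    def field(self) -> float:
        return self.npix * self.pitch


@lru_cache(maxsize=32)
def _radiance_weights(n_in: float, n_out: float) -> Tuple[float, float]:
    """Per-pixel combination (alpha, beta) with normal radiance proportional
    to alpha * sum(w) + beta * sum(w / mu_internal).

    Derived by inverting the Fresnel-weighted angular moments of the P1
    exit-radiance family: with T(mu) the internal-to-exterior Fresnel
    transmission and A_k = int_0^1 T(mu) mu^k dmu, the tallies
    S1 = sum w and S2 = sum w/mu estimate (phi A1 + 3 J A2)/2 and
    (phi A0 + 3 J A1)/2; solving for phi + 3 J (proportional to L(mu=1))
    gives fixed coefficients.  Total internal reflection bounds 1/mu, so
    the weights stay finite.
    """
    from scipy.integrate import quad

    def T(mu: float) -> float:
        refl, _ = _kernel._fresnel_r(n_in, n_out, mu)
        return 1.0 - refl

    a0 = quad(T, 0.0, 1.0, limit=200)[0]
    a1 = quad(lambda m: T(m) * m, 0.0, 1.0, limit=200)[0]
    a2 = quad(lambda m: T(m) * m * m, 0.0, 1.0, limit=200)[0]
    m = np.array([[a1, a2], [a0, a1]])
    alpha, beta = 2.0 * np.linalg.inv(m).sum(axis=0)
    return float(alpha), float(beta)


@dataclass
class PathStats:
    """Weight bookkeeping and pathlength statistics of one run.

    All weights are fractions of the power coupled into the slab.  The
    balance ``1 + roulette_gain ==
    detected + absorbed + back_reflected + side_escaped + roulette_killed``
    (per unit launched weight) holds to floating-point accuracy.
    """

    n_photons: int
    seed: int
    detected_weight: float
    detected_path_sum: float      # sum of weight * total pathlength, mm
    absorbed_weight: float
    back_reflected_weight: float
    side_escaped_weight: float
    roulette_killed: float
    roulette_gain: float
    detected_packets: int

    @property
    def total_transmittance(self) -> float:
        return self.detected_weight / self.n_photons

    @property
    def total_reflectance(self) -> float:
        return self.back_reflected_weight / self.n_photons

    @property
    def mean_total_pathlength(self) -> float:
        """Weight-averaged total pathlength of detected photons, mm."""
        if self.detected_weight == 0:
            return float("nan")
        return self.detected_path_sum / self.detected_weight

    def weight_balance_error(self) -> float:
        """Relative defect of the weight-conservation identity."""
        n = float(self.n_photons)
        lhs = n + self.roulette_gain
        rhs = (self.detected_weight + self.absorbed_weight
               + self.back_reflected_weight + self.side_escaped_weight
               + self.roulette_killed)
        return abs(lhs - rhs) / n


def _material_tables(phantom: VoxelPhantom):
    nlab = max(phantom.materials) + 1
    mua = np.zeros(nlab)
    mus = np.zeros(nlab)
    n = np.ones(nlab)
    g = np.zeros(nlab)
    for lab, props in phantom.materials.items():
        mua[lab] = props.mua
        mus[lab] = props.mus
        n[lab] = props.n
        g[lab] = props.g
    return mua, mus, n, g


def _safe_distance_map(phantom: VoxelPhantom) -> np.ndarray:
    """Per-voxel lower bound (mm) on the distance to a material change.

    Computed only in a padded crop around the heterogeneous region (it is
    consulted only there); a conservative voxel-diagonal margin is
    subtracted so the bound holds for any point inside the voxel.
    """
    from scipy.ndimage import distance_transform_edt

    labels = phantom.labels
    dsafe = np.zeros(labels.shape, dtype=np.float64)
    mask = labels != HOST_LABEL
    if not mask.any():
        return dsafe
    h = phantom.voxel_size
    idx = np.argwhere(mask)
    lo = np.maximum(idx.min(axis=0) - 4, 0)
    hi = np.minimum(idx.max(axis=0) + 5, labels.shape)
    crop = labels[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    out = np.zeros(crop.shape, dtype=np.float64)
    for lab in np.unique(crop):
        region = crop == lab
        d = distance_transform_edt(region, sampling=h)
        out[region] = d[region]
    margin = 1.75 * h  # > sqrt(3) voxel diagonals, centre-to-point slack
    dsafe[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = np.maximum(out - margin, 0.0)
    return dsafe


def _hetero_bbox(phantom: VoxelPhantom) -> Tuple[float, ...]:
    """Physical AABB of the non-host voxels, or an empty box."""
    mask = phantom.labels != HOST_LABEL
    if not mask.any():
        return (0.0, 0.0, 0.0, 0.0, 0.0, 0.0, False)
    ox, oy, _ = phantom.origin
    h = phantom.voxel_size
    idx = np.argwhere(mask)
    lo = idx.min(axis=0)
    hi = idx.max(axis=0) + 1
    return (ox + lo[0] * h, ox + hi[0] * h,
            oy + lo[1] * h, oy + hi[1] * h,
            lo[2] * h, hi[2] * h, True)


def simulate(
    phantom: VoxelPhantom,
    source: Optional[SourceSpec] = None,
    detector: Optional[DetectorSpec] = None,
    n_photons: int = 1_000_000,
    seed: int = 0,
    roulette_threshold: float = 1e-4,
    roulette_factor: float = 10.0,
    wavelength: float = 0.0,
) -> Tuple[DetectorImage, PathStats]:
    """Run a CW transmittance simulation through ``phantom``.

    Returns the accumulated exit-face image and the weight/pathlength
    statistics.  ``wavelength`` is a pass-through tag stored on the image.
    """
    source = source or SourceSpec()
    detector = detector or DetectorSpec()
    if n_photons < 1:
        raise ValueError("n_photons must be >= 1")
    if n_photons > 2**53:
        raise ValueError("photon count overflows the weight accumulator")
    ex, ey, ez = phantom.extent
    ox, oy, _ = phantom.origin
    if not (ox < source.x < ox + ex and oy < source.y < oy + ey):
        raise ValueError("source entry point lies outside the illuminated face")
    if roulette_threshold < 0 or roulette_factor <= 1:
        raise ValueError("invalid roulette parameters")

    mua, mus, n_tab, g_tab = _material_tables(phantom)
    bbox = _hetero_bbox(phantom)
    img = np.zeros((detector.npix, detector.npix), dtype=np.float64)
    img_inv = np.zeros_like(img)
    tallies = _kernel.run_photons(
        phantom.labels, _safe_distance_map(phantom), mua, mus, n_tab, g_tab,
        phantom.voxel_size, ox, oy, ex, ey, ez,
        phantom.exterior_n,
        bbox[0], bbox[1], bbox[2], bbox[3], bbox[4], bbox[5], bbox[6],
        source.x, source.y,
        n_photons, seed,
        img, img_inv, detector.npix, detector.pitch, detector.cos_min,
        roulette_threshold, roulette_factor,
    )
    if detector.mode == "radiance":
        alpha, beta = _radiance_weights(float(n_tab[HOST_LABEL]),
                                        float(phantom.exterior_n))
        img = np.maximum(alpha * img + beta * img_inv, 0.0)
    stats = PathStats(
        n_photons=n_photons,
        seed=seed,
        detected_weight=float(tallies[0]),
        detected_path_sum=float(tallies[1]),
        absorbed_weight=float(tallies[2]),
        back_reflected_weight=float(tallies[3]),
        side_escaped_weight=float(tallies[4]),
        roulette_killed=float(tallies[5]),
        roulette_gain=float(tallies[6]),
        detected_packets=int(tallies[7]),
    )
    image = DetectorImage(img, detector.pitch, wavelength, n_photons, seed)
    return image, stats


# --- exposed sampling primitives (used by the kernel; unit-testable) --------

def sample_scattering(g: float, n: int, seed: int = 0) -> Tuple[np.ndarray, np.ndarray]:
    """Draw ``n`` Henyey-Greenstein deflection angles.

    Returns (cos theta, phi).  For g = 0 the cosine is uniform on [-1, 1];
    the azimuth is always uniform on [0, 2 pi).
    """
    if not 0.0 <= g < 1.0:
        raise ValueError("anisotropy g must be in [0, 1)")
    rng = np.random.default_rng(seed)
    u = rng.random(n)
    if g < 1e-6:
        cost = 2.0 * u - 1.0
    else:
        tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
        cost = np.clip((1.0 + g * g - tmp * tmp) / (2.0 * g), -1.0, 1.0)
    phi = 2.0 * math.pi * rng.random(n)
    return cost, phi


def fresnel_boundary(
    n1: float,
    n2: float,
    cos_incidence: float,
    rng: Optional[np.random.Generator] = None,
):
    """Reflect-or-transmit decision at a refractive-index step.

    Returns ``(reflected, cos_transmitted)``: for index-matched media the
    packet always transmits with its direction unchanged; beyond the
    critical angle it always reflects (total internal reflection).  With
    ``rng=None`` the unpolarized reflectance itself is returned instead of a
    sampled decision.
    """
    if n1 < 1 or n2 < 1:
        raise ValueError("refractive indices must be >= 1")
    if not 0.0 <= cos_incidence <= 1.0:
        raise ValueError("incidence cosine must be in [0, 1]")
    refl, ct = _kernel._fresnel_r(n1, n2, cos_incidence)
    if rng is None:
        return refl, ct
    return bool(rng.random() < refl), ct


def roulette(
    weight: float,
    threshold: float = 1e-4,
    survival_factor: float = 10.0,
    rng: Optional[np.random.Generator] = None,
) -> float:
    """Russian roulette: unbiased termination of low-weight packets.

    Below ``threshold`` the packet survives with probability
    1/``survival_factor`` and is boosted by that factor, else it is killed
    (weight 0).  Above threshold the weight passes through unchanged.
    """
    if weight < 0:
        raise ValueError("weight must be >= 0")
    if weight >= threshold:
        return weight
    rng = rng or np.random.default_rng()
    if rng.random() * survival_factor < 1.0:
        return weight * survival_factor
    return 0.0
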