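"""Synthetic transmittance image stacks with known ground truth.

The generator emulates what the EMCCD camera sees in the 25-position scan:
a broad, smooth diffuse-transmittance spot (the unperturbed background),
dimmed locally by the inclusion's attenuation footprint that moves with the
inclusion across the grid, with photon shot noise and additive read noise
on top.

The forward model is deliberately consistent with the Modified Beer-Lambert
law used by the retrieval: each image is

    I_p(x, y) = B(x, y) * exp(-L * dmua((x, y) - p)),

with B the background profile, L the mean-pathlength scalar of the pipeline
and dmua a smooth bump of known amplitude.  That choice isolates pipeline
correctness (normalization, MBLL, unmixing) from Monte Carlo physics; the
physics-faithful stacks come from :mod:`dotphantom.mc`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Tuple

import numpy as np

from .absorbers import ConcentrationPair, ExtinctionSystem
from .diffusion import SlabModel, mean_total_pathlength
from .images import ConcentrationMap, DeltaMuaMap, ImageStack
from .phantom import ScanGrid, grid_positions, host_properties

__all__ = ["SyntheticScene", "generate_stack", "ground_truth",
           "fadn_adc_scene_pair", "default_pathlengths"]

_WAVELENGTHS = (670.0, 830.0)


def default_pathlengths(host: str = "solid",
                        thickness: float = 40.0) -> Dict[float, float]:
    """MTPL (mm) per wavelength for a host slab, from the diffusion model."""
    out = {}
    for wl in _WAVELENGTHS:
        p = host_properties(host, wl)
        out[wl] = mean_total_pathlength(
            SlabModel(p.mua, p.musp, thickness, n_in=p.n, n_out=1.0)
        )
    return out


@dataclass(frozen=True)
class SyntheticScene:
    """Parameters of one synthetic two-wavelength acquisition.

    The attenuation perturbation is specified either directly as per-
    wavelength ``dmua`` amplitudes (mm^-1, at the bump centre) or as
    concentration changes ``conc`` (uM) mapped through ``system``; exactly
    one of the two must be given.

    Noise: ``peak_counts`` sets the mean photon count at the background
    maximum (Poisson shot noise); ``read_sigma`` the additive Gaussian read
    noise in counts.  ``peak_counts=None`` produces noise-free images on an
    arbitrary intensity scale of 1 at the background peak.
    """

    npix: int = 128
    pitch: float = 0.625                    # mm; 80 mm field at 128 px
    background_sigma: float = 25.0          # mm; diffuse-spot width
    footprint_width: float = 12.0           # mm; bump full width (= 4 sigma)
    dmua: Optional[Dict[float, float]] = None
    conc: Optional[ConcentrationPair] = None
    system: Optional[ExtinctionSystem] = None
    pathlengths: Optional[Dict[float, float]] = None
    peak_counts: Optional[float] = 1e4
    read_sigma: float = 2.0
    grid: ScanGrid = field(default_factory=ScanGrid)
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.dmua is None) == (self.conc is None):
            raise ValueError("specify exactly one of dmua or conc")
        if self.conc is not None and self.system is None:
            raise ValueError("a concentration-defined scene needs a system")
        if self.background_sigma <= 0 or self.footprint_width <= 0:
            raise ValueError("widths must be positive")
        if self.peak_counts is not None and self.peak_counts <= 0:
            raise ValueError("peak count must be positive")
        if self.npix < 1 or self.pitch <= 0:
            raise ValueError("invalid image geometry")

    def pathlength(self, wavelength: float) -> float:
        table = self.pathlengths if self.pathlengths is not None \
            else _DEFAULT_L
        return table[wavelength]

    def dmua_amplitude(self, wavelength: float) -> float:
        """Peak dmua (mm^-1) of the perturbation at ``wavelength``."""
        if self.dmua is not None:
            return self.dmua[wavelength]
        idx = self.system.wavelengths.index(wavelength)
        row = self.system.matrix[idx]
        return float(row[0] * self.conc.dye * 1e-6
                     + row[1] * self.conc.inks * 1e-6)

    def pixel_axes(self) -> Tuple[np.ndarray, np.ndarray]:
        half = 0.5 * self.npix * self.pitch
        c = (np.arange(self.npix) + 0.5) * self.pitch - half
        return c, c  # (x along columns, y along rows)


# pathlengths of the 40 mm silicone slab; computed once at import
_DEFAULT_L = default_pathlengths("solid")


def _bump(scene: SyntheticScene, cx: float, cy: float) -> np.ndarray:
    """Unit-amplitude smooth footprint centred at (cx, cy), on the pixel grid."""
    x, y = scene.pixel_axes()
    sig = scene.footprint_width / 4.0
    gx = np.exp(-0.5 * ((x - cx) / sig) ** 2)
    gy = np.exp(-0.5 * ((y - cy) / sig) ** 2)
    return gy[:, None] * gx[None, :]


def _background(scene: SyntheticScene) -> np.ndarray:
    x, y = scene.pixel_axes()
    gx = np.exp(-0.5 * (x / scene.background_sigma) ** 2)
    gy = np.exp(-0.5 * (y / scene.background_sigma) ** 2)
    return gy[:, None] * gx[None, :]


def generate_stack(scene: SyntheticScene, wavelength: float) -> ImageStack:
    """Generate the full grid of camera images at one wavelength.

    Deterministic per (scene.seed, wavelength): the same scene renders
    bit-identical stacks.  The centre (on-axis) position is flagged for the
    normalization step.
    """
    if scene.dmua is not None and wavelength not in scene.dmua:
        raise ValueError(f"scene defines no perturbation at {wavelength} nm")
    positions = np.asarray(grid_positions(scene.grid))
    center = int(np.argmin(np.hypot(positions[:, 0], positions[:, 1])))
    bg = _background(scene)
    amp = scene.dmua_amplitude(wavelength)
    L = scene.pathlength(wavelength)
    rng = np.random.default_rng([scene.seed & 0x7FFFFFFF, int(wavelength)])
    images = np.empty((len(positions), scene.npix, scene.npix))
    for i, (px, py) in enumerate(positions):
        clean = bg * np.exp(-L * amp * _bump(scene, px, py))
        if scene.peak_counts is None:
            images[i] = clean
        else:
            counts = rng.poisson(clean * scene.peak_counts).astype(np.float64)
            counts += rng.normal(0.0, scene.read_sigma, counts.shape)
            images[i] = np.maximum(counts, 0.0)
    return ImageStack(images, positions, center, wavelength, scene.pitch,
                      provenance="synthetic")


def ground_truth(scene: SyntheticScene):
    """Analytic perturbation maps at the centre position.

    Returns ``(dmua_maps, conc_map)``: one :class:`DeltaMuaMap` per
    wavelength and, when the scene carries an extinction system, the exact
    :class:`ConcentrationMap` of the injected (dye, ink) change (otherwise
    ``None``).
    """
    bump = _bump(scene, 0.0, 0.0)
    valid = np.ones_like(bump, dtype=bool)
    maps = {}
    for wl in _WAVELENGTHS:
        if scene.dmua is not None and wl not in scene.dmua:
            continue
        maps[wl] = DeltaMuaMap(scene.dmua_amplitude(wl) * bump, valid.copy(),
                               wl, scene.pathlength(wl), scene.pitch)
    conc_map = None
    if scene.conc is not None:
        conc_map = ConcentrationMap(scene.conc.dye * bump,
                                    scene.conc.inks * bump,
                                    valid.copy(), scene.pitch)
    return maps, conc_map


def fadn_adc_scene_pair(
    system: ExtinctionSystem,
    ink_multiple: float = 4.0,
    dye_uM: float = 0.02,
    ink_uM: float = 0.03,
    **kwargs,
) -> Tuple[SyntheticScene, SyntheticScene]:
    """Benign/malignant scene pair with shared dye and scaled ink load.

    Both scenes carry the same dye (shell) perturbation; the malignant
    (ADC) scene's ink perturbation is ``ink_multiple`` times the benign
    (FADN) one, mirroring the roughly fourfold core-absorption ratio of the
    fabricated inclusions.  With ``ink_multiple=1`` the scenes coincide.
    """
    fadn = SyntheticScene(conc=ConcentrationPair(dye_uM, ink_uM),
                          system=system, **kwargs)
    adc = replace(fadn, conc=ConcentrationPair(dye_uM, ink_uM * ink_multiple))
    return fadn, adc
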