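"""Voxelized digital phantoms: slab hosts with core-shell tumor inclusions.

The digital phantom mirrors the physical transmittance setup: a 200 x 200 x
40 mm slab of host medium (milk/water or silicone) containing one spherical
core-shell inclusion at mid-depth.  The inner 10 mm core carries the
HbR-mimicking absorber load (printer inks) and the 20 mm shell the
HbO-mimicking dye, so that a malignant-tumor archetype (adenocarcinoma, ADC)
differs from a benign one (fibroadenoma, FADN) only through the core
absorption.

Coordinates are physical millimetres with the origin at the centre of the
illuminated face and z pointing into the slab.  Voxel membership is decided
by voxel-centre containment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np

__all__ = [
    "OpticalProperties",
    "VoxelPhantom",
    "CoreShellInclusion",
    "ScanGrid",
    "build_slab",
    "embed_core_shell",
    "grid_positions",
    "fixture_phantom",
    "HOST_LABEL",
    "SHELL_LABEL",
    "CORE_LABEL",
    "TISSUE_OPTICS",
    "REFRACTIVE_INDEX",
]

HOST_LABEL = 0
SHELL_LABEL = 1
CORE_LABEL = 2


@dataclass(frozen=True)
class OpticalProperties:
    """Optical properties of one material region.

    mua and musp (reduced scattering) are in mm^-1, g is the scattering
    anisotropy and n the refractive index.  The transport scattering
    coefficient used by the Monte Carlo is mus = musp / (1 - g); at fixed
    musp the diffuse observables of a thick slab are insensitive to g
    (similarity relation), so g is a sampling choice, not a physical one.
    """

    mua: float
    musp: float
    g: float = 0.0
    n: float = 1.4

    def __post_init__(self) -> None:
        if self.mua < 0:
            raise ValueError("mua must be >= 0")
        if self.musp <= 0:
            raise ValueError("musp must be > 0")
        if not 0.0 <= self.g < 1.0:
            raise ValueError("anisotropy g must be in [0, 1)")
        if self.n < 1.0:
            raise ValueError("refractive index must be >= 1")

    @property
    def mus(self) -> float:
        """Transport scattering coefficient mus = musp/(1-g), mm^-1."""
        return self.musp / (1.0 - self.g)


@dataclass
class VoxelPhantom:
    """Labelled voxel grid with per-label optical properties.

    ``labels`` has shape (nx, ny, nz); voxel (i, j, k) spans
    ``origin + [i, j, k] * voxel_size`` to ``origin + [i+1, j+1, k+1] *
    voxel_size`` in physical mm.  The slab faces lie at z = 0 (illuminated)
    and z = thickness (exit/camera face).
    """

    labels: np.ndarray
    voxel_size: float
    materials: Dict[int, OpticalProperties]
    exterior_n: float = 1.0

    def __post_init__(self) -> None:
        self.labels = np.ascontiguousarray(self.labels, dtype=np.uint8)
        if self.labels.ndim != 3:
            raise ValueError("labels must be 3-D")
        if self.voxel_size <= 0:
            raise ValueError("voxel size must be positive")
        present = set(np.unique(self.labels).tolist())
        missing = present - set(self.materials)
        if missing:
            raise ValueError(f"labels {sorted(missing)} have no materials entry")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.labels.shape

    @property
    def extent(self) -> Tuple[float, float, float]:
        """Physical (x, y, z) extent in mm."""
        return tuple(s * self.voxel_size for s in self.labels.shape)

    @property
    def thickness(self) -> float:
        return self.labels.shape[2] * self.voxel_size

    @property
    def origin(self) -> Tuple[float, float, float]:
        ex, ey, _ = self.extent
        return (-ex / 2.0, -ey / 2.0, 0.0)

    def voxel_centers(self, axis: int) -> np.ndarray:
        o = self.origin[axis]
        n = self.labels.shape[axis]
        return o + (np.arange(n) + 0.5) * self.voxel_size

    def label_counts(self) -> Dict[int, int]:
        vals, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(vals.tolist(), counts.tolist()))


@dataclass(frozen=True)
class CoreShellInclusion:
    """Concentric-sphere inclusion: absorber-loaded core inside a dye shell."""

    center: Tuple[float, float, float]
    core_props: OpticalProperties
    shell_props: OpticalProperties
    core_diameter: float = 10.0
    shell_diameter: float = 20.0

    def __post_init__(self) -> None:
        if self.core_diameter < 0 or self.shell_diameter <= 0:
            raise ValueError("diameters must be positive")
        if self.core_diameter > self.shell_diameter:
            raise ValueError("core diameter cannot exceed shell diameter")


@dataclass(frozen=True)
class ScanGrid:
    """Regular lateral grid of inclusion positions centred on the beam axis."""

    extent: float = 40.0
    step: float = 10.0
    depth: float = 20.0

    def __post_init__(self) -> None:
        if self.extent < 0:
            raise ValueError("extent must be >= 0")
        if self.extent > 0 and self.step <= 0:
            raise ValueError("step must be positive")


def _n_steps(extent: float, step: float) -> int:
    if extent == 0:
        return 0
    ratio = extent / step
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError(f"grid extent {extent} is not an integer multiple of "
                         f"step {step}")
    return int(round(ratio))


def build_slab(
    dimensions: Tuple[float, float, float],
    host: OpticalProperties,
    voxel_size: float = 1.0,
    exterior_n: float = 1.0,
) -> VoxelPhantom:
    """Build a homogeneous slab phantom of the given physical extent (mm)."""
    if voxel_size <= 0:
        raise ValueError("voxel size must be positive")
    shape = []
    for d in dimensions:
        ratio = d / voxel_size
        if abs(ratio - round(ratio)) > 1e-9 or d <= 0:
            raise ValueError(
                f"dimension {d} mm is not divisible by voxel size {voxel_size} mm"
            )
        shape.append(int(round(ratio)))
    labels = np.full(shape, HOST_LABEL, dtype=np.uint8)
    return VoxelPhantom(labels, voxel_size, {HOST_LABEL: host}, exterior_n)


def embed_core_shell(phantom: VoxelPhantom, inc: CoreShellInclusion) -> VoxelPhantom:
    """Rasterize a core-shell sphere into a copy of the phantom.

    Voxels whose centres fall within the core radius get the core label,
    within the shell radius (but outside the core) the shell label.  The
    inclusion must lie entirely inside the slab.
    """
    ex, ey, ez = phantom.extent
    ox, oy, oz = phantom.origin
    cx, cy, cz = inc.center
    r_shell = inc.shell_diameter / 2.0
    if not (ox + r_shell <= cx <= ox + ex - r_shell
            and oy + r_shell <= cy <= oy + ey - r_shell
            and oz + r_shell <= cz <= oz + ez - r_shell):
        raise ValueError("inclusion crosses the slab boundary")

    xs = phantom.voxel_centers(0) - cx
    ys = phantom.voxel_centers(1) - cy
    zs = phantom.voxel_centers(2) - cz
    r2 = (xs[:, None, None] ** 2 + ys[None, :, None] ** 2
          + zs[None, None, :] ** 2)
    labels = phantom.labels.copy()
    labels[r2 <= r_shell ** 2] = SHELL_LABEL
    labels[r2 <= (inc.core_diameter / 2.0) ** 2] = CORE_LABEL
    materials = dict(phantom.materials)
    materials[SHELL_LABEL] = inc.shell_props
    materials[CORE_LABEL] = inc.core_props
    return VoxelPhantom(labels, phantom.voxel_size, materials, phantom.exterior_n)


def grid_positions(grid: ScanGrid) -> List[Tuple[float, float]]:
    """Row-major (x, y) inclusion centres of the scan protocol.

    A 40 mm extent at 10 mm steps gives the 5 x 5 = 25 acquisition positions
    of the transmittance protocol, symmetric about the beam axis.
    """
    n = _n_steps(grid.extent, grid.step)
    coords = [-grid.extent / 2.0 + i * grid.step for i in range(n + 1)]
    return [(x, y) for y in coords for x in coords]


# --- tabulated phantom optics -------------------------------------------------

#: Measured (mua, musp) in mm^-1 per material and wavelength (nm), from
#: time-resolved characterization of the fabricated phantoms.
TISSUE_OPTICS: Dict[Tuple[str, float], Tuple[float, float]] = {
    ("fadn_core", 670.0): (0.00451, 0.919),
    ("fadn_core", 830.0): (0.00102, 0.731),
    ("adc_core", 670.0): (0.0179, 0.883),
    ("adc_core", 830.0): (0.000972, 0.760),
    ("shell", 670.0): (0.00210, 1.158),
    ("shell", 830.0): (0.00265, 0.821),
    ("liquid_host", 670.0): (0.000811, 1.095),
    ("liquid_host", 830.0): (0.00209, 0.759),
    ("solid_host", 670.0): (0.00177, 0.954),
    ("solid_host", 830.0): (0.00125, 0.772),
}

#: Refractive indices: epoxy-resin inclusions 1.56 (manufacturer value);
#: hosts set to standard water (milk dilution) and silicone optics.
REFRACTIVE_INDEX: Dict[str, float] = {
    "resin": 1.56,
    "liquid_host": 1.33,
    "solid_host": 1.40,
    "exterior": 1.00,
}

SLAB_DIMENSIONS_MM = (200.0, 200.0, 40.0)
INCLUSION_DEPTH_MM = 20.0


def host_properties(host: str, wavelength: float, g: float = 0.0) -> OpticalProperties:
    """Host-medium optical properties for ``host`` in {"solid", "liquid"}."""
    key = f"{host}_host"
    if (key, wavelength) not in TISSUE_OPTICS:
        raise ValueError(f"unknown host/wavelength case {host!r}/{wavelength}")
    mua, musp = TISSUE_OPTICS[(key, wavelength)]
    return OpticalProperties(mua, musp, g=g, n=REFRACTIVE_INDEX[key])


def fixture_phantom(
    tumor: str,
    host: str,
    wavelength: float,
    voxel_size: float = 1.0,
    g: float = 0.0,
    include_inclusion: bool = True,
) -> VoxelPhantom:
    """Digital phantom of one measured scenario.

    Parameters
    ----------
    tumor : {"FADN", "ADC"}
        Benign (fibroadenoma) or malignant (adenocarcinoma) archetype.
    host : {"solid", "liquid"}
        Silicone slab or milk/water cuvette.
    wavelength : {670, 830}
        Illumination wavelength in nm.
    g : float
        Scattering anisotropy used for transport (musp held fixed).
    include_inclusion : bool
        If False, return the bare homogeneous host slab (the matched
        reference medium used for normalization).
    """
    tumor_key = tumor.lower()
    if tumor_key not in ("fadn", "adc"):
        raise ValueError(f"unknown tumor archetype {tumor!r}")
    wavelength = float(wavelength)
    hostp = host_properties(host, wavelength, g=g)
    slab = build_slab(SLAB_DIMENSIONS_MM, hostp, voxel_size,
                      exterior_n=REFRACTIVE_INDEX["exterior"])
    if not include_inclusion:
        return slab
    n_resin = REFRACTIVE_INDEX["resin"]
    core_mua, core_musp = TISSUE_OPTICS[(f"{tumor_key}_core", wavelength)]
    shell_mua, shell_musp = TISSUE_OPTICS[("shell", wavelength)]
    inc = CoreShellInclusion(
        center=(0.0, 0.0, INCLUSION_DEPTH_MM),
        core_props=OpticalProperties(core_mua, core_musp, g=g, n=n_resin),
        shell_props=OpticalProperties(shell_mua, shell_musp, g=g, n=n_resin),
    )
    return embed_core_shell(slab, inc)
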