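"""Two-wavelength absorber model: extinction matrices and linear unmixing.

A pair of absorbers with crossed spectral behaviour emulates the two
hemoglobin species imaged in NIRS optical mammography: a printer ink
(Epson 673) absorbs strongly near 670 nm and almost not at all near 830 nm
(HbR-like), while the organic dye ADS830WS peaks near 830 nm (HbO-like).
The forward model is linear,

    mua(lambda) = k * sum_j eps_j(lambda) * C_j,

with ``eps_j`` the decadic molar extinction coefficient and ``k`` the unit
and log-convention factor (0.1 to go from cm^-1 to mm^-1, times ln(10) when
the absorption coefficient is on the natural-log scale).  Retrieving the two
concentrations from absorption measured at two wavelengths is the inverse
2x2 solve of that system.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from typing import Dict, Mapping, Tuple

import numpy as np

from .images import ConcentrationMap, DeltaMuaMap

__all__ = [
    "Absorber",
    "ExtinctionSystem",
    "ConcentrationPair",
    "AbsorptionPair",
    "ADS830WS",
    "EPSON673",
    "WAVELENGTHS",
    "build_extinction_system",
    "default_extinction_system",
    "mua_from_concentrations",
    "concentrations_from_mua",
    "recipe_mass_concentration",
    "unmix_map",
    "read_extinction_csv",
    "write_extinction_csv",
]

#: Working wavelengths (nm) of the two-laser transmittance setup.
WAVELENGTHS: Tuple[float, float] = (670.0, 830.0)

#: From mm^-1 = 0.1 * cm^-1.
_CM_TO_MM = 0.1


@dataclass(frozen=True)
class Absorber:
    """One absorbing species with tabulated decadic molar extinction.

    ``epsilon`` maps wavelength (nm) to the decadic molar extinction
    coefficient in M^-1 cm^-1; ``molecular_weight`` is in g/mol and is used
    only for converting molar recipes to mass recipes.
    """

    name: str
    epsilon: Mapping[float, float]
    molecular_weight: float

    def __post_init__(self) -> None:
        if self.molecular_weight <= 0:
            raise ValueError(f"{self.name}: molecular weight must be positive")
        for wl, eps in self.epsilon.items():
            if eps < 0:
                raise ValueError(f"{self.name}: epsilon({wl}) < 0")

    def epsilon_at(self, wavelength: float) -> float:
        try:
            return float(self.epsilon[wavelength])
        except KeyError:
            raise ValueError(
                f"absorber {self.name!r} has no extinction tabulated at "
                f"{wavelength} nm"
            ) from None


#: HbO-mimicking organic dye (American Dye Source).
ADS830WS = Absorber(
    name="ADS830WS",
    epsilon={670.0: 56049.20, 830.0: 62906.73},
    molecular_weight=827.49,
)

#: HbR-mimicking black printer ink.
EPSON673 = Absorber(
    name="Epson673",
    epsilon={670.0: 31409.55, 830.0: 1520.56},
    molecular_weight=68.14,
)


@dataclass(frozen=True)
class ExtinctionSystem:
    """2x2 wavelength-by-absorber extinction matrix in M^-1 mm^-1.

    Rows follow ``wavelengths``; columns are (dye, inks).  When
    ``log_convention == "natural"`` the stored entries already include the
    ln(10) factor, so the forward product directly yields a natural-log
    absorption coefficient.
    """

    wavelengths: Tuple[float, float]
    matrix: np.ndarray
    log_convention: str
    condition_number: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        object.__setattr__(self, "matrix", np.asarray(self.matrix, dtype=np.float64))
        if self.matrix.shape != (2, 2):
            raise ValueError("extinction matrix must be 2x2")
        if self.wavelengths[0] == self.wavelengths[1]:
            raise ValueError("the two rows must correspond to distinct wavelengths")

    @property
    def inverse(self) -> np.ndarray:
        return np.linalg.inv(self.matrix)


@dataclass(frozen=True)
class ConcentrationPair:
    """Absorber concentrations (or changes) in micromolar."""

    dye: float
    inks: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.dye) and math.isfinite(self.inks)):
            raise ValueError("concentrations must be finite")


@dataclass(frozen=True)
class AbsorptionPair:
    """Absorption coefficients (or changes) at the two wavelengths, mm^-1."""

    mua_l1: float
    mua_l2: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.mua_l1) and math.isfinite(self.mua_l2)):
            raise ValueError("absorption coefficients must be finite")


def build_extinction_system(
    dye: Absorber,
    ink: Absorber,
    wavelengths: Tuple[float, float] = WAVELENGTHS,
    log_convention: str = "natural",
    max_condition: float = 1e12,
) -> ExtinctionSystem:
    """Assemble the two-wavelength extinction matrix for a dye/ink pair.

    Entries are converted from M^-1 cm^-1 to M^-1 mm^-1 and, for the
    ``"natural"`` convention, multiplied by ln(10) so that concentrations map
    to natural-log absorption coefficients.  The matrix condition number is
    computed and attached; a system whose relative condition exceeds
    ``max_condition`` (or that is exactly singular) is rejected because the
    two absorbers then carry no independent spectral information.
    """
    if log_convention not in ("decadic", "natural"):
        raise ValueError(f"unknown log convention {log_convention!r}")
    scale = _CM_TO_MM * (math.log(10.0) if log_convention == "natural" else 1.0)
    m = np.array(
        [
            [dye.epsilon_at(wavelengths[0]), ink.epsilon_at(wavelengths[0])],
            [dye.epsilon_at(wavelengths[1]), ink.epsilon_at(wavelengths[1])],
        ]
    ) * scale
    det = m[0, 0] * m[1, 1] - m[0, 1] * m[1, 0]
    cond = float(np.linalg.cond(m)) if det != 0 else float("inf")
    if det == 0 or not math.isfinite(cond) or cond > max_condition:
        raise ValueError(
            f"extinction matrix is singular or ill-conditioned "
            f"(cond={cond:.3g}); the absorbers' spectra are not independent"
        )
    return ExtinctionSystem(tuple(wavelengths), m, log_convention, cond)


def default_extinction_system(log_convention: str = "natural") -> ExtinctionSystem:
    """The ADS830WS / Epson 673 system at 670 and 830 nm."""
    return build_extinction_system(ADS830WS, EPSON673, WAVELENGTHS, log_convention)


def _check_pair_finite(a: float, b: float, what: str) -> None:
    if not (math.isfinite(a) and math.isfinite(b)):
        raise ValueError(f"non-finite {what}")


def mua_from_concentrations(
    system: ExtinctionSystem, conc: ConcentrationPair
) -> AbsorptionPair:
    """Forward map: concentrations (uM) -> absorption coefficients (mm^-1)."""
    c = np.array([conc.dye, conc.inks]) * 1e-6  # uM -> M
    mua = system.matrix @ c
    return AbsorptionPair(float(mua[0]), float(mua[1]))


def concentrations_from_mua(
    system: ExtinctionSystem, mua: AbsorptionPair
) -> ConcentrationPair:
    """Inverse map: absorption coefficients (mm^-1) -> concentrations (uM).

    Exact solution of the 2x2 linear system; the forward map applied to the
    result reproduces the input to floating-point accuracy.
    """
    _check_pair_finite(mua.mua_l1, mua.mua_l2, "absorption input")
    rhs = np.array([mua.mua_l1, mua.mua_l2])
    c = np.linalg.solve(system.matrix, rhs) * 1e6  # M -> uM
    return ConcentrationPair(float(c[0]), float(c[1]))


def recipe_mass_concentration(
    conc: ConcentrationPair, dye: Absorber, ink: Absorber
) -> Tuple[float, float]:
    """Convert a molar recipe (uM) to mass concentrations in g/L.

    g/L = uM * 1e-6 * molecular weight (g/mol).  Used when weighing out the
    absorbers for a physical phantom batch.
    """
    return (
        conc.dye * 1e-6 * dye.molecular_weight,
        conc.inks * 1e-6 * ink.molecular_weight,
    )


def unmix_map(
    system: ExtinctionSystem,
    dmua_l1: DeltaMuaMap,
    dmua_l2: DeltaMuaMap,
) -> ConcentrationMap:
    """Per-pixel inversion of the extinction system on two delta-mua maps.

    The operation is strictly pixelwise: a perturbation confined to one pixel
    of the inputs stays confined to that pixel of the output.  Pixels flagged
    invalid in either input are invalid in the output.
    """
    if dmua_l1.values.shape != dmua_l2.values.shape:
        raise ValueError("delta-mua maps have mismatching shapes")
    if dmua_l1.pixel_pitch != dmua_l2.pixel_pitch:
        raise ValueError("delta-mua maps have mismatching pixel pitch")
    valid = dmua_l1.valid & dmua_l2.valid
    inv = system.inverse
    v1 = np.where(valid, dmua_l1.values, 0.0)
    v2 = np.where(valid, dmua_l2.values, 0.0)
    dye = (inv[0, 0] * v1 + inv[0, 1] * v2) * 1e6
    inks = (inv[1, 0] * v1 + inv[1, 1] * v2) * 1e6
    dye[~valid] = np.nan
    inks[~valid] = np.nan
    return ConcentrationMap(dye, inks, valid, dmua_l1.pixel_pitch)


def write_extinction_csv(path, absorbers) -> None:
    """Write absorbers as CSV rows (absorber, wavelength_nm, epsilon, MW)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["absorber", "wavelength_nm", "epsilon_per_M_cm",
                    "molecular_weight_g_mol"])
        for a in absorbers:
            for wl in sorted(a.epsilon):
                w.writerow([a.name, wl, a.epsilon[wl], a.molecular_weight])


def read_extinction_csv(path) -> Dict[str, Absorber]:
    """Read an extinction table written by :func:`write_extinction_csv`."""
    eps: Dict[str, Dict[float, float]] = {}
    mw: Dict[str, float] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            name = row["absorber"]
            eps.setdefault(name, {})[float(row["wavelength_nm"])] = float(
                row["epsilon_per_M_cm"]
            )
            mw[name] = float(row["molecular_weight_g_mol"])
    return {
        name: Absorber(name=name, epsilon=eps[name], molecular_weight=mw[name])
        for name in eps
    }
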