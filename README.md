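# dotphantom

Simulation and analysis toolkit for continuous-wave (CW) diffuse optical
transmittance imaging of breast-tumor-mimicking phantoms.

## The problem

CW near-infrared transmittance imaging discriminates benign from malignant
breast lesions through the concentrations of oxy- and deoxyhemoglobin (HbO,
HbR). Stable solid phantoms replace the hemoglobins with two artificial
absorbers with crossed spectra: an organic dye (ADS830WS, absorbing near
830 nm, HbO-like) and a printer ink (Epson 673, absorbing near 670 nm,
HbR-like). A core–shell resin sphere — ink-loaded 10 mm core inside a
dye-loaded 20 mm shell — embedded at mid-depth of a 40 mm slab host
emulates a fibroadenoma (FADN, benign) or an adenocarcinoma (ADC,
malignant; ~4× the core absorption at 670 nm).

`dotphantom` provides the computational side of validating such phantoms,
for phantom designers and diffuse-optics methods developers:

- **voxel Monte Carlo photon transport** (`dotphantom.mc`): weighted
  packets, Henyey–Greenstein scattering, Fresnel refractive boundaries,
  exit-face imaging (angle-integrated flux or the camera-faithful
  near-normal radiance), pathlength statistics; bit-reproducible per seed;
- **slab diffusion theory** (`dotphantom.diffusion`): closed-form CW
  transmittance of a slab with extrapolated boundaries and the mean total
  pathlength (MTPL) `L = -d ln T / d mua` used by the Modified
  Beer–Lambert law;
- **the imaging pipeline** (`dotphantom.pipeline`): 25-position grid (or
  homogeneous-reference) normalization, inclusion contrast `C = |1 - M|`,
  MBLL conversion `dmua = -ln(I/I0)/L`, per-pixel two-wavelength unmixing
  into dye/ink concentration-change maps, 7-px median filtering, 128×128
  cropping and SSIM comparison;
- **spectral unmixing** (`dotphantom.absorbers`): the 2×2 molar-extinction
  system linking `(mua(670), mua(830))` to `([dye], [inks])`, plus recipe
  conversion to g/L;
- **a synthetic camera-data generator** (`dotphantom.synthetic`) with known
  ground truth for end-to-end testing without long simulations.

## The model at the core

At two wavelengths the absorption changes relative to the host background
follow the linear system

    dmua(l) = ln(10) · 0.1 · [ eps_dye(l) · d[Dye] + eps_ink(l) · d[Inks] ] · 1e-6

(eps in M⁻¹cm⁻¹, concentrations in µM, mua in mm⁻¹). The Modified
Beer–Lambert law converts a normalized transmittance image into absorption
changes, `dA(l) = -ln(I/I0) = L(l) · dmua(l)`, with `L` the MTPL of
detected photons computed from the host slab's diffusion Green's function.
Inverting the 2×2 extinction matrix pixel by pixel yields maps of
`d[Dye]` and `d[Inks]`.

## Worked example

Retrieve concentration maps from a synthetic two-wavelength acquisition
with known truth (0.02 µM dye, 0.03 µM ink at the perturbation centre,
shot noise at 10⁴ peak counts):

```python
from dotphantom import (ConcentrationPair, MbllRetrieval, SyntheticScene,
                        default_extinction_system)
from dotphantom.synthetic import generate_stack

system = default_extinction_system()
scene = SyntheticScene(conc=ConcentrationPair(0.02, 0.03), system=system,
                       seed=7)
model = MbllRetrieval.from_stacks(generate_stack(scene, 670.0),
                                  generate_stack(scene, 830.0))
print(model.fit().summary())
```

```
Two-wavelength MBLL concentration retrieval
===========================================
extinction system: cond =     4.030 (natural convention)
host model: solid slab, 40 mm

wavelength   L [mm]   contrast C    extremum M
     670     603.6      0.2104       0.7896
     830     580.7      0.1370       0.8630

centre-of-inclusion concentration changes (vs background):
  d[dye]  =    +0.0220 uM
  d[inks] =    +0.0278 uM
valid pixels: 16384 / 16384
```

The pathlengths (603.6 / 580.7 mm — some 15× the slab thickness, as
expected for a diffusive medium) come from the slab diffusion model of the
silicone host; the retrieved centre concentrations agree with the injected
truth to within the shot-noise level.

A Monte Carlo contrast measurement of the malignant phantom in the silicone
host (10⁷ photons, ~2.5 min):

```sh
dotphantom contrast --tumor ADC --host solid --wavelength 670 --seed 1
```

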