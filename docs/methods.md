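# Methods

This note documents the models implemented in `dotphantom`, the choices
made where the design was genuinely open, and what the tests do and do not
demonstrate.

## Geometry and units

All lengths are millimetres, absorption and scattering coefficients mm⁻¹,
concentrations micromolar. Coordinates have their origin at the centre of
the illuminated slab face with z pointing into the slab; the digital
phantom is a 200 × 200 × 40 mm voxel grid (1 mm voxels by default) with a
core–shell sphere (10 mm core, 20 mm shell) centred at 20 mm depth on the
beam axis. Voxel membership is by voxel-centre containment; rasterized
sphere volumes converge to the analytic volumes as the voxel size shrinks
(tested at 2, 1, 0.5 mm).

Optical properties of the host media (silicone slab; milk/water cuvette),
the shell and the two core types at 670 and 830 nm are the measured values
tabulated in `dotphantom.phantom.TISSUE_OPTICS`. Refractive indices:
epoxy resin 1.56 (manufacturer value), silicone 1.40, milk/water 1.33,
air 1.0 — the host indices are standard optics values, as the
characterization did not report them.

## Extinction system and unit conventions

The tabulated molar extinctions are decadic, in M⁻¹cm⁻¹. The stored 2×2
system matrix is converted to M⁻¹mm⁻¹ (×0.1) and, under the default
`natural` convention, multiplied by ln(10) so that concentrations map
directly to natural-log absorption coefficients (the MBLL uses a natural
logarithm). The convention is a flag because the source tables do not fix
it; every round-trip contract is convention-invariant and concentration
*ratios* are invariant by construction (the ln 10 factor cancels).

The ink column models the Epson 673 printer ink alone. The third absorber
used in physical cores (Powertec, spectrally flat in the working window,
with no tabulated extinction) is representable only as extra background
absorption folded into a region's mua; it does not enter the 2×2 system.

## Monte Carlo transport

Weighted packets with implicit capture: scattering lengths are sampled
against the local μs, absorption attenuates the weight by exp(−μa·ℓ) along
every sub-step, and Russian roulette (threshold 10⁻⁴, survival factor 10)
terminates low-weight packets unbiasedly. Scattering is Henyey–Greenstein;
refractive-index steps at voxel faces and slab boundaries use unpolarized
Fresnel reflect-or-transmit sampling with Snell refraction (total internal
reflection included). Photons enter as a pencil beam with unit weight just
inside the illuminated face, so all reported fractions are relative to the
power coupled into the slab. Every photon owns a counter-based RNG stream
derived from (seed, photon index); runs are bit-reproducible.

Two implementation accelerations, both exact:

- outside the bounding box of the non-host voxels the medium is the
  homogeneous host, so flights are advanced against slab faces and the box
  analytically instead of voxel by voxel;
- a precomputed per-voxel lower bound on the distance to the nearest
  material change (Euclidean distance transform minus a voxel-diagonal
  margin) lets flights that cannot reach any interface scatter without
  boundary tests.

A brute-force full-voxel-traversal run agrees with the accelerated path to
within counting noise (tested).

**Anisotropy.** The characterization provides only reduced scattering
μs′. The fixtures default to transport-matched isotropic scattering
(g = 0, μs = μs′): for slabs this thick (μs′·d ≈ 30–45) the diffuse
observables are insensitive to g at fixed μs′, which we verified directly
(g = 0 vs g = 0.9 dip profiles and transmittances agree within noise), and
isotropic transport is an order of magnitude cheaper — which sets the
photon budgets the desk-scale protocol can afford. g remains a per-material
parameter and the HG sampler is fully tested.

**Detection.** All packets crossing the exit face are tallied for the
transmittance and pathlength statistics, regardless of angle. For image
formation two observables are available. `flux` accumulates exit weight
per pixel (angle-integrated). `radiance` reconstructs, per pixel, the
radiance leaving the face along the normal — the quantity a lens focused
on the exit plane actually collects — from two angular moments of the
exiting packets (Σw and Σw/μ, μ the internal direction cosine, bounded
away from zero by the escape cone) under a two-term P1 model of the exit
radiance with the Fresnel escape-cone moments folded in. Steep-angle
photons carry a laterally blurred view of interior structure; the radiance
estimator de-emphasises them exactly as a camera does, at the price of a
higher per-pixel variance. The contrast protocol uses radiance mode.

## Slab diffusion model

CW transmittance of the homogeneous slab comes from the image-source
expansion of the diffusion Green's function with extrapolated boundaries:
an isotropic source at depth z₀ = 1/μs′ and image ladders with period
2(d + 2zₑ), where zₑ = 2AD, D = 1/(3μs′), and A = (1+r_d)/(1−r_d) with
r_d the Fresnel flux moment for diffuse internal incidence (numerical
quadrature; the standard cubic fit in the relative index is available and
agrees to 2%). The spatially integrated transmitted flux of each image
source has the closed form ½·exp(−μ_eff·|distance|), so T is an elementary
series, summed in symmetric pairs to a 10⁻¹² relative tolerance (the
ladder converges slowly as μa → 0; the default term cap of 10⁴ accommodates
μa ≥ 10⁻⁶ mm⁻¹, and μa = 0 uses the telescoped closed form
(z₀+zₑ)/(d+2zₑ)).

The mean total pathlength is L = −∂ln T/∂μa, differentiated term by term
(a central finite difference with step 10⁻⁶ mm⁻¹ is exposed as a
cross-check; both agree to 0.1%). One scalar L per wavelength, computed
from the host bulk properties, feeds the MBLL step — consistent with a
single pathlength scalar rather than a spatially resolved sensitivity map.
Monte Carlo runs of the homogeneous hosts reproduce both T and L within
5% at 10⁶ photons (tested at both wavelengths and in both hosts).

## Imaging pipeline

Normalization offers the 25-position protocol (centre image over the grid
mean) and a homogeneous-reference variant for scaled-down simulations. In
the grid protocol the reference mean *excludes* the centre image by
default: including the acquisition under analysis feeds its own dip into
I₀ and biases the recovered attenuation low by ~1/25 regardless of the
perturbation size; the leave-one-out mean removes that bias (the plain
all-images mean remains available as an option). Pixels whose reference
falls below 10⁻⁶ of its maximum are masked and stay masked downstream.

Contrast is read as C = |1 − M|, M being the extremum of the 7-px
median-filtered normalized image inside a central 32 × 32 px (20 × 20 mm)
window — the inclusion footprint; the median filter precedes the extremum
to keep the reading off the shot-noise floor. MBLL and unmixing are exact
pixelwise inversions; masked pixels propagate as NaN + mask.

SSIM is implemented directly from its definition (11 × 11 Gaussian window,
σ = 1.5, K₁ = 0.01, K₂ = 0.03, dynamic range = maximum of the pair, mean
over the interior full-window region); identical images score exactly 1,
and the implementation matches scikit-image's to 10⁻⁸ (which serves as an
independent oracle in the tests, never as the implementation).

## Synthetic data generator

The generator emulates the 25-position EMCCD acquisition: a broad Gaussian
diffuse-transmittance spot (σ = 25 mm), dimmed by a smooth attenuation
bump (12 mm full width = 4σ, approximating the blurred mid-slab shadow of
the 20 mm sphere) that moves with the inclusion across the grid, Poisson
shot noise at a configurable peak count (default 10⁴) and additive
Gaussian read noise (default σ = 2 counts, a minimal EMCCD abstraction).
The forward model is deliberately MBLL-consistent — images are
B(x)·exp(−L·dmua(x−p)) with the pipeline's own L — so recovery tests
isolate pipeline correctness from transport physics; the physics-faithful
stacks come from the Monte Carlo module. Background shape and exposure
scale are free parameters (the experimental values are unpublished).
Consequently, passing recovery tests demonstrates the correctness of the
normalization/MBLL/unmixing chain, not the fidelity of MBLL itself to
photon transport.

## The scaled-down contrast protocol

The published contrast table derives from 10⁹-photon GPU runs per grid
position. The desk-scale reproduction replaces the 25-position grid with a
single on-axis inclusion run normalized by a matched homogeneous-host run,
at 10⁷ photons each (one reference per host × wavelength, shared by both
archetypes). Both images are averaged over the dihedral symmetry of the
on-axis geometry before the ratio — an exact variance-reduction step for
this scene. Per-scenario seeds derive deterministically from the base seed
and a case label.

## Model/results interface

The two-wavelength retrieval is exposed as a model object
(`MbllRetrieval`: data = normalized image pair, configuration = extinction
system and pathlengths) whose `fit()` returns a results object carrying
the concentration maps, per-wavelength contrast diagnostics and a
`summary()` report — the natural shape for an inverse problem estimated
from data. The simulators (Monte Carlo, phantom builder, synthetic
generator) stay plain functions.

## Known limitations

- **Simulated vs published contrasts.** With the tabulated (measured)
  optical properties, the simulated contrasts fall short of the published
  experimental table by a systematic ~0.10–0.15 in all eight scenarios.
  We excluded, by direct experiment, the detection observable (flux,
  NA-cut, normal radiance), anisotropy, refractive-index handling, voxel
  acceleration and photon budget as causes; grid-mean normalization could
  only widen the gap. The recipe concentrations printed for the physical
  cores imply, through the tabulated extinctions, core absorptions orders
  of magnitude above the measured table — the two characterizations are
  mutually inconsistent, and the deep experimental dips are consistent
  with substantially more absorbing cores than the measured properties
  state. The package reports what transport physics gives for the
  tabulated properties; the qualitative structure (malignant > benign at
  670 nm in both hosts, near-equal contrasts at 830 nm from the shared
  dye shell, higher retrieved ink for the malignant archetype with
  matching dye channels) is reproduced.
- Retrieved concentrations are relative to the normalization background
  (CW measurement); no absolute quantification, no tomography.
- No time-resolved output, no fluorescence transport (experimentally
  filtered out), no lens PSF/speckle/vignetting modelling.
- The slab is laterally absorbing at its edges (side-escaped photons are
  terminated); for the 200 mm lateral extent this is irrelevant to the
  80 mm imaged field.
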