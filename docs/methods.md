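# Methods

## The head model

The accelerator head is represented by a small set of Gaussian virtual
photon sources on the beam axis. For the modeled Versa HD-style head two
sources are used per beam quality: the primary source at the target
(position 0) and a secondary source at the flattening-filter position
(150 mm), the latter representing primary-collimator scatter for the FFF
beam. Each source n carries a relative weight w_n and Gaussian widths
(sigma_x, sigma_y) in its own plane.

All coordinates are defined with the origin at the nominal source, +z
toward the patient (IEC61217 rotated 180 degrees about x). Apertures,
grids and off-axis distances are expressed at the isocenter plane
(z = d = 1000 mm); the phase-space plane sits at p = 548 mm and the
bottom of the MLC at c = 401.8 mm.

For each source, an 800 x 800 grid of points with 0.5 mm spacing at the
isocenter plane is:

1. projected onto the phase-space plane, x_p = x_d (p - s_n)/(d - s_n),
   giving per-source plane spacing (the sources diverge differently);
2. mapped to the *primary-divergent* system,
   x'_d = x_d d (c - s_n) / (c (d - s_n)), because collimator settings and
   the radial fluence profile are tabulated at isocenter with divergence
   from the primary source;
3. evaluated: Phi = phi(r'_d) * omega(x'_d, y'_d), where phi is the
   piecewise-linear radial primary-fluence profile and omega the binary
   aperture function of the y-jaws and the 80 opposed leaf pairs (5 mm
   pitch, straight ends, half-open interval convention, transmission 0);
4. blurred with a unit-integral Gaussian whose width is the source size
   projected to the plane, sigma_p = sigma (p - c)/(c - s_n), truncated at
   +/-5 sigma (mass loss < 1e-5) and applied by FFT convolution;
5. scaled to absolute units:

       Phi'_n = w_n * M * F(A) * C * dx * dy * (Phi_n (x) Omega_n).

   M is the segment's monitor units, A the open aperture area at
   isocenter (the integral of omega), F(A) the collimator scatter factor
   looked up at the equivalent-square width sqrt(A), and C the absolute
   calibration (particles per MU mm^2; 2.02e-14 flattened, 2.18e-14 FFF in
   model units). Writing the scaling with the grid cell area dx dy makes
   the *total* fluence proportional to M A F(A) C while the central
   fluence *density* is independent of the aperture area; an overall
   A-proportional density would make central dose grow with field area
   and contradict the published output-factor set, so the cell-count
   normalization is the only self-consistent reading. Source weights
   multiply each source's map (the weights are tabulated model
   parameters; the scaling step is where they enter).

Multi-segment beams sum the per-source maps of their segments. Cells
below 1% of the per-beam maximum are masked out of sampling and out of
the integral fluence, which concentrates rejection sampling on the beam.

Particles are emitted by rejection sampling: the source is chosen in
proportion to its masked integral, the cell by rejection against Phi' on
masked-in cells, and the energy by rejection sampling of the tabulated
10-line spectrum (the lines are treated as discrete, with the tabulated
intensities as line probabilities). Sampled particles receive a uniform
intra-cell jitter (suppressing a 0.5 mm lattice artifact in 2 mm dose
voxels without changing the expected fluence) and travel along the ray
from their source through their generating grid point.

## The dose engine

The transport engine is a deliberately simple analogue voxel Monte Carlo
photon code:

- Woodcock (fictitious-interaction) tracking through the density grid;
- interactions: Compton scattering with exact Klein-Nishina energy/angle
  sampling (Kahn's method), photoelectric absorption, and pair production
  above 1.022 MeV with two isotropic opposed annihilation photons;
- secondary electrons transported in the continuous slowing-down
  approximation: straight 0.05 g/cm^2 sub-steps depositing the collision
  stopping power, with Gaussian small-angle direction diffusion per step
  (Highland formula, X0 = 36.08 g/cm^2);
- cutoffs: photons 50 keV, electrons 200 keV (residual range below half a
  voxel), both deposited locally;
- dose scored to medium in medium, MeV/g per voxel.

Cross sections are built analytically for water-like media: Compton as
Klein-Nishina times the electron density of water (3.3428e23 e/g),
photoelectric as an E^-3 fit anchored at 50 keV, pair production from a
small table. The total agrees with standard water attenuation values
(coherent scattering excluded) to about 1-2% over 0.05-6 MeV. Other media
are density-scaled water; in this Compton-dominated regime mass
attenuation follows electron density, which is accurate for air, lung and
soft tissue and crude for cortical bone below ~100 keV. Electron collision
stopping powers are a packaged water table. There is no bremsstrahlung,
no Rayleigh scattering, no condensed-history multiple-scattering theory
and no electron contamination in the incident beam. The engine sits
behind `simulate_dose(particles, phantom, ...)` so a higher-fidelity
engine could be substituted without touching the phase-space model.

Statistical uncertainty is estimated per voxel from history-batch
statistics (default 10 batches); the stopping rule for
uncertainty-targeted runs averages the relative sigma over voxels above
50% of the running maximum dose (the assessment region is a package
choice; the protocol's 1.5% target leaves it open).

## Absolute dose and scaling

The scored grid accumulates energy per unit mass over all transported
histories. `scale_dose` divides by the history count H (dose per
particle) and multiplies by the integral fluence (the calibrated particle
count for the delivered monitor units), then converts to cGy with a
per-quality commissioning constant `cgy_per_unit` stored in the model
config. That constant was fixed once by running the packaged model for
100 MU of the 100 mm reference field and setting the dose maximum to
about 100 cGy (a conventional monitor-unit definition); it cancels in
every dose ratio, as does C itself.

A median-window filter (cubic neighborhood, boundary-clipped) with a
radius of three voxels smooths the final grid; for the 10 mm field the
radius is reduced to one voxel so the small high-dose region is not
flattened. When only a point dose is needed, the filter is evaluated
just on the readout neighborhood (identical values, much cheaper).

## Evaluation protocol

Output factors are the central-axis dose at 100 mm depth in a
300 x 300 x 300 mm water phantom relative to the 100 mm x 100 mm field of
the same beam quality, both read as the 3x3x3-voxel average of the
filtered grid (noise control applied identically to both grids, so it
cancels in the ratio). The beam axis is perpendicular to a phantom face
with the isocenter at 100 mm depth, so the measurement point lies at the
isocenter; the protocol source did not state the SSD and this is the
package's convention. For offset fields the readout point is the offset
field center at the same depth.

The gamma index is the standard global, one-directional comparison
(reference voxels against the trilinearly interpolated evaluated grid)
with the dose criterion taken as a percentage of a caller-supplied
normalization dose, a 0.2 mm search step out to 3x the
distance-to-agreement, and a low-dose threshold of 10% of the reference
maximum. Pass rates are monotone in both criteria; swapping the grids is
not guaranteed to give the same rate.

## Synthetic fixtures

`generate_fixture` recreates the benchmarking geometries
deterministically from (kind, parameters, seed): centered square fields
(widths 10-200 mm) and offset fields (30/50 mm at 50/100 mm toward +x or
+y) on the water cube, plus two toy step-and-shoot IMRT plans -- 7
equally spaced coplanar beams with 28 segments around a central target
in water, and 15 beams with 30 segments on a phantom with a 0.26 g/cm^3
shell around a unit-density 20 mm target. The toy plans match the
published beam and segment counts but not any patient anatomy or real
aperture shapes: they exercise multi-beam, multi-segment accumulation,
gantry rotation and heterogeneity handling, and nothing they produce is
compared against patient data. The water-cube fixtures likewise emulate
the benchmarking setup, not a real beam: passing tests demonstrate
internal consistency of model + engine against the published benchmark
values, not agreement with measurements on a physical machine.

## Problem sizes

The packaged benchmark driver (`scripts/acceptance.py`,
`benchmark_output_factors`) runs each reference field with 1.2e7
histories and each test field with 5e6 histories scaled up in proportion
to the aperture area beyond the reference area (the 200 mm field gets
2e7) -- mirroring the constant-fluence-per-area shape of the original
protocol's history counts at desk scale. With those sizes the
statistical noise of a filtered point readout is roughly 0.5-1.5%
(1 sigma), comparable to the 1.5% uncertainty target of the original
protocol.

## Known limitations

- The engine's field-size response differs from the reference
  condensed-history code that the collimator scatter factors were tuned
  against; small-field output factors carry a systematic offset of a few
  percent (see the acceptance results and the discussion above).
- Absolute doses rest on the package's own commissioning convention, not
  on measured machine output.
- Bone is treated as dense water; HU conversion supports material
  indices, but the cross-section set does not differentiate media beyond
  density.
- The gamma implementation is a standard reimplementation; pass rates
  against proprietary systems' values are not comparable.
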