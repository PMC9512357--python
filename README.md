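# phspdose

A virtual-source phase-space model of a medical linear accelerator head
(Elekta Versa HD-style, 6 MV flattened and flattening-filter-free beams)
coupled to a simplified voxel Monte Carlo photon dose engine, with the
evaluation tools used to benchmark such models: output factors, depth
doses and profiles, and gamma analysis.

**Who it is for.** Medical-physics researchers who want a compact,
fully inspectable implementation of the dual Gaussian-source phase-space
construction — for studying head-model behavior (source occlusion,
penumbra, FFF off-axis falloff), for prototyping fast dose-reconstruction
pipelines, or as a reference against which to test other engines. It is
a research code, not a clinical dose calculator.

## The model

The head is reduced to two Gaussian photon sources on the beam axis: the
primary source at the target and a secondary source at the flattening
filter (primary-collimator scatter for FFF). On an 800×800 grid (0.5 mm
at isocenter) the fluence of source *n* is

    Φ_n(i,j)  = φ(r′_d) · ω(x′_d, y′_d)                (profile × aperture)
    Φ′_n(i,j) = w_n · M · F(A) · C · δx δy · (Φ_n ⊗ Ω_n)   (blur + calibration)

where ω is the binary jaw/MLC aperture at the isocenter plane, primed
coordinates rescale each grid point into the primary-divergent system,
Ω_n is the unit-integral Gaussian of the source width projected to the
phase-space plane, M the monitor units, A the open aperture area, F(A)
the collimator scatter factor at the equivalent-square width √A, and C
the absolute calibration (particles per MU·mm²). Photons are drawn from
Φ′ by rejection sampling (cells below 1% of the per-beam maximum are
skipped), given energies by rejection sampling of a 10-line spectrum,
and transported through a voxel phantom by an analogue Monte Carlo
engine (Woodcock tracking, Klein–Nishina Compton, photoelectric, pair
production, CSDA electrons with Highland angular diffusion). Dose is
scaled by Σ Φ′ / H and median-filtered. See `docs/methods.md` for the
full account, assumptions and limitations.

## Worked example

Output factor of a 50 mm flattened field (central-axis dose at 100 mm
depth in a 300 mm water cube, relative to the 100 mm reference field):

```
$ phsp output-factor --quality flattened --width 50 --histories 2000000 --seed 7
flattened 50 mm offset (0, 0): OF = 0.904 +/- 0.048
```

The value 0.904 is the dose ratio (the published Monte Carlo benchmark
for this field is 0.900); the ± figure is a conservative statistical
estimate from batch statistics. The same computation from Python:

```python
from phspdose.pipeline import benchmark_output_factors

results = benchmark_output_factors([("flattened", 50.0, 0.0, 0.0)], seed=7)
(res, histories), = results.values()
print(res.factor, res.dose_cgy, res.reference_dose_cgy)
```

which prints the factor together with the two absolute point doses in
cGy (about 62 and 69 cGy for 100 MU — the model is commissioned so the
reference field's dose maximum is ~100 cGy per 100 MU).

Other entry points: `phsp fixtures` (synthetic square/offset fields and
toy step-and-shoot IMRT plans), `phsp plan-info`, `phsp fluence`,
`phsp sample` (phase-space export), `phsp dose`, `phsp gamma`,
`phsp profile`. For example:

```
$ phsp fixtures --kind toy_lung_imrt --out lung.yaml
toy_lung_imrt: 15 beams, 30 segments -> lung.yaml
$ phsp plan-info lung.yaml
plan: toy_lung_imrt  beams: 15  segments: 30
  beam 0: flattened, gantry 0.0 deg, MU 64.8, segment areas [mm^2]: 938, 895
  ...
```

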