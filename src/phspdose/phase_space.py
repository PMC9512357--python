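"""Per-source fluence maps at the phase-space plane and particle sampling.

For every virtual source the beam aperture and radial primary fluence are
evaluated on a rectangular grid defined at the isocenter plane, projected to
the phase-space plane, blurred by the (magnified) Gaussian source shape, and
scaled by monitor units, open area, collimator scatter factor and the
absolute calibration.  Particles are then emitted by rejection sampling of
the resulting fluence map and of the discrete energy spectrum.

Geometry (all z from the nominal source, +z toward the patient):

* grid points at the isocenter plane:  x_d = g_x + i*dx, z = d
* projection to the phase-space plane for source n at s_n:
  x_p = x_d * (p - s_n)/(d - s_n), z_p = p
* primary-divergent coordinates (collimator and fluence tables are stated at
  isocenter with divergence from the *primary* source):
  x'_d = x_d * d (c - s_n) / (c (d - s_n))
* source width at the plane: sigma_p = sigma * (p - c)/(c - s_n)

The calibrated per-source map is

  Phi'_n = w_n * M * F(A) * C * dx * dy * (Phi_n (x) Omega_n),

with Phi_n = phi(r'_d) * omega(x'_d, y'_d) and Omega_n the unit-integral
Gaussian of the projected source width.  The dx*dy factor expresses the open
area A as its open-cell count, so the summed map (the integral fluence used
for absolute dose scaling) is proportional to M * A * F(A) * C while the
central fluence *density* is independent of the aperture area.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
from scipy.signal import fftconvolve

from .aperture import Aperture, Segment
from .beam_model import BeamModel, MachineGeometry, VirtualSource, interp_profile

__all__ = [
    "ParticleRecord",
    "SourceFluence",
    "PhaseSpaceMap",
    "build_grid",
    "project_to_plane",
    "primary_divergent_coords",
    "sigma_at_plane",
    "raw_fluence",
    "compose_fluence",
    "build_phase_space",
    "sample_particles",
    "sample_particle_arrays",
    "export_phase_space_h5",
    "export_phase_space_text",
]

MASK_FRACTION = 0.01  # cells below this fraction of the per-beam max are neglected
GAUSS_TRUNC_SIGMA = 5.0


# ---------------------------------------------------------------------------
# Geometry

def build_grid(geometry: MachineGeometry):
    """Isocenter-plane grid points (x_d, y_d, d).

    Returns 1-D arrays ``x_d`` (length I) and ``y_d`` (length J); point (i, j)
    is (x_d[i], y_d[j], d).
    """
    g = geometry
    x_d = g.grid_edge_x_mm + g.grid_resolution_x_mm * np.arange(g.grid_size_i)
    y_d = g.grid_edge_y_mm + g.grid_resolution_y_mm * np.arange(g.grid_size_j)
    return x_d, y_d


def project_to_plane(x_d, y_d, s_n: float, geometry: MachineGeometry):
    """Project isocenter grid points to the phase-space plane for source s_n.

    Returns ``(x_p, y_p, z_p), (ux, uy, uz)``: the plane position and the unit
    direction of the ray from the source through that position.  Accepts
    scalars or arrays (broadcast).
    """
    p, d = geometry.phase_plane_mm, geometry.source_to_isocenter_mm
    if s_n >= p:
        raise ValueError(f"source position {s_n} mm must lie above the phase plane {p} mm")
    scale = (p - s_n) / (d - s_n)
    x_p = np.asarray(x_d, dtype=float) * scale
    y_p = np.asarray(y_d, dtype=float) * scale
    z_p = np.broadcast_to(p, np.broadcast_shapes(x_p.shape, y_p.shape)).astype(float)
    r_p = np.sqrt(x_p**2 + y_p**2 + (z_p - s_n) ** 2)
    return (x_p, y_p, z_p), (x_p / r_p, y_p / r_p, (z_p - s_n) / r_p)


def primary_divergent_coords(x_d, y_d, s_n: float, geometry: MachineGeometry):
    """Coordinates (x'_d, y'_d, r'_d) in the primary-divergent system.

    Collimator settings and the radial fluence profile are tabulated at the
    isocenter plane assuming divergence from the primary source; for a
    secondary source at s_n the grid point must be rescaled accordingly
    (identity for s_n = 0).
    """
    c, d = geometry.collimator_mm, geometry.source_to_isocenter_mm
    if s_n >= c:
        raise ValueError(f"source position {s_n} mm must lie above the collimator {c} mm")
    scale = d * (c - s_n) / (c * (d - s_n))
    xp = np.asarray(x_d, dtype=float) * scale
    yp = np.asarray(y_d, dtype=float) * scale
    return xp, yp, np.sqrt(xp**2 + yp**2)


def sigma_at_plane(source: VirtualSource, geometry: MachineGeometry):
    """Gaussian source width projected onto the phase-space plane (mm)."""
    p, c = geometry.phase_plane_mm, geometry.collimator_mm
    if source.position_mm >= c:
        raise ValueError("source must lie above the collimator plane")
    scale = (p - c) / (c - source.position_mm)
    return source.sigma_x_mm * scale, source.sigma_y_mm * scale


# ---------------------------------------------------------------------------
# Fluence maps

def raw_fluence(beam: BeamModel, aperture: Aperture, s_n: float) -> np.ndarray:
    """Unblurred fluence Phi(i, j) = phi(r'_d) * omega(x'_d, y'_d) for one source.

    Shape (I, J), indexed [i, j] with i along x.
    """
    x_d, y_d = build_grid(beam.geometry)
    xp, _, _ = primary_divergent_coords(x_d, 0.0, s_n, beam.geometry)
    _, yp, _ = primary_divergent_coords(0.0, y_d, s_n, beam.geometry)
    r = np.sqrt(xp[:, None] ** 2 + yp[None, :] ** 2)
    phi = interp_profile(beam.fluence_profile, r)
    omega = aperture.mask(xp[:, None], yp[None, :])
    return phi * omega


def _gaussian_kernel(sigma_cells_x: float, sigma_cells_y: float) -> np.ndarray:
    """Unit-sum 2-D Gaussian, truncated at +/-5 sigma (at least one cell)."""
    nx = max(1, int(math.ceil(GAUSS_TRUNC_SIGMA * sigma_cells_x)))
    ny = max(1, int(math.ceil(GAUSS_TRUNC_SIGMA * sigma_cells_y)))
    ix = np.arange(-nx, nx + 1)
    iy = np.arange(-ny, ny + 1)
    gx = np.exp(-0.5 * (ix / max(sigma_cells_x, 1e-12)) ** 2)
    gy = np.exp(-0.5 * (iy / max(sigma_cells_y, 1e-12)) ** 2)
    k = gx[:, None] * gy[None, :]
    return k / k.sum()


def compose_fluence(
    beam: BeamModel,
    segment: Segment,
    s_n: float | None = None,
    source: VirtualSource | None = None,
    method: str = "fft",
) -> np.ndarray:
    """Calibrated, source-blurred fluence map Phi'(i, j) for one source.

    ``Phi' = w_n * M * F(A) * C * dx * dy * (Phi (x) Omega)`` with Omega the
    unit-integral Gaussian of the source width projected to the plane,
    convolved over plane coordinates (per-source spacing).  ``method`` is
    ``"fft"`` (forward/inverse Fourier transform) or ``"direct"`` (direct
    summation, for small grids / verification).
    """
    if source is None:
        if s_n is None:
            raise ValueError("either a VirtualSource or a source position is required")
        matches = [s for s in beam.sources if s.position_mm == s_n]
        if not matches:
            raise ValueError(f"no source at {s_n} mm in this beam model")
        source = matches[0]
    g = beam.geometry
    area = segment.aperture.open_area_mm2()
    phi = raw_fluence(beam, segment.aperture, source.position_mm)
    if area == 0.0 and segment.aperture.transmission == 0.0:
        return np.zeros_like(phi)
    f_a = beam.scatter_factors.factor_for_area(area)
    scale_pn = (g.phase_plane_mm - source.position_mm) / (
        g.source_to_isocenter_mm - source.position_mm
    )
    dxp = g.grid_resolution_x_mm * scale_pn
    dyp = g.grid_resolution_y_mm * scale_pn
    sx, sy = sigma_at_plane(source, g)
    kernel = _gaussian_kernel(sx / dxp, sy / dyp)
    if method == "fft":
        blurred = fftconvolve(phi, kernel, mode="same")
        np.maximum(blurred, 0.0, out=blurred)  # clip FFT ringing at -1e-17 level
    elif method == "direct":
        from scipy.ndimage import convolve

        blurred = convolve(phi, kernel, mode="constant", cval=0.0)
    else:
        raise ValueError(f"unknown convolution method {method!r}")
    norm = (
        source.weight
        * segment.monitor_units
        * f_a
        * beam.calibration
        * g.grid_resolution_x_mm
        * g.grid_resolution_y_mm
    )
    return norm * blurred


# ---------------------------------------------------------------------------
# Phase-space container

@dataclass(frozen=True)
class ParticleRecord:
    """One sampled photon at the phase-space plane (beam frame, mm / MeV)."""

    position_mm: tuple[float, float, float]
    direction: tuple[float, float, float]
    energy_mev: float
    statistical_weight: float = 1.0


@dataclass
class SourceFluence:
    """Composed fluence of one virtual source, summed over a beam's segments."""

    source: VirtualSource
    phi_prime: np.ndarray  # (I, J) calibrated fluence map
    plane_spacing_mm: tuple[float, float]
    mask: np.ndarray | None = None  # boolean (I, J), built per beam

    @property
    def masked_integral(self) -> float:
        if self.mask is None:
            return float(self.phi_prime.sum())
        return float(self.phi_prime[self.mask].sum())


@dataclass
class PhaseSpaceMap:
    """Per-source fluence maps of one beam, with the per-beam inclusion mask."""

    beam: BeamModel
    sources: list[SourceFluence]
    gantry_angle_deg: float = 0.0

    @property
    def integral_fluence(self) -> float:
        """Sum of Phi' over masked-in cells of every source (absolute units)."""
        return sum(s.masked_integral for s in self.sources)

    @property
    def geometry(self) -> MachineGeometry:
        return self.beam.geometry


def build_phase_space(
    beam: BeamModel,
    segments: Segment | Sequence[Segment],
    mask_fraction: float = MASK_FRACTION,
) -> PhaseSpaceMap:
    """Compose the calibrated fluence of one beam (all its segments).

    Per-source maps are summed over segments; the inclusion mask keeps cells
    whose fluence is at least ``mask_fraction`` of the per-beam maximum
    (across all sources), which concentrates rejection sampling on the beam.
    """
    if isinstance(segments, Segment):
        segments = [segments]
    if not segments:
        raise ValueError("a beam needs at least one segment")
    gantry = segments[0].gantry_angle_deg
    if any(s.gantry_angle_deg != gantry for s in segments):
        raise ValueError("all segments of one beam must share the gantry angle")
    g = beam.geometry
    entries = []
    for src in beam.sources:
        total = None
        for seg in segments:
            m = compose_fluence(beam, seg, source=src)
            total = m if total is None else total + m
        scale = (g.phase_plane_mm - src.position_mm) / (
            g.source_to_isocenter_mm - src.position_mm
        )
        entries.append(
            SourceFluence(
                source=src,
                phi_prime=total,
                plane_spacing_mm=(
                    g.grid_resolution_x_mm * scale,
                    g.grid_resolution_y_mm * scale,
                ),
            )
        )
    beam_max = max(e.phi_prime.max() for e in entries)
    for e in entries:
        e.mask = e.phi_prime >= mask_fraction * beam_max
    return PhaseSpaceMap(beam=beam, sources=entries, gantry_angle_deg=gantry)


# ---------------------------------------------------------------------------
# Sampling

def _rejection_sample_cells(
    phi_masked: np.ndarray, count: int, rng: np.random.Generator
) -> np.ndarray:
    """Rejection-sample ``count`` indices into ``phi_masked`` with p ~ phi."""
    vmax = phi_masked.max()
    n_cells = phi_masked.size
    out = np.empty(count, dtype=np.int64)
    filled = 0
    while filled < count:
        draw = max(1024, int(1.2 * (count - filled) / max(phi_masked.mean() / vmax, 1e-3)))
        cand = rng.integers(0, n_cells, size=draw)
        keep = cand[rng.random(draw) * vmax < phi_masked[cand]]
        take = min(keep.size, count - filled)
        out[filled : filled + take] = keep[:take]
        filled += take
    return out


def _rejection_sample_lines(
    intensities: np.ndarray, count: int, rng: np.random.Generator
) -> np.ndarray:
    vmax = intensities.max()
    n = intensities.size
    out = np.empty(count, dtype=np.int64)
    filled = 0
    while filled < count:
        draw = max(1024, 2 * (count - filled))
        cand = rng.integers(0, n, size=draw)
        keep = cand[rng.random(draw) * vmax < intensities[cand]]
        take = min(keep.size, count - filled)
        out[filled : filled + take] = keep[:take]
        filled += take
    return out


def sample_particle_arrays(
    phase_space: PhaseSpaceMap,
    count: int,
    rng: np.random.Generator | int,
    jitter: bool = True,
):
    """Sample ``count`` photons; returns ``(pos, dir, energy)`` arrays.

    ``pos`` (N, 3) is on the phase-space plane in the beam frame (z = p from
    the source), ``dir`` (N, 3) unit direction through the generating grid
    point, ``energy`` (N,) MeV.  Source selection is proportional to the
    per-source masked integral, cell selection to Phi' on masked-in cells
    (rejection sampling), energy by rejection sampling of the spectrum lines.
    With ``jitter`` each particle gets a uniform intra-cell offset.
    """
    if count <= 0:
        raise ValueError("particle count must be positive")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    beam = phase_space.beam
    g = beam.geometry
    integrals = np.array([s.masked_integral for s in phase_space.sources])
    total = integrals.sum()
    if total <= 0.0:
        raise ValueError("empty beam: the composed fluence is zero everywhere")
    n_per_source = rng.multinomial(count, integrals / total)
    x_d, y_d = build_grid(g)
    J = g.grid_size_j

    pos = np.empty((count, 3))
    direction = np.empty((count, 3))
    offset = 0
    for sf, n_s in zip(phase_space.sources, n_per_source):
        if n_s == 0:
            continue
        s_n = sf.source.position_mm
        scale = (g.phase_plane_mm - s_n) / (g.source_to_isocenter_mm - s_n)
        masked_idx = np.flatnonzero(sf.mask.ravel())
        cells = masked_idx[_rejection_sample_cells(sf.phi_prime.ravel()[masked_idx], n_s, rng)]
        ii, jj = cells // J, cells % J
        x_p = x_d[ii] * scale
        y_p = y_d[jj] * scale
        if jitter:
            dxp, dyp = sf.plane_spacing_mm
            x_p = x_p + (rng.random(n_s) - 0.5) * dxp
            y_p = y_p + (rng.random(n_s) - 0.5) * dyp
        z_p = np.full(n_s, g.phase_plane_mm)
        r = np.sqrt(x_p**2 + y_p**2 + (z_p - s_n) ** 2)
        sl = slice(offset, offset + n_s)
        pos[sl, 0], pos[sl, 1], pos[sl, 2] = x_p, y_p, z_p
        direction[sl, 0] = x_p / r
        direction[sl, 1] = y_p / r
        direction[sl, 2] = (z_p - s_n) / r
        offset += n_s

    lines = _rejection_sample_lines(beam.spectrum.intensities, count, rng)
    energy = beam.spectrum.energies_mev[lines]
    # shuffle so per-source blocks do not correlate with batch splits downstream
    perm = rng.permutation(count)
    return pos[perm], direction[perm], energy[perm]


def sample_particles(
    phase_space: PhaseSpaceMap,
    count: int,
    seed: int | np.random.Generator = 0,
    jitter: bool = True,
) -> Iterator[ParticleRecord]:
    """Iterate ``count`` sampled :class:`ParticleRecord`s (reproducible per seed)."""
    pos, direction, energy = sample_particle_arrays(phase_space, count, seed, jitter=jitter)
    for k in range(count):
        yield ParticleRecord(
            position_mm=tuple(pos[k]),
            direction=tuple(direction[k]),
            energy_mev=float(energy[k]),
        )


# ---------------------------------------------------------------------------
# Export

def export_phase_space_h5(path, phase_space: PhaseSpaceMap, count: int, seed: int) -> None:
    """Write sampled particles to an HDF5 container.

    Layout: dataset ``records`` with columns (x, y, z, u, v, w, E, weight) in
    mm / MeV, plus header attributes (grid geometry, beam quality, seed,
    count).
    """
    import h5py

    pos, direction, energy = sample_particle_arrays(phase_space, count, seed)
    rec = np.column_stack([pos, direction, energy, np.ones(count)])
    g = phase_space.geometry
    with h5py.File(path, "w") as f:
        ds = f.create_dataset("records", data=rec)
        ds.attrs["columns"] = "x_mm y_mm z_mm u v w energy_MeV weight"
        f.attrs["beam_quality"] = phase_space.beam.quality
        f.attrs["seed"] = seed
        f.attrs["count"] = count
        f.attrs["phase_plane_mm"] = g.phase_plane_mm
        f.attrs["source_to_isocenter_mm"] = g.source_to_isocenter_mm
        f.attrs["grid_size"] = (g.grid_size_i, g.grid_size_j)
        f.attrs["grid_resolution_mm"] = (g.grid_resolution_x_mm, g.grid_resolution_y_mm)


def export_phase_space_text(path, phase_space: PhaseSpaceMap, count: int, seed: int) -> None:
    """Plain-text export for small particle counts (one record per line)."""
    pos, direction, energy = sample_particle_arrays(phase_space, count, seed)
    rec = np.column_stack([pos, direction, energy, np.ones(count)])
    header = (
        f"beam_quality={phase_space.beam.quality} seed={seed} count={count}\n"
        "x_mm y_mm z_mm u v w energy_MeV weight"
    )
    np.savetxt(path, rec, header=header)
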