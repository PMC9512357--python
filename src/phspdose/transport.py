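"""Simplified voxel Monte Carlo photon dose engine.

This is a declared-simplified engine in the spirit of fast voxel Monte Carlo
photon codes: analogue photon transport with Woodcock (fictitious
interaction) tracking through the density grid, Klein-Nishina Compton
scattering, photoelectric absorption and pair production (with annihilation
photons), and secondary electrons transported in the continuous
slowing-down approximation along straight sub-steps with Gaussian
small-angle (Highland) direction diffusion.  Dose is scored to medium in
medium.  There is no condensed-history multiple-scattering theory, no
bremsstrahlung photons, no Rayleigh scattering and no electron
contamination in the incident beam; the engine sits behind a small
interface so a higher-fidelity engine could be substituted.

Cross sections: the total attenuation is built analytically for water-like
media -- Compton from the Klein-Nishina cross section times the electron
density, photoelectric from an E^-3 fit anchored at 50 keV, pair production
from a small tabulated component above 1.022 MeV.  In the 0.05-6 MeV range
the mass attenuation of soft tissues is dominated by electron density, so
other media are treated as density-scaled water (a good approximation for
air/lung/soft tissue; crude for cortical bone below ~100 keV).

Units: positions mm, energies MeV, densities g/cm^3, mass coefficients
cm^2/g, scored dose MeV/g (converted to cGy by the dose-scaling step).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

__all__ = [
    "Phantom",
    "DoseGrid",
    "HUCalibration",
    "hu_to_density",
    "mu_rho_water",
    "simulate_dose",
    "scale_dose",
    "median_filter",
    "first_interaction_depths",
    "water_cube_phantom",
    "MEV_PER_G_TO_CGY",
]

ELECTRON_REST_MEV = 0.511
MEV_PER_G_TO_CGY = 1.602176634e-8  # 1 MeV/g = 1.602e-10 Gy = 1.602e-8 cGy
PHOTON_CUTOFF_MEV = 0.05
ELECTRON_CUTOFF_MEV = 0.20
_R_E_CM = 2.8179403262e-13
_N_E_WATER = 3.3428e23  # electrons per gram of water
_X0_WATER = 36.08  # radiation length, g/cm^2


# ---------------------------------------------------------------------------
# Photon cross sections (water-like media, per unit density)

def _kn_total_cm2(e_mev: np.ndarray) -> np.ndarray:
    """Total Klein-Nishina cross section per electron (cm^2)."""
    k = np.asarray(e_mev, dtype=float) / ELECTRON_REST_MEV
    t = 1.0 + 2.0 * k
    sigma = (
        2.0
        * math.pi
        * _R_E_CM**2
        * (
            (1.0 + k) / k**2 * (2.0 * (1.0 + k) / t - np.log(t) / k)
            + np.log(t) / (2.0 * k)
            - (1.0 + 3.0 * k) / t**2
        )
    )
    return sigma


_PAIR_TABLE_E = np.array([1.022, 1.5, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0])
_PAIR_TABLE_MU = np.array([0.0, 8.0e-5, 3.9e-4, 1.13e-3, 1.85e-3, 2.5e-3, 3.1e-3, 3.7e-3])


def _photo_mu_rho(e_mev: np.ndarray) -> np.ndarray:
    """Photoelectric mass attenuation of water, E^-3 fit (cm^2/g)."""
    e = np.maximum(np.asarray(e_mev, dtype=float), 0.01)
    return 2.75e-6 / e**3


def mu_rho_water(e_mev, component: str = "total"):
    """Mass attenuation coefficient of water (cm^2/g) used by the engine.

    ``component`` is one of ``total``, ``compton``, ``photoelectric``,
    ``pair``.
    """
    e = np.asarray(e_mev, dtype=float)
    compton = _kn_total_cm2(e) * _N_E_WATER
    photo = _photo_mu_rho(e)
    pair = np.interp(e, _PAIR_TABLE_E, _PAIR_TABLE_MU, left=0.0, right=_PAIR_TABLE_MU[-1])
    out = {
        "total": compton + photo + pair,
        "compton": compton,
        "photoelectric": photo,
        "pair": pair,
    }[component]
    return float(out) if np.isscalar(e_mev) else out


# Uniform energy grid for fast in-kernel lookups.
_EGRID_MIN, _EGRID_MAX, _EGRID_STEP = 0.01, 7.0, 0.005
_EGRID = np.arange(_EGRID_MIN, _EGRID_MAX + _EGRID_STEP, _EGRID_STEP)
_MU_TOTAL = mu_rho_water(_EGRID, "total")
_P_PHOTO = _photo_mu_rho(_EGRID) / _MU_TOTAL
_P_PAIR = mu_rho_water(_EGRID, "pair") / _MU_TOTAL

# Electron collision stopping power of water (MeV cm^2/g), standard values.
_ESP_E = np.array(
    [0.01, 0.02, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5, 0.7, 1.0, 1.5, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0]
)
_ESP_S = np.array(
    [22.56, 11.84, 6.603, 4.115, 2.793, 2.355, 2.148, 2.034, 1.931, 1.849,
     1.822, 1.824, 1.846, 1.870, 1.892, 1.911, 1.926]
)
_SP_GRID = np.interp(_EGRID, _ESP_E, _ESP_S)

_E_STEP_GCM2 = 0.05  # electron sub-step (0.5 mm of water)


@njit(cache=True, inline="always")
def _grid_lookup(table, e):
    x = (e - _EGRID_MIN) / _EGRID_STEP
    if x <= 0.0:
        return table[0]
    i = int(x)
    if i >= table.size - 1:
        return table[-1]
    f = x - i
    return table[i] * (1.0 - f) + table[i + 1] * f


@njit(cache=True, inline="always")
def _rotate(ux, uy, uz, cost, phi):
    """Rotate unit vector u by polar angle acos(cost) and azimuth phi."""
    sint = math.sqrt(max(0.0, 1.0 - cost * cost))
    cphi = math.cos(phi)
    sphi = math.sin(phi)
    if abs(uz) > 0.99999:
        sign = 1.0 if uz > 0.0 else -1.0
        return sint * cphi, sint * sphi * sign, cost * sign
    # orthonormal basis (a, b, u)
    norm = math.sqrt(ux * ux + uy * uy)
    ax, ay, az = uy / norm, -ux / norm, 0.0
    bx = uy * az - uz * ay
    by = uz * ax - ux * az
    bz = ux * ay - uy * ax
    nx = sint * (cphi * ax + sphi * bx) + cost * ux
    ny = sint * (cphi * ay + sphi * by) + cost * uy
    nz = sint * (cphi * az + sphi * bz) + cost * uz
    n = math.sqrt(nx * nx + ny * ny + nz * nz)
    return nx / n, ny / n, nz / n


@njit(cache=True, inline="always")
def _voxel_index(x, y, z, x0, y0, z0, dv, nx, ny, nz):
    i = int(math.floor((x - x0) / dv))
    j = int(math.floor((y - y0) / dv))
    k = int(math.floor((z - z0) / dv))
    if i < 0 or i >= nx or j < 0 or j >= ny or k < 0 or k >= nz:
        return -1
    return (i * ny + j) * nz + k


@njit(cache=True)
def _deposit_electron(e0, x, y, z, ux, uy, uz, rho, edep,
                      x0, y0, z0, dv, nx, ny, nz):
    """CSDA electron: straight sub-steps with Highland angular diffusion."""
    e = e0
    while e > ELECTRON_CUTOFF_MEV:
        idx = _voxel_index(x, y, z, x0, y0, z0, dv, nx, ny, nz)
        if idx < 0:
            return  # electron left the phantom; its remaining energy escapes
        rho_l = rho[idx]
        if rho_l <= 1e-6:
            rho_l = 1e-6
        sp = _grid_lookup(_SP_GRID, e)
        ds = _E_STEP_GCM2
        de = sp * ds
        if de > e - ELECTRON_CUTOFF_MEV:
            de = e - ELECTRON_CUTOFF_MEV
            ds = de / sp
        step_mm = ds / rho_l * 10.0
        mx = x + 0.5 * step_mm * ux
        my = y + 0.5 * step_mm * uy
        mz = z + 0.5 * step_mm * uz
        midx = _voxel_index(mx, my, mz, x0, y0, z0, dv, nx, ny, nz)
        if midx >= 0:
            edep[midx] += de
        x += step_mm * ux
        y += step_mm * uy
        z += step_mm * uz
        e -= de
        # Highland multiple-scattering angle for this sub-step
        etot = e + ELECTRON_REST_MEV
        pc2 = etot * etot - ELECTRON_REST_MEV * ELECTRON_REST_MEV
        if pc2 <= 0.0:
            break
        beta_pc = pc2 / etot
        xr = ds / _X0_WATER
        corr = 1.0 + 0.038 * math.log(xr)
        if corr < 0.25:
            corr = 0.25
        theta0 = 13.6 / beta_pc * math.sqrt(xr) * corr  # Highland, beta*pc in MeV
        theta = abs(np.random.normal(0.0, theta0))
        if theta > 1.5:
            theta = 1.5
        phi = 2.0 * math.pi * np.random.random()
        ux, uy, uz = _rotate(ux, uy, uz, math.cos(theta), phi)
    # residual range below cutoff is shorter than a voxel: deposit locally
    idx = _voxel_index(x, y, z, x0, y0, z0, dv, nx, ny, nz)
    if idx >= 0:
        edep[idx] += e


@njit(cache=True, inline="always")
def _sample_compton(e):
    """Kahn-style rejection sampling of the Klein-Nishina energy fraction.

    Returns (eps, cost): scattered-to-incident energy ratio and the photon
    scattering angle cosine.
    """
    k = e / ELECTRON_REST_MEV
    eps0 = 1.0 / (1.0 + 2.0 * k)
    alpha1 = math.log(1.0 / eps0)
    alpha2 = 0.5 * (1.0 - eps0 * eps0)
    while True:
        if np.random.random() * (alpha1 + alpha2) < alpha1:
            eps = eps0 * math.exp(alpha1 * np.random.random())
        else:
            eps = math.sqrt(eps0 * eps0 + (1.0 - eps0 * eps0) * np.random.random())
        t = (1.0 - eps) / (k * eps)
        sin2 = t * (2.0 - t)
        g = 1.0 - eps * sin2 / (1.0 + eps * eps)
        if np.random.random() < g:
            return eps, 1.0 - t


@njit(cache=True)
def _transport_batch(pos, direction, energy, rho, edep,
                     x0, y0, z0, dv, nx, ny, nz, rho_max, seed):
    """Transport one batch of photons; returns (energy_in, energy_deposited)."""
    np.random.seed(seed)
    n = energy.size
    e_in = 0.0
    e_dep0 = edep.sum()
    xmax = x0 + nx * dv
    ymax = y0 + ny * dv
    zmax = z0 + nz * dv
    # photon stack (annihilation quanta)
    cap = 16
    st_e = np.empty(cap)
    st_p = np.empty((cap, 3))
    st_d = np.empty((cap, 3))
    for ip in range(n):
        sp = 0
        st_e[0] = energy[ip]
        st_p[0, 0] = pos[ip, 0]
        st_p[0, 1] = pos[ip, 1]
        st_p[0, 2] = pos[ip, 2]
        st_d[0, 0] = direction[ip, 0]
        st_d[0, 1] = direction[ip, 1]
        st_d[0, 2] = direction[ip, 2]
        sp = 1
        entered_any = False
        while sp > 0:
            sp -= 1
            e = st_e[sp]
            x = st_p[sp, 0]
            y = st_p[sp, 1]
            z = st_p[sp, 2]
            ux = st_d[sp, 0]
            uy = st_d[sp, 1]
            uz = st_d[sp, 2]
            # advance to the phantom bounding box if outside
            inside = (x0 <= x < xmax) and (y0 <= y < ymax) and (z0 <= z < zmax)
            if not inside:
                t_en = -1.0e30
                t_ex = 1.0e30
                ok = True
                for ax in range(3):
                    if ax == 0:
                        u, c, lo, hi = ux, x, x0, xmax
                    elif ax == 1:
                        u, c, lo, hi = uy, y, y0, ymax
                    else:
                        u, c, lo, hi = uz, z, z0, zmax
                    if abs(u) < 1e-12:
                        if c < lo or c >= hi:
                            ok = False
                            break
                    else:
                        t1 = (lo - c) / u
                        t2 = (hi - c) / u
                        if t1 > t2:
                            t1, t2 = t2, t1
                        if t1 > t_en:
                            t_en = t1
                        if t2 < t_ex:
                            t_ex = t2
                if (not ok) or t_en > t_ex or t_ex < 0.0:
                    continue  # misses the phantom
                t = t_en + 1e-6
                if t < 0.0:
                    t = 0.0
                x += t * ux
                y += t * uy
                z += t * uz
                if not ((x0 <= x < xmax) and (y0 <= y < ymax) and (z0 <= z < zmax)):
                    continue
            if not entered_any:
                # only the primary photon adds to the energy entering the
                # phantom; annihilation quanta redistribute it internally
                e_in += e
                entered_any = True
            # Woodcock tracking
            alive = True
            while alive:
                if e < PHOTON_CUTOFF_MEV:
                    idx = _voxel_index(x, y, z, x0, y0, z0, dv, nx, ny, nz)
                    if idx >= 0:
                        edep[idx] += e
                    alive = False
                    break
                mu_maj = _grid_lookup(_MU_TOTAL, e) * rho_max * 0.1  # per mm
                # sample the next tentative interaction point
                while True:
                    s = -math.log(np.random.random() + 1e-300) / mu_maj
                    x += s * ux
                    y += s * uy
                    z += s * uz
                    idx = _voxel_index(x, y, z, x0, y0, z0, dv, nx, ny, nz)
                    if idx < 0:
                        alive = False
                        break
                    if np.random.random() < rho[idx] / rho_max:
                        break  # real interaction
                if not alive:
                    break
                p_photo = _grid_lookup(_P_PHOTO, e)
                p_pair = _grid_lookup(_P_PAIR, e)
                xi = np.random.random()
                if xi < p_photo:
                    _deposit_electron(e, x, y, z, ux, uy, uz, rho, edep,
                                      x0, y0, z0, dv, nx, ny, nz)
                    alive = False
                elif xi < p_photo + p_pair:
                    ek = e - 2.0 * ELECTRON_REST_MEV
                    f = np.random.random()
                    _deposit_electron(ek * f, x, y, z, ux, uy, uz, rho, edep,
                                      x0, y0, z0, dv, nx, ny, nz)
                    _deposit_electron(ek * (1.0 - f), x, y, z, ux, uy, uz, rho, edep,
                                      x0, y0, z0, dv, nx, ny, nz)
                    # two annihilation photons, isotropic and opposed
                    cost = 2.0 * np.random.random() - 1.0
                    phi = 2.0 * math.pi * np.random.random()
                    sint = math.sqrt(max(0.0, 1.0 - cost * cost))
                    ax_ = sint * math.cos(phi)
                    ay_ = sint * math.sin(phi)
                    az_ = cost
                    for sgn in (-1.0, 1.0):
                        if sp < cap:
                            st_e[sp] = ELECTRON_REST_MEV
                            st_p[sp, 0] = x
                            st_p[sp, 1] = y
                            st_p[sp, 2] = z
                            st_d[sp, 0] = sgn * ax_
                            st_d[sp, 1] = sgn * ay_
                            st_d[sp, 2] = sgn * az_
                            sp += 1
                        else:
                            edep[idx] += ELECTRON_REST_MEV
                    alive = False
                else:
                    eps, cost = _sample_compton(e)
                    e_sc = e * eps
                    phi = 2.0 * math.pi * np.random.random()
                    nux, nuy, nuz = _rotate(ux, uy, uz, cost, phi)
                    # electron from momentum conservation
                    pex = e * ux - e_sc * nux
                    pey = e * uy - e_sc * nuy
                    pez = e * uz - e_sc * nuz
                    pn = math.sqrt(pex * pex + pey * pey + pez * pez)
                    if pn > 1e-12:
                        _deposit_electron(e - e_sc, x, y, z,
                                          pex / pn, pey / pn, pez / pn,
                                          rho, edep, x0, y0, z0, dv, nx, ny, nz)
                    e = e_sc
                    ux, uy, uz = nux, nuy, nuz
    return e_in, edep.sum() - e_dep0


@njit(cache=True)
def _first_interaction_kernel(e_mev, n, rho, x0, y0, z0, dv, nx, ny, nz,
                              rho_max, seed, depths):
    """Depth (mm from z0) of the first real interaction of a +z pencil beam."""
    np.random.seed(seed)
    zmax = z0 + nz * dv
    for ip in range(n):
        z = z0 + 1e-6
        depth = -1.0
        mu_maj = _grid_lookup(_MU_TOTAL, e_mev) * rho_max * 0.1
        while True:
            z += -math.log(np.random.random() + 1e-300) / mu_maj
            if z >= zmax:
                break
            idx = _voxel_index(x0 + 0.5 * dv, y0 + 0.5 * dv, z, x0, y0, z0, dv, nx, ny, nz)
            if idx < 0:
                break
            if np.random.random() < rho[idx] / rho_max:
                depth = z - z0
                break
        depths[ip] = depth


@njit(cache=True)
def _median_filter_kernel(src, out, nx, ny, nz, radius, i0, i1, j0, j1, k0, k1):
    buf = np.empty((2 * radius + 1) ** 3)
    for i in range(i0, i1):
        ilo = i - radius if i - radius > 0 else 0
        ihi = i + radius + 1 if i + radius + 1 < nx else nx
        for j in range(j0, j1):
            jlo = j - radius if j - radius > 0 else 0
            jhi = j + radius + 1 if j + radius + 1 < ny else ny
            for k in range(k0, k1):
                klo = k - radius if k - radius > 0 else 0
                khi = k + radius + 1 if k + radius + 1 < nz else nz
                m = 0
                for ii in range(ilo, ihi):
                    for jj in range(jlo, jhi):
                        for kk in range(klo, khi):
                            buf[m] = src[ii, jj, kk]
                            m += 1
                out[i, j, k] = np.median(buf[:m])


# ---------------------------------------------------------------------------
# Phantom / dose containers

@dataclass
class Phantom:
    """Voxelized density grid in the room frame (isocenter at the origin)."""

    density: np.ndarray  # (nx, ny, nz), g/cm^3
    voxel_size_mm: float = 2.0
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)  # low corner

    def __post_init__(self) -> None:
        self.density = np.ascontiguousarray(self.density, dtype=np.float64)
        if self.density.ndim != 3:
            raise ValueError("density grid must be 3-D")
        if np.any(self.density < 0):
            raise ValueError("densities must be >= 0")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel size must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.density.shape

    def voxel_centers(self, axis: int) -> np.ndarray:
        n = self.density.shape[axis]
        return self.origin_mm[axis] + self.voxel_size_mm * (np.arange(n) + 0.5)

    def voxel_of_point(self, point_mm) -> tuple[int, int, int]:
        idx = tuple(
            int((point_mm[a] - self.origin_mm[a]) / self.voxel_size_mm) for a in range(3)
        )
        if any(i < 0 or i >= self.density.shape[a] for a, i in enumerate(idx)):
            raise ValueError(f"point {point_mm} lies outside the phantom")
        return idx


def water_cube_phantom(
    side_mm: float = 300.0, voxel_mm: float = 2.0, iso_depth_mm: float = 100.0
) -> Phantom:
    """Homogeneous water cube; beam (gantry 0) enters the z-low face.

    The isocenter sits on the beam axis at ``iso_depth_mm`` below the entry
    surface, i.e. the phantom spans z in [-iso_depth, side - iso_depth].
    """
    n = int(round(side_mm / voxel_mm))
    density = np.ones((n, n, n))
    origin = (-side_mm / 2, -side_mm / 2, -iso_depth_mm)
    return Phantom(density=density, voxel_size_mm=voxel_mm, origin_mm=origin)


@dataclass
class DoseGrid:
    """Voxel dose with per-voxel relative statistical uncertainty."""

    values: np.ndarray  # dose (unit per `unit` tag)
    uncertainty: np.ndarray | None  # relative sigma where dose > 0
    voxel_size_mm: float
    origin_mm: tuple[float, float, float]
    histories: int = 0
    unit: str = "MeV/g per run"

    def point_dose(self, point_mm, neighborhood: int = 1) -> float:
        """Dose at a point, averaged over a cubic voxel neighborhood.

        ``neighborhood`` is the half-width in voxels (1 -> 3x3x3 average, the
        protocol's noise-reduction readout; 0 -> single voxel).
        """
        i, j, k = self._index_of(point_mm)
        r = neighborhood
        sl = tuple(
            slice(max(0, c - r), min(nmax, c + r + 1))
            for c, nmax in zip((i, j, k), self.values.shape)
        )
        return float(self.values[sl].mean())

    def _index_of(self, point_mm) -> tuple[int, int, int]:
        idx = tuple(
            int((point_mm[a] - self.origin_mm[a]) / self.voxel_size_mm) for a in range(3)
        )
        if any(i < 0 or i >= self.values.shape[a] for a, i in enumerate(idx)):
            raise ValueError(f"point {point_mm} lies outside the dose grid")
        return idx

    def scaled(self, factor: float, unit: str) -> "DoseGrid":
        return DoseGrid(
            values=self.values * factor,
            uncertainty=None if self.uncertainty is None else self.uncertainty.copy(),
            voxel_size_mm=self.voxel_size_mm,
            origin_mm=self.origin_mm,
            histories=self.histories,
            unit=unit,
        )


# ---------------------------------------------------------------------------
# HU conversion (stoichiometric-style calibration)

@dataclass(frozen=True)
class HUCalibration:
    """HU -> relative electron density -> physical density -> material index.

    ``hu_to_red``: monotone knots mapping Hounsfield number to relative
    electron density (piecewise linear).  Physical density follows the
    empirical linear formula ``rho = red_to_density_slope * RED +
    red_to_density_offset``.  Material index is assigned from density
    ranges: air < lung < soft tissue < bone.
    """

    hu_to_red: np.ndarray = field(
        default_factory=lambda: np.array(
            [[-1000.0, 0.001], [-700.0, 0.29], [0.0, 1.0], [1000.0, 1.565], [3000.0, 2.5]]
        )
    )
    red_to_density_slope: float = 1.0
    red_to_density_offset: float = 0.0
    material_edges: np.ndarray = field(
        default_factory=lambda: np.array([0.05, 0.7, 1.1])  # air|lung|soft|bone
    )

    def __post_init__(self) -> None:
        t = np.asarray(self.hu_to_red, dtype=float)
        if np.any(np.diff(t[:, 0]) <= 0) or np.any(np.diff(t[:, 1]) < 0):
            raise ValueError("HU calibration table must be monotone")
        object.__setattr__(self, "hu_to_red", t)


def hu_to_density(hu, calibration: HUCalibration | None = None):
    """Convert Hounsfield numbers to (physical density g/cm^3, material index).

    HU below the table minimum clamps to the first knot (air).  Material
    indices: 0 air, 1 lung, 2 soft tissue, 3 bone-like.
    """
    cal = calibration or HUCalibration()
    t = cal.hu_to_red
    red = np.interp(np.asarray(hu, dtype=float), t[:, 0], t[:, 1])
    rho = cal.red_to_density_slope * red + cal.red_to_density_offset
    material = np.digitize(rho, cal.material_edges)
    if np.isscalar(hu):
        return float(rho), int(material)
    return rho, material


# ---------------------------------------------------------------------------
# Simulation driver

def simulate_dose(
    particles,
    phantom: Phantom,
    max_histories: int | None = None,
    target_uncertainty: float | None = None,
    batches: int = 10,
    seed: int = 0,
):
    """Run the photon engine and return ``(DoseGrid, histories_used)``.

    ``particles`` is either a callable ``f(n, rng) -> (pos, dir, energy)``
    producing room-frame photon batches, or a tuple of fixed arrays
    ``(pos, dir, energy)`` (then ``max_histories`` defaults to their length).
    The scored dose is the *accumulated* energy per unit mass over all
    histories (per-history units: divide by H or feed to
    :func:`scale_dose`).  Uncertainty is estimated from batch statistics
    over voxels above 50% of the running maximum dose; the run stops when
    the mean relative uncertainty there reaches ``target_uncertainty`` or at
    ``max_histories``.
    """
    if target_uncertainty is not None and target_uncertainty <= 0:
        raise ValueError("target uncertainty must be positive")
    fixed = None
    if not callable(particles):
        pos, direction, energy = particles
        if energy.size == 0:
            raise ValueError("empty particle stream")
        fixed = (np.ascontiguousarray(pos, dtype=np.float64),
                 np.ascontiguousarray(direction, dtype=np.float64),
                 np.ascontiguousarray(energy, dtype=np.float64))
        if max_histories is None:
            max_histories = energy.size
    if max_histories is None and target_uncertainty is None:
        raise ValueError("either max_histories or target_uncertainty is required")
    if max_histories is None:
        max_histories = 1_000_000_000
    if max_histories <= 0:
        raise ValueError("max_histories must be positive")

    rho = phantom.density
    nx, ny, nz = rho.shape
    rho_flat = rho.ravel()
    rho_max = float(rho_flat.max())
    if rho_max <= 0:
        raise ValueError("phantom contains no material")
    x0, y0, z0 = phantom.origin_mm
    dv = phantom.voxel_size_mm

    voxel_mass_g = rho_flat * (dv / 10.0) ** 3  # g per voxel
    safe_mass = np.where(voxel_mass_g > 0, voxel_mass_g, 1.0)

    rng = np.random.default_rng(seed)
    batch_size = max(1, int(math.ceil(min(max_histories, 10_000_000) / batches)))
    dose_sum = np.zeros(rho_flat.size)
    dose_sq = np.zeros(rho_flat.size)
    n_batches = 0
    used = 0
    while used < max_histories:
        n = min(batch_size, max_histories - used)
        if fixed is not None:
            pos, direction, energy = (a[used : used + n] for a in fixed)
            pos = np.ascontiguousarray(pos)
            direction = np.ascontiguousarray(direction)
            energy = np.ascontiguousarray(energy)
        else:
            pos, direction, energy = particles(n, rng)
        edep = np.zeros(rho_flat.size)
        kseed = int(rng.integers(0, 2**31 - 1))
        _transport_batch(pos, direction, energy, rho_flat, edep,
                         x0, y0, z0, dv, nx, ny, nz, rho_max, kseed)
        batch_dose = edep / safe_mass
        dose_sum += batch_dose
        dose_sq += batch_dose**2
        n_batches += 1
        used += n
        if target_uncertainty is not None and n_batches >= 3:
            if _mean_rel_uncertainty(dose_sum, dose_sq, n_batches) <= target_uncertainty:
                break

    unc = _rel_uncertainty_grid(dose_sum, dose_sq, n_batches)
    grid = DoseGrid(
        values=dose_sum.reshape(rho.shape),
        uncertainty=unc.reshape(rho.shape),
        voxel_size_mm=dv,
        origin_mm=phantom.origin_mm,
        histories=used,
        unit="MeV/g per run",
    )
    return grid, used


def _rel_uncertainty_grid(dose_sum, dose_sq, n_batches):
    """Relative sigma of the mean from per-batch first/second moments."""
    if n_batches < 2:
        return np.full_like(dose_sum, np.nan)
    mean = dose_sum / n_batches
    var = np.maximum(dose_sq / n_batches - mean**2, 0.0) / max(n_batches - 1, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(mean > 0, np.sqrt(var) / np.where(mean > 0, mean, 1.0), np.nan)
    return rel


def _mean_rel_uncertainty(dose_sum, dose_sq, n_batches) -> float:
    """Mean relative uncertainty over voxels above 50% of the max dose."""
    rel = _rel_uncertainty_grid(dose_sum, dose_sq, n_batches)
    hot = dose_sum >= 0.5 * dose_sum.max()
    vals = rel[hot]
    vals = vals[np.isfinite(vals)]
    return float(vals.mean()) if vals.size else math.inf


def scale_dose(
    dose: DoseGrid, integral_fluence: float, histories: int, cgy_per_unit: float = 1.0
) -> DoseGrid:
    """Convert an accumulated-dose grid to absolute dose (cGy).

    Divides by the number of transported histories (dose per particle) and
    multiplies by the integral fluence (the calibrated particle count for
    the delivered monitor units); ``cgy_per_unit`` is the commissioning
    constant of the beam model.
    """
    if histories <= 0:
        raise ValueError("history count must be positive")
    factor = integral_fluence / histories * cgy_per_unit
    return dose.scaled(factor, unit="cGy")


def median_filter(values: np.ndarray, radius: int, region: tuple | None = None) -> np.ndarray:
    """Median-window filter over the cubic neighborhood of ``radius`` voxels.

    Neighborhoods are clipped at the grid boundary; radius 0 is the
    identity.  ``region`` (optional) is a tuple of three ``(lo, hi)`` index
    ranges: only voxels inside it are filtered (their neighborhoods still
    use the full grid), the rest are copied -- the filtered values inside
    the region are identical to a full-grid filter.
    """
    if radius < 0 or int(radius) != radius:
        raise ValueError("radius must be a non-negative integer")
    src = np.ascontiguousarray(values, dtype=np.float64)
    if src.ndim != 3:
        raise ValueError("median_filter expects a 3-D grid")
    if radius == 0:
        return src.copy()
    out = src.copy()
    nx, ny, nz = src.shape
    if region is None:
        bounds = (0, nx, 0, ny, 0, nz)
    else:
        (i0, i1), (j0, j1), (k0, k1) = region
        bounds = (max(0, i0), min(nx, i1), max(0, j0), min(ny, j1), max(0, k0), min(nz, k1))
    _median_filter_kernel(src, out, nx, ny, nz, int(radius), *bounds)
    return out


def filter_dose(dose: DoseGrid, radius: int, region=None) -> DoseGrid:
    """Median-filtered copy of a :class:`DoseGrid`."""
    return DoseGrid(
        values=median_filter(dose.values, radius, region=region),
        uncertainty=dose.uncertainty,
        voxel_size_mm=dose.voxel_size_mm,
        origin_mm=dose.origin_mm,
        histories=dose.histories,
        unit=dose.unit,
    )


def first_interaction_depths(
    energy_mev: float, n: int, phantom: Phantom, seed: int = 0
) -> np.ndarray:
    """Diagnostic: first-interaction depths of a +z pencil beam (mm).

    Uses the engine's own attenuation tables and Woodcock tracking; the
    distribution in a homogeneous phantom is exponential with the packaged
    mu(E).  Entries of -1 mark photons that crossed without interacting.
    """
    depths = np.empty(n)
    rho_flat = phantom.density.ravel()
    x0, y0, z0 = phantom.origin_mm
    nx, ny, nz = phantom.density.shape
    _first_interaction_kernel(
        energy_mev, n, rho_flat, x0, y0, z0, phantom.voxel_size_mm,
        nx, ny, nz, float(rho_flat.max()), seed, depths
    )
    return depths
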